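"""Sequence diversity, neutrality tests and sudden-expansion demography.

Operates on two-clade haplotype alignments (mitochondrial-style,
non-recombining). Implements the classic summary chain: haplotype
collapsing, haplotype/nucleotide diversity, Tajima's D and Fu's Fs with
coalescent-simulation p-values, mismatch (pairwise difference)
distributions, least-squares fitting of the sudden-expansion model
(tau, theta0, theta1) with parametric-bootstrap goodness of fit, and
between-clade fixed differences / Dxy divergence.

Sites containing gaps or N are excluded alignment-wide (complete
deletion) before any statistic, matching the common default of
population-genetic packages; per-pair deletion is available by flag on
the pairwise operations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammainc, gammaln

from ._coalescent import mutation_sets

__all__ = [
    "HaplotypeAlignment",
    "DiversityStats",
    "MismatchFit",
    "collapse_haplotypes",
    "diversity_stats",
    "tajimas_d",
    "fus_fs",
    "mismatch_distribution",
    "mismatch_pmf",
    "fit_sudden_expansion",
    "fixed_differences",
    "tajima_constants",
    "summarize_groups",
]

_VALID = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class HaplotypeAlignment:
    """Equal-length aligned sequences with specimen ids and clade labels."""

    seqs: np.ndarray  # (n, sites) dtype S1, uppercase
    ids: list[str]
    clades: list[str]

    def __post_init__(self) -> None:
        self.seqs = np.asarray(self.seqs, dtype="S1")
        if self.seqs.ndim != 2:
            raise ValueError("seqs must be a (n, sites) character matrix")
        n = self.seqs.shape[0]
        if len(self.ids) != n or len(self.clades) != n:
            raise ValueError("ids/clades length must match the number of sequences")

    @property
    def n(self) -> int:
        return self.seqs.shape[0]

    @property
    def sites(self) -> int:
        return self.seqs.shape[1]

    def subset(self, which) -> "HaplotypeAlignment":
        idx = np.asarray(which)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return HaplotypeAlignment(
            self.seqs[idx],
            [self.ids[i] for i in idx],
            [self.clades[i] for i in idx],
        )

    def clade(self, label: str) -> "HaplotypeAlignment":
        return self.subset([c == label for c in self.clades])

    def complete_deletion(self) -> "HaplotypeAlignment":
        """Drop every column containing a character outside {A,C,G,T}."""
        ok = np.isin(self.seqs, _VALID).all(axis=0)
        return HaplotypeAlignment(self.seqs[:, ok], self.ids, self.clades)

    @classmethod
    def from_strings(cls, seqs, ids=None, clades=None) -> "HaplotypeAlignment":
        mat = np.array([list(s.upper()) for s in seqs], dtype="S1")
        n = mat.shape[0]
        ids = ids if ids is not None else [f"s{i:03d}" for i in range(n)]
        clades = clades if clades is not None else ["all"] * n
        return cls(mat, list(ids), list(clades))

    @classmethod
    def from_fasta(cls, path: str | Path, clade_delimiter: str = "_") -> "HaplotypeAlignment":
        """Read a FASTA alignment; the clade is the header prefix before
        the first ``clade_delimiter`` (e.g. ``>c1_s001`` -> clade ``c1``)."""
        from Bio import SeqIO

        ids, clades, seqs = [], [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            ids.append(rec.id)
            clades.append(rec.id.split(clade_delimiter)[0])
            seqs.append(str(rec.seq))
        if not seqs:
            raise ValueError(f"no sequences in {path}")
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            raise ValueError("sequences are not aligned (unequal lengths)")
        return cls.from_strings(seqs, ids, clades)

    def to_fasta(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            for i in range(self.n):
                fh.write(f">{self.ids[i]}\n{self.seqs[i].tobytes().decode()}\n")
        return path


@dataclass
class DiversityStats:
    """Per-group sequence summary (one row of a diversity table)."""

    n_samples: int
    n_haplotypes: int
    n_polymorphic: int
    haplotype_diversity: float
    pi: float  # per-site nucleotide diversity
    pi_sd: float
    tajimas_d: float | None = None
    tajimas_d_p: float | None = None
    fus_fs: float | None = None
    fus_fs_p: float | None = None


@dataclass
class MismatchFit:
    """Sudden-expansion model fit to a mismatch histogram."""

    histogram: np.ndarray
    tau: float
    theta0: float
    theta1: float
    ssd: float
    p_value: float | None = None
    tau_ci: tuple[float, float] | None = None
    theta0_ci: tuple[float, float] | None = None
    theta1_ci: tuple[float, float] | None = None
    n_bootstrap: int = 0
    theta1_cap: float = 10_000.0


# ---------------------------------------------------------------------------
# pairwise machinery


def _pairwise_diffs(seqs: np.ndarray, pairwise_deletion: bool = False) -> np.ndarray:
    """Condensed vector of pairwise difference counts (length n(n-1)/2)."""
    n = seqs.shape[0]
    out = np.empty(n * (n - 1) // 2, dtype=int)
    k = 0
    valid = np.isin(seqs, _VALID)
    for i in range(n - 1):
        neq = seqs[i + 1 :] != seqs[i]
        if pairwise_deletion:
            neq &= valid[i + 1 :] & valid[i]
        out[k : k + n - 1 - i] = neq.sum(axis=1)
        k += n - 1 - i
    return out


def _between_diffs(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """All between-group pairwise difference counts (len(a)*len(b),)."""
    return np.array([(b != row).sum(axis=1) for row in a]).ravel()


# ---------------------------------------------------------------------------
# diversity


def collapse_haplotypes(aln: HaplotypeAlignment) -> dict[bytes, int]:
    """Distinct sequences and their counts, after complete deletion.

    Sequences differing only at excluded (gap/N) sites are identical.
    """
    clean = aln.complete_deletion()
    counts: dict[bytes, int] = {}
    for i in range(clean.n):
        key = clean.seqs[i].tobytes()
        counts[key] = counts.get(key, 0) + 1
    return counts


def _segregating_sites(seqs: np.ndarray) -> int:
    return int((seqs != seqs[0]).any(axis=0).sum())


def diversity_stats(aln: HaplotypeAlignment) -> DiversityStats:
    """Haplotype diversity H, per-site nucleotide diversity pi, and S.

    H = n/(n-1) · (1 - sum p_h^2); pi is the mean pairwise difference per
    retained site, with the standard no-recombination sampling standard
    deviation sqrt(b1·k + b2·k^2)/L (b1, b2 the Tajima variance
    coefficients).
    """
    clean = aln.complete_deletion()
    n, sites = clean.n, clean.sites
    if n < 2:
        raise ValueError("need at least 2 sequences")
    if sites == 0:
        raise ValueError("no sites survive complete deletion")
    counts = np.array(list(collapse_haplotypes(clean).values()))
    freqs = counts / n
    h = n / (n - 1) * (1.0 - float(np.sum(freqs**2)))
    diffs = _pairwise_diffs(clean.seqs)
    kbar = float(diffs.mean())
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    pi_sd = float(np.sqrt(b1 * kbar + b2 * kbar * kbar) / sites)
    return DiversityStats(
        n_samples=n,
        n_haplotypes=len(counts),
        n_polymorphic=_segregating_sites(clean.seqs),
        haplotype_diversity=h,
        pi=kbar / sites,
        pi_sd=pi_sd,
    )


# ---------------------------------------------------------------------------
# neutrality tests


def tajima_constants(n: int) -> dict[str, float]:
    """The a1..e2 constant chain of Tajima's D for sample size n."""
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return dict(a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2)


def _neutral_replicates(n: int, theta: float, reps: int, rng) -> list[tuple[int, float, int]]:
    """(S, mean pairwise diffs, n_haplotypes) under the equilibrium coalescent."""
    out = []
    for _ in range(reps):
        muts = mutation_sets(n, theta, rng=rng)
        s = len(set().union(*muts)) if muts else 0
        tot = 0
        for i in range(n - 1):
            for j in range(i + 1, n):
                tot += len(muts[i] ^ muts[j])
        kbar = tot / (n * (n - 1) / 2)
        nh = len({frozenset(m) for m in muts})
        out.append((s, kbar, nh))
    return out


def tajimas_d(
    aln: HaplotypeAlignment, p_reps: int = 1000, seed: int | None = None
) -> tuple[float | None, float | None]:
    """Tajima's D with a coalescent-simulation p-value.

    D contrasts the pairwise (pi) and segregating-sites (S/a1) estimators
    of theta; negative values indicate an excess of rare variants
    (expansion or selection). The p-value is the one-sided probability
    P(D_sim <= D_obs) under the neutral equilibrium coalescent simulated
    at theta = S/a1; S = 0 makes D undefined and returns (None, None).
    """
    clean = aln.complete_deletion()
    n = clean.n
    s = _segregating_sites(clean.seqs)
    if s == 0:
        return None, None
    c = tajima_constants(n)
    kbar = float(_pairwise_diffs(clean.seqs).mean())
    d = (kbar - s / c["a1"]) / np.sqrt(c["e1"] * s + c["e2"] * s * (s - 1))
    p = None
    if p_reps > 0:
        rng = np.random.default_rng(seed)
        theta_w = s / c["a1"]
        below = total = 0
        for s_sim, k_sim, _ in _neutral_replicates(n, theta_w, p_reps, rng):
            if s_sim == 0:
                continue
            d_sim = (k_sim - s_sim / c["a1"]) / np.sqrt(
                c["e1"] * s_sim + c["e2"] * s_sim * (s_sim - 1)
            )
            total += 1
            below += d_sim <= d
        p = below / total if total else None
    return float(d), p


def _log_stirling_first(n: int) -> np.ndarray:
    """log |s(n, k)| for k = 0..n (unsigned Stirling numbers, first kind)."""
    prev = np.full(n + 1, -np.inf)
    prev[0] = 0.0  # |s(0,0)| = 1
    for m in range(1, n + 1):
        cur = np.full(n + 1, -np.inf)
        log_m1 = np.log(m - 1) if m > 1 else -np.inf
        cur[1 : m + 1] = np.logaddexp(prev[0:m], log_m1 + prev[1 : m + 1])
        prev = cur
    return prev


def ewens_k_pmf(n: int, theta: float) -> np.ndarray:
    """P(K = k | theta, n) for k = 0..n under the Ewens sampling formula."""
    if theta <= 0:
        raise ValueError("theta must be positive")
    log_s = _log_stirling_first(n)
    k = np.arange(n + 1)
    log_rising = np.sum(np.log(theta + np.arange(n)))
    logp = log_s + k * np.log(theta) - log_rising
    p = np.exp(logp)
    p[0] = 0.0
    return p / p.sum()


def fus_fs(
    aln: HaplotypeAlignment, p_reps: int = 1000, seed: int | None = None
) -> tuple[float, float | None]:
    """Fu's Fs with a coalescent-simulation p-value.

    S' = P(K >= observed haplotype number | theta = mean pairwise diffs)
    under the Ewens sampling distribution; Fs = ln(S'/(1-S')). Strongly
    negative Fs flags a haplotype excess typical of demographic
    expansion. p = P(Fs_sim <= Fs_obs) under the neutral coalescent at
    theta = mean pairwise differences.
    """
    clean = aln.complete_deletion()
    n = clean.n
    kbar = float(_pairwise_diffs(clean.seqs).mean())
    if kbar <= 0:
        raise ValueError("Fu's Fs undefined: no pairwise differences")
    nh = len(collapse_haplotypes(clean))

    def _fs(n_, kbar_, nh_) -> float:
        pmf = ewens_k_pmf(n_, kbar_)
        s_prime = float(pmf[nh_:].sum())
        s_prime = min(max(s_prime, 1e-300), 1 - 1e-16)
        return float(np.log(s_prime / (1.0 - s_prime)))

    fs = _fs(n, kbar, nh)
    p = None
    if p_reps > 0:
        rng = np.random.default_rng(seed)
        sims = _neutral_replicates(n, kbar, p_reps, rng)
        vals = [_fs(n, k, h) for _, k, h in sims if k > 0]
        p = float(np.mean([v <= fs for v in vals])) if vals else None
    return fs, p


# ---------------------------------------------------------------------------
# mismatch distribution and sudden-expansion fit


def mismatch_distribution(
    aln: HaplotypeAlignment, pairwise_deletion: bool = False
) -> np.ndarray:
    """Histogram of pairwise difference counts, classes 0..max observed."""
    clean = aln if pairwise_deletion else aln.complete_deletion()
    if clean.n < 2:
        raise ValueError("need at least 2 sequences")
    diffs = _pairwise_diffs(clean.seqs, pairwise_deletion=pairwise_deletion)
    return np.bincount(diffs)


def _equilibrium_pmf(kmax: int, theta: float) -> np.ndarray:
    """F_i(theta) = theta^i / (1+theta)^(i+1), the geometric equilibrium
    mismatch law; theta = 0 degenerates to a point mass at 0."""
    i = np.arange(kmax + 1)
    if theta <= 0:
        out = np.zeros(kmax + 1)
        out[0] = 1.0
        return out
    return np.exp(i * np.log(theta) - (i + 1) * np.log1p(theta))


def mismatch_pmf(kmax: int, tau: float, theta0: float, theta1: float) -> np.ndarray:
    """Sudden-expansion mismatch probabilities for classes 0..kmax.

    A population at theta0 grows instantaneously to theta1 at mutational
    time tau before the present. Conditioning on whether a random pair
    coalesces before or after the expansion gives

        F_i = F_i(theta1) * P(i+1, tau(1 + 1/theta1))
            + exp(-tau(1 + 1/theta1)) * sum_{j<=i} tau^(i-j)/(i-j)! F_j(theta0)

    with P the regularized lower incomplete gamma and F_i(theta) the
    equilibrium geometric law. tau = 0 reduces to equilibrium at theta0,
    tau -> inf to equilibrium at theta1.
    """
    if tau < 0 or theta0 < 0 or theta1 <= 0:
        raise ValueError("require tau >= 0, theta0 >= 0, theta1 > 0")
    i = np.arange(kmax + 1)
    rate = 1.0 + 1.0 / theta1
    recent = _equilibrium_pmf(kmax, theta1) * gammainc(i + 1, tau * rate)
    if tau == 0:
        kernel = np.zeros(kmax + 1)
        kernel[0] = 1.0
    else:
        kernel = np.exp(i * np.log(tau) - gammaln(i + 1))
    old = np.exp(-tau * rate) * np.convolve(_equilibrium_pmf(kmax, theta0), kernel)[
        : kmax + 1
    ]
    return recent + old


def _ssd(hist: np.ndarray, tau: float, theta0: float, theta1: float) -> float:
    obs = hist / hist.sum()
    exp = mismatch_pmf(len(hist) - 1, tau, theta0, theta1)
    return float(np.sum((obs - exp) ** 2))


def _fit_ssd(hist: np.ndarray, theta1_cap: float) -> tuple[float, float, float, float]:
    """Coarse grid over (tau, theta0, theta1) then bounded simplex refinement."""
    kbar = float(np.average(np.arange(len(hist)), weights=hist))
    tau_grid = np.unique(np.concatenate([[0.0, 0.5, 1, 2, 3, 5, 8, 12, 20], [kbar]]))
    theta0_grid = np.array([1e-6, 0.5, 1, 2, 5, 10])
    theta1_grid = np.unique(
        np.concatenate([[1, 5, 10, 25, 50, 100, 1000], [theta1_cap, max(kbar, 1e-3)]])
    )
    best, best_ssd = None, np.inf
    for t in tau_grid:
        for q0 in theta0_grid:
            for q1 in theta1_grid:
                v = _ssd(hist, t, q0, q1)
                if v < best_ssd:
                    best, best_ssd = (t, q0, q1), v
    res = minimize(
        lambda p: _ssd(hist, p[0], p[1], p[2]),
        x0=np.asarray(best),
        method="Nelder-Mead",
        bounds=[(0.0, 200.0), (0.0, theta1_cap), (1e-6, theta1_cap)],
        options={"xatol": 1e-4, "fatol": 1e-12, "maxiter": 2000},
    )
    tau, theta0, theta1 = res.x
    return float(tau), float(theta0), float(theta1), float(res.fun)


def fit_sudden_expansion(
    hist: np.ndarray,
    n_boot: int = 0,
    seed: int | None = None,
    theta1_cap: float = 10_000.0,
    n_samples: int | None = None,
) -> MismatchFit:
    """Least-squares (SSD) fit of the sudden-expansion model.

    The goodness-of-fit p-value and percentile confidence intervals come
    from a parametric bootstrap: ``n_boot`` coalescent datasets are
    simulated at the fitted parameters (sample size ``n_samples``,
    inferred from the pair count when omitted), each is refitted, and
    p = fraction of bootstrap SSDs >= the observed SSD.

    theta1 estimates at the cap correspond to the "infinite" post-
    expansion size that boundary fits print.
    """
    hist = np.asarray(hist, dtype=float)
    total = hist.sum()
    if total < 10:
        raise ValueError("need at least 10 sequence pairs to fit")
    if len(hist) == 1 or hist[0] == total:
        warnings.warn("all pairs identical: boundary fit tau = 0", stacklevel=2)
        return MismatchFit(
            histogram=hist, tau=0.0, theta0=0.0, theta1=theta1_cap, ssd=0.0,
            theta1_cap=theta1_cap,
        )
    tau, theta0, theta1, ssd = _fit_ssd(hist, theta1_cap)
    fit = MismatchFit(
        histogram=hist, tau=tau, theta0=theta0, theta1=theta1, ssd=ssd,
        theta1_cap=theta1_cap,
    )
    if n_boot > 0:
        if n_samples is None:
            n_samples = int(round((1 + np.sqrt(1 + 8 * total)) / 2))
            if n_samples * (n_samples - 1) // 2 != int(total):
                raise ValueError(
                    "histogram total is not a pair count; pass n_samples explicitly"
                )
        rng = np.random.default_rng(seed)
        taus, t0s, t1s, ge = [], [], [], 0
        for _ in range(n_boot):
            muts = mutation_sets(n_samples, theta1, theta0, tau, rng=rng)
            diffs = [
                len(muts[i] ^ muts[j])
                for i in range(n_samples - 1)
                for j in range(i + 1, n_samples)
            ]
            bhist = np.bincount(diffs).astype(float)
            if len(bhist) == 1:
                bt, b0, b1v, bs = 0.0, 0.0, theta1_cap, 0.0
            else:
                bt, b0, b1v, bs = _fit_ssd(bhist, theta1_cap)
            taus.append(bt)
            t0s.append(b0)
            t1s.append(b1v)
            ge += bs >= ssd
        fit.p_value = ge / n_boot
        fit.tau_ci = tuple(np.quantile(taus, [0.025, 0.975]))
        fit.theta0_ci = tuple(np.quantile(t0s, [0.025, 0.975]))
        fit.theta1_ci = tuple(np.quantile(t1s, [0.025, 0.975]))
        fit.n_bootstrap = n_boot
    return fit


# ---------------------------------------------------------------------------
# between-clade divergence


def fixed_differences(
    aln: HaplotypeAlignment, clade_a: str | None = None, clade_b: str | None = None
) -> tuple[int, float]:
    """(fixed difference count, Dxy) between two clades.

    A fixed difference is a retained column at which the two clades'
    observed character-state sets are disjoint. Dxy is the mean
    between-clade pairwise difference count per retained site. Complete
    deletion is applied over the full alignment so both statistics see
    the same columns.
    """
    labels = sorted(set(aln.clades))
    if clade_a is None or clade_b is None:
        if len(labels) != 2:
            raise ValueError(f"expected exactly 2 clades, found {labels}")
        clade_a, clade_b = labels
    clean = aln.complete_deletion()
    mask_a = np.array([c == clade_a for c in clean.clades])
    mask_b = np.array([c == clade_b for c in clean.clades])
    if not mask_a.any() or not mask_b.any():
        raise ValueError("both clades need at least one sequence")
    sa, sb = clean.seqs[mask_a], clean.seqs[mask_b]
    fixed = 0
    for col in range(clean.sites):
        if not set(sa[:, col]) & set(sb[:, col]):
            fixed += 1
    dxy = float(_between_diffs(sa, sb).mean()) / clean.sites
    return fixed, dxy


def summarize_groups(
    aln: HaplotypeAlignment, p_reps: int = 1000, seed: int | None = None
):
    """Diversity-table rows (one per clade plus the pooled sample).

    Returns a pandas DataFrame shaped like a standard per-group sequence
    summary: n_i, n_h, n_p, H, pi%, Tajima's D with p, Fu's Fs with p.
    """
    import pandas as pd

    groups = [("all", aln)] + [(lbl, aln.clade(lbl)) for lbl in sorted(set(aln.clades))]
    rows = []
    ss = np.random.SeedSequence(seed) if seed is not None else np.random.SeedSequence()
    child_seeds = ss.generate_state(2 * len(groups))
    for g, (name, sub) in enumerate(groups):
        stats = diversity_stats(sub)
        d, pd_ = tajimas_d(sub, p_reps=p_reps, seed=int(child_seeds[2 * g]))
        fs, pf = fus_fs(sub, p_reps=p_reps, seed=int(child_seeds[2 * g + 1]))
        rows.append(
            {
                "group": name,
                "n_i": stats.n_samples,
                "n_h": stats.n_haplotypes,
                "n_p": stats.n_polymorphic,
                "H": stats.haplotype_diversity,
                "pi_pct": 100 * stats.pi,
                "pi_pct_sd": 100 * stats.pi_sd,
                "tajimas_D": d,
                "p_D": pd_,
                "fus_Fs": fs,
                "p_Fs": pf,
            }
        )
    return pd.DataFrame(rows)
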