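"""Single-population coalescent with one instantaneous size change.

Time is measured in "mutational time" units s = u·t, where u is the
per-locus mutation rate per generation and t is time in generations.
In these units a lineage accumulates mutations at rate 1, a pair of
lineages coalesces at rate 2/θ (θ = 2Nu), and the sudden-expansion
event (θ0 → θ1 looking forward; θ1 → θ0 looking backward) sits at
s = τ/2, so that the expected pairwise difference contributed by the
recent epoch boundary equals the conventional τ = 2ut of mismatch
analysis.

Only neutral, non-recombining, infinite-sites genealogies are modelled;
this is the demographic scenario of a sudden-expansion mismatch fit.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "coalescent_times",
    "simulate_genealogy",
    "mutation_sets",
    "expected_tip_depth",
]


def coalescent_times(
    n: int,
    theta1: float,
    theta0: float | None = None,
    tau: float = np.inf,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw the n-1 coalescence times (mutational-time units, oldest last).

    ``theta1`` applies from the present back to s = tau/2, ``theta0``
    earlier.  ``tau=inf`` (or ``theta0 is None``) gives the constant-size
    coalescent at ``theta1``.  ``theta0 == 0`` collapses all remaining
    lineages instantaneously at the epoch boundary (a star genealogy,
    the tau-hat = tau limit of an extreme expansion).
    """
    if n < 2:
        raise ValueError("need at least 2 lineages")
    if theta1 <= 0:
        raise ValueError("theta1 must be positive")
    rng = np.random.default_rng() if rng is None else rng
    boundary = tau / 2.0
    if theta0 is None:
        boundary = np.inf
        theta0 = theta1

    times = np.empty(n - 1)
    s = 0.0
    theta = theta1
    in_recent = np.isfinite(boundary)
    k = n
    for i in range(n - 1):
        while True:
            if theta <= 0.0:
                w = 0.0
            else:
                rate = k * (k - 1) / theta  # C(k,2) * 2/theta
                w = rng.exponential(1.0 / rate)
            if in_recent and s + w > boundary:
                # memoryless: restart the wait in the older epoch
                s = boundary
                theta = theta0
                in_recent = False
                continue
            break
        s += w
        times[i] = s
        k -= 1
    return times


def simulate_genealogy(
    n: int,
    theta1: float,
    theta0: float | None = None,
    tau: float = np.inf,
    rng: np.random.Generator | None = None,
) -> tuple[list[frozenset[int]], np.ndarray]:
    """Simulate the tree topology as (clade tip-sets, branch lengths).

    Returns a list of branches; branch i subtends ``tipsets[i]`` and has
    length ``lengths[i]`` in mutational-time units.  The root branch is
    not included.  Tips are labelled 0..n-1.
    """
    rng = np.random.default_rng() if rng is None else rng
    times = coalescent_times(n, theta1, theta0, tau, rng)

    # active lineages: (tipset, birth time of the lineage)
    active: list[tuple[frozenset[int], float]] = [
        (frozenset([i]), 0.0) for i in range(n)
    ]
    tipsets: list[frozenset[int]] = []
    lengths: list[float] = []
    for t in times:
        i, j = rng.choice(len(active), size=2, replace=False)
        if i > j:
            i, j = j, i
        (set_j, birth_j) = active.pop(j)
        (set_i, birth_i) = active.pop(i)
        tipsets.append(set_i)
        lengths.append(t - birth_i)
        tipsets.append(set_j)
        lengths.append(t - birth_j)
        active.append((set_i | set_j, t))
    return tipsets, np.asarray(lengths)


def mutation_sets(
    n: int,
    theta1: float,
    theta0: float | None = None,
    tau: float = np.inf,
    rng: np.random.Generator | None = None,
) -> list[set[int]]:
    """Infinite-sites mutations per tip, as sets of mutation labels.

    Each mutation is a unique integer; tip i carries the union of the
    mutations on its root path.  Pairwise sequence differences are sizes
    of symmetric set differences; the segregating-site count is the
    number of distinct labels.
    """
    rng = np.random.default_rng() if rng is None else rng
    tipsets, lengths = simulate_genealogy(n, theta1, theta0, tau, rng)
    counts = rng.poisson(lengths)  # mutation rate 1 per unit length
    muts: list[set[int]] = [set() for _ in range(n)]
    label = 0
    for tipset, c in zip(tipsets, counts):
        for _ in range(c):
            for tip in tipset:
                muts[tip].add(label)
            label += 1
    return muts


def expected_tip_depth(
    n: int,
    theta1: float,
    theta0: float,
    tau: float,
    reps: int = 4000,
    seed: int = 20140408,
) -> float:
    """Mean root-to-tip path length (= TMRCA, the tree is ultrametric).

    Monte-Carlo estimate with an internal fixed seed; used to calibrate
    how many mutations a random sequence carries relative to its clade
    ancestor when planning between-clade divergence.
    """
    rng = np.random.default_rng(seed)
    tot = 0.0
    for _ in range(reps):
        tot += coalescent_times(n, theta1, theta0, tau, rng)[-1]
    return tot / reps
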