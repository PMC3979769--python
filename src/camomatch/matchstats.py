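"""Statistical core: repeatability, partial correlations, color mismatch
and mixed-model AIC selection.

These are the analyses that link specimen fur color to habitat color:

* one-way ANOVA intraclass correlation (ICC) for the repeatability of
  duplicated fur and scene measurements;
* partial Pearson correlation between fur and environment luminosity,
  controlling for covariates such as museum vs field origin;
* standardized fur-minus-environment "color mismatch" distributions per
  clade (histogram plus skewness);
* linear mixed models (random intercept per individual, ML fits) ranked
  by AIC, with Akaike weights and per-term relative importance.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ICCResult",
    "PartialCorrResult",
    "ColorMismatch",
    "ModelTable",
    "icc",
    "partial_pearson",
    "color_mismatch",
    "candidate_term_sets",
    "mixed_model_selection",
    "akaike_weights",
]


@dataclass
class ICCResult:
    icc: float
    ms_between: float
    ms_within: float
    f_statistic: float
    p_value: float
    n_groups: int
    k: int


@dataclass
class PartialCorrResult:
    r: float
    t_statistic: float
    df: int
    p_value: float
    n_covariates: int


@dataclass
class ColorMismatch:
    """Standardized fur minus standardized environment luminosity."""

    mismatch: np.ndarray
    clades: np.ndarray
    bin_edges: np.ndarray
    histograms: dict[str, np.ndarray]
    skewness: dict[str, float | None]


@dataclass
class ModelTable:
    """Ranked candidate mixed models with AIC bookkeeping."""

    table: pd.DataFrame  # terms, df, logLik, AIC, delta, weight (AIC ascending)
    importance: pd.Series  # per-term summed Akaike weight
    best_terms: tuple[str, ...]
    best_coefficients: pd.DataFrame  # estimate, SE, df, t, p
    n_candidates: int
    n_dropped: int


def icc(values: np.ndarray) -> ICCResult:
    """One-way ANOVA intraclass correlation for an (n groups x k) table.

    ICC = (MSB - MSW) / (MSB + (k-1) MSW); F = MSB/MSW on (n-1, n(k-1))
    degrees of freedom. Requires complete duplicated measurements
    (imbalance is not handled).
    """
    values = np.asarray(values, float)
    if values.ndim != 2:
        raise ValueError("values must be a 2-D (groups x measurements) array")
    if np.isnan(values).any():
        raise ValueError("incomplete measurements are not supported")
    n, k = values.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 groups and 2 measurements per group")
    grand = values.mean()
    group_means = values.mean(axis=1)
    ssb = k * float(np.sum((group_means - grand) ** 2))
    ssw = float(np.sum((values - group_means[:, None]) ** 2))
    msb = ssb / (n - 1)
    msw = ssw / (n * (k - 1))
    if msw == 0.0:
        return ICCResult(1.0, msb, 0.0, np.inf, 0.0, n, k)
    f = msb / msw
    p = float(sps.f.sf(f, n - 1, n * (k - 1)))
    return ICCResult((msb - msw) / (msb + (k - 1) * msw), msb, msw, f, p, n, k)


def _residualize(v: np.ndarray, design: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(design, v, rcond=None)
    return v - design @ beta


def partial_pearson(x, y, covariates=None) -> PartialCorrResult:
    """Pearson correlation of x and y after regressing both on covariates.

    t = r sqrt(df) / sqrt(1 - r^2) with df = n - 2 - (#covariates);
    two-sided p from the t distribution. With no covariates this is the
    plain Pearson correlation.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant input vector")
    n = len(x)
    if covariates is None:
        cov = np.empty((n, 0))
    else:
        cov = np.asarray(covariates, float)
        if cov.ndim == 1:
            cov = cov[:, None]
        # a constant covariate is absorbed by the intercept and carries no
        # information; keep df consistent by removing it
        cov = cov[:, cov.std(axis=0) > 0]
    q = cov.shape[1]
    if n <= q + 2:
        raise ValueError("too few observations for the covariate count")
    design = np.column_stack([np.ones(n), cov])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient covariate matrix")
    rx = _residualize(x, design)
    ry = _residualize(y, design)
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2 - q
    r_clip = min(max(r, -1 + 1e-15), 1 - 1e-15)
    t = r_clip * np.sqrt(df) / np.sqrt(1 - r_clip**2)
    p = 2 * float(sps.t.sf(abs(t), df))
    return PartialCorrResult(r=r, t_statistic=float(t), df=df, p_value=p, n_covariates=q)


def color_mismatch(fur, env, clades, n_bins: int = 10) -> ColorMismatch:
    """Per-clade distributions of relative fur-vs-environment mismatch.

    Both luminosity vectors are z-scored over the full sample ("relative"
    coloration), differenced, binned into a shared histogram, and
    summarized per clade by the adjusted Fisher-Pearson sample skewness.
    Skewness is reported as None for degenerate (zero-spread) clades.
    """
    fur = np.asarray(fur, float)
    env = np.asarray(env, float)
    clades = np.asarray(clades)
    if not (len(fur) == len(env) == len(clades)):
        raise ValueError("fur, env and clade vectors must have equal length")
    if np.std(fur) == 0 or np.std(env) == 0:
        raise ValueError("zero variance in fur or environment luminosity")
    z = lambda v: (v - v.mean()) / v.std(ddof=1)  # noqa: E731
    mism = z(fur) - z(env)
    edges = np.histogram_bin_edges(mism, bins=n_bins)
    hists, skews = {}, {}
    for lbl in np.unique(clades):
        sub = mism[clades == lbl]
        hists[str(lbl)] = np.histogram(sub, bins=edges)[0]
        if len(sub) < 3 or np.std(sub) == 0:
            skews[str(lbl)] = None
        else:
            skews[str(lbl)] = float(sps.skew(sub, bias=False))
    return ColorMismatch(
        mismatch=mism, clades=clades, bin_edges=edges, histograms=hists, skewness=skews
    )


# ---------------------------------------------------------------------------
# mixed-model AIC selection

#: default predictor pool: genetic clade, museum/field origin, environment
#: color channels and luminosity (continuous predictors on the 0-1 scale).
DEFAULT_TERMS = ("clade", "origin", "env_r", "env_g", "env_b", "env_lum")


def candidate_term_sets(
    terms: tuple[str, ...] = DEFAULT_TERMS,
    interactions: tuple[tuple[str, str], ...] = (),
) -> list[tuple[str, ...]]:
    """All subsets of the main-effect pool, optionally augmented with
    two-way factor-by-continuous interactions (added only to candidates
    already containing both parents)."""
    sets: list[tuple[str, ...]] = []
    for k in range(len(terms) + 1):
        for combo in itertools.combinations(terms, k):
            sets.append(combo)
            present = [
                f"{a}:{b}" for a, b in interactions if a in combo and b in combo
            ]
            for m in range(1, len(present) + 1):
                for extra in itertools.combinations(present, m):
                    sets.append(combo + extra)
    return sets


def akaike_weights(aics: np.ndarray) -> np.ndarray:
    """exp(-delta/2) normalized over the candidate set; invariant to a
    constant shift of all AICs."""
    aics = np.asarray(aics, float)
    delta = aics - aics.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


def _fit_mixed(formula: str, data: pd.DataFrame, groups: str):
    import statsmodels.formula.api as smf
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        model = smf.mixedlm(formula, data, groups=data[groups])
        return model.fit(reml=False)


def mixed_model_selection(
    data: pd.DataFrame,
    response: str = "fur_lum",
    candidates: list[tuple[str, ...]] | None = None,
    group_col: str = "id",
    top: int | None = 5,
    scale_continuous: bool = True,
) -> ModelTable:
    """Rank random-intercept mixed models of fur color by AIC.

    ``data`` is a long table with one row per measurement (two per
    individual), the response column, an individual id column, and the
    predictor columns. Each candidate term set is fitted by maximum
    likelihood (ML, so likelihoods are comparable across fixed-effect
    structures); AIC = -2 logLik + 2k with k = fixed effects (incl.
    intercept) + random-intercept variance + residual variance.
    Akaike weights and per-term importances are computed over all
    candidates that converged; the returned table is truncated to
    ``top`` rows. Non-convergent candidates are dropped with a warning.

    Continuous environment predictors (``env_*``) are divided by 255
    when ``scale_continuous`` is set, putting slopes on a reflectance-like
    0-1 predictor scale against the 0-255 response.
    """
    if candidates is None:
        candidates = candidate_term_sets()
    if not candidates:
        raise ValueError("empty candidate set")
    data = data.copy()
    if scale_continuous:
        for col in data.columns:
            if col.startswith("env_"):
                data[col] = data[col] / 255.0

    rows, dropped = [], 0
    for terms in candidates:
        rhs = " + ".join(terms) if terms else "1"
        formula = f"{response} ~ {rhs}"
        try:
            res = _fit_mixed(formula, data, group_col)
        except Exception as exc:  # non-convergence or singular fit
            dropped += 1
            warnings.warn(f"dropping candidate '{rhs}': {exc}", stacklevel=2)
            continue
        k = res.k_fe + 2  # fixed effects + random-intercept var + residual var
        rows.append(
            {
                "terms": terms,
                "model": rhs,
                "df": k,
                "logLik": float(res.llf),
                "AIC": float(-2 * res.llf + 2 * k),
            }
        )
    if not rows:
        raise RuntimeError("no candidate model converged")
    tab = pd.DataFrame(rows).sort_values("AIC", kind="stable").reset_index(drop=True)
    tab["delta"] = tab["AIC"] - tab["AIC"].iloc[0]
    tab["weight"] = akaike_weights(tab["AIC"].to_numpy())

    all_terms = sorted({t for terms in tab["terms"] for t in terms})
    importance = pd.Series(
        {
            t: float(tab.loc[[t in terms for terms in tab["terms"]], "weight"].sum())
            for t in all_terms
        }
    ).sort_values(ascending=False)

    best_terms = tuple(tab["terms"].iloc[0])
    best = _fit_mixed(f"{response} ~ {' + '.join(best_terms) or '1'}", data, group_col)
    fe = best.fe_params
    # denominator df in the classic mixed-model convention:
    # observations minus individuals minus fixed-effect slopes
    ddf = max(int(len(data) - data[group_col].nunique() - (best.k_fe - 1)), 1)
    coef = pd.DataFrame(
        {
            "estimate": fe,
            "se": best.bse_fe,
            "df": ddf,
            "t": fe / best.bse_fe,
        }
    )
    coef["p"] = 2 * sps.t.sf(np.abs(coef["t"]), ddf)

    if top is not None:
        tab = tab.head(top).copy()
    return ModelTable(
        table=tab,
        importance=importance,
        best_terms=best_terms,
        best_coefficients=coef,
        n_candidates=len(candidates),
        n_dropped=dropped,
    )
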