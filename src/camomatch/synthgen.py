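"""Synthetic data with the statistical structure the analysis assumes.

Three generators stand in for the study's non-redistributable raw data:

* :func:`generate_landscape` — a two-phase (sandy/rocky) reflectance
  mosaic encoded to 8-bit DN by inverting the exact calibration chain of
  :mod:`camomatch.rscolor`, with per-band metadata, an optional injected
  path radiance, and a validity mask;
* :func:`generate_specimens` / :func:`generate_phenotypes` — georeferenced
  individuals whose true fur color is a linear function of local
  environment color plus clade and museum/field offsets, measured twice
  with independent noise (known repeatability);
* :func:`generate_sequences` — two-clade haplotype alignments under the
  sudden-expansion coalescent with infinite-sites mutations, a planted
  number of clade-diagnostic fixed differences, and near-fixed divergence
  sites calibrated to a target between-clade per-site divergence.

Every function draws all randomness from a single explicit seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from ._coalescent import expected_tip_depth, mutation_sets
from .popgen import HaplotypeAlignment
from .rscolor import (
    BT601_WEIGHTS,
    CalibrationMeta,
    RasterScene,
    rgb_luminosity,
    scene_rgb255,
    buffer_extract,
)

__all__ = [
    "LandscapeParams",
    "PhenotypeParams",
    "SequenceParams",
    "generate_landscape",
    "generate_specimens",
    "generate_phenotypes",
    "generate_sequences",
    "simulate_clade_alignment",
    "simulate_duplicates",
    "phenotype_preset",
    "implied_partial_correlation",
    "specimens_to_long",
    "planted_near_fixed_sites",
]

#: quadratic norm of the BT.601 weights; converts a per-channel iid noise
#: sd into the sd it induces on the luminosity combination.
_BT601_L2 = float(np.sqrt(np.sum(BT601_WEIGHTS**2)))


# ---------------------------------------------------------------------------
# landscape


@dataclass
class LandscapeParams:
    """Two-phase desert mosaic plus the calibration constants of its scene.

    Reflectances are unitless 0-1 per band in (R, G, B) order; the DN
    encoding inverts the rscolor calibration exactly, so round-trip
    recovery is limited only by 8-bit quantization. ``inject_path_radiance``
    adds an atmospheric haze term to the encoded radiance that is *not*
    recorded in the scene metadata — dark-object estimation must recover
    it.
    """

    grid_size: int = 512
    pixel_size: float = 120.0  # m; coarsened Landsat-style grid
    correlation_length: float = 3000.0  # m; patch scale of the mosaic
    sandy_reflectance: tuple[float, float, float] = (0.52, 0.42, 0.33)
    rocky_reflectance: tuple[float, float, float] = (0.26, 0.22, 0.18)
    sandy_fraction: float = 0.5
    within_patch_sd: float = 0.02
    masked_fraction: float = 0.02
    lmin: tuple[float, float, float] = (-2.0, -2.0, -2.0)
    lmax: tuple[float, float, float] = (420.0, 490.0, 540.0)
    qcalmin: float = 0.0
    qcalmax: float = 255.0
    esun: tuple[float, float, float] = (1533.0, 1812.0, 1969.0)
    solar_elevation_deg: float = 55.0
    earth_sun_distance_au: float = 1.0
    inject_path_radiance: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def validate(self) -> None:
        if self.grid_size <= 0 or self.pixel_size <= 0:
            raise ValueError("grid and pixel size must be positive")
        for m in (self.sandy_reflectance, self.rocky_reflectance):
            if np.any((np.asarray(m) < 0) | (np.asarray(m) > 1)):
                raise ValueError("reflectance means must lie in [0, 1]")
        if self.qcalmax <= self.qcalmin:
            raise ValueError("Qcalmax must exceed Qcalmin")
        if not 0.0 <= self.masked_fraction < 1.0:
            raise ValueError("masked fraction must lie in [0, 1)")

    def calibration(self) -> CalibrationMeta:
        return CalibrationMeta(
            lmin=np.array(self.lmin),
            lmax=np.array(self.lmax),
            qcalmin=np.full(3, self.qcalmin),
            qcalmax=np.full(3, self.qcalmax),
            esun=np.array(self.esun),
            solar_zenith_deg=90.0 - self.solar_elevation_deg,
            earth_sun_distance_au=self.earth_sun_distance_au,
        )


def generate_landscape(
    params: LandscapeParams,
    seed: int,
    return_truth: bool = False,
    noise_seed: int | None = None,
):
    """Generate a calibrated two-phase scene.

    The mosaic is a thresholded Gaussian random field (filter scale =
    correlation length / pixel size); pixels above the sandy-fraction
    quantile are bright sandy substrate, the rest dark rocky substrate.
    With ``return_truth`` the generating reflectance field (3, N, N),
    clipped to [0, 1] before quantization, is returned alongside the
    scene. ``noise_seed`` redraws only the within-patch noise and the
    mask, keeping the mosaic fixed — the multi-epoch "same place, new
    acquisition" scenario used for repeatability studies.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    rng_noise = rng if noise_seed is None else np.random.default_rng(noise_seed)
    n = params.grid_size
    meta = params.calibration()

    noise = rng.standard_normal((n, n))
    sigma = params.correlation_length / params.pixel_size
    fld = gaussian_filter(noise, sigma=sigma, mode="wrap") if sigma > 0 else noise
    threshold = np.quantile(fld, 1.0 - params.sandy_fraction)
    sandy = fld >= threshold

    rho = np.empty((3, n, n))
    for b in range(3):
        rho[b] = np.where(sandy, params.sandy_reflectance[b], params.rocky_reflectance[b])
        rho[b] += rng_noise.normal(0.0, params.within_patch_sd, size=(n, n))
    rho = np.clip(rho, 0.0, 1.0)

    dn = np.empty((3, n, n), dtype=np.uint8)
    for b in range(3):
        # invert rscolor: rho -> radiance (+ hidden haze) -> DN
        radiance = (
            rho[b]
            * meta.tv
            * meta.irradiance_term(b)
            / (np.pi * meta.earth_sun_distance_au**2)
            + params.inject_path_radiance[b]
        )
        gain = (meta.lmax[b] - meta.lmin[b]) / (meta.qcalmax[b] - meta.qcalmin[b])
        q = np.rint((radiance - meta.lmin[b]) / gain + meta.qcalmin[b])
        if np.any((q < meta.qcalmin[b]) | (q > meta.qcalmax[b])):
            raise ValueError(
                "reflectance field does not fit the calibrated DN range; "
                "widen lmin/lmax"
            )
        dn[b] = q.astype(np.uint8)

    mask = rng_noise.random((n, n)) < params.masked_fraction
    scene = RasterScene(
        dn=dn, mask=mask, pixel_size=params.pixel_size, meta=meta, origin=(0.0, 0.0)
    )
    return (scene, rho) if return_truth else scene


# ---------------------------------------------------------------------------
# phenotypes


@dataclass
class PhenotypeParams:
    """Linear fur-color model with duplicated noisy measurements.

    Each fur channel c follows
    ``intercept_c + slope * env_c + clade2_offset_c * [clade 2]
    + museum_offset_c * [museum] + residual``; measured luminosity is
    the BT.601 combination of measured channels, so on the luminosity
    scale the model holds with the BT.601-combined intercept/offsets,
    ``residual_sd`` and ``measurement_sd`` (per-channel sds are scaled by
    the inverse BT.601 norm to make the luminosity-scale sds exact).
    Units are 8-bit luminosity (0-255); slope is unitless.
    """

    slope: float = 0.6
    env_reference: float = 140.0  # slope applies to (env - reference)
    channel_intercepts: tuple[float, float, float] = (181.5, 117.4, 80.0)
    channel_clade2_offsets: tuple[float, float, float] = (-16.8, -11.6, -11.2)
    channel_museum_offsets: tuple[float, float, float] = (-39.5, -20.9, -11.6)
    residual_sd: float = 18.36  # luminosity scale
    measurement_sd: float = 3.0  # within-individual duplicate sd, luminosity scale
    clade2_fraction: float = 0.4
    museum_fraction: float = 68 / 77

    def __post_init__(self) -> None:
        if self.residual_sd <= 0:
            raise ValueError("residual sd must be positive")
        if self.measurement_sd < 0:
            raise ValueError("measurement sd must be non-negative")

    @property
    def intercept(self) -> float:
        return float(np.dot(BT601_WEIGHTS, self.channel_intercepts))

    @property
    def clade2_offset(self) -> float:
        return float(np.dot(BT601_WEIGHTS, self.channel_clade2_offsets))

    @property
    def museum_offset(self) -> float:
        return float(np.dot(BT601_WEIGHTS, self.channel_museum_offsets))


def implied_partial_correlation(
    pheno: PhenotypeParams, env_lum_sd: float
) -> float:
    """Population partial correlation of fur vs environment luminosity
    controlling for museum/field origin (origin independent of habitat).

    The clade offset is *not* controlled, so its mixing variance stays in
    the fur-luminosity denominator:
    r = s·σe / sqrt(s²σe² + f(1-f)·Δc² + σr²).
    """
    s2 = (pheno.slope * env_lum_sd) ** 2
    f = pheno.clade2_fraction
    var_clade = f * (1 - f) * pheno.clade2_offset**2
    return float(np.sqrt(s2 / (s2 + var_clade + pheno.residual_sd**2)))


def phenotype_preset(r: float = 0.42, env_lum_sd: float = 15.0) -> PhenotypeParams:
    """Default-structure parameters with the residual sd solved so the
    implied fur-environment partial correlation equals ``r``."""
    base = PhenotypeParams()
    s2 = (base.slope * env_lum_sd) ** 2
    f = base.clade2_fraction
    var_clade = f * (1 - f) * base.clade2_offset**2
    resid_var = s2 / r**2 - s2 - var_clade
    if resid_var <= 0:
        raise ValueError(f"target correlation {r} unattainable with this structure")
    return PhenotypeParams(residual_sd=float(np.sqrt(resid_var)))


def _draw_fur(
    env_rgb: np.ndarray, clade2: np.ndarray, museum: np.ndarray,
    pheno: PhenotypeParams, rng: np.random.Generator,
) -> np.ndarray:
    """True (noise-free-of-measurement) fur channels, (n, 3)."""
    n = env_rgb.shape[0]
    chan_sd = pheno.residual_sd / _BT601_L2
    fur = np.empty((n, 3))
    resid = rng.normal(0.0, chan_sd, size=(n, 3))
    for c in range(3):
        fur[:, c] = (
            pheno.channel_intercepts[c]
            + pheno.slope * (env_rgb[:, c] - pheno.env_reference)
            + pheno.channel_clade2_offsets[c] * clade2
            + pheno.channel_museum_offsets[c] * museum
            + resid[:, c]
        )
    return fur


def _measure(fur_true: np.ndarray, pheno, rng) -> np.ndarray:
    chan_sd = pheno.measurement_sd / _BT601_L2
    return np.clip(fur_true + rng.normal(0.0, chan_sd, size=fur_true.shape), 0, 255)


def _assemble(ids, x, y, clade2, museum, env_rgb, fur_true, m1, m2) -> pd.DataFrame:
    lum = lambda a: a @ BT601_WEIGHTS  # noqa: E731  (no range check: model scale)
    return pd.DataFrame(
        {
            "id": ids,
            "x": x,
            "y": y,
            "clade": np.where(clade2 == 1, "c2", "c1"),
            "origin": np.where(museum == 1, "museum", "field"),
            "env_r": env_rgb[:, 0],
            "env_g": env_rgb[:, 1],
            "env_b": env_rgb[:, 2],
            "env_lum": lum(env_rgb),
            "fur_lum_true": lum(fur_true),
            "r1": m1[:, 0], "g1": m1[:, 1], "b1": m1[:, 2], "lum1": lum(m1),
            "r2": m2[:, 0], "g2": m2[:, 1], "b2": m2[:, 2], "lum2": lum(m2),
        }
    )


def generate_specimens(
    scene: RasterScene,
    n: int,
    pheno: PhenotypeParams,
    seed: int,
    radius: float = 10_000.0,
    correction: str = "toa",
) -> pd.DataFrame:
    """Sample specimens on a scene and measure their fur twice.

    Locations are uniform over unmasked pixel centers (without
    replacement); the environment color of each specimen is the
    calibrated circular-buffer mean around its location.
    """
    if n < 2:
        raise ValueError("need n >= 2 specimens")
    rng = np.random.default_rng(seed)
    valid = np.flatnonzero(~scene.mask.ravel())
    if n > len(valid):
        raise ValueError(f"n={n} exceeds {len(valid)} unmasked locations")
    pick = rng.choice(valid, size=n, replace=False)
    nr, nc = scene.shape
    rows, cols = np.unravel_index(pick, (nr, nc))
    xs = scene.origin[0] + (cols + 0.5) * scene.pixel_size
    ys = scene.origin[1] + (rows + 0.5) * scene.pixel_size

    rgb = scene_rgb255(scene, correction=correction)
    env = np.empty((n, 3))
    for i in range(n):
        bc = buffer_extract(scene, (xs[i], ys[i]), radius=radius, rgb=rgb)
        env[i] = (bc.r, bc.g, bc.b)

    clade2 = (rng.random(n) < pheno.clade2_fraction).astype(int)
    museum = (rng.random(n) < pheno.museum_fraction).astype(int)
    fur = _draw_fur(env, clade2, museum, pheno, rng)
    m1, m2 = _measure(fur, pheno, rng), _measure(fur, pheno, rng)
    ids = [f"jj{i:03d}" for i in range(n)]
    return _assemble(ids, xs, ys, clade2, museum, env, fur, m1, m2)


def generate_phenotypes(
    n: int,
    pheno: PhenotypeParams,
    seed: int,
    env_lum_mean: float = 140.0,
    env_lum_sd: float = 15.0,
    env_channel_jitter_sd: float = 6.0,
) -> pd.DataFrame:
    """Raster-free specimen table: environment luminosity drawn directly.

    Environment channels are a common normal base plus independent
    per-channel jitter; the base variance is deflated so the BT.601
    luminosity of the channels has standard deviation ``env_lum_sd``
    exactly. Used for fast statistical calibration runs where the
    remote-sensing stage is not under study.
    """
    if n < 2:
        raise ValueError("need n >= 2 specimens")
    rng = np.random.default_rng(seed)
    base_var = env_lum_sd**2 - (env_channel_jitter_sd * _BT601_L2) ** 2
    if base_var <= 0:
        raise ValueError("env_lum_sd too small for the channel jitter")
    base = rng.normal(env_lum_mean, np.sqrt(base_var), size=n)
    env = np.clip(
        base[:, None] + rng.normal(0.0, env_channel_jitter_sd, size=(n, 3)), 0, 255
    )
    clade2 = (rng.random(n) < pheno.clade2_fraction).astype(int)
    museum = (rng.random(n) < pheno.museum_fraction).astype(int)
    fur = _draw_fur(env, clade2, museum, pheno, rng)
    m1, m2 = _measure(fur, pheno, rng), _measure(fur, pheno, rng)
    ids = [f"jj{i:03d}" for i in range(n)]
    x = y = np.full(n, np.nan)
    return _assemble(ids, x, y, clade2, museum, env, fur, m1, m2)


def specimens_to_long(df: pd.DataFrame) -> pd.DataFrame:
    """One row per measurement (two per individual) for mixed models."""
    keep = ["id", "clade", "origin", "env_r", "env_g", "env_b", "env_lum"]
    out = []
    for m in (1, 2):
        sub = df[keep].copy()
        sub["measurement"] = m
        sub["fur_r"] = df[f"r{m}"].to_numpy()
        sub["fur_g"] = df[f"g{m}"].to_numpy()
        sub["fur_b"] = df[f"b{m}"].to_numpy()
        sub["fur_lum"] = df[f"lum{m}"].to_numpy()
        out.append(sub)
    return pd.concat(out, ignore_index=True)


def simulate_duplicates(
    n_groups: int, k: int, between_sd: float, within_sd: float, seed: int
) -> np.ndarray:
    """(n_groups, k) table of duplicated measurements with known
    repeatability between_sd² / (between_sd² + within_sd²)."""
    rng = np.random.default_rng(seed)
    mu = rng.normal(0.0, between_sd, size=n_groups)
    return mu[:, None] + rng.normal(0.0, within_sd, size=(n_groups, k))


# ---------------------------------------------------------------------------
# sequences


@dataclass
class SequenceParams:
    """Two-clade sudden-expansion alignment generator settings.

    Defaults are the study-scale conditions: 352 sites, clade sample
    sizes 72/52, clade-1 expansion (tau=3.4, theta0=1.7, theta1=24.7),
    clade-2 expansion (tau=1.4, theta0=1.0, theta1 capped "infinite"),
    16 diagnostic fixed differences, and a between-clade per-site
    divergence target of 0.10. ``theta`` values are in units of expected
    pairwise differences; ``tau`` in mutational time (pairwise-difference
    units).
    """

    sites: int = 352
    n_clade1: int = 72
    n_clade2: int = 52
    tau: tuple[float, float] = (3.4, 1.4)
    theta0: tuple[float, float] = (1.7, 1.0)
    theta1: tuple[float, float] = (24.7, 10_000.0)
    n_fixed_differences: int = 16
    divergence: float = 0.10
    seed: int | None = None

    def validate(self) -> None:
        if self.sites < self.n_fixed_differences:
            raise ValueError("more diagnostic sites than sites")
        if any(t < 0 for t in self.tau):
            raise ValueError("tau must be non-negative")
        if any(t < 0 for t in self.theta0) or any(t <= 0 for t in self.theta1):
            raise ValueError("theta0 >= 0 and theta1 > 0 required")
        if self.n_clade1 < 1 or self.n_clade2 < 1:
            raise ValueError("both clades need samples")


@lru_cache(maxsize=64)
def _mean_tip_depth(n: int, theta1: float, theta0: float, tau: float) -> float:
    return expected_tip_depth(n, theta1, theta0, tau)


def planted_near_fixed_sites(params: SequenceParams) -> int:
    """Number of near-fixed divergence sites needed to meet the target.

    Between-clade divergence decomposes into the planted fixed
    differences, within-clade polymorphism (one expected mutation per
    unit of mean tip depth per clade), and near-fixed sites (derived in
    all but one member of one clade, mimicking incomplete lineage
    sorting) contributing (n-1)/n differences each. The count solves
    E[Dxy] = divergence target given Monte-Carlo estimates of the tip
    depths.
    """
    params.validate()
    target_diffs = params.divergence * params.sites
    depth = 0.0
    for n, t1, t0, tau in (
        (params.n_clade1, params.theta1[0], params.theta0[0], params.tau[0]),
        (params.n_clade2, params.theta1[1], params.theta0[1], params.tau[1]),
    ):
        if n >= 2:
            depth += _mean_tip_depth(n, t1, t0, tau)
    residual = target_diffs - params.n_fixed_differences - depth
    if residual < -0.5:
        warnings.warn(
            "divergence target below the floor set by fixed differences and "
            "within-clade polymorphism; planting no near-fixed sites",
            stacklevel=2,
        )
        return 0
    contrib = 0.5 * ((params.n_clade1 - 1) / params.n_clade1
                     + (params.n_clade2 - 1) / params.n_clade2)
    return max(0, round(residual / contrib))


_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _derived(ancestral: bytes, rng) -> bytes:
    alt = [b.tobytes() for b in _BASES if b.tobytes() != ancestral]
    return alt[rng.integers(len(alt))]


def generate_sequences(
    params: SequenceParams | None = None, seed: int | None = None
) -> HaplotypeAlignment:
    """Two-clade alignment under the sudden-expansion coalescent.

    Construction guarantees: exactly ``n_fixed_differences`` columns with
    disjoint clade state sets on every seed; infinite sites (no column
    carries more than two states; diagnostic columns are never mutated
    within clades); per-clade genealogies drawn independently under the
    configured two-epoch demography. If the coalescent produces more
    mutations than free sites (vanishingly rare at the defaults), the
    overflow is dropped with a warning.
    """
    params = params or SequenceParams()
    params.validate()
    if seed is None:
        seed = params.seed
    rng = np.random.default_rng(seed)
    sites = params.sites
    n1, n2 = params.n_clade1, params.n_clade2
    n = n1 + n2

    ancestral = _BASES[rng.integers(4, size=sites)]
    seqs = np.tile(ancestral, (n, 1)).copy()
    clade_rows = [np.arange(n1), np.arange(n1, n)]

    free = list(rng.permutation(sites))

    # diagnostic fixed differences: clade 2 carries the derived state
    for _ in range(params.n_fixed_differences):
        site = free.pop()
        seqs[clade_rows[1], site] = _derived(ancestral[site].tobytes(), rng)

    # near-fixed divergence sites (incomplete lineage sorting stand-in):
    # derived in all but one random member of the carrier clade
    n_near = planted_near_fixed_sites(params)
    for i in range(n_near):
        c = i % 2
        site = free.pop()
        rows = clade_rows[c]
        keep_ancestral = rows[rng.integers(len(rows))]
        carriers = rows[rows != keep_ancestral]
        seqs[carriers, site] = _derived(ancestral[site].tobytes(), rng)

    # within-clade coalescent mutations on the remaining sites
    for c, rows in enumerate(clade_rows):
        if len(rows) < 2:
            continue
        muts = mutation_sets(
            len(rows), params.theta1[c], params.theta0[c], params.tau[c], rng=rng
        )
        labels = sorted(set().union(*muts))
        if len(labels) > len(free):
            warnings.warn(
                f"clade {c + 1}: dropping {len(labels) - len(free)} mutations "
                "(site pool exhausted)",
                stacklevel=2,
            )
            labels = labels[: len(free)]
        site_of = {}
        for lab in labels:
            site = free.pop()
            site_of[lab] = (site, _derived(ancestral[site].tobytes(), rng))
        for tip, mset in zip(rows, muts):
            for lab in mset:
                if lab in site_of:
                    site, base = site_of[lab]
                    seqs[tip, site] = base

    ids = [f"c1_s{i:03d}" for i in range(n1)] + [f"c2_s{i:03d}" for i in range(n2)]
    clades = ["c1"] * n1 + ["c2"] * n2
    return HaplotypeAlignment(seqs, ids, clades)


def simulate_clade_alignment(
    n: int,
    sites: int,
    tau: float,
    theta0: float,
    theta1: float,
    seed: int | None = None,
) -> HaplotypeAlignment:
    """Single-population sudden-expansion alignment (no planted sites)."""
    params = SequenceParams(
        sites=sites,
        n_clade1=n,
        n_clade2=1,
        tau=(tau, 0.0),
        theta0=(theta0, 0.0),
        theta1=(theta1, 1e-9),
        n_fixed_differences=0,
        divergence=0.0,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # divergence floor warning is expected
        aln = generate_sequences(params, seed=seed)
    return aln.clade("c1")
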