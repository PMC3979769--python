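# Methods

This note documents the models implemented in camomatch, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical choices that matter.

## Radiometric chain

Scenes are 8-bit multi-band rasters with per-band linear calibration
(`Lmin`, `Lmax` over `Qcalmin`, `Qcalmax`) and scene-level atmospheric
terms. Calibration is the standard two-step chain: DN → at-sensor
radiance (linear gain/bias), then radiance → surface reflectance

ρ = π (L − Lp) d² / (Tv (ESUN cos θs Tz + Edown)),

which reduces to top-of-atmosphere reflectance when `Lp = 0`,
`Tv = Tz = 1`, `Edown = 0`. Two correction variants are config-pinned:
`toa` (metadata as-is) and `dos`, a COST-style dark-object subtraction
in which per-band path radiance is estimated from a low percentile
(default 1%) of unmasked pixels under a 1%-reflectance dark-object
assumption. The estimator is only meaningful when the scene actually
contains near-dark targets; the test suite constructs such scenes
explicitly. DN values outside the calibrated range and negative
reflectances are flagged/warned, never silently clamped — both are
diagnostics of calibration problems that averaging would hide.

Bands are composed to RGB in red-green-blue metadata order (the
natural-color convention of the source sensors), scaled linearly to the
common 8-bit 0–255 scale shared with specimen photographs, and combined
into luminosity with the BT.601 weights (0.299, 0.587, 0.114). Buffer
extraction uses the pixel-center-in-radius rule (default radius
10 000 m, the nightly movement range of the study animal): unambiguous
and brute-force checkable. Habitat disturbance around historic
localities is handled by mask exclusion rather than by moving points —
deterministic and testable. Scenes with more than 10% masked cover are
rejected by default.

GeoTIFF I/O uses `tifffile` with the mask as an extra band and a YAML
sidecar for calibration metadata; coordinates are planar scene-local
meters throughout. No geographic CRS or reprojection is modelled: the
synthetic mode defines its own grid, and projection handling would add
ambiguity without exercising any of the statistics under study.

## Specimen photographs

White balance scales each channel by `target/reference-mean` using a
white patch, reporting the clipped fraction. Fur color is the channel
mean over a square ROI placed uniformly at random (seeded) inside the
usable-fur region, twice per specimen; ROIs must avoid excluded
rectangles (tail-adjacent dark fur, flank fur). The requested ROI side
is shrunk only when no placement exists. Specimen suitability (clean,
undusted) is a boolean input flag, not image analysis. In the synthetic
pipeline the duplicated fur values are generated directly and the image
path is exercised on constructed fixtures.

## Sequence statistics and demography

All statistics use complete deletion (columns with gaps or N dropped
alignment-wide), the common default of population-genetics packages;
per-pair deletion is available on the pairwise operations. Haplotype
diversity is `n/(n−1)(1 − Σp²)`; nucleotide diversity π is the mean
pairwise difference per retained site with the classic no-recombination
standard deviation `sqrt(b1 k̄ + b2 k̄²)/L`.

Tajima's D uses the standard a₁…e₂ constant chain. Fu's Fs computes
S′ = P(K ≥ observed haplotype count) under the Ewens sampling
distribution with θ set to the mean pairwise difference, via an exact
log-space Stirling-number recursion, and `Fs = ln(S′/(1−S′))`. Both
p-values come from neutral coalescent simulation conditional on the
corresponding θ̂ (S/a₁ for D, k̄ for Fs), one-sided as
P(stat_sim ≤ stat_obs) — the convention under which a strong positive
statistic yields p near 1.

The sudden-expansion mismatch model conditions a pair's coalescence on
the instantaneous θ₀ → θ₁ change at mutational time τ:

F_i = F̂_i(θ₁) P(i+1, τ(1+1/θ₁)) + e^{−τ(1+1/θ₁)} Σ_{j≤i} τ^{i−j}/(i−j)! F̂_j(θ₀),

with F̂ the geometric equilibrium law and P the regularized incomplete
gamma; the two limits (τ = 0 → equilibrium at θ₀, τ → ∞ → equilibrium
at θ₁) are asserted in tests. Fitting minimizes the sum of squared
deviations between observed and model class frequencies over classes
0…max-observed (no tail lumping, no renormalization), via a coarse grid
followed by bounded Nelder–Mead refinement — the SSD surface is
multimodal, and the grid step protects against the simplex settling in
a local basin. θ₁ is capped at 10⁴; estimates at the cap correspond to
the "infinite" post-expansion sizes that boundary fits report.
Goodness-of-fit p and percentile confidence intervals come from a
parametric bootstrap: coalescent datasets simulated at the fitted
parameters, each refitted, p = fraction of bootstrap SSDs at or above
the observed SSD.

The coalescent itself is the textbook exponential-times construction
with a piecewise θ (memoryless restart at the epoch boundary), in
mutational-time units where a lineage mutates at rate 1 and a pair
coalesces at rate 2/θ, so the epoch boundary sits at τ/2 and τ is on
the conventional pairwise-difference scale. Mutations are Poisson on
branch lengths under infinite sites. θ₀ = 0 collapses remaining
lineages instantly (star genealogy). An independent cross-check against
msprime (matched time scaling) is part of the test suite.

## Two-clade generator calibration

The default sequence preset encodes the study-scale conditions: 352
sites, clade sizes 72/52, clade-1 expansion (τ = 3.4, θ₀ = 1.7,
θ₁ = 24.7), clade-2 expansion (τ = 1.4, θ₀ = 1.0, θ₁ at the cap),
exactly 16 clade-diagnostic fixed differences, and a between-clade
divergence target of 0.10 per site.

The last two constraints cannot coexist in a pure pair-of-coalescents
infinite-sites model: stem mutations are either fixed differences
(breaking the count of 16) or absent (leaving Dxy ≈ 0.05 at these
demographies). Real data reconciles the two through incomplete lineage
sorting and recurrent mutation — high-frequency but unfixed variants.
The generator emulates this with *near-fixed divergence sites*: derived
in all but one random member of one clade, alternating clades. Each
contributes (n−1)/n to mean Dxy while never producing disjoint state
sets, so the fixed-difference count stays exactly at the planted 16.
The number of near-fixed sites solves
`E[Dxy]·sites = fixed + near·(n−1)/n + Σ_clades E[tip depth]`,
where the expected tip depth (one expected mutation per unit of mean
root-to-tip path, which equals the TMRCA on an ultrametric genealogy)
is estimated once by an internally seeded, cached Monte Carlo — the
preset is therefore deterministic. Mean Dxy over seeds lands within a
few percent of the target.

## Landscape and phenotype generators

The landscape is a thresholded Gaussian random field (white noise
filtered at `correlation_length/pixel_size`): the simplest two-phase
mosaic with a controllable patch scale. Sandy patches are bright,
rocky dark, with per-band means and within-patch Gaussian noise. DN
encoding inverts the exact calibration formulas, making calibration
correctness the test surface: recovery is exact up to one 8-bit
quantization step, which tests assert pixelwise. Masks are independent
random pixels at the configured fraction — cloud/water geometry is not
modelled, only the masking *rate* that the statistics see. An optional
injected path radiance is excluded from the written metadata so that
dark-object recovery can be tested plant-and-recover. A `noise_seed`
redraws only within-patch noise and mask, giving the "same place, new
acquisition" scene pairs used for repeatability checks. Defaults
(512² pixels at 120 m) coarsen the native 30 m sensor grid — buffer
statistics depend on the buffer-to-pixel ratio, not the absolute
resolution, and this keeps a whole-range scene tractable.

Fur color is linear in local environment color per channel:
intercept + slope·(env − 140) + clade-2 offset + museum offset +
residual, with duplicate measurements adding independent noise.
Channel intercepts and offsets are set so their BT.601 combination
matches the study-scale luminosity effects (intercept ≈ 131, clade
≈ −13.1, museum/field ≈ −25.4); per-channel residual and measurement
sds are the luminosity-scale sds divided by the BT.601 norm, so the
luminosity model holds exactly with the stated sds. The slope is
centered at a reference luminosity (140) purely to keep 8-bit values in
range; centering does not affect slopes, correlations or offsets. The
correlation preset solves the residual sd so that the partial
correlation controlling origin equals the target (default 0.42):
r = sσe / sqrt(s²σe² + f(1−f)Δc² + σr²), with the clade-mixing variance
in the denominator because clade is not a controlled covariate.
Specimen placement is uniform over unmasked pixels (the study gives no
within-clade spatial density); origin and clade are independent
Bernoulli draws (museum fraction 68/77, clade-2 fraction 0.4).

What the generator does *not* emulate — and hence what passing tests do
not show about real data: sensor noise and striping, spatially
structured clouds, geolocation error, clade–habitat spatial
association, phylogenetic structure in phenotypes, and recurrent or
selected mutations. The recovery results validate the estimators under
the assumed model, not the biology.

## Matching statistics

ICC is the one-way ANOVA estimator `(MSB − MSW)/(MSB + (k−1)MSW)` with
F = MSB/MSW on (n−1, n(k−1)) df; no imbalance handling (incomplete
duplicates are an input error). Partial Pearson correlation
residualizes both variables on covariates-plus-intercept;
t = r√df/√(1−r²) with df = n − 2 − #covariates. Constant covariate
columns are absorbed by the intercept and removed (with the df
adjusted), since they carry no partialling information. Color
mismatches are full-sample z-scores of fur and environment luminosity,
differenced; "relative" coloration is not otherwise defined, and
z-scoring is the admissible reading adopted here. Per-clade skewness is
the adjusted Fisher–Pearson estimator, reported absent for degenerate
clades.

Mixed models are random-intercept-per-individual linear models fitted
by maximum likelihood through statsmodels' MixedLM (ML, not REML:
REML likelihoods are not comparable across fixed-effect structures).
AIC counts fixed effects plus the random-intercept and residual
variances. The default candidate set is all subsets of {clade, origin,
env R, env G, env B, env luminosity}; factor-by-continuous two-way
interactions can be added per candidate and are only attached to models
containing both parents. Continuous environment predictors are divided
by 255, putting slopes on a reflectance-like 0–1 scale against 0–255
responses (matching the magnitude of the study-scale slopes).
Non-convergent candidates are dropped with a warning, never silently
ranked. Akaike weights are computed over all converged candidates
before any truncation of the reported table (default top 5); term
importance is the summed weight of models containing the term. No
multiple-testing correction is applied anywhere; p-values are raw.

A deliberate non-goal: the printed model-selection tables of the source
analysis are internally inconsistent (printed AICs do not equal
−2logLik + 2df for the printed values, and printed r/t/df triplets do
not satisfy t = r√df/√(1−r²)); this implementation reports the standard
formulas and does not attempt to imitate those numbers. Real-data
coefficient tables are likewise not reproducible without the original
specimens; the recovery targets are parameter-recovery statements about
the calibrated generator instead.

## Problem sizes and runtime

The recovery runs use the study-scale sizes: 77 individuals × 2
measurements (fur ICC, target 0.98), 90 scenes × 2 epochs (environment
ICC, 0.75), n = 77 correlation samples (r = 0.42), 200 seeds per
average, 200 coalescent datasets at n = 72 × 352 sites for the
expansion fit (median τ̂ against the 0.7–12.5 interval), 20/100 seeds
for the fixed-difference and divergence contracts. These sizes give
Monte-Carlo standard errors comfortably below the stated tolerances
while keeping a full recovery run under a minute on one core.

## Numerical conventions

Ties in mosaic thresholding go to sandy (≥ quantile). Buffer membership
is strict (< radius). The Ewens S′ is clipped away from {0, 1} before
the logit to keep Fs finite. Mismatch fitting requires ≥ 10 pairs; an
all-identical histogram returns the τ = 0 boundary with a warning.
Seeds: every public generator takes one explicit seed; the pipeline
derives named per-stage substreams from the top-level seed via
`numpy.random.SeedSequence.spawn`, so partial re-runs are reproducible.
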