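# camomatch

Phenotype–environment color matching over large spatial scales, rebuilt
as a tested, fully synthetic-data-driven pipeline.

The scientific question: do cryptic desert rodents (two mitochondrial
clades of African jerboas) carry dorsal fur whose color tracks the color
of their local habitat — the signature of camouflage under visual
predation? The original study answered this by combining museum/field
specimen photography, calibrated Landsat scenes, and mitochondrial
sequence data. Those raw inputs are not redistributable, so this package
couples every analysis stage to a synthetic-data generator that emulates
the study's statistical structure, making the whole chain testable end
to end.

## What it computes

* **Environmental coloration** (`rscolor`): 8-bit digital numbers →
  at-sensor radiance `L = (Lmax−Lmin)/(Qcalmax−Qcalmin)·(DN−Qcalmin)+Lmin`
  → surface reflectance
  `ρ = π(L−Lp)d² / (Tv(ESUN·cosθs·Tz + Edown))` with a COST-style
  dark-object path-radiance estimate, BT.601 luminosity
  `Y = 0.299R + 0.587G + 0.114B`, and circular-buffer zonal means
  (default radius 10 km) around specimen locations.
* **Specimen coloration** (`furcolor`): white-balance against a
  reference patch, duplicated random square-ROI fur measurements.
* **Sequence demography** (`popgen`): haplotype and nucleotide
  diversity, Tajima's D and Fu's Fs with coalescent-simulation p-values,
  mismatch distributions, least-squares sudden-expansion fits
  (τ, θ₀, θ₁) with parametric-bootstrap goodness of fit, fixed
  differences and Dxy between clades.
* **Matching statistics** (`matchstats`): one-way ANOVA intraclass
  correlation `ICC = (MSB−MSW)/(MSB+(k−1)MSW)`, partial Pearson
  correlations, per-clade standardized color-mismatch distributions, and
  random-intercept mixed models ranked by `AIC = −2ℓ + 2k` with Akaike
  weights and term importances.
* **Synthetic data** (`synthgen`): two-phase sandy/rocky reflectance
  mosaics encoded through the exact inverse of the calibration chain,
  linear fur-color phenotypes with duplicate measurement noise, and
  two-clade sudden-expansion coalescent alignments with planted
  diagnostic sites.

## Worked example

```python
import numpy as np
from camomatch import synthgen, popgen
from camomatch.matchstats import icc, partial_pearson

pheno = synthgen.phenotype_preset(r=0.42)      # study-calibrated effects
df = synthgen.generate_phenotypes(77, pheno, seed=42)

rep = icc(df[["lum1", "lum2"]].to_numpy())
fur = df[["lum1", "lum2"]].mean(axis=1).to_numpy()
origin = (df.origin == "museum").astype(float).to_numpy()
pc = partial_pearson(fur, df.env_lum.to_numpy(), origin)

aln = synthgen.generate_sequences(seed=42)
fixed, dxy = popgen.fixed_differences(aln)
c1 = aln.clade("c1")
fit = popgen.fit_sudden_expansion(popgen.mismatch_distribution(c1))
```

prints (via the obvious `print` statements):

```
fur luminosity ICC: 0.984 (F=126.6, p=5.04e-60)
fur~environment partial r: 0.259 (t=2.31, df=74, p=0.0236)
fixed differences: 16, Dxy: 0.102
clade 1 sudden-expansion fit: tau=3.26, theta0=2.01, theta1=37.2, SSD=0.0009
clade 1 diversity: n=72, haplotypes=35, S=49, H=0.97, pi%=1.34
```

Reading the numbers: duplicate fur measurements are highly repeatable
(ICC ≈ 0.98); fur luminosity correlates with habitat luminosity after
controlling for museum vs field origin (a single n = 77 sample scatters
around the generating r = 0.42 with sd ≈ 0.1 — the mean over many seeds
recovers 0.42); the two clades differ at exactly the 16 planted
diagnostic sites with ≈ 0.10 substitutions per site; and clade 1's
mismatch distribution fits a sudden demographic expansion near its
generating parameters (τ = 3.4, θ₀ = 1.7, θ₁ = 24.7).

## Command line

```bash
camomatch run --seed 1 --out-dir run1          # full pipeline + manifest
camomatch simulate --out-dir run1              # scene/specimens/sequences only
camomatch envcolor --scene run1/scene.tif --specimens run1/specimens.csv \
    --radius-km 10 --correction dos
camomatch popgen --fasta run1/sequences.fasta
camomatch fit --specimens run1/specimens.csv
```

All stages derive their randomness from the single top-level seed; the
run directory contains every intermediate artifact (GeoTIFF scene with a
YAML calibration sidecar, CSV tables, FASTA alignment) plus a
`manifest.json` with the config hash and per-stage counts.

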