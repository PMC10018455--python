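# Methods

## Overview

`plaquescope` re-implements, as one tested pipeline, the desk-side analysis
of a correlative single-section imaging experiment on amyloid plaque
pathology: trimodal MALDI mass spectrometry imaging (negative- and
positive-ion lipid mode, 400–2500 Da; linear-positive peptide mode,
1500–6000 Da, m/Δm = 1000 FWHM at m/z 4515; all at 10 μm pixel pitch)
interlaced with dual-probe LCO amyloid fluorescence microscopy (q-FTAA:
compact/mature cores; h-FTAA: diffuse amyloid) on two transgenic APP mouse
models — one forming compact plaques (tgArcSwe), one forming cored plaques
with a diffuse periphery (tgSwe).

Because no raw data of this kind are publicly deposited, the package ships
a synthetic cohort generator that plants known, recoverable structure and a
pipeline that must recover it:

1. TIC normalization of each modality;
2. bisecting k-means spatial segmentation → whole-plaque ROIs, validated
   against the h-FTAA amyloid mask (Dice ≥ 0.3) and refined into
   plaque-center ROIs;
3. per-ROI average spectra → peak/width detection → one common mass list →
   trapezoid AUC integration → accurate-mass annotation (one bin table);
4. PCA / OPLS-DA genotype discrimination with VIP ranking and Welch+BH
   univariate screens;
5. single-plaque Pearson correlation of every lipid bin with the Aβ1–40
   bin, per genotype and per ROI type, and a three-class "interplay"
   classifier on top-k membership quadruples.

## Synthetic cohort model

### Plaques

Each animal carries 4–6 plaques placed by rejection sampling, uniform over
the grid interior, with pairwise center separation > 3× the maximum radius
(capped at 10,000 attempts; the invariant only requires 2×, but 3× keeps
even dilated detected footprints of neighbouring plaques disjoint, so no
segmentation component ever covers two plaques). Plaque radius is Uniform(30, 60) μm (a
convention — plaque diameters are rarely reported), and each plaque has a
latent *maturity* m ~ Uniform(0.3, 1.0). Phenotype sets the core:
compact plaques have core_radius/radius ~ U(0.8, 0.95), cored plaques
U(0.3, 0.5).

Spatial influence uses three Gaussian kernels of distance d from the
center, each 1 at its own peak:

| kernel | form | scale |
|---|---|---|
| whole-plaque K_w | exp(−d²/2σ_w²) | σ_w = radius/2 |
| core K_c | exp(−d²/2σ_c²) | σ_c = min(core_radius, radius/2)/2.2 |
| periphery K_a | exp(−(d−r_a)²/2σ_a²) | r_a = core_radius + 0.6(radius−core_radius), σ_a = 0.07·radius |

The core scale divisor (2.2) keeps the core kernel meaningfully tighter
than the whole-plaque kernel even for compact plaques; the annulus width
(0.07·radius) keeps peripheral enrichment out of plaque-center ROIs. Both
are package conventions, configurable in code.

### Species

A species multiplies its background level B_s at each pixel by

    depleted:             1 − e·K_w
    enriched (kernel K):  1 + e·(1 + β·m)·m^γ·J_p·K

with effect size e, maturity coupling β, optional maturity exponent γ
(Aβ1–40 uses γ = 1, Aβ1–42 γ = 2, so Aβ amplitude rises monotonically —
and for Aβ1–42 core-weightedly — with maturity), and a per-plaque
log-normal jitter J_p (biological plaque-to-plaque heterogeneity beyond
maturity). Each species also rides its own smooth multiplicative tissue
texture field (correlated Gaussian field, σ = 0.05, correlation length
10 px) representing plaque-independent cortical heterogeneity.

### The default panel

The default study plants every effect the pipeline must recover (~60
annotated species + co-binned secondary pools):

* **sulfatides** ST(24:1), ST(24:0): depleted (e = 0.8/0.7) in both
  genotypes;
* **class III** ("continuous maturation"): GM1(d36:1), LPC(16:0),
  LPC(18:1) — whole-plaque enrichment coupled to maturity (β = 3) in both
  genotypes;
* **class II** ("seeding / core formation"): CerP(d36:1), PE-Cer(d38:1),
  PS(40:9) — a maturity-coupled core pool (e = 5) plus, at the same m/z,
  an independent high-variance diffuse peripheral pool (e = 26, jitter
  σ = 0.6). The diffuse pool dominates whole-plaque variation, so the
  species correlates with Aβ1–40 only in the plaque center — mimicking a
  lipid pool bound to fibrillar cores over a variable perilesional pool;
* **class I** ("plaque growth"): LPI(18:0), PI(38:4), LPE(O-16:1),
  LPC(20:4), LPC(22:6) — whole-kernel coupled in the compact genotype but
  periphery-coupled in the cored genotype, hence center-silent there;
* **five genotype-discriminative lipids** (PE(P-36:4), PA(40:6), PE(40:6),
  PS(40:6), SM(d36:1)) with strongly asymmetric abundance and no maturity
  coupling;
* **fillers** coupled in exactly one genotype and abundance-matched in the
  other (the uncoupled twin's effect size is scaled by 1 + β·E[m] = 2.95, so
  genotype means agree and they carry no VIP signal). Their counts are the
  panel's key structural choice: each of the four top-15 lists (whole/center
  × genotype) contains **exactly 15** strongly coupled species, so top-15
  membership is decided by design rather than by noise order statistics;
* **abundant background lipids and peptide-range background peaks** that
  anchor each modality's total ion current. Without them, TIC
  normalization couples all species to the plaque-enriched ones (and the
  Aβ peaks would self-normalize away their own amplitude variation).

Coupled species use β = 3 with small jitter (σ = 0.05); uncoupled species
use larger jitter (σ = 0.25). These values come from an a-priori
signal-to-noise analysis of the pooled Pearson design: with ~15 plaques
per genotype, a coupled species' expected correlation with the Aβ1–40 bin
is ≈ β·sd(m) / √(β²sd(m)² + (1+β·E[m])²σ_J²) ≈ 0.9, while uncoupled
species stay below ≈ 0.5 even including shared footprint-geometry and
TIC-normalization couplings.

### Spectra and noise

Spectra are sums of Gaussian peaks with FWHM(m) = m / 1000 (constant
resolving power, anchored at the stated m/z 4515 figure), sampled at
0.25 Da (lipid) and 1.0 Da (peptide). Instrument noise: per-peak
multiplicative log-normal (σ = 0.15), additive white Gaussian baseline
noise (σ = 0.5% of the modality's largest base abundance) over a constant
baseline offset (1%), clipped at zero. The "noiseless" configuration
switches off instrument noise only — biological jitter and tissue texture
are part of the emulated biology and remain.

The generator does **not** emulate matrix crystallization, analyte
delocalization, isotope envelopes, detector saturation, or mass-axis
miscalibration; passing tests therefore show that the analysis logic
recovers the planted statistical structure under realistic amplitude
noise, not that it is robust to every instrumental artifact of real MSI.

### Fluorescence

q-FTAA = Σ maturity·K_c per plaque; h-FTAA = Σ K_w; plus additive noise.
This encodes the probes' conformational selectivity (q-FTAA stains mature
cores, h-FTAA all amyloid) at the resolution the pipeline needs.

## Pipeline parameters

| parameter | default | rationale |
|---|---|---|
| segmentation leaves | 8 | enough depth to isolate plaque-like leaves |
| 2-means restarts | 10 (scaled up on ≤ 32-point clusters so tiny splits reach the global optimum) | fixed convention (split = largest-SSE leaf) |
| feature bins | 1 Da lipid, 5 Da peptide; top 60 per modality by spatial variance, then unit-variance scaled | SCiLS-like reduction; scaling weighs faint plaque bins and abundant background bins equally |
| plaque-leaf rule | ≥ 3 components, min ROI size (4 px) ≤ median component size < 5% of grid, leaf ≤ 10% of grid | plaque leaves fragment into several small blobs; the size guards reject noise speckle and anatomical background |
| ROI dilation | 1 px | captures the faint halo just outside the detected footprint |
| min ROI size | 4 px | one ~20 μm feature at 10 μm pitch |
| LCO validation | Dice ≥ 0.3 vs overlapping h-FTAA components | pipeline convention; no published value exists |
| center ROI | concentric, fraction 0.35 of the equivalent radius (area ≈ 12%) | tight enough to isolate cored-plaque cores; q-FTAA-mask mode available |
| peak SNR threshold | 5 (pipeline), estimator 1.4826·MAD(Δy)/√2, height above median baseline | suppresses white-noise local maxima on ROI averages |
| border fraction | 0.05 of apex height | peak borders at 5% height (≈ ±2.45σ) |
| bin merge overlap | 0.25 of the smaller interval | |
| annotation tolerance | 0.3 Da lipid, 2 Da peptide | linear-mode FWHM is ~4 Da |
| scaling | autoscale (unit variance) | the common metabolomics default |
| OPLS-DA | 1 orthogonal component, ±1 class encoding | two-class contrast only |
| multiple testing | Benjamini–Hochberg | standard for bin-wise families |
| top-k | 15 | the "top 15" convention used throughout |

## Numerical choices

* Bins are half-open [lo, hi) structurally; integration treats hi as
  included and interpolates linearly at borders, making AUC exactly
  additive over interior splits.
* Bisecting k-means asserts the leaf-partition invariant after every
  split, stops early (with a warning) when no leaf has two distinct rows,
  and derives per-split seeds from one root seed.
* VIP ties rank by ascending column (mass) order; correlation ties
  likewise.
* Zero-TIC pixels are kept (all-zero) so grids stay rectangular; zero-
  variance columns are centered-only and flagged, and are excluded from
  correlation ranking.
* Welch tests with NaN statistics (identical groups) report t = 0, p = 1.
* All cohort randomness descends from a single integer seed through
  `numpy` SeedSequence spawning; per-stage pipeline seeds are derived by
  SHA-256 of (seed, stage name, index).

## Design decisions that were genuinely open

* **Center ROIs**: the published analysis never quantifies "plaque
  center". Default is the concentric fraction; an alternative mode
  intersects the whole-plaque ROI with the q-FTAA core mask. The
  concentric mode proved more stable because global Otsu thresholds on the
  q channel make mask size track core brightness.
* **Class-I laterality**: which genotype keeps the center correlation is a
  declared attribute of the genotype (compact ⇒ center-coupled), not
  inferred from data.
* **Pooling**: correlations pool plaques across a genotype's animals
  (the per-animal-average alternative is available via the table's
  metadata).
* **Ranking sign**: top-k lists use signed descending Pearson r;
  magnitude ranking is available behind a flag.

## Problem sizes

Default study: 2 genotypes × 3 animals × 4–6 plaques on 200×200 px grids,
~60 annotated species across three modalities; one full cohort analysis
runs in roughly five minutes and under ~4.5 GB on one CPU core. Unit tests
use 32–96 px grids and reduced panels.

## Known limitations

* The interplay classifier's zero-noise identity depends on the panel's
  exact-15 list design; panels with different counts of coupled species
  per list will show borderline membership churn at the k-th rank.
* Correlations at n ≈ 15 plaques per genotype carry sampling error of
  ±0.25 (Fisher); planted-class recovery is designed with ~2σ margins,
  not guaranteed for every seed.
* Welch/BH univariate screens treat plaques as independent observations,
  as is conventional when plaques are the unit of analysis; animal-level
  random effects are not modelled.
* imzML IO supports continuous mode natively and resamples processed-mode
  files onto the first spectrum's axis; vendor raw formats are out of
  scope.
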