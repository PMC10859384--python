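# Methods

## Data model

All spectra live on a shared, strictly ascending wavenumber grid; the
canonical instrument grid spans 769–1801 cm⁻¹ at a 2 cm⁻¹ step
(517 points, odd wavenumbers). File readers sort descending or shuffled
input into this order and record the original order in metadata.
Intensities are in arbitrary units (a.u.); every preprocessing step is
per spectrum, so absolute scale never matters downstream.

## Preprocessing

* **SNV** (standard normal variate): per-spectrum centering and scaling to
  unit sample (n−1) standard deviation. Removes multiplicative scatter;
  `snv(a·x + b) = snv(x)` for any a > 0. Constant spectra are a
  degenerate-input error, never silently zeroed.
* **Savitzky–Golay**: polynomial order 3, 7 side points (15-point window)
  by default. Edges are mirror-reflected, which preserves length without
  extrapolating a trend; the filter passes polynomials up to its order
  through unchanged wherever the window sits fully inside the data.
  Mirror extension of a polynomial is not itself that polynomial, so
  edge points deviate slightly — the price of not fabricating a trend.
* **Baseline**: asymmetric least squares (smoothness `lam`, asymmetry `p`,
  `n_iter` reweighting passes; defaults 1e5 / 0.01 / 10). The weights are
  `p` above and `1−p` below the current baseline, so the smooth curve hugs
  the low envelope. This is a standard, fully parameterized replacement
  for the instrument vendor's closed single-knob baseline control; no
  attempt is made to reproduce the vendor's numeric output. Applying the
  correction twice changes the result by well under 5% of its range.
* **Min–max**: linear scaling to [0, 1], used before correlation
  comparison in the point-spectrum identification chain.

The conventional identification chain is smoothing → baseline → min–max;
model training uses SNV alone. A `PreprocessSpec` serializes the exact
chain with every parameter explicit, and travels inside each saved model.

## Correlation identification

Per particle, up to three spot spectra are preprocessed and correlated
against the preprocessed parent-plastic reference. Decision rule: any
r > 0.7 → MP; otherwise max r in [0.6, 0.7] → manual review; otherwise
non-MP. Both boundaries are strict (r exactly 0.60 or 0.70 lands in the
review band) — the literal reading of the thresholds. Fewer than three
spots are accepted with a logged warning, since small particles may not
offer three distinct spots. The correlation runs over the full grid by
default; an option restricts it to the selected discriminative
wavenumbers. The 0.6–0.7 band encodes a human judgment step and is
surfaced only as a flag.

## SVM discrimination and wavenumber selection

The discriminator is a linear-kernel soft-margin SVM (hinge loss, C = 1 by
default). Only a linear kernel yields the per-wavenumber weight vector
that coefficient-based feature importance requires; importance is
`|w_j|`, with signed weights retained for plotting. No feature scaling
beyond per-spectrum SNV is applied, so the importance profile is not
distorted by a second normalization.

The train/test split is stratified: per class, `floor(2/3 · n)` rows to
training, remainder to test, shuffled by a seeded generator. On class
sizes 1038/1052 this gives 692/701 training and 346/351 test rows. (The
published performance table for this problem implies a 715-spectrum test
set, which is inconsistent with a two-thirds split of 2090; the
convention here is ours and documented.)

Selection is greedy: wavenumbers are visited in descending importance and
accepted if at least `min_separation` (default 20 cm⁻¹) from every
already-accepted pick, until k (default 4) are found. The separation
constraint prevents one broad band from contributing two adjacent grid
points. With `min_separation = 0` this reduces to plain top-k.

**Reduced-model features.** A DFIR application pixel carries only the k
channel intensities, so the reduced model's default `vector_snv` feature
mode defines its features identically in development and application:
extract the raw intensities at the k wavenumbers, then SNV across that
short vector. The alternative `prep_extract` mode (full-spectrum SNV, then
extract) matches the full model's feature scale but does not transfer to
pixel vectors — applying such a model to images is a train/apply mismatch
that costs roughly 40 accuracy points on synthetic scenes, and
`classify_pixels` warns loudly when it detects it.

`metrics_from_counts` computes sensitivity, specificity, CCR (percent) and
MCC from a confusion matrix with MP as the positive class; MCC with a zero
denominator factor is reported as undefined, never as a silent 0. Display
rounding is CCR to 2 decimals, the rest to 4. `reconstruct_confusion`
inverts printed summary figures: it enumerates integer class totals whose
recomputed sensitivity/specificity round to the printed 4-decimal values,
using a printed CCR to break ties, and refuses ambiguous or inconsistent
inputs rather than guessing.

## DFIR imaging

Stacks are (channels × height × width) with one intensity image per
selected wavenumber, 2 µm pixels, default region 240 × 320 px
(480 × 640 µm). Coordinates are row-major, origin top-left, 0-based.
Channel-wise min–max normalization exists for display only; classification
normalizes each pixel's channel vector per the model's feature mode.

Segmentation takes connected components of the mask (8-connectivity
default; at 2 µm pixels any real particle ≥ 5 µm spans several pixels, so
components under `min_pixels = 2` are discarded as noise). Ids are
assigned in raster-scan order of each component's first pixel. A
particle is MP iff its MP pixels strictly outnumber non-MP pixels; ties go
to non-MP, the conservative choice against false positives.

Morphometry uses the moment-equivalent ellipse: axis lengths are
4√(eigenvalue) of the normalized second central moment matrix, scaled to
µm. Circularity is 4π·area/perimeter² with the weighted contour-length
perimeter estimator, computed in pixel units (hence exactly scale-free)
and capped at 1.0, since discretization can push small blobs above 1.
Degenerate shapes (single pixels, one-pixel-wide lines) floor both axes at
one pixel size — a pixel has physical extent — and a single pixel reports
circularity 1.

## Filter quantification

The default layout is a 25 mm filter whose outer 2.5 mm polypropylene ring
is dead space (active diameter 20 mm), subsampled by nine 480 × 640 µm
regions on a centered 3 × 3 grid. Geometric coverage is
9 · 0.3072 mm² / 314.159 mm² = 0.880%; a `coverage_override` (e.g. 0.0087
to match an externally stated 0.87%) replaces the geometric value and logs
a warning. Whole-filter totals divide subsample counts by coverage;
replicates are the unit of uncertainty, and reported spreads are replicate
standard deviations scaled by the same positive factors as the means (no
Poisson correction). Per-unit values divide by the number of source items
(e.g. three teabags per filter) and are reported to one decimal.

The representativeness check models reference microspheres as solid
spheres (density 1.13 g/cm³, supplier diameter range 15–20 µm; mass uses
the 17.5 µm midpoint unless overridden): mass = count · ρ · πd³/6. The
estimated-to-nominal mass ratio flags > 1 as overestimation.

Treatment comparisons on MP/All ratios use the paired t test for
before/after measurements of the same regions and Welch's unequal-variance
t test for independent groups, two-sided, α = 0.05.

Note an arithmetic fact the quantification makes visible: a subsample
count of 8.7 at 0.87% coverage extrapolates to ≈1000, so externally quoted
pairings of these figures with a total of 319 are mutually inconsistent;
the package implements the stated formula and takes no side.

## Synthetic data generator

The generator emulates the structure of an O-PTIR particle-spectra
database; no public one exists for this problem. Three class templates:

| class        | bands (center cm⁻¹, σ, amplitude) |
|--------------|------------------------------------|
| MP (nylon)   | 1635, 8, 1.00 (amide I); 1541, 8, 0.85 (amide II); 1464, 7, 0.15; 1416, 7, 0.12; 1370, 7, 0.10 |
| non-MP I     | 1740, 12, 1.00 (sharp carbonyl) |
| non-MP II    | 1077, 25, 0.90 (broad C–O region) |

A spectrum is (jittered band sum + weak linear baseline) × multiplicative
scatter factor U(0.7, 1.3), plus iid Gaussian noise (σ = 0.05 a.u.). Each
band's amplitude is additionally jittered by U(0.8, 1.2) per spectrum,
emulating composition variation between particles; this decorrelates the
bands so the SVM spreads weight over every discriminative band rather than
leaning on the amide channels alone. Band shape is Gaussian — adequate for
exercising the pipeline, configurable where it matters.

Design note on the type-II width: the emulated feature is a broad
1000–1200 cm⁻¹ band, and σ = 25 (FWHM ≈ 59 cm⁻¹) keeps it by far the
broadest feature while keeping wavenumber selection well-posed. At much
larger widths the SVM weight profile across the band becomes so flat near
its apex that the selected grid point wanders tens of cm⁻¹ under noise —
the argmax of a near-plateau is not a stable statistic — and
planted-band recovery to ±10 cm⁻¹ would fail for any classifier, not from
a defect of the selection rule.

Amplitudes were chosen so the four planted centers (1635, 1541, 1740,
1077 cm⁻¹) are the dominant class-contrast features; the selection
pipeline recovers all four to ±10 cm⁻¹ in ≥ 18 of 20 seeds, with the
carbonyl pick landing on the flank grid points (1737–1741). Noise-free
templates correlate pairwise below 0.6, so the correlation rule also
separates the classes.

Scenes rasterize non-overlapping disks/ellipses/rectangles into the
default region; particle pixels carry the class template evaluated at the
channel wavenumbers with per-pixel scatter jitter plus noise, background
carries a flat level plus noise. Ground-truth label maps use the same
raster-order id convention as segmentation. Filter experiments place
particles uniformly on the active disk by rejection sampling and count
them inside the layout rectangles.

What the generator does *not* emulate: photothermal signal physics,
instrument drift, water-vapor interference, Lorentzian/Voigt line shapes,
particle stacking or overlap, filter texture, or the spectral effects of
alcohol/temperature treatments. Passing tests therefore demonstrate the
correctness and internal consistency of the algorithms under the stated
noise model, not instrument-level performance on real filters.

## Problem sizes and determinism

Default test/acceptance scales: 600 spectra per class for training runs
(20 seeds for the property checks), 10 scenes × 20 particles for scene
accuracy, 100,000 planted particles × 20 seeds for the extrapolation
round trip. All randomness flows through seeded NumPy generators; the SVM
fit (libsvm, linear kernel) is deterministic, so identical configuration
and seed reproduce models, scenes and reports bit for bit.

## Known limitations

* Binary MP/non-MP only; extending to multi-polymer classification would
  need a multi-class decision rule and per-class wavenumber selection.
* The manual-masking step of real workflows is replaced by a global
  threshold utility; no optical-image registration is attempted.
* The MCC/CCR reconstruction utility assumes the printed figures were
  rounded (not truncated) at the stated precision.
* Replicate-based uncertainty understates error when only one filter is
  measured; no Poisson term is added.
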