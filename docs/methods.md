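# Methods

This note documents the models, operational definitions, defaults and
numerical choices behind each stage, and what the synthetic generators do
and do not emulate.

## OCTA vessel morphometry

An en-face angiogram is a calibrated 2-D intensity grid in [0, 1] for one
plexus (SVP, ICP or DCP) of one eye, with µm/px scales and a device
signal-strength Q score on a 0–40 scale supplied as sidecar metadata (the
device does not expose its calibration in the image file). Eyes with
Q < 30 are excluded before any metric is computed; the threshold is strict,
so Q = 30 passes.

**Binarization.** The source descriptions say only that images are
"automatically converted" to binary; the default here is a global Otsu
threshold with no pre-filtering — the most common published choice for
en-face OCTA — selectable via `binarize_method` ("otsu", "mean", "fixed").
Vessels are internally always the foreground (true) class; display polarity
is handled at read time by `bright_is_vessel`. A constant image has no
histogram to split and is rejected.

**Skeletonization** is morphological thinning to one-pixel-wide,
8-connected centerlines (scikit-image); connected components of the mask
remain connected.

**Metrics.** VAD = vessel pixels / total pixels; VLF = skeleton pixels /
total pixels (so VLF ≤ VAD always); VDI = vessel pixels / skeleton pixels
× µm/px — the average caliber, area per unit centerline length (the
defining formula is stated explicitly because the sources name the quantity
but not the formula); FD = ordinary-least-squares slope of log N(s) versus
log(1/s), where N(s) counts occupied boxes of side s over a ladder of
powers of two from 2 px to a quarter of the shorter image side, boxes
anchored at the origin. At least three ladder points are required. FAZ area
is the shoelace area of a user-traced simple polygon × scale_x × scale_y,
in mm²; tracing is manual in practice, so no automatic FAZ segmentation is
attempted.

## Hyperreflective foci

Counting is restricted to the central 3 mm of a linear B-scan
(window closed at both ends: a center at exactly ±1.5 mm is included, with
a half-pixel tolerance reflecting the pixel-center convention).

**Detection.** A per-band background model (median reflectivity between
consecutive segmentation markers — robust to the foci themselves) is
subtracted; the residual is median-filtered (3×3) against speckle, and a
Laplacian-of-Gaussian ladder with anisotropic sigmas (axial and lateral
scales differ) spanning 10–60 µm equivalent diameters returns bright local
maxima. Diameter is estimated as 2√2·σ at the response peak. Nested
multiscale detections are reduced to the largest blob (sum-of-radii
criterion). Each candidate carries a *contrast*: its peak height above the
band background, read off an extra Gaussian-smoothed (σ = 1 px) residual —
a real focus is a deterministic plateau and survives smoothing, a speckle
bump does not. The detection ladder deliberately extends above the
counting cap so oversized foci are seen and rejected rather than missed.

**Criteria filter.** A candidate is counted iff
(a) estimated diameter ≤ 30 µm — with an isolation check that the residual
on a ring at 1.5× the estimated radius has fallen below half the peak
contrast, which rejects small satellite detections riding inside an
oversized bright spot;
(b) mean reflectivity within [0.8, 1.2] × the RNFL band mean of the same
scan ("moderate, similar to RNFL"; the tolerance is a config key);
(c) shadow score ≥ 0.8, where the score is the mean intensity of the
column strip from just below the focus down to the RPE/Bruch's-membrane
boundary divided by the same strip in flanking columns (offset one focus
width plus 3 columns); grading of shadowing is visual in practice, so the
threshold is a config key;
(d) contrast ≥ 0.15 above the band background.

**Compartments.** The inner retina is, by default, ILM to the lower IPL
border and the outer retina the upper ONL limit to RPE/BM (the convention
of the illustrated counting figure, which is self-consistent); the
alternative textual convention (INL to lower OPL) is available via
`hrf_ir_convention = "text"`. Candidates in neither compartment are
discarded. Diameter is the maximum (equivalent) diameter, the direction of
measurement being unstated in the sources.

On 50 synthetic scans at the default conditions the caller reaches recall
and precision ≈ 1.0 with exact compartment assignment and rejects all
planted oversized and shadowed foci (see `tests/test_acceptance.py`).

## ETDRS thickness

The 11 segmentation markers bound, from vitreous to choroid: RNFL, GCL,
IPL, INL, OPL, ONL and the composite outer retinal layer ORL (ELM through
RPE/BM). Per sample, a layer's thickness is the row distance between its
bounding markers times the axial scale; the seven layers telescope, so
their sum reproduces the ILM-to-RPE/BM total exactly. Boundaries that
cross at any column raise an error naming the column.

Sectors: C1 for radius < 0.5 mm, inner ring to 1.5 mm, outer ring to 3 mm
inclusive, quadrants split at the ±45° diagonals (the boundary diagonal
belongs to the counterclockwise-following quadrant; nasal/temporal swap
with laterality, default right eye). Per layer the summaries are the C1
mean (total/central thickness) and the ring mean over the eight quadrant
values. A single horizontal line scan samples only C1 and the
nasal/temporal quadrants; unsampled sectors are NaN and the ring mean
averages what is available. Full nine-sector maps come from volume
boundary surfaces (`layer_thickness_volume`).

## mfERG

Features per trace: baseline = mean of the first 10 ms; N1 = minimum in
10–45 ms; P1 = maximum in (N1-IT, 60 ms]. N1 amplitude is
isoelectric-to-trough (positive), P1 amplitude trough-to-peak. The search
windows and baseline length are not dictated by any acquisition standard
exposed to us; the defaults reflect typical first-order kernel morphology
and are config keys.

By default the cursor reading initializes a least-squares fit of the
biphasic template c₀ − a·g(t; µ₁, w) + b·g(t; µ₂, w) (Gaussian lobes,
shared width fixed at the canonical 6 ms; set `mferg_fit_width_ms = 0` to
fit the width) and features are read off the fitted curve's extrema on a
dense grid. The fitted isoelectric level c₀ replaces the 10 ms baseline in
the amplitude measurement because the N1 upslope leaks into the baseline
window and would bias it. A zero-phase low-pass at the 300 Hz upper
recording-band edge is applied first. The fit brings P1-IT recovery at
SNR 10 (amplitude / noise SD) to within one sample in ≈98% of traces,
close to the Cramér–Rao bound; plain cursor extraction
(`mferg_refine = "cursor"`) is retained for transparency.

Ring summaries average each ring's traces before extracting features (how
clinical systems present ring responses); feature-averaging is available.
The normative database stores per-hexagon mean and sample SD (ddof = 1) of
P1-IT and P1 amplitude over the run's own control eyes (≥ 2 required; zero
variance is an error). Abnormality: z(P1-IT) ≥ 2 **or** z(amplitude) ≤ −2,
both inclusive; the criteria are listed without a connective in the
sources, so the inclusive OR is the default and AND is a config option.
Which amplitude enters the rule is likewise unstated; P1 amplitude (the
analyzed feature) is used, N1 switchable. An eye is abnormal iff at least
one of the 19 central hexagons is.

## Cohort statistics

Measurements are replicated in fellow eyes, which are not independent. The
default collapses eyes to patient means before a one-way ANOVA — a
conservative reduction with exact type-I control under any within-patient
correlation — and the eye-level ("naive") ANOVA is reported alongside, both
labeled, because the exact repeated-measures formulation used in practice
varies by software. Pairwise contrasts are two-sample t-tests with
Bonferroni adjustment over the three group contrasts
(p_adj = min(1, 3p)); metrics are *not* jointly corrected across metrics.
With two groups the omnibus F equals t². The correlation screen is OLS of
y on x with t = slope/SE on n−2 df, two-sided.

## Synthetic data

**Vessel networks** grow as correlated random walks from edge and interior
seeds (unit-pixel steps, Gaussian turning angle of SD 1 − persistence,
branching at ±~60°), rasterized as disks of fixed caliber, until the
vessel-pixel fraction reaches the target density. Walks are self-avoiding
at the vessel scale via a walker-territory grid; on contact a vessel
anastomoses into its neighbour rather than stopping short, so vessels do
not silently merge into blobs. Ground truth: the exact mask and density;
`centerline_length_px` = distinct rasterized centerline pixels (excluding
the 1-px merge zone around a foreign centerline, which contributes no
skeleton length of its own) — the centerline's length in the same pixel
units a skeleton count uses, which step-counting would overstate by
15–20% at oblique angles; `mean_caliber_px` = exact drawn area per unit
centerline length (square rasterization makes oblique ribbons wider than
the nominal stamp). In `respawn=False` mode growth ends when the initial
walkers and their branches terminate, so density and skeleton complexity
rise with branch probability — the regime in which fractal dimension
increases with branching. Defaults (256 px, ≈3×3 mm at 5.86 µm/px, caliber
3 px, target density 0.34/0.30/0.32 for SVP/ICP/DCP in cohorts) reflect
typical en-face parafoveal values.

**B-scans** are flat reflectivity bands bounded by the 11 markers (typical
parafoveal stack, ~315 µm retina) with multiplicative gamma speckle
(shape 4). The default speckle level of 0.3 (~15% intensity SD) emulates a
frame-averaged acquisition, in which averaging ~100 registered frames
strongly suppresses single-frame speckle; fully developed speckle is
level 1. Foci are elliptical disks (axial/lateral scales 3.9/5.7 µm/px):
"moderate" reflectivity equals the RNFL band mean, "high" (a rejection
case) 1.5× it; a shadowed focus halves everything below it down to
Bruch's membrane. Curved boundaries and a foveal pit are not modeled —
thickness tests use planted boundary surfaces instead.

**mfERG traces** are two Gaussian lobes of width 6 ms whose centers and
coefficients are Newton-calibrated so the noise-free minimum is exactly
−N1-A at N1-IT and the trough-to-peak range exactly P1-A at P1-IT
(compensating the cross-pull of overlapping lobes), plus white noise.
Amplitudes scale as 1/ring with eccentricity; only the relative structure
matters for the tests. Control-group normals (P1-IT ≈ 30 ms, ring-1
P1-A ≈ 80 nV/deg², N1 at 15 ms with half the P1 amplitude) are
conventional first-order kernel values, not measured normals.

**Cohorts** give each patient two eyes sharing a Gaussian multiplier
(SD 5%) on all metrics, plus 2% eye-level noise. Planted effects mirror
the qualitative pattern the analysis targets: diabetics without
retinopathy get reduced SVP density (×0.85), reduced SVP branching, a
+2 ms P1-IT delay and +3 mean HRF; the mild-retinopathy group gets the
ICP reductions, +1 ms and +3 HRF. `simulate_metric_cohort` draws a single
metric with the same hierarchical structure without rendering images — the
fast path for calibration/power studies of the statistics stage (null
rejection ≈ α over 50 replicates; the 15% SVP reduction at 11
patients/group is detected in ≈100% of replicates).

## What passing tests do and do not show

The generators emulate the statistical structure the analysis assumes —
two-level variance, plexus-specific multiplicative effects, eccentricity
scaling, band-limited biphasic waves, speckle — not device physics: no
flow decorrelation, projection artifacts, motion, curved anatomy, media
opacity, or fixation loss. Recovery results therefore validate the
algorithmic chain (binarize → skeletonize → metrics; detect → criteria →
count; extract → z-classify; ANOVA calibration), not robustness to
acquisition pathology. Problem sizes in the test suite and acceptance
script (256 px angiograms, 224×640 B-scans, 20–50 replicates) were chosen
as the smallest at which the targeted properties are statistically stable.

## Known limitations

- Otsu binarization assumes a bimodal histogram; very low-density or
  low-contrast angiograms may need the "fixed" method.
- The HRF contrast criterion (0.15) presumes focus/background reflectivity
  separation of the magnitude seen in the band model; scans with much
  heavier speckle need a recalibrated threshold.
- The template-based mfERG refinement assumes a biphasic morphology;
  multifocal responses with prominent N2 may fit poorly, in which case the
  cursor mode is the fallback (the extractor falls back automatically on
  fit failure).
- Patient-mean clustering discards between-eye information; it is
  conservative by design.
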