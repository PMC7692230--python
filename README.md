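# retimetrics

Quantification pipeline for early retinal changes in diabetes, combining
three modalities the way morpho-functional studies of diabetic retinopathy
do:

- **OCTA vessel morphometry** — en-face angiograms of the superficial
  (SVP), intermediate (ICP) and deep (DCP) capillary plexuses are
  binarized and skeletonized, yielding vessel area density
  (VAD = vessel pixels / total pixels), vessel length fraction
  (VLF = skeleton pixels / total pixels), vessel diameter index
  (VDI = vessel area / skeleton length × µm/px, the mean caliber),
  box-counting fractal dimension of the skeleton
  (FD = slope of log N(s) vs log 1/s), and the foveal avascular zone area
  from a traced polygon. Scans with a signal-strength Q score below 30
  (0–40 scale) are excluded.
- **Hyperreflective foci (HRF)** — small bright intraretinal spots on a
  structural B-scan, counted in the central 3 mm separately for the inner
  and outer retina. A blob is counted only if its maximum diameter is
  ≤ 30 µm, its reflectivity is moderate (within ±20% of the retinal nerve
  fiber layer band), and it casts no back-shadow.
- **ETDRS layer thickness** — seven retinal layers (RNFL, GCL, IPL, INL,
  OPL, ONL, ORL) summarized over the standard nine-sector ETDRS grid
  (1/3/6 mm rings); per layer the central 1 mm mean and the mean of the
  eight ring quadrants are reported.
- **mfERG** — N1/P1 implicit times (ms) and amplitudes (nV/deg²) extracted
  from the 103 hexagon first-order responses, summarized over six
  concentric rings; the 19 central hexagons are classified against a
  control normative database: a hexagon is abnormal when z(P1-IT) ≥ 2 or
  z(amplitude) ≤ −2, and an eye is abnormal when at least one central
  hexagon is.
- **Cohort statistics** — three-group (control / diabetic without
  retinopathy / mild retinopathy) comparisons with fellow eyes collapsed to
  patient means, one-way ANOVA, Bonferroni-adjusted pairwise contrasts, and
  an OLS correlation screen (Student t on the regression slope) between
  OCTA parameters and HRF counts.

A fully tested synthetic-data subpackage (`retimetrics.synth`) generates
every input with known ground truth — self-avoiding branching vessel
networks, layered speckled B-scans with planted foci, biphasic mfERG
waveforms, and three-group cohorts with planted plexus-specific effects —
so the whole pipeline is verifiable without patient data.

## Worked example

```python
from retimetrics import octa
from retimetrics.synth import generate_vessel_network

angiogram, truth = generate_vessel_network(
    size_px=256, seed=7, target_density=0.35, noise_level=0)
metrics = octa.compute_all_metrics(angiogram)
print(f"VAD {metrics.vad:.4f}  (planted density {truth.density:.4f})")
print(f"VLF {metrics.vlf:.4f}  VDI {metrics.vdi_um:.1f} µm  FD {metrics.fd:.3f}")
```

prints

```
VAD 0.3500  (planted density 0.3500)
VLF 0.0895  VDI 22.9 µm  FD 1.549
```

The measured VAD equals the planted vessel-pixel fraction exactly on a
noise-free image; the VLF says ~9% of pixels are centerline; the VDI of
22.9 µm at 5.86 µm/px matches the generator's drawn mean caliber
(≈3.9 px — square rasterization makes oblique vessels slightly wider than
the nominal 3 px stamp); and an FD of 1.55 is typical of a
moderately-branched parafoveal network.

An end-to-end run over a synthetic cohort:

```sh
retimetrics synth --out-dir cohort --n-per-group 4 --seed 1
retimetrics all --manifest cohort/manifest.csv --out-dir results
```

which writes `metrics.csv` (one row per eye), `comparisons.csv` (ANOVA +
Bonferroni pairwise p per metric, both patient-mean and eye-level
clustering), `correlations.csv`, and a JSONL run log. Single-stage
subcommands `octa`, `oct`, `mferg`, `stats` operate on individual files;
see `retimetrics --help`.

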