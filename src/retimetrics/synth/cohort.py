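"""Three-group synthetic cohorts with planted plexus-specific effects.

Each patient contributes two eyes that share a patient-level Gaussian
multiplier (SD 5% by default) on all metrics — the within-patient
correlation the repeated-measures analysis must tolerate. Group effects are
multiplicative on per-plexus vessel density and branching, additive on the
P1 implicit time, and additive on the Poisson means of the planted
hyperreflective-focus counts. Defaults plant the qualitative pattern the
analysis is meant to detect: reduced superficial-plexus metrics and delayed
implicit times without retinopathy, reduced intermediate-plexus metrics
with retinopathy, and elevated focus counts in both diabetic groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .. import io as rio
from ..types import GROUP_LABELS, PLEXUS_LABELS, CohortManifest
from .bscan import FocusSpec, generate_bscan
from .traces import default_wave_truth, generate_traceset
from .vessels import generate_vessel_network


@dataclass
class GroupEffects:
    """Planted effects of one group relative to controls."""

    vessel_density_mult: dict[str, float] = field(default_factory=dict)
    vessel_branch_mult: dict[str, float] = field(default_factory=dict)
    p1_it_shift_ms: float = 0.0
    hrf_rate_shift: float = 0.0

    def __post_init__(self) -> None:
        for d in (self.vessel_density_mult, self.vessel_branch_mult):
            if any(v <= 0 for v in d.values()):
                raise ValueError("multipliers must be > 0")

    def density_mult(self, plexus: str) -> float:
        return self.vessel_density_mult.get(plexus, 1.0)

    def branch_mult(self, plexus: str) -> float:
        return self.vessel_branch_mult.get(plexus, 1.0)


@dataclass
class EffectSpec:
    """Per-group planted effects; controls are the implicit reference."""

    noDR: GroupEffects = field(default_factory=lambda: GroupEffects(
        vessel_density_mult={"SVP": 0.85},
        vessel_branch_mult={"SVP": 0.6},
        p1_it_shift_ms=2.0,
        hrf_rate_shift=3.0,
    ))
    DR: GroupEffects = field(default_factory=lambda: GroupEffects(
        vessel_density_mult={"ICP": 0.85},
        vessel_branch_mult={"ICP": 0.6},
        p1_it_shift_ms=1.0,
        hrf_rate_shift=3.0,
    ))

    @classmethod
    def identity(cls) -> "EffectSpec":
        return cls(noDR=GroupEffects(), DR=GroupEffects())

    def of(self, group: str) -> GroupEffects:
        if group == "control":
            return GroupEffects()
        return getattr(self, group)


#: control-group baseline conditions
BASE_DENSITY = {"SVP": 0.34, "ICP": 0.30, "DCP": 0.32}
BASE_BRANCH_PROB = 0.02
BASE_CALIBER_PX = 3.0
BASE_HRF_MEAN = {"IR": 4.0, "OR": 2.0}
PATIENT_EFFECT_SD = 0.05
EYE_NOISE_SD = 0.02


def generate_cohort(
    out_dir: str | Path,
    n_per_group: int = 2,
    effects: EffectSpec | None = None,
    seed: int = 0,
    image_size: int = 256,
    bscan_size: tuple[int, int] = (224, 640),
    patient_effect_sd: float = PATIENT_EFFECT_SD,
) -> tuple[CohortManifest, pd.DataFrame]:
    """Write a full synthetic cohort to ``out_dir``.

    For every patient (two eyes per patient, ``n_per_group`` patients per
    group) this writes three per-plexus angiograms, a B-scan with planted
    compliant foci, and an mfERG trace set, in exactly the formats the
    readers consume, plus ``manifest.csv`` and a ``truth.csv`` table keyed
    by eye_id holding every planted quantity.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    effects = effects or EffectSpec()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    manifest_rows = []
    truth_rows = []
    for gi, group in enumerate(GROUP_LABELS):
        eff = effects.of(group)
        for pi in range(n_per_group):
            patient_id = f"{group}_p{pi:02d}"
            patient_mult = float(rng.normal(1.0, patient_effect_sd))
            patient_mult = max(patient_mult, 0.5)
            for eye in ("OD", "OS"):
                eye_id = f"{patient_id}_{eye}"
                eye_dir = out_dir / eye_id
                eye_dir.mkdir(exist_ok=True)
                eye_seed = int(rng.integers(0, 2**31 - 1))
                eye_rng = np.random.default_rng(eye_seed)
                truth = {"eye_id": eye_id, "patient_id": patient_id,
                         "group": group, "eye": eye,
                         "patient_mult": patient_mult}

                angio_paths = {}
                for plexus in PLEXUS_LABELS:
                    target = (BASE_DENSITY[plexus] * eff.density_mult(plexus)
                              * patient_mult
                              * (1.0 + eye_rng.normal(0.0, EYE_NOISE_SD)))
                    target = float(np.clip(target, 0.05, 0.55))
                    branch = BASE_BRANCH_PROB * eff.branch_mult(plexus)
                    angio, vt = generate_vessel_network(
                        size_px=image_size,
                        seed=int(eye_rng.integers(0, 2**31 - 1)),
                        branch_prob=branch,
                        caliber_px=BASE_CALIBER_PX,
                        target_density=target,
                        plexus=plexus, eye_id=eye_id,
                    )
                    path = eye_dir / f"angio_{plexus.lower()}.tif"
                    rio.write_angiogram(angio, path)
                    angio_paths[plexus] = path
                    truth[f"density_{plexus}"] = vt.density
                    truth[f"length_{plexus}"] = vt.centerline_length_px
                    truth[f"branches_{plexus}"] = vt.branch_count

                n_ir = int(eye_rng.poisson(
                    max(BASE_HRF_MEAN["IR"] * patient_mult
                        + eff.hrf_rate_shift, 0.0)))
                n_or = int(eye_rng.poisson(
                    max(BASE_HRF_MEAN["OR"] * patient_mult
                        + eff.hrf_rate_shift / 2.0, 0.0)))
                foci = _place_foci(n_ir, n_or, eye_rng)
                bscan, _ = generate_bscan(
                    size_px=bscan_size, foci_spec=tuple(foci),
                    seed=int(eye_rng.integers(0, 2**31 - 1)), eye_id=eye_id,
                )
                bscan_path = eye_dir / "bscan.tif"
                bounds_path = eye_dir / "boundaries.csv"
                rio.write_bscan(bscan, bscan_path, bounds_path)
                truth["hrf_ir"] = n_ir
                truth["hrf_or"] = n_or

                p1_shift = eff.p1_it_shift_ms + float(eye_rng.normal(0.0, 0.5))
                wave = default_wave_truth(
                    p1_amp_r1=80.0 * patient_mult
                    * (1.0 + eye_rng.normal(0.0, EYE_NOISE_SD)),
                    p1_it_shift_ms=p1_shift,
                    noise_sd=2.0,
                )
                ts = generate_traceset(
                    wave, seed=int(eye_rng.integers(0, 2**31 - 1)),
                    eye_id=eye_id)
                traces_path = eye_dir / "traces.csv"
                geometry_path = eye_dir / "geometry.csv"
                rio.write_traceset(ts, traces_path, geometry_path)
                truth["p1_it_central"] = 30.0 + p1_shift
                truth["p1_amp_r1"] = wave[0].p1_amp

                manifest_rows.append({
                    "patient_id": patient_id, "eye_id": eye_id, "group": group,
                    "angio_svp": str(angio_paths["SVP"]),
                    "angio_icp": str(angio_paths["ICP"]),
                    "angio_dcp": str(angio_paths["DCP"]),
                    "bscan": str(bscan_path),
                    "boundaries": str(bounds_path),
                    # geometry.csv is the traces file's sibling by convention
                    "traces": str(traces_path),
                })
                truth_rows.append(truth)

    manifest_df = pd.DataFrame(manifest_rows)
    truth_df = pd.DataFrame(truth_rows)
    manifest_df.to_csv(out_dir / "manifest.csv", index=False)
    truth_df.to_csv(out_dir / "truth.csv", index=False, float_format="%.6g")
    return CohortManifest(rows=manifest_df), truth_df


def _place_foci(n_ir: int, n_or: int, rng: np.random.Generator,
                window_um: float = 1400.0) -> list[FocusSpec]:
    """Scatter compliant foci inside the counting window, avoiding lateral
    overlap so planted counts stay countable."""
    specs: list[FocusSpec] = []
    taken: list[float] = []
    for compartment, n in (("IR", n_ir), ("OR", n_or)):
        placed = 0
        attempts = 0
        while placed < n and attempts < 200 * max(n, 1):
            attempts += 1
            x = float(rng.uniform(-window_um, window_um))
            if any(abs(x - t) < 80.0 for t in taken):
                continue
            taken.append(x)
            specs.append(FocusSpec(
                lateral_um=x, compartment=compartment,
                diameter_um=float(rng.uniform(18.0, 28.0)),
                depth_frac=float(rng.uniform(0.3, 0.6))
                if compartment == "IR" else float(rng.uniform(0.15, 0.4)),
            ))
            placed += 1
    return specs


def simulate_metric_cohort(
    n_per_group: int,
    base_mean: float = 0.34,
    group_mult: dict[str, float] | None = None,
    patient_sd: float = PATIENT_EFFECT_SD,
    eye_sd: float = EYE_NOISE_SD,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw one metric for a cohort without rendering images.

    Mirrors the hierarchical structure of :func:`generate_cohort` — a
    shared patient multiplier plus independent eye-level noise — and is the
    fast path for statistical calibration and power studies on the
    group-comparison stage.
    """
    group_mult = group_mult or {g: 1.0 for g in GROUP_LABELS}
    rng = np.random.default_rng(seed)
    rows = []
    for group in GROUP_LABELS:
        mult = group_mult.get(group, 1.0)
        for pi in range(n_per_group):
            patient_id = f"{group}_p{pi:02d}"
            pm = rng.normal(1.0, patient_sd)
            for eye in ("OD", "OS"):
                value = base_mean * mult * pm * (1.0 + rng.normal(0.0, eye_sd))
                rows.append({"patient_id": patient_id,
                             "eye_id": f"{patient_id}_{eye}",
                             "group": group, "value": value})
    return pd.DataFrame(rows)
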