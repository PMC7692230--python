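"""Layered B-scan generator with planted hyperreflective foci.

The clean reflectance map is a stack of horizontal bands bounded by the 11
segmentation markers (flat by default), with per-band mean reflectivities.
Foci are stamped as elliptical disks of controlled equivalent diameter:
"moderate" reflectivity equals the RNFL band mean — the simile used to
grade real foci — and "high" (a rejection case) is 1.5× it. A shadowed
focus multiplies everything below it, down to Bruch's membrane, by 0.5.
Speckle is multiplicative gamma noise (shape k, default 4), the standard
first-order OCT speckle approximation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ..errors import AnalysisError
from ..types import MARKER_ORDER, BScanRecord

#: reflectivity band names, vitreous to choroid; bands i is bounded by
#: markers (i-1, i) with virtual image borders at the ends
BAND_NAMES = ("vitreous", "RNFL", "GCL", "IPL", "INL", "OPL", "ONL",
              "ELM_EZ", "EZ_OS", "OS_RPE", "RPE_BM", "choroid")


@dataclass
class LayerProfile:
    """Flat layer geometry (µm below scan top) and band reflectivities."""

    marker_depths_um: dict[str, float]
    band_reflectivity: dict[str, float]

    def __post_init__(self) -> None:
        missing = [m for m in MARKER_ORDER if m not in self.marker_depths_um]
        if missing:
            raise ValueError(f"profile missing markers: {missing}")
        depths = [self.marker_depths_um[m] for m in MARKER_ORDER]
        if any(b < a for a, b in zip(depths, depths[1:])):
            raise ValueError("marker depths must be non-decreasing")
        missing = [b for b in BAND_NAMES if b not in self.band_reflectivity]
        if missing:
            raise ValueError(f"profile missing bands: {missing}")


def default_layer_profile() -> LayerProfile:
    """Typical parafoveal layer stack (~315 µm retina, ILM at 80 µm)."""
    thickness = {  # µm per band, RNFL..RPE_BM
        "RNFL": 15, "GCL": 40, "IPL": 35, "INL": 35, "OPL": 30, "ONL": 80,
        "ELM_EZ": 25, "EZ_OS": 20, "OS_RPE": 15, "RPE_BM": 20,
    }
    depths = {"ILM": 80.0}
    running = 80.0
    for marker, band in zip(MARKER_ORDER[1:],
                            ("RNFL", "GCL", "IPL", "INL", "OPL", "ONL",
                             "ELM_EZ", "EZ_OS", "OS_RPE", "RPE_BM")):
        running += thickness[band]
        depths[marker] = running
    reflectivity = {
        "vitreous": 0.05, "RNFL": 0.65, "GCL": 0.35, "IPL": 0.45,
        "INL": 0.30, "OPL": 0.45, "ONL": 0.22, "ELM_EZ": 0.50,
        "EZ_OS": 0.80, "OS_RPE": 0.45, "RPE_BM": 0.85, "choroid": 0.30,
    }
    return LayerProfile(marker_depths_um=depths, band_reflectivity=reflectivity)


@dataclass
class FocusSpec:
    """Requested planted focus.

    ``lateral_um`` is the signed offset of the focus center from the fovea;
    ``depth_frac`` places the center within the compartment's depth span
    (defaults put IR foci in the ganglion-cell region and OR foci in the
    outer nuclear layer, where contrast against the background band is
    realistic).
    """

    lateral_um: float
    compartment: str                  # "IR" or "OR"
    diameter_um: float = 25.0
    level: str = "moderate"           # "moderate" | "high"
    has_shadow: bool = False
    depth_frac: float | None = None


@dataclass
class FocusTruth:
    """Planted-focus ground truth."""

    center_row: float
    center_col: float
    diameter_um: float
    level: str
    has_shadow: bool
    compartment: str

    def meets_criteria(self, max_diameter_um: float = 30.0) -> bool:
        """True iff the focus satisfies the counting criteria (small,
        moderate reflectivity, no back-shadowing)."""
        return (self.diameter_um <= max_diameter_um
                and self.level == "moderate" and not self.has_shadow)


# IR per the Fig-1-caption convention (ILM to lower IPL border); OR from the
# upper ONL limit to Bruch's membrane. Matches the analysis default.
_COMPARTMENT_MARKERS = {"IR": ("ILM", "IPL_o"), "OR": ("OPL_o", "BM")}
_DEFAULT_DEPTH_FRAC = {"IR": 0.45, "OR": 0.25}


def generate_bscan(
    size_px: tuple[int, int] = (224, 640),
    axial_scale: float = 3.9,
    lateral_scale: float = 5.7,
    layer_profile: LayerProfile | None = None,
    foci_spec: tuple[FocusSpec, ...] = (),
    speckle_level: float = 0.3,
    speckle_k: float = 4.0,
    seed: int = 0,
    fovea_col: int | None = None,
    eye_id: str = "",
) -> tuple[BScanRecord, list[FocusTruth]]:
    """Render a layered B-scan with planted foci and speckle.

    ``speckle_level`` interpolates between the noise-free band means (0)
    and fully developed multiplicative gamma speckle of shape ``speckle_k``
    (1). The default of 0.3 (≈15% intensity SD) emulates a frame-averaged
    acquisition, where averaging ~100 registered frames strongly suppresses
    single-frame speckle. Raises if a requested focus is larger than its
    compartment's depth span.
    """
    rng = np.random.default_rng(seed)
    profile = layer_profile or default_layer_profile()
    n_rows, n_cols = size_px
    if fovea_col is None:
        fovea_col = n_cols // 2

    boundaries = {m: np.full(n_cols, profile.marker_depths_um[m] / axial_scale)
                  for m in MARKER_ORDER}

    rows = np.arange(n_rows, dtype=float)[:, None]
    clean = np.zeros((n_rows, n_cols))
    edges = [np.full(n_cols, -0.5)] + [boundaries[m] for m in MARKER_ORDER] \
        + [np.full(n_cols, n_rows - 0.5)]
    for band, upper, lower in zip(BAND_NAMES, edges[:-1], edges[1:]):
        sel = (rows >= upper[None, :]) & (rows < lower[None, :])
        clean[sel] = profile.band_reflectivity[band]

    rnfl_mean = profile.band_reflectivity["RNFL"]
    rr_grid, cc_grid = np.mgrid[0:n_rows, 0:n_cols]
    truths: list[FocusTruth] = []
    for spec in foci_spec:
        upper_m, lower_m = _COMPARTMENT_MARKERS[spec.compartment]
        top_um = profile.marker_depths_um[upper_m]
        bot_um = profile.marker_depths_um[lower_m]
        span_um = bot_um - top_um
        if spec.diameter_um > span_um:
            raise AnalysisError(
                f"focus diameter {spec.diameter_um} µm exceeds "
                f"{spec.compartment} span {span_um:.0f} µm"
            )
        frac = spec.depth_frac if spec.depth_frac is not None \
            else _DEFAULT_DEPTH_FRAC[spec.compartment]
        center_row = (top_um + frac * span_um) / axial_scale
        center_col = fovea_col + spec.lateral_um / lateral_scale
        if not (0 <= center_col < n_cols):
            raise AnalysisError("focus center outside image")
        r_ax = spec.diameter_um / 2.0 / axial_scale
        r_lat = spec.diameter_um / 2.0 / lateral_scale
        disk = (((rr_grid - center_row) / max(r_ax, 0.5)) ** 2
                + ((cc_grid - center_col) / max(r_lat, 0.5)) ** 2) <= 1.0
        value = rnfl_mean if spec.level == "moderate" else 1.5 * rnfl_mean
        clean[disk] = value
        if spec.has_shadow:
            c0 = max(int(math.floor(center_col - r_lat)), 0)
            c1 = min(int(math.ceil(center_col + r_lat)), n_cols - 1)
            shadow_top = int(math.ceil(center_row + r_ax)) + 1
            for col in range(c0, c1 + 1):
                bm_row = int(round(boundaries["BM"][col]))
                clean[shadow_top:bm_row + 1, col] *= 0.5
        truths.append(FocusTruth(
            center_row=float(center_row), center_col=float(center_col),
            diameter_um=float(spec.diameter_um), level=spec.level,
            has_shadow=spec.has_shadow, compartment=spec.compartment,
        ))

    if speckle_level > 0:
        gamma = rng.gamma(speckle_k, 1.0 / speckle_k, size=clean.shape)
        pixels = clean * (1.0 + speckle_level * (gamma - 1.0))
    else:
        pixels = clean
    pixels = np.clip(pixels, 0.0, 1.0)

    record = BScanRecord(
        pixels=pixels, axial_scale=axial_scale, lateral_scale=lateral_scale,
        fovea_col=fovea_col, boundaries=boundaries, eye_id=eye_id,
    )
    return record, truths
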