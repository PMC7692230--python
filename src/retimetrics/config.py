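"""Pipeline configuration.

A single flat key-value table (TOML on disk) drives every tunable stage so a
bare run is reproducible. Defaults encode the choices documented in
``docs/methods.md``; any subset of keys may be overridden.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass
from pathlib import Path

from .errors import FormatError


@dataclass
class PipelineConfig:
    # --- OCTA ---
    quality_min: float = 30.0          # Q-score gate: fail iff quality < 30
    binarize_method: str = "otsu"      # "otsu" | "mean" | "fixed"
    binarize_threshold: float = 0.5    # used when binarize_method == "fixed"
    bright_is_vessel: bool = True      # display polarity at read time
    fd_box_min: int = 2                # smallest box side (px), powers of 2
    fd_box_max_frac: float = 0.25      # largest box = min side * this

    # --- HRF detection ---
    hrf_window_mm: float = 1.5         # half-width of central counting window
    hrf_min_diameter_um: float = 10.0
    hrf_max_diameter_um: float = 30.0
    hrf_detect_max_diameter_um: float = 60.0  # LoG ladder upper end; larger
                                              # candidates must be seen to be
                                              # rejected on size
    hrf_reflectivity_low: float = 0.8  # bounds relative to RNFL band mean
    hrf_reflectivity_high: float = 1.2
    hrf_shadow_min: float = 0.8        # min sub-focus / flanking ratio
    hrf_flank_offset_cols: int = 3
    hrf_ir_convention: str = "fig1"    # "fig1": ILM->lower IPL; "text": INL->lower OPL
    hrf_log_threshold: float = 0.08    # LoG response floor for candidates
    hrf_min_contrast: float = 0.15     # min peak height above the band
                                       # background model

    # --- ETDRS grid ---
    laterality: str = "OD"             # right eye: nasal is +x

    # --- mfERG ---
    mferg_baseline_ms: float = 10.0
    mferg_n1_window_ms: tuple[float, float] = (10.0, 45.0)
    mferg_p1_max_ms: float = 60.0
    mferg_z_it: float = 2.0            # abnormal iff z(P1-IT) >= this ...
    mferg_z_amp: float = -2.0          # ... OR z(amplitude) <= this
    mferg_abnormal_rule: str = "or"    # "or" | "and"
    mferg_amp_feature: str = "p1_amp"  # amplitude entering the z rule
    mferg_bandpass: bool = False       # optional zero-phase 10-300 Hz filter
    mferg_lowpass_hz: float = 300.0    # zero-phase low-pass before feature
                                       # extraction (0 disables); the upper
                                       # edge of the recording band
    mferg_refine: str = "template"     # "template": biphasic least-squares
                                       # refinement of the cursor reading;
                                       # "cursor": raw extrema only
    mferg_fit_width_ms: float = 6.0    # template lobe width; 0 fits the
                                       # width as a free parameter
    mferg_ring_mode: str = "average_traces"  # or "average_features"

    # --- statistics ---
    alpha: float = 0.05
    clustering: str = "patient_mean"   # "patient_mean" | "naive"

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a flat TOML config; keys not present keep their defaults."""
    if path is None:
        return PipelineConfig()
    data = tomllib.loads(Path(path).read_text())
    valid = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - valid
    if unknown:
        raise FormatError(f"unknown config keys: {sorted(unknown)}")
    if "mferg_n1_window_ms" in data:
        data["mferg_n1_window_ms"] = tuple(data["mferg_n1_window_ms"])
    return PipelineConfig(**data)
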