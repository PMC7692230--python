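"""Core in-memory containers shared across the pipeline stages.

Coordinate convention, used everywhere in this package: image arrays are
0-based and row-major; a pixel index refers to the pixel center. In B-scans
rows are depth (increasing downward, i.e. toward the choroid) and columns are
lateral position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError

PLEXUS_LABELS = ("SVP", "ICP", "DCP")
GROUP_LABELS = ("control", "noDR", "DR")

#: The 11 segmentation markers, ordered from vitreous to choroid. Consecutive
#: markers bound the anatomical bands; the seven reported layers are RNFL,
#: GCL, IPL, INL, OPL, ONL and the composite outer retinal layer (ORL: ELM
#: through the RPE/Bruch's membrane complex).
MARKER_ORDER = (
    "ILM",      # inner limiting membrane
    "RNFL_o",   # RNFL / GCL border
    "GCL_o",    # GCL / IPL border
    "IPL_o",    # IPL / INL border
    "INL_o",    # INL / OPL border
    "OPL_o",    # OPL / ONL border
    "ELM",      # external limiting membrane (upper ORL limit)
    "EZ",       # ellipsoid zone
    "OS",       # outer segments / interdigitation
    "RPE",      # retinal pigment epithelium
    "BM",       # Bruch's membrane
)

#: Reported layer -> (upper marker, lower marker).
LAYER_BOUNDS = {
    "RNFL": ("ILM", "RNFL_o"),
    "GCL": ("RNFL_o", "GCL_o"),
    "IPL": ("GCL_o", "IPL_o"),
    "INL": ("IPL_o", "INL_o"),
    "OPL": ("INL_o", "OPL_o"),
    "ONL": ("OPL_o", "ELM"),
    "ORL": ("ELM", "BM"),
}

LAYER_NAMES = tuple(LAYER_BOUNDS)

N_HEXAGONS = 103
N_CENTRAL_HEXAGONS = 19


@dataclass
class EnFaceAngiogram:
    """Calibrated en-face angiogram of one vascular plexus of one eye.

    Parameters
    ----------
    pixels
        2-D float array of intensities in [0, 1].
    scale_x, scale_y
        Lateral calibration in micrometres per pixel.
    plexus
        One of ``SVP`` (superficial vascular), ``ICP`` (intermediate
        capillary) or ``DCP`` (deep capillary plexus).
    eye_id
        Opaque eye identifier.
    quality
        Device signal-strength ("Q score") on a 0-40 scale.
    """

    pixels: np.ndarray
    scale_x: float
    scale_y: float
    plexus: str
    eye_id: str = ""
    quality: float = 40.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise FormatError("angiogram pixels must be a non-empty 2D grid")
        if not (self.scale_x > 0 and self.scale_y > 0):
            raise FormatError("scales must be > 0")
        if self.plexus not in PLEXUS_LABELS:
            raise FormatError(
                f"plexus must be one of {PLEXUS_LABELS}, got {self.plexus!r}"
            )
        if not 0 <= self.quality <= 40:
            raise FormatError("quality outside [0,40]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class BScanRecord:
    """Structural OCT B-scan with per-column layer-boundary traces.

    ``boundaries`` maps each of the 11 segmentation markers to a row
    coordinate per column (float, sub-pixel allowed). Traces must be
    vertically ordered: the ILM lies above (smaller row than) the RPE/BM
    complex at every column.
    """

    pixels: np.ndarray
    axial_scale: float
    lateral_scale: float
    fovea_col: int
    boundaries: dict[str, np.ndarray]
    eye_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise FormatError("B-scan pixels must be a non-empty 2D grid")
        if not (self.axial_scale > 0 and self.lateral_scale > 0):
            raise FormatError("scales must be > 0")
        n_cols = self.pixels.shape[1]
        if not 0 <= self.fovea_col < n_cols:
            raise FormatError("fovea_col outside image width")
        missing = [m for m in MARKER_ORDER if m not in self.boundaries]
        if missing:
            raise FormatError(f"missing boundary markers: {missing}")
        traces = {}
        for name in MARKER_ORDER:
            tr = np.asarray(self.boundaries[name], dtype=float)
            if tr.shape != (n_cols,) or not np.all(np.isfinite(tr)):
                raise FormatError(
                    f"boundary {name} must have one finite value per column"
                )
            traces[name] = tr
        self.boundaries = traces
        stack = np.stack([traces[m] for m in MARKER_ORDER])
        bad = np.where(np.any(np.diff(stack, axis=0) < 0, axis=0))[0]
        if bad.size:
            raise FormatError(f"boundaries cross at col {int(bad[0])}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class MfergTraceSet:
    """103 per-hexagon first-order mfERG responses with ring geometry.

    ``traces`` is (103, n_samples) in nV/deg²; ``ring_of_hexagon`` assigns
    each hexagon to one of the six concentric rings R1-R6 (center to
    periphery). The 19 hexagons of rings R1-R3 form the central/macular set.
    """

    traces: np.ndarray
    sampling_rate: float
    hexagon_ids: np.ndarray
    ring_of_hexagon: np.ndarray
    eye_id: str = ""

    def __post_init__(self) -> None:
        self.traces = np.asarray(self.traces, dtype=float)
        self.hexagon_ids = np.asarray(self.hexagon_ids)
        self.ring_of_hexagon = np.asarray(self.ring_of_hexagon, dtype=int)
        if self.traces.ndim != 2 or self.traces.shape[0] != N_HEXAGONS:
            raise FormatError(
                f"expected {N_HEXAGONS} hexagons, got {self.traces.shape[0]}"
            )
        if self.hexagon_ids.shape != (N_HEXAGONS,):
            raise FormatError("hexagon_ids must have one entry per hexagon")
        if len(set(self.hexagon_ids.tolist())) != N_HEXAGONS:
            raise FormatError("hexagon_ids must be unique")
        if self.ring_of_hexagon.shape != (N_HEXAGONS,):
            raise FormatError("ring_of_hexagon must have one entry per hexagon")
        if self.ring_of_hexagon.min() < 1 or self.ring_of_hexagon.max() > 6:
            raise FormatError("ring indices must lie in 1..6")
        if not self.sampling_rate > 0:
            raise FormatError("sampling_rate must be > 0")
        if len(self.central_ids) != N_CENTRAL_HEXAGONS:
            raise FormatError(
                f"expected {N_CENTRAL_HEXAGONS} central hexagons (rings 1-3), "
                f"got {len(self.central_ids)}"
            )

    @property
    def central_ids(self) -> list:
        """Identifiers of the 19 hexagons in the three central rings."""
        return [
            h for h, r in zip(self.hexagon_ids.tolist(), self.ring_of_hexagon)
            if r <= 3
        ]

    @property
    def n_samples(self) -> int:
        return self.traces.shape[1]

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate * 1000.0

    def trace_of(self, hexagon_id) -> np.ndarray:
        idx = np.where(self.hexagon_ids == hexagon_id)[0]
        if idx.size == 0:
            raise KeyError(f"unknown hexagon id {hexagon_id!r}")
        return self.traces[idx[0]]


MANIFEST_COLUMNS = (
    "patient_id", "eye_id", "group",
    "angio_svp", "angio_icp", "angio_dcp",
    "bscan", "boundaries", "traces",
)


@dataclass
class CohortManifest:
    """Maps eyes to study groups and to that eye's input files."""

    rows: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.rows)
        missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"manifest missing columns: {missing}")
        if len(df) == 0:
            raise FormatError("no eyes in manifest")
        bad = set(df["group"]) - set(GROUP_LABELS)
        if bad:
            raise FormatError(f"unknown group labels: {sorted(bad)}")
        if df["eye_id"].duplicated().any():
            dup = df.loc[df["eye_id"].duplicated(), "eye_id"].iloc[0]
            raise FormatError(f"eye {dup!r} appears more than once")
        self.rows = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return (row for _, row in self.rows.iterrows())
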