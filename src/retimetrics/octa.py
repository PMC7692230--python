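"""En-face OCTA vessel quantification.

Pipeline per angiogram: quality gate -> binarization -> skeletonization ->
vessel area density (VAD), vessel length fraction (VLF), vessel diameter
index (VDI, mean caliber in µm) and box-counting fractal dimension (FD) of
the skeleton, plus the foveal avascular zone (FAZ) area from a user-traced
polygon.

Definitions
-----------
VAD = vessel pixels / total pixels of the binarized image.
VLF = skeleton pixels / total pixels.
VDI = (vessel pixels / skeleton pixels) × µm-per-pixel, the average vessel
caliber: area divided by centerline length.
FD  = slope of log N(s) against log(1/s), where N(s) is the number of boxes
of side s containing at least one skeleton pixel, over a geometric ladder of
box sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon
from skimage.filters import threshold_otsu
from skimage.morphology import skeletonize as _sk_skeletonize

from .config import PipelineConfig
from .errors import AnalysisError, QualityGateError
from .types import EnFaceAngiogram


@dataclass
class BinaryVesselMap:
    """Boolean vessel mask with the binarization provenance that made it."""

    mask: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)


@dataclass
class SkeletonMap:
    """One-pixel-wide, 8-connected vessel centerlines."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)


@dataclass
class VesselMetrics:
    """Per-plexus vessel metric bundle."""

    vad: float
    vlf: float
    vdi_um: float
    fd: float
    faz_mm2: float | None = None
    plexus: str = ""
    quality_pass: bool = True

    def as_dict(self) -> dict:
        return {
            "vad": self.vad, "vlf": self.vlf, "vdi_um": self.vdi_um,
            "fd": self.fd, "faz_mm2": self.faz_mm2,
        }


def quality_gate(angiogram: EnFaceAngiogram, quality_min: float = 30.0) -> bool:
    """Signal-strength gate: pass iff the Q score is >= ``quality_min``.

    Scans with signal strength strictly below 30 (on the device's 0-40
    scale) are excluded from all downstream metrics.
    """
    return angiogram.quality >= quality_min


def binarize(angiogram: EnFaceAngiogram, method: str = "otsu",
             threshold: float = 0.5, bright_is_vessel: bool = True) -> BinaryVesselMap:
    """Convert an angiogram into a binary vessel map.

    ``method`` is ``"otsu"`` (global histogram threshold, the default),
    ``"mean"`` or ``"fixed"``. Vessel pixels are those at or above the
    threshold when ``bright_is_vessel`` (the internal convention: vessels
    are always the foreground/true class regardless of display polarity).
    """
    img = angiogram.pixels
    if np.ptp(img) == 0:
        raise AnalysisError("degenerate histogram: constant image")
    if method == "otsu":
        thr = float(threshold_otsu(img))
    elif method == "mean":
        thr = float(img.mean())
    elif method == "fixed":
        thr = float(threshold)
    else:
        raise ValueError(f"unknown binarization method {method!r}")
    mask = img >= thr if bright_is_vessel else img <= thr
    return BinaryVesselMap(
        mask=mask,
        provenance={"method": method, "threshold": thr,
                    "bright_is_vessel": bright_is_vessel},
    )


def skeletonize(binary: BinaryVesselMap) -> SkeletonMap:
    """Thin the vessel mask until a single pixel remains per vessel segment.

    Morphological thinning to one-pixel-wide, 8-connected centerlines;
    connectivity of the input components is preserved. An empty mask yields
    an empty skeleton.
    """
    if not binary.mask.any():
        return SkeletonMap(mask=np.zeros_like(binary.mask))
    return SkeletonMap(mask=_sk_skeletonize(binary.mask))


def vessel_area_density(binary: BinaryVesselMap) -> float:
    """Vessel-pixel count divided by total pixel count."""
    return float(binary.mask.sum()) / binary.mask.size


def vessel_length_fraction(skeleton: SkeletonMap) -> float:
    """Skeleton-pixel count divided by total pixel count."""
    return float(skeleton.mask.sum()) / skeleton.mask.size


def vessel_diameter_index(binary: BinaryVesselMap, skeleton: SkeletonMap,
                          scale_um_per_px: float) -> float:
    """Average vessel caliber in µm: vessel area over centerline length."""
    n_skel = int(skeleton.mask.sum())
    if n_skel == 0:
        raise AnalysisError("empty skeleton: vessel diameter index undefined")
    return float(binary.mask.sum()) / n_skel * scale_um_per_px


def box_counts(mask: np.ndarray, box_sizes: np.ndarray) -> np.ndarray:
    """Number of s×s boxes (anchored at the origin) containing a true pixel."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    counts = np.empty(len(box_sizes), dtype=int)
    for i, s in enumerate(box_sizes):
        hp, wp = -(-h // s) * s, -(-w // s) * s
        padded = np.zeros((hp, wp), dtype=bool)
        padded[:h, :w] = mask
        blocks = padded.reshape(hp // s, s, wp // s, s)
        counts[i] = int(blocks.any(axis=(1, 3)).sum())
    return counts


def fd_box_sizes(shape: tuple[int, int], box_min: int = 2,
                 box_max_frac: float = 0.25) -> np.ndarray:
    """Geometric ladder of box sides: powers of 2 from ``box_min`` up to
    ``min(shape) * box_max_frac``."""
    s_max = int(min(shape) * box_max_frac)
    sizes = []
    s = box_min
    while s <= s_max:
        sizes.append(s)
        s *= 2
    return np.array(sizes, dtype=int)


def fractal_dimension(skeleton: SkeletonMap, box_min: int = 2,
                      box_max_frac: float = 0.25) -> float:
    """Box-counting fractal dimension of the skeleton.

    Least-squares slope of log N(s) versus log(1/s). Requires at least two
    skeleton pixels and three ladder points.
    """
    mask = skeleton.mask
    if int(mask.sum()) < 2:
        raise AnalysisError("skeleton must contain at least 2 pixels")
    sizes = fd_box_sizes(mask.shape, box_min, box_max_frac)
    if len(sizes) < 3:
        raise AnalysisError(
            f"image too small for box ladder: only {len(sizes)} box sizes"
        )
    counts = box_counts(mask, sizes)
    slope, _ = np.polyfit(np.log(1.0 / sizes), np.log(counts), 1)
    return float(slope)


def faz_area(polygon_vertices: np.ndarray, scale_x: float, scale_y: float) -> float:
    """Area in mm² of a traced FAZ polygon given in pixel coordinates.

    Shoelace area × scale_x × scale_y / 10⁶. The polygon must be simple
    (non-self-intersecting) with at least 3 vertices.
    """
    verts = np.asarray(polygon_vertices, dtype=float)
    if verts.ndim != 2 or verts.shape[0] < 3 or verts.shape[1] != 2:
        raise AnalysisError("FAZ polygon needs at least 3 (x, y) vertices")
    poly = Polygon(verts)
    if not poly.is_valid:
        raise AnalysisError("FAZ polygon is self-intersecting")
    return poly.area * scale_x * scale_y / 1e6


def compute_all_metrics(angiogram: EnFaceAngiogram,
                        faz_polygon: np.ndarray | None = None,
                        config: PipelineConfig | None = None) -> VesselMetrics:
    """Chain binarize -> skeletonize -> VAD/VLF/VDI/FD (+ FAZ area).

    Raises :class:`QualityGateError` when the angiogram fails the
    signal-strength gate; gated eyes contribute no metrics downstream.
    """
    cfg = config or PipelineConfig()
    if not quality_gate(angiogram, cfg.quality_min):
        raise QualityGateError(
            f"quality gate failed: Q score {angiogram.quality} < {cfg.quality_min}"
        )
    binary = binarize(angiogram, method=cfg.binarize_method,
                      threshold=cfg.binarize_threshold,
                      bright_is_vessel=cfg.bright_is_vessel)
    skeleton = skeletonize(binary)
    scale = (angiogram.scale_x + angiogram.scale_y) / 2.0
    faz = None
    if faz_polygon is not None:
        faz = faz_area(faz_polygon, angiogram.scale_x, angiogram.scale_y)
    return VesselMetrics(
        vad=vessel_area_density(binary),
        vlf=vessel_length_fraction(skeleton),
        vdi_um=vessel_diameter_index(binary, skeleton, scale),
        fd=fractal_dimension(skeleton, cfg.fd_box_min, cfg.fd_box_max_frac),
        faz_mm2=faz,
        plexus=angiogram.plexus,
        quality_pass=True,
    )
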