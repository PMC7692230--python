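"""Readers and writers for all on-disk formats.

Images are grayscale TIFF or PNG with a JSON sidecar carrying calibration
(``scale_x``/``scale_y`` or ``axial_scale``/``lateral_scale`` in µm/px) and
acquisition metadata. Boundary tables, trace sets, manifests and metric
tables are plain CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .errors import FormatError
from .types import (
    MARKER_ORDER,
    N_HEXAGONS,
    BScanRecord,
    CohortManifest,
    EnFaceAngiogram,
    MfergTraceSet,
)

_BITDEPTH_MAX = {np.uint8: 255, np.uint16: 65535}


def _read_gray_image(path: str | Path) -> np.ndarray:
    """Read a single-channel 8/16-bit image, rescaled to [0, 1]."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"image not found: {path}")
    if path.suffix.lower() in {".tif", ".tiff"}:
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path))
    if arr.ndim != 2:
        raise FormatError(f"{path.name}: expected single-channel image, got shape {arr.shape}")
    if arr.dtype == np.uint8:
        return arr.astype(float) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(float) / 65535.0
    if np.issubdtype(arr.dtype, np.floating):
        if arr.min() < 0 or arr.max() > 1:
            raise FormatError(f"{path.name}: float image must lie in [0,1]")
        return arr.astype(float)
    raise FormatError(f"{path.name}: unsupported dtype {arr.dtype}")


def _read_sidecar(path: str | Path, required: tuple[str, ...]) -> dict:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"metadata not found: {path}")
    try:
        meta = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path.name}: invalid JSON ({exc})") from exc
    missing = [k for k in required if k not in meta]
    if missing:
        raise FormatError(f"{path.name}: missing metadata field(s) {missing}")
    return meta


def read_angiogram(image_path: str | Path, metadata_path: str | Path | None = None) -> EnFaceAngiogram:
    """Read an en-face angiogram plus its JSON sidecar.

    The sidecar must supply ``scale_x``, ``scale_y`` (µm/px), ``plexus``
    and ``quality``; ``eye_id`` is optional. If ``metadata_path`` is omitted,
    ``<image>.json`` next to the image is used.
    """
    image_path = Path(image_path)
    if metadata_path is None:
        metadata_path = image_path.with_suffix(image_path.suffix + ".json")
    pixels = _read_gray_image(image_path)
    meta = _read_sidecar(metadata_path, ("scale_x", "scale_y", "plexus", "quality"))
    return EnFaceAngiogram(
        pixels=pixels,
        scale_x=float(meta["scale_x"]),
        scale_y=float(meta["scale_y"]),
        plexus=str(meta["plexus"]),
        eye_id=str(meta.get("eye_id", "")),
        quality=float(meta["quality"]),
    )


def write_angiogram(angiogram: EnFaceAngiogram, image_path: str | Path) -> Path:
    """Write an angiogram as 16-bit TIFF/PNG plus a JSON sidecar."""
    image_path = Path(image_path)
    arr = np.clip(np.round(angiogram.pixels * 65535), 0, 65535).astype(np.uint16)
    if image_path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(image_path, arr)
    else:
        Image.fromarray(arr).save(image_path)
    meta = {
        "scale_x": angiogram.scale_x,
        "scale_y": angiogram.scale_y,
        "plexus": angiogram.plexus,
        "quality": angiogram.quality,
        "eye_id": angiogram.eye_id,
    }
    sidecar = image_path.with_suffix(image_path.suffix + ".json")
    sidecar.write_text(json.dumps(meta, indent=1))
    return sidecar


def read_boundaries(csv_path: str | Path, n_cols: int) -> dict[str, np.ndarray]:
    """Read a long-format boundary table with columns ``marker,col,row``."""
    df = pd.read_csv(csv_path)
    for c in ("marker", "col", "row"):
        if c not in df.columns:
            raise FormatError(f"boundary CSV missing column {c!r}")
    out: dict[str, np.ndarray] = {}
    for marker, grp in df.groupby("marker"):
        trace = np.full(n_cols, np.nan)
        cols = grp["col"].to_numpy(dtype=int)
        if cols.min() < 0 or cols.max() >= n_cols:
            raise FormatError(f"boundary {marker}: column index outside image")
        trace[cols] = grp["row"].to_numpy(dtype=float)
        out[str(marker)] = trace
    return out


def write_boundaries(boundaries: dict[str, np.ndarray], csv_path: str | Path) -> None:
    frames = []
    for marker in MARKER_ORDER:
        tr = boundaries[marker]
        frames.append(pd.DataFrame({
            "marker": marker, "col": np.arange(len(tr)), "row": tr,
        }))
    pd.concat(frames, ignore_index=True).to_csv(csv_path, index=False)


def read_bscan(image_path: str | Path, boundaries_path: str | Path,
               metadata_path: str | Path | None = None) -> BScanRecord:
    """Read a structural B-scan, its boundary table and its JSON sidecar."""
    image_path = Path(image_path)
    if metadata_path is None:
        metadata_path = image_path.with_suffix(image_path.suffix + ".json")
    pixels = _read_gray_image(image_path)
    meta = _read_sidecar(metadata_path, ("axial_scale", "lateral_scale", "fovea_col"))
    boundaries = read_boundaries(boundaries_path, pixels.shape[1])
    return BScanRecord(
        pixels=pixels,
        axial_scale=float(meta["axial_scale"]),
        lateral_scale=float(meta["lateral_scale"]),
        fovea_col=int(meta["fovea_col"]),
        boundaries=boundaries,
        eye_id=str(meta.get("eye_id", "")),
    )


def write_bscan(bscan: BScanRecord, image_path: str | Path,
                boundaries_path: str | Path) -> None:
    image_path = Path(image_path)
    arr = np.clip(np.round(bscan.pixels * 65535), 0, 65535).astype(np.uint16)
    if image_path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(image_path, arr)
    else:
        Image.fromarray(arr).save(image_path)
    meta = {
        "axial_scale": bscan.axial_scale,
        "lateral_scale": bscan.lateral_scale,
        "fovea_col": bscan.fovea_col,
        "eye_id": bscan.eye_id,
    }
    image_path.with_suffix(image_path.suffix + ".json").write_text(json.dumps(meta, indent=1))
    write_boundaries(bscan.boundaries, boundaries_path)


def read_traceset(csv_path: str | Path, geometry_path: str | Path) -> MfergTraceSet:
    """Read an mfERG trace set.

    The trace CSV has a ``time_ms`` column plus one column per hexagon
    (header = hexagon id). The geometry CSV has columns ``hexagon,ring``
    mapping each hexagon id to its concentric ring 1-6; the 19 hexagons of
    rings 1-3 form the central set.
    """
    df = pd.read_csv(csv_path)
    if "time_ms" not in df.columns:
        raise FormatError("trace CSV missing time_ms column")
    hex_cols = [c for c in df.columns if c != "time_ms"]
    if len(hex_cols) != N_HEXAGONS:
        raise FormatError(f"expected {N_HEXAGONS} hexagons, got {len(hex_cols)}")
    t = df["time_ms"].to_numpy(dtype=float)
    if len(t) < 2:
        raise FormatError("trace CSV must contain at least 2 samples")
    dt = np.diff(t)
    dt_mean = (t[-1] - t[0]) / (len(t) - 1)
    # tolerance accommodates 6-significant-digit CSV rounding
    if dt_mean <= 0 or not np.allclose(dt, dt_mean, rtol=1e-3, atol=1e-4):
        raise FormatError("time_ms column must be uniformly sampled")
    sampling_rate = 1000.0 / dt_mean

    geo = pd.read_csv(geometry_path)
    for c in ("hexagon", "ring"):
        if c not in geo.columns:
            raise FormatError(f"geometry CSV missing column {c!r}")
    ring_map = {str(h): int(r) for h, r in zip(geo["hexagon"], geo["ring"])}
    missing = [h for h in hex_cols if h not in ring_map]
    if missing:
        raise FormatError(f"hexagons missing from geometry: {missing[:5]}")
    rings = np.array([ring_map[h] for h in hex_cols])
    if rings.min() < 1 or rings.max() > 6:
        raise FormatError("ring indices must lie in 1..6")
    traces = df[hex_cols].to_numpy(dtype=float).T
    return MfergTraceSet(
        traces=traces,
        sampling_rate=sampling_rate,
        hexagon_ids=np.array(hex_cols),
        ring_of_hexagon=rings,
    )


def write_traceset(ts: MfergTraceSet, csv_path: str | Path,
                   geometry_path: str | Path) -> None:
    data = {"time_ms": ts.times_ms}
    for hid, trace in zip(ts.hexagon_ids.tolist(), ts.traces):
        data[str(hid)] = trace
    pd.DataFrame(data).to_csv(csv_path, index=False, float_format="%.6g")
    pd.DataFrame({
        "hexagon": [str(h) for h in ts.hexagon_ids.tolist()],
        "ring": ts.ring_of_hexagon,
    }).to_csv(geometry_path, index=False)


def read_manifest(csv_path: str | Path) -> CohortManifest:
    """Read the cohort manifest mapping eyes to groups and input files."""
    path = Path(csv_path)
    if not path.exists():
        raise FormatError(f"manifest not found: {path}")
    df = pd.read_csv(path)
    if len(df) == 0:
        raise FormatError("no eyes in manifest")
    return CohortManifest(rows=df)


def write_metrics(df: pd.DataFrame, csv_path: str | Path) -> None:
    """Write a metric table; values round-trip to 6 significant digits."""
    df.to_csv(csv_path, index=False, float_format="%.6g")


def read_metrics(csv_path: str | Path) -> pd.DataFrame:
    return pd.read_csv(csv_path)
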