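"""End-to-end cohort pipeline: manifest in, metric and comparison tables out.

For every eye the pipeline computes per-plexus OCTA vessel metrics (quality
gated), hyperreflective-focus counts and layer-thickness summaries from the
B-scan, and mfERG ring features; builds the normative database from the
run's control eyes; classifies abnormal hexagons; and writes the per-eye
metric table, the three-group comparison table (both clustering modes), the
OCTA-vs-HRF correlation screen, and a JSONL run log.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as rio
from . import mferg, octa, stats
from .config import PipelineConfig, load_config
from .errors import QualityGateError, RetimetricsError
from .oct_structure import EtdrsGrid, count_hrf, layer_thickness
from .types import LAYER_NAMES, PLEXUS_LABELS, CohortManifest

ANGIO_COLUMNS = {"SVP": "angio_svp", "ICP": "angio_icp", "DCP": "angio_dcp"}


class PipelineError(RetimetricsError):
    """A stage failed for a specific eye."""

    def __init__(self, eye_id: str, stage: str, cause: Exception):
        self.eye_id, self.stage, self.cause = eye_id, stage, cause
        super().__init__(f"eye {eye_id!r}, stage {stage!r}: {cause}")


def _process_eye(row: pd.Series, config: PipelineConfig, log) -> dict:
    eye_id = row["eye_id"]
    metrics: dict = {"patient_id": row["patient_id"], "eye_id": eye_id,
                     "group": row["group"]}

    for plexus in PLEXUS_LABELS:
        stage = f"octa_{plexus.lower()}"
        try:
            angio = rio.read_angiogram(row[ANGIO_COLUMNS[plexus]])
            vm = octa.compute_all_metrics(angio, config=config)
        except QualityGateError as exc:
            log(eye_id, stage, "excluded", str(exc))
            metrics[f"quality_pass_{plexus.lower()}"] = False
            continue
        except Exception as exc:
            raise PipelineError(eye_id, stage, exc) from exc
        metrics[f"quality_pass_{plexus.lower()}"] = True
        for key, value in vm.as_dict().items():
            if value is not None:
                metrics[f"{key}_{plexus.lower()}"] = value
        log(eye_id, stage, "ok")

    try:
        bscan = rio.read_bscan(row["bscan"], row["boundaries"])
        grid = EtdrsGrid(laterality=config.laterality)
        thickness = layer_thickness(bscan, grid)
        for layer in LAYER_NAMES:
            metrics[f"thk_{layer.lower()}_central"] = thickness.central[layer]
            metrics[f"thk_{layer.lower()}_ring"] = thickness.ring_mean[layer]
        n_ir, n_or = count_hrf(bscan, config)
        metrics["hrf_ir"], metrics["hrf_or"] = n_ir, n_or
        metrics["hrf_total"] = n_ir + n_or
        log(eye_id, "oct", "ok")
    except Exception as exc:
        raise PipelineError(eye_id, "oct", exc) from exc

    try:
        traces_path = Path(row["traces"])
        geometry_path = traces_path.parent / "geometry.csv"
        ts = rio.read_traceset(traces_path, geometry_path)
        rings = mferg.ring_summary(ts, config)
        for ring in rings.index:
            for feat in ("n1_amp", "n1_it", "p1_amp", "p1_it"):
                metrics[f"{feat}_r{ring}"] = rings.loc[ring, feat]
        metrics["_features"] = mferg.extract_all_features(ts, config)
        metrics["_central_ids"] = ts.central_ids
        log(eye_id, "mferg", "ok")
    except Exception as exc:
        raise PipelineError(eye_id, "mferg", exc) from exc
    return metrics


def run_pipeline(manifest_path: str | Path,
                 config_path: str | Path | None = None,
                 out_dir: str | Path = ".") -> dict[str, Path]:
    """Run the full pipeline for a cohort manifest.

    Writes ``metrics.csv`` (one row per eye), ``comparisons.csv``,
    ``correlations.csv`` and ``run_log.jsonl`` into ``out_dir`` and returns
    their paths.
    """
    config = load_config(config_path)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = rio.read_manifest(manifest_path)
    log_path = out_dir / "run_log.jsonl"
    log_entries: list[dict] = []

    def log(eye_id: str, stage: str, status: str, message: str = "") -> None:
        log_entries.append({"eye_id": eye_id, "stage": stage,
                            "status": status, "message": message})

    def flush_log() -> None:
        with open(log_path, "w") as fh:
            for entry in log_entries:
                fh.write(json.dumps(entry) + "\n")

    eye_rows = []
    try:
        for row in manifest:
            eye_rows.append(_process_eye(row, config, log))
    except PipelineError as exc:
        log(exc.eye_id, exc.stage, "error", str(exc.cause))
        flush_log()
        raise

    # normative database from the run's control eyes, then classification
    control = [m for m in eye_rows if m["group"] == "control"]
    if len(control) >= 2:
        try:
            db = mferg.build_normative_db([m["_features"] for m in control],
                                          config)
            for m in eye_rows:
                result = mferg.classify_abnormal(
                    m["_features"], db, m["_central_ids"], config)
                m["n_abnormal_hex"] = result.n_abnormal
                m["eye_abnormal"] = int(result.eye_abnormal)
            log("-", "normative_db", "ok")
        except RetimetricsError as exc:
            log("-", "normative_db", "skipped", str(exc))
    else:
        log("-", "normative_db", "skipped", "fewer than 2 control eyes")

    for m in eye_rows:
        m.pop("_features", None)
        m.pop("_central_ids", None)
    metrics_df = pd.DataFrame(eye_rows)
    metrics_path = out_dir / "metrics.csv"
    rio.write_metrics(metrics_df, metrics_path)

    id_cols = {"patient_id", "eye_id", "group"}
    numeric = [c for c in metrics_df.columns
               if c not in id_cols and not c.startswith("quality_pass")
               and pd.api.types.is_numeric_dtype(metrics_df[c])]
    comparisons = []
    for metric in numeric:
        values = metrics_df[["patient_id", "eye_id", "group", metric]].rename(
            columns={metric: "value"}).dropna(subset=["value"])
        if len(values) == 0 or values["value"].std() < 1e-12:
            log("-", f"stats_{metric}", "skipped", "no variance")
            continue
        for clustering in ("patient_mean", "naive"):
            try:
                comparisons.append(stats.compare_groups(
                    values, metric=metric, clustering=clustering))
            except RetimetricsError as exc:
                log("-", f"stats_{metric}", "skipped", str(exc))
    comparisons_path = out_dir / "comparisons.csv"
    rio.write_metrics(stats.comparison_table(comparisons), comparisons_path)

    correlations = []
    octa_metrics = [c for c in numeric
                    if c.split("_")[0] in ("vad", "vlf", "vdi", "fd")]
    for x_metric in octa_metrics:
        for y_metric in ("hrf_ir", "hrf_or", "hrf_total"):
            if y_metric not in metrics_df.columns:
                continue
            sub = metrics_df[[x_metric, y_metric]].dropna()
            try:
                correlations.append(stats.correlate(
                    sub[x_metric].to_numpy(), sub[y_metric].to_numpy(),
                    x_metric=x_metric, y_metric=y_metric))
            except RetimetricsError as exc:
                log("-", f"corr_{x_metric}_{y_metric}", "skipped", str(exc))
    correlations_path = out_dir / "correlations.csv"
    rio.write_metrics(stats.correlation_table(correlations), correlations_path)

    log("-", "pipeline", "ok", f"{len(eye_rows)} eyes")
    flush_log()
    return {"metrics": metrics_path, "comparisons": comparisons_path,
            "correlations": correlations_path, "log": log_path}
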