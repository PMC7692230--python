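"""Three-group comparisons and the regression-based correlation screen.

Measurements are replicated in both eyes of a patient, so eyes are not
independent units. The default ``patient_mean`` clustering collapses fellow
eyes to the patient mean before a one-way ANOVA — a conservative reduction
with correct type-I error under arbitrary within-patient correlation. The
``naive`` mode treats eyes as independent units and is reported alongside
for comparison. Pairwise group contrasts are Welch-free two-sample t-tests
with Bonferroni correction over the three contrasts (adjusted
p = min(1, 3·p)); metrics are not jointly corrected across metrics.

The correlation screen regresses y on x by ordinary least squares and tests
the slope with a Student t on n−2 degrees of freedom.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import AnalysisError

PAIRWISE_CONTRASTS = (("noDR", "control"), ("DR", "control"), ("noDR", "DR"))


@dataclass
class GroupComparison:
    """Omnibus and pairwise results for one metric."""

    metric: str
    group_stats: pd.DataFrame = field(repr=False)  # n, mean, sd per group
    omnibus_f: float = np.nan
    omnibus_p: float = np.nan
    pairwise: dict[tuple[str, str], float] = field(default_factory=dict)
    pairwise_raw: dict[tuple[str, str], float] = field(default_factory=dict)
    clustering: str = "patient_mean"


@dataclass
class CorrelationResult:
    """OLS slope of y on x with its t statistic and two-sided p."""

    x_metric: str
    y_metric: str
    slope: float
    t_stat: float
    p_value: float
    n: int


def _collapse(df: pd.DataFrame, clustering: str) -> pd.DataFrame:
    """Reduce (patient, eye, group, value) rows to analysis units."""
    for col in ("patient_id", "group", "value"):
        if col not in df.columns:
            raise AnalysisError(f"values table missing column {col!r}")
    if clustering == "patient_mean":
        return (df.groupby(["patient_id", "group"], as_index=False)["value"]
                  .mean())
    if clustering == "naive":
        return df[["patient_id", "group", "value"]].copy()
    raise ValueError(f"unknown clustering {clustering!r}")


def compare_groups(values: pd.DataFrame, metric: str = "",
                   clustering: str = "patient_mean") -> GroupComparison:
    """One-way ANOVA across groups plus Bonferroni pairwise contrasts.

    ``values`` has columns ``patient_id, eye_id, group, value``. With
    ``clustering="patient_mean"`` fellow eyes are averaged per patient
    first; ``"naive"`` uses eyes as units.
    """
    units = _collapse(values, clustering)
    groups = sorted(units["group"].unique())
    if len(groups) < 2:
        raise AnalysisError("need at least 2 groups")
    samples = {g: units.loc[units["group"] == g, "value"].to_numpy()
               for g in groups}
    for g, arr in samples.items():
        if len(arr) < 2:
            raise AnalysisError(f"group {g!r} has < 2 units")
        if not np.all(np.isfinite(arr)):
            raise AnalysisError(f"group {g!r} has non-finite values")
    f_stat, p_omni = sps.f_oneway(*samples.values())
    gs = pd.DataFrame({
        "n": {g: len(a) for g, a in samples.items()},
        "mean": {g: float(a.mean()) for g, a in samples.items()},
        "sd": {g: float(a.std(ddof=1)) for g, a in samples.items()},
    })
    raw: dict[tuple[str, str], float] = {}
    adj: dict[tuple[str, str], float] = {}
    contrasts = [c for c in PAIRWISE_CONTRASTS
                 if c[0] in samples and c[1] in samples]
    if not contrasts:
        contrasts = list(itertools.combinations(groups, 2))
    n_contrasts = max(len(contrasts), 1)
    for a, b in contrasts:
        _, p = sps.ttest_ind(samples[a], samples[b])
        raw[(a, b)] = float(p)
        adj[(a, b)] = min(1.0, n_contrasts * float(p))
    return GroupComparison(
        metric=metric, group_stats=gs,
        omnibus_f=float(f_stat), omnibus_p=float(p_omni),
        pairwise=adj, pairwise_raw=raw, clustering=clustering,
    )


def correlate(x: np.ndarray, y: np.ndarray,
              x_metric: str = "x", y_metric: str = "y") -> CorrelationResult:
    """OLS slope of y on x and the Student t test of its significance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise AnalysisError("x and y must be paired 1-D arrays")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise AnalysisError("need at least 3 paired finite observations")
    if np.ptp(x) == 0:
        raise AnalysisError("zero variance in x: slope undefined")
    res = sps.linregress(x, y)
    if res.stderr == 0:
        t = np.inf if res.slope != 0 else 0.0
        p = 0.0 if res.slope != 0 else 1.0
    else:
        t = res.slope / res.stderr
        p = 2.0 * sps.t.sf(abs(t), n - 2)
    return CorrelationResult(x_metric=x_metric, y_metric=y_metric,
                             slope=float(res.slope), t_stat=float(t),
                             p_value=float(p), n=n)


def comparison_table(comparisons: list[GroupComparison]) -> pd.DataFrame:
    """Flatten GroupComparison results to one row per metric × clustering."""
    rows = []
    for comp in comparisons:
        row = {"metric": comp.metric, "clustering": comp.clustering,
               "omnibus_f": comp.omnibus_f, "omnibus_p": comp.omnibus_p}
        for g, s in comp.group_stats.iterrows():
            row[f"n_{g}"] = s["n"]
            row[f"mean_{g}"] = s["mean"]
            row[f"sd_{g}"] = s["sd"]
        for (a, b), p in comp.pairwise.items():
            row[f"p_adj_{a}_vs_{b}"] = p
        rows.append(row)
    return pd.DataFrame(rows)


def correlation_table(results: list[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "x_metric": r.x_metric, "y_metric": r.y_metric, "slope": r.slope,
        "t_stat": r.t_stat, "p_value": r.p_value, "n": r.n,
    } for r in results])
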