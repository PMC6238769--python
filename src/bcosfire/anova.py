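"""One-way ANOVA of each parameter's effect on each segmentation metric.

Observations are grid-search experiment records: each record is the
aggregate metric of one parameter combination, and records are grouped by
the levels of one parameter, marginalizing over the others.  The groups are
therefore not independent samples — the classical one-way F-test is applied
to them regardless, as is conventional when screening which tuning
parameters move the metrics at all.  A parameter/metric pair is flagged
significant when p <= 0.05; no multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .optimizer import ExperimentRecord

PARAMETERS = ("prep_threshold", "filter_threshold", "artifact_size")
METRICS = ("accuracy", "sensitivity", "specificity")

_PARAM_ATTR = {
    "prep_threshold": "preprocessing_threshold",
    "filter_threshold": "filter_threshold",
    "artifact_size": "artifact_size",
}

ALPHA = 0.05


@dataclass(frozen=True)
class AnovaResult:
    parameter: str
    metric: str
    f_stat: float
    p_value: float
    significant: bool
    df_between: int
    df_within: int
    degenerate: bool = False


def _group_values(
    records: Sequence[ExperimentRecord], parameter: str, metric: str
) -> list[np.ndarray]:
    if parameter not in _PARAM_ATTR:
        raise ValueError(f"unknown parameter {parameter!r}; expected one of {PARAMETERS}")
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")
    attr = _PARAM_ATTR[parameter]
    levels: dict[float, list[float]] = {}
    for rec in records:
        levels.setdefault(getattr(rec.params, attr), []).append(getattr(rec, metric))
    # sort by level value for a deterministic, order-independent grouping
    return [np.asarray(levels[k], dtype=np.float64) for k in sorted(levels)]


def one_way_anova(
    records: Sequence[ExperimentRecord], parameter: str, metric: str
) -> AnovaResult:
    """Classical one-way F-test of ``metric`` across the levels of ``parameter``.

    Requires at least two distinct levels and at least one level with two or
    more records.  Zero within-group variance everywhere yields a flagged
    degenerate result rather than an exception.
    """
    groups = _group_values(records, parameter, metric)
    if len(groups) < 2:
        raise ValueError(
            f"parameter {parameter!r} has fewer than two levels among the records"
        )
    if max(len(g) for g in groups) < 2:
        raise ValueError("at least one level needs two or more records")

    n_total = sum(len(g) for g in groups)
    df_between = len(groups) - 1
    df_within = n_total - len(groups)

    within_ss = sum(float(((g - g.mean()) ** 2).sum()) for g in groups)
    if within_ss == 0.0:
        grand = np.concatenate(groups).mean()
        between_ss = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        if between_ss == 0.0:  # all observations identical
            return AnovaResult(parameter, metric, 0.0, 1.0, False,
                               df_between, df_within, degenerate=True)
        return AnovaResult(parameter, metric, float("inf"), 0.0, True,
                           df_between, df_within, degenerate=True)

    f_stat, p_value = stats.f_oneway(*groups)
    return AnovaResult(
        parameter=parameter,
        metric=metric,
        f_stat=float(f_stat),
        p_value=float(p_value),
        significant=bool(p_value <= ALPHA),
        df_between=df_between,
        df_within=df_within,
    )


def anova_matrix(records: Sequence[ExperimentRecord]) -> list[AnovaResult]:
    """All parameter x metric combinations (3 x 3 = 9 results)."""
    return [
        one_way_anova(records, parameter, metric)
        for parameter in PARAMETERS
        for metric in METRICS
    ]


def significance_grid(results: Sequence[AnovaResult]) -> pd.DataFrame:
    """Check-mark grid (rows: parameters, columns: metrics)."""
    frame = pd.DataFrame(index=list(PARAMETERS), columns=list(METRICS), dtype=object)
    for res in results:
        frame.loc[res.parameter, res.metric] = "yes" if res.significant else "no"
    return frame


def detail_frame(results: Sequence[AnovaResult]) -> pd.DataFrame:
    """Long-form detail table: F statistic, p-value, and conclusion per pair."""
    return pd.DataFrame(
        {
            "parameter": [r.parameter for r in results],
            "metric": [r.metric for r in results],
            "f_stat": [r.f_stat for r in results],
            "p_value": [r.p_value for r in results],
            "significant": [r.significant for r in results],
            "df_between": [r.df_between for r in results],
            "df_within": [r.df_within for r in results],
            "degenerate": [r.degenerate for r in results],
        }
    )
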