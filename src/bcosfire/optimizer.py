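"""Grid search over the three segmentation parameters.

The search space is the Cartesian product of preprocessing threshold
(fractions, default 0.1-0.6 in steps of 0.1), filter threshold (integer
percent, default 25-50), background-artifact size (default the sizes
0/9/18/28/38/48 seen in published experiment tables), and the
artifact-removal algorithm.  Each grid point is evaluated by aggregate
metrics over an evaluation split; the expensive vessel-likelihood response
is cached per (image, preprocessing threshold) since thresholding and
component removal are cheap re-passes.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .metrics import ConfusionCounts, confusion, derive_metrics
from .postprocess import REMOVAL_ALGORITHMS, SegmentationParams, binarize, remove_artifacts
from .raster_io import DatasetItem

log = logging.getLogger(__name__)

#: callable returning the continuous vessel-likelihood map of one item at a
#: given preprocessing threshold
ResponseFn = Callable[[DatasetItem, float], np.ndarray]


def _dedup(values: Iterable, what: str) -> tuple:
    seen: list = []
    for v in values:
        if v in seen:
            log.info("duplicate %s value %r dropped from the grid", what, v)
        else:
            seen.append(v)
    return tuple(seen)


@dataclass(frozen=True)
class ParameterGrid:
    """Searchable parameter ranges (duplicates are dropped with a log note)."""

    prep_thresholds: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6)
    filter_thresholds: tuple[int, ...] = tuple(range(25, 51))
    artifact_sizes: tuple[int, ...] = (0, 9, 18, 28, 38, 48)
    removal_algorithms: tuple[str, ...] = ("component_filter",)

    def __post_init__(self) -> None:
        for name in ("prep_thresholds", "filter_thresholds", "artifact_sizes", "removal_algorithms"):
            values = getattr(self, name)
            if not values:
                raise ValueError(f"{name} must be non-empty")
            object.__setattr__(self, name, _dedup(values, name))
        unknown = set(self.removal_algorithms) - set(REMOVAL_ALGORITHMS)
        if unknown:
            raise ValueError(f"unknown removal algorithms: {sorted(unknown)}")

    def __len__(self) -> int:
        return (
            len(self.prep_thresholds)
            * len(self.filter_thresholds)
            * len(self.artifact_sizes)
            * len(self.removal_algorithms)
        )

    def points(self) -> Iterable[SegmentationParams]:
        for p, ft, sz, alg in itertools.product(
            self.prep_thresholds,
            self.filter_thresholds,
            self.artifact_sizes,
            self.removal_algorithms,
        ):
            yield SegmentationParams(
                preprocessing_threshold=p,
                filter_threshold=ft,
                artifact_size=sz,
                removal_algorithm=alg,
            )


@dataclass(frozen=True)
class ExperimentRecord:
    """One grid-search row: a parameter combination and its aggregate metrics."""

    params: SegmentationParams
    sensitivity: float
    specificity: float
    accuracy: float
    n_images: int = 0


def make_split(
    items: Sequence[DatasetItem], fraction: float = 0.5, seed: int = 0
) -> tuple[list[DatasetItem], list[DatasetItem]]:
    """Deterministic shuffle-and-split into evaluation and test sets."""
    if len(items) < 2:
        raise ValueError("need at least two items to split")
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"split fraction must lie in (0, 1), got {fraction}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(items))
    n_eval = min(max(int(round(fraction * len(items))), 1), len(items) - 1)
    eval_set = [items[i] for i in sorted(order[:n_eval])]
    test_set = [items[i] for i in sorted(order[n_eval:])]
    return eval_set, test_set


def evaluate_params(
    responses: Sequence[np.ndarray],
    items: Sequence[DatasetItem],
    params: SegmentationParams,
) -> ExperimentRecord:
    """Aggregate Se/Sp/Acc of one parameter combination over a set of items."""
    total = ConfusionCounts(0, 0, 0, 0)
    for resp, item in zip(responses, items):
        mask = remove_artifacts(binarize(resp, params.filter_threshold), params)
        total = total + confusion(mask, item.gt_mask, item.fov_mask)
    result = derive_metrics(total)
    return ExperimentRecord(
        params=params,
        sensitivity=result.sensitivity if result.sensitivity is not None else float("nan"),
        specificity=result.specificity if result.specificity is not None else float("nan"),
        accuracy=result.accuracy,
        n_images=len(items),
    )


def run_grid(
    items: Sequence[DatasetItem],
    grid: ParameterGrid,
    response_fn: ResponseFn,
) -> list[ExperimentRecord]:
    """Evaluate the full Cartesian product of the grid on an evaluation set."""
    for item in items:
        if item.gt_mask is None:
            raise ValueError(f"item '{item.identifier}' has no ground truth")

    records: list[ExperimentRecord] = []
    for p in grid.prep_thresholds:
        responses = [response_fn(item, p) for item in items]
        for ft, sz, alg in itertools.product(
            grid.filter_thresholds, grid.artifact_sizes, grid.removal_algorithms
        ):
            params = SegmentationParams(
                preprocessing_threshold=p,
                filter_threshold=ft,
                artifact_size=sz,
                removal_algorithm=alg,
            )
            records.append(evaluate_params(responses, items, params))
    return records


def _selection_key(record: ExperimentRecord):
    p = record.params
    return (
        -record.accuracy,
        -record.sensitivity,
        -record.specificity,
        p.preprocessing_threshold,
        p.filter_threshold,
        p.artifact_size,
        p.removal_algorithm,
    )


def select_best(records: Sequence[ExperimentRecord]) -> ExperimentRecord:
    """Best combination: maximize accuracy, break ties by higher sensitivity,
    then higher specificity, then lexicographically smallest parameters.

    The rule is deterministic and invariant to the order of ``records``.
    """
    if not records:
        raise ValueError("select_best needs at least one record")
    return min(records, key=_selection_key)


def records_frame(records: Sequence[ExperimentRecord]) -> pd.DataFrame:
    """Experiment records as a flat DataFrame (one row per combination)."""
    return pd.DataFrame(
        {
            "prep_threshold": [r.params.preprocessing_threshold for r in records],
            "filter_threshold": [r.params.filter_threshold for r in records],
            "artifact_size": [r.params.artifact_size for r in records],
            "removal_algorithm": [r.params.removal_algorithm for r in records],
            "sensitivity": [r.sensitivity for r in records],
            "specificity": [r.specificity for r in records],
            "accuracy": [r.accuracy for r in records],
            "n_images": [r.n_images for r in records],
        }
    )


SORT_KEYS = ("sensitivity", "specificity", "accuracy", "prep_threshold",
             "filter_threshold", "artifact_size")


def report(
    records: Sequence[ExperimentRecord],
    sort_key: str = "sensitivity",
    ascending: bool = False,
) -> str:
    """Delimited experiment table, sorted (default: sensitivity, descending),
    with the best combination flagged by ``*``."""
    if not records:
        raise ValueError("report needs at least one record")
    if sort_key not in SORT_KEYS:
        raise ValueError(f"unknown sort key {sort_key!r}; expected one of {SORT_KEYS}")
    frame = records_frame(records)
    best = select_best(records)
    frame["best"] = [
        "*" if r is best else "" for r in records
    ]
    frame = frame.sort_values(sort_key, ascending=ascending, kind="stable")
    frame.insert(0, "experiment", range(1, len(frame) + 1))
    return frame.to_string(index=False, float_format=lambda v: f"{v:.3f}")
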