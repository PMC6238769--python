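"""Published grid-search experiment records for the three fundus benchmarks.

These are the experiment-wise results reported by the published optimization
study of the trainable B-COSFIRE segmenter on DRIVE, STARE and CHASE-DB1
(one row per parameter combination: preprocessing threshold, filter
threshold, background-artifact size, then sensitivity / specificity /
accuracy).  They serve as fixed inputs for regression checks of the
best-combination selection rule — the datasets themselves are not required.

Transcription note: in the CHASE-DB1 table the sensitivity of row 5 is
corrupted in the source ("0.80.1"); it is transcribed as 0.801, the only
value consistent with the column's descending sort.
"""

from __future__ import annotations

from .optimizer import ExperimentRecord
from .postprocess import SegmentationParams

_DRIVE = [
    (0.4, 30, 18, 0.813, 0.965, 0.952),
    (0.4, 30, 28, 0.811, 0.966, 0.952),
    (0.5, 30, 18, 0.811, 0.965, 0.951),
    (0.4, 31, 48, 0.798, 0.969, 0.954),
    (0.4, 32, 18, 0.794, 0.970, 0.954),
    (0.3, 30, 28, 0.794, 0.970, 0.954),
    (0.4, 32, 28, 0.792, 0.970, 0.954),
    (0.5, 32, 18, 0.792, 0.970, 0.954),
    (0.3, 30, 38, 0.792, 0.970, 0.954),
    (0.3, 30, 48, 0.790, 0.971, 0.955),
    (0.4, 32, 48, 0.788, 0.971, 0.955),
    (0.5, 32, 38, 0.788, 0.971, 0.954),
    (0.5, 32, 48, 0.787, 0.971, 0.955),
]

_STARE = [
    (0.5, 31, 18, 0.802, 0.964, 0.948),
    (0.5, 31, 18, 0.802, 0.964, 0.949),
    (0.5, 31, 28, 0.801, 0.963, 0.951),
    (0.5, 31, 28, 0.801, 0.962, 0.953),
    (0.5, 27, 18, 0.800, 0.961, 0.953),
    (0.5, 28, 0, 0.800, 0.962, 0.953),
    (0.5, 28, 9, 0.799, 0.963, 0.953),
    (0.4, 28, 18, 0.798, 0.964, 0.953),
    (0.3, 30, 18, 0.786, 0.964, 0.952),
    (0.2, 31, 0, 0.784, 0.964, 0.952),
    (0.2, 31, 9, 0.784, 0.964, 0.952),
    (0.2, 41, 28, 0.779, 0.964, 0.952),
    (0.1, 41, 38, 0.779, 0.964, 0.952),
]

_CHASE_DB1 = [
    (0.1, 31, 18, 0.802, 0.964, 0.953),
    (0.2, 31, 18, 0.802, 0.964, 0.953),
    (0.1, 31, 28, 0.801, 0.964, 0.953),
    (0.2, 31, 28, 0.801, 0.964, 0.953),
    (0.1, 31, 38, 0.801, 0.964, 0.953),  # sensitivity transcribed from "0.80.1"
    (0.2, 31, 38, 0.800, 0.964, 0.953),
    (0.3, 31, 18, 0.800, 0.964, 0.953),
    (0.3, 31, 28, 0.799, 0.964, 0.953),
    (0.3, 31, 38, 0.798, 0.965, 0.953),
    (0.4, 31, 18, 0.786, 0.964, 0.952),
    (0.4, 31, 28, 0.785, 0.964, 0.952),
    (0.4, 31, 38, 0.784, 0.965, 0.952),
]

#: published best-combination summaries (prep, filter, size, Se, Sp, Acc)
BEST_COMBINATIONS = {
    "drive": (0.3, 30, 48, 0.790, 0.971, 0.955),
    "stare": (0.5, 27, 18, 0.865, 0.961, 0.953),
    "chase_db1": (0.2, 31, 38, 0.800, 0.964, 0.953),
}


def _to_records(rows: list[tuple]) -> list[ExperimentRecord]:
    return [
        ExperimentRecord(
            params=SegmentationParams(
                preprocessing_threshold=p, filter_threshold=ft, artifact_size=sz
            ),
            sensitivity=se,
            specificity=sp,
            accuracy=acc,
            n_images=0,
        )
        for p, ft, sz, se, sp, acc in rows
    ]


def published_records(dataset: str) -> list[ExperimentRecord]:
    """Published experiment records for ``dataset`` in {drive, stare, chase_db1}."""
    tables = {"drive": _DRIVE, "stare": _STARE, "chase_db1": _CHASE_DB1}
    key = dataset.lower().replace("-", "_")
    if key not in tables:
        raise KeyError(f"unknown dataset {dataset!r}; expected one of {sorted(tables)}")
    return _to_records(tables[key])
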