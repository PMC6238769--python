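import numpy as np
import pytest

import bcosfire as bc
from bcosfire.optimizer import (
    ExperimentRecord,
    ParameterGrid,
    make_split,
    records_frame,
    report,
    run_grid,
    select_best,
)
from bcosfire.postprocess import SegmentationParams
from bcosfire.raster_io import DatasetItem
from bcosfire.reference_records import BEST_COMBINATIONS, published_records


def record(prep=0.3, ft=30, size=0, se=0.5, sp=0.5, acc=0.5):
    return ExperimentRecord(
        params=SegmentationParams(
            preprocessing_threshold=prep, filter_threshold=ft, artifact_size=size
        ),
        sensitivity=se,
        specificity=sp,
        accuracy=acc,
    )


class TestMakeSplit:
    def _items(self, n):
        img = np.zeros((8, 8))
        return [DatasetItem(image=img, identifier=f"i{k}") for k in range(n)]

    def test_twenty_items_split_in_half(self):
        ev, te = make_split(self._items(20), 0.5, seed=3)
        assert len(ev) == 10 and len(te) == 10

    def test_same_seed_same_split(self):
        items = self._items(9)
        first = make_split(items, 0.5, seed=42)
        second = make_split(items, 0.5, seed=42)
        assert [i.identifier for i in first[0]] == [i.identifier for i in second[0]]

    @pytest.mark.parametrize("n, fraction", [(2, 0.5), (7, 0.3), (11, 0.8)])
    def test_union_and_disjointness(self, n, fraction):
        items = self._items(n)
        ev, te = make_split(items, fraction, seed=0)
        ids = {i.identifier for i in ev} | {i.identifier for i in te}
        assert len(ids) == n and not ({i.identifier for i in ev} & {i.identifier for i in te})

    def test_invalid_fraction_raises(self):
        with pytest.raises(ValueError):
            make_split(self._items(4), 1.0)


class TestParameterGrid:
    def test_cardinality_is_product(self):
        grid = ParameterGrid((0.1, 0.2), (30, 31), (0, 9), ("component_filter",))
        assert len(grid) == 8
        assert len(list(grid.points())) == 8

    def test_duplicates_dropped_with_note(self, caplog):
        with caplog.at_level("INFO"):
            grid = ParameterGrid((0.1, 0.1, 0.2), (30,), (0,), ("component_filter",))
        assert grid.prep_thresholds == (0.1, 0.2)
        assert "duplicate" in caplog.text

    def test_empty_axis_raises(self):
        with pytest.raises(ValueError):
            ParameterGrid(prep_thresholds=())


class TestSelectBest:
    def test_published_drive_records_recover_best_combination(self):
        best = select_best(published_records("drive"))
        prep, ft, size, se, sp, acc = BEST_COMBINATIONS["drive"]
        assert best.params.preprocessing_threshold == prep
        assert best.params.filter_threshold == ft
        assert best.params.artifact_size == size
        assert best.accuracy == acc and best.sensitivity == se

    def test_single_record_returns_itself(self):
        r = record()
        assert select_best([r]) is r

    def test_specificity_breaks_remaining_tie(self):
        a = record(sp=0.90)
        b = record(sp=0.95)
        assert select_best([a, b]) is b

    def test_sensitivity_breaks_accuracy_tie(self):
        a = record(se=0.70, acc=0.95)
        b = record(se=0.80, acc=0.95)
        assert select_best([b, a]) is b

    def test_permutation_stable(self, rng):
        records = published_records("stare")
        order = rng.permutation(len(records))
        shuffled = [records[i] for i in order]
        assert select_best(shuffled).params == select_best(records).params

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            select_best([])


class TestRunGrid:
    def test_item_without_gt_is_named(self, small_suite):
        items = list(small_suite)
        items[1] = DatasetItem(image=items[1].image, identifier="nogt")
        grid = ParameterGrid((0.3,), (30,), (0,), ("component_filter",))
        with pytest.raises(ValueError, match="nogt"):
            run_grid(items, grid, lambda item, p: item.image)

    def test_one_record_per_grid_point(self, small_suite):
        grid = ParameterGrid((0.2, 0.4), (30, 40), (0, 9), ("component_filter",))
        seg = bc.VesselSegmenter().fit()
        records = run_grid(
            small_suite[:2], grid,
            lambda item, p: seg.response(item.image, item.fov_mask, p),
        )
        assert len(records) == 8
        assert all(r.n_images == 2 for r in records)


class TestReport:
    def test_published_table_order_is_sensitivity_descending(self):
        records = published_records("drive")
        text = report(records)
        se_column = [r.sensitivity for r in records]
        assert se_column == sorted(se_column, reverse=True)
        assert text.splitlines()[1].split()[0] == "1"

    def test_best_row_flagged(self):
        records = published_records("drive")
        text = report(records)
        starred = [ln for ln in text.splitlines() if ln.rstrip().endswith("*")]
        assert len(starred) == 1 and "0.790" in starred[0]

    def test_ascending_accuracy_sort(self):
        records = published_records("chase_db1")
        frame_text = report(records, sort_key="accuracy", ascending=True)
        accs = [
            float(line.split()[7])
            for line in frame_text.splitlines()[1:]
        ]
        assert accs == sorted(accs)

    def test_unknown_key_raises(self):
        with pytest.raises(ValueError):
            report([record()], sort_key="banana")

    def test_single_record_single_row(self):
        assert len(report([record()]).splitlines()) == 2


def test_records_frame_round_trip():
    records = published_records("stare")
    frame = records_frame(records)
    assert len(frame) == 13
    assert frame["accuracy"].max() == pytest.approx(0.953)
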