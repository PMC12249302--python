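"""Matching protocol, error taxonomy, metrics arithmetic, reports."""

import numpy as np
import pandas as pd
import pytest

from sishdetect.errors import MetricsError, ParameterError, SchemaError
from sishdetect.evaluation import (
    MatchResult,
    aggregate_report,
    compare_methods,
    expert_filter,
    load_benchmark_counts,
    match_instances,
    match_points,
    metrics,
)
from sishdetect.starconvex import DetectionSet
from sishdetect.synthetic import SceneConfig, generate_scene

from .oracles import match_instances_oracle, match_points_oracle


def random_label_pair(rng, n_labels=4, size=30):
    """A ground-truth mask and a perturbed prediction of it."""
    gt = np.zeros((size, size), dtype=np.int32)
    for lab in range(1, n_labels + 1):
        r, c = rng.integers(5, size - 5, 2)
        rad = rng.integers(3, 6)
        rr, cc = np.mgrid[0:size, 0:size]
        gt[np.hypot(rr - r, cc - c) <= rad] = lab
    shift = rng.integers(-2, 3, 2)
    pred = np.roll(gt, tuple(shift), axis=(0, 1))
    if rng.uniform() < 0.5 and pred.max() > 1:
        pred[pred == pred.max()] = 0  # drop an instance
    return pred, gt


class TestMatchInstances:
    def test_perfect_prediction(self, default_scene):
        res = match_instances(default_scene.mask, default_scene.mask)
        n = default_scene.mask.max()
        assert (res.tp, res.fp, res.fn) == (n, 0, 0)

    def test_split_nucleus_one_tp_one_fp(self):
        gt = np.zeros((20, 20), dtype=np.int32)
        gt[4:16, 4:16] = 1
        pred = np.zeros_like(gt)
        pred[4:16, 4:10] = 1
        pred[4:16, 10:16] = 2
        res = match_instances(pred, gt, iou_thresh=0.4)
        assert (res.tp, res.fp, res.fn) == (1, 1, 0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pred, gt = random_label_pair(rng)
        for thresh in (0.3, 0.5):
            res = match_instances(pred, gt, thresh)
            assert (res.tp, res.fp, res.fn) == match_instances_oracle(pred, gt, thresh)

    def test_swap_symmetry(self):
        rng = np.random.default_rng(3)
        pred, gt = random_label_pair(rng)
        a = match_instances(pred, gt, 0.5)
        b = match_instances(gt, pred, 0.5)
        assert (a.tp, a.fp, a.fn) == (b.tp, b.fn, b.fp)

    def test_shape_mismatch(self):
        with pytest.raises(ParameterError):
            match_instances(np.zeros((3, 3), int), np.zeros((4, 4), int))


def _detections_from_mask(mask):
    centroids = []
    for lab in range(1, mask.max() + 1):
        sel = np.argwhere(mask == lab)
        centroids.append((sel[:, 0].mean(), sel[:, 1].mean()))
    return DetectionSet(polygons=[None] * mask.max(), centroids=centroids,
                        instance_mask=mask)


class TestMatchPoints:
    def test_each_point_in_distinct_instance(self):
        mask = np.zeros((20, 20), dtype=np.int32)
        mask[2:8, 2:8] = 1
        mask[12:18, 12:18] = 2
        ds = _detections_from_mask(mask)
        res = match_points(ds, [(5, 5), (15, 15)])
        assert (res.tp, res.fp, res.fn) == (2, 0, 0)

    def test_background_point_is_fn(self):
        mask = np.zeros((20, 20), dtype=np.int32)
        mask[2:8, 2:8] = 1
        ds = _detections_from_mask(mask)
        res = match_points(ds, [(5, 5), (15, 15)])
        assert (res.tp, res.fp, res.fn) == (1, 0, 1)

    def test_two_points_one_instance_nearest_wins(self):
        mask = np.zeros((20, 20), dtype=np.int32)
        mask[4:16, 4:16] = 1
        ds = _detections_from_mask(mask)
        res = match_points(ds, [(9, 9), (5, 5)])
        assert (res.tp, res.fp, res.fn) == (1, 0, 1)

    def test_unclaimed_instance_is_fp(self):
        mask = np.zeros((20, 20), dtype=np.int32)
        mask[2:8, 2:8] = 1
        mask[12:18, 12:18] = 2
        ds = _detections_from_mask(mask)
        res = match_points(ds, [(5, 5)])
        assert (res.tp, res.fp, res.fn) == (1, 1, 0)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_containment_oracle(self, seed):
        rng = np.random.default_rng(50 + seed)
        mask = np.zeros((30, 30), dtype=np.int32)
        for lab in (1, 2, 3):
            r, c = rng.integers(5, 25, 2)
            rr, cc = np.mgrid[0:30, 0:30]
            mask[np.hypot(rr - r, cc - c) <= 4] = lab
        from sishdetect.labeling import relabel_consecutive

        mask = relabel_consecutive(mask)
        if mask.max() == 0:
            return
        ds = _detections_from_mask(mask)
        points = [tuple(rng.integers(0, 30, 2).astype(float)) for _ in range(5)]
        res = match_points(ds, points)
        assert (res.tp, res.fp, res.fn) == match_points_oracle(
            mask, ds.centroids, points
        )
        assert res.tp + res.fn == len(points)


class TestExpertFilter:
    def test_single_red_signal_excluded(self):
        df = pd.DataFrame(
            [{"red_signals": 1, "overlaps_neighbor": False, "touches_border": False}]
        )
        assert len(expert_filter(df)) == 0

    def test_border_touching_excluded_despite_signals(self):
        df = pd.DataFrame(
            [{"red_signals": 5, "overlaps_neighbor": False, "touches_border": True}]
        )
        assert len(expert_filter(df)) == 0

    def test_matches_row_predicate(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {
                "red_signals": rng.integers(0, 5, 50),
                "overlaps_neighbor": rng.integers(0, 2, 50).astype(bool),
                "touches_border": rng.integers(0, 2, 50).astype(bool),
            }
        )
        got = expert_filter(df)
        expected = [
            i for i, r in df.iterrows()
            if r.red_signals >= 2 and not r.overlaps_neighbor and not r.touches_border
        ]
        assert list(got.index) == expected

    def test_missing_column_rejected(self):
        with pytest.raises(SchemaError):
            expert_filter(pd.DataFrame({"red_signals": [2]}))


class TestMetrics:
    @pytest.mark.parametrize(
        "tp,fp,fn,recall,precision,f1",
        [
            (143, 3, 3, 97.9, 97.9, 97.9),
            (6, 2, 0, 100.0, 75.0, 85.7),
            (5, 0, 0, 100.0, 100.0, 100.0),
            (62, 2, 2, 96.9, 96.9, 96.9),  # exercises the half-up tie at 96.875
        ],
    )
    def test_reported_count_triples(self, tp, fp, fn, recall, precision, f1):
        row = metrics(MatchResult(tp, fp, fn))
        assert (row.recall, row.precision, row.f1) == (recall, precision, f1)

    def test_f1_is_harmonic_mean_before_rounding(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            tp = int(rng.integers(1, 200))
            fp = int(rng.integers(0, 50))
            fn = int(rng.integers(0, 50))
            r = tp / (tp + fn)
            p = tp / (tp + fp)
            f1 = 2 * tp / (2 * tp + fp + fn)
            assert f1 == pytest.approx(2 * p * r / (p + r))

    def test_all_zero_counts_rejected(self):
        with pytest.raises(MetricsError):
            metrics(MatchResult(0, 0, 0))


class TestAggregateReport:
    def test_single_row_mean_equals_row(self):
        row = metrics(MatchResult(9, 1, 0))
        rep = aggregate_report([row])
        assert rep.mean_f1 == row.f1
        assert rep.std_f1 == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ParameterError):
            aggregate_report([])

    @pytest.mark.parametrize(
        "table,means,stds",
        [
            ("visual", (98.34, 97.5, 97.87), (2.4, 3.0, 1.9)),
            ("expert", (99.02, 96.3, 97.50), (1.8, 6.6, 3.6)),
        ],
    )
    def test_benchmark_tables_reproduce(self, table, means, stds):
        """Every published per-image row and the summary rows are
        recomputed exactly from the TP/FP/FN triples."""
        df = load_benchmark_counts()
        sub = df[df.table == table]
        assert len(sub) == 20
        rows = []
        for _, r in sub.iterrows():
            row = metrics(MatchResult(int(r.tp), int(r.fp), int(r.fn)),
                          image_id=r.image_id)
            assert (row.recall, row.precision, row.f1) == (r.recall, r.precision, r.f1)
            rows.append(row)
        rep = aggregate_report(rows)
        assert (rep.mean_recall, rep.mean_precision, rep.mean_f1) == means
        assert (rep.std_recall, rep.std_precision, rep.std_f1) == stds


class TestCompareMethods:
    def test_ground_truth_method_scores_100(self):
        scenes = [generate_scene(SceneConfig(seed=s, n_nuclei=5)) for s in (1, 2)]
        truth = {sc.config.seed: sc.mask for sc in scenes}

        def perfect(img):
            for sc in scenes:
                if np.array_equal(img, sc.image):
                    return sc.mask
            raise AssertionError("unknown scene")

        def empty(img):
            return np.zeros(img.shape[:2], dtype=np.int32)

        table = compare_methods({"perfect": perfect, "empty": empty}, scenes)
        row = table[table.method == "perfect"].iloc[0]
        assert (row.precision, row.recall, row.f1) == (100.0, 100.0, 100.0)

    def test_pooled_counts_additive(self):
        scenes = [generate_scene(SceneConfig(seed=s, n_nuclei=4)) for s in (3, 4)]

        def shifted(img):
            for sc in scenes:
                if np.array_equal(img, sc.image):
                    return np.roll(sc.mask, 1, axis=0)
            raise AssertionError

        total = MatchResult(0, 0, 0)
        for sc in scenes:
            total = total + match_instances(np.roll(sc.mask, 1, axis=0), sc.mask)
        table = compare_methods({"a": shifted, "b": shifted}, scenes)
        row = table.iloc[0]
        expected = metrics(total)
        assert (row.precision, row.recall, row.f1) == (
            expected.precision, expected.recall, expected.f1,
        )
        assert table.iloc[0].f1 == table.iloc[1].f1

    def test_needs_two_methods(self):
        with pytest.raises(ParameterError):
            compare_methods({"only": lambda im: im}, [])
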