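"""Metrics against brute-force oracles; split protocols; downsampling."""

import numpy as np
import pytest
from sklearn.metrics import average_precision_score

from modtransfer.errors import DataError, MetricError, ProtocolError
from modtransfer.evaluation import (TargetSegmentSet, accuracy, average_f1,
                                    class_ap, downsample_training,
                                    evaluate_model, make_split,
                                    mean_average_precision)


# -- independent brute-force references -------------------------------------

def _brute_accuracy(pred, lab):
    return sum(int(p == l) for p, l in zip(pred, lab)) / len(lab)


def _brute_f1(pred, lab, n_classes):
    f1s = []
    for c in range(n_classes):
        tp = sum(1 for p, l in zip(pred, lab) if p == c and l == c)
        fp = sum(1 for p, l in zip(pred, lab) if p == c and l != c)
        fn = sum(1 for p, l in zip(pred, lab) if p != c and l == c)
        f1s.append(2 * tp / (2 * tp + fp + fn) if tp + fp + fn else 0.0)
    return sum(f1s) / n_classes


def _brute_ap(scores, positives):
    order = sorted(range(len(scores)), key=lambda i: (-scores[i], i))
    precisions, hits = [], 0
    for rank, i in enumerate(order, start=1):
        if positives[i]:
            hits += 1
            precisions.append(hits / rank)
    return sum(precisions) / len(precisions)


class TestAccuracy:
    @pytest.mark.parametrize("pred,lab,expected", [
        ([1, 2, 3], [1, 2, 3], 1.0),
        ([1, 2, 3], [0, 0, 0], 0.0),
        ([1, 1, 0, 0], [1, 1, 0, 1], 0.75),
    ])
    def test_closed_cases(self, pred, lab, expected):
        assert accuracy(np.array(pred), np.array(lab)) == expected

    def test_length_mismatch(self):
        with pytest.raises(MetricError):
            accuracy(np.array([1]), np.array([1, 2]))


class TestAverageF1:
    def test_perfect_predictions(self):
        y = np.array([0, 1, 2, 0])
        assert average_f1(y, y, 3) == 1.0

    def test_two_class_hand_confusion(self):
        # class 0: TP=2 FP=1 FN=1 -> 0.6667; class 1: TP=1 FP=1 FN=1 -> 0.5
        labels = np.array([0, 0, 0, 1, 1])
        preds = np.array([0, 0, 1, 1, 0])
        assert average_f1(preds, labels, 2) == pytest.approx(
            (2 * 2 / (2 * 2 + 1 + 1) + 2 * 1 / (2 * 1 + 1 + 1)) / 2)

    def test_absent_class_contributes_zero(self):
        labels = np.array([0, 1, 0, 1])
        preds = labels.copy()
        assert average_f1(preds, labels, 3) == pytest.approx(2 / 3)


class TestClassAP:
    def test_perfect_ranking(self):
        assert class_ap([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    @pytest.mark.parametrize("r", [1, 2, 3, 5, 8])
    def test_single_positive_at_rank_r(self, r):
        n = 8
        scores = np.linspace(1.0, 0.1, n)
        positives = np.zeros(n, dtype=bool)
        positives[r - 1] = True
        assert class_ap(scores, positives) == pytest.approx(1 / r)

    def test_positives_at_ranks_one_and_three(self):
        scores = [0.9, 0.8, 0.7, 0.6, 0.5]
        positives = [1, 0, 1, 0, 0]
        assert class_ap(scores, positives) == pytest.approx((1 + 2 / 3) / 2)

    def test_tie_break_is_stable_original_index(self):
        # equal scores: earlier index outranks later
        assert class_ap([0.5, 0.5], [0, 1]) == pytest.approx(1 / 2)
        assert class_ap([0.5, 0.5], [1, 0]) == pytest.approx(1.0)

    def test_no_positives_undefined(self):
        with pytest.raises(MetricError):
            class_ap([0.1, 0.2], [0, 0])

    def test_matches_sklearn_on_tie_free_cases(self, rng):
        for _ in range(200):
            n = rng.integers(3, 30)
            scores = rng.permutation(n) + rng.uniform(0, 0.5)  # no ties
            pos = rng.integers(0, 2, n).astype(bool)
            if not pos.any():
                pos[rng.integers(0, n)] = True
            assert class_ap(scores, pos) == pytest.approx(
                average_precision_score(pos, scores))

    def test_ap_bounds_property(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 20))
            scores = rng.standard_normal(n)
            pos = rng.integers(0, 2, n).astype(bool)
            if not pos.any():
                pos[0] = True
            ap = class_ap(scores, pos)
            order = np.argsort(-scores, kind="stable")
            best_rank = int(np.flatnonzero(pos[order])[0]) + 1
            n_pos = int(pos.sum())
            # precision at the best positive's rank is 1/best_rank; the
            # mean over n_pos nonnegative terms is at least 1/n_pos of it
            assert 1 / (best_rank * n_pos) - 1e-12 <= ap <= 1.0 + 1e-12
            if n_pos == 1:
                assert ap == pytest.approx(1 / best_rank)
            all_on_top = pos[order][:n_pos].all()
            assert (ap == pytest.approx(1.0)) == bool(all_on_top)


class TestMAP:
    def test_closed_cases(self):
        assert mean_average_precision([1.0, 1.0]) == 1.0
        assert mean_average_precision({0: 1.0, 1: 0.5}) == 0.75
        assert mean_average_precision({0: 1.0, 1: None, 2: 0.5}) == 0.75

    def test_all_undefined_raises(self):
        with pytest.raises(MetricError):
            mean_average_precision({0: None})


def test_metric_oracle_equivalence_on_random_toy_cases(rng):
    """Accuracy, AF1 and AP agree with brute-force references on 1,000
    random toy prediction sets."""
    for _ in range(1000):
        n = int(rng.integers(2, 20))
        n_classes = int(rng.integers(2, 6))
        labels = rng.integers(0, n_classes, n)
        preds = rng.integers(0, n_classes, n)
        assert accuracy(preds, labels) == pytest.approx(
            _brute_accuracy(preds, labels))
        assert average_f1(preds, labels, n_classes) == pytest.approx(
            _brute_f1(preds, labels, n_classes))
        scores = rng.standard_normal(n)
        pos = labels == 0
        if pos.any():
            assert class_ap(scores, pos) == pytest.approx(
                _brute_ap(scores.tolist(), pos.tolist()))


# -- splits ------------------------------------------------------------------

def _target(rng, n=40, n_classes=4, subjects=4, sessions=2):
    return TargetSegmentSet(
        rng.standard_normal((n, 16, 2)),
        np.arange(n) % n_classes,
        subjects=np.arange(n) % subjects,
        sessions=np.arange(n) // (n // sessions) + 1,
    )


class TestSplits:
    def test_loso_one_fold_per_subject(self, rng):
        target = _target(rng)
        folds = make_split(target, "leave_one_subject_out")
        assert len(folds) == 4
        for s, (train, test) in enumerate(folds):
            assert set(target.subjects[test]) == {s}
            assert s not in set(target.subjects[train])

    def test_kfold_sizes(self, rng):
        target = _target(rng, n=100)
        folds = make_split(target, "kfold", seed=0, n_folds=10)
        assert len(folds) == 10
        assert all(te.size == 10 for _, te in folds)

    def test_subject_dependent_first_session_trains(self, rng):
        target = _target(rng)
        ((train, test),) = make_split(target, "subject_dependent")
        assert set(target.sessions[train]) == {1}
        assert set(target.sessions[test]) == {2}

    @pytest.mark.parametrize("protocol", ["subject_dependent",
                                          "leave_one_subject_out", "kfold"])
    def test_folds_disjoint_and_exhaustive(self, rng, protocol):
        target = _target(rng)
        for train, test in make_split(target, protocol, seed=1, n_folds=5):
            assert np.intersect1d(train, test).size == 0
            assert np.union1d(train, test).size == target.n

    def test_missing_metadata_raises(self, rng):
        bare = TargetSegmentSet(rng.standard_normal((10, 16, 2)),
                                np.zeros(10, dtype=int))
        with pytest.raises(ProtocolError):
            make_split(bare, "leave_one_subject_out")
        with pytest.raises(ProtocolError):
            make_split(bare, "subject_dependent")
        with pytest.raises(ProtocolError):
            make_split(bare, "nested_cv")


class TestDownsample:
    def test_full_fraction_is_identity(self, rng):
        target = _target(rng)
        assert downsample_training(target, 1.0) is target

    def test_quarter_of_200(self, rng):
        target = _target(rng, n=200, n_classes=5)
        reduced = downsample_training(target, 0.25, seed=0)
        assert reduced.n == 50

    def test_stratified_counts(self, rng):
        target = _target(rng, n=120, n_classes=3)
        reduced = downsample_training(target, 0.3, seed=4)
        counts = np.bincount(reduced.y, minlength=3)
        for c in range(3):
            assert abs(counts[c] - round(0.3 * 40)) <= 1

    def test_empty_class_warns(self, rng):
        target = TargetSegmentSet(rng.standard_normal((21, 8, 1)),
                                  np.array([0] * 20 + [1]))
        with pytest.warns(UserWarning, match="zero examples"):
            reduced = downsample_training(target, 0.05, seed=0)
        assert set(reduced.y) == {0}

    def test_invalid_fraction(self, rng):
        with pytest.raises(DataError):
            downsample_training(_target(rng), 0.0)


class TestEvalReport:
    def test_map_is_mean_of_defined_aps(self, tiny_mdnn_spec, rng):
        from modtransfer.models import build_mdnn
        net = build_mdnn(tiny_mdnn_spec, seed=0)
        target = TargetSegmentSet(rng.standard_normal((30, 32, 3)),
                                  rng.integers(0, 3, 30))  # class 3 absent
        report = evaluate_model(net, target)
        defined = [v for v in report.per_class_ap.values() if v is not None]
        assert report.per_class_ap[3] is None
        assert report.map == pytest.approx(np.mean(defined))
        assert 0 <= report.accuracy <= 1
        assert report.confusion.shape == (4, 4)

    def test_json_serialisable(self, tiny_mdnn_spec, rng, tmp_path):
        import json
        from modtransfer.models import build_mdnn
        net = build_mdnn(tiny_mdnn_spec, seed=0)
        target = TargetSegmentSet(rng.standard_normal((10, 32, 3)),
                                  rng.integers(0, 4, 10))
        report = evaluate_model(net, target, config={"strategy": "tto"})
        report.to_json(tmp_path / "r.json")
        data = json.loads((tmp_path / "r.json").read_text())
        assert data["config"]["strategy"] == "tto"
        assert data["accuracy"] == report.accuracy
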