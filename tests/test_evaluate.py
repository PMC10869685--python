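import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dvscreen import (BoundingBox, ConfusionMatrix, SynthParams, TrainConfig,
                      auc_roc, average_precision, confusion, cross_validate,
                      generate_exams_in_memory, group_kfold,
                      mean_average_precision, metrics)


def _box(x0, y0, x1, y1, score=1.0, cls="suspicious_mass"):
    return BoundingBox(x_min=x0, y_min=y0, x_max=x1, y_max=y1,
                       class_name=cls, objectness=score)


def _auc_oracle(labels, scores):
    """Exhaustive pairwise U-statistic: mean over (pos, neg) pairs of
    1[s_pos > s_neg] + 0.5·1[s_pos == s_neg]."""
    pos = [s for y, s in zip(labels, scores) if y == 1]
    neg = [s for y, s in zip(labels, scores) if y == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestConfusion:
    def test_perfect_and_inverted(self):
        cm = confusion([1, 1, 0, 0], [1, 1, 0, 0])
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (2, 2, 0, 0)
        cm = confusion([1, 0], [0, 1])
        assert (cm.fn, cm.fp) == (1, 1)

    def test_matches_tally_oracle_on_random_pairs(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 200)
        p = rng.integers(0, 2, 200)
        cm = confusion(y, p)
        tally = {"tp": 0, "fp": 0, "fn": 0, "tn": 0}
        for yi, pi in zip(y, p):
            tally[{(1, 1): "tp", (0, 1): "fp", (1, 0): "fn", (0, 0): "tn"}[(yi, pi)]] += 1
        assert dataclasses.asdict(cm) == tally
        assert cm.total == 200

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion([1, 0], [1])


class TestMetrics:
    def test_hand_arithmetic(self):
        m = metrics(ConfusionMatrix(tp=8, fp=2, fn=1, tn=9))
        assert m["precision"] == pytest.approx(0.8)
        assert m["recall"] == pytest.approx(8 / 9)
        assert m["f1"] == pytest.approx(2 * 0.8 * (8 / 9) / (0.8 + 8 / 9))
        assert m["accuracy"] == pytest.approx(0.85)
        assert m["undefined"] == []

    def test_undefined_ratio_convention(self):
        m = metrics(ConfusionMatrix(tp=0, fp=0, fn=3, tn=5))
        assert m["precision"] == 0.0 and "precision" in m["undefined"]

    def test_perfect_predictions(self):
        m = metrics(ConfusionMatrix(tp=5, fp=0, fn=0, tn=5))
        assert all(m[k] == 1.0 for k in ("precision", "recall", "f1", "accuracy"))


class TestAucRoc:
    def test_perfect_ranking(self):
        assert auc_roc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 4000)
        s = rng.random(4000)
        assert abs(auc_roc(y, s) - 0.5) < 0.03

    def test_matches_pairwise_oracle_small_n(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            n = int(rng.integers(2, 13))
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                continue
            s = np.round(rng.random(n), 1)  # coarse scores force ties
            assert auc_roc(y, s) == pytest.approx(_auc_oracle(y, s), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc_roc([1, 1], [0.2, 0.8])


class TestAveragePrecision:
    def test_perfect_predictions(self):
        gt = [_box(0, 0, 10, 10), _box(30, 30, 40, 40)]
        assert average_precision(list(gt), list(gt)) == pytest.approx(1.0)

    def test_no_predictions(self):
        assert average_precision([], [_box(0, 0, 10, 10)]) == 0.0

    def test_hand_traced_pr_curve(self):
        gt = [_box(0, 0, 10, 10)]
        preds = [_box(0, 0, 10, 10, score=0.9), _box(50, 50, 60, 60, score=0.8)]
        assert average_precision(preds, gt) == pytest.approx(1.0)

    def test_miss_before_hit_lowers_ap(self):
        gt = [_box(0, 0, 10, 10)]
        preds = [_box(50, 50, 60, 60, score=0.9), _box(0, 0, 10, 10, score=0.8)]
        assert average_precision(preds, gt) == pytest.approx(0.5)

    def test_low_score_unmatched_extra_never_increases_ap(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            gt = [_box(i * 20, 0, i * 20 + 10, 10) for i in range(int(rng.integers(1, 4)))]
            preds = [dataclasses.replace(g, objectness=round(float(rng.uniform(0.5, 1)), 3))
                     for g in gt if rng.random() < 0.8]
            base = average_precision(list(preds), list(gt))
            extra = preds + [_box(200, 200, 210, 210, score=0.01)]
            assert average_precision(extra, list(gt)) <= base + 1e-12

    def test_map_averages_over_classes(self):
        gt = [_box(0, 0, 10, 10, cls="suspicious_mass"),
              _box(30, 30, 40, 40, cls="lymph_node")]
        preds = [_box(0, 0, 10, 10, score=0.9, cls="suspicious_mass")]  # node missed
        out = mean_average_precision(preds, gt)
        assert out["per_class"]["suspicious_mass"] == pytest.approx(1.0)
        assert out["per_class"]["lymph_node"] == 0.0
        assert out["mAP"] == pytest.approx(0.5)


class TestGroupKFold:
    def test_even_deal(self):
        sids = [f"S{i}" for i in range(10) for _ in range(2)]
        assign = group_kfold(sids, k=5, seed=0)
        sizes = np.bincount(assign.fold_index, minlength=5)
        assert (sizes == 4).all()  # 2 studies x 2 breasts per fold

    def test_never_splits_a_study(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            n = int(rng.integers(6, 30))
            sids = [f"S{i}" for i in range(n) for _ in range(int(rng.integers(1, 5)))]
            k = int(rng.integers(2, min(6, n + 1)))
            assign = group_kfold(sids, k=k, seed=int(rng.integers(1000)))
            folds_of = {}
            for sid, f in zip(sids, assign.fold_index):
                folds_of.setdefault(sid, set()).add(f)
            assert all(len(v) == 1 for v in folds_of.values())

    def test_deterministic_under_seed(self):
        sids = [f"S{i}" for i in range(12)]
        a1 = group_kfold(sids, 4, seed=7)
        a2 = group_kfold(sids, 4, seed=7)
        assert a1 == a2

    def test_too_few_studies_rejected(self):
        with pytest.raises(ValueError):
            group_kfold(["A", "B"], k=3)


@pytest.fixture(scope="module")
def cv_cohort():
    return [e for e, _ in generate_exams_in_memory(SynthParams(seed=2), 40)]


class TestCrossValidate:
    def test_report_structure(self, cv_cohort):
        rep = cross_validate(cv_cohort, TrainConfig(seed=2, max_epochs=10), k=5, seed=2)
        assert len(rep["folds"]) == 5
        for f in rep["folds"]:
            assert {"tp", "fp", "fn", "tn"} == set(f["val"]["confusion"])
        assert "val_recall" in rep["mean"] and "test_auc" in rep["mean"]

    def test_separable_cohort_high_recall(self, cv_cohort):
        rep = cross_validate(cv_cohort, TrainConfig(seed=2, max_epochs=60), k=5, seed=2)
        assert rep["mean"]["val_recall"] >= 0.85

    def test_shuffled_labels_yield_chance_auc(self, cv_cohort):
        rng = np.random.default_rng(5)
        labels = [e.label for e in cv_cohort]
        shuffled = rng.permutation(labels)
        null = [dataclasses.replace(e, label=int(l)) for e, l in zip(cv_cohort, shuffled)]
        rep = cross_validate(null, TrainConfig(seed=5, max_epochs=15), k=5, seed=5)
        assert 0.4 <= rep["mean"]["val_auc"] <= 0.6
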