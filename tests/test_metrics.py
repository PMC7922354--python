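"""Confusion and ranking parameters against hand values and brute force."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import qsarbench as qb
from qsarbench.metrics import (
    CONFUSION_METRIC_NAMES,
    METRIC_NAMES,
    RANKING_METRIC_NAMES,
    InputError,
    _binary_ranking,
)
from conftest import make_prediction_set


def brute_force_auc(y, scores):
    """Pairwise concordance probability; ties count one half."""
    act, inact = scores[y], scores[~y]
    wins = sum((a > i) + 0.5 * (a == i) for a in act for i in inact)
    return wins / (len(act) * len(inact))


def perfect_prediction(k=3, per_class=4):
    classes = np.array([f"c{i}" for i in range(k)])
    true = np.repeat(classes, per_class)
    scores = np.full((len(true), k), -5.0)
    for j, c in enumerate(classes):
        scores[true == c, j] = 5.0 + np.arange((true == c).sum())
    return qb.PredictionSet(true, true.copy(), scores, classes)


class TestConfusionCounts:
    def test_perfect_three_class_identity(self):
        pred = qb.PredictionSet(["a", "b", "c"], ["a", "b", "c"],
                                np.eye(3), np.array(["a", "b", "c"]))
        cm, ovr = qb.confusion_counts(pred)
        assert (cm.to_numpy() == np.eye(3)).all()
        assert (ovr["TP"] == 1).all() and (ovr["FP"] == 0).all()
        assert (ovr["FN"] == 0).all() and (ovr["TN"] == 2).all()

    def test_direct_tally(self):
        pred = qb.PredictionSet(["a", "a", "b", "b"], ["a", "b", "b", "b"],
                                np.zeros((4, 2)), np.array(["a", "b"]))
        cm, ovr = qb.confusion_counts(pred)
        assert cm.to_numpy().sum() == 4
        assert ovr.loc["a"].tolist() == [1, 0, 1, 2]  # TP FP FN TN

    def test_counts_conserved_with_empty_predicted_class(self):
        pred = qb.PredictionSet(["a", "b", "c"], ["a", "b", "b"],
                                np.zeros((3, 3)), np.array(["a", "b", "c"]))
        cm, ovr = qb.confusion_counts(pred)
        assert cm["c"].sum() == 0
        assert ((ovr.sum(axis=1)) == 3).all()

    def test_label_outside_class_set_rejected(self):
        with pytest.raises(InputError):
            qb.PredictionSet(["a", "z"], ["a", "a"], np.zeros((2, 2)),
                             np.array(["a", "b"]))


class TestConfusionMetrics:
    def test_perfect_prediction_maxima(self):
        pred = perfect_prediction()
        out = qb.confusion_metrics(*qb.confusion_counts(pred))
        for name in ("ACC", "Cohen", "MCC", "BM", "F1", "TPR", "TNR",
                     "BACC", "Jaccard"):
            assert out[name] == pytest.approx(1.0), name

    def test_cohen_binary_hand_value(self):
        # TP=3 FN=1 FP=1 TN=3: p_o = 0.75, p_e = 0.5 -> kappa = 0.5
        true = ["p"] * 4 + ["n"] * 4
        pred_labels = ["p", "p", "p", "n", "n", "n", "n", "p"]
        pred = qb.PredictionSet(true, pred_labels, np.zeros((8, 2)),
                                np.array(["n", "p"]))
        out = qb.confusion_metrics(*qb.confusion_counts(pred))
        assert out["Cohen"] == pytest.approx(0.5)
        assert out["ACC"] == pytest.approx(0.75)

    def test_chance_level_confusion_is_zero_kappa(self):
        # identical rows: prediction independent of truth
        cm = pd.DataFrame([[5, 5], [5, 5]], index=["a", "b"], columns=["a", "b"])
        ovr = pd.DataFrame({"TP": [5, 5], "FP": [5, 5], "FN": [5, 5],
                            "TN": [5, 5]}, index=["a", "b"])
        out = qb.confusion_metrics(cm, ovr)
        assert out["Cohen"] == pytest.approx(0.0)
        assert out["BM"] == pytest.approx(0.0)

    def test_absent_class_excluded_from_macro(self):
        pred = qb.PredictionSet(["a", "a", "b"], ["a", "a", "b"],
                                np.zeros((3, 3)), np.array(["a", "b", "c"]))
        out = qb.confusion_metrics(*qb.confusion_counts(pred))
        assert out["TPR"] == pytest.approx(1.0)  # average over a, b only


class TestRankingMetrics:
    def test_auc_hand_value(self):
        y = np.array([True, True, False, False])
        s = np.array([0.9, 0.6, 0.7, 0.1])
        out = _binary_ranking(y, s, qb.MetricConfig())
        assert out["AUC"] == pytest.approx(0.75)

    def test_ef1_hand_value(self):
        y = np.zeros(100, bool)
        y[:10] = True
        s = np.linspace(0, 1, 100)
        s[0] = 2.0  # one active ranked first; ceil(1% of 100) = 1
        out = _binary_ranking(y, s, qb.MetricConfig())
        assert out["EF1"] == pytest.approx(10.0)

    def test_perfect_ranking_maxima(self):
        pred = perfect_prediction(k=3, per_class=5)
        out = qb.ranking_metrics(pred)
        for name in ("AUC", "AP", "BEDROC20", "BEDROC1609"):
            assert out[name] == pytest.approx(1.0, abs=1e-9), name
        # AUAC's ceiling under the continuous-rank convention is 1 - Ra/2
        assert out["AUAC"] == pytest.approx(1.0 - (5 / 15) / 2)

    @given(st.integers(0, 500))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_auc_rank_formula_equals_concordance(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 51))
        y = np.zeros(n, bool)
        y[rng.choice(n, size=int(rng.integers(1, n)), replace=False)] = True
        # quantized scores force ties
        s = np.round(rng.normal(size=n), 1)
        out = _binary_ranking(y, s, qb.MetricConfig())
        assert out["AUC"] == pytest.approx(brute_force_auc(y, s))

    def test_all_equal_scores_are_handled(self):
        y = np.array([True, False, True, False])
        out = _binary_ranking(y, np.ones(4), qb.MetricConfig())
        assert out["AUC"] == pytest.approx(0.5)
        assert np.isfinite(list(out.values())).all()

    def test_random_score_expectations(self, rng):
        """E[AUC] = 0.5 and E[EF] = 1 under shuffled scores (3 SE band)."""
        n, n_act, reps = 100, 10, 1000
        y = np.zeros(n, bool)
        y[:n_act] = True
        cfg = qb.MetricConfig()
        aucs, ef1s, ef5s = [], [], []
        for _ in range(reps):
            s = rng.permutation(n).astype(float)
            out = _binary_ranking(y, s, cfg)
            aucs.append(out["AUC"])
            ef1s.append(out["EF1"])
            ef5s.append(out["EF5"])
        for vals, expected in ((aucs, 0.5), (ef1s, 1.0), (ef5s, 1.0)):
            se = np.std(vals, ddof=1) / np.sqrt(reps)
            assert abs(np.mean(vals) - expected) < 3 * se + 1e-12

    def test_single_class_scores_skipped(self):
        pred = qb.PredictionSet(["a", "a", "b"], ["a", "a", "b"],
                                np.random.default_rng(0).normal(size=(3, 3)),
                                np.array(["a", "b", "c"]))
        out = qb.ranking_metrics(pred)  # class c skipped, a and b averaged
        assert set(out) == set(RANKING_METRIC_NAMES)


class TestBattery:
    def test_exactly_25_canonical_parameters(self, rng):
        mv = qb.metric_battery(make_prediction_set(rng))
        assert tuple(mv.to_series().index) == METRIC_NAMES
        assert len(METRIC_NAMES) == 25
        assert set(METRIC_NAMES) == set(CONFUSION_METRIC_NAMES) | set(RANKING_METRIC_NAMES)

    def test_deterministic(self, rng):
        pred = make_prediction_set(rng)
        a = qb.metric_battery(pred).to_series()
        b = qb.metric_battery(pred).to_series()
        assert (a == b).all()

    @given(st.integers(0, 300))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_bounds_on_random_inputs(self, seed):
        rng = np.random.default_rng(seed)
        mv = qb.metric_battery(make_prediction_set(
            rng, n=int(rng.integers(12, 80)), k=int(rng.integers(2, 5)),
            quality=float(rng.uniform(0, 3))))
        v = mv.values
        for name in ("AUC", "AUAC", "AP", "BEDROC20", "BEDROC1609", "ACC",
                     "BACC", "TPR", "TNR", "PPV", "NPV", "F1", "Jaccard"):
            assert 0.0 <= v[name] <= 1.0 + 1e-12, name
        for name in ("MCC", "Cohen", "BM", "MK"):
            assert -1.0 - 1e-12 <= v[name] <= 1.0 + 1e-12, name
        for name in ("EF1", "EF5", "ROC_EF1", "ROC_EF5", "RIE20", "RIE1609",
                     "LRp", "DOR"):
            assert v[name] >= 0.0 and np.isfinite(v[name]), name

    def test_macro_average_of_identical_per_class_values(self):
        # symmetric two-class problem: macro average equals the per-class value
        pred = perfect_prediction(k=2, per_class=6)
        out = qb.ranking_metrics(pred)
        y = pred.true_labels == "c0"
        single = _binary_ranking(y, pred.class_scores[:, 0], qb.MetricConfig())
        assert out["AUC"] == pytest.approx(single["AUC"])

    def test_csv_row_serialization(self, rng):
        mv = qb.metric_battery(make_prediction_set(rng))
        row = mv.to_csv_row()
        assert len(row.split(",")) == 25

    def test_invalid_vector_rejected(self):
        with pytest.raises(InputError):
            qb.MetricVector({"AUC": 1.0})
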