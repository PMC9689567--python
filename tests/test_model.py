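"""Correlation pruning, outlier diagnostics, logistic fit and metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from liftrisk.model import (
    evaluate,
    evaluate_confusion,
    fit_classifier,
    prune_correlated,
    remove_outliers,
)


def _labels(n):
    return np.array(["NO_RISK", "RISK"] * (n // 2))


class TestPruneCorrelated:
    def test_duplicated_column_keeps_first(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=100)
        table = pd.DataFrame({"A": a, "B": a.copy(), "C": rng.normal(size=100)})
        assert prune_correlated(table, ["A", "B", "C"]) == ["A", "C"]

    def test_orthogonal_features_all_kept(self):
        rng = np.random.default_rng(1)
        table = pd.DataFrame(rng.normal(size=(500, 5)),
                             columns=list("ABCDE"))
        assert prune_correlated(table, list("ABCDE")) == list("ABCDE")

    def test_high_correlation_drops_later_feature(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=400)
        y = 0.9 * x + np.sqrt(1 - 0.81) * rng.normal(size=400)
        r = np.corrcoef(x, y)[0, 1]
        assert r > 0.7  # oracle: direct correlation computation
        table = pd.DataFrame({"X": x, "Y": y})
        assert prune_correlated(table, ["X", "Y"]) == ["X"]

    def test_constant_column_dropped_with_warning(self, caplog):
        table = pd.DataFrame({"K": np.ones(50), "X": np.arange(50.0)})
        with caplog.at_level("WARNING", logger="liftrisk.model"):
            kept = prune_correlated(table, ["K", "X"])
        assert kept == ["X"]
        assert any("constant" in m for m in caplog.messages)


class TestRemoveOutliers:
    def test_clean_data_removes_few_rows(self):
        rng = np.random.default_rng(3)
        n = 400
        labels = _labels(n)
        shift = (labels == "RISK") * 2.0
        table = pd.DataFrame({
            "F1": rng.normal(size=n) + shift,
            "F2": rng.normal(size=n) + 0.5 * shift,
        })
        pruned, removed = remove_outliers(table, ["F1", "F2"], labels)
        # Gaussian designs put a few percent of mass beyond 3x mean leverage,
        # so "clean" still loses a handful of rows, never a large share
        assert len(removed) <= 0.05 * n
        assert len(pruned) + len(removed) == n

    def test_injected_extreme_point_removed(self):
        rng = np.random.default_rng(4)
        n = 200
        labels = _labels(n)
        shift = (labels == "RISK") * 1.5
        table = pd.DataFrame({
            "F1": rng.normal(size=n) + shift,
            "F2": rng.normal(size=n),
        })
        # 10-sigma design point on the wrong side of its NO_RISK label;
        # leave-one-out refit confirms it dominates the fit (Cook's D > 1)
        table.loc[16, ["F1", "F2"]] = [10.0, -10.0]
        _, removed = remove_outliers(table, ["F1", "F2"], labels)
        assert 16 in removed

    def test_guard_against_underdetermined_fit(self):
        rng = np.random.default_rng(5)
        table = pd.DataFrame(rng.normal(size=(12, 4)), columns=list("ABCD"))
        with pytest.raises(ValueError, match="refusing"):
            remove_outliers(table, list("ABCD"), _labels(12))


class TestFitClassifier:
    def test_perfectly_separable_feature_retained(self):
        n = 100
        labels = _labels(n)
        table = pd.DataFrame({
            "G": np.where(labels == "RISK", 1.0, -1.0),
            "label": labels,
        })
        report = fit_classifier(table, ["G"])
        assert report.final_features == ["G"]
        assert report.separation_flag
        assert report.metrics.accuracy == 100.0

    def test_pure_noise_features_prune_to_chance(self):
        accs = []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            n = 500
            table = pd.DataFrame(
                rng.normal(size=(n, 6)), columns=[f"N{i}" for i in range(6)]
            )
            table["label"] = _labels(n)
            report = fit_classifier(table, [f"N{i}" for i in range(6)])
            accs.append(report.metrics.accuracy)
            assert len(report.final_features) <= 6
        # null models must hover at chance (resubstitution inflation included)
        assert np.mean(accs) <= 60.0

    def test_informative_cohort_keeps_features_and_epv(self):
        rng = np.random.default_rng(6)
        n = 520
        labels = _labels(n)
        shift = (labels == "RISK").astype(float)
        table = pd.DataFrame({
            "A": rng.normal(size=n) + 0.8 * shift,
            "B": rng.normal(size=n) + 0.6 * shift,
            "C": rng.normal(size=n),
            "label": labels,
        })
        report = fit_classifier(table, ["A", "B", "C"])
        assert len(report.final_features) >= 1
        assert report.events_per_variable > 10
        assert "A" in report.final_features

    def test_rounds_recorded(self):
        rng = np.random.default_rng(9)
        n = 300
        labels = _labels(n)
        table = pd.DataFrame({
            "A": rng.normal(size=n) + (labels == "RISK"),
            "C": rng.normal(size=n),
            "label": labels,
        })
        report = fit_classifier(table, ["A", "C"])
        assert len(report.rounds) >= 1
        dropped = [f for r in report.rounds for f in r.dropped]
        assert "C" in dropped

    def test_determinism(self):
        rng = np.random.default_rng(8)
        n = 200
        table = pd.DataFrame({
            "A": rng.normal(size=n) + (_labels(n) == "RISK"),
            "label": _labels(n),
        })
        r1 = fit_classifier(table, ["A"])
        r2 = fit_classifier(table, ["A"])
        assert r1.to_dict() == r2.to_dict()


class TestEvaluate:
    def test_reference_confusion_matrix_metrics(self):
        """The canonical 2x2 check: counts (218, 39 / 49, 207) give accuracy
        82.8%, sensitivity 84.8%, specificity 80.9% and 425/513 correct."""
        m = evaluate_confusion(np.array([[218, 39], [49, 207]]))
        assert m.accuracy == 82.8
        assert m.sensitivity == 84.8
        assert m.specificity == 80.9
        assert m.n_correct == 425
        assert m.n_total == 513

    def test_perfect_predictions(self):
        labels = _labels(40)
        m = evaluate(labels, labels)
        assert (m.accuracy, m.sensitivity, m.specificity) == (100.0, 100.0, 100.0)

    def test_constant_predictor_on_balanced_set(self):
        labels = np.array(["NO_RISK"] * 100 + ["RISK"] * 100)
        preds = np.array(["NO_RISK"] * 200)
        m = evaluate(preds, labels)
        assert (m.accuracy, m.sensitivity, m.specificity) == (50.0, 100.0, 0.0)

    def test_unseen_label_rejected(self):
        with pytest.raises(ValueError, match="unseen"):
            evaluate(["MAYBE"], ["RISK"])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            evaluate(["RISK"], ["RISK", "NO_RISK"])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 500), min_size=4, max_size=4))
    def test_metric_identities_on_random_matrices(self, counts):
        cm = np.array(counts).reshape(2, 2)
        if cm.sum() == 0:
            return
        m = evaluate_confusion(cm)
        assert m.n_correct == cm[0, 0] + cm[1, 1]
        assert m.accuracy == pytest.approx(100 * m.n_correct / cm.sum(), abs=0.05)
        if cm[0].sum():
            assert m.sensitivity == pytest.approx(100 * cm[0, 0] / cm[0].sum(), abs=0.05)
        if cm[1].sum():
            assert m.specificity == pytest.approx(100 * cm[1, 1] / cm[1].sum(), abs=0.05)
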