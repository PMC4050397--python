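"""Tests for the logistic model: IRLS fit, stepwise selection, ROC/Youden."""

import numpy as np
import pandas as pd
import pytest

from ssi_ident.claims_model import PatientEpisode
from ssi_ident.regression_classifier import (
    LogisticModel,
    SeparationWarning,
    classify_logistic,
    fit_logistic,
    roc_and_youden,
    stepwise_select,
)


def brute_force_auc(scores, labels) -> float:
    """Explicit positive/negative pair counting, ties worth one half."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def brute_force_youden(scores, labels):
    """Best (cutoff, J) over all 'score >= c' rules, smallest cutoff on ties."""
    pos = sum(1 for y in labels if y == 1)
    neg = len(labels) - pos
    best = None
    for c in sorted(set(scores)) + [max(scores) + 1.0]:
        tp = sum(1 for s, y in zip(scores, labels) if s >= c and y == 1)
        tn = sum(1 for s, y in zip(scores, labels) if s < c and y == 0)
        j = tp / pos + tn / neg - 1.0
        if best is None or j > best[1] + 1e-12:
            best = (c, j)
    return best


class TestFitLogistic:
    def test_saturated_two_by_two_matches_closed_form(self):
        # exposed: 8/10 events; unexposed: 2/10 events
        x = [1.0] * 10 + [0.0] * 10
        y = [1] * 8 + [0] * 2 + [1] * 2 + [0] * 8
        fit = fit_logistic(pd.DataFrame({"x": x, "y": y}), ["x"], outcome="y")
        assert fit.coefficients[1] == pytest.approx(np.log(16.0), abs=1e-6)
        assert fit.coefficients[0] == pytest.approx(np.log(2 / 8), abs=1e-6)
        assert fit.converged and not fit.separation

    def test_independent_balanced_outcome_gives_null_coefficients(self):
        x = [-1.0, 1.0, -1.0, 1.0] * 25
        y = [0, 0, 1, 1] * 25
        fit = fit_logistic(pd.DataFrame({"x": x, "y": y}), ["x"], outcome="y")
        assert fit.coefficients[0] == pytest.approx(0.0, abs=1e-8)
        assert fit.coefficients[1] == pytest.approx(0.0, abs=1e-8)

    def test_matches_independent_glm_to_1e6(self):
        statsmodels = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(42)
        n = 400
        X = rng.normal(size=(n, 3))
        lp = -1.0 + X @ np.array([0.8, -0.5, 0.3])
        y = (rng.random(n) < 1 / (1 + np.exp(-lp))).astype(int)
        data = pd.DataFrame(X, columns=["a", "b", "c"]).assign(y=y)
        fit = fit_logistic(data, ["a", "b", "c"], outcome="y")
        ref = statsmodels.GLM(
            y, statsmodels.add_constant(X), family=statsmodels.families.Binomial()
        ).fit()
        np.testing.assert_allclose(fit.coefficients, ref.params, atol=1e-6)

    def test_parameter_recovery_on_simulated_cohort(self):
        rng = np.random.default_rng(7)
        n = 100_000
        los = rng.gamma(4.0, 4.5, size=n)
        lp = -4.0 + 0.15 * los
        y = (rng.random(n) < 1 / (1 + np.exp(-lp))).astype(int)
        fit = fit_logistic(pd.DataFrame({"los": los, "y": y}), ["los"], outcome="y")
        assert fit.coefficients[0] == pytest.approx(-4.0, rel=0.05)
        assert fit.coefficients[1] == pytest.approx(0.15, rel=0.05)

    def test_perfect_separation_is_flagged_not_silent(self):
        x = list(range(-5, 5))
        y = [0] * 5 + [1] * 5
        with pytest.warns(SeparationWarning):
            fit = fit_logistic(pd.DataFrame({"x": x, "y": y}), ["x"], outcome="y")
        assert fit.separation

    def test_collinear_predictors_rejected_by_name(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=60)
        y = (rng.random(60) < 0.4).astype(int)
        data = pd.DataFrame({"x1": x, "x2": 2.0 * x, "y": y})
        with pytest.raises(ValueError, match="x"):
            fit_logistic(data, ["x1", "x2"], outcome="y")

    def test_constant_predictor_rejected(self):
        data = pd.DataFrame({"x": [1.0] * 20, "y": [0, 1] * 10})
        with pytest.raises(ValueError, match="constant"):
            fit_logistic(data, ["x"], outcome="y")

    def test_single_class_outcome_rejected(self):
        data = pd.DataFrame({"x": [1.0, 2.0], "y": [1, 1]})
        with pytest.raises(ValueError, match="both classes"):
            fit_logistic(data, ["x"], outcome="y")


class TestStepwise:
    @staticmethod
    def _one_signal_frame(seed: int, n: int = 2000) -> pd.DataFrame:
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 4))
        lp = -2.0 + 1.0 * X[:, 0]
        y = (rng.random(n) < 1 / (1 + np.exp(-lp))).astype(int)
        return pd.DataFrame(X, columns=["x1", "x2", "x3", "x4"]).assign(y=y)

    def test_selects_exactly_the_signal_variable(self):
        data = self._one_signal_frame(seed=1)
        assert stepwise_select(data, ["x1", "x2", "x3", "x4"], outcome="y") == ["x1"]

    def test_pure_noise_selects_nothing(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(500, 3))
        y = (rng.random(500) < 0.3).astype(int)
        data = pd.DataFrame(X, columns=["x1", "x2", "x3"]).assign(y=y)
        assert stepwise_select(data, ["x1", "x2", "x3"], outcome="y") == []

    def test_duplicated_predictor_enters_once(self):
        data = self._one_signal_frame(seed=2)
        data["x1_copy"] = data["x1"]
        selected = stepwise_select(data, ["x1", "x1_copy", "x2"], outcome="y")
        assert selected == ["x1"]  # the copy adds zero likelihood improvement

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            stepwise_select(pd.DataFrame({"y": [0, 1]}), [], outcome="y")


class TestRocYouden:
    def test_perfect_separation(self):
        roc = roc_and_youden([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert roc.auc == pytest.approx(1.0)
        assert roc.youden_j == pytest.approx(1.0)

    def test_all_scores_tied_gives_chance_auc(self):
        roc = roc_and_youden([0.5] * 10, [1] * 4 + [0] * 6)
        assert roc.auc == pytest.approx(0.5)

    @pytest.mark.parametrize(
        "scores,labels,expected_auc",
        [
            ((0.9, 0.8, 0.4, 0.3), (1, 1, 0, 0), 1.0),
            ((0.9, 0.4, 0.8, 0.3), (1, 1, 0, 0), 0.75),  # frozen from the pair-count oracle
        ],
    )
    def test_interleaved_scores_match_pair_counting(self, scores, labels, expected_auc):
        assert brute_force_auc(scores, labels) == pytest.approx(expected_auc)
        assert roc_and_youden(scores, labels).auc == pytest.approx(expected_auc)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_and_youden([0.1, 0.2], [1, 1])

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        scores = rng.random(40)
        labels = (rng.random(40) < 0.3).astype(int)
        base = roc_and_youden(scores, labels).auc
        for transform in (lambda s: 2 * s + 1, np.exp, lambda s: s**3):
            assert roc_and_youden(transform(scores), labels).auc == pytest.approx(base)

    def test_sensitivity_non_increasing_along_rising_cutoffs(self):
        rng = np.random.default_rng(8)
        scores = rng.random(60)
        labels = (rng.random(60) < 0.4).astype(int)
        roc = roc_and_youden(scores, labels)
        sens = [p[1] for p in roc.points]
        assert all(a >= b - 1e-12 for a, b in zip(sens, sens[1:]))

    def test_youden_matches_brute_force_on_random_scores(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            n = rng.integers(4, 40)
            scores = list(np.round(rng.random(n), 2))
            labels = list((rng.random(n) < 0.5).astype(int))
            if len(set(labels)) < 2:
                continue
            cut, j = brute_force_youden(scores, labels)
            roc = roc_and_youden(scores, labels)
            assert roc.youden_cutoff == pytest.approx(cut)
            assert roc.youden_j == pytest.approx(j)


class TestClassifyLogistic:
    @staticmethod
    def _episode(los: float) -> PatientEpisode:
        return PatientEpisode(
            patient_id="p", age=60, sex="male", los=los, vessels_obstructed=2,
            antibiotic_types=1, antibiotic_ddd_total=3.0, cefazolin_ddd=0.0,
        )

    def test_zero_linear_predictor_scores_one_half(self):
        model = LogisticModel(("los",), (0.0, 0.0), cutoff=0.5)
        assert classify_logistic(model, self._episode(30.0)).score == pytest.approx(0.5)

    def test_zero_cutoff_flags_everyone(self):
        model = LogisticModel(("los",), (-10.0, 0.01), cutoff=0.0)
        assert classify_logistic(model, self._episode(1.0)).prediction == 1

    def test_score_monotone_in_length_of_stay(self):
        model = LogisticModel(("los",), (-5.0, 0.2), cutoff=0.5)
        s = [classify_logistic(model, self._episode(los)).score for los in (5.0, 20.0, 60.0)]
        assert s[0] < s[1] < s[2]

    def test_json_round_trip(self, tmp_path):
        model = LogisticModel(("los", "antibiotic_types"), (-3.0, 0.1, 0.5), cutoff=0.03, auc=0.98)
        path = tmp_path / "model.json"
        model.to_json(path)
        assert LogisticModel.from_json(path) == model
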