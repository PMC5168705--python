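"""Detection-index model, LOOCV, and the exhaustive combination search."""

from collections import Counter

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.svm import SVC

from cfmethyl import model
from cfmethyl.ddmsp import _rank_auc
from cfmethyl.model import (
    FIXED_PUBLISHED_MODEL,
    LinearDetectionModel,
    classify,
    exhaustive_search,
    fit_linear_svm,
    loocv_scores,
    variable_subsets,
)

VARS6 = list(FIXED_PUBLISHED_MODEL.variable_names)


class TestDetectionIndex:
    def test_zero_vector_returns_intercept(self):
        fv = {v: 0.0 for v in VARS6}
        assert FIXED_PUBLISHED_MODEL.detection_index(fv) == pytest.approx(-6.98073, abs=1e-12)

    def test_unit_vector_is_coefficient_sum(self):
        fv = {v: 1.0 for v in VARS6}
        expected = 0.62449 + 0.78110 + 0.12115 + 0.36760 + 0.65288 + 2.44704 - 6.98073
        assert FIXED_PUBLISHED_MODEL.detection_index(fv) == pytest.approx(expected, abs=1e-12)

    def test_empty_variable_model_returns_intercept(self):
        m = LinearDetectionModel((), (), intercept=3.5)
        assert m.detection_index({"anything": 1.0}) == 3.5

    def test_missing_variable_raises(self):
        with pytest.raises(KeyError):
            FIXED_PUBLISHED_MODEL.detection_index({"RASGRF1": 1.0})

    def test_dataframe_evaluation_matches_scalar(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(0, 1, (5, 6)), columns=VARS6)
        series = FIXED_PUBLISHED_MODEL.detection_index(df)
        for i in range(5):
            assert series.iloc[i] == pytest.approx(
                FIXED_PUBLISHED_MODEL.detection_index(df.iloc[i])
            )

    @given(st.integers(0, 5), st.floats(0.01, 2.0))
    @settings(max_examples=30, deadline=None)
    def test_monotone_in_each_positively_weighted_variable(self, var_idx, delta):
        fv = {v: 0.5 for v in VARS6}
        base = FIXED_PUBLISHED_MODEL.detection_index(fv)
        fv[VARS6[var_idx]] += delta
        assert FIXED_PUBLISHED_MODEL.detection_index(fv) > base


class TestClassify:
    def test_exactly_at_cutoff_is_negative(self):
        assert classify(-0.07923) is False

    def test_above_and_below(self):
        assert classify(0.0) is True
        assert classify(-10.0) is False

    def test_series_classification(self):
        s = pd.Series([-0.07923, -0.07922, -1.0])
        calls = FIXED_PUBLISHED_MODEL.classify(s)
        assert list(calls) == [False, True, False]


class TestFitLinearSvm:
    def _toy(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(0, 0.5, 20), rng.normal(4, 0.5, 20)])
        y = np.array([0] * 20 + [1] * 20)
        return pd.DataFrame({"x": x}), y

    def test_weight_points_toward_positive_class(self):
        X, y = self._toy()
        m = fit_linear_svm(X, y)
        assert m.weights[0] > 0

    def test_label_flip_negates_weights(self):
        X, y = self._toy()
        m1 = fit_linear_svm(X, y)
        m2 = fit_linear_svm(X, 1 - y)
        assert m1.weights[0] == pytest.approx(-m2.weights[0], rel=1e-3)

    def test_single_class_rejected(self):
        X, y = self._toy()
        with pytest.raises(ValueError):
            fit_linear_svm(X, np.zeros_like(y))

    def test_refit_decision_values_match_detection_index(self, quantified_cohort):
        """The model's stored weights/intercept reproduce its decision values."""
        table = quantified_cohort["features"][VARS6]
        y = quantified_cohort["y"]
        m = fit_linear_svm(table, y, standardize=False)
        clf = SVC(kernel="linear", C=1.0).fit(table.to_numpy(), y)
        np.testing.assert_allclose(
            m.detection_index(table).to_numpy(),
            clf.decision_function(table.to_numpy()),
            rtol=1e-8,
        )

    def test_string_labels_accepted(self):
        X, y = self._toy()
        lab = np.where(y == 1, "BC", "HV")
        m = fit_linear_svm(X, lab)
        assert m.weights[0] > 0


class TestLoocv:
    def test_matches_naive_refit_loop_bitwise(self):
        rng = np.random.default_rng(2)
        n = 16
        X = pd.DataFrame(rng.normal(0, 1, (n, 3)), columns=list("abc"))
        y = np.array([0] * 8 + [1] * 8)
        X.loc[y == 1, "a"] += 1.0
        got = loocv_scores(X, y, c_param=1.0).to_numpy()
        # independent naive loop
        x = X.to_numpy()
        expected = np.empty(n)
        for i in range(n):
            mask = np.arange(n) != i
            xt, xi = x[mask], x[i : i + 1]
            mu, sd = xt.mean(axis=0), xt.std(axis=0, ddof=0)
            clf = SVC(kernel="linear", C=1.0).fit((xt - mu) / sd, y[mask])
            expected[i] = clf.decision_function((xi - mu) / sd)[0]
        np.testing.assert_array_equal(got, expected)

    def test_perfectly_separable_auc_one(self):
        n = 20
        X = pd.DataFrame({"a": np.r_[np.zeros(10), np.ones(10) * 5]})
        y = np.array([0] * 10 + [1] * 10)
        scores = loocv_scores(X, y)
        assert _rank_auc(scores.to_numpy(), y) == pytest.approx(1.0)

    def test_label_independent_features_near_chance(self):
        rng = np.random.default_rng(7)
        n = 120
        X = pd.DataFrame(rng.normal(0, 1, (n, 2)), columns=["a", "b"])
        y = np.array([0, 1] * (n // 2))
        auc = model.loocv_auc(X, y)
        assert abs(auc - 0.5) < 0.15

    def test_too_few_per_class_rejected(self):
        X = pd.DataFrame({"a": np.arange(5.0)})
        with pytest.raises(ValueError):
            loocv_scores(X, np.array([0, 0, 1, 1, 1]))


class TestExhaustiveSearch:
    def test_subset_count_formula(self):
        for v in (1, 3, 6, 10, 15):
            names = [f"v{i}" for i in range(v)]
            assert sum(1 for _ in variable_subsets(names)) == 2**v - 1

    def test_single_variable(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"a": np.r_[rng.normal(0, 1, 10), rng.normal(2, 1, 10)]})
        y = np.array([0] * 10 + [1] * 10)
        res = exhaustive_search(X, y)
        assert len(res.records) == 1
        assert res.best.variable_names == ("a",)

    def test_three_variable_winner_matches_brute_force(self):
        rng = np.random.default_rng(4)
        n = 24
        X = pd.DataFrame(rng.normal(0, 1, (n, 3)), columns=list("abc"))
        y = np.array([0] * 12 + [1] * 12)
        X.loc[y == 1, "a"] += 2.0
        res = exhaustive_search(X, y)
        assert len(res.records) == 7

        # oracle: independent scan with its own LOOCV loop
        def naive_auc(cols):
            x = X[list(cols)].to_numpy()
            out = np.empty(n)
            for i in range(n):
                mask = np.arange(n) != i
                xt, xi = x[mask], x[i : i + 1]
                mu, sd = xt.mean(axis=0), xt.std(axis=0, ddof=0)
                sd = np.where(sd == 0, 1, sd)
                clf = SVC(kernel="linear", C=1.0).fit((xt - mu) / sd, y[mask])
                out[i] = clf.decision_function((xi - mu) / sd)[0]
            return _rank_auc(out, y)

        import itertools

        best_auc, best_sub = -1, None
        for size in (1, 2, 3):
            for sub in itertools.combinations("abc", size):
                clf = SVC(kernel="linear", C=1.0)
                xs = X[list(sub)].to_numpy()
                mu, sd = xs.mean(axis=0), xs.std(axis=0, ddof=0)
                clf.fit((xs - mu) / sd, y)
                if not np.all(clf.coef_[0] / sd > 0):
                    continue
                auc = naive_auc(sub)
                if auc > best_auc + 1e-12:
                    best_auc, best_sub = auc, sub
        assert res.best.variable_names == best_sub
        assert res.best_loocv_auc == pytest.approx(best_auc)

    def test_constraint_failure_flagged(self):
        # the only informative direction has a negative weight
        rng = np.random.default_rng(5)
        X = pd.DataFrame({"a": np.r_[rng.normal(2, 0.3, 10), rng.normal(0, 0.3, 10)]})
        y = np.array([0] * 10 + [1] * 10)  # positive class has LOWER a
        res = exhaustive_search(X, y)
        assert not res.constraint_satisfied

    def test_signal_variables_recovered_across_replicates(self):
        """With signal planted only in RASGRF1, CPXM1 and IC, each signal
        variable dominates the winners across seeded replicates and noise
        variables stay rare."""
        signal = {"RASGRF1", "CPXM1", "IC"}
        freq = Counter()
        n_half = 30
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            y = np.array([0] * n_half + [1] * n_half)
            X = pd.DataFrame(
                rng.normal(0, 1, (2 * n_half, 6)),
                columns=VARS6,
                index=[f"s{i}" for i in range(2 * n_half)],
            )
            for v in signal:
                X.loc[y == 1, v] += 1.5
            res = exhaustive_search(X, y, VARS6)
            freq.update(res.best.variable_names)
        for v in signal:
            assert freq[v] >= 17, f"{v} selected only {freq[v]}/20 times"
        for v in set(VARS6) - signal:
            assert freq[v] <= 8, f"noise variable {v} selected {freq[v]}/20 times"


class TestModelStatePersistence:
    def test_roundtrip(self, tmp_path):
        path = tmp_path / "model.json"
        model.save_model_state(path, FIXED_PUBLISHED_MODEL, extra={"note": 1})
        loaded, extra = model.load_model_state(path)
        assert loaded == FIXED_PUBLISHED_MODEL
        assert extra["note"] == 1
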