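import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phenotrace import modeling as mod


def _pair_count_auc(scores, labels):
    """Brute-force Mann-Whitney AUC with ties counted one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestEnumerateCandidates:
    def test_ten_models_for_three_features(self):
        cands = mod.enumerate_candidates(["a", "b", "c"], "fatigue")
        assert len(cands) == 10
        forms = {c.formula() for c in cands}
        assert {"a", "b", "c", "a+b", "a+c", "b+c", "a+b+c"} <= forms
        assert "a+b+a:b" in forms  # interaction form

    def test_wrong_feature_count_rejected(self):
        with pytest.raises(mod.ModelingError, match="3"):
            mod.enumerate_candidates(["a", "b"], "fatigue")
        with pytest.raises(mod.ModelingError):
            mod.enumerate_candidates(["a", "a", "b"], "fatigue")

    def test_deterministic_order(self):
        c1 = mod.enumerate_candidates(["a", "b", "c"], "fatigue")
        c2 = mod.enumerate_candidates(["a", "b", "c"], "fatigue")
        assert [c.formula() for c in c1] == [c.formula() for c in c2]

    def test_general_scheme_for_five_features(self):
        cands = mod.enumerate_candidates_general(list("abcde"), "depressed_mood")
        # 5 singles + 10 pairs + 10 pairs-with-interaction + 1 full
        assert len(cands) == 26

    def test_general_scheme_single_feature(self):
        cands = mod.enumerate_candidates_general(["x"], "depressed_mood")
        assert [c.formula() for c in cands] == ["x"]


class TestFitLogistic:
    def test_intercept_only_closed_form(self):
        y = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0], dtype=float)
        fit = mod.fit_logistic(np.ones((10, 1)), y, ["(Intercept)"])
        assert fit.coefficients["(Intercept)"] == pytest.approx(
            math.log(0.3 / 0.7), abs=1e-8
        )

    def test_parameter_recovery(self, rng):
        n = 5000
        X = rng.normal(size=(n, 1))
        eta = -1.0 + 1.5 * X[:, 0]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        fit = mod.fit_logistic(np.column_stack([np.ones(n), X]), y, ["b0", "b1"])
        assert fit.coefficients["b0"] == pytest.approx(-1.0, abs=0.15)
        assert fit.coefficients["b1"] == pytest.approx(1.5, abs=0.15)
        assert fit.converged

    def test_matches_scipy_optimizer_oracle(self, rng):
        import scipy.optimize as opt

        n = 200
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 3))])
        y = (rng.random(n) < 0.5).astype(float)
        fit = mod.fit_logistic(X, y)

        def nll(b):
            eta = X @ b
            return float(np.sum(np.logaddexp(0, eta) - y * eta))

        res = opt.minimize(nll, np.zeros(4), method="BFGS", options={"gtol": 1e-12})
        ours = np.array(list(fit.coefficients.values()))
        assert np.max(np.abs(ours - res.x)) < 1e-6

    def test_single_class_rejected(self):
        with pytest.raises(mod.ModelingError, match="binary"):
            mod.fit_logistic(np.ones((5, 1)), np.ones(5))

    def test_rank_deficiency_names_aliased_term(self, rng):
        x = rng.normal(size=20)
        X = np.column_stack([np.ones(20), x, 2 * x])
        y = (rng.random(20) < 0.5).astype(float)
        y[:2] = [0, 1]
        with pytest.raises(mod.ModelingError, match="aliased"):
            mod.fit_logistic(X, y, ["(Intercept)", "x", "x2"])

    def test_perfect_separation_flagged_scores_usable(self):
        x = np.concatenate([np.linspace(-3, -1, 10), np.linspace(1, 3, 10)])
        y = np.concatenate([np.zeros(10), np.ones(10)])
        X = np.column_stack([np.ones(20), x])
        fit = mod.fit_logistic(X, y, ["b0", "b1"])
        assert not fit.converged
        scores = mod.predict_proba(fit, X, ["b0", "b1"])
        assert mod.roc_and_auc(scores, y)[1] == 1.0


class TestRocAuc:
    def test_worked_example(self):
        roc, auc = mod.roc_and_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert auc == pytest.approx(0.75)
        assert tuple(roc[0]) == (0.0, 0.0)
        assert tuple(roc[-1]) == (1.0, 1.0)

    def test_perfect_separation(self):
        _, auc = mod.roc_and_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert auc == 1.0

    def test_all_tied_scores(self):
        _, auc = mod.roc_and_auc([0.5] * 6, [0, 1, 0, 1, 0, 1])
        assert auc == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(mod.ModelingError, match="both classes"):
            mod.roc_and_auc([0.1, 0.2], [1, 1])

    def test_matches_pair_counting_with_ties(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 50))
            y = np.zeros(n)
            y[: int(rng.integers(1, n))] = 1
            rng.shuffle(y)
            if len(np.unique(y)) < 2:
                continue
            scores = rng.choice([0.1, 0.25, 0.5, 0.5, 0.8], size=n)
            _, auc = mod.roc_and_auc(scores, y)
            assert auc == pytest.approx(_pair_count_auc(scores, y), abs=1e-12)


@settings(max_examples=40, deadline=None)
@given(st.lists(st.floats(1e-3, 1, allow_nan=False), min_size=4, max_size=30), st.data())
def test_auc_antisymmetry_and_monotone_invariance(scores, data):
    scores = np.asarray(scores)
    if len(np.unique(scores)) < len(scores):
        scores = scores + np.linspace(0, 1e-9, len(scores))  # break ties
    labels = np.array(
        data.draw(
            st.lists(st.integers(0, 1), min_size=len(scores), max_size=len(scores))
        )
    )
    if labels.sum() in (0, len(labels)):
        return
    _, auc = mod.roc_and_auc(scores, labels)
    _, auc_neg = mod.roc_and_auc(-scores, labels)
    assert auc + auc_neg == pytest.approx(1.0, abs=1e-9)
    _, auc_mono = mod.roc_and_auc(np.exp(3 * scores), labels)
    assert auc_mono == pytest.approx(auc, abs=1e-12)


def _feature_frame(rng, n, shift=0.0):
    ids = [f"P{i}" for i in range(n)]
    y = np.zeros(n)
    y[: n // 2] = 1
    rng.shuffle(y)
    x = rng.normal(size=n) + shift * y
    return pd.DataFrame({"f": x}, index=ids), y


class TestCVAuc:
    def test_every_participant_scored_once(self, rng):
        values, y = _feature_frame(rng, 50, shift=1.0)
        cand = mod.CandidateModel("fatigue", ("f",))
        res = mod.cv_auc(cand, values, y, folds=5, seed=0)
        assert set(res.oof_scores) == set(values.index)
        assert sorted(set(res.fold_assignment.values())) == [1, 2, 3, 4, 5]

    def test_same_seed_reproducible(self, rng):
        values, y = _feature_frame(rng, 60, shift=0.5)
        cand = mod.CandidateModel("fatigue", ("f",))
        r1 = mod.cv_auc(cand, values, y, folds=10, seed=4)
        r2 = mod.cv_auc(cand, values, y, folds=10, seed=4)
        assert r1.auc == r2.auc
        assert r1.fold_assignment == r2.fold_assignment

    def test_too_few_participants_suggests_fewer_folds(self, rng):
        values, y = _feature_frame(rng, 6)
        cand = mod.CandidateModel("fatigue", ("f",))
        with pytest.raises(mod.ModelingError, match="folds"):
            mod.cv_auc(cand, values, y, folds=10, seed=0)


class TestSelectBest:
    def _res(self, auc, terms, interactions=()):
        cand = mod.CandidateModel("fatigue", terms, interactions)
        return mod.CVResult(cand, {}, {}, np.zeros((2, 2)), auc)

    def test_dominant_candidate_wins(self):
        results = [self._res(0.6, ("a",)), self._res(0.9, ("b",))]
        assert mod.select_best(results).candidate.terms == ("b",)

    def test_exact_tie_prefers_parsimony(self):
        with_int = self._res(0.8, ("a", "b"), (("a", "b"),))
        plain = self._res(0.8, ("a", "b"))
        assert mod.select_best([with_int, plain]).candidate.interactions == ()

    def test_tie_same_size_prefers_enumeration_order(self):
        r1, r2 = self._res(0.7, ("a",)), self._res(0.7, ("b",))
        assert mod.select_best([r1, r2]).candidate.terms == ("a",)


class TestThresholdMetrics:
    scores = np.array([0.1, 0.3, 0.45, 0.55, 0.7, 0.9])
    labels = np.array([0, 0, 1, 0, 1, 1])

    def test_threshold_zero_all_positive(self):
        df = mod.threshold_metrics(self.scores, self.labels, [0.0])
        assert df.loc[0, "sensitivity"] == 1.0
        assert df.loc[0, "specificity"] == 0.0
        assert math.isnan(df.loc[0, "npv"])

    def test_threshold_above_max_all_negative(self):
        df = mod.threshold_metrics(self.scores, self.labels, [0.99])
        assert df.loc[0, "sensitivity"] == 0.0
        assert df.loc[0, "npv"] == pytest.approx(1 - self.labels.mean())
        assert math.isnan(df.loc[0, "ppv"])

    def test_confusion_counts_conserved(self):
        df = mod.threshold_metrics(self.scores, self.labels, [0.2, 0.5, 0.8])
        n = len(self.labels)
        for _, row in df.iterrows():
            tp = row["sensitivity"] * self.labels.sum()
            tn = row["specificity"] * (n - self.labels.sum())
            assert row["accuracy"] == pytest.approx((tp + tn) / n)

    def test_midpoint_example(self):
        df = mod.threshold_metrics(self.scores, self.labels, [0.5])
        assert df.loc[0, "sensitivity"] == pytest.approx(2 / 3)
        assert df.loc[0, "specificity"] == pytest.approx(2 / 3)
        assert df.loc[0, "ppv"] == pytest.approx(2 / 3)
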