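import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from melrad.model import (
    MlpHyperparams,
    PerformanceReport,
    backward_eliminate,
    cross_validate,
    efficiency,
    evaluate,
    feature_importance,
    select_threshold,
    split_development,
    train_mlp,
)


class TestSplit:
    def test_95_patients_split_57_38(self):
        labels = np.array([1] * 46 + [0] * 49)
        tr, va = split_development(labels, ratio=0.6, seed=0)
        assert len(tr) == 57 and len(va) == 38
        assert len(set(tr) | set(va)) == 95

    def test_same_seed_same_partition(self):
        labels = np.array([1] * 46 + [0] * 49)
        tr1, va1 = split_development(labels, seed=4)
        tr2, va2 = split_development(labels, seed=4)
        np.testing.assert_array_equal(tr1, tr2)
        np.testing.assert_array_equal(va1, va2)

    def test_stratification_within_one_patient(self):
        labels = np.array([1] * 46 + [0] * 49)
        tr, va = split_development(labels, seed=1)
        overall = labels.mean()
        for part in (tr, va):
            events = labels[part].sum()
            assert abs(events - overall * len(part)) <= 1.0

    def test_tiny_stratum_rejected(self):
        labels = np.array([1] + [0] * 19)
        with pytest.raises(ValueError):
            split_development(labels)


class TestTrainMlp:
    def test_probabilities_in_unit_interval_and_complementary(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((40, 3))
        y = (X[:, 0] > 0).astype(int)
        m = train_mlp(X, y, MlpHyperparams(seed=0))
        p = m.predict_proba(X)
        assert np.all((p >= 0) & (p <= 1))
        # softmax over two classes: P(0) + P(1) = 1 exactly
        both = m.clf.predict_proba((X - m.scale_mean) / m.scale_sd)
        np.testing.assert_allclose(both.sum(axis=1), 1.0, atol=1e-12)

    def test_xor_is_separable_with_four_hidden_units(self):
        X = np.array([[0.0, 0], [0, 1], [1, 0], [1, 1]] * 4)
        y = np.array([0, 1, 1, 0] * 4)
        m = train_mlp(X, y, MlpHyperparams(seed=0))
        assert ((m.predict_proba(X) > 0.5).astype(int) == y).all()

    def test_separated_gaussians_reach_high_auc(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 300)
        X = rng.standard_normal((300, 2))
        X[y == 1] += 3.0
        m = train_mlp(X[:200], y[:200], MlpHyperparams(seed=1))
        assert roc_auc_score(y[200:], m.predict_proba(X[200:])) > 0.95

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((50, 2))
        y = (X.sum(axis=1) > 0).astype(int)
        p1 = train_mlp(X, y, MlpHyperparams(seed=7)).predict_proba(X)
        p2 = train_mlp(X, y, MlpHyperparams(seed=7)).predict_proba(X)
        np.testing.assert_array_equal(p1, p2)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_mlp(np.ones((10, 2)), np.ones(10, int))

    def test_invalid_hyperparams_rejected(self):
        with pytest.raises(ValueError):
            MlpHyperparams(hidden_units=0)
        with pytest.raises(ValueError):
            MlpHyperparams(init_offset=0.0)
        with pytest.raises(ValueError):
            MlpHyperparams(lambda_init=0.0)


class TestCrossValidate:
    def _data(self, seed=0, n=60):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(
            rng.standard_normal((n, 2)), columns=["signal", "noise"]
        )
        y = (X["signal"] + 0.5 * rng.standard_normal(n) > 0).astype(int)
        return X, y.to_numpy()

    def test_every_patient_out_of_fold_exactly_once(self):
        X, y = self._data()
        cv = cross_validate(X, y, MlpHyperparams(seed=0), k=10)
        assert np.isfinite(cv.oof_probability.to_numpy()).all()
        assert len(cv.models) == 10

    def test_out_of_fold_probabilities_order_classes(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(1)
        y = np.array([0] * 30 + [1] * 30)
        X = pd.DataFrame({"f": y * 3.0 + rng.standard_normal(60)})
        cv = cross_validate(X, y, MlpHyperparams(seed=2), k=10)
        assert roc_auc_score(y, cv.oof_probability) > 0.95

    def test_mean_rank_is_average_of_fold_permutations(self):
        X, y = self._data(seed=3)
        cv = cross_validate(X, y, MlpHyperparams(seed=3), k=5)
        assert set(cv.mean_rank.index) == {"signal", "noise"}
        assert cv.mean_rank.sum() == pytest.approx(3.0)  # ranks 1+2 per fold


class TestFeatureImportance:
    def test_noise_feature_ranked_last_in_most_seeds(self):
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 95
            X = pd.DataFrame(
                rng.standard_normal((n, 2)), columns=["signal", "noise"]
            )
            y = (X["signal"] + 0.3 * rng.standard_normal(n) > 0).astype(int)
            m = train_mlp(X, y.to_numpy(), MlpHyperparams(seed=seed))
            imp = feature_importance(m, X, y.to_numpy(), seed=seed)
            if imp["signal"] > imp["noise"]:
                wins += 1
        assert wins >= 9

    def test_identical_inputs_identical_ranks(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.standard_normal((40, 3)), columns=list("abc"))
        y = (X["a"] > 0).astype(int).to_numpy()
        m = train_mlp(X, y, MlpHyperparams(seed=1))
        i1 = feature_importance(m, X, y, seed=5)
        i2 = feature_importance(m, X, y, seed=5)
        assert i1.equals(i2)


class TestEfficiency:
    def test_perfect_classifier(self):
        assert efficiency(1.0, 1.0, 0.3) == 1.0

    def test_worked_arithmetic(self):
        assert efficiency(0.938, 0.319, 0.484) == pytest.approx(0.618596)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            efficiency(1.2, 0.5, 0.5)

    @settings(deadline=None, max_examples=100)
    @given(
        se=st.floats(0, 1), sp=st.floats(0, 1), p=st.floats(0, 1),
    )
    def test_always_between_se_and_sp(self, se, sp, p):
        eff = efficiency(se, sp, p)
        assert min(se, sp) - 1e-12 <= eff <= max(se, sp) + 1e-12


class TestSelectThreshold:
    def test_perfect_separation_smallest_maximizer(self):
        t, report = select_threshold([0.2, 0.8], [0, 1])
        assert report.eff == 1.0
        assert t == pytest.approx(0.2)

    def test_uninformative_classifier_max_eff_is_majority_rate(self):
        rng = np.random.default_rng(0)
        probs = rng.random(4000)
        labels = (rng.random(4000) < 0.3).astype(int)
        _, report = select_threshold(probs, labels)
        assert report.eff == pytest.approx(max(labels.mean(), 1 - labels.mean()),
                                           abs=0.05)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            select_threshold([0.1, 0.9], [1, 1])


class TestEvaluate:
    def test_testing_cohort_worked_example(self):
        r = PerformanceReport.from_counts(tp=22, fn=1, fp=26, tn=10)
        assert round(100 * r.sensitivity, 1) == 95.7
        assert round(100 * r.specificity, 1) == 27.8
        assert round(100 * r.ppv, 1) == 45.8
        assert round(100 * r.npv, 1) == 90.9
        assert round(r.c_statistic, 2) == 0.62

    def test_development_cohort_worked_example(self):
        r = PerformanceReport.from_counts(tp=45, fn=3, fp=32, tn=15)
        assert round(100 * r.sensitivity, 1) == 93.8
        assert round(100 * r.specificity, 1) == 31.9
        assert round(100 * r.ppv, 1) == 58.4
        assert round(r.c_statistic, 2) == 0.63

    def test_perfect_ranking_auc_one(self):
        r = evaluate([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1], 0.5)
        assert r.auc == 1.0

    def test_label_flip_mirrors_auc(self):
        rng = np.random.default_rng(1)
        probs = rng.random(50)
        labels = rng.integers(0, 2, 50)
        while labels.min() == labels.max():
            labels = rng.integers(0, 2, 50)
        a = evaluate(probs, labels, 0.5).auc
        b = evaluate(probs, 1 - labels, 0.5).auc
        assert a == pytest.approx(1.0 - b, abs=1e-12)

    def test_auc_equals_pair_enumeration(self):
        # oracle: normalized Mann-Whitney U by explicit pair counting
        rng = np.random.default_rng(2)
        probs = np.round(rng.random(40), 2)  # ties on purpose
        labels = rng.integers(0, 2, 40)
        while labels.min() == labels.max():
            labels = rng.integers(0, 2, 40)
        pos = probs[labels == 1]
        neg = probs[labels == 0]
        wins = sum(
            1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg
        )
        oracle = wins / (len(pos) * len(neg))
        assert evaluate(probs, labels, 0.5).auc == pytest.approx(oracle, abs=1e-12)

    def test_bayes_identities_hold_on_counts(self):
        r = PerformanceReport.from_counts(tp=30, fn=10, fp=20, tn=40)
        p, se, sp = r.prevalence, r.sensitivity, r.specificity
        assert r.ppv == pytest.approx(
            se * p / (se * p + (1 - sp) * (1 - p)), abs=1e-12
        )
        assert r.npv == pytest.approx(
            sp * (1 - p) / (sp * (1 - p) + (1 - se) * p), abs=1e-12
        )

    def test_positive_means_strictly_greater_than_threshold(self):
        r = evaluate([0.55, 0.56], [1, 1], 0.55)
        assert r.tp == 1 and r.fn == 1

    def test_absent_class_flagged_not_zeroed(self):
        r = evaluate([0.9, 0.8], [1, 1], 0.5)
        assert np.isnan(r.specificity)
        assert "specificity" in r.undefined


class TestBackwardElimination:
    def _cohort(self, seed, n=95, effect=1.5):
        rng = np.random.default_rng(seed)
        y = np.array([1] * 46 + [0] * (n - 46))
        rng.shuffle(y)
        X = rng.standard_normal((n, 6))
        X[y == 1, :3] += effect
        cols = ["sigA", "sigB", "sigC", "noiseA", "noiseB", "noiseC"]
        return pd.DataFrame(X, columns=cols), y

    def test_single_feature_sequence_of_length_one(self):
        X, y = self._cohort(0)
        tr, va = split_development(y, seed=0)
        res = backward_eliminate(
            X.iloc[tr][["sigA"]], y[tr], X.iloc[va][["sigA"]], y[va],
            ["sigA"], MlpHyperparams(seed=0), k=5,
        )
        assert len(res.stages) == 1
        assert res.best_features == ["sigA"]

    def test_planted_features_survive_to_three_feature_stage(self):
        hits = 0
        n_seeds = 5
        for seed in range(n_seeds):
            X, y = self._cohort(seed)
            tr, va = split_development(y, seed=seed)
            res = backward_eliminate(
                X.iloc[tr], y[tr], X.iloc[va], y[va], list(X.columns),
                MlpHyperparams(seed=seed), k=5,
            )
            row = res.stages[res.stages.n_features == 3].iloc[0]
            if set(row["features"]) == {"sigA", "sigB", "sigC"}:
                hits += 1
        assert hits >= 0.8 * n_seeds

    def test_elimination_deterministic_under_seed(self):
        X, y = self._cohort(3)
        tr, va = split_development(y, seed=3)
        args = (X.iloc[tr], y[tr], X.iloc[va], y[va], list(X.columns))
        r1 = backward_eliminate(*args, MlpHyperparams(seed=11), k=5)
        r2 = backward_eliminate(*args, MlpHyperparams(seed=11), k=5)
        assert r1.stages["features"].tolist() == r2.stages["features"].tolist()
        assert r1.best_threshold == r2.best_threshold
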