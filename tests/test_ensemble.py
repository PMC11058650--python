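import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import precision_score, roc_auc_score

from pharmscreen.ensemble import (
    EnsembleModel,
    ModelOutputMatrix,
    build_stacking_dataset,
    evaluate_protocol,
    feature_select,
    filter_models,
    fit_ensemble,
    global_voting,
    predict_ensemble,
    train_meta,
    wilcoxon_compare,
)
from pharmscreen.synthdata import synth_score_matrix


def _matrix(n_act=200, n_dec=2000, targets=(0.55, 0.65, 0.75), seed=1, corr=0.0):
    return synth_score_matrix(n_act, n_dec, list(targets), correlation=corr, seed=seed)


class TestFilterModels:
    def test_planted_aucs_filtered_at_threshold(self):
        m = _matrix(n_act=2000, n_dec=2000, seed=2)
        top = filter_models(m, 0.6)
        assert top == ["model_2", "model_1"]  # descending AUC order

    def test_half_threshold_keeps_all(self):
        m = _matrix(seed=3)
        assert set(filter_models(m, 0.5)) == set(m.model_names)

    def test_unreachable_threshold_errors(self):
        m = _matrix(seed=4)
        with pytest.raises(ValueError, match="no_models_pass_threshold"):
            filter_models(m, 1.0)


class TestVoting:
    def _votes(self, patterns):
        arr = np.asarray(patterns)
        return ModelOutputMatrix(
            molecule_ids=[f"m{i}" for i in range(arr.shape[0])],
            model_names=[f"p{j}" for j in range(arr.shape[1])],
            predictions=arr,
            rescores=arr.astype(float),
            labels=np.zeros(arr.shape[0], dtype=int),
        )

    def test_majority_and_tie_rules(self):
        m = self._votes([[1, 1, 0], [1, 0, 0]])
        assert global_voting(m, m.model_names).tolist() == [1, 0]

    def test_truth_table_even_panel(self):
        # all 2^4 vote patterns: active iff strictly more than 2 votes
        patterns = list(itertools.product([0, 1], repeat=4))
        m = self._votes(patterns)
        expected = [1 if sum(p) > 2 else 0 for p in patterns]
        assert global_voting(m, m.model_names).tolist() == expected

    def test_single_model_passthrough(self):
        m = _matrix(seed=5)
        votes = global_voting(m, ["model_1"])
        assert np.array_equal(votes, m.predictions[:, 1])

    def test_model_order_invariance(self):
        m = _matrix(seed=6)
        a = global_voting(m, ["model_0", "model_1", "model_2"])
        b = global_voting(m, ["model_2", "model_0", "model_1"])
        assert np.array_equal(a, b)


class TestStackingDataset:
    def test_mode_shapes(self):
        m = _matrix(seed=7)
        top = list(m.model_names)
        assert build_stacking_dataset(m, top, "predict").shape[1] == 3
        assert build_stacking_dataset(m, top, "score").shape[1] == 3
        assert build_stacking_dataset(m, top, "both").shape[1] == 6

    def test_both_mode_on_49_models_gives_98_features(self):
        m = synth_score_matrix(40, 400, [0.7] * 49, seed=8)
        d = build_stacking_dataset(m, list(m.model_names), "both")
        assert d.shape[1] == 98

    def test_column_order_predictions_before_rescores(self):
        m = _matrix(seed=9)
        d = build_stacking_dataset(m, ["model_0"], "both")
        assert list(d.columns) == ["pred:model_0", "score:model_0"]

    def test_unknown_mode_errors(self):
        m = _matrix(seed=9)
        with pytest.raises(ValueError):
            build_stacking_dataset(m, list(m.model_names), "weird")

    def test_column_permutation_equivariance(self):
        m = _matrix(seed=10)
        d1 = build_stacking_dataset(m, ["model_0", "model_2"], "score")
        d2 = build_stacking_dataset(m, ["model_2", "model_0"], "score")
        assert list(d1.columns) == ["score:model_0", "score:model_2"]
        assert np.array_equal(d1["score:model_0"], d2["score:model_0"])


class TestFeatureSelect:
    @staticmethod
    def _informative_plus_noise(n_inf=10, n_noise=88, n=1000, seed=123):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, n)
        cols = {f"inf_{i}": y + rng.normal(0, 1.0, n) for i in range(n_inf)}
        cols.update({f"noise_{i}": rng.normal(0, 1.0, n) for i in range(n_noise)})
        return pd.DataFrame(cols), y

    def test_recovers_informative_features(self):
        d, y = self._informative_plus_noise()
        selected = feature_select(d, y, seed=0)
        assert sum(s.startswith("inf_") for s in selected) >= 8

    def test_identical_informative_features_at_least_one_kept(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 500)
        x = y + rng.normal(0, 0.5, 500)
        d = pd.DataFrame({"a": x, "b": x.copy(),
                          **{f"n{i}": rng.normal(size=500) for i in range(8)}})
        selected = feature_select(d, y, seed=0)
        assert {"a", "b"} & set(selected)

    def test_degenerate_small_feature_sets_keep_all(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, 100)
        d = pd.DataFrame({"only": rng.normal(size=100)})
        assert feature_select(d, y, seed=0) == ["only"]


class TestTrainMeta:
    def test_perfect_feature_reaches_full_training_accuracy(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 400)
        d = pd.DataFrame({"f": y.astype(float)})
        model = train_meta(d, y, seed=0)
        assert (model.predict(d.to_numpy()) == y).all()

    def test_single_class_collapses_to_constant_majority(self):
        d = pd.DataFrame({"f": np.random.default_rng(0).normal(size=50)})
        with pytest.warns(UserWarning):
            model = train_meta(d, np.zeros(50, dtype=int), seed=0)
        assert (model.predict(d.to_numpy()) == 0).all()

    def test_imbalanced_weak_collapse_yields_zero_f1_and_gh(self):
        from pharmscreen.metrics import confusion, f1, gh

        m = synth_score_matrix(20, 1000, [0.62, 0.61], seed=11)
        spec = EnsembleModel(kind="stack_predict", auc_threshold=0.6, seed=3)
        res = evaluate_protocol(spec, m, seed=3)
        assert res["holdout"]["f1"] == 0.0
        assert res["holdout"]["gh"] == 0.0


class TestProtocol:
    def test_fold_shapes_and_stratification(self):
        m = _matrix(n_act=100, n_dec=900, targets=(0.75, 0.8), seed=12)
        res = evaluate_protocol(
            EnsembleModel(kind="voting", auc_threshold=0.6, seed=0), m, seed=0
        )
        folds = res["fold_metrics"]
        assert len(folds) == 30
        assert set(folds.columns) >= {"auc", "ef1", "gh", "f1"}

    def test_determinism_under_fixed_seed(self):
        m = _matrix(n_act=100, n_dec=900, targets=(0.7, 0.75), seed=13)
        spec = EnsembleModel(kind="stack_score", auc_threshold=0.6, seed=4)
        r1 = evaluate_protocol(spec, m, seed=4)
        r2 = evaluate_protocol(spec, m, seed=4)
        pd.testing.assert_frame_equal(r1["fold_metrics"], r2["fold_metrics"])
        assert r1["holdout"] == r2["holdout"]

    def test_perfect_model_gives_ceiling_metrics(self):
        n_act, n_dec = 40, 360
        labels = np.r_[np.ones(n_act, dtype=int), np.zeros(n_dec, dtype=int)]
        scores = labels.astype(float)
        m = ModelOutputMatrix(
            molecule_ids=[f"m{i}" for i in range(n_act + n_dec)],
            model_names=["oracle"],
            predictions=labels[:, None],
            rescores=scores[:, None] + np.linspace(0, 0.01, n_act + n_dec)[:, None],
            labels=labels,
        )
        res = evaluate_protocol(
            EnsembleModel(kind="voting", auc_threshold=0.6, seed=0), m, seed=0
        )
        assert res["holdout"]["auc"] == 1.0
        assert res["holdout"]["gh"] == 1.0
        assert res["holdout"]["f1"] == 1.0
        assert (res["fold_metrics"]["auc"] == 1.0).all()

    def test_too_few_actives_errors(self):
        m = synth_score_matrix(10, 500, [0.7], seed=14)
        with pytest.raises(ValueError):
            evaluate_protocol(EnsembleModel(kind="voting", seed=0), m, seed=0)


class TestEnsembleBehaviours:
    def test_voting_auc_nondecreasing_in_panel_size(self):
        # conditionally independent members of equal skill: adding voters
        # should not hurt (replicate-averaged)
        sizes = (1, 3, 5, 7)
        mean_aucs = {s: [] for s in sizes}
        for rep in range(40):
            m = synth_score_matrix(60, 600, [0.7] * 7, seed=1000 + rep)
            for s in sizes:
                votes = global_voting(m, m.model_names[:s])
                frac = m.predictions[:, :s].mean(axis=1)
                mean_aucs[s].append(roc_auc_score(m.labels, frac))
        means = [np.mean(mean_aucs[s]) for s in sizes]
        assert all(b >= a - 0.01 for a, b in zip(means, means[1:]))

    def test_voting_precision_beats_mean_member_precision(self):
        m = synth_score_matrix(100, 5000, [0.75] * 5, seed=7)
        votes = global_voting(m, m.model_names)
        vote_prec = precision_score(m.labels, votes)
        member_prec = np.mean(
            [precision_score(m.labels, m.predictions[:, j]) for j in range(5)]
        )
        assert vote_prec >= member_prec

    def test_score_stacking_beats_prediction_stacking_when_scores_carry_signal(self):
        m = synth_score_matrix(150, 3000, [0.72] * 5, seed=21)
        res_s = evaluate_protocol(
            EnsembleModel(kind="stack_score", auc_threshold=0.6, seed=2), m, seed=2
        )
        res_p = evaluate_protocol(
            EnsembleModel(kind="stack_predict", auc_threshold=0.6, seed=2), m, seed=2
        )
        assert res_s["holdout"]["auc"] >= res_p["holdout"]["auc"]

    def test_correlation_hurts_voting(self):
        aucs = {0.0: [], 0.9: []}
        for rep in range(50):
            for corr in (0.0, 0.9):
                m = synth_score_matrix(40, 400, [0.7] * 5, correlation=corr,
                                       seed=3000 + rep)
                frac = m.predictions.mean(axis=1)
                aucs[corr].append(roc_auc_score(m.labels, frac))
        assert np.mean(aucs[0.0]) > np.mean(aucs[0.9])


class TestWilcoxon:
    def test_identical_series_not_significant(self):
        series = np.linspace(0.5, 0.9, 30)
        res = wilcoxon_compare(series, series.copy())
        assert res["p_value"] == 1.0
        assert not res["significant"]

    def test_uniform_improvement_significant(self):
        rng = np.random.default_rng(6)
        a = rng.uniform(0.5, 0.9, 30)
        res = wilcoxon_compare(a, a + 0.1)
        assert res["significant"]
        # all-positive differences: the exact signed-rank p for n = 30 is tiny
        assert res["p_value"] < 1e-5

    def test_short_series_errors(self):
        with pytest.raises(ValueError):
            wilcoxon_compare(np.ones(3), np.zeros(3))


class TestLongFormRoundTrip:
    def test_csv_round_trip(self):
        m = _matrix(n_act=10, n_dec=50, seed=15)
        back = ModelOutputMatrix.from_long_frame(m.to_long_frame())
        idx = [back.molecule_ids.index(i) for i in m.molecule_ids]
        assert np.array_equal(back.predictions[idx], m.predictions)
        assert np.allclose(back.rescores[idx], m.rescores)
        assert np.array_equal(back.labels[idx], m.labels)
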