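import numpy as np
import pandas as pd
import pytest

from dtscore.ensemble import (
    EnsembleConfig,
    fit_predict_ensemble,
    fit_replicate,
    sample_negatives,
    tune_mtry,
)
from dtscore.errors import InputError
from dtscore.features import FeatureMatrix
from dtscore.targets import StudySets


class TestEnsembleConfig:
    def test_defaults_match_published_protocol(self):
        cfg = EnsembleConfig()
        assert cfg.n_models == 10_000
        assert cfg.n_trees == 1000

    @pytest.mark.parametrize("kw", [{"n_models": 0}, {"n_trees": 0}, {"mtry": 0}, {"mtry": "sqrt"}])
    def test_invalid_config_rejected(self, kw):
        with pytest.raises(InputError):
            EnsembleConfig(**kw)

    def test_auto_mtry_is_floor_sqrt(self):
        assert EnsembleConfig().resolve_mtry(70) == 8
        assert EnsembleConfig().resolve_mtry(1) == 1

    def test_mtry_cannot_exceed_feature_count(self):
        with pytest.raises(InputError):
            EnsembleConfig(mtry=5).resolve_mtry(3)


class TestSampleNegatives:
    def test_exhaustive_sample_returns_whole_pool(self):
        pool = {f"p{i}" for i in range(102)}
        rng = np.random.default_rng(0)
        assert sample_negatives(pool, 102, rng) == frozenset(pool)

    def test_same_seed_same_sample(self):
        pool = {f"p{i}" for i in range(50)}
        s1 = sample_negatives(pool, 10, np.random.default_rng(42))
        s2 = sample_negatives(pool, 10, np.random.default_rng(42))
        assert s1 == s2

    def test_independent_of_pool_iteration_order(self):
        pool_list = [f"p{i}" for i in range(30)]
        s1 = sample_negatives(set(pool_list), 5, np.random.default_rng(7))
        s2 = sample_negatives(list(reversed(pool_list)), 5, np.random.default_rng(7))
        assert s1 == s2

    def test_oversampling_rejected(self):
        with pytest.raises(InputError):
            sample_negatives({"a"}, 2, np.random.default_rng(0))

    def test_selection_frequency_uniform(self):
        # 10,000 draws of k=100 from 1,000: each protein picked ~10% of draws
        pool = [f"p{i}" for i in range(1000)]
        rng = np.random.default_rng(1)
        counts = np.zeros(1000)
        n_draws = 10_000
        ordered = sorted(pool)
        index = {p: i for i, p in enumerate(ordered)}
        for _ in range(n_draws):
            for p in sample_negatives(pool, 100, rng):
                counts[index[p]] += 1
        freq = counts / n_draws
        se = np.sqrt(0.1 * 0.9 / n_draws)
        assert np.all(np.abs(freq - 0.1) < 3 * se + 1e-9) or (
            # allow a handful of 3-se excursions out of 1000 bins
            (np.abs(freq - 0.1) > 3 * se).sum() <= 10
        )


class TestFitReplicate:
    def test_separating_feature_gets_max_importance(self, separable_fm):
        fm, positives, background = separable_fm
        negatives = frozenset(sorted(background)[: len(positives)])
        cfg = EnsembleConfig(n_models=1, n_trees=100)
        _, imp = fit_replicate(fm, positives, negatives, cfg, random_state=0)
        assert fm.data.columns[np.argmax(imp)] == "oracle"

    def test_deterministic_given_state(self, separable_fm):
        fm, positives, background = separable_fm
        negatives = frozenset(sorted(background)[: len(positives)])
        cfg = EnsembleConfig(n_models=1, n_trees=50)
        clf1, imp1 = fit_replicate(fm, positives, negatives, cfg, random_state=3)
        clf2, imp2 = fit_replicate(fm, positives, negatives, cfg, random_state=3)
        X = fm.data.to_numpy()
        assert np.array_equal(clf1.predict_proba(X), clf2.predict_proba(X))
        assert np.array_equal(imp1, imp2)

    def test_resubstitution_probability_on_separable_data(self, separable_fm):
        fm, positives, background = separable_fm
        negatives = frozenset(sorted(background)[: len(positives)])
        cfg = EnsembleConfig(n_models=1, n_trees=100)
        clf, _ = fit_replicate(fm, positives, negatives, cfg, random_state=0)
        col = list(clf.classes_).index(1)
        for p in positives:
            prob = clf.predict_proba(fm.data.loc[[p]].to_numpy())[0, col]
            assert prob >= 0.5

    def test_class_overlap_rejected(self, toy_fm):
        with pytest.raises(InputError):
            fit_replicate(
                toy_fm, frozenset({"p1", "p2"}), frozenset({"p2", "p3"}),
                EnsembleConfig(), 0,
            )

    def test_empty_class_rejected(self, toy_fm):
        with pytest.raises(InputError):
            fit_replicate(toy_fm, frozenset(), frozenset({"p3"}), EnsembleConfig(), 0)


def study_sets(fm, positives, holdout=frozenset()):
    pool = frozenset(fm.data.index) - positives - holdout
    return StudySets(positives=positives, clinical_holdout=holdout, negative_pool=pool)


class TestFitPredictEnsemble:
    def test_single_model_reduces_to_one_replicate(self, separable_fm):
        fm, positives, _ = separable_fm
        sets = study_sets(fm, positives)
        cfg = EnsembleConfig(n_models=1, n_trees=50, seed=5)
        result = fit_predict_ensemble(fm, sets, cfg)

        child = np.random.SeedSequence(cfg.seed).spawn(1)[0]
        rng = np.random.default_rng(child)
        model_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        negatives = sample_negatives(sets.negative_pool, len(positives), rng)
        clf, _ = fit_replicate(fm, positives, negatives, cfg, model_seed)
        col = list(clf.classes_).index(1)
        direct = clf.predict_proba(fm.data.to_numpy())[:, col]
        assert np.allclose(result.scores.to_numpy(), direct, atol=1e-12)

    def test_scores_bounded_and_importances_nonnegative(self, separable_fm):
        fm, positives, _ = separable_fm
        result = fit_predict_ensemble(
            fm, study_sets(fm, positives), EnsembleConfig(n_models=10, n_trees=30, seed=1)
        )
        assert ((result.scores >= 0) & (result.scores <= 1)).all()
        assert (result.importances >= 0).all()
        assert len(result.importances) == fm.data.shape[1]

    def test_bit_identical_across_runs(self, separable_fm):
        fm, positives, _ = separable_fm
        cfg = EnsembleConfig(n_models=15, n_trees=40, seed=9)
        r1 = fit_predict_ensemble(fm, study_sets(fm, positives), cfg)
        r2 = fit_predict_ensemble(fm, study_sets(fm, positives), cfg)
        assert r1.scores.equals(r2.scores)
        assert r1.importances.equals(r2.importances)
        assert r1.replicate_seeds == r2.replicate_seeds

    def test_positives_score_above_background_on_separable_data(self, separable_fm):
        fm, positives, background = separable_fm
        holdout = frozenset(sorted(background)[:2])
        sets = study_sets(fm, positives, holdout)
        result = fit_predict_ensemble(fm, sets, EnsembleConfig(n_models=25, n_trees=50, seed=2))
        assert result.scores[sorted(positives)].mean() > result.scores[
            sorted(sets.negative_pool)
        ].mean()

    def test_too_few_positives_rejected(self, toy_fm):
        sets = study_sets(toy_fm, frozenset({"p1"}))
        with pytest.raises(InputError):
            fit_predict_ensemble(toy_fm, sets, EnsembleConfig(n_models=1))

    def test_result_files_roundtrip(self, separable_fm, tmp_path):
        fm, positives, _ = separable_fm
        result = fit_predict_ensemble(
            fm, study_sets(fm, positives), EnsembleConfig(n_models=2, n_trees=20, seed=0)
        )
        paths = result.write(tmp_path)
        scores = pd.read_csv(paths["scores"], sep="\t", index_col=0)
        assert np.allclose(scores["score"].to_numpy(), result.scores.to_numpy())
        assert paths["manifest"].exists()


class TestTuneMtry:
    def test_single_feature_returns_one(self):
        data = pd.DataFrame(
            {"only": np.r_[np.ones(10), np.zeros(10)]},
            index=[f"p{i}" for i in range(20)],
        )
        fm = FeatureMatrix(data=data)
        pos = frozenset(data.index[:10])
        neg = frozenset(data.index[10:])
        assert tune_mtry(fm, pos, neg, EnsembleConfig(n_trees=30, seed=0)) == 1

    def test_degenerate_step_factor_falls_back_to_sqrt(self, separable_fm):
        fm, positives, background = separable_fm
        negatives = frozenset(sorted(background)[: len(positives)])
        cfg = EnsembleConfig(n_trees=30, seed=0, step_factor=1.0)
        assert tune_mtry(fm, positives, negatives, cfg) == 1  # floor(sqrt(3))

    def test_result_within_bounds(self, separable_fm):
        fm, positives, background = separable_fm
        negatives = frozenset(sorted(background)[: len(positives)])
        cfg = EnsembleConfig(n_trees=50, seed=0)
        mtry = tune_mtry(fm, positives, negatives, cfg)
        assert 1 <= mtry <= fm.data.shape[1]
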