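"""Tests for the CV plan, ensemble training, prediction and tuning."""

import numpy as np
import pytest

import purityboost as pb
from purityboost import (
    DataError,
    GBMConfig,
    PurityVector,
    build_cv_plan,
    grid_search,
    predict,
    restrict_and_retrain,
    simulate_bulk,
    train_ensemble,
)
from purityboost.ensemble import TEN_GENE_PANEL, load_ensemble, save_ensemble
from purityboost.preprocess import LOGIT, ORIGINAL, logit_transform


class TestGBMConfig:
    def test_defaults_are_the_tuned_set(self):
        c = GBMConfig()
        assert (c.learning_rate, c.max_depth, c.min_leaf_weight) == (0.05, 4, 1.0)
        assert (c.colsample_per_tree, c.subsample_per_tree) == (0.65, 0.85)
        assert (c.max_trees, c.early_stop_patience) == (5000, 5)

    def test_validation(self):
        with pytest.raises(ValueError):
            GBMConfig(colsample_per_tree=0.0)
        with pytest.raises(ValueError):
            GBMConfig(max_trees=0)

    def test_panel_constant(self):
        assert TEN_GENE_PANEL == (
            "CSF2RB", "RHOH", "C1S", "CCDC69", "CCL22",
            "CYTIP", "POU2AF1", "FGR", "CCL21", "IL7R",
        )


class TestBuildCVPlan:
    def test_each_fold_one_sample(self):
        plan = build_cv_plan([f"s{i}" for i in range(10)], 1, 10, 0)
        counts = np.bincount(plan.fold_assignment[0], minlength=10)
        assert (counts == 1).all()

    def test_fold_sizes_differ_by_at_most_one(self):
        plan = build_cv_plan([f"s{i}" for i in range(23)], 1, 10, 0)
        counts = sorted(np.bincount(plan.fold_assignment[0], minlength=10))
        assert counts == [2, 2, 2, 2, 2, 2, 2, 3, 3, 3]

    def test_every_sample_in_one_validation_fold(self):
        plan = build_cv_plan([f"s{i}" for i in range(17)], 3, 4, 1)
        for r in range(3):
            assert set(plan.fold_assignment[r]) == {0, 1, 2, 3}

    def test_repetitions_differ_and_deterministic(self):
        ids = [f"s{i}" for i in range(30)]
        plan = build_cv_plan(ids, 2, 5, 7)
        assert not np.array_equal(plan.fold_assignment[0], plan.fold_assignment[1])
        again = build_cv_plan(ids, 2, 5, 7)
        np.testing.assert_array_equal(plan.fold_assignment, again.fold_assignment)

    def test_errors(self):
        with pytest.raises(ValueError):
            build_cv_plan(["a", "b"], 1, 1, 0)
        with pytest.raises(ValueError):
            build_cv_plan(["a", "b"], 1, 3, 0)


class TestTrainEnsemble:
    def test_model_count(self, small_synthetic):
        m, p, _ = small_synthetic
        plan = build_cv_plan(m.sample_ids, 2, 5, 0)
        e = train_ensemble(m, logit_transform(p), GBMConfig(max_trees=30), plan)
        assert e.n_models == 10
        assert all(rec.n_trees <= 30 for rec in e.records)

    def test_noise_free_fit_is_near_perfect(self):
        m, p, _ = simulate_bulk(n_samples=150, n_genes=60, n_markers=10,
                                effect_size=4.0, noise_sd=0.0,
                                type_shift_sd=0.0, n_types=1, seed=13)
        plan = build_cv_plan(m.sample_ids, 1, 5, 13)
        e = train_ensemble(m, logit_transform(p), GBMConfig(max_trees=400), plan)
        mean_val_r = np.mean([rec.val_pearson for rec in e.records])
        assert mean_val_r >= 0.99

    def test_constant_target_all_skipped(self, small_synthetic):
        m, _, _ = small_synthetic
        const = PurityVector(m.sample_ids, np.zeros(m.n_samples), LOGIT)
        plan = build_cv_plan(m.sample_ids, 1, 3, 0)
        with pytest.raises(DataError):
            with pytest.warns(UserWarning):
                train_ensemble(m, const, GBMConfig(max_trees=10), plan)

    def test_scale_flags_enforced(self, small_synthetic):
        m, p, _ = small_synthetic
        with pytest.raises(DataError):
            train_ensemble(m, p, GBMConfig())  # original-scale target


@pytest.fixture(scope="module")
def fitted(small_synthetic):
    m, p, _ = small_synthetic
    plan = build_cv_plan(m.sample_ids, 1, 4, 3)
    return m, p, train_ensemble(m, logit_transform(p),
                                GBMConfig(max_trees=60), plan)


class TestPredict:
    def test_final_is_mean_of_per_model(self, fitted):
        m, p, e = fitted
        res = predict(e, m)
        np.testing.assert_allclose(res.final, res.per_model.mean(axis=0),
                                   atol=1e-12)
        assert ((res.final > 0) & (res.final < 1)).all()

    def test_logit_averaging_option(self, fitted):
        from scipy.special import expit, logit

        m, p, e = fitted
        res = predict(e, m, avg_scale="logit")
        manual = expit(np.mean(logit(predict(e, m).per_model), axis=0))
        np.testing.assert_allclose(res.final, manual, atol=1e-6)

    def test_missing_genes_error(self, fitted):
        m, p, e = fitted
        with pytest.raises(DataError, match="genes"):
            predict(e, m.subset_genes(m.gene_symbols[:-5]))

    def test_extra_genes_ignored(self, fitted):
        import pandas as pd

        from purityboost.preprocess import LOG2, ExpressionMatrix

        m, p, e = fitted
        extra = m.data.copy()
        extra["NOVEL"] = 1.0
        res_extra = predict(e, ExpressionMatrix(extra, LOG2))
        np.testing.assert_array_equal(res_extra.final, predict(e, m).final)

    def test_validation_rmse_matches_recomputation(self, fitted):
        """Stored per-model validation RMSE equals an independent recompute."""
        from scipy.special import expit

        m, p, e = fitted
        y = p.values
        pos = {s: i for i, s in enumerate(m.sample_ids)}
        res = predict(e, m)
        for k, rec in enumerate(e.records):
            val_ids = [s for s in m.sample_ids if s not in set(rec.train_ids)]
            idx = [pos[s] for s in val_ids]
            recomputed = float(np.sqrt(np.mean(
                (y[idx] - res.per_model[k, idx]) ** 2)))
            assert rec.val_rmse == pytest.approx(recomputed, abs=1e-10)


class TestReproducibility:
    def test_bitwise_identical_predictions(self, small_synthetic):
        m, p, _ = small_synthetic
        outs = []
        for _ in range(2):
            plan = build_cv_plan(m.sample_ids, 1, 3, 99)
            e = train_ensemble(m, logit_transform(p), GBMConfig(max_trees=40), plan)
            outs.append(predict(e, m).final)
        np.testing.assert_array_equal(outs[0], outs[1])


class TestGridSearch:
    def test_single_config_returned(self, small_synthetic):
        m, p, _ = small_synthetic
        cfg = GBMConfig(max_trees=20)
        best, summary = grid_search(m, logit_transform(p), [cfg], n_folds=3, seed=0)
        assert best == cfg
        assert len(summary) == 1

    def test_selection_matches_recomputed_rmse(self, small_synthetic):
        m, p, _ = small_synthetic
        grid = [GBMConfig(max_depth=2, max_trees=40),
                GBMConfig(max_depth=4, max_trees=40)]
        best, summary = grid_search(m, logit_transform(p), grid, n_folds=3, seed=1)
        means = summary["cv_rmse_mean"].to_numpy()
        assert best == grid[int(np.argmin(means))]

    def test_deterministic(self, small_synthetic):
        m, p, _ = small_synthetic
        grid = [GBMConfig(max_trees=30), GBMConfig(learning_rate=0.3, max_trees=30)]
        r1 = grid_search(m, logit_transform(p), grid, n_folds=3, seed=5)
        r2 = grid_search(m, logit_transform(p), grid, n_folds=3, seed=5)
        assert r1[0] == r2[0]
        assert r1[1].equals(r2[1])

    def test_empty_grid_errors(self, small_synthetic):
        m, p, _ = small_synthetic
        with pytest.raises(ValueError):
            grid_search(m, logit_transform(p), [], n_folds=3)


class TestRestrictAndRetrain:
    def test_unknown_panel_gene_errors(self, small_synthetic):
        m, p, _ = small_synthetic
        with pytest.raises(DataError, match="absent"):
            restrict_and_retrain(m, p, ["NOPE"], grid=[GBMConfig(max_trees=10)],
                                 n_repetitions=1, n_folds=3)

    def test_panel_run_trains_on_panel_only(self, small_synthetic):
        m, p, truth = small_synthetic
        e = restrict_and_retrain(m, p, truth.marker_genes,
                                 grid=[GBMConfig(max_trees=40)],
                                 n_repetitions=1, n_folds=3, master_seed=2,
                                 tune_folds=3)
        assert e.gene_symbols == truth.marker_genes
        res = predict(e, m.subset_genes(truth.marker_genes))
        r = np.corrcoef(res.final, p.values)[0, 1]
        assert r > 0.8  # markers carry the whole signal


class TestSerialization:
    def test_save_load_roundtrip(self, small_synthetic, tmp_path):
        m, p, _ = small_synthetic
        plan = build_cv_plan(m.sample_ids, 1, 3, 17)
        e = train_ensemble(m, logit_transform(p), GBMConfig(max_trees=30), plan)
        save_ensemble(e, tmp_path / "ens")
        loaded = load_ensemble(tmp_path / "ens")
        assert loaded.n_models == e.n_models
        assert loaded.gene_symbols == e.gene_symbols
        assert loaded.config == e.config
        np.testing.assert_allclose(loaded.per_model_importance,
                                   e.per_model_importance, atol=1e-12)
        np.testing.assert_allclose(predict(loaded, m).final,
                                   predict(e, m).final, atol=1e-7)


def test_bagging_rmse_stabilizes_with_model_count(small_synthetic):
    """RMSE of the bagged predictor changes little once many models average."""
    m, p, _ = small_synthetic
    plan = build_cv_plan(m.sample_ids, 8, 5, 23)  # 40 models
    e = train_ensemble(m, logit_transform(p), GBMConfig(max_trees=40), plan)
    res = predict(e, m)
    y = p.values
    rng = np.random.default_rng(0)

    def subset_rmse(k):
        vals = []
        for _ in range(20):
            pick = rng.choice(e.n_models, size=k, replace=False)
            vals.append(pb.rmse(y, res.per_model[pick].mean(axis=0)))
        return float(np.mean(vals))

    assert abs(subset_rmse(10) - subset_rmse(40)) < 0.02
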