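import numpy as np
import pytest

from leafwp import (
    AblationConfig,
    CGANConfig,
    IRACConfig,
    LossConfig,
    TrainConfig,
    aggregate_metrics,
    compute_metrics,
    grid_search_sigma_l,
    repeated_holdout_split,
    sweep_C,
    train_cidl,
)

# small-but-stable settings for protocol tests (full-size runs live in the
# acceptance suite)
FAST_TRAIN = TrainConfig(epochs=4)
FAST_IRAC = IRACConfig(channels=4)
FAST_CGAN = CGANConfig(epochs=15, batch_size=16, n_synthetic=20)


class TestSplits:
    def test_stated_sizes_for_default_campaign(self):
        plan = repeated_holdout_split(229, [0])[0]
        assert (len(plan.train), len(plan.val), len(plan.test)) == (160, 22, 47)

    def test_disjoint_and_complete(self):
        for plan in repeated_holdout_split(229, list(range(10))):
            joined = np.concatenate([plan.train, plan.val, plan.test])
            assert len(joined) == 229
            assert len(np.unique(joined)) == 229

    def test_same_seed_same_plan_distinct_seeds_distinct_plans(self):
        a = repeated_holdout_split(100, [7])[0]
        b = repeated_holdout_split(100, [7])[0]
        np.testing.assert_array_equal(a.train, b.train)
        plans = repeated_holdout_split(100, list(range(10)))
        trains = {tuple(p.train) for p in plans}
        assert len(trains) == 10

    def test_duplicate_seeds_rejected(self):
        with pytest.raises(ValueError):
            repeated_holdout_split(100, [1, 1])


class TestMetrics:
    def test_worked_example(self):
        m = compute_metrics([0, 1, 2, 3], [0.5, 1.5, 1.5, 2.5])
        assert m["rmse"] == pytest.approx(0.5)
        assert m["r2"] == pytest.approx(0.8)
        assert m["mae"] == pytest.approx(0.5)
        assert m["rpd"] == pytest.approx(np.std([0, 1, 2, 3], ddof=1) / 0.5)
        assert m["rpiq"] == pytest.approx(3.0)

    def test_perfect_prediction_flags_infinite_ratios(self):
        m = compute_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert m["r2"] == 1.0 and m["rmse"] == 0.0 and m["mae"] == 0.0
        assert np.isinf(m["rpd"]) and np.isinf(m["rpiq"])

    def test_mean_predictor_scores_zero_r2(self, rng):
        y = rng.normal(size=50)
        m = compute_metrics(y, np.full(50, y.mean()))
        assert m["r2"] == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_reference_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics([1.0, 1.0], [1.0, 2.0])

    def test_aggregate_recomputes_from_records(self, rng):
        records = [
            compute_metrics(rng.normal(size=30), rng.normal(size=30)) for _ in range(4)
        ]
        agg = aggregate_metrics(records)
        assert agg["r2_mean"] == pytest.approx(np.mean([r["r2"] for r in records]))
        assert agg["r2_sd"] == pytest.approx(np.std([r["r2"] for r in records], ddof=1))
        # pooled RPD uses pooled rmse over all rows
        pooled_rmse = np.sqrt(sum(r["ss_res"] for r in records) / sum(r["n"] for r in records))
        assert agg["rpd_pooled"] == pytest.approx(
            np.mean([r["sd"] for r in records]) / pooled_rmse
        )


class TestTrainingPipeline:
    def test_deterministic_end_to_end(self, default_dataset):
        plan = repeated_holdout_split(default_dataset.n_samples, [2])[0]
        args = dict(
            ablation=AblationConfig(False, False, True),
            tcfg=FAST_TRAIN, icfg=FAST_IRAC, ccfg=FAST_CGAN,
        )
        _, rec_a = train_cidl(default_dataset, plan, **args)
        _, rec_b = train_cidl(default_dataset, plan, **args)
        assert rec_a["test"] == rec_b["test"]

    def test_baseline_has_no_gan_rows_and_point_head(self, default_dataset):
        plan = repeated_holdout_split(default_dataset.n_samples, [2])[0]
        model, rec = train_cidl(
            default_dataset, plan, AblationConfig(False, False, False),
            tcfg=FAST_TRAIN, icfg=FAST_IRAC, ccfg=FAST_CGAN,
        )
        assert not model.distributional
        assert rec["label_grid_k"] > 0  # grid is built but unused by the head

    def test_training_loss_decreases(self, default_dataset):
        plan = repeated_holdout_split(default_dataset.n_samples, [3])[0]
        _, rec = train_cidl(
            default_dataset, plan, AblationConfig(False, False, True),
            tcfg=TrainConfig(epochs=12), icfg=FAST_IRAC, ccfg=FAST_CGAN,
        )
        assert rec["loss_trace"][-1] < rec["loss_trace"][0]

    def test_distribution_head_predictions_stay_on_grid(self, default_dataset):
        plan = repeated_holdout_split(default_dataset.n_samples, [4])[0]
        model, _ = train_cidl(
            default_dataset, plan, AblationConfig(False, False, True),
            tcfg=FAST_TRAIN, icfg=FAST_IRAC, ccfg=FAST_CGAN,
        )
        preds = model.predict(default_dataset)
        assert preds.min() >= model.grid.centers.min() - 1e-9
        assert preds.max() <= model.grid.centers.max() + 1e-9

    def test_unlabeled_dataset_rejected(self, default_dataset):
        from leafwp import SpectraSet

        unlabeled = SpectraSet(grid=default_dataset.grid, spectra=default_dataset.spectra)
        plan = repeated_holdout_split(229, [0])[0]
        with pytest.raises(ValueError, match="label"):
            train_cidl(unlabeled, plan, tcfg=FAST_TRAIN, icfg=FAST_IRAC)


class TestSearches:
    def test_singleton_grids_return_that_pair(self, default_dataset):
        best, matrix = grid_search_sigma_l(
            default_dataset, [5], sigma_grid=[0.4], l_grid=[0.15],
            ablation=AblationConfig(False, False, True),
            tcfg=FAST_TRAIN, icfg=FAST_IRAC, ccfg=FAST_CGAN,
        )
        assert best == (0.4, 0.15)
        assert matrix.shape == (1, 1)
        assert matrix.iloc[0, 0] <= 1.0

    def test_sweep_c_singleton(self, default_dataset):
        best_C, curve = sweep_C(
            default_dataset, [5], C_grid=[1.0],
            ablation=AblationConfig(False, False, True),
            tcfg=FAST_TRAIN, icfg=FAST_IRAC, ccfg=FAST_CGAN,
        )
        assert best_C == 1.0
        assert list(curve.columns) == ["C", "val_r2_mean", "val_r2_sd"]
        assert len(curve) == 1

    def test_empty_grid_rejected(self, default_dataset):
        with pytest.raises(ValueError):
            grid_search_sigma_l(default_dataset, [5], sigma_grid=[], l_grid=[0.1])
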