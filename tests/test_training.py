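import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rxnforge.errors import ConfigError, RxnForgeError
from rxnforge.training import (RunConfig, aggregate_seeds, compute_metrics,
                               cosine_warmup_lr, fit, relative_performance,
                               rung_schedule, scale_targets, subsample_train,
                               sweep)


class TestTargetScaler:
    def test_hand_example(self):
        scaler, scaled = scale_targets([1.0, 2.0, 3.0])
        assert scaler.mean == 2.0 and scaler.std == 1.0
        assert np.allclose(scaled, [-1, 0, 1])

    @given(st.lists(st.floats(-50, 50), min_size=3, max_size=30))
    @settings(max_examples=30, deadline=None)
    def test_round_trip(self, y):
        if np.std(y, ddof=1) == 0:
            return
        scaler, scaled = scale_targets(y)
        assert np.allclose(scaler.unscale(scaled), y, rtol=1e-10, atol=1e-8)

    def test_constant_targets_rejected(self):
        with pytest.raises(RxnForgeError, match="degenerate"):
            scale_targets([4.0, 4.0, 4.0])


class TestCosineWarmup:
    def test_ramp_endpoint(self):
        assert cosine_warmup_lr(10, 100, 0.5, warmup=10) == 0.5

    def test_final_step_is_zero(self):
        assert cosine_warmup_lr(100, 100, 0.5, warmup=10) == pytest.approx(0.0)

    def test_halfway_is_half(self):
        assert cosine_warmup_lr(55, 100, 0.5, warmup=10) == pytest.approx(0.25)

    def test_too_short_run_rejected(self):
        with pytest.raises(ConfigError):
            cosine_warmup_lr(1, 10, 0.5, warmup=10)


class TestMetrics:
    def test_perfect_prediction(self):
        assert compute_metrics([1.0, 2.0], [1.0, 2.0]) == (0.0, 0.0)

    def test_hand_example(self):
        mae, rmse = compute_metrics([0.0, 0.0], [3.0, 4.0])
        assert mae == 3.5 and rmse == pytest.approx(3.5355339)

    @given(st.lists(st.floats(-100, 100), min_size=1, max_size=40),
           st.integers(0, 5))
    @settings(max_examples=40, deadline=None)
    def test_rmse_dominates_mae(self, true, seed):
        pred = np.random.default_rng(seed).normal(size=len(true))
        mae, rmse = compute_metrics(pred, true)
        assert rmse >= mae >= 0

    def test_length_mismatch(self):
        with pytest.raises(RxnForgeError):
            compute_metrics([1.0], [1.0, 2.0])


class TestAggregateSeeds:
    def test_hand_example(self):
        rep = aggregate_seeds([(2.0, 3.0), (4.0, 5.0)])
        assert rep.mae_mean == 3.0
        assert rep.mae_std == pytest.approx(np.sqrt(2), abs=1e-9)

    def test_identical_replicates_zero_std(self):
        rep = aggregate_seeds([(1.5, 2.0)] * 4)
        assert rep.mae_std == 0.0 and rep.rmse_std == 0.0

    def test_exclusion_recorded(self):
        rep = aggregate_seeds([(2.0, 3.0), (4.0, 5.0)], seeds=[0, 1],
                              excluded={2: "training anomaly"})
        assert rep.excluded == {2: "training anomaly"}
        assert len(rep.per_seed) == 2

    def test_duplicate_seed_ids_rejected(self):
        with pytest.raises(RxnForgeError, match="duplicate"):
            aggregate_seeds([(1.0, 1.0), (2.0, 2.0)], seeds=[3, 3])


class TestRelativePerformance:
    def test_best_scaling_on_published_style_table(self):
        table = pd.DataFrame({"random": [2.54, 4.10, 10.36, 14.50]},
                             index=["a", "b", "c", "d"])
        by_best, by_random = relative_performance(table)
        assert np.allclose(by_best["random"], [1.0, 1.614, 4.079, 5.709],
                           atol=5e-4)
        assert np.allclose(by_random["random"], 1.0)

    def test_single_model_all_ones(self):
        table = pd.DataFrame({"random": [3.3], "core": [4.4]}, index=["m"])
        by_best, _ = relative_performance(table)
        assert np.allclose(by_best.values, 1.0)

    def test_missing_random_column_rejected(self):
        table = pd.DataFrame({"core": [1.0, 2.0]}, index=["a", "b"])
        with pytest.raises(RxnForgeError, match="random"):
            relative_performance(table)


class TestSubsample:
    def test_full_fraction_is_identity(self):
        idx = [3, 1, 4, 1, 5]
        assert subsample_train(idx, 1.0) == idx

    def test_half_of_ten(self):
        idx = list(range(10))
        sub = subsample_train(idx, 0.5, seed=0)
        assert len(sub) == 5 and set(sub) <= set(idx)

    def test_nesting_across_fractions(self):
        idx = list(range(40))
        small = set(subsample_train(idx, 0.25, seed=7))
        big = set(subsample_train(idx, 0.5, seed=7))
        assert small <= big

    @pytest.mark.parametrize("frac", [0.0, -0.1, 1.5])
    def test_bad_fraction(self, frac):
        with pytest.raises(ConfigError):
            subsample_train([0, 1], frac)


def _tiny_cfg(**routine):
    base = {"representation": {"name": "cgr"},
            "model": {"architecture": "dmpnn", "width": 8, "depth": 1},
            "routine": {"max_epochs": 3, "batch_size": 16, **routine}}
    return RunConfig(base)


class TestFit:
    def test_identical_config_and_seed_bit_identical(self, small_table):
        a = fit(_tiny_cfg(), table=small_table)
        b = fit(_tiny_cfg(), table=small_table)
        assert a.metrics == b.metrics
        assert all(np.array_equal(x.data, y.data) for x, y in
                   zip(a.model.parameters(), b.model.parameters()))

    def test_scaler_fitted_on_train_only(self, small_table):
        res = fit(_tiny_cfg(), table=small_table)
        y = small_table.targets()
        assert res.scaler.mean == pytest.approx(y[res.split.train].mean())
        assert res.scaler.std == pytest.approx(y[res.split.train].std(ddof=1))

    def test_early_stopping_halts_within_patience(self, small_table):
        # an impossible improvement threshold: only the first epoch counts as
        # an improvement, so training must stop at patience + 1 epochs
        res = fit(_tiny_cfg(max_epochs=30, patience=2, min_delta=1e9),
                  table=small_table)
        assert res.metrics["epochs_run"] <= 3

    def test_metrics_reported_in_original_units(self, small_table):
        res = fit(_tiny_cfg(), table=small_table)
        y = small_table.targets()
        # predicting the train mean would give roughly the target spread;
        # a barely trained model must be in that ballpark, not in scaled units
        assert 0.1 < res.metrics["test_mae"] < 3 * np.abs(y - y.mean()).max()

    def test_run_dir_artifacts(self, small_table, tmp_path):
        cfg = _tiny_cfg()
        cfg.set("trainer.run_dir", str(tmp_path / "run"))
        fit(cfg, table=small_table)
        for name in ("config.resolved.yaml", "split.json", "metrics.json",
                     "epochs.csv"):
            assert (tmp_path / "run" / name).exists()


class TestSweep:
    SPACE = {"model.width": {"type": "choice", "values": [4, 8]},
             "routine.lr": {"type": "loguniform", "low": 1e-3, "high": 1e-2}}

    def test_budget_one_returns_single_trial(self, small_table):
        res = sweep(self.SPACE, budget=1, eta=3.0, min_epochs=2,
                    base_config=_tiny_cfg(), master_seed=0, table=small_table)
        assert len(res.trials) == 1

    def test_successive_halving_schedule(self):
        assert rung_schedule(9, 3.0, 2) == [(9, 2), (3, 6), (1, 18)]
        assert rung_schedule(10, 1.5, 30)[:3] == [(10, 30), (6, 45), (4, 68)]

    def test_rung_sizes_in_trial_table(self, small_table):
        res = sweep(self.SPACE, budget=4, eta=2.0, min_epochs=1,
                    base_config=_tiny_cfg(), master_seed=1, table=small_table)
        sizes = res.trials.groupby("rung")["trial"].count().tolist()
        assert sizes == [4, 2, 1]

    def test_same_master_seed_identical_tables(self, small_table):
        kw = dict(budget=3, eta=2.0, min_epochs=1, base_config=_tiny_cfg(),
                  master_seed=5, table=small_table)
        a = sweep(self.SPACE, **kw)
        b = sweep(self.SPACE, **kw)
        pd.testing.assert_frame_equal(a.trials, b.trials)

    def test_unknown_path_rejected(self, small_table):
        with pytest.raises(ConfigError, match="sweep path"):
            sweep({"model.nonexistent": {"type": "choice", "values": [1]}},
                  budget=1, eta=2.0, min_epochs=1, base_config=_tiny_cfg(),
                  table=small_table)


class TestRunConfig:
    def test_dot_path_overrides(self):
        cfg = RunConfig().apply_overrides(["model.width=128", "routine.lr=0.01"])
        assert cfg.get("model.width") == 128
        assert cfg.get("routine.lr") == 0.01

    def test_unknown_key_rejected(self):
        with pytest.raises(ConfigError):
            RunConfig().set("model.wdth", 3)

    def test_yaml_round_trip(self, tmp_path):
        cfg = RunConfig({"model": {"width": 99}})
        path = str(tmp_path / "cfg.yaml")
        cfg.to_yaml(path)
        assert RunConfig.from_yaml(path).to_dict() == cfg.to_dict()
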