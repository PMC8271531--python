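import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_continuous_dataset
from whalefs.binary_fs import (
    FeatureMask,
    FitnessConfig,
    binarize,
    evaluate_mask,
    fitness_max,
    fitness_min,
    select_features,
    transfer,
)
from whalefs.data import SplitSpec, SyntheticSpec, synthesize, train_test_split
from whalefs.woa import WOAConfig


class TestTransfer:
    def test_symmetry_point_and_saturation(self):
        assert transfer(0.0) == 0.5
        assert transfer(10.0) > 0.9999
        assert transfer(-10.0) < 0.0001

    def test_odd_symmetry_about_half(self):
        assert transfer(-1.7) == pytest.approx(1.0 - transfer(1.7), abs=1e-12)

    @given(st.floats(-15, 15), st.floats(-15, 15))
    @settings(deadline=None, derandomize=True)
    def test_strictly_increasing(self, u, v):
        # resolvable gaps only: float saturation merges near-equal inputs
        if u + 1e-6 < v:
            assert transfer(u) < transfer(v)


class TestBinarize:
    def test_saturated_positive_positions_give_all_ones(self):
        rng = np.random.default_rng(7)
        pos = np.full(12, 20.0)
        for _ in range(1000):
            assert binarize(pos, rng).bits.sum() == 12

    def test_repair_guarantees_one_bit(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            mask = binarize(np.full(9, -20.0), rng)
            assert mask.n_selected == 1

    def test_seeded_determinism(self):
        pos = np.random.default_rng(3).normal(size=15)
        m1 = binarize(pos, np.random.default_rng(99))
        m2 = binarize(pos, np.random.default_rng(99))
        np.testing.assert_array_equal(m1.bits, m2.bits)


class TestFitness:
    def test_extremes(self):
        assert fitness_min(0.0, 0, 8, 0.99) == 0.0
        assert fitness_min(1.0, 8, 8, 0.99) == 1.0
        assert fitness_max(1.0, 0, 8, 0.99) == 1.0
        assert fitness_max(0.0, 8, 8, 0.99) == 0.0

    def test_worked_example(self):
        # 4-of-8 subset at 79.82% accuracy: 0.99*0.2018 + 0.01*0.5
        assert fitness_min(0.2018, 4, 8, 0.99) == pytest.approx(0.204782, abs=1e-12)
        assert fitness_max(0.7982, 4, 8, 0.99) == pytest.approx(0.795218, abs=1e-12)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            fitness_min(0.1, 1, 0, 0.99)
        with pytest.raises(ValueError):
            fitness_min(1.5, 1, 4, 0.99)
        with pytest.raises(ValueError):
            fitness_min(0.1, 5, 4, 0.99)

    @given(
        err=st.floats(0, 1), R=st.integers(0, 60),
        C=st.integers(1, 60), alpha=st.floats(0, 1),
    )
    @settings(deadline=None, derandomize=True)
    def test_complement_identity_and_range(self, err, R, C, alpha):
        R = min(R, C)
        f_min = fitness_min(err, R, C, alpha)
        f_max = fitness_max(1.0 - err, R, C, alpha)
        assert 0.0 <= f_min <= 1.0
        assert f_min + f_max == pytest.approx(1.0, abs=1e-12)

    def test_monotone_in_error_and_size(self):
        assert fitness_min(0.3, 4, 10, 0.9) > fitness_min(0.2, 4, 10, 0.9)
        assert fitness_min(0.2, 6, 10, 0.9) > fitness_min(0.2, 4, 10, 0.9)


class TestEvaluateMask:
    def test_single_class_is_trivially_perfect(self):
        ds = make_continuous_dataset(n=40, separation=0.0)
        ds.y[:] = 0
        mask = FeatureMask(np.ones(1, dtype=int))
        err, acc = evaluate_mask(mask, ds, ds)
        assert acc == 1.0 and err == 0.0

    def test_well_separated_signal_feature(self):
        ds = make_continuous_dataset(n=400, separation=6.0, k_noise=3, seed=1)
        tr, te = train_test_split(ds, SplitSpec(seed=1))
        mask = FeatureMask(np.array([1, 0, 0, 0]))
        _, acc = evaluate_mask(mask, tr, te)
        assert acc > 0.99

    def test_noise_only_mask_is_at_chance(self):
        accs = []
        for seed in range(10):
            ds = make_continuous_dataset(n=400, separation=6.0, k_noise=2, seed=seed)
            tr, te = train_test_split(ds, SplitSpec(seed=seed))
            _, acc = evaluate_mask(FeatureMask(np.array([0, 1, 1])), tr, te)
            accs.append(acc)
        n_eval = 120  # 30% of 400
        se = math.sqrt(0.25 / n_eval) / math.sqrt(10)
        assert abs(np.mean(accs) - 0.5) < 3 * se + 0.02


class TestSelectFeatures:
    def test_single_feature_is_selected(self):
        ds = make_continuous_dataset(n=120, separation=6.0, k_noise=0, seed=0)
        res = select_features(ds, WOAConfig(population_size=4, max_iterations=5, seed=0))
        np.testing.assert_array_equal(res.mask.bits, [1])

    def test_history_non_increasing_and_roundtrip(self):
        ds, _ = synthesize(SyntheticSpec(n=300, k_informative=3, k_noise=5, seed=4))
        res = select_features(
            ds, WOAConfig(population_size=8, max_iterations=15, seed=4), split_seed=4
        )
        assert all(a >= b for a, b in zip(res.history, res.history[1:]))
        assert res.error_rate == pytest.approx(1.0 - res.accuracy, abs=1e-12)
        recomputed = fitness_min(res.error_rate, res.mask.n_selected,
                                 ds.n_features, 0.99)
        assert res.fitness == pytest.approx(recomputed, abs=1e-12)
        assert res.mask.n_selected == int(res.mask.bits.sum())

    def test_end_to_end_determinism(self):
        ds, _ = synthesize(SyntheticSpec(n=300, k_informative=3, k_noise=5, seed=5))
        kwargs = dict(
            woa_config=WOAConfig(population_size=8, max_iterations=15, seed=5),
            split_seed=5,
        )
        r1 = select_features(ds, **kwargs)
        r2 = select_features(ds, **kwargs)
        np.testing.assert_array_equal(r1.mask.bits, r2.mask.bits)
        assert r1.history == r2.history and r1.fitness == r2.fitness

    def test_memoization_does_not_change_results(self):
        ds, _ = synthesize(SyntheticSpec(n=200, k_informative=2, k_noise=4, seed=6))
        cfg = WOAConfig(population_size=6, max_iterations=10, seed=6)
        r_mem = select_features(ds, cfg, split_seed=6, memoize=True)
        r_raw = select_features(ds, cfg, split_seed=6, memoize=False)
        np.testing.assert_array_equal(r_mem.mask.bits, r_raw.mask.bits)
        assert r_mem.history == r_raw.history

    def test_alpha_zero_drives_subset_to_repair_floor(self):
        ds, _ = synthesize(SyntheticSpec(n=200, k_informative=2, k_noise=6, seed=0))
        res = select_features(
            ds,
            WOAConfig(population_size=10, max_iterations=50, seed=0),
            FitnessConfig(alpha=0.0),
            split_seed=0,
        )
        assert res.mask.n_selected == 1

    def test_alpha_one_fitness_is_pure_error(self):
        ds, _ = synthesize(SyntheticSpec(n=200, k_informative=2, k_noise=6, seed=1))
        res = select_features(
            ds,
            WOAConfig(population_size=10, max_iterations=20, seed=1),
            FitnessConfig(alpha=1.0),
            split_seed=1,
        )
        assert res.fitness == pytest.approx(res.error_rate, abs=1e-12)

    def test_maximize_accuracy_mode_matches_minimize_error(self):
        ds, _ = synthesize(SyntheticSpec(n=200, k_informative=2, k_noise=4, seed=2))
        cfg = WOAConfig(population_size=6, max_iterations=10, seed=2)
        r_min = select_features(ds, cfg, FitnessConfig(mode="minimize-error"), split_seed=2)
        r_max = select_features(ds, cfg, FitnessConfig(mode="maximize-accuracy"), split_seed=2)
        np.testing.assert_array_equal(r_min.mask.bits, r_max.mask.bits)
        assert r_min.fitness == pytest.approx(r_max.fitness, abs=1e-12)

    def test_internal_holdout_runs_and_differs_from_test_holdout(self):
        ds, _ = synthesize(SyntheticSpec(n=400, k_informative=3, k_noise=5, seed=3))
        cfg = WOAConfig(population_size=6, max_iterations=10, seed=3)
        r_int = select_features(ds, cfg, split_seed=3, holdout="internal")
        assert 1 <= r_int.mask.n_selected <= ds.n_features

    def test_degenerate_dataset_rejected(self):
        ds = make_continuous_dataset(n=40, separation=1.0)
        ds.y[:] = 1
        with pytest.raises(ValueError):
            select_features(ds)
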