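"""Transfer functions, binarization, KNN CV error, the blended fitness and
the wrapper driver."""

import numpy as np
import pytest

from coffo import (BinaryState, Dataset, FSConfig, FitnessWeights, binarize_step,
                   fs_fitness, initial_bits, knn_error, run_fs, selection_ratio,
                   transfer_v)
from coffo.feature_selection import _FastCV, _minmax_scale
from coffo.datasets import GeneratorSpec, generate_classification
from coffo.errors import InvalidArgument, InvalidConfiguration, InvalidDataset


class TestTransferFunctions:
    @pytest.mark.parametrize("name,x,expected", [
        ("V2", 0.0, 0.0),
        ("V3", 1.0, 1.0 / np.sqrt(2.0)),
        ("V2", 2.0, np.tanh(2.0)),
        ("V1", 0.0, 0.0),
        ("V4", 0.0, 0.0),
    ])
    def test_values(self, name, x, expected):
        assert transfer_v(name, x) == pytest.approx(expected)

    @pytest.mark.parametrize("name", ["V1", "V2", "V3", "V4"])
    def test_even_and_bounded(self, name):
        xs = np.linspace(-30.0, 30.0, 201)
        pos = transfer_v(name, xs)
        neg = transfer_v(name, -xs)
        np.testing.assert_allclose(pos, neg)
        assert np.all(pos >= 0.0) and np.all(pos < 1.0 + 1e-12)

    def test_unknown_name_rejected(self):
        with pytest.raises(InvalidArgument):
            transfer_v("S1", 0.3)


class TestBinarize:
    def test_zero_argument_changes_nothing(self):
        state = BinaryState(np.array([True, False, True]), np.zeros(3))
        out = binarize_step(state, "V2", np.random.default_rng(0))
        np.testing.assert_array_equal(out.bits, state.bits)

    def test_huge_argument_flips_everything(self):
        state = BinaryState(np.array([True, False, True, False]), np.full(4, 50.0))
        out = binarize_step(state, "V2", np.random.default_rng(0))
        np.testing.assert_array_equal(out.bits, ~state.bits)

    def test_replays_seeded_uniform_stream(self):
        # oracle: replicate the seeded draws by hand against tanh(3)
        companion = np.full(5, 3.0)
        bits = np.array([True, False, True, False, True])
        out = binarize_step(BinaryState(bits.copy(), companion), "V2",
                            np.random.default_rng(77))
        ref = np.random.default_rng(77)
        flips = ref.random(5) < np.tanh(3.0)
        expected = np.where(flips, ~bits, bits)
        np.testing.assert_array_equal(out.bits, expected)

    def test_empty_mask_repaired_to_one_bit(self):
        state = BinaryState(np.array([True, False]), np.full(2, 50.0))
        # flipping everything empties the second bit only; force emptiness
        state = BinaryState(np.array([True, False]), np.array([50.0, 0.0]))
        out = binarize_step(state, "V2", np.random.default_rng(1))
        assert out.bits.sum() >= 1

    def test_min_flips_guarantees_movement(self):
        state = BinaryState(np.array([True, False, True]), np.zeros(3))
        out = binarize_step(state, "V2", np.random.default_rng(0),
                            argument=np.zeros(3), min_flips=1)
        assert (out.bits != state.bits).sum() == 1

    def test_initial_bits_follow_transfer_probability(self):
        rng = np.random.default_rng(5)
        companion = np.full(2000, 3.0)
        bits = initial_bits(companion, "V2", rng)
        assert abs(bits.mean() - np.tanh(3.0)) < 0.03


def _clouds(n_per=30, d=4, gap=50.0, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.standard_normal((n_per, d))
    b = rng.standard_normal((n_per, d)) + gap
    x = np.vstack([a, b])
    y = np.array([0] * n_per + [1] * n_per)
    return Dataset(x, y)


class TestKnnError:
    def test_separated_clouds_have_zero_error(self):
        data = _clouds()
        assert knn_error(data, np.ones(4, bool), k=5, n_folds=10) == 0.0

    def test_label_independent_data_near_prior_error(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((600, 5))
        y = (rng.random(600) < 0.7).astype(int)
        er = knn_error(Dataset(x, y), np.ones(5, bool), k=5, n_folds=10)
        assert abs(er - (1.0 - max(y.mean(), 1 - y.mean()))) < 0.08

    def test_deterministic_for_fixed_fold_seed(self):
        data = _clouds(gap=2.0, seed=9)
        mask = np.array([True, True, False, False])
        a = knn_error(data, mask, fold_seed=11)
        b = knn_error(data, mask, fold_seed=11)
        assert a == b

    def test_small_class_rejected(self):
        data = _clouds(n_per=5)
        with pytest.raises(InvalidDataset):
            knn_error(data, np.ones(4, bool), n_folds=10)

    def test_empty_mask_rejected(self):
        with pytest.raises(InvalidArgument):
            knn_error(_clouds(), np.zeros(4, bool))

    def test_fast_cv_matches_sklearn_path(self):
        spec = GeneratorSpec(n_samples=120, n_features=15, n_informative=3,
                             effect_size=1.5, seed=21)
        data, _ = generate_classification(spec)
        scaled = Dataset(_minmax_scale(data.features), data.labels)
        fast = _FastCV(scaled, k=5, n_folds=10, fold_seed=33)
        rng = np.random.default_rng(2)
        for _ in range(15):
            mask = rng.random(15) < 0.5
            if not mask.any():
                mask[0] = True
            assert fast.error(mask) == knn_error(scaled, mask, fold_seed=33)

    def test_stratified_folds_preserve_class_proportions(self):
        from sklearn.model_selection import StratifiedKFold
        rng = np.random.default_rng(0)
        y = np.array([0] * 73 + [1] * 47)
        for _, test_idx in StratifiedKFold(10, shuffle=True,
                                           random_state=1).split(np.zeros((120, 1)), y):
            share = y[test_idx].mean()
            assert abs(share * len(test_idx) - 47 / 10) <= 1.0


class TestFitness:
    @pytest.mark.parametrize("er,s,total,alpha,expected", [
        (0.0, 10, 10, 0.99, 0.01),
        (0.1, 5, 10, 0.99, 0.104),
        (1.0, 1, 10, 1.0, 1.0),
    ])
    def test_values(self, er, s, total, alpha, expected):
        assert fs_fitness(er, s, total, FitnessWeights(alpha)) == pytest.approx(expected)

    def test_strictly_increasing_in_both_terms(self):
        w = FitnessWeights(0.9)
        assert fs_fitness(0.2, 3, 10, w) > fs_fitness(0.1, 3, 10, w)
        assert fs_fitness(0.1, 4, 10, w) > fs_fitness(0.1, 3, 10, w)

    def test_empty_subset_rejected(self):
        with pytest.raises(InvalidArgument):
            fs_fitness(0.1, 0, 10)

    def test_weights_sum_to_one(self):
        w = FitnessWeights(0.7)
        assert w.alpha + w.beta_w == pytest.approx(1.0)


class TestSelectionRatio:
    @pytest.mark.parametrize("bits,expected", [
        ([1, 1] + [0] * 13, 2 / 15),
        ([1] * 6, 1.0),
        ([1] + [0] * 8, 1 / 9),
    ])
    def test_values(self, bits, expected):
        assert selection_ratio(np.array(bits, dtype=bool)) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(InvalidArgument):
            selection_ratio(np.zeros(4, bool))


@pytest.fixture(scope="module")
def small_problem():
    spec = GeneratorSpec(n_samples=100, n_features=12, n_informative=3,
                         effect_size=2.5, seed=8)
    return generate_classification(spec)


@pytest.fixture(scope="module")
def result(small_problem):
    data, _ = small_problem
    return run_fs(data, FSConfig(runs=4, max_ffes=300, seed=1))


class TestRunFs:
    def test_beats_all_features_baseline(self, small_problem, result):
        data, _ = small_problem
        scaled = Dataset(_minmax_scale(data.features), data.labels)
        # recompute the all-ones fitness under an arbitrary fixed partition
        er_all = knn_error(scaled, np.ones(12, bool), fold_seed=0)
        all_ones = fs_fitness(er_all, 12, 12, FitnessWeights(0.99))
        assert result.best_fitness < all_ones

    def test_summary_statistics_are_consistent(self, result):
        assert result.mean_fitness >= result.best_fitness
        assert result.best_fitness == result.per_run_fitness.min()
        assert result.selection_ratio == pytest.approx(
            result.best_mask.sum() / 12)
        assert np.all((0.0 <= result.selection_frequency)
                      & (result.selection_frequency <= 1.0))

    def test_traces_are_monotone_and_masks_nonempty(self, result):
        for trace in result.traces:
            values = [f for _, f in trace]
            assert all(a >= b for a, b in zip(values, values[1:]))
        assert all(m.sum() >= 1 for m in result.per_run_masks)

    def test_reproducible_for_fixed_seed(self, small_problem):
        data, _ = small_problem
        cfg = FSConfig(runs=2, max_ffes=150, seed=4)
        a = run_fs(data, cfg)
        b = run_fs(data, cfg)
        np.testing.assert_array_equal(a.per_run_masks, b.per_run_masks)
        np.testing.assert_array_equal(a.per_run_fitness, b.per_run_fitness)

    def test_ffo_variant_runs(self, small_problem):
        data, _ = small_problem
        res = run_fs(data, FSConfig(algo="ffo", runs=2, max_ffes=150, seed=2))
        assert res.best_fitness <= res.mean_fitness

    def test_invalid_configs_rejected(self):
        with pytest.raises(InvalidConfiguration):
            FSConfig(algo="pso")
        with pytest.raises(InvalidConfiguration):
            FSConfig(transfer="S2")
        with pytest.raises(InvalidConfiguration):
            FSConfig(companion_low=4.0, companion_high=-4.0)
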