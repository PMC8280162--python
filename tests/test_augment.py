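"""Minority-class augmentation: fold arithmetic, mixup law, noise statistics,
TimeGAN behavior, majority immutability."""

import numpy as np
import pytest
from scipy import stats

from glyco.augment import (AugmentationPlan, TimeGANConfig,
                           build_augmented_training_set, mixup_augment,
                           noise_augment, oversample_repeat, select_minority,
                           timegan_fit, timegan_validate)
from glyco.cgm_data import assign_labels
from tests.conftest import toy_segments


@pytest.fixture
def labeled():
    return assign_labels(toy_segments(100, seed=2, minority_fraction=0.1),
                         scheme="binary")


class TestSelectMinority:
    def test_split_by_threshold(self):
        segs = toy_segments(2, seed=0)
        segs.targets[:] = np.array([75.0, 85.0]) * segs.scale
        minority, majority = select_minority(segs, 80.0)
        assert len(minority) == 1 and len(majority) == 1

    def test_partition_is_exhaustive(self, labeled):
        minority, majority = select_minority(labeled, 80.0)
        assert len(minority) + len(majority) == len(labeled)
        assert (minority.targets_mgdl < 80).all()
        assert (majority.targets_mgdl >= 80).all()

    def test_no_minority_gives_empty_set(self):
        segs = toy_segments(10, seed=3)  # all targets >= 85 mg/dL
        minority, _ = select_minority(segs, 80.0)
        assert len(minority) == 0


class TestRepeat:
    @pytest.mark.parametrize("n,k,expected", [(10, 2, 20), (7, 5, 35)])
    def test_exact_copy_counts(self, n, k, expected):
        minority = toy_segments(n, seed=4, minority_fraction=1.0)
        out = oversample_repeat(minority, k)
        assert len(out) == expected

    def test_k_one_is_identity(self):
        minority = toy_segments(5, seed=4, minority_fraction=1.0)
        out = oversample_repeat(minority, 1)
        np.testing.assert_array_equal(out.inputs, minority.inputs)


class TestNoise:
    def test_zero_variance_copies_exactly(self):
        minority = toy_segments(5, seed=5, minority_fraction=1.0)
        out = noise_augment(minority, 0.0, seed=1)
        np.testing.assert_array_equal(out.inputs, minority.inputs)

    def test_empirical_variance_matches(self):
        minority = toy_segments(15_000, seed=6, minority_fraction=1.0,
                                scale=1.0)
        out = noise_augment(minority, 50.0, seed=2)
        noise = (out.inputs - minority.inputs).ravel()
        assert noise.var() == pytest.approx(50.0, abs=2.0)
        # unbiased: mean perturbation within 3 standard errors of zero
        assert abs(noise.mean()) < 3 * np.sqrt(50.0 / noise.size)

    def test_targets_and_labels_untouched(self):
        minority = assign_labels(toy_segments(20, seed=7, minority_fraction=1.0),
                                 scheme="binary")
        out = noise_augment(minority, 25.0, seed=3)
        np.testing.assert_array_equal(out.targets, minority.targets)
        np.testing.assert_array_equal(out.labels, minority.labels)

    def test_noise_applied_on_mgdl_scale(self):
        minority = toy_segments(2000, seed=8, minority_fraction=1.0, scale=0.01)
        out = noise_augment(minority, 25.0, seed=4)
        noise_mgdl = (out.inputs - minority.inputs).ravel() / minority.scale
        assert noise_mgdl.var() == pytest.approx(25.0, rel=0.15)


class TestMixup:
    def test_endpoint_lambda_one_returns_first_parent(self):
        minority = toy_segments(2, seed=9, minority_fraction=1.0)
        x_i, x_j = minority.inputs
        y_i, y_j = minority.targets
        assert np.allclose(1.0 * x_i + 0.0 * x_j, x_i)
        assert 1.0 * y_i + 0.0 * y_j == y_i

    def test_midpoint_interpolation(self):
        minority = toy_segments(2, seed=9, minority_fraction=1.0)
        minority.inputs[0, :] = 0.5
        minority.inputs[1, :] = 0.7
        lam = 0.5
        mixed = lam * minority.inputs[0] + (1 - lam) * minority.inputs[1]
        np.testing.assert_allclose(mixed, 0.6)

    def test_synthetic_count_and_convex_hull(self):
        minority = toy_segments(30, seed=10, minority_fraction=1.0)
        out = mixup_augment(minority, k=4, alpha=2.0, seed=5)
        assert len(out) == 3 * 30
        lo, hi = minority.inputs.min(), minority.inputs.max()
        assert (out.inputs >= lo - 1e-12).all() and (out.inputs <= hi + 1e-12).all()

    def test_minority_label_preserved_by_convexity(self):
        minority = assign_labels(toy_segments(50, seed=11, minority_fraction=1.0),
                                 scheme="binary")
        out = mixup_augment(minority, k=3, alpha=0.4, seed=6)
        assert (out.targets_mgdl < 80.0).all()
        assert (out.labels == 1).all()

    def test_alpha_one_lambda_uniform(self):
        rng = np.random.default_rng(12)
        lam = rng.beta(1.0, 1.0, 10_000)
        assert stats.kstest(lam, "uniform").pvalue > 0.01

    def test_too_few_parents_rejected(self):
        minority = toy_segments(1, seed=13, minority_fraction=1.0)
        with pytest.raises(ValueError, match="at least 2"):
            mixup_augment(minority, k=2, alpha=1.0, seed=0)


class TestBuildAugmentedTrainingSet:
    @pytest.mark.parametrize("method", ["repeat", "noise", "mixup"])
    @pytest.mark.parametrize("k", [1, 2, 3, 5])
    def test_exact_fold_arithmetic(self, labeled, method, k):
        plan = AugmentationPlan(method=method, fold_k=k, seed=0)
        out = build_augmented_training_set(labeled, plan, epoch_index=0)
        n_min = int((labeled.targets_mgdl < 80).sum())
        n_maj = len(labeled) - n_min
        out_min = int((out.targets_mgdl < 80).sum())
        assert out_min == k * n_min
        assert len(out) - out_min == n_maj

    @pytest.mark.parametrize("method", ["repeat", "noise", "mixup"])
    def test_majority_segments_bitwise_unchanged(self, labeled, method):
        plan = AugmentationPlan(method=method, fold_k=3, seed=1)
        out = build_augmented_training_set(labeled, plan, epoch_index=0)
        _, maj_in = select_minority(labeled, 80.0)
        _, maj_out = select_minority(out, 80.0)
        order_in = np.lexsort(maj_in.inputs.T)
        order_out = np.lexsort(maj_out.inputs.T)
        np.testing.assert_array_equal(maj_out.inputs[order_out],
                                      maj_in.inputs[order_in])
        np.testing.assert_array_equal(maj_out.targets[order_out],
                                      maj_in.targets[order_in])

    def test_none_plan_returns_input_unchanged(self, labeled):
        plan = AugmentationPlan(method="none")
        assert build_augmented_training_set(labeled, plan, 0) is labeled

    def test_fold_one_is_noop_for_any_method(self, labeled):
        plan = AugmentationPlan(method="mixup", fold_k=1)
        assert build_augmented_training_set(labeled, plan, 0) is labeled

    def test_regeneration_differs_across_epochs_originals_identical(self, labeled):
        plan = AugmentationPlan(method="mixup", fold_k=2, seed=2,
                                regenerate_each_epoch=True)
        e1 = build_augmented_training_set(labeled, plan, epoch_index=1)
        e2 = build_augmented_training_set(labeled, plan, epoch_index=2)
        assert not np.array_equal(e1.inputs, e2.inputs)
        n_orig = len(labeled)
        np.testing.assert_array_equal(e1.inputs[:n_orig], e2.inputs[:n_orig])

    def test_frozen_plan_reuses_epoch_zero_draw(self, labeled):
        plan = AugmentationPlan(method="noise", fold_k=2, seed=3,
                                regenerate_each_epoch=False)
        e1 = build_augmented_training_set(labeled, plan, epoch_index=1)
        e5 = build_augmented_training_set(labeled, plan, epoch_index=5)
        np.testing.assert_array_equal(e1.inputs, e5.inputs)


def tiny_timegan_config(**kw):
    base = dict(hidden_dim=8, num_layers=1, latent_dim=2,
                iterations_embedding=120, iterations_supervised=60,
                iterations_joint=40, batch_size=16, seed=0)
    base.update(kw)
    return TimeGANConfig(**base)


class TestTimeGAN:
    def test_too_few_sequences_advises_alternatives(self):
        with pytest.raises(ValueError, match="noise or mixup"):
            timegan_fit(np.full((10, 8), 70.0), tiny_timegan_config())

    def test_constant_sequences_reproduced(self):
        data = np.full((60, 8), 70.0)
        gen = timegan_fit(data, tiny_timegan_config(iterations_embedding=300))
        samples = gen.sample(20, seed=1)
        assert samples.shape == (20, 8)
        # recovery maps synthetic sequences back to the training constant
        assert np.abs(samples - 70.0).max() <= 1.0

    def test_fixed_seed_identical_samples(self):
        rng = np.random.default_rng(14)
        data = 60.0 + 15.0 * rng.random((60, 8))
        gen = timegan_fit(data, tiny_timegan_config())
        np.testing.assert_array_equal(gen.sample(5, seed=7), gen.sample(5, seed=7))

    def test_samples_have_configured_length(self):
        rng = np.random.default_rng(15)
        data = 60.0 + 15.0 * rng.random((55, 11))
        gen = timegan_fit(data, tiny_timegan_config(iterations_embedding=40,
                                                    iterations_supervised=20,
                                                    iterations_joint=10))
        assert gen.sample(3, seed=0).shape == (3, 11)

    def test_timegan_plan_fold_arithmetic(self):
        segs = assign_labels(toy_segments(120, seed=16, minority_fraction=0.5),
                             scheme="binary")
        plan = AugmentationPlan(method="timegan", fold_k=2, seed=4,
                                timegan=tiny_timegan_config(
                                    iterations_embedding=40,
                                    iterations_supervised=20,
                                    iterations_joint=10))
        out = build_augmented_training_set(segs, plan, epoch_index=0)
        n_min = int((segs.targets_mgdl < 80).sum())
        assert len(out) == len(segs) + n_min


class TestTimeGANValidate:
    def test_identical_sets_zero_gaps(self):
        rng = np.random.default_rng(17)
        real = rng.normal(70, 5, (40, 8))
        report = timegan_validate(real, real)
        assert report["max_mean_gap"] == pytest.approx(0.0, abs=1e-9)
        assert report["energy_distance_normalized"] == pytest.approx(0.0,
                                                                     abs=1e-9)
        assert report["ok"]

    def test_shifted_synthetic_flagged(self):
        rng = np.random.default_rng(18)
        real = rng.normal(70, 5, (40, 8))
        report = timegan_validate(real, real + 100.0)
        assert not report["ok"]
        assert report["max_mean_gap"] > 1.0

    def test_report_fields_present(self):
        rng = np.random.default_rng(19)
        report = timegan_validate(rng.random((10, 8)), rng.random((12, 8)))
        for key in ("mean_gap", "sd_gap", "energy_distance",
                    "energy_distance_normalized", "ok"):
            assert key in report
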