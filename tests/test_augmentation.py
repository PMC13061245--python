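"""Augmentation tests: Mixup algebra, scaling round trips, fidelity
matching, peak calibration and GAN training contracts (short budgets)."""

import numpy as np
import pytest

from scrumforce.augmentation import (
    AugmentationError,
    GanConfig,
    build_augmented_dataset,
    calibrate_peaks,
    gan_fidelity,
    generate_pairs,
    mixup_pair,
    train_gan,
)
from scrumforce.io_preprocess import VelocityForcePair


def _pair(v_peak=3.0, f_peak=2000.0, tid="t", phase=0.0):
    t = np.linspace(0, 1, 101)
    return VelocityForcePair(
        velocity=v_peak * np.exp(-0.5 * ((t - 0.6 - phase) / 0.2) ** 2),
        force=f_peak * t**1.5,
        meta={"trial_id": tid},
        source="synthetic",
    )


@pytest.fixture(scope="module")
def small_gan(pairs_200):
    """GAN trained on 40 pairs with a tiny epoch budget (contract tests only)."""
    return train_gan(pairs_200[:40], GanConfig(epochs=30, batch_size=16, seed=0))


class TestMixup:
    def test_self_mixup_is_identity(self):
        a = _pair()
        m = mixup_pair(a, a, 0.5)
        np.testing.assert_allclose(m.velocity, a.velocity)
        np.testing.assert_allclose(m.force, a.force)
        assert m.source == "mixup"

    def test_constant_channels_average(self):
        t = np.linspace(0, 1, 101)
        a = VelocityForcePair(2 * np.ones(101), 1000 * t, source="synthetic")
        b = VelocityForcePair(4 * np.ones(101), 3000 * t, source="synthetic")
        m = mixup_pair(a, b, 0.5)
        np.testing.assert_allclose(m.velocity, 3.0)
        np.testing.assert_allclose(m.force, 2000 * t)

    def test_lam_one_returns_first_parent(self):
        a, b = _pair(3.0, 2000.0), _pair(4.0, 3000.0, phase=0.05)
        m = mixup_pair(a, b, 1.0)
        np.testing.assert_array_equal(m.velocity, a.velocity)
        np.testing.assert_array_equal(m.force, a.force)

    def test_convex_combination_bounds(self, rng):
        a, b = _pair(3.0, 2000.0), _pair(4.0, 3500.0, phase=0.1)
        m = mixup_pair(a, b, 0.5)
        lo = np.minimum(a.force, b.force)
        hi = np.maximum(a.force, b.force)
        assert np.all(m.force >= lo - 1e-12) and np.all(m.force <= hi + 1e-12)
        assert lo.max() - 1e-12 <= m.f_peak <= hi.max() + 1e-12

    def test_invalid_lam_rejected(self):
        with pytest.raises(AugmentationError):
            mixup_pair(_pair(), _pair(), 1.5)


class TestScaling:
    def test_scale_unscale_round_trip(self, small_gan, pairs_200):
        V = np.array([p.velocity for p in pairs_200[:10]])
        F = np.array([p.force for p in pairs_200[:10]])
        stacked = small_gan.scale(V, F)
        flat = np.concatenate([stacked[..., 0], stacked[..., 1]], axis=1)
        V2, F2 = small_gan.unscale(flat)
        np.testing.assert_allclose(V2, V, atol=1e-9)
        np.testing.assert_allclose(F2, F, atol=1e-9)
        assert np.abs(stacked).max() <= 1.0 + 1e-9


class TestFidelity:
    def test_identical_sets_are_perfect(self, pairs_200):
        rep = gan_fidelity(pairs_200[:20], pairs_200[:20])
        assert rep.velocity_corr == pytest.approx(1.0)
        assert rep.force_corr == pytest.approx(1.0)
        assert rep.velocity_rmse == pytest.approx(0.0, abs=1e-12)
        assert rep.force_rmse == pytest.approx(0.0, abs=1e-12)

    def test_constant_force_offset(self, pairs_200):
        shifted = [
            VelocityForcePair(p.velocity, p.force + 10.0, dict(p.meta), "synthetic")
            for p in pairs_200[:20]
        ]
        rep = gan_fidelity(shifted, pairs_200[:20])
        assert rep.force_corr == pytest.approx(1.0)
        assert rep.force_rmse == pytest.approx(10.0)

    def test_time_reversal_degrades_correlation(self, pairs_200):
        reversed_pairs = [
            VelocityForcePair(p.velocity[::-1].copy(), p.force[::-1].copy(), dict(p.meta), "gan")
            for p in pairs_200[:30]
        ]
        rep_rev = gan_fidelity(reversed_pairs, pairs_200[:30])
        rep_id = gan_fidelity(pairs_200[:30], pairs_200[:30])
        assert rep_rev.force_corr < rep_id.force_corr

    def test_empty_sets_rejected(self, pairs_200):
        with pytest.raises(AugmentationError):
            gan_fidelity([], pairs_200[:5])


class TestCalibratePeaks:
    def test_peak_distribution_matches_measured(self, pairs_200, rng):
        # curves with badly collapsed amplitudes
        collapsed = [
            _pair(3.5 + 0.01 * rng.standard_normal(), 2200 + 10 * rng.standard_normal(), f"c{i}")
            for i in range(100)
        ]
        cal = calibrate_peaks(collapsed, pairs_200)
        peaks = np.sort([p.f_peak for p in cal])
        m_peaks = np.sort([p.f_peak for p in pairs_200])
        # matched within quantile interpolation error
        q = np.quantile(m_peaks, (np.arange(100) + 0.5) / 100)
        np.testing.assert_allclose(peaks, q, rtol=1e-9)

    def test_monotone_rank_preserving(self, pairs_200, rng):
        collapsed = [_pair(3.0 + 0.1 * i / 50, 1500 + 10 * i, f"c{i}") for i in range(50)]
        cal = calibrate_peaks(collapsed, pairs_200)
        before = np.argsort([p.f_peak for p in collapsed])
        after = np.argsort([p.f_peak for p in cal])
        np.testing.assert_array_equal(before, after)

    def test_shape_correlation_unchanged(self, pairs_200):
        subset = pairs_200[:20]
        cal = calibrate_peaks(subset, pairs_200)
        for orig, new in zip(subset, cal):
            r = np.corrcoef(orig.force, new.force)[0, 1]
            assert r == pytest.approx(1.0, abs=1e-9)


class TestGanContracts:
    def test_too_few_pairs_rejected(self, pairs_200):
        with pytest.raises(AugmentationError):
            train_gan(pairs_200[:5], GanConfig(epochs=1))

    def test_loss_history_finite_and_complete(self, small_gan):
        assert len(small_gan.gen_loss) == 30 and len(small_gan.disc_loss) == 30
        assert np.isfinite(small_gan.gen_loss).all() and np.isfinite(small_gan.disc_loss).all()

    def test_training_reproducible_for_fixed_seed(self, pairs_200):
        cfg = GanConfig(epochs=3, batch_size=16, seed=11)
        m1 = train_gan(pairs_200[:30], cfg)
        m2 = train_gan(pairs_200[:30], cfg)
        np.testing.assert_array_equal(m1.gen_loss, m2.gen_loss)
        np.testing.assert_array_equal(m1.disc_loss, m2.disc_loss)
        for a, b in zip(m1.generator.get_weights(), m2.generator.get_weights()):
            np.testing.assert_array_equal(a, b)

    def test_generate_pairs_shape_and_determinism(self, small_gan):
        out = generate_pairs(small_gan, 5, seed=3)
        assert len(out) == 5
        for p in out:
            assert p.velocity.shape == (101,) and p.force.shape == (101,)
            assert np.isfinite(p.velocity).all() and np.isfinite(p.force).all()
            assert p.source == "gan"
        again = generate_pairs(small_gan, 5, seed=3)
        np.testing.assert_array_equal(out[0].velocity, again[0].velocity)
        with pytest.raises(AugmentationError):
            generate_pairs(small_gan, 0)


class TestBuildAugmentedDataset:
    def test_counts_and_provenance(self, small_gan, pairs_200):
        out = build_augmented_dataset(pairs_200[:40], small_gan, n_gan=10, n_mix=5, seed=0)
        assert len(out) == 15
        assert [p.source for p in out[:10]] == ["gan"] * 10
        assert [p.source for p in out[10:]] == ["mixup"] * 5

    def test_empty_configuration_passes_through(self, small_gan, pairs_200):
        assert build_augmented_dataset(pairs_200[:40], small_gan, 0, 0) == []

    def test_mixup_members_are_half_averages_of_pool(self, small_gan, pairs_200):
        out = build_augmented_dataset(pairs_200[:40], small_gan, n_gan=10, n_mix=5, seed=1)
        pool = out[:10]
        for m in out[10:]:
            found = False
            for i in range(10):
                for j in range(10):
                    if i == j:
                        continue
                    if np.allclose(
                        m.velocity, 0.5 * pool[i].velocity + 0.5 * pool[j].velocity, atol=1e-9
                    ) and np.allclose(m.force, 0.5 * pool[i].force + 0.5 * pool[j].force, atol=1e-9):
                        found = True
            assert found, "mixup output is not a 0.5-average of two distinct pool members"

    def test_mix_without_pool_rejected(self, small_gan, pairs_200):
        with pytest.raises(AugmentationError):
            build_augmented_dataset(pairs_200[:40], small_gan, n_gan=0, n_mix=3)

    def test_every_output_has_101_finite_samples(self, small_gan, pairs_200):
        out = build_augmented_dataset(pairs_200[:40], small_gan, n_gan=20, n_mix=10, seed=2)
        for p in out:
            assert p.velocity.shape == (101,) and p.force.shape == (101,)
            assert np.isfinite(p.velocity).all() and np.isfinite(p.force).all()
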