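"""Biexponential decay fitting, lifetime maps, and redox ratios."""

import numpy as np
import pytest

from spheroprofile import flim, synthetic
from spheroprofile.flim import BiexpFit
from spheroprofile.images import ImageGrid


BIN_WIDTH = 12.5 / 256


class TestBiexpModel:
    def test_t_zero_equals_i0_for_normalized_amplitudes(self):
        out = flim.biexp_model(np.array([0.0]), 120.0, 0.7, 0.4, 0.3, 2.5)
        assert out[0] == pytest.approx(120.0)

    def test_monoexponential_closed_form(self):
        out = flim.biexp_model(np.array([0.4]), 100.0, 0.8, 0.4, 0.0, 2.5)
        assert out[0] == pytest.approx(100.0 * 0.8 / np.e)

    def test_matches_scalar_loop(self, rng):
        t = rng.uniform(0, 12.5, 40)
        I0, A1, tau1, A2, tau2 = 87.0, 0.65, 0.31, 0.35, 2.9
        out = flim.biexp_model(t, I0, A1, tau1, A2, tau2)
        for i, ti in enumerate(t):
            expected = I0 * (A1 * np.exp(-ti / tau1) + A2 * np.exp(-ti / tau2))
            assert out[i] == pytest.approx(expected, rel=1e-14)

    def test_nonpositive_lifetime_rejected(self):
        with pytest.raises(ValueError):
            flim.biexp_model(np.array([0.0]), 1.0, 0.5, -0.4, 0.5, 2.5)


class TestFitPixelDecay:
    def test_noiseless_inverse_crime(self):
        h = synthetic.decay_histogram(0.8, 0.2, 0.4, 2.5, 1e6, 256, 12.5)
        fit = flim.fit_pixel_decay(h, BIN_WIDTH)
        assert fit.valid
        assert fit.A1 == pytest.approx(0.8, rel=1e-3)
        assert fit.tau1_ns == pytest.approx(0.4, rel=1e-3)
        assert fit.tau2_ns == pytest.approx(2.5, rel=1e-3)
        assert fit.chi2 <= 1e-6  # fit reproduces a noiseless histogram

    def test_monoexponential_truth_recovered(self):
        h = synthetic.decay_histogram(1e-12, 1.0, 0.4, 1.2, 1e5, 256, 12.5)
        fit = flim.fit_pixel_decay(h, BIN_WIDTH)
        assert abs(flim.mean_lifetime(fit) - 1.2) < 0.05

    def test_below_photon_threshold_skipped(self):
        h = synthetic.decay_histogram(0.8, 0.2, 0.4, 2.5, 50, 256, 12.5)
        fit = flim.fit_pixel_decay(np.rint(h), BIN_WIDTH, photon_threshold=100)
        assert not fit.valid and fit.n_photons < 100

    def test_all_zero_histogram_skipped(self):
        fit = flim.fit_pixel_decay(np.zeros(256), BIN_WIDTH)
        assert not fit.valid

    def test_amplitudes_normalised(self, rng):
        h = rng.poisson(synthetic.decay_histogram(0.75, 0.25, 0.4, 2.5, 5000,
                                                  256, 12.5))
        fit = flim.fit_pixel_decay(h, BIN_WIDTH)
        assert fit.A1 + fit.A2 == pytest.approx(1.0)

    def test_mean_tau_monotone_in_bound_fraction(self):
        taus = []
        for a2 in (0.1, 0.2, 0.3, 0.4, 0.5):
            h = synthetic.decay_histogram(1 - a2, a2, 0.4, 2.5, 1e6, 256, 12.5)
            taus.append(flim.mean_lifetime(flim.fit_pixel_decay(h, BIN_WIDTH)))
        assert np.all(np.diff(taus) > 0)


class TestMeanLifetime:
    def test_limit_and_symmetry_cases(self):
        f = BiexpFit(1, 1.0, 0.0, 0.7, 2.5, 0, 0, 1000)
        assert flim.mean_lifetime(f) == pytest.approx(0.7)
        f = BiexpFit(1, 0.5, 0.5, 0.4, 2.4, 0, 0, 1000)
        assert flim.mean_lifetime(f) == pytest.approx((0.4 + 2.4) / 2)

    def test_adopted_formula_arithmetic(self):
        f = BiexpFit(1, 0.8, 0.2, 0.4, 2.5, 0, 0, 1000)
        assert flim.mean_lifetime(f) == pytest.approx(0.82)


class TestFitStack:
    def test_uniform_phantom_map_means(self):
        spec = synthetic.DecayPhantomSpec(shape=(8, 8), photons_per_pixel=5000,
                                          seed=3)
        stack, truth = synthetic.make_decay_stack(spec)
        maps = flim.fit_stack(stack, spatial_bin=3)
        interior = maps.valid.copy()
        assert interior.mean() >= 0.99
        true_ratio = spec.A1 / spec.A2
        true_tau = spec.A1 * spec.tau1_ns + spec.A2 * spec.tau2_ns
        assert np.nanmean(maps.a1a2_ratio) == pytest.approx(true_ratio, rel=0.02)
        assert np.nanmean(maps.mean_tau_ns) == pytest.approx(true_tau, rel=0.02)

    def test_two_region_phantom_separable(self):
        core_ratio, edge_ratio = 4.9, 4.3
        spec = synthetic.DecayPhantomSpec(
            A1=edge_ratio / (1 + edge_ratio), A2=1 / (1 + edge_ratio),
            shape=(16, 16), photons_per_pixel=5000, seed=5,
            core_params={"A1": core_ratio / (1 + core_ratio),
                         "A2": 1 / (1 + core_ratio),
                         "tau1_ns": 0.4, "tau2_ns": 2.5})
        stack, truth = synthetic.make_decay_stack(spec)
        maps = flim.fit_stack(stack, spatial_bin=3)
        # 3x3 binning mixes the two regions across their shared boundary;
        # compare interiors (one binning radius away from the border)
        from scipy.ndimage import binary_erosion
        core_interior = binary_erosion(truth["core_mask"], iterations=2)
        edge_interior = binary_erosion(~truth["core_mask"], iterations=2,
                                       border_value=1)
        core = maps.a1a2_ratio[core_interior & maps.valid]
        edge = maps.a1a2_ratio[edge_interior & maps.valid]
        pooled_sd = np.sqrt((core.std() ** 2 + edge.std() ** 2) / 2)
        assert (core.mean() - edge.mean()) / pooled_sd > 3

    def test_zero_stack_no_crash(self):
        from spheroprofile.images import DecayStack
        stack = DecayStack(np.zeros((4, 4, 32), int), BIN_WIDTH)
        maps = flim.fit_stack(stack)
        assert not maps.valid.any()
        assert np.all(np.isnan(maps.mean_tau_ns))


class TestNormalizeIntensity:
    def test_unit_gain_and_power_identity(self, rng):
        img = ImageGrid(rng.uniform(0, 100, (8, 8)), 1.0)
        out = flim.normalize_intensity(img, 100, 1.0, {0: 1.0, 200: 1.0})
        np.testing.assert_allclose(out.values, img.values)

    def test_two_photon_power_scaling_cancels(self, rng):
        scene = rng.uniform(0, 50, (6, 6))
        curve = {0: 1.0, 400: 1.0}
        low = flim.normalize_intensity(ImageGrid(scene, 1.0), 100, 1.0, curve)
        high = flim.normalize_intensity(ImageGrid(4 * scene, 1.0), 100, 2.0, curve)
        np.testing.assert_allclose(low.values, high.values)

    def test_log_linear_gain_curve_arithmetic(self):
        img = ImageGrid(np.full((4, 4), 800.0), 1.0)
        curve = {0: 1.0, 100: 10.0, 200: 100.0, 300: 1000.0}  # g = 10^(G/100)
        out = flim.normalize_intensity(img, 200, 2.0, curve, power_exponent=2)
        np.testing.assert_allclose(out.values, 800.0 / 400.0)

    def test_gain_outside_calibration_rejected(self):
        img = ImageGrid(np.ones((2, 2)), 1.0)
        with pytest.raises(ValueError, match="calibration range"):
            flim.normalize_intensity(img, 500, 1.0, {0: 1.0, 400: 100.0})


class TestRedoxMap:
    def test_equal_channels_give_half(self, rng):
        v = rng.uniform(10, 100, (8, 8))
        out = flim.redox_map(ImageGrid(v, 1.0), ImageGrid(v, 1.0))
        np.testing.assert_allclose(out.ratio[out.valid], 0.5)

    def test_zero_nadh_gives_one(self):
        nadh = ImageGrid(np.zeros((4, 4)), 1.0)
        fad = ImageGrid(np.full((4, 4), 20.0), 1.0)
        out = flim.redox_map(nadh, fad)
        np.testing.assert_allclose(out.ratio[out.valid], 1.0)

    def test_matches_scalar_loop_and_bounds(self, rng):
        nadh = rng.uniform(1, 100, (6, 6))
        fad = rng.uniform(1, 100, (6, 6))
        out = flim.redox_map(ImageGrid(nadh, 1.0), ImageGrid(fad, 1.0), floor=0.0)
        for i in range(6):
            for j in range(6):
                assert out.ratio[i, j] == pytest.approx(
                    fad[i, j] / (fad[i, j] + nadh[i, j]))
        assert np.all((out.ratio >= 0) & (out.ratio <= 1))

    def test_scale_invariance(self, rng):
        nadh = rng.uniform(1, 100, (5, 5))
        fad = rng.uniform(1, 100, (5, 5))
        a = flim.redox_map(ImageGrid(nadh, 1.0), ImageGrid(fad, 1.0))
        b = flim.redox_map(ImageGrid(7 * nadh, 1.0), ImageGrid(7 * fad, 1.0))
        np.testing.assert_allclose(a.ratio[a.valid], b.ratio[b.valid])

    def test_floor_marks_background_invalid(self):
        nadh = np.full((4, 4), 0.001)
        fad = np.full((4, 4), 0.001)
        fad[0, 0] = 50.0
        out = flim.redox_map(ImageGrid(nadh, 1.0), ImageGrid(fad, 1.0))
        assert out.valid[0, 0] and not out.valid[1, 1]
        assert np.isnan(out.ratio[1, 1])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            flim.redox_map(ImageGrid(np.ones((4, 4)), 1.0),
                           ImageGrid(np.ones((5, 5)), 1.0))


class TestMapsFeedProfiling:
    def test_lifetime_map_profiles_like_any_image(self):
        # the metabolic-imaging workflow: radial profiling applied to a
        # fitted-parameter map obeys the same contracts as intensity images
        from spheroprofile import profiling
        from conftest import disk_mask
        rr, cc = np.mgrid[0:64, 0:64]
        rad = np.hypot(rr - 32, cc - 32)
        mask = rad <= 25
        fake_tau = np.where(mask, 1.0 + 0.1 * rad / 25, 0.0)
        img = ImageGrid(fake_tau, 2.0)
        pset = profiling.cast_profiles(img, mask, (32.0, 32.0), K=12, M=40)
        assert pset.profiles.shape == (12, 40)
        assert np.all(np.isfinite(pset.profiles))
        assert not pset.degenerate
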