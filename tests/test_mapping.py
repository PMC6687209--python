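"""Orientation tuning fits, maps, periodicity, pinwheels, prediction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from orisel.params import MosaicSpec
from orisel.mosaic import build_channel_array, ChannelArray
from orisel.dynamics import CorticalSheet
from orisel.mapping import (probe_directions, relative_modulation,
                            double_von_mises, fit_double_von_mises,
                            von_mises_hwhh_deg, hwhh_from_curve,
                            preferred_orientation_map, OrientationMap,
                            map_periodicity, count_pinwheels,
                            map_correlation, gabor_bank_response,
                            predict_map_from_mosaic, onoff_difference_map,
                            subcortical_periodicity, onoff_pair_periodicity,
                            offset_difference_periodicity, analyze_map)


class TestRelativeModulation:
    def test_constant_rate(self):
        assert relative_modulation(np.full(64, 5.0)) == 0.0

    def test_single_bin_impulse_train(self):
        trace = np.zeros(64)
        trace[0] = 30.0
        assert relative_modulation(trace) == pytest.approx(2.0)

    def test_halfwave_rectified_sinusoid(self):
        t = np.arange(256) / 256
        trace = np.maximum(np.sin(2 * np.pi * t), 0.0)
        assert relative_modulation(trace) == pytest.approx(np.pi / 2,
                                                           rel=1e-3)

    def test_zero_mean_flagged(self):
        assert np.isnan(relative_modulation(np.zeros(16)))

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(0, 2**31 - 1))
    def test_bounded_for_nonnegative_traces(self, seed):
        rng = np.random.default_rng(seed)
        trace = rng.uniform(0, 50, 64)
        rm = relative_modulation(trace)
        assert 0.0 <= rm <= 2.0


class TestVonMisesFit:
    def test_exact_recovery_from_noiseless_curve(self):
        dirs = probe_directions(16)
        truth = dict(baseline=2.0, amp1=20.0, amp2=8.0, pref_deg=73.0,
                     kappa=3.0)
        y = double_von_mises(dirs, **truth)
        fit = fit_double_von_mises(dirs, y)
        assert fit.converged
        for name, val in truth.items():
            got = getattr(fit, name)
            assert got == pytest.approx(val, rel=1e-4), name

    def test_hwhh_closed_form(self):
        # single von Mises: bandwidth from the dense fitted curve equals
        # the closed form arccos(1 + ln((1+e^(-2k))/2)/k)
        grid = np.arange(0.0, 360.0, 0.02)
        for kappa in (0.5, 2.0, 8.0):
            curve = double_von_mises(grid, 0.0, 10.0, 0.0, 90.0, kappa)
            assert hwhh_from_curve(grid, curve) == pytest.approx(
                von_mises_hwhh_deg(kappa), abs=0.05)

    def test_bandwidth_scale_invariant(self):
        dirs = probe_directions(16)
        y = double_von_mises(dirs, 1.0, 15.0, 10.0, 30.0, 4.0)
        a = fit_double_von_mises(dirs, y).hwhh_deg
        b = fit_double_von_mises(dirs, 7.5 * y).hwhh_deg
        assert a == pytest.approx(b, rel=1e-3)

    def test_needs_enough_directions(self):
        with pytest.raises(ValueError):
            fit_double_von_mises(probe_directions(4), np.ones(4))


class TestPreferredOrientationMap:
    def test_uniform_curves_give_uniform_map(self):
        sheet = CorticalSheet(1.0, 0.2)
        dirs = probe_directions(16)
        curve = double_von_mises(dirs, 0.0, 10.0, 10.0, 45.0, 3.0)
        resp = np.tile(curve, (len(sheet), 1))
        omap = preferred_orientation_map(dirs, resp, sheet)
        # motion direction 45 deg -> bars (and orientation label) at 135
        assert np.all(omap.orientation_deg == 135.0)

    def test_argmax_matches_fitted_peak_within_step(self):
        rng = np.random.default_rng(4)
        dirs = probe_directions(16)
        step = 360.0 / 16
        for _ in range(10):
            pref = rng.uniform(0, 360)
            y = double_von_mises(dirs, 1.0, 12.0, 6.0, pref, 3.0)
            fit = fit_double_von_mises(dirs, y)
            raw = dirs[y.argmax()] % 180.0
            diff = abs(raw - fit.preferred_orientation_deg) % 180.0
            assert min(diff, 180.0 - diff) <= step

    def test_silent_nodes_flagged(self):
        sheet = CorticalSheet(0.4, 0.2)
        dirs = probe_directions(8)
        resp = np.ones((len(sheet), 8))
        resp[3] = 0.0
        omap = preferred_orientation_map(dirs, resp, sheet)
        assert np.isnan(omap.orientation_deg.ravel()[3])
        assert np.isfinite(np.delete(omap.orientation_deg.ravel(),
                                     3)).all()


class TestMapPeriodicity:
    @staticmethod
    def _striped_map(freq, n=50, spacing=0.1):
        # doubled angle advancing linearly along x: planted periodicity
        x = np.arange(n) * spacing
        theta = np.mod(180.0 * freq * x, 180.0)
        return OrientationMap(np.tile(theta, (n, 1)), spacing)

    def test_planted_frequency_recovered(self):
        omap = self._striped_map(freq=0.6)
        per = map_periodicity(omap, crop_deg=5.0)
        assert per["peak_freq"] == pytest.approx(0.6, abs=0.2 / 2)

    def test_translation_invariance(self):
        omap = self._striped_map(freq=0.4, n=80)
        a = map_periodicity(omap, 5.0)["peak_freq"]
        rolled = OrientationMap(np.roll(omap.orientation_deg, 7, axis=1),
                                omap.spacing)
        b = map_periodicity(rolled, 5.0)["peak_freq"]
        assert a == pytest.approx(b)

    def test_mm_conversion(self):
        per = map_periodicity(self._striped_map(0.5), 5.0)
        assert per["periodicity_mm"] == pytest.approx(
            per["periodicity_deg"] * np.sqrt(0.45))

    def test_crop_larger_than_map_errors(self):
        with pytest.raises(ValueError):
            map_periodicity(self._striped_map(0.5, n=30), crop_deg=5.0)


class TestPinwheels:
    def test_uniform_map_has_none(self):
        omap = OrientationMap(np.full((40, 40), 30.0), 0.1)
        assert count_pinwheels(omap, 3.0)["count"] == 0

    def test_planted_singularity_counted_once(self):
        # ideal pinwheel: orientation = half the polar angle, with the
        # core inside a plaquette (not on a grid node)
        n, spacing = 40, 0.1
        ax = (np.arange(n) - n // 2 + 0.5) * spacing
        x, y = np.meshgrid(ax, ax)
        theta = np.degrees(np.arctan2(y, x)) / 2.0 % 180.0
        omap = OrientationMap(theta, spacing)
        res = count_pinwheels(omap, 3.0)
        assert res["count"] == 1
        assert abs(res["charge"].sum()) == 1

    def test_charge_is_quantised(self):
        rng = np.random.default_rng(11)
        omap = OrientationMap(rng.uniform(0, 180, (30, 30)), 0.1)
        res = count_pinwheels(omap, 2.0, smooth_sd=0.0, n_bins=None)
        assert set(np.unique(res["charge"])) <= {-1, 0, 1}

    def test_total_charge_matches_boundary_winding(self):
        # discrete Stokes: summed plaquette charges equal the winding of
        # the doubled angle around the crop boundary
        rng = np.random.default_rng(5)
        field = rng.normal(size=(24, 24)) + \
            1j * rng.normal(size=(24, 24))
        from scipy.ndimage import gaussian_filter
        field = gaussian_filter(field.real, 2) + \
            1j * gaussian_filter(field.imag, 2)
        theta = np.degrees(np.angle(field)) / 2.0 % 180.0
        omap = OrientationMap(theta, 0.1)
        res = count_pinwheels(omap, 2.4, smooth_sd=0.0, n_bins=None)
        phi = 2.0 * omap.crop(2.4)
        edge = np.concatenate([phi[0, :-1], phi[:-1, -1],
                               phi[-1, ::-1][:-1], phi[::-1, 0][:-1]])
        d = (np.diff(np.r_[edge, edge[0]]) + 180.0) % 360.0 - 180.0
        boundary_winding = int(np.rint(d.sum() / 360.0))
        assert res["charge"].sum() == boundary_winding


class TestMapCorrelation:
    def test_identical_maps(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(0, 180, 400)
        assert map_correlation(a, a) == pytest.approx(1.0)

    def test_orthogonal_maps(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(0, 180, 400)
        assert map_correlation(a, (a + 90.0) % 180.0) == \
            pytest.approx(-1.0)

    def test_shuffled_maps_uncorrelated(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(0, 180, 5000)
        b = rng.permutation(a)
        r, p = map_correlation(a, b, n_permutations=200,
                               rng=np.random.default_rng(3))
        assert abs(r) < 0.05
        assert p > 0.05

    def test_grid_mismatch_errors(self):
        with pytest.raises(ValueError):
            map_correlation(np.ones(10), np.ones(11))


class TestGaborPrediction:
    def test_line_of_on_cells_predicts_line_orientation(self):
        # a row of on-centre impulses along 30 deg: the preferred
        # orientation at its midpoint is the line's own angle
        spec = MosaicSpec(patch_half_width=2.0, seed=0)
        t = np.linspace(-1.5, 1.5, 31)
        ang = np.radians(30.0)
        ch = ChannelArray(t * np.cos(ang), t * np.sin(ang),
                          np.ones(t.size, dtype=int), spec)
        orientations, resp = gabor_bank_response(ch, [(0.0, 0.0)])
        best = resp[0].reshape(-1).argmax()
        assert orientations[best // resp.shape[2]] == pytest.approx(30.0,
                                                                    abs=12)

    def test_matches_direct_convolution_at_probe_points(self):
        # oracle: rasterise the impulse map and take the literal dot
        # product with an explicitly constructed Gabor
        ch = build_channel_array(MosaicSpec(patch_half_width=1.0, seed=2))
        pts = [(0.1, -0.2), (0.4, 0.3)]
        orientations, resp = gabor_bank_response(ch, pts, sd=0.7)
        psi = 2 * np.pi * 0.5
        for pi, (px, py) in enumerate(pts):
            for oi, th_deg in enumerate(orientations):
                th = np.radians(th_deg) + np.pi / 2  # carrier axis
                for qi in range(8):
                    phase = qi * 2 * np.pi / 8
                    u = np.cos(th) * (ch.x - px) + \
                        np.sin(th) * (ch.y - py)
                    d2 = (ch.x - px) ** 2 + (ch.y - py) ** 2
                    gabor = np.exp(-d2 / (2 * 0.7**2)) * \
                        np.cos(psi * u + phase)
                    direct = float((ch.sign * gabor).sum())
                    assert resp[pi, oi, qi] == pytest.approx(
                        direct, abs=1e-9 + 1e-9 * abs(direct))

    def test_predicted_map_shape(self, standard_array):
        sheet = CorticalSheet(4.0, 0.4)  # coarse grid keeps this quick
        omap = predict_map_from_mosaic(standard_array, sheet)
        assert omap.shape == sheet.shape
        assert np.all((omap.orientation_deg >= 0)
                      & (omap.orientation_deg < 180))


class TestOnOffDifferenceMap:
    def test_colocated_pairs_cancel(self):
        spec = MosaicSpec(patch_half_width=1.0, seed=0)
        pts = np.random.default_rng(0).uniform(-0.8, 0.8, (40, 2))
        ch = ChannelArray(np.r_[pts[:, 0], pts[:, 0]],
                          np.r_[pts[:, 1], pts[:, 1]],
                          np.r_[np.ones(40, int), -np.ones(40, int)],
                          spec)
        field, _ = onoff_difference_map(ch)
        assert np.abs(field).max() < 1e-9

    def test_mass_conservation(self):
        ch = build_channel_array(MosaicSpec(patch_half_width=1.0, seed=1))
        field, axis = onoff_difference_map(ch, smoothing_sd=0.05,
                                           raster=0.02)
        integral = field.sum() * 0.02**2
        assert integral == pytest.approx(ch.n_on - ch.n_off, abs=1.0)

    def test_structured_mosaic_cancels_more_than_shuffled_signs(self):
        # opposite-sign nearest neighbours cancel under smoothing, so the
        # real mosaic's difference field has far lower variance than a
        # sign-shuffled control -- yet remains clearly patterned
        ch = build_channel_array(MosaicSpec(patch_half_width=2.0, seed=1))
        real_var = onoff_difference_map(ch)[0].var()
        rng = np.random.default_rng(0)
        shuffled_vars = []
        for _ in range(5):
            sign = ch.sign.copy()
            rng.shuffle(sign)
            shuffled_vars.append(
                onoff_difference_map(
                    ChannelArray(ch.x, ch.y, sign, ch.spec))[0].var())
        assert real_var > 0
        assert real_var < min(shuffled_vars)


class TestSubcorticalPeriodicity:
    def test_planted_sign_modulation_recovered(self):
        # channels on a fine grid with signs from a sinusoid: the
        # difference-map spectrum peaks at the planted frequency
        spec = MosaicSpec(patch_half_width=4.0, seed=0)
        ax = np.arange(-3.95, 4.0, 0.1)
        x, y = np.meshgrid(ax, ax)
        freq = 0.5
        sign = np.where(np.cos(2 * np.pi * freq * x) > 0, 1, -1)
        ch = ChannelArray(x.ravel(), y.ravel(), sign.ravel(), spec)
        peak = subcortical_periodicity(ch)
        assert peak == pytest.approx(freq, abs=1 / 6 + 1e-9)

    def test_infinite_smoothing_suppresses_structure(self, standard_array):
        broad = subcortical_periodicity(standard_array, r_s=3.0)
        narrow = subcortical_periodicity(standard_array, r_s=0.4)
        assert broad < narrow


class TestPairPeriodicity:
    def test_default_radius_values(self):
        freq, period = onoff_pair_periodicity(0.4)
        assert round(freq, 2) == 0.56
        assert round(period, 1) == 1.8

    def test_radius_scaling_law(self):
        f1, _ = onoff_pair_periodicity(0.4)
        f2, _ = onoff_pair_periodicity(0.8)
        assert f2 == pytest.approx(f1 / 2)

    def test_numeric_offset_difference_matches_analytic(self):
        analytic, _ = onoff_pair_periodicity(0.4)
        numeric = offset_difference_periodicity(0.4, offset=0.1)
        assert abs(numeric - analytic) / analytic < 0.02

    def test_invalid_radius(self):
        with pytest.raises(ValueError):
            onoff_pair_periodicity(0.0)


class TestAnalyzeMap:
    def test_summary_consistency(self):
        omap = TestMapPeriodicity._striped_map(0.5, n=60)
        s = analyze_map(omap, crop_deg=5.0)
        assert s.periodicity_deg == pytest.approx(1.0 / s.peak_freq)
        assert s.pinwheels_per_hypercolumn == pytest.approx(
            s.pinwheel_density_per_deg2 * s.periodicity_deg**2)
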