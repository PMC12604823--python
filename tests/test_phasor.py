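"""Tests for the phasor transform, calibration, and bound-fraction tools."""

import numpy as np
import pytest

from metaflim import (
    BiexpParams,
    DecayStack,
    PhasorEndpoints,
    bound_fraction_distance,
    bound_fraction_normalized,
    calibrate_phasor,
    fit_phasor_line,
    lifetimes_from_phasor,
    median_filter_phasor,
    monoexp_phasor,
    phasor_of_decay,
    phasor_transform,
)
from metaflim.phasor import CalibrationError
from metaflim.synthetic import FLUORESCEIN_LIFETIME_S, expected_decay_shape

from .conftest import biexp_with_intensity_fraction


def stack_from_decay(decay: np.ndarray, grid, shape=(2, 2)) -> DecayStack:
    counts = np.tile(np.round(decay).astype(np.int64)[:, None, None], (1, *shape))
    return DecayStack(counts=counts, grid=grid)


def noiseless_stack(params: BiexpParams, grid, irf=None, total=1e6, shape=(2, 2)) -> DecayStack:
    return stack_from_decay(expected_decay_shape(params, grid, irf) * total, grid, shape)


class TestPhasorTransform:
    @pytest.mark.parametrize("tau", [0.4e-9, 2.81e-9, 3.05e-9])
    def test_monoexponential_lands_on_closed_form(self, grid, tau):
        d = expected_decay_shape(BiexpParams.monoexponential(tau), grid, None) * 1e7
        g, s = phasor_of_decay(d, grid)
        g0, s0 = monoexp_phasor(tau, grid.omega(1))
        assert g == pytest.approx(g0, abs=1e-3)
        assert s == pytest.approx(s0, abs=1e-3)
        assert s**2 == pytest.approx(g * (1 - g), abs=1e-3)

    def test_known_coordinates_at_04ns(self, grid):
        g, s = monoexp_phasor(0.4e-9, grid.omega(1))
        assert g == pytest.approx(0.9611, abs=1e-4)
        assert s == pytest.approx(0.1933, abs=1e-4)

    def test_impulse_maps_to_one_zero(self, grid):
        d = np.zeros(grid.n_bins)
        d[0] = 1000.0
        g, s = phasor_of_decay(d, grid)
        # an impulse at the first bin center carries a half-bin phase
        assert g == pytest.approx(1.0, abs=1e-3)
        assert s == pytest.approx(0.0, abs=0.02)

    def test_constant_signal_maps_to_origin(self, grid):
        g, s = phasor_of_decay(np.full(grid.n_bins, 50.0), grid)
        assert g == pytest.approx(0.0, abs=1e-12)
        assert s == pytest.approx(0.0, abs=1e-12)

    def test_zero_count_pixels_masked_not_nan_propagated(self, grid):
        counts = np.zeros((grid.n_bins, 2, 2), dtype=np.int64)
        counts[:, 0, 0] = 10
        field = phasor_transform(DecayStack(counts, grid))
        assert field.mask[0, 0] and not field.mask[1, 1]
        g, s, w = field.masked_arrays()
        assert len(g) == 1 and np.isfinite(g).all()

    @pytest.mark.parametrize("harmonic", [1, 2, 3])
    def test_harmonic_consistency(self, grid, harmonic):
        tau = 1.5e-9
        d = expected_decay_shape(BiexpParams.monoexponential(tau), grid, None) * 1e7
        g, s = phasor_of_decay(d, grid, harmonic)
        g0, s0 = monoexp_phasor(tau, grid.omega(harmonic))
        assert g == pytest.approx(g0, abs=2e-3)
        assert s == pytest.approx(s0, abs=2e-3)

    @pytest.mark.parametrize("fracs", [(0.4, 0.6), (0.2, 0.5, 0.3)])
    def test_mixture_linearity(self, grid, fracs):
        taus = (0.4e-9, 1.2e-9, 3.0e-9)[: len(fracs)]
        total = 1e7
        mix = np.zeros(grid.n_bins)
        g_exp = s_exp = 0.0
        for f, tau in zip(fracs, taus):
            mix += expected_decay_shape(BiexpParams.monoexponential(tau), grid, None) * total * f
            gk, sk = monoexp_phasor(tau, grid.omega(1))
            g_exp += f * gk
            s_exp += f * sk
        g, s = phasor_of_decay(mix, grid)
        assert g == pytest.approx(g_exp, abs=1e-3)
        assert s == pytest.approx(s_exp, abs=1e-3)


class TestCalibration:
    def test_fluorescein_roundtrip_recovers_phase_lifetime(self, grid, irf):
        ref = noiseless_stack(BiexpParams.monoexponential(FLUORESCEIN_LIFETIME_S), grid, irf)
        field = phasor_transform(ref)
        cal = calibrate_phasor(field, ref, FLUORESCEIN_LIFETIME_S)
        tau_phi, _ = lifetimes_from_phasor(cal.g, cal.s, cal.omega)
        assert np.nanmean(tau_phi) == pytest.approx(FLUORESCEIN_LIFETIME_S, rel=0.005)

    def test_calibration_removes_irf_shift_for_other_lifetimes(self, grid, irf):
        ref = noiseless_stack(BiexpParams.monoexponential(FLUORESCEIN_LIFETIME_S), grid, irf)
        for tau in (0.5e-9, 1e-9, 2e-9, 4e-9):
            sample = noiseless_stack(BiexpParams.monoexponential(tau), grid, irf)
            cal = calibrate_phasor(phasor_transform(sample), ref, FLUORESCEIN_LIFETIME_S)
            g, s = cal.g[0, 0], cal.s[0, 0]
            assert s**2 == pytest.approx(g * (1 - g), abs=1e-3)

    def test_ideal_reference_calibration_is_idempotent(self, grid):
        tau = 2e-9
        ref_decay = expected_decay_shape(BiexpParams.monoexponential(tau), grid, None) * 1e6
        sample = noiseless_stack(BiexpParams.monoexponential(1e-9), grid, None)
        once = calibrate_phasor(phasor_transform(sample), ref_decay, tau, grid=grid)
        twice = calibrate_phasor(once, ref_decay, tau, grid=grid)
        # an ideal (IRF-free) reference matches its theoretical phasor to
        # the Riemann-sum discretization accuracy, so the second unit
        # correction is bounded by that scale
        np.testing.assert_allclose(twice.g, once.g, atol=2e-4)
        np.testing.assert_allclose(twice.s, once.s, atol=2e-4)

    def test_zero_modulation_reference_rejected(self, grid):
        sample = noiseless_stack(BiexpParams.monoexponential(1e-9), grid, None)
        flat = np.full(grid.n_bins, 100.0)
        with pytest.raises(CalibrationError):
            calibrate_phasor(phasor_transform(sample), flat, 3e-9, grid=grid)


class TestLifetimesFromPhasor:
    def test_inverse_of_closed_form(self, grid):
        g, s = monoexp_phasor(0.4e-9, grid.omega(1))
        tp, tm = lifetimes_from_phasor(g, s, grid.omega(1))
        assert tp == pytest.approx(0.4e-9, rel=0.01)
        assert tm == pytest.approx(0.4e-9, rel=0.01)

    def test_mixture_phase_below_modulation(self, grid):
        w = grid.omega(1)
        g1, s1 = monoexp_phasor(0.4e-9, w)
        g2, s2 = monoexp_phasor(2.81e-9, w)
        g, s = (g1 + g2) / 2, (s1 + s2) / 2
        tp, tm = lifetimes_from_phasor(g, s, w)
        assert tp == pytest.approx(1.021e-9, rel=0.005)
        assert tm == pytest.approx(1.874e-9, rel=0.005)
        assert tp < tm

    def test_phase_equals_modulation_only_on_circle(self, grid):
        w = grid.omega(1)
        for f2 in (0.0, 0.3, 0.7, 1.0):
            p = biexp_with_intensity_fraction(max(f2, 1e-9)) if 0 < f2 < 1 else None
            if p is None:
                tau = 0.5e-9 if f2 == 0.0 else 3.0e-9
                g, s = monoexp_phasor(tau, w)
            else:
                g1, s1 = monoexp_phasor(0.5e-9, w)
                g2, s2 = monoexp_phasor(3.0e-9, w)
                g, s = (1 - f2) * g1 + f2 * g2, (1 - f2) * s1 + f2 * s2
            tp, tm = lifetimes_from_phasor(g, s, w)
            if f2 in (0.0, 1.0):
                assert tp == pytest.approx(tm, rel=1e-6)
            else:
                assert tp < tm * (1 - 1e-6)

    def test_degenerate_point(self):
        tp, tm = lifetimes_from_phasor(1.0, 0.0, 2 * np.pi * 80e6)
        assert tp == 0.0 and tm == 0.0

    def test_out_of_domain_yields_nan(self):
        tp, tm = lifetimes_from_phasor(np.array([-0.1]), np.array([0.5]), 5e8)
        assert np.isnan(tp).all() and np.isnan(tm).all()


class TestBoundFraction:
    def test_requires_calibration(self, grid):
        sample = noiseless_stack(BiexpParams.monoexponential(1e-9), grid, None)
        field = phasor_transform(sample)
        with pytest.raises(CalibrationError):
            bound_fraction_distance(field)

    def test_distance_examples(self, grid):
        w = grid.omega(1)
        free = monoexp_phasor(0.4e-9, w)
        bound = monoexp_phasor(2.81e-9, w)
        endpoint_dist = np.hypot(bound[0] - free[0], bound[1] - free[1])
        assert endpoint_dist == pytest.approx(0.686, abs=1e-3)
        # pure bound species
        sample = noiseless_stack(BiexpParams.monoexponential(2.81e-9), grid, None)
        cal = calibrate_phasor(
            phasor_transform(sample),
            expected_decay_shape(BiexpParams.monoexponential(3.05e-9), grid, None) * 1e6,
            3.05e-9,
            grid=grid,
        )
        d = bound_fraction_distance(cal, free_point=free)
        assert d[0, 0] == pytest.approx(0.686, abs=2e-3)
        # pixel exactly at the free point
        at_free = noiseless_stack(BiexpParams.monoexponential(0.4e-9), grid, None)
        cal2 = calibrate_phasor(
            phasor_transform(at_free),
            expected_decay_shape(BiexpParams.monoexponential(3.05e-9), grid, None) * 1e6,
            3.05e-9,
            grid=grid,
        )
        assert bound_fraction_distance(cal2, free_point=free)[0, 0] == pytest.approx(0.0, abs=2e-3)

    def test_equal_mixture_at_half_endpoint_distance(self, grid):
        mix = biexp_with_intensity_fraction(0.5, tau1=0.4e-9, tau2=2.81e-9)
        sample = noiseless_stack(mix, grid, None)
        ref = expected_decay_shape(BiexpParams.monoexponential(3.05e-9), grid, None) * 1e6
        cal = calibrate_phasor(phasor_transform(sample), ref, 3.05e-9, grid=grid)
        d = bound_fraction_distance(cal)
        assert d[0, 0] == pytest.approx(0.343, abs=2e-3)

    def test_normalized_fraction_matches_generating_intensity_fraction(self, grid):
        w = grid.omega(1)
        endpoints = PhasorEndpoints.from_lifetimes(0.5e-9, 3.0e-9, w)
        ref = expected_decay_shape(BiexpParams.monoexponential(3.05e-9), grid, None) * 1e6
        for f2_true in (0.0, 0.6, 1.0):
            if f2_true == 0.0:
                p = BiexpParams.monoexponential(0.5e-9)
            elif f2_true == 1.0:
                p = BiexpParams.monoexponential(3.0e-9)
            else:
                p = biexp_with_intensity_fraction(f2_true)
            cal = calibrate_phasor(phasor_transform(noiseless_stack(p, grid, None)), ref, 3.05e-9, grid=grid)
            f2_map, _ = bound_fraction_normalized(cal, endpoints)
            assert f2_map[0, 0] == pytest.approx(f2_true, abs=1e-3)

    def test_coincident_endpoints_rejected(self):
        with pytest.raises(ValueError):
            PhasorEndpoints((0.5, 0.4), (0.5, 0.4))


class TestPhasorLineFit:
    def test_collinear_cloud_recovers_analytic_intersections(self, grid):
        w = grid.omega(1)
        tau_f, tau_b = 0.4e-9, 2.81e-9
        gf, sf = monoexp_phasor(tau_f, w)
        gb, sb = monoexp_phasor(tau_b, w)
        fracs = np.array([0.25, 0.5, 0.75])
        g = np.array([(1 - f) * gf + f * gb for f in fracs]).reshape(1, 3)
        s = np.array([(1 - f) * sf + f * sb for f in fracs]).reshape(1, 3)
        from metaflim.phasor import PhasorField

        field = PhasorField(g=g, s=s, harmonic=1, omega=w, intensity=np.full((1, 3), 1e4), calibrated=True)
        ep = fit_phasor_line(field, min_pixels=3)
        assert ep.free_point[0] == pytest.approx(gf, abs=1e-6)
        assert ep.bound_point[0] == pytest.approx(gb, abs=1e-6)
        assert ep.provenance == "cloud-fit"

    def test_two_component_cloud_recovery_with_noise(self, grid):
        from metaflim import CellScene, simulate_tcspc_image

        mask = np.ones((24, 24), dtype=np.int32)
        mask[:, 12:] = 2
        scene = CellScene(
            label_mask=mask,
            decay_params={
                1: biexp_with_intensity_fraction(0.3, 0.4e-9, 2.81e-9),
                2: biexp_with_intensity_fraction(0.8, 0.4e-9, 2.81e-9),
            },
            photon_budget={1: 30000.0, 2: 30000.0},
        )
        stack = simulate_tcspc_image(scene, grid, None, seed=13)
        field = phasor_transform(stack)
        field.calibrated = True  # no IRF: the raw transform is already calibrated
        ep = fit_phasor_line(field)
        w = grid.omega(1)
        tp_free, _ = lifetimes_from_phasor(*ep.free_point, w)
        tp_bound, _ = lifetimes_from_phasor(*ep.bound_point, w)
        assert tp_free == pytest.approx(0.4e-9, rel=0.10)
        assert tp_bound == pytest.approx(2.81e-9, rel=0.10)

    def test_single_lifetime_cloud_is_degenerate(self, grid):
        rng = np.random.default_rng(0)
        w = grid.omega(1)
        g0, s0 = monoexp_phasor(1.5e-9, w)
        g = g0 + rng.normal(0, 1e-3, (10, 10))
        s = s0 + rng.normal(0, 1e-3, (10, 10))
        from metaflim.phasor import PhasorField

        field = PhasorField(g=g, s=s, harmonic=1, omega=w, intensity=np.full((10, 10), 1e3), calibrated=True)
        with pytest.raises(ValueError, match="degenerate"):
            fit_phasor_line(field)


class TestMedianFilter:
    def make_field(self, g, s, grid):
        from metaflim.phasor import PhasorField

        return PhasorField(
            g=g, s=s, harmonic=1, omega=grid.omega(1),
            intensity=np.full(g.shape, 100.0), calibrated=True,
        )

    def test_constant_field_unchanged(self, grid):
        g = np.full((6, 6), 0.4)
        s = np.full((6, 6), 0.3)
        out = median_filter_phasor(self.make_field(g, s, grid), 3)
        np.testing.assert_array_equal(out.g, g)
        np.testing.assert_array_equal(out.s, s)

    def test_single_outlier_removed(self, grid):
        g = np.full((5, 5), 0.5)
        g[2, 2] = 0.9
        out = median_filter_phasor(self.make_field(g, g.copy(), grid), 5)
        assert out.g[2, 2] == pytest.approx(0.5)

    def test_noise_reduced_mean_preserved(self, grid):
        rng = np.random.default_rng(8)
        g = 0.5 + rng.normal(0, 0.05, (40, 40))
        out = median_filter_phasor(self.make_field(g, g.copy(), grid), 3)
        assert out.g.std() < g.std()
        assert abs(out.g.mean() - g.mean()) / g.mean() < 0.005

    def test_even_kernel_rejected(self, grid):
        with pytest.raises(ValueError):
            median_filter_phasor(self.make_field(np.ones((4, 4)), np.ones((4, 4)), grid), 2)
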