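"""Lineshape models, band fitting, dispersion and LST contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import phonliq as pq
from phonliq.constants import (
    SLOPE_CM1_NM_TO_M_S,
    gamma_cm1_to_tau_ps,
    wavenumber_to_radps,
)
from phonliq.lineshape import DispersionBranch, debye_im, fit_band, vvw_im
from phonliq.response import SusceptibilitySpectrum


def dho_im(w, A, w0, gamma_half):
    """Independent oracle: damped harmonic oscillator with full friction
    2*gamma_half, Im chi = A w0^2 (2g) w / ((w0^2-w^2)^2 + (2g)^2 w^2)."""
    g2 = 2.0 * gamma_half
    w = np.asarray(w, float)
    return A * w0**2 * g2 * w / ((w0**2 - w**2) ** 2 + g2**2 * w**2)


def spectrum_from(im, grid, component="L", k=1.0):
    return SusceptibilitySpectrum(component, k, grid, 1j * np.asarray(im), 1.0)


class TestDebyeLineshape:
    def test_zero_frequency(self):
        assert debye_im(0.0, 1.0, 1.0) == 0.0

    def test_maximum_at_inverse_tau(self):
        tau = 0.5
        w_peak = 1.0 / tau / wavenumber_to_radps(1.0)
        assert debye_im(w_peak, 2.0, tau) == pytest.approx(1.0, rel=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(1.0, 3000.0), st.floats(0.01, 10.0))
    def test_algebraic_identity(self, w, tau):
        x = wavenumber_to_radps(w) * tau
        val = debye_im(w, 1.7, tau)
        assert val * (1 + x * x) / x == pytest.approx(1.7, rel=1e-10)


class TestVVWLineshape:
    def test_zero_frequency(self):
        assert vvw_im(0.0, 1.0, 600.0, 50.0) == 0.0

    def test_narrow_line_peak_location(self):
        w0, g = 900.0, 10.0
        w = np.arange(800.0, 1000.0, 0.05)
        peak = w[np.argmax(vvw_im(w, 1.0, w0, g))]
        assert abs(peak - w0) <= g * g / w0 + 0.1

    def test_equivalent_to_damped_oscillator_in_fit_regime(self):
        # pointwise equivalence in the damping regime where the two forms
        # are used interchangeably (gamma/w0 ~ 0.013)
        w = np.arange(1.0, 3000.0, 1.0)
        v = vvw_im(w, 1.0, 900.0, 12.07)
        d = dho_im(w, 1.0, 900.0, 12.07)
        assert np.abs(v - d).max() < 0.02 * d.max()

    def test_vvw_fit_recovers_oscillator_frequency_at_strong_damping(self):
        # at gamma/w0 ~ 0.11 the shapes differ pointwise, but a VVW fit of
        # the oscillator spectrum still recovers w0 within 2%
        grid = np.arange(2.0, 3000.0, 2.0)
        spec = spectrum_from(dho_im(grid, 1.0, 900.0, 100.0), grid)
        f = fit_band(spec, init={"dchi": 1e-6})
        assert f.omega0 == pytest.approx(900.0, rel=0.02)


class TestFitBand:
    def test_recovers_planted_debye_plus_resonance(self):
        grid = np.arange(0.0, 4000.0, 2.0)
        im = debye_im(grid, 1.0, 1.0) + vvw_im(grid, 0.5, 900.0, 379.0)
        f = fit_band(spectrum_from(im, grid))
        assert f.omega0 == pytest.approx(900.0, rel=0.01)
        assert f.gamma == pytest.approx(379.0, rel=0.01)
        assert f.tau_ps == pytest.approx(gamma_cm1_to_tau_ps(379.0), rel=0.01)
        assert f.debye_tau_ps == pytest.approx(1.0, rel=0.02)

    def test_pure_debye_resonance_amplitude_vanishes(self):
        grid = np.arange(0.0, 1000.0, 2.0)
        im = debye_im(grid, 2.0, 0.5)
        f = fit_band(spectrum_from(im, grid))
        A = f.resonances[-1][0] if f.resonances[-1][1] > 0 else 0.0
        # amplitude consistent with zero within its own uncertainty
        i_A = [i for i, n in enumerate(f.param_names) if n.startswith("A")][0]
        sigma_A = np.sqrt(max(f.covariance[i_A, i_A], 0.0))
        assert min(r[0] for r in f.resonances) <= max(3 * sigma_A, 1e-4)
        assert f.debye_dchi == pytest.approx(2.0, rel=0.01)

    def test_two_resonance_recovery(self):
        # librational band plus hydrogen-bond stretch near 200 cm^-1
        grid = np.arange(0.0, 3000.0, 2.0)
        im = (
            debye_im(grid, 0.8, 2.0)
            + vvw_im(grid, 0.5, 700.0, 60.0)
            + vvw_im(grid, 0.3, 200.0, 50.0)
        )
        f = fit_band(spectrum_from(im, grid), model="debye+2res")
        w0s = sorted(r[1] for r in f.resonances)
        assert w0s[0] == pytest.approx(200.0, rel=0.02)
        assert w0s[1] == pytest.approx(700.0, rel=0.02)

    def test_deterministic(self):
        grid = np.arange(0.0, 2000.0, 2.0)
        im = debye_im(grid, 1.0, 1.0) + vvw_im(grid, 0.5, 600.0, 50.0)
        a = fit_band(spectrum_from(im, grid))
        b = fit_band(spectrum_from(im, grid))
        assert a.omega0 == b.omega0 and a.gamma == b.gamma

    def test_noisy_parameter_recovery_statistics(self):
        # 50 random planted parameter sets, 1% additive noise:
        # median error < 2% (w0), < 10% (gamma)
        rng = np.random.default_rng(77)
        grid = np.arange(0.0, 4000.0, 2.0)
        err_w0, err_g = [], []
        for _ in range(50):
            w0 = rng.uniform(400.0, 1200.0)
            g = rng.uniform(0.03, 0.5) * w0
            dchi = rng.uniform(0.2, 2.0)
            tau = rng.uniform(0.2, 2.0)
            A = rng.uniform(0.2, 1.0)
            im = debye_im(grid, dchi, tau) + vvw_im(grid, A, w0, g)
            noisy = im + rng.normal(0, 0.01 * im.max(), im.size)
            f = fit_band(spectrum_from(noisy, grid))
            err_w0.append(abs(f.omega0 / w0 - 1))
            err_g.append(abs(f.gamma / g - 1))
        assert np.median(err_w0) < 0.02
        assert np.median(err_g) < 0.10

    def test_underdamped_flag(self):
        grid = np.arange(0.0, 2000.0, 2.0)
        im = vvw_im(grid, 0.5, 600.0, 50.0) + debye_im(grid, 0.3, 1.0)
        f = fit_band(spectrum_from(im, grid))
        assert f.underdamped

    def test_splitting_stable_under_grid_refinement(self):
        vals = {}
        for step in (2.0, 1.0):
            grid = np.arange(0.0, 2000.0, step)
            fl = fit_band(spectrum_from(
                debye_im(grid, 1.0, 1.0) + vvw_im(grid, 0.5, 900.0, 80.0), grid))
            ft = fit_band(spectrum_from(
                debye_im(grid, 1.0, 1.0) + vvw_im(grid, 0.5, 632.0, 80.0), grid))
            vals[step] = pq.lo_to_splitting(fl.omega0, ft.omega0)
        assert abs(vals[2.0] - vals[1.0]) < 0.5


def branch_fits(k, w0s, gamma=50.0, component="L"):
    return [
        pq.LineshapeFit(
            component=component, k_mag=float(ki), debye_dchi=0.0, debye_tau_ps=1.0,
            resonances=[(1.0, float(w), gamma)], residual_rms=0.0, covariance=None,
            param_names=["dchi", "tau_d", "A1", "w01", "gamma1"], success=True,
        )
        for ki, w in zip(k, w0s)
    ]


class TestDispersion:
    def test_planted_linear_slope(self):
        k = np.linspace(2.0, 6.0, 6)
        fits = branch_fits(k, 600.0 + 50.0 * k)
        br = pq.dispersion(fits, "L")
        assert br.v_g == pytest.approx(50.0 * SLOPE_CM1_NM_TO_M_S, rel=0.01)

    def test_flat_dispersion_zero_velocity(self):
        k = np.linspace(2.0, 6.0, 5)
        br = pq.dispersion(branch_fits(k, np.full(5, 600.0)), "L")
        assert br.v_g == pytest.approx(0.0, abs=1e-9)

    def test_noisy_slope_within_three_sigma(self):
        # Monte Carlo: sigma = 5 cm^-1 noise on a planted linear dispersion
        rng = np.random.default_rng(5)
        k = np.linspace(2.0, 6.0, 8)
        slope_true = 50.0
        slopes = []
        for _ in range(100):
            w0s = 600.0 + slope_true * k + rng.normal(0, 5.0, k.size)
            br = pq.dispersion(branch_fits(k, w0s), "L", k_window=(k[0], k[-1]))
            slopes.append(br.v_g / SLOPE_CM1_NM_TO_M_S)
        slopes = np.array(slopes)
        sigma_pred = 5.0 / np.sqrt(np.sum((k - k.mean()) ** 2))
        assert abs(slopes.mean() - slope_true) < 3 * sigma_pred / np.sqrt(100)

    def test_too_few_points_rejected(self):
        k = [1.0, 2.0]
        with pytest.raises(ValueError):
            pq.dispersion(branch_fits(k, [600.0, 610.0]), "L")

    def test_no_linear_window_warns(self):
        k = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        w0s = 600.0 + 40.0 * np.sin(3.0 * k) ** 2  # strongly nonlinear
        with pytest.warns(UserWarning, match="linear"):
            br = pq.dispersion(branch_fits(k, w0s), "L", r2_min=0.9999)
        assert br.v_g is None


class TestSplittingAndRange:
    @pytest.mark.parametrize(
        "lo,to,expect", [(900.0, 632.0, 268.0), (721.0, 410.0, 311.0), (5.0, 5.0, 0.0)]
    )
    def test_splitting_is_exact_difference(self, lo, to, expect):
        assert pq.lo_to_splitting(lo, to) == expect

    def test_transverse_range(self):
        r = pq.propagation_range(0.18, 1800.0)
        assert r == pytest.approx(0.324)
        assert pq.round_one_sig(r) == pytest.approx(0.3)

    def test_longitudinal_range(self):
        assert pq.propagation_range(0.44, 2700.0) == pytest.approx(1.188)

    def test_zero_lifetime(self):
        assert pq.propagation_range(0.0, 2000.0) == 0.0


class TestLSTCheck:
    def test_no_modes_both_sides_unity(self):
        rep = pq.lst_check([], [], 5.0, 5.0)
        assert rep.lhs == 1.0 and rep.rhs == 1.0

    def test_single_lossless_oscillator_closed_form(self):
        # eps = eps_inf + wp^2/(w0^2 - w^2): both sides (w0^2 + wp^2/eps_inf)/w0^2
        eps_inf, w0, wp = 2.0, 600.0, 500.0
        eps_static = eps_inf + wp**2 / w0**2
        w_l = np.sqrt(w0**2 + wp**2 / eps_inf)
        rep = pq.lst_check([], [(w_l, w0, 0.0)], eps_static, eps_inf)
        assert rep.rhs == pytest.approx(rep.lhs, rel=1e-12)

    def test_damped_oscillator_exact_with_complex_modulus(self):
        # roots of eps_inf(w^2 + i G w - w0^2) = wp^2 have |w_L|^2 = w0^2+wp^2/eps_inf
        eps_inf, w0, wp, G = 1.5, 600.0, 400.0, 120.0
        eps_static = eps_inf + wp**2 / w0**2
        Om2 = w0**2 + wp**2 / eps_inf
        g_l = G / 2.0
        w_l_res = np.sqrt(Om2 - g_l**2)
        g_t = G / 2.0
        w_t_res = np.sqrt(w0**2 - g_t**2)
        rep = pq.lst_check([], [(w_l_res, w_t_res, g_l, g_t)], eps_static, eps_inf)
        assert rep.relative_discrepancy < 1e-12

    def test_debye_plus_oscillator_synthetic(self):
        # single Debye (longitudinal rate scaled by eps ratio) + damped mode
        eps_inf, d_eps, tau = 2.0, 70.0, 8.0
        wp, w0, G = 450.0, 650.0, 60.0
        eps_osc0 = wp**2 / w0**2
        eps_static = eps_inf + d_eps + eps_osc0
        # approximate longitudinal Debye rate: w_DL/w_D ~ eps_static/eps(high side)
        w_d = 1.0 / tau
        w_dl = w_d * eps_static / (eps_inf + eps_osc0)
        w_l = np.sqrt(w0**2 + wp**2 / eps_inf)
        rep = pq.lst_check([(w_dl, w_d)], [(w_l, w0, 0.0)], eps_static, eps_inf)
        assert rep.relative_discrepancy < 0.05

    def test_low_frequency_cutoff_excludes_modes(self):
        rep = pq.lst_check(
            [], [(700.0, 650.0, 0.0), (150.0, 100.0, 0.0)], 2.0, 1.0,
            cutoff_cm1=300.0,
        )
        assert rep.n_resonances == 1
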