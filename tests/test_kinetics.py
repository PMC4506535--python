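import numpy as np
import pytest

from flcs2d import (
    CorrelationCurve,
    KineticScheme,
    State,
    ExchangePair,
    Diffusion,
    diffusion_correlation,
    diffusion_only,
    diffusion_plus_relaxation,
    fit_relaxation,
    fit_two_state,
    forster_distance,
    fret_efficiency,
    global_decay_fit,
    scheme_total_correlation,
    truncated_brightness,
    truncated_exponential_moments,
    two_state_models,
)
from flcs2d.ilt import decay_basis


class TestDiffusionCorrelation:
    def test_zero_lag_is_one(self):
        assert diffusion_correlation(0.0, 1.0, 0.078) == 1.0

    def test_half_at_tau_diff_in_thin_focus_limit(self):
        assert diffusion_correlation(1.0, 1.0, 1e-9) == pytest.approx(0.5)

    def test_closed_form_at_tau_diff(self):
        expected = 0.5 / np.sqrt(1.0 + 0.078 ** 2)
        assert diffusion_correlation(1.0, 1.0, 0.078) == pytest.approx(expected)

    def test_monotone_decreasing(self):
        t = np.geomspace(1e-7, 1.0, 200)
        g = diffusion_correlation(t, 5e-4, 0.078)
        assert np.all(np.diff(g) < 0)


class TestTwoStateModels:
    def test_weighted_sum_identity_machine_precision(self):
        # f_A^2 G_AA + f_B^2 G_BB + 2 f_A f_B G_AB == g_D/N over 6 decades
        K, N, tr, td, w = 0.25, 1.7, 5e-6, 5e-4, 0.078
        fa, fb = 1 / (1 + K), K / (1 + K)
        t = np.geomspace(1e-8, 1e-2, 120)
        gaa, gbb, gab = two_state_models(t, N, K, tr, td, w)
        lhs = fa ** 2 * gaa + fb ** 2 * gbb + 2 * fa * fb * gab
        rhs = diffusion_correlation(t, td, w) / N
        assert np.allclose(lhs, rhs, rtol=1e-14, atol=0)

    def test_cross_correlation_vanishes_at_zero_lag(self):
        _, _, gab = two_state_models(0.0, 1.0, 0.25, 5e-6, 5e-4, 0.078)
        assert gab == 0.0

    def test_convergence_beyond_exchange_time(self):
        t = 1e-3  # 200x the 5 us exchange time
        gaa, gbb, gab = two_state_models(t, 1.0, 0.25, 5e-6, 5e-4, 0.078)
        assert gaa == pytest.approx(gab, rel=1e-12)
        assert gbb == pytest.approx(gab, rel=1e-12)

    def test_self_consistent_parameter_recovery(self):
        """Fitting noiseless curves generated by the same equations recovers
        the parameters to better than 6 significant digits."""
        K, w = 0.25, 0.078
        truth = dict(N=1.4, tr=5e-6, td=5e-4)
        t = np.geomspace(3e-7, 1e-3, 30)
        gaa, gbb, gab = two_state_models(t, truth["N"], K, truth["tr"],
                                         truth["td"], w)
        widths = np.diff(np.concatenate([[t[0] * 0.8], t]))
        err = np.full(t.size, 1e-4)
        curves = {
            "AA": CorrelationCurve(t, widths, gaa, err),
            "BB": CorrelationCurve(t, widths, gbb, err),
            "AB": CorrelationCurve(t, widths, gab, err),
        }
        fit = fit_two_state(curves, K=K, w=w)
        assert fit.N_pair == pytest.approx(truth["N"], rel=1e-6)
        assert fit.tau_R_us == pytest.approx(truth["tr"] * 1e6, rel=1e-6)
        assert fit.tau_diff_ms == pytest.approx(truth["td"] * 1e3, rel=1e-6)
        assert fit.k_ab_per_us + fit.k_ba_per_us == pytest.approx(
            1.0 / fit.tau_R_us)

    def test_relaxation_fit_recovery(self):
        t = np.geomspace(3e-7, 1e-3, 25)
        y = diffusion_plus_relaxation(t, 1.2, 0.5, 7e-6, 5e-4, 0.078)
        curve = CorrelationCurve(t, np.gradient(t), y, np.full(t.size, 1e-4))
        fit = fit_relaxation(curve, tau_diff_ms=0.5, w=0.078)
        assert fit.tau_R_us == pytest.approx(7.0, rel=1e-5)
        assert fit.amplitude == pytest.approx(0.5, rel=1e-5)

    def test_zero_amplitude_reduces_to_diffusion_only(self):
        t = np.geomspace(1e-7, 1e-2, 50)
        assert np.allclose(
            diffusion_plus_relaxation(t, 2.0, 0.0, 5e-6, 5e-4, 0.078),
            diffusion_only(t, 2.0, 5e-4, 0.078))


class TestForster:
    def test_half_lifetime_gives_r0(self):
        assert fret_efficiency(2.0, 4.0) == 0.5
        assert forster_distance(2.0, 4.0, R0=41.0) == pytest.approx(41.0)

    def test_cytc_distances(self):
        # 280 ps component lies ~26-27 A from the haem; 70 ps ~6 A closer
        r_280 = forster_distance(0.280, 4.0, 41.0)
        r_70 = forster_distance(0.070, 4.0, 41.0)
        assert 26.0 < r_280 < 27.0
        assert r_280 - r_70 == pytest.approx(6.0, abs=0.5)

    def test_monotone_in_donor_lifetime(self):
        taus = np.linspace(0.05, 3.9, 40)
        r = [forster_distance(t, 4.0) for t in taus]
        assert np.all(np.diff(r) > 0)

    def test_round_trip_efficiency(self):
        E = fret_efficiency(0.28, 4.0)
        r = forster_distance(0.28, 4.0, 41.0)
        E_back = 1.0 / (1.0 + (r / 41.0) ** 6)
        assert E_back == pytest.approx(E, rel=1e-12)

    def test_invalid_lifetimes_raise(self):
        with pytest.raises(ValueError):
            fret_efficiency(5.0, 4.0)


class TestTruncatedBrightness:
    def test_negligible_truncation(self):
        tau_eff, q = truncated_brightness(0.07, t_max_ns=9.5)
        assert tau_eff == pytest.approx(0.07, rel=1e-10)
        # q proportional to tau against the 4.0 ns reference
        z_ref = 4.0 * (1 - np.exp(-9.5 / 4.0))
        assert q == pytest.approx(0.07 / z_ref, rel=1e-10)

    def test_closed_form_at_3p3ns(self):
        tau, t_max = 3.3, 9.5
        x = t_max / tau
        expected = tau - t_max * np.exp(-x) / (1 - np.exp(-x))
        tau_eff, _ = truncated_brightness(tau, t_max_ns=t_max)
        assert tau_eff == pytest.approx(expected, rel=1e-12)
        assert tau_eff < tau

    def test_uniform_limit(self):
        tau_eff, _ = truncated_exponential_moments(1e9, 9.5)
        assert tau_eff == pytest.approx(9.5 / 2.0, rel=1e-5)

    def test_histogram_agrees_with_closed_form(self):
        edges = np.linspace(0, 12.0, 24001)
        centers = 0.5 * (edges[:-1] + edges[1:])
        y = np.exp(-centers / 3.3)
        tau_eff, q = truncated_brightness(y, 9.5, 4.0, edges_ns=edges)
        ref, _ = truncated_exponential_moments(3.3, 9.5)
        assert tau_eff == pytest.approx(ref, rel=1e-3)

    def test_invalid_window(self):
        with pytest.raises(ValueError):
            truncated_exponential_moments(1.0, -1.0)


class TestGlobalDecayFit:
    edges = np.linspace(0.0, 9.5, 160)
    lifetimes = np.array([0.07, 0.28, 1.7, 3.3])

    def test_single_component(self):
        E = decay_basis(self.lifetimes, self.edges)
        y = 5e4 * E[:, 2]
        amps = global_decay_fit([y], self.lifetimes, self.edges)[0]
        assert amps[2] == pytest.approx(5e4, rel=1e-6)
        others = np.delete(amps, 2)
        assert np.all(others < 1e-3 * amps[2])

    def test_mixture_recovery_noiseless(self):
        E = decay_basis(self.lifetimes, self.edges)
        truth = np.array([4e4, 2e4, 8e3, 1.5e4])
        y = E @ truth
        amps = global_decay_fit([y, 2 * y], self.lifetimes, self.edges)
        assert np.allclose(amps[0], truth, rtol=0.02)
        assert np.allclose(amps[1], 2 * truth, rtol=0.02)

    def test_near_degenerate_lifetimes_warn(self):
        with pytest.warns(RuntimeWarning, match="near-degenerate"):
            global_decay_fit([np.ones(159)], [1.0, 1.0 + 1e-9], self.edges)

    def test_residual_whiteness_runs_test(self):
        """Residuals of a correctly specified fit carry no sign structure."""
        rng = np.random.default_rng(5)
        E = decay_basis(self.lifetimes, self.edges)
        y = rng.poisson(E @ np.array([4e4, 2e4, 8e3, 1.5e4])).astype(float)
        amps = global_decay_fit([y], self.lifetimes, self.edges)[0]
        resid = y - E @ amps
        signs = resid > 0
        runs = 1 + int(np.sum(signs[1:] != signs[:-1]))
        n1, n2 = int(signs.sum()), int((~signs).sum())
        mu = 2 * n1 * n2 / (n1 + n2) + 1
        sigma = np.sqrt(2 * n1 * n2 * (2 * n1 * n2 - n1 - n2)
                        / ((n1 + n2) ** 2 * (n1 + n2 - 1)))
        assert abs(runs - mu) < 3.5 * sigma


class TestSchemeTotalCorrelation:
    def test_no_exchange_equal_states_reduce_to_diffusion(self):
        s = KineticScheme(
            states=[State("A", 2.0, 1e4, 0.5), State("B", 2.0, 1e4, 0.5)],
            diffusion=Diffusion(0.5, 0.078), mean_occupancy=2.0)
        t = np.geomspace(1e-6, 1e-2, 30)
        assert np.allclose(scheme_total_correlation(t, s),
                           diffusion_only(t, 2.0, 5e-4, 0.078), rtol=1e-12)

    def test_bright_dark_pair_equals_relaxation_model(self):
        K = 0.5
        fb = 1 / (1 + K)
        s = KineticScheme(
            states=[State("B", 1.7, 1e5, fb), State("D", 0.0, 0.0, 1 - fb)],
            exchange_pairs=[ExchangePair("B", "D", 7.0, K)],
            diffusion=Diffusion(0.5, 0.078), mean_occupancy=1.3)
        t = np.geomspace(1e-7, 1e-2, 40)
        expected = diffusion_plus_relaxation(t, 1.3, K, 7e-6, 5e-4, 0.078)
        assert np.allclose(scheme_total_correlation(t, s), expected, rtol=1e-12)

    def test_lifetime_weighting_amplifies_long_components(self):
        # heterogeneous lifetimes: lifetime weighting raises the amplitude
        s = KineticScheme(
            states=[State("N", 0.07, 7e4, 0.6), State("I", 0.28, 2.8e5, 0.15),
                    State("U", 3.3, 3.3e6, 0.25)],
            exchange_pairs=[ExchangePair("N", "I", 5.0, 0.25)],
            diffusion=Diffusion(0.5, 0.078), mean_occupancy=1.0)
        t = np.array([1e-6])
        gi = scheme_total_correlation(t, s, "intensity")[0]
        gl = scheme_total_correlation(t, s, "lifetime")[0]
        assert gl > gi

    def test_overlapping_pairs_rejected(self):
        s = KineticScheme(
            states=[State("A", 1.0, 1e4, 0.25), State("B", 2.0, 1e4, 0.25),
                    State("C", 3.0, 1e4, 0.5)],
            exchange_pairs=[ExchangePair("A", "B", 5.0, 1.0),
                            ExchangePair("B", "C", 3.0, 2.0)])
        with pytest.raises(ValueError, match="disjoint"):
            scheme_total_correlation(np.array([1e-6]), s)
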