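"""Crossing detection, survival fits, Landau-Zener transmission and rates."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pmmkin import (
    CouplingGeometry,
    CrossingEvent,
    GapStatistics,
    InputError,
    TransitionEnergyTrace,
    crossing_rate,
    detect_first_crossing,
    fc_series,
    fit_survival,
    gaussian_rate,
    gen_gap_ensemble,
    GapProcessSpec,
    lz_adiabatic_fraction,
    mean_coupling_alpha_e,
    omega,
    reaction_lifetime,
    survival_trace,
    transmission_approx,
    transmission_explicit,
)
from pmmkin.constants import HBAR


class TestDetectFirstCrossing:
    def test_monotone_positive_trace_has_no_crossing(self):
        t = np.arange(100.0)
        trace = TransitionEnergyTrace.from_gap(t, 5.0 + 0.01 * t)
        assert detect_first_crossing(trace) is None

    def test_linear_ramp(self):
        t = np.arange(0.0, 11.0)
        trace = TransitionEnergyTrace.from_gap(t, 5.0 - t)
        ev = detect_first_crossing(trace)
        assert ev.time == pytest.approx(5.0)
        assert ev.speed == pytest.approx(1.0)

    def test_sinusoid_matches_analytic_root(self):
        dt = 0.5
        t = np.arange(0.0, 400.0, dt)
        om, phi = 0.05, 0.3
        gap = 3.62 + 7.1 * np.sin(om * t + phi)
        trace = TransitionEnergyTrace.from_gap(t, gap)
        ev = detect_first_crossing(trace)
        # first downward root of 3.62 + 7.1 sin(om t + phi) = 0
        alpha = math.asin(-3.62 / 7.1)           # in (-pi/2, 0)
        t_root = ((math.pi - alpha) - phi) / om  # descending branch
        assert ev.time == pytest.approx(t_root, abs=dt / 2)

    def test_nonpositive_start_rejected(self):
        trace = TransitionEnergyTrace.from_gap(np.arange(10.0), -np.ones(10))
        with pytest.raises(InputError):
            detect_first_crossing(trace)


class TestSurvival:
    def test_all_crossings_at_same_time_step_function(self):
        events = [CrossingEvent(time=30.0, speed=1.0)] * 50
        grid, surv = survival_trace(events, horizon=100.0)
        assert np.all(surv[grid < 30.0] == 1.0)
        assert np.all(surv[grid > 30.0] == 0.0)

    def test_no_crossings_constant_one(self):
        grid, surv = survival_trace([None] * 20, horizon=50.0)
        assert np.all(surv == 1.0)

    def test_exponential_sample_recovers_lifetime(self):
        rng = np.random.default_rng(77)
        k = 1.0 / 120.0
        times = rng.exponential(1.0 / k, size=2000)
        events = [CrossingEvent(time=float(t), speed=1.0) for t in times]
        grid, surv = survival_trace(events, horizon=1000.0)
        fit = fit_survival(grid, surv)
        assert fit.tau0 == pytest.approx(1.0 / k, rel=0.05)
        assert fit.single  # nested-model fallback for one timescale

    def test_biexponential_recovery(self):
        t = np.linspace(0.0, 2000.0, 600)
        surv = 0.4 * np.exp(-t / 50.0) + 0.6 * np.exp(-t / 300.0)
        fit = fit_survival(t, surv)
        assert not fit.single
        assert fit.tau0 == pytest.approx(0.4 * 50 + 0.6 * 300, rel=0.05)
        assert fit.n1 + fit.n2 == pytest.approx(1.0)

    def test_constant_survival_rejected(self):
        with pytest.raises(InputError):
            fit_survival(np.arange(10.0), np.ones(10))


class TestLandauZener:
    def test_diabatic_limit(self):
        assert lz_adiabatic_fraction(0.0, 0.4) == 0.0

    def test_adiabatic_limit(self):
        assert lz_adiabatic_fraction(0.1, 1e-9) == pytest.approx(1.0)

    def test_direct_evaluation(self):
        chi = lz_adiabatic_fraction(0.1, 0.4)
        assert chi == pytest.approx(
            1.0 - math.exp(-2 * math.pi * 0.01 / (HBAR * 0.4)), rel=1e-12
        )
        assert chi == pytest.approx(2.470e-3, rel=1e-3)

    def test_nonpositive_speed_rejected(self):
        with pytest.raises(InputError):
            lz_adiabatic_fraction(0.1, 0.0)


class TestOmega:
    def test_partial_poisson_sum(self):
        xi2 = fc_series(0.5, tol=1e-12)
        assert omega(xi2, 2) == pytest.approx(math.exp(-0.5) * 1.5, rel=1e-9)

    def test_single_surface_is_ground_overlap(self):
        xi2 = fc_series(1.2, tol=1e-12)
        assert omega(xi2, 1) == pytest.approx(xi2[0])

    def test_complete_coverage_is_unity(self):
        xi2 = fc_series(0.8, tol=1e-14)
        assert omega(xi2, xi2.size) == pytest.approx(1.0, abs=1e-10)


class TestTransmission:
    def test_fully_adiabatic_events(self):
        events = [CrossingEvent(1.0, 1.0, chi_e=1.0, omega=0.7)] * 5
        a, _ = transmission_explicit(events, n_boot=10, seed=0)
        assert a == pytest.approx(1.0)

    def test_omega_one_reduces_to_mean_chi(self):
        chis = [0.2, 0.5, 0.9]
        events = [CrossingEvent(1.0, 1.0, chi_e=c, omega=1.0) for c in chis]
        a, _ = transmission_explicit(events, n_boot=10, seed=0)
        assert a == pytest.approx(np.mean(chis))

    def test_hand_averaged_two_events(self):
        events = [
            CrossingEvent(1.0, 1.0, chi_e=0.5, omega=1.0),
            CrossingEvent(2.0, 1.0, chi_e=0.5, omega=0.5),
        ]
        a, se = transmission_explicit(events, n_boot=200, seed=1)
        assert a == pytest.approx(1.0 - (0.5 + 0.5**0.5) / 2.0, rel=1e-9)
        assert se >= 0.0

    def test_approx_identities_and_value(self):
        assert transmission_approx(0.3, 1.0) == pytest.approx(0.3)
        assert transmission_approx(1.0, 0.4) == pytest.approx(1.0)
        assert transmission_approx(0.3, 0.5) == pytest.approx(1 - 0.7**0.5, rel=1e-9)

    def test_explicit_equals_approx_for_degenerate_events(self):
        events = [CrossingEvent(1.0, 1.0, chi_e=0.37, omega=0.62)] * 8
        a_exp, _ = transmission_explicit(events, n_boot=10, seed=0)
        assert a_exp == pytest.approx(transmission_approx(0.37, 0.62), rel=1e-12)

    @given(a=st.floats(0.01, 0.99), w=st.floats(0.05, 1.0))
    @settings(max_examples=40, deadline=None)
    def test_transmission_monotone_and_bounded(self, a, w):
        g = transmission_approx(a, w)
        assert 0.0 < g <= 1.0
        assert transmission_approx(min(a + 0.01, 1.0), w) >= g
        assert transmission_approx(a, min(w + 0.01, 1.0)) >= g


class TestGaussianRate:
    @pytest.mark.parametrize(
        "mean,sigma,speed,tau_printed",
        [(3.62, 7.1, 0.4, 105.0), (13.15, 6.5, 0.4, 614.0)],
    )
    def test_reactant_statistics_reproduce_attempt_lifetimes(
        self, mean, sigma, speed, tau_printed
    ):
        est = gaussian_rate(GapStatistics(mean, sigma, speed))
        assert est.tau0 == pytest.approx(tau_printed, rel=0.05)

    def test_equals_rice_formula_for_gaussian_velocity(self):
        mu, sig, sig_v = 5.0, 7.0, 0.6
        est = gaussian_rate(GapStatistics(mu, sig, sig_v * math.sqrt(2 / math.pi)))
        rice = sig_v / (2 * math.pi * sig) * math.exp(-(mu**2) / (2 * sig**2))
        assert 1.0 / est.tau0 == pytest.approx(rice, rel=1e-12)

    def test_langevin_surrogate_crossing_rate(self):
        # empirical downcrossing rate of the stationary surrogate vs k0
        spec = GapProcessSpec(mean=7.1, sigma=7.1, duration=40_000.0, seed=9)
        traces = gen_gap_ensemble(spec, 8)
        emp = np.mean([crossing_rate(tr) for tr in traces])
        k0 = 1.0 / gaussian_rate(GapStatistics.from_trace(traces[0])).tau0
        assert emp == pytest.approx(k0, rel=0.10)

    def test_invalid_statistics_rejected(self):
        with pytest.raises(InputError):
            GapStatistics(3.0, -1.0, 0.4)
        with pytest.raises(InputError):
            gaussian_rate(GapStatistics(-3.0, 7.0, 0.4))


class TestMeanCoupling:
    def test_geometric_null(self):
        geom = CouplingGeometry(
            delta_mu=[1.0, 0.0, 0.0],
            mean_transition_dipole=[0.0, 0.0, 0.03],
            delta_eps=10.0,
            e_perp_mean=5.0,
            e_perp_sq_mean=30.0,
            eta_perp_override=[0.0, 1.0, 0.0],
        )
        assert mean_coupling_alpha_e(geom, 0.4) == pytest.approx(0.0)

    def test_zero_variance_matches_single_coupling(self):
        e = 4.0
        geom = CouplingGeometry(
            delta_mu=[0.08, 0.0, 0.0],
            mean_transition_dipole=[0.02, 0.015, 0.0],
            delta_eps=1.0,
            e_perp_mean=e,
            e_perp_sq_mean=e**2,
        )
        h = abs(geom.e_par_crossing * 0.02 + 0.015 * e)
        assert mean_coupling_alpha_e(geom, 0.4) == pytest.approx(
            lz_adiabatic_fraction(h, 0.4), rel=1e-9
        )

    def test_brute_force_ensemble_oracle(self):
        # Gaussian E_perp ensemble, explicit LZ averaging vs the
        # equilibrium-statistics formula
        rng = np.random.default_rng(21)
        e_mean, e_std = 2.0, 1.5
        geom = CouplingGeometry(
            delta_mu=[0.08, 0.0, 0.0],
            mean_transition_dipole=[0.01, 0.02, 0.0],
            delta_eps=0.8,
            e_perp_mean=e_mean,
            e_perp_sq_mean=e_mean**2 + e_std**2,
        )
        speed = 0.4
        alpha = mean_coupling_alpha_e(geom, speed)
        e_perp = rng.normal(e_mean, e_std, size=200_000)
        h = -(geom.e_par_crossing * 0.01 + 0.02 * e_perp)
        brute = 1.0 - np.mean(np.exp(-2 * np.pi * h**2 / (HBAR * speed)))
        assert alpha == pytest.approx(brute, rel=0.10)

    def test_degenerate_dipole_difference_rejected(self):
        with pytest.raises(InputError):
            CouplingGeometry(
                delta_mu=[1e-12, 0, 0],
                mean_transition_dipole=[0.01, 0, 0],
                delta_eps=1.0,
                e_perp_mean=0.0,
                e_perp_sq_mean=1.0,
            )


class TestReactionLifetime:
    @pytest.mark.parametrize(
        "tau0,alpha_g,tau_printed",
        [(176.0, 0.295, 350.0), (1727.0, 0.422, 2593.0)],
    )
    def test_two_hop_combination_reproduces_lifetimes(self, tau0, alpha_g, tau_printed):
        assert reaction_lifetime(tau0, alpha_g) == pytest.approx(tau_printed, rel=0.02)

    def test_fully_adiabatic_limit(self):
        assert reaction_lifetime(105.0, 1.0) == pytest.approx(105.0)

    def test_zero_transmission_absent(self):
        assert reaction_lifetime(100.0, 0.0) is None

    @given(a=st.floats(0.01, 0.99))
    @settings(max_examples=40, deadline=None)
    def test_strictly_decreasing_in_transmission(self, a):
        t1 = reaction_lifetime(100.0, a)
        t2 = reaction_lifetime(100.0, min(a + 0.01, 1.0))
        assert t2 < t1
        assert t1 >= 100.0
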