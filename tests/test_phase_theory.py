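import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from delaycomm import phase_theory as pt
from delaycomm.errors import InvalidInputError, UndefinedCorrelationError


class TestCouplingCombinations:
    @settings(derandomize=True, max_examples=40)
    @given(
        st.floats(min_value=-np.pi, max_value=np.pi),
        st.floats(min_value=0.0, max_value=2 * np.pi),
    )
    def test_sinusoidal_gamma_identity(self, phi, delta):
        # Q = sin: Q(-phi-d) - Q(phi-d) = -2 sin(phi) cos(d)
        assert pt.gamma(phi, delta) == pytest.approx(
            -2.0 * np.sin(phi) * np.cos(delta), abs=1e-12
        )

    def test_symmetric_points(self):
        assert pt.gamma(0.0, 1.3) == pytest.approx(0.0, abs=1e-15)
        assert pt.lambda_fn(0.0, 0.0) == pytest.approx(0.0, abs=1e-15)


class TestLockedPhase:
    def test_symmetric_pair_locks_in_phase(self):
        assert pt.locked_phase(0.0, 4.0, 0.0) == pytest.approx(0.0, abs=1e-10)

    def test_closed_form_for_sinusoidal_coupling(self):
        phi = pt.locked_phase(2.0, 4.0, 0.0)
        assert phi == pytest.approx(np.arcsin(0.25), abs=1e-10)

    def test_outside_locking_returns_nan(self):
        assert np.isnan(pt.locked_phase(9.0, 4.0, 0.0))

    def test_returned_root_is_stable_for_inverted_coupling(self):
        # cos(delta) < 0 flips stability to the pi - arcsin branch
        delta = 2.5
        phi = pt.locked_phase(1.0, 4.0, delta)
        target = np.arcsin(1.0 / (8.0 * np.cos(delta)))
        assert phi == pytest.approx(np.pi - target, abs=1e-9) or \
            phi == pytest.approx(-np.pi - target, abs=1e-9)
        dgam = (pt.gamma(phi + 1e-7, delta) - pt.gamma(phi - 1e-7, delta)) / 2e-7
        assert dgam <= 0

    def test_boundary_width(self):
        K, delta = 4.0, 0.7
        edge = pt.locking_boundary_detuning(K, delta)
        assert not np.isnan(pt.locked_phase(0.99 * edge, K, delta))
        assert np.isnan(pt.locked_phase(1.01 * edge, K, delta))

    def test_antisymmetry_in_detuning(self):
        phi_p = pt.locked_phase(1.5, 4.0, 0.4)
        phi_m = pt.locked_phase(-1.5, 4.0, 0.4)
        assert phi_m == pytest.approx(-phi_p, abs=1e-10)


class TestNprcTheory:
    def test_zero_at_ineffective_pulse_phase(self):
        assert pt.nprc_theory(0.0, 1.0, 4.0, 0.5) == pytest.approx(0.0, abs=1e-9)

    def test_symmetric_zero_delay_maximum(self):
        assert pt.nprc_theory(np.pi / 2, 0.0, 4.0, 0.0) == pytest.approx(
            1.0, abs=1e-9
        )

    def test_matches_direct_perturbation(self):
        for D, d in [(1.0, 0.8), (-1.5, 0.5), (2.0, 5.9)]:
            th = pt.nprc_theory(2.1, D, 4.0, d)
            nm = pt.nprc_numeric(2.1, D, 4.0, d)
            assert nm == pytest.approx(th, rel=0.05)


class TestResponseFunction:
    def test_zero_detuning_is_unit_response(self):
        assert pt.response_function(0.0, 4.0, 0.9) == pytest.approx(1.0)
        assert pt.imbalance(0.0, 4.0, 0.9) == 0.0

    def test_closed_form_example(self):
        S = pt.response_function(2.0, 4.0, np.pi / 4)
        assert S == pytest.approx(1.0 + 2.0 / np.sqrt(28.0), rel=1e-12)
        assert pt.imbalance(2.0, 4.0, np.pi / 4) == pytest.approx(
            2.0 * 2.0 / np.sqrt(28.0), rel=1e-12
        )

    @settings(derandomize=True, max_examples=40)
    @given(
        st.floats(min_value=-3.0, max_value=3.0),
        st.floats(min_value=0.05, max_value=1.2),
    )
    def test_pair_sum_and_antisymmetry(self, Delta, delta):
        from hypothesis import assume

        # stay strictly inside the locking zone, away from the boundary
        assume(4 * 16.0 * np.cos(delta) ** 2 - Delta**2 > 0.25)
        Sp = pt.response_function(Delta, 4.0, delta)
        Sm = pt.response_function(-Delta, 4.0, delta)
        assert Sp + Sm == pytest.approx(2.0, rel=1e-12)
        assert pt.imbalance(-Delta, 4.0, delta) == pytest.approx(
            -pt.imbalance(Delta, 4.0, delta), rel=1e-12
        )

    def test_outside_locking_and_singular_delay_masked(self):
        assert np.isnan(pt.response_function(9.0, 4.0, 0.0))
        assert np.isnan(pt.response_function(0.5, 4.0, np.pi / 2))


class TestSimulatePair:
    def test_identical_oscillators_stay_on_invariant_manifold(self):
        p = pt.PhaseModelParams(omega1=100.0, omega2=100.0, delta=0.0)
        _, th1, th2 = pt.simulate_pair(p, 1.0, dt=1e-3)
        assert np.max(np.abs(th1 - th2)) < 1e-12

    def test_converges_to_locked_phase(self):
        D, K, d = 2.0, 4.0, 0.6
        p = pt.PhaseModelParams(omega1=100.0 + D / 2, omega2=100.0 - D / 2,
                                delta=d)
        _, th1, th2 = pt.simulate_pair(p, 6.0, dt=1e-4, theta0=(0.3, 0.0))
        phi_end = th1[-1] - th2[-1]
        assert phi_end == pytest.approx(pt.locked_phase(D, K, d), abs=1e-3)

    def test_drifts_outside_locking_zone(self):
        D, K, d = 9.0, 4.0, 0.0
        p = pt.PhaseModelParams(omega1=100.0 + D / 2, omega2=100.0 - D / 2,
                                delta=d)
        t, th1, th2 = pt.simulate_pair(p, 4.0, dt=1e-4)
        phi = th1 - th2
        drift = (phi[-1] - phi[len(phi) // 2]) / (t[-1] - t[len(t) // 2])
        assert abs(drift) > 1.0

    def test_collective_rate_identity(self):
        # locked noiseless pair: dTheta/dt = Omega + K * Lam(phi*, delta)
        D, K, d = 1.0, 4.0, 0.9
        p = pt.PhaseModelParams(omega1=120.0 + D / 2, omega2=120.0 - D / 2,
                                delta=d)
        t, th1, th2 = pt.simulate_pair(p, 6.0, dt=1e-4)
        half = len(t) // 2
        rate = ((th1[-1] + th2[-1]) - (th1[half] + th2[half])) / (
            t[-1] - t[half]
        )
        assert rate == pytest.approx(pt.collective_rate(p), rel=1e-4)

    def test_too_coarse_step_rejected(self):
        p = pt.PhaseModelParams(omega1=100.0, omega2=100.0)
        with pytest.raises(InvalidInputError):
            pt.simulate_pair(p, 1.0, dt=0.05)


class TestDichotomousSignal:
    def test_two_valued_and_zero_amplitude(self):
        sig = pt.dichotomous_signal(10.0, switch_rate=5.0, amplitude=0.7,
                                    seed=1)
        assert set(np.unique(sig)) == {-0.7, 0.7}
        assert not pt.dichotomous_signal(1.0, amplitude=0.0).any()

    def test_mean_holding_time_matches_rate(self):
        rate = 20.0
        sig = pt.dichotomous_signal(60.0, switch_rate=rate, amplitude=1.0,
                                    seed=2)
        flips = np.nonzero(np.diff(sig))[0]
        assert len(flips) > 200
        mean_hold = np.mean(np.diff(flips)) * 2e-4
        assert mean_hold == pytest.approx(1.0 / rate, rel=0.10)


class TestTransmissionCorrelation:
    def test_uncoupled_receiver_uncorrelated(self):
        sig = pt.dichotomous_signal(20.0, switch_rate=2.0, amplitude=1.0,
                                    seed=5)
        p = pt.PhaseModelParams(omega1=346.0, omega2=346.0, K12=0.0, K21=0.0)
        _, _, th2 = pt.simulate_pair(p, 20.0, dt=2e-4, signal=sig,
                                     noise_sigma=0.1, seed=6)
        assert abs(pt.transmission_correlation(th2, sig, 2e-4,
                                               smooth_sigma=0.1)) < 0.15

    def test_self_driven_oscillator_strongly_correlated(self):
        sig = pt.dichotomous_signal(20.0, switch_rate=2.0, amplitude=1.0,
                                    seed=5)
        p = pt.PhaseModelParams(omega1=346.0, omega2=346.0, K12=0.0, K21=0.0)
        _, th1, _ = pt.simulate_pair(p, 20.0, dt=2e-4, signal=sig,
                                     noise_sigma=0.1, seed=6)
        assert pt.transmission_correlation(th1, sig, 2e-4,
                                           smooth_sigma=0.1) > 0.8

    def test_zero_variance_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            pt.transmission_correlation(np.zeros(100), np.zeros(100), 1e-3)


class TestUnitConversion:
    def test_delay_phase_round_trip(self):
        tau = 7.0  # ms at 70 Hz is about half a cycle
        delta = pt.tau_to_delta(tau, 70.0)
        assert delta == pytest.approx(2 * np.pi * 0.49, rel=1e-12)
        assert pt.delta_to_tau(delta, 70.0) == pytest.approx(tau, rel=1e-12)
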