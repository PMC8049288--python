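"""Two delay-coupled phase oscillators: locking, transmission, response.

The reduced model for two oscillating populations coupled with an
interaction phase lag delta (the delay tau expressed as a phase,
delta = omega_locked * tau):

    dtheta1/dt = omega1 + K12 * Q(theta2 - theta1 - delta)
    dtheta2/dt = omega2 + K21 * Q(theta1 - theta2 - delta)

with Q the (collective) phase response function, canonically sin for
type-II oscillators.  In terms of the phase difference phi = theta1 -
theta2 and the collective phase Theta = theta1 + theta2 (equal couplings
K, equal Q):

    dTheta/dt = W + K * Lam(phi, delta),   Lam = Q(-phi-d) + Q(phi-d)
    dphi/dt   = Delta + K * Gam(phi, delta), Gam = Q(-phi-d) - Q(phi-d)

with W = omega1 + omega2 and Delta = omega1 - omega2.  Locked states phi*
solve Gam(phi*, delta) = -Delta/K, are stable when dGam/dphi <= 0, and
exist while -Delta/K lies between min and max of Gam.

Units: frequencies, couplings, detunings and noise amplitudes are all in
rad/s; durations and time steps in seconds.  ``hz_to_radps`` converts
ordinary frequencies.  Quantities returned by the closed-form maps
(phi*, S, Delta-S, transmission) are dimensionless/radians, so they do
not depend on the unit choice, only on Delta/K.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.optimize import brentq

from .errors import InvalidInputError, UndefinedCorrelationError

__all__ = [
    "PhaseModelParams",
    "TheoryMaps",
    "hz_to_radps",
    "tau_to_delta",
    "delta_to_tau",
    "gamma",
    "lambda_fn",
    "locked_phase",
    "locking_boundary_detuning",
    "nprc_theory",
    "transmission_magnitude",
    "response_function",
    "imbalance",
    "collective_rate",
    "theory_maps",
    "simulate_pair",
    "simulate_pair_grid",
    "dichotomous_signal",
    "transmission_correlation",
]

_DPHI = 1e-6  # step for numeric derivatives of Q


def hz_to_radps(f_hz: float) -> float:
    """Convert an ordinary frequency in Hz to angular frequency in rad/s."""
    return 2.0 * np.pi * f_hz


def tau_to_delta(tau_ms, f_locked_hz):
    """Interaction phase (rad) equivalent to a delay tau (ms) at the locked
    frequency: delta = omega_locked * tau."""
    return 2.0 * np.pi * np.asarray(f_locked_hz) * np.asarray(tau_ms) / 1000.0


def delta_to_tau(delta_rad, f_locked_hz):
    """Inverse of :func:`tau_to_delta`; returns the delay in ms."""
    return 1000.0 * np.asarray(delta_rad) / (2.0 * np.pi * np.asarray(f_locked_hz))


@dataclass(frozen=True)
class PhaseModelParams:
    """Parameters of the two-oscillator phase model (rad/s; delta in rad)."""

    omega1: float
    omega2: float
    K12: float = 4.0
    K21: float = 4.0
    delta: float = 0.0
    Q: Callable = np.sin

    def __post_init__(self) -> None:
        if self.K12 < 0 or self.K21 < 0:
            raise InvalidInputError("couplings must be >= 0")

    @property
    def Delta(self) -> float:
        return self.omega1 - self.omega2

    @property
    def Omega(self) -> float:
        return self.omega1 + self.omega2


def gamma(phi, delta, Q: Callable = np.sin):
    """Antisymmetric coupling combination Gam(phi, delta) = Q(-phi-delta) - Q(phi-delta)."""
    phi = np.asarray(phi, dtype=float)
    return Q(-phi - delta) - Q(phi - delta)


def lambda_fn(phi, delta, Q: Callable = np.sin):
    """Symmetric coupling combination Lam(phi, delta) = Q(-phi-delta) + Q(phi-delta)."""
    phi = np.asarray(phi, dtype=float)
    return Q(-phi - delta) + Q(phi - delta)


@dataclass
class LockedPhase:
    """A stable locked phase difference, or NaN outside the locking zone."""

    phi: float
    multistable: bool = False
    residual: float = np.nan


def locked_phase(
    Delta: float,
    K: float,
    delta: float,
    Q: Callable = np.sin,
    full: bool = False,
    n_scan: int = 2001,
):
    """Stable locked phase difference phi* solving Gam(phi*, delta) = -Delta/K.

    Roots are bracketed on a dense scan of (-pi, pi] and polished by Brent's
    method; only roots with dGam/dphi <= 0 (stable) are kept.  With several
    stable roots the one closest to 0 is returned and flagged multistable.
    Outside the locking zone (no root) the result is NaN - a signal, not an
    exception.  Set ``full=True`` for a :class:`LockedPhase` record.
    """
    if K <= 0:
        raise InvalidInputError("K must be positive")
    target = -Delta / K

    def f(phi: float) -> float:
        return float(gamma(phi, delta, Q)) - target

    grid = np.linspace(-np.pi, np.pi, n_scan)
    vals = np.array([f(p) for p in grid])
    roots = []
    for i in range(n_scan - 1):
        a, b = grid[i], grid[i + 1]
        fa, fb = vals[i], vals[i + 1]
        if fa == 0.0:
            roots.append(a)
        elif fa * fb < 0:
            roots.append(brentq(f, a, b, xtol=1e-13, rtol=8.9e-16))
    if vals[-1] == 0.0:
        roots.append(grid[-1])
    stable = []
    for r in roots:
        dgam = (gamma(r + _DPHI, delta, Q) - gamma(r - _DPHI, delta, Q)) / (2 * _DPHI)
        if dgam <= 0:
            stable.append(float(r))
    if not stable:
        out = LockedPhase(phi=np.nan)
        return out if full else out.phi
    phi = min(stable, key=abs)
    out = LockedPhase(phi=phi, multistable=len(stable) > 1, residual=abs(f(phi)))
    return out if full else out.phi


def locking_boundary_detuning(K: float, delta: float) -> float:
    """Half-width |Delta| of the sinusoidal locking zone: 2 K |cos delta|."""
    return 2.0 * K * abs(np.cos(delta))


def _q_prime(Q: Callable, x: float) -> float:
    return (Q(x + _DPHI) - Q(x - _DPHI)) / (2 * _DPHI)


def nprc_theory(
    beta, Delta: float, K: float, delta: float, Q: Callable = np.sin
):
    """Predicted receiver phase shift Q21(beta, delta) = Q(beta) * Q'(phi* - delta).

    Q(beta) is the sender's own response to a pulse at phase beta; the
    factor Q'(phi* - delta) is the sensitivity of the receiver to the
    resulting timing change of the incoming volleys.  NaN outside locking.
    """
    phi = locked_phase(Delta, K, delta, Q)
    if np.isnan(phi):
        return np.nan if np.ndim(beta) == 0 else np.full(np.shape(beta), np.nan)
    qp = _q_prime(Q, phi - delta)
    return Q(np.asarray(beta, dtype=float)) * qp


def nprc_numeric(
    beta: float,
    Delta: float,
    K: float,
    delta: float,
    Q: Callable = np.sin,
    eps: float = 0.01,
    omega_mean: float = 100.0,
    dt: float = 1e-5,
) -> float:
    """Direct perturbation measurement of the non-local PRC.

    Starting from the locked state, the sender's phase is kicked by
    eps * Q(beta) (the sender's own response to a pulse at phase beta) and
    the receiver's displacement over a short horizon h << 1/K, normalised
    by eps*K*h, estimates Q21(beta, delta).  Independent of the closed
    form: only the integrator and the locked phase are used.  NaN outside
    locking.
    """
    phi = locked_phase(Delta, K, delta, Q)
    if np.isnan(phi):
        return np.nan
    horizon = 0.02 / K
    w1 = omega_mean + Delta / 2.0
    w2 = omega_mean - Delta / 2.0
    params = PhaseModelParams(omega1=w1, omega2=w2, K12=K, K21=K,
                              delta=delta, Q=Q)
    kick = eps * Q(beta)
    _, _, th2_base = simulate_pair(params, horizon, dt=dt,
                                   theta0=(phi, 0.0))
    _, _, th2_kick = simulate_pair(params, horizon, dt=dt,
                                   theta0=(phi + kick, 0.0))
    h_eff = horizon - dt  # displacement accrued between the first samples
    return float((th2_kick[-1] - th2_base[-1]) / (eps * K * h_eff))


def transmission_magnitude(Delta: float, K: float, delta: float, Q: Callable = np.sin):
    """|Q'(phi* - delta)|: the pulse-transmission gain; NaN outside locking."""
    phi = locked_phase(Delta, K, delta, Q)
    if np.isnan(phi):
        return np.nan
    return abs(_q_prime(Q, phi - delta))


def response_function(Delta: float, K: float, delta: float) -> float:
    """Slow-signal response S = 1 + Delta*tan(delta)/sqrt(4K^2cos^2(delta)-Delta^2).

    Sensitivity of the collective phase rate to the sender's natural
    frequency, for sinusoidal Q.  S > 1 means the slow signal injected into
    oscillator 1 is amplified into the pair's collective rhythm; S - 1
    measures the directional gain.  NaN outside (or on the boundary of) the
    locking zone and at the singular delay cos(delta) = 0.
    """
    c = np.cos(delta)
    disc = 4.0 * K**2 * c**2 - Delta**2
    if disc <= 0 or abs(c) < 1e-12:
        return np.nan
    return float(1.0 + Delta * np.tan(delta) / np.sqrt(disc))


def imbalance(Delta: float, K: float, delta: float) -> float:
    """Transmission imbalance dS = S(Delta) - S(-Delta) =
    2*Delta*tan(delta)/sqrt(4K^2cos^2(delta)-Delta^2); NaN outside locking."""
    c = np.cos(delta)
    disc = 4.0 * K**2 * c**2 - Delta**2
    if disc <= 0 or abs(c) < 1e-12:
        return np.nan
    return float(2.0 * Delta * np.tan(delta) / np.sqrt(disc))


def collective_rate(params: PhaseModelParams) -> float:
    """Locked collective phase rate dTheta/dt = Omega + K*Lam(phi*, delta).

    Valid for equal couplings; NaN outside locking."""
    K = params.K12
    phi = locked_phase(params.Delta, K, params.delta, params.Q)
    if np.isnan(phi):
        return np.nan
    return float(params.Omega + K * lambda_fn(phi, params.delta, params.Q))


@dataclass
class TheoryMaps:
    """Closed-form prediction surfaces over a (Delta, delta) grid."""

    Delta_grid: np.ndarray
    delta_grid: np.ndarray
    phi_star: np.ndarray       # (nDelta, ndelta), NaN outside locking
    transmission: np.ndarray   # |Q'(phi* - delta)|
    S: np.ndarray              # slow-signal response function
    dS: np.ndarray             # imbalance S(Delta) - S(-Delta)
    K: float = 4.0


def theory_maps(
    Delta_grid, delta_grid, K: float = 4.0, Q: Callable = np.sin
) -> TheoryMaps:
    """Evaluate phi*, pulse transmission, S and the imbalance on a grid.

    S and dS use the sinusoidal closed forms and are only filled when Q is
    ``np.sin``; for other Q they are NaN (phi* and transmission remain
    general)."""
    Dg = np.asarray(Delta_grid, dtype=float)
    dg = np.asarray(delta_grid, dtype=float)
    shape = (len(Dg), len(dg))
    phi = np.full(shape, np.nan)
    trans = np.full(shape, np.nan)
    S = np.full(shape, np.nan)
    dS = np.full(shape, np.nan)
    sinusoidal = Q is np.sin
    for i, D in enumerate(Dg):
        for j, d in enumerate(dg):
            p = locked_phase(D, K, d, Q)
            phi[i, j] = p
            if not np.isnan(p):
                trans[i, j] = abs(_q_prime(Q, p - d))
            if sinusoidal:
                S[i, j] = response_function(D, K, d)
                dS[i, j] = imbalance(D, K, d)
    return TheoryMaps(Delta_grid=Dg, delta_grid=dg, phi_star=phi,
                      transmission=trans, S=S, dS=dS, K=K)


def simulate_pair(
    params: PhaseModelParams,
    duration: float,
    dt: float = 2e-4,
    signal: np.ndarray | None = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
    theta0: tuple[float, float] = (0.0, 0.0),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Euler-Maruyama integration of the two-oscillator model.

    `signal` (rad/s, on the dt grid) perturbs the *sender* oscillator 1's
    natural frequency additively; independent Gaussian white noise of
    amplitude `noise_sigma` (rad/s^(1/2) scaling: sigma*sqrt(dt) per step)
    is added to both phases.  Returns (t, theta1, theta2) with t in
    seconds.  Requires K*dt < 0.1 for accuracy.
    """
    if duration <= 0 or dt <= 0:
        raise InvalidInputError("duration and dt must be positive")
    if max(params.K12, params.K21) * dt >= 0.1:
        raise InvalidInputError("dt too large: require K*dt < 0.1")
    n = int(round(duration / dt))
    if signal is not None and len(signal) != n:
        raise InvalidInputError("signal length must equal duration/dt")
    rng = np.random.default_rng(seed)
    Q, d = params.Q, params.delta
    th1 = np.empty(n)
    th2 = np.empty(n)
    x1, x2 = float(theta0[0]), float(theta0[1])
    sq = noise_sigma * np.sqrt(dt)
    for k in range(n):
        s = signal[k] if signal is not None else 0.0
        d1 = params.omega1 + s + params.K12 * Q(x2 - x1 - d)
        d2 = params.omega2 + params.K21 * Q(x1 - x2 - d)
        x1 += dt * d1
        x2 += dt * d2
        if noise_sigma > 0:
            x1 += sq * rng.standard_normal()
            x2 += sq * rng.standard_normal()
        th1[k] = x1
        th2[k] = x2
    t = np.arange(n) * dt
    return t, th1, th2


def simulate_pair_grid(
    Delta_grid,
    delta_grid,
    omega_mean: float,
    K: float,
    duration: float,
    dt: float = 2e-4,
    signal: np.ndarray | None = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
    signal_to: int = 1,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised sinusoidal-Q pair simulation over a (Delta, delta) grid.

    All cells share the injected `signal` (on oscillator `signal_to`, 1 or
    2) but draw independent noise.  Returns (t, theta1, theta2) with
    trailing shape (nDelta, ndelta).  Runs differing only in the injected
    signal reuse identical noise streams for a given seed, enabling paired
    (noise-cancelling) comparisons of the two injection directions.  Used
    by the sweep layer where per-cell python loops would dominate runtime.
    """
    if signal_to not in (1, 2):
        raise InvalidInputError("signal_to must be 1 or 2")
    Dg = np.asarray(Delta_grid, dtype=float)[:, None]
    dg = np.asarray(delta_grid, dtype=float)[None, :]
    shape = (len(Delta_grid), dg.shape[1])
    n = int(round(duration / dt))
    rng = np.random.default_rng(seed)
    w1 = omega_mean + Dg / 2.0 + np.zeros(shape)
    w2 = omega_mean - Dg / 2.0 + np.zeros(shape)
    x1 = np.zeros(shape)
    x2 = np.zeros(shape)
    th1 = np.empty((n,) + shape)
    th2 = np.empty((n,) + shape)
    sq = noise_sigma * np.sqrt(dt)
    for k in range(n):
        s = signal[k] if signal is not None else 0.0
        s1 = s if signal_to == 1 else 0.0
        s2 = s if signal_to == 2 else 0.0
        d1 = w1 + s1 + K * np.sin(x2 - x1 - dg)
        d2 = w2 + s2 + K * np.sin(x1 - x2 - dg)
        x1 = x1 + dt * d1
        x2 = x2 + dt * d2
        if noise_sigma > 0:
            x1 = x1 + sq * rng.standard_normal(shape)
            x2 = x2 + sq * rng.standard_normal(shape)
        th1[k] = x1
        th2[k] = x2
    t = np.arange(n) * dt
    return t, th1, th2


def dichotomous_signal(
    duration: float,
    switch_rate: float = 10.0,
    amplitude: float = 1.0,
    seed: int = 0,
    dt: float = 2e-4,
) -> np.ndarray:
    """Telegraph signal: +-amplitude with exponential holding times.

    `switch_rate` is the expected number of state switches per second
    (mean holding time 1/switch_rate).
    """
    if switch_rate <= 0:
        raise InvalidInputError("switch_rate must be positive")
    n = int(round(duration / dt))
    if amplitude == 0:
        return np.zeros(n)
    rng = np.random.default_rng(seed)
    out = np.empty(n)
    state = amplitude if rng.random() < 0.5 else -amplitude
    k = 0
    while k < n:
        hold = rng.exponential(1.0 / switch_rate)
        k2 = min(k + max(int(round(hold / dt)), 1), n)
        out[k:k2] = state
        state = -state
        k = k2
    return out


def transmission_correlation(
    theta_receiver: np.ndarray,
    signal: np.ndarray,
    dt: float,
    smooth_sigma: float = 0.01,
) -> float:
    """Pearson correlation between the smoothed receiver phase rate and the
    injected signal.

    The receiver's instantaneous rate dtheta/dt is Gaussian-smoothed with
    SD `smooth_sigma` seconds before correlating, to suppress the carrier
    oscillation and integrator noise.
    """
    from scipy.ndimage import gaussian_filter1d

    theta = np.asarray(theta_receiver, dtype=float)
    sig = np.asarray(signal, dtype=float)
    if theta.shape != sig.shape:
        raise InvalidInputError("phase trace and signal must share a grid")
    rate = np.gradient(theta, dt)
    rate_s = gaussian_filter1d(rate, smooth_sigma / dt)
    if np.std(rate_s) == 0 or np.std(sig) == 0:
        raise UndefinedCorrelationError("zero-variance input")
    return float(np.corrcoef(rate_s, sig)[0, 1])
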