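"""Hodgkin-Huxley single-neuron dynamics and the double-exponential synapse.

The classic squid-axon HH model (voltages in mV, times in ms, currents in
uA/cm^2, conductances in mS/cm^2) with the standard rate functions whose
removable singularities (alpha_n at v = -55 mV, alpha_m at v = -40 mV) are
evaluated by their analytic limits.  Synaptic efficacy is a rise/decay
double exponential normalised to unit peak, so synaptic weights are peak
conductances.

The stochastic integrator is Euler-Maruyama with additive Gaussian white
noise on the voltage equation only; for additive noise the Milstein
correction term vanishes, so this *is* the Milstein scheme for this model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .errors import InvalidInputError

__all__ = [
    "NeuronParams",
    "NeuronState",
    "SynapseParams",
    "gating_rates",
    "gating_steady_state",
    "hh_derivatives",
    "resting_state",
    "synaptic_kernel",
    "kernel_peak_time",
    "kernel_peak_value",
    "integrate_step",
    "simulate_neuron",
    "SPIKE_THRESHOLD_MV",
    "SPIKE_REFRACTORY_MS",
]

#: Upward crossing of this voltage registers a spike.
SPIKE_THRESHOLD_MV = 0.0
#: Lockout after a registered spike, so one action potential = one event.
SPIKE_REFRACTORY_MS = 2.0


@dataclass(frozen=True)
class NeuronParams:
    """Membrane parameters (defaults: standard values for this model)."""

    C: float = 1.0       # membrane capacitance, uF/cm^2
    gK: float = 36.0     # max K conductance, mS/cm^2
    gNa: float = 120.0   # max Na conductance, mS/cm^2
    gL: float = 0.3      # leak conductance, mS/cm^2
    EK: float = -77.0    # K reversal, mV
    ENa: float = 50.0    # Na reversal, mV
    EL: float = -54.4    # leak reversal, mV

    def __post_init__(self) -> None:
        if min(self.gK, self.gNa, self.gL, self.C) <= 0:
            raise InvalidInputError("conductances and capacitance must be positive")
        if not (self.EK < self.EL < self.ENa):
            raise InvalidInputError("expected EK < EL < ENa")


@dataclass
class NeuronState:
    """Membrane potential (mV) and the three gating variables."""

    v: float
    n: float
    m: float
    h: float

    def __post_init__(self) -> None:
        for name in ("n", "m", "h"):
            x = getattr(self, name)
            if not 0.0 <= x <= 1.0:
                raise InvalidInputError(f"gating variable {name}={x} outside [0, 1]")
        if not np.isfinite(self.v):
            raise InvalidInputError("non-finite membrane potential")


@dataclass(frozen=True)
class SynapseParams:
    """Double-exponential synapse: rise/decay times, reversal, peak weight, delay."""

    tau_r: float = 0.5    # rise time, ms
    tau_d: float = 3.0    # decay time, ms
    E_syn: float = 0.0    # reversal potential, mV
    g: float = 3.75       # peak conductance, uS/cm^2
    t_delay: float = 0.5  # axonal delay, ms

    def __post_init__(self) -> None:
        if not 0.0 < self.tau_r < self.tau_d:
            raise InvalidInputError("require 0 < tau_r < tau_d")
        if self.t_delay < 0:
            raise InvalidInputError("t_delay must be >= 0")


def gating_rates(v):
    """Voltage-dependent opening/closing rates (ms^-1).

    Parameters
    ----------
    v : float or ndarray
        Membrane potential in mV.

    Returns
    -------
    tuple
        ``(alpha_n, beta_n, alpha_m, beta_m, alpha_h, beta_h)``, each with
        the shape of `v`.
    """
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise InvalidInputError("membrane potential must be finite")

    def _ratefn(f):
        return np.vectorize(f, otypes=[float])

    if v.ndim == 0:
        out = (
            _kernels.alpha_n(float(v)),
            _kernels.beta_n(float(v)),
            _kernels.alpha_m(float(v)),
            _kernels.beta_m(float(v)),
            _kernels.alpha_h(float(v)),
            _kernels.beta_h(float(v)),
        )
        return out
    return (
        _ratefn(_kernels.alpha_n)(v),
        _ratefn(_kernels.beta_n)(v),
        _ratefn(_kernels.alpha_m)(v),
        _ratefn(_kernels.beta_m)(v),
        _ratefn(_kernels.alpha_h)(v),
        _ratefn(_kernels.beta_h)(v),
    )


def gating_steady_state(v: float) -> tuple[float, float, float]:
    """Steady-state gating values (n_inf, m_inf, h_inf) at clamped voltage."""
    an, bn, am, bm, ah, bh = gating_rates(v)
    return an / (an + bn), am / (am + bm), ah / (ah + bh)


def hh_derivatives(
    state: NeuronState, I_total: float, params: NeuronParams = NeuronParams()
) -> tuple[float, float, float, float]:
    """Time derivatives (dv/dt, dn/dt, dm/dt, dh/dt) of the HH equations.

    `I_total` is the sum of injected and synaptic currents in uA/cm^2.
    Pure function of its inputs.
    """
    if not np.isfinite(I_total):
        raise InvalidInputError("current must be finite")
    v, n, m, h = state.v, state.n, state.m, state.h
    an, bn, am, bm, ah, bh = gating_rates(v)
    dv = (
        I_total
        - params.gK * n**4 * (v - params.EK)
        - params.gNa * m**3 * h * (v - params.ENa)
        - params.gL * (v - params.EL)
    ) / params.C
    dn = an * (1.0 - n) - bn * n
    dm = am * (1.0 - m) - bm * m
    dh = ah * (1.0 - h) - bh * h
    return dv, dn, dm, dh


def resting_state(params: NeuronParams = NeuronParams()) -> NeuronState:
    """Resting fixed point at zero current, located by root-finding on dv/dt.

    Gating variables are at steady state for the returned voltage.
    """
    from scipy.optimize import brentq

    def f(v: float) -> float:
        n_inf, m_inf, h_inf = gating_steady_state(v)
        return (
            -params.gK * n_inf**4 * (v - params.EK)
            - params.gNa * m_inf**3 * h_inf * (v - params.ENa)
            - params.gL * (v - params.EL)
        )

    v_rest = brentq(f, -80.0, -50.0, xtol=1e-12)
    n_inf, m_inf, h_inf = gating_steady_state(v_rest)
    return NeuronState(v=v_rest, n=n_inf, m=m_inf, h=h_inf)


def kernel_peak_time(tau_r: float, tau_d: float) -> float:
    """Time (ms) at which the raw double exponential peaks."""
    return tau_r * tau_d / (tau_d - tau_r) * np.log(tau_d / tau_r)


def kernel_peak_value(tau_r: float, tau_d: float) -> float:
    """Peak of exp(-t/tau_d) - exp(-t/tau_r); the normalisation constant."""
    tp = kernel_peak_time(tau_r, tau_d)
    return np.exp(-tp / tau_d) - np.exp(-tp / tau_r)


def synaptic_kernel(t_since_spike, p: SynapseParams = SynapseParams()):
    """Unit-peak synaptic efficacy S(t) at time `t_since_spike` (ms) after arrival.

    S(0) = 0, S rises with time constant ``tau_r``, decays with ``tau_d``,
    and max_t S(t) = 1 exactly.  Negative times (before arrival) give 0.
    """
    t = np.asarray(t_since_spike, dtype=float)
    norm = kernel_peak_value(p.tau_r, p.tau_d)
    s = (np.exp(-t / p.tau_d) - np.exp(-t / p.tau_r)) / norm
    return np.where(t < 0.0, 0.0, s)


def integrate_step(
    state: NeuronState,
    I_ext: float,
    I_syn: float,
    noise_sigma: float,
    dt: float,
    rng: np.random.Generator,
    params: NeuronParams = NeuronParams(),
) -> NeuronState:
    """One Euler-Maruyama step.

    Additive Gaussian white-noise current (SD `noise_sigma`, uA/cm^2) enters
    the voltage equation as ``sigma * sqrt(dt) * xi / C``; gating variables
    are advanced deterministically and clipped to [0, 1].  With
    ``noise_sigma=0`` the step is deterministic.
    """
    if dt <= 0:
        raise InvalidInputError("dt must be positive")
    dv, dn, dm, dh = hh_derivatives(state, I_ext + I_syn, params)
    v = state.v + dt * dv
    if noise_sigma > 0:
        v += noise_sigma * np.sqrt(dt) * rng.standard_normal() / params.C
    clip = lambda x: float(min(max(x, 0.0), 1.0))  # noqa: E731
    return NeuronState(
        v=v,
        n=clip(state.n + dt * dn),
        m=clip(state.m + dt * dm),
        h=clip(state.h + dt * dh),
    )


def simulate_neuron(
    I_ext,
    duration: float,
    dt: float = 0.01,
    noise_sigma: float = 0.0,
    seed: int = 0,
    params: NeuronParams = NeuronParams(),
    state0: NeuronState | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate a single neuron; returns (t, v, spike_times) in ms.

    `I_ext` may be a scalar (constant drive) or an array sampled on the dt
    grid.  Spikes are upward crossings of 0 mV with a 2 ms lockout.
    """
    if dt <= 0 or duration <= 0:
        raise InvalidInputError("dt and duration must be positive")
    n_steps = int(round(duration / dt))
    i_ext = np.broadcast_to(np.asarray(I_ext, dtype=float), (n_steps,)) \
        if np.ndim(I_ext) == 0 else np.asarray(I_ext, dtype=float)
    if i_ext.shape[0] != n_steps:
        raise InvalidInputError("I_ext array length must match duration/dt")
    s0 = state0 if state0 is not None else resting_state(params)
    v_trace, spike_steps = _kernels.single_neuron_kernel(
        n_steps, dt, s0.v, s0.n, s0.m, s0.h, np.ascontiguousarray(i_ext),
        noise_sigma, seed, params.C, params.gK, params.gNa, params.gL,
        params.EK, params.ENa, params.EL,
        SPIKE_THRESHOLD_MV, SPIKE_REFRACTORY_MS,
    )
    t = np.arange(n_steps) * dt
    return t, v_trace, spike_steps * dt
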