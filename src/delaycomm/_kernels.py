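"""Numba-compiled inner loops for the Hodgkin-Huxley simulators.

Everything in here is a plain-number/ndarray function so it can be jitted;
the public, validated API lives in :mod:`delaycomm.hh` and
:mod:`delaycomm.netsim`.  All voltages are mV, times ms, currents uA/cm^2,
conductances mS/cm^2.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Branch to the analytic limit this close to a removable singularity.
_SING_EPS = 1e-7


@njit(cache=True, inline="always")
def alpha_n(v: float) -> float:
    x = v + 55.0
    if abs(x) < _SING_EPS:
        return 0.1
    return 0.01 * x / (1.0 - np.exp(-0.1 * x))


@njit(cache=True, inline="always")
def beta_n(v: float) -> float:
    return 0.125 * np.exp(-0.0125 * (v + 65.0))


@njit(cache=True, inline="always")
def alpha_m(v: float) -> float:
    x = v + 40.0
    if abs(x) < _SING_EPS:
        return 1.0
    return 0.1 * x / (1.0 - np.exp(-0.1 * x))


@njit(cache=True, inline="always")
def beta_m(v: float) -> float:
    return 4.0 * np.exp(-0.0556 * (v + 65.0))


@njit(cache=True, inline="always")
def alpha_h(v: float) -> float:
    return 0.07 * np.exp(-0.05 * (v + 65.0))


@njit(cache=True, inline="always")
def beta_h(v: float) -> float:
    return 1.0 / (1.0 + np.exp(-0.1 * (v + 35.0)))


@njit(cache=True)
def single_neuron_kernel(
    n_steps: int,
    dt: float,
    v0: float,
    n0: float,
    m0: float,
    h0: float,
    i_ext: np.ndarray,  # (n_steps,) injected current
    noise_sigma: float,
    seed: int,
    C: float,
    gK: float,
    gNa: float,
    gL: float,
    EK: float,
    ENa: float,
    EL: float,
    spike_thresh: float,
    refrac_ms: float,
):
    """Euler-Maruyama integration of one HH neuron; returns (v_trace, spike_times)."""
    np.random.seed(seed)
    sqrt_dt = np.sqrt(dt)
    refrac_steps = int(refrac_ms / dt)
    v = v0
    n = n0
    m = m0
    h = h0
    v_trace = np.empty(n_steps)
    spike_steps = np.empty(n_steps, dtype=np.int64)
    n_spikes = 0
    last_spike = -refrac_steps - 1
    for t in range(n_steps):
        dv = (
            i_ext[t]
            - gK * n**4 * (v - EK)
            - gNa * m**3 * h * (v - ENa)
            - gL * (v - EL)
        ) / C
        v_new = v + dt * dv
        if noise_sigma > 0.0:
            v_new += noise_sigma * sqrt_dt * np.random.standard_normal() / C
        an = alpha_n(v)
        bn = beta_n(v)
        am = alpha_m(v)
        bm = beta_m(v)
        ah = alpha_h(v)
        bh = beta_h(v)
        n = min(max(n + dt * (an * (1.0 - n) - bn * n), 0.0), 1.0)
        m = min(max(m + dt * (am * (1.0 - m) - bm * m), 0.0), 1.0)
        h = min(max(h + dt * (ah * (1.0 - h) - bh * h), 0.0), 1.0)
        if v < spike_thresh <= v_new and t - last_spike > refrac_steps:
            spike_steps[n_spikes] = t
            n_spikes += 1
            last_spike = t
        v = v_new
        v_trace[t] = v
    return v_trace, spike_steps[:n_spikes]


@njit(cache=True)
def network_kernel(
    n_steps: int,
    dt: float,
    v: np.ndarray,  # (N,) initial membrane potentials, modified in place
    n: np.ndarray,
    m: np.ndarray,
    h: np.ndarray,
    is_exc: np.ndarray,  # (N,) bool
    i0: np.ndarray,  # (N,) constant drive
    noise_sigma: np.ndarray,  # (N,)
    indptr: np.ndarray,  # CSR by presynaptic neuron
    targets: np.ndarray,
    weights: np.ndarray,  # peak conductances, mS/cm^2
    delay_steps: np.ndarray,
    sig1: np.ndarray,  # (n_steps,) or (0,): current added where sig1_mask
    sig1_mask: np.ndarray,  # (N,) bool
    sig2: np.ndarray,
    sig2_mask: np.ndarray,
    tau_r: float,
    tau_d: float,
    kern_norm: float,  # peak of exp(-t/tau_d)-exp(-t/tau_r)
    E_exc: float,
    E_inh: float,
    C: float,
    gK: float,
    gNa: float,
    gL: float,
    EK: float,
    ENa: float,
    EL: float,
    spike_thresh: float,
    refrac_ms: float,
    seed: int,
    max_spikes: int,
):
    """Integrate a delayed-synapse HH network.

    Synaptic conductances are tracked with two exponential accumulators per
    neuron and transmitter class (decay / rise); a spike arriving after its
    axonal delay increments both, so the conductance (a_d - a_r)/kern_norm
    rises from zero and follows the unit-peak double-exponential exactly.
    Returns (spike_step_array, spike_id_array, n_spikes, n_gate_clips).
    """
    np.random.seed(seed)
    N = v.shape[0]
    sqrt_dt = np.sqrt(dt)
    refrac_steps = int(refrac_ms / dt)
    dec_d = np.exp(-dt / tau_d)
    dec_r = np.exp(-dt / tau_r)
    L = 1
    for e in range(delay_steps.shape[0]):
        if delay_steps[e] + 1 > L:
            L = delay_steps[e] + 1
    buf_e = np.zeros((L, N))
    buf_i = np.zeros((L, N))
    a_ed = np.zeros(N)
    a_er = np.zeros(N)
    a_id = np.zeros(N)
    a_ir = np.zeros(N)
    last_spike = np.full(N, -refrac_steps - 1, dtype=np.int64)
    spike_steps = np.empty(max_spikes, dtype=np.int64)
    spike_ids = np.empty(max_spikes, dtype=np.int64)
    n_spikes = 0
    n_clips = 0
    inv_norm = 1.0 / kern_norm
    has_sig1 = sig1.shape[0] == n_steps
    has_sig2 = sig2.shape[0] == n_steps

    for t in range(n_steps):
        slot = t % L
        for i in range(N):
            w_e = buf_e[slot, i]
            if w_e != 0.0:
                a_ed[i] += w_e
                a_er[i] += w_e
                buf_e[slot, i] = 0.0
            w_i = buf_i[slot, i]
            if w_i != 0.0:
                a_id[i] += w_i
                a_ir[i] += w_i
                buf_i[slot, i] = 0.0

        for i in range(N):
            g_e = (a_ed[i] - a_er[i]) * inv_norm
            g_i = (a_id[i] - a_ir[i]) * inv_norm
            i_syn = g_e * (E_exc - v[i]) + g_i * (E_inh - v[i])
            i_ext = i0[i]
            if has_sig1 and sig1_mask[i]:
                i_ext += sig1[t]
            if has_sig2 and sig2_mask[i]:
                i_ext += sig2[t]
            vi = v[i]
            dv = (
                i_ext
                + i_syn
                - gK * n[i] ** 4 * (vi - EK)
                - gNa * m[i] ** 3 * h[i] * (vi - ENa)
                - gL * (vi - EL)
            ) / C
            v_new = vi + dt * dv
            if noise_sigma[i] > 0.0:
                v_new += noise_sigma[i] * sqrt_dt * np.random.standard_normal() / C

            an = alpha_n(vi)
            bn = beta_n(vi)
            am = alpha_m(vi)
            bm = beta_m(vi)
            ah = alpha_h(vi)
            bh = beta_h(vi)
            ni = n[i] + dt * (an * (1.0 - n[i]) - bn * n[i])
            mi = m[i] + dt * (am * (1.0 - m[i]) - bm * m[i])
            hi = h[i] + dt * (ah * (1.0 - h[i]) - bh * h[i])
            if ni < 0.0 or ni > 1.0 or mi < 0.0 or mi > 1.0 or hi < 0.0 or hi > 1.0:
                n_clips += 1
            n[i] = min(max(ni, 0.0), 1.0)
            m[i] = min(max(mi, 0.0), 1.0)
            h[i] = min(max(hi, 0.0), 1.0)

            if vi < spike_thresh <= v_new and t - last_spike[i] > refrac_steps:
                if n_spikes < max_spikes:
                    spike_steps[n_spikes] = t
                    spike_ids[n_spikes] = i
                    n_spikes += 1
                last_spike[i] = t
                for e in range(indptr[i], indptr[i + 1]):
                    arrive = (slot + delay_steps[e]) % L
                    if is_exc[i]:
                        buf_e[arrive, targets[e]] += weights[e]
                    else:
                        buf_i[arrive, targets[e]] += weights[e]
            v[i] = v_new

        a_ed *= dec_d
        a_er *= dec_r
        a_id *= dec_d
        a_ir *= dec_r

    return spike_steps[:n_spikes], spike_ids[:n_spikes], n_spikes, n_clips
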