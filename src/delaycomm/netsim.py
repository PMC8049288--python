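"""Network construction and simulation of one or two coupled populations.

A population is 100 HH neurons (80% excitatory, 20% inhibitory) with random
intra-population connectivity (probability 0.1) and a fixed 0.5 ms intra
axonal delay.  Two populations are coupled by random long-range projections
between excitatory neurons only (probability 0.05) with a common delay
``delta`` that is the main experimental knob, alongside the detuning of the
mean drive I0.  All neurons receive a constant current plus independent
Gaussian white noise; slow signals and pulse packets are injected into the
excitatory neurons of the sender population.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as _sig

from . import _kernels, hh
from .errors import ConfigError, InvalidInputError

__all__ = [
    "PopulationSpec",
    "CouplingSpec",
    "SignalSpec",
    "NetworkSpec",
    "SpikeRaster",
    "build_network",
    "make_slow_signal",
    "make_pulse_train",
    "simulate",
    "DEFAULT_DT_MS",
    "DEFAULT_TRANSIENT_MS",
]

#: Integration step of the stochastic solver (ms).
DEFAULT_DT_MS = 0.01
#: Settling time discarded before any measurement (ms).
DEFAULT_TRANSIENT_MS = 500.0


@dataclass(frozen=True)
class PopulationSpec:
    """One population; defaults are the standard operating point.

    Synaptic weights are peak conductances in uS/cm^2, named by
    (post <- pre) class: ``g_EI`` is the weight of I->E synapses.
    """

    N: int = 100
    frac_exc: float = 0.8
    p_intra: float = 0.1
    g_EE: float = 3.75
    g_EI: float = 15.0
    g_IE: float = 7.5
    g_II: float = 15.0
    intra_delay: float = 0.5   # ms
    I0: float = 11.0           # uA/cm^2
    noise_mu: float = 0.0      # uA/cm^2
    noise_sigma: float = 0.5   # uA/cm^2

    def __post_init__(self) -> None:
        if self.N <= 0:
            raise ConfigError("N must be positive")
        if not 0.0 <= self.frac_exc <= 1.0:
            raise ConfigError("frac_exc must lie in [0, 1]")
        if not 0.0 <= self.p_intra <= 1.0:
            raise ConfigError("p_intra must lie in [0, 1]")
        if self.intra_delay < 0 or self.noise_sigma < 0:
            raise ConfigError("delays and noise_sigma must be >= 0")

    @property
    def n_exc(self) -> int:
        return int(round(self.N * self.frac_exc))


@dataclass(frozen=True)
class CouplingSpec:
    """Long-range E->E projections between the two populations."""

    p_inter: float = 0.05
    g_forward: float = 3.75   # pop 0 -> pop 1, uS/cm^2
    g_backward: float = 3.75  # pop 1 -> pop 0
    delta: float = 3.0        # inter-population axonal delay, ms

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_inter <= 1.0:
            raise ConfigError("p_inter must lie in [0, 1]")
        if self.delta < 0:
            raise ConfigError("delta must be >= 0")
        if self.g_forward < 0 or self.g_backward < 0:
            raise ConfigError("coupling weights must be >= 0")


@dataclass(frozen=True)
class SignalSpec:
    """Current injected into the excitatory neurons of one population."""

    kind: str = "none"            # {"slow_random", "pulse", "none"}
    amplitude: float = 1.0        # uA/cm^2 (peak for slow_random)
    pulse_width: float = 2.0      # ms
    pulse_times: tuple = ()       # onset times, ms (kind="pulse")
    cutoff_freq: float = 5.0      # Hz (kind="slow_random")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("slow_random", "pulse", "none"):
            raise ConfigError(f"unknown signal kind {self.kind!r}")
        if self.amplitude < 0:
            raise ConfigError("amplitude must be >= 0")
        if self.kind == "pulse" and self.pulse_width <= 0:
            raise ConfigError("pulse_width must be positive")

    def render(self, n_steps: int, dt: float) -> np.ndarray:
        """Materialise the signal on the integration grid."""
        if self.kind == "none":
            return np.zeros(0)
        if self.kind == "slow_random":
            return make_slow_signal(
                n_steps * dt, dt=dt, cutoff_freq=self.cutoff_freq,
                amplitude=self.amplitude, seed=self.seed,
            )
        return make_pulse_train(
            n_steps * dt, dt=dt, onsets=self.pulse_times,
            width=self.pulse_width, amplitude=self.amplitude,
        )


@dataclass
class NetworkSpec:
    """Explicit adjacency (CSR by presynaptic neuron) plus per-neuron drive."""

    n_total: int
    pop_id: np.ndarray       # (N,) int, 0 or 1
    is_exc: np.ndarray       # (N,) bool
    i0: np.ndarray           # (N,) uA/cm^2 (constant drive incl. noise mean)
    noise_sigma: np.ndarray  # (N,) uA/cm^2
    indptr: np.ndarray
    targets: np.ndarray
    weights: np.ndarray      # mS/cm^2 (converted from uS/cm^2)
    delay_steps: np.ndarray  # in units of dt
    dt: float
    seed: int
    synapse_tau_r: float = 0.5
    synapse_tau_d: float = 3.0
    E_exc: float = 0.0
    E_inh: float = -80.0
    neuron: hh.NeuronParams = field(default_factory=hh.NeuronParams)

    @property
    def n_edges(self) -> int:
        return int(self.targets.shape[0])

    def exc_mask(self, pop: int) -> np.ndarray:
        return self.is_exc & (self.pop_id == pop)


def _bernoulli_edges(rng, pre_ids, post_ids, p, exclude_self=True):
    """Ordered-pair Bernoulli(p) edges pre->post, optionally without self-loops."""
    if p <= 0 or len(pre_ids) == 0 or len(post_ids) == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    draw = rng.random((len(pre_ids), len(post_ids))) < p
    if exclude_self:
        pre_arr = np.asarray(pre_ids)
        post_arr = np.asarray(post_ids)
        same = pre_arr[:, None] == post_arr[None, :]
        draw &= ~same
    src_idx, dst_idx = np.nonzero(draw)
    return np.asarray(pre_ids)[src_idx], np.asarray(post_ids)[dst_idx]


def build_network(
    pop1: PopulationSpec,
    pop2: PopulationSpec | None = None,
    coupling: CouplingSpec | None = None,
    seed: int = 0,
    dt: float = DEFAULT_DT_MS,
) -> NetworkSpec:
    """Draw the random connectivity and freeze it into a NetworkSpec.

    Intra-population edges are Bernoulli(p_intra) over ordered pairs without
    self-loops, with class-dependent weights; inter-population edges are
    Bernoulli(p_inter) over excitatory->excitatory ordered pairs only.
    Fully reproducible from `seed`.
    """
    if coupling is not None and pop2 is None:
        raise ConfigError("coupling requires a second population")
    rng = np.random.default_rng(seed)
    pops = [pop1] if pop2 is None else [pop1, pop2]
    offsets = np.cumsum([0] + [p.N for p in pops])
    n_total = int(offsets[-1])
    pop_id = np.concatenate([np.full(p.N, k) for k, p in enumerate(pops)])
    is_exc = np.concatenate(
        [np.arange(p.N) < p.n_exc for p in pops]
    ).astype(np.bool_)
    i0 = np.concatenate([np.full(p.N, p.I0 + p.noise_mu) for p in pops])
    sigma = np.concatenate([np.full(p.N, p.noise_sigma) for p in pops])

    srcs, dsts, ws, ds = [], [], [], []

    def add(pre, post, w_us, delay_ms):
        if len(pre) == 0:
            return
        srcs.append(pre)
        dsts.append(post)
        ws.append(np.full(len(pre), w_us * 1e-3))  # uS -> mS per cm^2
        ds.append(np.full(len(pre), max(int(round(delay_ms / dt)), 1), dtype=np.int64))

    for k, p in enumerate(pops):
        lo = int(offsets[k])
        exc = np.arange(lo, lo + p.n_exc)
        inh = np.arange(lo + p.n_exc, lo + p.N)
        # weight names are post <- pre
        for pre, post, w in (
            (exc, exc, p.g_EE),
            (inh, exc, p.g_EI),
            (exc, inh, p.g_IE),
            (inh, inh, p.g_II),
        ):
            s, d = _bernoulli_edges(rng, pre, post, p.p_intra)
            add(s, d, w, p.intra_delay)

    if coupling is not None:
        exc1 = np.arange(0, pops[0].n_exc)
        lo2 = int(offsets[1])
        exc2 = np.arange(lo2, lo2 + pops[1].n_exc)
        s, d = _bernoulli_edges(rng, exc1, exc2, coupling.p_inter, exclude_self=False)
        add(s, d, coupling.g_forward, coupling.delta)
        s, d = _bernoulli_edges(rng, exc2, exc1, coupling.p_inter, exclude_self=False)
        add(s, d, coupling.g_backward, coupling.delta)

    if srcs:
        src = np.concatenate(srcs)
        order = np.argsort(src, kind="stable")
        src = src[order]
        dst = np.concatenate(dsts)[order]
        w = np.concatenate(ws)[order]
        dly = np.concatenate(ds)[order]
    else:
        src = dst = np.empty(0, dtype=np.int64)
        w = np.empty(0)
        dly = np.empty(0, dtype=np.int64)
    indptr = np.zeros(n_total + 1, dtype=np.int64)
    np.add.at(indptr, src + 1, 1)
    indptr = np.cumsum(indptr)

    return NetworkSpec(
        n_total=n_total, pop_id=pop_id, is_exc=is_exc, i0=i0,
        noise_sigma=sigma, indptr=indptr, targets=dst.astype(np.int64),
        weights=w, delay_steps=dly.astype(np.int64), dt=dt, seed=seed,
    )


def make_slow_signal(
    duration: float,
    dt: float = DEFAULT_DT_MS,
    cutoff_freq: float = 5.0,
    amplitude: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Zero-mean low-pass-filtered Gaussian noise rescaled to a peak amplitude.

    The non-periodic "slow" drive: white noise filtered by a 4th-order
    Butterworth low-pass at `cutoff_freq` Hz (forward-backward, so zero
    phase), generated on a coarse 1 ms grid and linearly interpolated onto
    the integration grid.  ``amplitude`` is the peak absolute value in
    uA/cm^2; 0 returns an identically zero trace.
    """
    if duration <= 0:
        raise InvalidInputError("duration must be positive")
    n_steps = int(round(duration / dt))
    if amplitude == 0:
        return np.zeros(n_steps)
    coarse_dt = 1.0  # ms
    n_coarse = max(int(round(duration / coarse_dt)) + 1, 64)
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(n_coarse)
    fs = 1000.0 / coarse_dt  # Hz
    sos = _sig.butter(4, cutoff_freq, btype="low", fs=fs, output="sos")
    # pad to let the filter settle, then trim
    pad = int(2 * fs / cutoff_freq)
    padded = np.concatenate([rng.standard_normal(pad), white, rng.standard_normal(pad)])
    slow = _sig.sosfiltfilt(sos, padded)[pad : pad + n_coarse]
    slow = slow - slow.mean()
    peak = np.max(np.abs(slow))
    if peak > 0:
        slow = slow * (amplitude / peak)
    t_coarse = np.arange(n_coarse) * coarse_dt
    t_fine = np.arange(n_steps) * dt
    return np.interp(t_fine, t_coarse, slow)


def make_pulse_train(
    duration: float,
    dt: float = DEFAULT_DT_MS,
    onsets=(),
    width: float = 2.0,
    amplitude: float = 0.25,
) -> np.ndarray:
    """Rectangular pulses of given width (ms) and amplitude at `onsets` (ms)."""
    n_steps = int(round(duration / dt))
    out = np.zeros(n_steps)
    w = int(round(width / dt))
    for t0 in onsets:
        a = int(round(t0 / dt))
        if a >= n_steps:
            continue
        out[max(a, 0) : min(a + w, n_steps)] += amplitude
    return out


@dataclass
class SpikeRaster:
    """Event list: spike times (ms), neuron ids, and population ids."""

    times: np.ndarray
    neuron_ids: np.ndarray
    pop_ids: np.ndarray
    duration: float
    dt: float
    n_neurons: int
    n_gate_clips: int = 0

    def select(self, pop: int | None = None) -> "SpikeRaster":
        if pop is None:
            return self
        m = self.pop_ids == pop
        return SpikeRaster(
            self.times[m], self.neuron_ids[m], self.pop_ids[m],
            self.duration, self.dt, self.n_neurons, self.n_gate_clips,
        )

    def n_spikes(self) -> int:
        return int(self.times.shape[0])

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(
            {
                "time_ms": self.times,
                "neuron_id": self.neuron_ids,
                "population_id": self.pop_ids,
            }
        )
        with open(path, "w") as fh:
            fh.write(f"# duration_ms={self.duration}\tdt_ms={self.dt}"
                     f"\tn_neurons={self.n_neurons}\n")
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "SpikeRaster":
        meta = {}
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("#"):
                for tok in first[1:].strip().split("\t"):
                    k, v = tok.split("=")
                    meta[k] = float(v)
                df = pd.read_csv(fh, sep="\t")
            else:
                df = pd.read_csv(path, sep="\t")
        duration = meta.get("duration_ms", float(df["time_ms"].max()) if len(df) else 0.0)
        return cls(
            times=df["time_ms"].to_numpy(float),
            neuron_ids=df["neuron_id"].to_numpy(np.int64),
            pop_ids=df["population_id"].to_numpy(np.int64),
            duration=duration,
            dt=meta.get("dt_ms", DEFAULT_DT_MS),
            n_neurons=int(meta.get("n_neurons", df["neuron_id"].max() + 1 if len(df) else 0)),
        )


def simulate(
    network: NetworkSpec,
    duration: float,
    seed: int = 0,
    signal: SignalSpec | np.ndarray | None = None,
    signal_pop: int = 0,
    pulse: SignalSpec | np.ndarray | None = None,
    pulse_pop: int = 0,
    state0: tuple | str | None = None,
) -> SpikeRaster:
    """Integrate the network for `duration` ms and return its spike raster.

    `signal` and `pulse` are two independent injection channels, each added
    to the excitatory neurons of the named population; either a
    :class:`SignalSpec` or a raw current array on the dt grid.  The noise
    stream is determined entirely by `seed`, so two calls differing only in
    an injected current share identical noise (useful for perturbation
    experiments).  Initial conditions default to the common resting state;
    ``state0="random"`` draws per-neuron membrane potentials uniformly from
    [-75, -45] mV (gates at steady state, seeded by `seed`), which
    de-aligns the collective phases of replicate runs.
    """
    if duration <= 0:
        raise InvalidInputError("duration must be positive")
    dt = network.dt
    n_steps = int(round(duration / dt))

    def render(ch) -> np.ndarray:
        if ch is None:
            return np.zeros(0)
        if isinstance(ch, SignalSpec):
            return np.ascontiguousarray(ch.render(n_steps, dt))
        arr = np.ascontiguousarray(np.asarray(ch, dtype=float))
        if arr.shape[0] != n_steps:
            raise InvalidInputError("injected current length must equal duration/dt")
        return arr

    sig1 = render(signal)
    sig2 = render(pulse)
    mask1 = network.exc_mask(signal_pop)
    mask2 = network.exc_mask(pulse_pop)

    if state0 is None:
        rest = hh.resting_state(network.neuron)
        v = np.full(network.n_total, rest.v)
        n = np.full(network.n_total, rest.n)
        m = np.full(network.n_total, rest.m)
        h = np.full(network.n_total, rest.h)
    elif isinstance(state0, str):
        if state0 != "random":
            raise InvalidInputError(f"unknown state0 preset {state0!r}")
        rng0 = np.random.default_rng(seed)
        v = rng0.uniform(-75.0, -45.0, network.n_total)
        gates = np.array([hh.gating_steady_state(vi) for vi in v])
        n, m, h = gates[:, 0].copy(), gates[:, 1].copy(), gates[:, 2].copy()
    else:
        v, n, m, h = (np.array(x, dtype=float) for x in state0)

    p = network.neuron
    # generous bound: no neuron can exceed refractory-limited 500 Hz
    max_spikes = int(network.n_total * duration / hh.SPIKE_REFRACTORY_MS) + 16
    steps, ids, n_sp, n_clips = _kernels.network_kernel(
        n_steps, dt, v, n, m, h,
        network.is_exc, network.i0, network.noise_sigma,
        network.indptr, network.targets, network.weights, network.delay_steps,
        sig1, mask1, sig2, mask2,
        network.synapse_tau_r, network.synapse_tau_d,
        hh.kernel_peak_value(network.synapse_tau_r, network.synapse_tau_d),
        network.E_exc, network.E_inh,
        p.C, p.gK, p.gNa, p.gL, p.EK, p.ENa, p.EL,
        hh.SPIKE_THRESHOLD_MV, hh.SPIKE_REFRACTORY_MS,
        int(seed) & 0x7FFFFFFF, max_spikes,
    )
    return SpikeRaster(
        times=steps * dt,
        neuron_ids=ids,
        pop_ids=network.pop_id[ids],
        duration=duration,
        dt=dt,
        n_neurons=network.n_total,
        n_gate_clips=int(n_clips),
    )
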