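"""Analysis quantities: multi-unit activity, coherency, cross-covariance,
delayed mutual information, phase locking, and population phase response
curves (local and non-local).

Conventions
-----------
* Rates are weighted spike counts under a **unit-peak** Gaussian kernel, so
  a rate peak of N means all N neurons fired simultaneously.
* Phase-shift sign: a pulse that *shortens* the ongoing period (phase
  advance) gives a **positive** PRC value, computed as (T0 - T) * 2*pi/T0.
* Phase difference of a locked pair is phi = phi_1 - phi_2 wrapped to
  (-pi, pi]; positive means population 1 leads.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _sig
from scipy import stats as _stats

from . import netsim
from .errors import (
    InsufficientDataError,
    InsufficientOscillationError,
    InvalidInputError,
    UnlockedPairError,
)

__all__ = [
    "RateSeries",
    "DMICurve",
    "PRCCurve",
    "LockingResult",
    "firing_rate",
    "detect_peaks",
    "coherency",
    "zero_lag_cov",
    "delayed_mutual_information",
    "net_information",
    "assess_locking",
    "estimate_pprc",
    "estimate_nprc",
]


@dataclass
class RateSeries:
    """Instantaneous multi-unit activity on a regular time grid (ms)."""

    t: np.ndarray
    r: np.ndarray
    kernel_sigma: float

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0]) if len(self.t) > 1 else np.nan


@dataclass
class DMICurve:
    """Delayed mutual information (bits) over a symmetric lag grid (ms)."""

    lags: np.ndarray
    dmi: np.ndarray
    n_bins: int
    net_flow: float = np.nan  # bits*ms; > 0 means flow x -> y


@dataclass
class PRCCurve:
    """Phase shift (radians, advance positive) vs pulse phase beta."""

    phases: np.ndarray       # segment centres, [0, 2*pi)
    shift: np.ndarray        # trial-mean shift per segment
    stderr: np.ndarray       # standard error of the mean per segment
    n_segments: int
    amplitude: float
    width: float


@dataclass
class LockingResult:
    """Frequency ratio and circular phase statistics of a population pair."""

    freq_ratio: float
    phase_diff: float        # radians, NaN when not locked
    is_locked: bool
    f1: float                # Hz
    f2: float
    circ_sd: float           # radians, dispersion of per-cycle offsets


def firing_rate(
    raster: netsim.SpikeRaster,
    pop: int | None = None,
    kernel_sigma: float = 2.0,
    grid_dt: float = 0.1,
    t_start: float = 0.0,
    t_stop: float | None = None,
) -> RateSeries:
    """Gaussian-smoothed multi-unit activity of one population.

    r(t) = sum over spikes of exp(-(t - t_spike)^2 / (2 sigma^2)): a
    unit-peak kernel, so coincident spikes add and the rate is bounded by
    the spike count.  An empty raster yields an all-zero series.
    """
    if kernel_sigma <= 0 or grid_dt <= 0:
        raise InvalidInputError("kernel_sigma and grid_dt must be positive")
    stop = raster.duration if t_stop is None else t_stop
    sub = raster.select(pop)
    t = np.arange(t_start, stop, grid_dt)
    n = len(t)
    mask = (sub.times >= t_start) & (sub.times < stop)
    idx = np.clip(((sub.times[mask] - t_start) / grid_dt).round().astype(int), 0, n - 1)
    counts = np.bincount(idx, minlength=n).astype(float)
    half = int(np.ceil(6 * kernel_sigma / grid_dt))
    kt = np.arange(-half, half + 1) * grid_dt
    kernel = np.exp(-0.5 * (kt / kernel_sigma) ** 2)
    r = _sig.fftconvolve(counts, kernel, mode="same")
    return RateSeries(t=t, r=np.maximum(r, 0.0), kernel_sigma=kernel_sigma)


def detect_peaks(
    rate: RateSeries, prominence_frac: float = 0.2
) -> tuple[np.ndarray, float]:
    """Oscillation peaks of a rate series and the mean inter-peak period.

    Local maxima with prominence at least ``prominence_frac`` of the series'
    peak-to-peak span, refined to sub-grid precision by a parabolic fit
    through each maximum and its neighbours (the smooth Gaussian-kernel
    rate is locally quadratic, so this resolves peak times well below the
    grid step).  Returns (peak_times_ms, mean_period_ms); raises
    :class:`InsufficientOscillationError` with fewer than 3 peaks.
    """
    span = float(rate.r.max() - rate.r.min())
    if span <= 0:
        raise InsufficientOscillationError("rate series is constant")
    idx, _ = _sig.find_peaks(rate.r, prominence=prominence_frac * span)
    if len(idx) < 3:
        raise InsufficientOscillationError(f"only {len(idx)} peaks found")
    idx = idx[(idx > 0) & (idx < len(rate.r) - 1)]
    r = rate.r
    dy = (r[idx + 1] - r[idx - 1]) / 2.0
    d2y = r[idx + 1] - 2.0 * r[idx] + r[idx - 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        off = np.where(d2y < 0, -dy / d2y, 0.0)
    off = np.clip(off, -0.5, 0.5)
    peak_t = rate.t[idx] + off * rate.dt
    return peak_t, float(np.mean(np.diff(peak_t)))


def coherency(rate: RateSeries, n_neurons: int, n_peaks: int = 20) -> float:
    """Coherency index C in [0, 1].

    Mean height of `n_peaks` successive population-activity peaks divided by
    the all-synchronous maximum (= `n_neurons` under the unit-peak kernel).
    """
    try:
        peak_t, _ = detect_peaks(rate)
    except InsufficientOscillationError as e:
        raise InsufficientDataError(str(e)) from e
    if len(peak_t) < n_peaks:
        raise InsufficientDataError(
            f"need {n_peaks} peaks for the coherency index, found {len(peak_t)}"
        )
    heights = np.interp(peak_t[:n_peaks], rate.t, rate.r)
    return float(np.mean(heights) / n_neurons)


def zero_lag_cov(x, y) -> float:
    """Unbiased, unnormalized cross-covariance at zero lag:
    sum((x - mean x)(y - mean y)) / (n - 1)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise InvalidInputError("series must be equal-length 1-D with n >= 2")
    return float(np.sum((x - x.mean()) * (y - y.mean())) / (len(x) - 1))


def _entropy_bits(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-np.sum(p * np.log2(p)))


def delayed_mutual_information(
    x,
    y,
    dt: float,
    lags: np.ndarray | None = None,
    n_bins: int = 16,
) -> DMICurve:
    """Plug-in delayed mutual information dMI(d) = I(x(t); y(t+d)) in bits.

    Equal-width bins over each series' observed range; base-2 logs.  A
    positive lag d asks how much x *now* tells about y *later*, so an
    excess at d > 0 indicates flow x -> y.  `lags` in ms must be symmetric
    about zero (default +-30 ms in 0.5 ms steps); `dt` is the sample
    spacing of the series.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidInputError("series must be equal-length 1-D")
    if n_bins < 2:
        raise InvalidInputError("n_bins must be >= 2")
    if lags is None:
        lags = np.arange(-30.0, 30.0 + 1e-9, 0.5)
    lags = np.asarray(lags, dtype=float)

    def edges(z):
        lo, hi = float(z.min()), float(z.max())
        if hi <= lo:
            hi = lo + 1e-12
        return np.linspace(lo, hi, n_bins + 1)

    ex, ey = edges(x), edges(y)
    dmi = np.empty(len(lags))
    n = len(x)
    for i, lag in enumerate(lags):
        s = int(round(lag / dt))
        if abs(s) >= n - 1:
            raise InvalidInputError("lag exceeds series length")
        if s >= 0:
            xa, ya = x[: n - s], y[s:]
        else:
            xa, ya = x[-s:], y[: n + s]
        if len(xa) < 10 * n_bins:
            raise InvalidInputError(
                "series overlap too short for the requested bin count"
            )
        joint, _, _ = np.histogram2d(xa, ya, bins=(ex, ey))
        hx = _entropy_bits(joint.sum(axis=1))
        hy = _entropy_bits(joint.sum(axis=0))
        hxy = _entropy_bits(joint.ravel())
        dmi[i] = max(hx + hy - hxy, 0.0)
    curve = DMICurve(lags=lags, dmi=dmi, n_bins=n_bins)
    curve.net_flow = net_information(curve)
    return curve


def net_information(curve: DMICurve) -> float:
    """Positive-lag integral minus negative-lag integral of dMI (bits*ms).

    Positive values indicate net information flow from the first to the
    second series.  Requires a lag grid symmetric about zero.
    """
    lags, dmi = curve.lags, curve.dmi
    if not np.allclose(lags, -lags[::-1]):
        raise InvalidInputError("lag grid must be symmetric about 0")
    pos = lags >= 0
    neg = lags <= 0
    return float(
        np.trapezoid(dmi[pos], lags[pos]) - np.trapezoid(dmi[neg][::-1], -lags[neg][::-1])
    )


def _wrap_pi(phi):
    """Wrap angles to (-pi, pi]."""
    return -((-np.asarray(phi) + np.pi) % (2 * np.pi) - np.pi)


def assess_locking(
    raster: netsim.SpikeRaster,
    kernel_sigma: float = 2.0,
    grid_dt: float = 0.1,
    transient: float = netsim.DEFAULT_TRANSIENT_MS,
    ratio_tol: float = 0.01,
    circ_sd_tol: float = 0.5,
) -> LockingResult:
    """Phase-locking diagnosis of a two-population raster.

    Locked iff the mean-period frequency ratio is within `ratio_tol` of 1
    AND the per-cycle phase offsets have circular SD below `circ_sd_tol`
    (the second clause rejects slowly drifting near-1 ratios).  The phase
    difference phi_1 - phi_2 is only reported for locked pairs.
    """
    r1 = firing_rate(raster, pop=0, kernel_sigma=kernel_sigma,
                     grid_dt=grid_dt, t_start=transient)
    r2 = firing_rate(raster, pop=1, kernel_sigma=kernel_sigma,
                     grid_dt=grid_dt, t_start=transient)
    pk1, T1 = detect_peaks(r1)
    pk2, T2 = detect_peaks(r2)
    ratio = T2 / T1  # = f1 / f2
    T = 0.5 * (T1 + T2)
    # offset of each pop-1 peak to the nearest pop-2 peak
    j = np.searchsorted(pk2, pk1)
    offs = []
    for i, t0 in enumerate(pk1):
        cands = []
        if j[i] > 0:
            cands.append(t0 - pk2[j[i] - 1])
        if j[i] < len(pk2):
            cands.append(t0 - pk2[j[i]])
        offs.append(min(cands, key=abs))
    phases = _wrap_pi(2 * np.pi * np.asarray(offs) / T)
    circ_sd = float(_stats.circstd(phases, high=np.pi, low=-np.pi))
    locked = bool(abs(ratio - 1.0) < ratio_tol and circ_sd < circ_sd_tol)
    phase = float(_stats.circmean(phases, high=np.pi, low=-np.pi)) if locked else np.nan
    return LockingResult(
        freq_ratio=float(ratio), phase_diff=phase, is_locked=locked,
        f1=1000.0 / T1, f2=1000.0 / T2, circ_sd=circ_sd,
    )


# ---------------------------------------------------------------------------
# Phase response curves
# ---------------------------------------------------------------------------

def _segment_phases(n_segments: int) -> np.ndarray:
    return (np.arange(n_segments) + 0.5) * 2 * np.pi / n_segments


class _PulseTrialContext:
    """One noise seed's unperturbed reference run for PRC estimation.

    The baseline and every pulsed rerun share the noise seed, so they are
    bit-identical up to pulse onset: the pulse phase (read off the baseline
    peaks) is exact and the measured peak displacement is purely the
    pulse's doing."""

    def __init__(self, network, seed, pulse_pop, measure_pop, transient,
                 settle_cycles, extra_ms, grid_dt):
        self.network = network
        self.seed = seed
        self.pulse_pop = pulse_pop
        self.measure_pop = measure_pop
        self.settle_cycles = settle_cycles
        self.grid_dt = grid_dt
        self.transient = transient
        self.duration = transient + settle_cycles * 20.0 + extra_ms
        self.base = netsim.simulate(network, self.duration, seed=seed)
        self.ok = False
        try:
            rate_b = firing_rate(self.base, pop=pulse_pop, grid_dt=grid_dt,
                                 t_start=transient)
            self.pk_pulse, self.T0 = detect_peaks(rate_b)
            rate_m = firing_rate(self.base, pop=measure_pop, grid_dt=grid_dt,
                                 t_start=transient)
            self.pk_measure, self.T0_m = detect_peaks(rate_m)
        except InsufficientOscillationError:
            return
        self.ok = len(self.pk_pulse) >= settle_cycles + 3

    def shift(self, beta: float, amplitude: float, width: float) -> float | None:
        """Advance (rad, positive) of the measured population's peak for one
        pulse at phase `beta`; None when the measurement fails."""
        if not self.ok:
            return None
        k = self.settle_cycles  # reference cycle, well past the transient
        t_pulse = self.pk_pulse[k] + beta / (2 * np.pi) * (
            self.pk_pulse[k + 1] - self.pk_pulse[k]
        )
        pulse = netsim.SignalSpec(kind="pulse", amplitude=amplitude,
                                  pulse_width=width, pulse_times=(t_pulse,))
        pert = netsim.simulate(self.network, self.duration, seed=self.seed,
                               pulse=pulse, pulse_pop=self.pulse_pop)
        rate_p = firing_rate(pert, pop=self.measure_pop, grid_dt=self.grid_dt,
                             t_start=self.transient)
        try:
            pkm_p, _ = detect_peaks(rate_p)
        except InsufficientOscillationError:
            return None
        # first measured-population baseline peak after the pulse has arrived
        after = self.pk_measure[self.pk_measure > t_pulse + width]
        if len(after) < 2:
            return None
        t_ref = after[1]  # second peak: lets delayed arrivals take effect
        near = pkm_p[np.abs(pkm_p - t_ref) < 0.75 * self.T0_m]
        if len(near) == 0:
            return None
        t_p = near[np.argmin(np.abs(near - t_ref))]
        # advance (earlier perturbed peak) is positive
        return float((t_ref - t_p) * 2 * np.pi / self.T0_m)


def estimate_pprc(
    network: netsim.NetworkSpec,
    amplitude: float = 1.0,
    width: float = 2.0,
    n_segments: int = 30,
    trials: int = 20,
    base_seed: int = 0,
    transient: float = netsim.DEFAULT_TRANSIENT_MS,
    grid_dt: float = 0.1,
) -> PRCCurve:
    """Population phase response curve of a single oscillating population.

    For each phase segment beta, a rectangular pulse (default 1 uA/cm^2,
    2 ms) is injected into all excitatory neurons at that phase of the
    ongoing cycle, and the advance of the next activity peak relative to a
    noise-matched unperturbed run gives the shift (T0 - T) * 2*pi/T0.
    Averages `trials` independent noise realisations per segment.
    """
    phases = _segment_phases(n_segments)
    shifts = [[] for _ in range(n_segments)]
    for trial in range(trials):
        ctx = _PulseTrialContext(
            network, seed=base_seed + 7919 * trial, pulse_pop=0,
            measure_pop=0, transient=transient, settle_cycles=5,
            extra_ms=120.0, grid_dt=grid_dt,
        )
        for si, beta in enumerate(phases):
            s = ctx.shift(beta, amplitude, width)
            if s is not None:
                shifts[si].append(s)
    mean = np.array([np.mean(s) if s else np.nan for s in shifts])
    sem = np.array(
        [np.std(s, ddof=1) / np.sqrt(len(s)) if len(s) > 1 else np.nan for s in shifts]
    )
    return PRCCurve(phases=phases, shift=mean, stderr=sem,
                    n_segments=n_segments, amplitude=amplitude, width=width)


def estimate_nprc(
    network: netsim.NetworkSpec,
    amplitude: float = 0.25,
    width: float = 2.0,
    n_segments: int = 50,
    trials: int = 20,
    base_seed: int = 0,
    sender: int = 0,
    transient: float = netsim.DEFAULT_TRANSIENT_MS,
    grid_dt: float = 0.1,
    require_locked: bool = True,
) -> PRCCurve:
    """Non-local PRC: receiver phase shift vs the phase at which a pulse
    packet hits the *sender* population.

    Requires a phase-locked pair (checked on an unperturbed control run);
    raises :class:`UnlockedPairError` otherwise.  The pulse (default
    0.25 uA/cm^2, 2 ms) goes to all sender excitatory neurons.
    """
    if network.pop_id.max() < 1:
        raise InvalidInputError("nPRC needs a two-population network")
    receiver = 1 - sender
    if require_locked:
        control = netsim.simulate(network, transient + 1500.0, seed=base_seed)
        lock = assess_locking(control, transient=transient)
        if not lock.is_locked:
            raise UnlockedPairError(
                f"pair is not phase locked (ratio {lock.freq_ratio:.3f}, "
                f"circ SD {lock.circ_sd:.2f} rad)"
            )
    phases = _segment_phases(n_segments)
    shifts = [[] for _ in range(n_segments)]
    for trial in range(trials):
        ctx = _PulseTrialContext(
            network, seed=base_seed + 7919 * trial, pulse_pop=sender,
            measure_pop=receiver, transient=transient, settle_cycles=5,
            extra_ms=160.0, grid_dt=grid_dt,
        )
        for si, beta in enumerate(phases):
            s = ctx.shift(beta, amplitude, width)
            if s is not None:
                shifts[si].append(s)
    mean = np.array([np.mean(s) if s else np.nan for s in shifts])
    sem = np.array(
        [np.std(s, ddof=1) / np.sqrt(len(s)) if len(s) > 1 else np.nan for s in shifts]
    )
    return PRCCurve(phases=phases, shift=mean, stderr=sem,
                    n_segments=n_segments, amplitude=amplitude, width=width)
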