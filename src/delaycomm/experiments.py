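"""Config-driven experiment protocols at desk scale.

Each function reproduces one of the study protocols on a coarse grid and
returns a tidy :class:`pandas.DataFrame` (long form: one row per grid cell
and measure).  The command-line front end in :mod:`delaycomm.cli` is a thin
wrapper around these functions.

The two-population protocols fix population 2 at the default drive
I0 = 11 uA/cm^2 and detune population 1 to 11 + dI; positive dI therefore
makes the *sender* (population 1) the faster oscillator.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import measures, netsim, phase_theory
from .errors import InsufficientDataError, InsufficientOscillationError

__all__ = [
    "coupled_pair",
    "run_single_population_characterization",
    "run_locking_sweep",
    "run_slow_transmission_sweep",
    "run_pulse_transmission_sweep",
    "run_asymmetry_sweep",
    "run_theory_experiments",
    "DEFAULTS",
]

DEFAULTS = {
    "I0": 11.0,
    "noise_sigma": 0.5,
    "g_inter": 3.75,       # uS/cm^2, long-range E->E weight
    "signal_amplitude": 1.0,
    "dmi_bins": 16,
    "dmi_lag_max": 30.0,   # ms
    "dmi_lag_step": 0.5,   # ms
    "rate_sigma_fast": 2.0,    # ms
    "rate_sigma_slow": 100.0,  # ms
}


def coupled_pair(
    dI: float,
    delay_ms: float,
    g_forward: float | None = None,
    g_backward: float | None = None,
    seed: int = 0,
) -> netsim.NetworkSpec:
    """Two default populations with population 1 detuned to I0 = 11 + dI and
    long-range delay `delay_ms`; population 1 (index 0) is the sender."""
    g_for = DEFAULTS["g_inter"] if g_forward is None else g_forward
    g_back = DEFAULTS["g_inter"] if g_backward is None else g_backward
    pop1 = netsim.PopulationSpec(I0=DEFAULTS["I0"] + dI)
    pop2 = netsim.PopulationSpec(I0=DEFAULTS["I0"])
    coupling = netsim.CouplingSpec(
        g_forward=g_for, g_backward=g_back, delta=delay_ms
    )
    return netsim.build_network(pop1, pop2, coupling, seed=seed)


def _population_stats(raster, n_neurons, transient):
    rate = measures.firing_rate(raster, pop=0, t_start=transient)
    peak_t, T = measures.detect_peaks(rate)
    C = measures.coherency(rate, n_neurons)
    return C, 1000.0 / T


def run_single_population_characterization(
    I0_grid=(10.0, 11.0, 12.0),
    sigma_grid=(0.5,),
    trials: int = 3,
    duration: float = 3500.0,
    transient: float = netsim.DEFAULT_TRANSIENT_MS,
    seed: int = 0,
) -> pd.DataFrame:
    """Coherency C and oscillation frequency f of one isolated population
    over an (I0, noise sigma) grid, with per-cell trial statistics."""
    rows = []
    for I0 in I0_grid:
        for sig in sigma_grid:
            Cs, fs = [], []
            for trial in range(trials):
                s = seed + 1000 * trial
                net = netsim.build_network(
                    netsim.PopulationSpec(I0=I0, noise_sigma=sig), seed=s
                )
                raster = netsim.simulate(net, duration, seed=s + 1)
                try:
                    C, f = _population_stats(raster, net.n_total, transient)
                except (InsufficientOscillationError, InsufficientDataError):
                    continue
                Cs.append(C)
                fs.append(f)
            rows.append(
                dict(
                    I0=I0, sigma=sig, n_trials=len(Cs),
                    C=np.mean(Cs) if Cs else np.nan,
                    C_sd=np.std(Cs, ddof=1) if len(Cs) > 1 else np.nan,
                    f=np.mean(fs) if fs else np.nan,
                    f_sd=np.std(fs, ddof=1) if len(fs) > 1 else np.nan,
                )
            )
    return pd.DataFrame(rows)


def run_locking_sweep(
    dI_grid=(-0.4, -0.2, 0.0, 0.2, 0.4),
    delay_grid=(0.5, 2.0, 4.0, 6.0, 8.0, 10.0, 12.0, 14.0),
    duration: float = 2500.0,
    transient: float = netsim.DEFAULT_TRANSIENT_MS,
    seed: int = 0,
) -> pd.DataFrame:
    """Frequency-ratio / phase-difference map over the (dI, delay) grid."""
    rows = []
    for dI in dI_grid:
        for delay in delay_grid:
            s = seed + hash((round(dI * 100), round(delay * 10))) % 100000
            net = coupled_pair(dI, delay, seed=s)
            raster = netsim.simulate(net, duration, seed=s + 1)
            try:
                lock = measures.assess_locking(raster, transient=transient)
                rows.append(
                    dict(dI=dI, delay_ms=delay, seed=s,
                         freq_ratio=lock.freq_ratio, phase_diff=lock.phase_diff,
                         is_locked=lock.is_locked, f1=lock.f1, f2=lock.f2,
                         circ_sd=lock.circ_sd, flag="")
                )
            except InsufficientOscillationError as e:
                rows.append(dict(dI=dI, delay_ms=delay, seed=s,
                                 freq_ratio=np.nan, phase_diff=np.nan,
                                 is_locked=False, f1=np.nan, f2=np.nan,
                                 circ_sd=np.nan, flag=str(e)))
    return pd.DataFrame(rows)


def _cell_transmission(net, duration, transient, signal_seed, noise_seed,
                       amplitude):
    """ZLC(receiver slow rate, signal) and net dMI(sender -> receiver) for
    one simulated cell."""
    sig_spec = netsim.SignalSpec(kind="slow_random", amplitude=amplitude,
                                 seed=signal_seed)
    raster = netsim.simulate(net, duration, seed=noise_seed,
                             signal=sig_spec, signal_pop=0)
    # slow modulation: sigma = 100 ms rate on a 1 ms grid vs the signal
    slow_dt = 1.0
    r2 = measures.firing_rate(raster, pop=1,
                              kernel_sigma=DEFAULTS["rate_sigma_slow"],
                              grid_dt=slow_dt, t_start=transient)
    sig_full = sig_spec.render(int(round(duration / net.dt)), net.dt)
    stride = int(round(slow_dt / net.dt))
    sig_grid = sig_full[int(round(transient / net.dt))::stride][: len(r2.r)]
    zlc = measures.zero_lag_cov(r2.r[: len(sig_grid)], sig_grid)
    # fast MUA for the information-flow measure
    fast_dt = 0.5
    r1f = measures.firing_rate(raster, pop=0, grid_dt=fast_dt, t_start=transient)
    r2f = measures.firing_rate(raster, pop=1, grid_dt=fast_dt, t_start=transient)
    lags = np.arange(-DEFAULTS["dmi_lag_max"],
                     DEFAULTS["dmi_lag_max"] + 1e-9, DEFAULTS["dmi_lag_step"])
    curve = measures.delayed_mutual_information(
        r1f.r, r2f.r, dt=fast_dt, lags=lags, n_bins=DEFAULTS["dmi_bins"]
    )
    return zlc, curve.net_flow


def run_slow_transmission_sweep(
    dI_grid=(-0.4, -0.2, 0.0, 0.2, 0.4),
    delay_grid=(0.5, 2.0, 4.0, 6.0, 8.0, 11.0),
    duration: float = 4000.0,
    transient: float = netsim.DEFAULT_TRANSIENT_MS,
    amplitude: float | None = None,
    trials: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Slow-signal transmission map: per-cell zero-lag cross-covariance of
    the receiver rate with the injected signal, and the net delayed mutual
    information sender -> receiver."""
    amp = DEFAULTS["signal_amplitude"] if amplitude is None else amplitude
    rows = []
    for dI in dI_grid:
        for delay in delay_grid:
            zs, nf = [], []
            for trial in range(trials):
                s = (seed + 17 * trial
                     + hash((round(dI * 100), round(delay * 10))) % 100000)
                net = coupled_pair(dI, delay, seed=s)
                try:
                    z, f = _cell_transmission(
                        net, duration, transient,
                        signal_seed=seed + 31 * trial, noise_seed=s + 1,
                        amplitude=amp,
                    )
                    zs.append(z)
                    nf.append(f)
                except (InsufficientOscillationError, InsufficientDataError):
                    continue
            rows.append(
                dict(dI=dI, delay_ms=delay, n_trials=len(zs),
                     zlc=np.mean(zs) if zs else np.nan,
                     net_dmi=np.mean(nf) if nf else np.nan)
            )
    return pd.DataFrame(rows)


def run_pulse_transmission_sweep(
    dI_grid=(-0.2, 0.0, 0.2),
    delay_grid=(2.0, 5.0, 8.0),
    n_segments: int = 8,
    trials: int = 2,
    seed: int = 0,
) -> pd.DataFrame:
    """Pulse-packet transmission at desk scale.

    Per locked cell: the sender pPRC, the simulated receiver nPRC, and the
    phase-model prediction (sender response times the receiver sensitivity
    |Q'| at the arrival phase, with the measured pPRC standing in for Q).
    Reports the max-|shift| amplitudes; unlocked cells are flagged.
    """
    rows = []
    for dI in dI_grid:
        for delay in delay_grid:
            s = seed + hash((round(dI * 100), round(delay * 10))) % 100000
            net = coupled_pair(dI, delay, seed=s)
            control = netsim.simulate(net, 2000.0, seed=s + 1)
            try:
                lock = measures.assess_locking(control)
            except InsufficientOscillationError:
                rows.append(dict(dI=dI, delay_ms=delay, locked=False,
                                 pprc_max=np.nan, nprc_max=np.nan,
                                 nprc_pred_max=np.nan))
                continue
            if not lock.is_locked:
                rows.append(dict(dI=dI, delay_ms=delay, locked=False,
                                 pprc_max=np.nan, nprc_max=np.nan,
                                 nprc_pred_max=np.nan))
                continue
            pprc = measures.estimate_pprc(
                net, n_segments=n_segments, trials=trials, base_seed=s + 2
            )
            nprc = measures.estimate_nprc(
                net, n_segments=n_segments, trials=trials, base_seed=s + 3,
                require_locked=False,
            )
            # smooth the measured pPRC with its first Fourier mode to get
            # a differentiable surrogate Q
            ph, sh = pprc.phases, np.nan_to_num(pprc.shift)
            a1 = 2 * np.mean(sh * np.cos(ph))
            b1 = 2 * np.mean(sh * np.sin(ph))
            f_locked = 0.5 * (lock.f1 + lock.f2)
            delta_phase = float(phase_theory.tau_to_delta(delay, f_locked))
            arrival = lock.phase_diff - delta_phase
            qprime = -a1 * np.sin(arrival) + b1 * np.cos(arrival)
            pred_max = float(np.nanmax(np.abs(sh)) * abs(qprime))
            rows.append(dict(dI=dI, delay_ms=delay, locked=True,
                             pprc_max=float(np.nanmax(np.abs(pprc.shift))),
                             nprc_max=float(np.nanmax(np.abs(nprc.shift))),
                             nprc_pred_max=pred_max))
    return pd.DataFrame(rows)


def run_asymmetry_sweep(
    ratio_grid=(0.0, 0.5, 1.0, 1.5, 2.0),
    delay_grid=(0.5, 3.0, 6.0, 9.0, 12.0),
    dI: float = 0.4,
    duration: float = 3500.0,
    transient: float = netsim.DEFAULT_TRANSIENT_MS,
    seed: int = 0,
) -> pd.DataFrame:
    """Net information flow vs feedback/feedforward weight ratio and delay.

    The forward weight is fixed at the default long-range strength, the
    backward weight is ratio * forward, and the detuning is fixed (default
    +0.4 uA/cm^2, sender faster).  No external signal: the measure is the
    spontaneous net dMI sender -> receiver.
    """
    g_for = DEFAULTS["g_inter"]
    lags = np.arange(-DEFAULTS["dmi_lag_max"],
                     DEFAULTS["dmi_lag_max"] + 1e-9, DEFAULTS["dmi_lag_step"])
    rows = []
    for ratio in ratio_grid:
        for delay in delay_grid:
            s = seed + hash((round(ratio * 100), round(delay * 10))) % 100000
            net = coupled_pair(dI, delay, g_forward=g_for,
                               g_backward=ratio * g_for, seed=s)
            raster = netsim.simulate(net, duration, seed=s + 1)
            try:
                fast_dt = 0.5
                r1 = measures.firing_rate(raster, pop=0, grid_dt=fast_dt,
                                          t_start=transient)
                r2 = measures.firing_rate(raster, pop=1, grid_dt=fast_dt,
                                          t_start=transient)
                curve = measures.delayed_mutual_information(
                    r1.r, r2.r, dt=fast_dt, lags=lags,
                    n_bins=DEFAULTS["dmi_bins"],
                )
                rows.append(dict(ratio=ratio, delay_ms=delay, dI=dI,
                                 net_dmi=curve.net_flow, flag=""))
            except (InsufficientOscillationError, InsufficientDataError) as e:
                rows.append(dict(ratio=ratio, delay_ms=delay, dI=dI,
                                 net_dmi=np.nan, flag=str(e)))
    return pd.DataFrame(rows)


def run_theory_experiments(
    K: float = 4.0,
    Delta_grid=None,
    delta_grid=None,
    omega_hz: float = 55.0,
    noise_sigma: float = 1.0,
    signal_amplitude: float = 1.0,
    switch_rate: float = 2.0,
    smooth_sigma: float = 0.1,
    duration: float = 40.0,
    dt: float = 2e-4,
    seed: int = 0,
) -> pd.DataFrame:
    """Closed-form maps plus delay-Kuramoto simulations on the same grid.

    Per (Delta, delta) cell: phi*, |Q'| transmission, S and dS from the
    sinusoidal theory, the simulated correlation of the receiver phase rate
    with a dichotomous signal injected into oscillator 1, and the simulated
    transmission imbalance measured as a *paired-direction* difference:
    the same signal and identical noise streams are run once into
    oscillator 1 (reading oscillator 2) and once into oscillator 2
    (reading oscillator 1), and the two correlations are subtracted, so
    the shared phase-diffusion noise cancels.

    The telegraph signal's mean holding time (1/switch_rate) is chosen
    long compared with the locking relaxation time ~1/K so each state is a
    quasi-static detuning step; its amplitude is K/4, weak relative to the
    locking half-width 2K.  The default delta grid is offset from 0 so no
    column sits exactly on the singular delay or the locking boundary.
    """
    if Delta_grid is None:
        Delta_grid = np.linspace(-4.0, 4.0, 9)
    if delta_grid is None:
        delta_grid = 0.26 + np.arange(12) * 2 * np.pi / 12
    Delta_grid = np.asarray(Delta_grid, dtype=float)
    delta_grid = np.asarray(delta_grid, dtype=float)
    maps = phase_theory.theory_maps(Delta_grid, delta_grid, K=K)
    signal = phase_theory.dichotomous_signal(
        duration, switch_rate=switch_rate, amplitude=signal_amplitude,
        seed=seed, dt=dt,
    )
    omega = phase_theory.hz_to_radps(omega_hz)
    burn = int(round(2.0 / dt))  # discard the locking transient
    corr_dir = {}
    for direction in (1, 2):
        _, th1, th2 = phase_theory.simulate_pair_grid(
            Delta_grid, delta_grid, omega_mean=omega, K=K, duration=duration,
            dt=dt, signal=signal, noise_sigma=noise_sigma, seed=seed + 1,
            signal_to=direction,
        )
        recv = th2 if direction == 1 else th1
        c = np.full(maps.phi_star.shape, np.nan)
        for i in range(len(Delta_grid)):
            for j in range(len(delta_grid)):
                c[i, j] = phase_theory.transmission_correlation(
                    recv[burn:, i, j], signal[burn:], dt,
                    smooth_sigma=smooth_sigma,
                )
        corr_dir[direction] = c
    corr = corr_dir[1]
    dS_sim = corr_dir[1] - corr_dir[2]
    rows = []
    for i, D in enumerate(Delta_grid):
        for j, d in enumerate(delta_grid):
            rows.append(dict(
                Delta=D, delta_rad=d, K=K,
                phi_star=maps.phi_star[i, j],
                transmission=maps.transmission[i, j],
                S=maps.S[i, j], dS=maps.dS[i, j],
                corr_sim=corr[i, j], dS_sim=dS_sim[i, j],
                locked=not np.isnan(maps.phi_star[i, j]),
            ))
    return pd.DataFrame(rows)
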