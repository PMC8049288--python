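"""Deterministic synthetic inputs with known ground truth.

These generators exercise the measurement layer without running the
network simulator: perfectly periodic (optionally jittered) rasters with a
known period and participation, correlated Gaussian pairs with closed-form
mutual information, and lagged copies with a known flow direction.  They
are oracles, not surrogates for real spike statistics.
"""

from __future__ import annotations

import numpy as np

from .errors import InvalidInputError
from .netsim import SpikeRaster

__all__ = [
    "periodic_raster",
    "gaussian_pair",
    "gaussian_mi_bits",
    "lagged_copy",
]


def periodic_raster(
    N: int = 100,
    period: float = 14.0,
    participation: float = 1.0,
    jitter_sd: float = 0.0,
    duration: float = 1000.0,
    seed: int = 0,
    dt: float = 0.01,
    pop: int = 0,
) -> SpikeRaster:
    """Raster in which, every `period` ms, a Bernoulli(`participation`)
    subset of the N neurons fires at the cycle time plus Gaussian jitter.

    With no jitter and full participation the coherency index is exactly 1
    and the detected period equals `period`.
    """
    if period <= 0 or duration <= 0:
        raise InvalidInputError("period and duration must be positive")
    rng = np.random.default_rng(seed)
    cycle_times = np.arange(period, duration - period, period)
    times, ids = [], []
    for t0 in cycle_times:
        fire = rng.random(N) < participation
        who = np.nonzero(fire)[0]
        tt = np.full(len(who), t0)
        if jitter_sd > 0:
            tt = tt + jitter_sd * rng.standard_normal(len(who))
        keep = (tt > 0) & (tt < duration)
        times.append(tt[keep])
        ids.append(who[keep])
    t = np.concatenate(times) if times else np.empty(0)
    i = np.concatenate(ids) if ids else np.empty(0, dtype=np.int64)
    order = np.argsort(t, kind="stable")
    return SpikeRaster(
        times=t[order],
        neuron_ids=i[order].astype(np.int64),
        pop_ids=np.full(len(t), pop, dtype=np.int64),
        duration=duration,
        dt=dt,
        n_neurons=N,
    )


def gaussian_mi_bits(rho: float) -> float:
    """Mutual information of a bivariate normal pair: -log2(1 - rho^2)/2."""
    return float(-0.5 * np.log2(1.0 - rho**2))


def gaussian_pair(
    n: int, rho: float, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, float]:
    """Bivariate normal samples with correlation `rho`.

    Returns (x, y, mi_bits) where mi_bits is the analytic mutual
    information ground truth.
    """
    if not -1.0 < rho < 1.0:
        raise InvalidInputError("|rho| must be < 1")
    rng = np.random.default_rng(seed)
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    x = z1
    y = rho * z1 + np.sqrt(1.0 - rho**2) * z2
    return x, y, gaussian_mi_bits(rho)


def lagged_copy(
    x: np.ndarray,
    lag_samples: int,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """y(t) = x(t - lag) + noise, with the leading `lag_samples` entries of
    y filled by wrapping x (so lengths match).

    For small noise, the delayed-mutual-information curve dMI(x -> y) peaks
    at the configured lag, and the net information flow is x -> y.
    """
    x = np.asarray(x, dtype=float)
    y = np.roll(x, lag_samples)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + noise_sd * rng.standard_normal(len(x))
    return y
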