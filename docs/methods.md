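# Methods

## Spiking model

Single neurons follow the classic Hodgkin–Huxley equations with
C = 1 μF/cm², g_K = 36, g_Na = 120, g_L = 0.3 mS/cm², E_K = −77,
E_Na = 50, E_L = −54.4 mV and the standard rate functions; the removable
singularities of α_n (v = −55 mV) and α_m (v = −40 mV) are evaluated by
their analytic limits whenever |v − v_sing| < 1e−7 mV. With these
parameters a neuron driven at 10–12 μA/cm² fires tonically at ≈68–73 Hz.

Synaptic efficacy is the positive double exponential
S(t) = (e^{−t/τ_d} − e^{−t/τ_r})/A with τ_r = 0.5 ms, τ_d = 3 ms and A the
peak value, so S has unit maximum and the synaptic weights are peak
conductances: g_EE = 3.75, g_IE = 7.5, g_EI = g_II = 15 μS/cm² (named
post ← pre), E_exc = 0 mV, E_inh = −80 mV. The synaptic current is the
conductance form I_syn = Σ g S (E_syn − v), which depolarizes for
excitatory reversal; long-range projections connect excitatory neurons of
the two populations only (p = 0.05) and use the E→E weight (3.75 μS/cm²)
unless configured otherwise.

Integration is Euler–Maruyama at dt = 0.01 ms with additive Gaussian
white-noise current on the voltage equation only, entering as
σ√dt·ξ/C per step with σ in μA/cm² (σ is a standard deviation; the default
is 0.5). For additive noise the Milstein correction vanishes, so this is
also the Milstein scheme for this model. Gating variables are clipped to
[0, 1] after each step and the (rare) clip events are counted on the
returned raster. Spikes are upward crossings of 0 mV with a 2 ms lockout.
Delays are realised as per-edge circular buffers at dt resolution; an edge
delay of 0 is clamped to one step (0.01 ms) because a buffer slot is read
before the current step's writes land in it. Each synapse's conductance is
tracked by two exponential accumulators (rise and decay), which reproduces
the summed double-exponential kernels exactly at machine precision.

Because the noise stream depends only on the seed and not on the injected
currents, two simulations differing only in a signal or pulse share
bit-identical noise. All perturbation measurements exploit this: the
zero-amplitude control is identically zero, and a pulse's effect is read
as the displacement of activity peaks between the matched runs.

## Signals

* **Slow signal**: Gaussian white noise low-pass filtered by a 4th-order
  Butterworth at 5 Hz (forward–backward, zero phase) on a 1 ms grid,
  interpolated to the integration grid, mean-removed and rescaled to a
  peak amplitude (default 1 μA/cm²; the amplitude is a free parameter of
  the protocol). Injected into the excitatory neurons of the sender only.
* **Pulse packets**: rectangular, default 0.25 μA/cm² × 2 ms for
  transmission experiments and 1 μA/cm² × 2 ms for the local pPRC, applied
  to all excitatory neurons of the target population at a prescribed
  phase of the ongoing cycle.

## Measures

Rates (MUA) are sums of **unit-peak** Gaussian kernels centred on spike
times (σ = 2 ms for cycle-resolved analysis on a 0.1–0.5 ms grid;
σ = 100 ms on a 1 ms grid for slow-modulation analysis), so N simultaneous
spikes give a peak of exactly N. The coherency index is the mean of 20
successive activity-peak heights divided by the population size. Peaks are
prominence-filtered local maxima (floor: 20% of the series span) refined
to sub-grid precision by a parabolic fit — without the refinement,
receiver-side phase shifts of ~0.02 ms would quantize to zero on the rate
grid. The oscillation period is the mean inter-peak interval; at least
three peaks are required, otherwise an insufficient-oscillation error is
raised.

Delayed mutual information uses the plug-in estimator on equal-width bins
(default 16) over each series' observed range, base-2 logs, over a
symmetric lag grid (default ±30 ms in 0.5 ms steps); the net flow is the
trapezoidal integral over positive lags minus that over negative lags.
No bias correction is applied; the bin count is recorded with every
output. Note that the plug-in estimate converges to the mutual
information of the *binned* variables, which is strictly below the
continuous value — for a ρ = 0.9 Gaussian pair, 16 equal-width bins over
the observed range retain 1.067 of the 1.198 continuous bits (an ~11%
quantization loss that no sample size removes; 64 bins reduce it to ~3%). For independent series the estimator's expected value is the
first-order bias (n_bins−1)²/(2n ln 2) — realizations scatter *around*
that value, so "no information" should be read as dMI at the scale of,
not strictly below, that bias. The zero-lag cross-covariance is unbiased
and unnormalized: Σ(x−x̄)(y−ȳ)/(n−1).

Phase locking of a pair requires both |T₂/T₁ − 1| < 0.01 and a circular
standard deviation of per-cycle peak offsets < 0.5 rad; the second clause
rejects slowly drifting near-unit ratios. The phase difference
(φ₁ − φ₂, wrapped to (−π, π], positive = population 1 leads) is reported
only for locked pairs.

PRC sign convention: a pulse that shortens the ongoing period (phase
advance) is positive; the shift is (T₀ − T)·2π/T₀ measured on the first
full cycle after the pulse has arrived (for the nPRC, the second baseline
peak after arrival, which lets conduction-delayed volleys act). The pPRC
partitions the cycle into 30 segments (pulse 1 μA/cm²) and the nPRC into
50 (pulse 0.25 μA/cm² into the sender), with ≥20 matched-noise trials per
segment at full resolution; the sweep layer defaults to 8 segments × 2
trials per cell, which resolves the curve shape at desk scale.

## Phase-oscillator theory

Two oscillators θ̇ᵢ = ωᵢ + K Q(θⱼ − θᵢ − δ) with equal couplings and
Q = sin unless supplied. δ is the *interaction phase* equivalent of the
conduction delay, δ = ω_locked·τ; converters between ms and radians use
the measured locked frequency. Internally frequencies are rad/s.

Locked phases solve Γ(φ*, δ) = −Δ/K with Γ(φ,δ) = Q(−φ−δ) − Q(φ−δ); roots
are found by a 2001-point scan of (−π, π] with bracketed Brent polishing
(residual < 1e−10) and filtered by the stability condition dΓ/dφ ≤ 0.
With several stable roots the one nearest 0 is returned and flagged
multistable. Outside the locking zone (|Δ| > 2K|cos δ| for sinusoidal Q)
the result is NaN rather than an exception, so grids can be mapped
directly. The closed forms S = 1 + Δ tan δ/√(4K²cos²δ − Δ²) and
ΔS = 2Δ tan δ/√(4K²cos²δ − Δ²) are masked (NaN) on and outside the
locking boundary and at the singular delays cos δ = 0.

The pulse prediction Q₂₁(β) = Q(β)·Q′(φ*−δ) is validated by a direct
numeric oracle: kick the locked sender phase by ε·Q(β) (ε = 0.01 rad) and
read the receiver displacement over a horizon h = 0.02/K, normalised by
εKh; relaxation back to the locked state biases this estimate by O(Kh),
about 2%.

## Kuramoto transmission experiment

The delay-Kuramoto runs use ω = 55 Hz (2π·55 rad/s), K = 4, phase noise
σ = 1 (per √s), Δ ∈ [−4, 4] on 9 values and 12 interaction phases over a
full cycle, offset by +0.26 rad so no column sits exactly on the singular
delay or on the locking boundary where the closed forms diverge. The
telegraph (dichotomous) signal switches at 2 s⁻¹ — its mean holding time
(0.5 s) is long compared with the locking relaxation time ~1/K = 0.25 s,
so each state acts as a quasi-static detuning step — with amplitude
K/4 = 1 rad/s, weak relative to the locking half-width 2K. Transmission is
the Pearson correlation of the receiver's phase rate (Gaussian-smoothed,
σ = 0.1 s) with the signal over 40 s runs (2 s burn-in).

The simulated **imbalance** is a paired-direction difference: the same
signal with identical noise streams is injected once into oscillator 1
(reading oscillator 2) and once into oscillator 2 (reading oscillator 1),
and the two correlations are subtracted. The shared phase-diffusion noise
cancels, which resolves imbalances an order of magnitude below the
single-run correlation noise floor. Cells where the theoretical imbalance
is exactly zero (Δ = 0) carry no sign information and are excluded from
theory/simulation sign comparisons.

## Problem sizes and protocol defaults

Sweeps run at desk scale by default: the single-population operating
point uses 3 s of simulation × 3 seeds; locking maps 2.5 s per cell;
slow-signal transmission 4 s per cell on a 5 detuning × 6 delay grid with
a 1 μA/cm² signal; the pulse sweep 8 segments × 2 trials per cell; the
Kuramoto grid 9 × 12 × 40 s. A `--full` flag on the relevant CLI commands
restores publication-scale resolution (30/50 segments, 20 trials,
multi-second cells) at a runtime of hours. The 500 ms at the start of
every spiking run is discarded before analysis (settling of the network
rhythm and the delay buffers).

## What the synthetic generators do and do not emulate

The fixture generators (periodic/jittered rasters, correlated Gaussian
pairs, lagged copies) have closed-form ground truth and exercise the
measurement layer end to end, but they are oracles, not surrogate data:
they contain no refractoriness, no rate–phase coupling, no E/I structure.
Tests passing on them certify the *estimators* (kernels, binning,
integration, sign conventions), while the claims about transmission
directionality rest on the spiking and phase-model simulations
themselves. The spiking model, in turn, is a single-frequency gamma
oscillator in a high-coherence regime: conclusions do not automatically
extend to multi-band rhythms, unstable/low-coherence oscillations, or
anatomically structured connectivity.

## Known limitations

* The delayed mutual information is a plug-in estimate without bias
  correction; comparisons across conditions with equal sample sizes are
  unbiased in rank, but absolute values depend on the bin count.
* The nPRC at desk-scale resolution (few trials) has a noise floor of
  ~0.005 rad; structure below that needs the full protocol.
* The phase reduction assumes weak coupling and delays comparable to or
  smaller than the period; the spiking network respects neither exactly,
  so theory/simulation agreement is qualitative (sign and shape), not
  quantitative.
* Exactly on the locking boundary the closed-form response diverges;
  cells there are masked rather than extrapolated.
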