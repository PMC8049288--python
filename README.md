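# delaycomm

Simulation and analysis of signal transmission between two oscillating
neural populations coupled with an axonal **transmission delay** δ and a
**natural-frequency detuning** ΔI, together with the delay-coupled
phase-oscillator theory that predicts when and in which direction signals
get through.

The package is for computational neuroscientists studying
communication-through-coherence: it answers, for a concrete spiking model,
*how the efficacy and the preferred direction of inter-areal communication
depend on the conduction delay and on which population oscillates faster.*

## The model

Each population is 100 Hodgkin–Huxley neurons (80% excitatory, 20%
inhibitory; random intra-population connectivity p = 0.1, intra delay
0.5 ms) with conductance synapses shaped by a unit-peak double exponential
(τ_r = 0.5 ms, τ_d = 3 ms):

    C dv/dt = I_ext + I_syn − g_K n⁴(v−E_K) − g_Na m³h(v−E_Na) − g_L(v−E_L)

Each neuron receives a constant drive I₀ plus independent Gaussian white
noise (σ = 0.5 μA/cm², Euler–Maruyama, dt = 0.01 ms). At I₀ = 11 μA/cm²
the population oscillates coherently in the low gamma range (~70 Hz,
coherency C ≈ 0.8). Two populations are coupled by sparse long-range
excitatory projections (p = 0.05) with a common delay δ; detuning is
imposed by driving population 1 at I₀ = 11 + ΔI.

The analysis layer provides the multi-unit activity (Gaussian-kernel
rates), the coherency index, zero-lag cross-covariance with an injected
slow signal, delayed mutual information dMI(d) and its net flow
(∫_{d>0} − ∫_{d<0}), phase-locking diagnosis, and population / non-local
phase response curves (pPRC, nPRC) estimated with noise-matched pulse
experiments.

The theory layer treats each population as a phase oscillator:

    θ̇₁ = ω₁ + K Q(θ₂ − θ₁ − δ),   θ̇₂ = ω₂ + K Q(θ₁ − θ₂ − δ)

with Q = sin. For the phase difference φ = θ₁ − θ₂ this gives the locked
state sin φ* = Δ/(2K cos δ), the pulse-transmission prediction
Q₂₁(β) = Q(β)·Q′(φ* − δ), and the slow-signal response function

    S = 1 + Δ tan δ / √(4K² cos²δ − Δ²),    ΔS = S(Δ) − S(−Δ)

whose sign structure explains why, for small delays (δ < π/2), the faster
population is the better sender, while for π/2 < δ < π the preferred
direction reverses.

## Worked example

```python
import numpy as np
from delaycomm import netsim, measures

net = netsim.build_network(netsim.PopulationSpec(), seed=0)   # I0=11, sigma=0.5
raster = netsim.simulate(net, duration=3500.0, seed=10)
rate = measures.firing_rate(raster, pop=0, t_start=500.0)     # sigma=2 ms MUA
peaks, T = measures.detect_peaks(rate)
print(f"f = {1000.0/T:.1f} Hz, C = {measures.coherency(rate, net.n_total):.2f}")
```

prints

```
f = 70.3 Hz, C = 0.87
```

i.e. the default population oscillates at ≈70 Hz and, on average, 87% of
the theoretical all-synchronous activity peak is reached each cycle.

On the theory side:

```python
from delaycomm import phase_theory as pt
phi = pt.locked_phase(Delta=2.0, K=4.0, delta=0.0)   # 0.2527 rad = arcsin(1/4)
S   = pt.response_function(2.0, 4.0, np.pi/4)        # 1.378: fast->slow amplified
dS  = pt.imbalance(2.0, 4.0, np.pi/4)                # 0.756: asymmetric channel
```

Sweep protocols (locking maps, slow-signal and pulse transmission,
connection asymmetry, Kuramoto runs) are exposed both as functions in
`delaycomm.experiments` and as CLI subcommands:

```
delaycomm characterize --seed 1 --out results/
delaycomm lock-sweep --di-grid -0.4,0,0.4 --delay-grid 0.5,4,8 --out results/
delaycomm theory-map --k 4 --out results/
```

Each command writes a TSV table with a JSON manifest (full configuration
and seeds) so any cell can be recomputed exactly.

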