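# Methods

## Model overview

`lsosim` simulates a principal neuron of the lateral superior olive (LSO)
as a single-compartment integrate-and-fire (IF) unit driven by stochastic
synaptic input, and quantifies how its binaural tuning degrades when
inhibitory afferents are removed and recovers when the surviving synapses
are homeostatically scaled.

Two membrane models are implemented.  The **active IF** model carries a
low-voltage-activated potassium (KLVA) conductance:

- C dV/dt = g_L(E_L − V) + g_KL·d(E_K − V) + g_ex(E_ex − V) + g_inh(E_inh − V) + I_spike,
  with C = 24 pF, g_L = 14.4 nS, g_KL = 21.6 nS, E_L = −56 mV, E_K = −75 mV.
- KLVA activation d(t) relaxes to d_∞(V) = α_d/(α_d + β_d) with time
  constant 1/(α_d + β_d), where α_d(V) = 0.5·e^{(V+50)/16} ms⁻¹ and
  β_d(V) = 0.5·e^{−(V+50)/16} ms⁻¹.
- A spike is counted when V ≥ V_θ = −45.8 mV.  The neuron is then
  absolutely refractory for T_ref = 1.6 ms: the membrane keeps integrating
  (so the injected spike current can shape a spike-like voltage excursion)
  but threshold crossings are not counted.  Threshold testing resumes at
  T_θ + T_ref; if V is still suprathreshold at that moment the next spike
  fires at the refractory limit.  This is the literal reading of the model
  definition; the alternative (waiting for V to re-cross from below) would
  interact with the spike current and is noted as a sensitivity candidate.
- Each crossing injects I_spike(s) = 24·e^{−s/0.15} − 12·e^{−s/0.30} nA
  (s = time since crossing).  Overlapping injections superpose linearly;
  they are carried by two exponential state variables, which makes the
  superposition exact.

The **passive IF** variant (g_KL = 0, g_L = 26.4 nS, E_L = V_reset =
−60 mV, V_θ = −45.1 mV) clamps V to the reset potential during the
refractory period.  It serves as a control showing that the conclusions do
not depend on the KLVA conductance.

Units are chosen self-consistently: time ms, voltage mV, conductance nS,
capacitance pF, current pA (nS·mV = pA; pA/pF = mV/ms).  The spike current
is specified in nA and converted internally.

## Synaptic input

Each presynaptic spike adds a unitary alpha conductance
α(t) = A·(t/τ)·e^{1−t/τ}, peaking at A a lag τ after the spike
(excitatory: A_ex = 3.5 nS, τ_ex = 0.16 ms, E_ex = 0 mV; inhibitory:
A_inh = 12 nS default, τ_inh = 0.32 ms, E_inh = −75 mV).  The neuron
receives M_ex = 20 excitatory fibers and M_inh = 0–16 inhibitory fibers
(default 8), all mutually independent.

Fiber firing:

- **Unmodulated tones** — homogeneous Poisson with the sigmoidal rate
  λ(SPL) = 30 + 240/(1 + e^{−(SPL−20)/6}) spikes/s.  The ipsilateral
  (excitatory) level is fixed at +35 dB; the contralateral (inhibitory)
  level is 35 + ILD.  Implemented by exponential inter-event sampling;
  the logistic is evaluated via `expit`/`tanh` forms for overflow safety.
- **AM tones** — inhomogeneous Poisson whose per-cycle intensity profile is
  a von Mises density scaled so the cycle-averaged rate is
  λ(f_m) = 180 − 0.03·f_m spikes/s, with concentration κ solved from the
  target vector strength VS(f_m) = 0.65·(1 − e^{(f_m−2000)/500})/(1 +
  e^{(f_m−2000)/500}) through the Bessel-ratio identity VS = I₁(κ)/I₀(κ)
  (bracketed Brent root find, cached, 1e-10 relative tolerance).
  Sampling is by thinning against the homogeneous envelope at the
  intensity peak λ_max = λ·e^κ/I₀(κ), which is exact for bounded
  intensities.  All excitatory fibers lock to phase 0; inhibitory fibers
  lock to −Δφ, so a positive interaural phase difference Δφ means
  inhibition arrives earlier in the cycle.

Fibers start emitting at t = 0 and the full 500-ms window enters the rate
statistics; no onset ramp or onset exclusion is applied, because the
analysis targets sustained responses.

## Numerical integration

Both membrane equations and the KLVA kinetics are conditionally linear in
their own state variable, so each is advanced with an **exponential Euler**
update (exact for frozen coefficients over one step).  Synaptic
conductances are *not* obtained by summing kernels over all past spikes;
each receptor type carries the equivalent two-state linear filter
(a′ = −a/τ, g′ = −g/τ + a, impulse weight A·e/τ), advanced by its exact
discrete-time map.  This is algebraically identical to direct kernel
summation with spike times quantized to the step grid (verified to 1e-9
relative in the tests) and costs O(steps + spikes).

The production step is **dt = 4 µs**.  Convergence was measured directly:
tuning-curve mean rates at dt = 4 µs differ by < 0.3% from dt = 2 µs and
1 µs at every probed ILD, comfortably inside the 1% dt-halving criterion
asserted by the test suite, and per-trial spike counts change by at most
one spike.  Spikes are assigned to the first grid time with V ≥ V_θ
(no sub-step interpolation); dt ≪ τ_ex makes the resulting timing bias
negligible at the rate level.  The integrator is numba-compiled with a
restricted fast-math subset (`contract`, `arcp`, `reassoc`, `nsz`) that
preserves NaN/Inf semantics so a diverging state still raises.

A brute-force pure-Python reference integrator (direct kernel summation at
every step) lives in the test suite and must reproduce the production
integrator's spike times exactly on fixed fixtures, for both membrane
models.

## Randomness and reproducibility

One master seed controls everything.  Every (stimulus, trial) pair draws
from its own `SeedSequence` substream keyed by the *physical* stimulus
(contralateral SPL, or modulation frequency and phase difference), and
each fiber spawns a child stream.  Consequences: results are independent
of execution order, identical configurations are bit-reproducible, and a
tuning curve simulated on a wider grid contains — sample for sample — the
curves of all midpoint-shifted neurons (used by the population driver).
Scenario sweeps derive per-scenario seeds from the master seed and keep
them below 2³¹.

## Tuning analysis

For each stimulus grid point the across-trial mean μ and standard
deviation σ of the spike rate (count/duration) are computed, plus the Fano
factor (count variance / count mean; undefined and reported as NaN when no
spikes occur).  Derived measures:

- **Modulation depth** = max μ − min μ.
- **Midpoint** = the ILD where μ crosses (max + min)/2, linearly
  interpolated; with multiple crossings the one nearest the
  steepest-slope segment is used.  Half-height is the standard midpoint
  definition for sigmoids; the analysis never needed the tie-break on
  simulated curves.
- **Discriminability** D = (μ₁ − μ₂)/√((σ₁² + σ₂²)/2) for neighboring grid
  points (ΔS = 2 dB or 10°); for Gaussian rates |D| = ΔS·√I_F.
  Range summaries average **|D|**: on the periodic phase task D changes
  sign across the grid, so a signed average would vanish by symmetry and
  could not represent task performance; |D| is the only reading under
  which the summary is meaningful on both tasks, and on the ILD task
  (where D keeps one sign) it coincides with the signed average.
- Zero pooled variance with equal means yields D = 0; with unequal means
  D is undefined and flagged as NaN with a warning.

Standard errors of normalized summaries are estimated by splitting the
trial ensemble into 10 disjoint blocks, recomputing the summary per block,
and combining numerator and denominator block-SEs in quadrature.

## Inhibition-loss scenarios

The unitary inhibitory amplitude follows the scenario rule exactly
(`uncompensated` 12 nS; `compensated` 12·8/M_inh nS; `overcompensated`
additionally ×(2 − M_inh/8), i.e. applied on top of the compensated
amplitude — the only reading under which the total conductance decreases
linearly in M_inh and is 50% above default at M_inh = 4).  M_inh = 0 is
valid only uncompensated: no fibers remain to potentiate.  Nothing else
changes between scenarios.

## Population coding

22 neurons with tuning-curve midpoints uniformly spanning −26…+16 dB
(2-dB steps) are built by *input-level translation*: the neuron is driven
with contralateral SPL = 35 + ILD − shift, which translates the curve
exactly with no interpolation.  The population driver simulates one master
curve per scenario on a superset grid (−61…+71 dB) and slices it, which is
bit-identical to direct simulation of each shifted neuron (by the
stimulus-keyed substreams above) at a fraction of the cost.  Each neuron is
paired with a mirrored twin (curve reflected about 0 dB, the contralateral
LSO's delegate); the bilateral difference has mean μ(ILD) − μ(−ILD) and
variance σ²(ILD) + σ²(−ILD) (independent sides, symmetric bilateral
circuits assumed).  The per-pair |D| curves are averaged across the
population (every pair weighted equally), summarized over ±35 dB, and
normalized to the default scenario, which removes the dependence on
population size and trial count.

## What the generator does and does not emulate

The synthetic input model reproduces the level-driven rates, the
modulation-frequency-dependent rates and phase locking, and the mutual
independence of bushy-cell and MNTB afferents.  It does **not** model
auditory-nerve/bushy-cell mechanisms upstream of those rate functions,
onset-type LSO neurons, temporal-jitter changes with age, interaural
correlation structure, or adaptation within a stimulus.  Passing tests
therefore establish the behavior of this idealized circuit, not of every
physiological detail of real LSO input.

## Problem sizes

The reference protocol for tuning statistics is 4000 trials of 500-ms
stimulation per grid point.  The package default (`run_tuning`) and the
test/acceptance runs use scaled-down ensembles — 500 trials per point for
midpoint estimates, 150–300 for discriminability sweeps and population
runs, with tolerances widened by the corresponding √n standard-error
inflation — chosen so the full analysis reruns in tens of minutes on a
single core.  Grids: ILD −45…+15 dB in 2-dB steps (31 points; population
superset −61…+71 dB), envelope phase −180…+180° in 10° steps (37 points),
modulation frequencies 150/300/450 Hz (default 300 Hz).

## Known limitations

- Rate-based measures only; no spike-timing decoders or ROC analysis.
- The averaged-|D| summary is one specific readout convention; unnormalized
  discriminability would additionally depend on trial counts.
- Amplitude compensation is static and uniform across synapses; no
  dynamic or activity-dependent plasticity rule is simulated.
- Single-compartment morphology: no dendritic placement of synapses.
- Monte-Carlo acceptance checks inherit sampling noise; their tolerances
  include explicit 3-SE terms rather than pretending determinism.
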