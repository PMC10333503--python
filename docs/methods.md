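# Methods

This note records the model, the numerical conventions, and the design
choices behind `spikerls`, in enough detail to reproduce or audit any
number the package computes.

## Network model

N leaky integrate-and-fire neurons with dimensionless voltage
(`v_rest = 0`, `v_threshold = 1`, `v_reset = 0`), `tau_m = 10` ms,
absolute refractory period 2 ms. Sub-threshold integration uses the exact
exponential propagator with the input held constant over the step:

    V <- v_rest + (V - v_rest) e^(-dt/tau_m) + (1 - e^(-dt/tau_m)) mu,

with `dt = 0.1` ms by default. Reciprocals/exponentials of all time
constants are precomputed once. Threshold crossing, reset and refractory
clamping are expressed branchlessly (`where(spiked, v_reset, v)`), so the
update is vectorization- and accelerator-friendly; spike effects land on
their targets within the same step (the model has no propagation delays).
The sub-threshold rule is a plugin (`CellModel`); the packaged
implementation is the standard LIF, and generalized LIF variants
(adaptation currents, dynamic thresholds) can be supplied without touching
the simulator.

Each trial begins with a stimulus epoch (default 50 ms) in which every
neuron receives a constant current with a random, seed-frozen amplitude
(default Uniform(0, 1)); this sets the network to a reproducible state
from which the target interval `[0, T]` unfolds. Initial voltages are
drawn Uniform(v_rest, v_threshold) from the trial seed so the first
integration step does not produce a synchronized volley.

## Synapses and the read-out identity

Synaptic filtering is a double exponential with shared rise constant
`tau_rise = 2` ms. Two conventions coexist, deliberately:

* **Trace / plastic pathway.** Each neuron j carries a trace `r_j` of its
  own spikes with *per-neuron* decay constant `tau_d,j`, log-uniform in
  [10, 100] ms, and **unit area** per spike — so `r_j` estimates the
  instantaneous firing rate in kHz (a 10 Hz neuron has mean trace 0.01).
  The plastic synaptic current is evaluated every step through the exact
  identity `u_i = sum_l W[i,l] r[pre[i,l]]` (a batched gather-dot).
  Consequences: (a) the RLS regression problem is exactly linear in the
  stored weights, and weight updates act on the current instantly; (b) the
  regressor magnitudes keep the RLS matrix P of order one, inside the
  representable range of the scaled-integer codes; (c) the heterogeneous
  decay constants give the regressor pool temporally diverse basis
  functions. The last point is load-bearing: with a single shared time
  constant the noise-driven (K = 0) network cannot bootstrap — the
  closed-loop structure decays between trials and training stalls near
  zero correlation, whereas with the 10–100 ms spread the same benchmark
  trains to correlation ≈ 0.95.

* **Static pathway.** Static synapses use a single shared decay constant
  (`tau_decay_static = 10` ms) and classic postsynaptic accumulation: a
  spike of neuron j adds `w_e` to the rise variable of each target, with
  pure sum semantics (order-independent up to float association). The
  filter area is `tau_decay_static`, so balanced `j0/sqrt(K)` weights
  yield O(1) drives at rates of tens of Hz.

## Balanced-state defaults

Cell types: 80% excitatory. Weight constants (× `1/sqrt(K)`):
`j_EE = +1`, `j_EI = -6`, `j_IE = +1`, `j_II = -5`; external drives
`X_E = 0.10 sqrt(K)`, `X_I = 0.08 sqrt(K)`. These were chosen from the
two-population mean-field balance equations with the E/I fractions folded
in: the fraction-weighted interaction matrix must have negative trace and
positive determinant for the balanced fixed point to be dynamically
stable (weaker inhibition, e.g. `j_II = -1.8`, satisfies the rate
equations but is unstable and the simulation runs away to the refractory
limit). Measured at N = 4096, K = 400, sigma = 0: population rate
≈ 13.6 Hz, mean CV-ISI ≈ 1.07 — fluctuation-driven irregular firing.

With no static synapses (K = 0) the drive defaults to `X = 1.1` with
noise `sigma = 0.1`; the resulting ~50 Hz operating point is the
benchmark regime used throughout the tests (see below).

## Noise convention

Noise is a per-step voltage increment `sigma * sqrt(dt) * N(0,1)`, i.e.
an Ornstein-Uhlenbeck voltage with stationary variance
`sigma^2 tau_m / 2`. The F-I curve's voltage-noise parameter relates as
`sigma_v = sigma * sqrt(tau_m)` (`FICurveParams.from_network` applies
this). Stated so that `sigma` is comparable across `dt`.

## RLS trainer

Per neuron, `P(0) = I/lambda` with `lambda = 1` (config-exposed), learn
interval 10 ms (an integer multiple of `dt`, validated). Within a tick
the order is fixed: compute `k = P r`, update the weights with gain
`c·e·k` where `c = 1/(1 + r'k)`, then update `P` by the rank-1
subtraction. One pass over any fixed sample sequence equals the ridge
solution exactly; this is asserted against a direct normal-equations
solve in the tests. The training error uses `u` sampled at the learn tick
through the read-out identity; targets are held on the learn-tick grid
(no sub-tick interpolation).

Only `P` is precision-reduced; weights, traces, currents and voltages
stay float64. Integer codes store `round(P * 2^(nbits-2))` with
saturating conversion; kernels dequantize during accumulation in a
float64 accumulator and re-quantize once on write-back. In exact
arithmetic `1 + r'Pr >= 1`; when a coarsely quantized panel accumulates
enough rounding error to certify indefiniteness (denominator < 0.5, i.e.
a gain impossible for any positive-semidefinite P), the training loop
applies *covariance resetting* — the standard adaptive-filtering remedy:
that panel returns to `I/lambda` and the neuron skips one update
(counted in the diagnostics). The strict `rls_step` contract (raising on
loss of positive-definiteness) is preserved for the float codes.

Observed ladder behavior on the benchmark, which tracks the storage
resolution: f64 ≈ f32 ≈ i16 (rank-1 updates, ~1e-3 in magnitude, resolve
cleanly at 2^-14); the 12-bit code sits at its rounding edge — updates
register with large relative rounding error, so P slowly corrupts and the
correlation peaks and then declines; the 8-bit code cannot represent the
updates at all, so P stays frozen at the identity and learning degrades
to constant-gain LMS. Frozen-weight correlations order accordingly:
floats ≈ i16 > i12 > i8.

## Targets

* **Sinusoids**: `f_i(t) = offset + A sin(2 pi t / period + phi_i)` with
  seed-frozen uniform phases. Benchmark conditions: A = 0.5, offset 0,
  period 1 s, trial 2 s.
* **F-I curve**: noiseless closed form
  `1000/(tau_ref + tau_m ln((mu - v_reset)/(mu - v_threshold)))` above
  threshold; for `sigma_v > 0` the diffusion-approximation first-passage
  rate with the integrand written as `erfcx(-x)` for numerical stability
  (adaptive quadrature; means more than 8 noise s.d. below threshold
  report rate 0, below 1e-25 Hz). Verified against a Monte-Carlo LIF at
  small `dt`.
* **Inversion**: Brent root-finding on the monotone noisy curve
  (requires `sigma_v > 0` and a rate below the refractory ceiling);
  round-trip accurate to ~1e-9. PSTH conversion clips rates to
  [0.1 Hz, 0.95 × 1000/tau_ref] (zero rates are not invertible; all-zero
  rows are floored with a warning), inverts bin-by-bin with a bracket
  walked along each trajectory, resamples 20 ms → learn grid by monotone
  cubic (PCHIP, no overshoot into non-invertible ranges), and subtracts
  the constant external drive so that trained `u + X_bal` reproduces the
  inferred mean input.

## Synthetic PSTH generator

Stands in for session-averaged electrophysiology: per neuron, a baseline
rate (2–10 Hz) plus per-condition random ramp and Gaussian-bump
components in latent-current space, clipped to keep rates in
[~0, 40 Hz], passed through the same F-I curve — so the latent currents
are known exactly and the inversion pipeline can be tested for parameter
recovery. Two conditions per neuron emulate a two-alternative task. What
it does **not** emulate: trial-count sampling noise in the PSTHs,
correlated across-neuron variability, non-stationary baselines, or any
cell-type structure — passing tests therefore demonstrate the pipeline's
correctness, not robustness to real recording artifacts.

## Benchmark conditions and problem sizes

The synthetic benchmark used by the tests and `scripts/acceptance.py`:
N = 512 (ladder: 256), L = 64, K = 0, sigma = 0.1, X = 1.1, sinusoid
targets as above, lambda = 1, learn every 10 ms, trials of 2 s. Training
correlation is the per-iteration mean Pearson r between tick-sampled `u`
and `f`; frozen correlation re-runs trials with learning off and averages
over noise realizations (phase diffusion of the autonomous replay makes
single frozen trials noisy, so comparisons average 10–16 trials).
The plastic-input comparison trains L = 32 vs 128 for a matched 10
iterations on 2–3 seeds. These sizes were chosen as the smallest at which
the studied effects are comfortably resolved.

## Determinism

All sampling flows through seeded numpy Generators; execution is serial.
Each training iteration derives its noise stream from
`SeedSequence((seed_noise, iteration))`, so resuming from a checkpoint is
bit-identical to the uninterrupted run without serializing RNG state.
Checkpoints carry a hash of the science-relevant configuration (budget
and stopping fields excluded) and are refused against a mismatched
config unless forced.

## Known limitations

* The trained network replays targets as an autonomous noisy dynamical
  system; the phase of the replay diffuses over seconds, which bounds
  single-trial frozen correlations well below the training correlation,
  and more so at small N.
* Only the standard LIF cell is packaged; the plugin seam accepts
  generalized variants but the F-I inversion assumes the LIF form.
* Integer-coded P is faithful to scaled fixed-point storage but no speed
  advantage is claimed; kernels aim at correctness and memory shape, not
  throughput.
* Static and plastic pathways use different filter-area conventions
  (documented above); mixed K > 0 training works but the plastic weights
  are not interpretable on the static `j/sqrt(K)` scale.
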