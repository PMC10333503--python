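# spikerls

Recursive least-squares (RLS) training of spiking recurrent neural
networks: fit the incoming plastic synapses of every neuron in a leaky
integrate-and-fire (LIF) network so that its synaptic current reproduces a
prescribed target trajectory.

## Who this is for

Computational neuroscientists who want to build *data-driven* spiking
network models: given trial-averaged firing rates (peri-stimulus time
histograms, PSTHs) of recorded neurons — or synthetic benchmark targets —
the trainer finds recurrent weights under which the network autonomously
replays those activity patterns after a brief stimulus sets its state.
The package is equally usable as a plain balanced-network LIF simulator.

## The model and the algorithm

**Network.** N current-based LIF neurons (dimensionless voltage: rest 0,
threshold 1; `tau_m` = 10 ms, refractory 2 ms). Each neuron receives

* an average of K **static** synapses (Erdos-Renyi, balanced `1/sqrt(K)`
  scaling, Dale's law by cell type) — fixed;
* exactly L **plastic** synapses (uniform random partners, `1/L` scaling)
  — trained, allowed to change sign;
* a constant external drive `X_bal`, and optionally white noise of
  variance `sigma^2` (the K = 0 regime).

Spikes are filtered by double-exponential synapses whose decay constants
vary across neurons (log-uniform 10–100 ms), giving each presynaptic
neuron a trace `r_j(t)`. Because filtering sits on the presynaptic side,
the plastic synaptic current obeys the exact identity

```
u_i(t) = sum_j W_ij r_j(t),
```

which makes every neuron an independent linear read-out of its L
presynaptic traces.

**Learning.** Each neuron i keeps the inverse regularized correlation
matrix `P_i` of its regressor stream (`P_i(0) = I/lambda`), an L×L
symmetric matrix stored as a packed triangle, batched over all N neurons
(the dominant memory cost, `N·L(L+1)/2` elements). Every `dt_learn`
(10 ms) the standard RLS update runs for all neurons at once:

```
k = P_i r,   c = 1/(1 + r'k),   w_i -= c e_i k,   P_i -= c k k',
e_i = u_i - f_i(t).
```

One pass of this recursion equals ridge regression exactly — the package's
core correctness oracle. `P` may be stored in reduced precision: float64,
float32, or integers scaled by `2^(nbits-2)` (int16, a 12-bit code inside
int16, int8) with saturating conversion.

**Targets.** Either sinusoids with random phases (the benchmark), or
currents obtained from firing-rate trajectories by inverting the noisy-LIF
transfer function (Ricciardi first-passage rate, Brent root-finding). A
synthetic PSTH generator produces smooth, condition-dependent rate
trajectories (0–40 Hz) with known latent currents for end-to-end testing.

## Worked example

```python
from spikerls import NetworkConfig, TrainConfig, sinusoid_targets
from spikerls.model import SpikingRLSModel

config = NetworkConfig(n_neurons=256, n_plastic=48, k_static=0)
targets = sinusoid_targets(256, period=1000.0, amplitude=0.5, offset=0.0,
                           duration=2000.0, bin_ms=10.0, seed=7)
model = SpikingRLSModel(targets, config, TrainConfig(n_iterations=12))
result = model.fit()
print(result.summary())
print(result.evaluate(seed=0).summary_line())
```

prints

```
          Spiking-network RLS training results
==========================================================
neurons (N):             256    static K:        0
plastic L:                48    noise sigma:    0.100
precision (P):           f64    lambda:       1.000
dt / dt_learn (ms):     0.10        10.0
iterations run:           12
----------------------------------------------------------
final mean corr:      0.9631    median:   0.9633
final error RMS:      0.1078    rate:   49.10 Hz
==========================================================
mean corr 0.804, median corr 0.804, mean rate 48.35 Hz, mean CV-ISI 0.85
```

The first block is the training summary: after 12 stimulated trials the
mean Pearson correlation between each neuron's synaptic current and its
target, sampled at the learn ticks of the final training trial, is 0.96.
The last line is a *frozen-weight* evaluation — a fresh trial with
learning switched off: the trained network autonomously reproduces the
targets at correlation 0.80 on a single noisy trial, firing irregularly
at ~48 Hz. PSTH-driven training works the same way via
`SpikingRLSModel.from_psth(...)`.

A command-line interface wraps the same pipeline:

```bash
spikerls init --out run.yaml
spikerls train --config run.yaml --out-dir runs/
spikerls run   --config run.yaml --checkpoint runs/checkpoint.npz --n-trials 5
spikerls eval  --config run.yaml --checkpoint runs/checkpoint.npz
spikerls benchmark --sizes 256,512 --n-plastic 64
```

## Layout

| module | contents |
|---|---|
| `spikerls.linalg` | packed-symmetric storage, batched mat-vec/rank-1 kernels, precision codes |
| `spikerls.network` | static/plastic graph builders, stimulus, noise, configuration |
| `spikerls.simulate` | LIF network integration (pluggable cell model) |
| `spikerls.rls` | batched per-neuron RLS updates and the training loop |
| `spikerls.targets` | sinusoids, F-I curve and inversion, PSTH conversion, synthetic PSTHs |
| `spikerls.evaluate` | correlation reports, PSTHs from rasters, CV-ISI |
| `spikerls.io`, `spikerls.cli` | configs, checkpoints, text artifacts, CLI |
| `spikerls.model` | the `SpikingRLSModel` / `SpikingRLSResults` facade |

See `docs/methods.md` for the modelling choices, parameter conventions and
known limitations.
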