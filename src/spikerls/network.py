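"""Connectivity, stimulus, and noise construction for the spiking network.

Two kinds of synapses coexist:

* **static** synapses — an Erdos-Renyi graph with mean in-degree K, weights
  of magnitude j0/sqrt(K) signed by the presynaptic cell type (balanced
  scaling; these are never trained);
* **plastic** synapses — exactly L presynaptic partners per neuron, sampled
  uniformly without replacement, initial weights of magnitude O(1/L); these
  are the weights the RLS trainer adjusts, and they are allowed to change
  sign during training.

All builders are deterministic functions of their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import numpy as np


@dataclass
class StaticGraph:
    """Fixed balanced connectivity in CSR-by-presynaptic-neuron form."""

    n_neurons: int
    mean_in_degree: float
    is_excitatory: np.ndarray          # (N,) bool cell-type labels
    out_ptr: np.ndarray                # (N+1,) edge offsets per presynaptic neuron
    out_tgt: np.ndarray                # postsynaptic neuron per edge
    out_w: np.ndarray                  # signed weight per edge

    @property
    def n_edges(self) -> int:
        return int(self.out_tgt.size)

    def in_degrees(self) -> np.ndarray:
        return np.bincount(self.out_tgt, minlength=self.n_neurons)

    @classmethod
    def empty(cls, n_neurons: int) -> "StaticGraph":
        return cls(
            n_neurons, 0.0,
            is_excitatory=np.ones(n_neurons, dtype=bool),
            out_ptr=np.zeros(n_neurons + 1, dtype=np.int64),
            out_tgt=np.empty(0, dtype=np.int64),
            out_w=np.empty(0, dtype=np.float64),
        )


@dataclass
class PlasticGraph:
    """Exactly L trainable presynaptic partners per neuron.

    ``pre_idx[i]`` lists neuron i's partners; ``weights[i]`` the matching
    weights.  The synaptic current is read through the live weight matrix
    (u_i = sum_l weights[i, l] * r[pre_idx[i, l]]), so weight updates take
    effect immediately.
    """

    n_neurons: int
    n_plastic: int                     # L
    pre_idx: np.ndarray                # (N, L) presynaptic partner of each slot
    weights: np.ndarray                # (N, L) trainable weights

    def copy(self) -> "PlasticGraph":
        return PlasticGraph(self.n_neurons, self.n_plastic,
                            self.pre_idx.copy(), self.weights.copy())


@dataclass
class StimulusProtocol:
    """Constant per-neuron current pulse that resets the network state.

    Active on [onset, onset + duration) ms relative to the learning window's
    origin (onset is negative: the pulse precedes t = 0).  Amplitudes are a
    frozen function of the seed, so every trial starts from the same
    stimulated state distribution.
    """

    amplitudes: np.ndarray
    onset: float
    duration: float

    def current(self, t: float) -> np.ndarray | float:
        if self.onset <= t < self.onset + self.duration:
            return self.amplitudes
        return 0.0


@dataclass
class NoiseSpec:
    """White-noise drive: per-step voltage increment sigma*sqrt(dt)*N(0,1)."""

    sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


@dataclass
class NetworkConfig:
    """Sizes, scalings and seeds that define one network realization.

    Voltage is dimensionless (rest 0, threshold 1); times are in ms.
    ``x_bal_e``/``x_bal_i`` default to the balanced-scaling values
    sqrt(K)*0.1 and sqrt(K)*0.08 when K > 0, else to a constant 1.1 (the
    noise-driven operating point used when static synapses are absent).
    """

    n_neurons: int = 512
    k_static: int = 0                  # mean static in-degree K
    n_plastic: int = 64                # plastic in-degree L
    sigma: float = 0.1                 # noise s.d. (voltage / sqrt(ms))
    x_bal_e: float | None = None
    x_bal_i: float | None = None
    frac_excitatory: float = 0.8
    j_ee: float = 1.0
    j_ei: float = -6.0
    j_ie: float = 1.0
    j_ii: float = -5.0
    plastic_init_scale: float = 1.0    # initial |w| ~ init_scale / L
    dt: float = 0.1                    # integration step (ms)
    tau_m: float = 10.0
    v_rest: float = 0.0
    v_threshold: float = 1.0
    v_reset: float = 0.0
    tau_ref: float = 2.0
    tau_rise: float = 2.0
    tau_decay_min: float = 10.0        # per-neuron synaptic decay constants are
    tau_decay_max: float = 100.0       # log-uniform in [min, max] ms
    tau_decay_static: float = 10.0     # shared decay of the static pathway
    stim_onset: float = -50.0
    stim_duration: float = 50.0
    stim_range: tuple = (0.0, 1.0)
    seed_graph: int = 1
    seed_stimulus: int = 2
    seed_noise: int = 3
    seed_rls: int = 4

    def __post_init__(self):
        if self.x_bal_e is None:
            self.x_bal_e = 0.1 * np.sqrt(self.k_static) if self.k_static > 0 else 1.1
        if self.x_bal_i is None:
            self.x_bal_i = 0.08 * np.sqrt(self.k_static) if self.k_static > 0 else 1.1

    def validate(self) -> None:
        problems = []
        if self.n_neurons < 2:
            problems.append("n_neurons must be at least 2")
        if not (0 <= self.k_static < self.n_neurons):
            problems.append("k_static must satisfy 0 <= K < N")
        if not (1 <= self.n_plastic < self.n_neurons):
            problems.append("n_plastic must satisfy 1 <= L < N")
        if self.sigma < 0:
            problems.append("sigma must be non-negative")
        if self.dt <= 0:
            problems.append("dt must be positive")
        if self.stim_duration <= 0:
            problems.append("stim_duration must be positive")
        if self.stim_range[0] > self.stim_range[1]:
            problems.append("stim_range low must not exceed high")
        if not (0.0 <= self.frac_excitatory <= 1.0):
            problems.append("frac_excitatory must be in [0, 1]")
        if self.v_reset >= self.v_threshold:
            problems.append("v_reset must be below v_threshold")
        if not (0 < self.tau_decay_min <= self.tau_decay_max):
            problems.append("tau_decay range must satisfy 0 < min <= max")
        if problems:
            raise ValueError("invalid network config: " + "; ".join(problems))

    def replace(self, **kw) -> "NetworkConfig":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d["stim_range"] = list(self.stim_range)
        return d


def assign_cell_types(n_neurons: int, frac_excitatory: float) -> np.ndarray:
    """Deterministic E/I labels: the first round(f*N) neurons are excitatory."""
    n_exc = int(round(frac_excitatory * n_neurons))
    labels = np.zeros(n_neurons, dtype=bool)
    labels[:n_exc] = True
    return labels


def build_static_graph(config: NetworkConfig, seed: int | None = None) -> StaticGraph:
    """Erdos-Renyi balanced graph: each directed edge i<-j present with
    probability K/N, weight j_{type(i),type(j)} / sqrt(K), no self-edges."""
    n, k = config.n_neurons, config.k_static
    if not (0 <= k < n):
        raise ValueError(f"K must satisfy 0 <= K < N, got K={k}, N={n}")
    is_exc = assign_cell_types(n, config.frac_excitatory)
    if k == 0:
        g = StaticGraph.empty(n)
        g.is_excitatory = is_exc
        return g
    rng = np.random.default_rng(config.seed_graph if seed is None else seed)
    p = k / n
    scale = 1.0 / np.sqrt(k)
    out_ptr = np.zeros(n + 1, dtype=np.int64)
    tgt_chunks, w_chunks = [], []
    for j in range(n):                      # j = presynaptic neuron
        mask = rng.random(n) < p
        mask[j] = False                     # no self-connections
        tgt = np.flatnonzero(mask)
        j_exc = is_exc[j]
        jw = np.where(is_exc[tgt],
                      config.j_ee if j_exc else config.j_ei,
                      config.j_ie if j_exc else config.j_ii) * scale
        tgt_chunks.append(tgt)
        w_chunks.append(jw)
        out_ptr[j + 1] = out_ptr[j] + tgt.size
    return StaticGraph(n, float(k), is_exc, out_ptr,
                       np.concatenate(tgt_chunks).astype(np.int64),
                       np.concatenate(w_chunks))


def build_plastic_graph(n_neurons: int, n_plastic: int, seed: int,
                        init_scale: float = 1.0) -> PlasticGraph:
    """Per neuron, L distinct partners without replacement (self excluded);
    initial weights ~ Uniform(-1, 1) * init_scale / L."""
    if not (1 <= n_plastic < n_neurons):
        raise ValueError(
            f"L must satisfy 1 <= L < N, got L={n_plastic}, N={n_neurons}")
    rng = np.random.default_rng(seed)
    pre = np.empty((n_neurons, n_plastic), dtype=np.int64)
    for i in range(n_neurons):
        pick = rng.choice(n_neurons - 1, size=n_plastic, replace=False)
        # map [0, N-2] onto [0, N-1] \ {i}
        pre[i] = np.where(pick >= i, pick + 1, pick)
    w = rng.uniform(-1.0, 1.0, size=(n_neurons, n_plastic)) * (init_scale / n_plastic)
    return PlasticGraph(n_neurons, n_plastic, pre, w)


def build_stimulus(n_neurons: int, onset: float, duration: float,
                   amp_low: float, amp_high: float, seed: int) -> StimulusProtocol:
    """Per-neuron amplitudes ~ Uniform(amp_low, amp_high), frozen per seed."""
    if duration <= 0:
        raise ValueError("stimulus duration must be positive")
    if amp_low > amp_high:
        raise ValueError("amp_low must not exceed amp_high")
    rng = np.random.default_rng(seed)
    amps = rng.uniform(amp_low, amp_high, size=n_neurons)
    if amp_low == amp_high:
        amps = np.full(n_neurons, float(amp_low))
    return StimulusProtocol(amps, onset, duration)


def build_network(config: NetworkConfig):
    """Convenience: (StaticGraph, PlasticGraph, StimulusProtocol, NoiseSpec)."""
    config.validate()
    static = build_static_graph(config)
    plastic = build_plastic_graph(config.n_neurons, config.n_plastic,
                                  config.seed_graph + 1, config.plastic_init_scale)
    stim = build_stimulus(config.n_neurons, config.stim_onset, config.stim_duration,
                          config.stim_range[0], config.stim_range[1],
                          config.seed_stimulus)
    noise = NoiseSpec(config.sigma, config.seed_noise)
    return static, plastic, stim, noise
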