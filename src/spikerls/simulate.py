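"""Leaky integrate-and-fire network integration.

Dynamics per step of size dt (ms):

1. the plastic synaptic current is evaluated through the exact relationship
   ``u_plastic_i = sum_j W_ij r_j``, where r_j is presynaptic neuron j's
   filtered spike train — so weight changes act on the current instantly;
2. membrane update by the cell model from the total drive
   ``mu = u_static + u_plastic + X_bal + stimulus(t)``, plus (if sigma > 0)
   a white-noise voltage increment ``sigma*sqrt(dt)*N(0,1)``;
3. refractory neurons are clamped at V_reset;
4. neurons with V >= V_threshold spike; the reset is branchless
   (``V = where(spiked, V_reset, V)``) so non-spiking neurons are "reset"
   to their current value;
5. each spike increments the spiking neuron's own rise variable (unit
   jump) and, through the static graph, the static rise variable of its
   postsynaptic targets by the edge weight — pure sum semantics, in the
   same step (no propagation delays);
6. all rise/trace pairs decay exponentially using precomputed one-step
   coefficients (reciprocals of the time constants are taken once).

Synapse filter: double exponential with shared rise tau_r and *per-neuron*
decay constants tau_d,j (log-uniform over a configured range — synapses
with varying spike-filtering time scales, which gives the trainer a
temporally diverse regressor basis).  A spike injects a unit jump into the
rise variable and the trace integrates to tau_d per spike, so a neuron
firing at rate nu (kHz) carries a steady trace of about nu*tau_d.  The
filter sits on the *presynaptic* side: the same trace r_j serves every
target of j, which is what makes u = W r exact.  The static pathway keeps
a single shared decay constant and the classic weighted postsynaptic
accumulation.

The sub-threshold rule is a plugin: any object satisfying `CellModel`
(see `LIFCell`) can replace the standard leaky integrator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, runtime_checkable

import numpy as np

from . import _kernels
from .network import NetworkConfig, NoiseSpec, PlasticGraph, StaticGraph, StimulusProtocol


@runtime_checkable
class CellModel(Protocol):
    """Plugin contract for single-cell sub-threshold dynamics.

    Implementations expose the spike/reset parameters and a vectorized
    sub-threshold update.  Threshold crossing and reset are handled by the
    simulator (shared across cell models).
    """

    v_threshold: float
    v_reset: float
    tau_ref: float

    def prepare(self, dt: float) -> None: ...

    def subthreshold(self, v: np.ndarray, mu: np.ndarray) -> np.ndarray: ...


@dataclass
class LIFCell:
    """Standard leaky integrate-and-fire neuron.

    Sub-threshold: tau_m dV/dt = -(V - V_rest) + mu, integrated with the
    exact exponential propagator for the decay and the input held constant
    over the step: V <- V_rest + (V - V_rest) e^{-dt/tau_m} + (1 - e^{-dt/tau_m}) mu.
    With zero input V decays monotonically to V_rest.
    """

    tau_m: float = 10.0
    v_rest: float = 0.0
    v_threshold: float = 1.0
    v_reset: float = 0.0
    tau_ref: float = 2.0

    def prepare(self, dt: float) -> None:
        self._decay = np.exp(-dt / self.tau_m)
        self._gain = 1.0 - self._decay

    def subthreshold(self, v, mu):
        return self.v_rest + (v - self.v_rest) * self._decay + self._gain * mu

    @classmethod
    def from_config(cls, cfg: NetworkConfig) -> "LIFCell":
        return cls(cfg.tau_m, cfg.v_rest, cfg.v_threshold, cfg.v_reset, cfg.tau_ref)


def _filter_coefficients(tau_rise, tau_decay, dt, area=1.0):
    """Exact one-step propagator of the double-exponential filter.

    x decays with tau_rise, r with tau_decay, and a unit spike injected
    into x yields a trace r of integral ``area`` (area=1: r estimates the
    firing rate in kHz; area=tau_decay: r ~ rate * tau_decay, O(1) at tens
    of Hz).  Works elementwise for array tau_decay.  Returns (er, ed, cx)
    with x <- x*er and r <- r*ed + x*cx.
    """
    er = np.exp(-dt / tau_rise)
    ed = np.exp(-dt / tau_decay)
    close = np.abs(tau_decay - tau_rise) < 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        cx = np.where(close, (dt / tau_rise ** 2) * ed,
                      (ed - er) / (tau_decay - tau_rise))
    return er, ed, area * cx


@dataclass
class NetworkState:
    """Full dynamical state of the network at time t."""

    t: float
    v: np.ndarray
    refrac: np.ndarray        # remaining refractory time (ms)
    x_static: np.ndarray      # postsynaptic rise variable of the static pathway
    u_static: np.ndarray
    u_plastic: np.ndarray     # W r, refreshed every step
    x_trace: np.ndarray       # rise variable of the per-neuron spike trace
    r_trace: np.ndarray       # filtered own-spike train r_j (RLS regressor)
    rng: np.random.Generator | None = None

    @property
    def u_total(self) -> np.ndarray:
        return self.u_static + self.u_plastic


@dataclass
class SpikeRaster:
    """Ordered (time_ms, neuron_id) spike list."""

    times: np.ndarray
    neurons: np.ndarray

    def __len__(self) -> int:
        return self.times.size

    def in_window(self, t0: float, t1: float) -> "SpikeRaster":
        m = (self.times >= t0) & (self.times < t1)
        return SpikeRaster(self.times[m], self.neurons[m])


@dataclass
class TrialResult:
    raster: SpikeRaster
    u_times: np.ndarray | None = None
    u_traces: np.ndarray | None = None     # (N, T) total synaptic current
    state: NetworkState | None = None


class Simulator:
    """Steps the coupled membrane/synapse dynamics of one network."""

    #: refuse dense u recording beyond this many float64 elements (~512 MB)
    DENSE_RECORD_BUDGET = 64_000_000

    def __init__(self, config: NetworkConfig,
                 static_graph: StaticGraph,
                 plastic_graph: PlasticGraph,
                 stimulus: StimulusProtocol | None = None,
                 noise: NoiseSpec | None = None,
                 cell_model: CellModel | None = None):
        config.validate()
        self.config = config
        self.static = static_graph
        self.plastic = plastic_graph
        self.stimulus = stimulus
        self.noise = noise if noise is not None else NoiseSpec(config.sigma, config.seed_noise)
        self.cell = cell_model if cell_model is not None else LIFCell.from_config(config)
        self.dt = config.dt
        self.cell.prepare(self.dt)
        # per-neuron synaptic decay constants, log-uniform, frozen by the graph seed
        tau_rng = np.random.default_rng(config.seed_graph + 2)
        self.tau_decay = np.exp(tau_rng.uniform(np.log(config.tau_decay_min),
                                                np.log(config.tau_decay_max),
                                                config.n_neurons))
        # regressor traces are unit-area (r ~ instantaneous rate, kHz), which
        # keeps P of order one — inside the integer codes' representable range
        self._er, self._ed, self._cx = _filter_coefficients(
            config.tau_rise, self.tau_decay, self.dt, area=1.0)
        # static pathway: shared decay, area tau_decay_static, so balanced
        # O(1/sqrt(K)) weights produce O(1) drive at tens of Hz
        self._er_s, self._ed_s, self._cx_s = _filter_coefficients(
            config.tau_rise, config.tau_decay_static, self.dt,
            area=config.tau_decay_static)
        self._sq_noise = self.noise.sigma * np.sqrt(self.dt)
        self.x_bal = np.where(static_graph.is_excitatory,
                              config.x_bal_e, config.x_bal_i).astype(np.float64)
        self._finite_check_every = 100
        self._steps_since_check = 0

    # -- state management ---------------------------------------------------

    def init_state(self, noise_seed: int | None = None) -> NetworkState:
        """Fresh state: V ~ Uniform(v_rest, v_threshold) (desynchronized start),
        synapses empty.  Deterministic in the seed; the same seed also feeds
        the trial's noise stream."""
        n = self.config.n_neurons
        seed = self.noise.seed if noise_seed is None else noise_seed
        init_rng = np.random.default_rng(np.random.SeedSequence((seed, 0x5eed)))
        v0 = init_rng.uniform(self.cell.v_reset if self.cell.v_reset > self.config.v_rest
                              else self.config.v_rest,
                              self.cell.v_threshold, size=n)
        rng = np.random.default_rng(seed) if self.noise.sigma > 0 else None
        z = lambda: np.zeros(n)
        return NetworkState(0.0, v0, z(), z(), z(), z(), z(), z(), rng)

    # -- stepping -----------------------------------------------------------

    def step(self, state: NetworkState) -> np.ndarray:
        """Advance one dt; returns the indices of the neurons that spiked."""
        cfg = self.config
        # exact linear decay of the rise/trace pairs (precomputed coefficients)
        state.u_static = state.u_static * self._ed_s + state.x_static * self._cx_s
        state.x_static *= self._er_s
        state.r_trace = state.r_trace * self._ed + state.x_trace * self._cx
        state.x_trace *= self._er

        # plastic current through the exact identity u = W r
        _kernels.plastic_current(self.plastic.weights, self.plastic.pre_idx,
                                 state.r_trace, state.u_plastic)
        stim = self.stimulus.current(state.t) if self.stimulus is not None else 0.0
        mu = state.u_static + state.u_plastic + self.x_bal + stim

        v = self.cell.subthreshold(state.v, mu)
        if self._sq_noise > 0.0:
            v = v + self._sq_noise * state.rng.standard_normal(cfg.n_neurons)

        refractory = state.refrac > 0.0
        v = np.where(refractory, self.cell.v_reset, v)

        spiked_mask = v >= self.cell.v_threshold
        # branchless reset: non-spiking neurons are "reset" to their own value
        state.v = np.where(spiked_mask, self.cell.v_reset, v)
        state.refrac = np.where(spiked_mask, self.cell.tau_ref,
                                np.maximum(state.refrac - self.dt, 0.0))

        spiked = np.flatnonzero(spiked_mask)
        if spiked.size:
            state.x_trace[spiked] += 1.0
            if self.static.n_edges:
                _kernels.propagate_spikes_static(
                    spiked, self.static.out_ptr, self.static.out_tgt,
                    self.static.out_w, state.x_static)

        state.t += self.dt
        self._steps_since_check += 1
        if self._steps_since_check >= self._finite_check_every:
            self._steps_since_check = 0
            self._assert_finite(state)
        return spiked

    def _assert_finite(self, state: NetworkState) -> None:
        for name in ("v", "u_static", "u_plastic", "r_trace"):
            arr = getattr(state, name)
            if not np.all(np.isfinite(arr)):
                idx = int(np.flatnonzero(~np.isfinite(arr))[0])
                raise FloatingPointError(
                    f"non-finite state in '{name}' (first at neuron {idx}, "
                    f"t={state.t:.2f} ms)")

    # -- trials -------------------------------------------------------------

    def run_trial(self, duration: float, noise_seed: int | None = None,
                  record_u: bool = False, record_every: int = 10,
                  state: NetworkState | None = None,
                  learn_hook=None, learn_interval: float | None = None) -> TrialResult:
        """One stimulated trial: stimulus epoch on [onset, 0), then the
        learning/evaluation window [0, duration).

        ``learn_hook(state)`` fires every ``learn_interval`` ms of the
        learning window (used by the RLS trainer).  Dense recording of the
        total synaptic current u is optional and downsampled by
        ``record_every`` steps.
        """
        cfg = self.config
        if self.stimulus is not None and duration <= self.stimulus.duration:
            raise ValueError("trial duration must exceed the stimulus duration")
        if state is None:
            state = self.init_state(noise_seed)
        t_start = self.stimulus.onset if self.stimulus is not None else 0.0
        state.t = t_start
        n_steps = int(round((duration - t_start) / self.dt))

        rec = 0
        if record_u:
            n_rec = int(np.ceil(n_steps / record_every))
            if n_rec * cfg.n_neurons > self.DENSE_RECORD_BUDGET:
                raise MemoryError(
                    "dense u recording would exceed the memory budget; "
                    "increase record_every to downsample")
            u_traces = np.empty((cfg.n_neurons, n_rec))
            u_times = np.empty(n_rec)
        times, ids = [], []

        learn_steps = None
        if learn_hook is not None:
            if learn_interval is None or learn_interval < self.dt:
                raise ValueError("learn_interval must be >= dt")
            learn_steps = int(round(learn_interval / self.dt))

        for k in range(n_steps):
            spiked = self.step(state)
            if spiked.size:
                times.append(np.full(spiked.size, state.t))
                ids.append(spiked)
            if record_u and k % record_every == 0:
                u_traces[:, rec] = state.u_total
                u_times[rec] = state.t
                rec += 1
            if learn_steps is not None and state.t > 1e-9:
                # fire on completed multiples of the learn interval
                step_in_window = int(round((state.t - t_start) / self.dt))
                if (step_in_window - int(round(-t_start / self.dt))) % learn_steps == 0:
                    learn_hook(state)

        raster = SpikeRaster(
            np.concatenate(times) if times else np.empty(0),
            np.concatenate(ids).astype(np.int64) if ids else np.empty(0, dtype=np.int64))
        return TrialResult(raster,
                           u_times[:rec] if record_u else None,
                           u_traces[:, :rec] if record_u else None,
                           state)


def synaptic_current_decomposition(state: NetworkState, plastic: PlasticGraph):
    """Recompute u_plastic from scratch as sum_j W_ij r_j.

    Returns (u_recomputed, R) where R[i] = r at neuron i's plastic partners,
    the L-vector the RLS update uses as its regressor.  Matches the
    simulator's running u_plastic (which is evaluated through the same
    identity each step).
    """
    R = state.r_trace[plastic.pre_idx]
    u = np.einsum("il,il->i", plastic.weights, R)
    return u, R
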