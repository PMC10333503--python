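"""High-level modelling interface: build, fit, inspect, simulate.

`SpikingRLSModel` bundles a network configuration with a set of target
synaptic-current trajectories; `fit` runs the recursive least-squares
training loop and returns a `SpikingRLSResults` carrying the learned
weights, per-iteration diagnostics, and evaluation utilities, in the spirit
of a statsmodels model/results pair::

    targets = sinusoid_targets(256, period=1000, amplitude=0.5, offset=0.0,
                               duration=2000, bin_ms=10, seed=7)
    model = SpikingRLSModel(targets, NetworkConfig(n_neurons=256, n_plastic=48))
    res = model.fit(n_iterations=30)
    print(res.summary())
    report = res.evaluate(n_trials=5)
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import io as _io
from .evaluate import EvalReport, evaluate_trial, psth_from_raster
from .network import NetworkConfig, build_network
from .rls import RLSState, TrainConfig, init_rls, iteration_noise_seed, train
from .simulate import Simulator, TrialResult
from .targets import (FICurveParams, PSTHMatrix, TargetSet, psth_to_targets,
                      sinusoid_targets)


class SpikingRLSModel:
    """A spiking recurrent network to be trained against target currents.

    Parameters
    ----------
    targets : TargetSet
        Per-neuron target synaptic currents on the learning window.  Must
        have one row per network neuron.
    config : NetworkConfig
        Network sizes, scalings and seeds.
    train_config : TrainConfig, optional
        Learning-loop parameters (regularization, learn interval, precision,
        iteration budget).  The trial duration is taken from the targets.
    cell_model : CellModel, optional
        Plugin sub-threshold dynamics; defaults to the standard LIF.
    """

    def __init__(self, targets: TargetSet, config: NetworkConfig,
                 train_config: TrainConfig | None = None, cell_model=None):
        if targets.n_neurons != config.n_neurons:
            raise ValueError(
                f"targets have {targets.n_neurons} rows but the network has "
                f"{config.n_neurons} neurons")
        config.validate()
        self.targets = targets
        self.config = config
        self.train_config = train_config or TrainConfig()
        self.train_config.duration = targets.duration
        self.train_config.validate(config.dt)
        static, plastic, stim, noise = build_network(config)
        self.sim = Simulator(config, static, plastic, stim, noise, cell_model)

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_config_file(cls, path, targets: TargetSet | None = None):
        net, train_cfg = _io.load_config(path)
        if targets is None:
            targets = sinusoid_targets(
                net.n_neurons, period=1000.0, amplitude=0.5, offset=0.0,
                duration=train_cfg.duration, bin_ms=train_cfg.dt_learn,
                seed=net.seed_rls)
        return cls(targets, net, train_cfg)

    @classmethod
    def from_psth(cls, psth: PSTHMatrix, config: NetworkConfig,
                  train_config: TrainConfig | None = None,
                  fi_params: FICurveParams | None = None):
        """Build targets by inverting the PSTH through the noisy-LIF F-I curve."""
        if fi_params is None:
            fi_params = FICurveParams.from_network(config)
        tc = train_config or TrainConfig()
        x_bal = np.where(np.arange(config.n_neurons)
                         < round(config.frac_excitatory * config.n_neurons),
                         config.x_bal_e, config.x_bal_i)
        tset = psth_to_targets(psth, fi_params, tc.dt_learn, x_bal=x_bal)
        return cls(tset, config, tc)

    # -- fitting ------------------------------------------------------------

    def fit(self, n_iterations: int | None = None, callback=None,
            rls_state: RLSState | None = None) -> "SpikingRLSResults":
        tc = self.train_config
        if n_iterations is not None:
            tc.n_iterations = n_iterations
        rls, history = train(self.sim, self.targets, tc, rls=rls_state,
                             callback=callback)
        return SpikingRLSResults(self, rls, history)

    def resume(self, checkpoint_path, n_iterations: int,
               force: bool = False) -> "SpikingRLSResults":
        """Continue training from a checkpoint, bit-identically to an
        uninterrupted run with the same seeds."""
        h = _io.config_hash(self.config, self.train_config)
        weights, rls, _, _, _ = _io.load_checkpoint(checkpoint_path, h, force)
        self.sim.plastic.weights[:] = weights
        self.train_config.n_iterations = n_iterations
        return self.fit(rls_state=rls)


class SpikingRLSResults:
    """Learned weights, training history, and evaluation of a fitted model."""

    def __init__(self, model: SpikingRLSModel, rls: RLSState, history):
        self.model = model
        self.rls = rls
        self.history = history
        self.weights = model.sim.plastic.weights

    # -- training diagnostics ----------------------------------------------

    @property
    def mean_corr(self) -> float:
        return self.history[-1].mean_corr if self.history else float("nan")

    @property
    def n_iterations(self) -> int:
        return len(self.history)

    def history_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"iteration": d.iteration, "mean_corr": d.mean_corr,
             "median_corr": d.median_corr, "error_rms": d.error_rms,
             "weight_update_rms": d.weight_update_rms,
             "mean_rate_hz": d.mean_rate_hz}
            for d in self.history])

    def summary(self) -> str:
        cfg, tc = self.model.config, self.model.train_config
        last = self.history[-1] if self.history else None
        lines = [
            "          Spiking-network RLS training results",
            "=" * 58,
            f"neurons (N):        {cfg.n_neurons:>8}    static K: {cfg.k_static:>8}",
            f"plastic L:          {cfg.n_plastic:>8}    noise sigma: {cfg.sigma:>8.3f}",
            f"precision (P):      {tc.precision:>8}    lambda: {tc.lam:>11.3f}",
            f"dt / dt_learn (ms): {cfg.dt:>8.2f}    {tc.dt_learn:>8.1f}",
            f"iterations run:     {self.n_iterations:>8}",
        ]
        if last is not None:
            lines += [
                "-" * 58,
                f"final mean corr:    {last.mean_corr:>8.4f}"
                f"    median: {last.median_corr:>8.4f}",
                f"final error RMS:    {last.error_rms:>8.4f}"
                f"    rate: {last.mean_rate_hz:>7.2f} Hz",
            ]
        lines.append("=" * 58)
        return "\n".join(lines)

    # -- frozen-weight simulation ------------------------------------------

    def simulate(self, n_trials: int = 1, seed: int = 0,
                 record_u: bool = True, record_every: int = 10) -> list[TrialResult]:
        """Run trials with the trained weights frozen (no RLS updates)."""
        sim = self.model.sim
        out = []
        for trial in range(n_trials):
            ns = iteration_noise_seed(seed + 1_000_000, trial)
            out.append(sim.run_trial(self.model.targets.duration,
                                     noise_seed=ns, record_u=record_u,
                                     record_every=record_every))
        return out

    def evaluate(self, n_trials: int = 1, seed: int = 0,
                 psth_bin_ms: float = 20.0) -> EvalReport:
        """Frozen-weight evaluation: correlations, rates, CV-ISI."""
        trials = self.simulate(n_trials, seed)
        first = trials[0]
        report = evaluate_trial(first.u_traces, first.u_times,
                                self.model.targets, first.raster,
                                self.model.config.n_neurons,
                                (0.0, self.model.targets.duration))
        return report

    def psth(self, n_trials: int = 10, seed: int = 0,
             bin_ms: float = 20.0) -> PSTHMatrix:
        trials = self.simulate(n_trials, seed, record_u=False)
        return psth_from_raster([t.raster for t in trials], bin_ms,
                                self.model.targets.duration,
                                self.model.config.n_neurons)

    # -- persistence and plotting ------------------------------------------

    def save_checkpoint(self, path, save_p: bool = True) -> None:
        h = _io.config_hash(self.model.config, self.model.train_config)
        _io.save_checkpoint(path, self.weights, self.rls, h, self.history,
                            save_p=save_p)

    def plot_fit(self, neurons=(0, 1, 2), trial: TrialResult | None = None, ax=None):
        """Learned currents vs targets for a few neurons (frozen trial)."""
        import matplotlib.pyplot as plt

        if trial is None:
            trial = self.simulate(1)[0]
        if ax is None:
            _, ax = plt.subplots(figsize=(7, 3))
        tgt = self.model.targets
        for n in neurons:
            ax.plot(trial.u_times, trial.u_traces[n], lw=0.8,
                    label=f"neuron {n} (learned)")
            ax.plot(tgt.times, tgt.values[n], "--", lw=0.8,
                    label=f"neuron {n} (target)")
        ax.set_xlabel("time (ms)")
        ax.set_ylabel("synaptic current")
        ax.legend(fontsize=6, ncol=2)
        return ax
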