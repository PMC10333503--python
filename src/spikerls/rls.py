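"""Per-neuron recursive least-squares training of the plastic weights.

Each neuron i carries an independent ridge-regression problem: find the L
incoming plastic weights w_i such that the synaptic current
u_i(t) = w_i . r_{J(i)}(t) tracks the target f_i(t), where r_{J(i)} is the
vector of filtered spike trains at i's plastic presynaptic partners.  The
online solution maintains P_i, the inverse of the regularized presynaptic
correlation matrix, initialized to (1/lambda) I, and at every learn tick
applies

    k = P_i r,     c = 1 / (1 + r^T k),
    w_i <- w_i - c * e_i * k,          e_i = u_i - f_i(t)
    P_i <- P_i - c * k k^T.

One pass of this recursion over any fixed sequence of (r, f) samples
reproduces the direct regularized least-squares solution exactly (the
module's core correctness oracle).  All N neurons are updated in a batch;
only P is stored in the (possibly reduced) precision, while weights,
traces and currents stay in the working float64.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np

from .evaluate import rowwise_pearson
from .linalg import BatchedP, PrecisionSpec, get_precision
from .simulate import Simulator


@dataclass
class RLSState:
    """Batched P matrices plus the bookkeeping of the recursion."""

    P: BatchedP
    lam: float
    dt_learn: float
    iteration: int = 0
    last_skipped: int = 0              # neurons skipped at the latest tick

    @property
    def n_neurons(self) -> int:
        return self.P.n_batch

    @property
    def n_plastic(self) -> int:
        return self.P.dim


@dataclass
class TrainConfig:
    """Training-loop parameters.

    dt_learn must be an integer multiple of the simulation dt.  Training
    stops at ``n_iterations``, or earlier if the mean correlation changes by
    less than ``plateau_tol`` over ``plateau_window`` consecutive
    iterations, or (if ``stop_corr`` is set) when the mean correlation first
    reaches it.
    """

    n_iterations: int = 100
    dt_learn: float = 10.0
    lam: float = 1.0
    precision: str = "f64"
    duration: float = 2000.0
    plateau_tol: float = 0.0           # 0 disables plateau stopping
    plateau_window: int = 5
    stop_corr: float | None = None

    def validate(self, dt: float) -> None:
        problems = []
        if self.n_iterations < 0:
            problems.append("n_iterations must be non-negative")
        if self.lam <= 0:
            problems.append("lam (regularization) must be positive")
        ratio = self.dt_learn / dt
        if self.dt_learn < dt or abs(ratio - round(ratio)) > 1e-9:
            problems.append("dt_learn must be an integer multiple of dt")
        if self.duration <= 0:
            problems.append("duration must be positive")
        try:
            get_precision(self.precision)
        except ValueError as e:
            problems.append(str(e))
        if problems:
            raise ValueError("invalid train config: " + "; ".join(problems))

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def init_rls(n_neurons: int, n_plastic: int, lam: float,
             precision: str | PrecisionSpec = "f64",
             dt_learn: float = 10.0) -> RLSState:
    """All P_i = (1/lam) I in the requested precision."""
    if lam <= 0:
        raise ValueError("regularization lam must be positive")
    P = BatchedP.scaled_identity(n_neurons, n_plastic, 1.0 / lam, precision)
    return RLSState(P, lam, dt_learn)


def rls_step_batched(rls: RLSState, R: np.ndarray, e: np.ndarray,
                     on_indefinite: str = "raise") -> np.ndarray:
    """One RLS update for all neurons; returns the weight increments.

    R is the (N, L) matrix of presynaptic regressors, e the (N,) errors
    u - f.  Order within a tick (fixed): compute k, update weights, then P.

    In exact arithmetic 1 + r'Pr > 0 always; with coarse integer-coded P
    the accumulated rounding can drive it non-positive.  ``on_indefinite``
    selects the response: "raise" (default; the exact-arithmetic contract)
    or "reset" (covariance resetting, the standard adaptive-filter remedy
    for an ill-conditioned P: the offending neurons' panels are restored to
    the initial (1/lambda) identity and their weight update is suppressed
    for this tick — used by the training loop for integer codes, where
    occasional indefinite panels are expected behavior of the reduced
    precision, not a bug).
    """
    k = rls.P.matvec(R)                       # k_i = P_i r_i
    denom = 1.0 + np.einsum("il,il->i", R, k)
    if on_indefinite == "raise":
        bad = denom <= 0.0
        if np.any(bad):
            b = int(np.argmax(bad))
            raise FloatingPointError(
                f"RLS denominator 1 + r'Pr = {denom[b]:.3e} <= 0 at neuron "
                f"{b}: P lost positive-definiteness (reduce dt_learn or "
                f"increase lam/precision)")
    else:
        # with PD P the denominator is >= 1 and the gain c <= 1; values well
        # below 1 only arise from quantization-corrupted panels
        bad = denom < 0.5
        if np.any(bad):
            from .linalg import BatchedP

            fresh = BatchedP.scaled_identity(1, rls.P.dim, 1.0 / rls.lam,
                                             rls.P.precision)
            rls.P.data[bad] = fresh.data[0]
            k[bad] = 0.0                      # no weight/P update this tick
        denom = np.where(bad, np.inf, denom)
    c = 1.0 / denom
    dw = -(c * e)[:, None] * k
    rls.P.rank1_update(-c, k)                 # P_i <- P_i - c k k'
    rls.last_skipped = int(bad.sum())
    return dw


def rls_step(P_single: BatchedP, r: np.ndarray, e: float, lam: float = 1.0):
    """Single-neuron convenience wrapper: returns (dw, updated in place P)."""
    state = RLSState(P_single, lam, 0.0)
    dw = rls_step_batched(state, np.asarray(r, dtype=np.float64)[None, :],
                          np.array([e], dtype=np.float64))
    return dw[0]


@dataclass
class IterationDiagnostics:
    iteration: int
    mean_corr: float
    median_corr: float
    error_rms: float
    weight_update_rms: float
    mean_rate_hz: float
    skipped_updates: int = 0
    per_neuron_corr: np.ndarray = field(repr=False, default=None)


def train_iteration(sim: Simulator, targets, rls: RLSState,
                    duration: float, noise_seed: int | None = None,
                    update_weights: bool = True) -> IterationDiagnostics:
    """One stimulated trial with RLS updates every dt_learn.

    Every neuron is updated independently (no cross-neuron coupling): the
    error e_i = u_i - f_i(t) uses the running total synaptic current, the
    regressor is the L-vector of plastic presynaptic traces, and the weight
    increments are added into the live plastic weight matrix so they take
    effect immediately.  Returns correlation diagnostics computed on the
    per-tick samples of (u, f).
    """
    plastic = sim.plastic
    pre_idx = plastic.pre_idx
    # integer-coded P may transiently go indefinite; skip those panels
    on_indef = "reset" if rls.P.precision.is_integer else "raise"
    u_samples, f_samples = [], []
    dw_accum = [0.0, 0]
    skipped = [0]

    def hook(state):
        f = targets.at_time(state.t)
        # evaluate u through the exact identity u = W r at the tick's state
        R = state.r_trace[pre_idx]
        u = state.u_static + np.einsum("il,il->i", plastic.weights, R)
        e = u - f
        u_samples.append(u.copy())
        f_samples.append(f.copy())
        if update_weights:
            dw = rls_step_batched(rls, R, e, on_indefinite=on_indef)
            skipped[0] += rls.last_skipped
            plastic.weights += dw
            dw_accum[0] += float(np.mean(dw ** 2))
            dw_accum[1] += 1
        if not np.all(np.isfinite(plastic.weights)):
            bad = int(np.flatnonzero(~np.isfinite(plastic.weights))[0] // plastic.n_plastic)
            raise FloatingPointError(
                f"non-finite plastic weight at neuron {bad}, iteration "
                f"{rls.iteration}, t={state.t:.1f} ms")

    result = sim.run_trial(duration, noise_seed=noise_seed,
                           learn_hook=hook, learn_interval=rls.dt_learn)
    u_mat = np.array(u_samples).T              # (N, n_ticks)
    f_mat = np.array(f_samples).T
    corr = rowwise_pearson(u_mat, f_mat)
    n_window = duration - (sim.stimulus.onset if sim.stimulus else 0.0)
    rate = 1000.0 * len(result.raster) / (sim.config.n_neurons * n_window)
    diag = IterationDiagnostics(
        iteration=rls.iteration,
        mean_corr=float(np.mean(corr)),
        median_corr=float(np.median(corr)),
        error_rms=float(np.sqrt(np.mean((u_mat - f_mat) ** 2))),
        weight_update_rms=float(np.sqrt(dw_accum[0] / max(dw_accum[1], 1))),
        mean_rate_hz=float(rate),
        skipped_updates=skipped[0],
        per_neuron_corr=corr,
    )
    rls.iteration += 1
    return diag


def iteration_noise_seed(base_seed: int, iteration: int) -> int:
    """Independent, reproducible noise stream per training iteration.

    Seeding each trial from (base_seed, iteration) makes
    resume-from-checkpoint bit-identical without serializing RNG state.
    """
    return int(np.random.SeedSequence((base_seed, iteration)
                                      ).generate_state(1)[0] % (2 ** 31))


def train(sim: Simulator, targets, train_cfg: TrainConfig,
          rls: RLSState | None = None, callback=None) -> tuple[RLSState, list]:
    """Iterate stimulated training trials until budget, plateau, or target.

    Returns the final RLS state and the list of per-iteration diagnostics.
    ``callback(diag, rls, weights)`` runs after every iteration (used for
    checkpointing and logging).
    """
    train_cfg.validate(sim.config.dt)
    if rls is None:
        rls = init_rls(sim.config.n_neurons, sim.config.n_plastic,
                       train_cfg.lam, train_cfg.precision, train_cfg.dt_learn)
    history: list[IterationDiagnostics] = []
    for _ in range(train_cfg.n_iterations):
        seed = iteration_noise_seed(sim.config.seed_noise, rls.iteration)
        diag = train_iteration(sim, targets, rls, train_cfg.duration,
                               noise_seed=seed)
        history.append(diag)
        if callback is not None:
            callback(diag, rls, sim.plastic.weights)
        if train_cfg.stop_corr is not None and diag.mean_corr >= train_cfg.stop_corr:
            break
        if (train_cfg.plateau_tol > 0
                and len(history) > train_cfg.plateau_window):
            recent = [d.mean_corr for d in history[-(train_cfg.plateau_window + 1):]]
            if abs(recent[-1] - recent[0]) < train_cfg.plateau_tol:
                break
    return rls, history
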