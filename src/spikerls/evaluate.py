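"""Accuracy and spiking statistics of a trained, frozen network.

Training accuracy is the per-neuron Pearson correlation between the learned
synaptic current and its target over the post-stimulus window; spiking
statistics are per-neuron rates and the coefficient of variation of
inter-spike intervals (CV-ISI, ~1 for Poisson-like irregular firing — the
trainer does not optimize these, they are reported as a health check).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


def rowwise_pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson r per row; rows with zero variance in either input get 0."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    num = np.einsum("ij,ij->i", ac, bc)
    den = np.sqrt(np.einsum("ij,ij->i", ac, ac) * np.einsum("ij,ij->i", bc, bc))
    out = np.zeros(a.shape[0])
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    return np.clip(out, -1.0, 1.0)


@dataclass
class EvalReport:
    """Per-neuron and summary metrics of one evaluation."""

    correlation: np.ndarray            # per-neuron Pearson r (u vs f)
    constant_flag: np.ndarray          # True where a trace was constant
    rate_hz: np.ndarray
    cv_isi: np.ndarray                 # NaN where undefined (< 3 spikes)
    mean_corr: float = field(init=False)
    median_corr: float = field(init=False)

    def __post_init__(self):
        self.mean_corr = float(np.mean(self.correlation))
        self.median_corr = float(np.median(self.correlation))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "correlation": self.correlation,
            "constant_flag": self.constant_flag,
            "rate_hz": self.rate_hz,
            "cv_isi": self.cv_isi,
        })

    def summary_line(self) -> str:
        cv = self.cv_isi[np.isfinite(self.cv_isi)]
        return (f"mean corr {self.mean_corr:.3f}, median corr "
                f"{self.median_corr:.3f}, mean rate {np.mean(self.rate_hz):.2f} Hz, "
                f"mean CV-ISI {np.mean(cv) if cv.size else float('nan'):.2f}")


def performance_correlation(u_traces: np.ndarray, targets,
                            u_times: np.ndarray | None = None,
                            t_start: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Per-neuron Pearson r between recorded currents and targets.

    The comparison window excludes the stimulus epoch (t >= t_start).
    Targets are sampled at the recorded time points (nearest target bin).
    Constant traces are flagged and given correlation 0.
    """
    u_traces = np.asarray(u_traces)
    if u_times is None:
        if u_traces.shape[1] != targets.values.shape[1]:
            raise ValueError(
                f"trace length {u_traces.shape[1]} does not match target grid "
                f"{targets.values.shape[1]}; pass u_times for resampling")
        f = targets.values
        u = u_traces
    else:
        keep = np.asarray(u_times) >= t_start
        u = u_traces[:, keep]
        f = np.stack([targets.at_time(t) for t in np.asarray(u_times)[keep]], axis=1)
    const = (np.ptp(u, axis=1) == 0) | (np.ptp(f, axis=1) == 0)
    corr = rowwise_pearson(u, f)
    corr[const] = 0.0
    return corr, const


def psth_from_raster(rasters, bin_ms: float, duration: float,
                     n_neurons: int, t_start: float = 0.0):
    """Trial-averaged firing rates from one raster per trial.

    rate(i, b) = count(i, b) / (n_trials * bin_ms / 1000) in Hz, over the
    window [t_start, t_start + duration).
    """
    from .targets import PSTHMatrix

    rasters = list(rasters)
    if not rasters:
        raise ValueError("need at least one trial raster")
    n_bins = int(round(duration / bin_ms))
    counts = np.zeros((n_neurons, n_bins))
    for r in rasters:
        m = (r.times >= t_start) & (r.times < t_start + duration)
        b = ((r.times[m] - t_start) / bin_ms).astype(np.int64)
        np.add.at(counts, (r.neurons[m], b), 1.0)
    rates = counts / (len(rasters) * bin_ms / 1000.0)
    return PSTHMatrix(rates, bin_ms)


def spike_stats(raster, n_neurons: int, window: tuple[float, float]):
    """Per-neuron firing rate (Hz) and CV-ISI within a time window.

    CV-ISI = std(ISI)/mean(ISI), defined only for neurons with >= 3 spikes
    (NaN otherwise).
    """
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("window end must exceed start")
    m = (raster.times >= t0) & (raster.times < t1)
    times = raster.times[m]
    ids = raster.neurons[m]
    rate = np.bincount(ids, minlength=n_neurons) * (1000.0 / (t1 - t0))
    cv = np.full(n_neurons, np.nan)
    order = np.lexsort((times, ids))
    times, ids = times[order], ids[order]
    bounds = np.searchsorted(ids, np.arange(n_neurons + 1))
    for i in range(n_neurons):
        ts = times[bounds[i]:bounds[i + 1]]
        if ts.size >= 3:
            isi = np.diff(ts)
            mean = isi.mean()
            if mean > 0:
                cv[i] = isi.std() / mean
    return rate.astype(np.float64), cv


def evaluate_trial(u_traces, u_times, targets, raster, n_neurons: int,
                   window: tuple[float, float]) -> EvalReport:
    corr, const = performance_correlation(u_traces, targets, u_times,
                                          t_start=window[0])
    rate, cv = spike_stats(raster, n_neurons, window)
    return EvalReport(corr, const, rate, cv)
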