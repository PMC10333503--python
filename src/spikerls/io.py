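"""Configuration files, checkpoints, rasters, PSTHs, and run manifests.

Formats (none are imposed by the science; chosen for portability):

* config — flat key/value YAML covering both the network and the trainer;
* checkpoint — NumPy ``.npz`` holding the plastic weights, the packed P
  panels, iteration counter and the config hash;
* spike raster — two-column delimited text (time_ms, neuron_id);
* PSTH — delimited text with a ``#`` header carrying bin width/condition;
* manifest — JSON snapshot of the config, seeds, and per-iteration log.

Every artifact carries the config hash so mismatched checkpoint/config
pairs are refused (unless forced).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import yaml

from .network import NetworkConfig
from .rls import RLSState, TrainConfig
from .linalg import BatchedP, get_precision
from .simulate import SpikeRaster
from .targets import PSTHMatrix

_NETWORK_KEYS = {f.name for f in dataclasses.fields(NetworkConfig)}
_TRAIN_KEYS = {f.name for f in dataclasses.fields(TrainConfig)}


#: fields that do not change the trained object's identity (budget/stopping)
_VOLATILE_KEYS = {"n_iterations", "plateau_tol", "plateau_window", "stop_corr"}


def config_hash(net: NetworkConfig, train: TrainConfig) -> str:
    d = {**net.to_dict(), **train.to_dict()}
    blob = json.dumps({k: v for k, v in d.items() if k not in _VOLATILE_KEYS},
                      sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def default_config_dict() -> dict:
    return {**NetworkConfig().to_dict(), **TrainConfig().to_dict()}


def load_config(path) -> tuple[NetworkConfig, TrainConfig]:
    """Read a flat YAML config; all defaults filled, every problem reported."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a flat key: value mapping")
    problems = []
    unknown = set(raw) - _NETWORK_KEYS - _TRAIN_KEYS
    if unknown:
        problems.append(f"unknown keys: {sorted(unknown)}")
    net_kw = {k: v for k, v in raw.items() if k in _NETWORK_KEYS}
    train_kw = {k: v for k, v in raw.items() if k in _TRAIN_KEYS}
    if "stim_range" in net_kw:
        net_kw["stim_range"] = tuple(net_kw["stim_range"])
    net = NetworkConfig(**net_kw)
    train = TrainConfig(**train_kw)
    for check in (lambda: net.validate(), lambda: train.validate(net.dt)):
        try:
            check()
        except ValueError as e:
            problems.append(str(e))
    if problems:
        raise ValueError(f"config {path}: " + "; ".join(problems))
    return net, train


def save_config(path, net: NetworkConfig, train: TrainConfig) -> None:
    d = {**net.to_dict(), **train.to_dict()}
    Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


# -- checkpoints -----------------------------------------------------------

def save_checkpoint(path, weights: np.ndarray, rls: RLSState,
                    cfg_hash: str, history=None, save_p: bool = True) -> None:
    arrays = {
        "weights": weights,
        "iteration": np.int64(rls.iteration),
        "lam": np.float64(rls.lam),
        "dt_learn": np.float64(rls.dt_learn),
        "precision": np.bytes_(rls.P.precision.code.encode()),
        "config_hash": np.bytes_(cfg_hash.encode()),
    }
    if save_p:
        arrays["p_data"] = rls.P.data
    if history is not None:
        arrays["history_mean_corr"] = np.array([d.mean_corr for d in history])
    np.savez(path, **arrays)


def load_checkpoint(path, expected_hash: str | None = None, force: bool = False):
    """Returns (weights, RLSState, iteration, stored hash, history array)."""
    with np.load(path) as z:
        stored_hash = bytes(z["config_hash"]).decode()
        if expected_hash is not None and stored_hash != expected_hash and not force:
            raise ValueError(
                f"checkpoint {path} was written for config {stored_hash}, "
                f"expected {expected_hash} (pass force=True to override)")
        weights = z["weights"]
        spec = get_precision(bytes(z["precision"]).decode())
        n, L = weights.shape
        if "p_data" in z.files:
            P = BatchedP(n, L, spec, data=z["p_data"])
        else:
            P = BatchedP.scaled_identity(n, L, 1.0 / float(z["lam"]), spec)
        rls = RLSState(P, float(z["lam"]), float(z["dt_learn"]),
                       int(z["iteration"]))
        hist = z["history_mean_corr"] if "history_mean_corr" in z.files else None
    return weights, rls, rls.iteration, stored_hash, hist


# -- rasters and PSTHs -----------------------------------------------------

def save_raster(path, raster: SpikeRaster) -> None:
    np.savetxt(path, np.column_stack([raster.times, raster.neurons]),
               fmt=["%.4f", "%d"], header="time_ms neuron_id")


def load_raster(path) -> SpikeRaster:
    data = np.loadtxt(path, ndmin=2)
    if data.size == 0:
        return SpikeRaster(np.empty(0), np.empty(0, dtype=np.int64))
    return SpikeRaster(data[:, 0], data[:, 1].astype(np.int64))


def save_psth(path, psth: PSTHMatrix) -> None:
    np.savetxt(path, psth.rates,
               header=f"bin_ms={psth.bin_ms} condition={psth.condition}")


def load_psth(path) -> PSTHMatrix:
    path = Path(path)
    bin_ms, condition = 20.0, ""
    with path.open() as fh:
        first = fh.readline()
    if first.startswith("#"):
        for token in first[1:].split():
            if token.startswith("bin_ms="):
                bin_ms = float(token.split("=", 1)[1])
            elif token.startswith("condition="):
                condition = token.split("=", 1)[1]
    rates = np.loadtxt(path, ndmin=2)
    return PSTHMatrix(rates, bin_ms, condition)


# -- manifest --------------------------------------------------------------

def write_manifest(path, net: NetworkConfig, train: TrainConfig,
                   history=None, extra: dict | None = None) -> None:
    from . import __version__

    record = {
        "version": __version__,
        "config": {**net.to_dict(), **train.to_dict()},
        "config_hash": config_hash(net, train),
        "seeds": {k: getattr(net, k) for k in
                  ("seed_graph", "seed_stimulus", "seed_noise", "seed_rls")},
        "iterations": [
            {"iteration": d.iteration, "mean_corr": d.mean_corr,
             "median_corr": d.median_corr, "error_rms": d.error_rms,
             "mean_rate_hz": d.mean_rate_hz}
            for d in (history or [])
        ],
    }
    if extra:
        record.update(extra)
    Path(path).write_text(json.dumps(record, indent=2, default=float))


def read_manifest(path) -> dict:
    return json.loads(Path(path).read_text())
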