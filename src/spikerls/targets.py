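"""Target synaptic-current trajectories.

Two sources of targets:

* synthetic sinusoids with random phases (the benchmarking workload), and
* trial-averaged firing-rate histograms (PSTHs, neurons x bins in Hz),
  converted to underlying synaptic currents by inverting the stationary
  transfer function (F-I curve) of the noisy leaky integrate-and-fire
  neuron.

The noisy-LIF rate uses the standard diffusion approximation
(first-passage-time / Ricciardi form): with boundaries expressed in units
of the voltage noise sigma_v,

    rate(mu) = 1000 / (tau_ref + tau_m * sqrt(pi) * I),
    I = integral_{(V_reset-mu)/sigma_v}^{(V_th-mu)/sigma_v} e^{x^2} (1 + erf x) dx,

with taus in ms and the rate in Hz.  ``sigma_v`` relates to the
simulator's per-step noise amplitude sigma by the stationary
Ornstein-Uhlenbeck variance: Var(V) = sigma^2 tau_m / 2 = sigma_v^2 / 2,
i.e. sigma_v = sigma * sqrt(tau_m).  In the noiseless limit the rate is
the familiar closed form 1000/(tau_ref + tau_m ln((mu-V_reset)/(mu-V_th)))
above threshold and 0 below.

Because the noisy F-I curve is smooth and strictly increasing, it can be
inverted numerically (Brent's method) to map a target rate to the mean
input current that produces it; subtracting the constant external drive
X_bal then yields the recurrent synaptic-current target the RLS trainer
uses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq
from scipy.special import erfcx

# beyond this many noise s.d. between mean input and threshold, the
# diffusion rate underflows (< 1e-25 Hz) and is reported as exactly 0
_THRESHOLD_CUTOFF_SD = 8.0


@dataclass
class FICurveParams:
    """LIF parameters plus the voltage-noise s.d. entering the F-I curve."""

    tau_m: float = 10.0
    v_rest: float = 0.0
    v_threshold: float = 1.0
    v_reset: float = 0.0
    tau_ref: float = 2.0
    sigma_v: float = 0.5

    def __post_init__(self):
        if self.v_reset >= self.v_threshold:
            raise ValueError("v_reset must be below v_threshold")
        if self.sigma_v < 0:
            raise ValueError("sigma_v must be non-negative")

    @property
    def max_rate(self) -> float:
        """Refractory-limited ceiling, Hz."""
        return 1000.0 / self.tau_ref

    @classmethod
    def from_network(cls, cfg, sigma: float | None = None) -> "FICurveParams":
        """Tie sigma_v to the simulator's noise via sigma_v = sigma*sqrt(tau_m)."""
        s = cfg.sigma if sigma is None else sigma
        return cls(cfg.tau_m, cfg.v_rest, cfg.v_threshold, cfg.v_reset,
                   cfg.tau_ref, s * np.sqrt(cfg.tau_m))


@dataclass
class TargetSet:
    """Per-neuron target currents f_i(t) on a uniform time grid."""

    values: np.ndarray        # (N, T_bins)
    bin_ms: float
    duration: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("targets must be finite")
        n_bins = self.values.shape[1]
        if abs(n_bins * self.bin_ms - self.duration) > 1e-9 * max(1.0, self.duration):
            raise ValueError("T_bins * bin_ms must equal duration")

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Bin-center convention is not used: bin b covers [b*dt, (b+1)*dt);
        the value attributed to its left edge."""
        return np.arange(self.values.shape[1]) * self.bin_ms

    def at_time(self, t: float) -> np.ndarray:
        """Target vector at time t (nearest bin, clamped to the grid)."""
        b = int(round(t / self.bin_ms)) - 1
        b = min(max(b, 0), self.values.shape[1] - 1)
        return self.values[:, b]

    def resample(self, bin_ms: float) -> "TargetSet":
        """Monotone cubic (PCHIP, no overshoot) resampling to a new grid."""
        if abs(bin_ms - self.bin_ms) < 1e-12:
            return self
        t_old = self.times
        n_new = int(round(self.duration / bin_ms))
        t_new = np.arange(n_new) * bin_ms
        interp = PchipInterpolator(t_old, self.values, axis=1, extrapolate=True)
        return TargetSet(interp(np.clip(t_new, t_old[0], t_old[-1])), bin_ms,
                         n_new * bin_ms)


@dataclass
class PSTHMatrix:
    """Trial-averaged firing rates, neurons x bins, in Hz."""

    rates: np.ndarray
    bin_ms: float = 20.0
    condition: str = ""

    def __post_init__(self):
        self.rates = np.asarray(self.rates, dtype=np.float64)
        if np.any(self.rates < 0):
            raise ValueError("PSTH rates must be non-negative")

    @property
    def n_neurons(self) -> int:
        return self.rates.shape[0]

    @property
    def duration(self) -> float:
        return self.rates.shape[1] * self.bin_ms


def sinusoid_targets(n_neurons: int, period: float, amplitude: float,
                     offset: float, duration: float, bin_ms: float,
                     seed: int) -> TargetSet:
    """f_i(t) = offset + amplitude*sin(2 pi t / period + phi_i), random phases."""
    if period <= 0:
        raise ValueError("period must be positive")
    rng = np.random.default_rng(seed)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=n_neurons)
    n_bins = int(round(duration / bin_ms))
    t = np.arange(n_bins) * bin_ms
    vals = offset + amplitude * np.sin(2.0 * np.pi * t[None, :] / period
                                       + phases[:, None])
    return TargetSet(vals, bin_ms, n_bins * bin_ms)


def _ricciardi_integral(a: float, b: float) -> float:
    # integrand e^{x^2}(1+erf x) = erfcx(-x), numerically stable for x <= 0
    # and representable for x <~ 26; callers cap b well below that
    val, _ = quad(lambda x: erfcx(-x), a, b, limit=200)
    return val


def fi_rate(mu, params: FICurveParams):
    """Stationary firing rate (Hz) of the (noisy) LIF at mean input mu.

    Monotone non-decreasing in mu.  Scalar or array mu.
    """
    if np.ndim(mu) > 0:
        return np.array([fi_rate(float(m), params) for m in np.ravel(mu)]
                        ).reshape(np.shape(mu))
    mu = float(mu)
    p = params
    if p.sigma_v == 0.0:
        if mu <= p.v_threshold:
            return 0.0
        isi = p.tau_ref + p.tau_m * np.log((mu - p.v_reset) / (mu - p.v_threshold))
        return 1000.0 / isi
    a = (p.v_reset - mu) / p.sigma_v
    b = (p.v_threshold - mu) / p.sigma_v
    if b >= _THRESHOLD_CUTOFF_SD:
        return 0.0
    integral = _ricciardi_integral(a, b)
    return 1000.0 / (p.tau_ref + p.tau_m * np.sqrt(np.pi) * integral)


def invert_fi(rate, params: FICurveParams, bracket=None):
    """Mean input mu producing the requested stationary rate (Hz).

    Requires sigma_v > 0 (smooth strictly increasing map) and
    0 < rate < the refractory-limited maximum.  Brent root-finding on the
    monotone forward map; round-trip accurate to ~1e-9 relative.
    """
    if np.ndim(rate) > 0:
        return np.array([invert_fi(float(r), params, bracket) for r in np.ravel(rate)]
                        ).reshape(np.shape(rate))
    rate = float(rate)
    p = params
    if p.sigma_v <= 0.0:
        raise ValueError("invert_fi requires sigma_v > 0")
    if not (0.0 < rate < p.max_rate):
        raise ValueError(
            f"rate must lie in (0, {p.max_rate:.1f}) Hz, got {rate}")
    if bracket is None:
        lo = p.v_threshold - (_THRESHOLD_CUTOFF_SD - 0.5) * p.sigma_v
        hi = p.v_threshold + p.sigma_v
        while fi_rate(hi, p) < rate:
            hi += p.sigma_v + (hi - p.v_reset)
        while fi_rate(lo, p) > rate:
            lo -= 2.0 * p.sigma_v
    else:
        lo, hi = bracket
    return brentq(lambda m: fi_rate(m, p) - rate, lo, hi,
                  xtol=1e-12, rtol=1e-14)


def _invert_rows(rates: np.ndarray, params: FICurveParams) -> np.ndarray:
    """Row-wise inversion with a warm bracket walked along each trajectory."""
    out = np.empty_like(rates)
    span = 4.0 * params.sigma_v
    for i in range(rates.shape[0]):
        mu_prev = None
        for b in range(rates.shape[1]):
            r = rates[i, b]
            if mu_prev is not None:
                lo, hi = mu_prev - span, mu_prev + span
                if not (fi_rate(lo, params) <= r <= fi_rate(hi, params)):
                    lo = hi = None
            else:
                lo = hi = None
            mu = invert_fi(r, params, bracket=(lo, hi) if lo is not None else None)
            out[i, b] = mu
            mu_prev = mu
    return out


RATE_FLOOR_HZ = 0.1
RATE_CEIL_FRACTION = 0.95


def psth_to_targets(psth: PSTHMatrix, params: FICurveParams,
                    out_bin_ms: float, x_bal: float | np.ndarray = 0.0,
                    warn=None) -> TargetSet:
    """Convert firing-rate trajectories to recurrent-current targets.

    Rates are clipped to [0.1 Hz, 0.95 * refractory ceiling] (zero rates are
    not invertible), inverted bin-by-bin through the noisy-LIF F-I curve,
    resampled from the PSTH grid to the learning grid by monotone cubic
    interpolation, and the constant external drive x_bal is subtracted so
    that a trained network's u + x_bal reproduces the inferred mean input.
    """
    floor, ceil = RATE_FLOOR_HZ, RATE_CEIL_FRACTION * params.max_rate
    rates = psth.rates
    dead = ~np.any(rates > 0, axis=1)
    if np.any(dead) and warn is not None:
        warn(f"{int(dead.sum())} all-zero PSTH rows set to the rate floor "
             f"({floor} Hz)")
    clipped = np.clip(rates, floor, ceil)
    mu = _invert_rows(clipped, params)
    coarse = TargetSet(mu, psth.bin_ms, psth.duration)
    fine = coarse.resample(out_bin_ms)
    xb = np.asarray(x_bal, dtype=np.float64)
    fine.values = fine.values - (xb.reshape(-1, 1) if xb.ndim else xb)
    return fine


def synthetic_psth_generator(n_neurons: int, n_bins: int, bin_ms: float,
                             seed: int, params: FICurveParams | None = None,
                             n_conditions: int = 2, rate_max: float = 40.0,
                             amplitude_scale: float = 1.0):
    """Synthetic trial-averaged rate trajectories with known latent currents.

    Emulates condition-dependent cortical PSTHs (e.g. lick-left/lick-right):
    each neuron gets a baseline plus random ramp and bump components per
    condition, smooth and bounded to [~0, rate_max] Hz.  Rates are produced
    by passing the latent mean currents through the noisy-LIF F-I curve, so
    ``rates == fi_rate(latent_mu)`` holds by construction, enabling
    parameter-recovery tests of the inversion pipeline.

    Returns (list of PSTHMatrix, latent mu array of shape (C, N, n_bins)).
    """
    if params is None:
        params = FICurveParams()
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, 1.0, n_bins)
    mu_floor = invert_fi(RATE_FLOOR_HZ * 2, params)
    mu_ceil = invert_fi(rate_max, params)
    mu_base = rng.uniform(invert_fi(2.0, params), invert_fi(10.0, params),
                          size=n_neurons)
    psths, latents = [], []
    labels = ["lick_left", "lick_right", *[f"cond{c}" for c in range(2, n_conditions)]]
    for c in range(n_conditions):
        ramp_amp = rng.normal(0.0, 0.3, size=n_neurons) * amplitude_scale
        bump_amp = rng.normal(0.0, 0.5, size=n_neurons) * amplitude_scale
        bump_t = rng.uniform(0.2, 0.8, size=n_neurons)
        bump_w = rng.uniform(0.08, 0.25, size=n_neurons)
        mu = (mu_base[:, None]
              + ramp_amp[:, None] * t[None, :]
              + bump_amp[:, None]
              * np.exp(-0.5 * ((t[None, :] - bump_t[:, None]) / bump_w[:, None]) ** 2))
        mu = np.clip(mu, mu_floor, mu_ceil)
        rates = fi_rate(mu, params)
        psths.append(PSTHMatrix(rates, bin_ms, labels[c]))
        latents.append(mu)
    return psths, np.array(latents)
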