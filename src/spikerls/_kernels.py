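"""Compiled inner loops: batched packed-symmetric kernels and spike propagation.

The packed layout is the upper triangle, column-packed: element (i, j) with
i <= j lives at offset ``i + j*(j+1)//2``.  Each kernel iterates a batch of
N independent L x L matrices stored as the rows of an (N, L*(L+1)/2) array.

Accumulation is always carried in float64 ("wide accumulator"); for the
integer-coded matrices the stored values are dequantized (divided by the
scale) on read and re-quantized with saturation on write-back, so a full
update cycle performs exactly one rounding.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def spmv_batched_float(pdata, x, alpha, beta, y):
    """y_n <- alpha * P_n x_n + beta * y_n for each batch row n (float P)."""
    n_batch, dim = x.shape
    for n in range(n_batch):
        for i in range(dim):
            acc = 0.0
            base = i * (i + 1) // 2
            for j in range(i + 1):          # elements (j, i), j <= i
                acc += pdata[n, base + j] * x[n, j]
            for j in range(i + 1, dim):     # elements (i, j), j > i
                acc += pdata[n, i + j * (j + 1) // 2] * x[n, j]
            y[n, i] = alpha * acc + beta * y[n, i]


@njit(cache=True)
def spmv_batched_int(pdata, inv_scale, x, alpha, beta, y):
    """Integer-coded variant: dequantize during accumulation."""
    n_batch, dim = x.shape
    for n in range(n_batch):
        for i in range(dim):
            acc = 0.0
            base = i * (i + 1) // 2
            for j in range(i + 1):
                acc += pdata[n, base + j] * x[n, j]
            for j in range(i + 1, dim):
                acc += pdata[n, i + j * (j + 1) // 2] * x[n, j]
            y[n, i] = alpha * inv_scale * acc + beta * y[n, i]


@njit(cache=True)
def spr_batched_float(pdata, alpha, x):
    """P_n <- P_n + alpha_n * x_n x_n^T, touching only the stored triangle."""
    n_batch, dim = x.shape
    for n in range(n_batch):
        a = alpha[n]
        for j in range(dim):
            base = j * (j + 1) // 2
            axj = a * x[n, j]
            for i in range(j + 1):
                pdata[n, base + i] += axj * x[n, i]


@njit(cache=True)
def spr_batched_int(pdata, scale, inv_scale, qmin, qmax, alpha, x):
    """Integer-coded rank-1 update with a single saturating re-quantization."""
    n_batch, dim = x.shape
    for n in range(n_batch):
        a = alpha[n]
        for j in range(dim):
            base = j * (j + 1) // 2
            axj = a * x[n, j]
            for i in range(j + 1):
                v = pdata[n, base + i] * inv_scale + axj * x[n, i]
                q = np.rint(v * scale)
                if q > qmax:
                    q = qmax
                elif q < qmin:
                    q = qmin
                pdata[n, base + i] = q


@njit(cache=True)
def propagate_spikes_static(spiked, out_ptr, out_tgt, out_w, x_rise):
    """Add each spiking neuron's outgoing static weights to target rise vars.

    Pure sum semantics: the result is independent of the order of `spiked`
    up to floating-point association.
    """
    for s in spiked:
        for e in range(out_ptr[s], out_ptr[s + 1]):
            x_rise[out_tgt[e]] += out_w[e]


@njit(cache=True)
def plastic_current(weights, pre_idx, r_trace, out):
    """u_i = sum_l weights[i, l] * r_trace[pre_idx[i, l]] for every neuron."""
    n, L = weights.shape
    for i in range(n):
        acc = 0.0
        for l in range(L):
            acc += weights[i, l] * r_trace[pre_idx[i, l]]
        out[i] = acc


@njit(cache=True)
def lif_mc_spike_count(mu, sigma, tau_m, tau_ref, v_th, v_reset, v_rest,
                       dt, n_steps, seed):
    """Monte-Carlo spike count of a single noisy LIF (oracle for the F-I curve).

    Noise convention matches the network simulator: per-step voltage
    increment sigma*sqrt(dt)*N(0,1).
    """
    np.random.seed(seed)
    decay = np.exp(-dt / tau_m)
    gain = 1.0 - decay
    sq = sigma * np.sqrt(dt)
    v = v_rest
    refrac = 0.0
    count = 0
    for _ in range(n_steps):
        v = v_rest + (v - v_rest) * decay + gain * mu + sq * np.random.normal()
        if refrac > 0.0:
            v = v_reset
            refrac -= dt
        elif v >= v_th:
            count += 1
            v = v_reset
            refrac = tau_ref
    return count
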