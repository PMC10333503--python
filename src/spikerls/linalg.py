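"""Packed-symmetric matrix storage, batched RLS kernels, and precision codes.

The recursive least-squares update keeps, per trained neuron, a symmetric
L x L matrix P (the running inverse of the regularized presynaptic
correlation matrix).  P dominates memory (N * L^2 scaling), so only one
triangle is stored, column-packed, and may be held in a reduced precision:
plain floats or integers scaled by a fixed power of two.

Layout convention (fixed, documented): upper triangle, column-packed, so
element (i, j) with i <= j is at offset ``i + j*(j+1)//2``.

Precision ladder: f64, f32, i16 (scale 2^14), i12_in_i16 (12-bit range
stored in an int16, scale 2^10), i8 (scale 2^6).  Integer codes use
saturating conversion - out-of-range values clip to the representable
extremes rather than wrapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels


@dataclass(frozen=True)
class PrecisionSpec:
    """Storage precision for P: a float dtype or a scaled integer code.

    For integer codes the stored value is ``round(value * scale)`` with
    ``scale = 2**(nbits - 2)``, chosen so that values in the typical range
    of P (about -1 to 2) fit without overflow.
    """

    code: str
    nbits: int
    scale: float
    dtype: np.dtype
    qmin: int | None = None
    qmax: int | None = None

    @property
    def is_integer(self) -> bool:
        return self.qmin is not None

    @property
    def itemsize(self) -> int:
        return np.dtype(self.dtype).itemsize


_PRECISIONS = {
    "f64": PrecisionSpec("f64", 64, 1.0, np.dtype(np.float64)),
    "f32": PrecisionSpec("f32", 32, 1.0, np.dtype(np.float32)),
    "i16": PrecisionSpec("i16", 16, 2.0 ** 14, np.dtype(np.int16), -32768, 32767),
    "i12_in_i16": PrecisionSpec("i12_in_i16", 12, 2.0 ** 10, np.dtype(np.int16), -2048, 2047),
    "i8": PrecisionSpec("i8", 8, 2.0 ** 6, np.dtype(np.int8), -128, 127),
}

PRECISION_CODES = tuple(_PRECISIONS)


def get_precision(code: str | PrecisionSpec) -> PrecisionSpec:
    if isinstance(code, PrecisionSpec):
        return code
    # accept the CLI short form "i12"
    key = "i12_in_i16" if code == "i12" else code
    try:
        return _PRECISIONS[key]
    except KeyError:
        raise ValueError(
            f"unknown precision {code!r}; choose from {sorted(_PRECISIONS)}"
        ) from None


def quantize(values, spec: PrecisionSpec):
    """Saturating conversion of real values to the integer code of `spec`."""
    spec = get_precision(spec)
    if not spec.is_integer:
        return np.asarray(values, dtype=spec.dtype)
    q = np.rint(np.asarray(values, dtype=np.float64) * spec.scale)
    q = np.clip(q, spec.qmin, spec.qmax)
    return q.astype(spec.dtype)


def dequantize(stored, spec: PrecisionSpec):
    """Inverse of :func:`quantize` (up to the rounding error <= 0.5/scale)."""
    spec = get_precision(spec)
    if not spec.is_integer:
        return np.asarray(stored, dtype=np.float64)
    return np.asarray(stored, dtype=np.float64) / spec.scale


def packed_length(dim: int) -> int:
    return dim * (dim + 1) // 2


def packed_index(i: int, j: int, dim: int) -> int:
    """Offset of element (i, j) in the upper column-packed triangle.

    Symmetric in (i, j); a bijection from {(i, j): i <= j} onto
    {0, ..., L(L+1)/2 - 1}.
    """
    if not (0 <= i < dim and 0 <= j < dim):
        raise IndexError(f"index ({i}, {j}) out of range for dim {dim}")
    if i > j:
        i, j = j, i
    return i + j * (j + 1) // 2


@dataclass
class PackedSymmetric:
    """One symmetric matrix stored as its packed upper triangle."""

    dim: int
    data: np.ndarray
    precision: PrecisionSpec = field(default_factory=lambda: _PRECISIONS["f64"])
    triangle: str = "upper"

    def __post_init__(self):
        self.precision = get_precision(self.precision)
        self.data = np.asarray(self.data)
        if self.data.shape != (packed_length(self.dim),):
            raise ValueError(
                f"packed data must have length {packed_length(self.dim)} "
                f"for dim {self.dim}, got shape {self.data.shape}"
            )
        if self.triangle != "upper":
            raise ValueError("only the upper column-packed layout is implemented")

    @classmethod
    def from_dense(cls, mat: np.ndarray, precision="f64") -> "PackedSymmetric":
        mat = np.asarray(mat)
        if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
            raise ValueError("expected a square matrix")
        if not np.allclose(mat, mat.T):
            raise ValueError("matrix is not symmetric")
        dim = mat.shape[0]
        iu = np.triu_indices(dim)
        packed = np.empty(packed_length(dim))
        for i, j in zip(*iu):
            packed[packed_index(i, j, dim)] = mat[i, j]
        return cls(dim, quantize(packed, get_precision(precision)), get_precision(precision))

    def to_dense(self) -> np.ndarray:
        vals = dequantize(self.data, self.precision)
        out = np.empty((self.dim, self.dim))
        for j in range(self.dim):
            for i in range(j + 1):
                out[i, j] = out[j, i] = vals[packed_index(i, j, self.dim)]
        return out

    def __getitem__(self, ij):
        i, j = ij
        return dequantize(self.data[packed_index(i, j, self.dim)], self.precision)


class BatchedP:
    """N independent packed-symmetric L x L matrices in a common precision.

    This is the container the RLS trainer updates: row n of ``data`` is the
    packed triangle of neuron n's P matrix.  Total element count is
    N * L(L+1)/2, about half the dense N * L^2 footprint.
    """

    def __init__(self, n_batch: int, dim: int, precision="f64", data=None):
        if n_batch < 1 or dim < 1:
            raise ValueError("n_batch and dim must be positive")
        self.n_batch = int(n_batch)
        self.dim = int(dim)
        self.precision = get_precision(precision)
        shape = (self.n_batch, packed_length(self.dim))
        if data is None:
            self.data = np.zeros(shape, dtype=self.precision.dtype)
        else:
            data = np.asarray(data, dtype=self.precision.dtype)
            if data.shape != shape:
                raise ValueError(f"expected data of shape {shape}, got {data.shape}")
            self.data = data

    @classmethod
    def scaled_identity(cls, n_batch: int, dim: int, diag: float, precision="f64") -> "BatchedP":
        spec = get_precision(precision)
        if spec.is_integer and abs(diag) * spec.scale > spec.qmax:
            raise ValueError(
                f"diagonal value {diag} is not representable in {spec.code} "
                f"(max {spec.qmax / spec.scale}); use a larger regularization"
            )
        out = cls(n_batch, dim, spec)
        diag_offsets = np.array([packed_index(i, i, dim) for i in range(dim)])
        out.data[:, diag_offsets] = quantize(diag, spec) if spec.is_integer else diag
        return out

    @property
    def nbytes(self) -> int:
        return self.data.nbytes

    def neuron(self, n: int) -> PackedSymmetric:
        return PackedSymmetric(self.dim, self.data[n], self.precision)

    def to_dense(self, n: int) -> np.ndarray:
        return self.neuron(n).to_dense()

    def _check_batch(self, x):
        x = np.ascontiguousarray(x, dtype=np.float64)
        if x.shape != (self.n_batch, self.dim):
            raise ValueError(
                f"expected an ({self.n_batch}, {self.dim}) batch, got {x.shape}"
            )
        return x

    def matvec(self, x, alpha: float = 1.0, beta: float = 0.0, out=None):
        """out_n <- alpha * P_n x_n + beta * out_n, batched over n."""
        x = self._check_batch(x)
        if out is None:
            out = np.zeros((self.n_batch, self.dim))
            beta = 0.0
        elif (out.shape != (self.n_batch, self.dim) or out.dtype != np.float64
              or not out.flags.c_contiguous):
            raise ValueError("out must be a C-contiguous float64 (N, L) array")
        if self.precision.is_integer:
            _kernels.spmv_batched_int(self.data, 1.0 / self.precision.scale,
                                      x, float(alpha), float(beta), out)
        else:
            _kernels.spmv_batched_float(self.data, x, float(alpha), float(beta), out)
        return out

    def rank1_update(self, alpha, x):
        """P_n <- P_n + alpha_n * x_n x_n^T, batched; touches only the triangle."""
        x = self._check_batch(x)
        alpha = np.ascontiguousarray(np.broadcast_to(alpha, (self.n_batch,)),
                                     dtype=np.float64)
        spec = self.precision
        if spec.is_integer:
            _kernels.spr_batched_int(self.data, spec.scale, 1.0 / spec.scale,
                                     spec.qmin, spec.qmax, alpha, x)
        else:
            _kernels.spr_batched_float(self.data, alpha, x)
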