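"""Canonical design and the discrete sine eigenbasis of the Brownian covariance.

The regression model lives on the design ``x_i = i / n_+`` with ``n_+ = n + 1/2``
(1-based ``i``).  The prior covariance matrix ``U_n`` with entries
``x_i ∧ x_k`` is diagonalised exactly by the discretised sine functions

    e_j(x) = sqrt(2) * sin((j - 1/2) * pi * x),      j = 1, 2, ...

restricted to the grid and rescaled to unit Euclidean norm,

    e_{j,n} = (1 / sqrt(n_+)) * (e_j(x_1), ..., e_j(x_n)).

Coefficients with respect to this basis drive everything downstream: the
posterior mean is diagonal shrinkage in coefficient space, and the
empirical-Bayes criteria are sums over the eigenvalues ``lambda_{j,n} ≍ n/j^2``.

The module offers a direct O(n^2) blocked transform and a fast
O(n log n) path through a zero-padded complex FFT of length ``2*(2n+1)``;
both compute the same inner products and agree to floating-point accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import scipy.fft

__all__ = [
    "DesignGrid",
    "SpectralBasis",
    "make_design",
    "eigen_system",
    "to_coefficients",
    "from_coefficients",
    "alias_coefficients",
    "brownian_cov_matvec",
]

_BLOCK = 128  # row block for the O(n^2) paths; keeps extra memory at O(n)


@dataclass(frozen=True)
class DesignGrid:
    """The canonical equispaced design on (0, 1)."""

    n: int
    n_plus: float
    points: np.ndarray

    def __post_init__(self) -> None:
        self.points.setflags(write=False)


def make_design(n: int) -> DesignGrid:
    """Return the design grid ``x_i = i/(n + 1/2)``, ``i = 1..n``."""
    if not isinstance(n, (int, np.integer)) or isinstance(n, bool):
        raise TypeError(f"n must be an integer, got {type(n).__name__}")
    if n < 1:
        raise ValueError(f"n must be positive, got {n}")
    n = int(n)
    n_plus = n + 0.5
    points = np.arange(1, n + 1, dtype=float) / n_plus
    return DesignGrid(n=n, n_plus=n_plus, points=points)


def brownian_cov_matvec(v: np.ndarray, n_plus: float) -> np.ndarray:
    """Matrix-free product ``U_n v`` for ``(U_n)_{ik} = x_i ∧ x_k``.

    Uses ``(U v)_i = (1/n_+) * (sum_{k<=i} k v_k + i * sum_{k>i} v_k)``,
    which is two cumulative sums: O(n) time, O(n) memory.  Accepts a matrix
    of column vectors.
    """
    v = np.asarray(v, dtype=float)
    n = v.shape[0]
    idx = np.arange(1, n + 1, dtype=float)
    if v.ndim == 1:
        head = np.cumsum(idx * v)
        tail = np.cumsum(v[::-1])[::-1] - v  # sum_{k>i} v_k
        return (head + idx * tail) / n_plus
    idxc = idx[:, None]
    head = np.cumsum(idxc * v, axis=0)
    tail = np.cumsum(v[::-1], axis=0)[::-1] - v
    return (head + idxc * tail) / n_plus


class SpectralBasis:
    """Discrete sine eigenbasis of ``U_n`` with its eigenvalues.

    Eigenvalues are obtained from the exact quadratic forms
    ``lambda_{j,n} = e_{j,n}^T U_n e_{j,n}`` evaluated matrix-free in row
    blocks, never through a dense eigendecomposition.
    """

    def __init__(self, n: int):
        grid = make_design(n)
        self.n = grid.n
        self.n_plus = grid.n_plus
        self.grid = grid
        self.eigenvalues = self._quadratic_form_eigenvalues()
        self.eigenvalues.setflags(write=False)

    def basis_vector(self, j: int) -> np.ndarray:
        """The unit vector ``e_{j,n}`` (1-based ``j``)."""
        if not 1 <= j <= self.n:
            raise ValueError(f"j must be in [1, {self.n}], got {j}")
        return np.sqrt(2.0 / self.n_plus) * np.sin((j - 0.5) * np.pi * self.grid.points)

    def basis_block(self, j_lo: int, j_hi: int) -> np.ndarray:
        """Rows ``j_lo..j_hi`` (inclusive, 1-based) of the basis as a matrix."""
        js = np.arange(j_lo, j_hi + 1, dtype=float) - 0.5
        return np.sqrt(2.0 / self.n_plus) * np.sin(
            np.pi * js[:, None] * self.grid.points[None, :]
        )

    def _quadratic_form_eigenvalues(self) -> np.ndarray:
        lam = np.empty(self.n)
        for j_lo in range(1, self.n + 1, _BLOCK):
            j_hi = min(j_lo + _BLOCK - 1, self.n)
            block = self.basis_block(j_lo, j_hi)  # (b, n)
            ue = brownian_cov_matvec(block.T, self.n_plus)  # (n, b)
            lam[j_lo - 1 : j_hi] = np.einsum("bn,nb->b", block, ue)
        return lam


@lru_cache(maxsize=64)
def eigen_system(n: int) -> SpectralBasis:
    """Cached spectral basis for sample size ``n``."""
    return SpectralBasis(int(n))


def _check_length(values: np.ndarray, basis: SpectralBasis) -> np.ndarray:
    # transforms operate on a vector, or on a stack of row vectors
    values = np.asarray(values, dtype=float)
    if values.ndim not in (1, 2) or values.shape[-1] != basis.n:
        raise ValueError(f"expected trailing length {basis.n}, got shape {values.shape}")
    return values


def to_coefficients(grid_values: np.ndarray, basis: SpectralBasis, fast: bool = True) -> np.ndarray:
    """Coefficients ``f_{j,n} = f_n^T e_{j,n}`` of grid values (1-based j at index j-1).

    ``grid_values`` may be a vector or a stack of vectors (rows).  The fast
    path embeds the product in a complex FFT of length ``2*(2n+1)``:
    with ``M = 2(2n+1)`` the inner products are ``-Im FFT(v)`` read off at the
    odd frequencies ``1, 3, ..., 2n-1``.
    """
    v = _check_length(grid_values, basis)
    n = basis.n
    scale = np.sqrt(2.0 / basis.n_plus)
    if fast:
        single = v.ndim == 1
        v2 = v[None, :] if single else v
        m = 2 * (2 * n + 1)
        pad = np.zeros((v2.shape[0], m))
        pad[:, 1 : n + 1] = v2
        coef = -scale * scipy.fft.fft(pad, axis=1).imag[:, 1 : 2 * n : 2]
        return coef[0] if single else coef
    out = np.empty_like(v)
    for j_lo in range(1, n + 1, _BLOCK):
        j_hi = min(j_lo + _BLOCK - 1, n)
        block = basis.basis_block(j_lo, j_hi)
        if v.ndim == 1:
            out[j_lo - 1 : j_hi] = block @ v
        else:
            out[:, j_lo - 1 : j_hi] = v @ block.T
    return out


def from_coefficients(coefficients: np.ndarray, basis: SpectralBasis, fast: bool = True) -> np.ndarray:
    """Grid values ``sum_j c_j e_{j,n}``; inverse of :func:`to_coefficients`."""
    c = _check_length(coefficients, basis)
    n = basis.n
    scale = np.sqrt(2.0 / basis.n_plus)
    if fast:
        single = c.ndim == 1
        c2 = c[None, :] if single else c
        m = 2 * (2 * n + 1)
        q = np.zeros((c2.shape[0], m))
        q[:, 1 : 2 * n : 2] = c2
        vals = -scale * scipy.fft.fft(q, axis=1).imag[:, 1 : n + 1]
        return vals[0] if single else vals
    out = np.zeros_like(c)
    for j_lo in range(1, n + 1, _BLOCK):
        j_hi = min(j_lo + _BLOCK - 1, n)
        block = basis.basis_block(j_lo, j_hi)
        if c.ndim == 1:
            out += c[j_lo - 1 : j_hi] @ block
        else:
            out += c[:, j_lo - 1 : j_hi] @ block
    return out


def alias_coefficients(fourier_sequence: np.ndarray, n: int) -> np.ndarray:
    """Fold a continuous Fourier series onto the ``n`` discrete coefficients.

    Implements the aliasing identity

        f_{j,n} = sqrt(n_+) * sum_{l>=0} (f_{(2n+1)l + j} - f_{(2n+1)l + 2n+2-j}),

    with coefficients beyond the end of ``fourier_sequence`` treated as zero.
    The result equals ``to_coefficients`` of the series evaluated on the grid.
    """
    f = np.asarray(fourier_sequence, dtype=float)
    if f.ndim != 1:
        raise ValueError("fourier_sequence must be one-dimensional")
    grid = make_design(n)
    period = 2 * n + 1
    n_blocks = int(np.ceil(f.size / period)) or 1
    padded = np.zeros(n_blocks * period)
    padded[: f.size] = f
    blocks = padded.reshape(n_blocks, period)
    out = np.zeros(n)
    # within each block: +f at position j-1 (j = 1..n), -f at position 2n+1-j
    out += blocks[:, :n].sum(axis=0)
    out -= blocks[:, n + 1 :][:, ::-1].sum(axis=0)
    return np.sqrt(grid.n_plus) * out
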