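"""Posterior mean, covariance and path sampling for the scaled Brownian prior.

With prior ``f = sqrt(c) W`` for standard Brownian motion ``W`` and unit
Gaussian noise, the posterior mean at any point ``x`` is a linear combination
``fhat(x) = sum_i a_i(x, c) Y_i`` of the observations.  The weight vector
solves ``(c^{-1} I + U_n) a = (x ∧ x_i)_i``.  Double-differencing the rows of
that system turns it into a tridiagonal one with diagonal ``2 + c/n_+``
(last entry ``1 + c/n_+``) and off-diagonals ``-1``, solvable in O(n); for an
interior ``x`` the transformed right-hand side has exactly two nonzero
entries, ``c (x_{i_n+1} - x)`` and ``c (x - x_{i_n})`` at the rows flanking
``x``, and the same transform covers the boundary cases ``x <= x_1``
(right side ``c (x, 0, ..., 0)``) and ``x > x_n`` (right side of ``x_n``).

At the design points the posterior is diagonal in the sine eigenbasis: the
coefficients of the posterior mean are the data coefficients shrunk by
``c lambda_j / (1 + c lambda_j)``, which is also the spectral posterior
variance.  Between design points the posterior law is the prior Brownian
bridge given the design values, which the path sampler exploits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_banded

from .design import (
    DesignGrid,
    SpectralBasis,
    brownian_cov_matvec,
    eigen_system,
    from_coefficients,
    make_design,
    to_coefficients,
)

__all__ = [
    "PosteriorWeights",
    "PosteriorState",
    "DiagnosticDecomposition",
    "weights",
    "weights_dense",
    "posterior_state",
    "posterior_design_mean",
    "sample_centered_design",
    "posterior_mean",
    "posterior_cov",
    "sample_posterior_paths",
    "decompose",
    "discrete_bias",
    "shrinkage_factors",
]


@dataclass(frozen=True)
class PosteriorWeights:
    """Weights ``a_{i,n}(x, c)`` of the posterior mean at a single point."""

    x: float
    c: float
    weights: np.ndarray
    lambda_plus: float

    @property
    def total(self) -> float:
        return float(self.weights.sum())


def _validate_xc(x: float, c: float) -> None:
    if not 0.0 < x <= 1.0:
        raise ValueError(f"x must lie in (0, 1], got {x}")
    if not c > 0.0:
        raise ValueError(f"c must be positive, got {c}")


def lambda_plus(c: float, n_plus: float) -> float:
    """Larger root of the weight recurrence ``lam^2 - (2 + c/n_+) lam + 1``."""
    r = c / n_plus
    return 1.0 + np.sqrt(r) * np.sqrt(1.0 + r / 4.0) + r / 2.0


def _transformed_rhs(x: float, c: float, grid: DesignGrid) -> np.ndarray:
    """Right-hand side of the tridiagonal system: double differences of
    ``c * (x ∧ x_i)_i``.  For interior x only the two rows flanking x are
    nonzero."""
    u = np.minimum(x, grid.points)
    s = np.diff(u, prepend=0.0)
    t = s.copy()
    t[:-1] -= s[1:]
    return c * t


def weights(x: float, c: float, grid: DesignGrid) -> PosteriorWeights:
    """Solve the tridiagonal system for ``a_n(x, c)`` in O(n).

    For ``x`` beyond the last design point the covariance vector
    ``(x ∧ x_i)_i`` no longer changes, so the weights are those at ``x_n``.
    """
    _validate_xc(x, c)
    n, n_plus = grid.n, grid.n_plus
    rhs = _transformed_rhs(min(x, grid.points[-1]), c, grid)
    ab = np.zeros((3, n))
    ab[0, 1:] = -1.0
    ab[1, :] = 2.0 + c / n_plus
    ab[1, -1] = 1.0 + c / n_plus
    ab[2, :-1] = -1.0
    a = solve_banded((1, 1), ab, rhs)
    return PosteriorWeights(x=float(x), c=float(c), weights=a, lambda_plus=lambda_plus(c, n_plus))


def weights_dense(x: float, c: float, grid: DesignGrid) -> np.ndarray:
    """Dense-solve oracle ``(c^{-1} I + U_n) a = (x ∧ x_i)_i``; O(n^3), test use."""
    _validate_xc(x, c)
    pts = grid.points
    u_mat = np.minimum.outer(pts, pts)
    rhs = np.minimum(x, pts)
    return np.linalg.solve(np.eye(grid.n) / c + u_mat, rhs)


def shrinkage_factors(c: float, basis: SpectralBasis) -> np.ndarray:
    """Spectral shrinkage ``c lambda_j / (1 + c lambda_j)`` (also the posterior
    variance of each coefficient at the design points)."""
    cl = c * basis.eigenvalues
    return cl / (1.0 + cl)


@dataclass
class PosteriorState:
    """Posterior given ``(Y, c)``: spectral representation plus evaluators."""

    c: float
    data: np.ndarray
    basis: SpectralBasis
    data_coefficients: np.ndarray
    mean_coefficients: np.ndarray
    spectral_variances: np.ndarray
    design_mean: np.ndarray

    def mean(self, xs: np.ndarray) -> np.ndarray:
        return posterior_mean(self.data, self.c, xs, state=self)

    def cov(self, x: float, y: float) -> float:
        return posterior_cov(x, y, self.c, self.basis.grid)

    def tau(self, x: float, y: float) -> float:
        """Sampling covariance of the posterior mean, ``a(x)^T a(y)``."""
        grid = self.basis.grid
        ax = weights(x, self.c, grid).weights
        ay = ax if y == x else weights(y, self.c, grid).weights
        return float(ax @ ay)


def posterior_state(Y: np.ndarray, c: float, basis: SpectralBasis | None = None) -> PosteriorState:
    Y = np.asarray(Y, dtype=float)
    if basis is None:
        basis = eigen_system(Y.shape[0])
    if Y.shape[0] != basis.n:
        raise ValueError(f"Y has length {Y.shape[0]}, basis expects {basis.n}")
    if not c > 0:
        raise ValueError(f"c must be positive, got {c}")
    y_coef = to_coefficients(Y, basis)
    shrink = shrinkage_factors(c, basis)
    mean_coef = shrink * y_coef
    design_mean = from_coefficients(mean_coef, basis)
    return PosteriorState(
        c=float(c),
        data=Y,
        basis=basis,
        data_coefficients=y_coef,
        mean_coefficients=mean_coef,
        spectral_variances=shrink,
        design_mean=design_mean,
    )


def posterior_mean(Y: np.ndarray, c: float, xs: np.ndarray, state: PosteriorState | None = None) -> np.ndarray:
    """Posterior mean ``fhat_{n,c}`` at arbitrary query points.

    Computed spectrally at the design points; in between, ``fhat`` is the
    exact linear interpolant of its design values (the weight vector is
    piecewise linear in ``x``), anchored at ``fhat(0) = 0`` and constant
    beyond ``x_n``.
    """
    if state is None:
        state = posterior_state(Y, c)
    xs = np.atleast_1d(np.asarray(xs, dtype=float))
    pts = state.basis.grid.points
    xp = np.concatenate(([0.0], pts))
    fp = np.concatenate(([0.0], state.design_mean))
    return np.interp(xs, xp, fp)


def posterior_cov(x: float, y: float, c: float, grid: DesignGrid) -> float:
    """Posterior covariance ``sigma_n(x, y, c)`` of ``(f(x), f(y))``.

    Uses ``c [x∧y - u(x)^T a(y) - u(y)^T a(x) + a(x)^T U_n a(y)] + a(x)^T a(y)``
    with ``u(z) = (z ∧ x_i)_i``; all products are matrix-free.
    """
    _validate_xc(x, c)
    _validate_xc(y, c)
    ax = weights(x, c, grid).weights
    ay = ax if y == x else weights(y, c, grid).weights
    ux = np.minimum(x, grid.points)
    uy = ux if y == x else np.minimum(y, grid.points)
    u_ay = brownian_cov_matvec(ay, grid.n_plus)
    prior_part = min(x, y) - ux @ ay - uy @ ax + ax @ u_ay
    return float(c * prior_part + ax @ ay)


def _bridge_noise(rng: np.random.Generator, n_draws: int, n_segments: int,
                  seg_lengths: np.ndarray, m: int, c: float) -> np.ndarray:
    """Centered c-scaled Brownian-bridge values at m interior points of each
    segment; shape (n_draws, n_segments, m)."""
    # bridge B(t) = W(t) - (t/h) W(h) from a fresh BM per segment
    steps = rng.standard_normal((n_draws, n_segments, m + 1))
    dt = seg_lengths[None, :, None] / (m + 1)
    w = np.cumsum(steps * np.sqrt(c * dt), axis=2)
    frac = (np.arange(1, m + 2) / (m + 1))[None, None, :]
    bridge = w - frac * w[:, :, -1:]
    return bridge[:, :, :m]


def sample_posterior_paths(Y: np.ndarray, c: float, n_draws: int,
                           subgrid_factor: int = 8, seed: int | None = None,
                           centered: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Exact draws from the posterior on a refined grid.

    Discrete posterior values are drawn spectrally (mean coefficient plus
    ``sqrt(c lambda_j/(1+c lambda_j))`` times a standard normal, transformed
    back), then each inter-design interval is filled with an independent
    c-scaled Brownian bridge at ``subgrid_factor`` interior points, the left
    segment is a bridge pinned at ``f(0) = 0``, and the stub past ``x_n`` is
    continued with c-scaled Brownian increments.

    Returns ``(grid, paths)`` with ``paths`` of shape ``(n_draws, len(grid))``.
    With ``centered=True`` the posterior mean is omitted, giving draws of
    ``f - fhat`` (whose law does not depend on ``Y``).
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if subgrid_factor < 1:
        raise ValueError("subgrid_factor must be >= 1")
    state = posterior_state(np.asarray(Y, dtype=float), c)
    basis = state.basis
    n = basis.n
    rng = np.random.default_rng(seed)

    g = rng.standard_normal((n_draws, n))
    coef = np.sqrt(state.spectral_variances)[None, :] * g
    if not centered:
        coef = coef + state.mean_coefficients[None, :]
    design_vals = from_coefficients(coef, basis)

    m = subgrid_factor
    pts = basis.grid.points
    h = 1.0 / basis.n_plus
    knots = np.concatenate(([0.0], pts))  # n+1 knot locations, incl. the origin
    # n bridge segments (0, x_1], ..., (x_{n-1}, x_n], each of length h,
    # with m interior points; then a stub (x_n, 1] of length h/2
    frac1 = np.arange(1, m + 1) / (m + 1)
    interior = knots[:n, None] + h * frac1[None, :]
    stub_len = 1.0 - pts[-1]
    stub = pts[-1] + stub_len * (np.arange(1, m + 2) / (m + 1))
    grid_full = np.concatenate((knots, interior.ravel(), stub))
    order = np.argsort(grid_full, kind="stable")

    knot_vals = np.concatenate((np.zeros((n_draws, 1)), design_vals), axis=1)

    bridge = _bridge_noise(rng, n_draws, n, np.full(n, h), m, c)
    frac = frac1[None, None, :]
    lin = knot_vals[:, :n, None] * (1 - frac) + design_vals[:, :, None] * frac
    interior_vals = lin + bridge

    # stub past x_n: free Brownian motion increments
    stub_steps = rng.standard_normal((n_draws, m + 1))
    stub_dt = stub_len / (m + 1)
    stub_vals = design_vals[:, -1:] + np.cumsum(stub_steps * np.sqrt(c * stub_dt), axis=1)

    vals_full = np.concatenate((knot_vals, interior_vals.reshape(n_draws, -1), stub_vals), axis=1)
    return grid_full[order], vals_full[:, order]


def _posterior_precision_banded(n: int, c: float) -> np.ndarray:
    """Upper-banded storage of the design-point posterior precision.

    The posterior covariance at the design points is ``(I + cU_n)^{-1} c U_n``;
    its inverse ``(c U_n)^{-1} + I = (n_+/c) T + I`` is tridiagonal, with T the
    second-difference matrix (diagonal 2, last entry 1, off-diagonals -1).
    """
    n_plus = n + 0.5
    ab = np.zeros((2, n))
    ab[0, 1:] = -n_plus / c
    ab[1, :] = 2.0 * n_plus / c + 1.0
    ab[1, -1] = n_plus / c + 1.0
    return ab


def posterior_design_mean(Y: np.ndarray, c: float) -> np.ndarray:
    """Posterior mean at the design points by one O(n) tridiagonal solve.

    Solves ``[(c U_n)^{-1} + I] m = Y``; identical to the spectral shrinkage
    route up to floating point.
    """
    Y = np.asarray(Y, dtype=float)
    if not c > 0:
        raise ValueError(f"c must be positive, got {c}")
    ab = _posterior_precision_banded(Y.shape[0], c)
    full = np.zeros((3, Y.shape[0]))
    full[0] = ab[0]
    full[1] = ab[1]
    full[2, :-1] = ab[0, 1:]
    return solve_banded((1, 1), full, Y)


def sample_centered_design(n: int, c: float, n_draws: int,
                           rng: np.random.Generator) -> np.ndarray:
    """Exact draws of ``f - fhat`` at the design points, O(n) per draw.

    Uses the banded Cholesky ``P = R^T R`` of the tridiagonal posterior
    precision and back-substitutes standard normals through R, giving
    covariance ``P^{-1}`` — the same Gaussian law as the spectral route but
    without an O(n log n) transform per draw.  Returns shape (n_draws, n).
    """
    from scipy.linalg import cholesky_banded

    r = cholesky_banded(_posterior_precision_banded(n, c), lower=False)
    diag = r[1]
    sup = r[0]
    g = rng.standard_normal((n_draws, n))
    x = np.empty_like(g)
    x[:, n - 1] = g[:, n - 1] / diag[n - 1]
    for i in range(n - 2, -1, -1):
        x[:, i] = (g[:, i] - sup[i + 1] * x[:, i + 1]) / diag[i]
    return x


@dataclass(frozen=True)
class DiagnosticDecomposition:
    """Centered posterior mean ``T_n`` and bias ``mu_n`` on a grid of x."""

    xs: np.ndarray
    centered: np.ndarray  # T_n(x, c) = sum_i a_i(x, c) eps_i
    bias: np.ndarray      # mu_n(x, c) = sum_i a_i(x, c) f(x_i) - f(x)


def decompose(f, Y: np.ndarray, c: float, xs: np.ndarray) -> DiagnosticDecomposition:
    """Split ``fhat - f`` into noise part ``T_n`` and bias ``mu_n`` at ``xs``.

    ``f`` is any callable on [0, 1]; the realised noise is recovered as
    ``Y - f(x_i)``.  The identity ``T_n + mu_n = fhat - f`` holds exactly.
    """
    Y = np.asarray(Y, dtype=float)
    grid = make_design(Y.shape[0])
    xs = np.atleast_1d(np.asarray(xs, dtype=float))
    f_design = np.asarray(f(grid.points), dtype=float)
    eps = Y - f_design
    centered = np.empty(xs.shape)
    bias = np.empty(xs.shape)
    f_at_xs = np.asarray(f(xs), dtype=float)
    for k, x in enumerate(xs):
        a = weights(x, c, grid).weights
        centered[k] = a @ eps
        bias[k] = a @ f_design - f_at_xs[k]
    return DiagnosticDecomposition(xs=xs, centered=centered, bias=bias)


def discrete_bias(f_coefficients: np.ndarray, c: float, basis: SpectralBasis | None = None) -> np.ndarray:
    """Bias of the posterior mean at the design points, spectrally.

    For discrete coefficients ``f_{j,n}`` the bias at ``x_{j,n}`` is
    ``-(1/sqrt(n_+)) sum_i f_{i,n} e_i(x_{j,n}) / (1 + c lambda_{i,n})``,
    i.e. minus the inverse transform of ``f_{i,n}/(1 + c lambda_{i,n})``.
    """
    f_coefficients = np.asarray(f_coefficients, dtype=float)
    if basis is None:
        basis = eigen_system(f_coefficients.shape[0])
    if not c > 0:
        raise ValueError(f"c must be positive, got {c}")
    damped = f_coefficients / (1.0 + c * basis.eigenvalues)
    return -from_coefficients(damped, basis)
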