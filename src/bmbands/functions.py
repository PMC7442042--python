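"""True-function library and synthetic data for the regression model.

Three families with known smoothness structure:

* deterministic self-similar series ``f_j = M j^{-1/2-beta} s_j`` with signs
  ``s_j`` — the textbook self-similar function of order beta;
* random series draws ``gamma * Z_j / (j + delta)^{1/2+alpha}`` with i.i.d.
  standard normal ``Z_j`` — realisations of a Gaussian prior; the Brownian
  motion prior itself corresponds to ``alpha = 1/2``, ``delta = -1/2``,
  ``gamma = sqrt(2c)/pi``;
* the kink ``f(t) = |x0 - t|^alpha`` with ``x0 in (1/2, 1)`` — Hölder of
  order alpha but with Fourier coefficients of order ``j^{-1}`` (hence
  self-similar of order 1/2), the canonical example where adaptive bands
  under-cover for ``alpha < 1/2``.

Synthetic observations follow ``Y_i = f(x_i) + eps_i`` with independent
standard normal errors on the canonical design.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.integrate import quad

from .design import DesignGrid, alias_coefficients, eigen_system, from_coefficients, make_design

__all__ = [
    "TrueFunction",
    "RegressionSample",
    "SobolevNorms",
    "self_similar_series",
    "prior_draw",
    "brownian_prior_draw",
    "kink_function",
    "kink_fourier",
    "simulate_data",
    "sobolev_norms",
]

_EVAL_BLOCK = 512  # frequency block for direct series evaluation


def _series_eval(coefficients: np.ndarray, xs: np.ndarray) -> np.ndarray:
    """Partial-sum evaluation of sum_j f_j sqrt(2) sin((j-1/2) pi x), blocked."""
    xs = np.atleast_1d(np.asarray(xs, dtype=float))
    out = np.zeros_like(xs)
    for lo in range(0, coefficients.size, _EVAL_BLOCK):
        hi = min(lo + _EVAL_BLOCK, coefficients.size)
        js = np.arange(lo + 1, hi + 1) - 0.5
        out += coefficients[lo:hi] @ (np.sqrt(2.0) * np.sin(np.pi * np.outer(js, xs)))
    return out


@dataclass
class TrueFunction:
    """A regression function with evaluator, Fourier coefficients, metadata."""

    family: str
    params: dict
    evaluator: Callable[[np.ndarray], np.ndarray]
    fourier: np.ndarray | None = None  # continuous coefficients f_j, truncated
    seed: int | None = None

    def __call__(self, xs: np.ndarray) -> np.ndarray:
        return self.evaluator(np.asarray(xs, dtype=float))

    def design_values(self, n: int) -> np.ndarray:
        """Values at the design points.

        Series-defined families go through the aliasing map and the inverse
        coefficient transform — exactly the partial sum at the grid, but in
        O(J + n log n) — while closed-form families evaluate directly.
        """
        grid = make_design(n)
        if self.fourier is not None and self.family != "kink":
            return from_coefficients(self.discrete_coefficients(n), eigen_system(n))
        return self(grid.points)

    def discrete_coefficients(self, n: int) -> np.ndarray:
        """Grid coefficients ``f_{j,n}``: aliased for series families,
        transformed grid values otherwise."""
        if self.fourier is not None and self.family != "kink":
            return alias_coefficients(self.fourier, n)
        from .design import to_coefficients

        return to_coefficients(self(make_design(n).points), eigen_system(n))

    def to_json(self) -> str:
        payload = {"family": self.family, "params": self.params, "seed": self.seed}
        return json.dumps(payload)


def self_similar_series(beta: float, M: float = 1.0, J: int = 1000,
                        signs: np.ndarray | None = None,
                        seed: int | None = None) -> TrueFunction:
    """Self-similar function of order beta: ``f_j = M j^{-1/2-beta} s_j``.

    Signs default to all +1; pass ``seed`` for random ±1 signs.
    """
    if beta <= 0 or M <= 0 or J < 1:
        raise ValueError("require beta > 0, M > 0, J >= 1")
    j = np.arange(1, J + 1, dtype=float)
    if signs is not None:
        s = np.asarray(signs, dtype=float)
        if s.shape != (J,) or not np.all(np.abs(s) == 1):
            raise ValueError("signs must be a length-J vector of +/-1")
    elif seed is not None:
        s = np.random.default_rng(seed).choice([-1.0, 1.0], size=J)
    else:
        s = np.ones(J)
    coef = M * j ** (-0.5 - beta) * s
    return TrueFunction(
        family="self_similar",
        params={"beta": beta, "M": M, "J": J, "random_signs": signs is not None or seed is not None},
        evaluator=lambda xs: _series_eval(coef, xs),
        fourier=coef,
        seed=seed,
    )


def prior_draw(alpha: float = 0.5, gamma: float = 1.0, delta: float = 0.0,
               J: int = 4000, seed: int | None = None) -> TrueFunction:
    """Random series draw ``gamma sum_j Z_j e_j(x) / (j + delta)^{1/2+alpha}``.

    Truncated at J terms (pick ``J >= 4*(2n+1)`` for a target sample size n
    so several aliasing blocks are represented).
    """
    if alpha <= 0 or gamma <= 0 or delta <= -1 or J < 1:
        raise ValueError("require alpha > 0, gamma > 0, delta > -1, J >= 1")
    z = np.random.default_rng(seed).standard_normal(J)
    j = np.arange(1, J + 1, dtype=float)
    coef = gamma * z / (j + delta) ** (0.5 + alpha)
    return TrueFunction(
        family="prior_draw",
        params={"alpha": alpha, "gamma": gamma, "delta": delta, "J": J},
        evaluator=lambda xs: _series_eval(coef, xs),
        fourier=coef,
        seed=seed,
    )


def brownian_prior_draw(c: float, J: int, seed: int | None = None) -> TrueFunction:
    """Karhunen–Loève draw of ``sqrt(c) W``: alpha=1/2, delta=-1/2.

    The expansion ``sqrt(c) W = sum_j Z_j sqrt(c) e_j / ((j - 1/2) pi)``
    pins the scale at ``gamma = sqrt(c)/pi``, which reproduces the covariance
    ``c min(s, t)`` (checked by simulation in the test suite).
    """
    return prior_draw(alpha=0.5, gamma=np.sqrt(c) / np.pi, delta=-0.5, J=J, seed=seed)


def kink_function(x0: float = 0.75, alpha: float = 0.25) -> TrueFunction:
    """The Hölder-alpha kink ``f(t) = |x0 - t|^alpha``."""
    import warnings

    if not (0.5 < x0 < 1.0):
        warnings.warn(f"x0={x0} outside (1/2, 1); the coverage analysis assumes that range",
                      stacklevel=2)
    if not (0.0 < alpha < 1.0):
        warnings.warn(f"alpha={alpha} outside (0, 1); the coverage analysis assumes that range",
                      stacklevel=2)
    return TrueFunction(
        family="kink",
        params={"x0": x0, "alpha": alpha},
        evaluator=lambda xs: np.abs(x0 - np.asarray(xs, dtype=float)) ** alpha,
    )


def kink_fourier(x0: float, alpha: float, j_max: int, tol: float = 1e-10) -> np.ndarray:
    """Fourier coefficients of the kink by adaptive quadrature split at x0.

    ``f_j = sqrt(2) \\int_0^1 |x0 - t|^alpha sin((j - 1/2) pi t) dt``; the
    integrand's derivative blows up at ``t = x0``, so the integral is split
    there.  These decay like ``j^{-1}`` — far slower than the Hölder exponent
    alpha would suggest.
    """
    out = np.empty(j_max)
    for j in range(1, j_max + 1):
        w = (j - 0.5) * np.pi
        g = lambda t: np.abs(x0 - t) ** alpha * np.sin(w * t)
        left, _ = quad(g, 0.0, x0, epsabs=tol, epsrel=0.0, limit=200)
        right, _ = quad(g, x0, 1.0, epsabs=tol, epsrel=0.0, limit=200)
        out[j - 1] = np.sqrt(2.0) * (left + right)
    return out


@dataclass(frozen=True)
class RegressionSample:
    """One synthetic data set ``Y_i = f(x_i) + eps_i``."""

    design: DesignGrid
    responses: np.ndarray
    noise: np.ndarray
    truth: TrueFunction
    seed: int | None

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"x": self.design.points, "y": self.responses})


def simulate_data(f: TrueFunction, n: int, seed: int | None = None) -> RegressionSample:
    """Draw one sample of size n with i.i.d. standard normal noise."""
    grid = make_design(n)
    noise = np.random.default_rng(seed).standard_normal(n)
    f_design = f.design_values(n)
    responses = f_design + noise
    # store the float-rounded residual so Y - f(x_i) == noise holds exactly
    return RegressionSample(design=grid, responses=responses,
                            noise=responses - f_design, truth=f, seed=seed)


@dataclass(frozen=True)
class SobolevNorms:
    """Discrete Sobolev-type norms built from the grid coefficients."""

    beta: float
    l2: float    # ||f||_{n,beta}
    sup: float   # ||f||_{n,beta,infty}


def sobolev_norms(discrete_coefficients: np.ndarray, beta: float) -> SobolevNorms:
    """``||f||_{n,beta}^2 = (1/n) sum_j j^{2 beta} f_{j,n}^2`` and
    ``||f||_{n,beta,infty}^2 = (1/n) sup_j j^{1+2 beta} f_{j,n}^2``."""
    if beta < 0:
        raise ValueError(f"beta must be nonnegative, got {beta}")
    f = np.asarray(discrete_coefficients, dtype=float)
    n = f.shape[0]
    j = np.arange(1, n + 1, dtype=float)
    l2 = np.sqrt((j ** (2 * beta) * f**2).sum() / n)
    sup = np.sqrt((j ** (1 + 2 * beta) * f**2).max() / n)
    return SobolevNorms(beta=float(beta), l2=float(l2), sup=float(sup))
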