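"""Scikit-learn style front end for the adaptive band regressor.

`BrownianBandRegressor` bundles the pipeline — empirical- or
hierarchical-Bayes selection of the prior scale, posterior mean, Monte-Carlo
sup-norm quantile, band assembly — behind the familiar
``fit`` / ``predict`` / ``get_params`` surface, so it composes with sklearn
tooling.  The model assumes the canonical design ``x_i = i/(n + 1/2)``; pass
``X=None`` (the design is implied by ``len(y)``) or the design points
themselves, which are validated.
"""

from __future__ import annotations

import numbers

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .bands import BandDomain, CredibleBand, band_quantile, build_band, union_band
from .design import make_design
from .posterior import posterior_mean, posterior_state
from .scales import hb_posterior, quantile_pair, select_c_eb

__all__ = ["BrownianBandRegressor"]


class BrownianBandRegressor(RegressorMixin, BaseEstimator):
    """Nonparametric regression with a scaled Brownian-motion prior.

    Parameters
    ----------
    method : {'ml', 'risk', 'hb'}, default='ml'
        How to set the prior scale c: marginal-likelihood empirical Bayes,
        risk-based empirical Bayes, or hierarchical Bayes (truncated
        inverse-gamma hyperprior).
    c : float, optional
        Fix the scale instead of selecting it from the data.
    eta : float, default=0.95
        Credible level of the band (and of the hyperposterior interval).
    L : float, default=1.0
        Band inflation constant; the half-width is ``L * w``.
    band_type : {'discrete', 'continuous'}, default='discrete'
    domain : pair of floats, default=(0.1, 0.9)
        The interval on which the sup-norm is taken.
    n_draws : int, default=2000
        Monte-Carlo draws for the sup-norm quantile.
    subgrid_factor : int, default=8
        Interior points per design interval for the continuous band.
    kappa, hyper_lambda : float, default=1.0
        Hyperprior shape and rate (hierarchical Bayes only).
    n_c : int, default=16
        Number of scales in the union band (hierarchical Bayes only).
    c_grid_size : int, default=401
        Log-grid resolution for scale selection.
    random_state : int, optional
        Seed for the Monte-Carlo quantile.

    Attributes
    ----------
    n_ : sample size seen in fit.
    c_ : selected (or fixed) scale; hyperposterior median under 'hb'.
    c_interval_ : hyperposterior quantile pair (hb only, else None).
    coef_ : posterior-mean coefficients in the sine eigenbasis.
    design_mean_ : posterior mean at the design points.
    w_ : sup-norm quantile of the centered posterior (None under 'hb').
    """

    def __init__(self, method: str = "ml", c: float | None = None,
                 eta: float = 0.95, L: float = 1.0, band_type: str = "discrete",
                 domain: tuple = (0.1, 0.9), n_draws: int = 2000,
                 subgrid_factor: int = 8, kappa: float = 1.0,
                 hyper_lambda: float = 1.0, n_c: int = 16,
                 c_grid_size: int = 401, random_state: int | None = None):
        self.method = method
        self.c = c
        self.eta = eta
        self.L = L
        self.band_type = band_type
        self.domain = domain
        self.n_draws = n_draws
        self.subgrid_factor = subgrid_factor
        self.kappa = kappa
        self.hyper_lambda = hyper_lambda
        self.n_c = n_c
        self.c_grid_size = c_grid_size
        self.random_state = random_state

    def _validate_design(self, X, n: int) -> None:
        if X is None:
            return
        X = np.asarray(X, dtype=float).reshape(-1)
        if X.shape[0] != n:
            raise ValueError(f"X has {X.shape[0]} points but y has {n}")
        if not np.allclose(X, make_design(n).points, atol=1e-8):
            raise ValueError("X must be the canonical design i/(n + 1/2)")

    def fit(self, X, y):
        """Select the scale and compute the posterior for responses ``y``.

        ``X`` is either None or the canonical design points (validated);
        the model is determined by ``y`` alone.
        """
        y = np.asarray(y, dtype=float).reshape(-1)
        if y.size < 2:
            raise ValueError("need at least two observations")
        if not np.all(np.isfinite(y)):
            raise ValueError("y contains non-finite values")
        self._validate_design(X, y.size)
        self.n_ = y.size
        self.y_ = y
        self.c_interval_ = None
        if self.c is not None:
            if not (isinstance(self.c, numbers.Real) and self.c > 0):
                raise ValueError(f"c must be a positive number, got {self.c}")
            self.c_ = float(self.c)
        elif self.method in ("ml", "risk"):
            self.c_ = select_c_eb(y, self.method, self.c_grid_size).c_hat
        elif self.method == "hb":
            hb = hb_posterior(y, self.kappa, self.hyper_lambda, self.c_grid_size)
            self.c_interval_ = quantile_pair(hb, self.eta)
            self.c_ = hb.quantile(0.5)
        else:
            raise ValueError(f"method must be 'ml', 'risk' or 'hb', got {self.method!r}")
        state = posterior_state(y, self.c_)
        self.coef_ = state.mean_coefficients
        self.design_mean_ = state.design_mean
        self._state = state
        self.w_ = None
        if self.c_interval_ is None:
            self.w_ = band_quantile(self.n_, self.c_, self.eta, self.band_type,
                                    BandDomain(*self.domain), self.n_draws,
                                    self.subgrid_factor, self.random_state).value
        return self

    def predict(self, X) -> np.ndarray:
        """Posterior mean at query points in (0, 1]."""
        check_is_fitted(self, "c_")
        X = np.asarray(X, dtype=float).reshape(-1)
        return posterior_mean(self.y_, self.c_, X, state=self._state)

    def credible_band(self) -> CredibleBand:
        """The simultaneous band at level ``eta`` with inflation ``L``."""
        check_is_fitted(self, "c_")
        dom = BandDomain(*self.domain)
        if self.c_interval_ is not None:
            return union_band(self.y_, self.c_interval_, self.L, self.eta,
                              self.band_type, self.n_c, dom, self.n_draws,
                              self.subgrid_factor, self.random_state)
        return build_band(self.y_, self.c_, self.L, self.eta, self.band_type,
                          dom, self.n_draws, self.subgrid_factor, w=self.w_)
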