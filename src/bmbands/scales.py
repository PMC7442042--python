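"""Data-driven choice of the prior scale c.

Three routes are provided, all restricted to the interval
``I_n = [log(n)/n, n/log(n)]``:

* likelihood empirical Bayes — maximise the marginal likelihood of the data
  under the prior-predictive law ``Y ~ N(0, I + c U_n)``, i.e. minimise
  ``log det(I + c U_n) + Y^T (I + c U_n)^{-1} Y``;
* risk empirical Bayes — minimise an unbiased estimate of the quadratic risk
  of the posterior-mean estimator at the design points;
* hierarchical Bayes — a truncated inverse-gamma hyperprior
  ``pi(c) ∝ c^{-1-kappa} exp(-lambda/c)`` on ``I_n``, whose posterior is
  integrated on a log grid and summarised by a quantile pair.

Both empirical-Bayes criteria are sums over the sine eigenbasis, so a single
coefficient transform of the data makes every criterion evaluation O(n).
The deterministic skeleton of the criteria is the pair of D-functions:
a decreasing squared-bias proxy D1(c, f) and an increasing variance proxy
D2(c); their crossing point, the equaliser, is the oracle scale around which
the empirical-Bayes estimators concentrate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .design import SpectralBasis, eigen_system, to_coefficients

__all__ = [
    "ScaleInterval",
    "EBSelection",
    "HBPosterior",
    "DFunctions",
    "SmoothnessDiagnostics",
    "scale_interval",
    "eb_criterion",
    "eb_criterion_dense",
    "select_c_eb",
    "hb_posterior",
    "quantile_pair",
    "d_functions",
    "equalizer",
    "smoothness_checks",
    "bias_dominance",
]

_METHODS = ("likelihood", "risk")
_ALIASES = {"ml": "likelihood", "likelihood": "likelihood", "risk": "risk"}


@dataclass(frozen=True)
class ScaleInterval:
    """The admissible scale interval ``I_n = [log(n)/n, n/log(n)]``."""

    n: int
    lower: float
    upper: float

    def clip(self, c: float) -> float:
        return float(min(max(c, self.lower), self.upper))

    def log_grid(self, size: int) -> np.ndarray:
        return np.exp(np.linspace(np.log(self.lower), np.log(self.upper), size))


def scale_interval(n: int) -> ScaleInterval:
    if n < 2:
        raise ValueError(f"I_n is degenerate for n < 2, got n={n}")
    return ScaleInterval(n=n, lower=np.log(n) / n, upper=n / np.log(n))


def _canon_method(method: str) -> str:
    try:
        return _ALIASES[method]
    except KeyError:
        raise ValueError(f"method must be one of {sorted(_ALIASES)}, got {method!r}") from None


def _criterion_terms(c: np.ndarray, lam: np.ndarray, y2: np.ndarray, method: str) -> np.ndarray:
    """Vectorised criterion over an array of c values."""
    cl = np.multiply.outer(np.asarray(c, dtype=float), lam)  # (..., n)
    if method == "likelihood":
        return np.log1p(cl).sum(axis=-1) + (y2 / (1.0 + cl)).sum(axis=-1)
    shrink = cl / (1.0 + cl)
    inv2 = (1.0 + cl) ** -2
    return (shrink**2).sum(axis=-1) - inv2.sum(axis=-1) + (y2 * inv2).sum(axis=-1)


def eb_criterion(Y: np.ndarray, c: float, method: str = "likelihood",
                 basis: SpectralBasis | None = None) -> float:
    """Empirical-Bayes criterion at a single scale, computed spectrally."""
    method = _canon_method(method)
    if not np.all(np.asarray(c) > 0):
        raise ValueError(f"c must be positive, got {c}")
    Y = np.asarray(Y, dtype=float)
    if basis is None:
        basis = eigen_system(Y.shape[0])
    y2 = to_coefficients(Y, basis) ** 2
    return float(_criterion_terms(np.asarray(c, dtype=float), basis.eigenvalues, y2, method))


def eb_criterion_dense(Y: np.ndarray, c: float, method: str = "likelihood") -> float:
    """Direct matrix evaluation (log-det / traces / solves); test oracle."""
    method = _canon_method(method)
    Y = np.asarray(Y, dtype=float)
    n = Y.shape[0]
    pts = np.arange(1, n + 1) / (n + 0.5)
    sigma = np.eye(n) + c * np.minimum.outer(pts, pts)
    if method == "likelihood":
        sign, logdet = np.linalg.slogdet(sigma)
        return float(logdet + Y @ np.linalg.solve(sigma, Y))
    inv = np.linalg.inv(sigma)
    resid = np.eye(n) - inv
    return float(np.trace(resid @ resid) - np.trace(inv @ inv) + Y @ inv @ inv @ Y)


@dataclass(frozen=True)
class EBSelection:
    """Result of empirical-Bayes scale selection."""

    method: str
    c_hat: float
    interval: ScaleInterval
    grid: np.ndarray
    criterion_values: np.ndarray


def select_c_eb(Y: np.ndarray, method: str = "likelihood", grid_size: int = 401,
                basis: SpectralBasis | None = None) -> EBSelection:
    """Minimise the criterion over a log grid on ``I_n``, then refine.

    A golden-section search inside the bracketing cell polishes the grid
    minimum; ties break toward the smallest c (the rougher, coverage-safer
    choice).
    """
    method = _canon_method(method)
    Y = np.asarray(Y, dtype=float)
    n = Y.shape[0]
    interval = scale_interval(n)
    if basis is None:
        basis = eigen_system(n)
    y2 = to_coefficients(Y, basis) ** 2
    lam = basis.eigenvalues
    grid = interval.log_grid(max(int(grid_size), 1))
    values = _criterion_terms(grid, lam, y2, method)
    k = int(np.argmin(values))  # np.argmin returns the first (smallest-c) tie
    c_hat = grid[k]
    if grid.size > 1:
        lo = grid[max(k - 1, 0)]
        hi = grid[min(k + 1, grid.size - 1)]
        if hi > lo:
            res = minimize_scalar(
                lambda t: float(_criterion_terms(np.exp(t), lam, y2, method)),
                bounds=(np.log(lo), np.log(hi)), method="bounded",
                options={"xatol": 1e-10},
            )
            c_ref = interval.clip(np.exp(res.x))
            if float(_criterion_terms(np.asarray(c_ref), lam, y2, method)) <= values[k]:
                c_hat = c_ref
    return EBSelection(method=method, c_hat=float(c_hat), interval=interval,
                       grid=grid, criterion_values=values)


@dataclass(frozen=True)
class HBPosterior:
    """Hyperposterior of c on a log grid over ``I_n`` (trapezoid-normalised)."""

    kappa: float
    lam: float
    interval: ScaleInterval
    grid: np.ndarray
    log_density: np.ndarray
    density: np.ndarray
    cdf: np.ndarray

    def quantile(self, level: float) -> float:
        if not 0.0 <= level <= 1.0:
            raise ValueError(f"level must be in [0, 1], got {level}")
        return float(np.interp(level, self.cdf, self.grid))

    def mass(self, lo: float, hi: float) -> float:
        """Posterior mass of the interval [lo, hi] (clipped to the grid)."""
        cdf_at = lambda c: np.interp(c, self.grid, self.cdf)
        return float(cdf_at(hi) - cdf_at(lo))


def hb_posterior(Y: np.ndarray, kappa: float = 1.0, lam: float = 1.0,
                 grid_size: int = 401, basis: SpectralBasis | None = None) -> HBPosterior:
    """Posterior of c under the truncated inverse-gamma hyperprior.

    ``log density(c) = log pi(c) - (1/2) * likelihood criterion(c) + const``
    on a log-spaced grid over ``I_n``; the normalising constant comes from
    trapezoid integration in c.
    """
    if not (kappa > 0 and lam > 0):
        raise ValueError("kappa and lambda must be positive")
    Y = np.asarray(Y, dtype=float)
    n = Y.shape[0]
    interval = scale_interval(n)
    if basis is None:
        basis = eigen_system(n)
    y2 = to_coefficients(Y, basis) ** 2
    grid = interval.log_grid(max(int(grid_size), 2))
    crit = _criterion_terms(grid, basis.eigenvalues, y2, "likelihood")
    log_dens = (-1.0 - kappa) * np.log(grid) - lam / grid - 0.5 * crit
    log_dens -= log_dens.max()
    dens = np.exp(log_dens)
    total = np.trapezoid(dens, grid)
    dens /= total
    log_dens -= np.log(total)
    # cumulative trapezoid for the quantile function
    seg = 0.5 * (dens[1:] + dens[:-1]) * np.diff(grid)
    cdf = np.concatenate(([0.0], np.cumsum(seg)))
    cdf /= cdf[-1]
    return HBPosterior(kappa=float(kappa), lam=float(lam), interval=interval,
                       grid=grid, log_density=log_dens, density=dens, cdf=cdf)


def quantile_pair(hb: HBPosterior, eta: float) -> tuple[float, float]:
    """Symmetric hyperposterior quantiles ``(1-eta)/2`` and ``(1+eta)/2``."""
    if not 0.0 < eta < 1.0:
        raise ValueError(f"eta must be in (0, 1), got {eta}")
    return hb.quantile((1.0 - eta) / 2.0), hb.quantile((1.0 + eta) / 2.0)


@dataclass(frozen=True)
class DFunctions:
    """Deterministic bias proxy D1 (decreasing) and variance proxy D2
    (increasing) for one empirical-Bayes method."""

    method: str
    f_coefficients: np.ndarray
    eigenvalues: np.ndarray
    interval: ScaleInterval

    def d1(self, c) -> np.ndarray | float:
        cl = np.multiply.outer(np.asarray(c, dtype=float), self.eigenvalues)
        p = 1 if self.method == "likelihood" else 2
        out = (self.f_coefficients**2 / (1.0 + cl) ** p).sum(axis=-1)
        return out if out.ndim else float(out)

    def d2(self, c) -> np.ndarray | float:
        cl = np.multiply.outer(np.asarray(c, dtype=float), self.eigenvalues)
        if self.method == "likelihood":
            out = (np.log1p(cl) - cl / (1.0 + cl)).sum(axis=-1)
        else:
            out = ((cl / (1.0 + cl)) ** 2).sum(axis=-1)
        return out if out.ndim else float(out)


def d_functions(f_coefficients: np.ndarray, method: str = "likelihood",
                basis: SpectralBasis | None = None) -> DFunctions:
    method = _canon_method(method)
    f_coefficients = np.asarray(f_coefficients, dtype=float)
    n = f_coefficients.shape[0]
    if basis is None:
        basis = eigen_system(n)
    return DFunctions(method=method, f_coefficients=f_coefficients,
                      eigenvalues=basis.eigenvalues, interval=scale_interval(n))


def equalizer(d: DFunctions, rel_tol: float = 1e-6) -> tuple[float, bool]:
    """The scale at which D1 crosses D2, by bisection in log c over ``I_n``.

    Returns ``(c_tilde, boundary)``; ``boundary`` is set when the crossing
    lies outside ``I_n`` and the nearer endpoint is returned instead.
    """
    if not np.any(d.f_coefficients):
        raise ValueError("equaliser undefined for all-zero coefficients")
    gap = lambda logc: d.d1(np.exp(logc)) - d.d2(np.exp(logc))
    lo, hi = np.log(d.interval.lower), np.log(d.interval.upper)
    g_lo, g_hi = gap(lo), gap(hi)
    if g_lo <= 0:  # D1 already below D2 at the left end
        return d.interval.lower, True
    if g_hi >= 0:
        return d.interval.upper, True
    root = brentq(gap, lo, hi, xtol=rel_tol / 2)
    return float(np.exp(root)), False


@dataclass(frozen=True)
class SmoothnessDiagnostics:
    """Verdicts of the regularity conditions behind the coverage guarantees."""

    beta: float
    M: float
    epsilon: float
    rho: float
    tail_L: float
    self_similar_continuous: bool
    self_similar_discrete: bool
    polished_tail: bool
    self_similar_continuous_mask: np.ndarray
    self_similar_discrete_mask: np.ndarray
    polished_tail_mask: np.ndarray
    m_values: np.ndarray
    good_bias_exponent: float


def _block_sum(sq: np.ndarray, m: np.ndarray, upper: np.ndarray) -> np.ndarray:
    """sum of sq[j-1] for j in [m, upper], vectorised over blocks."""
    csum = np.concatenate(([0.0], np.cumsum(sq)))
    upper = np.clip(upper, 0, sq.size)
    lower = np.clip(m - 1, 0, sq.size)
    return csum[upper] - csum[lower]


def smoothness_checks(coefficients: np.ndarray, beta: float, M: float,
                      epsilon: float, rho: float, L: float,
                      discrete_coefficients: np.ndarray | None = None,
                      m_values: np.ndarray | None = None,
                      n: int | None = None) -> SmoothnessDiagnostics:
    """Self-similarity, discrete self-similarity and polished-tail checks.

    ``coefficients`` is a (finite stretch of the) continuous Fourier sequence
    ``f_j``; ``discrete_coefficients``, if given, are the grid coefficients
    ``f_{j,n}`` used for the discrete variant and the polished tail.  The
    continuous condition of order beta requires ``sup_j j^{1/2+beta}|f_j| <= M``
    and block energy ``sum_{j=m}^{rho m} f_j^2 >= eps M^2 / m^{2 beta}``; the
    polished tail requires the full tail energy to be at most L times the
    energy of the leading block ``[m, rho m ∧ n]``.
    """
    if rho <= 1:
        raise ValueError(f"rho must exceed 1, got {rho}")
    if min(M, epsilon, L) <= 0 or beta <= 0:
        raise ValueError("beta, M, epsilon and L must be positive")
    f = np.asarray(coefficients, dtype=float)
    fd = None if discrete_coefficients is None else np.asarray(discrete_coefficients, dtype=float)
    nd = fd.size if fd is not None else (n or f.size)
    if m_values is None:
        m_values = np.arange(2, max(int(nd / rho), 3))
    m_values = np.asarray(m_values, dtype=int)

    j = np.arange(1, f.size + 1)
    sup_ok = np.all(j ** (0.5 + beta) * np.abs(f) <= M * (1 + 1e-12))
    f2 = f**2
    rho_m = np.floor(rho * m_values).astype(int)
    cont_block = _block_sum(f2, m_values, rho_m)
    cont_mask = cont_block >= epsilon * M**2 / m_values.astype(float) ** (2 * beta)
    cont_ok = bool(sup_ok and cont_mask.all())

    if fd is not None:
        n_plus = nd + 0.5
        jd = np.arange(1, nd + 1)
        sup_d_ok = np.all(jd ** (0.5 + beta) * np.abs(fd) / np.sqrt(n_plus) <= M * (1 + 1e-12))
        fd2 = fd**2
        disc_block = _block_sum(fd2, m_values, np.minimum(rho_m, nd)) / n_plus
        disc_mask = disc_block >= epsilon * M**2 / m_values.astype(float) ** (2 * beta)
        disc_ok = bool(sup_d_ok and disc_mask.all())
        tail = _block_sum(fd2, m_values, np.full_like(m_values, nd))
        lead = _block_sum(fd2, m_values, np.minimum(rho_m, nd))
        tail_mask = tail <= L * lead + 1e-15
        tail_ok = bool(tail_mask.all())
    else:
        disc_mask = np.zeros(0, dtype=bool)
        tail_mask = np.zeros(0, dtype=bool)
        disc_ok = False
        tail_ok = False

    a = 2.0 * rho / ((1.0 + rho) * (1.0 + 4.0 * L))
    return SmoothnessDiagnostics(
        beta=beta, M=M, epsilon=epsilon, rho=rho, tail_L=L,
        self_similar_continuous=cont_ok, self_similar_discrete=disc_ok,
        polished_tail=tail_ok,
        self_similar_continuous_mask=cont_mask,
        self_similar_discrete_mask=disc_mask,
        polished_tail_mask=tail_mask,
        m_values=m_values, good_bias_exponent=a,
    )


def bias_dominance(f_coefficients: np.ndarray, c: float, L0: float,
                   domain: tuple[float, float] = (0.1, 0.9),
                   basis: SpectralBasis | None = None) -> tuple[bool, float]:
    """Check that the squared bias stays below the posterior-spread scale.

    Compares ``max_{j in J_n} mu_n(x_j, c)^2`` (via the spectral bias formula)
    with ``L0 * log(c n) * sqrt(c/n)``.  Returns ``(pass, ratio)``.
    """
    from .posterior import discrete_bias

    if not (c > 0 and L0 > 0):
        raise ValueError("c and L0 must be positive")
    f_coefficients = np.asarray(f_coefficients, dtype=float)
    if basis is None:
        basis = eigen_system(f_coefficients.shape[0])
    n = basis.n
    bias = discrete_bias(f_coefficients, c, basis)
    pts = basis.grid.points
    mask = (pts >= domain[0]) & (pts <= domain[1])
    lhs = float(np.max(bias[mask] ** 2)) if mask.any() else 0.0
    rhs = L0 * np.log(c * n) * np.sqrt(c / n)
    ratio = lhs / rhs if rhs > 0 else np.inf
    return bool(lhs < rhs), float(ratio)
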