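"""Simultaneous credible bands around the posterior mean.

A band is a uniform-norm ball ``{f : ||f - fhat_{n,c}|| < L w}`` over a
domain ``J_n = [1/l_n, 1 - 1/l_n]`` that stays away from the endpoints,
where ``w`` is the eta-quantile of the sup-norm of the centered posterior.
The centered posterior law does not depend on the data, so ``w`` is a pure
Monte-Carlo functional of ``(n, c, eta, domain)``: draw centered posterior
vectors at the design points (through the banded Cholesky of the tridiagonal
posterior precision — the same Gaussian law as spectral sampling with
per-coefficient standard deviation ``sqrt(c lambda_j/(1+c lambda_j))``, at
O(n) per draw), optionally add Brownian-bridge fill-in for the continuous
version, and take the empirical quantile of the max absolute value.

The discrete band restricts the sup to the design points in ``J_n``; the
continuous band approximates the sup on a refined grid (``subgrid_factor``
interior points per design interval), which can only underestimate the
continuum sup — refining the grid can only increase a maximum.  Union
bands take the pointwise envelope over a range of scales, as used with the
hierarchical-Bayes hyperposterior interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import make_design
from .posterior import posterior_state, sample_centered_design

__all__ = [
    "BandDomain",
    "BandQuantile",
    "CredibleBand",
    "band_domain",
    "band_quantile",
    "build_band",
    "union_band",
    "covers",
]

_DRAW_CHUNK = 512


@dataclass(frozen=True)
class BandDomain:
    """The interval ``J_n`` on which the sup-norm is taken."""

    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not 0.0 < self.lower < self.upper < 1.0:
            raise ValueError(f"need 0 < lower < upper < 1, got [{self.lower}, {self.upper}]")

    def design_indices(self, n: int) -> np.ndarray:
        """0-based indices of design points inside ``J_n``."""
        pts = make_design(n).points
        idx = np.nonzero((pts >= self.lower) & (pts <= self.upper))[0]
        if idx.size == 0:
            raise ValueError(f"no design points in [{self.lower}, {self.upper}] for n={n}")
        return idx

    @staticmethod
    def from_l(l_n: float) -> "BandDomain":
        if l_n <= 2:
            raise ValueError(f"l_n must exceed 2, got {l_n}")
        return BandDomain(1.0 / l_n, 1.0 - 1.0 / l_n)


def band_domain(lower: float = 0.1, upper: float = 0.9) -> BandDomain:
    return BandDomain(lower, upper)


@dataclass(frozen=True)
class BandQuantile:
    """Monte-Carlo sup-norm quantile ``w`` of the centered posterior."""

    value: float
    band_type: str
    n: int
    c: float
    eta: float
    n_draws: int
    seed: int | None
    domain: BandDomain
    subgrid_factor: int


def _centered_sups(n: int, c: float, band_type: str, domain: BandDomain,
                   n_draws: int, subgrid_factor: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Sup over the domain of |centered posterior draw|, for each draw."""
    grid = make_design(n)
    idx = domain.design_indices(n)
    pts = grid.points
    h = 1.0 / grid.n_plus
    m = subgrid_factor
    sups = np.empty(n_draws)
    # segments whose interiors intersect the domain (left knots 0..x_{n-1})
    knots = np.concatenate(([0.0], pts))
    if band_type == "continuous":
        frac = np.arange(1, m + 1) / (m + 1)
        seg_pts = knots[:n, None] + h * frac[None, :]
        seg_mask = (seg_pts >= domain.lower) & (seg_pts <= domain.upper)
        active = np.nonzero(seg_mask.any(axis=1))[0]
    for lo in range(0, n_draws, _DRAW_CHUNK):
        hi = min(lo + _DRAW_CHUNK, n_draws)
        k = hi - lo
        vals = sample_centered_design(n, c, k, rng)
        sup = np.abs(vals[:, idx]).max(axis=1)
        if band_type == "continuous":
            # Brownian-bridge fill-in between design values (knot at 0 is pinned)
            steps = rng.standard_normal((k, n, m + 1))
            w = np.cumsum(steps * np.sqrt(c * h / (m + 1)), axis=2)
            bridge = (w - (np.arange(1, m + 2) / (m + 1))[None, None, :] * w[:, :, -1:])[:, :, :m]
            left = np.concatenate((np.zeros((k, 1)), vals[:, :-1]), axis=1)
            lin = left[:, :, None] * (1 - frac[None, None, :]) + vals[:, :, None] * frac[None, None, :]
            fill = np.abs(lin + bridge)
            fill = np.where(seg_mask[None, :, :], fill, 0.0)
            sup = np.maximum(sup, fill[:, active, :].max(axis=(1, 2)))
        sups[lo:hi] = sup
    return sups


def band_quantile(n: int, c: float, eta: float = 0.95, band_type: str = "discrete",
                  domain: BandDomain | None = None, n_draws: int = 2000,
                  subgrid_factor: int = 8, seed: int | None = None) -> BandQuantile:
    """The quantile ``w`` with ``P(sup |f - fhat| < w | Y, c) = eta``.

    Data-free: depends only on ``(n, c, eta, domain)`` plus Monte-Carlo
    settings.  Uses the order statistic at ``ceil(eta * n_draws)``
    (conservative empirical-quantile convention).
    """
    if not 0.0 < eta < 1.0:
        raise ValueError(f"eta must be in (0, 1), got {eta}")
    if n_draws < 100:
        raise ValueError(f"n_draws must be at least 100, got {n_draws}")
    if band_type not in ("discrete", "continuous"):
        raise ValueError(f"band_type must be 'discrete' or 'continuous', got {band_type!r}")
    if domain is None:
        domain = BandDomain(0.1, 0.9)
    rng = np.random.default_rng(seed)
    sups = _centered_sups(n, c, band_type, domain, n_draws, subgrid_factor, rng)
    k = int(np.ceil(eta * n_draws))
    value = float(np.sort(sups)[k - 1])
    return BandQuantile(value=value, band_type=band_type, n=n, c=float(c), eta=eta,
                        n_draws=n_draws, seed=seed, domain=domain,
                        subgrid_factor=subgrid_factor)


@dataclass(frozen=True)
class CredibleBand:
    """A band: center ± L*w on its evaluation grid (or a union envelope)."""

    band_type: str  # 'discrete', 'continuous', 'union'
    xs: np.ndarray
    center: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    L: float
    w: float | None
    c: float | tuple[float, float]
    eta: float
    domain: BandDomain

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"x": self.xs, "mean": self.center,
                             "lower": self.lower, "upper": self.upper})

    def metadata(self) -> dict:
        return {"band_type": self.band_type, "n_points": int(self.xs.size),
                "c": self.c, "eta": self.eta, "L": self.L, "w": self.w,
                "domain": [self.domain.lower, self.domain.upper]}


def _band_grid(n: int, band_type: str, domain: BandDomain, subgrid_factor: int) -> np.ndarray:
    pts = make_design(n).points
    if band_type == "discrete":
        return pts[(pts >= domain.lower) & (pts <= domain.upper)]
    m = subgrid_factor
    knots = np.concatenate(([0.0], pts))
    refined = (knots[:, None] + np.diff(np.concatenate((knots, [pts[-1] + 1 / (n + 0.5)])))[:, None]
               * (np.arange(m + 1) / (m + 1))[None, :]).ravel()
    refined = np.unique(np.concatenate((refined, pts)))
    return refined[(refined >= domain.lower) & (refined <= domain.upper)]


def build_band(Y: np.ndarray, c: float, L: float = 1.0, eta: float = 0.95,
               band_type: str = "discrete", domain: BandDomain | None = None,
               n_draws: int = 2000, subgrid_factor: int = 8,
               seed: int | None = None, w: float | None = None) -> CredibleBand:
    """Assemble the band: posterior-mean center with half-width ``L * w``.

    ``w`` may be supplied to reuse a precomputed quantile (it is data-free).
    """
    Y = np.asarray(Y, dtype=float)
    n = Y.shape[0]
    if domain is None:
        domain = BandDomain(0.1, 0.9)
    if L < 0:
        raise ValueError(f"L must be nonnegative, got {L}")
    if w is None:
        w = band_quantile(n, c, eta, band_type, domain, n_draws, subgrid_factor, seed).value
    state = posterior_state(Y, c)
    xs = _band_grid(n, band_type, domain, subgrid_factor)
    center = state.mean(xs)
    half = L * w
    return CredibleBand(band_type=band_type, xs=xs, center=center,
                        lower=center - half, upper=center + half, L=L, w=w,
                        c=float(c), eta=eta, domain=domain)


def union_band(Y: np.ndarray, c_interval: tuple[float, float], L: float = 1.0,
               eta: float = 0.95, band_type: str = "discrete", n_c: int = 64,
               domain: BandDomain | None = None, n_draws: int = 2000,
               subgrid_factor: int = 8, seed: int | None = None) -> CredibleBand:
    """Pointwise envelope of bands over log-spaced scales in ``c_interval``.

    This realises the hierarchical-Bayes credible set: the union of the
    fixed-c bands over the hyperposterior quantile interval.
    """
    c1, c2 = c_interval
    if not 0 < c1 <= c2:
        raise ValueError(f"need 0 < c1 <= c2, got ({c1}, {c2})")
    if domain is None:
        domain = BandDomain(0.1, 0.9)
    cs = np.exp(np.linspace(np.log(c1), np.log(c2), 1 if c1 == c2 else n_c))
    lower = upper = None
    seeds = np.random.SeedSequence(seed).spawn(len(cs))
    for child, c in zip(seeds, cs):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        band = build_band(Y, float(c), L, eta, band_type, domain, n_draws,
                          subgrid_factor, seed=sub_seed)
        if lower is None:
            xs, lower, upper = band.xs, band.lower, band.upper
            center = band.center
        else:
            lower = np.minimum(lower, band.lower)
            upper = np.maximum(upper, band.upper)
    band_kind = "union" if len(cs) > 1 else band_type
    return CredibleBand(band_type=band_kind, xs=xs, center=center, lower=lower,
                        upper=upper, L=L, w=None, c=(float(c1), float(c2)),
                        eta=eta, domain=domain)


def covers(band: CredibleBand, f) -> bool:
    """Does the band contain the true function on its evaluation grid?

    Discrete bands check exactly at the design points in ``J_n``; continuous
    bands check on the refined grid (a documented approximation of the sup);
    union bands require the truth inside the envelope everywhere.
    """
    f_vals = np.asarray(f(band.xs), dtype=float)
    if band.band_type == "union":
        return bool(np.all((f_vals > band.lower) & (f_vals < band.upper)))
    half = band.L * band.w
    if half == 0:
        return False
    return bool(np.max(np.abs(f_vals - band.center)) < half)
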