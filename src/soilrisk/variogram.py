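"""Empirical variograms and weighted-least-squares variogram fitting."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.spatial.distance import pdist

from .fields import matern_correlation

logger = logging.getLogger(__name__)

FAMILIES = ("matern_nu1", "exponential", "spherical")


@dataclass
class VariogramModel:
    """Isotropic semivariogram gamma(h) = nugget + partial_sill * (1 - corr(h)).

    ``range_km`` is the practical range: the distance at which correlation
    has decayed to ~0.05 (exponential: 3x the scale parameter; spherical:
    the exact support; matern_nu1: sqrt(8)/kappa convention).
    """

    family: str
    nugget: float
    partial_sill: float
    range_km: float
    flags: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown variogram family {self.family!r}")
        if self.nugget < 0 or self.partial_sill <= 0 or self.range_km <= 0:
            raise ValueError("require nugget >= 0, partial_sill > 0, range_km > 0")

    @property
    def sill(self) -> float:
        return self.nugget + self.partial_sill

    def correlation(self, h) -> np.ndarray:
        h = np.asarray(h, dtype=float)
        if self.family == "matern_nu1":
            return matern_correlation(h, self.range_km)
        if self.family == "exponential":
            return np.exp(-3.0 * h / self.range_km)
        # spherical
        t = np.clip(h / self.range_km, 0.0, 1.0)
        return 1.0 - (1.5 * t - 0.5 * t**3)

    def semivariance(self, h) -> np.ndarray:
        h = np.asarray(h, dtype=float)
        g = self.nugget + self.partial_sill * (1.0 - self.correlation(h))
        return np.where(h <= 0, 0.0, g)

    def covariance(self, h) -> np.ndarray:
        """Covariance form used by the kriging system; the nugget appears
        only at exactly zero lag."""
        h = np.asarray(h, dtype=float)
        c = self.partial_sill * self.correlation(h)
        return np.where(h <= 0, self.partial_sill + self.nugget, c)

    def cross_covariance(self, h) -> np.ndarray:
        """Covariance between the noise-free field and an observation:
        the continuous part only, so kriging at a sampled site reproduces
        the observation exactly iff the nugget is zero."""
        return self.partial_sill * self.correlation(np.asarray(h, dtype=float))

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "nugget": self.nugget,
            "partial_sill": self.partial_sill,
            "range_km": self.range_km,
            "flags": list(self.flags),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VariogramModel":
        return cls(d["family"], d["nugget"], d["partial_sill"], d["range_km"], list(d.get("flags", [])))


def empirical_variogram(
    xy: np.ndarray, z: np.ndarray, n_bins: int = 15, max_lag: float | None = None
) -> pd.DataFrame:
    """Matheron estimator of the semivariogram on equal-width lag bins.

    gamma_hat(h) = (1 / 2 N_h) * sum over pairs in bin of (z_a - z_b)^2.
    Bins with no pairs are dropped (and logged).  Returns columns
    ``lag`` (bin midpoint), ``gamma``, ``n_pairs``.
    """
    xy = np.atleast_2d(np.asarray(xy, dtype=float))
    z = np.asarray(z, dtype=float)
    if xy.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    d = pdist(xy)
    if max_lag is None:
        max_lag = d.max() / 2.0
    dz2 = pdist(z[:, None], metric="sqeuclidean")
    keep = d <= max_lag
    if not keep.any():
        raise ValueError("no sample pairs within max_lag")
    edges = np.linspace(0.0, max_lag, n_bins + 1)
    which = np.clip(np.digitize(d[keep], edges) - 1, 0, n_bins - 1)
    counts = np.bincount(which, minlength=n_bins)
    sums = np.bincount(which, weights=dz2[keep], minlength=n_bins)
    nonempty = counts > 0
    if (~nonempty).any():
        logger.info("dropping %d empty lag bins", int((~nonempty).sum()))
    mid = 0.5 * (edges[:-1] + edges[1:])
    return pd.DataFrame(
        {
            "lag": mid[nonempty],
            "gamma": sums[nonempty] / (2.0 * counts[nonempty]),
            "n_pairs": counts[nonempty],
        }
    )


def fit_variogram(
    empirical: pd.DataFrame, family: str = "matern_nu1"
) -> VariogramModel:
    """Fit nugget, partial sill and range by weighted least squares.

    Weights are the per-bin pair counts; bounded trust-region optimisation
    from a small deterministic grid of starting points.  If the optimum
    pins against a parameter bound the result is flagged (``at_bound``).
    """
    if len(empirical) < 3:
        raise ValueError("need at least 3 non-empty variogram bins")
    lag = empirical["lag"].to_numpy(float)
    gam = empirical["gamma"].to_numpy(float)
    wts = np.sqrt(empirical["n_pairs"].to_numpy(float))

    gmax = max(gam.max(), 1e-12)
    lmax = lag.max()
    lo = np.array([0.0, 1e-8 * gmax, 1e-3 * lmax])
    hi = np.array([2.0 * gmax, 4.0 * gmax, 20.0 * lmax])

    def resid(p):
        m = VariogramModel(family, p[0], max(p[1], lo[1]), max(p[2], lo[2]))
        return wts * (m.semivariance(lag) - gam)

    best = None
    for r0 in (0.25, 0.5, 1.0):  # deterministic multistart over range scale
        p0 = np.array([0.1 * gmax, 0.9 * gmax, r0 * lmax])
        sol = least_squares(resid, p0, bounds=(lo, hi), xtol=1e-12, ftol=1e-12)
        if best is None or sol.cost < best.cost:
            best = sol
    p = best.x
    flags = []
    rel_gap = np.minimum(np.abs(p - lo), np.abs(hi - p)) / np.maximum(hi - lo, 1e-300)
    if (rel_gap < 1e-6).any():
        flags.append("at_bound")
        logger.warning("variogram fit pinned at parameter bound: %s", p)
    if p[2] < lag.min():
        # pure-nugget degeneracy: the range collapsed below the data's lag
        # resolution, so the spatial structure is unidentified
        flags.append("at_bound")
        logger.warning("fitted range %.3g below smallest lag %.3g", p[2], lag.min())
    return VariogramModel(family, float(p[0]), float(p[1]), float(p[2]), flags)
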