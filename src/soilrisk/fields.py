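"""Stationary Matérn Gaussian random fields on the plane.

The exposure surface is modelled as a zero-mean stationary Gaussian field
with Matérn covariance, smoothness fixed at ``nu = 1`` (the two-dimensional
SPDE default).  Distances are Euclidean on projected planar coordinates in
kilometres.  This module provides the closed-form correlation function
(used as an independent oracle elsewhere) and an exact simulator based on
dense Cholesky factorisation, suitable for up to a few thousand locations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from scipy.special import gamma as gamma_fn
from scipy.special import kv


@dataclass(frozen=True)
class MaternFieldParams:
    """Parameters of a Matérn field with smoothness nu = 1.

    Attributes
    ----------
    practical_range : float
        Distance (km) at which correlation drops to roughly 0.13, i.e.
        ``rho = sqrt(8 * nu) / kappa``.
    marginal_sd : float
        Stationary standard deviation of the field.
    nugget : float
        Small variance added on the diagonal for numerical stability
        (and to model micro-scale variation if desired).
    """

    practical_range: float
    marginal_sd: float
    nugget: float = 0.0

    def __post_init__(self) -> None:
        if self.practical_range <= 0:
            raise ValueError("practical_range must be > 0")
        if self.marginal_sd <= 0:
            raise ValueError("marginal_sd must be > 0")
        if self.nugget < 0:
            raise ValueError("nugget must be >= 0")

    @property
    def kappa(self) -> float:
        """Inverse-range parameter, kappa = sqrt(8 nu) / rho with nu = 1."""
        return np.sqrt(8.0) / self.practical_range


def matern_correlation(d, practical_range: float, nu: float = 1.0):
    """Matérn correlation at distance ``d``.

    r(d) = 2^(1-nu)/Gamma(nu) * (kappa d)^nu * K_nu(kappa d),
    with kappa = sqrt(8 nu) / practical_range; r(0) = 1.
    """
    d = np.asarray(d, dtype=float)
    kappa = np.sqrt(8.0 * nu) / practical_range
    h = kappa * np.maximum(d, 1e-300)
    r = (2.0 ** (1.0 - nu) / gamma_fn(nu)) * h**nu * kv(nu, h)
    return np.where(d <= 0, 1.0, r)


def matern_covariance_matrix(locations: np.ndarray, params: MaternFieldParams) -> np.ndarray:
    """Dense covariance matrix of the field at ``locations`` (n x 2 array)."""
    locations = np.atleast_2d(np.asarray(locations, dtype=float))
    d = cdist(locations, locations)
    cov = params.marginal_sd**2 * matern_correlation(d, params.practical_range)
    if params.nugget > 0:
        cov[np.diag_indices_from(cov)] += params.nugget
    return cov


def simulate_matern_field(
    locations,
    params: MaternFieldParams,
    seed: int | np.random.Generator,
    n_draws: int = 1,
    jitter: float = 1e-10,
) -> np.ndarray:
    """Draw exact realisations of the field at the given locations.

    Uses dense Cholesky factorisation of the covariance, so the draw is
    exact (up to the stabilising ``jitter`` on the diagonal).  Returns an
    array of shape ``(n_locations,)`` for a single draw, else
    ``(n_draws, n_locations)``.

    Raises
    ------
    ValueError
        If the covariance cannot be factorised, typically caused by
        duplicate locations with zero nugget; the offending pair is named.
    """
    locations = np.atleast_2d(np.asarray(locations, dtype=float))
    if locations.shape[0] < 1:
        raise ValueError("at least one location is required")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    cov = matern_covariance_matrix(locations, params)
    cov[np.diag_indices_from(cov)] += jitter
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        dup = _find_duplicate_pair(locations)
        if dup is not None:
            raise ValueError(
                f"covariance not positive definite: locations {dup[0]} and {dup[1]} "
                "coincide and the nugget is zero; add a nugget or jitter"
            ) from None
        raise ValueError("covariance not positive definite") from None

    z = rng.standard_normal((n_draws, locations.shape[0]))
    draws = z @ chol.T
    return draws[0] if n_draws == 1 else draws


def _find_duplicate_pair(locations: np.ndarray):
    d = cdist(locations, locations)
    np.fill_diagonal(d, np.inf)
    i, j = np.unravel_index(np.argmin(d), d.shape)
    if d[i, j] < 1e-12:
        return (int(min(i, j)), int(max(i, j)))
    return None
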