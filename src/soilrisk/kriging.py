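"""Ordinary kriging of log soil concentrations onto municipal centroids.

Approach A of the pipeline interpolates point-sampled log concentrations
to each town centroid with ordinary kriging — the best linear unbiased
predictor whose weights sum to one — and keeps the kriging variance for
diagnostics (the plug-in ecological regression ignores it; the joint model
does not).

The estimator follows the scikit-learn protocol: ``fit(X, y)`` stores the
samples and (if needed) fits a variogram; ``predict(X)`` solves one
ordinary-kriging system per target using the ``n_neighbors`` nearest
samples (set ``n_neighbors=None`` for the global dense system).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, RegressorMixin

from .variogram import VariogramModel, empirical_variogram, fit_variogram


class OrdinaryKriging(BaseEstimator, RegressorMixin):
    """Ordinary kriging with a fitted or user-supplied variogram.

    Parameters
    ----------
    variogram : VariogramModel or None
        If None, a variogram of family ``family`` is fitted to the training
        samples by weighted least squares at fit time.
    family : str
        Variogram family used when auto-fitting.
    n_neighbors : int or None
        Size of the kriging neighbourhood (nearest samples by Euclidean
        distance, ties broken by sample order).  None solves the global
        system — exact but cubic in the sample count.
    n_bins, max_lag : empirical-variogram settings for auto-fitting.

    Attributes
    ----------
    X_ : (n, 2) training locations (km); y_ : training values (log mg/kg).
    variogram_ : the variogram model used for prediction.
    """

    def __init__(
        self,
        variogram: VariogramModel | None = None,
        family: str = "matern_nu1",
        n_neighbors: int | None = 64,
        n_bins: int = 15,
        max_lag: float | None = None,
    ):
        self.variogram = variogram
        self.family = family
        self.n_neighbors = n_neighbors
        self.n_bins = n_bins
        self.max_lag = max_lag

    def fit(self, X, y):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float)
        if X.shape[0] < 2:
            raise ValueError("ordinary kriging needs at least 2 samples")
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y lengths differ")
        self.X_ = X
        self.y_ = y
        if self.variogram is not None:
            self.variogram_ = self.variogram
        else:
            emp = empirical_variogram(X, y, n_bins=self.n_bins, max_lag=self.max_lag)
            self.variogram_ = fit_variogram(emp, family=self.family)
        self._tree = cKDTree(X)
        return self

    def predict(self, X, return_std: bool = False, return_weights: bool = False):
        """Kriging prediction (and optionally standard error and weights).

        Returns predictions, plus the kriging standard deviation when
        ``return_std`` and a list of (neighbor_indices, weights) when
        ``return_weights``.
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        n_samp = self.X_.shape[0]
        k = n_samp if self.n_neighbors is None else min(self.n_neighbors, n_samp)
        pred = np.empty(X.shape[0])
        var = np.empty(X.shape[0])
        weights: list = []
        for t, x0 in enumerate(X):
            if k == n_samp:
                idx = np.arange(n_samp)
            else:
                # cKDTree breaks distance ties by index order (deterministic)
                _, idx = self._tree.query(x0, k=k)
                idx = np.atleast_1d(idx)
            p, v, w = self._solve_one(x0, idx)
            pred[t], var[t] = p, v
            if return_weights:
                weights.append((idx, w))
        out = [pred]
        if return_std:
            out.append(np.sqrt(np.maximum(var, 0.0)))
        if return_weights:
            out.append(weights)
        return tuple(out) if len(out) > 1 else pred

    def predict_variance(self, X) -> np.ndarray:
        """Kriging variance (mean squared prediction error) at targets."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        _, sd = self.predict(X, return_std=True)
        return sd**2

    def _solve_one(self, x0: np.ndarray, idx: np.ndarray):
        """Solve the ordinary-kriging system in covariance form.

        [ C  1 ] [w ]   [ c0 ]
        [ 1' 0 ] [mu] = [ 1  ]

        prediction = w'z, variance = C(0) - w'c0 - mu.
        """
        vg = self.variogram_
        pts = self.X_[idx]
        d = cdist(pts, pts)
        C = vg.covariance(d)
        c0 = vg.cross_covariance(cdist(pts, x0[None, :]).ravel())
        n = len(idx)
        A = np.empty((n + 1, n + 1))
        A[:n, :n] = C
        A[:n, n] = 1.0
        A[n, :n] = 1.0
        A[n, n] = 0.0
        b = np.append(c0, 1.0)
        try:
            sol = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            dup = _duplicate_pair(pts)
            msg = "singular kriging system"
            if dup is not None:
                msg += (
                    f": sample locations {idx[dup[0]]} and {idx[dup[1]]} coincide "
                    "and the nugget is zero"
                )
            raise ValueError(msg) from None
        w, mu = sol[:n], sol[n]
        pred = float(w @ self.y_[idx])
        var = float(vg.sill - w @ c0 - mu)
        return pred, var, w


def _duplicate_pair(pts: np.ndarray):
    d = cdist(pts, pts)
    np.fill_diagonal(d, np.inf)
    i, j = np.unravel_index(np.argmin(d), d.shape)
    if d[i, j] < 1e-12:
        return int(min(i, j)), int(max(i, j))
    return None


def ordinary_kriging(
    samples: pd.DataFrame,
    model: VariogramModel,
    targets: np.ndarray,
    n_neighbors: int | None = 64,
    value_col: str = "log_concentration",
) -> pd.DataFrame:
    """Functional wrapper: krige sample values onto target coordinates.

    Returns a table with ``x_km, y_km, pred_log, krig_var``.
    """
    ok = OrdinaryKriging(variogram=model, n_neighbors=n_neighbors)
    ok.fit(samples[["x_km", "y_km"]].to_numpy(), samples[value_col].to_numpy())
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    pred, sd = ok.predict(targets, return_std=True)
    return pd.DataFrame(
        {"x_km": targets[:, 0], "y_km": targets[:, 1], "pred_log": pred, "krig_var": sd**2}
    )


def attach_exposure(areas: pd.DataFrame, predictions: pd.DataFrame) -> pd.DataFrame:
    """Join kriged exposures onto the area table by ``area_id``.

    ``predictions`` must carry ``area_id, pred_log, krig_var``, one row per
    area; unknown or missing ids raise.
    """
    if "area_id" not in predictions:
        raise ValueError("predictions must carry an area_id column")
    unknown = set(predictions["area_id"]) - set(areas["area_id"])
    if unknown:
        raise ValueError(f"predictions for unknown area ids: {sorted(unknown)[:5]}")
    missing = set(areas["area_id"]) - set(predictions["area_id"])
    if missing:
        raise ValueError(f"missing predictions for areas: {sorted(missing)[:5]}")
    pred = predictions.set_index("area_id")
    areas = areas.copy()
    areas["expos"] = pred.loc[areas["area_id"], "pred_log"].to_numpy()
    areas["krig_var"] = pred.loc[areas["area_id"], "krig_var"].to_numpy()
    return areas
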