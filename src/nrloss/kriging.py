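"""County survey to grid: variogram fitting and ordinary kriging.

County-mean N application rates are interpolated to cell centers by
ordinary kriging: the best linear unbiased predictor whose weights solve
the semivariance system with a unit-sum (unbiasedness) constraint. The
variogram is estimated from the county records with the Matheron
moment estimator and fitted by weighted least squares; the default
family is exponential.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.spatial import cKDTree
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .pathways import REGIONS
from .raster import RasterStack

_FAMILIES = ("spherical", "exponential", "gaussian")


@dataclass(frozen=True)
class VariogramModel:
    """Isotropic variogram: ``gamma(h) = nugget + psill * g(h / range)``.

    For the exponential and gaussian families ``range`` is the scale
    parameter (practical range about 3x / 1.7x larger); for the
    spherical family the sill is reached exactly at ``range``.
    """

    family: str
    nugget: float
    psill: float
    range: float

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; pick from {_FAMILIES}")
        if self.nugget < 0 or self.psill < 0:
            raise ValueError("nugget and partial sill must be >= 0")
        if self.range <= 0:
            raise ValueError("range must be positive")

    def __call__(self, h: np.ndarray) -> np.ndarray:
        h = np.asarray(h, float)
        r = h / self.range
        if self.family == "exponential":
            g = 1.0 - np.exp(-r)
        elif self.family == "gaussian":
            g = 1.0 - np.exp(-(r**2))
        else:  # spherical
            g = np.where(r < 1.0, 1.5 * r - 0.5 * r**3, 1.0)
        out = self.nugget + self.psill * g
        return np.where(h == 0.0, 0.0, out)  # gamma(0) = 0 by definition

    @property
    def sill(self) -> float:
        return self.nugget + self.psill


def county_average(raw: pd.DataFrame) -> pd.DataFrame:
    """Aggregate raw farmer survey rows to county records.

    Expects columns county_id, x, y, n_rate. Returns per-county mean,
    sample sd (n-1 denominator, NaN for single-farmer counties) and
    farmer count; rows with missing rates are dropped with a warning.
    """
    raw = raw.copy()
    missing = raw["n_rate"].isna()
    if missing.any():
        warnings.warn(f"dropping {int(missing.sum())} survey rows with missing rates")
        raw = raw[~missing]
    if (raw["n_rate"] <= 0).any():
        raise ValueError("survey rates must be positive")
    grouped = raw.groupby("county_id")
    out = grouped.agg(
        x=("x", "mean"),
        y=("y", "mean"),
        mean_n_rate=("n_rate", "mean"),
        sd_n_rate=("n_rate", lambda s: s.std(ddof=1)),
        n_farmers=("n_rate", "size"),
    ).reset_index()
    return out


def empirical_variogram(
    points: np.ndarray,
    values: np.ndarray,
    n_lags: int = 15,
    max_dist: float | None = None,
) -> pd.DataFrame:
    """Matheron semivariance estimator in equal-width distance bins."""
    points = np.asarray(points, float)
    values = np.asarray(values, float)
    d = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=-1)
    iu = np.triu_indices(len(points), k=1)
    dist = d[iu]
    if dist.max() == 0:
        raise ValueError("all points are coincident")
    if max_dist is None:
        max_dist = 0.5 * dist.max()
    sq = (values[:, None] - values[None, :])[iu] ** 2
    keep = (dist > 0) & (dist <= max_dist)
    dist, sq = dist[keep], sq[keep]
    edges = np.linspace(0.0, max_dist, n_lags + 1)
    which = np.clip(np.digitize(dist, edges) - 1, 0, n_lags - 1)
    rows = []
    for b in range(n_lags):
        sel = which == b
        if not sel.any():
            continue
        rows.append((dist[sel].mean(), 0.5 * sq[sel].mean(), int(sel.sum())))
    return pd.DataFrame(rows, columns=["lag", "gamma", "n_pairs"])


def fit_variogram(
    records: pd.DataFrame,
    family: str = "exponential",
    n_lags: int = 15,
) -> VariogramModel:
    """Fit a variogram to county records (x, y, mean_n_rate) by
    pair-count-weighted least squares on the empirical semivariogram."""
    if len(records) < 5:
        raise ValueError("need at least 5 counties to fit a variogram")
    pts = records[["x", "y"]].to_numpy(float)
    vals = records["mean_n_rate"].to_numpy(float)
    var = vals.var(ddof=1)
    if var == 0.0:
        warnings.warn("constant rates: degenerate variogram with zero sill")
        span = max(np.ptp(pts[:, 0]) + np.ptp(pts[:, 1]), 1.0)
        return VariogramModel(family, 0.0, 0.0, span / 3.0)
    emp = empirical_variogram(pts, vals, n_lags=n_lags)
    lags, gammas, weights = (emp[c].to_numpy(float) for c in ("lag", "gamma", "n_pairs"))

    def residual(theta):
        nugget, psill, rng_ = theta
        model = VariogramModel(family, max(nugget, 0.0), max(psill, 0.0), max(rng_, 1e-9))
        return np.sqrt(weights) * (model(lags) - gammas)

    x0 = np.array([0.1 * var, var, lags.max() / 3.0])
    fit = least_squares(
        residual, x0,
        bounds=([0.0, 0.0, 1e-6], [np.inf, np.inf, 10.0 * lags.max()]),
    )
    nugget, psill, rng_ = fit.x
    return VariogramModel(family, float(nugget), float(psill), float(rng_))


def kriging_weights(
    points: np.ndarray,
    target: np.ndarray,
    variogram: VariogramModel,
) -> tuple[np.ndarray, float]:
    """Solve the ordinary-kriging system for one target.

    Returns (weights, lagrange multiplier); the weights sum to 1 exactly
    (unbiasedness constraint row of the system).
    """
    n = len(points)
    A = np.empty((n + 1, n + 1))
    d = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=-1)
    A[:n, :n] = variogram(d)
    A[n, :n] = A[:n, n] = 1.0
    A[n, n] = 0.0
    b = np.empty(n + 1)
    b[:n] = variogram(np.linalg.norm(points - target, axis=-1))
    b[n] = 1.0
    sol = np.linalg.solve(A, b)
    return sol[:n], float(sol[n])


class OrdinaryKriging(BaseEstimator):
    """Ordinary-kriging interpolator with a moving neighborhood.

    Parameters
    ----------
    variogram : fitted ``VariogramModel``; if None, fitted from the data
        at ``fit`` time with the given family.
    n_max : number of nearest data points used per target (None for the
        dense solve over all points, used by the oracle tests).
    family : variogram family when self-fitting.
    on_duplicates : 'error' or 'jitter' (1e-9-scale perturbation).
    """

    def __init__(
        self,
        variogram: VariogramModel | None = None,
        n_max: int | None = 16,
        family: str = "exponential",
        on_duplicates: str = "error",
    ):
        self.variogram = variogram
        self.n_max = n_max
        self.family = family
        self.on_duplicates = on_duplicates

    def fit(self, X, y) -> "OrdinaryKriging":
        X = np.asarray(X, float)
        y = np.asarray(y, float).ravel()
        if X.ndim != 2 or X.shape[1] != 2 or len(X) != len(y):
            raise ValueError("X must be (n, 2) coordinates matching y")
        if len(np.unique(X, axis=0)) < len(X):
            if self.on_duplicates == "jitter":
                span = max(np.ptp(X), 1.0)
                X = X + np.random.default_rng(0).normal(0, 1e-9 * span, X.shape)
            else:
                raise ValueError("duplicate data locations make the kriging "
                                 "system singular (set on_duplicates='jitter')")
        self.X_, self.y_ = X, y
        if self.variogram is not None:
            self.variogram_ = self.variogram
        else:
            recs = pd.DataFrame({"x": X[:, 0], "y": X[:, 1], "mean_n_rate": y})
            self.variogram_ = fit_variogram(recs, family=self.family)
        self.tree_ = cKDTree(X)
        return self

    def predict(self, targets, return_variance: bool = False):
        check_is_fitted(self, "X_")
        targets = np.atleast_2d(np.asarray(targets, float))
        n = len(self.X_)
        if n == 1 or self.variogram_.sill == 0.0:
            pred = np.full(len(targets), float(self.y_.mean()))
            var = np.zeros(len(targets))
            return (pred, var) if return_variance else pred
        k = n if self.n_max is None else min(self.n_max, n)
        _, neigh = self.tree_.query(targets, k=k)
        neigh = np.atleast_2d(neigh)
        pred = np.empty(len(targets))
        var = np.empty(len(targets))
        for t, target in enumerate(targets):
            idx = neigh[t]
            w, mu = kriging_weights(self.X_[idx], target, self.variogram_)
            pred[t] = w @ self.y_[idx]
            gamma0 = self.variogram_(np.linalg.norm(self.X_[idx] - target, axis=-1))
            var[t] = max(float(w @ gamma0 + mu), 0.0)
        return (pred, var) if return_variance else pred


def ordinary_kriging(
    records: pd.DataFrame,
    variogram: VariogramModel,
    targets: np.ndarray,
    n_max: int | None = 16,
    return_variance: bool = False,
):
    """Functional wrapper over :class:`OrdinaryKriging`."""
    ok = OrdinaryKriging(variogram=variogram, n_max=n_max)
    ok.fit(records[["x", "y"]].to_numpy(float), records["mean_n_rate"].to_numpy(float))
    return ok.predict(targets, return_variance=return_variance)


def build_grid(
    stack: RasterStack,
    records: pd.DataFrame,
    variogram: VariogramModel | None = None,
    n_max: int | None = 16,
) -> pd.DataFrame:
    """One row per active (masked-in) cell with covariates at cell
    centers, region label and the kriged N application rate.

    Negative kriged rates are floored at 0; the floored-cell count is in
    ``result.attrs['n_floored']``. Raises if layers are misaligned.
    """
    mask_r = stack["mask"]
    misaligned = [name for name, r in stack.layers.items() if not mask_r.same_grid(r)]
    if misaligned:
        raise ValueError(f"rasters not aligned with mask: {misaligned}")
    mask = mask_r.data > 0
    if not mask.any():
        warnings.warn("mask has no active cells; empty grid")
        return pd.DataFrame()
    xs, ys = mask_r.cell_centers()
    rows, cols = np.nonzero(mask)
    cells = pd.DataFrame({
        "cell_id": rows * mask_r.shape[1] + cols,
        "row": rows,
        "col": cols,
        "x": xs[mask],
        "y": ys[mask],
        "region": np.take(REGIONS, stack["region"].data[mask].astype(int)),
    })
    for name, layer in stack.layers.items():
        if name in ("mask", "region"):
            continue
        cells[name] = layer.data[mask]
    if variogram is None:
        variogram = fit_variogram(records)
    rates = ordinary_kriging(records, variogram, cells[["x", "y"]].to_numpy(float),
                             n_max=n_max)
    n_floored = int((rates < 0).sum())
    if n_floored:
        warnings.warn(f"floored {n_floored} negative kriged rates at 0")
    cells["n_rate"] = np.maximum(rates, 0.0)
    cells.attrs["n_floored"] = n_floored
    return cells
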