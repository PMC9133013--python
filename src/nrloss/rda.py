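"""Redundancy analysis (RDA) and per-pathway factor selection.

RDA is constrained ordination: each (centered) response column is
regressed on the explanatory matrix, and the fitted-value covariance is
eigen-decomposed into constrained axes. The total explained variation is

    trace(cov(Y_hat)) / trace(cov(Y)),

which for a single response column reduces to the multiple-regression
R^2. Marginal explanatory rates use each factor alone; conditional
rates come from greedy forward selection (largest added explained
variance first, ties broken by the canonical covariate order).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .pathways import COVARIATES, FACTOR_PRESETS, PRESET_EXPLANATORY_RATES, check_pathway


@dataclass(frozen=True)
class PathwaySpec:
    """A pathway's selected factor ensemble."""

    pathway: str
    factors: tuple[str, ...]
    total_explanatory_rate: float  # percent of response variance

    def __post_init__(self) -> None:
        check_pathway(self.pathway)
        if not self.factors:
            raise ValueError("factors must be non-empty")
        if len(set(self.factors)) != len(self.factors):
            raise ValueError("factors must be unique")
        unknown = set(self.factors) - set(COVARIATES)
        if unknown:
            raise ValueError(f"unknown covariates {sorted(unknown)}")


def preset_spec(pathway: str) -> PathwaySpec:
    """The frozen preset ensemble for a pathway (bypasses selection)."""
    check_pathway(pathway)
    return PathwaySpec(pathway, FACTOR_PRESETS[pathway], PRESET_EXPLANATORY_RATES[pathway])


def _as_2d(A) -> tuple[np.ndarray, list[str]]:
    if isinstance(A, pd.DataFrame):
        return A.to_numpy(float), list(A.columns)
    arr = np.asarray(A, float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr, [f"c{i}" for i in range(arr.shape[1])]


class RDA(BaseEstimator):
    """Redundancy analysis of a response table on an explanatory table.

    Parameters
    ----------
    standardize : scale explanatory columns to unit variance after
        centering (recommended for mixed units such as %, mm and deg C).
    allow_collinear : tolerate rank-deficient X (least squares picks the
        minimum-norm solution) instead of raising; used during forward
        selection where e.g. texture triplets summing to 100% make the
        full candidate set nearly dependent.

    Attributes (after ``fit(X, Y)``)
    --------------------------------
    total_explained_ : fraction of total response variance captured by
        the fitted values.
    eigenvalues_ : variances of the constrained axes (descending).
    site_scores_ : sample coordinates on the constrained axes.
    coef_ : regression coefficients of centered Y on processed X.
    """

    def __init__(self, standardize: bool = True, allow_collinear: bool = False):
        self.standardize = standardize
        self.allow_collinear = allow_collinear

    def fit(self, X, Y) -> "RDA":
        Xm, xnames = _as_2d(X)
        Ym, _ = _as_2d(Y)
        if Xm.shape[0] != Ym.shape[0]:
            raise ValueError("X and Y must have the same number of rows")
        n, p = Xm.shape
        if n <= p:
            raise ValueError(f"need more samples than predictors (n={n}, p={p})")
        Xc = Xm - Xm.mean(axis=0)
        if self.standardize:
            sd = Xc.std(axis=0, ddof=1)
            sd[sd == 0] = 1.0
            Xc = Xc / sd
        rank = np.linalg.matrix_rank(Xc)
        if rank < p and not self.allow_collinear:
            # name the dependent columns via pivoted QR
            from scipy.linalg import qr as _qr
            _, _, piv = _qr(Xc, pivoting=True)
            dependent = [xnames[j] for j in piv[rank:]]
            raise ValueError(f"explanatory columns are collinear: {dependent}")
        Yc = Ym - Ym.mean(axis=0)
        coef, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)
        fitted = Xc @ coef
        sst = float(np.sum(Yc * Yc))
        if sst == 0:
            raise ValueError("response has zero variance")
        self.total_explained_ = float(np.sum(fitted * fitted)) / sst
        # constrained axes: SVD of the fitted values
        u, s, _ = np.linalg.svd(fitted, full_matrices=False)
        self.eigenvalues_ = (s**2) / max(n - 1, 1)
        self.site_scores_ = u * s
        self.coef_ = coef
        self.feature_names_in_ = np.asarray(xnames, dtype=object)
        return self

    def score(self, X=None, Y=None) -> float:
        check_is_fitted(self, "total_explained_")
        return self.total_explained_


def fit_rda(Y, X, standardize: bool = True, allow_collinear: bool = False) -> RDA:
    """Functional wrapper: note the (Y, X) ordination argument order."""
    return RDA(standardize=standardize, allow_collinear=allow_collinear).fit(X, Y)


def _explained(Y, X_sub) -> float:
    return RDA(allow_collinear=True).fit(X_sub, Y).total_explained_


def factor_explanatory_rates(Y, X: pd.DataFrame) -> pd.DataFrame:
    """Marginal and conditional (forward-selection) explanatory rates.

    Returns a table indexed by factor with columns ``marginal`` (rate of
    that factor alone) and ``conditional`` (variance added when the
    factor enters the greedy forward selection), both as fractions; the
    ``order`` column gives the selection position (0 first).
    Conditional rates sum to the all-factor total explained variance.
    """
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, float))
    names = list(X.columns)
    canon = {name: i for i, name in enumerate(COVARIATES)}
    marginal = {name: _explained(Y, X[[name]]) for name in names}
    remaining = list(names)
    selected: list[str] = []
    conditional: dict[str, float] = {}
    current = 0.0
    while remaining:
        best_gain, best = -np.inf, None
        for name in sorted(remaining, key=lambda c: canon.get(c, len(canon))):
            gain = _explained(Y, X[selected + [name]]) - current
            if gain > best_gain + 1e-12:
                best_gain, best = gain, name
        selected.append(best)
        remaining.remove(best)
        conditional[best] = best_gain
        current += best_gain
    out = pd.DataFrame({
        "marginal": pd.Series(marginal),
        "conditional": pd.Series(conditional),
        "order": pd.Series({name: selected.index(name) for name in names}),
    }).loc[names]
    out.attrs["total_explained"] = current
    return out


def select_factors(
    rates: pd.DataFrame,
    pathway: str,
    threshold: float = 0.01,
) -> PathwaySpec:
    """Forward-select factors until the added conditional rate drops
    below ``threshold`` (fraction of variance, default 1%)."""
    check_pathway(pathway)
    ordered = rates.sort_values("order")
    chosen = []
    total = 0.0
    for name, row in ordered.iterrows():
        if chosen and row["conditional"] < threshold:
            break
        chosen.append(name)
        total += float(row["conditional"])
    if not chosen:
        raise ValueError(
            "no factor passed the selection threshold; lower `threshold`")
    return PathwaySpec(pathway, tuple(chosen), 100.0 * total)
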