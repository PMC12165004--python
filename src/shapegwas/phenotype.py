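"""Phenotype preparation: covariate residualization and inverse-normal transform.

The association and CCA stages consume eigenvalue phenotypes that have been
(1) regressed on the covariate set, keeping intercept + residuals so the
columns stay on their original location scale, and (2) mapped through the
rank-based inverse-normal transform (INT) so each column is marginally
normal.  Covariates never re-enter the association scan.

Both steps are sklearn transformers so they compose with pipelines; the
module-level `residualize` and `inverse_normal_transform` functions are thin
wrappers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "CovariateResidualizer",
    "InverseNormalTransformer",
    "residualize",
    "inverse_normal_transform",
    "prepare_phenotypes",
    "DEFAULT_COVARIATES",
]

#: covariate columns of the default design matrix (quality_index is the
#: mesh-quality stand-in for an MRI surface-defect count)
DEFAULT_COVARIATES = (
    "age",
    "age2",
    "sex",
    *[f"pc{i}" for i in range(1, 11)],
    "quality_index",
    "surface_area",
    "total_volume",
)


def _as_2d(x) -> np.ndarray:
    arr = np.asarray(x, dtype=np.float64)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr


class CovariateResidualizer(TransformerMixin, BaseEstimator):
    """Replace each phenotype column by fitted intercept + OLS residual.

    Parameters
    ----------
    covariates : array-like (n, c) or DataFrame
        The design matrix (without intercept; one is added internally).
        Rows must align with the phenotype rows passed to :meth:`fit`.

    After fitting, transformed columns have exactly zero sample correlation
    with every covariate, while keeping each column's mean.
    """

    def __init__(self, covariates=None):
        self.covariates = covariates

    def _design(self, n: int) -> np.ndarray:
        if self.covariates is None:
            raise ValueError("covariates must be provided")
        c = (
            self.covariates.to_numpy(dtype=np.float64)
            if isinstance(self.covariates, pd.DataFrame)
            else _as_2d(self.covariates)
        )
        if len(c) != n:
            raise ValueError(
                f"covariate rows ({len(c)}) do not match phenotype rows ({n})"
            )
        if np.isnan(c).any():
            raise ValueError("covariates contain missing values; drop or align first")
        x = np.column_stack([np.ones(n), c])
        rank = np.linalg.matrix_rank(x)
        if rank < x.shape[1]:
            # name the offending columns for the error message
            names = (
                list(self.covariates.columns)
                if isinstance(self.covariates, pd.DataFrame)
                else [f"cov{i}" for i in range(c.shape[1])]
            )
            collinear = []
            kept = [np.ones(n)]
            for i in range(c.shape[1]):
                trial = np.column_stack(kept + [c[:, i]])
                if np.linalg.matrix_rank(trial) == trial.shape[1]:
                    kept.append(c[:, i])
                else:
                    collinear.append(names[i])
            raise ValueError(
                f"rank-deficient design matrix; collinear columns: {collinear}"
            )
        return x

    def fit(self, X, y=None):
        X = _as_2d(X)
        x = self._design(len(X))
        self.coef_, _, _, _ = np.linalg.lstsq(x, X, rcond=None)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "coef_")
        X = _as_2d(X)
        x = self._design(len(X))
        fitted = x @ self.coef_
        # intercept + residuals: subtract only the covariate part of the fit
        return X - fitted + self.coef_[0][None, :]


class InverseNormalTransformer(TransformerMixin, BaseEstimator):
    """Rank-based inverse-normal transform (Blom offset), column-wise.

    value_j = Phi^-1((rank_j - 3/8) / (n + 1/4)), with average ranks for
    ties.  Strictly monotone in the input ranks; a constant column is an
    error.  The transform is rank-based, so `fit` only records the column
    count — each `transform` call ranks the data it is given.
    """

    def __init__(self, offset: float = 3.0 / 8.0):
        self.offset = offset

    def fit(self, X, y=None):
        X = _as_2d(X)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "n_features_in_")
        X = _as_2d(X)
        n = len(X)
        if n < 3:
            raise ValueError("INT requires at least 3 observations")
        out = np.empty_like(X)
        for j in range(X.shape[1]):
            col = X[:, j]
            # near-machine-epsilon spread (e.g. a residualized copy of a
            # covariate) is constant in all but rounding noise
            if np.ptp(col) <= 1e-12 * max(np.abs(col).max(), 1.0):
                raise ValueError(f"constant column (index {j}) cannot be INT-ed")
            ranks = rankdata(col, method="average")
            out[:, j] = norm.ppf((ranks - self.offset) / (n + 1.0 - 2.0 * self.offset))
        return out


def residualize(pheno, covariates):
    """Intercept + OLS residuals of each phenotype column on the covariates."""
    r = CovariateResidualizer(covariates=covariates)
    return r.fit_transform(_as_2d(pheno))


def inverse_normal_transform(column):
    """Rank-based INT of one column (or each column of a matrix)."""
    x = np.asarray(column, dtype=np.float64)
    out = InverseNormalTransformer().fit_transform(_as_2d(x))
    return out[:, 0] if x.ndim == 1 else out


def prepare_phenotypes(pheno, covariates) -> np.ndarray:
    """The fixed pipeline order: residualize, then INT per column."""
    return InverseNormalTransformer().fit_transform(residualize(pheno, covariates))
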