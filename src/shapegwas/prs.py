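"""Canonical correlation of the shape spectrum with polygenic scores.

With a scalar score on one side, canonical correlation analysis reduces to
the multiple correlation: the canonical variable is the fitted value of the
OLS regression of the prepared score on the 49 spectrum columns, and the
canonical correlation r equals sqrt(R^2) of that regression.  Loadings are
the Pearson correlations of each eigenvalue with the canonical variable; if
at least 90% of the loadings share one sign the association is flagged as a
"common direction of effects".

Scores are prepared like the phenotypes — residualized on age, age^2, sex,
the first 10 genetic PCs and total brain volume (note: NOT surface area or
the mesh-quality index) and then inverse-normal transformed.

Multiple testing over a (structures x scores) grid uses the two-level
scheme: Benjamini-Hochberg FDR across structures within each score,
followed by Bonferroni across the number of effective scores; the flat
Bonferroni across all tests is reported alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted
from statsmodels.stats.multitest import multipletests

from .phenotype import inverse_normal_transform, residualize

__all__ = [
    "PRS_COVARIATES",
    "prepare_prs",
    "CCAResult",
    "cca_scalar",
    "SpectrumCCA",
    "common_direction",
    "permutation_p",
    "two_level_correction",
]

#: covariates used when preparing a polygenic score (no surface area or
#: mesh-quality column, unlike the phenotype design matrix)
PRS_COVARIATES = ("age", "age2", "sex", *[f"pc{i}" for i in range(1, 11)], "total_volume")


def prepare_prs(prs, covariates) -> np.ndarray:
    """Residualize a scalar score on the PRS covariate set, then INT it."""
    resid = residualize(np.asarray(prs, dtype=np.float64).reshape(-1, 1), covariates)
    return inverse_normal_transform(resid[:, 0])


@dataclass(frozen=True)
class CCAResult:
    """One structure x score canonical correlation with its loading profile."""

    r: float
    p_parametric: float
    loadings: np.ndarray
    mean_loading: float
    n_positive: int
    n_negative: int
    common_direction: bool
    p_permutation: float | None = None


class SpectrumCCA(BaseEstimator):
    """CCA of a multi-column spectrum block against one scalar score.

    ``fit(X, y)`` with X the (n, q) prepared spectrum and y the prepared
    score.  The canonical variable's sign is fixed so its correlation with
    the score is positive.

    Attributes
    ----------
    r_ : canonical correlation in [0, 1].
    r_adjusted_ : dimension-bias-corrected canonical correlation (via the
        adjusted R^2); the honest estimate of a weak population correlation.
    pvalue_ : parametric P from Rao's F approximation (for a scalar score
        this is the overall regression F test on (q, n-q-1) df).
    loadings_ : per-column correlation with the canonical variable.
    canonical_variable_ : (n,) scores of the canonical variable.
    coef_ : regression weights defining the canonical variable.
    """

    def __init__(self, common_direction_threshold: float = 0.9):
        self.common_direction_threshold = common_direction_threshold

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64).ravel()
        n, q = X.shape
        if len(y) != n:
            raise ValueError("spectrum and score lengths differ")
        if n <= q:
            raise ValueError(
                f"n={n} must exceed the spectrum dimension q={q} with margin"
            )
        xc = X - X.mean(axis=0)
        yc = y - y.mean()
        coef, _, rank, _ = np.linalg.lstsq(xc, yc, rcond=None)
        if rank < q:
            warnings.warn(
                f"spectrum block is rank deficient ({rank} < {q}); "
                "minimum-norm (pseudo-inverse) weights used",
                stacklevel=2,
            )
        cv = xc @ coef
        ss_tot = yc @ yc
        r2 = 0.0 if ss_tot == 0 else float((cv @ yc) / ss_tot)
        r2 = min(max(r2, 0.0), 1.0)
        self.r_ = float(np.sqrt(r2))
        # dimension-bias-corrected value (adjusted R^2): the raw sample r is
        # inflated by ~ sqrt(q/n) even under independence
        if n - q - 1 > 0:
            adj = 1.0 - (1.0 - r2) * (n - 1) / (n - q - 1)
        else:
            adj = r2
        self.r_adjusted_ = float(np.sqrt(max(adj, 0.0)))

        # sign convention: canonical variable correlates positively with y
        if cv @ yc < 0:  # pragma: no cover - cv@yc >= 0 by construction of OLS
            coef, cv = -coef, -cv
        self.coef_ = coef
        self.canonical_variable_ = cv

        df1, df2 = rank, n - rank - 1
        if r2 >= 1.0:
            self.pvalue_ = 0.0
        else:
            f = (r2 / df1) / ((1.0 - r2) / df2)
            self.pvalue_ = float(st.f.sf(f, df1, df2))

        cv_sd = cv.std()
        if cv_sd == 0:
            self.loadings_ = np.zeros(q)
        else:
            xs = X.std(axis=0)
            safe = np.where(xs == 0, 1.0, xs)
            self.loadings_ = (xc * cv[:, None]).mean(axis=0) / (safe * cv_sd)
            self.loadings_[xs == 0] = 0.0
        (
            self.mean_loading_,
            self.n_positive_,
            self.n_negative_,
            self.common_direction_,
        ) = common_direction(self.loadings_, self.common_direction_threshold)
        return self

    def result(self, p_permutation: float | None = None) -> CCAResult:
        check_is_fitted(self, "r_")
        return CCAResult(
            r=self.r_,
            p_parametric=self.pvalue_,
            loadings=self.loadings_,
            mean_loading=self.mean_loading_,
            n_positive=self.n_positive_,
            n_negative=self.n_negative_,
            common_direction=self.common_direction_,
            p_permutation=p_permutation,
        )


def cca_scalar(spectrum, prs, common_direction_threshold: float = 0.9) -> CCAResult:
    """Canonical correlation of a spectrum block with a scalar score."""
    return SpectrumCCA(common_direction_threshold).fit(spectrum, prs).result()


def common_direction(
    loadings, threshold: float = 0.9
) -> tuple[float, int, int, bool]:
    """Mean loading, sign counts, and the >= 90%-same-sign flag.

    Zero loadings count toward neither direction; the flag compares the
    dominant sign count against ``threshold`` times ALL loadings.
    """
    lo = np.asarray(loadings, dtype=np.float64)
    n_pos = int(np.sum(lo > 0))
    n_neg = int(np.sum(lo < 0))
    flag = max(n_pos, n_neg) >= threshold * len(lo)
    return float(lo.mean()), n_pos, n_neg, bool(flag)


def permutation_p(
    spectrum,
    prs,
    n_perm: int = 100_000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Empirical P of the canonical correlation by score permutation.

    The score vector's individual assignment is permuted ``n_perm`` times;
    P = (1 + #{permuted r >= observed r}) / (1 + n_perm).
    """
    if n_perm < 100:
        warnings.warn(
            f"n_perm={n_perm} gives a coarse empirical P (granularity "
            f"{1.0 / (1 + n_perm):.3g})",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    X = np.asarray(spectrum, dtype=np.float64)
    y = np.asarray(prs, dtype=np.float64).ravel()
    n, q = X.shape

    # r^2 = y' H y / y'y with H the centered-column hat matrix: precompute an
    # orthonormal basis once, each permutation is then one matrix-vector pass
    xc = X - X.mean(axis=0)
    qmat, _ = np.linalg.qr(xc)
    yc = y - y.mean()
    ss_tot = yc @ yc
    proj = qmat.T @ yc
    r_obs = np.sqrt(max((proj @ proj) / ss_tot, 0.0))

    count = 0
    for _ in range(n_perm):
        yp = yc[rng.permutation(n)]
        pr = qmat.T @ yp
        r_perm = np.sqrt(max((pr @ pr) / ss_tot, 0.0))
        if r_perm >= r_obs - 1e-15:
            count += 1
    return (1.0 + count) / (1.0 + n_perm)


def two_level_correction(
    pvalues: pd.DataFrame | np.ndarray, n_effective_scores: int = 6
) -> dict[str, pd.DataFrame | np.ndarray]:
    """Two-level multiple-testing adjustment of a (structures x scores) grid.

    Within each score's column, Benjamini-Hochberg across structures; the
    result is multiplied by ``n_effective_scores`` and capped at 1.  The
    flat Bonferroni across all structures x scores cells is reported under
    ``"overall_bonferroni"`` for comparison.
    """
    is_frame = isinstance(pvalues, pd.DataFrame)
    p = pvalues.to_numpy(dtype=np.float64) if is_frame else np.asarray(pvalues, dtype=np.float64)
    if p.ndim != 2:
        raise ValueError("pvalues must be a (structures x scores) matrix")
    bh = np.empty_like(p)
    for j in range(p.shape[1]):
        bh[:, j] = multipletests(p[:, j], method="fdr_bh")[1]
    two_level = np.minimum(bh * n_effective_scores, 1.0)
    overall = np.minimum(p * p.size, 1.0)
    out = {"bh_within_score": bh, "two_level": two_level, "overall_bonferroni": overall}
    if is_frame:
        out = {
            k: pd.DataFrame(v, index=pvalues.index, columns=pvalues.columns)
            for k, v in out.items()
        }
    return out
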