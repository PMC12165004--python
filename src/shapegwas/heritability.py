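"""SNP heritability of the shape spectrum.

Univariate heritability of each eigenvalue phenotype is estimated by
Haseman-Elston regression on the genomic relatedness matrix (GRM): the
cross-products y_j * y_k of the standardized phenotype over all individual
pairs j < k are regressed on the corresponding GRM entries; the slope is an
unbiased estimate of h^2.  Standard errors come from a delete-block
jackknife over individuals.

The multidimensional aggregate over the spectrum weights each eigenvalue's
univariate heritability by the relative size of its phenotypic variance,

    h^2 = sum_m gamma_m h_m^2,  gamma_m = sigma^2_Pm / sum_k sigma^2_Pk,

with the standard error from Bienayme's identity assuming independent
univariate errors, SE(h^2) = sqrt(sum_m gamma_m^2 SE(h_m^2)^2).  The test of
h^2 = 0 uses the boundary Wald statistic distributed as the mixture
(1/2) chi^2_0 + (1/2) chi^2_1, because the null lies on the boundary of the
constrained space h^2 >= 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats as st
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .genio import GenotypeMatrix

__all__ = [
    "compute_grm",
    "he_regression",
    "HasemanElstonRegression",
    "HeritabilityReport",
    "multidimensional_h2",
    "wald_boundary_p",
    "wald_difference_p",
]


def compute_grm(g) -> np.ndarray:
    """Genomic relatedness matrix Z Z' / p from column-standardized dosages."""
    d = g.dosage if isinstance(g, GenotypeMatrix) else np.asarray(g, dtype=np.float64)
    if np.isnan(d).any():
        raise ValueError("missing dosages; run QC first")
    sd = d.std(axis=0)
    if np.any(sd == 0):
        n_mono = int(np.sum(sd == 0))
        raise ValueError(f"{n_mono} monomorphic variant(s); remove before GRM")
    z = (d - d.mean(axis=0)) / sd
    return z @ z.T / d.shape[1]


def _pair_sums(grm: np.ndarray, y: np.ndarray):
    """Sufficient statistics of the pairwise HE regression.

    All sums run over unordered pairs j < k; they are assembled from matrix
    identities so the cost is one O(n^2) pass, and the per-quantity row sums
    needed by the block jackknife are returned alongside.
    """
    n = len(y)
    diag = np.diag(grm)
    g_row = grm.sum(axis=1) - diag  # row sums excluding diagonal
    gy = grm @ y
    g2 = grm * grm
    g2_row = g2.sum(axis=1) - diag**2

    x_row = g_row  # Q = G_jk
    xx_row = g2_row  # Q = G_jk^2
    xy_row = y * (gy - diag * y)  # Q = G_jk y_j y_k
    yy_row = y * (y.sum() - y)  # Q = y_j y_k

    sums = {
        "x": x_row.sum() / 2.0,
        "xx": xx_row.sum() / 2.0,
        "xy": xy_row.sum() / 2.0,
        "y": yy_row.sum() / 2.0,
        "m": n * (n - 1) / 2.0,
    }
    rows = {"x": x_row, "xx": xx_row, "xy": xy_row, "y": yy_row}
    return sums, rows


def _he_slope(s) -> float:
    sxx = s["xx"] - s["x"] ** 2 / s["m"]
    sxy = s["xy"] - s["x"] * s["y"] / s["m"]
    if sxx <= 0:
        raise ValueError("GRM off-diagonals have zero variance")
    return sxy / sxx


def he_regression(
    grm: np.ndarray,
    y: np.ndarray,
    n_blocks: int = 100,
    standardize: bool = True,
) -> tuple[float, float]:
    """Haseman-Elston estimate of h^2 for one phenotype column, with SE.

    The point estimate is the slope of y_j y_k on GRM_jk over all pairs
    j < k; it is NOT clamped to [0, 1] (clamping is a reporting concern).
    The SE is a delete-block jackknife over ``n_blocks`` contiguous
    individual blocks.
    """
    grm = np.asarray(grm, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    n = len(y)
    if grm.shape != (n, n):
        raise ValueError("GRM shape does not match phenotype length")
    if np.ptp(y) == 0:
        raise ValueError("constant phenotype")
    if standardize:
        y = (y - y.mean()) / y.std()

    sums, rows = _pair_sums(grm, y)
    h2 = _he_slope(sums)

    n_blocks = min(n_blocks, n)
    bounds = np.linspace(0, n, n_blocks + 1).astype(int)
    estimates = np.empty(n_blocks)
    for b in range(n_blocks):
        idx = np.arange(bounds[b], bounds[b + 1])
        nb = len(idx)
        sub = grm[np.ix_(idx, idx)]
        yb = y[idx]
        # pair sums within the removed block (unordered)
        w = {
            "x": (sub.sum() - np.trace(sub)) / 2.0,
            "xx": ((sub**2).sum() - (np.diag(sub) ** 2).sum()) / 2.0,
            "xy": (yb @ sub @ yb - np.diag(sub) @ yb**2) / 2.0,
            "y": ((yb.sum()) ** 2 - (yb**2).sum()) / 2.0,
        }
        reduced = {
            key: sums[key] - rows[key][idx].sum() + w[key] for key in w
        }
        reduced["m"] = (n - nb) * (n - nb - 1) / 2.0
        estimates[b] = _he_slope(reduced)
    se = float(np.sqrt((n_blocks - 1) / n_blocks * ((estimates - estimates.mean()) ** 2).sum()))
    return float(h2), se


class HasemanElstonRegression(BaseEstimator):
    """Haseman-Elston heritability estimator, sklearn-shaped.

    ``fit(X, y)`` accepts either a dosage matrix (GRM computed internally)
    or, with ``grm='precomputed'``, a relatedness matrix directly.

    Attributes
    ----------
    h2_ : unclamped point estimate.
    se_ : jackknife standard error.
    pvalue_ : boundary Wald P value against h^2 = 0.
    h2_reported_ : estimate clamped to [0, 1] for human-readable reports.
    clamped_ : True when clamping changed the value.
    """

    def __init__(self, grm: str = "compute", n_blocks: int = 100):
        self.grm = grm
        self.n_blocks = n_blocks

    def fit(self, X, y):
        if self.grm == "precomputed":
            K = np.asarray(X, dtype=np.float64)
        elif self.grm == "compute":
            K = compute_grm(X)
        else:
            raise ValueError("grm must be 'compute' or 'precomputed'")
        self.h2_, self.se_ = he_regression(K, y, n_blocks=self.n_blocks)
        self.pvalue_ = wald_boundary_p(self.h2_, self.se_)
        self.h2_reported_ = float(np.clip(self.h2_, 0.0, 1.0))
        self.clamped_ = self.h2_reported_ != self.h2_
        return self


@dataclass(frozen=True)
class HeritabilityReport:
    """Per-eigenvalue and aggregated heritability of one structure."""

    h2_per_eigenvalue: np.ndarray
    se_per_eigenvalue: np.ndarray
    phenotypic_variance: np.ndarray
    weights: np.ndarray  # gamma_m, summing to 1
    h2: float
    se: float
    pvalue_boundary: float
    pvalue_difference: float | None = None

    def __post_init__(self) -> None:
        if abs(self.weights.sum() - 1.0) > 1e-12:
            raise ValueError("weights must sum to 1")


def multidimensional_h2(
    h2_per_eigenvalue,
    se_per_eigenvalue,
    phenotypic_variance,
    h2_ref: float | None = None,
    se_ref: float | None = None,
) -> HeritabilityReport:
    """Variance-weighted aggregate heritability across the spectrum.

    ``phenotypic_variance`` holds the per-eigenvalue variances of the
    residualized phenotypes (they define the weights gamma_m).  If a
    reference estimate ``h2_ref +- se_ref`` is supplied, the difference Wald
    P value is included.
    """
    h2m = np.asarray(h2_per_eigenvalue, dtype=np.float64)
    sem = np.asarray(se_per_eigenvalue, dtype=np.float64)
    var = np.asarray(phenotypic_variance, dtype=np.float64)
    if not (len(h2m) == len(sem) == len(var)):
        raise ValueError("per-eigenvalue arrays must share a length")
    if np.any(var < 0):
        raise ValueError("negative phenotypic variance")
    if np.any(sem < 0):
        raise ValueError("negative standard error")
    gamma = var / var.sum()
    h2 = float(gamma @ h2m)
    se = float(np.sqrt(np.sum(gamma**2 * sem**2)))
    p_diff = None
    if h2_ref is not None:
        if se_ref is None:
            raise ValueError("se_ref required with h2_ref")
        p_diff = wald_difference_p(h2, se, h2_ref, se_ref)
    return HeritabilityReport(
        h2_per_eigenvalue=h2m,
        se_per_eigenvalue=sem,
        phenotypic_variance=var,
        weights=gamma,
        h2=h2,
        se=se,
        pvalue_boundary=wald_boundary_p(h2, se) if se > 0 else float("nan"),
        pvalue_difference=p_diff,
    )


def wald_boundary_p(h2: float, se: float) -> float:
    """P value of the boundary Wald test of h^2 = 0.

    The statistic (h^2/SE)^2 is distributed as (1/2) chi^2_0 + (1/2) chi^2_1
    under the null because h^2 is constrained nonnegative: for a positive
    estimate P = 0.5 * Pr(chi^2_1 > w); a non-positive estimate can never be
    evidence against the null, so P >= 0.5 there.
    """
    if se <= 0:
        raise ValueError("SE must be positive")
    w = (h2 / se) ** 2
    tail = st.chi2.sf(w, df=1)
    return float(0.5 * tail if h2 > 0 else 1.0 - 0.5 * tail)


def wald_difference_p(
    h2: float,
    se: float,
    h2_ref: float,
    se_ref: float,
    correlation: float = 0.0,
) -> float:
    """Wald test of equality with an external estimate h2_ref +- se_ref.

    The variance of the difference is SE_ref^2 by default: when the internal
    SE is small relative to the reference SE the cross-term (which would
    need the unknown correlation of the two estimators) is negligible.  Pass
    ``correlation`` to use the full expression
    SE^2 + SE_ref^2 - SE * SE_ref * cor.
    """
    if se_ref <= 0:
        raise ValueError("reference SE must be positive")
    if correlation == 0.0:
        var_diff = se_ref**2  # reference-dominated approximation
    else:
        var_diff = se**2 + se_ref**2 - se * se_ref * correlation
    w = (h2 - h2_ref) ** 2 / var_diff
    return float(st.chi2.sf(w, df=1))
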