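"""Multivariate omnibus genome-wide association on the shape spectrum.

Per variant, 49 univariate GWAS z-scores (one per eigenvalue phenotype) are
combined into the Mahalanobis statistic t = z' R^-1 z, where R is the
correlation matrix of z-scores obtained from the same scan run on
once-permuted genotypes (which preserves the phenotype correlation but
breaks genotype-phenotype association).  Tail P values come from a gamma
distribution fitted to the permuted-genotype statistics, which extrapolates
the null far below 1/#variants and removes the need to correct across the
49 univariate scans.

Genotype QC (call rate, MAF, Hardy-Weinberg exact test with mid-P
adjustment) precedes the scan; covariates are handled entirely by
pre-residualization of the phenotypes, so the scan itself is covariate-free
simple regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import lgamma, log

import numpy as np
import scipy.stats as st
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .genio import GenotypeMatrix

__all__ = [
    "QCReport",
    "genotype_qc",
    "hwe_exact_test",
    "univariate_scan",
    "null_correlation",
    "omnibus_statistic",
    "fit_gamma_null",
    "omnibus_p",
    "significance_threshold",
    "MultivariateOmnibusGWAS",
]

GENOME_WIDE_ALPHA = 5e-8


def significance_threshold(n_structures: int) -> float:
    """Genome-wide threshold Bonferroni-corrected across structures."""
    if n_structures < 1:
        raise ValueError("n_structures must be >= 1")
    return GENOME_WIDE_ALPHA / n_structures


def hwe_exact_test(
    n_hom_ref: int, n_het: int, n_hom_alt: int, mid_p: bool = True
) -> float:
    """Exact Hardy-Weinberg test by conditional enumeration of heterozygotes.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts no more likely than the observed one.  The mid-P
    variant (default) counts only half the observed outcome's probability,
    reducing the test's conservatism for variants with missing data.
    """
    counts = (n_hom_ref, n_het, n_hom_alt)
    if any(c < 0 for c in counts):
        raise ValueError(f"negative genotype count in {counts}")
    n = sum(counts)
    if n == 0:
        return 1.0
    n_rare = min(2 * n_hom_ref + n_het, 2 * n_hom_alt + n_het)
    # heterozygote count shares the parity of the rare-allele count
    het_values = np.arange(n_rare % 2, n_rare + 1, 2)
    log_probs = np.empty(len(het_values), dtype=np.float64)
    for i, h in enumerate(het_values):
        rare_hom = (n_rare - h) // 2
        common_hom = n - rare_hom - h
        if common_hom < 0:
            log_probs[i] = -np.inf
            continue
        # multinomial count of genotype configurations x 2^het phasings
        log_probs[i] = (
            h * log(2.0)
            + lgamma(n + 1)
            - lgamma(rare_hom + 1)
            - lgamma(h + 1)
            - lgamma(common_hom + 1)
            + lgamma(n_rare + 1)
            + lgamma(2 * n - n_rare + 1)
            - lgamma(2 * n + 1)
        )
    probs = np.exp(log_probs - log_probs.max())
    probs /= probs.sum()
    p_obs = probs[het_values == n_het]
    if len(p_obs) == 0:
        raise ValueError(
            f"heterozygote count {n_het} inconsistent with allele counts"
        )
    p_obs = float(p_obs[0])
    tail = float(probs[probs <= p_obs * (1.0 + 1e-12)].sum())
    if mid_p:
        tail -= 0.5 * p_obs
    return min(tail, 1.0)


@dataclass
class QCReport:
    """Per-filter attrition counts from genotype QC."""

    n_input: int
    n_fail_call_rate: int
    n_fail_maf: int
    n_fail_hwe: int
    n_retained: int
    thresholds: dict = field(default_factory=dict)


def genotype_qc(
    g: GenotypeMatrix,
    call_rate_min: float = 0.95,
    maf_min: float = 0.01,
    hwe_p_min: float = 1e-6,
    mid_p: bool = True,
) -> tuple[GenotypeMatrix, QCReport]:
    """Remove variants failing call-rate, MAF or Hardy-Weinberg filters.

    A variant is dropped if its call rate < ``call_rate_min``, its minor
    allele frequency < ``maf_min``, or its HWE exact-test P value (mid-P by
    default) < ``hwe_p_min``.  Surviving variants keep any residual NaN
    calls: downstream code requires complete dosages, so the caller decides
    explicitly how to handle remaining missingness.
    """
    call = g.call_rate()
    maf = g.minor_allele_frequency()
    hwe = np.ones(g.n_variants)
    for j in range(g.n_variants):
        col = g.dosage[:, j]
        col = col[~np.isnan(col)]
        n_hom_ref = int(np.sum(col == 0))
        n_het = int(np.sum(col == 1))
        n_hom_alt = int(np.sum(col == 2))
        hwe[j] = hwe_exact_test(n_hom_ref, n_het, n_hom_alt, mid_p=mid_p)

    fail_call = call < call_rate_min
    fail_maf = maf < maf_min
    fail_hwe = hwe < hwe_p_min
    keep = ~(fail_call | fail_maf | fail_hwe)
    if not keep.any():
        raise ValueError("all variants removed by QC; check thresholds")
    report = QCReport(
        n_input=g.n_variants,
        n_fail_call_rate=int(fail_call.sum()),
        n_fail_maf=int((fail_maf & ~fail_call).sum()),
        n_fail_hwe=int((fail_hwe & ~fail_call & ~fail_maf).sum()),
        n_retained=int(keep.sum()),
        thresholds={
            "call_rate_min": call_rate_min,
            "maf_min": maf_min,
            "hwe_p_min": hwe_p_min,
            "mid_p": mid_p,
        },
    )
    return g.take_variants(keep), report


def _dosage_array(g) -> np.ndarray:
    d = g.dosage if isinstance(g, GenotypeMatrix) else np.asarray(g, dtype=np.float64)
    if np.isnan(d).any():
        raise ValueError("missing dosages present; run genotype_qc / impute first")
    return np.asarray(d, dtype=np.float64)


_R_CLIP = 1.0 - 1e-12


def univariate_scan(g, y: np.ndarray) -> np.ndarray:
    """z-score matrix (variants x phenotypes) of simple-regression slope tests.

    For dosage x and phenotype column y, z = r * sqrt((n-2)/(1-r^2)) with r
    the sample correlation; |r| is clipped just below 1 so degenerate exact
    fits give a large finite z instead of infinity.
    """
    d = _dosage_array(g)
    y = np.asarray(y, dtype=np.float64)
    if y.ndim == 1:
        y = y[:, None]
    n = d.shape[0]
    if y.shape[0] != n:
        raise ValueError("genotype and phenotype row counts differ")
    if n < 30:
        raise ValueError(f"n={n} too small for the normal z approximation")
    sd_g = d.std(axis=0)
    if np.any(sd_g == 0):
        raise ValueError("zero-variance dosage column; QC should have removed it")
    zg = (d - d.mean(axis=0)) / sd_g
    zy = (y - y.mean(axis=0)) / y.std(axis=0)
    r = zg.T @ zy / n
    r = np.clip(r, -_R_CLIP, _R_CLIP)
    return r * np.sqrt((n - 2.0) / (1.0 - r**2))


def null_correlation(
    g, y: np.ndarray, seed: int | np.random.Generator = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Correlation matrix R of z-scores under once-permuted genotypes.

    One random permutation of the individual order is applied to the
    genotype rows (the same permutation for every variant), which preserves
    the phenotype correlation structure while breaking association.
    Returns (R, permuted z matrix).
    """
    d = _dosage_array(g)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(d.shape[0])
    z_perm = univariate_scan(d[perm], y)
    q = z_perm.shape[1]
    if z_perm.shape[0] < q:
        warnings.warn(
            f"only {z_perm.shape[0]} variants for a {q}x{q} correlation "
            "matrix; R is rank-deficient and will be pseudo-inverted",
            stacklevel=2,
        )
    R = np.corrcoef(z_perm, rowvar=False)
    return R, z_perm


def omnibus_statistic(
    z: np.ndarray, R: np.ndarray, cond_tol: float = 1e-10
) -> np.ndarray:
    """Mahalanobis norm t = z' R^+ z via eigendecomposition of R.

    Eigencomponents below ``cond_tol`` times the largest eigenvalue are
    discarded (pseudo-inverse), regularizing near-singular correlation
    matrices of strongly dependent phenotypes.  Accepts a single z vector or
    a (variants x phenotypes) matrix.
    """
    R = np.asarray(R, dtype=np.float64)
    if not np.allclose(R, R.T, atol=1e-8):
        raise ValueError("R must be symmetric")
    vals, vecs = np.linalg.eigh(R)
    keep = vals > cond_tol * vals.max()
    inv_vals = np.zeros_like(vals)
    inv_vals[keep] = 1.0 / vals[keep]
    z = np.atleast_2d(np.asarray(z, dtype=np.float64))
    proj = z @ vecs
    t = np.einsum("ij,j,ij->i", proj, inv_vals, proj)
    return t if t.shape[0] > 1 else float(t[0])


def fit_gamma_null(
    null_stats: np.ndarray,
    method: str = "moment",
    tail_fraction: float | None = None,
    min_stats: int = 1000,
) -> tuple[float, float, float]:
    """Fit a gamma distribution to permuted-genotype omnibus statistics.

    Moment matching (default): shape = mean^2/var, scale = var/mean, shift
    fixed at 0.  ``method='mle'`` refines by maximum likelihood with the
    location still fixed at 0.  ``tail_fraction`` restricts the fit to the
    upper quantile of the statistics (exposed for sensitivity analysis, not
    default).  Returns (shape, scale, shift).
    """
    s = np.asarray(null_stats, dtype=np.float64)
    if len(s) < min_stats:
        raise ValueError(
            f"need >= {min_stats} permuted statistics for a stable gamma "
            f"fit, got {len(s)} (lower min_stats explicitly to override)"
        )
    if tail_fraction is not None:
        if not (0.0 < tail_fraction <= 1.0):
            raise ValueError("tail_fraction must be in (0, 1]")
        cutoff = np.quantile(s, 1.0 - tail_fraction)
        s = s[s >= cutoff]
    mean, var = s.mean(), s.var()
    if var <= 0:
        raise ValueError("permuted statistics have non-positive variance")
    shape = mean**2 / var
    scale = var / mean
    if method == "mle":
        shape, _, scale = st.gamma.fit(s, floc=0.0)
    elif method != "moment":
        raise ValueError(f"unknown method {method!r}")
    return float(shape), float(scale), 0.0


def gamma_fit_diagnostic(
    null_stats: np.ndarray, params: tuple[float, float, float]
) -> float:
    """Kolmogorov-Smirnov distance between statistics and fitted gamma."""
    shape, scale, shift = params
    res = st.kstest(null_stats, st.gamma(a=shape, scale=scale, loc=shift).cdf)
    return float(res.statistic)


def omnibus_p(t, params: tuple[float, float, float]):
    """Upper-tail gamma probability of the omnibus statistic."""
    shape, scale, shift = params
    return st.gamma.sf(t, a=shape, scale=scale, loc=shift)


class MultivariateOmnibusGWAS(BaseEstimator):
    """Multivariate omnibus association scan, sklearn-estimator shaped.

    ``fit(G, Y)`` takes complete post-QC dosages (``GenotypeMatrix`` or
    plain (n, p) array) and an (n, q) residualized + INT phenotype matrix,
    then computes the per-variant z-score matrix, the once-permuted null,
    the Mahalanobis statistics and gamma-tail P values.

    Parameters
    ----------
    seed : int
        Seed of the genotype permutation.
    cond_tol : float
        Relative eigenvalue cutoff for pseudo-inverting R.
    gamma_method : 'moment' or 'mle'
        Gamma-null fitting method.
    tail_fraction : float or None
        Restrict the gamma fit to the upper tail of the permuted statistics.

    Attributes
    ----------
    z_ : (p, q) observed z-scores.
    null_corr_ : (q, q) correlation matrix of permuted z-scores.
    gamma_params_ : (shape, scale, shift) of the fitted null.
    stats_ : (p,) omnibus statistics.
    pvalues_ : (p,) gamma-tail P values.
    extrapolated_ : (p,) bool, True where the observed statistic exceeds the
        permuted maximum (tail P relies on gamma extrapolation).
    """

    def __init__(
        self,
        seed: int = 0,
        cond_tol: float = 1e-10,
        gamma_method: str = "moment",
        tail_fraction: float | None = None,
        min_null_stats: int = 1000,
    ):
        self.seed = seed
        self.cond_tol = cond_tol
        self.gamma_method = gamma_method
        self.tail_fraction = tail_fraction
        self.min_null_stats = min_null_stats

    def fit(self, G, Y):
        d = _dosage_array(G)
        Y = np.asarray(Y, dtype=np.float64)
        self.z_ = univariate_scan(d, Y)
        self.null_corr_, null_z = null_correlation(d, Y, seed=self.seed)
        null_stats = omnibus_statistic(null_z, self.null_corr_, self.cond_tol)
        self.null_stats_ = np.atleast_1d(null_stats)
        self.gamma_params_ = fit_gamma_null(
            self.null_stats_, method=self.gamma_method,
            tail_fraction=self.tail_fraction, min_stats=self.min_null_stats,
        )
        self.gamma_ks_ = gamma_fit_diagnostic(self.null_stats_, self.gamma_params_)
        stats = omnibus_statistic(self.z_, self.null_corr_, self.cond_tol)
        self.stats_ = np.atleast_1d(stats)
        self.pvalues_ = np.asarray(omnibus_p(self.stats_, self.gamma_params_))
        self.extrapolated_ = self.stats_ > self.null_stats_.max()
        return self

    def results_frame(self, variants=None):
        """Per-variant results table (chrom, pos, id, t, P, flag)."""
        check_is_fitted(self, "stats_")
        import pandas as pd

        base = {}
        if variants is not None:
            base = {k: variants[k].to_numpy() for k in ("chrom", "pos", "id")}
        return pd.DataFrame(
            {
                **base,
                "t": self.stats_,
                "p": self.pvalues_,
                "flag_extrapolated": self.extrapolated_,
            }
        )
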