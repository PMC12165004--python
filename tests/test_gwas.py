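import numpy as np
import pandas as pd
import pytest
import scipy.stats as st
from scipy.special import comb

from shapegwas.genio import GenotypeMatrix
from shapegwas.gwas import (
    MultivariateOmnibusGWAS,
    fit_gamma_null,
    genotype_qc,
    hwe_exact_test,
    null_correlation,
    omnibus_p,
    omnibus_statistic,
    significance_threshold,
    univariate_scan,
)
from shapegwas.synthetic import simulate_genotypes, simulate_spectrum_phenotypes


def _geno_from_dosage(dosage):
    p = dosage.shape[1]
    return GenotypeMatrix(
        dosage=dosage,
        variants=pd.DataFrame(
            {
                "chrom": ["1"] * p,
                "pos": np.arange(1, p + 1),
                "id": [f"v{i}" for i in range(p)],
                "ref": ["A"] * p,
                "alt": ["G"] * p,
            }
        ),
    )


def _hwe_oracle(n_aa, n_ab, n_bb, mid_p):
    """Independent brute-force oracle: probabilities of every genotype
    configuration with the observed allele counts, from binomial
    coefficients directly."""
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    configs = []
    for het in range(min(n_a, 2 * n - n_a) + 1):
        if (n_a - het) % 2:
            continue
        hom_a = (n_a - het) // 2
        hom_b = n - hom_a - het
        if hom_b < 0:
            continue
        # P(config | allele counts) ~ multinomial x phasing factor
        weight = (
            comb(n, hom_a, exact=True)
            * comb(n - hom_a, het, exact=True)
            * 2**het
        )
        configs.append((het, weight))
    total = sum(w for _, w in configs)
    probs = {h: w / total for h, w in configs}
    p_obs = probs[n_ab]
    tail = sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12))
    return tail - 0.5 * p_obs if mid_p else tail


class TestHWE:
    @pytest.mark.parametrize("mid_p", [False, True])
    @pytest.mark.parametrize(
        "counts",
        [(25, 50, 25), (10, 5, 85), (0, 10, 90), (40, 20, 40), (3, 0, 7), (50, 0, 0)],
    )
    def test_matches_enumeration_oracle(self, counts, mid_p):
        ours = hwe_exact_test(*counts, mid_p=mid_p)
        oracle = _hwe_oracle(*counts, mid_p=mid_p)
        assert ours == pytest.approx(oracle, rel=1e-10)

    def test_perfect_proportions_retained(self):
        # (25, 50, 25) sits at the mode of the conditional distribution
        assert hwe_exact_test(25, 50, 25, mid_p=False) == pytest.approx(1.0)
        assert hwe_exact_test(25, 50, 25) > 0.5

    def test_gross_disequilibrium_detected(self):
        # all heterozygotes absent despite intermediate frequency
        assert hwe_exact_test(50, 0, 50) < 1e-20

    def test_monomorphic_is_p_one(self):
        assert hwe_exact_test(100, 0, 0, mid_p=False) == pytest.approx(1.0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 2, 3)


class TestQC:
    def test_low_maf_variant_removed(self):
        rng = np.random.default_rng(0)
        dosage = rng.binomial(2, 0.3, size=(1000, 10)).astype(float)
        dosage[:, 4] = 0.0
        dosage[:5, 4] = 1.0  # MAF 0.0025
        g = _geno_from_dosage(dosage)
        out, report = genotype_qc(g, 0.95, 0.01, 1e-6)
        assert out.n_variants == 9
        assert report.n_fail_maf == 1
        assert "v4" not in list(out.variants["id"])

    def test_vacuous_thresholds_keep_everything(self):
        g = simulate_genotypes(200, 20, seed=1, missing_rate=0.2)
        out, report = genotype_qc(g, 0.0, 0.0, 0.0)
        assert out.n_variants == 20
        assert report.n_retained == 20

    def test_call_rate_filter(self):
        rng = np.random.default_rng(2)
        dosage = rng.binomial(2, 0.4, size=(100, 5)).astype(float)
        dosage[:20, 0] = np.nan  # call rate 0.8
        g = _geno_from_dosage(dosage)
        out, report = genotype_qc(g, 0.95, 0.0, 0.0)
        assert report.n_fail_call_rate == 1
        assert out.n_variants == 4

    def test_hwe_filter_removes_het_deficit(self):
        dosage = np.concatenate(
            [np.zeros((50, 1)), 2 * np.ones((50, 1))], axis=0
        )  # no hets at MAF 0.5
        ok = np.random.default_rng(3).binomial(2, 0.5, size=(100, 3)).astype(float)
        g = _geno_from_dosage(np.hstack([dosage, ok]))
        out, report = genotype_qc(g, 0.95, 0.01, 1e-6)
        assert report.n_fail_hwe == 1
        assert out.n_variants == 3

    def test_everything_removed_is_an_error(self):
        g = _geno_from_dosage(np.zeros((100, 2)))
        with pytest.raises(ValueError, match="all variants removed"):
            genotype_qc(g, 0.95, 0.01, 1e-6)


class TestUnivariateScan:
    def test_null_z_scores_standard_normal(self):
        g = simulate_genotypes(1000, 500, seed=4)
        y, _ = simulate_spectrum_phenotypes(g, n_phenotypes=5, seed=5)
        z = univariate_scan(g, y)
        assert abs(z.mean()) < 0.1
        assert 0.9 < z.var() < 1.1

    def test_exact_proportionality_gives_large_finite_z(self):
        rng = np.random.default_rng(6)
        dosage = rng.binomial(2, 0.5, size=(100, 1)).astype(float)
        z = univariate_scan(dosage, dosage[:, 0] * 2.0 + 1.0)
        assert np.isfinite(z[0, 0])
        assert z[0, 0] > 1e5

    def test_noncentrality_matches_power_formula(self):
        # E[z] ~ sqrt(n) * rho for a causal variant with correlation rho
        n, rho = 2000, 0.1
        zs = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            x = rng.binomial(2, 0.5, size=n).astype(float)
            xs = (x - x.mean()) / x.std()
            y = rho * xs + np.sqrt(1 - rho**2) * rng.standard_normal(n)
            zs.append(univariate_scan(x[:, None], y)[0, 0])
        expected = np.sqrt(n) * rho
        assert abs(np.mean(zs) - expected) < 2 * np.std(zs) / np.sqrt(len(zs))

    def test_zero_variance_dosage_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            univariate_scan(np.ones((100, 2)), np.random.default_rng(0).standard_normal(100))

    def test_small_n_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            univariate_scan(np.random.default_rng(0).binomial(2, 0.5, (10, 2)).astype(float),
                            np.random.default_rng(1).standard_normal(10))


class TestNullCorrelation:
    def test_duplicated_phenotype_columns_give_unit_correlation(self):
        g = simulate_genotypes(300, 400, seed=7)
        y = np.random.default_rng(8).standard_normal((300, 1))
        y2 = np.hstack([y, y])
        R, _ = null_correlation(g, y2, seed=9)
        assert R[0, 1] == pytest.approx(1.0, abs=1e-10)

    def test_r_estimates_phenotype_correlation(self):
        # the permuted-genotype null preserves phenotype correlation: R
        # converges to corr(y) as the variant count grows
        g = simulate_genotypes(500, 2000, seed=10)
        y = np.random.default_rng(11).standard_normal((500, 8))
        R, _ = null_correlation(g, y, seed=12)
        target = np.corrcoef(y, rowvar=False)
        diff = np.abs(R - target)[~np.eye(8, dtype=bool)]
        assert np.mean(diff < 3 / np.sqrt(2000)) >= 0.9

    def test_seed_reproducibility(self):
        g = simulate_genotypes(200, 100, seed=13)
        y = np.random.default_rng(14).standard_normal((200, 4))
        R1, z1 = null_correlation(g, y, seed=15)
        R2, z2 = null_correlation(g, y, seed=15)
        np.testing.assert_array_equal(R1, R2)
        np.testing.assert_array_equal(z1, z2)

    def test_few_variants_warns(self):
        g = simulate_genotypes(200, 10, seed=16)
        y = np.random.default_rng(17).standard_normal((200, 20))
        with pytest.warns(UserWarning, match="rank-deficient"):
            null_correlation(g, y, seed=18)


class TestOmnibusStatistic:
    def test_identity_correlation_closed_form(self):
        z = np.zeros(49)
        z[0], z[1] = 1.0, 2.0
        assert omnibus_statistic(z, np.eye(49)) == pytest.approx(5.0)

    def test_two_dim_closed_form(self):
        for rho in (-0.5, 0.0, 0.3, 0.9):
            R = np.array([[1.0, rho], [rho, 1.0]])
            t = omnibus_statistic(np.array([1.0, 1.0]), R)
            assert t == pytest.approx(2.0 / (1.0 + rho), rel=1e-10)

    def test_zero_vector_gives_zero(self):
        assert omnibus_statistic(np.zeros(5), np.eye(5)) == pytest.approx(0.0)

    def test_identity_equals_sum_of_squares(self, rng):
        z = rng.standard_normal((50, 7))
        t = omnibus_statistic(z, np.eye(7))
        np.testing.assert_allclose(t, (z**2).sum(axis=1), rtol=1e-10)

    def test_nonsymmetric_rejected(self):
        R = np.array([[1.0, 0.5], [0.2, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            omnibus_statistic(np.ones(2), R)

    def test_singular_correlation_pseudo_inverted(self):
        R = np.ones((3, 3))  # rank 1
        t = omnibus_statistic(np.array([1.0, 1.0, 1.0]), R)
        assert np.isfinite(t) and t > 0


class TestGammaNull:
    def test_chi_square_moments_recovered(self):
        s = np.random.default_rng(19).chisquare(49, size=50_000)
        shape, scale, shift = fit_gamma_null(s)
        assert shape == pytest.approx(24.5, abs=0.5)
        assert scale == pytest.approx(2.0, abs=0.05)
        assert shift == 0.0

    def test_constant_statistics_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            fit_gamma_null(np.full(2000, 3.0))

    def test_median_p_near_half(self):
        s = np.random.default_rng(20).chisquare(10, size=20_000)
        params = fit_gamma_null(s)
        assert omnibus_p(np.median(s), params) == pytest.approx(0.5, abs=0.02)

    def test_p_at_zero_is_one_and_monotone(self):
        params = (5.0, 2.0, 0.0)
        assert omnibus_p(0.0, params) == pytest.approx(1.0)
        t = np.linspace(0, 50, 100)
        p = omnibus_p(t, params)
        assert np.all(np.diff(p) < 0)

    def test_percentile_self_consistency(self):
        params = (24.5, 2.0, 0.0)
        t95 = st.gamma.ppf(0.95, a=params[0], scale=params[1])
        assert omnibus_p(t95, params) == pytest.approx(0.05, abs=1e-12)

    def test_mle_refinement_close_to_moments(self):
        s = np.random.default_rng(21).gamma(5.0, 2.0, size=20_000)
        m = fit_gamma_null(s, method="moment")
        mle = fit_gamma_null(s, method="mle")
        assert m[0] == pytest.approx(mle[0], rel=0.05)


class TestThreshold:
    def test_printed_bonferroni_value(self):
        assert significance_threshold(22) == pytest.approx(2.27e-9, rel=5e-3)

    @pytest.mark.parametrize("n,expected", [(1, 5e-8), (2, 2.5e-8)])
    def test_simple_cases(self, n, expected):
        assert significance_threshold(n) == pytest.approx(expected)

    def test_invalid_count(self):
        with pytest.raises(ValueError):
            significance_threshold(0)


class TestEstimator:
    def test_power_causal_beats_null(self):
        # a variant explaining ~1% of variance of 10 columns separates from
        # the null distribution of omnibus P values
        medians_causal, medians_null = [], []
        for seed in range(20):
            g = simulate_genotypes(2000, 1000, seed=100 + seed)
            y, causal = simulate_spectrum_phenotypes(
                g, n_phenotypes=10, h2=0.01, n_causal=1, seed=200 + seed
            )
            scan = MultivariateOmnibusGWAS(seed=seed).fit(g, y)
            null_mask = np.ones(1000, bool)
            null_mask[causal] = False
            medians_causal.append(scan.pvalues_[causal[0]])
            medians_null.append(np.median(scan.pvalues_[null_mask]))
        assert np.median(medians_causal) < np.median(medians_null)

    def test_extrapolation_flag(self):
        g = simulate_genotypes(500, 1500, seed=30)
        y, _ = simulate_spectrum_phenotypes(
            g, n_phenotypes=5, h2=0.1, n_causal=1, seed=31
        )
        scan = MultivariateOmnibusGWAS(seed=32).fit(g, y)
        np.testing.assert_array_equal(
            scan.extrapolated_, scan.stats_ > scan.null_stats_.max()
        )

    def test_sklearn_params_roundtrip(self):
        from sklearn.base import clone

        est = MultivariateOmnibusGWAS(seed=5, cond_tol=1e-8)
        cloned = clone(est)
        assert cloned.get_params()["seed"] == 5
        assert cloned.get_params()["cond_tol"] == 1e-8
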