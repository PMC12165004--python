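"""Orchestration: run configuration, cohort splitting, replication rates,
and the end-to-end synthetic analysis used by the command-line interface.

The replication design mirrors a discovery/replication split of one cohort:
individuals are divided 80/20 within (age-bin x sex) strata so both sets
share the age and sex distribution; variants reaching the Bonferroni
genome-wide threshold in the discovery scan are re-tested in the
replication set, and replication rates are reported at the nominal level
and after Benjamini-Hochberg correction within each structure.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from statsmodels.stats.multitest import multipletests

from . import gwas as _gwas
from .genio import GenotypeMatrix
from .phenotype import DEFAULT_COVARIATES, InverseNormalTransformer, residualize
from .spectrum import compute_shape_spectrum

logger = logging.getLogger("shapegwas")

__all__ = [
    "RunConfig",
    "SplitPlan",
    "stratified_split",
    "standardized_mean_difference",
    "replication_rates",
    "run_synthetic_analysis",
]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (YAML-serializable)."""

    output_dir: str = "shapegwas_output"
    mesh_dir: str | None = None
    genotype_prefix: str | None = None
    covariate_path: str | None = None
    prs_path: str | None = None
    structures: list[str] = field(default_factory=lambda: ["synthetic"])
    k_eigenvalues: int = 50
    call_rate_min: float = 0.95
    maf_min: float = 0.01
    hwe_p_min: float = 1e-6
    n_structures_bonferroni: int = 22
    n_effective_scores: int = 6
    split_fraction: float = 0.8
    age_bin_years: float = 5.0
    seed: int = 0
    # synthetic-cohort knobs, used when no real inputs are given
    n_individuals: int = 200
    n_variants: int = 500
    n_causal: int = 10
    target_h2: float = 0.3

    def __post_init__(self) -> None:
        if self.k_eigenvalues < 2:
            raise ValueError("k_eigenvalues must be >= 2")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


@dataclass(frozen=True)
class SplitPlan:
    """Discovery/replication assignment with its stratification variables."""

    labels: pd.Series  # 'discovery' | 'replication', indexed by individual
    fraction: float
    age_bin_years: float
    seed: int

    @property
    def discovery_ids(self) -> pd.Index:
        return self.labels.index[self.labels == "discovery"]

    @property
    def replication_ids(self) -> pd.Index:
        return self.labels.index[self.labels == "replication"]


def standardized_mean_difference(a: np.ndarray, b: np.ndarray) -> float:
    """|mean(a) - mean(b)| over the pooled standard deviation."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2.0)
    if pooled == 0:
        return 0.0
    return float(abs(a.mean() - b.mean()) / pooled)


def stratified_split(
    covariates: pd.DataFrame,
    fraction: float = 0.8,
    seed: int = 0,
    age_bin_years: float = 5.0,
) -> SplitPlan:
    """Assign individuals to discovery/replication within age x sex strata.

    Within each (age-bin, sex) stratum a random ``fraction`` goes to the
    discovery set, keeping the two sets' age and sex distributions matched.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must be in (0, 1)")
    for col in ("age", "sex"):
        if col not in covariates.columns:
            raise ValueError(f"covariate table lacks required column {col!r}")
    rng = np.random.default_rng(seed)
    age_bin = (covariates["age"] // age_bin_years).astype(int)
    labels = pd.Series("replication", index=covariates.index, dtype=object)
    for _, stratum in covariates.groupby([age_bin, covariates["sex"]], sort=True):
        idx = stratum.index.to_numpy()
        n_disc = int(round(fraction * len(idx)))
        chosen = rng.choice(idx, size=n_disc, replace=False)
        labels.loc[chosen] = "discovery"
    return SplitPlan(
        labels=labels, fraction=fraction, age_bin_years=age_bin_years, seed=seed
    )


def replication_rates(
    discovery: pd.DataFrame,
    replication: pd.DataFrame,
    alpha: float = 0.05,
    discovery_threshold: float | None = None,
) -> dict:
    """Replication rates of discovery-significant associations.

    Both frames need columns ``variant``, ``structure`` and ``p``.  The
    discovery-significant set is defined by ``discovery_threshold`` (the
    Bonferroni genome-wide threshold by default).  Within that set, the
    nominal rate is the fraction with replication P < alpha; the FDR rate
    applies Benjamini-Hochberg to the replication P values within each
    structure first.
    """
    if discovery_threshold is None:
        discovery_threshold = _gwas.significance_threshold(22)
    for frame, name in ((discovery, "discovery"), (replication, "replication")):
        missing = {"variant", "structure", "p"} - set(frame.columns)
        if missing:
            raise ValueError(f"{name} frame lacks columns {sorted(missing)}")

    sig = discovery[discovery["p"] < discovery_threshold]
    n_sig = len(sig)
    if n_sig == 0:
        return {
            "n_discovery_significant": 0,
            "n_replicated_nominal": None,
            "n_replicated_fdr": None,
            "rate_nominal": None,
            "rate_fdr": None,
        }
    merged = sig.merge(
        replication,
        on=["variant", "structure"],
        suffixes=("_disc", "_rep"),
        how="inner",
    )
    nominal = merged["p_rep"] < alpha
    fdr_pass = pd.Series(False, index=merged.index)
    for _, grp in merged.groupby("structure"):
        adj = multipletests(grp["p_rep"].to_numpy(), method="fdr_bh")[1]
        fdr_pass.loc[grp.index] = adj < alpha
    return {
        "n_discovery_significant": n_sig,
        "n_replicated_nominal": int(nominal.sum()),
        "n_replicated_fdr": int(fdr_pass.sum()),
        "rate_nominal": float(nominal.mean()),
        "rate_fdr": float(fdr_pass.mean()),
    }


def run_synthetic_analysis(config: RunConfig) -> dict:
    """End-to-end run on a simulated cohort; writes result tables.

    Simulates a cohort of deformed spheres with additive genetic shape
    effects, computes spectra, prepares phenotypes, runs QC + the omnibus
    scan, heritability and an 80/20 replication check, and writes TSV/JSON
    outputs under ``config.output_dir``.  Returns a summary dict.
    """
    from . import heritability as _h2
    from .synthetic import ShapePopulationConfig, simulate_shape_population

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = ShapePopulationConfig(
        n_individuals=config.n_individuals,
        n_variants=config.n_variants,
        n_causal=config.n_causal,
        target_h2=config.target_h2,
        seed=config.seed,
    )
    logger.info("simulating cohort: %s", cfg)
    meshes, geno, covs, truth = simulate_shape_population(cfg)

    k = min(config.k_eigenvalues, meshes[0].n_vertices - 1)
    spectra = np.vstack(
        [compute_shape_spectrum(m, k=k, validate=False).normalized for m in meshes]
    )
    logger.info("spectra computed: %s individuals x %s eigenvalues", *spectra.shape)

    cov_block = covs[list(DEFAULT_COVARIATES)]
    resid = residualize(spectra, cov_block)
    pheno = InverseNormalTransformer().fit_transform(resid)

    geno_qc, report = _gwas.genotype_qc(
        geno, config.call_rate_min, config.maf_min, config.hwe_p_min
    )
    logger.info("QC: %s -> %s variants", report.n_input, report.n_retained)

    scan = _gwas.MultivariateOmnibusGWAS(seed=config.seed).fit(geno_qc, pheno)
    results = scan.results_frame(geno_qc.variants)
    results.to_csv(out / "gwas_results.tsv", sep="\t", index=False)

    grm = _h2.compute_grm(geno_qc)
    h2s, ses = zip(
        *[_h2.he_regression(grm, pheno[:, m]) for m in range(pheno.shape[1])]
    )
    # weights use the residualized (pre-INT) phenotypic variances
    rep = _h2.multidimensional_h2(h2s, ses, np.var(resid, axis=0))
    summary = {
        "n_individuals": cfg.n_individuals,
        "n_variants_post_qc": report.n_retained,
        "bonferroni_threshold": _gwas.significance_threshold(
            config.n_structures_bonferroni
        ),
        "min_p": float(results["p"].min()),
        "h2_aggregate": rep.h2,
        "h2_se": rep.se,
        "h2_wald_p": rep.pvalue_boundary,
        "causal_variants": truth.causal_variant_ids,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary
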