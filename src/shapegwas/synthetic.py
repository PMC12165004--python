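"""Synthetic shape-genetics cohorts.

Real cohorts of segmented brain surfaces with genotypes cannot be
redistributed, so every downstream stage is exercised on simulated data with
the statistical structure the analysis assumes:

* closed surfaces: icospheres deformed radially along real spherical
  harmonics with l >= 2 (l = 0 is pure scaling and l = 1 approximates
  translation, so both are excluded — the deformations change shape, not
  size or position);
* genotypes: independent biallelic variants in Hardy-Weinberg proportions
  with configurable minor-allele frequency;
* additive genetics: latent deformation coefficients are linear in
  standardized causal dosages plus Gaussian environmental noise, scaled so
  the genetic variance fraction hits a target heritability;
* covariates (age, sex, genetic PCs, mesh-quality index) independent of
  genotype by default, with an optional confounding switch;
* scalar polygenic scores with a prescribed canonical correlation to the
  spectrum matrix.

Every generator is a pure function of its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import trimesh as _trimesh
from scipy.special import sph_harm_y

from .genio import GenotypeMatrix
from .mesh import TriangleMesh, mesh_area, mesh_volume

__all__ = [
    "ShapePopulationConfig",
    "SyntheticTruth",
    "make_icosphere",
    "harmonic_modes",
    "real_spherical_harmonic",
    "make_deformed_sphere",
    "simulate_genotypes",
    "simulate_shape_population",
    "simulate_spectrum_phenotypes",
    "simulate_prs",
]


@dataclass(frozen=True)
class ShapePopulationConfig:
    """Configuration of a synthetic shape-genetics cohort.

    ``target_h2`` is the variance fraction of the genetic term in each
    latent deformation coefficient; ``noise_sd`` multiplies the
    environmental part (1 keeps the realized fraction at ``target_h2``; 0
    makes shape a deterministic function of genotype); and
    ``deformation_scale`` is the overall amplitude of the harmonic
    displacements relative to ``base_radius``.
    """

    n_individuals: int = 200
    n_variants: int = 500
    n_causal: int = 10
    maf_range: tuple[float, float] = (0.05, 0.5)
    target_h2: float = 0.3
    n_harmonics: int = 5
    base_radius: float = 10.0
    noise_sd: float = 1.0
    deformation_scale: float = 0.03
    mesh_subdivisions: int = 2
    confounded: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_causal > self.n_variants:
            raise ValueError("n_causal must not exceed n_variants")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie within (0, 0.5], got {self.maf_range}")
        if not (0.0 <= self.target_h2 < 1.0):
            raise ValueError("target_h2 must be in [0, 1)")
        if self.target_h2 > 0 and self.n_causal == 0:
            raise ValueError("target_h2 > 0 requires at least one causal variant")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of a simulated cohort, for parameter-recovery tests."""

    causal_variant_ids: list[str]
    effect_sizes: np.ndarray  # (n_harmonics, n_causal)
    realized_h2: np.ndarray  # per latent mode, in [0, 1]
    latent_coefficients: np.ndarray  # (n_individuals, n_harmonics)


def make_icosphere(radius: float = 1.0, subdivisions: int = 3) -> TriangleMesh:
    """Closed icosphere: subdivided icosahedron with 20*4^s faces."""
    if subdivisions < 0:
        raise ValueError("subdivisions must be >= 0")
    tm = _trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    mesh = TriangleMesh(np.asarray(tm.vertices), np.asarray(tm.faces))
    mesh.validate()
    return mesh


def harmonic_modes(n_modes: int, l_min: int = 2) -> list[tuple[int, int]]:
    """First ``n_modes`` real spherical-harmonic (l, m) pairs with l >= l_min."""
    modes: list[tuple[int, int]] = []
    l = l_min
    while len(modes) < n_modes:
        for m in range(-l, l + 1):
            modes.append((l, m))
            if len(modes) == n_modes:
                break
        l += 1
    return modes


def real_spherical_harmonic(
    l: int, m: int, theta: np.ndarray, phi: np.ndarray
) -> np.ndarray:
    """Real-valued Y_lm at polar angle theta and azimuth phi."""
    if abs(m) > l:
        raise ValueError(f"|m| <= l required, got l={l}, m={m}")
    if m == 0:
        return np.real(sph_harm_y(l, 0, theta, phi))
    y = sph_harm_y(l, abs(m), theta, phi)
    if m > 0:
        return np.sqrt(2.0) * (-1.0) ** m * np.real(y)
    return np.sqrt(2.0) * (-1.0) ** m * np.imag(y)


def make_deformed_sphere(
    base: TriangleMesh,
    harmonic_coeffs: Mapping[tuple[int, int], float] | Sequence[float],
) -> TriangleMesh:
    """Displace each vertex radially by a real spherical-harmonic field.

    ``harmonic_coeffs`` is either a mapping {(l, m): c} with l >= 2 or a flat
    sequence interpreted along `harmonic_modes(len(coeffs))`.  Coefficients
    large enough to push the radius near zero (self-intersection) are
    rejected.
    """
    if not isinstance(harmonic_coeffs, Mapping):
        seq = np.asarray(harmonic_coeffs, dtype=np.float64)
        harmonic_coeffs = dict(zip(harmonic_modes(len(seq)), seq))
    for (l, m) in harmonic_coeffs:
        if l < 2:
            raise ValueError(
                f"harmonic degree l={l} < 2: l=0 is pure scaling and l=1 "
                "approximates translation; both are excluded"
            )

    v = base.vertices
    r = np.linalg.norm(v, axis=1)
    if np.any(r <= 0):
        raise ValueError("base mesh has a vertex at the origin")
    theta = np.arccos(np.clip(v[:, 2] / r, -1.0, 1.0))
    phi = np.arctan2(v[:, 1], v[:, 0])

    disp = np.zeros_like(r)
    for (l, m), c in harmonic_coeffs.items():
        if c != 0.0:
            disp += c * real_spherical_harmonic(l, m, theta, phi)

    r_new = r + disp
    if np.any(r_new <= 0.1 * r):
        worst = float(np.min(r_new / r))
        raise ValueError(
            "harmonic displacement too large: minimum radius ratio "
            f"{worst:.3f} <= 0.1, the deformed surface would self-intersect; "
            "reduce the coefficient magnitudes"
        )
    vertices = v * (r_new / r)[:, None]
    return TriangleMesh(vertices, base.faces.copy())


def simulate_genotypes(
    n: int,
    p: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int | np.random.Generator = 0,
    missing_rate: float = 0.0,
) -> GenotypeMatrix:
    """Independent biallelic dosages: per-variant Binomial(2, f), f ~ U(maf_range)."""
    if n < 1 or p < 1:
        raise ValueError("n and p must be >= 1")
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(maf_range[0], maf_range[1], size=p)
    dosage = rng.binomial(2, freqs[None, :], size=(n, p)).astype(np.float64)
    if missing_rate > 0:
        mask = rng.random((n, p)) < missing_rate
        dosage[mask] = np.nan
    variants = pd.DataFrame(
        {
            "chrom": np.repeat("1", p),
            "pos": np.arange(1, p + 1) * 1000,
            "id": [f"snp{i}" for i in range(p)],
            "ref": np.repeat("A", p),
            "alt": np.repeat("G", p),
        }
    )
    return GenotypeMatrix(dosage=dosage, variants=variants)


def _standardize_columns(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("monomorphic variant among causal set; increase MAF or n")
    return (x - mu) / sd


def simulate_shape_population(
    config: ShapePopulationConfig,
) -> tuple[list[TriangleMesh], GenotypeMatrix, pd.DataFrame, SyntheticTruth]:
    """Simulate a cohort of deformed spheres with additive genetic shape effects.

    For individual j and harmonic mode k, the latent deformation coefficient is

        d_jk = sqrt(h2) * g_jk / sd(g_k) + noise_sd * sqrt(1 - h2) * e_jk

    with g_jk the sum of standardized causal dosages weighted by the mode's
    effect sizes and e ~ N(0, 1), then scaled by
    ``deformation_scale * base_radius`` so deformations stay in the
    small-displacement regime.  With ``noise_sd = 0`` the meshes are a
    deterministic function of the causal genotypes.  Returns the meshes,
    genotypes, a covariate table and the simulation ground truth.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    geno = simulate_genotypes(
        cfg.n_individuals, cfg.n_variants, cfg.maf_range, seed=rng
    )
    causal_idx = np.sort(
        rng.choice(cfg.n_variants, size=cfg.n_causal, replace=False)
    )
    causal_ids = [geno.variants["id"].iloc[i] for i in causal_idx]

    n, k = cfg.n_individuals, cfg.n_harmonics
    effects = (
        rng.standard_normal((k, cfg.n_causal))
        if cfg.n_causal
        else np.zeros((k, 0))
    )
    noise = rng.standard_normal((n, k))

    h2 = cfg.target_h2
    if h2 > 0:
        z = _standardize_columns(geno.dosage[:, causal_idx])
        genetic = z @ effects.T  # (n, k)
        g_sd = genetic.std(axis=0)
        if np.any(g_sd == 0):
            raise ValueError("degenerate genetic values; increase n or MAF")
        latent = (
            np.sqrt(h2) * genetic / g_sd
            + cfg.noise_sd * np.sqrt(1.0 - h2) * noise
        )
    else:
        genetic = np.zeros((n, k))
        latent = cfg.noise_sd * noise

    if cfg.confounded:
        # age drives shape directly, to exercise residualization
        age_effect = rng.standard_normal(k)
    else:
        age_effect = np.zeros(k)

    age = rng.uniform(45.0, 82.0, size=n)
    age_std = (age - age.mean()) / age.std()
    latent = latent + age_std[:, None] * age_effect * 0.5

    var_total = latent.var(axis=0)
    if h2 == 0:
        realized_h2 = np.zeros(k)
    else:
        genetic_part = np.sqrt(h2) * genetic / genetic.std(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            realized_h2 = np.where(
                var_total > 0, genetic_part.var(axis=0) / var_total, 0.0
            )

    scale = cfg.deformation_scale * cfg.base_radius
    base = make_icosphere(cfg.base_radius, cfg.mesh_subdivisions)
    modes = harmonic_modes(k)
    meshes = [
        make_deformed_sphere(base, dict(zip(modes, scale * latent[j])))
        for j in range(n)
    ]

    sex = rng.integers(0, 2, size=n)
    pcs = rng.standard_normal((n, 10))
    quality = rng.poisson(30, size=n).astype(int)
    area = np.array([mesh_area(m) for m in meshes])
    volume = np.array([mesh_volume(m) for m in meshes])
    covs = pd.DataFrame(
        {
            "individual_id": geno.sample_ids,
            "age": age,
            "age2": age**2,
            "sex": sex,
            **{f"pc{i + 1}": pcs[:, i] for i in range(10)},
            "quality_index": quality,
            "surface_area": area,
            "total_volume": volume * rng.uniform(95.0, 105.0, size=n),
        }
    ).set_index("individual_id")

    truth = SyntheticTruth(
        causal_variant_ids=causal_ids,
        effect_sizes=effects,
        realized_h2=np.clip(realized_h2, 0.0, 1.0),
        latent_coefficients=latent,
    )
    return meshes, geno, covs, truth


def simulate_spectrum_phenotypes(
    genotypes: GenotypeMatrix,
    n_phenotypes: int = 49,
    h2: float = 0.0,
    n_causal: int = 0,
    cross_corr: float = 0.6,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Phenotype-level shortcut: simulate a correlated multi-trait matrix.

    Bypasses the mesh pipeline for large-n association calibration.  The
    environmental part has equicorrelation ``cross_corr`` across traits
    (eigenvalue phenotypes are strongly correlated in practice); the genetic
    part assigns each causal variant an effect on every trait so each trait
    has heritability ``h2``.  Returns (phenotype matrix, causal indices).
    """
    rng = np.random.default_rng(seed)
    n, p = genotypes.dosage.shape
    if not (0.0 <= cross_corr < 1.0):
        raise ValueError("cross_corr must be in [0, 1)")
    shared = rng.standard_normal((n, 1))
    unique = rng.standard_normal((n, n_phenotypes))
    env = np.sqrt(cross_corr) * shared + np.sqrt(1.0 - cross_corr) * unique
    if h2 > 0:
        if n_causal < 1:
            raise ValueError("h2 > 0 requires n_causal >= 1")
        causal = np.sort(rng.choice(p, size=n_causal, replace=False))
        z = _standardize_columns(genotypes.dosage[:, causal])
        w = rng.standard_normal((n_causal, n_phenotypes))
        g = z @ w
        g = g / g.std(axis=0)
        y = np.sqrt(h2) * g + np.sqrt(1.0 - h2) * env / env.std(axis=0)
    else:
        causal = np.array([], dtype=int)
        y = env
    return y, causal


def simulate_prs(
    spectrum_matrix: np.ndarray,
    target_canonical_r: float,
    seed: int | np.random.Generator = 0,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Scalar polygenic score with a prescribed canonical correlation.

    PRS = S @ w + noise, with the noise variance chosen so the population
    canonical correlation between the score and the spectrum matrix ``S``
    equals ``target_canonical_r``.  ``weights`` defaults to i.i.d. normal
    draws; pass an all-positive (or all-negative) vector to construct
    common-direction loading patterns.
    """
    if not (0.0 <= target_canonical_r <= 1.0):
        raise ValueError("target_canonical_r must be in [0, 1]")
    rng = np.random.default_rng(seed)
    s = np.asarray(spectrum_matrix, dtype=np.float64)
    n, q = s.shape
    if weights is None:
        weights = rng.standard_normal(q)
    signal = s @ weights
    sig_var = signal.var()
    if target_canonical_r == 0.0:
        return rng.standard_normal(n)
    if sig_var <= 1e-24 * (1.0 + np.abs(signal).max() ** 2):
        raise ValueError(
            "spectrum projection has zero variance; cannot hit a nonzero "
            "canonical correlation"
        )
    if target_canonical_r == 1.0:
        return signal.copy()
    noise_var = sig_var * (1.0 / target_canonical_r**2 - 1.0)
    return signal + rng.standard_normal(n) * np.sqrt(noise_var)
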