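# Methods

This note documents the models, numerical choices and simulation design
behind `shapegwas`, in the spirit of a statistical software appendix: what
is computed, under which assumptions, and what the synthetic experiments do
and do not demonstrate.

## Spectral shape descriptor

A closed, oriented, connected 2-manifold triangle mesh is required. The
Laplace-Beltrami eigenproblem Δf = −λf is discretized with linear (P1)
Lagrange elements: the stiffness matrix uses the cotangent formula (each
triangle contributes cot(α)/2 on the edge opposite its angle α; row sums
are zero, so the constant vector spans the nullspace), and the mass matrix
is the **consistent** linear-FEM form (per triangle of area s: s/6 diagonal,
s/12 off-diagonal). A row-lumped mass matrix is available behind a flag for
comparison; consistent mass is the default because it is the standard
choice for spectral shape descriptors and converges faster for smooth
surfaces.

The generalized symmetric problem A f = λ B f is solved by ARPACK
shift-invert. Two numerical choices matter:

* **Shift.** σ = −10⁻³ · tr(A)/tr(B), i.e. a small negative shift scaled to
  the spectrum's magnitude, so the singular zero mode is handled at any
  mesh scale (eigenvalues scale as 1/s² under uniform scaling by s).
* **Tolerance and start vector.** The convergence tolerance is machine
  precision (`tol=0`) and the start vector is a fixed-seed generic random
  vector. Both were forced by degeneracy: sphere-like spectra carry
  eigenvalue clusters of multiplicity 2l+1, a loose tolerance can terminate
  with a cluster only partially resolved, and a structured start vector
  (e.g. the constant vector) is exactly orthogonal to whole eigenspaces on
  symmetric meshes, which makes ARPACK skip them. The fixed seed keeps runs
  bit-reproducible.

The first eigenvalue of a closed connected surface is 0; it is identified
by value and dropped, with a hard failure if |λ₁| ≥ 10⁻⁸ λ₂ (a
disconnected mesh has a multiplicity-2 zero mode and must not pass
silently; the mesh validator also rejects disconnection outright). Volume
is the signed-tetrahedron sum (positive for outward orientation, negative
volume is an error pointing at the winding), area the triangle-area sum.
The retained phenotype is λ̄ₘ = (1/m) λₘ V^(2/3), m = 2…50: V^(2/3) cancels
the 1/s² eigenvalue scaling (exact scale invariance, verified to 10⁻⁸
relative), and the 1/m reweighting damps the high modes, whose FEM error
and biological noise are largest.

Galerkin theory makes the P1 eigenvalues upper bounds that decrease toward
the analytic values under refinement; the test suite checks this
monotonicity on icospheres (subdivisions 2→5) against the closed form
l(l+1) with multiplicities 3 and 5. At subdivision 4 (2562 vertices) the
l=1 triplet is within 0.15 % and the l=2 quintet within 0.3 %.

## Phenotype preparation

Each λ̄ₘ is regressed on the covariate block (age, age², sex, 10 genetic
PCs, a mesh-quality index, per-structure surface area, total volume) and
replaced by **intercept + residuals** — the columns stay on their original
location scale, and their sample correlation with every covariate is
exactly zero. Note the output mean is the fitted intercept, which equals
the raw column mean only when covariates are centered. The rank-based
inverse-normal transform uses the Blom offset, Φ⁻¹((r − 3/8)/(n + 1/4)),
with average ranks for ties; a column whose spread is at rounding-noise
level (e.g. the residual of a score that *is* a covariate) is treated as
constant and rejected. The pipeline order is fixed: normalize →
residualize → INT; covariates never re-enter the association scan.

The mesh-quality index is a declared stand-in covariate: real pipelines use
an MRI surface-defect count (Euler number) as an image-quality covariate,
which has no analogue for synthetic meshes; the column exists so the design
matrix has the full production shape.

## Multivariate omnibus association

Per variant, z = r·√((n−2)/(1−r²)) per phenotype column (|r| clipped at
1−10⁻¹²). The null correlation matrix R is estimated from a scan of
once-permuted genotypes: **one** global permutation of individuals reused
for every variant (a per-variant permutation is available behind a flag).
R is inverted by eigendecomposition with components below 10⁻¹⁰ of the
largest eigenvalue discarded — the phenotype correlations among eigenvalue
traits are strong (often > 0.9), so R is routinely near-singular and the
pseudo-inverse path is the normal path, not an edge case.

The gamma null is moment-matched to all permuted statistics (shape =
mean²/var, scale = var/mean, location 0); MLE refinement and tail-only
fitting are exposed but not default. Observed statistics exceeding the
permuted maximum are flagged as extrapolated. Calibration under the global
null (1000 individuals × 10,000 variants × 49 correlated traits): fraction
of P < 0.05 within 0.05 ± 0.01 and QQ slope within 1 ± 0.05.

Genotype QC before the scan: call rate ≥ 0.95, MAF ≥ 0.01, Hardy-Weinberg
exact test P ≥ 10⁻⁶. The HWE test is the conditional exact enumeration
over heterozygote counts with the mid-P adjustment by default (half weight
on the observed outcome), which reduces the conservatism that otherwise
favours variants with missing calls.

## SNP heritability

GRM = ZZᵀ/p from column-standardized dosages. Haseman-Elston regression of
yⱼyₖ on GRMⱼₖ over all pairs j<k; the slope is assembled from O(n²) matrix
identities rather than an explicit pair enumeration, and the SE is a
delete-block jackknife over 100 contiguous individual blocks with the same
identities applied per block (so the full computation stays O(n²)). Point
estimates are deliberately **not** clamped to [0,1] — clamping before
aggregation would bias the variance-weighted sum — and are clamped only in
the human-readable report, with a flag.

Aggregation: h² = Σ γₘ h²ₘ, γₘ = σ²ₘ/Σσ²ₖ computed from the residualized
(pre-INT) phenotypic variances; SE by Bienaymé's identity assuming
independent univariate errors. The boundary Wald test uses the ½χ²₀ + ½χ²₁
mixture (P = 0.5 for an estimate of exactly 0; a negative estimate can
never reject). The difference test against an external estimate drops the
covariance cross-term by default (reference-dominated approximation); the
correlation is an optional parameter defaulting to 0.

This estimator is an exact-pairs Haseman-Elston regression: the same
estimand as the randomized biobank-scale estimators, computed exactly at
the cohort sizes this package targets.

## PRS canonical correlation

With a scalar score, CCA degenerates to multiple correlation: the canonical
variable is the OLS fit of the prepared score on the 49 columns, r = √R²,
and the parametric P is the overall regression F test — this equivalence is
enforced against an independent regression implementation to 10⁻¹⁰.
Score preparation residualizes on age, age², sex, 10 PCs and total volume
only (no surface area, no quality index), then applies INT. The canonical
variable's sign is fixed to correlate positively with the score; loadings
(per-eigenvalue correlations with the canonical variable) are computed
after this convention. Zero loadings count toward neither direction in the
≥90 % common-direction rule.

The raw sample canonical correlation carries an upward dimension bias
(null expectation ≈ √(q/n) ≈ 0.10 at n = 5000, q = 49), which matters
precisely at the weak effect sizes of interest (r ≈ 0.07). `SpectrumCCA`
therefore also reports `r_adjusted_`, the adjusted-R²-based correction,
which is the consistent estimate of a weak population correlation; recovery
tests assert the adjusted value at weak targets and the raw value at strong
ones. The empirical permutation P uses the add-one estimator
(1 + #{r_perm ≥ r_obs})/(1 + n_perm) with a QR-based per-permutation cost
of one matrix-vector product.

Multiple testing over the structures × scores grid: Benjamini-Hochberg
within each score's column, then multiplication by the number of effective
scores (an input, not estimated), capped at 1; the flat Bonferroni over all
cells is emitted alongside for comparison.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, not
anatomical realism:

* **Shapes.** Icospheres (radius 10 mm, subdivision 2 by default = 162
  vertices) deformed radially along real spherical harmonics with l ≥ 2
  (l = 0 is pure scaling, l = 1 approximates translation; both are excluded
  so deformations change shape only). Displacements large enough to drive
  the radius near zero are rejected as self-intersecting.
* **Genetics.** Independent biallelic variants, per-variant Binomial(2, f)
  with f uniform in the configured MAF range — Hardy-Weinberg by
  construction, no linkage disequilibrium. Latent deformation coefficients
  are d = √h²·ĝ + noise_sd·√(1−h²)·e with ĝ the standardized weighted sum
  of causal dosages; `noise_sd` = 1 realizes the target heritability,
  `noise_sd` = 0 makes shape a deterministic function of genotype (the
  degenerate case used to test the mesh→spectrum map). The overall
  deformation amplitude is `deformation_scale` × radius (default 0.03,
  keeping the small-displacement regime where the latent-coefficient
  heritability transfers to the eigenvalue phenotypes approximately
  linearly).
* **Covariates** are independent of genotype by default; a confounding
  switch routes an age effect into the deformation coefficients to
  exercise residualization.
* **Phenotype-level shortcut.** Large-n calibration experiments bypass the
  mesh pipeline and simulate the 49-trait matrix directly with an
  equicorrelated environmental component (default cross-trait correlation
  0.6, mimicking the strong dependence of eigenvalue traits) plus an
  additive genetic part of configurable per-trait h².
* **Scores.** PRS = Sw + ε with the noise variance solved from the target
  population canonical correlation; all-positive or all-negative weight
  vectors construct common-direction loading patterns.

What passing tests show: the estimators recover the parameters of this
generative family at the stated sample sizes, and the test statistics are
calibrated under its null. What they do not show: robustness to linkage
disequilibrium, population structure, segmentation artifacts, non-radial
or non-harmonic shape variation, or covariate distributions of real
cohorts — none of which the generator produces.

## Problem sizes and determinism

Simulation-backed checks run at deliberately chosen desk scales: omnibus
calibration at n = 1000 × 10,000 variants; heritability recovery at
n = 2000, p = 1000, 20 replicates per target h² ∈ {0, 0.15, 0.3} with a
6-trait phenotype block (the aggregation formulas are
dimension-independent; six traits exercise them fully at a fraction of the
49-trait cost); CCA recovery at n = 5000, q = 49. Every stochastic
component takes an explicit seed, generators are pure functions of their
seeds, and the end-to-end pipeline is byte-reproducible for a fixed
configuration.

## Known limitations

* No open-boundary (Neumann/Dirichlet) spectra; meshes must be closed,
  oriented and connected — validation rejects, it does not repair.
* The FEM degree/mass treatment is one defensible discretization; numeric
  agreement with other spectral-shape implementations is approximate, not
  exact.
* Exact-pairs HE regression is O(n²) memory and time in individuals;
  cohorts beyond ~50k individuals need a randomized estimator instead.
* The gamma tail is an extrapolation below the permutation resolution;
  extreme P values inherit its parametric form (flagged per variant).
* Replication-rate experiments inherit winner's-curse effects from the
  discovery threshold; rates are reported, not corrected.
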