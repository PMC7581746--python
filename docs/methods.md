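# Methods

This note documents the statistical models, the synthetic-data generator, the
numerical choices and the known limitations of `tracheidgwas`.

## Per-ring mixed model and trajectory refinement

For one trait at one cambial age the observation on tree *l* of family *k* in
block *j* of site *i* is modelled as

    Y_ijkl = u + S_i + B_j(i) + F_k + SF_ik + e_ijkl,

with fixed general mean, site and block-within-site effects, and independent
random effects F_k ~ N(0, σ²_F), SF_ik ~ N(0, σ²_SF), e ~ N(0, σ²_e). Under
the open-pollinated half-sib interpretation σ²_F estimates a quarter of the
additive genetic variance. There is no within-family genetic term: the family
BLUP is the finest genetic resolution the model offers, and each tree inherits
its family's refined curve.

**Estimation.** Variance components are estimated by EM-REML on Henderson's
mixed-model equations. Per iteration the MME coefficient matrix
`M = [[X'X, X'Z], [Z'X, Z'Z + diag(σ²_e/σ²_F, σ²_e/σ²_SF)]]` is factorised
(Cholesky); the EM updates are the classical
`σ²_i ← (ûᵢ'ûᵢ + σ²_e·tr(M⁻¹)_ii)/q_i` and `σ²_e ← (y'y − sol'W'y)/(n − p)`.
The REML log-likelihood is evaluated from MME quantities via
`−2ℓ = (n−p−q)·log σ²_e + log|G| + log|M| + SSR/σ²_e` (validated against the
direct dense-V formula in the test suite). Convergence: relative
log-likelihood change < 1e-6; iteration cap 2000 — EM contracts slowly when a
component approaches zero, and at desk scale the extra iterations cost
milliseconds; non-convergence is flagged, never raised. Negative-variance
iterates are truncated at a tiny positive floor and reported as 0.

**Identifiability.** Treatment coding (first site/block as reference) keeps
the fixed design full-rank for any properly nested block structure; a block
label observed in more than one site is rejected with the offending labels
named. Single-site data drop the SF term, which would otherwise be perfectly
confounded with the family term.

**Refined trajectories.** The refined value for family *k* at age *t* is
`EBV_k(t) + m̂(t)`, where `m̂(t)` is the fixed-effects-adjusted population
mean — the prediction at the reference site and block (the intercept under
treatment coding). Adjusted rather than raw means are used so that refined
trajectories are invariant to constant shifts applied to non-reference sites
(tested); the choice of reference level shifts all families equally and is
therefore immaterial for association.

## Spline latent traits

Trajectories are summarised by the two-knot truncated-linear spline
`y(t) = β0 + β1 t + β2 (t−K1)+ + β3 (t−K2)+`, fitted by OLS. Two knots are
the default trajectory family for tracheid dimension and coarseness traits.
One knot pair per trait is selected by minimising the total SSE over all
trajectories on an integer grid (ties break to the smaller K1, then K2); the
per-family (or per-tree) coefficient estimates are the latent traits. A fit
with no observations beyond K2 is rank-deficient: the empty segment is
dropped, β3 reported as NaN and the fit flagged.

Association uses family means of the latent traits by default (the family is
the genotyped unit a half-sib design informs on); per-tree mode is available
(`run_pipeline(..., family_mean=False)`).

## MFA latents

MFA trajectories decay from ~30° at the pith toward a 10–12° plateau. The
package fits the monotone decay `m(t) = c + (v0 − c)·e^{−r(t−t0)}` (bounded
least squares, `c, v0 ∈ [0°, 90°]`, `r ∈ [1e-4, 10]`). This exponential
family is a deliberate, swappable surrogate: the "central-peak" regression
family used in earlier SilviScan work is not parametrically specified in the
sources available here, and any monotone decay with a plateau supports the
same latent construction. Outliers are screened at 4 robust SDs
(1.4826·MAD) of the residuals from an initial fit, then the curve is refitted
(screening raw values would amputate the legitimately high pith region).

The transition age `MFA_TA` is the first age where the fitted curve is ≤ 20°,
linearly interpolated between the bracketing ring ages; `MFA_CORE`/`MFA_OUTER`
are the means of observed MFA at ages ≤ / > `MFA_TA`. The 20° threshold marks
the juvenile core; a tree whose fitted curve never reaches it is flagged
(`crossed=False`) and excluded from association, mirroring how such trees
would otherwise have to be discarded. A ring belongs to the core iff its age
is ≤ the (fractional) transition age — the simplest membership rule; the
boundary ring's assignment changes only the core/outer means, not `MFA_TA`.

## Stability-selection LASSO

The association model per latent trait is the L1-penalised regression of the
latent on all standardised marker dosages with an unpenalised intercept and
covariate block (top-5 genotype PCs by default, deterministic sign
convention). The solver is cyclic coordinate descent with soft-thresholding;
covariates are projected out first (Frisch–Waugh), which is algebraically
equivalent to keeping them unpenalised in the descent and considerably
faster. Convergence: max standardised coefficient change < 1e-7 per sweep.
KKT conditions are verified in the test suite against an independent
reference implementation.

**Subsampling and λ rule.** 100 subsamples of size ⌊n/2⌋ without replacement;
the sources behind this design do not state their λ rule, so the package's
default is declared here: per subsample, λ is calibrated (warm-started
descending path, factor 0.9, with bisection refinement) so the active set
lands on `q_target` markers, with `q_target` the largest q for which the
stability bound `E[V] ≤ q²/((2π−1)p)` stays ≤ 1 at π = 0.52 —
`q_target = ⌊√((2π−1)·p)⌋`. This makes the printed threshold and the bound
mutually consistent at any p: q = 84 at the study's p = 178,101, q = 8 at the
desk scale p = 2,000. A marginal-correlation screen (top `max(20q, 200)`
markers) keeps the subsample fits cheap; a global KKT check guards against
the screen ever dropping a marker the full LASSO would select.

**Power at desk scale.** The q_target consistency has a visible cost in
small-p simulations: with 10 equal-effect QTLs and only q = 8 active slots
per subsample, the average SSP of a true QTL cannot exceed q/10 = 0.8, and
dataset-level variation in realised effect size leaves 2–4 of 10 QTLs below
the 0.52 threshold at standardised effect 0.3 and n = 500 (measured power
≈ 0.67–0.69 across replicate datasets). This is a property of the calibrated
operating point, not of the optimiser.

## Effect characterisation

**Adaptive-LASSO PVE.** The plain LASSO's single λ over-shrinks large
effects and hence understates PVE. On the selected set the package computes
initial OLS estimates (ridge with penalty 1e-3·n if ill-conditioned), weights
`w_j = 1/|β̂_init,j|^γ` (γ = 1, capped at 1e8), and solves the weighted-L1
problem along a 50-point geometric λ path with 5-fold cross-validation.
`PVE_j = Var(x_j α̂_j)/Var(y) × 100` over the analysis individuals — the
standard variance-ratio definition, adopted here as the package's own choice.

**Gene action.** For one marker, `2a = |G_BB − G_bb|` and
`d = G_Bb − ½(G_BB + G_bb)` from the genotype-class means; d is invariant
under swapping the homozygote labels, so pairing it with `a = 2a/2 ≥ 0`
fixes the orientation. Mode of gene action from |d/a|: additive ≤ 0.50,
partial-to-full dominant in (0.50, 1.25), over-dominant ≥ 1.25. The source
bands are open intervals, leaving the boundary points unassigned; boundaries
here resolve to the lower-named class. When association runs on family
means, genotype classes are populated by the individual trees (each carrying
its family latent), since family-mean dosages almost never round to a
homozygote class. The Kruskal–Wallis statistic uses the tie-corrected H with
a χ² approximation on (classes − 1) df; all-tied data return H = 0, p = 1.

## Synthetic-data generator

The generator emulates the study design the pipeline assumes; its defaults
are the package's reference conditions.

| parameter | default | rationale |
|---|---|---|
| families × trees | 200 × 12 | desk-scale version of ~500 families; 6 trees per family per site, two sites |
| sites / blocks | 2 / 4 | two progeny trials, randomized blocks |
| markers, MAF | 2000, U(0.05, 0.5) | post-filter exome panel at desk scale |
| QTLs | 10 × a = 0.3 on β0 | sparse architecture on a latent trait |
| σ²_F, σ²_SF, σ²_e | 0.25, 0.10, 1.00 | family-mean h² ≈ 0.8, family/total ≈ 0.19 — upper range of tracheid-trait heritabilities |
| rings, knots | 15, (4, 9) | typical juvenile-wood core lengths |
| site effects, block SD | (0, 2), 0.5 | sizeable fixed effects for the refinement stage to remove |
| missingness | 0.02 | MCAR, below the 0.20 filter |
| MFA | 30° → 11° plateau, rate 0.35 | ~20° at age ~3–4, stabilising near age 10 |

Genotypes: per marker an allele frequency is drawn, each family's mother is
Hardy–Weinberg, offspring get one random maternal allele and one pollen
allele drawn i.i.d. from the population frequency (open pollination). Codes
0/1/2 = AA/AB/BB; missingness is completely at random; a two-subpopulation
allele-frequency shift can be enabled solely to exercise PC correction.

Phenotypes: per-tree latents are population means + QTL contributions
`a(x−1) + d·1[x=1]` + a family deviation N(0, σ²_F) on β0; ring values add
site, block, site×family, residual and measurement noise. Because the family
deviation enters only the intercept, the per-ring variance decomposition is
exactly (σ²_F, σ²_SF, σ²_e) at every age — the moment-oracle tests depend on
this. An optional `beta1_family_sd` (default 0) adds between-family slope
variation when slope recovery is under study.

**What the generator does not emulate:** linkage disequilibrium between
markers, pedigree structure beyond half-sib, spatial field trends,
age-dependent residual variance, genotype-by-environment interaction at the
QTL level, and ascertainment of the exome panel. Passing tests therefore
demonstrate the pipeline's correctness under its own model assumptions, not
robustness to these real-data features.

**Recovery scenarios.** Variance-component recovery runs at the default
conditions (20 replicates; mean REML estimates within 15%). Latent-trait
recovery correlation is scenario-dependent: under the defaults the
site×family deviation (constant across a family's rings, var σ²_SF/2 after
two-site averaging) bounds family-level β0 recovery near r ≈ 0.8 regardless
of replication, so the r > 0.9 recovery demonstration uses a documented
low-measurement-noise scenario — σ²_SF = 0.02, σ²_e = 0.30, measurement
SD 0.1, between-family slope SD 0.15 (≈ 10% CV of the mean slope), 150
families — representative of trait/instrument combinations with small
non-genetic trajectory noise.

## Numerical choices

- EM-REML: tolerance 1e-6 (relative log-likelihood), cap 2000 iterations,
  variance floor 1e-10·Var(y); initial values (0.3, 0.1, 0.6)·Var(y).
- Coordinate descent: tolerance 1e-7, cap 10,000 sweeps; columns with SD
  ≤ 1e-12 after covariate projection are dropped from the penalised fit.
- Knot grid SSE ties: 1e-12 relative tolerance, first (smallest) pair wins.
- MFA decay fit: `scipy.optimize.curve_fit` with bounds; a failed fit flags
  the tree rather than raising.
- Genotype PCs: exact SVD of the centered dosage matrix; component signs
  fixed by the largest-|loading| convention.
- Problem sizes in tests and the acceptance script (p = 2,000 markers,
  n = 200–500, 50 null replicates, 20 REML replicates, 10 power replicates)
  are the package's desk-scale reference conditions; all scale linearly.

## Limitations

- Only the univariate joint-site mixed model is implemented; multivariate
  per-trait model selection (e.g. by AIC) is out of scope.
- Family EBVs are the genetic resolution; per-tree association reuses the
  family curve and adds no within-family genetic information.
- Mean imputation of missing genotypes is simple and replaceable; it is
  adequate for LASSO on standardised dosages at low missingness.
- The MFA decay family is a surrogate; transition ages from a differently
  shaped (e.g. peaked) juvenile curve would differ near the pith.
- PVE from the adaptive LASSO is conditional on the selected set and is not
  corrected for winner's curse.
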