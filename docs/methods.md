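# Methods

## Model

All five methods fit the same linear model for N phenotypes y and an N×m
dosage matrix Z (allele counts 0/1/2, used raw — no centering or scaling of
the stored data enters the model definition):

    y = 1 β₀ + Z u + e,   u_l ~ N(0, σ_l²) independent,   e ~ N(0, σ_e² I).

Given penalties λ_l = σ_e²/σ_l², the effects solve the (m+1)×(m+1)
mixed-model equations with coefficient matrix [[N, 1'Z], [Z'1, Z'Z +
diag(λ)]]. The system is positive definite for any λ > 0, so the solution
is unique. The methods differ only in how λ is constructed.

### Solver

Block elimination of the intercept row shows the marker block of the system
is exactly (Z_c'Z_c + diag(λ)) with column-centered Z_c, and β₀ = ȳ − z̄'û.
Two paths exploit this:

- **primal** — Cholesky factorization of the full (m+1) system;
- **dual** — for m ≫ N, the Woodbury identity
  û = Λ⁻¹Z_c'(Z_cΛ⁻¹Z_c' + I)⁻¹ y_c reduces the solve to an N×N system.

`solve_mme(..., method="auto")` picks the dual path when m > 2N. Both paths
verify the residual of the original system against a 1e-8 relative bound and
raise with a condition-number diagnostic on failure; the test suite checks
primal, dual and an explicit-inverse oracle against each other to 1e-8.

## Penalty constructions

**RIR.** λ_l = (1/h_p² − 1)·m from a user-supplied preliminary heritability
h_p² ∈ (0,1). No data-dependent estimation.

**Single-marker ANOVA components.** For each marker a random one-way ANOVA
of y on the observed dosage classes gives MQM_l (between-class mean square,
df a−1) and MQE_l (within, df N−a), and the moment estimator

    σ*_l = (MQM_l − MQE_l) / [ (N − Σᵢ nᵢ²/N) / (a_l − 1) ],

truncated below at 0. The denominator is the general unbalanced-layout
form: with three dosage classes the divisor (a−1) is 2 (the familiar ½
factor); doubled-haploid data have two classes, where the divisor is 1.
Monomorphic markers get σ*_l = 0 by convention. The σ*_l are computed
marker by marker and are not independent across markers; they are used only
as relative weights. Negative moment estimates are truncated at 0 rather
than allowed to cancel in the weights — a zero weight maps to the penalty
cap, which is the conservative choice (the marker is shrunk out rather than
given a sign-flipped weight).

**RMLA.** λ_l = (σ̂_e²/σ̂_g²)·Σσ*_{l'}/σ*_l with (σ̂_e², σ̂_g² = m·σ̂_u²)
from homoscedastic EM-REML. Equivalent to partitioning σ̂_g² over markers
proportionally to σ*_l (`partition_genetic_variance`, which conserves the
total exactly) and setting λ_l = σ̂_e²/σ̂_l².

**RRWA.** λ_l = (1/h_p² − 1)·Σσ*_{l'}/σ*_l. Two properties pin this form
down: it reduces to RIR when all σ*_l are equal, and it equals RMLA
elementwise when h_p² = σ̂_g²/(σ̂_g²+σ̂_e²). The ratio Σσ*/σ*_l is computed
after normalizing by the largest component, which makes the homoscedastic
collapse to RIR exact in floating point, not just to rounding error.

**BLUP (homoscedastic EM-REML).** Starting from σ_e² = var(y)/2,
σ_u² = σ_e²/m, iterate: solve the system at λ = σ_e²/σ_u², then

    σ_e² ← (y'y − β̂₀·1'y − û'Z'y)/(N − 1)
    σ_u² ← (û'û + σ_e²·tr C_uu)/m,

where C_uu is the marker block of the inverse coefficient matrix (tr C_uu =
Σᵢ 1/(sᵢ² + λ) over the eigenvalues sᵢ² of Z_c'Z_c, so one thin SVD of Z_c
makes every iteration O(m)). The **plus sign** in the σ_u² update is the
conditional-expectation EM-REML form: E[u'u | y] = û'û + σ_e² tr C_uu, so
iterates stay positive and the restricted likelihood is non-decreasing
(both verified in tests; the converged point matches an independent
Nelder-Mead REML maximizer to 3+ significant figures). A variant update
with a minus sign — a form sometimes printed in summaries of the algorithm —
is exposed as `FitConfig(em_update="minus")` for comparison; it can go
negative and is floored at the variance floor. The divisor q = m is the
number of random effects; a rank-based divisor is not meaningful when
m > N. Residual degrees of freedom are N − 1 (intercept-only fixed design).

**RMLV.** Stage 1 runs the homoscedastic EM-REML; its converged σ̂_e² is
then frozen and its σ̂_u² initializes all per-marker variances (a warm
start). Stage 2 iterates: solve at λ_l = σ̂_e²/σ_l² (capped), extract the
per-marker diagonal C_ll of the inverse coefficient matrix, and update
σ_l² ← û_l² + σ̂_e²·C_ll (q_l = 1 column per component). A config switch
(`rmlv_residual="first_iteration"`) freezes instead the residual variance
of stage 1's first iteration, for users who read "estimated in the first
round" as the first iteration rather than the first stage; the default is
the converged stage-1 value, which is the better-determined estimate.

C_ll is obtained by one Cholesky factorization per iteration with
diagonal-of-inverse back-substitution (LAPACK `dpotri`) when m ≤ N, and via
the Woodbury identity diag(Λ⁻¹) − diag(Λ⁻¹Z_c'K⁻¹Z_cΛ⁻¹) with the N×N
kernel K = Z_cΛ⁻¹Z_c' + I when m > N; the two paths agree to 1e-10 in
tests.

### Convergence, floors, caps

- Homoscedastic EM: max relative parameter change < 1e-8, ≤ 1000 iterations.
- RMLV stage 2: max relative change in σ_l² < 1e-6, ≤ 500 iterations. For
  null markers the update contracts sublinearly toward zero (σ ~ c/t), so
  the relative-change criterion is often still above 1e-6 at the iteration
  cap; the fit is returned with `converged=False` and a warning. This is
  expected behavior at a boundary fixed point, not a defect: by then null
  variances sit orders of magnitude below σ̂_e² and the effect estimates
  are stable to well below plotting precision. Each iteration costs a
  factorization (O(min(m,N)³)), which is why RMLV is by far the slowest
  method here.
- Variance floor 1e-12·σ̂_e²; penalty cap 1e12 (`FitConfig.lambda_cap`),
  applied wherever a penalty is formed, including σ*_l = 0 markers.

## Simulator

`popsim` emulates a biparental DH program. Defaults define the standard
scenario: 10 chromosomes of 1.6 Morgan; markers on an even grid including
both telomeres (so 1/2/5 cM spacing gives 161/81/33 markers per chromosome,
1610/810/330 total); two QTL per chromosome at 0.401 and 1.201 M (never on
the marker grid for those spacings); per-allele QTL effect 2.5, so DH
genotype classes differ by 5; F1 intermating for ngen ∈ {3, 19} generations;
600 DH lines; h² ∈ {0.5, 0.8}.

Choices where the design was genuinely open:

- **Crossover process**: Poisson count with mean = map length, uniform
  positions, no interference (Haldane). Testable against the closed form
  r(d) = (1 − e^{−2d})/2, and the package's tests do exactly that at 10⁵
  meioses.
- **Intermating population**: 1000 individuals ("large" F1), random pairs
  with replacement, selfing excluded, non-overlapping generations. Size and
  scheme are configurable; 1000 keeps drift small (allele-frequency sd
  ≈ 0.02 over 3 generations) at negligible cost.
- **Effect coding**: 2.5 is the allele-substitution effect (per allele
  copy), so estimated marker effects live on the same dosage scale as the
  fitted model and can be compared to 2.5 directly.
- **Heritability calibration**: σ_e² = var(g)·(1/h² − 1) from the
  *empirical* variance of g in the realized sample, so h² is calibrated per
  replicate; realized var(g)/var(y) is within ±0.05 of the target at 600
  lines (verified over seeds).
- **Reproducibility**: one seeded generator per study; replicate substreams
  spawned deterministically (`SeedSequence.spawn`), making study tables
  bit-reproducible.

What the simulator does **not** emulate: genotyping errors or missing data,
selection, mutation, crossover interference, dominance/epistasis,
population structure beyond a single biparental cross, and non-normal
residuals. Passing tests therefore demonstrate correctness of the methods
under the idealized generative model, not performance on any real breeding
panel.

## Evaluation

Cross-validation uses repeated random subsampling: floor(0.8·N) training
individuals drawn without replacement per run (fresh split each run,
train/validation proven disjoint), Pearson correlation between observed and
predicted values on the held-out 20%, 100 runs by default; zero-variance
runs are excluded from the mean and counted.

Effect accuracy against simulated truth is summarized by (i) the MSE of the
mean effect profile against a zero-baseline truth profile that assigns the
per-allele effect to the marker nearest each QTL — QTL are deliberately off
the marker grid, so any assignment of "the true effect of a marker" is a
convention, and the nearest-marker choice makes the all-zero-estimate MSE
exactly n_qtl·(2.5)²/m; (ii) the summed estimated effects of markers within
±window_cM of each QTL, which is assignment-free and is the statistic used
for method comparisons; and (iii) the maximum absolute estimated effect.

At the scaled study conditions used in the test suite (2 chromosomes, 1 cM
spacing, ngen = 3, h² = 0.8, 10 replicates) the mean-profile MSE orders
RMLV < RMLA < BLUP and the largest BLUP effect stays below the true 2.5 —
the high-density/high-LD regime where homoscedastic shrinkage dilutes
single-marker effects the most. Problem sizes in the tests (replicate
counts, chromosome numbers, N and m of the EM checks) are scaled to keep
the default suite fast while leaving every Monte-Carlo check at least 3
standard errors of headroom.

## Degenerate inputs and tie-breaks

- Polymorphic marker with N − a ≤ 0: ANOVA raises (no within-class df).
- All σ*_l = 0: no partition/weighting defined; RMLA/RRWA raise.
- Constant y: all ANOVA mean squares 0; weighting methods raise via the
  previous rule.
- Constant g in phenotype calibration: raises (heritability undefined).
- h² = 1: allowed; phenotypes equal genotypic values exactly.
- Missing dosages: rejected by default; optional per-marker mean imputation
  (fractional values enter Z unrounded; ANOVA class assignment uses the
  nearest integer dosage).

## Known limitations

- Fixed effects are limited to the global intercept, exactly as the model
  above; general fixed-effect designs are out of scope.
- The RMLV iteration cap makes its null-marker variances depend (weakly) on
  the cap; downstream effect estimates are insensitive, but the reported
  σ_l² of null markers should be read as "numerically zero", not as
  calibrated estimates.
- The ANOVA moment estimator treats dosage classes as a random one-way
  layout; for an additive locus the class means are ordered, which the
  estimator ignores (it only needs a relative signal strength).
- VCF import handles diploid GT of biallelic records only.
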