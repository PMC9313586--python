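# Methods

This note documents the model, the estimators, the numerical choices, and
the synthetic-data conditions behind `mgirt`, including the design
decisions that were genuinely open and how they were resolved.

## Model

A multiple-group unidimensional IRT model: respondents belong to one of G
known groups; within group *g* the latent trait Z is N(μ_g, σ_g²) and the
J categorical item responses are conditionally independent given Z.
Category probabilities follow one of four models in **slope–intercept
form** (linear predictor a·z + b; the difficulty parameterization is
b_diff = −b/a):

- GRM: P_k = P*_k − P*_{k+1} with cumulatives P*_k = expit(a z + b_{k−1}),
  intercepts strictly decreasing in the category index;
- GPCM: adjacent-category logits, P_k ∝ exp(Σ_{v≤k}(a z + b_{v−1})) with
  m−1 free intercepts (the first category's term is normalized away);
- 2PL: the binary special case of both;
- 3PL: P(correct) = c + (1−c)·expit(a z + b), guessing c ∈ [0, 1).

Categories are 0-based internally with default integer scores
W_k = 0..m−1 (per-item overrides allowed, restricted to nonnegative
integers — see *Score lattice* below).

Expected item information is I_j(z) = Σ_k (∂P_k/∂z)² / P_k.  Because the
probabilities sum to one, the second-derivative term of the observed
information vanishes in expectation, so this single sum *is* the expected
information; the unit tests verify it against the expected negative
curvature of the category log-likelihoods by finite differences.  Test
information is the sum over items; an empty battery has information 0 by
convention so additivity tests compose naturally.

## Reliability estimators

The four coefficients are described in the README.  Shared machinery:

- **Lord–Wingersky recursion.**  The conditional sum-score distribution
  is built item by item: starting from the first item's category-score
  distribution, each new item's scores are convolved in on the integer
  score lattice.  Equivalence with brute-force enumeration over all
  response patterns is asserted to 1e−12 on randomized batteries with up
  to 10,000 patterns.
- **Quadrature.**  Gauss–Hermite rules rescaled so that
  Σ_l w_l f(z_l) ≈ E[f(Z)] for standard normal Z (nodes ×√2, weights
  /√π, hence weights sum to 1 and all downstream formulas read as plain
  expectations).  Group nodes are z_lg = σ_g z_l + μ_g.  Default L = 61
  for reliability evaluation; the refinement-stability tests show the
  marginal score distribution of the 14-item preset is stable to 1e−8
  from about L ≈ 100 on, and E[1/I] to ~1e−10 at L = 101, so L = 61 is
  comfortably inside the regime where acceptance tolerances absorb the
  remaining quadrature error.
- **Score lattice.**  Non-integer category scores are rejected rather
  than approximated: the recursion's index arithmetic assumes integer
  offsets and a real-valued generalization would silently change the
  estimand.
- **Boundary handling.**  Coefficients are clamped onto [0, 1] only
  within 1e−10 of the boundary (with a warning); values farther outside
  raise, because they signal a degenerate model or quadrature failure
  rather than sampling noise.
- **Group shares.**  p_g are fixed and known (set to observed
  proportions); they contribute no sampling variance and no gradient
  components.

## Estimation

Marginal maximum likelihood via Bock–Aitkin EM on the quadrature nodes:

- **E-step** computes posterior node weights per respondent from the
  group-transformed nodes and prior weights w_l.
- **M-step (items)**: one safeguarded Fisher-scoring step per cycle on
  each item's expected complete-data log-likelihood (a generalized EM
  step; step-halving guarantees the Q-function never decreases).
  Invariant items pool expected counts across groups at each group's own
  nodes; group-specific (DIF) items are updated per group.  The 3PL
  guessing parameter is optimized on a logit scale bounded to (0, 0.5).
- **M-step (distributions)**: μ_g, σ_g² from posterior moments (reference
  group fixed at N(0, 1)); σ² floored at 1e−3 with a Heywood flag.
- **Acceleration**: SQUAREM-style extrapolation over pairs of EM steps,
  accepted only when it does not decrease the marginal log-likelihood, so
  the recorded log-likelihood path is nondecreasing (up to ~1e−9 relative
  noise from the node re-transformation, tolerated in the monotonicity
  assertion).  When the log-likelihood change per cycle falls below 1e−4
  while the stopping rule is not yet met — EM's slow tail — a safeguarded
  Newton finisher on the full free vector (finite-difference Hessian of
  the analytic score, line search on the log-likelihood) jumps to the
  quadrature-likelihood optimum, typically in two or three steps, driving
  the score to machine zero.
- **Convergence**: max |Δξ| < 1e−5 *and* |Δ loglik| < 1e−8 between
  accepted iterates, iteration cap 2000.  Hitting the cap is reported as
  nonconvergence (warning + flag), never silently accepted; diverging
  Heywood-type items (a slope growing without bound on quasi-separable
  data) surface this way, which matches how nonconvergence is tallied in
  the study harness.
- **Distribution polish**: the moment update for (μ_g, σ_g²) targets the
  exact integral, not its quadrature approximation, so the plain-EM fixed
  point carries small nonzero score components on those coordinates.
  When the Newton finisher has not already zeroed the full score, a few
  Newton steps restricted to the distribution parameters run after
  convergence; with the finisher active this pass is a no-op.
- **Starting values**: a = 1, intercepts from smoothed marginal category
  logits, μ_g = 0, σ_g² = 1 — fixed and seed-independent.
- **Default L = 21 for fitting** (61 for reliability evaluation); at
  n = 4000 the quadrature bias of the estimates is far below Monte-Carlo
  noise, and fitting cost scales linearly in L.
- **Missing data** are rejected explicitly; the model expects complete
  response matrices.

**Covariance.**  The sandwich A⁻¹BA⁻¹: B is the sum of outer products of
per-respondent *analytic* score vectors (Fisher's identity through the
posterior node weights); A is the negative Hessian of the marginal
log-likelihood by central finite differences of the analytic gradient
(step 1e−5·max(1, |ξ_i|), one-sided at parameter-space boundaries).  The
choice of the *observed* Hessian in A (rather than an expected one) is
recorded here as the implementation's convention; the SE-calibration
experiment (mean estimated SE vs. empirical SD over replications) passes
with it.  Singular A raises an error naming the most nearly aliased
parameters.

**Delta method.**  Gradients of the reliability coefficients over the
free parameter vector are central finite differences of the reliability
functionals (same stepping rule).  Analytic derivatives would be an
equivalent fast path behind the same contract; numerical agreement is the
correctness criterion either way, and the Jacobian is verified against an
independent differencing loop at a different step size.  Wald intervals
are untruncated (they may protrude beyond [0, 1] near the boundary — a
known limitation; transformed boundary-respecting intervals are out of
scope).

**Constraint granularity.**  Invariance is declared per item, not per
individual parameter: an item is either invariant or wholly
group-specific.  Whole-item DIF is what the motivating analysis and the
simulation design use; per-parameter mixing would require joint
cross-group item updates for a case with no user here.

## Synthetic data

The generator emulates a two-group cognitive-screening design:

- 14 GRM items (alternating 2- and 3-category; 28-item variant doubles
  this), slopes a ~ U(0.8, 2.2), intercepts drawn from a ±2.5 spread and
  forced strictly decreasing with a minimum gap of 0.4;
- 3 of 14 items (6 of 28) with DIF: group-2 slope shifted by ±U(0.2, 0.6)
  and all intercepts shifted by ±U(0.3, 0.8);
- group shares (0.55, 0.45), latent distributions N(0, 1) and
  N(−1.081, 1.096) — the published two-group MoCA estimates by education
  level serve as the documented stand-in truth;
- group sizes are largest-remainder roundings of the shares, so p_g is
  exactly fixed and known as the formulas assume;
- parameter generation and response draws are deterministic functions of
  their seeds; the preset battery is the fixed draw at the default design
  seed 20220301.

What the generator does *not* emulate: real MoCA item content and its
ceiling effects (real screening items are concentrated at the easy end of
the scale), non-normal latent distributions, missing responses, response
styles, and local dependence between tasks.  Passing tests therefore
demonstrate the estimators' statistical behaviour under a correctly
specified partial-invariance GRM, not robustness to those features.

## The Monte-Carlo harness

Per replication: simulate at the preset truth; fit the multigroup model
with the generating constraints plus three single-group models (each
group alone and the pooled sample, latent distribution fixed at N(0, 1));
record coefficients, delta-method SEs, and CI coverage of the true
values (the coefficients at the generating parameters).  Aggregation uses
converged replications only, with nonconvergence tallied separately;
relative efficiency (single-group MSE / multigroup MSE) is computed on
the intersection of replications where both fits converged.
Per-replication seeds derive from the master seed as
`SeedSequence(seed, spawn_key=(rep,))`, making results independent of
execution order and partial re-runs reproducible.

**Problem sizes.**  The acceptance-level experiments run at n = 4000 with
320 replications (bias, coverage, relative efficiency), n = 8000 with 100
replications (parameter recovery and SE calibration), and 200
replications of the invariant null for the equality test's type-I error;
binomial tolerances are computed from the replication counts actually
used.  These are single-CPU batch sizes; the harness accepts larger
`--reps` (e.g. 5000) and `--jobs` for parallel replication.

**A relative-efficiency caveat.**  Under this generator the pooled
single-group estimators of the *overall* coefficients are essentially
asymptotically unbiased (checked directly at n = 60,000: bias ≤ 0.001 for
both score types), so the efficiency comparison for the overall MLE
coefficient reduces to a variance comparison — and the pooled fit, whose
latent variance is fixed at 1 rather than estimated, has *smaller*
variance.  The expected misspecification-driven MSE inflation of the
pooled estimator evidently requires item batteries whose information
profile makes E[1/I(Z)] sensitive to the shape of the latent mixture
(e.g. strongly ceiling-heavy screening items); with this battery the
effect is absent and the corresponding relative-efficiency check fails.
The generator was not re-tuned to manufacture the effect; the behaviour
is reported as found.

## Known limitations

- Normal latent distributions within groups; known group membership only
  (no mixture IRT with unknown membership).
- The MLE-reliability error variance uses the asymptotic 1/I(z) with no
  finite-item correction, so the coefficient is an infinite-test-length
  approximation.
- Wald intervals are untruncated; no multiple-testing adjustment is
  applied across coefficients.
- No support for missing responses, real-valued category scores,
  multidimensional traits, or nominal models.
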