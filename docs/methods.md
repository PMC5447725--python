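# Methods

## Estimation

Indicators are standardized to mean 0 and variance 1 with the population
(1/N) convention, so every column of Z and every component score has sum of
squares exactly N; this keeps the least-squares criterion's algebra exact
(the 1/(N−1) convention changes FIT in the fourth decimal). Rows with
missing entries are dropped listwise before standardizing.

The alternating least squares implementation writes the criterion as
Φ = ‖Z V₀ + Z W (D − A)‖² with V₀ = [I | 0] and D = [0 | I]. The A-step is
per-equation ordinary least squares on the permitted component scores. The
W-step updates one column at a time: with the other columns fixed, Φ is
affine in w\_p up to the constraint wₚᵀZᵀZwₚ = N, so the constrained
minimizer is the (negatively scaled) solution of a single linear system
restricted to the column's pattern support. Because both half-steps are
exact conditional minimizers *including the normalization*, the criterion
is monotonically non-increasing — this is asserted, not hoped for, in the
tests. Convergence is declared when the relative decrease of Φ falls below
`tol` (default 1e-6, `max_iter` 300). Initialization is deterministic equal
weights (1/√block-size, then normalized); a seeded random start is
available for multistart checks. After convergence each component's sign is
fixed so its loadings sum positive, which stops sign-flipping across
bootstrap resamples. Exactly collinear indicators inside a block leave the
weights underdetermined; the update then takes the minimum-norm solution,
which still minimizes Φ (this is the perfect-fit limit with duplicated
indicators). Bootstrap standard errors resample rows with replacement at
size N, re-standardize, refit, and take standard deviations over converged
resamples; resamples that fail (constant column, non-convergence) are
flagged, and more than 50% failures is an error.

A supermatrix convention has to be chosen because the criterion is usually
written without dimensions: here A = [C | B] is P × (J+P), so the residual
is Vᵀz − AᵀWᵀz with V = [I | W] of size J × (J+P). All J+P equations enter
FIT's total, and an equation with no predictors (an exogenous component, or
any component in a path-free model) contributes R² = 0 — which is why a
path-free two-factor model has a visibly lower FIT than the same
measurement model with a structural path.

## Model-implied correlation matrix

The reconstruction Σ̂ = CᵀΦ\_γC with Φ\_γ = WᵀSW and a forced unit diagonal
is the package's definition of the implied matrix, chosen because (a) it
gives each block the rank-one structure whose vanishing tetrads the test
needs, and (b) with standardized indicators it coincides with the
factor-analytic implied correlation evaluated at the composite loadings.
Two consequences are worth knowing. First, the loadings are
composite–indicator covariances, not factor loadings, so even under a
correct population factor model Σ̂ does not converge to S: GFI saturates
just below 1 and SRMR just above 0 (the higher the loadings, the closer).
Second, re-fitting on moments equal to Σ̂ is not an exact fixed point of
the reconstruction (the unit diagonal re-enters the composite loadings);
the map is a contraction, which the tests verify. Free-parameter count δ
for AFIT is #weights + #loadings + #paths + #free exogenous correlations.

## Second-order components

The formalization of a hierarchical component is genuinely open; here a
second-order component is a composite whose weight pattern spans the union
of its first-order components' indicators, with no direct loadings and
directed paths to each first-order component. This stays inside the
ordinary W/C/B algebra (no special-case code in the estimator). A
consequence that follows from the reconstruction, not from this choice:
any second-order model over two first-order components is
*tetrad-equivalent* to the correlated two-factor model — every implied
correlation is a product of two loadings times a scalar, so the two models'
vanishing sets coincide exactly and the difference test correctly refuses
to compare them. With three or more first-order components the structures
separate.

## Tetrad machinery

Tetrads are enumerated per 4-subset in lexicographic order with the three
pairings in a fixed canonical order, 3·C(J,4) in total. The vanishing set
is read off Σ̂ with `tol_vanish` = 1e-6 on the correlation scale: implied
tetrads of the reconstruction vanish to machine precision, so any small
threshold works; 1e-6 guards rounding from the iterative fit. The
asymptotic covariance of sample covariances is estimated
distribution-free from centered fourth moments (the point of pairing CTA
with a least-squares estimator is that nothing in the chain needs
normality); a normal-theory closed form (σ\_gi σ\_hj + σ\_gj σ\_hi) is
available behind a flag for comparison. The Jacobian ∂τ/∂σ is analytic,
four nonzeros per row, evaluated at the sample correlations; the σ-vector
ordering contract is the column-stacked lower triangle excluding the
diagonal. The statistic's quadratic form is computed on a non-redundant
subset selected by sweeping the tetrads' covariance matrix in a seeded
random order; a candidate is retained when its conditional variance given
the already-retained set exceeds 1e-8 of the largest diagonal entry. The
conditional variances are computed against the retained submatrix directly
(not a running Schur complement), which keeps the retained count equal to
the numerical rank instead of drifting with accumulated roundoff. The
modified statistic T1 replaces the covariance by its diagonal; T is the
default since both are standard. Samples above n = 1000 trigger a warning:
the statistic scales with n and single-model rejections become
uninformative, while the few-df difference test remains usable.

Degrees of freedom deserve a caveat: the Jacobian is evaluated at the
sample matrix, so when the restrictive model is badly wrong the covariance
of its vanishing tetrads can reach the maximal rank J(J−1)/2, while near a
well-fitting model the rank drops toward the model's structural codimension.
df is therefore data-dependent by construction, which is also why the
comparison is replicated.

## Nested comparison

Model B is tetrad-nested in model A iff B's vanishing set is a strict
subset of A's; identical sets raise an equivalence error and non-nested
pairs raise an error carrying the offending tetrads. Within each
replication the restrictive model's sweep order visits the shared tetrads
first, so its selection restricted to the shared set is itself a maximal
non-redundant selection for the less restrictive model — guaranteeing a
valid nested difference with Δdf ≥ 1 by construction rather than by luck.
Negative ΔT (possible in finite samples when selections differ) is
reported with a warning and p = 1, never silently clamped. Default
replication count is 5.

## Synthetic data

The generator emulates an eight-scale, two-rater social-skills instrument:
latent-Gaussian draws from the population correlation matrix implied by one
of four structures, affinely mapped to the published marginal means/SDs of
the eight scales, optionally clipped to the 1–4 rating range. Defaults:
within-block loadings 0.8 (composite reliabilities land above 0.9,
comfortably in the good range); factor correlation 0.4 for the two-factor
structure; standardized regression 0.367 for the path variant; second-order
loadings √0.4 each (so the implied first-order correlation matches the
two-factor structure); four-factor correlations 0.6 within rater, 0.3
across. The equicorrelated cross-rater block is a degenerate point of the
four-factor structure: the exact population matrix vanishes on 16 extra
tetrads beyond the 54 structural ones. Fitted matrices are generic
(sampling noise breaks the tie), so pipeline behavior is unaffected, but
population-matrix analyses should expect 70.

What the generator does not emulate: survey weights and stratification,
item-level scoring, ordinal measurement (scales are treated as continuous;
clipping induces mild non-normality on purpose, since the machinery is
distribution-free), negatively keyed problem scales (all loadings are
positive), and missing data. Passing tests therefore demonstrate
correctness of the algorithms under the stated population structures, not
robustness to those real-data features.

## Problem sizes in the checks

The acceptance script uses 1000 Monte-Carlo replications at n = 500 for
the calibration of T, 200 replications at n = 2000 for the power of the
difference test, and n = 5000 for parameter recovery — sizes at which the
Monte-Carlo error of the reported rates is a small fraction of the margins
being asserted, while the whole script runs in seconds.

## Known limitations

- Formative/MIMIC blocks, multi-group constraints and categorical
  quantification are out of scope; formative syntax is rejected explicitly.
- The single-model test at very large n rejects essentially always (the
  statistic scales with n); use the difference test there.
- Tetrad-equivalent model pairs (same vanishing sets — e.g. a correlation
  vs a directed path between the same two composites) are indistinguishable
  to CTA by construction; the descriptive indices still differ and are the
  only recourse.
- The sweep-selected df depends on the sample through the Jacobian and the
  pivot threshold; replications make this visible rather than hiding it.
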