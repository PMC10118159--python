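# Methods

## Model

A trial compares placebo (condition 0) with two treatments (1, 2) on a
quantitative outcome. The score of subject `j` under condition `i` is
`y_ij = mu_i + e_ij`, where the within-subject residual vector has a
general covariance

    D = [[s0^2,  s01,  s02],
         [s01,  s1^2,  s12],
         [s02,  s12,  s2^2]],    s_ii' = rho_ii' * s_i * s_i'.

The model deliberately omits period and carryover effects; it describes a
design stage where only the second-moment structure of the outcomes
matters. `D` must be positive definite, which is enforced at construction
through the leading principal minors.

In the incomplete design each subject receives one condition combination:
{0,1}, {0,2} or {1,2} (scenario 1 excludes {1,2}; the complete design uses
{0,1,2}). The rows of the identity design matrix for the missing
conditions are dropped, so a subject on combination `c` has response
covariance `V_c`, the submatrix of `D` on `c`, and contributes information
`I_c = X_c' V_c^{-1} X_c` (a 3x3 matrix that is zero outside the rows and
columns of `c`). With `N_c` subjects per combination the GLS estimator of
`mu = (mu_0, mu_1, mu_2)` has covariance `M^{-1}`, `M = sum_c N_c I_c`.
Working with submatrices of `D` is mathematically identical to carrying
the residual design matrices explicitly (they are identity selectors) and
much cheaper inside the enumeration loop.

### Estimability

Boundary allocations can leave a condition uninformed (e.g. `N01 = 0` and
`N12 = 0` leaves treatment 1 unobserved). `M` is then singular, with the
uninformed condition's row exactly zero. Estimability is tracked per
condition: `mean_covariance` inverts `M` on its informed block and flags
the rest NaN, and `contrast_variance` raises a distinct
`NonEstimableContrastError` (the variance is infinite, not numerically
broken). For the valid combination sets, `M` has full rank exactly when
all three conditions are informed, which for two or more distinct positive
combinations is automatic; this is what lets the optimizer use a single
closed-form 3x3 inverse on the full-rank mask and the paired-difference
closed form `(s0^2 + s_i^2 - 2 s0i)/n` on single-pair supports.

## Optimality criteria

Contrast variances `Phi_0i = a_0i' M^{-1} a_0i` with `a_01 = (1,-1,0)`,
`a_02 = (1,0,-1)`.

* `Phi_DA = det(A' M^{-1} A)` with `A = [a_01, a_02]` (3x2): the
  generalized variance of the two contrasts.
* `Phi_compound = lambda1 * Phi_01 + (1-lambda1) * Phi_02`, `lambda1` in
  [0, 1].

At `lambda1` exactly 0 or 1 the zero-weighted contrast is *not evaluated*
(the convention 0 x infinity = 0), so allocations that drop one pair
entirely are admissible; this is required for the boundary optima the
sweep produces (e.g. `N01* = 0` at `lambda1 = 0`).

Relative efficiency of an allocation `xi` versus the optimum `xi*` is
`Phi(xi*)/Phi(xi)` for the compound criterion and
`(Phi_DA(xi*)/Phi_DA(xi))^(1/2)` for D_A — the 1/2 exponent is hard-coded
for exactly two contrasts and not generalized. The reciprocal of RE is the
replication factor `xi` needs to match `xi*`. Comparisons against the
complete design evaluate the same criterion on `var(mu_hat) = D / N012`
and apply the same efficiency formulas.

## Search algorithm

The design space is Omega = {integer `N_c >= 0` : `sum_c N_c C_sc <= B`},
with `C_sc = C_s + sum_{i in c} C_i`. Constrained continuous optimizers
are unreliable here (sensitive to starting values, non-integer output), so
the optimum is found by exhaustive enumeration of Omega. Implementation
choices:

* per-combination information matrices `I_c` are precomputed once;
* candidates are generated in lexicographic slices with the trailing two
  count dimensions fully vectorized; each batch is scored through the
  closed-form symmetric 3x3 inverse written in numpy vector arithmetic.
  The scenario-2 benchmark (about 6.8 million feasible triples at budget
  50,000) scores in roughly a second; scenario 1 is instantaneous;
* budget comparisons use an absolute tolerance of 1e-6 currency units:
  costs are decimal (e.g. 923.6) and real optima sit within cents of the
  budget, so binary rounding must not flip feasibility;
* ties (criterion values within relative tolerance 1e-10) are broken by
  lower total cost, then lexicographically smaller counts in combination
  order {0,1}, {0,2}, {1,2} — deterministic and reproducible; all tied
  allocations are reported;
* the all-zero allocation is feasible but always has an infinite
  criterion, so it is never returned; if *no* allocation has a finite
  criterion the search raises an infeasible-design error naming the
  contrast that cannot be estimated.

The uniform baseline assigns the largest equal integer count per allowed
combination that fits the budget (leftover budget is never spent on an
extra subject in a cheaper combination; this strict definition matches the
uniform designs the efficiency grids are defined against). The complete
design enrols `floor(B / C_s012)` subjects.

## Power calculations

For one contrast with variance `Phi` the normal-approximation z-test
gives the minimum detectable raw effect
`(z_{1-alpha} + z_{1-beta}) * sqrt(Phi)` (two-sided tests use
`z_{1-alpha/2}`) and power `PhiN(delta/sqrt(Phi) - z_{1-alpha})` for a
user-specified effect `delta`; the two are exact inverses. Defaults are
one-sided `alpha = 0.05` and target power 0.8. Cohen's d standardizes a
raw effect by `sqrt((s0^2 + s_i^2)/2)` — the average of the placebo and
treatment variances — so both heteroscedastic conditions contribute
symmetrically; this is the only standardizer consistent with the
detectable-effect and d values the worked example reports side by side.
Multiplicity-adjusted (simultaneous) power is out of scope.

## Monte-Carlo validation

The simulation harness draws each subject's observed sub-vector from a
multivariate normal with mean equal to the restriction of the true
condition means and covariance `V_c`, then applies the known-`D` GLS
estimator (the design-stage premise; `D` is never estimated from the
simulated data). Replicates are vectorized: per combination, the sum of
outcome vectors is a sufficient statistic for the GLS solve, so only
those sums are accumulated. The empirical variance of each contrast over
`R` replicates is compared with the analytic `Phi_0i` using the
normal-sample variance standard error `Phi * sqrt(2/(R-1))`; agreement
within three standard errors at `R = 20,000` is the validation criterion.
Default seed 20230420 makes every run reproducible.

What the simulations emulate — and what they do not: outcomes are exactly
multivariate normal with the assumed `D`, there is no attrition, no
period/carryover structure and no misspecification, so passing validation
demonstrates the internal consistency of the variance formulas, not
robustness of the design to departures from the planning assumptions.

## Problem sizes and numerical choices

The benchmark grids (budget 50,000, overhead 100, three cost triples,
three variance triples, rho 0.5, four criteria) enumerate about 74,000
scenario-1 pairs and about 6-9 million scenario-2 triples per cell; one
full scenario-2 grid is 36 optimizer runs and completes in under a
minute. Benchmark optima are cached per cell so the efficiency grids
reuse them. Matrix singularity checks use a relative condition threshold
of 1e-12; the validation suite uses 20,000 replicates, and unit tests use
2,000-5,000 where only stochastic agreement is asserted.

## Known limitations

* Exactly one placebo and two treatments; more conditions would grow the
  combination set and the enumeration cost combinatorially.
* No attrition adjustment, categorical outcomes, extra nesting levels, or
  maximin/internal-pilot robustness analyses.
* Efficiency-based design only; power-constrained cost minimization is
  not implemented.
* The enumeration is exact but brute-force: extremely large budgets or
  very cheap combinations will slow it proportionally to |Omega|.
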