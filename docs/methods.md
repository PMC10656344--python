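# Methods

## The model and the missingness mechanisms

`missem` works with a three-variable linear structural equation model: two
jointly normal explanatory variables,

    (X, Z) ~ N(0, Psi),   Psi = [[psiXX, psiXZ], [psiXZ, psiZZ]],

and a response

    Y = beta0 + betaX X + betaZ Z + eps,   eps | X, Z ~ N(0, sigma2).

`Z` is always observed; `X` and `Y` may be missing, with selection
indicators `Sx`, `Sy` (1 = observed).  The model is just-identified, so its
nine structural parameters are in bijection with the saturated Gaussian
moments of `(X, Z, Y)`; `missem.model` implements both directions of that
map, and every estimator works internally on the saturated moments.

Missingness is *realistically* MAR (R-MAR) when selection depends only on
the always-observed `Z`.  The package handles the two specific violations
that are testable from observed data, and their combination:

- **MNAR-X** — a path `X -> Sy`: the partially observed covariate drives
  missingness of the response.
- **MNAR-Y** — a path `Y -> Sx`: the response drives missingness of the
  covariate.
- **MNAR-XY** — both paths at once.

Mechanisms in which a variable drives its *own* missingness
(`X -> Sx`, `Y -> Sy`) are out of scope.

## The simulator

Selection is generated from latent probit indices,

    My* = gamma0 + gammaX X + gammaZ Z + u0,   u0 ~ N(0,1),   Sy = 1{My* <= 0},
    Mx* = alpha0 + alphaZ Z + alphaY Y + u1,   u1 ~ N(0,1),   Sx = 1{Mx* <= 0}.

Users state the violation strength on an interpretable scale — the partial
correlations `rho_MyX = Cor(My*, X | Z)` and `rho_MxY = Cor(Mx*, Y | X, Z)`
— together with the marginal observation rates `Px = P(Sx=1)` and
`Py = P(Sy=1)`.  The solver inverts this parameterization in closed form:

    gammaX = rho_MyX / (sd(X|Z) * sqrt(1 - rho_MyX^2)),
    alphaY = rho_MxY / (sd(Y|X,Z) * sqrt(1 - rho_MxY^2)),

and the intercepts come from the marginal normal law of each index
(including its mean, which is nonzero whenever `E[Y] != 0`):

    gamma0 = -Phi^{-1}(Py) * sd(My*) - E[gammaX X + gammaZ Z],

analogously for `alpha0`.  The closed forms are certified behaviorally in
the test suite: at n = 10^6 the simulated latent indices reproduce the
target partial correlations to ±0.01 and the observation rates to ±0.002.
`Px = 1` or `Py = 1` are handled as explicit "always observed" branches
rather than infinite intercepts.

Default study conditions follow the canonical design used throughout the
tests: `psiXX = psiZZ = 1`, `psiXZ = 0.5`, `beta0 = betaX = betaZ =
sigma2 = 1`, `gammaZ = alphaZ = 1`, observation rates 0.8 (population
studies) or {0.3, 0.8} (finite-sample studies), violation strengths in
{0, 0.5, 0.6, 0.9}.

What the generator does *not* emulate: non-normal or heteroscedastic
substantive variables, non-probit selection, clustered or longitudinal
structure, and more than one fully observed covariate.  Passing tests
therefore certify the estimators and tests under a correctly specified
trivariate Gaussian/probit world, not robustness beyond it.

## Estimators

**FIML ("SEM").**  The observed-data Gaussian log-likelihood sums, per
unit, the density of its observed coordinates under the saturated
`(mu, Sigma)`.  With three variables there are at most four missingness
patterns, so the likelihood and the EM updates are functions of per-pattern
sufficient statistics (count, sum, cross-product sum) — each EM iteration
is O(patterns), not O(n).  Units missing both `X` and `Y` contribute a
Z-only term (the standard FIML convention; recorded in the result
metadata).  Numerical strategy:

- starting values: available-case means/variances with complete-case
  correlations, ridge-repaired to positive definite if needed;
- EM until the log-likelihood change is small, then Newton steps on the
  9-dimensional packed parameter (finite-difference gradient; curvature
  computed once and refreshed only if convergence stalls) down to a
  gradient tolerance of ~1e-9·n.  The polish makes the exact identities
  below hold to optimizer precision rather than EM's linear-convergence
  precision;
- when the observed sets are *nested* (monotone missingness — complete
  data and both deletion estimators), the exact factorized MLE is used
  instead: each newly observed block is regressed on the previous block
  with ML residual covariance, and the joint moments are assembled from
  the chain.  The EM and closed-form routes agree to ~1e-10 and are
  cross-checked in the tests.

Standard errors: observed information by central finite differences of the
pattern log-likelihood at the MLE (step `1e-5 * max(1, |theta|)`), mapped
to the structural scale by a numerically differentiated delta method.

**Deletion estimators.**  `SEM-X` discards `Y` wherever `X` is missing
(`Sy' = Sx*Sy`) and runs FIML; `SEM-Y` mirrors it.  Deleting makes the
modified process MAR when the corresponding single violation is present,
so the estimator is consistent under "its" mechanism and generally biased
under the other.  Because the deleted likelihood factorizes, `SEM-X`'s
conditional-block estimates coincide *exactly* with complete-case OLS —
an identity the suite asserts at 1e-8.

**Complete-case OLS and WLS-X.**  OLS of `Y` on `(1, X, Z)` over complete
cases targets only `P(Y|X,Z)`; it is consistent whenever selection is
independent of `Y` given `(X, Z)` (R-MAR, MNAR-X).  `WLS-X` reweights the
complete cases by `1 / P(Sx=1 | Z, Y)` and is consistent for the
conditional distribution under all four mechanisms.  Residual variances
are reported in the ML convention (RSS/n) for consistency with the
likelihood estimators; OLS texts divide by n−p, and the coefficient SEs
use the conventional model-based formula (HC0 sandwich for WLS-X, weights
treated as fixed).

**SEM-XY.**  Weighted pseudo-ML of the saturated Gaussian over complete
cases with weights `1 / (P(Sx=1|Z,Y) * P(Sy=1|X,Z))` — operationally the
weight-normalized mean and ML covariance mapped through the bijection.
The selection probabilities factor along the missingness graph, so each
binary model is fit (probit by default; logistic available) on the largest
subsample where its outcome varies and its covariates are observed: the
Sx-model on units with `Y` observed, the Sy-model on units with `X`
observed.  Fitted probabilities are clipped at 1e-6 with a positivity
warning; weights are not trimmed by default.  Sandwich variances use the
per-unit moment estimating equations with weights treated as fixed (at the
solution the weighted Jacobian is `-sum(w) * I`, so the sandwich reduces to
`sum(w^2 psi psi') / (sum w)^2`).

A caution the package surfaces deliberately: under the canonical design the
selection indices have variance well above 1, so `E[(1/pi)^2]` diverges and
the weighted estimator of `psiXZ`, while consistent, has no finite
variance — single large-sample draws scatter widely and sandwich SEs merely
indicate (and sometimes understate) that instability.  The tests therefore
judge SEM-XY's covariance parameter by replicate medians against the
unweighted complete-case bias it must remove, not by a tight band around
the truth; the regression coefficients, which are far stabler, are checked
directly.  This mirrors the well-known inefficiency of IPW relative to
likelihood methods.

## Diagnostics of R-MAR

Both tests condition on the tested variable being observed, which makes the
hypotheses functions of observed data only:

- target **MNAR-X**: among units with `Sx = 1`, test `X* ⊥ Sy | Z`;
- target **MNAR-Y**: among units with `Sy = 1`, test `Y* ⊥ Sx | Z`.

**Heteroscedastic LRT.**  The alternative fits, within each selection
group, its own regression line of the tested variable on `Z` with its own
ML residual variance; the null pools both groups.  Equivalently the
alternative mean model is `delta0 + delta1 Z + delta2 S + delta3 SZ` with
group variances `sigma0^2, sigma1^2`, and the null imposes
`delta2 = delta3 = 0, sigma0^2 = sigma1^2` — three constraints, so the
statistic `n log s2_pooled − sum_g n_g log s2_g` is referred to
chi-square(3).  Testing both moments (not just the mean) is what
covariance-structure estimation requires, and under normality it is an
exact conditional-independence test.  The statistic is computed from the
closed-form group OLS fits; a generic numerically optimized heteroscedastic
likelihood reproduces it to 1e-6 in the tests.  Each group must have at
least 5 units (a package choice), otherwise the test reports
`feasible = False` and no p-value.

**KCI.**  The kernel conditional-independence test uses Gaussian kernels
with median-heuristic bandwidths on standardized inputs; the
tested-variable kernel is computed on the `(variable, Z/2)` block, the
indicator enters its own kernel, and both centered kernel matrices are
residualized by `R = eps (K_Z + eps I)^{-1}` with `eps = 1e-3`.  The
statistic is `trace(Kv|z Ks|z) / n`; its null is approximated by matching a
gamma distribution to the first two moments of the spectral product
structure of the residualized matrices.  A permutation null (default 500
permutations of the indicator block) is available as a robustness check.
Working samples above 5000 are subsampled (seeded) because the kernel
matrices are dense.  These hyperparameters follow the standard KCI
construction and are exposed as arguments; empirically the defaults give a
type I error of ~0.04-0.05 at n = 500 and p-values within Kolmogorov
distance 0.08 of uniform.

## Test-based estimator

Run both diagnostics at level `alpha` (default 0.05, no multiplicity
correction — deliberately, to avoid abandoning the efficient FIML for
small violations); dispatch `SEM-X` if only the MNAR-X test rejects,
`SEM-Y` if only the MNAR-Y test rejects, and FIML if neither or both
reject.  The both-reject case is judged MNAR-XY, yet FIML is still used
because the consistent alternative (SEM-XY) has much larger MSE at
realistic sample sizes.  An infeasible test counts as a non-rejection and
is flagged in the decision record; this choice (rather than silently
skipping the test) is a package decision since the decision rule itself
must remain total.

## Study harnesses and reproducibility

`run_population_study` simulates one large dataset per mechanism (default
N = 10^6; at that size non-IPW estimator SEs are below 0.005, so printed
three-decimal probability limits are meaningfully checkable) and applies
all six estimators.  `run_finite_sample_study` replicates the small-sample
grid (default 100 replicates per condition, as in the standard design) and
reports bias and MSE against the generating values with Monte Carlo
standard errors.  `run_power_study` measures rejection rates of the
diagnostics on the design where `X` is the only partially observed
variable.

All randomness flows from one root seed: replicate `r` of condition `c`
uses `SeedSequence([root, c, r])`, so results are independent of execution
order and identical under any parallel schedule.  CLI commands refuse to
run without an explicit seed (`--seed auto` draws one and prints it), and
every output embeds a run record (seed, config hash, library versions).

## Known limitations

- Exactly one partially observed covariate and one partially observed
  response; no latent variables or categorical endogenous variables.
- The diagnostics test R-MAR against the two specific violations above;
  Rubin-MAR proper is untestable without further assumptions, and MCAR
  tests are out of scope.
- Sandwich variances treat estimated selection probabilities as fixed
  (conservative) and no doubly robust or trimmed-weight variants are
  provided.
- The KCI implementation targets working samples up to a few thousand
  units; beyond that it subsamples rather than using low-rank
  approximations.
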