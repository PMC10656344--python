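# missem

Estimation and diagnosis of linear structural equation models when data are
missing **not** at random.

Complete-case analysis and "ignorable likelihood" methods (FIML, multiple
imputation) are routinely justified by a missing-at-random assumption.  In
many studies that assumption fails in one of two concrete ways: the
partially observed covariate drives missingness of the response, or the
response drives missingness of the covariate.  `missem` implements, for a
trivariate linear SEM, the estimators that remain consistent under each of
these violations, statistical tests that detect which violation is
present, and a *test-based estimator* that chains the two.  It is aimed at
biostatisticians and methodologists studying missing-data procedures:
every component is paired with a calibrated simulator so that consistency,
bias, test size and power claims can be verified by Monte Carlo.

## Model

Two jointly normal covariates and a linear response,

```
(X, Z) ~ N(0, Psi),   Psi = [[psiXX, psiXZ], [psiXZ, psiZZ]]
Y = beta0 + betaX X + betaZ Z + eps,   eps | X, Z ~ N(0, sigma2)
```

with `Z` always observed and selection indicators `Sx`, `Sy` for `X` and
`Y`.  Missingness is generated (and modeled) through probit selection:

```
My* = gamma0 + gammaX X + gammaZ Z + u0,   Sy = 1{My* <= 0}
Mx* = alpha0 + alphaZ Z + alphaY Y + u1,   Sx = 1{Mx* <= 0}
```

The mechanism labels are **R-MAR** (`gammaX = alphaY = 0`; selection
depends on `Z` only), **MNAR-X** (`X -> Sy`), **MNAR-Y** (`Y -> Sx`), and
**MNAR-XY** (both).  Violation strength is parameterized by the partial
correlations `Cor(My*, X | Z)` and `Cor(Mx*, Y | X, Z)`.

Estimators: saturated-Gaussian FIML (`SEM`); the data-deletion estimators
`SEM-X` (discard `Y` where `X` is missing) and `SEM-Y` (the mirror image),
which are consistent under MNAR-X and MNAR-Y respectively; complete-case
`OLS` and inverse-probability-weighted `WLS-X` for the conditional
distribution `P(Y|X,Z)`; and the doubly weighted pseudo-ML `SEM-XY` for
the joint distribution under MNAR-XY.  Diagnostics: a heteroscedastic-
regression likelihood-ratio test (chi-square, 3 df) and a kernel
conditional-independence (KCI) test of R-MAR against each violation.  The
test-based estimator runs both diagnostics and dispatches to `SEM-X`,
`SEM-Y`, or `SEM`.  See `docs/methods.md` for assumptions, numerics, and
limitations.

## Worked example

Simulate a sample of 2000 with a strong `X -> Sy` violation (partial
correlation 0.8, half of each variable observed), then compare naive FIML
with the test-based estimator:

```python
import missem as ms

params = ms.SemParams(beta0=1, betaX=1, betaZ=1, sigma2=1,
                      psiXX=1, psiZZ=1, psiXZ=0.5)
spec = ms.MissingnessSpec(rhoMyX=0.8, rhoMxY=0.0, Px=0.5, Py=0.5)
ds = ms.simulate_dataset(params, spec, 2000, seed=1)

naive = ms.fit_fiml(ds)
result, decision = ms.test_based_estimate(ds, alpha=0.05, test="LRT")
```

Output (printed values from this exact run):

```
complete cases: 689 of 2000
naive FIML    psiXZ = 0.438 (SE 0.034)
LRT p-values: MNAR-X 4.97e-74, MNAR-Y 0.449
verdict: MNAR-X -> dispatched SEM-X
test-based    psiXZ = 0.484 (SE 0.035)
              betaX = 1.018, betaZ = 0.959
```

Naive FIML, which wrongly assumes the missingness ignorable, estimates the
X–Z covariance at 0.438 — almost two standard errors below the generating
value 0.5.  The MNAR-X diagnostic rejects decisively while the MNAR-Y
diagnostic does not, so the procedure dispatches the `SEM-X` deletion
estimator, whose estimate 0.484 is within one standard error of the truth.

The same pipeline is available from a shell:

```
missem simulate --params params.json --spec spec.json --n 2000 --seed 1 --out data.csv
missem fit --method sem --data data.csv --out naive.json
missem diagnose --data data.csv --test lrt --out tests.json
missem autofit --data data.csv --alpha 0.05 --test lrt --out result.json
missem study mc --config study.json --seed 7 --out table.csv
```

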