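"""Diagnostic tests of realistic-MAR against specific MNAR alternatives.

R-MAR (missingness depending only on the always-observed Z) is testable
against the two violations this package handles:

- MNAR-X (path ``X -> Sy``): among units with X observed, test
  ``X* independent of Sy given Z``;
- MNAR-Y (path ``Y -> Sx``): among units with Y observed, test
  ``Y* independent of Sx given Z``.

Conditioning on the tested variable being observed makes both statements
involve only observed quantities, hence testable.

Two tests are provided.  The parametric likelihood-ratio test fits a
heteroscedastic Gaussian regression of the tested variable on
``(1, Z, S, S*Z)`` where the residual variance differs by the selection
group, against the pooled homoscedastic null — three constraints, so the
statistic is referred to chi-square(3).  Under joint normality this tests
exactly the first two conditional moments, which is what covariance-model
estimation requires.  The nonparametric alternative is the kernel
conditional independence (KCI) test: Gaussian kernels with median-heuristic
bandwidths on standardized inputs, kernel-ridge residualization with
respect to Z, and a two-moment gamma approximation to the null of the trace
statistic.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2, gamma as gamma_dist

from .simulate import IncompleteDataset

__all__ = ["TestResult", "HetRegFit", "lrt_rmar", "kci_rmar", "power_simulation"]

#: Minimum units per selection group for a test to be feasible.
MIN_GROUP_SIZE = 5
#: Working samples above this size are subsampled for KCI (dense kernels).
KCI_MAX_N = 5000


@dataclass
class HetRegFit:
    """Fitted heteroscedastic regression underlying the LRT.

    Mean model ``V = delta0 + delta1*Z + delta2*S + delta3*S*Z`` with
    group residual variances ``sigma0sq`` (S=0) and ``sigma1sq`` (S=1).
    """

    delta0: float
    delta1: float
    delta2: float
    delta3: float
    sigma0sq: float
    sigma1sq: float
    loglik_alt: float
    loglik_null: float
    group_counts: tuple


@dataclass
class TestResult:
    """Outcome of one R-MAR diagnostic test."""

    test_name: str  # "LRT" or "KCI"
    target: str  # "MNAR-X" or "MNAR-Y"
    statistic: float | None
    df: int | None
    pvalue: float | None
    n_used: int
    feasible: bool
    warnings: list = field(default_factory=list)
    details: object = None

    def to_dict(self) -> dict:
        return {
            "test": self.test_name,
            "target": self.target,
            "statistic": None if self.statistic is None else float(self.statistic),
            "df": self.df,
            "pvalue": None if self.pvalue is None else float(self.pvalue),
            "nUsed": self.n_used,
            "feasible": self.feasible,
            "warnings": list(self.warnings),
        }


def _working_sample(ds: IncompleteDataset, target: str):
    """(tested variable, indicator, z) for the given alternative."""
    if target == "MNAR-X":
        rows = ds.sx.astype(bool)
        tested = np.ma.getdata(ds.xstar)[rows]
        indicator = ds.sy[rows].astype(int)
    elif target == "MNAR-Y":
        rows = ds.sy.astype(bool)
        tested = np.ma.getdata(ds.ystar)[rows]
        indicator = ds.sx[rows].astype(int)
    else:
        raise ValueError(f"target must be 'MNAR-X' or 'MNAR-Y', got {target!r}")
    return tested, indicator, ds.z[rows]


def _ols_ml(y, design):
    """OLS coefficients, ML residual variance and Gaussian log-likelihood."""
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    n = y.shape[0]
    s2 = float(resid @ resid) / n
    ll = -0.5 * n * (np.log(2 * np.pi) + np.log(s2) + 1.0)
    return coef, s2, ll


def lrt_rmar(ds: IncompleteDataset, target: str) -> TestResult:
    """Heteroscedastic-regression likelihood-ratio test of R-MAR.

    The alternative fits a separate regression line and ML residual
    variance within each selection group (equivalent to the interacted
    heteroscedastic model); the null pools both groups into one line and
    one variance.  The statistic ``n log s2_pooled - sum_g n_g log s2_g``
    is referred to chi-square with 3 degrees of freedom.

    Returns ``feasible=False`` (p-value absent) when either selection group
    has fewer than 5 units in the working sample.
    """
    v, s, z = _working_sample(ds, target)
    n = v.shape[0]
    counts = (int((s == 0).sum()), int((s == 1).sum()))
    warns = []
    if min(counts) < MIN_GROUP_SIZE:
        warns.append(
            f"{target} LRT infeasible: selection groups of sizes {counts} "
            f"(minimum {MIN_GROUP_SIZE})"
        )
        _warnings.warn(warns[-1], RuntimeWarning, stacklevel=2)
        return TestResult("LRT", target, None, 3, None, n, False, warns)

    fits = {}
    ll_alt = 0.0
    for g in (0, 1):
        rows = s == g
        coef, s2, ll = _ols_ml(v[rows], np.column_stack([np.ones(rows.sum()), z[rows]]))
        fits[g] = (coef, s2)
        ll_alt += ll
    coef0, s2_0 = fits[0]
    coef1, s2_1 = fits[1]
    _, s2_null, ll_null = _ols_ml(v, np.column_stack([np.ones(n), z]))
    stat = float(
        n * np.log(s2_null) - counts[0] * np.log(s2_0) - counts[1] * np.log(s2_1)
    )
    stat = max(stat, 0.0)
    pvalue = float(chi2.sf(stat, df=3))
    details = HetRegFit(
        delta0=float(coef0[0]),
        delta1=float(coef0[1]),
        delta2=float(coef1[0] - coef0[0]),
        delta3=float(coef1[1] - coef0[1]),
        sigma0sq=s2_0,
        sigma1sq=s2_1,
        loglik_alt=ll_alt,
        loglik_null=ll_null,
        group_counts=counts,
    )
    return TestResult("LRT", target, stat, 3, pvalue, n, True, warns, details)


# ---------------------------------------------------------------------------
# KCI test
# ---------------------------------------------------------------------------


def _standardize(a):
    a = np.asarray(a, dtype=float)
    sd = a.std()
    return (a - a.mean()) / sd if sd > 0 else a - a.mean()


def _gaussian_kernel(block):
    """Gaussian kernel matrix with median-heuristic bandwidth."""
    block = np.atleast_2d(block.T).T  # ensure (n, d)
    sq = ((block[:, None, :] - block[None, :, :]) ** 2).sum(axis=2)
    med = np.median(sq[np.triu_indices_from(sq, k=1)])
    if med <= 0:
        med = 1.0
    return np.exp(-0.5 * sq / med)


def _center(K):
    n = K.shape[0]
    H = np.eye(n) - np.ones((n, n)) / n
    return H @ K @ H


def kci_rmar(
    ds: IncompleteDataset,
    target: str,
    *,
    epsilon: float = 1e-3,
    null_method: str = "gamma",
    n_permutations: int = 500,
    seed: int = 0,
) -> TestResult:
    """Kernel conditional independence test of R-MAR.

    On the working sample, tests (tested variable) independent of (selection
    indicator) given Z.  The tested-variable kernel is computed on the
    standardized (variable, Z/2) block as in the original construction, the
    indicator enters its own Gaussian kernel, and both centered kernel
    matrices are residualized by ``R = eps * (Kz_centered + eps*I)^-1``.
    The statistic is ``trace(Kv|z * Ks|z) / n``; its null is approximated by
    moment-matching a gamma distribution on the spectral decomposition of
    the residualized matrices (``null_method="gamma"``, default), or by
    permutation of the indicator block (``null_method="permutation"``).

    Working samples larger than 5000 are subsampled (seeded) with a warning.
    """
    v, s, z = _working_sample(ds, target)
    n = v.shape[0]
    counts = (int((s == 0).sum()), int((s == 1).sum()))
    warns = []
    if min(counts) < MIN_GROUP_SIZE:
        warns.append(
            f"{target} KCI infeasible: selection groups of sizes {counts} "
            f"(minimum {MIN_GROUP_SIZE})"
        )
        _warnings.warn(warns[-1], RuntimeWarning, stacklevel=2)
        return TestResult("KCI", target, None, None, None, n, False, warns)
    if n > KCI_MAX_N:
        warns.append(f"KCI working sample {n} subsampled to {KCI_MAX_N}")
        _warnings.warn(warns[-1], RuntimeWarning, stacklevel=2)
        idx = np.random.default_rng(seed).choice(n, size=KCI_MAX_N, replace=False)
        v, s, z = v[idx], s[idx], z[idx]
        n = KCI_MAX_N

    v_std = _standardize(v)
    z_std = _standardize(z)
    s_std = _standardize(s.astype(float))

    K_v = _gaussian_kernel(np.column_stack([v_std, 0.5 * z_std]))
    K_s = _gaussian_kernel(s_std[:, None])
    K_z = _gaussian_kernel(z_std[:, None])

    Kv_c = _center(K_v)
    Ks_c = _center(K_s)
    Kz_c = _center(K_z)

    R = epsilon * np.linalg.inv(Kz_c + epsilon * np.eye(n))
    KvR = R @ Kv_c @ R.T
    KsR = R @ Ks_c @ R.T

    stat_raw = float(np.einsum("ij,ji->", KvR, KsR))
    statistic = stat_raw / n

    if null_method == "permutation":
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_permutations):
            perm = rng.permutation(n)
            if float(np.einsum("ij,ji->", KvR, KsR[np.ix_(perm, perm)])) >= stat_raw:
                count += 1
        pvalue = (count + 1) / (n_permutations + 1)
    else:
        # two-moment gamma approximation on the spectral product structure
        wv, Vv = np.linalg.eigh(0.5 * (KvR + KvR.T))
        ws, Vs = np.linalg.eigh(0.5 * (KsR + KsR.T))
        thresh = 1e-5
        keep_v = wv > max(wv.max(), 0) * thresh
        keep_s = ws > max(ws.max(), 0) * thresh
        Pv = Vv[:, keep_v] * np.sqrt(wv[keep_v])
        Ps = Vs[:, keep_s] * np.sqrt(ws[keep_s])
        # columns of U are elementwise products of eigen-directions
        U = (Pv[:, :, None] * Ps[:, None, :]).reshape(n, -1)
        if U.shape[1] > n:
            prod = U @ U.T
        else:
            prod = U.T @ U
        mean_appr = float(np.trace(prod))
        var_appr = 2.0 * float(np.sum(prod * prod.T))
        if mean_appr <= 0 or var_appr <= 0:
            pvalue = 1.0
        else:
            k = mean_appr**2 / var_appr
            theta = var_appr / mean_appr
            pvalue = float(gamma_dist.sf(stat_raw, a=k, scale=theta))
    pvalue = float(min(max(pvalue, 0.0), 1.0))
    details = {
        "epsilon": epsilon,
        "null_method": null_method,
        "group_counts": counts,
    }
    return TestResult("KCI", target, statistic, None, pvalue, n, True, warns, details)


def power_simulation(
    *,
    rho: float,
    px: float,
    n: int,
    reps: int,
    alpha: float = 0.05,
    tests: tuple = ("LRT",),
    seed: int = 0,
    params=None,
) -> dict:
    """Empirical rejection rates of the R-MAR tests under a Y -> Sx design.

    X is the only partially observed variable (``Py = 1``); its missingness
    follows the probit model with partial correlation ``rho`` between the
    latent index and Y, and marginal observation probability ``px``.  Each
    replicate runs the requested tests with target MNAR-Y at level
    ``alpha``.  Infeasible replicates count as non-rejections.
    """
    from .model import SemParams
    from .simulate import MissingnessSpec, simulate_dataset

    if params is None:
        params = SemParams(
            beta0=1, betaX=1, betaZ=1, sigma2=1, psiXX=1, psiZZ=1, psiXZ=0.5
        )
    spec = MissingnessSpec(rhoMyX=0.0, rhoMxY=rho, Px=px, Py=1.0)
    rejections = {t: 0 for t in tests}
    feasible = {t: 0 for t in tests}
    for rep in range(reps):
        rng = np.random.default_rng(np.random.SeedSequence([seed, rep]))
        ds = simulate_dataset(params, spec, n, rng)
        for t in tests:
            if t == "LRT":
                res = lrt_rmar(ds, "MNAR-Y")
            else:
                res = kci_rmar(ds, "MNAR-Y", seed=rep)
            if res.feasible:
                feasible[t] += 1
                if res.pvalue <= alpha:
                    rejections[t] += 1
    return {
        "rho": rho,
        "px": px,
        "n": n,
        "reps": reps,
        "alpha": alpha,
        "rejection_rate": {t: rejections[t] / reps for t in tests},
        "feasible_rate": {t: feasible[t] / reps for t in tests},
    }
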