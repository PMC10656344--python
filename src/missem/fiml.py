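"""Maximum-likelihood estimators for the incomplete trivariate Gaussian model.

``fit_fiml`` maximizes the observed-data ("full information") Gaussian
log-likelihood

    sum_i log N( v_i[obs_i] ; mu[obs_i], Sigma[obs_i, obs_i] )

over the saturated mean vector and covariance matrix of ``(X, Z, Y)``, then
maps the moments to structural parameters through the just-identified SEM
bijection.  Because there are only four missingness patterns (complete,
X missing, Y missing, both missing), the likelihood and the EM updates are
functions of per-pattern sufficient statistics, so each iteration costs
O(patterns) rather than O(n).  EM is run to near-convergence and the optimum
is then polished with Newton steps on the 9-dimensional saturated parameter
vector, so downstream exact identities (e.g. complete-case OLS coinciding
with the deletion estimator's conditional parameters) hold to optimizer
precision.

The deletion estimators ``fit_sem_x`` / ``fit_sem_y`` are FIML applied after
the corresponding deletion operator, and ``fit_ols_cc`` is complete-case
least squares for the conditional distribution only.

Standard errors: observed information by central finite differences of the
pattern log-likelihood at the MLE, mapped to the structural scale by the
delta method.  Units with both X and Y missing contribute a Z-only
likelihood term (the standard FIML convention); this choice is recorded in
the result's ``extras``.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .model import ImpliedMoments, SemParams, params_from_moments
from .simulate import IncompleteDataset, delete_for_mnar_x, delete_for_mnar_y

__all__ = [
    "EstimateResult",
    "fit_fiml",
    "fit_sem_x",
    "fit_sem_y",
    "fit_ols_cc",
    "observed_loglik",
    "pattern_statistics",
    "STRUCTURAL_NAMES",
    "CONDITIONAL_NAMES",
    "EstimationError",
]

STRUCTURAL_NAMES = (
    "beta0",
    "betaX",
    "betaZ",
    "sigma2",
    "psiXX",
    "psiZZ",
    "psiXZ",
    "muX",
    "muZ",
)
#: Parameters of P(Y | X, Z) only — what the conditional-distribution
#: estimators (OLS, WLS-X) report.
CONDITIONAL_NAMES = ("beta0", "betaX", "betaZ", "sigma2")

_LOG2PI = float(np.log(2.0 * np.pi))


class EstimationError(RuntimeError):
    """Raised when an estimator cannot be computed on the given data."""


@dataclass
class EstimateResult:
    """Point estimates, standard errors and fit metadata for one estimator.

    ``estimates`` and ``se`` map parameter names to values; conditional-only
    methods carry just the Y-equation parameters and omit the psi's.
    """

    method: str
    estimates: dict
    se: dict
    n_used: dict
    converged: bool = True
    loglik: float | None = None
    warnings: list = field(default_factory=list)
    extras: dict = field(default_factory=dict)

    @property
    def params(self) -> SemParams:
        """Structural parameters, available for joint-distribution methods."""
        missing = [k for k in STRUCTURAL_NAMES if k not in self.estimates]
        if missing:
            raise AttributeError(
                f"method {self.method!r} does not estimate {missing}"
            )
        return SemParams(**{k: self.estimates[k] for k in STRUCTURAL_NAMES})

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "estimates": {k: float(v) for k, v in self.estimates.items()},
            "se": {k: float(v) for k, v in self.se.items()},
            "nUsed": self.n_used,
            "converged": bool(self.converged),
            "loglik": None if self.loglik is None else float(self.loglik),
            "warnings": list(self.warnings),
            "extras": self.extras,
        }


# ---------------------------------------------------------------------------
# pattern sufficient statistics and observed-data log-likelihood
# ---------------------------------------------------------------------------

_PATTERN_NAMES = {
    (True, True): "complete",
    (True, False): "y_missing",
    (False, True): "x_missing",
    (False, False): "both_missing",
}


def pattern_statistics(ds: IncompleteDataset) -> list[dict]:
    """Per-missingness-pattern counts, sums and cross-product sums.

    Each entry holds the observed coordinate indices into the (X, Z, Y)
    ordering, the unit count, the sum of the observed sub-vector and the sum
    of its outer products.  These are the only data reductions FIML needs.
    """
    x = np.ma.getdata(ds.xstar)
    y = np.ma.getdata(ds.ystar)
    v = np.column_stack([x, ds.z, y])
    sx = ds.sx.astype(bool)
    sy = ds.sy.astype(bool)
    out = []
    for x_obs in (True, False):
        for y_obs in (True, False):
            rows = (sx == x_obs) & (sy == y_obs)
            n_g = int(rows.sum())
            if n_g == 0:
                continue
            obs = tuple(
                i for i, keep in enumerate([x_obs, True, y_obs]) if keep
            )
            sub = v[np.ix_(rows, obs)]
            s = sub.sum(axis=0)
            S = sub.T @ sub
            out.append(
                {
                    "name": _PATTERN_NAMES[(x_obs, y_obs)],
                    "obs": obs,
                    "n": n_g,
                    "sum": s,
                    "sumsq": S,
                    # flat float copies for the scalar likelihood hot path
                    "_s": tuple(float(a) for a in s),
                    "_S": tuple(tuple(float(a) for a in row) for row in S),
                }
            )
    return out


def _loglik_patterns(stats: list[dict], mean: np.ndarray, cov: np.ndarray) -> float:
    """Observed-data log-likelihood from pattern sufficient statistics.

    Written in explicit scalar form for the 1/2/3-dimensional observed
    blocks: this sits in the inner loop of both EM and the finite-difference
    information matrix, where generic linalg dispatch dominates runtime.
    Returns -inf when the relevant covariance block is not positive
    definite.
    """
    from math import log

    m0, m1, m2 = float(mean[0]), float(mean[1]), float(mean[2])
    c00 = float(cov[0, 0]); c01 = float(cov[0, 1]); c02 = float(cov[0, 2])
    c11 = float(cov[1, 1]); c12 = float(cov[1, 2]); c22 = float(cov[2, 2])
    mu = (m0, m1, m2)
    ll = 0.0
    for g in stats:
        o = g["obs"]
        n_g = g["n"]
        s = g["_s"]
        S = g["_S"]
        k = len(o)
        if k == 3:
            det = (
                c00 * (c11 * c22 - c12 * c12)
                - c01 * (c01 * c22 - c12 * c02)
                + c02 * (c01 * c12 - c11 * c02)
            )
            if det <= 0 or c00 <= 0 or c00 * c11 - c01 * c01 <= 0:
                return -np.inf
            i00 = (c11 * c22 - c12 * c12) / det
            i01 = (c02 * c12 - c01 * c22) / det
            i02 = (c01 * c12 - c02 * c11) / det
            i11 = (c00 * c22 - c02 * c02) / det
            i12 = (c02 * c01 - c00 * c12) / det
            i22 = (c00 * c11 - c01 * c01) / det
            M00 = S[0][0] - 2 * s[0] * m0 + n_g * m0 * m0
            M11 = S[1][1] - 2 * s[1] * m1 + n_g * m1 * m1
            M22 = S[2][2] - 2 * s[2] * m2 + n_g * m2 * m2
            M01 = S[0][1] - s[0] * m1 - s[1] * m0 + n_g * m0 * m1
            M02 = S[0][2] - s[0] * m2 - s[2] * m0 + n_g * m0 * m2
            M12 = S[1][2] - s[1] * m2 - s[2] * m1 + n_g * m1 * m2
            tr = (
                i00 * M00 + i11 * M11 + i22 * M22
                + 2 * (i01 * M01 + i02 * M02 + i12 * M12)
            )
            ll += -0.5 * (n_g * (3 * _LOG2PI + log(det)) + tr)
        elif k == 2:
            i, j = o
            mi, mj = mu[i], mu[j]
            a = float(cov[i, i]); b = float(cov[i, j]); d = float(cov[j, j])
            det = a * d - b * b
            if det <= 0 or a <= 0:
                return -np.inf
            M00 = S[0][0] - 2 * s[0] * mi + n_g * mi * mi
            M01 = S[0][1] - s[0] * mj - s[1] * mi + n_g * mi * mj
            M11 = S[1][1] - 2 * s[1] * mj + n_g * mj * mj
            tr = (d * M00 - 2 * b * M01 + a * M11) / det
            ll += -0.5 * (n_g * (2 * _LOG2PI + log(det)) + tr)
        else:
            i = o[0]
            v = float(cov[i, i])
            if v <= 0:
                return -np.inf
            M = S[0][0] - 2 * s[0] * mu[i] + n_g * mu[i] * mu[i]
            ll += -0.5 * (n_g * (_LOG2PI + log(v)) + M / v)
    return ll


def observed_loglik(ds: IncompleteDataset, mean: np.ndarray, cov: np.ndarray) -> float:
    """Observed-data Gaussian log-likelihood at a saturated (mean, cov)."""
    return _loglik_patterns(pattern_statistics(ds), np.asarray(mean, float), np.asarray(cov, float))


# ---------------------------------------------------------------------------
# EM + Newton on the saturated parameters
# ---------------------------------------------------------------------------


def _em_step(stats, mean, cov, n):
    """One EM update of (mean, cov) from pattern sufficient statistics."""
    T1 = np.zeros(3)
    T2 = np.zeros((3, 3))
    for g in stats:
        o = list(g["obs"])
        m = [i for i in range(3) if i not in o]
        n_g, s, S = g["n"], g["sum"], g["sumsq"]
        T1[o] += s
        T2[np.ix_(o, o)] += S
        if not m:
            continue
        mu_o, mu_m = mean[o], mean[m]
        Soo = cov[np.ix_(o, o)]
        B = np.linalg.solve(Soo, cov[np.ix_(o, m)]).T  # Sigma_mo Sigma_oo^-1
        dso = s - n_g * mu_o
        t1m = n_g * mu_m + B @ dso
        T1[m] += t1m
        Mo = S - np.outer(s, mu_o) - np.outer(mu_o, s) + n_g * np.outer(mu_o, mu_o)
        C_mo = np.outer(mu_m, s) + B @ (S - np.outer(mu_o, s))
        T2[np.ix_(m, o)] += C_mo
        T2[np.ix_(o, m)] += C_mo.T
        cond_cov = cov[np.ix_(m, m)] - B @ cov[np.ix_(o, m)]
        Emm = (
            n_g * np.outer(mu_m, mu_m)
            + np.outer(mu_m, dso) @ B.T
            + B @ np.outer(dso, mu_m)
            + B @ Mo @ B.T
        )
        T2[np.ix_(m, m)] += n_g * cond_cov + Emm
    mean_new = T1 / n
    cov_new = T2 / n - np.outer(mean_new, mean_new)
    cov_new = 0.5 * (cov_new + cov_new.T)
    return mean_new, cov_new


_TRIL = np.tril_indices(3)


def _pack(mean, cov):
    return np.concatenate([mean, cov[_TRIL]])


def _unpack(theta):
    mean = theta[:3]
    cov = np.zeros((3, 3))
    cov[_TRIL] = theta[3:]
    cov = cov + np.tril(cov, -1).T
    return mean, cov


def _start_values(ds: IncompleteDataset):
    """Available-case means/variances with complete-case correlations,
    ridge-repaired to positive definite if needed."""
    x = np.ma.getdata(ds.xstar)
    y = np.ma.getdata(ds.ystar)
    sx = ds.sx.astype(bool)
    sy = ds.sy.astype(bool)
    cc = sx & sy
    mean = np.array(
        [x[sx].mean(), ds.z.mean(), y[sy].mean()]
    )
    var = np.array(
        [x[sx].var() if sx.sum() > 1 else 1.0, ds.z.var(), y[sy].var() if sy.sum() > 1 else 1.0]
    )
    var = np.maximum(var, 1e-8)
    corr = np.eye(3)
    if cc.sum() >= 3:
        v = np.column_stack([x[cc], ds.z[cc], y[cc]])
        with np.errstate(invalid="ignore", divide="ignore"):
            c = np.corrcoef(v.T)
        if np.all(np.isfinite(c)):
            corr = c
    cov = corr * np.sqrt(np.outer(var, var))
    cov = 0.5 * (cov + cov.T)
    eps = 1e-6
    while np.linalg.eigvalsh(cov)[0] <= 1e-10:
        cov = cov + eps * np.diag(var)
        eps *= 10
    return mean, cov


def _numeric_grad_hess(f, theta, rel_step=1e-5):
    """Central finite-difference gradient and Hessian of scalar f."""
    p = theta.size
    h = rel_step * np.maximum(1.0, np.abs(theta))
    grad = np.zeros(p)
    for i in range(p):
        e = np.zeros(p)
        e[i] = h[i]
        grad[i] = (f(theta + e) - f(theta - e)) / (2 * h[i])
    hess = np.zeros((p, p))
    f0 = f(theta)
    for i in range(p):
        ei = np.zeros(p)
        ei[i] = h[i]
        hess[i, i] = (f(theta + ei) - 2 * f0 + f(theta - ei)) / h[i] ** 2
        for j in range(i):
            ej = np.zeros(p)
            ej[j] = h[j]
            hess[i, j] = hess[j, i] = (
                f(theta + ei + ej)
                - f(theta + ei - ej)
                - f(theta - ei + ej)
                + f(theta - ei - ej)
            ) / (4 * h[i] * h[j])
    return grad, hess


def _monotone_mle(stats, n):
    """Exact MLE when the observed sets form a chain (monotone missingness).

    For nested patterns O_1 subset O_2 subset ... the Gaussian likelihood
    factorizes into variation-independent regression blocks: each newly
    observed variable is regressed (with ML residual covariance) on the
    previous block using every unit that observes it, and the joint moments
    are assembled from the chain.  This covers complete data and both
    deletion estimators, where it makes identities such as "complete-case
    OLS equals the deletion estimator's conditional parameters" exact.

    Returns (mean, cov) or None when the patterns are not monotone or a
    regression block is degenerate.
    """
    obs_sets = sorted((set(g["obs"]) for g in stats), key=len)
    for a, b in zip(obs_sets, obs_sets[1:]):
        if not a <= b:
            return None
    levels = sorted(stats, key=lambda g: len(g["obs"]))

    # accumulate sufficient statistics from the top: units observing a
    # superset of level j contribute to level j's regression
    mean = np.zeros(3)
    cov = np.zeros((3, 3))
    prev: list[int] = []
    for j, g in enumerate(levels):
        obs = list(g["obs"])
        new = [i for i in obs if i not in prev]
        # pooled stats over this level and all higher (superset) levels,
        # restricted to the coordinates in `obs`
        n_pool = 0
        s_pool = np.zeros(len(obs))
        S_pool = np.zeros((len(obs), len(obs)))
        for h in levels[j:]:
            sel = [h["obs"].index(i) for i in obs]
            n_pool += h["n"]
            s_pool += h["sum"][sel]
            S_pool += h["sumsq"][np.ix_(sel, sel)]
        if n_pool <= len(obs):
            return None
        loc = {v: k for k, v in enumerate(obs)}
        ip = [loc[v] for v in prev]
        inw = [loc[v] for v in new]
        if not prev:
            mu_new = s_pool[inw] / n_pool
            R = S_pool[np.ix_(inw, inw)] / n_pool - np.outer(mu_new, mu_new)
            mean[new] = mu_new
            cov[np.ix_(new, new)] = R
        else:
            # multivariate regression of `new` on (1, prev) by normal equations
            q = len(prev)
            G = np.zeros((q + 1, q + 1))
            G[0, 0] = n_pool
            G[0, 1:] = s_pool[ip]
            G[1:, 0] = s_pool[ip]
            G[1:, 1:] = S_pool[np.ix_(ip, ip)]
            rhs = np.zeros((q + 1, len(new)))
            rhs[0, :] = s_pool[inw]
            rhs[1:, :] = S_pool[np.ix_(ip, inw)]
            try:
                coefs = np.linalg.solve(G, rhs)  # (1+q) x |new|
            except np.linalg.LinAlgError:
                return None
            a = coefs[0, :]
            B = coefs[1:, :].T  # |new| x q
            # ML residual covariance: (S_nn - coefs' G coefs residual form)/n
            Snn = S_pool[np.ix_(inw, inw)]
            R = (Snn - rhs.T @ coefs) / n_pool
            R = 0.5 * (R + R.T)
            mu_prev = mean[prev]
            S_prev = cov[np.ix_(prev, prev)]
            mean[new] = a + B @ mu_prev
            C_np = B @ S_prev
            cov[np.ix_(new, prev)] = C_np
            cov[np.ix_(prev, new)] = C_np.T
            cov[np.ix_(new, new)] = R + B @ S_prev @ B.T
        prev = prev + new
    if len(prev) < 3:
        return None  # some variable never observed; joint model unidentified
    if np.linalg.eigvalsh(0.5 * (cov + cov.T))[0] <= 0:
        return None
    return mean, 0.5 * (cov + cov.T)


def _maximize(stats, n, mean0, cov0, em_tol=1e-10, max_em_iter=5000):
    """EM to near-convergence, then Newton polish on the packed parameters.

    Returns (mean, cov, loglik, converged, em_iters, trace).  EM guarantees
    a monotone likelihood ascent from anywhere; Newton (with a Hessian
    computed once and reused across steps) sharpens the optimum to roughly
    machine precision, which the exact coefficient identities rely on.  A
    Newton step that fails to improve the likelihood is discarded.
    """
    mean, cov = mean0.copy(), cov0.copy()
    ll = _loglik_patterns(stats, mean, cov)
    trace = [ll]
    converged = False
    it = 0
    # switch to Newton once EM has localized the optimum
    em_switch_tol = max(em_tol, 1e-6 * max(1.0, abs(ll)) * 1e-2)
    for it in range(1, max_em_iter + 1):
        mean, cov = _em_step(stats, mean, cov, n)
        ll_new = _loglik_patterns(stats, mean, cov)
        trace.append(ll_new)
        if abs(ll_new - ll) < em_switch_tol:
            ll = ll_new
            converged = True
            break
        ll = ll_new

    def negll(theta):
        m, c = _unpack(theta)
        return -_loglik_patterns(stats, m, c)

    def grad_only(theta):
        p = theta.size
        h = 1e-5 * np.maximum(1.0, np.abs(theta))
        g = np.zeros(p)
        for i in range(p):
            e = np.zeros(p)
            e[i] = h[i]
            g[i] = (negll(theta + e) - negll(theta - e)) / (2 * h[i])
        return g

    theta = _pack(mean, cov)
    grad, hess = _numeric_grad_hess(negll, theta)
    grad_tol = 1e-9 * max(1.0, n)
    for outer in range(40):
        if float(np.max(np.abs(grad))) < grad_tol:
            converged = True
            break
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        scale = 1.0
        improved = False
        for _ in range(30):
            cand = theta - scale * step
            ll_cand = -negll(cand)
            if np.isfinite(ll_cand) and ll_cand >= ll - 1e-12:
                improved = ll_cand > ll - 1e-12
                theta, ll = cand, ll_cand
                break
            scale *= 0.5
        if not improved:
            break
        grad = grad_only(theta)
        if outer in (6, 14, 25):  # refresh curvature if convergence is slow
            _, hess = _numeric_grad_hess(negll, theta)
    if float(np.max(np.abs(grad))) < 1e-6 * max(1.0, n):
        converged = True
    mean, cov = _unpack(theta)
    return mean, cov, ll, converged, it, trace


def _structural_from_theta(theta):
    mean, cov = _unpack(theta)
    p = params_from_moments(ImpliedMoments(mean=mean, cov=cov))
    return np.array([getattr(p, k) for k in STRUCTURAL_NAMES])


def _fiml_se(stats, n, theta):
    """Observed-information SEs on the saturated scale, delta-mapped to the
    structural scale.  Returns (se dict, warning list)."""
    warns = []

    def negll(t):
        m, c = _unpack(t)
        return -_loglik_patterns(stats, m, c)

    _, hess = _numeric_grad_hess(negll, theta)
    try:
        cov_sat = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        warns.append("observed information singular; standard errors unavailable")
        return {k: np.nan for k in STRUCTURAL_NAMES}, warns
    # delta method: numeric Jacobian of the structural map
    p = theta.size
    h = 1e-6 * np.maximum(1.0, np.abs(theta))
    J = np.zeros((len(STRUCTURAL_NAMES), p))
    for i in range(p):
        e = np.zeros(p)
        e[i] = h[i]
        J[:, i] = (_structural_from_theta(theta + e) - _structural_from_theta(theta - e)) / (
            2 * h[i]
        )
    cov_struct = J @ cov_sat @ J.T
    var = np.diag(cov_struct).copy()
    if np.any(var < -1e-8):
        warns.append("negative variance from observed information; check convergence")
    var[var < 0] = np.nan
    return dict(zip(STRUCTURAL_NAMES, np.sqrt(var))), warns


def fit_fiml(
    ds: IncompleteDataset,
    *,
    compute_se: bool = True,
    em_tol: float = 1e-10,
    max_em_iter: int = 5000,
    method_label: str = "SEM",
    force_em: bool = False,
) -> EstimateResult:
    """Saturated-Gaussian FIML over all available data ("SEM" estimator).

    When the missingness patterns are monotone (nested observed sets — in
    particular complete data and both deletion estimators), the exact
    factorized MLE is used; otherwise EM over pattern sufficient statistics
    with a Newton polish.  ``force_em=True`` bypasses the closed form (the
    two routes agree to optimizer tolerance and are cross-checked in the
    test suite).

    Raises
    ------
    EstimationError
        If n < 5 or there is no complete case (the joint model is then
        unidentified).
    """
    if ds.n < 5:
        raise EstimationError(f"FIML requires n >= 5, got n = {ds.n}")
    if int(ds.complete.sum()) < 1:
        raise EstimationError("FIML requires at least one complete case")
    stats = pattern_statistics(ds)
    solver = "em"
    em_iters = 0
    trace: list = []
    closed = None if force_em else _monotone_mle(stats, ds.n)
    if closed is not None:
        mean, cov = closed
        ll = _loglik_patterns(stats, mean, cov)
        converged = True
        solver = "monotone-exact"
    else:
        mean0, cov0 = _start_values(ds)
        mean, cov, ll, converged, em_iters, trace = _maximize(
            stats, ds.n, mean0, cov0, em_tol=em_tol, max_em_iter=max_em_iter
        )
    theta = _pack(mean, cov)
    params = params_from_moments(ImpliedMoments(mean=mean, cov=cov))
    estimates = {k: getattr(params, k) for k in STRUCTURAL_NAMES}
    warns = []
    if not converged:
        warns.append(f"EM did not converge within {max_em_iter} iterations")
        _warnings.warn(warns[-1], RuntimeWarning, stacklevel=2)
    if compute_se:
        se, se_warns = _fiml_se(stats, ds.n, theta)
        warns += se_warns
    else:
        se = {}
    counts = {g["name"]: g["n"] for g in stats}
    counts["n"] = ds.n
    return EstimateResult(
        method=method_label,
        estimates=estimates,
        se=se,
        n_used=counts,
        converged=converged,
        loglik=ll,
        warnings=warns,
        extras={
            "solver": solver,
            "em_iterations": em_iters,
            "em_loglik_trace": trace,
            "mean": mean.tolist(),
            "cov": cov.tolist(),
            "both_missing_handling": "Z-only likelihood contribution",
        },
    )


def fit_sem_x(ds: IncompleteDataset, **kwargs) -> EstimateResult:
    """Data-deletion estimator for MNAR-X: discard Y when X is missing, then FIML."""
    res = fit_fiml(delete_for_mnar_x(ds), method_label="SEM-X", **kwargs)
    return res


def fit_sem_y(ds: IncompleteDataset, **kwargs) -> EstimateResult:
    """Data-deletion estimator for MNAR-Y: discard X when Y is missing, then FIML."""
    res = fit_fiml(delete_for_mnar_y(ds), method_label="SEM-Y", **kwargs)
    return res


def fit_ols_cc(ds: IncompleteDataset) -> EstimateResult:
    """Complete-case OLS of Y on (1, X, Z) for the conditional distribution.

    The residual variance is reported in the ML convention (RSS / n_cc) for
    consistency with the likelihood-based estimators; coefficient standard
    errors are the conventional model-based ones.
    """
    cc = ds.complete.astype(bool)
    n_cc = int(cc.sum())
    if n_cc < 4:
        raise EstimationError(f"complete-case OLS requires >= 4 complete cases, got {n_cc}")
    x = np.ma.getdata(ds.xstar)[cc]
    y = np.ma.getdata(ds.ystar)[cc]
    z = ds.z[cc]
    design = np.column_stack([np.ones(n_cc), x, z])
    if np.linalg.matrix_rank(design) < 3:
        raise EstimationError("singular complete-case design matrix")
    fit = sm.OLS(y, design).fit()
    rss = float(fit.ssr)
    sigma2 = rss / n_cc
    estimates = {
        "beta0": float(fit.params[0]),
        "betaX": float(fit.params[1]),
        "betaZ": float(fit.params[2]),
        "sigma2": sigma2,
    }
    se = {
        "beta0": float(fit.bse[0]),
        "betaX": float(fit.bse[1]),
        "betaZ": float(fit.bse[2]),
        "sigma2": float(np.sqrt(2.0 / n_cc) * sigma2),
    }
    return EstimateResult(
        method="OLS",
        estimates=estimates,
        se=se,
        n_used={"complete": n_cc, "n": ds.n},
        converged=True,
        loglik=float(fit.llf),
    )
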