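"""Inverse-probability-weighted estimators for the MNAR-XY mechanism.

When both R-MAR violations are present (``X -> Sy`` and ``Y -> Sx``), neither
deletion estimator is consistent.  The estimating-equation route reweights
complete cases by the inverse of

    pi_joint = P(Sx=1 | Z, Y) * P(Sy=1 | X, Z)        (joint distribution)
    pi_cond  = P(Sx=1 | Z, Y)                          (conditional P(Y|X,Z))

yielding the SEM-XY pseudo-ML estimator of the full joint distribution and
the WLS-X weighted-least-squares estimator of the Y-equation only.  The two
selection probabilities factor along the m-graph: ``Sx`` depends on (Z, Y)
and ``Sy`` on (X, Z), so each selection model is fit by binary regression on
the largest subsample where its outcome varies and its covariates are
observed (the Sx-model on units with Y observed, the Sy-model on units with
X observed); the graph's independencies make those subsamples valid.

Standard errors are sandwich estimators treating the fitted weights as
fixed.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .fiml import (
    CONDITIONAL_NAMES,
    STRUCTURAL_NAMES,
    EstimateResult,
    EstimationError,
)
from .model import ImpliedMoments, params_from_moments
from .simulate import IncompleteDataset

__all__ = [
    "IpwWeights",
    "fit_selection_models",
    "oracle_weights",
    "fit_wls_x",
    "fit_sem_xy",
]

_PROB_FLOOR = 1e-6


@dataclass
class IpwWeights:
    """Fitted selection probabilities and weights for the complete cases.

    ``pix`` and ``piy`` are P(Sx=1 | Z, Y) and P(Sy=1 | X, Z) evaluated at
    the complete cases.  Weights are computed per target: ``1/pix`` for the
    conditional estimator, ``1/(pix*piy)`` for the joint estimator.  Fitted
    probabilities below 1e-6 are clipped with a positivity warning.
    """

    pix: np.ndarray
    piy: np.ndarray
    link: str
    sx_model: dict
    sy_model: dict
    warnings: list = field(default_factory=list)

    @property
    def weight_conditional(self) -> np.ndarray:
        return 1.0 / self.pix

    @property
    def weight_joint(self) -> np.ndarray:
        return 1.0 / (self.pix * self.piy)

    def diagnostics(self) -> dict:
        w = self.weight_joint
        return {
            "min_pix": float(self.pix.min()),
            "min_piy": float(self.piy.min()),
            "joint_weight_quantiles": {
                q: float(np.quantile(w, q)) for q in (0.0, 0.5, 0.95, 1.0)
            },
        }


def _binary_fit(endog, exog, link, model_name):
    cls = sm.Probit if link == "probit" else sm.Logit
    try:
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            res = cls(endog, exog).fit(disp=0, maxiter=200)
    except Exception as err:  # separation, non-convergence blow-ups
        raise EstimationError(f"{model_name} selection model failed to fit: {err}") from err
    if not np.all(np.isfinite(res.params)):
        raise EstimationError(f"{model_name} selection model returned non-finite coefficients")
    return res


def fit_selection_models(ds: IncompleteDataset, link: str = "probit") -> IpwWeights:
    """Fit the two binary selection models and evaluate them at complete cases.

    The Sx-model regresses ``sx`` on (1, z, y*) over units with ``sy = 1``;
    the Sy-model regresses ``sy`` on (1, z, x*) over units with ``sx = 1``.
    A model whose outcome does not vary in its fitting subsample is flagged
    degenerate and its probabilities are set to 1 with a warning.
    """
    if link not in ("probit", "logistic"):
        raise ValueError(f"link must be 'probit' or 'logistic', got {link!r}")
    x = np.ma.getdata(ds.xstar)
    y = np.ma.getdata(ds.ystar)
    sy_obs = ds.sy.astype(bool)
    sx_obs = ds.sx.astype(bool)
    cc = sx_obs & sy_obs
    warns = []

    def fit_one(endog, exog_cc_builder, sample, name):
        endog_s = endog[sample]
        n_s = int(sample.sum())
        if n_s < 10:
            raise EstimationError(f"{name} selection model needs >= 10 units, got {n_s}")
        if endog_s.min() == endog_s.max():
            warns.append(f"{name} indicator constant in fitting sample; probabilities set to 1")
            return np.ones(int(cc.sum())), {"degenerate": True, "coef": None}
        exog = exog_cc_builder(sample)
        res = _binary_fit(endog_s.astype(float), exog, link, name)
        probs = np.asarray(res.predict(exog_cc_builder(cc)))
        return probs, {
            "degenerate": False,
            "coef": {n: float(v) for n, v in zip(["const", "z", name[-1].lower()], res.params)},
            "n_fit": n_s,
        }

    pix, sx_summary = fit_one(
        ds.sx,
        lambda rows: np.column_stack([np.ones(int(rows.sum())), ds.z[rows], y[rows]]),
        sy_obs,
        "Sx-on-ZY",
    )
    piy, sy_summary = fit_one(
        ds.sy,
        lambda rows: np.column_stack([np.ones(int(rows.sum())), ds.z[rows], x[rows]]),
        sx_obs,
        "Sy-on-ZX",
    )

    for name, probs in (("pix", pix), ("piy", piy)):
        low = probs < _PROB_FLOOR
        if low.any():
            warns.append(
                f"{int(low.sum())} fitted {name} probabilities below {_PROB_FLOOR}; "
                "clipped (positivity warning)"
            )
        np.clip(probs, _PROB_FLOOR, 1.0, out=probs)

    for w in warns:
        _warnings.warn(w, RuntimeWarning, stacklevel=2)
    return IpwWeights(
        pix=pix, piy=piy, link=link, sx_model=sx_summary, sy_model=sy_summary, warnings=warns
    )


def fit_wls_x(
    ds: IncompleteDataset,
    link: str = "probit",
    weights: IpwWeights | None = None,
) -> EstimateResult:
    """IPW estimator of P(Y | X, Z): weighted least squares with weights 1/pix.

    Pass ``weights`` to reuse fitted (or oracle) selection probabilities;
    otherwise selection models are fit with the given link.  Sandwich (HC0)
    standard errors, treating the weights as fixed.
    """
    cc = ds.complete.astype(bool)
    n_cc = int(cc.sum())
    if n_cc < 10:
        raise EstimationError(f"WLS-X requires >= 10 complete cases, got {n_cc}")
    if weights is None:
        weights = fit_selection_models(ds, link=link)
    w = weights.weight_conditional
    x = np.ma.getdata(ds.xstar)[cc]
    y = np.ma.getdata(ds.ystar)[cc]
    z = ds.z[cc]
    design = np.column_stack([np.ones(n_cc), x, z])
    fit = sm.WLS(y, design, weights=w).fit(cov_type="HC0")
    resid = y - design @ fit.params
    sigma2 = float(np.sum(w * resid**2) / np.sum(w))
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
        "sigma2": float("nan"),
    }
    return EstimateResult(
        method="WLS-X",
        estimates=estimates,
        se=se,
        n_used={"complete": n_cc, "n": ds.n},
        converged=True,
        warnings=list(weights.warnings),
        extras={"selection": {"sx": weights.sx_model, "sy": weights.sy_model},
                "weights": weights.diagnostics(), "link": weights.link},
    )


def oracle_weights(ds: IncompleteDataset, coef) -> IpwWeights:
    """True selection probabilities from known probit coefficients.

    For simulation studies where the generating mechanism is known:
    ``P(Sx=1 | Z, Y) = Phi(-(alpha0 + alphaZ Z + alphaY Y))`` and
    ``P(Sy=1 | X, Z) = Phi(-(gamma0 + gammaX X + gammaZ Z))``, evaluated at
    the complete cases.
    """
    from scipy.stats import norm

    cc = ds.complete.astype(bool)
    x = np.ma.getdata(ds.xstar)[cc]
    y = np.ma.getdata(ds.ystar)[cc]
    z = ds.z[cc]
    if coef.always_observe_x:
        pix = np.ones(len(z))
    else:
        pix = norm.cdf(-(coef.alpha0 + coef.alphaZ * z + coef.alphaY * y))
    if coef.always_observe_y:
        piy = np.ones(len(z))
    else:
        piy = norm.cdf(-(coef.gamma0 + coef.gammaX * x + coef.gammaZ * z))
    pix = np.clip(pix, _PROB_FLOOR, 1.0)
    piy = np.clip(piy, _PROB_FLOOR, 1.0)
    return IpwWeights(
        pix=pix, piy=piy, link="probit",
        sx_model={"oracle": True}, sy_model={"oracle": True},
    )


def fit_sem_xy(
    ds: IncompleteDataset,
    link: str = "probit",
    weights: IpwWeights | None = None,
) -> EstimateResult:
    """IPW pseudo-ML estimator of the full joint distribution (SEM-XY).

    Complete cases are weighted by ``1/(pix*piy)``; the weighted pseudo-ML
    of the saturated Gaussian is the weighted mean and weighted covariance
    (weight-normalized, ML divisor), mapped through the moments-to-structure
    bijection.  Sandwich standard errors from the weighted per-unit scores,
    weights treated as fixed.
    """
    cc = ds.complete.astype(bool)
    n_cc = int(cc.sum())
    if n_cc < 10:
        raise EstimationError(f"SEM-XY requires >= 10 complete cases, got {n_cc}")
    if weights is None:
        weights = fit_selection_models(ds, link=link)
    w = weights.weight_joint
    v = np.column_stack(
        [np.ma.getdata(ds.xstar)[cc], ds.z[cc], np.ma.getdata(ds.ystar)[cc]]
    )
    wsum = float(w.sum())
    mean = (w[:, None] * v).sum(axis=0) / wsum
    d = v - mean
    cov = (w[:, None, None] * (d[:, :, None] * d[:, None, :])).sum(axis=0) / wsum
    cov = 0.5 * (cov + cov.T)
    params = params_from_moments(ImpliedMoments(mean=mean, cov=cov))
    estimates = {k: getattr(params, k) for k in STRUCTURAL_NAMES}

    # sandwich on the moment estimating equations:
    # psi_i = (v_i - mu ; vech((v_i-mu)(v_i-mu)' - Sigma)); at the solution the
    # weighted Jacobian is -sum(w) * I, so Cov(theta) = sum(w_i^2 psi psi') / wsum^2
    il, jl = np.tril_indices(3)
    psi_mu = d
    psi_sig = (d[:, :, None] * d[:, None, :] - cov[None, :, :])[:, il, jl]
    psi = np.concatenate([psi_mu, psi_sig], axis=1)
    meat = (w[:, None] * psi).T @ (w[:, None] * psi)
    cov_theta = meat / wsum**2
    # delta method to the structural scale
    theta = np.concatenate([mean, cov[il, jl]])
    h = 1e-6 * np.maximum(1.0, np.abs(theta))

    def struct(t):
        mu = t[:3]
        c = np.zeros((3, 3))
        c[il, jl] = t[3:]
        c = c + np.tril(c, -1).T
        p = params_from_moments(ImpliedMoments(mean=mu, cov=c))
        return np.array([getattr(p, k) for k in STRUCTURAL_NAMES])

    J = np.zeros((9, 9))
    for i in range(9):
        e = np.zeros(9)
        e[i] = h[i]
        J[:, i] = (struct(theta + e) - struct(theta - e)) / (2 * h[i])
    var = np.diag(J @ cov_theta @ J.T).copy()
    var[var < 0] = np.nan
    se = dict(zip(STRUCTURAL_NAMES, np.sqrt(var)))

    return EstimateResult(
        method="SEM-XY",
        estimates=estimates,
        se=se,
        n_used={"complete": n_cc, "n": ds.n},
        converged=True,
        warnings=list(weights.warnings),
        extras={"selection": {"sx": weights.sx_model, "sy": weights.sy_model},
                "weights": weights.diagnostics(), "link": weights.link},
    )
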