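"""Trivariate linear structural equation model and its implied Gaussian moments.

The substantive model has two jointly normal explanatory variables ``(X, Z)``
and a response generated by the linear equation

    Y = beta0 + betaX * X + betaZ * Z + eps,   eps | X, Z ~ N(0, sigma2),

with ``Cov(X, Z)`` parameterized by the free covariance matrix
``Psi = [[psiXX, psiXZ], [psiXZ, psiZZ]]``.  The model is just-identified:
its nine structural parameters are in bijection with the saturated Gaussian
moments (3 means, 6 covariances) of the joint vector.  Both directions of
that map live here.

Variable ordering is fixed as ``(X, Z, Y)`` everywhere in this package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, fields

import numpy as np

__all__ = [
    "SemParams",
    "ImpliedMoments",
    "MECHANISMS",
    "VARIABLE_ORDER",
    "implied_moments",
    "params_from_moments",
    "ParameterDomainError",
]

#: Canonical variable ordering used for every mean vector and covariance matrix.
VARIABLE_ORDER = ("x", "z", "y")

#: Closed set of missingness-mechanism labels.
MECHANISMS = ("R-MAR", "MNAR-X", "MNAR-Y", "MNAR-XY")


class ParameterDomainError(ValueError):
    """Raised when structural parameters violate their domain constraints."""


@dataclass
class SemParams:
    """Structural parameters of the trivariate linear SEM.

    Parameters
    ----------
    beta0, betaX, betaZ
        Intercept and slopes of the Y-equation.
    sigma2
        Residual variance of Y given (X, Z); must be positive.
    psiXX, psiZZ, psiXZ
        Covariance matrix of (X, Z); must be positive definite.
    muX, muZ
        Means of X and Z.  Default 0, matching the canonical simulation
        design, but kept free so saturated-mean models can be represented.
    """

    beta0: float
    betaX: float
    betaZ: float
    sigma2: float
    psiXX: float
    psiZZ: float
    psiXZ: float
    muX: float = 0.0
    muZ: float = 0.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not np.isfinite(self.as_array()).all():
            raise ParameterDomainError("all structural parameters must be finite")
        if self.sigma2 <= 0:
            raise ParameterDomainError(f"sigma2 must be > 0, got {self.sigma2}")
        psi = self.psi
        if psi[0, 0] <= 0 or np.linalg.det(psi) <= 0:
            raise ParameterDomainError(
                f"covariance of (X, Z) must be positive definite, got {psi.tolist()}"
            )

    @property
    def psi(self) -> np.ndarray:
        """2x2 covariance matrix of (X, Z)."""
        return np.array([[self.psiXX, self.psiXZ], [self.psiXZ, self.psiZZ]])

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f.name) for f in fields(self)], dtype=float)

    # -- flat JSON serialization ------------------------------------------------
    def to_dict(self) -> dict:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "SemParams":
        known = {f.name for f in fields(cls)}
        extra = set(d) - known
        if extra:
            raise ValueError(f"unknown SemParams fields: {sorted(extra)}")
        return cls(**{k: float(v) for k, v in d.items()})

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, s: str) -> "SemParams":
        return cls.from_dict(json.loads(s))


@dataclass
class ImpliedMoments:
    """Saturated Gaussian moments of (X, Z, Y), in that order.

    ``mean`` is length 3 and ``cov`` is 3x3 symmetric positive definite.
    """

    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float).reshape(3)
        self.cov = np.asarray(self.cov, dtype=float).reshape(3, 3)
        if not np.allclose(self.cov, self.cov.T, atol=1e-12):
            raise ParameterDomainError("covariance matrix must be symmetric")
        if np.linalg.eigvalsh(self.cov)[0] <= 0:
            raise ParameterDomainError("covariance matrix must be positive definite")

    # named accessors: the fixed (X, Z, Y) ordering is enforced through these
    @property
    def mean_x(self) -> float:
        return float(self.mean[0])

    @property
    def mean_z(self) -> float:
        return float(self.mean[1])

    @property
    def mean_y(self) -> float:
        return float(self.mean[2])

    def var(self, v: str) -> float:
        i = VARIABLE_ORDER.index(v)
        return float(self.cov[i, i])

    def cov_of(self, a: str, b: str) -> float:
        return float(self.cov[VARIABLE_ORDER.index(a), VARIABLE_ORDER.index(b)])


def implied_moments(params: SemParams) -> ImpliedMoments:
    """Map structural parameters to the implied joint moments of (X, Z, Y).

    The covariance entries follow the usual path algebra of a linear system:

    - ``Var(Y)   = betaX^2 psiXX + betaZ^2 psiZZ + 2 betaX betaZ psiXZ + sigma2``
    - ``Cov(X,Y) = betaX psiXX + betaZ psiXZ``
    - ``Cov(Z,Y) = betaX psiXZ + betaZ psiZZ``
    """
    params.validate()
    b = np.array([params.betaX, params.betaZ])
    psi = params.psi
    mean_y = params.beta0 + params.betaX * params.muX + params.betaZ * params.muZ
    cov_xy, cov_zy = psi @ b
    var_y = float(b @ psi @ b) + params.sigma2
    mean = np.array([params.muX, params.muZ, mean_y])
    cov = np.array(
        [
            [params.psiXX, params.psiXZ, cov_xy],
            [params.psiXZ, params.psiZZ, cov_zy],
            [cov_xy, cov_zy, var_y],
        ]
    )
    return ImpliedMoments(mean=mean, cov=cov)


def params_from_moments(m: ImpliedMoments) -> SemParams:
    """Invert :func:`implied_moments`: recover structural parameters from moments.

    Because the SEM is just-identified this is an exact bijection; the slopes
    are the population regression coefficients of Y on (X, Z) and ``sigma2``
    is the corresponding residual variance.

    Raises
    ------
    ParameterDomainError
        If the (X, Z) covariance block is (numerically) singular.
    """
    psi = m.cov[:2, :2]
    if np.linalg.det(psi) <= 0:
        raise ParameterDomainError("(X, Z) covariance block is singular")
    c = m.cov[:2, 2]  # (Cov(X,Y), Cov(Z,Y))
    betas = np.linalg.solve(psi, c)
    sigma2 = float(m.cov[2, 2] - betas @ c)
    if sigma2 <= 0:
        raise ParameterDomainError(
            "implied residual variance is non-positive; moments are degenerate"
        )
    beta0 = float(m.mean[2] - betas[0] * m.mean[0] - betas[1] * m.mean[1])
    return SemParams(
        beta0=beta0,
        betaX=float(betas[0]),
        betaZ=float(betas[1]),
        sigma2=sigma2,
        psiXX=float(psi[0, 0]),
        psiZZ=float(psi[1, 1]),
        psiXZ=float(psi[0, 1]),
        muX=float(m.mean[0]),
        muZ=float(m.mean[1]),
    )
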