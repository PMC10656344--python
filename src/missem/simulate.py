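"""Simulation of incomplete trivariate data under probit selection mechanisms.

The data-generating process draws ``(X, Z)`` bivariate normal, generates the
response from the linear Y-equation, and then generates latent missingness
indices from two probit models:

    My* = gamma0 + gammaX * X + gammaZ * Z + u0,   u0 ~ N(0, 1)
    Mx* = alpha0 + alphaZ * Z + alphaY * Y + u1,   u1 ~ N(0, 1)

``Y`` is missing when ``My* > 0`` (selection indicator ``Sy = 0``) and ``X``
is missing when ``Mx* > 0`` (``Sx = 0``).  The path ``X -> Sy`` (MNAR-X
violation) is controlled by ``gammaX`` and the path ``Y -> Sx`` (MNAR-Y
violation) by ``alphaY``.  Rather than setting those slopes directly, a
:class:`MissingnessSpec` states the violation strength on an interpretable
scale — the partial correlations ``Cor(My*, X | Z)`` and
``Cor(Mx*, Y | X, Z)`` — together with the marginal observation
probabilities ``Px = P(Sx=1)`` and ``Py = P(Sy=1)``;
:func:`solve_probit_coefficients` inverts that parameterization in closed
form.

Missing values are carried as :class:`numpy.ma.MaskedArray` entries, never as
a magic numeric value; CSV serialization writes them as empty cells
(:mod:`missem.io`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .model import SemParams, implied_moments

__all__ = [
    "MissingnessSpec",
    "ProbitCoefficients",
    "IncompleteDataset",
    "solve_probit_coefficients",
    "simulate_dataset",
    "delete_for_mnar_x",
    "delete_for_mnar_y",
    "UnsolvableSpecError",
]


class UnsolvableSpecError(ValueError):
    """Raised when a missingness specification admits no probit coefficients."""


@dataclass
class MissingnessSpec:
    """Target strength and amount of missingness.

    Parameters
    ----------
    rhoMyX
        Target partial correlation ``Cor(My*, X | Z)`` — strength of the
        ``X -> Sy`` path.  0 means no MNAR-X violation.
    rhoMxY
        Target partial correlation ``Cor(Mx*, Y | X, Z)`` — strength of the
        ``Y -> Sx`` path.  0 means no MNAR-Y violation.
    Px, Py
        Marginal probabilities of observing X and Y.  A value of exactly 1
        switches that selection indicator off (variable always observed).
    gammaZ, alphaZ
        Fixed slopes of Z in the two probit indices (default 1, the
        canonical design).
    """

    rhoMyX: float
    rhoMxY: float
    Px: float
    Py: float
    gammaZ: float = 1.0
    alphaZ: float = 1.0

    def __post_init__(self) -> None:
        if not (abs(self.rhoMyX) < 1 and abs(self.rhoMxY) < 1):
            raise UnsolvableSpecError("partial correlations must lie in (-1, 1)")
        if not (0 < self.Px <= 1 and 0 < self.Py <= 1):
            raise UnsolvableSpecError("Px and Py must lie in (0, 1]")

    def mechanism(self) -> str:
        """Mechanism label implied by which violation strengths are nonzero."""
        if self.rhoMyX != 0 and self.rhoMxY != 0:
            return "MNAR-XY"
        if self.rhoMyX != 0:
            return "MNAR-X"
        if self.rhoMxY != 0:
            return "MNAR-Y"
        return "R-MAR"

    def to_dict(self) -> dict:
        return {
            "rhoMyX": self.rhoMyX,
            "rhoMxY": self.rhoMxY,
            "Px": self.Px,
            "Py": self.Py,
            "gammaZ": self.gammaZ,
            "alphaZ": self.alphaZ,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MissingnessSpec":
        return cls(**{k: float(v) for k, v in d.items()})


@dataclass
class ProbitCoefficients:
    """Solved coefficients of the two probit selection models.

    ``always_observe_x`` / ``always_observe_y`` flag the boundary cases
    ``Px = 1`` / ``Py = 1``, where the corresponding indicator is constant 1
    and the intercept is not used (kept at 0 rather than -inf).
    """

    gamma0: float
    gammaX: float
    gammaZ: float
    alpha0: float
    alphaZ: float
    alphaY: float
    always_observe_x: bool = False
    always_observe_y: bool = False

    def __post_init__(self) -> None:
        vals = [self.gamma0, self.gammaX, self.gammaZ, self.alpha0, self.alphaZ, self.alphaY]
        if not np.all(np.isfinite(vals)):
            raise UnsolvableSpecError("probit coefficients must be finite")


@dataclass
class IncompleteDataset:
    """Observed data: proxies X*, Y*, fully observed Z, selection indicators.

    ``xstar`` and ``ystar`` are masked arrays whose masks mirror
    ``sx == 0`` and ``sy == 0``.  The complete-case indicator is derived as
    ``sx * sy`` on demand and never stored.
    """

    z: np.ndarray
    xstar: np.ma.MaskedArray
    ystar: np.ma.MaskedArray
    sx: np.ndarray
    sy: np.ndarray

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.sx = np.asarray(self.sx, dtype=np.int8)
        self.sy = np.asarray(self.sy, dtype=np.int8)
        self.xstar = np.ma.masked_array(
            np.asarray(np.ma.getdata(self.xstar), dtype=float), mask=self.sx == 0
        )
        self.ystar = np.ma.masked_array(
            np.asarray(np.ma.getdata(self.ystar), dtype=float), mask=self.sy == 0
        )
        n = self.z.shape[0]
        for name in ("xstar", "ystar", "sx", "sy"):
            if getattr(self, name).shape != (n,):
                raise ValueError(f"{name} must have shape ({n},)")
        if np.ma.is_masked(self.z) or not np.isfinite(self.z).all():
            raise ValueError("z must be fully observed and finite")

    @property
    def n(self) -> int:
        return self.z.shape[0]

    @property
    def complete(self) -> np.ndarray:
        """Complete-case indicator C = Sx * Sy (derived, never stored)."""
        return (self.sx * self.sy).astype(np.int8)

    def copy(self) -> "IncompleteDataset":
        return IncompleteDataset(
            z=self.z.copy(),
            xstar=self.xstar.copy(),
            ystar=self.ystar.copy(),
            sx=self.sx.copy(),
            sy=self.sy.copy(),
        )


def _sigma_x_given_z(params: SemParams) -> float:
    return float(np.sqrt(params.psiXX - params.psiXZ**2 / params.psiZZ))


def solve_probit_coefficients(
    spec: MissingnessSpec, params: SemParams
) -> ProbitCoefficients:
    """Solve the probit slopes and intercepts hitting the spec's targets.

    The partial correlation between the latent index and the driving
    variable, conditional on the rest of the index, pins down the slope:
    given Z, ``My* = gammaX * X + const + u0`` with
    ``Var(X|Z) = sxz2 = psiXX - psiXZ^2/psiZZ``, so

        Cor(My*, X | Z) = gammaX * s / sqrt(gammaX^2 s^2 + 1),  s = sqrt(sxz2)

    which inverts to ``gammaX = rho / (s * sqrt(1 - rho^2))``.  The same
    algebra with the residual sd of Y given (X, Z) gives ``alphaY``.  The
    intercepts then come from the marginal normal law of each index:
    ``My* ~ N(gamma0, V + 1)`` with ``V = Var(gammaX X + gammaZ Z)``, so
    ``P(Sy=1) = P(My* <= 0) = Py`` yields
    ``gamma0 = -Phi^{-1}(Py) * sqrt(V + 1)``; analogously for ``alpha0``
    using the implied moments of (Z, Y).
    """
    params.validate()
    m = implied_moments(params)

    s_xz = _sigma_x_given_z(params)
    s_y = float(np.sqrt(params.sigma2))
    gammaX = spec.rhoMyX / (s_xz * np.sqrt(1.0 - spec.rhoMyX**2))
    alphaY = spec.rhoMxY / (s_y * np.sqrt(1.0 - spec.rhoMxY**2))

    always_y = spec.Py == 1.0
    always_x = spec.Px == 1.0

    if always_y:
        gamma0 = 0.0
    else:
        var_index_y = (
            gammaX**2 * params.psiXX
            + spec.gammaZ**2 * params.psiZZ
            + 2 * gammaX * spec.gammaZ * params.psiXZ
        )
        mean_index_y = gammaX * params.muX + spec.gammaZ * params.muZ
        gamma0 = float(
            -norm.ppf(spec.Py) * np.sqrt(var_index_y + 1.0) - mean_index_y
        )

    if always_x:
        alpha0 = 0.0
    else:
        var_index_x = (
            spec.alphaZ**2 * params.psiZZ
            + alphaY**2 * m.var("y")
            + 2 * spec.alphaZ * alphaY * m.cov_of("z", "y")
        )
        mean_index_x = spec.alphaZ * params.muZ + alphaY * m.mean_y
        alpha0 = float(
            -norm.ppf(spec.Px) * np.sqrt(var_index_x + 1.0) - mean_index_x
        )

    return ProbitCoefficients(
        gamma0=gamma0,
        gammaX=float(gammaX),
        gammaZ=spec.gammaZ,
        alpha0=alpha0,
        alphaZ=spec.alphaZ,
        alphaY=float(alphaY),
        always_observe_x=always_x,
        always_observe_y=always_y,
    )


def simulate_dataset(
    params: SemParams,
    spec: MissingnessSpec,
    n: int,
    seed: int | np.random.Generator,
) -> IncompleteDataset:
    """Draw one incomplete dataset of size ``n`` from the full DGP.

    Draw order (fixed for reproducibility): the (X, Z) pair, the Y residual,
    then the two probit errors ``u0`` (Y-selection) and ``u1`` (X-selection).
    Identical ``(params, spec, n, seed)`` give identical datasets.
    """
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    rng = np.random.default_rng(seed)
    coef = solve_probit_coefficients(spec, params)

    chol = np.linalg.cholesky(params.psi)
    xz = np.array([params.muX, params.muZ]) + rng.standard_normal((n, 2)) @ chol.T
    x, z = xz[:, 0], xz[:, 1]
    y = (
        params.beta0
        + params.betaX * x
        + params.betaZ * z
        + np.sqrt(params.sigma2) * rng.standard_normal(n)
    )
    u0 = rng.standard_normal(n)
    u1 = rng.standard_normal(n)

    if coef.always_observe_y:
        sy = np.ones(n, dtype=np.int8)
    else:
        my_star = coef.gamma0 + coef.gammaX * x + coef.gammaZ * z + u0
        sy = (my_star <= 0).astype(np.int8)
    if coef.always_observe_x:
        sx = np.ones(n, dtype=np.int8)
    else:
        mx_star = coef.alpha0 + coef.alphaZ * z + coef.alphaY * y + u1
        sx = (mx_star <= 0).astype(np.int8)

    return IncompleteDataset(
        z=z,
        xstar=np.ma.masked_array(x, mask=sx == 0),
        ystar=np.ma.masked_array(y, mask=sy == 0),
        sx=sx,
        sy=sy,
    )


def delete_for_mnar_x(ds: IncompleteDataset) -> IncompleteDataset:
    """Delete Y wherever X is missing: the modified indicator is Sy' = Sx*Sy.

    Under an ``X -> Sy`` violation this makes the remaining missingness
    depend on X only where X is observed, i.e. the modified process is MAR
    ("made MAR"); ignorable-likelihood estimation on the result is the
    SEM-X estimator.  The input is not mutated.
    """
    out = ds.copy()
    sy_new = (out.sx * out.sy).astype(np.int8)
    return IncompleteDataset(
        z=out.z, xstar=out.xstar, ystar=np.ma.getdata(out.ystar), sx=out.sx, sy=sy_new
    )


def delete_for_mnar_y(ds: IncompleteDataset) -> IncompleteDataset:
    """Delete X wherever Y is missing: Sx' = Sx*Sy (mirror of MNAR-X deletion)."""
    out = ds.copy()
    sx_new = (out.sx * out.sy).astype(np.int8)
    return IncompleteDataset(
        z=out.z, xstar=np.ma.getdata(out.xstar), ystar=out.ystar, sx=sx_new, sy=out.sy
    )
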