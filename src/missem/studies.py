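"""Batch simulation studies: population, finite-sample, and power.

Three reproducible harnesses over the simulator and estimators:

- :func:`run_population_study` — one very large dataset per missingness
  mechanism, all six estimators, to exhibit (in)consistency: the empirical
  analogue of probability limits.
- :func:`run_finite_sample_study` — replicated small-sample designs over a
  grid of violation strengths, observation probabilities and sample sizes,
  reporting bias and MSE per estimator and parameter with Monte Carlo
  standard errors.
- :func:`run_power_study` — empirical Type I error and power of the R-MAR
  diagnostics over a grid of violation strength, observation probability
  and sample size.

Seeding: one root seed; the stream for replicate ``r`` of condition ``c``
is ``numpy.random.SeedSequence([root, c, r])``.  Replicates are therefore
independent, reproducible and embarrassingly parallel, and results do not
depend on execution order.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diagnostics import power_simulation
from .fiml import (
    EstimationError,
    fit_fiml,
    fit_ols_cc,
    fit_sem_x,
    fit_sem_y,
)
from .ipw import fit_sem_xy, fit_wls_x
from .model import SemParams
from .simulate import MissingnessSpec, simulate_dataset
from .testbased import decide
from .diagnostics import lrt_rmar, kci_rmar

__all__ = [
    "StudyConfig",
    "default_params",
    "run_population_study",
    "run_finite_sample_study",
    "run_power_study",
]


def default_params() -> SemParams:
    """The canonical generating parameters used throughout the studies."""
    return SemParams(beta0=1, betaX=1, betaZ=1, sigma2=1, psiXX=1, psiZZ=1, psiXZ=0.5)


@dataclass
class StudyConfig:
    """Configuration of a replicated simulation study.

    Grids are lists; the study runs every combination.  ``replicates`` is
    per condition.  For the power study only ``rho_mxy``, ``px`` and ``n``
    are used (Y is fully observed there).
    """

    rho_myx: list = field(default_factory=lambda: [0.0, 0.5, 0.9])
    rho_mxy: list = field(default_factory=lambda: [0.0, 0.5, 0.9])
    px: list = field(default_factory=lambda: [0.3, 0.8])
    py: list = field(default_factory=lambda: [0.3, 0.8])
    n: list = field(default_factory=lambda: [200, 500, 1000])
    replicates: int = 100
    seed: int = 0
    alpha: float = 0.05
    test: str = "LRT"
    estimators: list = field(default_factory=lambda: ["SEM", "TEST-BASED"])
    parameters: list = field(default_factory=lambda: ["betaX", "betaZ", "psiXZ"])

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        for name in ("rho_myx", "rho_mxy", "px", "py", "n"):
            if not getattr(self, name):
                raise ValueError(f"grid {name} must be non-empty")

    @classmethod
    def from_json(cls, s: str) -> "StudyConfig":
        return cls(**json.loads(s))

    def to_dict(self) -> dict:
        return {
            "rho_myx": self.rho_myx,
            "rho_mxy": self.rho_mxy,
            "px": self.px,
            "py": self.py,
            "n": self.n,
            "replicates": self.replicates,
            "seed": self.seed,
            "alpha": self.alpha,
            "test": self.test,
            "estimators": self.estimators,
            "parameters": self.parameters,
        }


_POPULATION_MECHANISMS = {
    "MNAR-X": (0.6, 0.0),
    "MNAR-Y": (0.0, 0.6),
    "MNAR-XY": (0.6, 0.6),
    "R-MAR": (0.0, 0.0),
}


def run_population_study(
    n: int = 1_000_000,
    seed: int = 0,
    *,
    params: SemParams | None = None,
    px: float = 0.8,
    py: float = 0.8,
    rho: float = 0.6,
    estimators: tuple = ("OLS", "SEM", "SEM-X", "SEM-Y", "WLS-X", "SEM-XY"),
) -> pd.DataFrame:
    """One large dataset per mechanism, all requested estimators.

    Returns a long-format table with columns ``mechanism, method,
    parameter, estimate, se, n``.  The four mechanisms use violation
    strength ``rho`` on the active paths and 0 on the inactive ones.
    """
    if n < 10_000:
        raise ValueError("population study requires n >= 10^4")
    params = params or default_params()
    rows = []
    for c, (mech, (base_x, base_y)) in enumerate(_POPULATION_MECHANISMS.items()):
        spec = MissingnessSpec(
            rhoMyX=rho if base_x else 0.0, rhoMxY=rho if base_y else 0.0, Px=px, Py=py
        )
        rng = np.random.default_rng(np.random.SeedSequence([seed, c, 0]))
        ds = simulate_dataset(params, spec, n, rng)
        fitters = {
            "OLS": fit_ols_cc,
            "SEM": fit_fiml,
            "SEM-X": fit_sem_x,
            "SEM-Y": fit_sem_y,
            "WLS-X": fit_wls_x,
            "SEM-XY": fit_sem_xy,
        }
        for method in estimators:
            res = fitters[method](ds)
            for p, est in res.estimates.items():
                rows.append(
                    {
                        "mechanism": mech,
                        "method": method,
                        "parameter": p,
                        "estimate": est,
                        "se": res.se.get(p, np.nan),
                        "converged": res.converged,
                        "n": n,
                    }
                )
    return pd.DataFrame(rows)


def _fit_condition_replicate(ds, estimators, alpha, test):
    """Fit the requested estimators on one replicate, sharing FIML fits.

    TEST-BASED reuses whichever of SEM / SEM-X / SEM-Y it dispatches to.
    Returns {method: estimates-dict}; a failed fit maps to None.
    """
    cache: dict = {}

    def get(label):
        if label not in cache:
            fitter = {
                "SEM": fit_fiml,
                "SEM-X": fit_sem_x,
                "SEM-Y": fit_sem_y,
            }[label]
            try:
                cache[label] = fitter(ds, compute_se=False).estimates
            except EstimationError:
                cache[label] = None
        return cache[label]

    out = {}
    for method in estimators:
        if method in ("SEM", "SEM-X", "SEM-Y"):
            out[method] = get(method)
        elif method == "SEM-XY":
            try:
                out[method] = fit_sem_xy(ds).estimates
            except EstimationError:
                out[method] = None
        elif method == "TEST-BASED":
            runner = lrt_rmar if test.upper() == "LRT" else kci_rmar
            rx = runner(ds, "MNAR-X")
            ry = runner(ds, "MNAR-Y")
            d = decide(rx.pvalue, ry.pvalue, alpha, rx.feasible, ry.feasible, test)
            out[method] = get(d.dispatched)
        else:
            raise ValueError(f"unknown estimator {method!r}")
    return out


def run_finite_sample_study(
    config: StudyConfig, params: SemParams | None = None
) -> pd.DataFrame:
    """Replicated bias/MSE study over the configured grid.

    For each condition, ``config.replicates`` datasets are simulated and
    each requested estimator fit; bias and MSE are computed against the
    generating values, with Monte Carlo standard errors.  Returns a
    long-format table with one row per (condition, method, parameter).
    """
    params = params or default_params()
    truth = {k: getattr(params, k) for k in config.parameters}
    conditions = list(
        itertools.product(config.rho_myx, config.rho_mxy, config.px, config.py, config.n)
    )
    rows = []
    for c, (rmyx, rmxy, px, py, n) in enumerate(conditions):
        spec = MissingnessSpec(rhoMyX=rmyx, rhoMxY=rmxy, Px=px, Py=py)
        draws: dict = {m: {p: [] for p in config.parameters} for m in config.estimators}
        failures = {m: 0 for m in config.estimators}
        for rep in range(config.replicates):
            rng = np.random.default_rng(np.random.SeedSequence([config.seed, c, rep]))
            ds = simulate_dataset(params, spec, n, rng)
            fits = _fit_condition_replicate(ds, config.estimators, config.alpha, config.test)
            for m, est in fits.items():
                if est is None:
                    failures[m] += 1
                    continue
                for p in config.parameters:
                    draws[m][p].append(est[p])
        for m in config.estimators:
            for p in config.parameters:
                vals = np.asarray(draws[m][p])
                if vals.size == 0:
                    continue
                err = vals - truth[p]
                bias = float(err.mean())
                mse = float((err**2).mean())
                rows.append(
                    {
                        "rhoMyX": rmyx,
                        "rhoMxY": rmxy,
                        "Px": px,
                        "Py": py,
                        "N": n,
                        "method": m,
                        "parameter": p,
                        "mean_estimate": float(vals.mean()),
                        "bias": bias,
                        "mse": mse,
                        "mc_se_bias": float(err.std(ddof=1) / np.sqrt(err.size)),
                        "mc_se_mse": float((err**2).std(ddof=1) / np.sqrt(err.size)),
                        "replicates": int(err.size),
                        "failures": failures[m],
                    }
                )
    return pd.DataFrame(rows)


def run_power_study(config: StudyConfig, params: SemParams | None = None) -> pd.DataFrame:
    """Rejection-rate study of the diagnostics over (rho, Px, N).

    Uses the design with X as the only partially observed variable; each
    cell runs ``config.replicates`` replicates of the tests named in
    ``config.test`` (comma-separated, e.g. ``"LRT,KCI"``).
    """
    tests = tuple(t.strip().upper() for t in config.test.split(","))
    cells = list(itertools.product(config.rho_mxy, config.px, config.n))
    rows = []
    for c, (rho, px, n) in enumerate(cells):
        cell_seed = int(
            np.random.SeedSequence([config.seed, c]).generate_state(1)[0] % (2**31)
        )
        res = power_simulation(
            rho=rho,
            px=px,
            n=n,
            reps=config.replicates,
            alpha=config.alpha,
            tests=tests,
            seed=cell_seed,
            params=params,
        )
        for t in tests:
            rate = res["rejection_rate"][t]
            rows.append(
                {
                    "rhoMxY": rho,
                    "Px": px,
                    "N": n,
                    "test": t,
                    "rejection_rate": rate,
                    "mc_se": float(np.sqrt(rate * (1 - rate) / config.replicates)),
                    "feasible_rate": res["feasible_rate"][t],
                    "replicates": config.replicates,
                    "alpha": config.alpha,
                }
            )
    return pd.DataFrame(rows)
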