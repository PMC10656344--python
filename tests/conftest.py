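import numpy as np
import pytest

from missem import MissingnessSpec, SemParams, simulate_dataset


@pytest.fixture(scope="session")
def params() -> SemParams:
    """Canonical generating parameters of the simulation design."""
    return SemParams(beta0=1, betaX=1, betaZ=1, sigma2=1, psiXX=1, psiZZ=1, psiXZ=0.5)


@pytest.fixture(scope="session")
def mnar_xy_dataset(params):
    """Moderate-size dataset with both R-MAR violations active."""
    spec = MissingnessSpec(rhoMyX=0.6, rhoMxY=0.6, Px=0.8, Py=0.8)
    return simulate_dataset(params, spec, 5000, seed=101)


def partial_correlation(a, b, conditioning):
    """Residual correlation of a and b after linear adjustment (MC oracle)."""
    design = np.column_stack([np.ones(len(a))] + list(conditioning))
    ra = a - design @ np.linalg.lstsq(design, a, rcond=None)[0]
    rb = b - design @ np.linalg.lstsq(design, b, rcond=None)[0]
    return float(np.corrcoef(ra, rb)[0, 1])
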