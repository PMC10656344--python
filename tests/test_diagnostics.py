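"""Heteroscedastic LRT and kernel conditional-independence diagnostics."""

import numpy as np
import pytest
from scipy.optimize import minimize

from missem import IncompleteDataset, MissingnessSpec, simulate_dataset
from missem.diagnostics import kci_rmar, lrt_rmar, power_simulation


def _dataset_from_arrays(v, s, z, target="MNAR-Y"):
    """Pack (tested variable, indicator, z) into a dataset for the given
    target: for MNAR-Y the tested variable is Y (fully observed) and the
    indicator is sx."""
    n = len(v)
    ones = np.ones(n, dtype=np.int8)
    if target == "MNAR-Y":
        return IncompleteDataset(
            z=z, xstar=np.ma.masked_array(np.zeros(n), mask=s == 0),
            ystar=np.ma.masked_array(v), sx=np.asarray(s, dtype=np.int8), sy=ones,
        )
    return IncompleteDataset(
        z=z, xstar=np.ma.masked_array(v),
        ystar=np.ma.masked_array(np.zeros(n), mask=s == 0),
        sx=ones, sy=np.asarray(s, dtype=np.int8),
    )


class TestLrt:
    def test_exact_null_gives_zero_statistic(self):
        """Duplicating the same (z, v) rows in both indicator groups makes the
        group fits identical, so the statistic vanishes."""
        rng = np.random.default_rng(0)
        z = rng.standard_normal(60)
        v = 1 + z + rng.standard_normal(60)
        zz = np.r_[z, z]
        vv = np.r_[v, v]
        s = np.r_[np.zeros(60, dtype=np.int8), np.ones(60, dtype=np.int8)]
        res = lrt_rmar(_dataset_from_arrays(vv, s, zz), "MNAR-Y")
        assert res.feasible
        assert res.statistic == pytest.approx(0.0, abs=1e-8)
        assert res.pvalue == pytest.approx(1.0, abs=1e-8)

    def test_matches_generic_ml_optimization(self):
        """The closed-form statistic equals 2*(ll_alt - ll_null) from a
        numerically maximized heteroscedastic Gaussian likelihood."""
        rng = np.random.default_rng(1)
        n = 300
        z = rng.standard_normal(n)
        s = (rng.random(n) < 0.5).astype(np.int8)
        v = 0.5 + 0.8 * z + 0.4 * s + 0.2 * s * z + (1 + 0.5 * s) * rng.standard_normal(n)

        def negll_alt(theta):
            d0, d1, d2, d3, ls0, ls1 = theta
            mu = d0 + d1 * z + d2 * s + d3 * s * z
            lv = np.where(s == 1, ls1, ls0)
            return 0.5 * np.sum(np.log(2 * np.pi) + lv + (v - mu) ** 2 / np.exp(lv))

        def negll_null(theta):
            d0, d1, lv = theta
            mu = d0 + d1 * z
            return 0.5 * np.sum(np.log(2 * np.pi) + lv + (v - mu) ** 2 / np.exp(lv))

        alt = minimize(negll_alt, np.zeros(6), method="Nelder-Mead",
                       options={"maxiter": 20000, "xatol": 1e-10, "fatol": 1e-12})
        null = minimize(negll_null, np.zeros(3), method="Nelder-Mead",
                        options={"maxiter": 20000, "xatol": 1e-10, "fatol": 1e-12})
        stat_ref = 2 * (null.fun - alt.fun)
        res = lrt_rmar(_dataset_from_arrays(v, s, z), "MNAR-Y")
        assert res.statistic == pytest.approx(stat_ref, abs=1e-6)
        assert res.df == 3

    def test_affine_invariance(self):
        rng = np.random.default_rng(2)
        n = 400
        z = rng.standard_normal(n)
        s = (rng.random(n) < 0.6).astype(np.int8)
        v = z + 0.3 * s + rng.standard_normal(n)
        a = lrt_rmar(_dataset_from_arrays(v, s, z), "MNAR-Y")
        b = lrt_rmar(_dataset_from_arrays(3.7 * v - 2, s, -0.5 * z + 4), "MNAR-Y")
        assert a.statistic == pytest.approx(b.statistic, abs=1e-8)

    def test_statistic_nonnegative_pvalue_valid(self, mnar_xy_dataset):
        for target in ("MNAR-X", "MNAR-Y"):
            res = lrt_rmar(mnar_xy_dataset, target)
            assert res.statistic >= 0
            assert 0 <= res.pvalue <= 1

    def test_infeasible_when_group_too_small(self):
        rng = np.random.default_rng(3)
        n = 50
        s = np.ones(n, dtype=np.int8)
        s[:3] = 0
        res = lrt_rmar(
            _dataset_from_arrays(rng.standard_normal(n), s, rng.standard_normal(n)),
            "MNAR-Y",
        )
        assert not res.feasible
        assert res.pvalue is None

    def test_detects_strong_violation(self, params):
        ds = simulate_dataset(params, MissingnessSpec(0.0, 0.9, 0.8, 1.0), 1000, 7)
        res = lrt_rmar(ds, "MNAR-Y")
        assert res.pvalue < 1e-4

    def test_hetreg_details(self, params):
        ds = simulate_dataset(params, MissingnessSpec(0.0, 0.5, 0.8, 1.0), 2000, 8)
        res = lrt_rmar(ds, "MNAR-Y")
        fit = res.details
        assert fit.sigma0sq > 0 and fit.sigma1sq > 0
        assert fit.loglik_alt >= fit.loglik_null - 1e-8
        assert sum(fit.group_counts) == res.n_used


class TestKci:
    def test_infeasible_when_indicator_constant(self, params):
        ds = simulate_dataset(params, MissingnessSpec(0.0, 0.0, 1.0, 0.8), 300, 9)
        # target MNAR-X tests X* against sy; make sy constant instead
        ds2 = IncompleteDataset(
            z=ds.z, xstar=np.ma.getdata(ds.xstar), ystar=np.ma.getdata(ds.ystar),
            sx=ds.sx, sy=np.ones(ds.n, dtype=np.int8),
        )
        res = kci_rmar(ds2, "MNAR-X")
        assert not res.feasible and res.pvalue is None

    def test_pvalue_valid_and_detects_violation(self, params):
        ds = simulate_dataset(params, MissingnessSpec(0.0, 0.9, 0.8, 1.0), 500, 10)
        res = kci_rmar(ds, "MNAR-Y")
        assert res.feasible
        assert 0 <= res.pvalue <= 1
        assert res.pvalue < 0.01

    def test_null_pvalue_not_degenerate(self, params):
        ds = simulate_dataset(params, MissingnessSpec(0.0, 0.0, 0.8, 1.0), 500, 11)
        res = kci_rmar(ds, "MNAR-Y")
        assert res.pvalue > 0.01

    def test_permutation_null_agrees_qualitatively(self, params):
        ds = simulate_dataset(params, MissingnessSpec(0.0, 0.9, 0.8, 1.0), 400, 12)
        g = kci_rmar(ds, "MNAR-Y", null_method="gamma")
        p = kci_rmar(ds, "MNAR-Y", null_method="permutation", n_permutations=200)
        assert g.pvalue < 0.05 and p.pvalue < 0.05

    def test_subsampling_large_working_sample(self, params):
        ds = simulate_dataset(params, MissingnessSpec(0.0, 0.5, 0.8, 1.0), 7000, 13)
        with pytest.warns(RuntimeWarning, match="subsampled"):
            res = kci_rmar(ds, "MNAR-Y")
        assert res.n_used == 5000


class TestPowerSimulation:
    def test_type_one_error_near_nominal(self):
        """Smoke-level check; the tight 4000-replicate version is part of
        the acceptance suite."""
        r = power_simulation(rho=0.0, px=0.8, n=500, reps=200, alpha=0.05,
                             tests=("LRT",), seed=1)
        assert 0.01 <= r["rejection_rate"]["LRT"] <= 0.12

    def test_power_increases_with_violation_strength(self):
        lo = power_simulation(rho=0.2, px=0.8, n=300, reps=150, tests=("LRT",), seed=2)
        hi = power_simulation(rho=0.6, px=0.8, n=300, reps=150, tests=("LRT",), seed=2)
        assert hi["rejection_rate"]["LRT"] >= lo["rejection_rate"]["LRT"]
        assert hi["rejection_rate"]["LRT"] > 0.9

    def test_extreme_dependence_saturates_power(self):
        r = power_simulation(rho=0.9, px=0.8, n=1000, reps=100, tests=("LRT",), seed=3)
        assert r["rejection_rate"]["LRT"] >= 0.99
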