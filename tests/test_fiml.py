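"""FIML, deletion estimators, and complete-case OLS."""

import numpy as np
import pytest

from missem import (
    EstimationError,
    IncompleteDataset,
    MissingnessSpec,
    observed_loglik,
    simulate_dataset,
)
from missem.fiml import fit_fiml, fit_ols_cc, fit_sem_x, fit_sem_y
from missem.model import implied_moments


def _complete_ds(rng, n=200):
    x = rng.standard_normal(n)
    z = 0.5 * x + rng.standard_normal(n)
    y = 1 + x + z + rng.standard_normal(n)
    ones = np.ones(n, dtype=np.int8)
    return IncompleteDataset(
        z=z, xstar=np.ma.masked_array(x), ystar=np.ma.masked_array(y), sx=ones, sy=ones
    )


class TestFimlCore:
    def test_complete_data_equals_closed_form_mle(self):
        """With no missingness FIML is the sample mean and 1/n covariance."""
        ds = _complete_ds(np.random.default_rng(0))
        res = fit_fiml(ds)
        v = np.column_stack([np.ma.getdata(ds.xstar), ds.z, np.ma.getdata(ds.ystar)])
        mean_ref = v.mean(axis=0)
        cov_ref = np.cov(v.T, bias=True)
        np.testing.assert_allclose(res.extras["mean"], mean_ref, atol=1e-8)
        np.testing.assert_allclose(res.extras["cov"], cov_ref, atol=1e-8)

    def test_em_route_matches_closed_form_on_complete_data(self):
        ds = _complete_ds(np.random.default_rng(1))
        a = fit_fiml(ds, compute_se=False)
        b = fit_fiml(ds, compute_se=False, force_em=True)
        for k in a.estimates:
            assert a.estimates[k] == pytest.approx(b.estimates[k], abs=1e-7)

    def test_em_loglik_monotone(self, params):
        """The observed-data log-likelihood never decreases across EM steps."""
        ds = simulate_dataset(params, MissingnessSpec(0.6, 0.6, 0.5, 0.5), 400, 5)
        res = fit_fiml(ds, compute_se=False, force_em=True)
        trace = np.asarray(res.extras["em_loglik_trace"])
        assert trace.size > 2
        assert np.all(np.diff(trace) >= -1e-10)

    def test_em_beats_random_parameter_grid(self, params):
        """On a tiny instance the EM/Newton optimum dominates 10^4 random
        saturated-parameter draws (brute-force search oracle)."""
        rng = np.random.default_rng(2)
        ds = simulate_dataset(params, MissingnessSpec(0.4, 0.4, 0.7, 0.7), 6, 77)
        # force one X-missing and one Y-missing unit
        sx = np.array([1, 1, 1, 1, 0, 1], dtype=np.int8)
        sy = np.array([1, 1, 1, 0, 1, 1], dtype=np.int8)
        ds = IncompleteDataset(
            z=ds.z, xstar=np.ma.getdata(ds.xstar), ystar=np.ma.getdata(ds.ystar),
            sx=sx, sy=sy,
        )
        res = fit_fiml(ds, compute_se=False, force_em=True)
        best = -np.inf
        for _ in range(10_000):
            mean = rng.uniform(-3, 3, size=3)
            A = rng.uniform(-1.5, 1.5, size=(3, 3))
            cov = A @ A.T + 0.05 * np.eye(3)
            best = max(best, observed_loglik(ds, mean, cov))
        assert res.loglik >= best - 1e-8

    def test_monotone_closed_form_agrees_with_em(self, params):
        """Deleted datasets have monotone patterns; the exact factorized MLE
        and the EM route coincide."""
        ds = simulate_dataset(params, MissingnessSpec(0.7, 0.7, 0.5, 0.5), 600, 9)
        from missem import delete_for_mnar_x

        dsx = delete_for_mnar_x(ds)
        a = fit_fiml(dsx, compute_se=False)
        b = fit_fiml(dsx, compute_se=False, force_em=True)
        assert a.extras["solver"] == "monotone-exact"
        assert b.extras["solver"] == "em"
        for k in a.estimates:
            assert a.estimates[k] == pytest.approx(b.estimates[k], abs=1e-7)
        assert a.loglik == pytest.approx(b.loglik, abs=1e-7)

    def test_rmar_consistency(self, params):
        """FIML recovers the generating parameters under R-MAR."""
        ds = simulate_dataset(params, MissingnessSpec(0.0, 0.0, 0.8, 0.8), 200_000, 31)
        res = fit_fiml(ds)
        truth = params.to_dict()
        for k in ("betaX", "betaZ", "psiXZ", "sigma2", "psiXX"):
            assert res.estimates[k] == pytest.approx(truth[k], abs=4 * res.se[k])

    def test_errors(self, params):
        tiny = simulate_dataset(params, MissingnessSpec(0, 0, 0.9, 0.9), 3, 0)
        with pytest.raises(EstimationError, match="n >= 5"):
            fit_fiml(tiny)
        ds = simulate_dataset(params, MissingnessSpec(0, 0, 0.9, 0.9), 50, 1)
        none_complete = IncompleteDataset(
            z=ds.z, xstar=np.ma.getdata(ds.xstar), ystar=np.ma.getdata(ds.ystar),
            sx=np.ones(50, dtype=np.int8),
            sy=np.zeros(50, dtype=np.int8),
        )
        with pytest.raises(EstimationError, match="complete case"):
            fit_fiml(none_complete)

    def test_standard_errors_positive_and_plausible(self, params):
        ds = simulate_dataset(params, MissingnessSpec(0.5, 0.5, 0.8, 0.8), 2000, 41)
        res = fit_fiml(ds)
        for k, v in res.se.items():
            assert v > 0, k
        # root-n scale sanity for a covariance parameter
        assert 0.2 / np.sqrt(2000) < res.se["psiXZ"] < 5.0 / np.sqrt(2000)


class TestDeletionEstimators:
    def test_no_missingness_all_estimators_coincide(self):
        ds = _complete_ds(np.random.default_rng(3))
        a, b, c = fit_fiml(ds), fit_sem_x(ds), fit_sem_y(ds)
        for k in a.estimates:
            assert a.estimates[k] == pytest.approx(b.estimates[k], abs=1e-10)
            assert a.estimates[k] == pytest.approx(c.estimates[k], abs=1e-10)

    def test_labels(self, mnar_xy_dataset):
        assert fit_sem_x(mnar_xy_dataset, compute_se=False).method == "SEM-X"
        assert fit_sem_y(mnar_xy_dataset, compute_se=False).method == "SEM-Y"

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_ols_equals_sem_x_conditional_parameters(self, params, seed):
        """OLS and SEM-X give identical Y-equation estimates on any dataset:
        the deletion likelihood factorizes and its conditional block is the
        complete-case regression."""
        ds = simulate_dataset(params, MissingnessSpec(0.6, 0.6, 0.6, 0.6), 800, seed)
        ols = fit_ols_cc(ds)
        semx = fit_sem_x(ds, compute_se=False)
        for k in ("beta0", "betaX", "betaZ", "sigma2"):
            assert semx.estimates[k] == pytest.approx(ols.estimates[k], abs=1e-8)

    def test_sem_x_recovers_joint_under_mnar_x(self, params):
        ds = simulate_dataset(params, MissingnessSpec(0.6, 0.0, 0.8, 0.8), 200_000, 51)
        res = fit_sem_x(ds)
        for k, truth in [("betaX", 1.0), ("betaZ", 1.0), ("psiXZ", 0.5)]:
            assert res.estimates[k] == pytest.approx(truth, abs=4 * res.se[k])

    def test_sem_y_recovers_joint_under_mnar_y(self, params):
        ds = simulate_dataset(params, MissingnessSpec(0.0, 0.6, 0.8, 0.8), 200_000, 52)
        res = fit_sem_y(ds)
        for k, truth in [("betaX", 1.0), ("betaZ", 1.0), ("psiXZ", 0.5)]:
            assert res.estimates[k] == pytest.approx(truth, abs=4 * res.se[k])

    def test_sem_y_biased_under_mnar_x(self, params):
        """With the X -> Sy path active, the SEM-Y deletion estimator
        underestimates the X-Z covariance."""
        ds = simulate_dataset(params, MissingnessSpec(0.6, 0.0, 0.8, 0.8), 200_000, 53)
        res = fit_sem_y(ds)
        assert res.estimates["psiXZ"] < 0.5 - 10 * res.se["psiXZ"]


class TestOlsCc:
    def test_noiseless_recovery(self):
        n = 50
        rng = np.random.default_rng(4)
        x, z = rng.standard_normal(n), rng.standard_normal(n)
        y = 1 + x + z
        ones = np.ones(n, dtype=np.int8)
        ds = IncompleteDataset(
            z=z, xstar=np.ma.masked_array(x), ystar=np.ma.masked_array(y),
            sx=ones, sy=ones,
        )
        res = fit_ols_cc(ds)
        assert res.estimates["beta0"] == pytest.approx(1.0, abs=1e-10)
        assert res.estimates["betaX"] == pytest.approx(1.0, abs=1e-10)
        assert res.estimates["betaZ"] == pytest.approx(1.0, abs=1e-10)
        assert res.estimates["sigma2"] == pytest.approx(0.0, abs=1e-16)

    def test_conditional_consistency_under_mnar_x(self, params):
        """Complete cases recover P(Y|X,Z) when selection does not depend on
        Y given (X, Z)."""
        ds = simulate_dataset(params, MissingnessSpec(0.6, 0.0, 0.8, 0.8), 200_000, 54)
        res = fit_ols_cc(ds)
        assert res.estimates["betaX"] == pytest.approx(1.0, abs=4 * res.se["betaX"])
        assert res.estimates["betaZ"] == pytest.approx(1.0, abs=4 * res.se["betaZ"])

    def test_biased_z_slope_under_mnar_y(self, params):
        ds = simulate_dataset(params, MissingnessSpec(0.0, 0.6, 0.8, 0.8), 200_000, 55)
        res = fit_ols_cc(ds)
        assert res.estimates["betaZ"] < 1.0 - 10 * res.se["betaZ"]

    def test_too_few_complete_cases(self, params):
        ds = simulate_dataset(params, MissingnessSpec(0, 0, 0.9, 0.9), 40, 5)
        crippled = IncompleteDataset(
            z=ds.z, xstar=np.ma.getdata(ds.xstar), ystar=np.ma.getdata(ds.ystar),
            sx=np.r_[np.ones(3, dtype=np.int8), np.zeros(37, dtype=np.int8)],
            sy=np.ones(40, dtype=np.int8),
        )
        with pytest.raises(EstimationError):
            fit_ols_cc(crippled)
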