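import numpy as np
import pandas as pd
import pytest

from lvfit import (ConstraintMask, LVObjective, LVParameters,
                   ObservationTable, ValidationError, approx_se, fit_lv,
                   generate, optimize_lv, pack, preset, unpack)
from lvfit.optimize import SIMULATION_FAILURE_PENALTY

from conftest import free_parameter_vectors


def two_species_params():
    return LVParameters(["a", "b"], r=[1.1, 0.9],
                        A=[[-0.01, -0.004], [-0.006, -0.012]], N0=[1.5, 2.0])


class TestPackUnpack:
    def test_round_trip_identity(self):
        p = two_species_params()
        mask = ConstraintMask.free_all(p.species)
        mask.r_sign[:] = 1
        mask.A_sign[:] = -1
        q = unpack(pack(p, mask), mask)
        assert np.allclose(q.r, p.r, rtol=1e-15)
        assert np.allclose(q.A, p.A, rtol=1e-15)
        assert np.allclose(q.N0, p.N0, rtol=1e-15)

    def test_round_trip_with_zeros(self):
        p = two_species_params()
        p.A[0, 1] = 0.0
        mask = ConstraintMask.free_all(p.species).fix_zero(a=[("a", "b")])
        mask.A_sign[:] = -1
        q = unpack(pack(p, mask), mask)
        assert q.A[0, 1] == 0.0
        assert np.allclose(q.A, p.A)

    def test_log_magnitude_entries(self):
        p = LVParameters(["x"], r=[0.96], A=[[-0.005]], N0=[1.0])
        mask = ConstraintMask.free_all(["x"])
        theta = pack(p, mask)
        assert theta[0] == pytest.approx(np.log(0.96))
        assert theta[1] == pytest.approx(np.log(0.005))

    def test_sign_mismatch_rejected(self):
        p = LVParameters(["x"], r=[-0.96], A=[[-0.005]], N0=[1.0])
        mask = ConstraintMask.free_all(["x"])  # default r sign +1
        with pytest.raises(ValidationError):
            pack(p, mask)

    def test_random_round_trips(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            n = int(rng.integers(1, 4))
            sp = [f"s{i}" for i in range(n)]
            p = LVParameters(sp, r=rng.uniform(-2, 2, n),
                             A=rng.uniform(-0.1, 0.1, (n, n)),
                             N0=rng.uniform(0.1, 50, n))
            # avoid exact zeros (not packable as free parameters)
            p.r[p.r == 0] = 0.1
            p.A[p.A == 0] = 0.01
            mask = ConstraintMask(sp, r_sign=np.sign(p.r).astype(int),
                                  A_sign=np.sign(p.A).astype(int))
            q = unpack(pack(p, mask), mask)
            assert np.allclose(q.r, p.r, rtol=1e-14)
            assert np.allclose(q.A, p.A, rtol=1e-14)
            assert np.allclose(q.N0, p.N0, rtol=1e-14)


@pytest.fixture(scope="module")
def logistic_noise_free():
    spec = preset("logistic_monoculture", noise_sd=0.0)
    return generate(spec)


class TestObjective:
    def test_zero_at_generating_parameters(self, logistic_noise_free):
        table, truth = logistic_noise_free
        mask = ConstraintMask.free_all(truth.species)
        obj = LVObjective(table, mask)
        assert obj(pack(truth, mask)) < 1e-8

    def test_penalty_on_divergent_dynamics(self):
        p = LVParameters(["a", "b"], r=[1.0, 1.0],
                         A=[[0.0, 0.5], [0.5, 0.0]], N0=[10.0, 10.0])
        mask = ConstraintMask(
            ["a", "b"], A_free=[[False, True], [True, False]],
            A_sign=[[1, 1], [1, 1]])
        df = pd.DataFrame({"time": [0, 10, 20, 30] * 2,
                           "species": ["a"] * 4 + ["b"] * 4,
                           "abundance": [10, 12, 14, 16] * 2})
        obj = LVObjective(ObservationTable(df), mask)
        assert obj(pack(p, mask)) == SIMULATION_FAILURE_PENALTY

    def test_standardization_makes_units_irrelevant(self, logistic_noise_free):
        # rescaling one species' unit (observations, N0 and the incoming
        # interaction column together) leaves the objective unchanged
        table, truth = logistic_noise_free
        mask = ConstraintMask.free_all(truth.species)
        c = 37.0
        scaled_df = table.data.copy()
        scaled_df["abundance"] *= c
        scaled = ObservationTable(scaled_df)
        truth_scaled = truth.copy()
        truth_scaled.N0 = truth.N0 * c
        truth_scaled.A = truth.A / c
        f = LVObjective(table, mask)(pack(truth, mask))
        g = LVObjective(scaled, mask)(pack(truth_scaled, mask))
        assert g == pytest.approx(f, abs=1e-12)

    def test_requires_single_treatment(self):
        df = pd.DataFrame({"time": [0, 1, 0, 1], "species": "a",
                           "abundance": [1, 2, 1, 2],
                           "treatment": ["x", "x", "y", "y"]})
        with pytest.raises(ValidationError, match="treatment"):
            LVObjective(ObservationTable(df),
                        ConstraintMask.free_all(["a"]))


class TestOptimize:
    def test_recovers_logistic_from_perturbed_start(self, logistic_noise_free):
        table, truth = logistic_noise_free
        start = truth.copy()
        start.r = truth.r * 1.5
        start.A = truth.A * 1.5
        start.N0 = truth.N0 * 1.5
        res = optimize_lv(start, table, compute_se=False)
        assert res.params.r[0] == pytest.approx(truth.r[0], rel=0.01)
        assert res.params.A[0, 0] == pytest.approx(truth.A[0, 0], rel=0.01)
        assert res.params.N0[0] == pytest.approx(truth.N0[0], rel=0.01)

    def test_optimal_start_is_fixed_point(self, logistic_noise_free):
        table, truth = logistic_noise_free
        res = optimize_lv(truth.copy(), table, compute_se=False)
        assert res.start_objective - res.objective_value < 1e-10

    def test_objective_value_matches_reevaluation(self, logistic_noise_free):
        table, truth = logistic_noise_free
        res = optimize_lv(truth.copy(), table, compute_se=False)
        obj = LVObjective(table, res.mask)
        assert res.objective_value == pytest.approx(
            obj(pack(res.params, res.mask)), abs=1e-8)

    def test_deterministic_repeat_runs(self, logistic_noise_free):
        spec = preset("logistic_monoculture", noise_sd=0.1, seed=9)
        table, _ = generate(spec)
        a = fit_lv(table, compute_se=False)
        b = fit_lv(table, compute_se=False)
        assert np.array_equal(a.params.r, b.params.r)
        assert np.array_equal(a.params.A, b.params.A)
        assert np.array_equal(a.params.N0, b.params.N0)

    def test_monotone_improvement_and_constraints(self, preset_closure):
        name, truth, table, res = preset_closure
        assert res.objective_value <= res.start_objective
        mask = res.mask
        # zero-status parameters exactly zero, free ones keep assigned sign
        assert np.all(res.params.r[~mask.r_free] == 0.0)
        assert np.all(res.params.A[~mask.A_free] == 0.0)
        assert np.all(np.sign(res.params.r[mask.r_free])
                      == mask.r_sign[mask.r_free])
        assert np.all(np.sign(res.params.A[mask.A_free])
                      == mask.A_sign[mask.A_free])
        assert np.all(res.params.N0 > 0)


class TestWrapper:
    def test_user_zero_constraints_enforced(self):
        spec = preset("paramecium_competition", noise_sd=0.05, seed=1)
        table, _ = generate(spec)
        mask = ConstraintMask.free_all(
            ["P_aurelia", "P_caudatum"]).fix_zero(
            a=[("P_aurelia", "P_caudatum"), ("P_caudatum", "P_aurelia")])
        res = fit_lv(table, user_mask=mask, treatment="mixture",
                     maxiter=500, compute_se=False)
        assert res.params.A[0, 1] == 0.0
        assert res.params.A[1, 0] == 0.0

    def test_multi_treatment_requires_selection(self):
        spec = preset("paramecium_competition", noise_sd=0.0)
        table, _ = generate(spec)
        with pytest.raises(ValidationError, match="treatment"):
            fit_lv(table)


class TestApproxSE:
    class Quadratic:
        """f(theta) = (t0-1)^2 + (t1-2)^2 + c with known Hessian 2I."""

        def __init__(self, c, m):
            self.c = c
            self.n_residuals = m

        def __call__(self, theta):
            return float((theta[0] - 1) ** 2 + (theta[1] - 2) ** 2 + self.c)

    def mask(self):
        # one species, self-limitation fixed to zero: packed = (ln r, ln N0)
        return ConstraintMask(["x"], A_free=[[False]])

    def test_quadratic_oracle(self):
        c, m, k = 0.09, 3, 2
        obj = self.Quadratic(c, m)
        theta = np.array([1.0, 2.0])
        r_se, A_se, N0_se, log_sd = approx_se(obj, theta, self.mask(),
                                              f_min=c)
        # sigma^2 = c/(m-k) = c; cov = 2 sigma^2 H^{-1} = c I; s = sqrt(c)
        s = np.sqrt(c)
        assert np.allclose(log_sd, s, rtol=1e-5)
        assert r_se[0] == pytest.approx(np.e * (1 - np.exp(-s)), rel=1e-5)
        assert N0_se[0] == pytest.approx(np.e**2 * (1 - np.exp(-s)), rel=1e-5)
        assert np.all(np.isnan(A_se))

    def test_zero_curvature_spread_gives_zero_se(self):
        obj = self.Quadratic(0.0, 3)
        r_se, _, N0_se, log_sd = approx_se(obj, np.array([1.0, 2.0]),
                                           self.mask(), f_min=0.0)
        assert log_sd[0] == pytest.approx(0.0, abs=1e-12)
        assert r_se[0] == pytest.approx(0.0, abs=1e-12)

    def test_no_residual_dof_warns_and_returns_nan(self):
        obj = self.Quadratic(0.1, 2)  # m == k
        with pytest.warns(UserWarning, match="degrees of freedom"):
            r_se, A_se, N0_se, _ = approx_se(obj, np.array([1.0, 2.0]),
                                             self.mask(), f_min=0.1)
        assert np.all(np.isnan(r_se)) and np.all(np.isnan(N0_se))

    def test_negative_curvature_warns(self):
        class Saddle(self.Quadratic):
            def __call__(self, theta):
                return float((theta[0] - 1) ** 2 - (theta[1] - 2) ** 2
                             + self.c)

        with pytest.warns(UserWarning, match="negative curvature"):
            r_se, _, N0_se, _ = approx_se(Saddle(0.1, 5),
                                          np.array([1.0, 2.0]), self.mask(),
                                          f_min=0.1)
        assert np.isfinite(r_se[0])
        assert np.isnan(N0_se[0])
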