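"""Path-model algebra, ML fitting, fit indices, enumeration, and the
exhaustive search with AIC selection."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from heteropath import pathsem, simdata
from heteropath.pathsem import (
    DEFAULT_CRITERIA,
    DEFAULT_VARIABLES,
    PathModel,
    enumerate_models,
    fit_indices,
    fit_path_model,
    implied_covariance,
    ml_discrepancy,
    model_search,
)

from conftest import PIFB47_CORR, mvn_sample

FIG_EDGES = frozenset(
    [
        ("heterozygosity", "GA"),
        ("GA", "BR"),
        ("GA", "PHT"),
        ("BR", "PHT"),
        ("heterozygosity", "PHT"),
    ]
)


def sample_cov(n, seed, params=None):
    params = params or simdata.default_structural_params()
    rng = np.random.default_rng(seed)
    data = simdata.structural_sample(params, rng.standard_normal(n), rng)
    return data[list(DEFAULT_VARIABLES)].cov(), data


class TestImpliedCovariance:
    def test_no_edges_unit_variances_identity(self):
        model = PathModel(variables=("x", "y"), edges=frozenset())
        sigma = implied_covariance(model, B={}, psi={"x": 1.0, "y": 1.0})
        np.testing.assert_allclose(sigma.to_numpy(), np.eye(2))

    def test_single_edge_hand_algebra(self):
        model = PathModel(variables=("x", "y"), edges=frozenset({("x", "y")}))
        sigma = implied_covariance(
            model, B={("x", "y"): 0.7}, psi={"x": 1.0, "y": 1.0}
        )
        assert sigma.loc["x", "y"] == pytest.approx(0.7)
        assert sigma.loc["y", "y"] == pytest.approx(0.49 + 1.0)

    def test_final_topology_matches_path_tracing(self, default_params):
        # correlations from summed products over directed paths
        model = PathModel(
            variables=DEFAULT_VARIABLES, edges=FIG_EDGES, exogenous=("heterozygosity",)
        )
        e = default_params.edges
        psi = {"heterozygosity": 1.0}
        psi.update({k: v**2 for k, v in default_params.residual_sd.items()})
        sigma = implied_covariance(model, B=e, psi=psi)
        a = e[("heterozygosity", "GA")]
        b = e[("GA", "BR")]
        c = e[("heterozygosity", "PHT")]
        d = e[("GA", "PHT")]
        f = e[("BR", "PHT")]
        assert sigma.loc["heterozygosity", "GA"] == pytest.approx(a)
        assert sigma.loc["heterozygosity", "BR"] == pytest.approx(a * b)
        assert sigma.loc["heterozygosity", "PHT"] == pytest.approx(c + a * d + a * b * f)
        assert sigma.loc["GA", "PHT"] == pytest.approx(a * c + d + b * f)


class TestFitPathModel:
    def test_saturated_model_fits_exactly(self):
        S, _ = sample_cov(200, seed=1)
        saturated = PathModel(
            variables=DEFAULT_VARIABLES,
            edges=frozenset(
                [
                    ("heterozygosity", "GA"),
                    ("heterozygosity", "BR"),
                    ("heterozygosity", "PHT"),
                    ("GA", "BR"),
                    ("GA", "PHT"),
                    ("BR", "PHT"),
                ]
            ),
            exogenous=("heterozygosity",),
        )
        assert saturated.df == 0
        estimates, indices = fit_path_model(saturated, S, N=200)
        assert indices.chi2 == pytest.approx(0.0, abs=1e-8)
        np.testing.assert_allclose(
            estimates["sigma"].to_numpy(), S.to_numpy(), atol=1e-8
        )

    def test_estimates_equal_per_equation_least_squares(self):
        S, data = sample_cov(500, seed=2)
        model = PathModel(
            variables=DEFAULT_VARIABLES, edges=FIG_EDGES, exogenous=("heterozygosity",)
        )
        estimates, _ = fit_path_model(model, S, N=500)
        # raw-data OLS, equation by equation (with intercept; data are
        # not centred, covariances are)
        X = np.column_stack([np.ones(len(data)), data["heterozygosity"]])
        beta = np.linalg.lstsq(X, data["GA"], rcond=None)[0]
        assert estimates["B"][("heterozygosity", "GA")] == pytest.approx(
            beta[1], abs=1e-6
        )
        X = np.column_stack(
            [np.ones(len(data)), data["BR"], data["GA"], data["heterozygosity"]]
        )
        beta = np.linalg.lstsq(X, data["PHT"], rcond=None)[0]
        assert estimates["B"][("BR", "PHT")] == pytest.approx(beta[1], abs=1e-6)
        assert estimates["B"][("GA", "PHT")] == pytest.approx(beta[2], abs=1e-6)
        assert estimates["B"][("heterozygosity", "PHT")] == pytest.approx(
            beta[3], abs=1e-6
        )

    def test_closed_form_is_the_numerical_ml_optimum(self):
        # independent route: minimize F_ML numerically over the free
        # parameters from a neutral start; must land on the same point
        S, _ = sample_cov(300, seed=3)
        model = PathModel(
            variables=DEFAULT_VARIABLES, edges=FIG_EDGES, exogenous=("heterozygosity",)
        )
        edges = sorted(model.edges)

        def unpack(theta):
            B = dict(zip(edges, theta[: len(edges)]))
            psi = dict(zip(DEFAULT_VARIABLES, np.exp(theta[len(edges) :])))
            return B, psi

        def objective(theta):
            B, psi = unpack(theta)
            sigma = implied_covariance(model, B, psi)
            return ml_discrepancy(sigma.to_numpy(), S.to_numpy())

        x0 = np.concatenate([np.zeros(len(edges)), np.log(np.diag(S))])
        res = optimize.minimize(objective, x0, method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
        B_num, _ = unpack(res.x)
        estimates, _ = fit_path_model(model, S, N=300)
        assert estimates["F_ML"] <= res.fun + 1e-9
        for edge in edges:
            assert estimates["B"][edge] == pytest.approx(B_num[edge], abs=1e-4)

    def test_parameter_recovery_at_large_n(self, default_params):
        S, _ = sample_cov(10_000, seed=4, params=default_params)
        model = PathModel(
            variables=DEFAULT_VARIABLES, edges=FIG_EDGES, exogenous=("heterozygosity",)
        )
        estimates, _ = fit_path_model(model, S, N=10_000)
        for edge, truth in default_params.edges.items():
            assert estimates["B"][edge] == pytest.approx(truth, abs=0.05)

    def test_nesting_monotonicity_of_chi2(self):
        # adding a free edge never increases chi-square
        S, _ = sample_cov(400, seed=5)
        rng = np.random.default_rng(6)
        models = enumerate_models()
        by_edges = {m.edges: m for m in models}
        pairs = 0
        while pairs < 10:
            m = models[rng.integers(len(models))]
            if not m.edges:
                continue
            smaller = frozenset(
                e for e in m.edges if e != sorted(m.edges)[rng.integers(len(m.edges))]
            )
            if smaller not in by_edges:
                continue
            _, big = fit_path_model(m, S, N=400)
            _, small = fit_path_model(by_edges[smaller], S, N=400)
            assert big.chi2 <= small.chi2 + 1e-8
            pairs += 1

    def test_sample_covariance_must_be_positive_definite(self):
        model = PathModel(variables=("x", "y"), edges=frozenset())
        S = pd.DataFrame([[1.0, 1.0], [1.0, 1.0]], index=["x", "y"], columns=["x", "y"])
        with pytest.raises(ValueError, match="positive definite"):
            fit_path_model(model, S, N=50)


class TestFitIndices:
    def test_exact_expected_fit_gives_zero_rmsea(self):
        idx = fit_indices(5.0, 5, 100.0, 6, N=200, q=5, sigma=np.eye(2), S=np.eye(2))
        assert idx.RMSEA == 0.0

    def test_perfect_fit_limits(self):
        idx = fit_indices(0.0, 2, 80.0, 6, N=150, q=8, sigma=np.eye(2), S=np.eye(2))
        assert idx.CFI == 1.0 and idx.NFI == 1.0 and idx.GFI == 1.0

    def test_worked_example_matches_hand_formulas(self):
        # one constrained edge on four variables: df = 1; every index
        # recomputed from its defining formula
        S, _ = sample_cov(300, seed=7)
        d = np.sqrt(np.diag(S))
        S = S / np.outer(d, d)
        model = PathModel(
            variables=DEFAULT_VARIABLES, edges=FIG_EDGES, exogenous=("heterozygosity",)
        )
        estimates, idx = fit_path_model(model, S, N=300)
        chi2, df, q, N = idx.chi2, idx.df, idx.q, idx.N
        chi2_b = (300 - 1) * (
            np.sum(np.log(np.diag(S))) - np.linalg.slogdet(S.to_numpy())[1]
        )
        df_b = 6
        assert df == 1 and q == 9
        assert idx.p_chi2 == pytest.approx(stats.chi2.sf(chi2, df), abs=1e-12)
        assert idx.RMSEA == pytest.approx(
            math.sqrt(max(chi2 - df, 0) / (df * (N - 1))), abs=1e-12
        )
        assert idx.CFI == pytest.approx(
            1 - max(chi2 - df, 0) / max(chi2_b - df_b, chi2 - df, 0), abs=1e-10
        )
        assert idx.NFI == pytest.approx((chi2_b - chi2) / chi2_b, abs=1e-10)
        assert idx.RFI == pytest.approx(
            1 - (chi2 / df) / (chi2_b / df_b), abs=1e-10
        )
        assert idx.IFI == pytest.approx((chi2_b - chi2) / (chi2_b - df), abs=1e-10)
        sigma = estimates["sigma"].to_numpy()
        ratio = np.linalg.solve(sigma, S.to_numpy())
        gfi = 1 - np.trace((ratio - np.eye(4)) @ (ratio - np.eye(4))) / np.trace(
            ratio @ ratio
        )
        assert idx.GFI == pytest.approx(gfi, abs=1e-10)
        assert idx.AGFI == pytest.approx(1 - (4 * 5 / (2 * df)) * (1 - gfi), abs=1e-10)
        assert idx.AIC == pytest.approx(chi2 + 2 * q, abs=1e-12)

    def test_saturated_model_indices_not_applicable(self):
        idx = fit_indices(0.0, 0, 50.0, 6, N=100, q=10, sigma=np.eye(2), S=np.eye(2))
        assert idx.RMSEA is None and idx.RFI is None and idx.p_chi2 is None


class TestEnumeration:
    def test_two_variable_case(self):
        models = enumerate_models(("x", "y"), exogenous_only=("x",), sink_only=("y",))
        assert len(models) == 2

    def test_three_variable_unconstrained_dag_count(self):
        # 25 labelled DAGs on 3 nodes, via independent generate-and-filter
        variables = ("a", "b", "c")
        all_edges = [
            (s, t) for s in variables for t in variables if s != t
        ]
        count = 0
        for r in range(len(all_edges) + 1):
            for subset in itertools.combinations(all_edges, r):
                adj = {v: [] for v in variables}
                for s, t in subset:
                    adj[s].append(t)
                # cycle check by DFS
                state = dict.fromkeys(variables, 0)

                def cyclic(v):
                    state[v] = 1
                    for w in adj[v]:
                        if state[w] == 1 or (state[w] == 0 and cyclic(w)):
                            return True
                    state[v] = 2
                    return False

                if not any(cyclic(v) for v in variables if state[v] == 0):
                    count += 1
        assert count == 25
        models = enumerate_models(variables, exogenous_only=(), sink_only=())
        # over-parameterized DAGs (q > moments) are excluded by contract;
        # on 3 variables every DAG satisfies q <= 6, so counts agree
        assert len(models) == 25

    def test_default_constrained_count_matches_brute_force(self):
        models = enumerate_models()
        allowed = [
            (s, t)
            for s in DEFAULT_VARIABLES
            for t in DEFAULT_VARIABLES
            if s != t and t != "heterozygosity" and s != "PHT"
        ]
        brute = 0
        for r in range(len(allowed) + 1):
            for subset in itertools.combinations(allowed, r):
                if ("GA", "BR") in subset and ("BR", "GA") in subset:
                    continue
                brute += 1
        assert len(models) == brute == 96

    def test_refuses_large_variable_sets(self):
        with pytest.raises(ValueError):
            enumerate_models(tuple("abcdefg"))


class TestModelSearch:
    def test_independence_data_prefers_empty_model(self):
        rng = np.random.default_rng(8)
        data = pd.DataFrame(
            rng.standard_normal((500, 4)), columns=DEFAULT_VARIABLES
        )
        result = model_search(data.cov(), N=500)
        passing_edge_sets = [m.edges for m, _, _ in result.passing_models]
        assert frozenset() in passing_edge_sets
        assert len(result.best_edges()) <= 1

    def test_impossible_criteria_give_empty_passing_set(self):
        S, _ = sample_cov(300, seed=9)
        criteria = dict(DEFAULT_CRITERIA, CFI=(">", 1.5))
        result = model_search(S, N=300, criteria=criteria)
        assert result.passing_models == []
        assert result.best is None
        assert len(result.audit) == 96

    def test_generating_topology_recovered(self, default_params):
        S, _ = sample_cov(300, seed=10, params=default_params)
        result = model_search(S, N=300)
        assert result.best_edges() == FIG_EDGES

    def test_audit_is_complete_and_consistent(self):
        S, _ = sample_cov(250, seed=11)
        result = model_search(S, N=250)
        assert len(result.audit) == 96
        assert result.audit["passes"].sum() == len(result.passing_models)
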