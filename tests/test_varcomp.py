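"""REML fitter checked against independent dense-formula oracles.

The oracle used throughout is the textbook restricted log-likelihood

    l_R = -1/2 [ log|V| + log|X' V^-1 X| + y' P y + (n - p) log 2 pi ]

computed here with plain inverses and slogdet, entirely independent of the
fitter's Cholesky/Woodbury/eigendecomposition code paths.
"""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

import hapreml as H
from hapreml.geno_io import PhenotypeTable, RelationshipMatrix
from hapreml.varcomp import ModelSpec, reml_fit, restricted_loglik_at

from conftest import random_hwe_panel


def oracle_loglik(y, X, covs, theta):
    """Direct dense REML log-likelihood (independent of the fitter)."""
    n, p = X.shape
    V = theta[-1] * np.eye(n)
    for t, C in zip(theta[:-1], covs):
        V = V + t * C
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    P = Vi - Vi @ X @ np.linalg.inv(XtViX) @ X.T @ Vi
    return -0.5 * (
        np.linalg.slogdet(V)[1]
        + np.linalg.slogdet(XtViX)[1]
        + y @ P @ y
        + (n - p) * np.log(2 * np.pi)
    )


def simple_table(y, **cols):
    df = pd.DataFrame({"id": [f"i{k}" for k in range(len(y))], "y": y, **cols})
    return PhenotypeTable(df, "y")


def psd_matrix(rng, n, rank=None, ids=None):
    b = rng.normal(size=(n, rank or n))
    vals = b @ b.T
    d = np.sqrt(np.diag(vals)).mean() ** 2
    vals = vals / d  # keep scale near 1
    return RelationshipMatrix(
        individual_ids=np.array(ids or [f"i{k}" for k in range(n)], dtype=object),
        values=vals,
        kind="snp_regional",
        n_markers=rank or n,
    )


class TestClosedForms:
    def test_intercept_only_residual_is_sample_variance(self, rng):
        y = rng.normal(size=40)
        fit = reml_fit(ModelSpec("y"), simple_table(y))
        n = len(y)
        s2 = y.var(ddof=1)
        assert fit.variance_estimates["residual"] == pytest.approx(s2, rel=1e-12)
        # closed-form REML loglik for V = s2*I, X = intercept
        expect = -0.5 * (
            n * np.log(s2) + np.log(n / s2) + (n - 1) + (n - 1) * np.log(2 * np.pi)
        )
        assert fit.restricted_loglik == pytest.approx(expect, abs=1e-10)

    def test_zero_response_reduces_to_determinant_terms(self, rng):
        # y = 0 with an intercept: y'Py = 0 exactly
        tab = simple_table(np.zeros(8))
        ll = restricted_loglik_at(ModelSpec("y"), tab, {"residual": 1.0})
        n = 8
        assert ll == pytest.approx(-0.5 * (np.log(n) + (n - 1) * np.log(2 * np.pi)))

    def test_constant_response_rejected_by_fit(self):
        with pytest.raises(ValueError, match="zero variance"):
            reml_fit(ModelSpec("y"), simple_table(np.full(5, 3.0)))


class TestLoglikEvaluator:
    def test_agrees_with_textbook_formula_5x5(self, rng):
        y = rng.normal(size=5)
        k = psd_matrix(rng, 5)
        tab = simple_table(y, sex=rng.integers(0, 2, size=5))
        spec = ModelSpec("y", fixed_effects=["sex"], genetic_components=[(k, "g")])
        for vg, ve in [(0.5, 1.0), (2.0, 0.3), (0.0, 1.7)]:
            got = restricted_loglik_at(spec, tab, {"g": vg, "residual": ve})
            X = np.column_stack([np.ones(5), tab.records["sex"].to_numpy(float)])
            want = oracle_loglik(y, X, [k.values], np.array([vg, ve]))
            assert got == pytest.approx(want, abs=1e-10)

    def test_optimum_dominates_perturbations(self, rng):
        y = rng.normal(size=30)
        k = psd_matrix(rng, 30, rank=5)
        tab = simple_table(y)
        spec = ModelSpec("y", genetic_components=[(k, "g")])
        fit = reml_fit(spec, tab)
        base = fit.restricted_loglik
        for factor in (0.8, 1.25):
            pert = {
                lab: max(v, 1e-6) * factor
                for lab, v in fit.variance_estimates.items()
            }
            assert restricted_loglik_at(spec, tab, pert) <= base + 1e-8


class TestRemlFit:
    def test_matches_brute_force_surface_maximum(self, rng):
        # n=6: grid + Nelder-Mead on the oracle surface, vs the fitter
        y = rng.normal(size=6)
        k = psd_matrix(rng, 6)
        tab = simple_table(y)
        spec = ModelSpec("y", genetic_components=[(k, "g")])
        fit = reml_fit(spec, tab)

        grid = [
            (vg, ve)
            for vg in np.linspace(0, 3, 31)
            for ve in np.linspace(0.05, 3, 30)
        ]
        best = max(grid, key=lambda t: oracle_loglik(y, np.ones((6, 1)), [k.values], np.array(t)))
        res = minimize(
            lambda t: -oracle_loglik(
                y, np.ones((6, 1)), [k.values],
                np.array([max(t[0], 0.0), max(t[1], 1e-8)]),
            ),
            x0=np.array(best), method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12},
        )
        assert fit.restricted_loglik == pytest.approx(-res.fun, abs=1e-6)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_fast_path_matches_general_path(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.normal(size=25)
        k = psd_matrix(rng, 25, rank=6)
        tab = simple_table(y)
        spec = ModelSpec("y", genetic_components=[(k, "g")])
        fast = reml_fit(spec, tab)
        general = reml_fit(spec, tab, force_general=True)
        assert fast.restricted_loglik == pytest.approx(
            general.restricted_loglik, abs=1e-6
        )

    def test_nesting_monotonicity(self, rng):
        y = rng.normal(size=40)
        k1 = psd_matrix(rng, 40, rank=5)
        k2 = psd_matrix(rng, 40, rank=4)
        tab = simple_table(y)
        ll_null = reml_fit(ModelSpec("y"), tab).restricted_loglik
        ll_one = reml_fit(
            ModelSpec("y", genetic_components=[(k1, "a")]), tab
        ).restricted_loglik
        ll_two = reml_fit(
            ModelSpec("y", genetic_components=[(k1, "a"), (k2, "b")]), tab
        ).restricted_loglik
        assert ll_one >= ll_null - 1e-6
        assert ll_two >= ll_one - 1e-6

    def test_permutation_invariance(self, rng):
        y = rng.normal(size=20)
        k = psd_matrix(rng, 20, rank=6)
        tab = simple_table(y, sex=rng.integers(0, 2, size=20))
        spec = ModelSpec("y", fixed_effects=["sex"], genetic_components=[(k, "g")])
        base = reml_fit(spec, tab).restricted_loglik
        perm = rng.permutation(20)
        tab2 = PhenotypeTable(tab.records.iloc[perm].reset_index(drop=True), "y")
        assert reml_fit(spec, tab2).restricted_loglik == pytest.approx(base, abs=1e-8)

    def test_boundary_estimates_are_exact_zeros(self):
        # under a pure-noise response some seeds must hit the 0 boundary
        zeros = 0
        for seed in range(6):
            rng = np.random.default_rng(100 + seed)
            y = rng.normal(size=30)
            k = psd_matrix(rng, 30, rank=5)
            fit = reml_fit(
                ModelSpec("y", genetic_components=[(k, "g")]), simple_table(y)
            )
            assert fit.variance_estimates["g"] >= 0.0
            zeros += fit.variance_estimates["g"] == 0.0
        assert zeros >= 1

    def test_aliased_components_reported(self, rng):
        y = rng.normal(size=15)
        eye = RelationshipMatrix(
            individual_ids=np.array([f"i{k}" for k in range(15)], dtype=object),
            values=np.eye(15), kind="snp_regional", n_markers=1,
        )
        fit = reml_fit(
            ModelSpec("y", genetic_components=[(eye, "a"), (eye, "b")]),
            simple_table(y),
        )
        assert any("aliased" in m for m in fit.messages)

    def test_aliased_fixed_columns_dropped(self, rng):
        y = rng.normal(size=12)
        sex = rng.integers(0, 2, size=12)
        tab = simple_table(y, sex=sex, sex_copy=sex)
        fit = reml_fit(ModelSpec("y", fixed_effects=["sex", "sex_copy"]), tab)
        assert fit.dropped_fixed == ["sex_copy"]

    def test_repeated_measures_recovers_pe(self):
        # strong permanent-environment signal, 4 records each
        rng = np.random.default_rng(7)
        n, R = 120, 4
        pe = rng.normal(size=n) * np.sqrt(2.0)
        y = np.repeat(pe, R) + rng.normal(size=n * R) * 0.5
        df = pd.DataFrame(
            {"id": np.repeat([f"i{k}" for k in range(n)], R), "y": y}
        )
        tab = PhenotypeTable(df, "y", repeated=True)
        fit = reml_fit(ModelSpec("y", repeated=True), tab)
        assert fit.converged
        assert fit.variance_estimates["pe"] == pytest.approx(2.0, rel=0.35)
        assert fit.variance_estimates["residual"] == pytest.approx(0.25, rel=0.35)

    def test_iid_random_effect_blups_shrink_group_means(self, rng):
        n = 60
        grp = np.repeat(list("abcdef"), 10)
        eff = dict(zip("abcdef", rng.normal(size=6) * 2))
        y = np.array([eff[g] for g in grp]) + rng.normal(size=n) * 0.5
        df = pd.DataFrame({"id": [f"i{k}" for k in range(n)], "y": y, "grp": grp})
        tab = PhenotypeTable(df, "y")
        fit = reml_fit(ModelSpec("y", iid_random_effects=["grp"]), tab)
        u = fit.blups["grp"]
        assert np.corrcoef(u, [eff[g] for g in "abcdef"])[0, 1] > 0.95
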