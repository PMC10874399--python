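"""Feasibility, bisection, vertex enumeration and composition sweeps."""

import itertools

import numpy as np
import pytest

from ribocell.analytic import analytic_mu_max
from ribocell.growth_solver import (
    SolverError,
    enumerate_extreme_solutions,
    is_feasible,
    maximize_growth,
    sweep_composition,
)
from ribocell.model_builder import build_constraints, derive_composition
from ribocell.parameters import DegradationModel, random_parameters

from conftest import assert_valid_solution


class TestFeasibility:
    def test_low_mu_feasible_high_mu_infeasible(self, glc):
        comp = derive_composition(glc, 0.36)
        ok, witness = is_feasible(build_constraints(glc, comp, 0.01, "base"))
        assert ok
        sys = build_constraints(glc, comp, 0.01, "base")
        resid = sys.residuals(witness)
        for r, s in zip(resid, sys.sign):
            assert r >= -1e-6 if s == "ge" else abs(r) < 1e-6
        ok, _ = is_feasible(build_constraints(glc, comp, 100.0, "base"))
        assert not ok

    def test_feasibility_monotone_in_mu(self, glc):
        # no re-entrant feasibility across a fine growth-rate grid
        comp = derive_composition(glc, 0.36)
        flags = []
        for mu in np.linspace(0.01, 1.5, 200):
            ok, _ = is_feasible(build_constraints(glc, comp, float(mu),
                                                  "base"))
            flags.append(ok)
        switch = np.flatnonzero(np.diff(np.asarray(flags, dtype=int)))
        assert len(switch) == 1 and flags[0] and not flags[-1]


class TestMaximizeGrowth:
    def test_bisection_tolerance_contract(self, glc):
        coarse = maximize_growth(glc, 0.36, tol=1e-3).mu
        fine = maximize_growth(glc, 0.36, tol=1e-9).mu
        assert abs(coarse - fine) < 1e-3

    def test_matches_analytic_root(self, glc):
        sol = maximize_growth(glc, 0.36, tol=1e-9)
        assert sol.mu == pytest.approx(analytic_mu_max(glc, 0.36), rel=1e-6)
        assert_valid_solution(sol, glc)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_sets_match_analytic(self, seed):
        p = random_parameters(seed)
        for x in (0.0, 0.5, 1.0):
            mu_a = analytic_mu_max(p, x)
            sol = maximize_growth(p, x, tol=min(1e-9 * mu_a, 1e-9) + 1e-12,
                                  mu_hi=2 * mu_a)
            assert sol.mu == pytest.approx(mu_a, rel=1e-6)
            assert_valid_solution(sol, p)

    def test_base_model_mu_decreasing_in_x(self, glc):
        # rRNA synthesis is the cheaper route with realistic parameters
        mus = [maximize_growth(glc, x, tol=1e-7).mu
               for x in (0.0, 0.25, 0.5, 0.75, 1.0)]
        assert all(np.diff(mus) < 0)

    def test_invalid_tol(self, glc):
        with pytest.raises(ValueError):
            maximize_growth(glc, 0.36, tol=0.0)


def brute_force_vertices(sys, tol=1e-7):
    """Independent vertex oracle: full-space active-set search.

    A vertex of {A_ge x >= 0, A_eq x = b, x >= 0} activates n linearly
    independent constraints.  Enumerate all ways of adding inequality rows
    and coordinate bounds to the equality rows, solve each square system and
    keep feasible solutions.  O(C(m, n - n_eq)) -- fine at this scale.
    """
    from ribocell.growth_solver import _normalized
    A, rhs = _normalized(sys)
    n = A.shape[1]
    eq = [i for i, s in enumerate(sys.sign) if s == "eq"]
    ge = [i for i, s in enumerate(sys.sign) if s == "ge"]
    candidates = [("row", i) for i in ge] + [("bound", j) for j in range(n)]
    base_A = A[eq]
    base_b = rhs[eq]
    need = n - len(eq)
    found = []
    for combo in itertools.combinations(candidates, need):
        rows = [base_A]
        bs = [base_b]
        for kind, i in combo:
            if kind == "row":
                rows.append(A[i][None, :])
                bs.append(rhs[i][None] if np.ndim(rhs[i]) else
                          np.array([rhs[i]]))
            else:
                e = np.zeros((1, n))
                e[0, i] = 1.0
                rows.append(e)
                bs.append(np.zeros(1))
        M = np.vstack(rows)
        b = np.concatenate(bs)
        if np.linalg.matrix_rank(M) < n:
            continue
        x = np.linalg.lstsq(M, b, rcond=None)[0]
        if np.max(np.abs(M @ x - b)) > 1e-8:
            continue
        resid = A[ge] @ x - rhs[ge]
        if np.min(resid) >= -tol and np.min(x) >= -tol:
            found.append(x)
    if not found:
        return np.empty((0, n))
    X = np.array(found)
    key = np.round(X / max(1.0, np.max(np.abs(X))), 9)
    _, idx = np.unique(key, axis=0, return_index=True)
    return X[np.sort(idx)]


@pytest.fixture(scope="module")
def half_max(glc):
    mu_max = maximize_growth(glc, 0.36, tol=1e-8).mu
    return mu_max, enumerate_extreme_solutions(glc, 0.36, 0.5 * mu_max)


class TestVertexEnumeration:
    def test_all_vertices_satisfy_constraints(self, glc, half_max):
        _, ext = half_max
        assert len(ext) > 0
        assert ext.max_violation < 1e-6
        comp = derive_composition(glc, 0.36)
        sys = build_constraints(glc, comp, ext.mu, "base")
        for v in ext.vertices:
            resid = sys.residuals(v)
            for r, s in zip(resid, sys.sign):
                scaled = r / max(1.0, np.max(np.abs(sys.A)))
                assert scaled >= -1e-6 if s == "ge" else abs(scaled) < 1e-6

    def test_matches_brute_force_oracle(self, glc, half_max):
        _, ext = half_max
        comp = derive_composition(glc, 0.36)
        sys = build_constraints(glc, comp, ext.mu, "base")
        oracle = brute_force_vertices(sys)
        assert len(oracle) == len(ext)
        # match up to permutation
        for v in ext.vertices:
            dists = np.min(np.max(np.abs(oracle - v), axis=1))
            assert dists < 1e-6 * max(1.0, np.max(np.abs(v)))

    def test_rrna_and_cap_r_limiting_vertex_exists(self, half_max):
        _, ext = half_max
        assert any("rRNA" in act and "cap R" in act
                   for act in ext.active_rows)

    def test_vertices_converge_at_maximum_growth(self, glc):
        mu_max = maximize_growth(glc, 0.36, tol=1e-9).mu
        ext = enumerate_extreme_solutions(glc, 0.36, mu_max - 1e-7)
        iv = ext.columns.index("v_RNAP")
        assert len(ext) >= 1
        assert np.ptp(ext.vertices[:, iv]) < 1e-6

    def test_unbounded_polytope_reported(self, glc):
        # at a pure-protein ribosome the transcription flux is free
        with pytest.raises(SolverError, match="unbounded"):
            enumerate_extreme_solutions(glc, 1.0, 0.5)


class TestSweep:
    def test_base_argmax_at_zero(self, glc):
        sweep = sweep_composition(glc, np.arange(0, 1.0001, 0.05), tol=1e-6,
                                  keep_solutions=False)
        assert sweep.argmax_x == 0.0
        assert not sweep.interior_optimum
        assert np.all(sweep.mu_max >= 0)

    def test_expensive_transcription_flips_argmax(self, glc):
        import dataclasses
        slow = dataclasses.replace(glc, kel_RNAP=glc.kel_RNAP / 100.0)
        sweep = sweep_composition(slow, np.arange(0, 1.0001, 0.05), tol=1e-6,
                                  keep_solutions=False)
        assert sweep.argmax_x == 1.0

    def test_extended_hill_interior_optimum(self, glc):
        import dataclasses
        p = dataclasses.replace(
            glc, degradation=DegradationModel("hill", 160.0, 0.2, 6))
        sweep = sweep_composition(p, np.arange(0, 1.0001, 0.05),
                                  variant="extended", tol=1e-5,
                                  keep_solutions=False)
        assert sweep.interior_optimum
        assert 0.0 < sweep.argmax_x < 1.0

    def test_unsorted_grid_rejected(self, glc):
        with pytest.raises(ValueError):
            sweep_composition(glc, [0.5, 0.1])
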