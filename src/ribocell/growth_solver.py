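"""Numerical growth-rate maximization.

The constraint table of :mod:`ribocell.model_builder` is linear in the
fluxes once the growth rate mu is fixed, so feasibility at fixed mu is a
small linear program, and the maximum growth rate is found by bisection on
mu (the feasible set shrinks monotonically with mu).  At fixed mu the
feasible fluxes form a bounded polytope whose vertices are the elementary
growth vectors; systems are at most 14 rows by 13 fluxes, so all vertices
can be enumerated exactly by exhaustive active-set search.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .model_builder import (
    Composition,
    ConstraintSystem,
    allocations,
    build_constraints,
    concentrations_from_fluxes,
    derive_composition,
    dry_mass,
)
from .parameters import ParameterSet

#: residual tolerance on rows normalized to unit max-abs coefficient
FEAS_TOL = 1e-9

_LP_OPTIONS = {
    "presolve": True,
    "primal_feasibility_tolerance": 1e-10,
    "dual_feasibility_tolerance": 1e-10,
}


class SolverError(RuntimeError):
    """LP failure that is not a clean infeasibility verdict."""


@dataclass(frozen=True)
class GrowthSolution:
    """A feasible (typically optimal) state of the model at growth rate mu."""

    mu: float
    columns: tuple
    fluxes: np.ndarray
    concentrations: dict
    phi: dict
    active_rows: tuple
    variant: str
    x_rP: float

    @property
    def flux(self) -> dict:
        return dict(zip(self.columns, self.fluxes))


@dataclass(frozen=True)
class SweepResult:
    """mu_max over a grid of ribosomal protein fractions for one scenario."""

    scenario: str
    x_grid: np.ndarray
    mu_max: np.ndarray
    solutions: tuple
    errors: tuple
    interior_tol: float = 1e-6

    @property
    def argmax_index(self) -> int:
        return int(np.nanargmax(self.mu_max))

    @property
    def argmax_x(self) -> float:
        return float(self.x_grid[self.argmax_index])

    @property
    def interior_optimum(self) -> bool:
        i = self.argmax_index
        if i == 0 or i == len(self.x_grid) - 1:
            return False
        edge = max(self.mu_max[0], self.mu_max[-1])
        return self.mu_max[i] > edge + self.interior_tol

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"x_rP": self.x_grid, "mu_max": self.mu_max,
                             "scenario": self.scenario})


@dataclass(frozen=True)
class ExtremeSolutionSet:
    """All vertices of the flux polytope at fixed mu."""

    mu: float
    columns: tuple
    vertices: np.ndarray            # (k, n) flux vectors
    active_rows: tuple              # per vertex: tuple of tight row labels
    active_bounds: tuple            # per vertex: tuple of flux names at 0
    max_violation: float = field(default=0.0)

    def __len__(self) -> int:
        return len(self.vertices)


# ---------------------------------------------------------------------------
# feasibility at fixed mu

def _normalized(sys: ConstraintSystem):
    """Row-normalize the table to unit max-abs coefficient (incl. rhs)."""
    scale = np.maximum(np.max(np.abs(sys.A), axis=1), np.abs(sys.rhs))
    scale[scale == 0] = 1.0
    return sys.A / scale[:, None], sys.rhs / scale


def is_feasible(sys: ConstraintSystem, tol: float = FEAS_TOL):
    """Feasibility of the constraint system; returns (flag, witness).

    Solves a max-min-slack LP: maximize t such that every inequality row has
    normalized slack at least t and all equality rows hold.  The system is
    feasible iff the optimum t* >= -tol; the witness then lies as centrally
    as the rows allow.  The mass row pins the flux scale, so there is no
    normalization ambiguity.
    """
    A, rhs = _normalized(sys)
    eq = [i for i, s in enumerate(sys.sign) if s == "eq"]
    ge = [i for i, s in enumerate(sys.sign) if s == "ge"]
    n = A.shape[1]
    # variables: fluxes x (>= 0) then slack t (free, capped for boundedness)
    c = np.zeros(n + 1)
    c[-1] = -1.0
    A_ub = np.hstack([-A[ge], np.ones((len(ge), 1))])
    b_ub = -rhs[ge]
    A_eq = np.hstack([A[eq], np.zeros((len(eq), 1))])
    b_eq = rhs[eq]
    bounds = [(0, None)] * n + [(None, 1e6)]
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                  bounds=bounds, method="highs", options=_LP_OPTIONS)
    if res.status == 2:
        return False, None
    if res.status != 0:
        raise SolverError(f"linprog failed with status {res.status}: "
                          f"{res.message}")
    t_opt = -res.fun
    if t_opt < -tol:
        return False, None
    return True, res.x[:-1]


# ---------------------------------------------------------------------------
# bisection for mu_max

def _polish_witness(sys: ConstraintSystem, fluxes: np.ndarray,
                    tol: float = 1e-6):
    """Snap a near-optimal LP witness onto its active constraint set.

    The LP solver satisfies rows only to its own tolerance, which downstream
    division by mu can amplify into small negative concentrations.  Solving
    the (typically square) system of near-active rows and near-zero bounds
    by least squares removes that noise.  Returns ``(fluxes, clean)`` where
    ``clean`` says whether an exactly-satisfying vertex was found.
    """
    import itertools as it

    A, rhs = _normalized(sys)
    n = A.shape[1]
    resid = A @ fluxes - rhs
    eq = [i for i, s in enumerate(sys.sign) if s == "eq"]
    near = [i for i, (s, r) in enumerate(zip(sys.sign, resid))
            if s == "ge" and abs(r) < tol]
    scale = max(1.0, float(np.max(np.abs(fluxes))))
    hard_zero = [j for j, x in enumerate(fluxes) if abs(x) < 1e-12 * scale]
    soft_zero = sorted(
        (j for j, x in enumerate(fluxes)
         if 1e-12 * scale <= abs(x) < tol * scale),
        key=lambda j: abs(fluxes[j]),
    )
    eye = np.eye(n)

    def acceptable(x):
        # backward-error criterion: each row residual is compared to the
        # magnitude of the terms it sums, so rows over tiny fluxes are held
        # to a correspondingly tight absolute tolerance
        r = A @ x - rhs
        lim = 1e-11 * np.maximum(np.abs(A) @ np.abs(x) + np.abs(rhs), 1e-300)
        ok = all(abs(ri) <= li if s == "eq" else ri >= -li
                 for s, ri, li in zip(sys.sign, r, lim))
        return ok and np.min(x) > -1e-12 * scale

    def square_solve(rows, bnds):
        E = np.vstack([A[rows], eye[bnds]]) if bnds else A[rows]
        b = np.concatenate([rhs[rows], np.zeros(len(bnds))])
        try:
            x = np.linalg.solve(E, b)
            for _ in range(3):  # iterative refinement to machine precision
                x += np.linalg.solve(E, b - E @ x)
        except np.linalg.LinAlgError:
            return None
        return x if acceptable(x) else None

    # choose exactly n active constraints (equalities always in) so the
    # vertex solves a square system to machine precision: drop surplus
    # near-active inequalities, or pin additional near-zero fluxes, in all
    # (few) combinations
    base_count = len(eq) + len(near) + len(hard_zero)
    attempts = 0
    if base_count >= n:
        surplus = base_count - n
        droppable = ([("row", i) for i in near]
                     + [("bound", j) for j in hard_zero])
        for drop in it.combinations(droppable, surplus):
            rows = eq + [i for i in near if ("row", i) not in drop]
            bnds = [j for j in hard_zero if ("bound", j) not in drop]
            x = square_solve(rows, bnds)
            attempts += 1
            if x is not None:
                return np.clip(x, 0.0, None), True
            if attempts > 300:
                break
    else:
        deficit = base_count - n
        for add in it.combinations(soft_zero, -deficit):
            x = square_solve(eq + near, hard_zero + list(add))
            attempts += 1
            if x is not None:
                return np.clip(x, 0.0, None), True
            if attempts > 300:
                break
    return fluxes, False


def _solution_from_witness(sys: ConstraintSystem, fluxes: np.ndarray,
                           tol: float = 1e-7) -> GrowthSolution:
    fluxes, _ = _polish_witness(sys, np.asarray(fluxes, dtype=float))
    # every row except mass is homogeneous, so rescaling the fluxes onto the
    # mass row is exact and preserves feasibility (dry mass comes out at 1)
    mass_lhs = float(sys.row("mass") @ fluxes)
    if mass_lhs > 0:
        fluxes = fluxes * (sys.mu / mass_lhs)
    A, rhs = _normalized(sys)
    resid = A @ fluxes - rhs
    active = tuple(
        label for label, s, r in zip(sys.rows, sys.sign, resid)
        if s == "eq" or abs(r) < tol
    )
    conc = concentrations_from_fluxes(sys, fluxes, sys.mu)
    phi = allocations(fluxes, sys.mu, sys.params, sys.composition, sys.variant)
    return GrowthSolution(
        mu=sys.mu, columns=sys.columns, fluxes=np.asarray(fluxes),
        concentrations=conc, phi=phi, active_rows=active,
        variant=sys.variant, x_rP=sys.composition.x_rP,
    )


def maximize_growth(params: ParameterSet, x_rP: float, variant: str = "base",
                    tol: float = 1e-6, accumulation_mode: str = "allow",
                    mu_hi: float | None = None) -> GrowthSolution:
    """Maximum growth rate at fixed ribosome composition, by bisection.

    The initial upper bracket is the autocatalytic ceiling
    kel_bar_R*omega_AA/omega_R (doubled until infeasible, for parameter sets
    whose optimum exceeds it); the returned mu is within ``tol`` (1/h) below
    the supremum of feasible growth rates, with the LP witness attached.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    comp = derive_composition(params, x_rP)

    # strict slack threshold: the max-min-slack value decreases smoothly
    # through zero at the optimum, so a zero cut-off keeps the bisection
    # error at the level of the LP solution accuracy rather than tol/slope
    def feasible(mu):
        sys = build_constraints(params, comp, mu, variant, accumulation_mode)
        return is_feasible(sys, tol=0.0)

    lo = min(tol, 1e-6)
    ok, witness = feasible(lo)
    if not ok:
        raise SolverError(
            f"model infeasible even at mu={lo:g} (degenerate parameters)"
        )
    hi = mu_hi if mu_hi is not None else params.mu_ceiling
    for _ in range(80):
        ok_hi, w_hi = feasible(hi)
        if not ok_hi:
            break
        lo, witness = hi, w_hi
        hi *= 2.0
    else:
        raise SolverError("no infeasible upper bracket found")
    while hi - lo > 0.5 * tol:
        mid = 0.5 * (lo + hi)
        ok, w = feasible(mid)
        if ok:
            lo, witness = mid, w
        else:
            hi = mid
    # the LP can declare feasibility a hair beyond the true optimum (its
    # objective is accurate to ~1e-12, worth up to ~1e-8*mu here); back off
    # below the bisection point until the witness snaps onto an exact vertex
    unit = max(0.5 * tol, 1e-8 * lo)
    for backoff in (0.0, 0.25, 0.5, 1.0, 2.0):
        mu_try = lo - backoff * unit
        if mu_try <= 0:
            continue
        w = witness
        if backoff > 0.0:
            ok, w = feasible(mu_try)
            if not ok:
                continue
        sys = build_constraints(params, comp, mu_try, variant,
                                accumulation_mode)
        polished, clean = _polish_witness(sys, np.asarray(w, dtype=float))
        if clean:
            return _solution_from_witness(sys, polished)
    sys = build_constraints(params, comp, lo, variant, accumulation_mode)
    return _solution_from_witness(sys, witness)


def sweep_composition(params: ParameterSet, grid, variant: str = "base",
                      tol: float = 1e-6, accumulation_mode: str = "allow",
                      keep_solutions: bool = True,
                      scenario: str | None = None) -> SweepResult:
    """mu_max over a sorted grid of ribosomal protein fractions.

    Per-point solver errors are recorded (mu_max = NaN there), not fatal.
    """
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) < 0):
        raise ValueError("grid must be sorted ascending")
    if np.any((grid < 0) | (grid > 1)):
        raise ValueError("grid must lie within [0, 1]")
    mu_max = np.full(len(grid), np.nan)
    sols: list = []
    errors: list = []
    for i, x in enumerate(grid):
        try:
            sol = maximize_growth(params, float(x), variant, tol,
                                  accumulation_mode)
            mu_max[i] = sol.mu
            sols.append(sol if keep_solutions else None)
        except SolverError as exc:
            errors.append((float(x), str(exc)))
            sols.append(None)
    label = scenario or (
        f"{params.condition_label}:{variant}:{params.degradation.scenario}"
    )
    return SweepResult(scenario=label, x_grid=grid, mu_max=mu_max,
                       solutions=tuple(sols), errors=tuple(errors),
                       interior_tol=max(tol, 1e-9))


# ---------------------------------------------------------------------------
# vertex (elementary growth vector) enumeration

def _cone_is_trivial(M: np.ndarray, tol: float = 1e-9) -> bool:
    """True iff the recession cone {y : M y >= 0} is {0} (bounded polytope)."""
    d = M.shape[1]
    for j in range(d):
        for sense in (1.0, -1.0):
            c = np.zeros(d)
            c[j] = -sense  # maximize sense*y_j
            res = linprog(c, A_ub=-M, b_ub=np.zeros(M.shape[0]),
                          bounds=[(-1, 1)] * d, method="highs")
            if res.status == 0 and -res.fun > tol:
                return False
    return True


def enumerate_extreme_solutions(params: ParameterSet, x_rP: float, mu: float,
                                variant: str = "base",
                                accumulation_mode: str = "allow",
                                tol: float = 1e-8,
                                chunk: int = 100_000) -> ExtremeSolutionSet:
    """All vertices of the feasible flux polytope at fixed mu.

    Equality rows are eliminated first (particular solution plus null-space
    basis); in the reduced space every vertex activates exactly dim
    inequalities (rows or nonnegativity bounds), so exhaustive active-set
    enumeration with rank checks is exact.  Raises for unbounded polytopes
    (possible only at the degenerate compositions x_rP = 0 or 1).
    """
    comp = derive_composition(params, x_rP)
    sys = build_constraints(params, comp, mu, variant, accumulation_mode)
    A, rhs = _normalized(sys)
    eq = [i for i, s in enumerate(sys.sign) if s == "eq"]
    ge = [i for i, s in enumerate(sys.sign) if s == "ge"]
    n = A.shape[1]

    from scipy.linalg import lstsq, null_space
    x0, *_ = lstsq(A[eq], rhs[eq])
    if np.max(np.abs(A[eq] @ x0 - rhs[eq])) > 1e-8:
        return ExtremeSolutionSet(mu=mu, columns=sys.columns,
                                  vertices=np.empty((0, n)),
                                  active_rows=(), active_bounds=())
    Z = null_space(A[eq])
    d = Z.shape[1]
    # reduced inequalities M y >= q: constraint rows then flux bounds
    M = np.vstack([A[ge] @ Z, Z])
    q = np.concatenate([rhs[ge] - A[ge] @ x0, -x0])
    labels = [sys.rows[i] for i in ge] + [f"{c}=0" for c in sys.columns]
    if not _cone_is_trivial(M):
        raise SolverError(
            "flux polytope is unbounded at this composition; "
            "vertex enumeration is not defined"
        )

    combos = np.array(list(itertools.combinations(range(M.shape[0]), d)))
    verts: list = []
    vert_active: list = []
    for start in range(0, len(combos), chunk):
        sub = combos[start:start + chunk]
        Ms = M[sub]                      # (k, d, d)
        qs = q[sub]                      # (k, d)
        dets = np.abs(np.linalg.det(Ms))
        ok = dets > 1e-10
        if not np.any(ok):
            continue
        ys = np.linalg.solve(Ms[ok], qs[ok][..., None])[..., 0]
        resid = ys @ M.T - q             # (k_ok, m)
        feas = np.all(resid >= -1e-7, axis=1)
        for y, combo in zip(ys[feas], sub[ok][feas]):
            verts.append(y)
            vert_active.append(combo)
    if not verts:
        return ExtremeSolutionSet(mu=mu, columns=sys.columns,
                                  vertices=np.empty((0, n)),
                                  active_rows=(), active_bounds=())
    Y = np.array(verts)
    X = x0 + Y @ Z.T
    # dedupe vertices that share the same point (degenerate active sets)
    scale = max(1.0, np.max(np.abs(X)))
    key = np.round(X / scale, 9)
    _, idx = np.unique(key, axis=0, return_index=True)
    idx = np.sort(idx)
    X = X[idx]
    active_rows = []
    active_bounds = []
    max_violation = 0.0
    for x in X:
        resid_rows = A[ge] @ x - rhs[ge]
        max_violation = max(max_violation, float(-np.min(resid_rows)),
                            float(-np.min(x)))
        tight = [sys.rows[i] for k, i in enumerate(ge)
                 if abs(resid_rows[k]) < 1e-7]
        zero = [c for c, xi in zip(sys.columns, x) if abs(xi) < 1e-10]
        active_rows.append(tuple(tight))
        active_bounds.append(tuple(zero))
    return ExtremeSolutionSet(
        mu=mu, columns=sys.columns, vertices=X,
        active_rows=tuple(active_rows), active_bounds=tuple(active_bounds),
        max_violation=max(0.0, max_violation),
    )


# ---------------------------------------------------------------------------
# solution sanity

def check_solution(sol: GrowthSolution, params: ParameterSet,
                   tol: float = 1e-9) -> dict:
    """Invariant report for a solution: nonnegativity, dry mass, allocations.

    Returns a dict of named residuals; all should be within tolerance for
    any solution produced by this module.
    """
    comp = derive_composition(params, sol.x_rP)
    sys = build_constraints(params, comp, sol.mu, sol.variant)
    return {
        "min_flux": float(np.min(sol.fluxes)),
        "min_concentration": float(min(sol.concentrations.values())),
        "dry_mass_error": abs(dry_mass(sys, sol.concentrations) - 1.0),
        "phi_sum": float(sum(sol.phi.values())),
    }
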