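"""Shared fixtures and the solution-invariant checker.

Every growth solution produced anywhere in the suite is expected to pass
``assert_valid_solution``: nonnegative fluxes and concentrations, unit dry
mass, ribosome allocations summing to at most one, and growth rate below
both fixed-allocation autocatalytic bounds evaluated at the realized
allocations.
"""

import numpy as np
import pytest

from ribocell.analytic import kr_bounds
from ribocell.growth_solver import GrowthSolution
from ribocell.model_builder import build_constraints, derive_composition, dry_mass
from ribocell.parameters import ParameterSet, ecoli_fixture


def assert_valid_solution(sol: GrowthSolution, params: ParameterSet,
                          tol: float = 1e-9) -> None:
    assert np.min(sol.fluxes) >= -tol, "negative flux"
    assert min(sol.concentrations.values()) >= -tol, "negative concentration"
    comp = derive_composition(params, sol.x_rP)
    sys = build_constraints(params, comp, sol.mu, sol.variant)
    assert abs(dry_mass(sys, sol.concentrations) - 1.0) <= 1e-9, \
        "dry mass differs from 1"
    phi_sum = sum(sol.phi.values())
    assert phi_sum <= 1.0 + 1e-9, "ribosome allocations exceed 1"
    # growth rate must respect both autocatalytic-loop bounds at the
    # realized allocations (they relax the full constraint set)
    phi_rP = sol.phi.get("rP", 0.0)
    phi_RNAP = sol.phi.get("RNAP", 0.0)
    if phi_rP > 0 and phi_RNAP > 0 and 0 < sol.x_rP < 1 \
            and params.rp_import_fraction == 0:
        b = kr_bounds(params, sol.x_rP, phi_rP, phi_RNAP)
        assert sol.mu <= b.bound_rP + 1e-9
        assert sol.mu <= b.bound_RNAP + 1e-9


@pytest.fixture(scope="session")
def glc():
    return ecoli_fixture("glc")


@pytest.fixture(scope="session")
def all_conditions():
    from ribocell.parameters import ECOLI_CONDITIONS
    return {c: ecoli_fixture(c) for c in ECOLI_CONDITIONS}
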