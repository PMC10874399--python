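"""Constraint-table fidelity, composition algebra and mass conservation."""

import dataclasses

import numpy as np
import pytest

from ribocell.model_builder import (
    allocations,
    build_constraints,
    concentrations_from_fluxes,
    derive_composition,
    dry_mass,
    kdeg_value,
    stoichiometric_matrix,
)
from ribocell.parameters import DegradationModel, random_parameters


@pytest.fixture(scope="module")
def glc_ext(glc):
    return dataclasses.replace(
        glc, degradation=DegradationModel("hill", 160.0, 0.2, 6))


class TestComposition:
    def test_endpoints(self, glc):
        pure_rna = derive_composition(glc, 0.0)
        assert pure_rna.n_rP == 0.0
        assert pure_rna.n_rRNA == pytest.approx(glc.omega_R / glc.omega_NT)
        pure_protein = derive_composition(glc, 1.0)
        assert pure_protein.n_rRNA == 0.0
        assert pure_protein.n_rP == pytest.approx(glc.omega_R / glc.omega_AA)

    def test_observed_composition_is_7400_amino_acids(self, glc):
        assert derive_composition(glc, 0.36).n_rP == pytest.approx(7400.0)

    def test_mass_identity_and_bijection_on_grid(self, glc):
        for x in np.arange(0.0, 1.0001, 0.01):
            comp = derive_composition(glc, float(x))
            total = comp.n_rRNA * glc.omega_NT + comp.n_rP * glc.omega_AA
            assert total == pytest.approx(glc.omega_R, rel=1e-14)
            # reading the fraction back is exact
            assert comp.n_rP * glc.omega_AA / glc.omega_R == \
                pytest.approx(x, abs=1e-14)

    def test_out_of_range_rejected(self, glc):
        with pytest.raises(ValueError):
            derive_composition(glc, 1.2)


class TestDegradationRate:
    def test_scenarios(self):
        hill = DegradationModel("hill", kdeg_max=10.0, K=0.2, n_hill=6)
        assert kdeg_value(DegradationModel("none"), 0.5) == 0.0
        assert kdeg_value(DegradationModel("constant", 7.0), 0.9) == 7.0
        assert kdeg_value(hill, 0.0) == pytest.approx(10.0)
        # half-saturation at x = K by definition
        assert kdeg_value(hill, 0.2) == pytest.approx(5.0)

    def test_cooperativity_suppresses_degradation_above_K(self):
        h2 = DegradationModel("hill", 10.0, 0.2, 2)
        h6 = DegradationModel("hill", 10.0, 0.2, 6)
        assert kdeg_value(h6, 0.36) < kdeg_value(h2, 0.36)

    @pytest.mark.parametrize("n_hill", [1, 2, 6, 10])
    def test_non_increasing_in_x(self, n_hill):
        deg = DegradationModel("hill", 10.0, 0.2, n_hill)
        values = [kdeg_value(deg, x) for x in np.linspace(0, 1, 101)]
        assert all(np.diff(values) <= 1e-12)
        assert values[0] == pytest.approx(deg.kdeg_max)


class TestConstraintTable:
    def test_shapes(self, glc, glc_ext):
        comp = derive_composition(glc, 0.36)
        assert build_constraints(glc, comp, 1.0, "base").shape == (12, 11)
        assert build_constraints(glc_ext, comp, 1.0, "extended").shape \
            == (14, 13)

    def test_extended_requires_degradation(self, glc):
        comp = derive_composition(glc, 0.36)
        with pytest.raises(ValueError, match="degradation"):
            build_constraints(glc, comp, 1.0, "extended")

    @pytest.mark.parametrize("seed", range(10))
    def test_capacity_rows_match_hand_derivation(self, seed):
        # every capacity row is (-mu * demand, +k * supply); spot-check all
        p = dataclasses.replace(
            random_parameters(seed),
            degradation=DegradationModel("hill", 5.0, 0.2, 2))
        mu = 0.7
        comp = derive_composition(p, 0.41)
        sys = build_constraints(p, comp, mu, "extended")
        c = {n: j for j, n in enumerate(sys.columns)}
        for enz, kcat in (("IC", p.kcat_IC), ("EAA", p.kcat_EAA),
                          ("ENT", p.kcat_ENT), ("AF", p.kcat_AF)):
            row = sys.row(f"cap {enz}")
            assert row[c[f"v_{enz}"]] == pytest.approx(-mu)
            assert row[c[f"w_{enz}"]] == pytest.approx(kcat)
            assert np.count_nonzero(row) == 2
        row = sys.row("cap RNAP")
        assert row[c["v_RNAP"]] == pytest.approx(-mu * comp.n_rRNA)
        assert row[c["w_RNAP"]] == pytest.approx(p.kel_bar_RNAP)
        row = sys.row("cap RNase")
        assert row[c["v_RNase"]] == pytest.approx(-mu * comp.n_rRNA)
        assert row[c["w_RNase"]] == pytest.approx(p.kdeg_RNase)
        row = sys.row("cap R")
        assert row[c["v_AF"]] == pytest.approx(p.kel_bar_R)
        assert row[c["w_rP"]] == pytest.approx(-mu * comp.n_rP)
        row = sys.row("min deg")
        assert row[c["v_RNase"]] == pytest.approx(mu)
        kdeg = kdeg_value(p.degradation, comp.x_rP)
        assert row[c["v_AF"]] == pytest.approx(-kdeg * (1 - comp.x_rP))
        row = sys.row("mass")
        assert row[c["v_IC"]] == pytest.approx(p.omega_C)
        assert sys.rhs[sys.rows.index("mass")] == pytest.approx(mu)
        assert np.all(sys.rhs[:-1] == 0.0)

    def test_accumulation_forbid_switches_signs(self, glc_ext):
        comp = derive_composition(glc_ext, 0.36)
        allow = build_constraints(glc_ext, comp, 1.0, "extended", "allow")
        forbid = build_constraints(glc_ext, comp, 1.0, "extended", "forbid")
        for label in ("rRNA", "cap R", "min deg"):
            assert allow.sign[allow.rows.index(label)] == "ge"
            assert forbid.sign[forbid.rows.index(label)] == "eq"

    @pytest.mark.parametrize("seed", range(100))
    def test_internal_mass_conservation(self, seed):
        # omega^T N vanishes on every internal column; carbon import is the
        # only exchange reaction and carries omega_C
        rng = np.random.default_rng(seed)
        p = random_parameters(seed)
        comp = derive_composition(p, float(rng.uniform(0, 1)))
        species, columns, N, omega = stoichiometric_matrix(p, comp, "base")
        audit = omega @ N
        for j, name in enumerate(columns):
            expected = p.omega_C if name == "v_IC" else 0.0
            assert audit[j] == pytest.approx(expected, abs=1e-9 * p.omega_R)

    def test_mito_import_discounts_rp_charges(self, glc):
        mito = dataclasses.replace(glc, rp_import_fraction=1.0 / 3.0)
        comp = derive_composition(mito, 0.36)
        sys = build_constraints(mito, comp, 1.0, "base")
        c = {n: j for j, n in enumerate(sys.columns)}
        eff = (2.0 / 3.0) * comp.n_rP
        assert sys.row("AA")[c["w_rP"]] == pytest.approx(-eff)
        assert sys.row("cap R")[c["w_rP"]] == pytest.approx(-1.0 * eff)
        # imported residues appear as an exchange mass contribution
        assert sys.row("mass")[c["w_rP"]] == pytest.approx(
            comp.n_rP * glc.omega_AA / 3.0)

    def test_frame_export_round_trips(self, glc):
        comp = derive_composition(glc, 0.36)
        sys = build_constraints(glc, comp, 1.0, "base")
        frame = sys.to_frame()
        assert list(frame.index) == list(sys.rows)
        np.testing.assert_allclose(
            frame[list(sys.columns)].to_numpy(), sys.A)


class TestConcentrationsAndAllocations:
    def test_concentrations_identities(self, glc):
        from ribocell.growth_solver import maximize_growth
        sol = maximize_growth(glc, 0.36, tol=1e-8)
        flux = sol.flux
        assert sol.concentrations["RNAP"] == pytest.approx(
            flux["w_RNAP"] / sol.mu)
        assert sol.concentrations["R"] == pytest.approx(
            flux["v_AF"] / sol.mu)
        comp = derive_composition(glc, 0.36)
        sys = build_constraints(glc, comp, sol.mu, "base")
        assert dry_mass(sys, sol.concentrations) == pytest.approx(1.0,
                                                                  abs=1e-9)

    def test_mu_must_be_positive(self, glc):
        comp = derive_composition(glc, 0.36)
        sys = build_constraints(glc, comp, 1.0, "base")
        with pytest.raises(ValueError):
            concentrations_from_fluxes(sys, np.zeros(11), 0.0)

    def test_allocations_error_without_ribosome_synthesis(self, glc):
        comp = derive_composition(glc, 0.36)
        with pytest.raises(ValueError, match="v_AF"):
            allocations(np.zeros(11), 1.0, glc, comp)

    def test_allocations_sum_to_one_at_optimum(self, glc):
        # ribosome capacity binds at the optimum, so allocations exhaust it
        from ribocell.growth_solver import maximize_growth
        sol = maximize_growth(glc, 0.36, tol=1e-8)
        assert sum(sol.phi.values()) == pytest.approx(1.0, abs=1e-6)
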