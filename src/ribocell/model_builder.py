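"""Constraint-system construction for the self-fabricating-cell model.

The cell imports a carbon source (C), lumped enzymes EAA/ENT make amino
acids and nucleotides, RNA polymerase transcribes rRNA, the ribosome (R)
translates all proteins, and assembly factors (AF) combine rRNA and the
ribosomal protein complex (rP) into new ribosomes.  The extended variant
adds an RNase that degrades rRNA back to nucleotides, a capacity cost for
that RNase, and a minimum-degradation requirement.

At a fixed growth rate mu, steady state plus catalyst capacities reduce to
a linear system in the fluxes (v: enzymatic, w: protein synthesis):
stoichiometric rows (C, AA, NT, rRNA, rP), capacity rows of the form
-mu*demand + k*supply >= 0 (catalyst concentrations eliminated via
c_i = w_i/mu, c_R = v_AF/mu), and the dry-mass row that pins the scale.
The base system is 12 rows x 11 fluxes; the extended one 14 x 13.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .parameters import DegradationModel, ParameterSet

BASE_COLUMNS = ("v_IC", "v_EAA", "v_ENT", "v_RNAP", "v_AF",
                "w_IC", "w_EAA", "w_ENT", "w_RNAP", "w_AF", "w_rP")
EXT_COLUMNS = ("v_IC", "v_EAA", "v_ENT", "v_RNAP", "v_RNase", "v_AF",
               "w_IC", "w_EAA", "w_ENT", "w_RNAP", "w_RNase", "w_AF", "w_rP")
BASE_ROWS = ("C", "AA", "NT", "rRNA", "rP", "cap IC", "cap EAA", "cap ENT",
             "cap RNAP", "cap AF", "cap R", "mass")
EXT_ROWS = ("C", "AA", "NT", "rRNA", "rP", "cap IC", "cap EAA", "cap ENT",
            "cap RNAP", "cap RNase", "cap AF", "cap R", "min deg", "mass")

#: species of the full stoichiometric matrix, in row order
BASE_SPECIES = ("C", "AA", "NT", "rRNA", "rP",
                "IC", "EAA", "ENT", "RNAP", "AF", "R")
EXT_SPECIES = ("C", "AA", "NT", "rRNA", "rP",
               "IC", "EAA", "ENT", "RNAP", "RNase", "AF", "R")


@dataclass(frozen=True)
class Composition:
    """Ribosome composition at fixed total mass omega_R.

    x_rP is the protein mass fraction; n_rRNA and n_rP are the (real-valued)
    nucleotide and amino-acid counts satisfying
    n_rRNA*omega_NT + n_rP*omega_AA = omega_R exactly.
    """

    x_rP: float
    n_rRNA: float
    n_rP: float


def derive_composition(params: ParameterSet, x_rP: float) -> Composition:
    """Split the fixed ribosome mass into rRNA and protein at fraction x_rP."""
    if not (0.0 <= x_rP <= 1.0):
        raise ValueError(f"x_rP must lie in [0, 1], got {x_rP}")
    return Composition(
        x_rP=x_rP,
        n_rRNA=(1.0 - x_rP) * params.omega_R / params.omega_NT,
        n_rP=x_rP * params.omega_R / params.omega_AA,
    )


def kdeg_value(deg: DegradationModel, x_rP: float) -> float:
    """Degradation rate constant k_deg(x_rP) in 1/h for the given scenario."""
    if not (0.0 <= x_rP <= 1.0):
        raise ValueError(f"x_rP must lie in [0, 1], got {x_rP}")
    return deg.rate(x_rP)


@dataclass(frozen=True)
class ConstraintSystem:
    """Growth-rate-parameterized constraint table.

    ``sign[i]`` is "eq" or "ge"; ``rhs`` is zero except for the mass row,
    which equals the growth rate mu at which the system was instantiated.
    """

    rows: tuple
    columns: tuple
    A: np.ndarray
    sign: tuple
    rhs: np.ndarray
    mu: float
    variant: str
    accumulation_mode: str
    params: ParameterSet = field(repr=False)
    composition: Composition = field(repr=False)

    @property
    def shape(self):
        return self.A.shape

    def row(self, label: str) -> np.ndarray:
        return self.A[self.rows.index(label)]

    def residuals(self, fluxes: np.ndarray) -> np.ndarray:
        """Row residuals A @ fluxes - rhs (>= 0 required on 'ge' rows)."""
        return self.A @ np.asarray(fluxes, dtype=float) - self.rhs

    def to_frame(self):
        """Labeled coefficient table (pandas DataFrame) for inspection."""
        import pandas as pd
        frame = pd.DataFrame(self.A, index=list(self.rows),
                             columns=list(self.columns))
        frame["sign"] = ["=" if s == "eq" else ">=" for s in self.sign]
        frame["rhs"] = self.rhs
        return frame


def build_constraints(params: ParameterSet, comp: Composition, mu: float,
                      variant: str = "base",
                      accumulation_mode: str = "allow") -> ConstraintSystem:
    """Assemble the constraint table at growth rate mu.

    ``variant`` is "base" (no RNA degradation) or "extended" (RNase column
    pair plus cap RNase and min deg rows).  ``accumulation_mode`` "allow"
    keeps the rRNA, cap R and min deg rows as inequalities (free rRNA or
    idle ribosome capacity may accumulate); "forbid" turns them into
    equalities (the no-accumulation branch).
    """
    if mu <= 0:
        raise ValueError("mu must be strictly positive")
    if variant not in ("base", "extended"):
        raise ValueError(f"unknown variant {variant!r}")
    if accumulation_mode not in ("allow", "forbid"):
        raise ValueError(f"unknown accumulation_mode {accumulation_mode!r}")
    extended = variant == "extended"
    if extended and params.degradation.scenario == "none":
        raise ValueError(
            "extended variant requires a degradation scenario "
            "(constant or hill)"
        )
    columns = EXT_COLUMNS if extended else BASE_COLUMNS
    rows = EXT_ROWS if extended else BASE_ROWS
    col = {name: j for j, name in enumerate(columns)}
    n = {"IC": params.n_IC, "EAA": params.n_EAA, "ENT": params.n_ENT,
         "RNAP": params.n_RNAP, "RNase": params.n_RNase, "AF": params.n_AF}
    proteins = ["IC", "EAA", "ENT", "RNAP", "AF"]
    if extended:
        proteins.insert(4, "RNase")
    f_imp = params.rp_import_fraction
    n_rP_eff = (1.0 - f_imp) * comp.n_rP

    A = np.zeros((len(rows), len(columns)))
    rhs = np.zeros(len(rows))
    sign = ["ge"] * len(rows)

    def put(label, entries, s="ge", b=0.0):
        i = rows.index(label)
        for cname, value in entries.items():
            A[i, col[cname]] = value
        rhs[i] = b
        sign[i] = s

    put("C", {"v_IC": 1.0, "v_EAA": -params.n_AA, "v_ENT": -params.n_NT},
        s="eq")
    aa = {"v_EAA": 1.0, "v_ENT": -1.0, "w_rP": -n_rP_eff}
    for p in proteins:
        aa[f"w_{p}"] = -n[p]
    put("AA", aa, s="eq")
    nt = {"v_ENT": 1.0, "v_RNAP": -comp.n_rRNA}
    if extended:
        nt["v_RNase"] = comp.n_rRNA
    put("NT", nt, s="eq")
    rrna = {"v_RNAP": 1.0, "v_AF": -1.0}
    if extended:
        rrna["v_RNase"] = -1.0
    acc = "eq" if accumulation_mode == "forbid" else "ge"
    put("rRNA", rrna, s=acc)
    put("rP", {"v_AF": -1.0, "w_rP": 1.0})
    put("cap IC", {"v_IC": -mu, "w_IC": params.kcat_IC})
    put("cap EAA", {"v_EAA": -mu, "w_EAA": params.kcat_EAA})
    put("cap ENT", {"v_ENT": -mu, "w_ENT": params.kcat_ENT})
    put("cap RNAP", {"v_RNAP": -mu * comp.n_rRNA,
                     "w_RNAP": params.kel_bar_RNAP})
    if extended:
        put("cap RNase", {"v_RNase": -mu * comp.n_rRNA,
                          "w_RNase": params.kdeg_RNase})
    put("cap AF", {"v_AF": -mu, "w_AF": params.kcat_AF})
    cap_r = {"v_AF": params.kel_bar_R, "w_rP": -mu * n_rP_eff}
    for p in proteins:
        cap_r[f"w_{p}"] = -mu * n[p]
    put("cap R", cap_r, s=acc)
    if extended:
        kdeg = kdeg_value(params.degradation, comp.x_rP)
        put("min deg", {"v_RNase": mu, "v_AF": -kdeg * (1.0 - comp.x_rP)},
            s=acc)
    mass = {"v_IC": params.omega_C}
    if f_imp > 0:
        # imported rP residues enter the dry mass as an exchange contribution
        mass["w_rP"] = f_imp * comp.n_rP * params.omega_AA
    put("mass", mass, s="eq", b=mu)

    return ConstraintSystem(
        rows=tuple(rows), columns=tuple(columns), A=A, sign=tuple(sign),
        rhs=rhs, mu=mu, variant=variant, accumulation_mode=accumulation_mode,
        params=params, composition=comp,
    )


# ---------------------------------------------------------------------------
# full stoichiometric matrix (for the mass audit and concentrations)

def stoichiometric_matrix(params: ParameterSet, comp: Composition,
                          variant: str = "base"):
    """Full stoichiometric matrix N (species x fluxes) and molar masses.

    Returns ``(species, columns, N, omega)`` where ``omega[i]`` is the molar
    mass of species i.  Internal columns of N are mass-balanced
    (omega @ N = 0) except for carbon import and, with rP import, the
    partially-exchange w_rP column.
    """
    extended = variant == "extended"
    species = EXT_SPECIES if extended else BASE_SPECIES
    columns = EXT_COLUMNS if extended else BASE_COLUMNS
    col = {name: j for j, name in enumerate(columns)}
    row = {name: i for i, name in enumerate(species)}
    n = {"IC": params.n_IC, "EAA": params.n_EAA, "ENT": params.n_ENT,
         "RNAP": params.n_RNAP, "RNase": params.n_RNase, "AF": params.n_AF}
    proteins = [s for s in species if s in n]
    f_imp = params.rp_import_fraction
    N = np.zeros((len(species), len(columns)))
    N[row["C"], col["v_IC"]] = 1.0
    N[row["C"], col["v_EAA"]] = -params.n_AA
    N[row["AA"], col["v_EAA"]] = 1.0
    N[row["C"], col["v_ENT"]] = -params.n_NT
    N[row["AA"], col["v_ENT"]] = -1.0
    N[row["NT"], col["v_ENT"]] = 1.0
    N[row["NT"], col["v_RNAP"]] = -comp.n_rRNA
    N[row["rRNA"], col["v_RNAP"]] = 1.0
    if extended:
        N[row["rRNA"], col["v_RNase"]] = -1.0
        N[row["NT"], col["v_RNase"]] = comp.n_rRNA
    N[row["rRNA"], col["v_AF"]] = -1.0
    N[row["rP"], col["v_AF"]] = -1.0
    N[row["R"], col["v_AF"]] = 1.0
    for p in proteins:
        N[row["AA"], col[f"w_{p}"]] = -n[p]
        N[row[p], col[f"w_{p}"]] = 1.0
    N[row["AA"], col["w_rP"]] = -(1.0 - f_imp) * comp.n_rP
    N[row["rP"], col["w_rP"]] = 1.0
    omega = np.array(
        [params.omega_C, params.omega_AA, params.omega_NT,
         comp.n_rRNA * params.omega_NT, comp.n_rP * params.omega_AA]
        + [n[p] * params.omega_AA for p in proteins]
        + [params.omega_R]
    )
    return species, columns, N, omega


def concentrations_from_fluxes(sys: ConstraintSystem, fluxes: np.ndarray,
                               mu: float) -> dict:
    """Species concentrations c = N v / mu (mmol/g).

    Enzyme concentrations are c_i = w_i/mu and the ribosome c_R = v_AF/mu;
    accumulating species (free rRNA, free rP) get their net production over
    mu.  Metabolites held at steady state by equality rows come out as zero.
    """
    if mu <= 0:
        raise ValueError("mu must be strictly positive")
    species, _, N, _ = stoichiometric_matrix(
        sys.params, sys.composition, sys.variant
    )
    c = N @ np.asarray(fluxes, dtype=float) / mu
    out = dict(zip(species, c))
    # metabolites held by equality rows have identically zero steady-state
    # concentration; suppress solver roundoff there
    for met in ("C", "AA", "NT"):
        out[met] = 0.0
    return out


def dry_mass(sys: ConstraintSystem, concentrations: dict) -> float:
    """Mass-weighted concentration sum omega^T c (should equal 1)."""
    species, _, _, omega = stoichiometric_matrix(
        sys.params, sys.composition, sys.variant
    )
    return float(sum(w * concentrations[s] for s, w in zip(species, omega)))


def allocations(fluxes: np.ndarray, mu: float, params: ParameterSet,
                comp: Composition, variant: str = "base") -> dict:
    """Ribosome allocations phi_i = mu*n_i*w_i / (kel_bar_R * v_AF).

    The fraction of active ribosome elongation capacity spent on protein i;
    with rP import only the synthesized (1-f)*n_rP residues count.
    """
    columns = EXT_COLUMNS if variant == "extended" else BASE_COLUMNS
    x = dict(zip(columns, np.asarray(fluxes, dtype=float)))
    v_AF = x["v_AF"]
    if v_AF <= 0:
        raise ValueError("allocations undefined: v_AF = 0 (no ribosome "
                         "synthesis)")
    n = {"IC": params.n_IC, "EAA": params.n_EAA, "ENT": params.n_ENT,
         "RNAP": params.n_RNAP, "RNase": params.n_RNase, "AF": params.n_AF,
         "rP": (1.0 - params.rp_import_fraction) * comp.n_rP}
    denom = params.kel_bar_R * v_AF
    return {p: mu * n[p] * x[f"w_{p}"] / denom
            for p in n if f"w_{p}" in x}
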