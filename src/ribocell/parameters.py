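"""Parameter sets for the coarse-grained self-fabricating-cell model.

A :class:`ParameterSet` holds all kinetic and mass constants that define one
growth condition: molar masses of the carbon unit, amino acid, nucleotide and
ribosome; lengths of the lumped proteins; enzyme turnover numbers; effective
transcription/translation elongation rates; and the rRNA degradation model.

All rates are stored per hour internally.  The file loader accepts per-second
values with explicit unit tags and converts on load.

The module doubles as the synthetic-data generator: :func:`ecoli_fixture`
returns E. coli-like parameter sets for six growth media spanning growth
rates of roughly 0.4-2.1 1/h.  Values printed in the literature (translation
elongation 21 AA/s, RNase turnover 88 NT/s, a 7400-amino-acid ribosomal
protein complex at a 36% protein mass fraction, 80-85% active ribosomes,
Hill protection with K = 0.2 and n in {2, 6}) are used as anchors; everything
else is a documented fixture choice and flagged as such in the metadata.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

SCHEMA_VERSION = "1"

#: Fields that are rates (per hour internally); accepted with unit tags.
_RATE_FIELDS = (
    "kcat_IC", "kcat_EAA", "kcat_ENT", "kcat_AF",
    "kel_RNAP", "kel_R", "kdeg_RNase",
)
_PER_SECOND_UNITS = {"per_second", "1/s", "AA/s", "NT/s", "s^-1"}
_PER_HOUR_UNITS = {"per_hour", "1/h", "AA/h", "NT/h", "h^-1"}

DEGRADATION_SCENARIOS = ("none", "constant", "hill")


class ParameterError(ValueError):
    """Raised when a parameter set fails validation; names the field."""


@dataclass(frozen=True)
class DegradationModel:
    """rRNA degradation scenario.

    ``none``     -- no degradation (base model).
    ``constant`` -- minimum degradation at fixed rate constant ``kdeg_max``.
    ``hill``     -- rate constant kdeg_max * (1 - x^n / (K^n + x^n)),
                    cooperative protection of rRNA by ribosomal proteins
                    (K: half-saturation on the x_rP scale, n_hill: Hill factor).
    """

    scenario: str = "none"
    kdeg_max: float = 0.0  # 1/h
    K: float = 0.2
    n_hill: float = 1.0

    def __post_init__(self) -> None:
        if self.scenario not in DEGRADATION_SCENARIOS:
            raise ParameterError(
                f"degradation.scenario: unknown scenario {self.scenario!r}"
            )
        if self.kdeg_max < 0:
            raise ParameterError("degradation.kdeg_max: must be >= 0")
        if self.scenario == "hill":
            if not (0.0 < self.K < 1.0):
                raise ParameterError("degradation.K: must lie in (0, 1)")
            if self.n_hill < 1:
                raise ParameterError("degradation.n_hill: must be >= 1")

    def rate(self, x_rP: float) -> float:
        """Degradation rate constant k_deg(x_rP) in 1/h."""
        if self.scenario == "none":
            return 0.0
        if self.scenario == "constant":
            return self.kdeg_max
        xn = x_rP ** self.n_hill
        return self.kdeg_max * (1.0 - xn / (self.K ** self.n_hill + xn))


@dataclass(frozen=True)
class ParameterSet:
    """All constants defining one growth condition.

    Masses are g/mmol, lengths are residue counts, rates are per hour.
    ``omega_AA`` and ``omega_NT`` must be mass-consistent with the lumped
    synthesis stoichiometry (omega_AA = n_AA*omega_C,
    omega_NT = n_NT*omega_C + omega_AA), so that every internal reaction
    conserves mass exactly.
    """

    # masses (g/mmol)
    omega_C: float
    omega_AA: float
    omega_NT: float
    omega_R: float
    # stoichiometric counts
    n_AA: float
    n_NT: float
    # protein lengths (amino acids)
    n_IC: float
    n_EAA: float
    n_ENT: float
    n_RNAP: float
    n_RNase: float
    n_AF: float
    # turnover numbers (1/h)
    kcat_IC: float
    kcat_EAA: float
    kcat_ENT: float
    kcat_AF: float
    # transcription (NT/h) and translation (AA/h)
    kel_RNAP: float
    kel_R: float
    f_act_RNAP: float = 1.0
    f_act_R: float = 1.0
    phi_rRNA_RNAP: float = 1.0
    # RNase turnover (NT/h)
    kdeg_RNase: float = 0.0
    degradation: DegradationModel = field(default_factory=DegradationModel)
    # mitochondrial variant: fraction of rP imported free of synthesis cost
    rp_import_fraction: float = 0.0
    condition_label: str = ""
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        positive = (
            "omega_C", "omega_AA", "omega_NT", "omega_R", "n_AA", "n_NT",
            "n_IC", "n_EAA", "n_ENT", "n_RNAP", "n_AF",
            "kcat_IC", "kcat_EAA", "kcat_ENT", "kcat_AF",
            "kel_RNAP", "kel_R",
        )
        for name in positive:
            if not getattr(self, name) > 0:
                raise ParameterError(f"{name}: must be strictly positive")
        if self.n_RNase < 0:
            raise ParameterError("n_RNase: must be >= 0")
        if self.kdeg_RNase < 0:
            raise ParameterError("kdeg_RNase: must be >= 0")
        for name in ("f_act_RNAP", "f_act_R", "phi_rRNA_RNAP"):
            if not (0.0 < getattr(self, name) <= 1.0):
                raise ParameterError(f"{name}: must lie in (0, 1]")
        if not (0.0 <= self.rp_import_fraction < 1.0):
            raise ParameterError("rp_import_fraction: must lie in [0, 1)")
        # mass consistency of the lumped stoichiometry
        if not math.isclose(self.omega_AA, self.n_AA * self.omega_C,
                            rel_tol=1e-9):
            raise ParameterError(
                "omega_AA: must equal n_AA*omega_C for mass conservation"
            )
        if not math.isclose(self.omega_NT,
                            self.n_NT * self.omega_C + self.omega_AA,
                            rel_tol=1e-9):
            raise ParameterError(
                "omega_NT: must equal n_NT*omega_C + omega_AA "
                "for mass conservation"
            )

    # effective elongation rates -------------------------------------------
    @property
    def kel_bar_RNAP(self) -> float:
        """Effective rRNA transcription rate (NT/h)."""
        return self.kel_RNAP * self.f_act_RNAP * self.phi_rRNA_RNAP

    @property
    def kel_bar_R(self) -> float:
        """Effective translation elongation rate (AA/h)."""
        return self.kel_R * self.f_act_R

    @property
    def mu_ceiling(self) -> float:
        """Autocatalytic growth-rate scale kel_bar_R*omega_AA/omega_R (1/h).

        This is the rate at which a ribosome replaces its own mass in protein
        and sets the time rescaling of the closed-form analysis.
        """
        return self.kel_bar_R * self.omega_AA / self.omega_R


# ---------------------------------------------------------------------------
# serialization

def _rate_to_hours(name: str, entry) -> float:
    if isinstance(entry, (int, float)):
        return float(entry)
    if isinstance(entry, dict):
        try:
            value = float(entry["value"])
        except KeyError as exc:
            raise ParameterError(f"{name}: rate entry missing 'value'") from exc
        unit = entry.get("unit", "per_hour")
        if unit in _PER_SECOND_UNITS:
            return value * 3600.0
        if unit in _PER_HOUR_UNITS:
            return value
        raise ParameterError(f"{name}: unknown unit {unit!r}")
    raise ParameterError(f"{name}: malformed rate entry")


_SECTIONS = {
    "masses": ("omega_C", "omega_AA", "omega_NT", "omega_R"),
    "lengths": ("n_AA", "n_NT", "n_IC", "n_EAA", "n_ENT", "n_RNAP",
                "n_RNase", "n_AF"),
    "rates": _RATE_FIELDS,
    "fractions": ("f_act_RNAP", "f_act_R", "phi_rRNA_RNAP"),
}


def load_parameters(path, schema_version: str = SCHEMA_VERSION) -> ParameterSet:
    """Load and validate a parameter file (JSON with sections, or TSV).

    The JSON layout has sections ``masses``, ``lengths``, ``rates``,
    ``fractions``, ``degradation`` and optional ``variant``; rate entries may
    be plain numbers (per hour) or ``{"value": v, "unit": "1/s"}`` tagged
    objects which are converted to per-hour on load.  The TSV alternative has
    columns (name, value, unit).  Partially specified sets are rejected with
    an error naming the missing field.
    """
    path = Path(path)
    if not path.exists():
        raise ParameterError(f"file: {path} does not exist")
    if path.suffix.lower() in (".tsv", ".txt"):
        kwargs = _load_tsv(path)
    else:
        kwargs = _load_json(path, schema_version)
    return ParameterSet(**kwargs)


def _load_json(path: Path, schema_version: str) -> dict:
    with open(path) as fh:
        doc = json.load(fh)
    if str(doc.get("schema_version", SCHEMA_VERSION)) != schema_version:
        raise ParameterError(
            f"schema_version: expected {schema_version}, "
            f"got {doc.get('schema_version')}"
        )
    kwargs: dict = {}
    for section, names in _SECTIONS.items():
        block = doc.get(section, {})
        for name in names:
            if name in ("f_act_RNAP", "f_act_R", "phi_rRNA_RNAP") \
                    and name not in block:
                continue  # optional, defaulted
            if name not in block:
                raise ParameterError(f"{name}: missing from section {section}")
            if section == "rates":
                kwargs[name] = _rate_to_hours(name, block[name])
            else:
                kwargs[name] = float(block[name])
    deg = doc.get("degradation", {"scenario": "none"})
    kdeg_max = deg.get("kdeg_max", 0.0)
    if isinstance(kdeg_max, dict):
        kdeg_max = _rate_to_hours("degradation.kdeg_max", kdeg_max)
    kwargs["degradation"] = DegradationModel(
        scenario=deg.get("scenario", "none"),
        kdeg_max=float(kdeg_max),
        K=float(deg.get("K", 0.2)),
        n_hill=float(deg.get("n_hill", 1.0)),
    )
    variant = doc.get("variant", {})
    kwargs["rp_import_fraction"] = float(variant.get("rp_import_fraction", 0.0))
    kwargs["condition_label"] = str(doc.get("condition_label", path.stem))
    return kwargs


def _load_tsv(path: Path) -> dict:
    kwargs: dict = {}
    deg: dict = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["name", "value", "unit"]:
            raise ParameterError("header: TSV must start with name\tvalue\tunit")
        for line in fh:
            if not line.strip():
                continue
            name, value, unit = line.rstrip("\n").split("\t")[:3]
            if name == "degradation.scenario":
                deg["scenario"] = value
                continue
            if name.startswith("degradation."):
                deg[name.split(".", 1)[1]] = float(value) * (
                    3600.0 if unit in _PER_SECOND_UNITS else 1.0
                )
                continue
            if name == "condition_label":
                kwargs[name] = value
                continue
            if name in _RATE_FIELDS:
                kwargs[name] = _rate_to_hours(
                    name, {"value": value, "unit": unit or "per_hour"}
                )
            else:
                kwargs[name] = float(value)
    if deg:
        kwargs["degradation"] = DegradationModel(**deg)
    required = [n for names in _SECTIONS.values() for n in names
                if n not in ("f_act_RNAP", "f_act_R", "phi_rRNA_RNAP")]
    for name in required:
        if name not in kwargs:
            raise ParameterError(f"{name}: missing from TSV file")
    return kwargs


def write_parameters(params: ParameterSet, path) -> None:
    """Write a ParameterSet as a schema-versioned JSON file (per-hour rates).

    Round-trip invariant: ``load_parameters(write_parameters(p))`` reproduces
    the numeric content exactly.
    """
    doc: dict = {"schema_version": SCHEMA_VERSION,
                 "condition_label": params.condition_label}
    for section, names in _SECTIONS.items():
        doc[section] = {name: getattr(params, name) for name in names}
    doc["degradation"] = dataclasses.asdict(params.degradation)
    doc["variant"] = {"rp_import_fraction": params.rp_import_fraction}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


# ---------------------------------------------------------------------------
# E. coli-like fixtures
#
# Shared anchors (printed values): kel_R = 21 AA/s, kdeg_RNase = 88 NT/s,
# n_rP = 7400 AA at x_rP = 0.36 (fixing omega_R = 7400*omega_AA/0.36),
# 15-20% inactive ribosomes.  Everything else is a fixture choice:
# the carbon unit is a 27 g/mol carbon equivalent, an average amino acid is
# 4 carbon units (108 g/mol) and a nucleotide 8 carbon units plus one amino
# acid (324 g/mol); lumped pathway lengths and turnover numbers are set to
# biologically plausible scales; kcat_EAA/kcat_ENT encode nutrient quality
# and increase from poor to rich media so that base-model mu_max at
# x_rP = 0.36 spans roughly 0.45-2.05 1/h.

ECOLI_CONDITIONS = ("min1", "min2", "glc", "gly_aa", "glc_aa", "lb")

#: per-condition (kcat_EAA 1/h, kcat_ENT 1/h, f_act_R); fixture-derived.
_CONDITION_TABLE = {
    "min1":   (458.6, 611.4, 0.80),
    "min2":   (764.9, 1019.9, 0.80),
    "glc":    (1178.1, 1570.8, 0.83),
    "gly_aa": (1844.6, 2459.5, 0.83),
    "glc_aa": (2522.4, 3363.2, 0.85),
    "lb":     (3224.5, 4299.4, 0.85),
}


def ecoli_fixture(condition: str,
                  degradation: DegradationModel | None = None) -> ParameterSet:
    """E. coli-like parameter set for one of six growth media.

    ``min1``/``min2`` are poor minimal media, ``glc`` glucose minimal medium,
    ``gly_aa``/``glc_aa`` glycerol/glucose plus amino acids, ``lb`` LB rich
    medium.  An optional degradation model switches the set to the extended
    (RNA-turnover) variant.
    """
    if condition not in _CONDITION_TABLE:
        raise ParameterError(
            f"condition: unknown label {condition!r}; "
            f"expected one of {ECOLI_CONDITIONS}"
        )
    kcat_EAA, kcat_ENT, f_act_R = _CONDITION_TABLE[condition]
    omega_C = 0.027
    n_AA, n_NT = 4.0, 8.0
    omega_AA = n_AA * omega_C
    omega_NT = n_NT * omega_C + omega_AA
    omega_R = 7400.0 * omega_AA / 0.36
    return ParameterSet(
        omega_C=omega_C, omega_AA=omega_AA, omega_NT=omega_NT, omega_R=omega_R,
        n_AA=n_AA, n_NT=n_NT,
        n_IC=650.0, n_EAA=900.0, n_ENT=1200.0, n_RNAP=3407.0,
        n_RNase=813.0, n_AF=600.0,
        kcat_IC=100.0 * 3600.0, kcat_EAA=kcat_EAA, kcat_ENT=kcat_ENT,
        kcat_AF=30.0 * 3600.0,
        kel_RNAP=85.0 * 3600.0, f_act_RNAP=0.3, phi_rRNA_RNAP=1.0,
        kel_R=21.0 * 3600.0, f_act_R=f_act_R,
        kdeg_RNase=88.0 * 3600.0,
        degradation=degradation or DegradationModel(),
        condition_label=condition,
        metadata={
            "anchored": ["kel_R", "kdeg_RNase", "omega_R", "f_act_R"],
            "fixture_derived": [
                "omega_C", "n_AA", "n_NT", "n_IC", "n_EAA", "n_ENT",
                "n_RNAP", "n_RNase", "n_AF", "kcat_IC", "kcat_EAA",
                "kcat_ENT", "kcat_AF", "kel_RNAP", "f_act_RNAP",
            ],
        },
    )


def random_parameters(seed: int, ranges: dict | None = None) -> ParameterSet:
    """Draw a random valid ParameterSet (property-test generator).

    Deterministic for a fixed seed.  ``ranges`` maps field names to
    (low, high) bounds overriding the defaults below; omega_AA/omega_NT are
    derived from omega_C and the counts so mass conservation holds exactly.
    """
    rng = np.random.default_rng(seed)
    defaults = {
        "omega_C": (0.01, 0.05),
        "n_AA": (2.0, 8.0),
        "n_NT": (4.0, 12.0),
        "omega_R_over_omega_AA": (5000.0, 40000.0),
        "n_IC": (300.0, 1500.0),
        "n_EAA": (400.0, 3000.0),
        "n_ENT": (400.0, 3000.0),
        "n_RNAP": (1000.0, 5000.0),
        "n_RNase": (300.0, 1500.0),
        "n_AF": (200.0, 2000.0),
        "kcat_IC": (1e4, 1e6),
        "kcat_EAA": (3e2, 3e4),
        "kcat_ENT": (3e2, 3e4),
        "kcat_AF": (1e4, 1e6),
        "kel_RNAP": (1e4, 5e5),
        "kel_R": (2e4, 2e5),
        "f_act_RNAP": (0.1, 1.0),
        "f_act_R": (0.5, 1.0),
        "kdeg_RNase": (1e4, 1e6),
    }
    if ranges:
        for key, bounds in ranges.items():
            if key not in defaults:
                raise ParameterError(f"{key}: no sampling range for this field")
            lo, hi = bounds
            if not (lo <= hi):
                raise ParameterError(f"{key}: infeasible range {bounds}")
            defaults[key] = (float(lo), float(hi))
    draw = {k: rng.uniform(*v) for k, v in defaults.items()}
    omega_AA = draw["n_AA"] * draw["omega_C"]
    omega_NT = draw["n_NT"] * draw["omega_C"] + omega_AA
    omega_R = draw.pop("omega_R_over_omega_AA") * omega_AA
    return ParameterSet(
        omega_AA=omega_AA, omega_NT=omega_NT, omega_R=omega_R,
        condition_label=f"random-{seed}", **draw,
    )


# ---------------------------------------------------------------------------
# scenario variants

def variant_archaea(base: ParameterSet, deg_factor: float) -> ParameterSet:
    """Archaeal variant: scale the maximal rRNA degradation rate.

    Models harsher environments (temperature, pH) as a ``deg_factor``-fold
    increase of kdeg_max; the two-fold case is the packaged archaeal scenario.
    """
    if base.degradation.scenario == "none":
        raise ParameterError(
            "degradation.scenario: archaeal variant needs constant or hill "
            "degradation (nothing to scale)"
        )
    if not deg_factor > 0:
        raise ParameterError("deg_factor: must be strictly positive")
    deg = replace(base.degradation,
                  kdeg_max=base.degradation.kdeg_max * deg_factor)
    return replace(base, degradation=deg,
                   condition_label=f"{base.condition_label}-archaea")


def variant_mitochondria(base: ParameterSet,
                         import_fraction: float) -> ParameterSet:
    """Mitochondrial variant: a fraction of rP is imported free of cost.

    Downstream, protein synthesis of rP is charged only
    (1 - import_fraction)*n_rP amino acids and ribosome time; the imported
    residues enter the dry mass as an exchange contribution.
    """
    if not (0.0 <= import_fraction < 1.0):
        raise ParameterError("import_fraction: must lie in [0, 1)")
    return replace(base, rp_import_fraction=import_fraction,
                   condition_label=f"{base.condition_label}-mito")
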