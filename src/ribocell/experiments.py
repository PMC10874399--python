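"""Analysis pipelines over the growth model.

Pipelines reproduce the standard study outputs: the linear RNA-to-protein
ratio versus growth rate, the alternative RNA-polymerase flux branches at
sub-optimal growth rates, composition sweeps per scenario, the fraction of
transcribed rRNA that is degraded, the calibration of the maximal rRNA
degradation rate so that the optimal composition matches the observed
protein mass fraction (0.36 in E. coli), and the archaeal/mitochondrial
variants.  Everything is table-first: results are tidy DataFrames, and
:func:`run_scenario` serializes them as CSV plus a JSON manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .growth_solver import (
    GrowthSolution,
    SolverError,
    SweepResult,
    enumerate_extreme_solutions,
    maximize_growth,
    sweep_composition,
)
from .model_builder import Composition, derive_composition
from .parameters import (
    ECOLI_CONDITIONS,
    DegradationModel,
    ParameterSet,
    ecoli_fixture,
    variant_archaea,
    variant_mitochondria,
)


# ---------------------------------------------------------------------------
# observables

def rna_protein_ratio(sol: GrowthSolution, params: ParameterSet,
                      comp: Composition) -> float:
    """Total RNA mass over total protein mass for one solution.

    RNA: rRNA inside ribosomes plus any free rRNA.  Protein: all enzymes,
    the protein moiety of ribosomes, and any free ribosomal protein.
    """
    c = sol.concentrations
    rna = comp.n_rRNA * params.omega_NT * (c["R"] + c.get("rRNA", 0.0))
    lengths = {"IC": params.n_IC, "EAA": params.n_EAA, "ENT": params.n_ENT,
               "RNAP": params.n_RNAP, "RNase": params.n_RNase,
               "AF": params.n_AF}
    protein = sum(lengths[s] * params.omega_AA * c[s]
                  for s in lengths if s in c)
    protein += comp.n_rP * params.omega_AA * (c["R"] + c.get("rP", 0.0))
    if protein <= 0:
        raise ValueError("zero protein mass; solution is degenerate")
    return rna / protein


def degraded_fraction(sol: GrowthSolution) -> float:
    """Fraction of transcribed rRNA that is degraded, v_RNase / v_RNAP."""
    if sol.variant != "extended":
        raise ValueError("degraded fraction is defined for the extended "
                         "model only")
    flux = sol.flux
    if flux["v_RNAP"] <= 0:
        raise ValueError("v_RNAP = 0; degraded fraction undefined")
    return flux["v_RNase"] / flux["v_RNAP"]


# ---------------------------------------------------------------------------
# RNAP flux branches (validation at sub-optimal growth rates)

def classify_branch(active_rows) -> str:
    """Branch label from the activity of the rRNA and cap R rows."""
    rrna = "rRNA" in active_rows
    cap_r = "cap R" in active_rows
    if rrna and cap_r:
        return "no-accumulation"
    if not rrna:
        return "excess-rRNA"
    if not cap_r:
        return "excess-ribosome"
    return "other"


def rnap_flux_branches(params: ParameterSet, x_rP: float, mu_grid,
                       variant: str = "base") -> pd.DataFrame:
    """Alternative RNAP fluxes at fixed compositions across growth rates.

    For every mu on the grid, all vertices of the flux polytope are
    enumerated and classified: solutions accumulating free rRNA, solutions
    accumulating ribosomes beyond demand (idle cap R), and the
    no-accumulation branch where transcription exactly matches demand.
    Returns one row per (mu, branch) with the branch RNAP flux.
    """
    records = []
    for mu in np.asarray(mu_grid, dtype=float):
        ext = enumerate_extreme_solutions(params, x_rP, float(mu), variant)
        iv = ext.columns.index("v_RNAP")
        per_branch: dict = {}
        for vertex, active in zip(ext.vertices, ext.active_rows):
            per_branch.setdefault(classify_branch(active), []).append(
                vertex[iv]
            )
        for branch, values in per_branch.items():
            values = np.asarray(values)
            records.append({
                "mu": mu, "branch": branch,
                "v_RNAP": float(values.mean()),
                "v_RNAP_spread": float(np.ptp(values)),
                "n_vertices": len(values),
            })
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# kdeg_max calibration

def _grid_argmax(params: ParameterSet, variant: str, grid_step: float,
                 tol: float) -> float:
    """Two-stage grid argmax of mu_max over x_rP (coarse then refined)."""
    coarse_step = 4 * grid_step
    coarse = np.arange(0.0, 1.0 + 1e-12, coarse_step)
    sw = sweep_composition(params, coarse, variant, tol=tol,
                           keep_solutions=False)
    xc = sw.argmax_x
    lo = max(0.0, xc - coarse_step)
    hi = min(1.0, xc + coarse_step)
    fine = np.arange(lo, hi + 1e-12, grid_step)
    sw = sweep_composition(params, fine, variant, tol=tol,
                           keep_solutions=False)
    return sw.argmax_x


def calibrate_kdeg_max(params: ParameterSet, target_x: float = 0.36,
                       grid_step: float = 0.01, tol: float = 1e-4,
                       bracket: tuple = (1e-2, 1e5),
                       max_iter: int = 60):
    """Find kdeg_max so that the optimal composition matches ``target_x``.

    The grid argmax of mu_max(x_rP) is non-decreasing in kdeg_max, so a
    bisection on log(kdeg_max) converges; the search stops once the argmax
    equals the target within the grid resolution.  Returns
    (kdeg_max, verifying SweepResult over the full 0-1 grid).
    """
    if not (0.0 < target_x < 1.0):
        raise ValueError("target_x must lie in (0, 1)")
    if params.degradation.scenario == "none":
        raise ValueError("calibration requires a constant or hill "
                         "degradation scenario")

    from dataclasses import replace

    def argmax_at(kmax: float) -> float:
        deg = replace(params.degradation, kdeg_max=kmax)
        return _grid_argmax(replace(params, degradation=deg), "extended",
                            grid_step, tol)

    lo, hi = bracket
    a_lo, a_hi = argmax_at(lo), argmax_at(hi)
    for _ in range(10):
        if a_lo < target_x:
            break
        lo /= 10.0
        a_lo = argmax_at(lo)
    for _ in range(10):
        if a_hi > target_x:
            break
        hi *= 10.0
        a_hi = argmax_at(hi)
    if not (a_lo < target_x < a_hi):
        raise SolverError(
            f"target argmax {target_x} unreachable: bracket argmax values "
            f"are [{a_lo}, {a_hi}] for kdeg_max in [{lo}, {hi}]"
        )
    best = None
    for _ in range(max_iter):
        mid = float(np.sqrt(lo * hi))
        a_mid = argmax_at(mid)
        if abs(a_mid - target_x) <= 0.501 * grid_step:
            best = mid
            break
        if a_mid < target_x:
            lo = mid
        else:
            hi = mid
        if hi / lo < 1.0 + 1e-6:
            best = mid
            break
    if best is None:
        raise SolverError("calibration bisection did not converge; "
                          f"final bracket [{lo}, {hi}]")
    deg = replace(params.degradation, kdeg_max=best)
    calibrated = replace(params, degradation=deg)
    verify = sweep_composition(
        calibrated, np.arange(0.0, 1.0 + 1e-12, grid_step), "extended",
        tol=tol, keep_solutions=False,
        scenario=f"{params.condition_label}:calibrated",
    )
    return best, verify


# ---------------------------------------------------------------------------
# multi-condition panels and scenario orchestration

@dataclass(frozen=True)
class ConditionPanel:
    """Sweeps plus optimum diagnostics across growth conditions."""

    entries: tuple  # of dicts: condition, params, sweep, optimum
    summary: pd.DataFrame


def condition_panel(conditions=ECOLI_CONDITIONS, variant: str = "base",
                    degradation: DegradationModel | None = None,
                    grid_step: float = 0.01, tol: float = 1e-6,
                    transform=None) -> ConditionPanel:
    """Sweep every condition and summarize the optimum per condition.

    ``transform`` optionally maps each fixture ParameterSet (e.g. the
    archaeal or mitochondrial variant) before solving.
    """
    grid = np.arange(0.0, 1.0 + 1e-12, grid_step)
    entries = []
    rows = []
    for cond in conditions:
        params = ecoli_fixture(cond, degradation=degradation)
        if transform is not None:
            params = transform(params)
        sweep = sweep_composition(params, grid, variant, tol=tol)
        opt = sweep.solutions[sweep.argmax_index]
        comp = derive_composition(params, sweep.argmax_x)
        row = {
            "condition": cond,
            "mu_max": sweep.mu_max[sweep.argmax_index],
            "x_star": sweep.argmax_x,
            "interior_optimum": sweep.interior_optimum,
            "rna_protein_ratio": rna_protein_ratio(opt, params, comp),
        }
        if variant == "extended":
            row["degraded_fraction"] = degraded_fraction(opt)
        rows.append(row)
        entries.append({"condition": cond, "params": params,
                        "sweep": sweep, "optimum": opt})
    return ConditionPanel(entries=tuple(entries),
                          summary=pd.DataFrame(rows))


def rna_protein_panel(conditions=ECOLI_CONDITIONS, x_rP: float = 0.36,
                      variant: str = "base",
                      degradation: DegradationModel | None = None,
                      tol: float = 1e-6) -> pd.DataFrame:
    """RNA/protein mass ratio at the optimum of each condition, fixed x_rP.

    The model predicts the ratio to grow linearly with growth rate through
    the origin (no growth-independent offset).
    """
    rows = []
    for cond in conditions:
        params = ecoli_fixture(cond, degradation=degradation)
        sol = maximize_growth(params, x_rP, variant, tol=tol)
        comp = derive_composition(params, x_rP)
        rows.append({"condition": cond, "mu": sol.mu,
                     "rna_protein_ratio": rna_protein_ratio(sol, params,
                                                            comp)})
    return pd.DataFrame(rows)


_SCENARIOS = ("base_sweep", "extended_sweep", "rna_protein", "branches",
              "archaea", "mitochondria")


def run_scenario(config: dict, out_dir=None):
    """Run one named scenario; returns (tables, manifest).

    ``config`` keys: ``kind`` (one of base_sweep, extended_sweep,
    rna_protein, branches, archaea, mitochondria), ``conditions``,
    ``degradation`` ({scenario, kdeg_max | calibrate_target, K, n_hill}),
    ``grid_step``, ``tol``, ``x_rP``, ``deg_factor``, ``import_fractions``,
    ``seed``.  Deterministic given the config.  With ``out_dir`` set, every
    table is written as ``<name>.csv`` and a ``manifest.json`` records the
    config hash, package version and output checksums.
    """
    kind = config.get("kind")
    if kind not in _SCENARIOS:
        raise ValueError(f"unknown scenario kind {kind!r}; "
                         f"expected one of {_SCENARIOS}")
    conditions = tuple(config.get("conditions", ECOLI_CONDITIONS))
    grid_step = float(config.get("grid_step", 0.01))
    tol = float(config.get("tol", 1e-6))
    deg_cfg = config.get("degradation")
    degradation = None
    status: dict = {}
    if deg_cfg:
        degradation = DegradationModel(
            scenario=deg_cfg.get("scenario", "hill"),
            kdeg_max=float(deg_cfg.get("kdeg_max", 0.0)),
            K=float(deg_cfg.get("K", 0.2)),
            n_hill=float(deg_cfg.get("n_hill", 1.0)),
        )
        if "calibrate_target" in deg_cfg:
            base = ecoli_fixture(config.get("calibration_condition", "glc"),
                                 degradation=degradation)
            kmax, _ = calibrate_kdeg_max(
                base, target_x=float(deg_cfg["calibrate_target"]),
                grid_step=grid_step, tol=max(tol, 1e-4),
            )
            from dataclasses import replace
            degradation = replace(degradation, kdeg_max=kmax)
            status["calibrated_kdeg_max"] = kmax

    tables: dict = {}
    if kind in ("base_sweep", "extended_sweep"):
        variant = "base" if kind == "base_sweep" else "extended"
        panel = condition_panel(conditions, variant, degradation,
                                grid_step, tol)
        tables["summary"] = panel.summary
        tables["sweeps"] = pd.concat(
            [e["sweep"].to_frame().assign(condition=e["condition"])
             for e in panel.entries], ignore_index=True)
    elif kind == "rna_protein":
        tables["rna_protein"] = rna_protein_panel(
            conditions, float(config.get("x_rP", 0.36)),
            "extended" if degradation else "base", degradation, tol)
    elif kind == "branches":
        params = ecoli_fixture(config.get("condition", "glc"))
        x_rP = float(config.get("x_rP", 0.36))
        mu_max = maximize_growth(params, x_rP, tol=tol).mu
        fracs = np.asarray(config.get("mu_fractions",
                                      np.linspace(0.1, 0.999, 10)))
        tables["branches"] = rnap_flux_branches(params, x_rP, fracs * mu_max)
    elif kind == "archaea":
        factor = float(config.get("deg_factor", 2.0))
        panel = condition_panel(
            conditions, "extended", degradation, grid_step, tol,
            transform=lambda p: variant_archaea(p, factor))
        tables["summary"] = panel.summary
    elif kind == "mitochondria":
        rows = []
        for frac in config.get("import_fractions", (0.0, 1.0 / 3.0)):
            panel = condition_panel(
                conditions, "extended", degradation, grid_step, tol,
                transform=lambda p: variant_mitochondria(p, float(frac)))
            rows.append(panel.summary.assign(import_fraction=float(frac)))
        tables["summary"] = pd.concat(rows, ignore_index=True)

    manifest = {
        "tool_version": __version__,
        "config": config,
        "config_hash": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "seed": config.get("seed"),
        "status": status,
        "outputs": {},
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, frame in tables.items():
            path = out_dir / f"{name}.csv"
            frame.to_csv(path, index=False)
            manifest["outputs"][path.name] = hashlib.sha256(
                path.read_bytes()).hexdigest()
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)
    return tables, manifest
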