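"""End-to-end experiment orchestration.

A run executes, on one model and one biomass composition, the full
analysis sequence: consistency checks -> flux-minimizing FBA -> FVA at
Vc/Vo 1:1 and 3:1 -> Vc/Vo scan -> light scan -> random-weight ensemble ->
flux-parameter correlation.  All outputs are tab-separated tables plus a
JSON run manifest carrying the seed, configuration hash and package
version, so an identical configuration reproduces identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import yaml

from . import __version__
from .consistency import detect_energy_cycle, elemental_balance_audit, find_leaks
from .correlation import classify_strength, compare_strong_sets, correlate_scan
from .ensemble import run_ensemble
from .fba import ConstraintSet, FluxSolution, apply_biomass_composition, minimize_weighted_flux
from .fva import classify_ranges, run_fva
from .model import Model, ModelError, load_model
from .scenarios import (
    ScanResult,
    VcVoRatio,
    default_light_grid,
    derived_metrics,
    light_scan,
    vcvo_scan,
)
from .synthetic import TRACKED_PRESETS, build_core_leaf_model, core_constraints

__all__ = ["RunConfig", "run_experiment", "load_config"]

logger = logging.getLogger("leaffba")

_KNOWN_KEYS = {
    "model", "composition", "maintenance_flux", "out", "seed",
    "vcvo", "light", "ensemble", "fva", "tolerances", "skip_consistency",
}
_VCVO_KEYS = {"ratios", "carb_id", "oxy_id"}
_LIGHT_KEYS = {"start", "stop", "step", "photon_id", "cyclic_id", "noncyclic_id"}
_ENSEMBLE_KEYS = {"n", "tracked", "fix_vcvo"}


@dataclass
class RunConfig:
    """Validated configuration of one experiment run."""

    model_path: Optional[str] = None          # None -> bundled core leaf model
    composition_path: Optional[str] = None    # None -> generator defaults
    maintenance_flux: float = 0.1
    out_dir: str = "leaffba_run"
    seed: int = 0
    vcvo_ratios: List[str] = field(default_factory=lambda: ["1:1", "2:1", "3:1", "4:1", "5:1"])
    carb_id: str = "chl_RuBisCO_carb"
    oxy_id: str = "chl_RuBisCO_oxy"
    light_start: float = 0.33
    light_stop: float = 10.0
    light_step: float = 0.1
    photon_id: str = "photon_ex"
    cyclic_id: str = "chl_LightCyc"
    noncyclic_id: str = "chl_LightNonCyc"
    ensemble_n: int = 1000
    ensemble_tracked: str = "transporters"
    ensemble_fix_vcvo: Optional[str] = "3:1"
    skip_consistency: bool = False

    @classmethod
    def from_mapping(cls, data: Dict) -> "RunConfig":
        unknown = set(data) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        for block, allowed in (("vcvo", _VCVO_KEYS), ("light", _LIGHT_KEYS),
                               ("ensemble", _ENSEMBLE_KEYS)):
            extra = set(data.get(block) or {}) - allowed
            if extra:
                raise ValueError(f"unknown keys in {block!r} block: {sorted(extra)}")
        vcvo = data.get("vcvo") or {}
        light = data.get("light") or {}
        ens = data.get("ensemble") or {}
        config = cls(
            model_path=data.get("model"),
            composition_path=data.get("composition"),
            maintenance_flux=float(data.get("maintenance_flux", 0.1)),
            out_dir=str(data.get("out", "leaffba_run")),
            seed=int(data.get("seed", 0)),
            vcvo_ratios=[str(r) for r in vcvo.get("ratios", ["1:1", "2:1", "3:1", "4:1", "5:1"])],
            carb_id=str(vcvo.get("carb_id", "chl_RuBisCO_carb")),
            oxy_id=str(vcvo.get("oxy_id", "chl_RuBisCO_oxy")),
            light_start=float(light.get("start", 0.33)),
            light_stop=float(light.get("stop", 10.0)),
            light_step=float(light.get("step", 0.1)),
            photon_id=str(light.get("photon_id", "photon_ex")),
            cyclic_id=str(light.get("cyclic_id", "chl_LightCyc")),
            noncyclic_id=str(light.get("noncyclic_id", "chl_LightNonCyc")),
            ensemble_n=int(ens.get("n", 1000)),
            ensemble_tracked=str(ens.get("tracked", "transporters")),
            ensemble_fix_vcvo=ens.get("fix_vcvo", "3:1"),
            skip_consistency=bool(data.get("skip_consistency", False)),
        )
        if config.model_path is not None and not Path(config.model_path).exists():
            raise ValueError(f"model file not found: {config.model_path}")
        if config.composition_path is not None and not Path(config.composition_path).exists():
            raise ValueError(f"composition file not found: {config.composition_path}")
        if config.maintenance_flux < 0 or config.ensemble_n < 1:
            raise ValueError("maintenance_flux must be >= 0 and ensemble n >= 1")
        return config

    def digest(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    with open(path, "r", encoding="utf-8") as handle:
        data = yaml.safe_load(handle) or {}
    if not isinstance(data, dict):
        raise ValueError("configuration must be a mapping")
    return RunConfig.from_mapping(data)


def load_composition_table(path: str | Path) -> Dict[str, float]:
    """Two-column TSV (biomass transporter id, flux), with optional header."""
    out: Dict[str, float] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        cells = line.split("\t")
        if len(cells) < 2:
            raise ValueError(f"malformed composition row: {line!r}")
        if cells[0] in ("reaction_id", "transporter"):
            continue
        out[cells[0]] = float(cells[1])
    return out


# -- table writers ----------------------------------------------------------

def write_flux_table(solution: FluxSolution, weights: Dict[str, float], path: Path) -> None:
    lines = ["reaction_id\tflux\tweight"]
    for rid, flux in solution.fluxes.items():
        lines.append(f"{rid}\t{flux!r}\t{weights.get(rid, 1.0)!r}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_scan_table(scan: ScanResult, path: Path) -> None:
    lines = ["parameter_value\treaction_id\tflux"]
    for p, s in scan.feasible_points:
        for rid, flux in s.fluxes.items():
            lines.append(f"{p!r}\t{rid}\t{flux!r}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_scan_table(path: str | Path, parameter_name: str = "scan") -> ScanResult:
    """Rebuild a ScanResult from a long-format scan table."""
    points: Dict[float, Dict[str, float]] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines()[1:]:
        if not line.strip():
            continue
        p, rid, flux = line.split("\t")
        points.setdefault(float(p), {})[rid] = float(flux)
    scan = ScanResult(parameter_name=parameter_name)
    for p in sorted(points):
        scan.points.append((p, FluxSolution(points[p], float("nan"), "optimal")))
    return scan


# -- the run ----------------------------------------------------------------

def _resolve_model(config: RunConfig):
    if config.model_path is None:
        model, manifest = build_core_leaf_model()
        constraints = core_constraints(model=model)
        constraints.maintenance_flux = config.maintenance_flux
        return model, constraints
    model = load_model(config.model_path)
    if config.composition_path is not None:
        composition = load_composition_table(config.composition_path)
        constraints = apply_biomass_composition(
            model, composition, maintenance_flux=config.maintenance_flux
        )
    else:
        constraints = ConstraintSet(maintenance_flux=config.maintenance_flux)
    return model, constraints


def run_experiment(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the output directory.

    Stages run in order (consistency, fba, fva, scans, ensemble,
    correlation); a failure halts the run with a stage-labeled error while
    earlier outputs are retained on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model, constraints = _resolve_model(config)
    stage = "setup"
    manifest: Dict[str, object] = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.digest(),
        "model_id": model.id,
        "n_reactions": len(model.reactions),
    }
    try:
        if not config.skip_consistency:
            stage = "consistency"
            logger.info("stage %s", stage)
            leaks = find_leaks(model)
            report = {
                "leaks": sorted(leaks.leaking_metabolites),
                "energy_cycles": [],
                "unbalanced": elemental_balance_audit(model),
            }
            for pair in (("ATP", "ADP"), ("NADH", "NAD")):
                if pair[0] in model.metabolites and pair[1] in model.metabolites:
                    cycle = detect_energy_cycle(model, pair)
                    if cycle.has_cycle:
                        report["energy_cycles"].append(pair[0])
            (out / "consistency.json").write_text(json.dumps(report, indent=2))
            if report["leaks"] or report["energy_cycles"]:
                raise ModelError(f"model failed consistency: {report}")

        stage = "fba"
        logger.info("stage %s", stage)
        solution = minimize_weighted_flux(model, constraints)
        if not solution.optimal:
            raise ModelError(f"baseline FBA not optimal: {solution.status}")
        write_flux_table(solution, {}, out / "fba_fluxes.tsv")
        (out / "fba.json").write_text(json.dumps(
            {"objective": solution.objective_value, "status": solution.status}, indent=2))

        can_vcvo = config.carb_id in model.reactions and config.oxy_id in model.reactions

        if can_vcvo:
            stage = "fva"
            logger.info("stage %s", stage)
            from .scenarios import lump_rubisco

            for label in ("1:1", "3:1"):
                lumped, _ = lump_rubisco(
                    model, config.carb_id, config.oxy_id, VcVoRatio.from_string(label)
                )
                ranges = run_fva(lumped, constraints)
                classes = classify_ranges(ranges)
                lines = ["reaction_id\tfba_value\tfva_min\tfva_max\tclass"]
                for fr in ranges:
                    lines.append(
                        f"{fr.reaction_id}\t{fr.fba_value!r}\t{fr.fva_min!r}"
                        f"\t{fr.fva_max!r}\t{classes[fr.reaction_id]}"
                    )
                (out / f"fva_{label.replace(':', 'to')}.tsv").write_text(
                    "\n".join(lines) + "\n")

            stage = "scan-vcvo"
            logger.info("stage %s", stage)
            ratios = [VcVoRatio.from_string(r) for r in config.vcvo_ratios]
            vscan = vcvo_scan(model, constraints, ratios,
                              carb_id=config.carb_id, oxy_id=config.oxy_id)
            write_scan_table(vscan, out / "scan_vcvo.tsv")
            metrics = {
                str(p): derived_metrics(
                    s, photon_id=config.photon_id,
                    cyclic_id=config.cyclic_id, noncyclic_id=config.noncyclic_id
                ).__dict__
                for p, s in vscan.feasible_points
            }
            (out / "scan_vcvo_metrics.json").write_text(json.dumps(metrics, indent=2))
        else:
            vscan = None

        lscan = None
        if config.photon_id in model.reactions:
            stage = "scan-light"
            logger.info("stage %s", stage)
            grid = default_light_grid(config.light_start, config.light_stop,
                                      config.light_step)
            lscan = light_scan(model, constraints, grid,
                               cyclic_id=config.cyclic_id,
                               noncyclic_id=config.noncyclic_id,
                               photon_id=config.photon_id)
            write_scan_table(lscan, out / "scan_light.tsv")

        stage = "ensemble"
        logger.info("stage %s", stage)
        tracked = TRACKED_PRESETS.get(config.ensemble_tracked)
        if tracked is None:
            tracked = tuple(t for t in config.ensemble_tracked.split(",") if t)
        tracked = tuple(t for t in tracked if t in model.reactions)
        if tracked:
            ens_model = model
            if config.ensemble_fix_vcvo and can_vcvo:
                from .scenarios import lump_rubisco

                ens_model, _ = lump_rubisco(
                    model, config.carb_id, config.oxy_id,
                    VcVoRatio.from_string(config.ensemble_fix_vcvo),
                )
                tracked = tuple(t for t in tracked if t in ens_model.reactions)
            summary, _ = run_ensemble(
                ens_model, constraints, n=config.ensemble_n,
                master_seed=config.seed, tracked=tracked,
            )
            lines = ["signature\tcount\tfrequency"]
            for sig, count in sorted(summary.mode_counts.items(),
                                     key=lambda kv: -kv[1]):
                lines.append(f"{sig}\t{count}\t{count / summary.n_iterations!r}")
            (out / "ensemble_modes.tsv").write_text("\n".join(lines) + "\n")
            manifest["ensemble"] = {
                "n": summary.n_iterations,
                "infeasible": summary.infeasible_count,
                "tracked": list(tracked),
                "n_modes": len(summary.mode_counts),
            }

        stage = "correlation"
        logger.info("stage %s", stage)
        tables = {}
        for name, scan in (("vcvo", vscan), ("light", lscan)):
            if scan is None or len(scan.feasible_points) < 3:
                continue
            table = correlate_scan(scan)
            tables[name] = table
            classes = classify_strength(table)
            lines = ["reaction_id\tabs_r\tclass"]
            for rid, r in sorted(table.entries.items()):
                lines.append(f"{rid}\t{r!r}\t{classes[rid]}")
            (out / f"correlation_{name}.tsv").write_text("\n".join(lines) + "\n")
        if len(tables) == 2:
            only_a, only_b, both = compare_strong_sets(tables["vcvo"], tables["light"])
            (out / "correlation_strong_sets.json").write_text(json.dumps(
                {"only_vcvo": sorted(only_a), "only_light": sorted(only_b),
                 "both": sorted(both)}, indent=2))

        (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return out
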