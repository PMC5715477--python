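"""Download-free test beds: a curated core leaf model and micro-fixtures.

The core model is a hand-curated four-compartment network (cytosol,
chloroplast ``chl_``, mitochondrion ``mit_``, peroxisome ``per_``) of
roughly seventy reactions covering the Calvin cycle, the full
photorespiratory chain (phosphoglycolate -> glycolate -> glyoxylate ->
glycine -> serine -> hydroxypyruvate -> glycerate), GS/GOGAT ammonia
refixation with cytosolic (GS1) and chloroplastic (GS2) isoforms, malate
valves in all three organelles, triose-phosphate transporters, a
mitochondrial electron-transport chain with COX and AOX branches, and
peroxisomal catalase plus a glutathione-ascorbate alternative.  Every
metabolite carries a simplified elemental composition (C, H, O, N, P, S;
cofactor pairs balanced as couples; photons and proton-motive force are
massless), so the whole network passes the elemental audit and the
closed-system leak/energy checks by construction.

The network is *curated, not random*: its stoichiometry and the fixed
biomass demands are chosen so that the flux-minimizing optimum exhibits
the canonical leaf responses (chloroplastic malate-valve flux falling as
Vc/Vo rises, cytosolic GAPDH/PGK switching on only at low
photorespiration, complete GS2 refixation of photorespiratory ammonia,
photorespiration rising with excess fixed photon flux).  These expected
behaviors are declared in the generator manifest and verified by running
the actual scenario operations.

Micro-fixtures (chain, diamond, parallel arms, photon toy) have
analytically known optima recorded in their manifests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from fractions import Fraction
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .fba import ConstraintSet, FluxLP, ObjectiveSpec, apply_biomass_composition
from .model import (
    INF_BOUND,
    Metabolite,
    Model,
    ModelError,
    Reaction,
    parse_formula,
    parse_reaction_equation,
)

__all__ = [
    "CoreLeafModelOptions",
    "GeneratorManifest",
    "build_core_leaf_model",
    "build_fixture_network",
    "make_broken_variant",
    "core_constraints",
    "verify_behaviors",
    "TRACKED_PRESETS",
]


@dataclass
class GeneratorManifest:
    """Declared properties of an emitted model.

    ``expected_behaviors`` is a list of (behavior id, description,
    parameter regime) records; each is checked by running the relevant
    scenario operation, so the manifest doubles as the acceptance surface
    for the generator.
    """

    model_id: str
    seed: int
    reaction_count_total: int = 0
    metabolite_count_total: int = 0
    per_compartment_counts: Dict[str, int] = field(default_factory=dict)
    per_category_counts: Dict[str, int] = field(default_factory=dict)
    expected_behaviors: List[Dict[str, str]] = field(default_factory=list)
    extra: Dict[str, object] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


@dataclass
class CoreLeafModelOptions:
    """Switches and study conditions of the core leaf network.

    ``biomass_composition`` fixes the biomass-transporter fluxes (flux
    units); the defaults place the light-limitation threshold inside the
    0.33-10.00 photon grid and keep cytosolic ATP demand between the
    mitochondrial supply available at Vc/Vo = 1:1 and that at 3:1, which
    is what makes the GAPDH/PGK switch observable.
    ``photons_per_noncyclic``/``photons_per_cyclic`` set the photon cost of
    one unit of each photophosphorylation reaction (yields stay 3 ATP +
    2 NADPH and 2 ATP respectively).  ``pmf_per_nadh``/``pmf_per_atp`` fix
    the respiratory P/O ratio.  ``mit_malate_import_only`` optionally
    restricts the mitochondrial dicarboxylate exchange to malate import;
    by default all three organelle Mal-OAA antiports are reversible and
    directionality enters only through the light-activated chloroplastic
    NADP-MDH, which runs toward malate export.
    """

    include_gs1: bool = True
    include_glutathione_ascorbate: bool = True
    include_aox: bool = True
    photons_per_noncyclic: int = 8
    photons_per_cyclic: int = 4
    pmf_per_nadh: int = 10
    pmf_per_atp: int = 4
    mit_malate_import_only: bool = False
    maintenance_flux: float = 0.1
    biomass_composition: Dict[str, float] = field(
        default_factory=lambda: {
            "biomass_GAP_tx": 0.02,
            "biomass_Suc_tx": 0.004,
            "biomass_G3P_tx": 0.01,
        }
    )


#: Tracked-reaction presets for the ensemble module.
TRACKED_PRESETS = {
    # chloroplastic and mitochondrial transporters
    "transporters": (
        "chl_GAP_tx",
        "chl_DHAP_tx",
        "chl_PGA_tx",
        "chl_Maloxac_tx",
        "chl_Mal_2OG_tx",
        "chl_Glu_Mal_tx",
        "chl_Gln_Glt_tx",
        "chl_NH3_tx",
        "mit_ATP_tx",
        "mit_Maloxac_tx",
        "mit_NH3_tx",
    ),
    # Glu-Gln transporter and the two glutamine synthetase isoforms
    "glu-gln": ("chl_Gln_Glt_tx", "GS1", "chl_GS2"),
    # peroxisomal hydrogen-peroxide disposal alternatives
    "h2o2": ("per_CAT", "per_APX"),
}


# ---------------------------------------------------------------------------
# Elemental compositions (simplified: C, H, O, N, P, S; couples balanced)
# ---------------------------------------------------------------------------

_BASE_COMPOSITIONS = {
    "CO2": "CO2",
    "O2": "O2",
    "H2O": "H2O",
    "H2O2": "H2O2",
    "Pi": "H3PO4",
    "NH3": "NH3",
    "NO3": "HNO3",
    "SO4": "H2SO4",
    "Photon": "0",
    "PMF": "0",
    "ATP": "C10H16N5O13P3",
    "ADP": "C10H15N5O10P2",
    "NAD": "C21H27N7O14P2",
    "NADH": "C21H29N7O14P2",
    "NADP": "C21H28N7O17P3",
    "NADPH": "C21H30N7O17P3",
    "RuBP": "C5H12O11P2",
    "PGA": "C3H7O7P",
    "BPGA": "C3H8O10P2",
    "GAP": "C3H7O6P",
    "DHAP": "C3H7O6P",
    "Ru5P": "C5H11O8P",
    "Pgly": "C2H5O6P",
    "Glyco": "C2H4O3",
    "Glyox": "C2H2O3",
    "Glycerate": "C3H6O4",
    "HPyr": "C3H4O4",
    "Gly": "C2H5NO2",
    "Ser": "C3H7NO3",
    "Glu": "C5H9NO4",
    "Gln": "C5H10N2O3",
    "2OG": "C5H6O5",
    "Mal": "C4H6O5",
    "OAA": "C4H4O5",
    "AsA": "C6H8O6",
    "DHA": "C6H6O6",
    "FBP": "C6H14O12P2",
    "F6P": "C6H13O9P",
    "G6P": "C6H13O9P",
    "G1P": "C6H13O9P",
    "Suc": "C12H22O11",
    "G3P": "C3H9O6P",
}


def _composition_for(met_id: str) -> Optional[Dict[str, int]]:
    base = met_id
    for prefix in ("chl_", "mit_", "per_", "ext_"):
        if base.startswith(prefix):
            base = base[len(prefix):]
            break
    formula = _BASE_COMPOSITIONS.get(base)
    return parse_formula(formula) if formula is not None else None


def _add(model: Model, rid: str, equation: str, category: str,
         lower: Optional[float] = None, upper: Optional[float] = None) -> None:
    stoich, reversible = parse_reaction_equation(equation)
    lb = lower if lower is not None else (-INF_BOUND if reversible else 0.0)
    ub = upper if upper is not None else INF_BOUND
    model.add_reaction(
        Reaction(id=rid, stoichiometry=stoich, lower_bound=lb, upper_bound=ub,
                 category=category)
    )


def _annotate(model: Model) -> None:
    for met_id in list(model.metabolites):
        comp = _composition_for(met_id)
        if comp is not None:
            old = model.metabolites[met_id]
            model.metabolites[met_id] = Metabolite(
                id=old.id, name=old.name, compartment=old.compartment,
                elemental_composition=comp,
            )


# ---------------------------------------------------------------------------
# Core leaf model
# ---------------------------------------------------------------------------

def build_core_leaf_model(
    options: Optional[CoreLeafModelOptions] = None,
    seed: int = 0,
) -> Tuple[Model, GeneratorManifest]:
    """Emit the curated core leaf network and its manifest.

    Construction is deterministic: the same options and seed produce a
    byte-identical model table.  The seed only enters the manifest (the
    network is curated, not sampled).
    """
    opt = options or CoreLeafModelOptions()
    model = Model("core_leaf")
    pn, pc = opt.photons_per_noncyclic, opt.photons_per_cyclic
    pmf_n, pmf_a = opt.pmf_per_nadh, opt.pmf_per_atp

    # -- chloroplast: light reactions, Calvin cycle, photorespiration entry
    _add(model, "chl_LightNonCyc",
         f"{pn} chl_Photon + 3 chl_ADP + 3 chl_Pi + 2 chl_NADP -> "
         "chl_O2 + 3 chl_ATP + 2 chl_NADPH + chl_H2O",
         "photophosphorylation")
    _add(model, "chl_LightCyc",
         f"{pc} chl_Photon + 2 chl_ADP + 2 chl_Pi -> 2 chl_ATP + 2 chl_H2O",
         "photophosphorylation")
    _add(model, "chl_RuBisCO_carb",
         "chl_RuBP + chl_CO2 + chl_H2O -> 2 chl_PGA", "metabolic")
    _add(model, "chl_RuBisCO_oxy",
         "chl_RuBP + chl_O2 -> chl_PGA + chl_Pgly", "metabolic")
    _add(model, "chl_PGK", "chl_PGA + chl_ATP <> chl_BPGA + chl_ADP", "metabolic")
    _add(model, "chl_GAPDH",
         "chl_BPGA + chl_NADPH <> chl_GAP + chl_NADP + chl_Pi", "metabolic")
    _add(model, "chl_TPI", "chl_GAP <> chl_DHAP", "metabolic")
    _add(model, "chl_Regen",
         "5 chl_GAP + 2 chl_H2O -> 3 chl_Ru5P + 2 chl_Pi", "metabolic")
    _add(model, "chl_Ru5Pk", "chl_Ru5P + chl_ATP -> chl_RuBP + chl_ADP", "metabolic")
    _add(model, "chl_PGlyPase", "chl_Pgly + chl_H2O -> chl_Glyco + chl_Pi", "metabolic")
    _add(model, "chl_GLYK",
         "chl_Glycerate + chl_ATP -> chl_PGA + chl_ADP", "metabolic")
    _add(model, "chl_GS2",
         "chl_Glu + chl_NH3 + chl_ATP -> chl_Gln + chl_ADP + chl_Pi", "metabolic")
    _add(model, "chl_GOGAT",
         "chl_Gln + chl_2OG + chl_NADPH -> 2 chl_Glu + chl_NADP", "metabolic")
    # redox-regulated in vivo (thioredoxin-activated in the light); modeled
    # irreversible so the valve only exports chloroplast reducing power
    _add(model, "chl_NADP_MDH", "chl_OAA + chl_NADPH -> chl_Mal + chl_NADP", "metabolic")

    # -- chloroplast envelope transporters (positive flux = import;
    #    negative = export toward the cytosol)
    _add(model, "chl_Photon_tx", "Photon -> chl_Photon", "intracellular_transporter")
    _add(model, "chl_GAP_tx", "GAP + chl_Pi <> chl_GAP + Pi", "intracellular_transporter")
    _add(model, "chl_DHAP_tx", "DHAP + chl_Pi <> chl_DHAP + Pi", "intracellular_transporter")
    _add(model, "chl_PGA_tx", "PGA + chl_Pi <> chl_PGA + Pi", "intracellular_transporter")
    _add(model, "chl_Maloxac_tx", "Mal + chl_OAA <> chl_Mal + OAA", "intracellular_transporter")
    _add(model, "chl_Mal_2OG_tx", "2OG + chl_Mal <> chl_2OG + Mal", "intracellular_transporter")
    _add(model, "chl_Glu_Mal_tx", "Mal + chl_Glu <> chl_Mal + Glu", "intracellular_transporter")
    _add(model, "chl_Gln_Glt_tx", "Glu + chl_Gln <> chl_Glu + Gln", "intracellular_transporter")
    _add(model, "chl_NH3_tx", "NH3 <> chl_NH3", "intracellular_transporter")
    _add(model, "chl_CO2_tx", "CO2 <> chl_CO2", "intracellular_transporter")
    _add(model, "chl_O2_tx", "O2 <> chl_O2", "intracellular_transporter")
    _add(model, "chl_H2O_tx", "H2O <> chl_H2O", "intracellular_transporter")
    _add(model, "chl_Pi_tx", "Pi <> chl_Pi", "intracellular_transporter")
    _add(model, "chl_Glyco_tx", "Glyco <> chl_Glyco", "intracellular_transporter")
    _add(model, "chl_Glycerate_tx", "Glycerate <> chl_Glycerate", "intracellular_transporter")

    # -- peroxisome: glycolate oxidation, H2O2 disposal, transaminations
    _add(model, "per_GOX", "per_Glyco + per_O2 -> per_Glyox + per_H2O2", "metabolic")
    _add(model, "per_CAT", "2 per_H2O2 -> 2 per_H2O + per_O2", "metabolic")
    if opt.include_glutathione_ascorbate:
        _add(model, "per_APX", "per_H2O2 + per_AsA -> per_DHA + 2 per_H2O", "metabolic")
        _add(model, "per_MDHAR", "per_DHA + per_NADH -> per_AsA + per_NAD", "metabolic")
    _add(model, "per_SGAT", "per_Glyox + per_Ser -> per_Gly + per_HPyr", "metabolic")
    _add(model, "per_GGAT", "per_Glyox + per_Glu -> per_Gly + per_2OG", "metabolic")
    _add(model, "per_HPR1", "per_HPyr + per_NADH -> per_Glycerate + per_NAD", "metabolic")
    _add(model, "per_MDH", "per_Mal + per_NAD <> per_OAA + per_NADH", "metabolic")
    _add(model, "per_Maloxac_tx", "Mal + per_OAA <> per_Mal + OAA", "intracellular_transporter")
    _add(model, "per_Glyco_tx", "Glyco <> per_Glyco", "intracellular_transporter")
    _add(model, "per_Glycerate_tx", "Glycerate <> per_Glycerate", "intracellular_transporter")
    _add(model, "per_Gly_tx", "Gly <> per_Gly", "intracellular_transporter")
    _add(model, "per_Ser_tx", "Ser <> per_Ser", "intracellular_transporter")
    _add(model, "per_Glu_tx", "Glu <> per_Glu", "intracellular_transporter")
    _add(model, "per_2OG_tx", "2OG <> per_2OG", "intracellular_transporter")
    _add(model, "per_O2_tx", "O2 <> per_O2", "intracellular_transporter")
    _add(model, "per_H2O_tx", "H2O <> per_H2O", "intracellular_transporter")

    # -- mitochondrion: glycine decarboxylation, ETC with COX/AOX branches
    _add(model, "mit_GDC",
         "2 mit_Gly + mit_H2O + mit_NAD -> mit_Ser + mit_CO2 + mit_NH3 + mit_NADH",
         "metabolic")
    _add(model, "mit_ETC",
         f"2 mit_NADH + mit_O2 -> 2 mit_NAD + 2 mit_H2O + {2 * pmf_n} mit_PMF",
         "metabolic")
    if opt.include_aox:
        _add(model, "mit_AOX", "2 mit_NADH + mit_O2 -> 2 mit_NAD + 2 mit_H2O", "metabolic")
    _add(model, "mit_Complex_V",
         f"{pmf_a} mit_PMF + mit_ADP + mit_Pi -> mit_ATP + mit_H2O", "metabolic")
    _add(model, "mit_MDH", "mit_Mal + mit_NAD <> mit_OAA + mit_NADH", "metabolic")
    _add(model, "mit_ATP_tx", "ATP + mit_ADP <> mit_ATP + ADP", "intracellular_transporter")
    _add(model, "mit_Maloxac_tx", "Mal + mit_OAA <> mit_Mal + OAA",
         "intracellular_transporter",
         lower=0.0 if opt.mit_malate_import_only else None)
    _add(model, "mit_Gly_tx", "Gly <> mit_Gly", "intracellular_transporter")
    _add(model, "mit_Ser_tx", "Ser <> mit_Ser", "intracellular_transporter")
    _add(model, "mit_NH3_tx", "NH3 <> mit_NH3", "intracellular_transporter")
    _add(model, "mit_CO2_tx", "CO2 <> mit_CO2", "intracellular_transporter")
    _add(model, "mit_O2_tx", "O2 <> mit_O2", "intracellular_transporter")
    _add(model, "mit_H2O_tx", "H2O <> mit_H2O", "intracellular_transporter")
    _add(model, "mit_Pi_tx", "Pi <> mit_Pi", "intracellular_transporter")

    # -- cytosol: glycolytic triose handling, sucrose synthesis, N shuttling
    _add(model, "GAPDH", "GAP + NAD + Pi <> BPGA + NADH", "metabolic")
    _add(model, "PGK", "BPGA + ADP <> PGA + ATP", "metabolic")
    _add(model, "GAPN", "GAP + NADP + H2O -> PGA + NADPH", "metabolic")
    _add(model, "MDH", "Mal + NAD <> OAA + NADH", "metabolic")
    if opt.include_gs1:
        _add(model, "GS1", "Glu + NH3 + ATP -> Gln + ADP + Pi", "metabolic")
    _add(model, "GLUTAMINASE", "Gln + H2O -> Glu + NH3", "metabolic")
    _add(model, "TPI", "GAP <> DHAP", "metabolic")
    _add(model, "ALDO", "GAP + DHAP -> FBP", "metabolic")
    _add(model, "FBPase", "FBP + H2O -> F6P + Pi", "metabolic")
    _add(model, "PGI", "F6P <> G6P", "metabolic")
    _add(model, "PGM", "G6P <> G1P", "metabolic")
    _add(model, "SPS",
         "G1P + F6P + ATP + 2 H2O -> Suc + ADP + 3 Pi", "metabolic")
    _add(model, "G3PDH", "DHAP + NADH -> G3P + NAD", "metabolic")
    _add(model, "NR", "NO3 + 4 NADPH -> NH3 + 3 H2O + 4 NADP", "metabolic")
    _add(model, "ATPase_maintenance", "ATP + H2O -> ADP + Pi", "maintenance")

    # -- exchanges (positive flux = uptake, negative = release)
    _add(model, "photon_ex", "-> Photon", "exchange")
    _add(model, "co2_ex", "-> CO2", "exchange", lower=-INF_BOUND)
    _add(model, "o2_ex", "-> O2", "exchange", lower=-INF_BOUND)
    _add(model, "nh3_ex", "-> NH3", "exchange", lower=-INF_BOUND)
    _add(model, "no3_ex", "-> NO3", "exchange", lower=-INF_BOUND)
    _add(model, "pi_ex", "-> Pi", "exchange", lower=-INF_BOUND)
    _add(model, "so4_ex", "-> SO4", "exchange", lower=-INF_BOUND)
    _add(model, "h2o_ex", "-> H2O", "exchange", lower=-INF_BOUND)

    # -- biomass drains (fixed by the composition in core_constraints)
    _add(model, "biomass_GAP_tx", "GAP ->", "biomass_transporter")
    _add(model, "biomass_Suc_tx", "Suc ->", "biomass_transporter")
    _add(model, "biomass_G3P_tx", "G3P ->", "biomass_transporter")

    _annotate(model)
    model.validate()

    from .model import model_statistics  # local import avoids cycle at import time

    stats = model_statistics(model)
    manifest = GeneratorManifest(
        model_id="core_leaf",
        seed=seed,
        reaction_count_total=stats.reaction_count_total,
        metabolite_count_total=stats.metabolite_count_total,
        per_compartment_counts=dict(stats.per_compartment_counts),
        per_category_counts=dict(stats.per_category_counts),
        expected_behaviors=[
            {
                "id": "balanced",
                "description": "no closed-system leaks and no energy-generating "
                               "cycle for ATP or NADH currencies",
                "regime": "all exchanges closed",
            },
            {
                "id": "malate-valve-vs-vcvo",
                "description": "|chl_Maloxac_tx| is non-increasing from Vc/Vo "
                               "1:1 to 5:1 (valve exports chloroplast redox "
                               "under high photorespiration)",
                "regime": "vcvo scan 1:1..5:1, biomass fixed",
            },
            {
                "id": "gapdh-pgk-vcvo",
                "description": "cytosolic GAPDH/PGK carry zero flux at Vc/Vo "
                               "1:1 and positive flux at 3:1 (cytosolic ATP "
                               "shifts from mitochondrial to triose-shuttle "
                               "supply as photorespiration falls)",
                "regime": "vcvo scan, biomass fixed",
            },
            {
                "id": "gs2-refixation",
                "description": "at Vc/Vo 1:1 the ammonia released by mit_GDC "
                               "equals the chloroplast NH3 import and the GS2 "
                               "flux (complete photorespiratory refixation)",
                "regime": "vcvo 1:1, biomass fixed",
            },
            {
                "id": "hpr1-light",
                "description": "per_HPR1 flux is non-decreasing across the "
                               "upper half of the photon grid (excess fixed "
                               "light is dissipated photorespiratorily)",
                "regime": "light scan, upper grid",
            },
            {
                "id": "cyclic-le-noncyclic",
                "description": "cyclic photophosphorylation never exceeds "
                               "non-cyclic at any feasible light-scan point",
                "regime": "light scan",
            },
        ],
        extra={
            "biomass_composition": dict(opt.biomass_composition),
            "maintenance_flux": opt.maintenance_flux,
            "photon_reaction": "photon_ex",
            "co2_reaction": "co2_ex",
            "rubisco": ["chl_RuBisCO_carb", "chl_RuBisCO_oxy"],
            "light_reactions": ["chl_LightNonCyc", "chl_LightCyc"],
        },
    )
    return model, manifest


def core_constraints(
    options: Optional[CoreLeafModelOptions] = None,
    model: Optional[Model] = None,
) -> ConstraintSet:
    """The study conditions: fixed biomass drains plus maintenance demand."""
    opt = options or CoreLeafModelOptions()
    if model is None:
        model, _ = build_core_leaf_model(opt)
    return apply_biomass_composition(
        model, opt.biomass_composition, maintenance_flux=opt.maintenance_flux
    )


# ---------------------------------------------------------------------------
# Micro-fixtures with analytically known optima
# ---------------------------------------------------------------------------

def build_fixture_network(kind: str, **params) -> Tuple[Model, GeneratorManifest]:
    """Named micro-networks whose optima are known in closed form.

    kinds: ``chain`` (n unit steps), ``diamond`` (1-step vs 2-step arm),
    ``equal_parallel`` (two identical arms), ``k_parallel`` (k identical
    arms), ``photon_toy`` (fixed-stoichiometry light demand with a known
    feasibility threshold).  The manifest records the fixed demand, the
    optimal objective and, for the photon toy, the feasibility threshold.
    """
    demand = float(params.get("demand", 1.0))
    manifest = GeneratorManifest(model_id=kind, seed=int(params.get("seed", 0)))

    model = Model(kind)
    if kind == "chain":
        n = int(params.get("n", 3))
        if n < 1:
            raise ModelError("chain needs n >= 1")
        _add(model, "in_ex", "-> M0", "exchange")
        for i in range(n - 2):
            _add(model, f"R{i + 1}", f"M{i} -> M{i + 1}", "metabolic")
        last = max(n - 2, 0)
        _add(model, "out_ex", f"M{last} ->", "exchange")
        manifest.extra = {"demand_reaction": "out_ex", "demand": demand,
                          "optimal_objective": n * demand}
    elif kind == "diamond":
        _add(model, "in_ex", "-> A", "exchange")
        _add(model, "R1", "A -> B", "metabolic")
        _add(model, "R2", "A -> C", "metabolic")
        _add(model, "R3", "C -> B", "metabolic")
        _add(model, "out_ex", "B ->", "exchange")
        manifest.extra = {"demand_reaction": "out_ex", "demand": demand,
                          "optimal_objective": 3 * demand,
                          "short_arm": "R1", "long_arm": ["R2", "R3"]}
    elif kind in ("equal_parallel", "k_parallel"):
        k = 2 if kind == "equal_parallel" else int(params.get("k", 3))
        if k < 2:
            raise ModelError("parallel fixtures need k >= 2")
        _add(model, "in_ex", "-> A", "exchange")
        for i in range(k):
            _add(model, f"P{i + 1}", "A -> B", "metabolic")
        _add(model, "out_ex", "B ->", "exchange")
        manifest.extra = {"demand_reaction": "out_ex", "demand": demand,
                          "optimal_objective": 3 * demand, "arms": k,
                          "arm_reactions": [f"P{i + 1}" for i in range(k)]}
    elif kind == "photon_toy":
        ppb = Fraction(str(params.get("photons_per_biomass", 2)))
        _add(model, "photon_ex", "-> Photon", "exchange")
        _add(model, "c_ex", "-> C", "exchange")
        _add(model, "Rsyn", f"{ppb} Photon + C -> B", "metabolic")
        _add(model, "photon_sink", "Photon ->", "metabolic")
        _add(model, "out_ex", "B ->", "exchange")
        manifest.extra = {
            "demand_reaction": "out_ex", "demand": demand,
            "photon_reaction": "photon_ex",
            "photons_per_biomass": float(ppb),
            "feasibility_threshold": float(ppb) * demand,
        }
    else:
        raise ModelError(f"unknown fixture kind {kind!r}")

    model.validate()
    from .model import model_statistics

    stats = model_statistics(model)
    manifest.reaction_count_total = stats.reaction_count_total
    manifest.metabolite_count_total = stats.metabolite_count_total
    manifest.per_compartment_counts = dict(stats.per_compartment_counts)
    manifest.per_category_counts = dict(stats.per_category_counts)
    return model, manifest


def fixture_constraints(manifest: GeneratorManifest) -> ConstraintSet:
    """Fix the fixture's demand drain at its manifest value."""
    return ConstraintSet(
        fixed_fluxes={str(manifest.extra["demand_reaction"]): float(manifest.extra["demand"])},
        maintenance_flux=0.0,
    )


# ---------------------------------------------------------------------------
# Behavior verification
# ---------------------------------------------------------------------------

def verify_behaviors(
    model: Model,
    manifest: GeneratorManifest,
    options: Optional[CoreLeafModelOptions] = None,
    light_grid: Optional[Sequence[float]] = None,
) -> Dict[str, Dict[str, object]]:
    """Run the scenario operations that check each declared behavior.

    Returns ``{behavior_id: {"passed": bool, "detail": ...}}`` for every
    entry in ``manifest.expected_behaviors``.  The light-scan checks use a
    coarse grid (2.0 to 10.0 in steps of 0.5 by default) so the whole
    verification stays in the seconds range.
    """
    from .consistency import detect_energy_cycle, find_leaks
    from .scenarios import VcVoRatio, light_scan, vcvo_scan

    opt = options or CoreLeafModelOptions()
    constraints = core_constraints(opt, model)
    declared = {b["id"] for b in manifest.expected_behaviors}
    results: Dict[str, Dict[str, object]] = {}
    tol = 1e-6

    if "balanced" in declared:
        leaks = find_leaks(model)
        cycles = [
            detect_energy_cycle(model, pair).has_cycle
            for pair in (("ATP", "ADP"), ("NADH", "NAD"), ("chl_ATP", "chl_ADP"))
        ]
        results["balanced"] = {
            "passed": leaks.clean and not any(cycles),
            "detail": {"leaks": sorted(leaks.leaking_metabolites),
                       "energy_cycles": cycles},
        }

    scan = None
    if declared & {"malate-valve-vs-vcvo", "gapdh-pgk-vcvo", "gs2-refixation"}:
        ratios = [VcVoRatio(Fraction(k), Fraction(1)) for k in (1, 2, 3, 4, 5)]
        scan = vcvo_scan(model, constraints, ratios)
        by_ratio = {p: s for p, s in scan.points if s.optimal}

    if "malate-valve-vs-vcvo" in declared:
        series = [abs(by_ratio[p].fluxes["chl_Maloxac_tx"]) for p in sorted(by_ratio)]
        monotone = all(a >= b - tol for a, b in zip(series, series[1:]))
        results["malate-valve-vs-vcvo"] = {"passed": monotone, "detail": series}

    if "gapdh-pgk-vcvo" in declared:
        low_pr = by_ratio[1.0]
        normal = by_ratio[3.0]
        passed = (
            abs(low_pr.fluxes["GAPDH"]) < tol
            and abs(low_pr.fluxes["PGK"]) < tol
            and normal.fluxes["GAPDH"] > tol
            and normal.fluxes["PGK"] > tol
        )
        results["gapdh-pgk-vcvo"] = {
            "passed": passed,
            "detail": {"at_1:1": (low_pr.fluxes["GAPDH"], low_pr.fluxes["PGK"]),
                       "at_3:1": (normal.fluxes["GAPDH"], normal.fluxes["PGK"])},
        }

    if "gs2-refixation" in declared:
        s = by_ratio[1.0]
        gdc_nh3 = s.fluxes["mit_GDC"]  # one NH3 per GDC unit
        detail = {"gdc_nh3": gdc_nh3, "chl_import": s.fluxes["chl_NH3_tx"],
                  "gs2": s.fluxes["chl_GS2"]}
        passed = (
            abs(gdc_nh3 - s.fluxes["chl_NH3_tx"]) < 1e-5
            and abs(gdc_nh3 - s.fluxes["chl_GS2"]) < 1e-5
            and gdc_nh3 > tol
        )
        results["gs2-refixation"] = {"passed": passed, "detail": detail}

    if declared & {"hpr1-light", "cyclic-le-noncyclic"}:
        grid = list(light_grid) if light_grid is not None else [
            round(2.0 + 0.5 * i, 10) for i in range(17)
        ]
        ls = light_scan(model, constraints, grid)
        feasible = ls.feasible_points
        if "hpr1-light" in declared:
            hpr1 = [s.fluxes["per_HPR1"] for _, s in feasible]
            monotone = all(b >= a - tol for a, b in zip(hpr1, hpr1[1:]))
            results["hpr1-light"] = {"passed": monotone and len(feasible) >= 3,
                                     "detail": hpr1}
        if "cyclic-le-noncyclic" in declared:
            ok = all(
                s.fluxes["chl_LightCyc"] <= s.fluxes["chl_LightNonCyc"] + 1e-9
                for _, s in feasible
            )
            results["cyclic-le-noncyclic"] = {"passed": ok,
                                              "detail": len(feasible)}
    return results


# ---------------------------------------------------------------------------
# Deliberately broken variants
# ---------------------------------------------------------------------------

def make_broken_variant(
    model: Model,
    defect: str,
    seed: int = 0,
) -> Tuple[Model, Dict[str, str]]:
    """Inject one seeded consistency defect into a balanced model.

    ``defect="leak"`` adds an unbalanced creation reaction for one seeded
    internal carbon-bearing metabolite; ``defect="energy_cycle"`` adds a
    free ATP-regenerating reaction.  Returns the broken copy and a record
    of what was injected.
    """
    broken = model.copy()
    rng = np.random.default_rng(seed)
    if defect == "leak":
        candidates = sorted(
            m.id for m in model.metabolites.values()
            if m.compartment != "external"
            and m.elemental_composition
            and m.elemental_composition.get("C", 0) > 0
        )
        if not candidates:
            candidates = sorted(model.internal_metabolite_ids())
        target = candidates[int(rng.integers(len(candidates)))]
        rid = f"leak_{target}"
        broken.add_reaction(
            Reaction(id=rid, stoichiometry={target: Fraction(1)},
                     lower_bound=0.0, upper_bound=INF_BOUND, category="metabolic")
        )
        return broken, {"defect": "leak", "reaction": rid, "metabolite": target}
    if defect == "energy_cycle":
        for prefix in ("", "chl_", "mit_"):
            atp, adp, pi = f"{prefix}ATP", f"{prefix}ADP", f"{prefix}Pi"
            if atp in model.metabolites and adp in model.metabolites:
                stoich = {adp: Fraction(-1), atp: Fraction(1)}
                if pi in model.metabolites:
                    stoich[pi] = Fraction(-1)
                    water = f"{prefix}H2O"
                    if water in model.metabolites:
                        stoich[water] = Fraction(1)
                rid = f"free_{atp}_regen"
                broken.add_reaction(
                    Reaction(id=rid, stoichiometry=stoich, lower_bound=0.0,
                             upper_bound=INF_BOUND, category="metabolic")
                )
                return broken, {"defect": "energy_cycle", "reaction": rid,
                                "currency": atp}
        raise ModelError("no ATP/ADP pair found to miswire")
    if defect == "none":
        return broken, {"defect": "none"}
    raise ModelError(f"unknown defect {defect!r}")
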