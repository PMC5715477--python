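"""Domain types for compartmentalized stoichiometric leaf models.

A model is a set of metabolites and reactions whose stoichiometric matrix
``S`` (rows: internal metabolites, columns: reactions) defines the
steady-state constraint ``S @ v = 0`` used by the solver modules.

Conventions
-----------
* Metabolite ids are compartment-prefixed: ``chl_`` chloroplast, ``mit_``
  mitochondrion, ``per_`` peroxisome, ``ext_`` external, no prefix cytosol.
* Stoichiometric coefficients are exact :class:`fractions.Fraction` values
  (negative = consumed, positive = produced); they are converted to floating
  point only when a linear program is built.  Exactness matters when
  reactions are lumped in rational proportions.
* For intracellular transporters, negative flux means export toward the
  cytosol.
* Reaction bounds default to ``(0, 1e6)`` for irreversible and
  ``(-1e6, 1e6)`` for reversible reactions; ``1e6`` is the finite stand-in
  for an unconstrained flux.
"""

from __future__ import annotations

import copy as _copy
import re
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "INF_BOUND",
    "COMPARTMENTS",
    "CATEGORIES",
    "Metabolite",
    "Reaction",
    "Model",
    "ModelStatistics",
    "ModelError",
    "EquationError",
    "infer_compartment",
    "parse_reaction_equation",
    "format_reaction_equation",
    "load_model",
    "write_model",
    "read_sbml",
    "write_sbml",
    "model_statistics",
]

#: Finite sentinel used for "unconstrained" flux bounds.
INF_BOUND = 1.0e6

COMPARTMENTS = ("cytosol", "chloroplast", "mitochondrion", "peroxisome", "external")

CATEGORIES = (
    "metabolic",
    "intracellular_transporter",
    "biomass_transporter",
    "exchange",
    "photophosphorylation",
    "maintenance",
)

_PREFIX_COMPARTMENT = {
    "chl_": "chloroplast",
    "mit_": "mitochondrion",
    "per_": "peroxisome",
    "ext_": "external",
}


class ModelError(ValueError):
    """Raised when a model or reaction violates a structural invariant."""


class EquationError(ValueError):
    """Raised when a reaction equation string cannot be parsed."""


def infer_compartment(metabolite_id: str) -> str:
    """Compartment implied by the id prefix; total over all ids."""
    for prefix, comp in _PREFIX_COMPARTMENT.items():
        if metabolite_id.startswith(prefix):
            return comp
    return "cytosol"


@dataclass(frozen=True)
class Metabolite:
    """A chemical species in one compartment.

    ``elemental_composition`` maps element symbols to counts and may be an
    empty mapping for massless bookkeeping species (photons, proton-motive
    force); ``None`` means unannotated.
    """

    id: str
    name: str = ""
    compartment: str = ""
    elemental_composition: Optional[Mapping[str, int]] = None

    def __post_init__(self) -> None:
        if not self.compartment:
            object.__setattr__(self, "compartment", infer_compartment(self.id))
        if self.compartment not in COMPARTMENTS:
            raise ModelError(f"unknown compartment {self.compartment!r} for {self.id!r}")


@dataclass
class Reaction:
    """A stoichiometric conversion with flux bounds and a category tag."""

    id: str
    stoichiometry: Dict[str, Fraction]
    lower_bound: float = 0.0
    upper_bound: float = INF_BOUND
    category: str = "metabolic"
    genes: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.stoichiometry = {m: Fraction(c) for m, c in self.stoichiometry.items() if c != 0}
        if not self.stoichiometry:
            raise ModelError(f"reaction {self.id!r} has empty stoichiometry")
        if self.lower_bound > self.upper_bound:
            raise ModelError(
                f"reaction {self.id!r} has inverted bounds "
                f"({self.lower_bound} > {self.upper_bound})"
            )
        if self.category not in CATEGORIES:
            raise ModelError(f"reaction {self.id!r} has unknown category {self.category!r}")
        self.genes = tuple(self.genes)

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    def equation(self) -> str:
        return format_reaction_equation(self.stoichiometry, self.reversible)


@dataclass
class ModelStatistics:
    reaction_count_total: int
    metabolite_count_total: int
    per_compartment_counts: Dict[str, int]
    per_category_counts: Dict[str, int]


class Model:
    """A compartmentalized stoichiometric model.

    Reactions and metabolites are kept in insertion order so that matrix
    construction, serialization and solver output are deterministic.
    """

    def __init__(self, model_id: str = "model", annotations: Optional[Dict[str, str]] = None):
        self.id = model_id
        self.metabolites: Dict[str, Metabolite] = {}
        self.reactions: Dict[str, Reaction] = {}
        self.annotations: Dict[str, str] = dict(annotations or {})

    # -- construction -----------------------------------------------------

    def add_metabolite(self, metabolite: Metabolite) -> None:
        existing = self.metabolites.get(metabolite.id)
        if existing is not None and existing != metabolite:
            raise ModelError(f"conflicting definitions for metabolite {metabolite.id!r}")
        self.metabolites[metabolite.id] = metabolite

    def add_reaction(self, reaction: Reaction) -> None:
        if reaction.id in self.reactions:
            raise ModelError(f"duplicate reaction id {reaction.id!r}")
        for met_id in reaction.stoichiometry:
            if met_id not in self.metabolites:
                self.metabolites[met_id] = Metabolite(id=met_id)
        self.reactions[reaction.id] = reaction

    def remove_reaction(self, reaction_id: str) -> Reaction:
        try:
            return self.reactions.pop(reaction_id)
        except KeyError:
            raise ModelError(f"no reaction {reaction_id!r} in model {self.id!r}") from None

    def copy(self) -> "Model":
        clone = Model(self.id, dict(self.annotations))
        clone.metabolites = dict(self.metabolites)
        clone.reactions = {rid: _copy.deepcopy(r) for rid, r in self.reactions.items()}
        return clone

    # -- queries ----------------------------------------------------------

    def reactions_by_category(self, *categories: str) -> List[Reaction]:
        return [r for r in self.reactions.values() if r.category in categories]

    def internal_metabolite_ids(self) -> List[str]:
        return [m.id for m in self.metabolites.values() if m.compartment != "external"]

    def stoichiometric_matrix(self) -> Tuple[np.ndarray, List[str], List[str]]:
        """Dense ``S`` over internal metabolites, with row/column id orders."""
        met_ids = self.internal_metabolite_ids()
        rxn_ids = list(self.reactions)
        met_index = {m: i for i, m in enumerate(met_ids)}
        S = np.zeros((len(met_ids), len(rxn_ids)))
        for j, rid in enumerate(rxn_ids):
            for met_id, coeff in self.reactions[rid].stoichiometry.items():
                i = met_index.get(met_id)
                if i is not None:
                    S[i, j] = float(coeff)
        return S, met_ids, rxn_ids

    def validate(self) -> None:
        for reaction in self.reactions.values():
            for met_id in reaction.stoichiometry:
                if met_id not in self.metabolites:
                    raise ModelError(
                        f"reaction {reaction.id!r} references unknown metabolite {met_id!r}"
                    )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"<Model {self.id}: {len(self.reactions)} reactions, "
            f"{len(self.metabolites)} metabolites>"
        )


# ---------------------------------------------------------------------------
# Equation parsing
# ---------------------------------------------------------------------------

_ARROWS = ("<>", "->")
_COEFF_RE = re.compile(r"^\d+(?:/\d+)?(?:\.\d+)?$|^\.\d+$|^\d+\.\d*$")


def _parse_side(text: str, sign: int, out: Dict[str, Fraction]) -> None:
    text = text.strip()
    if not text:
        return
    for term in text.split("+"):
        tokens = term.split()
        if not tokens:
            raise EquationError(f"empty term in equation side {text!r}")
        if len(tokens) == 1:
            coeff, met = Fraction(1), tokens[0]
        elif len(tokens) == 2:
            if not _COEFF_RE.match(tokens[0]):
                raise EquationError(f"malformed coefficient {tokens[0]!r}")
            coeff, met = Fraction(tokens[0]), tokens[1]
        else:
            raise EquationError(f"malformed term {term.strip()!r}")
        if _COEFF_RE.match(met):
            raise EquationError(f"metabolite id {met!r} looks like a number")
        if coeff <= 0:
            raise EquationError(f"non-positive coefficient in term {term.strip()!r}")
        out[met] = out.get(met, Fraction(0)) + sign * coeff


def parse_reaction_equation(text: str) -> Tuple[Dict[str, Fraction], bool]:
    """Parse ``"A + 2 B -> C"`` into a signed coefficient map.

    Left-hand coefficients are negated, right-hand ones kept positive;
    ``"<>"`` marks the reaction reversible.  A metabolite may appear on both
    sides, in which case its coefficients are summed.  One side may be empty
    (exchange drains/sources).  Raises :class:`EquationError` for malformed
    tokens, an unknown arrow, or a fully cancelling equation.
    """
    arrow = None
    for candidate in _ARROWS:
        if candidate in text:
            arrow = candidate
            break
    if arrow is None:
        raise EquationError(f"no arrow ('->' or '<>') in equation {text!r}")
    left, _, right = text.partition(arrow)
    if arrow in right:
        raise EquationError(f"multiple arrows in equation {text!r}")
    stoich: Dict[str, Fraction] = {}
    _parse_side(left, -1, stoich)
    _parse_side(right, +1, stoich)
    stoich = {m: c for m, c in stoich.items() if c != 0}
    if not stoich:
        raise EquationError(f"equation {text!r} has zero net coefficient for all species")
    return stoich, arrow == "<>"


def _format_coeff(coeff: Fraction) -> str:
    coeff = abs(coeff)
    if coeff == 1:
        return ""
    if coeff.denominator == 1:
        return f"{coeff.numerator} "
    return f"{coeff.numerator}/{coeff.denominator} "


def format_reaction_equation(stoichiometry: Mapping[str, Fraction], reversible: bool) -> str:
    """Inverse of :func:`parse_reaction_equation` (up to term order)."""
    left = [f"{_format_coeff(c)}{m}" for m, c in stoichiometry.items() if c < 0]
    right = [f"{_format_coeff(c)}{m}" for m, c in stoichiometry.items() if c > 0]
    arrow = "<>" if reversible else "->"
    return f"{' + '.join(left)} {arrow} {' + '.join(right)}".strip()


# ---------------------------------------------------------------------------
# Tabular serialization
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = ["reaction_id", "equation", "lower_bound", "upper_bound", "category", "genes"]


def _infer_category(reaction_id: str, stoich: Mapping[str, Fraction]) -> str:
    """Name-based fallback when the category column is empty."""
    if reaction_id.startswith("biomass_"):
        return "biomass_transporter"
    if reaction_id.endswith("_tx"):
        return "intracellular_transporter"
    if reaction_id.endswith("_ex") or reaction_id.startswith("EX_"):
        return "exchange"
    if "maintenance" in reaction_id.lower():
        return "maintenance"
    return "metabolic"


def load_model(path: str | Path, model_id: Optional[str] = None) -> Model:
    """Read a model from the tab-separated reaction table format.

    Columns: reaction_id, equation, lower_bound, upper_bound, category,
    genes (pipe-separated); empty bound cells take the direction-dependent
    defaults, an empty category cell falls back to name-based inference.
    Metabolites are created on first reference with the compartment inferred
    from the id prefix.  An optional ``# composition:`` header line carries
    elemental annotations as ``met=CxHyOz`` pairs.
    """
    path = Path(path)
    model = Model(model_id or path.stem)
    compositions: Dict[str, Dict[str, int]] = {}
    with path.open("r", encoding="utf-8") as handle:
        lines = handle.read().splitlines()
    header: Optional[List[str]] = None
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.startswith("composition:"):
                for pair in body[len("composition:"):].split():
                    met, _, formula = pair.partition("=")
                    compositions[met] = parse_formula(formula)
            continue
        cells = line.split("\t")
        if header is None:
            header = [c.strip() for c in cells]
            missing = [c for c in _TABLE_COLUMNS[:2] if c not in header]
            if missing:
                raise ModelError(f"{path}: missing required columns {missing}")
            continue
        row = dict(zip(header, cells))
        rid = row.get("reaction_id", "").strip()
        if not rid:
            raise ModelError(f"{path}:{lineno}: empty reaction_id")
        try:
            stoich, reversible = parse_reaction_equation(row.get("equation", ""))
        except EquationError as exc:
            raise ModelError(f"{path}:{lineno}: {exc}") from exc
        lb_cell = row.get("lower_bound", "").strip()
        ub_cell = row.get("upper_bound", "").strip()
        lower = float(lb_cell) if lb_cell else (-INF_BOUND if reversible else 0.0)
        upper = float(ub_cell) if ub_cell else INF_BOUND
        category = row.get("category", "").strip() or _infer_category(rid, stoich)
        genes_cell = row.get("genes", "").strip()
        genes = tuple(g for g in genes_cell.split("|") if g) if genes_cell else ()
        model.add_reaction(
            Reaction(
                id=rid,
                stoichiometry=stoich,
                lower_bound=lower,
                upper_bound=upper,
                category=category,
                genes=genes,
            )
        )
    for met_id, comp in compositions.items():
        if met_id in model.metabolites:
            old = model.metabolites[met_id]
            model.metabolites[met_id] = Metabolite(
                id=old.id, name=old.name, compartment=old.compartment,
                elemental_composition=comp,
            )
    model.validate()
    return model


_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> Dict[str, int]:
    """Parse ``"C3H7O6P"`` into an element->count map; ``"0"`` means massless."""
    if formula in ("", "0"):
        return {}
    out: Dict[str, int] = {}
    pos = 0
    for match in _FORMULA_RE.finditer(formula):
        if match.start() != pos:
            raise ModelError(f"malformed formula {formula!r}")
        element, count = match.group(1), match.group(2)
        out[element] = out.get(element, 0) + (int(count) if count else 1)
        pos = match.end()
    if pos != len(formula):
        raise ModelError(f"malformed formula {formula!r}")
    return out


def format_formula(composition: Mapping[str, int]) -> str:
    if not composition:
        return "0"
    order = ["C", "H", "O", "N", "P", "S"]
    keys = [k for k in order if k in composition] + sorted(
        k for k in composition if k not in order
    )
    return "".join(f"{k}{composition[k] if composition[k] != 1 else ''}" for k in keys)


def write_model(model: Model, path: str | Path) -> Path:
    """Write the tab-separated table; inverse of :func:`load_model`."""
    path = Path(path)
    lines = []
    annotated = {
        m.id: m.elemental_composition
        for m in model.metabolites.values()
        if m.elemental_composition is not None
    }
    if annotated:
        pairs = " ".join(f"{mid}={format_formula(comp)}" for mid, comp in annotated.items())
        lines.append(f"# composition: {pairs}")
    lines.append("\t".join(_TABLE_COLUMNS))
    for reaction in model.reactions.values():
        lines.append(
            "\t".join(
                [
                    reaction.id,
                    reaction.equation(),
                    repr(reaction.lower_bound),
                    repr(reaction.upper_bound),
                    reaction.category,
                    "|".join(reaction.genes),
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


# ---------------------------------------------------------------------------
# SBML serialization (Level 3 + fbc flux bounds)
# ---------------------------------------------------------------------------

_SBML_COMPARTMENT_IDS = {
    "cytosol": "cyt",
    "chloroplast": "chl",
    "mitochondrion": "mit",
    "peroxisome": "per",
    "external": "ext",
}


def write_sbml(model: Model, path: str | Path) -> Path:
    """Export as SBML Level 3 with fbc v2 flux bounds.

    Stoichiometries are written as floats; categories and gene lists travel
    in reaction notes so that a leaffba round trip is lossless up to the
    rational->float->rational conversion.
    """
    import libsbml

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sbml_model = doc.createModel()
    sbml_model.setId(re.sub(r"[^A-Za-z0-9_]", "_", model.id) or "model")
    mplug = sbml_model.getPlugin("fbc")
    mplug.setStrict(False)

    for comp_name, comp_id in _SBML_COMPARTMENT_IDS.items():
        comp = sbml_model.createCompartment()
        comp.setId(comp_id)
        comp.setName(comp_name)
        comp.setConstant(True)

    for met in model.metabolites.values():
        sp = sbml_model.createSpecies()
        sp.setId(f"M_{met.id}")
        sp.setName(met.name or met.id)
        sp.setCompartment(_SBML_COMPARTMENT_IDS[met.compartment])
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(met.compartment == "external")
        sp.setConstant(False)
        if met.elemental_composition is not None:
            splug = sp.getPlugin("fbc")
            formula = format_formula(met.elemental_composition)
            if formula != "0":
                splug.setChemicalFormula(formula)

    bound_ids: Dict[float, str] = {}

    def _bound_parameter(value: float) -> str:
        if value not in bound_ids:
            pid = f"fb_{len(bound_ids)}"
            par = sbml_model.createParameter()
            par.setId(pid)
            par.setValue(value)
            par.setConstant(True)
            bound_ids[value] = pid
        return bound_ids[value]

    for reaction in model.reactions.values():
        rx = sbml_model.createReaction()
        rx.setId(f"R_{reaction.id}")
        rx.setName(reaction.id)
        rx.setReversible(reaction.reversible)
        rx.setFast(False)
        notes = [f"<p>category: {reaction.category}</p>"]
        if reaction.genes:
            notes.append(f"<p>genes: {'|'.join(reaction.genes)}</p>")
        rx.setNotes(
            "<body xmlns='http://www.w3.org/1999/xhtml'>" + "".join(notes) + "</body>"
        )
        rplug = rx.getPlugin("fbc")
        rplug.setLowerFluxBound(_bound_parameter(float(reaction.lower_bound)))
        rplug.setUpperFluxBound(_bound_parameter(float(reaction.upper_bound)))
        for met_id, coeff in reaction.stoichiometry.items():
            ref = rx.createReactant() if coeff < 0 else rx.createProduct()
            ref.setSpecies(f"M_{met_id}")
            ref.setStoichiometry(abs(float(coeff)))
            ref.setConstant(True)

    # empty objective keeps fbc-aware readers (e.g. cobrapy) happy
    objective = mplug.createObjective()
    objective.setId("obj")
    objective.setType("minimize")
    mplug.setActiveObjectiveId("obj")

    path = Path(path)
    libsbml.writeSBMLToFile(doc, str(path))
    return path


def read_sbml(path: str | Path, model_id: Optional[str] = None) -> Model:
    """Import an SBML Level 3 (+fbc) file written by :func:`write_sbml`.

    Float stoichiometries are converted back to rationals with
    ``Fraction.limit_denominator(10**9)``, which recovers simple ratios such
    as 1/3 exactly.
    """
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        raise ModelError(f"SBML parse error in {path}")
    sbml_model = doc.getModel()
    model = Model(model_id or sbml_model.getId() or Path(path).stem)

    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        met_id = sp.getId()[2:] if sp.getId().startswith("M_") else sp.getId()
        composition = None
        splug = sp.getPlugin("fbc")
        if splug is not None and splug.isSetChemicalFormula():
            composition = parse_formula(splug.getChemicalFormula())
        model.add_metabolite(Metabolite(id=met_id, name=sp.getName(), elemental_composition=composition))

    params = {
        sbml_model.getParameter(i).getId(): sbml_model.getParameter(i).getValue()
        for i in range(sbml_model.getNumParameters())
    }

    for i in range(sbml_model.getNumReactions()):
        rx = sbml_model.getReaction(i)
        rid = rx.getId()[2:] if rx.getId().startswith("R_") else rx.getId()
        stoich: Dict[str, Fraction] = {}
        for j in range(rx.getNumReactants()):
            ref = rx.getReactant(j)
            met = ref.getSpecies()
            met = met[2:] if met.startswith("M_") else met
            stoich[met] = stoich.get(met, Fraction(0)) - Fraction(
                ref.getStoichiometry()
            ).limit_denominator(10**9)
        for j in range(rx.getNumProducts()):
            ref = rx.getProduct(j)
            met = ref.getSpecies()
            met = met[2:] if met.startswith("M_") else met
            stoich[met] = stoich.get(met, Fraction(0)) + Fraction(
                ref.getStoichiometry()
            ).limit_denominator(10**9)
        rplug = rx.getPlugin("fbc")
        lower = upper = None
        if rplug is not None:
            if rplug.isSetLowerFluxBound():
                lower = params.get(rplug.getLowerFluxBound())
            if rplug.isSetUpperFluxBound():
                upper = params.get(rplug.getUpperFluxBound())
        if lower is None:
            lower = -INF_BOUND if rx.getReversible() else 0.0
        if upper is None:
            upper = INF_BOUND
        category = "metabolic"
        genes: Tuple[str, ...] = ()
        if rx.isSetNotes():
            notes = rx.getNotesString()
            cat_match = re.search(r"category:\s*([a-z_]+)", notes)
            if cat_match and cat_match.group(1) in CATEGORIES:
                category = cat_match.group(1)
            gene_match = re.search(r"genes:\s*([^<\s]+)", notes)
            if gene_match:
                genes = tuple(gene_match.group(1).split("|"))
        else:
            category = _infer_category(rid, stoich)
        model.add_reaction(
            Reaction(
                id=rid,
                stoichiometry=stoich,
                lower_bound=float(lower),
                upper_bound=float(upper),
                category=category,
                genes=genes,
            )
        )
    model.validate()
    return model


# ---------------------------------------------------------------------------
# Count statistics
# ---------------------------------------------------------------------------

def _reaction_compartment(reaction: Reaction, model: Model) -> Optional[str]:
    comps = {
        model.metabolites[m].compartment
        for m in reaction.stoichiometry
        if model.metabolites[m].compartment != "external"
    }
    if len(comps) == 1:
        return comps.pop()
    return None  # spans compartments: counted by category, not compartment


def model_statistics(model: Model) -> ModelStatistics:
    """Exact reaction/metabolite counts per compartment and category.

    Only single-compartment *metabolic* reactions contribute to the
    per-compartment tally; transporters, exchanges and other categories are
    counted by category alone, mirroring how genome-scale model tables
    report their totals.
    """
    per_compartment = {c: 0 for c in COMPARTMENTS if c != "external"}
    per_category = {c: 0 for c in CATEGORIES}
    for reaction in model.reactions.values():
        per_category[reaction.category] += 1
        if reaction.category == "metabolic":
            comp = _reaction_compartment(reaction, model)
            if comp is not None:
                per_compartment[comp] += 1
    return ModelStatistics(
        reaction_count_total=len(model.reactions),
        metabolite_count_total=len(model.metabolites),
        per_compartment_counts=per_compartment,
        per_category_counts=per_category,
    )
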