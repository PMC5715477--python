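"""Stoichiometric sanity checks: leaks, energy-generating cycles, balance.

A curated model must conserve mass, energy and redox.  These checks
operationalize that requirement with closed-system linear programs:

* **Leak detection** — with all exchange and biomass-transporter fluxes
  closed, no internal metabolite may be producible from nothing.  A
  temporary drain is added per metabolite and its flux maximized; any
  optimum above tolerance is a mass-conservation violation.
* **Energy cycles** — with exchanges closed, a currency-discharge reaction
  (e.g. ATP + H2O -> ADP + Pi) must carry zero maximal flux; anything more
  is a thermodynamically impossible free-energy loop.
* **Elemental balance** — reactions whose annotated species do not balance
  element-wise are reported.

The maintenance demand is forced to zero during the closed-system checks
so it cannot mask a leak.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, List, Mapping, Optional, Set, Tuple

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .fba import SOLVER_FEASIBILITY_TOL
from .model import INF_BOUND, Metabolite, Model, ModelError, Reaction

__all__ = [
    "LeakReport",
    "EnergyCycleReport",
    "find_leaks",
    "detect_energy_cycle",
    "elemental_balance_audit",
    "DEFAULT_TOLERANCE",
]

#: Flux-level tolerance above which a closed-system optimum counts as real.
DEFAULT_TOLERANCE = 1e-6


@dataclass
class LeakReport:
    """Internal metabolites producible in a fully closed system."""

    leaking_metabolites: Set[str] = field(default_factory=set)
    max_leak_flux: Dict[str, float] = field(default_factory=dict)
    failed_metabolites: Dict[str, str] = field(default_factory=dict)

    @property
    def clean(self) -> bool:
        return not self.leaking_metabolites


@dataclass
class EnergyCycleReport:
    """Closed-system currency discharge capacity for one currency pair."""

    currency_pair: Tuple[str, str]
    discharge_reaction_id: str
    max_closed_demand: float
    has_cycle: bool


def _closed_model(model: Model) -> Model:
    """Copy with exchanges/biomass transporters closed and maintenance off."""
    closed = model.copy()
    for reaction in closed.reactions.values():
        if reaction.category in ("exchange", "biomass_transporter", "maintenance"):
            reaction.lower_bound = 0.0
            reaction.upper_bound = 0.0
    return closed


def _solve_max_column(
    A_eq: sparse.csr_matrix,
    bounds: List[Tuple[float, float]],
    column: int,
) -> Tuple[Optional[float], str]:
    c = np.zeros(A_eq.shape[1])
    c[column] = -1.0  # maximize
    result = linprog(
        c,
        A_eq=A_eq,
        b_eq=np.zeros(A_eq.shape[0]),
        bounds=bounds,
        method="highs",
        options={
            "presolve": True,
            "primal_feasibility_tolerance": SOLVER_FEASIBILITY_TOL,
            "dual_feasibility_tolerance": SOLVER_FEASIBILITY_TOL,
        },
    )
    if result.status == 0:
        return -float(result.fun), "optimal"
    return None, {2: "infeasible", 3: "unbounded"}.get(result.status, "error")


def find_leaks(model: Model, tolerance: float = DEFAULT_TOLERANCE) -> LeakReport:
    """Maximal closed-system production of every internal metabolite.

    Per-metabolite LP failures are recorded in ``failed_metabolites``
    instead of aborting the sweep.
    """
    closed = _closed_model(model)
    S, met_ids, _ = closed.stoichiometric_matrix()
    S = sparse.csr_matrix(S)
    # direction-split columns keep the leak LP bounded even with free
    # reversible reactions
    A = sparse.hstack([S, -S], format="csr")
    bounds: List[Tuple[float, float]] = []
    for rid in closed.reactions:
        lb, ub = closed.reactions[rid].lower_bound, closed.reactions[rid].upper_bound
        bounds.append((max(lb, 0.0), max(ub, 0.0)))
    for rid in closed.reactions:
        lb, ub = closed.reactions[rid].lower_bound, closed.reactions[rid].upper_bound
        bounds.append((max(-ub, 0.0), max(-lb, 0.0)))

    report = LeakReport()
    n_cols = A.shape[1]
    for i, met_id in enumerate(met_ids):
        drain = sparse.csr_matrix(
            (np.array([-1.0]), (np.array([i]), np.array([0]))), shape=(A.shape[0], 1)
        )
        A_aug = sparse.hstack([A, drain], format="csr")
        optimum, status = _solve_max_column(A_aug, bounds + [(0.0, INF_BOUND)], n_cols)
        if status != "optimal":
            report.failed_metabolites[met_id] = status
            continue
        if optimum > tolerance:
            report.leaking_metabolites.add(met_id)
            report.max_leak_flux[met_id] = optimum
    return report


def detect_energy_cycle(
    model: Model,
    currency: Tuple[str, str] = ("ATP", "ADP"),
    tolerance: float = DEFAULT_TOLERANCE,
    discharge_reaction_id: Optional[str] = None,
    discharge_stoichiometry: Optional[Mapping[str, int]] = None,
) -> EnergyCycleReport:
    """Maximal currency discharge with every exchange closed.

    Uses ``discharge_reaction_id`` if given, otherwise the model's
    maintenance reaction when it hydrolyses the currency, otherwise a
    synthesized probe (``discharge_stoichiometry`` or the plain
    ``{high: -1, low: +1}`` pair, with water/phosphate balancing when those
    species exist).  Raises if the currency species are absent.
    """
    high, low = currency
    if high not in model.metabolites or low not in model.metabolites:
        raise ModelError(f"currency species {currency} not both present in model")
    closed = _closed_model(model)

    probe_id = discharge_reaction_id
    if probe_id is None:
        for reaction in model.reactions.values():
            if reaction.category == "maintenance" and (
                reaction.stoichiometry.get(high, 0) < 0
                and reaction.stoichiometry.get(low, 0) > 0
            ):
                probe_id = reaction.id
                break
    if probe_id is None:
        stoich = dict(discharge_stoichiometry or {})
        if not stoich:
            stoich = {high: Fraction(-1), low: Fraction(1)}
            prefix = high[: high.index("_") + 1] if "_" in high else ""
            water, phosphate = f"{prefix}H2O", f"{prefix}Pi"
            if water in model.metabolites and phosphate in model.metabolites:
                stoich[water] = Fraction(-1)
                stoich[phosphate] = Fraction(1)
        probe_id = f"__discharge_{high}"
        closed.add_reaction(
            Reaction(id=probe_id, stoichiometry=stoich, lower_bound=0.0,
                     upper_bound=INF_BOUND, category="metabolic")
        )
    else:
        probe = closed.reactions[probe_id]
        probe.lower_bound, probe.upper_bound = 0.0, INF_BOUND

    S, _, rxn_ids = closed.stoichiometric_matrix()
    S = sparse.csr_matrix(S)
    A = sparse.hstack([S, -S], format="csr")
    n = len(rxn_ids)
    bounds = [
        (max(closed.reactions[r].lower_bound, 0.0), max(closed.reactions[r].upper_bound, 0.0))
        for r in rxn_ids
    ] + [
        (max(-closed.reactions[r].upper_bound, 0.0), max(-closed.reactions[r].lower_bound, 0.0))
        for r in rxn_ids
    ]
    column = rxn_ids.index(probe_id)
    optimum, status = _solve_max_column(A, bounds, column)
    if optimum is None:
        raise RuntimeError(f"energy-cycle LP failed with status {status}")
    return EnergyCycleReport(
        currency_pair=(high, probe_id),
        discharge_reaction_id=probe_id,
        max_closed_demand=optimum,
        has_cycle=optimum > tolerance,
    )


def elemental_balance_audit(model: Model) -> List[str]:
    """Ids of reactions with a non-zero elemental imbalance.

    Reactions containing any species without an elemental annotation are
    skipped (the audit only judges what it can see); massless species
    (empty composition) count as annotated.  Exchange reactions and
    biomass transporters are system boundaries — single-sided by design —
    and are not audited.
    """
    unbalanced: List[str] = []
    for reaction in model.reactions.values():
        if reaction.category in ("exchange", "biomass_transporter"):
            continue
        totals: Dict[str, Fraction] = {}
        skip = False
        for met_id, coeff in reaction.stoichiometry.items():
            composition = model.metabolites[met_id].elemental_composition
            if composition is None:
                skip = True
                break
            for element, count in composition.items():
                totals[element] = totals.get(element, Fraction(0)) + coeff * count
        if skip:
            continue
        if any(total != 0 for total in totals.values()):
            unbalanced.append(reaction.id)
    return unbalanced
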