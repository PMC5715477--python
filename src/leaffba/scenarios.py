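"""Scenario construction and parameter scans.

Covers the two scanned experimental axes of the analysis:

* **Vc/Vo scans** — RuBisCO carboxylation and oxygenation are replaced by a
  single lumped reaction whose stoichiometry is the exact rational
  combination ``a * carboxylation + b * oxygenation`` for a flux ratio
  ``a:b``, so one unit of lumped flux performs ``a`` carboxylations and
  ``b`` oxygenations (Vc = a*v, Vo = b*v exactly).
* **Light scans** — the photon influx is fixed at each grid value
  (default grid 0.33 to 10.00) under the additional constraint that cyclic
  photophosphorylation flux cannot exceed the non-cyclic flux.  The lowest
  feasible photon flux is located by bisection.

Derived per-solution metrics: quantum demand (photons per net CO2 fixed)
and the ATP:NADPH production ratio of the photophosphorylation reactions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .fba import ConstraintSet, FluxLP, FluxSolution, ObjectiveSpec
from .model import Model, ModelError, Reaction

__all__ = [
    "VcVoRatio",
    "ScanResult",
    "DerivedMetrics",
    "PhotophosphorylationYields",
    "DEFAULT_LIGHT_GRID",
    "default_light_grid",
    "lump_rubisco",
    "vcvo_scan",
    "light_scan",
    "min_feasible_photon_flux",
    "derived_metrics",
]


@dataclass(frozen=True)
class VcVoRatio:
    """RuBisCO carboxylation:oxygenation flux ratio ``a:b``."""

    carboxylation_parts: Fraction
    oxygenation_parts: Fraction

    def __post_init__(self) -> None:
        a = Fraction(self.carboxylation_parts)
        b = Fraction(self.oxygenation_parts)
        object.__setattr__(self, "carboxylation_parts", a)
        object.__setattr__(self, "oxygenation_parts", b)
        if a <= 0 or b < 0:
            raise ValueError("require carboxylation_parts > 0 and oxygenation_parts >= 0")

    @classmethod
    def from_string(cls, text: str) -> "VcVoRatio":
        """Parse ``"3:1"`` (or a bare number meaning ``a:1``)."""
        if ":" in text:
            a, _, b = text.partition(":")
            return cls(Fraction(a.strip()), Fraction(b.strip()))
        return cls(Fraction(text.strip()), Fraction(1))

    @property
    def value(self) -> float:
        """Vc/Vo as a float (inf for pure carboxylation)."""
        if self.oxygenation_parts == 0:
            return math.inf
        return float(self.carboxylation_parts / self.oxygenation_parts)

    def __str__(self) -> str:
        return f"{self.carboxylation_parts}:{self.oxygenation_parts}"


@dataclass
class ScanResult:
    """Ordered series of (parameter value, solution) points.

    ``points`` keeps every grid point including infeasible ones;
    :attr:`feasible_points` filters to optimal solutions, which is what the
    correlation module consumes.
    """

    parameter_name: str  # "vcvo" | "photon_flux"
    points: List[Tuple[float, FluxSolution]] = field(default_factory=list)

    @property
    def feasible_points(self) -> List[Tuple[float, FluxSolution]]:
        return [(p, s) for p, s in self.points if s.optimal]

    def flux_frame(self) -> pd.DataFrame:
        """Feasible points as a DataFrame (index: parameter, columns: reactions)."""
        rows = {p: s.fluxes for p, s in self.feasible_points}
        frame = pd.DataFrame.from_dict(rows, orient="index")
        frame.index.name = self.parameter_name
        return frame.sort_index()

    def series(self, reaction_id: str) -> List[Tuple[float, float]]:
        return [(p, s.fluxes[reaction_id]) for p, s in self.feasible_points
                if reaction_id in s.fluxes]


@dataclass
class PhotophosphorylationYields:
    """(ATP, NADPH) produced per unit flux of each light reaction.

    Defaults: non-cyclic photophosphorylation 3 ATP + 2 NADPH per unit,
    cyclic 2 ATP + 0 NADPH per unit.
    """

    noncyclic: Tuple[float, float] = (3.0, 2.0)
    cyclic: Tuple[float, float] = (2.0, 0.0)


@dataclass
class DerivedMetrics:
    """Quantum demand and ATP/NADPH totals for one solution.

    ``quantum_demand`` (photons per net CO2 fixed) is ``None`` when net CO2
    uptake is not positive; ``atp_nadph_ratio`` is ``None`` when no NADPH
    is produced.
    """

    quantum_demand: Optional[float]
    atp_total: float
    nadph_total: float
    atp_nadph_ratio: Optional[float]


def default_light_grid(start: float = 0.33, stop: float = 10.0, step: float = 0.01) -> List[float]:
    """The photon-flux grid, default 0.33 to 10.00 in steps of 0.01."""
    n = int(round((stop - start) / step))
    return [round(start + i * step, 10) for i in range(n + 1)]


DEFAULT_LIGHT_GRID = (0.33, 10.0, 0.01)


# ---------------------------------------------------------------------------
# RuBisCO lumping and the Vc/Vo scan
# ---------------------------------------------------------------------------

def lump_rubisco(
    model: Model,
    carb_id: str,
    oxy_id: str,
    ratio: VcVoRatio,
    lumped_id: Optional[str] = None,
) -> Tuple[Model, str]:
    """Replace carboxylation + oxygenation by one ratio-locked reaction.

    The lumped stoichiometry is the coefficient-wise exact-rational sum
    ``a * carb + b * oxy`` (no normalization by ``a + b``), added as an
    irreversible reaction; both originals are removed and everything else
    is untouched.  Returns the modified copy and the lumped reaction id.
    """
    if carb_id == oxy_id:
        raise ModelError("carboxylation and oxygenation ids must differ")
    for rid in (carb_id, oxy_id):
        if rid not in model.reactions:
            raise ModelError(f"no reaction {rid!r} in model")
    a = ratio.carboxylation_parts
    b = ratio.oxygenation_parts
    out = model.copy()
    carb = out.remove_reaction(carb_id)
    oxy = out.remove_reaction(oxy_id)
    stoich: Dict[str, Fraction] = {}
    for met, coeff in carb.stoichiometry.items():
        stoich[met] = stoich.get(met, Fraction(0)) + a * coeff
    for met, coeff in oxy.stoichiometry.items():
        stoich[met] = stoich.get(met, Fraction(0)) + b * coeff
    stoich = {m: c for m, c in stoich.items() if c != 0}
    if not stoich:
        raise ModelError("lumped RuBisCO reaction cancels to nothing")
    new_id = lumped_id or f"{carb_id}_lump_{a}to{b}".replace("/", "over")
    out.add_reaction(
        Reaction(
            id=new_id,
            stoichiometry=stoich,
            lower_bound=0.0,
            upper_bound=max(carb.upper_bound, oxy.upper_bound),
            category="metabolic",
            genes=tuple(dict.fromkeys(carb.genes + oxy.genes)),
        )
    )
    return out, new_id


def vcvo_scan(
    model: Model,
    constraints: ConstraintSet,
    ratios: Sequence[VcVoRatio],
    carb_id: str = "chl_RuBisCO_carb",
    oxy_id: str = "chl_RuBisCO_oxy",
    objective: Optional[ObjectiveSpec] = None,
) -> ScanResult:
    """Flux-minimization solutions across a series of Vc/Vo ratios.

    Points are solved independently and recorded in increasing-ratio order.
    In each stored solution the lumped flux ``v`` is unfolded back onto the
    original reaction ids as ``Vc = a*v`` and ``Vo = b*v`` so flux series
    stay comparable across ratios; infeasible points are recorded with
    their status and skipped by downstream consumers.
    """
    if not ratios:
        raise ValueError("ratios must be non-empty")
    result = ScanResult(parameter_name="vcvo")
    for ratio in sorted(ratios, key=lambda r: r.value):
        lumped, lumped_rid = lump_rubisco(model, carb_id, oxy_id, ratio)
        solution = FluxLP(lumped, constraints, objective).solve()
        if solution.optimal:
            v = solution.fluxes[lumped_rid]
            solution.fluxes[carb_id] = float(ratio.carboxylation_parts) * v
            solution.fluxes[oxy_id] = float(ratio.oxygenation_parts) * v
        result.points.append((ratio.value, solution))
    return result


# ---------------------------------------------------------------------------
# Light scan
# ---------------------------------------------------------------------------

def _with_photon_flux(
    constraints: ConstraintSet,
    photon_id: str,
    value: float,
    cyclic_id: Optional[str],
    noncyclic_id: Optional[str],
) -> ConstraintSet:
    fixed = dict(constraints.fixed_fluxes)
    fixed[photon_id] = value
    couplings = [dict(c) for c in constraints.linear_couplings]
    if cyclic_id is not None and noncyclic_id is not None:
        couplings.append({cyclic_id: 1.0, noncyclic_id: -1.0})
    return ConstraintSet(
        fixed_fluxes=fixed,
        bound_overrides=dict(constraints.bound_overrides),
        linear_couplings=couplings,
        maintenance_flux=constraints.maintenance_flux,
    )


def light_scan(
    model: Model,
    constraints: ConstraintSet,
    photon_grid: Sequence[float],
    cyclic_id: str = "chl_LightCyc",
    noncyclic_id: str = "chl_LightNonCyc",
    photon_id: str = "photon_ex",
    objective: Optional[ObjectiveSpec] = None,
) -> ScanResult:
    """Fix the photon influx at each grid value and minimize total flux.

    The coupling ``v_cyclic - v_noncyclic <= 0`` is enforced at every
    point.  Grid values must be strictly increasing; infeasible points
    (below the light-limitation threshold) are flagged, not fatal.
    """
    if photon_id not in model.reactions:
        raise ModelError(f"photon influx reaction {photon_id!r} not in model")
    if any(b <= a for a, b in zip(photon_grid, photon_grid[1:])):
        raise ValueError("photon grid must be strictly increasing")
    result = ScanResult(parameter_name="photon_flux")
    for value in photon_grid:
        point_constraints = _with_photon_flux(
            constraints, photon_id, value, cyclic_id, noncyclic_id
        )
        solution = FluxLP(model, point_constraints, objective).solve()
        result.points.append((value, solution))
    return result


def min_feasible_photon_flux(
    model: Model,
    constraints: ConstraintSet,
    bracket: Tuple[float, float],
    tolerance: float = 1e-4,
    cyclic_id: Optional[str] = "chl_LightCyc",
    noncyclic_id: Optional[str] = "chl_LightNonCyc",
    photon_id: str = "photon_ex",
) -> float:
    """Bisect for the photon flux below which no feasible solution exists.

    Requires an infeasible lower bracket and a feasible upper bracket; the
    returned value is feasible and within ``tolerance`` of the threshold.
    """
    lo, hi = bracket
    if not lo < hi:
        raise ValueError("bracket must satisfy lo < hi")

    def feasible_at(value: float) -> bool:
        point = _with_photon_flux(constraints, photon_id, value, cyclic_id, noncyclic_id)
        return FluxLP(model, point).feasible()

    if feasible_at(lo):
        raise ValueError(f"bracket invalid: feasible at lower end {lo}")
    if not feasible_at(hi):
        raise ValueError(f"bracket invalid: infeasible at upper end {hi}")
    while hi - lo > tolerance:
        mid = 0.5 * (lo + hi)
        if feasible_at(mid):
            hi = mid
        else:
            lo = mid
    return hi


# ---------------------------------------------------------------------------
# Derived metrics
# ---------------------------------------------------------------------------

def derived_metrics(
    solution: FluxSolution,
    photon_id: str = "photon_ex",
    co2_uptake_id: str = "co2_ex",
    yields: Optional[Mapping[str, Tuple[float, float]]] = None,
    cyclic_id: str = "chl_LightCyc",
    noncyclic_id: str = "chl_LightNonCyc",
) -> DerivedMetrics:
    """Quantum demand and ATP:NADPH ratio of one optimal solution.

    ``yields`` maps each photophosphorylation reaction id to its (ATP,
    NADPH) production per unit flux; when omitted the defaults of
    :class:`PhotophosphorylationYields` are attached to ``cyclic_id`` and
    ``noncyclic_id``.  Quantum demand is photon influx divided by net CO2
    uptake and is undefined (``None``) when CO2 uptake is not positive.
    """
    if yields is None:
        defaults = PhotophosphorylationYields()
        yields = {noncyclic_id: defaults.noncyclic, cyclic_id: defaults.cyclic}
    atp_total = 0.0
    nadph_total = 0.0
    for rid, (atp_y, nadph_y) in yields.items():
        flux = solution.fluxes.get(rid, 0.0)
        atp_total += atp_y * flux
        nadph_total += nadph_y * flux
    photon = solution.fluxes.get(photon_id, 0.0)
    co2 = solution.fluxes.get(co2_uptake_id, 0.0)
    quantum_demand = photon / co2 if co2 > 0 else None
    ratio = atp_total / nadph_total if nadph_total > 0 else None
    return DerivedMetrics(
        quantum_demand=quantum_demand,
        atp_total=atp_total,
        nadph_total=nadph_total,
        atp_nadph_ratio=ratio,
    )
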