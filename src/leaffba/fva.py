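"""Flux variability analysis at the flux-minimization optimum.

For each reaction the flux is maximized and minimized subject to the
original constraints plus the optimality side-constraint
``sum w |v| <= Z* (1 + optimum_tolerance) + eps``, where ``Z*`` is the
optimum of the primary weighted-L1 objective.  The resulting
``[fva_min, fva_max]`` interval, together with the single FBA vertex value,
supports the standard classification of reactions into essential, locked,
alternate-route and bidirectional groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

from .fba import ConstraintSet, FluxLP, ObjectiveSpec
from .model import Model

__all__ = ["FluxRange", "run_fva", "classify_ranges", "OPTIMUM_SLACK"]

#: Absolute slack added to the optimal objective so the FVA polytope keeps a
#: non-empty interior under floating-point round-off.
OPTIMUM_SLACK = 1e-7

FVA_CLASSES = (
    "essential_fixed",
    "essential_lower_bounded",
    "alternate_route",
    "reversible_bidirectional",
    "zero",
)


@dataclass
class FluxRange:
    """Allowable flux interval of one reaction at the optimum."""

    reaction_id: str
    fva_min: float
    fva_max: float
    fba_value: float


def run_fva(
    model: Model,
    constraints: Optional[ConstraintSet] = None,
    objective: Optional[ObjectiveSpec] = None,
    optimum_tolerance: float = 0.0,
    reactions: Optional[Sequence[str]] = None,
) -> List[FluxRange]:
    """Per-reaction min/max fluxes consistent with the weighted-L1 optimum.

    ``optimum_tolerance`` relaxes the optimality constraint by a relative
    fraction (0 = strict optimality); a very large value reduces FVA to
    plain bound-constrained min/max of each flux.  Per-reaction LP failures
    are recorded as NaN ranges rather than aborting the sweep.
    """
    lp = FluxLP(model, constraints, objective)
    base = lp.solve()
    if not base.optimal:
        raise RuntimeError(f"primary objective not solvable: status {base.status}")
    cap = (lp.weights, base.objective_value * (1.0 + optimum_tolerance) + OPTIMUM_SLACK)
    targets = list(reactions) if reactions is not None else list(lp.rxn_ids)
    ranges: List[FluxRange] = []
    for rid in targets:
        lo = lp.solve_linear({rid: 1.0}, maximize=False, optimum_cap=cap)
        hi = lp.solve_linear({rid: 1.0}, maximize=True, optimum_cap=cap)
        ranges.append(
            FluxRange(
                reaction_id=rid,
                fva_min=lo.fluxes.get(rid, float("nan")) if lo.optimal else float("nan"),
                fva_max=hi.fluxes.get(rid, float("nan")) if hi.optimal else float("nan"),
                fba_value=base.fluxes[rid],
            )
        )
    return ranges


def classify_ranges(
    ranges: Sequence[FluxRange], tolerance: float = 1e-6
) -> Dict[str, str]:
    """Deterministic FVA classification with ``|x| < tolerance`` read as 0.

    Precedence: zero > essential_fixed > reversible_bidirectional >
    essential_lower_bounded > alternate_route.  A reaction whose interval is
    bounded away from zero on the negative side is classed
    ``essential_lower_bounded`` as well (required in its reverse direction).
    """
    out: Dict[str, str] = {}
    for fr in ranges:
        lo, hi = fr.fva_min, fr.fva_max
        if abs(lo) < tolerance and abs(hi) < tolerance:
            cls = "zero"
        elif hi - lo < tolerance:
            cls = "essential_fixed"
        elif lo < -tolerance and hi > tolerance:
            cls = "reversible_bidirectional"
        elif lo > tolerance or hi < -tolerance:
            cls = "essential_lower_bounded"
        else:
            cls = "alternate_route"
        out[fr.reaction_id] = cls
    return out
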