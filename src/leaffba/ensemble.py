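"""Random-weight "enzymatic cost" ensembles and transporter mode analysis.

Cells shift between metabolic states as enzyme expression changes.  The
ensemble mimics this by re-solving the flux-minimization problem many times
with random objective weights: each iteration draws an independent uniform
weight on [0, 1000] for every enzymatic reaction, while transporters (both
categories), exchanges, photophosphorylation and the maintenance demand
keep a fixed baseline weight of 1.  A baseline of 0 would let transport
fluxes grow without objective cost and admit unbounded futile shuttling,
so the excluded reactions stay at 1.

Each optimal solution is reduced to a *mode signature*: the componentwise
sign (+/0/-) of a tracked reaction set under a dead-zone tolerance.
Distinct signatures are the "modes" of the tracked transporters; the
summary counts how often each mode occurred over the iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from .fba import ConstraintSet, FluxLP, FluxSolution
from .model import Model, ModelError

__all__ = [
    "WEIGHT_RANGE",
    "MODE_TOLERANCE",
    "EXCLUDED_CATEGORIES",
    "WeightDraw",
    "ModeSignature",
    "ModeSummary",
    "draw_weights",
    "compute_mode_signature",
    "run_ensemble",
    "default_exclusions",
]

#: Random weights are uniform on this closed range.
WEIGHT_RANGE = (0.0, 1000.0)
#: |flux| below this counts as "inactive" in a mode signature.
MODE_TOLERANCE = 1e-6
#: Categories whose reactions keep the baseline weight.
EXCLUDED_CATEGORIES = (
    "intracellular_transporter",
    "biomass_transporter",
    "exchange",
    "photophosphorylation",
    "maintenance",
)


@dataclass
class WeightDraw:
    """One seeded draw of per-reaction objective weights."""

    seed: int
    weights: Dict[str, float]
    excluded: frozenset

    def vector(self, reaction_ids: Sequence[str]) -> np.ndarray:
        return np.array([self.weights[r] for r in reaction_ids])


@dataclass(frozen=True)
class ModeSignature:
    """Ordered sign pattern of the tracked reactions."""

    tracked: Tuple[str, ...]
    signs: Tuple[str, ...]  # each "+", "0" or "-"

    def __post_init__(self) -> None:
        if len(self.tracked) != len(self.signs):
            raise ValueError("tracked ids and signs must align")

    def __str__(self) -> str:
        return "".join(self.signs)


@dataclass
class ModeSummary:
    """Mode frequencies over an ensemble run."""

    n_iterations: int
    mode_counts: Dict[ModeSignature, int] = field(default_factory=dict)
    infeasible_count: int = 0

    def frequencies(self) -> Dict[ModeSignature, float]:
        return {m: c / self.n_iterations for m, c in self.mode_counts.items()}

    def check_conservation(self) -> bool:
        return sum(self.mode_counts.values()) + self.infeasible_count == self.n_iterations


def default_exclusions(model: Model) -> Callable[[str], bool]:
    """Predicate: True for reactions that keep the baseline weight."""

    def excluded(reaction_id: str) -> bool:
        return model.reactions[reaction_id].category in EXCLUDED_CATEGORIES

    return excluded


def draw_weights(
    model: Model,
    seed: int,
    baseline: float = 1.0,
    exclusions: Optional[Callable[[str], bool]] = None,
) -> WeightDraw:
    """Draw uniform [0, 1000] weights for every non-excluded reaction.

    The generator is numpy's seeded PCG64 (``default_rng``); identical
    seeds give identical draws.  Continuous weights make objective ties
    measure-zero, so the optimizer's route choice is almost surely unique
    per draw.
    """
    if exclusions is None:
        exclusions = default_exclusions(model)
    rng = np.random.default_rng(seed)
    lo, hi = WEIGHT_RANGE
    reaction_ids = list(model.reactions)
    raw = rng.uniform(lo, hi, size=len(reaction_ids))
    weights: Dict[str, float] = {}
    excluded = set()
    for rid, value in zip(reaction_ids, raw):
        if exclusions(rid):
            weights[rid] = baseline
            excluded.add(rid)
        else:
            weights[rid] = float(value)
    return WeightDraw(seed=seed, weights=weights, excluded=frozenset(excluded))


def compute_mode_signature(
    solution: FluxSolution,
    tracked: Sequence[str],
    tolerance: float = MODE_TOLERANCE,
) -> ModeSignature:
    """Componentwise flux sign of the tracked reactions with a dead zone."""
    signs = []
    for rid in tracked:
        if rid not in solution.fluxes:
            raise ModelError(f"tracked reaction {rid!r} missing from solution")
        flux = solution.fluxes[rid]
        if abs(flux) < tolerance:
            signs.append("0")
        else:
            signs.append("+" if flux > 0 else "-")
    return ModeSignature(tracked=tuple(tracked), signs=tuple(signs))


def _iteration_seed(master_seed: int, iteration: int) -> int:
    """Counter-based per-iteration seed; order-independent and stable."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(iteration,))
    return int(ss.generate_state(1, dtype=np.uint32)[0])


def run_ensemble(
    model: Model,
    constraints: ConstraintSet,
    n: int,
    master_seed: int,
    tracked: Sequence[str],
    mode_tolerance: float = MODE_TOLERANCE,
    baseline: float = 1.0,
    exclusions: Optional[Callable[[str], bool]] = None,
    keep_solutions: bool = False,
) -> Tuple[ModeSummary, Optional[List[Tuple[int, FluxSolution]]]]:
    """Solve ``n`` randomly weighted flux minimizations and count modes.

    Iteration ``i`` draws its weights from a seed derived deterministically
    from ``(master_seed, i)``, so identical inputs give identical
    summaries regardless of execution order.  Solver failures increment
    ``infeasible_count`` and never abort the run.  With ``keep_solutions``
    the per-iteration archive of (seed, solution) pairs is returned too.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    for rid in tracked:
        if rid not in model.reactions:
            raise ModelError(f"tracked reaction {rid!r} not in model")
    if exclusions is None:
        exclusions = default_exclusions(model)
    lp = FluxLP(model, constraints)
    summary = ModeSummary(n_iterations=n)
    archive: List[Tuple[int, FluxSolution]] = []
    for i in range(n):
        seed = _iteration_seed(master_seed, i)
        draw = draw_weights(model, seed, baseline=baseline, exclusions=exclusions)
        solution = lp.solve(draw.vector(lp.rxn_ids))
        if not solution.optimal:
            summary.infeasible_count += 1
            continue
        signature = compute_mode_signature(solution, tracked, mode_tolerance)
        summary.mode_counts[signature] = summary.mode_counts.get(signature, 0) + 1
        if keep_solutions:
            archive.append((seed, solution))
    return summary, (archive if keep_solutions else None)
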