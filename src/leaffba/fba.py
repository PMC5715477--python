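"""Weighted L1-minimizing flux balance analysis.

The solver minimizes the weighted sum of absolute fluxes

    min  sum_i w_i |v_i|   s.t.   S v = 0,  LB <= v <= UB,
                                  fixed fluxes, linear couplings,
                                  maintenance demand

by the canonical split ``v = v+ - v-`` with ``v+, v- >= 0``, which is exact
for reversible reactions.  Linear programs are solved with scipy's HiGHS
backend using deterministic settings, so repeated solves of the same
problem return the same vertex.  Degenerate problems can have many optimal
vertices; any scientific claim about a *unique* flux therefore has to be
certified by flux variability analysis (see :mod:`leaffba.fva`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .model import Model, ModelError

__all__ = [
    "SOLVER_FEASIBILITY_TOL",
    "ZERO_FLUX_TOL",
    "ConstraintSet",
    "ObjectiveSpec",
    "FluxSolution",
    "FluxLP",
    "minimize_weighted_flux",
    "apply_biomass_composition",
]

#: LP-level primal/dual feasibility tolerance.
SOLVER_FEASIBILITY_TOL = 1e-9
#: Reported fluxes below this magnitude are treated as numerically zero.
ZERO_FLUX_TOL = 1e-9


@dataclass
class ConstraintSet:
    """Scenario constraints layered on top of a model's intrinsic bounds.

    ``fixed_fluxes`` pins reactions (biomass transporters, a fixed photon
    influx) to exact values; ``bound_overrides`` replaces bounds;
    ``linear_couplings`` is a list of ``{reaction_id: coeff}`` maps, each
    enforcing ``sum(coeff * v) <= 0`` (used for the cyclic <= non-cyclic
    photophosphorylation constraint); ``maintenance_flux`` is the demand
    through every reaction of category ``maintenance`` (default 0.1 flux
    unit).
    """

    fixed_fluxes: Dict[str, float] = field(default_factory=dict)
    bound_overrides: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    linear_couplings: List[Dict[str, float]] = field(default_factory=list)
    maintenance_flux: float = 0.1

    def __post_init__(self) -> None:
        if self.maintenance_flux < 0:
            raise ValueError("maintenance_flux must be non-negative")


@dataclass
class ObjectiveSpec:
    """Non-negative per-reaction weights of the L1 objective.

    Reactions absent from ``weights`` carry ``default_weight`` (1 for the
    plain total-flux objective).
    """

    weights: Dict[str, float] = field(default_factory=dict)
    default_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.default_weight < 0 or any(w < 0 for w in self.weights.values()):
            raise ValueError("objective weights must be non-negative")

    def weight_vector(self, reaction_ids: Sequence[str]) -> np.ndarray:
        return np.array([self.weights.get(r, self.default_weight) for r in reaction_ids])


@dataclass
class FluxSolution:
    """Result of one LP solve: reaction->flux map, objective, status."""

    fluxes: Dict[str, float]
    objective_value: float
    status: str  # optimal | infeasible | unbounded | error

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def __getitem__(self, reaction_id: str) -> float:
        return self.fluxes[reaction_id]


_STATUS = {0: "optimal", 1: "error", 2: "infeasible", 3: "unbounded", 4: "error"}


class FluxLP:
    """Split-variable LP over a model, reusable across repeated solves.

    The constraint matrices are assembled once; :meth:`solve` accepts a
    weight vector so ensemble runs only change the objective, and
    :meth:`variability` / :meth:`solve_linear` support FVA and feasibility
    probing on the same matrices.
    """

    def __init__(
        self,
        model: Model,
        constraints: Optional[ConstraintSet] = None,
        objective: Optional[ObjectiveSpec] = None,
    ):
        constraints = constraints or ConstraintSet()
        self.model = model
        self.constraints = constraints
        self.objective = objective or ObjectiveSpec()
        S, self.met_ids, self.rxn_ids = model.stoichiometric_matrix()
        self._index = {r: j for j, r in enumerate(self.rxn_ids)}
        n = len(self.rxn_ids)
        self.n = n
        S = sparse.csr_matrix(S)
        self.A_eq = sparse.hstack([S, -S], format="csr")
        self.b_eq = np.zeros(S.shape[0])

        lower = np.empty(n)
        upper = np.empty(n)
        for j, rid in enumerate(self.rxn_ids):
            reaction = model.reactions[rid]
            lb, ub = reaction.lower_bound, reaction.upper_bound
            if rid in constraints.bound_overrides:
                lb, ub = constraints.bound_overrides[rid]
            if reaction.category == "maintenance" and rid not in constraints.fixed_fluxes:
                lb = ub = constraints.maintenance_flux
            if rid in constraints.fixed_fluxes:
                value = constraints.fixed_fluxes[rid]
                if not (lb - 1e-9 <= value <= ub + 1e-9):
                    raise ModelError(
                        f"fixed flux {value} for {rid!r} outside bounds ({lb}, {ub})"
                    )
                lb = ub = value
            if lb > ub:
                raise ModelError(f"inverted effective bounds for {rid!r}")
            lower[j], upper[j] = lb, ub
        self.lower, self.upper = lower, upper
        # v = v+ - v-; the split bounds below make every v in [lb, ub]
        # representable and nothing outside it.
        self._var_bounds = np.concatenate(
            [
                np.stack([np.maximum(lower, 0.0), np.maximum(upper, 0.0)], axis=1),
                np.stack([np.maximum(-upper, 0.0), np.maximum(-lower, 0.0)], axis=1),
            ]
        )

        rows = []
        for coupling in constraints.linear_couplings:
            row = np.zeros(n)
            for rid, coeff in coupling.items():
                if rid not in self._index:
                    raise ModelError(f"coupling references unknown reaction {rid!r}")
                row[self._index[rid]] = coeff
            rows.append(np.concatenate([row, -row]))
        self._coupling_rows = np.array(rows) if rows else np.empty((0, 2 * n))

        self.weights = self.objective.weight_vector(self.rxn_ids)

    # -- low-level solves -------------------------------------------------

    def _linprog(self, c: np.ndarray, extra_ub=None, extra_b=None):
        if self._coupling_rows.size or extra_ub is not None:
            blocks = [self._coupling_rows] if self._coupling_rows.size else []
            b_ub = [np.zeros(self._coupling_rows.shape[0])] if self._coupling_rows.size else []
            if extra_ub is not None:
                blocks.append(np.atleast_2d(extra_ub))
                b_ub.append(np.atleast_1d(extra_b))
            A_ub = np.vstack(blocks)
            b_ub = np.concatenate(b_ub)
        else:
            A_ub = b_ub = None
        return linprog(
            c,
            A_ub=A_ub,
            b_ub=b_ub,
            A_eq=self.A_eq,
            b_eq=self.b_eq,
            bounds=self._var_bounds,
            method="highs",
            options={
                "presolve": True,
                "primal_feasibility_tolerance": SOLVER_FEASIBILITY_TOL,
                "dual_feasibility_tolerance": SOLVER_FEASIBILITY_TOL,
            },
        )

    def _net_fluxes(self, x: np.ndarray) -> List[float]:
        v = x[: self.n] - x[self.n :]
        v[np.abs(v) < ZERO_FLUX_TOL] = 0.0
        return v.tolist()

    # -- public API -------------------------------------------------------

    def solve(self, weights: Optional[np.ndarray] = None) -> FluxSolution:
        """Minimize ``sum w |v|`` and return one optimal vertex."""
        w = self.weights if weights is None else np.asarray(weights, dtype=float)
        result = self._linprog(np.concatenate([w, w]))
        status = _STATUS.get(result.status, "error")
        if status != "optimal":
            return FluxSolution({}, float("nan"), status)
        v = self._net_fluxes(result.x)
        return FluxSolution(dict(zip(self.rxn_ids, v)), float(result.fun), "optimal")

    def solve_linear(self, coefficients: Mapping[str, float], maximize: bool = False,
                     optimum_cap: Optional[Tuple[np.ndarray, float]] = None) -> FluxSolution:
        """Optimize a plain linear objective ``sum c_i v_i`` over the space.

        ``optimum_cap`` is an optional ``(weights, bound)`` pair enforcing
        ``sum w |v| <= bound`` (the FVA optimality side-constraint).
        """
        c = np.zeros(2 * self.n)
        for rid, coeff in coefficients.items():
            j = self._index[rid]
            c[j] = coeff
            c[self.n + j] = -coeff
        if maximize:
            c = -c
        extra_ub = extra_b = None
        if optimum_cap is not None:
            w, bound = optimum_cap
            extra_ub = np.concatenate([w, w])
            extra_b = bound
        result = self._linprog(c, extra_ub=extra_ub, extra_b=extra_b)
        status = _STATUS.get(result.status, "error")
        if status != "optimal":
            return FluxSolution({}, float("nan"), status)
        v = self._net_fluxes(result.x)
        objective = float(result.fun) * (-1.0 if maximize else 1.0)
        return FluxSolution(dict(zip(self.rxn_ids, v)), objective, "optimal")

    def feasible(self) -> bool:
        result = self._linprog(np.zeros(2 * self.n))
        return _STATUS.get(result.status, "error") == "optimal"

    def residual(self, solution: FluxSolution) -> float:
        """``max |S v|`` over internal metabolites for a solution."""
        v = np.array([solution.fluxes[r] for r in self.rxn_ids])
        S = self.A_eq[:, : self.n]
        return float(np.max(np.abs(S @ v))) if S.shape[0] else 0.0


def minimize_weighted_flux(
    model: Model,
    constraints: Optional[ConstraintSet] = None,
    objective: Optional[ObjectiveSpec] = None,
) -> FluxSolution:
    """Solve the flux-minimization FBA problem for one scenario.

    Returns a :class:`FluxSolution`; ``status`` is ``"infeasible"`` when the
    constraints cannot be satisfied and ``"unbounded"`` when bounds are
    misconfigured.  With multiple optima, the vertex returned is
    deterministic for a fixed model/constraint ordering but not unique.
    """
    return FluxLP(model, constraints, objective).solve()


def apply_biomass_composition(
    model: Model,
    composition: Mapping[str, float],
    maintenance_flux: float = 0.1,
) -> ConstraintSet:
    """Fix each biomass transporter at its composition flux.

    Every key must name a ``biomass_transporter`` reaction of the model and
    every flux must be non-negative; the maintenance demand rides along in
    the returned :class:`ConstraintSet`.
    """
    fixed: Dict[str, float] = {}
    for rid, flux in composition.items():
        reaction = model.reactions.get(rid)
        if reaction is None:
            raise ModelError(f"unknown biomass transporter {rid!r}")
        if reaction.category != "biomass_transporter":
            raise ModelError(f"reaction {rid!r} is not a biomass transporter")
        if flux < 0:
            raise ModelError(f"negative biomass flux for {rid!r}")
        fixed[rid] = float(flux)
    return ConstraintSet(fixed_fluxes=fixed, maintenance_flux=maintenance_flux)
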