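"""Flux-minimizing FBA: oracle fixtures, invariants, cobrapy cross-check."""

import numpy as np
import pytest

from leaffba.fba import (
    ConstraintSet,
    FluxLP,
    ObjectiveSpec,
    apply_biomass_composition,
    minimize_weighted_flux,
)
from leaffba.model import ModelError, write_sbml
from leaffba.synthetic import build_fixture_network, fixture_constraints


def _residual(model, solution):
    S, met_ids, rxn_ids = model.stoichiometric_matrix()
    v = np.array([solution.fluxes[r] for r in rxn_ids])
    return np.max(np.abs(S @ v)) if len(met_ids) else 0.0


class TestOracleFixtures:
    def test_chain_every_flux_one(self, chain3):
        model, manifest, constraints = chain3
        solution = minimize_weighted_flux(model, constraints)
        assert solution.optimal
        assert solution.objective_value == pytest.approx(3.0, abs=1e-6)
        for flux in solution.fluxes.values():
            assert flux == pytest.approx(1.0, abs=1e-6)
        assert _residual(model, solution) <= 1e-6

    def test_diamond_short_arm_wins(self, diamond):
        # route enumeration: in+R1+out = 3 vs in+R2+R3+out = 4
        model, manifest, constraints = diamond
        solution = minimize_weighted_flux(model, constraints)
        assert solution.objective_value == pytest.approx(3.0, abs=1e-6)
        assert solution.fluxes["R1"] == pytest.approx(1.0, abs=1e-6)
        assert solution.fluxes["R2"] == pytest.approx(0.0, abs=1e-6)
        assert solution.fluxes["R3"] == pytest.approx(0.0, abs=1e-6)

    def test_diamond_weight_flips_route(self, diamond):
        # weight 10 on the short arm: 2-step route total 4 < 12
        model, manifest, constraints = diamond
        objective = ObjectiveSpec(weights={"R1": 10.0})
        solution = minimize_weighted_flux(model, constraints, objective)
        assert solution.fluxes["R1"] == pytest.approx(0.0, abs=1e-6)
        assert solution.fluxes["R2"] == pytest.approx(1.0, abs=1e-6)
        assert solution.fluxes["R3"] == pytest.approx(1.0, abs=1e-6)
        assert solution.objective_value == pytest.approx(4.0, abs=1e-6)

    def test_infeasible_status(self, chain3):
        model, manifest, constraints = chain3
        constraints.bound_overrides["R1"] = (0.0, 0.5)  # demand 1 unreachable
        solution = minimize_weighted_flux(model, constraints)
        assert solution.status == "infeasible"


class TestInvariants:
    def test_zero_demand_zero_flux(self, diamond):
        model, _, _ = diamond
        solution = minimize_weighted_flux(model, ConstraintSet(maintenance_flux=0.0))
        assert solution.objective_value == pytest.approx(0.0, abs=1e-9)
        assert all(abs(v) <= 1e-9 for v in solution.fluxes.values())

    def test_weight_scale_invariance(self, diamond):
        model, manifest, constraints = diamond
        base = minimize_weighted_flux(model, constraints)
        scaled = minimize_weighted_flux(
            model, constraints, ObjectiveSpec(default_weight=7.0)
        )
        assert scaled.objective_value == pytest.approx(7 * base.objective_value, rel=1e-9)
        for rid in base.fluxes:
            assert scaled.fluxes[rid] == pytest.approx(base.fluxes[rid], abs=1e-8)

    def test_optimality_against_random_feasible_vertices(self, core_model,
                                                         core_model_constraints):
        """The returned optimum beats 100 random feasible vertices on sum w|v|."""
        model, _ = core_model
        lp = FluxLP(model, core_model_constraints)
        best = lp.solve()
        assert best.optimal
        rng = np.random.default_rng(42)
        for _ in range(100):
            coeffs = dict(zip(lp.rxn_ids, rng.normal(size=lp.n)))
            alt = lp.solve_linear(coeffs)
            if not alt.optimal:
                continue
            alt_cost = sum(abs(v) for v in alt.fluxes.values())
            assert best.objective_value <= alt_cost + 1e-6

    def test_steady_state_residual_on_core_model(self, core_model,
                                                 core_model_constraints):
        model, _ = core_model
        solution = minimize_weighted_flux(model, core_model_constraints)
        assert solution.optimal
        assert _residual(model, solution) <= 1e-6


class TestBiomassComposition:
    def test_fixed_flux_carried(self, core_model):
        model, _ = core_model
        constraints = apply_biomass_composition(
            model, {"biomass_GAP_tx": 0.02, "biomass_Suc_tx": 0.004,
                    "biomass_G3P_tx": 0.01}
        )
        solution = minimize_weighted_flux(model, constraints)
        assert solution.optimal
        assert solution.fluxes["biomass_GAP_tx"] == pytest.approx(0.02, abs=1e-9)
        assert solution.fluxes["ATPase_maintenance"] == pytest.approx(0.1, abs=1e-9)

    def test_unknown_and_negative_rejected(self, core_model):
        model, _ = core_model
        with pytest.raises(ModelError):
            apply_biomass_composition(model, {"nope_tx": 0.1})
        with pytest.raises(ModelError):
            apply_biomass_composition(model, {"biomass_GAP_tx": -0.1})
        with pytest.raises(ModelError):
            # a metabolic reaction is not a biomass transporter
            apply_biomass_composition(model, {"GAPDH": 0.1})

    def test_maintenance_only_photon_demand(self):
        """With no biomass, photons are drawn only to drive the maintenance
        ATPase; the toy yields 1 ATP per 2 photons, so 0.1 ATP costs 0.2
        photons."""
        from fractions import Fraction

        from leaffba.model import Model, Reaction

        model = Model("toy")
        model.add_reaction(Reaction(id="photon_ex", stoichiometry={"Photon": Fraction(1)},
                                    category="exchange"))
        model.add_reaction(Reaction(
            id="photosynthesis",
            stoichiometry={"Photon": Fraction(-2), "ADP": Fraction(-1),
                           "ATP": Fraction(1)},
        ))
        model.add_reaction(Reaction(
            id="ATPase_maintenance",
            stoichiometry={"ATP": Fraction(-1), "ADP": Fraction(1)},
            category="maintenance",
        ))
        solution = minimize_weighted_flux(model, ConstraintSet(maintenance_flux=0.1))
        assert solution.optimal
        assert solution.fluxes["photon_ex"] == pytest.approx(0.2, abs=1e-9)

    def test_excess_demand_infeasible(self, core_model):
        model, _ = core_model
        constraints = apply_biomass_composition(model, {"biomass_GAP_tx": 0.02})
        constraints.fixed_fluxes["photon_ex"] = 0.01  # far below requirement
        solution = minimize_weighted_flux(model, constraints)
        assert solution.status == "infeasible"


class TestCobraCrossCheck:
    def test_pfba_objective_agrees_on_core_model(self, tmp_path, core_model,
                                                 core_model_constraints):
        """Independent oracle: cobrapy pFBA on the SBML export reproduces the
        minimal total flux under the same fixed demands."""
        cobra = pytest.importorskip("cobra")
        from cobra.flux_analysis import pfba

        model, _ = core_model
        ours = minimize_weighted_flux(model, core_model_constraints)
        assert ours.optimal

        path = write_sbml(model, tmp_path / "core.xml")
        cmodel = cobra.io.read_sbml_model(str(path))  # cobra strips R_/M_ prefixes
        for rid, value in core_model_constraints.fixed_fluxes.items():
            rxn = cmodel.reactions.get_by_id(rid)
            rxn.lower_bound = rxn.upper_bound = value
        maint = cmodel.reactions.get_by_id("ATPase_maintenance")
        maint.lower_bound = maint.upper_bound = core_model_constraints.maintenance_flux
        cmodel.objective = {}
        cobra_solution = pfba(cmodel)
        assert cobra_solution.objective_value == pytest.approx(
            ours.objective_value, rel=1e-5
        )
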