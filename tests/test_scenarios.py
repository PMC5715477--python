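"""RuBisCO lumping, scans, feasibility bisection, derived metrics."""

from fractions import Fraction

import pytest

from leaffba.consistency import elemental_balance_audit
from leaffba.fba import ConstraintSet, FluxSolution, minimize_weighted_flux
from leaffba.model import Model, Reaction
from leaffba.scenarios import (
    VcVoRatio,
    default_light_grid,
    derived_metrics,
    light_scan,
    lump_rubisco,
    min_feasible_photon_flux,
    vcvo_scan,
)
from leaffba.synthetic import build_fixture_network, fixture_constraints


CARB = {"RuBP": Fraction(-1), "CO2": Fraction(-1), "PGA": Fraction(2)}
OXY = {"RuBP": Fraction(-1), "O2": Fraction(-1), "PGA": Fraction(1),
       "PGLY": Fraction(1)}


def _two_reaction_model():
    model = Model("rubisco")
    model.add_reaction(Reaction(id="carb", stoichiometry=CARB))
    model.add_reaction(Reaction(id="oxy", stoichiometry=OXY))
    return model


def _lump_oracle(a, b):
    """Independent coefficient-wise weighted sum."""
    out = {}
    for met in set(CARB) | set(OXY):
        coeff = a * CARB.get(met, 0) + b * OXY.get(met, 0)
        if coeff != 0:
            out[met] = coeff
    return out


class TestLumping:
    def test_pure_carboxylation_identity(self):
        model = _two_reaction_model()
        lumped, rid = lump_rubisco(model, "carb", "oxy",
                                   VcVoRatio(Fraction(1), Fraction(0)))
        assert lumped.reactions[rid].stoichiometry == CARB
        assert "carb" not in lumped.reactions and "oxy" not in lumped.reactions

    def test_one_to_one_direct_sum(self):
        model = _two_reaction_model()
        lumped, rid = lump_rubisco(model, "carb", "oxy",
                                   VcVoRatio(Fraction(1), Fraction(1)))
        assert lumped.reactions[rid].stoichiometry == {
            "RuBP": Fraction(-2), "CO2": Fraction(-1), "O2": Fraction(-1),
            "PGA": Fraction(3), "PGLY": Fraction(1),
        }

    @pytest.mark.parametrize("a,b", [(1, 1), (2, 1), (3, 1), (4, 1), (5, 1),
                                     (3, 2), (7, 3)])
    def test_weighted_sum_oracle_exact(self, a, b):
        model = _two_reaction_model()
        ratio = VcVoRatio(Fraction(a), Fraction(b))
        lumped, rid = lump_rubisco(model, "carb", "oxy", ratio)
        assert lumped.reactions[rid].stoichiometry == _lump_oracle(
            Fraction(a), Fraction(b)
        )

    def test_lumping_linearity(self):
        """lump(a:b) equals b * lump(a/b : 1) coefficient-wise."""
        model = _two_reaction_model()
        a, b = Fraction(3), Fraction(2)
        whole, rid1 = lump_rubisco(model, "carb", "oxy", VcVoRatio(a, b))
        unit, rid2 = lump_rubisco(model, "carb", "oxy", VcVoRatio(a / b, Fraction(1)))
        for met, coeff in whole.reactions[rid1].stoichiometry.items():
            assert coeff == b * unit.reactions[rid2].stoichiometry[met]

    @pytest.mark.parametrize("a,b", [(1, 1), (3, 1), (5, 1)])
    def test_lumped_reaction_conserves_atoms(self, core_model, a, b):
        model, _ = core_model
        lumped, rid = lump_rubisco(model, "chl_RuBisCO_carb", "chl_RuBisCO_oxy",
                                   VcVoRatio(Fraction(a), Fraction(b)))
        assert rid not in elemental_balance_audit(lumped)

    def test_missing_reaction_errors(self, core_model):
        from leaffba.model import ModelError

        model, _ = core_model
        with pytest.raises(ModelError):
            lump_rubisco(model, "nope", "chl_RuBisCO_oxy",
                         VcVoRatio(Fraction(1), Fraction(1)))

    def test_zero_ratio_rejected(self):
        with pytest.raises(ValueError):
            VcVoRatio(Fraction(0), Fraction(0))


class TestVcVoScan:
    def test_points_ordered_and_conserving(self, core_model, core_model_constraints):
        import numpy as np

        model, _ = core_model
        ratios = [VcVoRatio.from_string(s) for s in ("5:1", "1:1", "3:1")]
        scan = vcvo_scan(model, core_model_constraints, ratios)
        params = [p for p, _ in scan.points]
        assert params == sorted(params) == [1.0, 3.0, 5.0]
        S, _, rxn_ids = model.stoichiometric_matrix()
        for p, solution in scan.points:
            assert solution.optimal
            # carb/oxy are unfolded from the lumped flux at the exact ratio
            assert solution.fluxes["chl_RuBisCO_carb"] == pytest.approx(
                p * solution.fluxes["chl_RuBisCO_oxy"], abs=1e-8
            )

    def test_requires_ratios(self, core_model, core_model_constraints):
        model, _ = core_model
        with pytest.raises(ValueError):
            vcvo_scan(model, core_model_constraints, [])


class TestLightScan:
    def test_below_threshold_infeasible_and_coupling_holds(
        self, core_model, core_model_constraints
    ):
        model, _ = core_model
        grid = [0.5, 1.0, 2.0, 4.0, 8.0]
        scan = light_scan(model, core_model_constraints, grid)
        statuses = {p: s.status for p, s in scan.points}
        assert statuses[0.5] == "infeasible"  # below the light-limitation edge
        assert statuses[8.0] == "optimal"
        for p, s in scan.feasible_points:
            assert s.fluxes["chl_LightCyc"] <= s.fluxes["chl_LightNonCyc"] + 1e-9
            assert s.fluxes["photon_ex"] == pytest.approx(p, abs=1e-9)

    def test_grid_must_increase(self, core_model, core_model_constraints):
        model, _ = core_model
        with pytest.raises(ValueError):
            light_scan(model, core_model_constraints, [1.0, 1.0])

    def test_default_grid_matches_convention(self):
        grid = default_light_grid()
        assert grid[0] == pytest.approx(0.33)
        assert grid[-1] == pytest.approx(10.0)
        assert grid[1] - grid[0] == pytest.approx(0.01)

    def test_objective_non_increasing_in_photon_cap(self, core_model,
                                                    core_model_constraints):
        """More available light can only help when the photon influx is an
        upper bound rather than fixed."""
        import copy

        model, _ = core_model
        objectives = []
        for cap in (2.0, 4.0, 8.0):
            constraints = copy.deepcopy(core_model_constraints)
            constraints.bound_overrides["photon_ex"] = (0.0, cap)
            solution = minimize_weighted_flux(model, constraints)
            assert solution.optimal
            objectives.append(solution.objective_value)
        assert objectives[0] >= objectives[1] - 1e-7 >= objectives[2] - 2e-7


class TestMinFeasiblePhotonFlux:
    def test_photon_toy_threshold(self):
        # 2 photons per biomass unit at demand 0.5 -> threshold exactly 1.0
        model, manifest = build_fixture_network(
            "photon_toy", photons_per_biomass=2, demand=0.5
        )
        constraints = fixture_constraints(manifest)
        threshold = min_feasible_photon_flux(
            model, constraints, bracket=(0.0, 5.0), tolerance=1e-4,
            cyclic_id=None, noncyclic_id=None,
        )
        assert threshold == pytest.approx(1.0, abs=1e-4)

    def test_agrees_with_brute_force_grid(self):
        model, manifest = build_fixture_network(
            "photon_toy", photons_per_biomass=3, demand=0.4
        )
        constraints = fixture_constraints(manifest)
        threshold = min_feasible_photon_flux(
            model, constraints, bracket=(0.0, 5.0), tolerance=1e-4,
            cyclic_id=None, noncyclic_id=None,
        )
        # brute force: first feasible grid value at 1e-3 spacing
        from leaffba.fba import FluxLP
        from leaffba.scenarios import _with_photon_flux

        grid_first = None
        value = 1.19
        while value <= 1.3:
            cs = _with_photon_flux(constraints, "photon_ex", round(value, 4),
                                   None, None)
            if FluxLP(model, cs).feasible():
                grid_first = round(value, 4)
                break
            value += 1e-3
        assert grid_first is not None
        assert abs(threshold - grid_first) <= 2e-3

    def test_invalid_bracket(self):
        model, manifest = build_fixture_network("photon_toy", demand=0.5)
        constraints = fixture_constraints(manifest)
        with pytest.raises(ValueError):
            min_feasible_photon_flux(model, constraints, bracket=(2.0, 5.0),
                                     cyclic_id=None, noncyclic_id=None)


class TestDerivedMetrics:
    def test_ratio_arithmetic(self):
        solution = FluxSolution({"nc": 1.0, "cyc": 0.0, "photon_ex": 8.0,
                                 "co2_ex": 1.0}, 0.0, "optimal")
        metrics = derived_metrics(solution, yields={"nc": (3, 2), "cyc": (2, 0)})
        assert metrics.atp_total == pytest.approx(3.0)
        assert metrics.nadph_total == pytest.approx(2.0)
        assert metrics.atp_nadph_ratio == pytest.approx(1.5)
        assert metrics.quantum_demand == pytest.approx(8.0)

    def test_undefined_cases_flagged(self):
        solution = FluxSolution({"nc": 0.0, "cyc": 1.0, "photon_ex": 2.0,
                                 "co2_ex": 0.0}, 0.0, "optimal")
        metrics = derived_metrics(solution, yields={"nc": (3, 2), "cyc": (2, 0)})
        assert metrics.quantum_demand is None
        assert metrics.nadph_total == 0.0
        assert metrics.atp_nadph_ratio is None

    def test_quantum_demand_falls_with_vcvo_on_core_model(
        self, core_model, core_model_constraints
    ):
        """Higher carboxylation share -> fewer photons per CO2 fixed."""
        model, _ = core_model
        scan = vcvo_scan(model, core_model_constraints,
                         [VcVoRatio.from_string(s) for s in ("1:1", "3:1", "5:1")])
        qd = [derived_metrics(s).quantum_demand for _, s in scan.feasible_points]
        assert all(q is not None for q in qd)
        assert qd[0] > qd[1] > qd[2]
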