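"""Domain types, equation parsing, tabular/SBML round trips, statistics."""

from fractions import Fraction

import pytest
from hypothesis import given, settings, strategies as st

from leaffba.model import (
    EquationError,
    Metabolite,
    Model,
    ModelError,
    Reaction,
    format_reaction_equation,
    infer_compartment,
    load_model,
    model_statistics,
    parse_reaction_equation,
    read_sbml,
    write_model,
    write_sbml,
)


class TestEquationParser:
    @pytest.mark.parametrize(
        "text,expected,reversible",
        [
            ("A + 2 B -> C", {"A": -1, "B": -2, "C": 1}, False),
            ("A <> B", {"A": -1, "B": 1}, True),
            ("-> B", {"B": 1}, False),
            ("B ->", {"B": -1}, False),
            ("1/2 A -> B", {"A": Fraction(-1, 2), "B": 1}, False),
            ("2 A -> A + C", {"A": -1, "C": 1}, False),  # both-side summing
        ],
    )
    def test_parses(self, text, expected, reversible):
        stoich, rev = parse_reaction_equation(text)
        assert stoich == {k: Fraction(v) for k, v in expected.items()}
        assert rev is reversible

    @pytest.mark.parametrize(
        "text", ["A -> A", "A = B", "A -> B -> C", "A + -> B", "2 -> B"]
    )
    def test_rejects_malformed(self, text):
        with pytest.raises(EquationError):
            parse_reaction_equation(text)

    @given(
        st.dictionaries(
            st.sampled_from(["A", "B", "chl_X", "mit_Y", "per_Z"]),
            st.fractions(min_value=-5, max_value=5).filter(lambda f: f != 0),
            min_size=1,
            max_size=5,
        ),
        st.booleans(),
    )
    @settings(max_examples=100, deadline=None)
    def test_unparse_parse_inverse(self, stoich, reversible):
        text = format_reaction_equation(stoich, reversible)
        parsed, rev = parse_reaction_equation(text)
        assert parsed == stoich
        assert rev is reversible


class TestCompartments:
    @pytest.mark.parametrize(
        "met_id,compartment",
        [
            ("GAP", "cytosol"),
            ("chl_GAP", "chloroplast"),
            ("mit_NADH", "mitochondrion"),
            ("per_H2O2", "peroxisome"),
            ("ext_CO2", "external"),
        ],
    )
    def test_prefix_inference(self, met_id, compartment):
        assert infer_compartment(met_id) == compartment
        assert Metabolite(id=met_id).compartment == compartment


class TestReactionInvariants:
    def test_inverted_bounds_rejected(self):
        with pytest.raises(ModelError):
            Reaction(id="r", stoichiometry={"A": Fraction(-1)},
                     lower_bound=1.0, upper_bound=-1.0)

    def test_reversible_iff_bounds_straddle_zero(self):
        r = Reaction(id="r", stoichiometry={"A": Fraction(-1), "B": Fraction(1)},
                     lower_bound=-10, upper_bound=10)
        assert r.reversible
        r2 = Reaction(id="r2", stoichiometry={"A": Fraction(-1), "B": Fraction(1)},
                      lower_bound=0, upper_bound=10)
        assert not r2.reversible

    def test_duplicate_reaction_rejected(self):
        model = Model("m")
        model.add_reaction(Reaction(id="r", stoichiometry={"A": Fraction(1)}))
        with pytest.raises(ModelError):
            model.add_reaction(Reaction(id="r", stoichiometry={"A": Fraction(1)}))


class TestTabularIO:
    def _chain_file(self, tmp_path, extra_row=None):
        rows = [
            "reaction_id\tequation\tlower_bound\tupper_bound\tcategory\tgenes",
            "in_ex\t-> A\t0\t\texchange\t",
            "R1\tA -> B\t\t\t\tg1|g2",
            "out_ex\tB ->\t0\t\texchange\t",
        ]
        if extra_row:
            rows.append(extra_row)
        path = tmp_path / "chain.tsv"
        path.write_text("\n".join(rows) + "\n")
        return path

    def test_load_counts_and_defaults(self, tmp_path):
        model = load_model(self._chain_file(tmp_path))
        assert len(model.reactions) == 3
        assert len(model.metabolites) == 2
        r1 = model.reactions["R1"]
        assert (r1.lower_bound, r1.upper_bound) == (0.0, 1.0e6)
        assert r1.category == "metabolic"  # inferred fallback
        assert r1.genes == ("g1", "g2")

    def test_duplicate_id_error(self, tmp_path):
        path = self._chain_file(tmp_path, "R1\tA -> B\t\t\t\t")
        with pytest.raises(ModelError):
            load_model(path)

    def test_tabular_round_trip(self, tmp_path, core_model):
        model, _ = core_model
        path = write_model(model, tmp_path / "core.tsv")
        reloaded = load_model(path)
        assert set(reloaded.reactions) == set(model.reactions)
        for rid, reaction in model.reactions.items():
            other = reloaded.reactions[rid]
            assert other.stoichiometry == reaction.stoichiometry
            assert other.lower_bound == reaction.lower_bound
            assert other.upper_bound == reaction.upper_bound
            assert other.category == reaction.category
        for mid, met in model.metabolites.items():
            assert reloaded.metabolites[mid].elemental_composition == met.elemental_composition

    def test_round_trip_is_deterministic(self, tmp_path, core_model):
        model, _ = core_model
        a = write_model(model, tmp_path / "a.tsv").read_text()
        b = write_model(model, tmp_path / "b.tsv").read_text()
        assert a == b


class TestSbmlIO:
    def test_sbml_round_trip(self, tmp_path, core_model):
        model, _ = core_model
        path = write_sbml(model, tmp_path / "core.xml")
        reloaded = read_sbml(path)
        assert set(reloaded.reactions) == set(model.reactions)
        for rid, reaction in model.reactions.items():
            other = reloaded.reactions[rid]
            assert other.stoichiometry == reaction.stoichiometry, rid
            assert other.lower_bound == pytest.approx(reaction.lower_bound)
            assert other.upper_bound == pytest.approx(reaction.upper_bound)
            assert other.category == reaction.category

    def test_sbml_preserves_fractional_coefficients(self, tmp_path):
        model = Model("frac")
        model.add_reaction(
            Reaction(id="r", stoichiometry={"A": Fraction(-1, 3), "B": Fraction(2, 7)})
        )
        reloaded = read_sbml(write_sbml(model, tmp_path / "f.xml"))
        assert reloaded.reactions["r"].stoichiometry == {
            "A": Fraction(-1, 3), "B": Fraction(2, 7)
        }


class TestStatistics:
    def test_empty_model_all_zero(self):
        stats = model_statistics(Model("empty"))
        assert stats.reaction_count_total == 0
        assert stats.metabolite_count_total == 0
        assert all(v == 0 for v in stats.per_compartment_counts.values())
        assert all(v == 0 for v in stats.per_category_counts.values())

    def test_core_model_matches_manifest(self, core_model):
        model, manifest = core_model
        stats = model_statistics(model)
        assert stats.reaction_count_total == manifest.reaction_count_total
        assert stats.metabolite_count_total == manifest.metabolite_count_total
        assert stats.per_compartment_counts == manifest.per_compartment_counts
        assert stats.per_category_counts == manifest.per_category_counts

    def test_loaded_file_matches_manifest(self, tmp_path, core_model):
        model, manifest = core_model
        reloaded = load_model(write_model(model, tmp_path / "core.tsv"))
        stats = model_statistics(reloaded)
        assert stats.reaction_count_total == manifest.reaction_count_total
        assert stats.per_category_counts == manifest.per_category_counts

    def test_compartment_counts_sum_to_metabolic_total(self, core_model):
        model, _ = core_model
        stats = model_statistics(model)
        assert (
            sum(stats.per_compartment_counts.values())
            == stats.per_category_counts["metabolic"]
        )
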