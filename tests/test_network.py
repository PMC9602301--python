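"""Parsing, serialization, stoichiometry, triggering and closure."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from worldviews import (
    NetworkError,
    ParseError,
    Reaction,
    ReactionNetwork,
    apply_process,
    closure,
    is_closed,
    network_from_json,
    network_to_json,
    parse_network,
    serialize_network,
    stoichiometric_matrix,
    triggered_reactions,
)

SIMPLE_SPECIES = ("S", "U", "D", "s", "p")


class TestParsing:
    def test_worked_example_document(self, worked_net):
        assert worked_net.species == ("s1", "s2")
        assert worked_net.n_reactions == 2
        r1, r2 = worked_net.reactions
        assert r1.reactants == {} and r1.products == {"s1": 1}
        assert r2.reactants == {"s1": 1, "s2": 1} and r2.products == {"s2": 2}

    def test_empty_document(self):
        net = parse_network("")
        assert net.species == () and net.reactions == ()

    def test_single_theme_document_matches_builder(self, simple_net):
        text = """\
        r0: D -> U ; k=0.1
        r1: U -> S ; k=0.1
        r2: S + s -> S + 2 s ; k=0.2
        r3: D + p -> D + 2 p ; k=0.3
        r4: S + p -> U + p ; k=0.3
        r5: U + p -> D + p ; k=0.3
        r6: D + s -> U + s ; k=0.3
        r7: U + s -> S + s ; k=0.3
        r8: 2 p -> p ; k=0.15
        r9: 2 s -> s ; k=0.15
        """
        net = parse_network("\n".join(l.strip() for l in text.splitlines()))
        assert set(net.species) == set(SIMPLE_SPECIES)
        assert net.n_reactions == 10
        for got, ref in zip(net.reactions, simple_net.reactions):
            assert got.id == ref.id
            assert got.reactants == ref.reactants
            assert got.products == ref.products
            assert got.rate_constant == ref.rate_constant

    @pytest.mark.parametrize(
        "doc, fragment",
        [
            ("A + B", "->"),                      # no arrow
            ("A -> B ; k=fast", "rate"),          # bad rate constant
            ("x: A -> B\nx: B -> A", "duplicate"),  # duplicate id
            ("2A -> B", "term"),                  # coefficient glued to name
        ],
    )
    def test_malformed_lines_name_the_line(self, doc, fragment):
        with pytest.raises(ParseError) as err:
            parse_network(doc)
        assert "line" in str(err.value)
        assert fragment in str(err.value)

    def test_text_round_trip(self, simple_net, worked_net, two_theme_net):
        for net in (simple_net, worked_net, two_theme_net, parse_network("")):
            back = parse_network(serialize_network(net))
            assert back.species == net.species
            assert back.tags == net.tags
            for a, b in zip(back.reactions, net.reactions):
                assert (a.id, a.reactants, a.products, a.rate_constant) == (
                    b.id, b.reactants, b.products, b.rate_constant
                )

    def test_json_round_trip(self, simple_net, two_theme_net):
        for net in (simple_net, two_theme_net):
            back = network_from_json(network_to_json(net))
            assert back.species == net.species
            assert back.tags == net.tags
            assert all(
                (a.id, a.reactants, a.products, a.rate_constant)
                == (b.id, b.reactants, b.products, b.rate_constant)
                for a, b in zip(back.reactions, net.reactions)
            )

    def test_undeclared_species_rejected(self):
        with pytest.raises(NetworkError):
            ReactionNetwork(("A",), (Reaction("r", {"A": 1}, {"B": 1}),))

    def test_empty_reaction_rejected(self):
        with pytest.raises(NetworkError):
            Reaction("r", {}, {})


class TestStoichiometry:
    def test_worked_example_matrix(self, worked_net):
        S = stoichiometric_matrix(worked_net)
        # r1 column (+1, 0); r2 column (-1, +1) over (s1, s2)
        assert S.tolist() == [[1, -1], [0, 1]]

    def test_catalyst_column_is_zero(self, simple_net):
        S = stoichiometric_matrix(simple_net)
        i = simple_net.reaction_index("r2")  # S + s -> S + 2 s
        assert S[simple_net.species_index("S"), i] == 0
        assert S[simple_net.species_index("s"), i] == 1

    def test_untouched_species_row_entry_zero(self, simple_net):
        S = stoichiometric_matrix(simple_net)
        # r0: D -> U touches neither s nor p
        i = simple_net.reaction_index("r0")
        assert S[simple_net.species_index("s"), i] == 0
        assert S[simple_net.species_index("p"), i] == 0

    def test_apply_process_worked_values(self, worked_net):
        assert apply_process(worked_net, [2, 1]).tolist() == [1, 1]
        assert apply_process(worked_net, [1, 2]).tolist() == [-1, 2]
        assert apply_process(worked_net, [0, 0]).tolist() == [0, 0]

    def test_apply_process_length_mismatch(self, worked_net):
        with pytest.raises(NetworkError):
            apply_process(worked_net, [1, 2, 3])

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        v1=st.lists(st.floats(0, 10, allow_nan=False), min_size=10, max_size=10),
        v2=st.lists(st.floats(0, 10, allow_nan=False), min_size=10, max_size=10),
    )
    def test_apply_process_is_linear(self, v1, v2):
        from worldviews import build_simple_model

        net = build_simple_model()
        lhs = apply_process(net, np.add(v1, v2))
        rhs = apply_process(net, v1) + apply_process(net, v2)
        assert np.allclose(lhs, rhs, atol=1e-12)


class TestClosure:
    def test_triggered_reactions_examples(self, simple_net):
        assert triggered_reactions(simple_net, {"S", "s"}) == {"r2", "r9"}
        assert triggered_reactions(simple_net, set()) == set()
        assert triggered_reactions(simple_net, set(SIMPLE_SPECIES)) == {
            f"r{i}" for i in range(10)
        }

    def test_reactant_free_reaction_triggered_by_empty_set(self, worked_net):
        assert "r1" in triggered_reactions(worked_net, set())

    def test_unknown_species_rejected(self, simple_net):
        with pytest.raises(NetworkError):
            triggered_reactions(simple_net, {"S", "nope"})

    def test_is_closed_examples(self, simple_net):
        assert not is_closed(simple_net, {"p", "U", "D"})  # r0 produces... r1 gives S
        assert is_closed(simple_net, {"p", "S", "U", "D"})
        assert is_closed(simple_net, set())

    def test_closure_examples(self, simple_net):
        assert closure(simple_net, {"p", "U", "D"}) == {"p", "S", "U", "D"}
        assert closure(simple_net, set()) == frozenset()
        closed = frozenset({"S", "s"})
        assert closure(simple_net, closed) == closed

    def test_closed_iff_closure_fixpoint_exhaustive(self, simple_net):
        """For all 2^5 subsets: is_closed(X) holds exactly when closure(X) = X."""
        import itertools

        for r in range(6):
            for X in itertools.combinations(SIMPLE_SPECIES, r):
                X = frozenset(X)
                assert is_closed(simple_net, X) == (closure(simple_net, X) == X)

    @settings(derandomize=True, max_examples=80, deadline=None)
    @given(
        X=st.sets(st.sampled_from(SIMPLE_SPECIES)),
        Y=st.sets(st.sampled_from(SIMPLE_SPECIES)),
    )
    def test_closure_is_a_closure_operator(self, X, Y):
        """Extensive, idempotent and monotone on the single-theme network."""
        from worldviews import build_simple_model

        net = build_simple_model()
        cX = closure(net, X)
        assert X <= cX
        assert closure(net, cX) == cX
        if X <= Y:
            assert cX <= closure(net, Y)
        assert triggered_reactions(net, X) <= triggered_reactions(net, X | Y)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(data=st.data())
    def test_closure_properties_on_two_theme_network(self, data, two_theme_net):
        species = two_theme_net.species
        X = data.draw(st.sets(st.sampled_from(species), max_size=6))
        cX = closure(two_theme_net, X)
        assert X <= cX
        assert closure(two_theme_net, cX) == cX
        assert is_closed(two_theme_net, cX)
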