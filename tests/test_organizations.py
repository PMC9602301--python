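"""Self-maintenance, organization enumeration and the Hasse diagram."""

import itertools

import numpy as np
import pytest

from worldviews import (
    NotClosedError,
    closure,
    enumerate_organizations,
    hasse_diagram,
    is_closed,
    is_self_maintaining,
    lattice_to_dot,
    organizations_report,
    reactive_trigger_set,
    self_maintaining_closure,
    triggered_reactions,
)

SIMPLE_ORGS = [
    frozenset({"S", "s"}),
    frozenset({"S", "U", "D", "p"}),
    frozenset({"S", "U", "D", "s", "p"}),
]


def all_closed_subsets(net):
    out = []
    for r in range(net.n_species + 1):
        for X in itertools.combinations(net.species, r):
            X = frozenset(X)
            if is_closed(net, X):
                out.append(X)
    return out


# ---------------------------------------------------------------------------
# independent exact oracle: rational simplex feasibility (sympy), plus a
# literal small-grid search where that is tractable
# ---------------------------------------------------------------------------


def sm_oracle_exact(net, X):
    """Exact rational feasibility of {v_i >= 1 on R_X, (S v)_j >= 0 for j in X}."""
    from sympy import Rational, symbols
    from sympy.solvers.simplex import InfeasibleLPError, lpmin

    trig = sorted(triggered_reactions(net, X))
    if not trig:
        return True
    cols = [net.reaction_index(r) for r in trig]
    S = net.stoichiometry
    rows = [net.species_index(sp) for sp in sorted(X)]
    v = symbols(f"v0:{len(cols)}", positive=True)
    constraints = [vi >= 1 for vi in v]
    for j in rows:
        constraints.append(
            sum(Rational(int(S[j, c])) * vi for c, vi in zip(cols, v)) >= 0
        )
    try:
        lpmin(sum(v), constraints)
        return True
    except InfeasibleLPError:
        return False


def sm_oracle_grid(net, X, C=20):
    """Brute-force search for an integer witness with components in {1..C}."""
    trig = sorted(triggered_reactions(net, X))
    if not trig:
        return True
    cols = [net.reaction_index(r) for r in trig]
    S = net.stoichiometry
    rows = [net.species_index(sp) for sp in sorted(X)]
    sub = S[np.ix_(rows, cols)]
    for v in itertools.product(range(1, C + 1), repeat=len(cols)):
        if (sub @ np.array(v) >= 0).all():
            return True
    return False


class TestSelfMaintenance:
    def test_satisfaction_pair_is_self_maintaining(self, simple_net):
        cert = is_self_maintaining(simple_net, {"S", "s"})
        assert cert.feasible
        trig = {"r2", "r9"}
        for i, r in enumerate(simple_net.reactions):
            if r.id in trig:
                assert cert.witness[i] >= 1
            else:
                assert cert.witness[i] == 0
        idx = [simple_net.species_index(sp) for sp in ("S", "s")]
        assert (cert.net_production[idx] >= -1e-9).all()

    def test_attitudes_alone_are_not_self_maintaining(self, simple_net):
        # r0 runs and drains D with nothing producing it
        assert not is_self_maintaining(simple_net, {"S", "U", "D"}).feasible

    def test_empty_set_vacuously_self_maintaining(self, simple_net):
        assert is_self_maintaining(simple_net, frozenset()).feasible

    def test_non_closed_input_rejected(self, simple_net):
        with pytest.raises(NotClosedError):
            is_self_maintaining(simple_net, {"p", "U", "D"})

    def test_closure_then_test_wrapper(self, simple_net):
        closed, cert = self_maintaining_closure(simple_net, {"p", "U", "D"})
        assert closed == {"p", "S", "U", "D"}
        assert cert.feasible

    def test_witness_scale_invariance(self, simple_net):
        """If v is a witness then so is a*v for a > 0 (the region is a cone)."""
        cert = is_self_maintaining(simple_net, frozenset(SIMPLE_ORGS[2]))
        S = simple_net.stoichiometry
        for a in (0.5, 3.0, 250.0):
            assert (S @ (a * cert.witness) >= -1e-6).all()

    def test_exact_oracle_agreement_on_all_closed_subsets(self, simple_net):
        """LP feasibility matches an exact rational simplex on every closed
        subset, and the literal 20-grid search where it is tractable."""
        for X in all_closed_subsets(simple_net):
            lp = is_self_maintaining(simple_net, X).feasible
            assert lp == sm_oracle_exact(simple_net, X), sorted(X)
            if len(triggered_reactions(simple_net, X)) <= 3:
                assert lp == sm_oracle_grid(simple_net, X), sorted(X)


class TestEnumeration:
    def test_single_theme_organizations(self, simple_lattice):
        assert [o.members for o in simple_lattice.organizations] == SIMPLE_ORGS

    def test_non_reactive_sets_exposed_on_request(self, simple_net):
        lattice = enumerate_organizations(simple_net, reactive_only=False)
        members = {o.members for o in lattice.organizations}
        assert members == set(SIMPLE_ORGS) | {frozenset(), frozenset({"S"})}

    def test_network_without_reactions_has_no_reactive_organizations(self):
        from worldviews import ReactionNetwork

        net = ReactionNetwork(("A", "B"), ())
        assert enumerate_organizations(net).organizations == []

    def test_every_organization_retests_closed_and_self_maintaining(
        self, simple_net, simple_lattice
    ):
        for org in simple_lattice.organizations:
            assert is_closed(simple_net, org.members)
            assert is_self_maintaining(simple_net, org.members).feasible
            assert org.size == len(org.members)

    def test_union_closure_consistency(self, simple_net, simple_lattice):
        """The closed self-maintaining join of two organizations is enumerated."""
        members = [o.members for o in simple_lattice.organizations]
        for a, b in itertools.combinations(members, 2):
            joined = closure(simple_net, a | b)
            if is_self_maintaining(simple_net, joined).feasible:
                assert joined in members

    def test_constructive_search_matches_exhaustive(self, simple_net):
        """The large-n join search finds the same organizations as exhaustion."""
        constructive = enumerate_organizations(simple_net, max_exhaustive=0)
        assert [o.members for o in constructive.organizations] == SIMPLE_ORGS


class TestHasseAndReports:
    def test_single_theme_covering_edges(self, simple_lattice):
        edges = hasse_diagram(simple_lattice)
        assert edges == [
            (("S", "s"), ("D", "S", "U", "p", "s")),
            (("D", "S", "U", "p"), ("D", "S", "U", "p", "s")),
        ]

    def test_single_organization_has_no_edges(self, simple_net):
        from worldviews.organizations import OrganizationLattice, _covering_edges

        assert _covering_edges([frozenset({"S", "s"})]) == []

    def test_two_theme_top_element(self, two_theme_net):
        lattice = enumerate_organizations(two_theme_net)
        top = lattice.organizations[-1]
        assert top.members == frozenset(two_theme_net.species)
        others = [o for o in lattice.organizations if o is not top]
        assert all(o.members < top.members for o in others)
        # top covers exactly the two size-9 organizations
        into_top = [i for i, j in lattice.edges
                    if lattice.organizations[j] is top]
        assert sorted(lattice.organizations[i].size for i in into_top) == [9, 9]

    def test_reactive_trigger_sets(self, simple_net, simple_lattice):
        assert reactive_trigger_set(simple_net, {"S", "s"}) == {"s"}
        got = [o.reactive_triggers for o in simple_lattice.organizations]
        assert got == [frozenset({"s"}), frozenset({"p"}), frozenset({"s", "p"})]

    def test_untagged_network_yields_empty_trigger_set(self, worked_net):
        assert reactive_trigger_set(worked_net, {"s1", "s2"}) == frozenset()

    def test_report_and_dot_outputs(self, simple_lattice):
        report = organizations_report(simple_lattice)
        assert [r["size"] for r in report] == [2, 4, 5]
        assert report[0]["members"] == ["S", "s"]
        dot = lattice_to_dot(simple_lattice)
        assert dot.count("->") == len(simple_lattice.edges)
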