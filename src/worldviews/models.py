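"""Generators for the bundled worldview networks.

Two models are provided:

* the 5-species single-theme model: three zero-sum belief attitudes S, U, D
  (satisfaction, uncomfortability, discontent) about one theme, plus two
  free belief-change triggers s (solution) and p (problem), wired by ten
  reactions r0..r9;
* the 40-species two-theme model: 36 compound beliefs — one attitude bonded
  with one trigger per theme, e.g. ``Sp1Us2`` — plus the four free triggers
  s1, p1, s2, p2.  Its reaction list is generated by applying the
  single-theme interaction rules componentwise per theme, together with two
  bond-level families (bond swap and satisfied-bond relaxation) that the
  narrative transitions of the source model require.

The two-theme generator is validated structurally: its reactive organizations
must be exactly the eight published ones (sizes 2, 2, 3, 8, 8, 9, 9, 40 with
the corresponding reactive trigger sets).  Organization structure depends on
stoichiometry only, never on rate constants.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

from .network import Reaction, ReactionNetwork, NetworkError
from .organizations import enumerate_organizations

__all__ = [
    "SimpleModelSpec",
    "TwoThemeModelSpec",
    "TwoThemeValidationError",
    "build_simple_model",
    "build_two_theme_model",
    "validate_two_theme",
    "TWO_THEME_REFERENCE",
]

ATTITUDES = ("S", "U", "D")


@dataclass(frozen=True)
class SimpleModelSpec:
    """Rate constants k0..k9 of the single-theme model.

    Defaults: spontaneous relaxation k0 = k1 = 0.1; solution reproduction
    k2 = 0.2 catalysed by S; problem reproduction k3 = 0.3 catalysed by D
    (discontent reproduces problems faster than satisfaction reproduces
    solutions, so k3 > k2); trigger-induced attitude shifts k4..k7 = 0.3;
    trigger decay (forgetting) k8 = k9 = 0.15.
    """

    k0: float = 0.1
    k1: float = 0.1
    k2: float = 0.2
    k3: float = 0.3
    k4: float = 0.3
    k5: float = 0.3
    k6: float = 0.3
    k7: float = 0.3
    k8: float = 0.15
    k9: float = 0.15

    def __post_init__(self):
        if not self.k3 > self.k2:
            warnings.warn(
                "k3 <= k2: problem reproduction is not faster than solution "
                "reproduction, contrary to the model's asymmetry assumption",
                stacklevel=3,
            )


def build_simple_model(spec: SimpleModelSpec | None = None) -> ReactionNetwork:
    """The 5-species single-theme network (species order S, U, D, s, p)."""
    sp = spec or SimpleModelSpec()
    k = sp
    reactions = (
        Reaction("r0", {"D": 1}, {"U": 1}, k.k0),
        Reaction("r1", {"U": 1}, {"S": 1}, k.k1),
        Reaction("r2", {"S": 1, "s": 1}, {"S": 1, "s": 2}, k.k2),
        Reaction("r3", {"D": 1, "p": 1}, {"D": 1, "p": 2}, k.k3),
        Reaction("r4", {"S": 1, "p": 1}, {"U": 1, "p": 1}, k.k4),
        Reaction("r5", {"U": 1, "p": 1}, {"D": 1, "p": 1}, k.k5),
        Reaction("r6", {"D": 1, "s": 1}, {"U": 1, "s": 1}, k.k6),
        Reaction("r7", {"U": 1, "s": 1}, {"S": 1, "s": 1}, k.k7),
        Reaction("r8", {"p": 2}, {"p": 1}, k.k8),
        Reaction("r9", {"s": 2}, {"s": 1}, k.k9),
    )
    tags = {"S": "attitude", "U": "attitude", "D": "attitude",
            "s": "trigger", "p": "trigger"}
    return ReactionNetwork(("S", "U", "D", "s", "p"), reactions, tags)


# ---------------------------------------------------------------------------
# two-theme model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TwoThemeModelSpec:
    """Rates and reaction-family toggles of the two-theme model.

    Rates reuse the single-theme values per theme.  The two toggles control
    the bond-level families: ``include_bond_swap`` — a free trigger induces
    replacement of the opposite bonded trigger of its theme, acting
    catalytically (belief-change triggers are informational and are not used
    up by inducing a change, exactly as in the attitude-shift family) while
    the displaced bonded trigger is released as a free species
    (``X(A,s_i) + p_i -> X(A,p_i) + p_i + s_i`` and conversely); and
    ``include_bond_relaxation`` — a satisfied theme slot spontaneously lets
    its problem bond relax to a solution bond (``(S,p_i) -> (S,s_i)``).
    Both default on; this is the configuration whose organization structure
    matches the published table (see :func:`validate_two_theme`).  Variants
    that keep the displaced trigger bound (purely catalytic swap) or consume
    the inducing trigger (strict exchange) fail that validation or suppress
    the model's perturbation-driven regime shifts.
    """

    spontaneous: float = 0.1        # attitude relaxation D->U, U->S (per theme)
    bond_relaxation: float = 0.1    # (S,p_i) -> (S,s_i)
    s_catalysis: float = 0.2        # (S,s_i) compound reproduces free s_i
    p_catalysis: float = 0.3        # (D,p_i) compound reproduces free p_i
    attitude_shift: float = 0.3     # free trigger raises/lowers a theme attitude
    bond_swap: float = 0.3          # free trigger displaces the opposite bond
    decay: float = 0.15             # free trigger decay 2x -> x
    include_bond_swap: bool = True
    include_bond_relaxation: bool = True

    def __post_init__(self):
        if not self.p_catalysis > self.s_catalysis:
            warnings.warn(
                "problem catalysis is not faster than solution catalysis, "
                "contrary to the model's asymmetry assumption",
                stacklevel=3,
            )


def _compound(a1: str, t1: str, a2: str, t2: str) -> str:
    return f"{a1}{t1}{a2}{t2}"


def _slots(name: str) -> tuple[tuple[str, str], tuple[str, str]]:
    """Split 'Sp1Us2' into (('S','p1'), ('U','s2'))."""
    return (name[0], name[1:3]), (name[3], name[4:6])


def _with_slot(name: str, theme: int, attitude: str, trigger: str) -> str:
    slots = list(_slots(name))
    slots[theme] = (attitude, trigger)
    return _compound(slots[0][0], slots[0][1], slots[1][0], slots[1][1])


def build_two_theme_model(
    spec: TwoThemeModelSpec | None = None, validate: bool = False
) -> ReactionNetwork:
    """Generate the 40-species two-theme network.

    Species are the 36 compounds (attitude, bonded trigger) x (attitude,
    bonded trigger) plus the free triggers s1, p1, s2, p2.  Reaction families,
    applied per theme slot ``i``:

    a. spontaneous attitude relaxation inside a compound: D -> U, U -> S;
    b. catalysis: a compound whose theme-``i`` slot is (S, s_i) reproduces
       free s_i, a (D, p_i) slot reproduces free p_i (faster);
    c. free s_i raises and free p_i lowers the theme-``i`` attitude of any
       compound, acting catalytically;
    d. free-trigger decay 2x -> x;
    e. bond swap (toggle): a free trigger induces, catalytically, the
       replacement of the opposite bonded trigger of its theme; the
       displaced bonded trigger is released as a free species;
    f. satisfied-bond relaxation (toggle): (S, p_i) -> (S, s_i) spontaneously.

    With ``validate=True`` the generated network is checked against the
    published organization table (raises :class:`TwoThemeValidationError`).
    """
    sp = spec or TwoThemeModelSpec()
    theme_triggers = (("s1", "p1"), ("s2", "p2"))
    compounds = [
        _compound(a1, t1, a2, t2)
        for a1, t1, a2, t2 in itertools.product(
            ATTITUDES, theme_triggers[0], ATTITUDES, theme_triggers[1]
        )
    ]
    frees = ["s1", "p1", "s2", "p2"]
    species = tuple(compounds + frees)
    tags = {c: "compound" for c in compounds}
    tags.update({f: "trigger" for f in frees})

    down = {"D": "U", "U": "S"}   # toward satisfaction
    up = {"S": "U", "U": "D"}     # toward discontent
    reactions: list[Reaction] = []

    for name in compounds:
        slots = _slots(name)
        for theme in (0, 1):
            att, bond = slots[theme]
            s_i, p_i = theme_triggers[theme]
            # (a) spontaneous relaxation
            if att in down:
                tgt = _with_slot(name, theme, down[att], bond)
                reactions.append(
                    Reaction(f"relax{theme + 1}_{name}", {name: 1}, {tgt: 1},
                             sp.spontaneous)
                )
            # (f) satisfied-bond relaxation
            if sp.include_bond_relaxation and att == "S" and bond == p_i:
                tgt = _with_slot(name, theme, "S", s_i)
                reactions.append(
                    Reaction(f"bondrelax{theme + 1}_{name}", {name: 1}, {tgt: 1},
                             sp.bond_relaxation)
                )
            # (b) catalysis of free-trigger reproduction
            if (att, bond) == ("S", s_i):
                reactions.append(
                    Reaction(f"cat_{s_i}_{name}", {name: 1, s_i: 1},
                             {name: 1, s_i: 2}, sp.s_catalysis)
                )
            if (att, bond) == ("D", p_i):
                reactions.append(
                    Reaction(f"cat_{p_i}_{name}", {name: 1, p_i: 1},
                             {name: 1, p_i: 2}, sp.p_catalysis)
                )
            # (c) trigger-induced attitude shifts (catalytic in the trigger)
            if att in down:
                tgt = _with_slot(name, theme, down[att], bond)
                reactions.append(
                    Reaction(f"shift_{s_i}_{name}", {name: 1, s_i: 1},
                             {tgt: 1, s_i: 1}, sp.attitude_shift)
                )
            if att in up:
                tgt = _with_slot(name, theme, up[att], bond)
                reactions.append(
                    Reaction(f"shift_{p_i}_{name}", {name: 1, p_i: 1},
                             {tgt: 1, p_i: 1}, sp.attitude_shift)
                )
            # (e) bond swap: catalytic in the inducing trigger, displaced bond released
            if sp.include_bond_swap:
                other = p_i if bond == s_i else s_i
                tgt = _with_slot(name, theme, att, other)
                reactions.append(
                    Reaction(f"swap_{other}_{name}", {name: 1, other: 1},
                             {tgt: 1, other: 1, bond: 1}, sp.bond_swap)
                )
    # (d) free-trigger decay
    for f in frees:
        reactions.append(Reaction(f"decay_{f}", {f: 2}, {f: 1}, sp.decay))

    net = ReactionNetwork(species, tuple(reactions), tags)
    if validate:
        validate_two_theme(net)
    return net


class TwoThemeValidationError(NetworkError):
    """The generated two-theme network does not reproduce the published organizations."""


def _reference_organizations() -> dict[frozenset[str], frozenset[str]]:
    """Published two-theme organizations: reactive trigger set -> member set."""
    base = "Ss1Ss2"
    theme1 = frozenset(
        _compound(a, t, "S", "s2") for a in ATTITUDES for t in ("s1", "p1")
    )
    theme2 = frozenset(
        _compound("S", "s1", a, t) for a in ATTITUDES for t in ("s2", "p2")
    )
    all_species = frozenset(
        _compound(a1, t1, a2, t2)
        for a1, t1, a2, t2 in itertools.product(
            ATTITUDES, ("s1", "p1"), ATTITUDES, ("s2", "p2")
        )
    ) | {"s1", "p1", "s2", "p2"}
    ref = {
        frozenset({"s1"}): frozenset({base, "s1"}),
        frozenset({"s2"}): frozenset({base, "s2"}),
        frozenset({"s1", "s2"}): frozenset({base, "s1", "s2"}),
        frozenset({"s1", "p1"}): theme1 | {"s1", "p1"},
        frozenset({"s2", "p2"}): theme2 | {"s2", "p2"},
        frozenset({"s1", "p1", "s2"}): theme1 | {"s1", "p1", "s2"},
        frozenset({"s2", "p2", "s1"}): theme2 | {"s2", "p2", "s1"},
        frozenset({"s1", "p1", "s2", "p2"}): all_species,
    }
    return ref


#: Reactive trigger set -> member set of the eight published organizations
#: (sizes 2, 2, 3, 8, 8, 9, 9, 40).
TWO_THEME_REFERENCE = _reference_organizations()


def validate_two_theme(net: ReactionNetwork) -> None:
    """Check the network's reactive organizations against the published table.

    Compares the full member sets, the reactive trigger sets and the sizes;
    raises :class:`TwoThemeValidationError` with the mismatch on failure.
    """
    lattice = enumerate_organizations(net, reactive_only=True)
    got = {o.reactive_triggers: o.members for o in lattice.organizations}
    ref = TWO_THEME_REFERENCE
    problems = []
    if len(lattice.organizations) != len(ref):
        problems.append(
            f"expected {len(ref)} reactive organizations, found "
            f"{len(lattice.organizations)}"
        )
    for trig, members in sorted(ref.items(), key=lambda kv: sorted(kv[0])):
        label = "{" + ",".join(sorted(trig)) + "}"
        if trig not in got:
            problems.append(f"missing organization with reactive triggers {label}")
        elif got[trig] != members:
            extra = sorted(got[trig] - members)
            missing = sorted(members - got[trig])
            problems.append(
                f"organization {label}: unexpected members {extra}, missing {missing}"
            )
    for trig in got:
        if trig not in ref:
            problems.append(
                "unexpected organization with reactive triggers {"
                + ",".join(sorted(trig)) + "}"
            )
    if problems:
        raise TwoThemeValidationError(
            "two-theme organization mismatch: " + "; ".join(problems)
        )
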