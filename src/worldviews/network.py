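"""Reaction-network data model: species, reactions, stoichiometry, closure.

A reaction network is a set of species ``M = {s1, ..., sn}`` together with
reactions ``r_i: c_i1 s1 + ... + c_in sn -> p_i1 s1 + ... + p_in sn`` whose
coefficients are non-negative integers.  The stoichiometric matrix
``S[j, i] = p_ij - c_ij`` records net production, and applying a non-negative
process vector ``v`` (how often each reaction fires along a pathway) gives the
pathway's net production ``S @ v``.

A species set ``X`` *triggers* the reactions whose entire reactant support lies
inside ``X``; ``X`` is *closed* when those reactions produce nothing outside
``X``.  These are the structural primitives on which chemical organization
theory (see :mod:`worldviews.organizations`) is built.

Networks are read and written in a plain-text reaction-list format
(one reaction per line, ``r0: D -> U ; k=0.1``; ``#`` starts a comment,
``#!`` a directive carrying species order and class tags) and in a JSON form.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "NetworkError",
    "ParseError",
    "Reaction",
    "ReactionNetwork",
    "parse_network",
    "serialize_network",
    "network_to_json",
    "network_from_json",
    "stoichiometric_matrix",
    "apply_process",
    "triggered_reactions",
    "is_closed",
    "closure",
]

#: Recognised species class tags.  Attitudes are zero-sum belief states,
#: triggers are free belief-change species (solutions/problems), compounds are
#: bonded attitude+trigger species of the two-theme model.
SPECIES_CLASSES = ("attitude", "trigger", "compound", "other")

_NAME_RE = re.compile(r"[A-Za-z_][A-Za-z0-9_]*\Z")
_TERM_RE = re.compile(r"(?:(\d+)\s+)?([A-Za-z_][A-Za-z0-9_]*)\Z")


class NetworkError(ValueError):
    """Invalid network structure or inconsistent arguments."""


class ParseError(NetworkError):
    """Malformed reaction-list document; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class Reaction:
    """A single reaction with integer stoichiometry and a mass-action rate constant."""

    id: str
    reactants: Mapping[str, int]
    products: Mapping[str, int]
    rate_constant: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "reactants", dict(self.reactants))
        object.__setattr__(self, "products", dict(self.products))
        if not self.reactants and not self.products:
            raise NetworkError(f"reaction {self.id!r}: both sides empty")
        for side in (self.reactants, self.products):
            for sp, coeff in side.items():
                if not isinstance(coeff, (int, np.integer)) or coeff < 0:
                    raise NetworkError(
                        f"reaction {self.id!r}: coefficient of {sp!r} must be a "
                        f"non-negative integer, got {coeff!r}"
                    )
        # zero-coefficient entries are equivalent to absence; drop them
        object.__setattr__(
            self, "reactants", {s: int(c) for s, c in self.reactants.items() if c > 0}
        )
        object.__setattr__(
            self, "products", {s: int(c) for s, c in self.products.items() if c > 0}
        )
        if self.rate_constant < 0:
            raise NetworkError(f"reaction {self.id!r}: negative rate constant")

    @property
    def species(self) -> set[str]:
        return set(self.reactants) | set(self.products)


@dataclass(eq=False)
class ReactionNetwork:
    """An ordered species list, ordered reaction list and optional class tags.

    Species order is declaration / first-appearance order and fixes the row
    order of the stoichiometric matrix and of every concentration vector.
    """

    species: tuple[str, ...]
    reactions: tuple[Reaction, ...]
    tags: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.species = tuple(self.species)
        self.reactions = tuple(self.reactions)
        seen: set[str] = set()
        for sp in self.species:
            if not _NAME_RE.match(sp):
                raise NetworkError(f"invalid species name {sp!r}")
            if sp in seen:
                raise NetworkError(f"duplicate species {sp!r}")
            seen.add(sp)
        ids: set[str] = set()
        for r in self.reactions:
            if r.id in ids:
                raise NetworkError(f"duplicate reaction id {r.id!r}")
            ids.add(r.id)
            missing = r.species - seen
            if missing:
                raise NetworkError(
                    f"reaction {r.id!r} references undeclared species {sorted(missing)}"
                )
        for sp, tag in self.tags.items():
            if sp not in seen:
                raise NetworkError(f"tag for unknown species {sp!r}")
            if tag not in SPECIES_CLASSES:
                raise NetworkError(f"unknown species class {tag!r} for {sp!r}")
        self._index = {sp: j for j, sp in enumerate(self.species)}
        self._cache: dict[str, np.ndarray] = {}

    # -- basic geometry ----------------------------------------------------

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def species_index(self, sp: str) -> int:
        try:
            return self._index[sp]
        except KeyError:
            raise NetworkError(f"unknown species {sp!r}") from None

    def species_of_class(self, tag: str) -> tuple[str, ...]:
        return tuple(sp for sp in self.species if self.tags.get(sp) == tag)

    def reaction_index(self, rid: str) -> int:
        for i, r in enumerate(self.reactions):
            if r.id == rid:
                return i
        raise NetworkError(f"unknown reaction id {rid!r}")

    # -- matrices (cached; do not mutate the returned arrays) --------------

    def _matrix(self, key: str) -> np.ndarray:
        if key not in self._cache:
            n, k = self.n_species, self.n_reactions
            C = np.zeros((n, k), dtype=np.int64)
            P = np.zeros((n, k), dtype=np.int64)
            for i, r in enumerate(self.reactions):
                for sp, c in r.reactants.items():
                    C[self._index[sp], i] = c
                for sp, p in r.products.items():
                    P[self._index[sp], i] = p
            self._cache["C"] = C
            self._cache["P"] = P
            self._cache["S"] = P - C
            self._cache["Csup"] = C > 0
            self._cache["Psup"] = P > 0
        return self._cache[key]

    @property
    def reactant_matrix(self) -> np.ndarray:
        """n x k matrix of reactant coefficients c_ij."""
        return self._matrix("C")

    @property
    def product_matrix(self) -> np.ndarray:
        """n x k matrix of product coefficients p_ij."""
        return self._matrix("P")

    @property
    def stoichiometry(self) -> np.ndarray:
        """n x k integer matrix with entry (j, i) = p_ij - c_ij."""
        return self._matrix("S")

    @property
    def rate_constants(self) -> np.ndarray:
        if "k" not in self._cache:
            self._cache["k"] = np.array(
                [r.rate_constant for r in self.reactions], dtype=float
            )
        return self._cache["k"]

    # -- species-set utilities --------------------------------------------

    def member_mask(self, X: Iterable[str]) -> np.ndarray:
        mask = np.zeros(self.n_species, dtype=bool)
        for sp in X:
            mask[self.species_index(sp)] = True
        return mask

    def mask_to_set(self, mask: np.ndarray) -> frozenset[str]:
        return frozenset(sp for sp, m in zip(self.species, mask) if m)

    def triggered_mask(self, member_mask: np.ndarray) -> np.ndarray:
        """Boolean reaction mask: reactions whose reactant support lies in the set."""
        Csup = self._matrix("Csup")
        return ~((Csup & ~member_mask[:, None]).any(axis=0))

    def closure_mask(self, member_mask: np.ndarray) -> np.ndarray:
        Psup = self._matrix("Psup")
        mask = member_mask.copy()
        while True:
            trig = self.triggered_mask(mask)
            new = mask | Psup[:, trig].any(axis=1)
            if (new == mask).all():
                return new
            mask = new


# ---------------------------------------------------------------------------
# operations (module-level functional surface)
# ---------------------------------------------------------------------------


def stoichiometric_matrix(net: ReactionNetwork) -> np.ndarray:
    """Return the n x k stoichiometric matrix (a defensive copy)."""
    return net.stoichiometry.copy()


def apply_process(net: ReactionNetwork, v: Sequence[float]) -> np.ndarray:
    """Net production ``S @ v`` of every species under the pathway ``v``.

    ``v`` must be a non-negative vector of length ``n_reactions``.
    """
    v = np.asarray(v, dtype=float)
    if v.shape != (net.n_reactions,):
        raise NetworkError(
            f"process vector has length {v.size}, expected {net.n_reactions}"
        )
    if (v < 0).any():
        raise NetworkError("process vector must be non-negative")
    return net.stoichiometry @ v


def triggered_reactions(net: ReactionNetwork, X: Iterable[str]) -> set[str]:
    """Ids of reactions whose entire reactant support lies in ``X``.

    Reactant-free reactions are triggered by every set, including the empty set.
    """
    mask = net.member_mask(X)
    trig = net.triggered_mask(mask)
    return {net.reactions[i].id for i in np.flatnonzero(trig)}


def is_closed(net: ReactionNetwork, X: Iterable[str]) -> bool:
    """True iff the products of every reaction triggered by ``X`` lie in ``X``."""
    mask = net.member_mask(X)
    trig = net.triggered_mask(mask)
    Psup = net._matrix("Psup")
    produced = Psup[:, trig].any(axis=1)
    return bool(~(produced & ~mask).any())


def closure(net: ReactionNetwork, X: Iterable[str]) -> frozenset[str]:
    """Smallest closed superset of ``X``.

    Iterates "add the products of all triggered reactions" to a fixpoint;
    terminates in at most ``n_species`` rounds.
    """
    return net.mask_to_set(net.closure_mask(net.member_mask(X)))


# ---------------------------------------------------------------------------
# plain-text reaction-list format
# ---------------------------------------------------------------------------


def _parse_side(text: str, ln: int) -> dict[str, int]:
    text = text.strip()
    if text in ("", "0"):
        return {}
    out: dict[str, int] = {}
    for term in text.split("+"):
        term = term.strip()
        m = _TERM_RE.match(term)
        if not m:
            raise ParseError(f"cannot parse term {term!r}", ln)
        coeff = int(m.group(1)) if m.group(1) else 1
        name = m.group(2)
        out[name] = out.get(name, 0) + coeff
    return out


def parse_network(text: str) -> ReactionNetwork:
    """Parse a reaction-list document into a :class:`ReactionNetwork`.

    Syntax, one reaction per non-comment line::

        [id :] <coeff> <sp> + ... -> <coeff> <sp> + ... ; k=<float>

    An empty side is written ``0`` (or left blank).  Coefficients default
    to 1.  ``# ...`` lines are comments; ``#! species: ...`` and
    ``#! tags: class: sp sp ; class: sp`` directives fix species order and
    class tags so that documents round-trip losslessly.
    """
    declared: list[str] = []
    tags: dict[str, str] = {}
    reactions: list[Reaction] = []
    order: list[str] = []
    seen_ids: set[str] = set()
    auto = 0

    def note(sp: str):
        if sp not in order:
            order.append(sp)

    for ln, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if line.startswith("#!"):
            body = line[2:].strip()
            key, _, rest = body.partition(":")
            key = key.strip().lower()
            if key == "species":
                declared.extend(rest.split())
            elif key == "tags":
                for group in rest.split(";"):
                    cls, _, names = group.partition(":")
                    cls = cls.strip()
                    if not cls:
                        continue
                    for sp in names.split():
                        tags[sp] = cls
            else:
                raise ParseError(f"unknown directive {key!r}", ln)
            continue
        if not line or line.startswith("#"):
            continue
        if "->" not in line:
            raise ParseError("missing '->'", ln)
        head, _, tail = line.partition("->")
        rid = None
        if ":" in head:
            rid, _, head = head.partition(":")
            rid = rid.strip()
            if not rid:
                raise ParseError("empty reaction id", ln)
        body, _, kpart = tail.partition(";")
        k = 1.0
        kpart = kpart.strip()
        if kpart:
            m = re.fullmatch(r"k\s*=\s*([^\s]+)", kpart)
            if not m:
                raise ParseError(f"cannot parse rate clause {kpart!r}", ln)
            try:
                k = float(m.group(1))
            except ValueError:
                raise ParseError(f"invalid rate constant {m.group(1)!r}", ln) from None
        if rid is None:
            rid = f"r{auto}"
        auto += 1
        if rid in seen_ids:
            raise ParseError(f"duplicate reaction id {rid!r}", ln)
        seen_ids.add(rid)
        try:
            reactants = _parse_side(head, ln)
            products = _parse_side(body, ln)
            reaction = Reaction(rid, reactants, products, k)
        except NetworkError as exc:
            if isinstance(exc, ParseError):
                raise
            raise ParseError(str(exc), ln) from None
        for sp in reaction.reactants:
            note(sp)
        for sp in reaction.products:
            note(sp)
        reactions.append(reaction)

    species: list[str] = []
    for sp in declared + order:
        if sp not in species:
            species.append(sp)
    return ReactionNetwork(tuple(species), tuple(reactions), tags)


def _format_side(side: Mapping[str, int], species_order: Sequence[str]) -> str:
    if not side:
        return "0"
    terms = []
    for sp in species_order:
        if sp in side:
            c = side[sp]
            terms.append(sp if c == 1 else f"{c} {sp}")
    return " + ".join(terms)


def serialize_network(net: ReactionNetwork) -> str:
    """Serialize to the plain-text reaction-list format (lossless round-trip)."""
    lines = [f"#! species: {' '.join(net.species)}"]
    if net.tags:
        groups: dict[str, list[str]] = {}
        for sp in net.species:
            if sp in net.tags:
                groups.setdefault(net.tags[sp], []).append(sp)
        body = " ; ".join(f"{cls}: {' '.join(sps)}" for cls, sps in groups.items())
        lines.append(f"#! tags: {body}")
    for r in net.reactions:
        lhs = _format_side(r.reactants, net.species)
        rhs = _format_side(r.products, net.species)
        lines.append(f"{r.id}: {lhs} -> {rhs} ; k={r.rate_constant!r}")
    return "\n".join(lines) + "\n"


def network_to_json(net: ReactionNetwork) -> str:
    doc = {
        "species": list(net.species),
        "tags": dict(net.tags),
        "reactions": [
            {
                "id": r.id,
                "reactants": dict(r.reactants),
                "products": dict(r.products),
                "k": r.rate_constant,
            }
            for r in net.reactions
        ],
    }
    return json.dumps(doc, indent=2)


def network_from_json(text: str) -> ReactionNetwork:
    doc = json.loads(text)
    reactions = tuple(
        Reaction(r["id"], r["reactants"], r["products"], r.get("k", 1.0))
        for r in doc["reactions"]
    )
    return ReactionNetwork(tuple(doc["species"]), reactions, dict(doc.get("tags", {})))
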