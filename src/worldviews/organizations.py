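"""Chemical organization theory: self-maintenance, organization enumeration, Hasse diagram.

A species set ``X`` is *self-maintaining* when there is a process vector ``v``
that is strictly positive on every reaction triggered by ``X`` and has
non-negative net production ``(S v)_j >= 0`` for every species ``j`` in ``X``.
An *organization* is a set that is both closed and self-maintaining: it
produces nothing new and can keep all of its members from decaying.  In the
worldview reading, organizations are the candidate stable worldviews of the
belief network.

Strict positivity ``v_i > 0`` is encoded as ``v_i >= 1``; this loses no
generality because the feasible region is a cone.  Feasibility is decided by
linear programming (HiGHS via :func:`scipy.optimize.linprog`).

Enumeration is exhaustive over the closed-set lattice for small networks
(``n <= 20``) and constructive for larger ones: closures of singletons are
joined pairwise with already-discovered self-maintaining closed sets until a
fixpoint.  The constructive search can in principle miss organizations that
are not unions of singleton closures; it is cross-validated against the
exhaustive search on small networks and against the published organization
table of the two-theme model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy.optimize import linprog

from .network import ReactionNetwork, NetworkError, is_closed

__all__ = [
    "NotClosedError",
    "SelfMaintenanceCertificate",
    "Organization",
    "OrganizationLattice",
    "is_self_maintaining",
    "self_maintaining_closure",
    "enumerate_organizations",
    "hasse_diagram",
    "reactive_trigger_set",
    "organizations_report",
    "lattice_to_dot",
]

#: Allowed constraint violation for (S v)_j >= 0.
SM_TOLERANCE = 1e-9


class NotClosedError(NetworkError):
    """Self-maintenance was requested for a non-closed set.

    Organizations pair closure and self-maintenance; call
    :func:`worldviews.network.closure` first, or use
    :func:`self_maintaining_closure`.
    """


@dataclass
class SelfMaintenanceCertificate:
    """Outcome of a self-maintenance test.

    When feasible, ``witness`` is a full-length process vector, strictly
    positive exactly on the triggered reactions of the tested set, and
    ``net_production = S @ witness`` is non-negative (within tolerance) on
    every member species.
    """

    feasible: bool
    witness: np.ndarray | None = None
    net_production: np.ndarray | None = None


@dataclass
class Organization:
    """A closed, self-maintaining species set."""

    members: frozenset[str]
    reactive_triggers: frozenset[str]
    size: int
    n_triggered: int
    witness: np.ndarray | None = None

    @property
    def is_reactive(self) -> bool:
        """Whether the organization triggers at least one reaction."""
        return self.n_triggered > 0

    def sort_key(self):
        return (self.size, tuple(sorted(self.members)))


@dataclass
class OrganizationLattice:
    """Organizations ordered by inclusion, with their covering (Hasse) edges.

    ``edges`` are index pairs ``(i, j)`` meaning ``organizations[i]`` is
    covered by ``organizations[j]`` (strict inclusion with nothing between).
    """

    organizations: list[Organization]
    edges: list[tuple[int, int]] = field(default_factory=list)

    def by_triggers(self) -> dict[frozenset[str], Organization]:
        return {o.reactive_triggers: o for o in self.organizations}

    def member_sets(self) -> list[frozenset[str]]:
        return [o.members for o in self.organizations]


def is_self_maintaining(
    net: ReactionNetwork, X: Iterable[str], tol: float = SM_TOLERANCE
) -> SelfMaintenanceCertificate:
    """Decide self-maintenance of the *closed* set ``X`` by LP feasibility.

    Variables are ``v_i >= 1`` for triggered reactions (zero otherwise);
    constraints ``(S v)_j >= -tol`` for every member species.  Raises
    :class:`NotClosedError` on a non-closed input.
    """
    members = frozenset(X)
    mask = net.member_mask(members)
    if not is_closed(net, members):
        raise NotClosedError(
            f"set {sorted(members)} is not closed; apply closure() first "
            "or use self_maintaining_closure()"
        )
    trig = np.flatnonzero(net.triggered_mask(mask))
    k = net.n_reactions
    if trig.size == 0:
        # vacuously self-maintaining: no reaction is forced to run
        return SelfMaintenanceCertificate(
            True, np.zeros(k), np.zeros(net.n_species)
        )
    rows = np.flatnonzero(mask)
    S = net.stoichiometry.astype(float)
    A_ub = -S[np.ix_(rows, trig)]
    b_ub = np.full(rows.size, tol)
    res = linprog(
        c=np.ones(trig.size),
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=(1.0, None),
        method="highs",
    )
    if res.status == 2:  # infeasible
        return SelfMaintenanceCertificate(False)
    if res.status != 0:
        raise RuntimeError(f"LP solver failed (status {res.status}): {res.message}")
    witness = np.zeros(k)
    # HiGHS may undershoot the bound by its own tolerance; clamp (<= 1e-9 shift)
    witness[trig] = np.maximum(res.x, 1.0)
    return SelfMaintenanceCertificate(True, witness, S @ witness)


def self_maintaining_closure(
    net: ReactionNetwork, X: Iterable[str]
) -> tuple[frozenset[str], SelfMaintenanceCertificate]:
    """Convenience wrapper: close ``X`` first, then test self-maintenance."""
    closed = net.mask_to_set(net.closure_mask(net.member_mask(X)))
    return closed, is_self_maintaining(net, closed)


def reactive_trigger_set(net: ReactionNetwork, members: Iterable[str]) -> frozenset[str]:
    """Trigger-tagged species of ``members`` touched by at least one triggered reaction.

    A trigger is *reactive* in an organization when it occurs free in the set
    and participates (as reactant or product) in some reaction the set
    triggers.  Networks without trigger tags yield the empty set.
    """
    members = frozenset(members)
    mask = net.member_mask(members)
    trig = net.triggered_mask(mask)
    touched = (net._matrix("Csup")[:, trig] | net._matrix("Psup")[:, trig]).any(axis=1)
    out = set()
    for sp in members:
        if net.tags.get(sp) == "trigger" and touched[net.species_index(sp)]:
            out.add(sp)
    return frozenset(out)


# ---------------------------------------------------------------------------
# enumeration
# ---------------------------------------------------------------------------


def _all_closed_masks(net: ReactionNetwork) -> list[np.ndarray]:
    """Every closed set, by breadth-first expansion of the closed-set lattice.

    Complete: any closed set is reached from closure of the empty set by
    repeatedly adding one of its members and re-closing (closure is monotone).
    """
    start = net.closure_mask(np.zeros(net.n_species, dtype=bool))
    seen = {start.tobytes(): start}
    queue = [start]
    while queue:
        mask = queue.pop()
        for j in np.flatnonzero(~mask):
            grown = mask.copy()
            grown[j] = True
            closed = net.closure_mask(grown)
            key = closed.tobytes()
            if key not in seen:
                seen[key] = closed
                queue.append(closed)
    return list(seen.values())


def _constructive_organization_masks(
    net: ReactionNetwork, tol: float
) -> dict[bytes, SelfMaintenanceCertificate]:
    """Organizations as joins of singleton closures with discovered organizations.

    May miss organizations not expressible as such joins; see module notes.
    """
    n = net.n_species
    seeds: dict[bytes, np.ndarray] = {}
    empty = net.closure_mask(np.zeros(n, dtype=bool))
    seeds[empty.tobytes()] = empty
    for j in range(n):
        m = np.zeros(n, dtype=bool)
        m[j] = True
        cm = net.closure_mask(m)
        seeds[cm.tobytes()] = cm

    tested: dict[bytes, SelfMaintenanceCertificate] = {}
    orgs: dict[bytes, np.ndarray] = {}

    def test(mask: np.ndarray):
        key = mask.tobytes()
        if key in tested:
            return
        cert = is_self_maintaining(net, net.mask_to_set(mask), tol)
        tested[key] = cert
        if cert.feasible:
            orgs[key] = mask

    for mask in seeds.values():
        test(mask)

    while True:
        partners = list(seeds.values()) + list(orgs.values())
        new_found = False
        for a in list(orgs.values()):
            for b in partners:
                joined = net.closure_mask(a | b)
                key = joined.tobytes()
                if key not in tested:
                    test(joined)
                    if key in orgs:
                        new_found = True
        if not new_found:
            break
    return {key: tested[key] for key in orgs}


def enumerate_organizations(
    net: ReactionNetwork,
    reactive_only: bool = True,
    tol: float = SM_TOLERANCE,
    max_exhaustive: int = 20,
) -> OrganizationLattice:
    """Enumerate organizations and their covering relations.

    With ``reactive_only`` (the default) organizations triggering no reaction
    at all (the empty set, isolated inert species) are dropped; this matches
    the organization lists the model builders are validated against.  Set it
    to False to also report the vacuously self-maintaining closed sets.

    Networks with at most ``max_exhaustive`` species are enumerated over the
    complete closed-set lattice; larger ones use the constructive join search.
    """
    found: list[tuple[np.ndarray, SelfMaintenanceCertificate]] = []
    if net.n_species <= max_exhaustive:
        for mask in _all_closed_masks(net):
            cert = is_self_maintaining(net, net.mask_to_set(mask), tol)
            if cert.feasible:
                found.append((mask, cert))
    else:
        for key, cert in _constructive_organization_masks(net, tol).items():
            mask = np.frombuffer(key, dtype=bool).copy()
            found.append((mask, cert))

    organizations = []
    for mask, cert in found:
        n_trig = int(net.triggered_mask(mask).sum())
        if reactive_only and n_trig == 0:
            continue
        members = net.mask_to_set(mask)
        organizations.append(
            Organization(
                members=members,
                reactive_triggers=reactive_trigger_set(net, members),
                size=len(members),
                n_triggered=n_trig,
                witness=cert.witness,
            )
        )
    organizations.sort(key=Organization.sort_key)

    edges = _covering_edges([o.members for o in organizations])
    return OrganizationLattice(organizations, edges)


def _covering_edges(sets: list[frozenset[str]]) -> list[tuple[int, int]]:
    edges = []
    for i, a in enumerate(sets):
        for j, b in enumerate(sets):
            if a < b:
                if not any(a < c < b for c in sets):
                    edges.append((i, j))
    edges.sort()
    return edges


def hasse_diagram(
    lattice: OrganizationLattice,
) -> list[tuple[tuple[str, ...], tuple[str, ...]]]:
    """Covering edges as (sub, super) pairs of sorted member tuples, deterministic."""
    out = [
        (
            tuple(sorted(lattice.organizations[i].members)),
            tuple(sorted(lattice.organizations[j].members)),
        )
        for i, j in lattice.edges
    ]
    out.sort(key=lambda e: (len(e[0]), e[0], len(e[1]), e[1]))
    return out


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------


def _org_label(org: Organization) -> str:
    return "{" + ",".join(sorted(org.members)) + "}"


def organizations_report(lattice: OrganizationLattice) -> list[dict]:
    """JSON-ready list of organizations (members, reactive triggers, size, witness)."""
    return [
        {
            "members": sorted(o.members),
            "reactive_triggers": sorted(o.reactive_triggers),
            "size": o.size,
            "witness": None if o.witness is None else [float(x) for x in o.witness],
        }
        for o in lattice.organizations
    ]


def lattice_to_dot(lattice: OrganizationLattice, name: str = "organizations") -> str:
    """Hasse diagram in Graphviz DOT form (edges point from subset to superset)."""
    lines = [f"digraph {name} {{", "  rankdir=BT;"]
    for i, org in enumerate(lattice.organizations):
        label = _org_label(org)
        lines.append(f'  n{i} [label="{label}\\nsize={org.size}"];')
    for i, j in lattice.edges:
        lines.append(f"  n{i} -> n{j};")
    lines.append("}")
    return "\n".join(lines) + "\n"
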