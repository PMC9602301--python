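"""Simulation experiments: initial-condition surveys, stochastic perturbation
protocols, and abstraction-trace analytics.

Three experiment families are provided, matching the studies the bundled
models were built for:

* random initial-condition surveys of the single-theme model, tabulating the
  distribution of end-state abstractions;
* stochastic perturbation runs where an external input of "problem" triggers
  is injected at random intervals, optionally stopped once discontent
  dominates (D > 2S), probing irreversible worldview transitions;
* abstraction-trace analytics for long perturbed runs of the two-theme model:
  per-transition set distances, expansion/contraction classes and abstraction
  frequencies (the scatter data behind size-vs-size trace plots).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .network import ReactionNetwork, NetworkError, closure
from .kinetics import (
    ConcentrationState,
    EpsilonRule,
    MassActionSystem,
    PerturbationEvent,
    Trajectory,
    abstraction,
    simulate,
)
from .organizations import OrganizationLattice, Organization

__all__ = [
    "PerturbationSchedule",
    "TraceEntry",
    "Transition",
    "TransitionTrace",
    "TraceSummary",
    "PerturbedRun",
    "EndStateDistribution",
    "sample_initial_conditions",
    "end_state_distribution",
    "draw_events",
    "run_perturbed",
    "abstraction_distance",
    "transition_trace",
    "trace_summary",
    "classify_abstraction",
]

#: Shortest allowed waiting time between perturbation events (days).  Normal
#: interval draws are truncated here so events stay causally ordered.
MIN_INTERVAL = 0.1


# ---------------------------------------------------------------------------
# initial-condition survey
# ---------------------------------------------------------------------------


def sample_initial_conditions(
    net: ReactionNetwork, n: int, seed: int
) -> np.ndarray:
    """Random initial states of the single-theme model, ``n`` rows.

    The three attitudes (S, D, U) are uniform on the 2-simplex (flat
    Dirichlet), the problem trigger p0 is uniform on [0, 1] and the solution
    trigger starts at 1 - p0, so attitudes and triggers each sum to one at
    t = 0.  Reproducible under ``seed``.
    """
    if n < 1:
        raise NetworkError("n must be >= 1")
    for sp in ("S", "U", "D", "s", "p"):
        net.species_index(sp)
    rng = np.random.default_rng(seed)
    attitudes = rng.dirichlet(np.ones(3), size=n)  # columns S0, D0, U0
    p0 = rng.uniform(0.0, 1.0, size=n)
    out = np.zeros((n, net.n_species))
    iS, iU, iD = (net.species_index(x) for x in ("S", "U", "D"))
    is_, ip = net.species_index("s"), net.species_index("p")
    out[:, iS] = attitudes[:, 0]
    out[:, iD] = attitudes[:, 1]
    out[:, iU] = attitudes[:, 2]
    out[:, ip] = p0
    out[:, is_] = 1.0 - p0
    return out


@dataclass
class EndStateDistribution:
    """Frequencies of final abstractions over a survey of initial conditions.

    Runs whose abstraction still changed during the trailing convergence
    window are tabulated separately under ``unconverged`` rather than being
    silently classified.
    """

    frequencies: Counter
    unconverged: int
    n: int
    horizon: float

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"abstraction": ",".join(sorted(k)), "count": v}
            for k, v in sorted(
                self.frequencies.items(), key=lambda kv: (-kv[1], sorted(kv[0]))
            )
        ]
        return pd.DataFrame(rows, columns=["abstraction", "count"])

    def modal_abstraction(self) -> frozenset[str]:
        return max(self.frequencies.items(), key=lambda kv: (kv[1], sorted(kv[0])))[0]


def end_state_distribution(
    net: ReactionNetwork,
    n: int,
    horizon: float = 500.0,
    rule: EpsilonRule | None = None,
    seed: int = 0,
    convergence_window: float = 50.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> EndStateDistribution:
    """Simulate ``n`` sampled initial conditions unperturbed and tabulate final abstractions.

    A run counts as converged when its abstraction is constant over the final
    ``convergence_window`` days of the reporting grid.
    """
    rule = rule or EpsilonRule()
    states = sample_initial_conditions(net, n, seed)
    system = MassActionSystem(net)
    freq: Counter = Counter()
    unconverged = 0
    for row in states:
        traj = simulate(
            net, row, horizon, system=system, rtol=rtol, atol=atol
        )
        tail = traj.times >= horizon - convergence_window
        abstractions = {
            abstraction(net, traj.values[i], rule) for i in np.flatnonzero(tail)
        }
        final = abstraction(net, traj.values[-1], rule)
        if len(abstractions) > 1:
            unconverged += 1
        else:
            freq[final] += 1
    return EndStateDistribution(freq, unconverged, n, horizon)


# ---------------------------------------------------------------------------
# perturbation protocol
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PerturbationSchedule:
    """Random external-input schedule.

    Waiting times between events are Normal(``interval_mean``,
    ``interval_sd``) days truncated below at 0.1 day; amounts are uniform on
    [0, ``amount_max``]; each event targets one species drawn uniformly from
    ``targets``.  ``n_events`` bounds the number of events (None: horizon
    bounded).  ``stop_rule="discontent"`` cancels all further events once
    D > ``stop_factor``·S first holds at a reporting point.
    """

    interval_mean: float = 7.0
    interval_sd: float = 1.0
    amount_max: float = 0.25
    targets: tuple[str, ...] = ("p",)
    n_events: int | None = None
    stop_rule: str | None = None
    stop_factor: float = 2.0
    stop_numerator: str = "D"
    stop_reference: str = "S"
    seed: int | None = None

    def __post_init__(self):
        if self.interval_mean <= 0 or self.interval_sd < 0 or self.amount_max < 0:
            raise NetworkError("invalid schedule parameters")
        if self.stop_rule not in (None, "discontent"):
            raise NetworkError(f"unknown stop rule {self.stop_rule!r}")
        object.__setattr__(self, "targets", tuple(self.targets))
        if not self.targets:
            raise NetworkError("schedule needs at least one target species")


def draw_events(
    schedule: PerturbationSchedule, horizon: float, rng: np.random.Generator
) -> list[PerturbationEvent]:
    """Draw the event times, amounts and targets of a schedule up to ``horizon``."""
    events: list[PerturbationEvent] = []
    t = 0.0
    while True:
        if schedule.n_events is not None and len(events) >= schedule.n_events:
            break
        t += max(MIN_INTERVAL, rng.normal(schedule.interval_mean, schedule.interval_sd))
        if t > horizon:
            break
        amount = rng.uniform(0.0, schedule.amount_max)
        target = schedule.targets[rng.integers(len(schedule.targets))]
        events.append(PerturbationEvent(t, target, amount))
    return events


@dataclass
class PerturbedRun:
    trajectory: Trajectory
    trace: "TransitionTrace"
    events_fired: tuple[PerturbationEvent, ...]
    stopped_at: float | None  # first reporting time the stop rule held


def run_perturbed(
    net: ReactionNetwork,
    initial: ConcentrationState | Sequence[float],
    schedule: PerturbationSchedule,
    horizon: float,
    rule: EpsilonRule | None = None,
    seed: int | None = None,
    grid_dt: float = 1.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> PerturbedRun:
    """Simulate under a stochastic perturbation schedule, with optional stop rule.

    The stop rule is evaluated on the reporting grid: once it first holds, no
    further events fire and the system evolves freely to the horizon.  Returns
    the stitched trajectory together with its compressed abstraction trace.
    """
    rule = rule or EpsilonRule()
    for sp in schedule.targets:
        net.species_index(sp)
    rng = np.random.default_rng(seed if seed is not None else schedule.seed)
    events = draw_events(schedule, horizon, rng)

    if schedule.stop_rule is None:
        traj = simulate(
            net, initial, horizon, events, grid_dt=grid_dt, rtol=rtol, atol=atol
        )
        trace = transition_trace(net, traj, rule)
        return PerturbedRun(traj, trace, traj.events, None)

    iN = net.species_index(schedule.stop_numerator)
    iR = net.species_index(schedule.stop_reference)
    system = MassActionSystem(net)
    conc = np.array(
        initial.concentrations if isinstance(initial, ConcentrationState) else initial,
        dtype=float,
    )

    times_parts: list[np.ndarray] = []
    vals_parts: list[np.ndarray] = []
    fired: list[PerturbationEvent] = []
    raw_min = 0.0
    stopped_at: float | None = None

    def check_stop(seg: Trajectory) -> float | None:
        hit = seg.values[:, iN] > schedule.stop_factor * seg.values[:, iR]
        idx = np.flatnonzero(hit)
        return float(seg.times[idx[0]]) if idx.size else None

    t_cur = 0.0
    pending = list(events)
    while True:
        next_event = pending[0] if (pending and stopped_at is None) else None
        t_next = next_event.time if next_event is not None else horizon
        seg_len = t_next - t_cur
        seg = simulate(
            net,
            conc,
            seg_len,
            grid_dt=grid_dt,
            rtol=rtol,
            atol=atol,
            system=system,
        )
        # report on the global clock; drop the duplicated segment start
        offset = 1 if times_parts else 0
        times_parts.append(seg.times[offset:] + t_cur)
        vals_parts.append(seg.values[offset:])
        raw_min = min(raw_min, seg.raw_min)
        conc = seg.values[-1].copy()
        if stopped_at is None:
            hit = check_stop(seg)
            if hit is not None:
                stopped_at = hit + t_cur
        t_cur = t_next
        if next_event is not None:
            pending.pop(0)
            if stopped_at is None:
                conc[net.species_index(next_event.species)] += next_event.amount
                fired.append(next_event)
        if t_cur >= horizon:
            break

    times = np.concatenate(times_parts)
    values = np.vstack(vals_parts)
    # reporting grid carries fractional event times; keep strictly increasing
    keep = np.concatenate([[True], np.diff(times) > 0])
    traj = Trajectory(
        net.species, times[keep], values[keep], tuple(fired), raw_min
    )
    trace = transition_trace(net, traj, rule)
    return PerturbedRun(traj, trace, tuple(fired), stopped_at)


# ---------------------------------------------------------------------------
# abstraction traces
# ---------------------------------------------------------------------------


def abstraction_distance(X1: Iterable[str], X2: Iterable[str]) -> float:
    """d(X1, X2) = |symmetric difference| / |union|; 0 when both sets are empty."""
    a, b = frozenset(X1), frozenset(X2)
    union = a | b
    if not union:
        return 0.0
    return len(a ^ b) / len(union)


@dataclass
class TraceEntry:
    time: float  # first time the abstraction was observed in this run of points
    members: frozenset[str]
    dwell_points: int


@dataclass
class Transition:
    time: float
    prev: frozenset[str]
    next: frozenset[str]
    distance: float
    size_change: str  # "expansion" | "contraction" | "same-size"


@dataclass
class TransitionTrace:
    """Run-length-compressed sequence of abstractions along a trajectory.

    Consecutive identical abstractions are merged, keeping the first time and
    dwell length; ``frequencies`` counts reporting points per abstraction over
    the whole (uncompressed) trajectory.
    """

    entries: list[TraceEntry]
    frequencies: Counter
    n_points: int

    @property
    def n_distinct(self) -> int:
        return len(self.frequencies)

    def most_frequent(self) -> frozenset[str]:
        return max(
            self.frequencies.items(), key=lambda kv: (kv[1], sorted(kv[0]))
        )[0]

    def to_json(self) -> list[dict]:
        return [
            {
                "time": e.time,
                "members": sorted(e.members),
                "dwell_points": e.dwell_points,
            }
            for e in self.entries
        ]


def transition_trace(
    net: ReactionNetwork, trajectory: Trajectory, rule: EpsilonRule | None = None
) -> TransitionTrace:
    rule = rule or EpsilonRule()
    entries: list[TraceEntry] = []
    freq: Counter = Counter()
    for t, row in zip(trajectory.times, trajectory.values):
        members = abstraction(net, row, rule)
        freq[members] += 1
        if entries and entries[-1].members == members:
            entries[-1].dwell_points += 1
        else:
            entries.append(TraceEntry(float(t), members, 1))
    return TransitionTrace(entries, freq, len(trajectory.times))


@dataclass
class TraceSummary:
    transitions: list[Transition]
    frequencies: Counter
    n_distinct: int
    n_points: int

    def to_scatter_frame(self) -> pd.DataFrame:
        """Size-vs-size scatter data: one row per transition, with the set
        distance and the relative frequency of the entered abstraction."""
        rows = [
            {
                "time": tr.time,
                "prev_size": len(tr.prev),
                "next_size": len(tr.next),
                "d": tr.distance,
                "frequency": self.frequencies[tr.next] / max(self.n_points, 1),
                "class": tr.size_change,
            }
            for tr in self.transitions
        ]
        return pd.DataFrame(
            rows, columns=["time", "prev_size", "next_size", "d", "frequency", "class"]
        )


def _size_class(prev: frozenset, nxt: frozenset) -> str:
    if len(nxt) > len(prev):
        return "expansion"
    if len(nxt) < len(prev):
        return "contraction"
    return "same-size"


def trace_summary(trace: TransitionTrace) -> TraceSummary:
    """Per-transition report (sizes, distance, class) plus abstraction frequencies."""
    if not trace.entries:
        raise NetworkError("empty trace")
    transitions = []
    for a, b in zip(trace.entries, trace.entries[1:]):
        transitions.append(
            Transition(
                time=b.time,
                prev=a.members,
                next=b.members,
                distance=abstraction_distance(a.members, b.members),
                size_change=_size_class(a.members, b.members),
            )
        )
    return TraceSummary(transitions, trace.frequencies, trace.n_distinct, trace.n_points)


def classify_abstraction(
    X: Iterable[str], lattice: OrganizationLattice
) -> Organization:
    """Nearest organization by set distance (ties broken toward the smaller one)."""
    X = frozenset(X)
    if not lattice.organizations:
        raise NetworkError("empty organization lattice")
    return min(
        lattice.organizations,
        key=lambda o: (abstraction_distance(X, o.members), o.size, tuple(sorted(o.members))),
    )
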