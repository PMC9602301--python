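"""Mass-action dynamics and the ε-abstraction linking states to species sets.

The concentration vector ``s(t)`` evolves as ``ds/dt = S · v(s)`` where the
process vector follows the mass-action law ``v_i = k_i · Π_j s_j^{c_ij}``.
Time is measured in model days; the rate constants of the bundled models are
per-day.

The ε-abstraction ``Ω(s(t))`` of a state is the set of species whose
concentration exceeds a class-dependent threshold ε — the structural
"worldview" the state instantiates.  Thresholds are fractions of the current
total concentration of each species class (belief attitudes and compound
beliefs on one side, free belief-change triggers on the other), recomputed at
every evaluated state; fixed absolute overrides and a per-species (class-mean)
normalisation are also supported.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .network import ReactionNetwork, NetworkError

__all__ = [
    "ConcentrationState",
    "EpsilonRule",
    "PerturbationEvent",
    "Trajectory",
    "SimulationError",
    "MassActionSystem",
    "mass_action_rates",
    "ode_rhs",
    "simulate",
    "abstraction",
    "make_instance",
    "state_from_dict",
]


@dataclass
class ConcentrationState:
    """Species concentrations at a time point, aligned with the network's species order."""

    time: float
    concentrations: np.ndarray

    def __post_init__(self):
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.time < 0:
            raise NetworkError("state time must be non-negative")


def state_from_dict(
    net: ReactionNetwork, values: Mapping[str, float], time: float = 0.0
) -> ConcentrationState:
    conc = np.zeros(net.n_species)
    for sp, val in values.items():
        conc[net.species_index(sp)] = val
    return ConcentrationState(time, conc)


@dataclass(frozen=True)
class EpsilonRule:
    """Class-dependent abstraction thresholds.

    ``attitude_fraction`` (default 0.10) scales the total concentration of all
    non-trigger species (belief attitudes, compound beliefs); the attitude
    total of the bundled models is conserved at 1, so the default attitude
    threshold is effectively 0.1.  ``trigger_fraction`` scales the current
    total of free trigger species, which is not conserved.  ``fixed_attitude``
    / ``fixed_trigger`` override the corresponding threshold with an absolute
    value.  With ``per_species`` the fractions apply to the class *mean*
    concentration instead of the class total — the appropriate scale when the
    conserved belief mass is spread over many compound species, as in the
    two-theme model.
    """

    attitude_fraction: float = 0.10
    trigger_fraction: float = 0.10
    fixed_attitude: float | None = None
    fixed_trigger: float | None = None
    per_species: bool = False

    def __post_init__(self):
        for f in (self.attitude_fraction, self.trigger_fraction):
            if not 0 < f < 1:
                raise NetworkError("epsilon fractions must lie in (0, 1)")

    def thresholds(self, net: ReactionNetwork, conc: np.ndarray) -> np.ndarray:
        trig_mask = np.array(
            [net.tags.get(sp) == "trigger" for sp in net.species], dtype=bool
        )
        n_trig = max(int(trig_mask.sum()), 1)
        n_att = max(int((~trig_mask).sum()), 1)
        if self.fixed_attitude is not None:
            eps_att = self.fixed_attitude
        else:
            eps_att = self.attitude_fraction * float(conc[~trig_mask].sum())
            if self.per_species:
                eps_att /= n_att
        if self.fixed_trigger is not None:
            eps_trig = self.fixed_trigger
        else:
            eps_trig = self.trigger_fraction * float(conc[trig_mask].sum())
            if self.per_species:
                eps_trig /= n_trig
        return np.where(trig_mask, eps_trig, eps_att)


@dataclass(frozen=True)
class PerturbationEvent:
    """An instantaneous external input: add ``amount`` to ``species`` at ``time``."""

    time: float
    species: str
    amount: float


@dataclass
class Trajectory:
    """Simulated states on a reporting grid, plus the perturbation events applied.

    Reported concentrations are clipped at zero; ``raw_min`` records the most
    negative value produced by the integrator before clipping (round-off scale
    for a healthy run).
    """

    species: tuple[str, ...]
    times: np.ndarray
    values: np.ndarray  # len(times) x n_species
    events: tuple[PerturbationEvent, ...] = ()
    raw_min: float = 0.0

    def __len__(self) -> int:
        return len(self.times)

    def state(self, i: int) -> ConcentrationState:
        return ConcentrationState(float(self.times[i]), self.values[i].copy())

    @property
    def final_state(self) -> ConcentrationState:
        return self.state(len(self.times) - 1)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.species))
        df.insert(0, "time", self.times)
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def events_json(self) -> list[dict]:
        return [
            {"time": e.time, "species": e.species, "amount": e.amount}
            for e in self.events
        ]


class SimulationError(RuntimeError):
    """Integration failure; carries the last valid state."""

    def __init__(self, message: str, last_state: ConcentrationState | None = None):
        super().__init__(message)
        self.last_state = last_state


class MassActionSystem:
    """Precompiled mass-action rate law and ODE right-hand side for a network.

    The reactant multiset of every reaction is flattened into an index table
    so that rate evaluation is a single gather + row product; a dummy index
    holding concentration 1.0 pads reactions with fewer factors.
    """

    def __init__(self, net: ReactionNetwork):
        self.net = net
        C = net.reactant_matrix
        n, k = C.shape
        factor_lists = []
        for i in range(k):
            idx = []
            for j in np.flatnonzero(C[:, i]):
                idx.extend([j] * int(C[j, i]))
            factor_lists.append(idx)
        L = max((len(f) for f in factor_lists), default=0)
        self._factors = np.full((k, max(L, 1)), n, dtype=np.intp)
        for i, f in enumerate(factor_lists):
            self._factors[i, : len(f)] = f
        self._k = net.rate_constants
        self._S = net.stoichiometry.astype(float)

    def rates(self, conc: np.ndarray) -> np.ndarray:
        padded = np.append(conc, 1.0)
        return self._k * padded[self._factors].prod(axis=1)

    def rhs(self, t: float, conc: np.ndarray) -> np.ndarray:
        return self._S @ self.rates(conc)


def mass_action_rates(net: ReactionNetwork, state: ConcentrationState) -> np.ndarray:
    """Process vector ``v_i = k_i Π_j s_j^{c_ij}`` at the given state."""
    return MassActionSystem(net).rates(np.asarray(state.concentrations, dtype=float))


def ode_rhs(net: ReactionNetwork, state: ConcentrationState) -> np.ndarray:
    """Net concentration change ``S · v(s)`` at the given state."""
    return MassActionSystem(net).rhs(
        state.time, np.asarray(state.concentrations, dtype=float)
    )


def _segment(
    system: MassActionSystem,
    conc: np.ndarray,
    t0: float,
    t1: float,
    report: np.ndarray,
    rtol: float,
    atol: float,
    method: str,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Integrate [t0, t1]; return (values at report times, state at t1, raw min)."""
    t_eval = np.append(report, t1) if report.size == 0 or report[-1] < t1 else report
    sol = solve_ivp(
        system.rhs,
        (t0, t1),
        conc,
        method=method,
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        last = ConcentrationState(float(sol.t[-1]) if sol.t.size else t0, conc)
        raise SimulationError(f"integration failed: {sol.message}", last)
    raw_min = float(sol.y.min()) if sol.y.size else 0.0
    vals = sol.y.T[: report.size]
    final = sol.y[:, -1]
    return np.maximum(vals, 0.0), np.maximum(final, 0.0), raw_min


def simulate(
    net: ReactionNetwork,
    initial: ConcentrationState | Sequence[float],
    horizon: float,
    events: Iterable[PerturbationEvent] = (),
    *,
    grid_dt: float = 1.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
    system: MassActionSystem | None = None,
) -> Trajectory:
    """Integrate the mass-action ODE over ``horizon`` days with optional input events.

    Integration splits at every event time; the event amount is added to the
    named species and the run continues.  States are reported on a uniform
    grid (default one point per day, the grid point at an event time showing
    the post-event state); reported concentrations are clipped at zero.
    A zero horizon returns the initial state only.
    """
    if horizon < 0:
        raise NetworkError("horizon must be non-negative")
    if isinstance(initial, ConcentrationState):
        conc = np.array(initial.concentrations, dtype=float)
    else:
        conc = np.array(initial, dtype=float)
    if conc.shape != (net.n_species,):
        raise NetworkError(
            f"initial state has length {conc.size}, expected {net.n_species}"
        )

    events = tuple(
        e for e in sorted(events, key=lambda e: e.time) if e.amount != 0.0
    )
    for e in events:
        net.species_index(e.species)  # validate
        if not 0 <= e.time <= horizon:
            raise NetworkError(f"event time {e.time} outside [0, {horizon}]")

    grid = np.arange(0.0, horizon + 0.5 * grid_dt, grid_dt)
    if grid.size == 0 or grid[-1] < horizon:
        grid = np.append(grid, horizon)
    grid = grid[grid <= horizon]

    if horizon == 0:
        return Trajectory(net.species, np.array([0.0]), conc[None, :].copy(), events)

    sys_ = system or MassActionSystem(net)
    out = np.empty((grid.size, net.n_species))
    raw_min = 0.0
    t_cur = 0.0
    gi = 0
    if grid[0] == 0.0:
        out[0] = np.maximum(conc, 0.0)
        gi = 1

    breakpoints = [e.time for e in events] + [horizon]
    ei = 0
    for bp in breakpoints:
        if bp > t_cur:
            hi = np.searchsorted(grid, bp, side="right")
            report = grid[gi:hi]
            vals, conc, seg_min = _segment(
                sys_, conc, t_cur, bp, report, rtol, atol, method
            )
            out[gi:hi] = vals[: hi - gi] if report.size else vals
            gi = hi
            raw_min = min(raw_min, seg_min)
            t_cur = bp
        # apply every event scheduled at this breakpoint
        while ei < len(events) and events[ei].time == bp:
            e = events[ei]
            conc[net.species_index(e.species)] += e.amount
            # the grid point at the event time shows the post-event state
            j = np.searchsorted(grid, bp)
            if j < grid.size and grid[j] == bp:
                out[j] = np.maximum(conc, 0.0)
            ei += 1

    return Trajectory(net.species, grid, out, events, raw_min)


def abstraction(
    net: ReactionNetwork,
    state: ConcentrationState | Sequence[float],
    rule: EpsilonRule | None = None,
) -> frozenset[str]:
    """ε-abstraction Ω(s): species whose concentration strictly exceeds their threshold."""
    rule = rule or EpsilonRule()
    conc = (
        state.concentrations
        if isinstance(state, ConcentrationState)
        else np.asarray(state, dtype=float)
    )
    eps = rule.thresholds(net, conc)
    return frozenset(
        sp for sp, c, e in zip(net.species, conc, eps) if c > e
    )


def make_instance(
    net: ReactionNetwork,
    X: Iterable[str],
    rule: EpsilonRule | None = None,
    level_in: float = 1.0,
    level_out: float = 0.0,
) -> ConcentrationState:
    """An ε-instance of ``X``: members at ``level_in``, others at ``level_out``.

    Raises if the chosen levels do not straddle the implied thresholds, i.e.
    if the constructed state's abstraction is not exactly ``X``.
    """
    rule = rule or EpsilonRule()
    members = frozenset(X)
    mask = net.member_mask(members)
    if level_in <= 0 or level_out < 0:
        raise NetworkError("level_in must be positive and level_out non-negative")
    conc = np.where(mask, level_in, level_out)
    state = ConcentrationState(0.0, conc)
    got = abstraction(net, state, rule)
    if got != members:
        raise NetworkError(
            f"levels ({level_in}, {level_out}) do not instantiate {sorted(members)}: "
            f"abstraction is {sorted(got)}"
        )
    return state
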