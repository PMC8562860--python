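"""Gillespie direct-method engine for elementary and QSSA-reduced networks.

Reactions carry either mass-action propensities (with the 1/Omega
convention folded into bimolecular rate constants, i.e. the binding
propensity is ``(k_f/Omega) * A * B``) or non-elementary propensities in
which a QSSA estimator of a rapid binding pair's unbound or complexed
count -- exact conditional mean, stQSSA, k-state slQSSA, sQSSA, or the
policy-driven adaptive choice -- is re-evaluated from the *current* slow
totals at every propensity evaluation.  Estimator values are cached per
totals tuple, since the slow totals change far less often than reactions
fire.

The sampler is the plain direct method: one exponential waiting time and
one categorical reaction choice per event, driven by a seeded
``numpy.random.Generator`` (PCG64) so identical inputs reproduce
identical paths bit-for-bit.  Recording is either on a fixed time grid
(memory-bounded; the default for stiff full models) or event-driven.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from stoqssa.binding import (
    BindingPair,
    exact_mean,
    slqssa_unbound,
    stqssa_unbound,
)
from stoqssa.policy import ReductionPolicy

__all__ = [
    "QssaTerm",
    "Reaction",
    "ReactionNetwork",
    "Trajectory",
    "simulate",
    "simulate_reduced",
    "ensemble",
    "SimulationError",
]

_RNG_CHUNK = 8192


class SimulationError(RuntimeError):
    """A propensity went negative or non-finite; message carries the state."""


@dataclass(frozen=True)
class QssaTerm:
    """A QSSA-derived factor in a non-elementary propensity.

    ``total`` and ``partner`` name the slow species holding the A-role and
    B-role totals (or give fixed numbers for conserved totals).  ``role``
    selects the unbound-A count, the unbound partner count
    ``B_T - A_T + A`` (role ``partner``), or the complex count ``A_T - A``;
    ``estimator`` is one of ``exact``, ``stqssa``, ``slqssa:<k>``,
    ``sqssa`` or ``adaptive`` (which needs a policy under ``pair_name`` at
    simulation time).  The factor enters the propensity raised to
    ``power``.
    """

    total: str | float
    partner: str | float
    K_d: float
    role: str = "unbound"  # "unbound" | "partner" | "complex"
    estimator: str = "stqssa"
    power: int = 1
    pair_name: str = "pair"

    def __post_init__(self):
        if self.role not in ("unbound", "partner", "complex"):
            raise ValueError(
                f"role must be unbound|partner|complex, got {self.role!r}"
            )
        est = self.estimator
        ok = est in ("exact", "stqssa", "sqssa", "adaptive") or (
            est.startswith("slqssa:") and est.split(":", 1)[1].isdigit()
        )
        if not ok:
            raise ValueError(f"unknown estimator {est!r}")


@dataclass(frozen=True)
class Reaction:
    """One reaction channel.

    ``changes`` maps species to stoichiometric change.  The propensity is

        rate * prod_falling(reactants) * prod(modifiers ** power) * qssa**power

    where ``reactants`` contribute falling factorials ``x(x-1)...`` (the
    elementary mass-action factor, zero whenever a reactant is absent) and
    ``modifiers`` contribute plain powers ``x**p`` (catalytic/regulatory
    species that are not consumed as elementary collisions).
    """

    name: str
    changes: dict[str, int]
    rate: float
    reactants: dict[str, int] = field(default_factory=dict)
    modifiers: dict[str, int] = field(default_factory=dict)
    qssa: QssaTerm | None = None

    def __post_init__(self):
        if self.rate < 0 or not math.isfinite(self.rate):
            raise ValueError(f"rate must be finite and >= 0, got {self.rate!r}")


@dataclass
class ReactionNetwork:
    """Species with initial counts, reactions, and declared linear invariants.

    ``conserved_totals`` entries are ``(name, {species: coef}, value)``;
    each is checked at construction to be orthogonal to every reaction's
    stoichiometry and consistent with the initial counts.
    """

    species: list[str]
    initial: dict[str, int]
    reactions: list[Reaction]
    conserved_totals: list[tuple[str, dict[str, int], int]] = field(
        default_factory=list
    )
    name: str = "network"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        sset = set(self.species)
        for s in self.initial:
            if s not in sset:
                raise ValueError(f"initial count for unknown species {s!r}")
        for s, v in self.initial.items():
            if v < 0 or v != int(v):
                raise ValueError(f"initial count of {s} must be a non-negative int")
        for r in self.reactions:
            for s in list(r.changes) + list(r.reactants) + list(r.modifiers):
                if s not in sset:
                    raise ValueError(f"reaction {r.name!r} uses unknown species {s!r}")
            if r.qssa is not None:
                for src in (r.qssa.total, r.qssa.partner):
                    if isinstance(src, str) and src not in sset:
                        raise ValueError(
                            f"reaction {r.name!r} qssa source {src!r} unknown"
                        )
        for cname, coefs, value in self.conserved_totals:
            for r in self.reactions:
                drift = sum(coefs.get(s, 0) * d for s, d in r.changes.items())
                if drift != 0:
                    raise ValueError(
                        f"conserved total {cname!r} broken by reaction {r.name!r}"
                    )
            init_val = sum(coefs.get(s, 0) * self.initial.get(s, 0) for s in coefs)
            if init_val != value:
                raise ValueError(
                    f"conserved total {cname!r}: initial value {init_val} != {value}"
                )


@dataclass
class Trajectory:
    """A piecewise-constant sample path (right-continuous)."""

    times: np.ndarray
    states: np.ndarray  # shape (len(times), n_species), integer counts
    species: list[str]
    seed: int
    recording_mode: str  # "grid" | "events"

    def series(self, species: str) -> np.ndarray:
        return self.states[:, self.species.index(species)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=self.species)
        df.insert(0, "time", self.times)
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, seed: int = -1) -> "Trajectory":
        df = pd.read_csv(path)
        return cls(
            times=df["time"].to_numpy(float),
            states=df.drop(columns="time").to_numpy(np.int64),
            species=[c for c in df.columns if c != "time"],
            seed=seed,
            recording_mode="grid",
        )


def _estimator_fn(term: QssaTerm, policies: dict[str, ReductionPolicy] | None):
    """Compile a QssaTerm into value(a_t, b_t) with a per-totals cache."""
    est, kd = term.estimator, term.K_d
    if est == "adaptive":
        if not policies or term.pair_name not in policies:
            raise SimulationError(
                f"adaptive estimator for pair {term.pair_name!r} needs a policy"
            )
        pol = policies[term.pair_name]
        if not math.isclose(pol.K_d, kd, rel_tol=1e-9):
            raise SimulationError(
                f"policy K_d {pol.K_d} != pair K_d {kd} for {term.pair_name!r}"
            )

    def unbound(a_t: int, b_t: int) -> float:
        if a_t == 0:
            return 0.0
        if est == "stqssa":
            return stqssa_unbound(float(a_t), float(b_t), kd)
        if est == "exact":
            return exact_mean(BindingPair(a_t, b_t, kd)).value
        if est == "sqssa":
            return a_t * kd / (b_t + kd)
        if est == "adaptive":
            if a_t < pol.threshold_total:
                return slqssa_unbound(a_t, b_t, kd, pol.L)
            return stqssa_unbound(float(a_t), float(b_t), kd)
        k = int(est.split(":", 1)[1])
        return slqssa_unbound(a_t, b_t, kd, k)

    cache: dict[tuple[int, int], float] = {}

    def value(a_t: int, b_t: int) -> float:
        key = (a_t, b_t)
        v = cache.get(key)
        if v is None:
            u = unbound(a_t, b_t)
            if term.role == "complex":
                v = a_t - u
            elif term.role == "partner":
                v = max(b_t - a_t + u, 0.0)
            else:
                v = u
            if len(cache) < 200_000:
                cache[key] = v
        return v

    return value


class _Compiled:
    """Index-resolved network ready for the event loop."""

    def __init__(
        self,
        net: ReactionNetwork,
        policies: dict[str, ReductionPolicy] | None,
    ):
        self.species = list(net.species)
        idx = {s: i for i, s in enumerate(self.species)}
        self.init = np.array(
            [net.initial.get(s, 0) for s in self.species], dtype=np.int64
        )
        self.stoich = [
            [(idx[s], d) for s, d in r.changes.items() if d != 0]
            for r in net.reactions
        ]
        self.fns = []
        depends: list[set[int]] = []
        for r in net.reactions:
            deps = {idx[s] for s in r.reactants} | {idx[s] for s in r.modifiers}
            react = [(idx[s], n) for s, n in r.reactants.items()]
            mods = [(idx[s], p) for s, p in r.modifiers.items()]
            t_idx = p_idx = None
            t_const = p_const = 0
            qval = None
            qpow = 1
            if r.qssa is not None:
                term = r.qssa
                if isinstance(term.total, str):
                    t_idx = idx[term.total]
                    deps.add(t_idx)
                else:
                    t_const = int(round(float(term.total)))
                if isinstance(term.partner, str):
                    p_idx = idx[term.partner]
                    deps.add(p_idx)
                else:
                    p_const = int(round(float(term.partner)))
                qval = _estimator_fn(term, policies)
                qpow = term.power

            def fn(
                state,
                rate=r.rate,
                react=react,
                mods=mods,
                qval=qval,
                t_idx=t_idx,
                p_idx=p_idx,
                t_const=t_const,
                p_const=p_const,
                qpow=qpow,
            ):
                a = rate
                for i, n in react:
                    x = state[i]
                    for m in range(n):
                        a *= x - m
                    if a <= 0.0:
                        return 0.0
                for i, p in mods:
                    a *= float(state[i]) ** p
                if qval is not None:
                    a_t = state[t_idx] if t_idx is not None else t_const
                    b_t = state[p_idx] if p_idx is not None else p_const
                    v = qval(int(a_t), int(b_t))
                    a *= v if qpow == 1 else v**qpow
                return a

            self.fns.append(fn)
            depends.append(deps)
        # reaction -> reactions whose propensity must be refreshed after it
        self.affects: list[list[int]] = []
        for j, changes in enumerate(self.stoich):
            changed = {i for i, _ in changes}
            self.affects.append(
                [k for k, deps in enumerate(depends) if deps & changed]
            )
        self.names = [r.name for r in net.reactions]


def _recording_plan(recording, t_end: float):
    if recording in (None, "events"):
        return "events", None
    if isinstance(recording, tuple) and recording[0] == "grid":
        dt = float(recording[1])
    elif isinstance(recording, (int, float)):
        dt = float(recording)
    else:
        raise ValueError(f"bad recording spec {recording!r}")
    if dt <= 0:
        raise ValueError("recording grid step must be positive")
    n = int(math.floor(t_end / dt + 1e-9)) + 1
    return "grid", np.arange(n) * dt


def simulate(
    network: ReactionNetwork,
    t_end: float,
    seed: int,
    recording=("grid", 1.0),
    policies: dict[str, ReductionPolicy] | None = None,
) -> Trajectory:
    """Sample one exact SSA path of ``network`` up to ``t_end``.

    ``recording`` is ``("grid", dt)`` (or a bare number ``dt``) for
    fixed-grid sampling, or ``"events"`` to record every jump.  The same
    ``(network, t_end, seed, recording)`` reproduces the identical path.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    comp = _Compiled(network, policies)
    mode, grid = _recording_plan(recording, t_end)
    rng = np.random.default_rng(seed)
    state = comp.init.copy()
    fns, stoich, affects = comp.fns, comp.stoich, comp.affects
    props = [f(state) for f in fns]
    _check_props(props, state, comp)

    if mode == "grid":
        rec_states = np.empty((len(grid), len(state)), dtype=np.int64)
        next_rec = 0
    else:
        ev_times = [0.0]
        ev_states = [state.copy()]

    t = 0.0
    chunk = rng.random(_RNG_CHUNK)
    ptr = 0
    n_rx = len(fns)
    while True:
        total = 0.0
        for a in props:
            total += a
        if total <= 0.0:
            break
        if ptr >= _RNG_CHUNK - 1:
            chunk = rng.random(_RNG_CHUNK)
            ptr = 0
        u1 = chunk[ptr]
        u2 = chunk[ptr + 1]
        ptr += 2
        t_next = t + (-math.log(1.0 - u1) / total)
        if mode == "grid":
            while next_rec < len(grid) and grid[next_rec] < t_next:
                rec_states[next_rec] = state
                next_rec += 1
        if t_next > t_end:
            t = t_end
            break
        t = t_next
        target = u2 * total
        acc = 0.0
        j = n_rx - 1
        for i in range(n_rx):
            acc += props[i]
            if target < acc:
                j = i
                break
        for i, d in stoich[j]:
            state[i] += d
            if state[i] < 0:
                raise SimulationError(
                    f"negative count of {comp.species[i]} after {comp.names[j]}: "
                    f"state={dict(zip(comp.species, state.tolist()))}"
                )
        for k in affects[j]:
            a = fns[k](state)
            if a < 0.0 or not math.isfinite(a):
                raise SimulationError(
                    f"invalid propensity {a!r} for {comp.names[k]} at "
                    f"state={dict(zip(comp.species, state.tolist()))}"
                )
            props[k] = a
        if mode == "events":
            ev_times.append(t)
            ev_states.append(state.copy())

    if mode == "grid":
        while next_rec < len(grid):
            rec_states[next_rec] = state
            next_rec += 1
        return Trajectory(grid, rec_states, comp.species, seed, "grid")
    times = np.asarray(ev_times)
    return Trajectory(times, np.vstack(ev_states), comp.species, seed, "events")


def _check_props(props, state, comp):
    for a, nm in zip(props, comp.names):
        if a < 0.0 or not math.isfinite(a):
            raise SimulationError(
                f"invalid initial propensity {a!r} for {nm}: "
                f"state={dict(zip(comp.species, state.tolist()))}"
            )


def simulate_reduced(
    network: ReactionNetwork,
    policy_map: dict[str, ReductionPolicy] | None,
    t_end: float,
    seed: int,
    recording=("grid", 1.0),
) -> Trajectory:
    """Simulate a reduced network whose propensities carry QSSA terms.

    ``policy_map`` supplies a certified :class:`ReductionPolicy` per
    ``pair_name`` for reactions using the ``adaptive`` estimator; networks
    whose QSSA terms name a fixed estimator need no policy.  Estimators
    are re-evaluated from the current slow totals at every propensity
    refresh, so real-valued (non-integer) propensities occur by design.
    """
    missing = [
        r.qssa.pair_name
        for r in network.reactions
        if r.qssa is not None
        and r.qssa.estimator == "adaptive"
        and (policy_map is None or r.qssa.pair_name not in policy_map)
    ]
    if missing:
        raise SimulationError(f"missing policy for pair(s): {sorted(set(missing))}")
    return simulate(network, t_end, seed, recording, policies=policy_map)


def ensemble(
    network: ReactionNetwork,
    n_paths: int,
    t_end: float,
    base_seed: int,
    recording=("grid", 1.0),
    policy_map: dict[str, ReductionPolicy] | None = None,
) -> list[Trajectory]:
    """``n_paths`` independent paths seeded ``base_seed + i``."""
    if n_paths < 1:
        raise ValueError("n_paths must be >= 1")
    return [
        simulate(network, t_end, base_seed + i, recording, policies=policy_map)
        for i in range(n_paths)
    ]
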