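"""Gillespie SSA kernels for RNA folding kinetics.

Two simulators share one event rule.  The single-trajectory simulator
(``simulate_fold``) walks one molecule from a start structure to an
absorbing target, drawing per event two uniforms: xi1 selects the move by
the cumulative-propensity rule, xi2 sets the exponential waiting time
tau = ln(1/xi2)/a_sum.  The ensemble simulator (``simulate_ensemble``)
runs n molecules under ONE global clock and ONE flattened propensity
vector: each event advances exactly one molecule and recomputes only that
molecule's neighborhood; folded molecules drop out of the propensity sum,
which makes the remaining transitions proportionally more probable.
Neighborhoods and rates are memoized in a shared LRU cache because folding
paths revisit the same basins over and over.

Rates follow the Metropolis rule (1 downhill, exp(-dG/RT) uphill) or the
Kawasaki rule (exp(-dG/2RT) both ways); both satisfy detailed balance with
the Boltzmann distribution at thermal energy RT.  Time units are
arbitrary: one unit is one expected event at a_sum = 1.
"""

from __future__ import annotations

import logging
import math
from collections import OrderedDict
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .energy import EnergyModel, RT_37C
from .errors import AbsorbingStateError, DeadEndError, StateSpaceTooLargeError
from .movesets import (DEFAULT_CONSTRAINTS, MoveConstraints, Neighborhood,
                       neighborhood)
from .structures import base_pair_distance

logger = logging.getLogger(__name__)

#: rates are clamped here to keep a_sum finite on pathological parameters
MAX_RATE = 1e12


@dataclass(frozen=True)
class RateModel:
    """Transition-rate rule: ``metropolis`` or ``kawasaki``, at thermal RT."""

    kind: str = "metropolis"
    RT: float = RT_37C

    def __post_init__(self):
        if self.kind not in ("metropolis", "kawasaki"):
            raise ValueError(f"unknown rate model {self.kind!r}")
        if self.RT <= 0:
            raise ValueError("RT must be positive")


def transition_rate(dG, model: RateModel):
    """Rate of a move with free-energy change ``dG`` (kcal/mol).

    Metropolis: 1 for downhill (dG < 0), exp(-dG/RT) uphill.
    Kawasaki:   exp(-dG/(2 RT)) for all dG.
    Accepts scalars or arrays; overflowing rates are clamped to
    ``MAX_RATE`` with a logged warning.
    """
    dG = np.asarray(dG, dtype=float)
    with np.errstate(over="ignore"):
        if model.kind == "metropolis":
            rates = np.where(dG >= 0, np.exp(-np.minimum(dG, 700.0) / model.RT), 1.0)
        else:
            rates = np.exp(-np.minimum(dG, 1400.0) / (2.0 * model.RT))
    if np.any(rates > MAX_RATE):
        logger.warning("transition rate exceeded %g; clamping", MAX_RATE)
        rates = np.minimum(rates, MAX_RATE)
    if rates.ndim == 0:
        return float(rates)
    return rates


class _Entry:
    """Cached per-state kinetics: neighborhood, rates, cumulative sums."""

    __slots__ = ("nbhd", "rates", "cumsum", "a_sum")

    def __init__(self, nbhd: Neighborhood, rates: np.ndarray):
        self.nbhd = nbhd
        self.rates = rates
        self.cumsum = np.cumsum(rates)
        self.a_sum = float(self.cumsum[-1]) if len(rates) else 0.0


class NeighborhoodCache:
    """LRU memoization of neighborhoods and their rates.

    Keyed by (sequence, structure); a hit returns content identical to a
    fresh computation, so caching never changes a trajectory.  Capacity 0
    disables caching entirely.
    """

    def __init__(self, capacity: int = 10_000):
        if capacity < 0:
            raise ValueError("capacity must be >= 0")
        self.capacity = capacity
        self._data: OrderedDict[tuple[str, str], _Entry] = OrderedDict()
        self.hits = 0
        self.misses = 0

    def __len__(self) -> int:
        return len(self._data)

    def get(self, key: tuple[str, str]) -> Optional[_Entry]:
        entry = self._data.get(key)
        if entry is not None:
            self._data.move_to_end(key)
            self.hits += 1
        else:
            self.misses += 1
        return entry

    def put(self, key: tuple[str, str], entry: _Entry) -> None:
        if self.capacity == 0:
            return
        self._data[key] = entry
        self._data.move_to_end(key)
        while len(self._data) > self.capacity:
            self._data.popitem(last=False)


@dataclass
class SimulationConfig:
    """Everything a simulation needs besides the molecules themselves."""

    energy: EnergyModel
    rates: RateModel = field(default_factory=RateModel)
    constraints: MoveConstraints = DEFAULT_CONSTRAINTS
    cache_capacity: int = 10_000
    max_steps: int = 50_000_000
    stop_time: float = math.inf
    mfe_cap: int = 200_000

    def new_cache(self) -> NeighborhoodCache:
        return NeighborhoodCache(self.cache_capacity)


def _energy_of(config: SimulationConfig, seq: str, struct: str,
               ecache: dict) -> float:
    value = ecache.get(struct)
    if value is None:
        value = config.energy.evaluate(seq, struct)
        ecache[struct] = value
    return value


def _entry_for(config: SimulationConfig, seq: str, struct: str,
               cache: Optional[NeighborhoodCache],
               ecache: dict) -> _Entry:
    if cache is not None:
        entry = cache.get((seq, struct))
        if entry is not None:
            return entry
    nbhd = neighborhood(seq, struct, config.constraints)
    g0 = _energy_of(config, seq, struct, ecache)
    dG = np.array(
        [_energy_of(config, seq, s, ecache) - g0 for s in nbhd.structs],
        dtype=float,
    )
    entry = _Entry(nbhd, np.atleast_1d(transition_rate(dG, config.rates))
                   if len(dG) else np.empty(0))
    if cache is not None:
        cache.put((seq, struct), entry)
    return entry


def build_rates(seq: str, struct: str, energy: EnergyModel,
                model: RateModel,
                cache: Optional[NeighborhoodCache] = None,
                constraints: MoveConstraints = DEFAULT_CONSTRAINTS,
                absorbing: bool = False,
                ) -> tuple[Neighborhood, np.ndarray, float]:
    """Neighborhood of ``struct`` with per-neighbor rates and their sum.

    Rate k is ``transition_rate(G(neighbor k) - G(struct))``.  With
    ``absorbing=True`` (the state IS the folding target) the neighborhood
    is empty and a_sum is 0: a folded molecule never moves again.
    """
    if absorbing:
        return Neighborhood(seq, struct, []), np.empty(0), 0.0
    config = SimulationConfig(energy=energy, rates=model,
                              constraints=constraints)
    entry = _entry_for(config, seq, struct, cache, {})
    if len(entry.rates) == 0:
        raise DeadEndError(
            f"structure {struct!r} has no neighbors but is not absorbing"
        )
    return entry.nbhd, entry.rates.copy(), entry.a_sum


def ssa_step(rates: Sequence[float], a_sum: float,
             xi1: float, xi2: float) -> tuple[int, float]:
    """One SSA event: pick reaction j and waiting time tau.

    ``j`` (0-based) is the smallest index whose cumulative rate exceeds
    ``xi1 * a_sum``; ``tau = ln(1/xi2) / a_sum``.
    """
    if a_sum <= 0:
        raise AbsorbingStateError("total rate is zero; no move possible")
    cumsum = np.cumsum(np.asarray(rates, dtype=float))
    j = int(np.searchsorted(cumsum, xi1 * a_sum, side="right"))
    tau = math.log(1.0 / xi2) / a_sum
    return j, tau


def _draw(rng: np.random.Generator) -> float:
    """A uniform (0,1) draw; exact zeros are rejected and redrawn."""
    x = rng.random()
    while x == 0.0:
        x = rng.random()
    return x


@dataclass
class Trajectory:
    """One molecule's folding path.

    ``records`` holds (time, structure, energy) tuples, starting with the
    start structure at t = 0; when ``record`` was disabled at simulation
    time only the first and last states are kept.
    """

    sequence: str
    records: list[tuple[float, str, float]]
    first_passage_time: Optional[float]
    terminated_reason: str  # target_reached | time_limit | step_limit
    n_steps: int

    @property
    def final_structure(self) -> str:
        return self.records[-1][1]


def simulate_fold(seq: str, start: str, target: str,
                  config: SimulationConfig,
                  seed: Optional[int] = None,
                  rng: Optional[np.random.Generator] = None,
                  cache: Optional[NeighborhoodCache] = None,
                  ecache: Optional[dict] = None,
                  record: bool = True) -> Trajectory:
    """Single-trajectory SSA: fold ``seq`` from ``start`` until ``target``.

    Fully reproducible: the same seed yields the same event stream
    (exactly two uniform draws per event, xi1 then xi2).  Hitting
    ``config.max_steps`` or ``config.stop_time`` returns a truncated
    trajectory (terminated_reason tells which), not an exception.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if cache is None:
        cache = config.new_cache()
    if ecache is None:
        ecache = {}
    g = _energy_of(config, seq, start, ecache)
    t = 0.0
    struct = start
    records = [(0.0, start, g)]
    n_steps = 0
    if struct == target:
        return Trajectory(seq, records, 0.0, "target_reached", 0)
    while True:
        entry = _entry_for(config, seq, struct, cache, ecache)
        a_sum = entry.a_sum
        if a_sum <= 0:
            raise DeadEndError(
                f"no exit from {struct!r} (disable absorbing states "
                "other than the target)"
            )
        xi1 = _draw(rng)
        xi2 = _draw(rng)
        j = int(np.searchsorted(entry.cumsum, xi1 * a_sum, side="right"))
        tau = math.log(1.0 / xi2) / a_sum
        if t + tau > config.stop_time:
            if record:
                records.append((config.stop_time, struct,
                                _energy_of(config, seq, struct, ecache)))
            else:
                records = [records[0],
                           (config.stop_time, struct,
                            _energy_of(config, seq, struct, ecache))]
            return Trajectory(seq, records, None, "time_limit", n_steps)
        t += tau
        struct = entry.nbhd.neighbors[j][1]
        n_steps += 1
        g = _energy_of(config, seq, struct, ecache)
        if record:
            records.append((t, struct, g))
        if struct == target:
            if not record:
                records = [records[0], (t, struct, g)]
            return Trajectory(seq, records, t, "target_reached", n_steps)
        if n_steps >= config.max_steps:
            if not record:
                records = [records[0], (t, struct, g)]
            return Trajectory(seq, records, None, "step_limit", n_steps)


@dataclass
class Molecule:
    """Per-molecule slot of the ensemble state."""

    sequence: str
    struct: str
    target: str
    folded: bool = False
    fold_time: Optional[float] = None


@dataclass
class EnsembleState:
    """Resumable state of an ensemble (global-clock) simulation.

    Holds every molecule's current structure, the global clock, the RNG,
    and — when the previous run was cut off mid-event — the pending pair
    of uniform draws, so that resuming reproduces the uninterrupted event
    stream bit for bit.
    """

    molecules: list[Molecule]
    t: float = 0.0
    rng: Optional[np.random.Generator] = None
    pending: Optional[tuple[float, float]] = None
    n_events: int = 0

    @property
    def n_folded(self) -> int:
        return sum(m.folded for m in self.molecules)

    @property
    def all_folded(self) -> bool:
        return all(m.folded for m in self.molecules)


@dataclass
class FoldRecord:
    """Outcome of one molecule of an ensemble run."""

    molecule_id: int
    sequence: str
    fold_time: Optional[float]
    folded: bool
    bp_distance_remaining: int


def _records_from(state: EnsembleState) -> list[FoldRecord]:
    return [
        FoldRecord(
            molecule_id=i,
            sequence=m.sequence,
            fold_time=m.fold_time,
            folded=m.folded,
            bp_distance_remaining=(0 if m.folded else
                                   base_pair_distance(m.struct, m.target)),
        )
        for i, m in enumerate(state.molecules)
    ]


def simulate_ensemble(specs: Sequence[tuple[str, str, str]],
                      config: SimulationConfig,
                      seed: Optional[int] = None,
                      state: Optional[EnsembleState] = None,
                      cache: Optional[NeighborhoodCache] = None,
                      stop_time: Optional[float] = None,
                      ) -> tuple[list[FoldRecord], EnsembleState]:
    """Ensemble SSA: fold many molecules under one global clock.

    ``specs`` is a list of (sequence, start, target) triples — identical
    triples repeat one experiment, distinct ones (e.g. point mutants of a
    wildtype) are co-simulated in the same propensity space.  One shared
    LRU cache serves all molecules.  Each event selects one flat
    propensity index over all live molecules, advances that molecule only,
    and recomputes only its neighborhood.  Molecules that reach their
    target drop out of the propensity sum.

    The run stops when all molecules fold, or at ``stop_time`` (anytime
    mode): the returned state can be passed back (with a later stop time)
    and the continuation is event-identical to an uninterrupted run.
    Pass ``state`` to resume; ``specs`` is then ignored.
    """
    if state is None:
        if len(specs) == 0:
            raise ValueError("need at least one molecule spec")
        rng = np.random.default_rng(seed)
        molecules = [Molecule(seq, start, target)
                     for seq, start, target in specs]
        state = EnsembleState(molecules=molecules, t=0.0, rng=rng)
        # pre-loop stop check: molecules starting at their target count as
        # folded at t = 0
        for m in molecules:
            if m.struct == m.target:
                m.folded = True
                m.fold_time = 0.0
    horizon = stop_time if stop_time is not None else config.stop_time
    if cache is None:
        cache = config.new_cache()
    ecache: dict[str, dict] = {}
    mols = state.molecules
    n = len(mols)

    def entry_of(m: Molecule) -> Optional[_Entry]:
        if m.folded:
            return None
        ec = ecache.setdefault(m.sequence, {})
        return _entry_for(config, m.sequence, m.struct, cache, ec)

    entries: list[Optional[_Entry]] = [entry_of(m) for m in mols]
    totals = np.array([0.0 if e is None else e.a_sum for e in entries])
    rng = state.rng
    while not state.all_folded and state.n_events < config.max_steps:
        a_sum = float(totals.sum())
        if a_sum <= 0:
            raise DeadEndError("live molecules but zero total rate")
        if state.pending is not None:
            xi1, xi2 = state.pending
        else:
            xi1 = _draw(rng)
            xi2 = _draw(rng)
        tau = math.log(1.0 / xi2) / a_sum
        if state.t + tau > horizon:
            # stash the draws: resuming recomputes the same event
            state.pending = (xi1, xi2)
            break
        state.pending = None
        r = xi1 * a_sum
        mol_cum = np.cumsum(totals)
        mi = int(np.searchsorted(mol_cum, r, side="right"))
        local_r = r - (mol_cum[mi - 1] if mi > 0 else 0.0)
        entry = entries[mi]
        j = int(np.searchsorted(entry.cumsum, local_r, side="right"))
        j = min(j, len(entry.rates) - 1)  # guard fp edge at segment border
        state.t += tau
        state.n_events += 1
        m = mols[mi]
        m.struct = entry.nbhd.neighbors[j][1]
        if m.struct == m.target:
            m.folded = True
            m.fold_time = state.t
            entries[mi] = None
            totals[mi] = 0.0
        else:
            entries[mi] = entry_of(m)
            totals[mi] = entries[mi].a_sum
    if not state.all_folded and state.pending is None:
        logger.warning("ensemble stopped at max_steps=%d", config.max_steps)
    # note: state.t is NOT advanced to the horizon on truncation — the
    # pending event must fire at (t at draw) + tau when resumed
    return _records_from(state), state


def extract_results(state: EnsembleState, t_cut: float,
                    ) -> tuple[list[float], list[tuple[int, int]]]:
    """Anytime extraction at time ``t_cut``.

    Returns (fold times of molecules folded by t_cut, list of
    (molecule_id, base-pair distance to target) for the rest).  The
    distance predicts how much folding work remains, i.e. the error made
    by stopping early.
    """
    if t_cut < 0:
        raise ValueError("t_cut must be >= 0")
    folded: list[float] = []
    unfolded: list[tuple[int, int]] = []
    for i, m in enumerate(state.molecules):
        if m.folded and m.fold_time <= t_cut:
            folded.append(m.fold_time)
        else:
            unfolded.append((i, base_pair_distance(m.struct, m.target)))
    return folded, unfolded


def sample_first_passage_times(seq: str, n: int, config: SimulationConfig,
                               seed: Optional[int] = None,
                               start: Optional[str] = None,
                               target: Optional[str] = None) -> np.ndarray:
    """First-passage times of ``n`` independent single-trajectory runs.

    One RNG stream, one shared neighborhood cache and one energy cache
    serve all runs.  ``start`` defaults to the open chain; ``target``
    defaults to the minimum-free-energy structure (by enumeration, or by
    the Turner backend's predictor for long sequences).  Trajectories
    that hit a step or time limit contribute NaN.
    """
    if start is None:
        start = "." * len(seq)
    if target is None:
        target = default_target(seq, config)
    rng = np.random.default_rng(seed)
    cache = config.new_cache()
    ecache: dict = {}
    times = np.empty(n)
    for i in range(n):
        traj = simulate_fold(seq, start, target, config, rng=rng,
                             cache=cache, ecache=ecache, record=False)
        times[i] = (traj.first_passage_time
                    if traj.terminated_reason == "target_reached"
                    else np.nan)
    return times


def default_target(seq: str, config: SimulationConfig) -> str:
    """The folding target Op(R): the MFE structure under the active model.

    The Turner backend has its own MFE predictor; other models fall back
    to exhaustive enumeration (refused beyond ``config.mfe_cap``).
    """
    if hasattr(config.energy, "mfe"):
        return config.energy.mfe(seq)[0]
    return mfe_structure(seq, config.energy, config.constraints,
                         config.mfe_cap)


def mfe_structure(seq: str, energy: EnergyModel,
                  constraints: MoveConstraints = DEFAULT_CONSTRAINTS,
                  cap: int = 200_000) -> str:
    """Default folding target: the minimum-free-energy structure.

    Found by exhaustive enumeration under the active energy model; ties
    are broken lexicographically on the dot-bracket string (logged).  For
    sequences beyond the enumeration cap the target must be supplied by
    the caller (e.g. from an external MFE predictor).
    """
    from .movesets import enumerate_structures

    structs = enumerate_structures(seq, constraints, cap)
    energies = [energy.evaluate(seq, s) for s in structs]
    best = min(energies)
    winners = sorted(s for s, g in zip(structs, energies) if g == best)
    if len(winners) > 1:
        logger.info("MFE tie among %d structures; lexicographic pick",
                    len(winners))
    return winners[0]
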