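"""Exact chemical-master-equation oracle on enumerable structure spaces.

For a sequence whose feasible structure set F(R) can be enumerated, the
folding process is a finite continuous-time Markov chain.  Its master
equation dP/dt = Q^T P — one linear ODE per structure — is solved exactly
here, both freely (relaxation to the Boltzmann distribution) and with the
folding target made absorbing, in which case the probability mass absorbed
at the target by time t IS the folding-time CDF.  This is the ground truth
the stochastic simulators are verified against; it is for verification,
not production — the state count M(R) grows exponentially with length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.sparse.csgraph import connected_components

from .energy import EnergyModel
from .errors import SSAFoldError
from .kinetics import RateModel, transition_rate
from .movesets import (DEFAULT_CONSTRAINTS, MoveConstraints,
                       enumerate_structures, neighborhood)

logger = logging.getLogger(__name__)

#: above this state count a dense generator is replaced by a sparse one
DENSE_LIMIT = 2_000


@dataclass
class StateSpace:
    """The enumerated structure space of one sequence.

    states are in canonical (lexicographic) order and always include the
    open chain; adjacency[i] lists the state indices one move away from
    state i (symmetric by move reversibility).
    """

    sequence: str
    states: list[str]
    energies: np.ndarray
    adjacency: list[list[int]]
    constraints: MoveConstraints = DEFAULT_CONSTRAINTS

    @property
    def M(self) -> int:
        return len(self.states)

    def index(self, struct: str) -> int:
        try:
            return self._index[struct]
        except AttributeError:
            self._index = {s: i for i, s in enumerate(self.states)}
            return self._index[struct]

    def boltzmann(self, RT: float) -> np.ndarray:
        """Equilibrium distribution exp(-G_i/RT)/Z."""
        w = np.exp(-(self.energies - self.energies.min()) / RT)
        return w / w.sum()


def build_state_space(seq: str, energy: EnergyModel,
                      constraints: MoveConstraints = DEFAULT_CONSTRAINTS,
                      cap: int = 200_000) -> StateSpace:
    """Enumerate F(R) with per-state energies and move adjacency."""
    states = enumerate_structures(seq, constraints, cap)
    index = {s: i for i, s in enumerate(states)}
    energies = np.array([energy.evaluate(seq, s) for s in states])
    adjacency = []
    for s in states:
        nbrs = sorted({index[t] for t in neighborhood(seq, s, constraints).structs})
        adjacency.append(nbrs)
    for i, nbrs in enumerate(adjacency):
        for j in nbrs:
            if i not in adjacency[j]:
                raise SSAFoldError(
                    "asymmetric adjacency: "
                    f"{states[i]!r} -> {states[j]!r} but not back"
                )
    return StateSpace(seq, states, energies, adjacency, constraints)


def build_rate_matrix(space: StateSpace, model: RateModel,
                      absorbing: int | str | None = None) -> np.ndarray:
    """The CTMC generator Q: Q[i, j] = rate(i -> j), diagonal = -row sum.

    With ``absorbing`` set (state index or structure string), that state's
    outgoing row is zeroed — probability reaching it stays there, which
    turns occupancy of the target into a first-passage CDF.  Returns a
    dense array up to ``DENSE_LIMIT`` states, scipy CSR beyond.
    """
    M = space.M
    if isinstance(absorbing, str):
        absorbing = space.index(absorbing)
    if M <= DENSE_LIMIT:
        Q = np.zeros((M, M))
        for i, nbrs in enumerate(space.adjacency):
            if absorbing is not None and i == absorbing:
                continue
            dg = space.energies[nbrs] - space.energies[i]
            Q[i, nbrs] = transition_rate(dg, model)
        Q[np.arange(M), np.arange(M)] = -Q.sum(axis=1)
        return Q
    from scipy.sparse import lil_matrix

    Q = lil_matrix((M, M))
    for i, nbrs in enumerate(space.adjacency):
        if absorbing is not None and i == absorbing:
            continue
        dg = space.energies[nbrs] - space.energies[i]
        Q[i, nbrs] = transition_rate(dg, model)
    Q.setdiag(-np.asarray(Q.sum(axis=1)).ravel())
    return Q.tocsr()


def solve_cme(Q, p0: np.ndarray, times: np.ndarray,
              rtol: float = 1e-9, atol: float = 1e-12) -> np.ndarray:
    """Solve dP/dt = Q^T P on the given time grid.

    Returns an array of shape (len(times), M); each row is a probability
    vector.  The grid need not start at 0.  Raises a solver error with a
    tolerance hint on stiff failure.
    """
    p0 = np.asarray(p0, dtype=float)
    if np.any(p0 < -1e-12) or abs(p0.sum() - 1.0) > 1e-9:
        raise ValueError("p0 must be a probability vector")
    times = np.asarray(times, dtype=float)
    QT = Q.T if not hasattr(Q, "tocsr") else Q.T.tocsr()

    def rhs(_t, p):
        return QT @ p

    dense = not hasattr(Q, "tocsr")
    sol = solve_ivp(rhs, (0.0, float(times[-1])), p0, t_eval=times,
                    method="BDF", rtol=rtol, atol=atol,
                    jac=(QT if dense else None))
    if not sol.success:
        raise SSAFoldError(
            f"CME integration failed: {sol.message}; try looser rtol/atol"
        )
    P = sol.y.T
    sums = P.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-6):
        raise SSAFoldError("probability not conserved; tighten tolerances")
    return P


def first_passage_cdf(space: StateSpace, model: RateModel,
                      start: str, target: str,
                      times: np.ndarray) -> np.ndarray:
    """Exact folding-time CDF: P(first passage to target <= t).

    Computed by making the target absorbing and reading the probability
    mass accumulated there.  Nondecreasing; tends to 1 for a connected
    space.  A target unreachable from the start yields a plateau below 1
    (with a warning).
    """
    ti = space.index(target)
    si = space.index(start)
    Qa = build_rate_matrix(space, model, absorbing=ti)
    adj = np.zeros((space.M, space.M), dtype=bool)
    for i, nbrs in enumerate(space.adjacency):
        adj[i, nbrs] = True
    ncomp, labels = connected_components(adj, directed=False)
    if labels[si] != labels[ti]:
        logger.warning("target unreachable from start; CDF will plateau")
    p0 = np.zeros(space.M)
    p0[si] = 1.0
    P = solve_cme(Qa, p0, times)
    return P[:, ti]
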