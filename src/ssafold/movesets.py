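"""Single-step move set and neighborhood generation.

The kinetic neighborhood of a structure is the set of structures reachable
by one elementary move: adding a base pair, removing a base pair, or
shifting one end of an existing pair to a new partner (the Kinfold-style
shift move).  Feasibility means canonical/wobble pairing (AU, GC, GU), a
minimum hairpin loop of unpaired bases, and no crossing pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional

from .errors import StateSpaceTooLargeError
from .structures import pair_table

_VALID_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE_PAIRS = {("G", "U"), ("U", "G")}


@dataclass(frozen=True)
class MoveConstraints:
    """Feasibility constraints for the move set.

    min_loop
        Minimum number of unpaired bases enclosed by a hairpin-closing
        pair; a pair (i, j) requires j - i > min_loop.  Default 3, the
        standard steric constraint.
    allow_shift
        Enable shift moves (disable for a pure add/remove move set).
    allow_gu
        Treat G·U wobbles as valid pairs.
    """

    min_loop: int = 3
    allow_shift: bool = True
    allow_gu: bool = True


DEFAULT_CONSTRAINTS = MoveConstraints()

_KIND_RANK = {"add": 0, "remove": 1, "shift": 2}


class Move(NamedTuple):
    """One elementary structural change.

    ``add`` carries only ``to_pair``; ``remove`` only ``from_pair``;
    ``shift`` carries both, sharing exactly one index.
    """

    kind: str
    from_pair: Optional[tuple[int, int]]
    to_pair: Optional[tuple[int, int]]


@dataclass
class Neighborhood:
    """The single-step neighborhood of ``struct``: ordered, duplicate-free.

    ``neighbors`` is a list of ``(Move, structure string)`` in canonical
    order (add < remove < shift, then lexicographic on move indices).
    """

    sequence: str
    struct: str
    neighbors: list[tuple[Move, str]] = field(default_factory=list)

    @property
    def structs(self) -> list[str]:
        return [s for _, s in self.neighbors]

    def __len__(self) -> int:
        return len(self.neighbors)


def is_valid_pair(x: str, y: str, allow_gu: bool = True) -> bool:
    """True iff bases x, y can pair (AU, GC, and optionally GU wobble)."""
    if (x, y) in _VALID_PAIRS:
        return True
    return allow_gu and (x, y) in _WOBBLE_PAIRS


def _noncrossing(table: list[int], i: int, j: int) -> bool:
    """Candidate pair (i, j) nests properly with the pairs in ``table``."""
    for k in range(i + 1, j):
        p = table[k]
        if p >= 0 and not (i < p < j):
            return False
    return True


def _apply(struct: str, remove: Optional[tuple[int, int]],
           add: Optional[tuple[int, int]]) -> str:
    chars = list(struct)
    if remove is not None:
        chars[remove[0]] = chars[remove[1]] = "."
    if add is not None:
        chars[add[0]], chars[add[1]] = "(", ")"
    return "".join(chars)


def neighborhood(seq: str, struct: str,
                 constraints: MoveConstraints = DEFAULT_CONSTRAINTS) -> Neighborhood:
    """All structures one elementary move away from ``struct``.

    The result is all and only the feasible single-move neighbors, in a
    deterministic canonical order, so that two calls on the same state are
    interchangeable (required for memoization).
    """
    n = len(struct)
    table = pair_table(struct)  # validates struct
    min_loop = constraints.min_loop
    allow_gu = constraints.allow_gu
    pairs = sorted((i, table[i]) for i in range(n) if 0 <= i < table[i])

    adds: list[tuple[Move, str]] = []
    for i in range(n):
        if table[i] >= 0:
            continue
        for j in range(i + min_loop + 1, n):
            if table[j] >= 0:
                continue
            if not is_valid_pair(seq[i], seq[j], allow_gu):
                continue
            if not _noncrossing(table, i, j):
                continue
            adds.append((Move("add", None, (i, j)), _apply(struct, None, (i, j))))

    removes: list[tuple[Move, str]] = [
        (Move("remove", (i, j), None), _apply(struct, (i, j), None))
        for i, j in pairs
    ]

    shifts: list[tuple[Move, str]] = []
    if constraints.allow_shift:
        for i, j in pairs:
            table[i] = table[j] = -1  # temporarily open this pair
            for fixed, old in ((i, j), (j, i)):
                for k in range(n):
                    if k == old or k == fixed or table[k] >= 0:
                        continue
                    a, b = (fixed, k) if fixed < k else (k, fixed)
                    if b - a <= min_loop:
                        continue
                    if not is_valid_pair(seq[a], seq[b], allow_gu):
                        continue
                    if not _noncrossing(table, a, b):
                        continue
                    shifts.append((
                        Move("shift", (i, j), (a, b)),
                        _apply(struct, (i, j), (a, b)),
                    ))
            table[i], table[j] = j, i
        shifts.sort(key=lambda ms: (ms[0].from_pair, ms[0].to_pair))

    return Neighborhood(seq, struct, adds + removes + shifts)


def _count_structures(seq: str, constraints: MoveConstraints,
                      cap: int) -> int:
    """Count feasible structures by interval recursion (cheap pre-check)."""
    n = len(seq)
    min_loop = constraints.min_loop
    allow_gu = constraints.allow_gu
    memo: dict[tuple[int, int], int] = {}

    def count(lo: int, hi: int) -> int:  # structures on [lo, hi)
        if hi - lo <= min_loop:
            return 1
        key = (lo, hi)
        if key in memo:
            return memo[key]
        total = count(lo + 1, hi)  # lo unpaired
        for j in range(lo + min_loop + 1, hi):
            if is_valid_pair(seq[lo], seq[j], allow_gu):
                total += count(lo + 1, j) * count(j + 1, hi)
                if total > cap:
                    break
        memo[key] = total
        return total

    return count(0, n)


def enumerate_structures(seq: str,
                         constraints: MoveConstraints = DEFAULT_CONSTRAINTS,
                         cap: int = 200_000) -> list[str]:
    """Exhaustively enumerate the feasible structure space of ``seq``.

    Returns every valid non-crossing structure (including the open chain)
    under the pair-validity and minimum-loop constraints, sorted
    lexicographically for a deterministic canonical order.  Raises
    :class:`StateSpaceTooLargeError` when the count exceeds ``cap``; the
    structure space grows exponentially with sequence length, so exhaustive
    enumeration is only meant for verification-scale inputs.
    """
    m = _count_structures(seq, constraints, cap)
    if m > cap:
        raise StateSpaceTooLargeError(
            f"structure space exceeds cap ({cap}); "
            "use the stochastic simulator instead"
        )
    n = len(seq)
    min_loop = constraints.min_loop
    allow_gu = constraints.allow_gu
    memo: dict[tuple[int, int], list[tuple[tuple[int, int], ...]]] = {}

    def enum(lo: int, hi: int) -> list[tuple[tuple[int, int], ...]]:
        if hi - lo <= min_loop:
            return [()]
        key = (lo, hi)
        if key in memo:
            return memo[key]
        out = list(enum(lo + 1, hi))
        for j in range(lo + min_loop + 1, hi):
            if is_valid_pair(seq[lo], seq[j], allow_gu):
                for inner in enum(lo + 1, j):
                    for outer in enum(j + 1, hi):
                        out.append(((lo, j),) + inner + outer)
        memo[key] = out
        return out

    chars_base = ["."] * n
    structs = []
    for pair_list in enum(0, n):
        chars = chars_base.copy()
        for i, j in pair_list:
            chars[i], chars[j] = "(", ")"
        structs.append("".join(chars))
    assert len(structs) == m
    structs.sort()
    return structs
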