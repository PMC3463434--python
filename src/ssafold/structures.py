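"""Dot-bracket secondary structures and base-pair utilities.

An RNA secondary structure is represented by two equal-length strings: the
sequence over ``{A, C, G, U}`` and the structure in dot-bracket notation,
where each matched ``(`` / ``)`` is a base pair and ``.`` is an unpaired
base.  Pseudoknots cannot be expressed in this alphabet and are rejected
everywhere in the package.

Indexing is 0-based throughout the API; positions quoted in error messages
are 1-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import cached_property
from typing import Iterable

from .errors import MalformedStructureError, PseudoknotError

logger = logging.getLogger(__name__)

RNA_ALPHABET = frozenset("ACGU")

PairSet = frozenset  # of (i, j) tuples with i < j


def clean_sequence(sequence: str) -> str:
    """Normalize a nucleotide sequence to the RNA alphabet.

    Upper-cases the input and transliterates T to U (DNA-alphabet FASTA
    files are common) with a logged warning.  Raises ``ValueError`` on any
    other character.
    """
    seq = sequence.strip().upper()
    if "T" in seq:
        logger.warning("sequence contains T; transliterating to U")
        seq = seq.replace("T", "U")
    for pos, base in enumerate(seq):
        if base not in RNA_ALPHABET:
            raise ValueError(
                f"illegal base {base!r} at position {pos + 1}; expected A/C/G/U"
            )
    return seq


def parse_dotbracket(dotbracket: str) -> PairSet:
    """Parse a dot-bracket string into its set of base pairs.

    Returns a frozenset of ``(i, j)`` index pairs with ``i < j``, 0-based,
    found by stack matching.  Raises :class:`MalformedStructureError` on an
    unbalanced string or an illegal character, naming the offending
    (1-based) position.
    """
    stack: list[int] = []
    pairs: set[tuple[int, int]] = set()
    for pos, char in enumerate(dotbracket):
        if char == "(":
            stack.append(pos)
        elif char == ")":
            if not stack:
                raise MalformedStructureError(
                    f"unmatched ')' at position {pos + 1}"
                )
            pairs.add((stack.pop(), pos))
        elif char != ".":
            raise MalformedStructureError(
                f"illegal character {char!r} at position {pos + 1}; "
                "expected '.', '(' or ')'"
            )
    if stack:
        raise MalformedStructureError(
            f"unmatched '(' at position {stack[-1] + 1}"
        )
    return frozenset(pairs)


def write_dotbracket(pairs: Iterable[tuple[int, int]], length: int) -> str:
    """Render a pair set as a dot-bracket string (inverse of parse).

    Raises :class:`PseudoknotError` if any two pairs cross and
    ``ValueError`` on out-of-range or overlapping indices.
    """
    chars = ["."] * length
    norm = sorted((min(i, j), max(i, j)) for i, j in pairs)
    for i, j in norm:
        if i == j:
            raise ValueError(f"pair ({i}, {j}) pairs a base with itself")
        if not (0 <= i and j < length):
            raise ValueError(f"pair ({i}, {j}) out of range for length {length}")
        if chars[i] != "." or chars[j] != ".":
            raise ValueError(f"index reused by pair ({i}, {j})")
        chars[i], chars[j] = "(", ")"
    # crossing check: (i, j) and (k, l) with i < k < j < l
    open_ends: list[int] = []
    for i, j in norm:
        while open_ends and open_ends[-1] < i:
            open_ends.pop()
        if open_ends and open_ends[-1] < j:
            raise PseudoknotError(
                f"pairs cross at ({i}, {j}); pseudoknots are unsupported"
            )
        open_ends.append(j)
    return "".join(chars)


def open_chain(length: int) -> str:
    """The open-chain structure (all dots): the canonical folding start state."""
    if length < 1:
        raise ValueError(f"length must be >= 1, got {length}")
    return "." * length


def pair_table(dotbracket: str) -> list[int]:
    """Partner index per position (-1 where unpaired)."""
    table = [-1] * len(dotbracket)
    for i, j in parse_dotbracket(dotbracket):
        table[i], table[j] = j, i
    return table


def base_pair_distance(a: str, b: str) -> int:
    """Base-pair distance: |pairs(a) Δ pairs(b)| (symmetric difference).

    The standard structural metric, used here as the folding-progress
    measure for unfinished molecules.
    """
    if len(a) != len(b):
        raise ValueError(
            f"structures have different lengths ({len(a)} vs {len(b)})"
        )
    return len(parse_dotbracket(a) ^ parse_dotbracket(b))


@dataclass(frozen=True)
class SecondaryStructure:
    """A sequence string plus a dot-bracket structure string.

    Invariants checked on construction: equal lengths, RNA alphabet,
    balanced and properly nested brackets.
    """

    sequence: str
    dotbracket: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.dotbracket):
            raise ValueError(
                f"sequence length {len(self.sequence)} != structure length "
                f"{len(self.dotbracket)}"
            )
        for pos, base in enumerate(self.sequence):
            if base not in RNA_ALPHABET:
                raise ValueError(
                    f"illegal base {base!r} at position {pos + 1}"
                )
        parse_dotbracket(self.dotbracket)  # validates

    @cached_property
    def pairs(self) -> PairSet:
        return parse_dotbracket(self.dotbracket)

    def __len__(self) -> int:
        return len(self.sequence)

    @classmethod
    def open(cls, sequence: str) -> "SecondaryStructure":
        sequence = clean_sequence(sequence)
        return cls(sequence, open_chain(len(sequence)))
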