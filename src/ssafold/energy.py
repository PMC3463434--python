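"""Free-energy evaluation of (sequence, structure) pairs.

Two evaluators sit behind one contract: a self-contained toy
nearest-neighbor-flavoured model for deterministic tests, and an adapter
over an external Turner-rules evaluator (the ViennaRNA Python bindings when
available, or any callable ``(sequence, dotbracket) -> kcal/mol``).

Every model satisfies: the open chain has energy exactly 0.0, and the
energy depends only on the base-pair set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

from .errors import EnergyEvaluatorUnavailableError
from .structures import parse_dotbracket

#: gas constant in kcal/(mol K)
GAS_CONSTANT = 0.0019872

#: thermal energy at 37 C (310.15 K), kcal/mol
RT_37C = GAS_CONSTANT * 310.15


def rt_from_celsius(temperature_c: float) -> float:
    """Thermal energy RT in kcal/mol at the given temperature."""
    return GAS_CONSTANT * (temperature_c + 273.15)


@dataclass(frozen=True)
class ToyParams:
    """Per-pair and stacking terms of the toy model, kcal/mol.

    Defaults give a funnel-like landscape on GC-rich sequences: GC pairs
    are worth more than AU, AU more than GU wobbles, and adjacent
    (stacked) pairs earn a bonus.
    """

    gc: float = -3.0
    au: float = -2.0
    gu: float = -1.0
    stack: float = -1.0


DEFAULT_TOY_PARAMS = ToyParams()


def toy_energy(seq: str, struct: str,
               params: ToyParams = DEFAULT_TOY_PARAMS) -> float:
    """Toy free energy: sum of per-pair terms plus stacking bonuses.

    Each pair (i, j) contributes its pair-type term; a pair whose inner
    neighbor (i+1, j-1) is also paired contributes an extra ``stack``.
    The open chain scores exactly 0.0.
    """
    pairs = parse_dotbracket(struct)
    total = 0.0
    for i, j in pairs:
        bases = frozenset((seq[i], seq[j]))
        if bases == frozenset("GC"):
            total += params.gc
        elif bases == frozenset("AU"):
            total += params.au
        elif bases == frozenset("GU"):
            total += params.gu
        else:
            raise ValueError(
                f"non-pairable bases {seq[i]}-{seq[j]} at ({i}, {j})"
            )
        if (i + 1, j - 1) in pairs:
            total += params.stack
    return total


class EnergyModel:
    """Contract: ``evaluate(seq, dotbracket) -> kcal/mol`` plus RT."""

    name: str = "abstract"

    def __init__(self, RT: float = RT_37C):
        if RT <= 0:
            raise ValueError("RT must be positive")
        self.RT = RT

    def evaluate(self, seq: str, struct: str) -> float:
        raise NotImplementedError

    def __call__(self, seq: str, struct: str) -> float:
        return self.evaluate(seq, struct)


class ToyEnergyModel(EnergyModel):
    """Deterministic built-in model; no external software needed."""

    name = "toy"

    def __init__(self, params: ToyParams = DEFAULT_TOY_PARAMS,
                 RT: float = RT_37C):
        super().__init__(RT)
        self.params = params

    def evaluate(self, seq: str, struct: str) -> float:
        return toy_energy(seq, struct, self.params)


class TurnerEnergyModel(EnergyModel):
    """Adapter over an external Turner-rules nearest-neighbor evaluator.

    With no explicit ``evaluator``, the ViennaRNA Python bindings are used
    (``RNA.fold_compound.eval_structure``, the library behind RNAeval).
    Evaluations are cached per (sequence, structure); the evaluator must be
    deterministic.
    """

    name = "turner"

    def __init__(self, evaluator: Optional[Callable[[str, str], float]] = None,
                 RT: float = RT_37C):
        super().__init__(RT)
        self._cache: dict[tuple[str, str], float] = {}
        self._rna = None
        self._fc_cache: dict[str, object] = {}
        if evaluator is None:
            try:
                import RNA  # ViennaRNA python bindings
            except ImportError as exc:
                raise EnergyEvaluatorUnavailableError(
                    "no Turner-rules evaluator available (ViennaRNA python "
                    "bindings not importable); use ToyEnergyModel or pass "
                    "an evaluator callable"
                ) from exc
            self._rna = RNA
            evaluator = self._vienna_eval
        self._evaluator = evaluator

    def _vienna_eval(self, seq: str, struct: str) -> float:
        fc = self._fc_cache.get(seq)
        if fc is None:
            fc = self._rna.fold_compound(seq)
            self._fc_cache[seq] = fc
        return fc.eval_structure(struct)

    def evaluate(self, seq: str, struct: str) -> float:
        key = (seq, struct)
        value = self._cache.get(key)
        if value is None:
            value = float(self._evaluator(seq, struct))
            self._cache[key] = value
        return value

    def mfe(self, seq: str) -> tuple[str, float]:
        """Minimum-free-energy structure and energy via the evaluator.

        Only available with the ViennaRNA backend (an arbitrary callable
        cannot be minimized over).
        """
        if self._rna is None:
            raise EnergyEvaluatorUnavailableError(
                "MFE prediction needs the ViennaRNA backend"
            )
        fc = self._rna.fold_compound(seq)
        struct, energy = fc.mfe()
        return struct, float(energy)


def turner_adapter(evaluator: Optional[Callable[[str, str], float]] = None,
                   RT: float = RT_37C) -> TurnerEnergyModel:
    """Wrap an external nearest-neighbor evaluator as an :class:`EnergyModel`."""
    return TurnerEnergyModel(evaluator, RT)
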