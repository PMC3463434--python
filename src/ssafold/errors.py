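"""Exception hierarchy shared across the package."""


class SSAFoldError(Exception):
    """Base class for all package-specific errors."""


class MalformedStructureError(SSAFoldError, ValueError):
    """A dot-bracket string is unbalanced or contains an illegal character."""


class PseudoknotError(SSAFoldError, ValueError):
    """A pair set contains crossing pairs and cannot be written in dot-bracket."""


class StateSpaceTooLargeError(SSAFoldError):
    """Exhaustive enumeration would exceed the configured state cap.

    Use the stochastic simulator (``simulate_fold`` / ``simulate_ensemble``)
    for sequences whose structure space cannot be enumerated.
    """


class EnergyEvaluatorUnavailableError(SSAFoldError, RuntimeError):
    """No external nearest-neighbor evaluator could be loaded.

    Fall back to the built-in toy model (``ssafold.energy.ToyEnergyModel``)
    or plug in any callable ``(sequence, dotbracket) -> kcal/mol``.
    """


class AbsorbingStateError(SSAFoldError):
    """An SSA event was requested from a state with zero total exit rate."""


class DeadEndError(SSAFoldError):
    """An unfolded molecule has an empty neighborhood.

    Cannot occur when pair-removal moves are enabled: any structure with at
    least one pair has a remove neighbor, and the open chain of a sequence
    with no feasible pair is its own (single-state) landscape.
    """


class DegenerateSampleError(SSAFoldError, ValueError):
    """A first-passage-time sample has zero variance; no density estimate."""
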