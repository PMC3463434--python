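"""Single-point-mutant screening by folding smoothness.

Several different point mutations of one wildtype often refold to the
same (or a very similar) rearranged structure — static MFE prediction
cannot discriminate between them.  Kinetics can: for each mutant an
ensemble of folding trajectories is simulated and the folding
characteristic computed; a mutant that reaches its target down a single
funnel (no humps, short median folding time) is a smoother — and under
the rearrangement hypothesis more effective — candidate than one that
lingers in kinetic traps.

The ranking key (hump count ascending, then median fold time ascending)
is this package's operationalization of "smooth folding"; it is a design
choice, not a measured constant of nature.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from . import analysis
from .energy import TurnerEnergyModel
from .errors import DegenerateSampleError, StateSpaceTooLargeError
from .kinetics import (NeighborhoodCache, SimulationConfig, mfe_structure,
                       simulate_ensemble)
from .structures import clean_sequence, open_chain

BASES = "ACGU"


def single_point_mutants(seq: str) -> list[tuple[str, str]]:
    """All 3n single-point mutants of ``seq`` as (mutant id, sequence).

    Ids follow the wildtype-base / 1-based position / mutant-base
    convention (e.g. ``G89C``).  Deterministic order: position, then base
    order A < C < G < U.  The wildtype itself is excluded.
    """
    seq = clean_sequence(seq)
    if not seq:
        raise ValueError("empty sequence")
    mutants = []
    for pos, wt in enumerate(seq):
        for base in BASES:
            if base == wt:
                continue
            mutants.append((f"{wt}{pos + 1}{base}",
                            seq[:pos] + base + seq[pos + 1:]))
    return mutants


@dataclass
class MutantReport:
    """Fold-kinetics summary of one mutant (or the wildtype control)."""

    mutant_id: str
    sequence: str
    target: str
    n_trajectories: int
    fraction_folded: float
    median_fold_time: Optional[float]
    iqr_fold_time: Optional[float]
    n_humps: Optional[int]
    failed: bool = False


def _report_row(mutant_id: str, seq: str, target: str,
                records, t_cut: float) -> MutantReport:
    sample = analysis.FoldingTimeSample.from_records(records)
    n = len(records)
    frac = sample.times.size / n if n else 0.0
    if sample.times.size:
        median = float(np.median(sample.times))
        q1, q3 = np.percentile(sample.times, [25, 75])
        iqr = float(q3 - q1)
    else:
        median = iqr = None
    try:
        fc = analysis.folding_characteristic(sample)
        humps = fc.n_humps
    except DegenerateSampleError:
        humps = None
    return MutantReport(mutant_id, seq, target, n, frac, median, iqr, humps)


def scan(seq: str, config: SimulationConfig, seed: int,
         n_trajectories: int = 100,
         t_cut: float = float("inf"),
         include_wildtype: bool = True,
         targets: Optional[dict[str, str]] = None) -> pd.DataFrame:
    """Screen every single-point mutant of ``seq`` for folding smoothness.

    For each mutant (plus the wildtype control) an ensemble of
    ``n_trajectories`` identical molecules is folded from the open chain
    to the mutant's own target structure, stopping at ``t_cut``
    (anytime mode).  Targets default to the MFE structure: by exhaustive
    enumeration under the configured energy model when feasible, else by
    the Turner backend's MFE predictor; a ``targets`` dict (sequence ->
    dot-bracket) overrides.  Mutants whose target cannot be determined
    are flagged and skipped, not fatal.

    Returns a DataFrame sorted by (n_humps, median_fold_time), smoothest
    first, with a ``target_group`` column grouping degenerate mutants
    that share one rearranged target structure.  Deterministic: the same
    (seq, config, seed) yields an identical report.
    """
    seq = clean_sequence(seq)
    entries = []
    if include_wildtype:
        entries.append(("wildtype", seq))
    entries.extend(single_point_mutants(seq))

    cache = NeighborhoodCache(config.cache_capacity)
    ss = np.random.SeedSequence(seed)
    rows = []
    for (mid, mseq), child in zip(entries, ss.spawn(len(entries))):
        target = None
        if targets and mseq in targets:
            target = targets[mseq]
        else:
            try:
                target = mfe_structure(mseq, config.energy,
                                       config.constraints, config.mfe_cap)
            except StateSpaceTooLargeError:
                if isinstance(config.energy, TurnerEnergyModel):
                    target, _ = config.energy.mfe(mseq)
        if target is None:
            rows.append(MutantReport(mid, mseq, "", 0, 0.0, None, None,
                                     None, failed=True))
            continue
        start = open_chain(len(mseq))
        specs = [(mseq, start, target)] * n_trajectories
        mseed = int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))
        records, state = simulate_ensemble(specs, config, seed=mseed,
                                           cache=cache, stop_time=t_cut)
        rows.append(_report_row(mid, mseq, target, records, t_cut))

    df = pd.DataFrame([r.__dict__ for r in rows])
    groups = {t: i for i, t in enumerate(sorted(set(df["target"])))}
    df["target_group"] = df["target"].map(groups)
    df = df.sort_values(
        ["failed", "n_humps", "median_fold_time", "mutant_id"],
        na_position="last", kind="mergesort",
    ).reset_index(drop=True)
    return df
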