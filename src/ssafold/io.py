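"""FASTA input and TSV/JSON output helpers."""

from __future__ import annotations

import json
import platform
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO

from .kinetics import FoldRecord, Trajectory
from .structures import clean_sequence


def read_fasta(path) -> list[tuple[str, str]]:
    """Read (id, RNA sequence) records; DNA alphabets are transliterated."""
    records = [(rec.id, clean_sequence(str(rec.seq)))
               for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(path, records: Iterable[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


def trajectory_frame(traj: Trajectory, trajectory_id: int = 0) -> pd.DataFrame:
    return pd.DataFrame(
        [(trajectory_id, step, t, s, e)
         for step, (t, s, e) in enumerate(traj.records)],
        columns=["trajectory_id", "step", "time", "structure",
                 "energy_kcal_mol"],
    )


def write_trajectories(path, trajectories: Iterable[Trajectory]) -> None:
    frames = [trajectory_frame(t, i) for i, t in enumerate(trajectories)]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def fold_times_frame(records: Iterable[FoldRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.molecule_id, r.sequence, r.fold_time, r.folded,
          r.bp_distance_remaining) for r in records],
        columns=["molecule_id", "sequence", "fold_time", "folded",
                 "bp_distance_remaining"],
    )


def write_fold_times(path, records: Iterable[FoldRecord]) -> None:
    fold_times_frame(records).to_csv(path, sep="\t", index=False)


def read_fold_times(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_manifest(path, config: dict) -> None:
    """A JSON run manifest: config, seed and versions, for reruns."""
    import numpy
    import scipy

    from . import __version__

    manifest = {
        "config": config,
        "versions": {
            "ssafold": __version__,
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "python": platform.python_version(),
        },
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True))
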