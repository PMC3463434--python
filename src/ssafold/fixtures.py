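"""Bundled example sequences and synthetic analysis fixtures.

Two mid-20s-nt example sequences with opposite kinetic personalities are
shipped for demonstrations and tests: a 29-mer that folds smoothly down a
single funnel, and a GC-helix 28-mer whose register-shifted misfolds
produce kinetic traps and a multi-humped folding characteristic.  The
synthetic two-timescale fold-time sample exercises the analysis layer
without any simulation.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

#: 29-nt example: folds smoothly, no humps in the folding characteristic
EXAMPLE_SMOOTH = "GAGCAUCCGUGUAACCAUUCACACUGCUC"

#: 28-nt GC-helix example: kinetic traps, multi-humped characteristic
EXAMPLE_ROUGH = "GGGGGGGGGGGGAAAUCCCCCCCCCCCC"

#: tiny fully-enumerable landscapes used throughout the tests
TOY_HAIRPIN = "GAAAC"          # 2 structures
TOY_TRIPLEX = "GGGAAACCC"      # small multi-state space

MIXTURE_SEED = 20120907
MIXTURE_N = 2000
MIXTURE_RATES = (1.0, 1e-3)
MIXTURE_WEIGHTS = (0.5, 0.5)


def two_timescale_sample(n: int = MIXTURE_N,
                         seed: int = MIXTURE_SEED) -> np.ndarray:
    """Draws from the 0.5 Exp(1) + 0.5 Exp(1e-3) fold-time mixture.

    The two rates sit three decades apart, so the folding characteristic
    of this sample shows two well-separated humps — the canonical
    multi-pathway fixture.
    """
    rng = np.random.default_rng(seed)
    component = rng.random(n) < MIXTURE_WEIGHTS[0]
    scales = np.where(component, 1.0 / MIXTURE_RATES[0], 1.0 / MIXTURE_RATES[1])
    return rng.exponential(scales)


def make_fixtures(out_dir) -> list[Path]:
    """Write the packaged fixtures to ``out_dir``; returns the paths."""
    from .io import write_fasta

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []

    fasta = out / "examples.fa"
    write_fasta(fasta, [("example_smooth_29nt", EXAMPLE_SMOOTH),
                        ("example_rough_28nt", EXAMPLE_ROUGH)])
    paths.append(fasta)

    toys = out / "toys.fa"
    write_fasta(toys, [("toy_hairpin", TOY_HAIRPIN),
                       ("toy_triplex", TOY_TRIPLEX)])
    paths.append(toys)

    mixture = out / "two_timescale_times.tsv"
    times = two_timescale_sample()
    with open(mixture, "w") as fh:
        fh.write("fold_time\n")
        fh.writelines(f"{t!r}\n" for t in times)
    paths.append(mixture)
    return paths
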