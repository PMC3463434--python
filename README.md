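# ssafold

Stochastic simulation of RNA secondary-structure folding kinetics.

Static structure prediction says where an RNA ends up; it says nothing
about how long it takes to get there or which misfolded intermediates it
visits on the way — and for riboswitches, conformationally rearranging
mutants and other kinetics-limited systems that is the interesting part.
`ssafold` is for computational RNA people who want folding *time*
information: it simulates the folding of an RNA molecule at base-pair
resolution as a continuous-time Markov jump process and turns the
resulting first-passage times into distributional summaries.

## The model in brief

States are pseudoknot-free secondary structures of a sequence R; moves
add, remove or shift one base pair; a move with free-energy change ΔG
fires at the Metropolis rate

    a_ij = 1                 if ΔG < 0
    a_ij = exp(−ΔG/RT)       otherwise

(Kawasaki rates exp(−ΔG/2RT) optional), with energies from a built-in
toy model or Turner-rules via the ViennaRNA bindings. Trajectories are
generated with Gillespie's stochastic simulation algorithm: per event,
reaction j is chosen by the cumulative-propensity rule and the clock
advances by τ = ln(1/ξ)/a_sum. The package provides

* `simulate_fold` — one molecule, open chain → MFE target, exact SSA;
* `simulate_ensemble` — n molecules under one global clock, with LRU
  neighborhood memoization, anytime stopping and exact resume;
* `build_state_space` / `solve_cme` / `first_passage_cdf` — an exact
  chemical-master-equation oracle on enumerable landscapes;
* `folding_characteristic` / `count_humps` — the distribution of folding
  times P(t) on a log axis and the folding characteristic t·P′(t)/P(t),
  whose humps mark distinct folding timescales;
* `scan` — a single-point-mutant screen ranking mutants by folding
  smoothness.

See `docs/methods.md` for the full model description and design choices.

## Worked example

Exact versus simulated folding-time law on an enumerable toy landscape
(`examples/04_master_equation_oracle.py`):

```
$ python examples/04_master_equation_oracle.py
GGGAAACCC: M(R) = 20 feasible structures, target (((...))) at -11.0 kcal/mol
sup-distance between empirical and exact CDF: 0.0114 (KS 1% band: 0.0230)
exact median folding time: 3.34
```

The 9-mer's landscape has 20 feasible structures, so the master equation
is solved exactly; 5 000 SSA trajectories give an empirical first-passage
CDF whose largest deviation from the exact law (0.0114) sits inside the
Kolmogorov–Smirnov 1 % band (0.0230) — simulator and oracle describe the
same process. On the trap-rich bundled 28-mer
(`examples/02_folding_time_distribution.py`):

```
folding times: 10%/50%/90% quantiles = 17 / 5089 / 15098 (arbitrary units)
spread: 4.1 decades
humps in the folding characteristic: 2
  hump near t =       13  (prominence 0.12)
  hump near t =     7140  (prominence 0.72)
```

Two humps = two folding pathways: direct zipping into the full helix
(t ≈ 13) versus escape from register-shifted helix traps (t ≈ 7000).

A thin CLI wraps the same calls:

```sh
ssafold simulate --seq GAAAC --n 100 --seed 7 --out run/
ssafold ensemble --fasta wt.fa --n 500 --t-cut 1e4 --seed 1 --out run/
ssafold analyze --times run/fold_times.tsv --out run/
ssafold mutscan --seq GGGAAACCC --n 100 --seed 5 --out report.tsv
```

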