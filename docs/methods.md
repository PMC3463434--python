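# Methods

## The model

An RNA secondary structure is a pseudoknot-free set of base pairs (AU, GC
and GU wobble) over a fixed sequence, written in dot-bracket notation.
`ssafold` models folding as a continuous-time Markov jump process on the
finite set F(R) of feasible structures of a sequence R: every structure
satisfying pair validity and a minimum hairpin loop of `min_loop`
unpaired bases (default 3, the standard steric constraint; a pair (i, j)
requires j − i > 3). Elementary transitions are the single-base-pair
moves: **add** a pair, **remove** a pair, or **shift** one endpoint of an
existing pair to a new partner. Shift moves are on by default (they model
helix slippage and defect diffusion; `MoveConstraints(allow_shift=False)`
gives a pure add/remove move set). Isolated ("lonely") pairs are allowed;
there is no helix-length constraint.

A move from structure i to neighbor j fires at rate

* Metropolis: a_ij = 1 if ΔG < 0, else exp(−ΔG/RT),
* Kawasaki: a_ij = exp(−ΔG/2RT),

with ΔG = G_j − G_i the free-energy change in kcal/mol and RT the thermal
energy (0.6163 kcal/mol at the default 37 °C). Both rules satisfy
detailed balance against the Boltzmann distribution exp(−G_i/RT)/Z, which
the test suite verifies exhaustively on enumerated landscapes. The
Kawasaki exponent convention (ΔG/2RT) is a convention choice, matching
common kinetic-simulation practice. Time units are arbitrary: one unit is
one expected event at total exit rate 1; no calibration to seconds is
attempted.

## Energies

Two evaluators satisfy one contract (`evaluate(seq, dotbracket)` →
kcal/mol; the open chain is exactly 0; the value depends only on the pair
set):

* **Toy model** (`ToyEnergyModel`): per-pair terms e(GC) = −3, e(AU) = −2,
  e(GU) = −1 plus a stacking bonus of −1 for each pair whose inner
  neighbor is also paired. The values are artifact choices, not fitted
  thermodynamics; they produce funnel-like landscapes on GC-rich toys and
  make every test deterministic with no external software.
* **Turner adapter** (`TurnerEnergyModel`): wraps the ViennaRNA Python
  bindings (`fold_compound.eval_structure`) — or any user callable — with
  per-structure caching. ViennaRNA is used with its default settings
  (Turner 2004 parameters, dangles = 2, 37 °C); runs at other settings
  should state them. ViennaRNA is an optional runtime dependency: absent
  bindings raise a capability error pointing at the toy model.

The folding target Op(R) defaults to the minimum-free-energy structure:
by exhaustive enumeration under the active model when F(R) fits the cap
(200 000 states), or by the ViennaRNA MFE predictor for the Turner model.
Energy ties are broken lexicographically on the dot-bracket string
(logged).

## Stochastic simulation

Both simulators implement the exact Gillespie event rule. Each event
draws two uniforms in a fixed order (ξ1 then ξ2; exact zeros are rejected
and redrawn), selects the reaction as the smallest index whose cumulative
propensity exceeds ξ1·a_sum, and advances the clock by τ = ln(1/ξ2)/a_sum.
One named, seedable generator (`numpy.random.default_rng`) drives a run,
so trajectories are bit-reproducible from the seed.

**Single-trajectory** (`simulate_fold`) walks one molecule from a start
structure until it reaches an absorbing target (or a step/time limit,
reported in `terminated_reason`, never as an exception).

**Ensemble** (`simulate_ensemble`) runs n molecules — identical repeats
or different sequences, e.g. point mutants — under ONE global clock and
one flattened propensity vector. Each event touches exactly one molecule,
and only that molecule's neighborhood is recomputed; a molecule that
reaches its target is marked folded at the current global time and its
propensities leave the sum, making every remaining transition
proportionally more likely. A molecule whose start equals its target is
folded at t = 0 (the stop check runs before the first event). With n = 1
the event stream is identical to `simulate_fold` under the same seed.

**Memoization.** Neighborhoods and their rate vectors are cached in an
LRU map keyed by (sequence, structure), default capacity 10 000 states;
folding paths revisit basin states constantly, so hit rates in practice
exceed 95 %. Caching is transparent: capacities 0, 10 and 10 000 yield
event-identical trajectories (tested). Energies are cached separately and
unboundedly per sequence.

**Anytime stopping.** A run given `stop_time` halts before the first
event that would overshoot the horizon; `extract_results(state, t_cut)`
returns the fold times collected so far and, for each unfolded molecule,
its base-pair distance to target — a concrete measure of how much folding
work the early stop left undone. The state stashes the uniform draws of
the cut-off event, so resuming reproduces the uninterrupted event stream
exactly (tested event-for-event); the memoryless property would make
redrawing statistically equivalent, but exact reproducibility is the
stronger and more testable contract.

## The master-equation oracle

On an enumerable landscape the process is a finite CTMC with generator
Q[i,j] = a_ij for neighbors, diagonal = −row sum. `solve_cme` integrates
dP/dt = QᵀP with scipy's BDF solver (rtol 1e−9, atol 1e−12, analytic
Jacobian for dense systems) and checks probability conservation to 1e−6.
The first-passage (folding-time) CDF is read off by zeroing the target's
outgoing row and tracking the probability absorbed there — numerically
simpler than flux integration and equivalent. Dense generators are used
up to 2 000 states, scipy sparse beyond; enumeration refuses above
200 000 states, because M(R) grows exponentially with length — the oracle
is for verification, not production. The stochastic simulators are
validated against it: on three toy landscapes the empirical CDF of 5 000
trajectories sits inside the Kolmogorov–Smirnov 1 % band of the exact
CDF.

## Folding-time analysis

From a first-passage sample (possibly censored by an early stop) the
package computes, on a log-spaced grid spanning [min/10, max·10]:

* **P(t)** — the empirical fraction of the whole ensemble folded by t;
  censored molecules count in the denominator only.
* **P′(t)** — by Gaussian kernel density estimation on log10(t), mapped
  back as P′(t) = f_log(log10 t)/(t ln 10) and scaled by the uncensored
  fraction. Finite differences of a step CDF are unusable on a log axis;
  the KDE bandwidth defaults to scipy's Silverman rule and can be
  overridden.
* the **folding characteristic** t·P′(t)/P(t), NaN where P = 0.

**Hump counting.** Humps of the characteristic flag distinct folding
timescales (pathways). The count is implemented as the number of
prominence-passing modes of the log-time density (prominence ≥ 5 % of the
curve's range by default), with a single mode counting as zero. Rationale:
for any folding-time law the true characteristic declines from the onset
log-slope d ln P/d ln t as t → 0⁺, so the *fastest* timescale never
creates a strict local maximum — a unimodal sample yields a monotone,
hump-free characteristic (the single-exponential closed form
λt·e^(−λt)/(1 − e^(−λt)) is the canonical case). Every *additional*
timescale produces one fall–rise–fall bump, and once the curve is
multimodal the fastest mode is visible as a bump too; counting modes
therefore counts humps while staying exact in the unimodal limit. The
two-timescale mixture 0.5·Exp(1) + 0.5·Exp(10⁻³) gives 2 humps three
decades apart, robustly to halving or doubling the bandwidth.

**Known estimator bias.** Gaussian KDE attenuates sharp density crests by
≈ ½·bw²·f″. At the default bandwidth and n = 2000 this puts the empirical
characteristic ~15 % of its maximum below the closed-form mixture curve
at the fast-mode crest. This is bias, not noise (stable across seeds);
analyses needing crest accuracy should shrink the bandwidth explicitly.

## Example sequences and what validation shows

Two bundled sequences have opposite kinetic personalities under
Turner-rules energies:

* `EXAMPLE_SMOOTH` (29 nt) folds down a single funnel: folding times are
  unimodal and the characteristic has no humps.
* `EXAMPLE_ROUGH` (28 nt, a 12-GC helix with a tetraloop) misfolds into
  register-shifted helices: fold times spread over four decades and the
  characteristic shows one hump per resolved timescale. Under the default
  smoothing the pipeline resolves two (direct zip ~t = 15, trap escape
  ~t = 7000); the intermediate mass is a monotone ramp between them, not
  a separate mode — a conclusion cross-checked by analyzing first-passage
  samples from an independent reference simulator (ViennaRNA's Kinfold)
  with the same pipeline, which also yields two.

The toy landscapes (`GAAAC`, `GGGAAACCC`, random 10-mers) exist to make
exact verification possible: they are small enough to enumerate, so SSA
output can be compared with the exact master-equation law, stationarity
with the Boltzmann distribution, and move generation with brute-force
oracles. Passing these tests shows the simulator is internally consistent
and exact for its model; it does not show that the toy energies, the
move-set resolution, or the arbitrary time units predict laboratory
folding times. Co-transcriptional folding, pseudoknots, tertiary
contacts and modified bases are outside the model.

## Mutant screening

`scan` enumerates all 3n single-point mutants (ids like `G12C`:
wildtype base, 1-based position, mutant base), folds an ensemble per
mutant to the mutant's own MFE target with anytime stopping, and reports
fold statistics, hump count and target structure. Mutants are ranked by
(hump count ascending, median fold time ascending) — fewer humps = fewer
competing pathways = smoother folding. The ranking key is this package's
operationalization of smoothness, not a measured constant. Mutants whose
rearranged targets coincide (mutation degeneracy) share a
`target_group`, so kinetics can discriminate candidates that static MFE
prediction cannot.

## Validation problem sizes

The shipped suite uses: 1 000 Turner-rules trajectories per example
sequence; 5 000 trajectories per landscape for the oracle comparison;
10⁶ events (25 batch means) for stationarity; 10⁵ pooled waiting times;
2 000-point analytic fixtures. These sizes put the statistical tests'
1 %-level critical bands well below the effects being checked while
keeping the whole suite around a minute of compute plus ~40 s per
Turner-rules example.

## Numerical choices

* Uniform draws of exactly 0.0 are rejected and redrawn (τ and the
  selection rule need open-interval uniforms).
* Rates are clamped at 10¹² with a warning — pathological toy parameters
  otherwise overflow a_sum.
* The flat-index selection guards the floating-point edge where the
  subtracted remainder lands exactly on a molecule's cumulative boundary.
* Generator rows sum to zero to 10⁻¹²; CME solutions must conserve
  probability to 10⁻⁶ or the solver errors out.
* The neighborhood cache key is (sequence, structure); rate-model and
  energy-model settings are fixed per cache instance, so a cache must not
  be shared across configurations.
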