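# Methods

## Model

**Agents and genomes.** `N` agents (odd) each hold one bit.  All agents in a
system share one genome: a Boolean function of `k` inputs (own state plus
`k − 1` neighbors), stored as a `2^k`-bit lookup table.  The lookup index
places the agent's own state in the most significant bit and neighbor slot
`j` at weight `2^(k−2−j)`.  Under this numbering the 3-input majority
function is rule 232 (its table reads `11101000` from index 7 down to 0),
and tables map to decimal rule ids bijectively at any `k` via
arbitrary-precision integers.

**Topology.** Agents sit on a ring, each wired to its `k − 1` nearest
neighbors, and the ring is rewired by degree-preserving double-edge swaps:
two random edges `(a,b)`, `(c,d)` become `(a,d)`, `(c,b)` unless that would
create a self-loop or duplicate edge.  The number of swaps is
`⌈s · N(k−1)/2⌉` with `s = 0.1` by default — about 10% of edges swapped,
enough for a small-world regime while every agent keeps exactly `k − 1`
neighbors.  A swapped-in neighbor takes the slot of the one it replaced, so
slot order stays well defined.  Promotions raise the degree, so networks are
rebuilt (and re-rewired) whenever the genome size changes; in fact a fresh
set of networks is drawn every generation together with the initial
conditions.

**Dynamics and noise.** Updates are synchronous from the pre-step state.
Communication noise flips each perceived neighbor bit independently with
probability `η`, with fresh draws per receiving agent, slot, and step;
agents always read their own state exactly.  Noise therefore corrupts
transmission, never state.

**Consensus criterion.** With noise on, strict unanimity never lasts, so a
realization counts as classified when, were the noise switched off, the
system would converge to the all-correct state in the next step.  Two
clauses: (i) one noiseless synchronous step from the current state yields
every agent in the initial-majority bit, and (ii) the unanimous-target
state is a noiseless fixed point of the rule, i.e. `f(b, b, …, b) = b`.
Clause (ii) is what "converge" adds to "visit": without it, an oscillator
family (rules 1, 7, 23, 31, 63, 127, … at `k = 3`) that blinks between the
two unanimous states is scored as solving the task for *both* targets by
sampling the right phase, and the fitness landscape loses its golf-course
shape entirely.  With it, a rule must actually settle on the answer.
Consensus is checked after every step (first-passage semantics), and rules
that fail clause (ii) for a given target skip simulation outright.

**Fitness.** A genome's fitness is its success fraction over `R = 100`
realizations: half start with 60% of agents in state 1, half with 60% in
state 0 (`ρ = 0.6`, task difficulty `Δ = 2ρ − 1 = 0.2`), with exactly
`round(ρN)` majority agents at uniformly random positions and `T` steps
allowed per realization.  All genomes of a generation are evaluated on the
identical set of (initial state, network) pairs, which is redrawn only
between generations — selection compares genomes on the same problems, not
on sampling luck.  Constant rules score exactly 1/2 on such balanced sets
("guessers"), a useful exact anchor.

**Selection.** Each generation the population of `P = 100` genomes is
ranked (ties broken by a seeded shuffle ahead of a stable sort), the top
20% survive unchanged, and the bottom 80% is replaced by children of
uniformly drawn elite pairs: single-point crossover at a uniform cut,
then independent per-bit mutation at rate `2/2^k` (about two expected flips
per offspring regardless of genome length).  The mutation and crossover
operators are the standard classical-GA choices; nothing in the results
hinges on their details.

**The variable-environment schedule.** Starting from `P` random 32-bit
genomes (`k = 5`) at `η = 0`: whenever the generation's best fitness
exceeds 0.98, the elite is snapshotted and `η` rises by 0.01; when a
patience window (50 generations by default) passes without a threshold
pass, the last snapshot — the genomes that mastered `η − 0.01` — is
promoted to `k + 2` (each table tiled 4×, new inputs silent), the
population is refilled from the promoted elite, and evolution continues at
the stalled `η`.  The stagnation clock only runs once the current `k` has
been mastered at least once: promotion generalizes *successful* genomes,
and the initial guesser phase of a stage routinely outlasts the patience
window, so arming the clock from generation zero would promote random
material.  The run ends when promotion would exceed `k_max = 11` or at the
generation cap.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `N` | 149 | agents per system (odd) |
| `rho` | 0.6 | initial majority fraction |
| `eta` | 0.0 | per-link perception-flip probability |
| `T` | `10·N` | step budget per realization |
| `R` | 100 | realizations per genome, balanced halves |
| `swap_fraction` | 0.1 | fraction of ring edges double-edge-swapped |
| `P` | 100 | population size |
| `elite_fraction` | 0.2 | surviving fraction per generation |
| `per_bit_mutation_rate` | `2/2^k` | expected two bit flips per child |
| `fitness_threshold` | 0.98 | ratchet trigger |
| `eta_increment` | 0.01 | ratchet step |
| `patience_generations` | 50 | stall window before promotion |
| `k_start`, `k_step`, `k_max` | 5, 2, 11 | genome-size schedule |

All randomness flows from one master seed through
`numpy.random.Generator`; a run is exactly reproducible from its persisted
config file plus that seed.

## Numerical and engineering choices

The inner loop — every (genome, realization) pair run to completion — is a
numba-compiled per-run kernel.  Noise flips are drawn by geometric
skip-sampling over the `N(k−1)` perception channels per step, which is
exact for iid Bernoulli draws and makes the cost scale with the number of
flips rather than channels.  A vectorized pure-numpy engine implements the
same semantics as a fallback; at `η = 0` both are deterministic and
bit-identical, under noise they use different random streams and agree
statistically (both properties are tested).  Exhaustively enumerating all
256 `k = 3` rules at the default conditions takes well under a minute per
noise level on one core.

Conservatism profiles `p₁(s, c)` — the probability the updated state is 1
given own state `s` and `c` neighbors in state 1 — are computed by exact
enumeration of all perceived patterns (feasible through `k = 13`), with a
seeded Monte Carlo estimator beyond.  A rule's *flip threshold* is the
smallest opposing-neighbor count at which the flip probability exceeds 1/2
(`k` if it never does); larger thresholds mean more conservative rules.

## Study conditions at desk scale

Three regimes recur in the tests, chosen once and fixed:

- **Landscape conditions** (`N = 149`, `T = 10N`, `η` scanned over
  {0, 0.05, 0.10}): the exhaustive `k = 3` enumeration shows the
  golf-course structure — at `η = 0.10` about 207 of 256 rules score
  exactly zero and about 49 sit in the guesser band (0, 0.5].  The band's
  upper edge *includes* the ~45 guessers at exactly 1/2; "high" means
  strictly better than a coin flip.  No `k = 3` rule beats guessing here:
  a degree-2 ring needs on the order of `N²` steps to order, far beyond
  this step budget.
- **`k = 3` ordering regime** (`N = 29`, `T = 300N`, `η = 0.10`): a small
  system given time to order, with enough noise to anneal the frozen
  domains of the noiseless dynamics.  Here rule 232 reaches fitness ≈ 1.0
  and is the *unique* rule above 0.5, and a classical GA finds it within a
  handful of generations.
- **Scaled-down VEGA** (`N = 59`, `R = 20`, `P = 30`, patience 15,
  `η_start = 0.05`, `k: 5 → 7`): small-population runs in which the noise
  ceiling mastered at `k = 7` exceeds the `k = 5` ceiling (measured in 5/5
  seeds, e.g. 0.12 → 0.25).  The run starts inside the noise-solvable band
  because at this scale *no* rule classifies at `η = 0` (noise is the
  annealer); and with `R = 20` a threshold pass means a perfect 20/20, so
  passes arrive by a mix of genuine quality and sampling luck — the
  mechanism that lets a reduced-scale ratchet climb at all.

The evolved-rule fixture (`tests/data/evolved_rule_k7.txt`) comes from a
seeded run of the `k = 7` stage initialized with the promoted `k = 5`
majority rule, ratcheted to its ceiling (`η ≈ 0.32`), with the champion
selected by re-evaluating all milestone genomes at `η = 0.30` with
`R = 400` (`scripts/evolve_fixture.py`).  Its flip thresholds are
{own 0: 5, own 1: 4} against the majority rule's {4, 4}: it demands five of
six neighbors opposing before leaving state 0, and still holds state 1
almost half the time at the majority rule's certain-flip boundary.

## What the synthetic environments do and do not show

The generator produces exactly the study conditions above: balanced 60/40
initial conditions, degree-regular small-world rings, iid perception noise.
Passing tests demonstrate the claimed *mechanisms* — golf-course landscape
statistics, exact behavior-preserving promotion, the noise ratchet, ceiling
growth with `k`, emergent conservatism — at reduced scale.  They do not
certify full-scale quantitative milestones (e.g. reaching `k = 11` within
hundreds of generations), which require paper-scale populations and run
lengths; the default configuration ships that full schedule unchanged for
anyone willing to spend the compute.

Known limitations:

- At `N = 59` the majority rule itself is anomalously noise-robust (small
  systems order by fluctuation), so desk-scale evolved genomes do not beat
  the matched-`k` majority rule on raw robustness, only on conservatism;
  the dominance of evolved rules over majority is a large-`N` phenomenon.
- Promotion preserves behavior exactly only with respect to the inputs the
  base rule read.  On rebuilt higher-degree rings the active inputs occupy
  an asymmetric stencil of the new neighborhood, which shifts (typically
  raises) measured fitness; the exactness tests therefore align the slots
  explicitly.
- The fitness estimator is a success *fraction*: everything inherits
  binomial noise at scale `1/√R`, and small-`R` ratchets are deliberately
  lenient (see above).
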