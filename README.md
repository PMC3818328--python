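# vegadct

Variable-environment genetic algorithms (VEGA) for the noisy density
classification task.

## The problem

In the **density classification task**, `N` binary agents on a sparse
communication network must all converge to the value initially held by the
strict majority, exchanging information only with `k − 1` neighbors.  The
evolving genome is a Boolean rule — a lookup table of `2^k` output bits over
the agent's own state and its neighbors' perceived states.  The fitness of a
genome is the fraction of random 60/40 initial conditions its agents
classify correctly.

This landscape is **golf-course-like**: of the 256 rules at `k = 3`, about
81% have exactly zero fitness, a thin band does no better than guessing, and
essentially only rule 232 (the majority function) genuinely classifies.
Because the space grows as `2^(2^k)` (a 2048-bit integer at `k = 11`) while
the fit fraction shrinks, blind selection stalls and classical GAs fail for
large `k`.

**VEGA** escapes the trap by co-evolving task difficulty with genome
complexity.  Communication noise `η` — the probability a neighbor's
transmitted bit is perceived flipped — is the environmental dial:

1. evolve rules at the current `(k, η)` with a classical elitist GA
   (top 20% survive, the rest are replaced by single-point crossover plus
   per-bit mutation of elite parents);
2. whenever a genome exceeds fitness 0.98, raise `η` by 0.01 and re-estimate
   all fitnesses (the ratchet);
3. when no genome passes for a patience window, **promote** the last
   successful elite: each `k`-input rule becomes a `k+2`-input rule whose two
   new inputs are initially silent (the table is tiled 4×), preserving
   behavior exactly while opening new adaptive dimensions; keep `η` and
   continue.

Under high noise the evolved rules become **conservative**: they demand a
larger opposing-neighbor majority than the majority rule before abandoning
their own state — noise-robust stubbornness emerges from selection alone.

## Worked example

```python
import numpy as np
import vegadct as v

# the k=3 majority rule is Boolean function 232
maj = v.make_majority_rule(3)
print(v.rule_decimal(maj))                      # 232

# a constant rule is a guesser: exactly 0.5 on a balanced evaluation set
rng = np.random.default_rng(2)
cfg = v.TaskConfig(N=59, R=50, eta=0.15, swap_fraction=0.1)
es = v.make_evaluation_set(cfg, degree=2, rng=rng)
print(v.evaluate_fitness(v.rule_from_decimal(3, 0), es, 0.15, cfg.max_steps, rng))
                                                # 0.5

# scaled-down VEGA: noise tolerance and genome complexity co-evolve
rng = np.random.default_rng(0)
log, pop = v.run_vega(
    v.VEGAConfig(k_start=5, k_max=7, eta_start=0.05,
                 patience_generations=15, max_generations=400),
    v.GAConfig(P=30, max_generations=400),
    v.TaskConfig(N=59, R=20, swap_fraction=0.1),
    rng, seed=0,
)
print(v.eta_ceilings(log))                      # {5: 0.12, 7: 0.25}
```

The ceiling dictionary reads: genomes with 32 bits (`k = 5`) mastered noise
up to `η = 0.12`; after promotion, 128-bit genomes (`k = 7`) pushed on to
`η = 0.25` — more complex rules sustain harder environments.

The same machinery is scriptable from the shell:

```bash
dct-vega run --seed 0 --out vega_out --n 59 --r 20 --p 30 \
             --k-start 5 --k-max 7 --eta-start 0.05 --patience-generations 15
dct-vega landscape --seed 11 --k 3 --eta 0.10 --out landscape_out
dct-vega profile vega_out/rule_k7_eta0.25.txt
```

`run` writes `evolution.csv` (one row per generation), the best genome at
each mastered `(k, η)` milestone as a rule file, and the effective config;
`landscape` writes per-rule fitnesses and the zero / guesser-band / high bin
counts; `profile` prints a rule's conservatism profile
`P(next state = 1 | own state, #neighbors in 1)`.

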