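"""Regenerate tests/data/evolved_rule_k7.txt.

Runs the k=7 stage of the variable-environment GA at reduced scale,
initialized from the promoted k=5 majority rule (the state the full
schedule reaches after mastering k=5), lets the noise ratchet climb to its
k=7 ceiling (~0.30), then selects the champion among all milestone genomes
and the final population by a high-replication re-evaluation at eta=0.30.
Fully seeded; rerunning reproduces the stored fixture bit for bit.

Usage:  python scripts/evolve_fixture.py [--seed 2] [--out tests/data/evolved_rule_k7.txt]
"""

import argparse

import numpy as np

import vegadct as v


def evolve_fixture(seed: int) -> v.RuleGenome:
    rng = np.random.default_rng(seed)
    vega_cfg = v.VEGAConfig(
        k_start=7, k_max=7, eta_start=0.15,
        patience_generations=25, max_generations=500,
    )
    ga_cfg = v.GAConfig(P=50, max_generations=500)
    task_cfg = v.TaskConfig(N=59, R=20, swap_fraction=0.1)
    start = [v.promote(v.make_majority_rule(5))]
    log, pop = v.run_vega(
        vega_cfg, ga_cfg, task_cfg, rng, seed=seed, initial_population=start
    )
    print(f"ratchet ceiling: {v.eta_ceilings(log)}")

    candidates = [r.best_rule for r in log.records if r.event == "eta_increment"]
    candidates += pop
    candidates = list({v.rule_decimal(c): c for c in candidates}.values())
    select_cfg = v.TaskConfig(N=59, R=400, eta=0.30, swap_fraction=0.1)
    rng_sel = np.random.default_rng(1000 + seed)
    eval_set = v.make_evaluation_set(select_cfg, 6, rng_sel)
    fits = v.evaluate_population_fitness(
        candidates, eval_set, 0.30, select_cfg.max_steps, rng_sel
    )
    best = int(np.argmax(fits))
    print(f"champion fitness at eta=0.30 (R=400): {fits[best]:.3f}")
    return candidates[best]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=2)
    ap.add_argument("--out", default="tests/data/evolved_rule_k7.txt")
    args = ap.parse_args()
    champ = evolve_fixture(args.seed)
    v.write_rule(champ, args.out)
    prof = v.conservative_profile(champ)
    print(f"wrote {args.out}  (decimal {v.rule_decimal(champ)})")
    print(f"flip thresholds: {v.flip_thresholds(prof)}")


if __name__ == "__main__":
    main()
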