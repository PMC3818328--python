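"""Exhaustive small-k landscape enumeration and robustness analyses.

For small genomes the whole rule space can be evaluated: at k=3 there are
only ``2**8 = 256`` Boolean rules, and binning their fitnesses exposes the
golf-course structure of the landscape — the overwhelming majority score
exactly zero, a thin band of guesser-like rules sits strictly below 0.5,
and essentially only the majority rule (232) performs well.  The space
grows as ``2**(2**k)``, which is why exhaustive enumeration (and blind
search) collapses beyond k=4.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._engine import eval_population_runs
from .fitness import TaskConfig, make_evaluation_set, evaluate_fitness
from .rules import RuleGenome

__all__ = [
    "count_genomes",
    "LandscapeHistogram",
    "landscape_histogram",
    "robustness_curve",
    "ENUMERATION_K_MAX",
]

ENUMERATION_K_MAX = 4
_SEED_MAX = 2**31


def count_genomes(k: int) -> int:
    """Number of Boolean rules over ``k`` inputs: ``2**(2**k)``, exact at
    any ``k`` (super-exponential growth; a k=11 count has 2048 bits)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return 2 ** (2**k)


@dataclass(frozen=True)
class LandscapeHistogram:
    """Fitness of every rule at one (eta, rho) regime, plus the bin counts.

    ``fitness[i]`` is the fitness of the rule with decimal id ``i``.  The
    three bins partition the rule set:

    ``zero``
        fitness exactly 0 — the flat bulk of the golf course;
    ``low``
        fitness in (0, 0.5] — partial credit up to and including the
        guessers, the constant-like rules that drive the system to one
        fixed consensus and so score exactly 1/2 on a balanced set;
    ``high``
        fitness strictly above 0.5 — rules that genuinely classify, i.e.
        beat guessing.

    Placing the guesser band (exactly 1/2) in the middle bin rather than
    the top one keeps "high" meaning "better than a coin flip".
    """

    k: int
    eta: float
    fitness: np.ndarray  # (2**(2**k),)

    @property
    def bins(self) -> dict[str, int]:
        f = self.fitness
        return {
            "zero": int(np.sum(f == 0.0)),
            "low": int(np.sum((f > 0.0) & (f <= 0.5))),
            "high": int(np.sum(f > 0.5)),
        }

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"rule_decimal": np.arange(self.fitness.size), "fitness": self.fitness}
        )


def landscape_histogram(
    k: int,
    task_cfg: TaskConfig,
    rng: np.random.Generator,
    engine: str = "auto",
) -> LandscapeHistogram:
    """Evaluate every ``2**(2**k)`` rule on one shared evaluation set.

    Enumeration order is the decimal rule numbering (row ``i`` is the rule
    whose table encodes the integer ``i``).  Refuses ``k > 4``: beyond that
    the rule space is astronomically large.
    """
    if k > ENUMERATION_K_MAX:
        raise ValueError(
            f"exhaustive enumeration is infeasible for k={k} "
            f"(2**(2**{k}) rules); limit is k <= {ENUMERATION_K_MAX}"
        )
    if k < 1:
        raise ValueError("k must be >= 1")
    n_rules = count_genomes(k)
    n_bits = 2**k
    # row i = table of rule i: bit j of i is the output for input pattern j
    ids = np.arange(n_rules, dtype=np.uint64)
    tables = (
        (ids[:, None] >> np.arange(n_bits, dtype=np.uint64)[None, :]) & 1
    ).astype(np.uint8)
    eval_set = make_evaluation_set(task_cfg, k - 1, rng)
    seeds = rng.integers(0, _SEED_MAX, size=(n_rules, eval_set.R))
    success, _ = eval_population_runs(
        tables, eval_set.networks, eval_set.inits, eval_set.targets,
        task_cfg.eta, task_cfg.max_steps, seeds, engine=engine,
    )
    return LandscapeHistogram(k, task_cfg.eta, success.mean(axis=1))


def robustness_curve(
    rule: RuleGenome,
    eta_grid,
    task_cfg: TaskConfig,
    rng: np.random.Generator,
    engine: str = "auto",
) -> np.ndarray:
    """Fitness of one rule across a noise grid.

    Each eta gets its own independently generated evaluation set (seeded
    through ``rng``, so the curve is reproducible); used to compare the
    noise robustness of evolved rules against the majority rule.
    """
    eta_grid = np.asarray(eta_grid, dtype=float)
    if np.any(eta_grid < 0) or np.any(eta_grid > 1):
        raise ValueError("eta values must lie in [0, 1]")
    out = np.empty(eta_grid.size)
    for i, eta in enumerate(eta_grid):
        cfg = task_cfg.with_eta(float(eta))
        eval_set = make_evaluation_set(cfg, rule.k - 1, rng)
        out[i] = evaluate_fitness(
            rule, eval_set, float(eta), cfg.max_steps, rng, engine=engine
        )
    return out
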