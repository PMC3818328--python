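"""Classical genetic algorithm and the variable-environment loop (VEGA).

The classical GA ranks the population by fitness each generation, keeps the
top 20% unchanged (elitism) and refills the rest by single-point crossover
plus per-bit mutation of uniformly drawn elite parents.

VEGA wraps that GA in an environmental ratchet.  Whenever some genome
masters the current noise level (fitness above 0.98), the elite is
snapshotted and the communication noise is raised by 0.01, restoring
evolutionary pressure.  When no genome passes the threshold for a patience
window (50 generations at full scale), the noise has exceeded what rules of
the current complexity can sustain: the last successful elite is *promoted*
— each genome gains two initially silent neighbor inputs (k -> k + 2) — the
networks are rebuilt at the matching degree, and evolution resumes at the
stalled noise level.  Noise and rule complexity thereby co-evolve.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fitness import TaskConfig, make_evaluation_set, evaluate_population_fitness
from .rules import RuleGenome, mutate, promote, random_rule

__all__ = [
    "GAConfig",
    "VEGAConfig",
    "GenerationRecord",
    "EvolutionLog",
    "crossover",
    "rank_population",
    "next_generation",
    "run_classical_ga",
    "run_vega",
    "eta_ceilings",
]

logger = logging.getLogger(__name__)

_SEED_MAX = 2**31


@dataclass(frozen=True)
class GAConfig:
    """Selection and variation parameters of the classical GA.

    ``per_bit_mutation_rate=None`` means ``2 / 2**k`` — about two expected
    bit flips per offspring at any genome length.
    """

    P: int = 100
    elite_fraction: float = 0.2
    per_bit_mutation_rate: float | None = None
    fitness_threshold: float = 0.98
    max_generations: int = 1000

    def __post_init__(self) -> None:
        if self.P < 1:
            raise ValueError("P must be >= 1")
        if not 0.0 < self.elite_fraction < 1.0:
            raise ValueError("elite_fraction must be in (0, 1)")
        if self.per_bit_mutation_rate is not None and not (
            0.0 <= self.per_bit_mutation_rate <= 1.0
        ):
            raise ValueError("per_bit_mutation_rate must be in [0, 1]")
        if not 0.0 < self.fitness_threshold <= 1.0:
            raise ValueError("fitness_threshold must be in (0, 1]")
        if self.max_generations < 1:
            raise ValueError("max_generations must be >= 1")

    @property
    def n_elite(self) -> int:
        return max(1, math.ceil(self.elite_fraction * self.P))

    def mutation_rate(self, k: int) -> float:
        if self.per_bit_mutation_rate is not None:
            return self.per_bit_mutation_rate
        return 2.0 / 2**k


@dataclass(frozen=True)
class VEGAConfig:
    """Schedule of the variable environment.

    The noise ratchet raises eta by ``eta_increment`` whenever best fitness
    exceeds ``fitness_threshold``; after ``patience_generations`` without a
    pass, genomes are promoted (k -> k + k_step) until ``k_max``.
    """

    k_start: int = 5
    k_step: int = 2
    k_max: int = 11
    fitness_threshold: float = 0.98
    eta_increment: float = 0.01
    eta_start: float = 0.0
    patience_generations: int = 50
    max_generations: int = 1000

    def __post_init__(self) -> None:
        if self.k_start < 1 or self.k_start % 2 == 0:
            raise ValueError("k_start must be odd and >= 1")
        if self.k_step < 2 or self.k_step % 2 != 0:
            raise ValueError("k_step must be even and >= 2")
        if self.k_max < self.k_start:
            raise ValueError("k_max must be >= k_start")
        if not 0.0 < self.fitness_threshold <= 1.0:
            raise ValueError("fitness_threshold must be in (0, 1]")
        if self.eta_increment <= 0:
            raise ValueError("eta_increment must be > 0")
        if not 0.0 <= self.eta_start <= 1.0:
            raise ValueError("eta_start must be in [0, 1]")
        if self.patience_generations < 1:
            raise ValueError("patience_generations must be >= 1")


@dataclass(frozen=True)
class GenerationRecord:
    generation: int
    k: int
    eta: float
    best_fitness: float
    mean_fitness: float
    best_rule: RuleGenome
    event: str = "none"  # none | eta_increment | promotion


@dataclass
class EvolutionLog:
    """Per-generation record of an evolution run."""

    seed: int | None = None
    records: list[GenerationRecord] = field(default_factory=list)

    def append(self, record: GenerationRecord) -> None:
        self.records.append(record)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def best_fitness_trace(self) -> np.ndarray:
        return np.array([r.best_fitness for r in self.records])

    @property
    def eta_trace(self) -> np.ndarray:
        return np.array([r.eta for r in self.records])

    def first_success_generation(self, threshold: float) -> int | None:
        """Generation index at which best fitness first reached the
        threshold, or None."""
        for r in self.records:
            if r.best_fitness >= threshold:
                return r.generation
        return None

    def to_dataframe(self) -> pd.DataFrame:
        from .rules import rule_decimal

        rows = [
            {
                "generation": r.generation,
                "k": r.k,
                "eta": r.eta,
                "best_fitness": r.best_fitness,
                "mean_fitness": r.mean_fitness,
                "event": r.event,
                "best_rule_decimal": str(rule_decimal(r.best_rule)),
            }
            for r in self.records
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "generation", "k", "eta", "best_fitness",
                "mean_fitness", "event", "best_rule_decimal",
            ],
        )


def crossover(a: RuleGenome, b: RuleGenome, rng: np.random.Generator) -> RuleGenome:
    """Single-point crossover: a uniformly drawn cut in ``1..2**k - 1``
    splices a's prefix onto b's suffix."""
    if a.k != b.k:
        raise ValueError(f"cannot cross rules with k={a.k} and k={b.k}")
    n = a.table.size
    cut = int(rng.integers(1, n))
    child = np.concatenate([a.table[:cut], b.table[cut:]])
    return RuleGenome(a.k, child)


def rank_population(
    fitnesses: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Indices sorted by descending fitness, ties broken by a seeded random
    shuffle ahead of a stable sort."""
    fitnesses = np.asarray(fitnesses)
    perm = rng.permutation(fitnesses.size)
    order = perm[np.argsort(-fitnesses[perm], kind="stable")]
    return order


def next_generation(
    population: list[RuleGenome],
    fitnesses: np.ndarray,
    cfg: GAConfig,
    rng: np.random.Generator,
) -> list[RuleGenome]:
    """Elitist selection step: the top ``ceil(elite_fraction * P)`` genomes
    survive unchanged, the bottom 80% is discarded, and the vacated slots
    are refilled with mutated crossover children of uniformly drawn elite
    parents (with replacement)."""
    if len(population) != cfg.P or len(fitnesses) != cfg.P:
        raise ValueError("population/fitness size mismatch with cfg.P")
    order = rank_population(fitnesses, rng)
    elite = [population[i] for i in order[: cfg.n_elite]]
    rate = cfg.mutation_rate(population[0].k)
    children = []
    for _ in range(cfg.P - len(elite)):
        x, y = rng.integers(0, len(elite), size=2)
        child = crossover(elite[x], elite[y], rng) if elite[x].table.size > 1 else elite[x]
        children.append(mutate(child, rate, rng))
    return elite + children


def _refill_from_elite(
    elite: list[RuleGenome], cfg: GAConfig, rng: np.random.Generator
) -> list[RuleGenome]:
    rate = cfg.mutation_rate(elite[0].k)
    out = list(elite[: cfg.P])
    while len(out) < cfg.P:
        x, y = rng.integers(0, len(elite), size=2)
        child = crossover(elite[x], elite[y], rng) if elite[x].table.size > 1 else elite[x]
        out.append(mutate(child, rate, rng))
    return out


def run_classical_ga(
    k: int,
    ga_cfg: GAConfig,
    task_cfg: TaskConfig,
    rng: np.random.Generator,
    seed: int | None = None,
) -> EvolutionLog:
    """Fixed-environment GA baseline at genome size ``k``.

    Starts from P uniformly random rules and iterates evaluation plus
    selection until the best fitness reaches ``ga_cfg.fitness_threshold``
    or ``max_generations``; non-convergence is a logged outcome.  A fresh
    shared evaluation set is drawn every generation.
    """
    population = [random_rule(k, rng) for _ in range(ga_cfg.P)]
    log = EvolutionLog(seed=seed)
    degree = k - 1
    for gen in range(ga_cfg.max_generations):
        eval_set = make_evaluation_set(task_cfg, degree, rng)
        fits = evaluate_population_fitness(
            population, eval_set, task_cfg.eta, task_cfg.max_steps, rng
        )
        best = int(np.argmax(fits))
        log.append(
            GenerationRecord(
                gen, k, task_cfg.eta, float(fits[best]), float(fits.mean()),
                population[best],
            )
        )
        logger.info(
            "gen %d k=%d eta=%.3f best=%.3f mean=%.3f",
            gen, k, task_cfg.eta, fits[best], fits.mean(),
        )
        if fits[best] >= ga_cfg.fitness_threshold:
            break
        population = next_generation(population, fits, ga_cfg, rng)
    return log


def run_vega(
    vega_cfg: VEGAConfig,
    ga_cfg: GAConfig,
    task_cfg: TaskConfig,
    rng: np.random.Generator,
    seed: int | None = None,
    initial_population: list[RuleGenome] | None = None,
) -> tuple[EvolutionLog, list[RuleGenome]]:
    """The variable-environment loop: noise ratchet plus genome promotion.

    Each generation draws a fresh shared evaluation set at the current
    degree and evaluates the whole population at the current eta.  On a
    threshold pass the elite is snapshotted, eta rises by ``eta_increment``
    and the stagnation counter resets (the next generation re-estimates all
    fitnesses in the harder environment).  Otherwise a normal selection
    step runs; once ``patience_generations`` pass without a threshold pass,
    the last snapshotted elite (the genomes that mastered
    ``eta - eta_increment``) is promoted to ``k + k_step``, the population
    is refilled from the promoted elite, and eta stays at the stalled
    value.  The run stops when promotion would exceed ``k_max`` or at
    ``max_generations``.
    """
    k = vega_cfg.k_start
    eta = vega_cfg.eta_start
    if initial_population is not None:
        if any(r.k != k for r in initial_population):
            raise ValueError("initial population must have k == k_start")
        population = _refill_from_elite(list(initial_population), ga_cfg, rng)
    else:
        population = [random_rule(k, rng) for _ in range(ga_cfg.P)]
    snapshot: list[RuleGenome] | None = None
    stall = 0
    log = EvolutionLog(seed=seed)

    for gen in range(vega_cfg.max_generations):
        eval_set = make_evaluation_set(task_cfg, k - 1, rng)
        fits = evaluate_population_fitness(
            population, eval_set, eta, task_cfg.max_steps, rng
        )
        order = rank_population(fits, rng)
        best = int(order[0])
        # record this generation's environment and champion before any
        # transition mutates them
        rec_k, rec_eta = k, eta
        best_rule = population[best]
        best_fit, mean_fit = float(fits[best]), float(fits.mean())
        event = "none"
        stop = False

        if best_fit > vega_cfg.fitness_threshold:
            event = "eta_increment"
            snapshot = [population[i] for i in order[: ga_cfg.n_elite]]
            eta = round(eta + vega_cfg.eta_increment, 10)
            stall = 0
        elif snapshot is not None and stall + 1 >= vega_cfg.patience_generations:
            # the stagnation clock only runs once this k has been mastered at
            # least once: promotion generalizes the genomes that succeeded at
            # the previous noise level, so before any success the GA simply
            # keeps grinding (the initial guesser phase can far outlast the
            # patience window)
            stall = 0
            source = snapshot
            if k + vega_cfg.k_step > vega_cfg.k_max:
                stop = True  # promotion would exceed k_max: schedule exhausted
            else:
                event = "promotion"
                population = _refill_from_elite(
                    [promote(r) for r in source], ga_cfg, rng
                )
                k += vega_cfg.k_step
                snapshot = None
        else:
            if snapshot is not None:
                stall += 1
            population = next_generation(population, fits, ga_cfg, rng)

        log.append(
            GenerationRecord(gen, rec_k, rec_eta, best_fit, mean_fit, best_rule, event)
        )
        logger.info(
            "gen %d k=%d eta=%.3f best=%.3f mean=%.3f event=%s",
            gen, rec_k, rec_eta, best_fit, mean_fit, event,
        )
        if stop:
            break
    return log, population


def eta_ceilings(log: EvolutionLog) -> dict[int, float]:
    """Highest noise level mastered at each genome size: per ``k``, the
    maximum eta at which the fitness threshold was passed (the eta recorded
    at ``eta_increment`` events, i.e. before the ratchet raised it)."""
    out: dict[int, float] = {}
    for r in log.records:
        if r.event == "eta_increment":
            out[r.k] = max(out.get(r.k, r.eta), r.eta)
    return out
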