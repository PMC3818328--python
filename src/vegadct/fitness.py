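"""Fitness estimation: success fraction over a shared set of initial conditions.

A genome's fitness is the fraction of density-classification realizations it
solves.  Each generation draws one evaluation set — ``R`` paired (initial
state, rewired network) fixtures, half with a 60/40 majority of ones and
half with a 60/40 majority of zeros — and every genome in the population is
scored on that identical set, so selection compares genomes on the same
problems rather than on sampling luck.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._engine import eval_population_runs
from .rules import RuleGenome
from .topology import build_ring, rewire_swaps, swap_count

__all__ = [
    "TaskConfig",
    "EvaluationSet",
    "make_evaluation_set",
    "evaluate_fitness",
    "evaluate_population_fitness",
]

_SEED_MAX = 2**31


@dataclass(frozen=True)
class TaskConfig:
    """Parameters of one density-classification environment.

    N
        Agents per system (odd, so strict majorities exist).
    rho
        Initial majority fraction; task difficulty is ``2 * rho - 1``
        (default 0.6, the 60/40 split).
    eta
        Communication-noise probability in [0, 1].
    T
        Step budget per realization; ``None`` means ``10 * N``, long enough
        for the noisy dynamics to order while early stopping keeps typical
        cost far smaller.
    R
        Realizations per genome (even; split into balanced halves).
    swap_fraction
        Rewiring intensity: the fraction of ring edges passed through a
        degree-preserving double-edge swap.
    """

    N: int = 149
    rho: float = 0.6
    eta: float = 0.0
    T: int | None = None
    R: int = 100
    swap_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.N < 3 or self.N % 2 == 0:
            raise ValueError(f"N must be odd and >= 3, got {self.N}")
        if not 0.5 < self.rho <= 1.0:
            raise ValueError(f"rho must be in (0.5, 1], got {self.rho}")
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError(f"eta must be in [0, 1], got {self.eta}")
        if self.R < 2 or self.R % 2 != 0:
            raise ValueError(f"R must be even and >= 2, got {self.R}")
        if self.T is not None and self.T < 1:
            raise ValueError("T must be >= 1")
        if self.swap_fraction < 0:
            raise ValueError("swap_fraction must be >= 0")

    @property
    def max_steps(self) -> int:
        return self.T if self.T is not None else 10 * self.N

    @property
    def majority_count(self) -> int:
        """Agents initially holding the majority bit: ``round(rho * N)``,
        a strict majority since N is odd."""
        return round(self.rho * self.N)

    def with_eta(self, eta: float) -> "TaskConfig":
        return replace(self, eta=eta)


@dataclass(frozen=True)
class EvaluationSet:
    """``R`` shared (initial state, network) fixtures at one degree.

    Exactly half the initial states have majority bit 1 and half majority
    bit 0, each with ``round(rho * N)`` agents in the majority.  Every
    realization carries its own independently rewired ring.
    """

    degree: int
    networks: np.ndarray = field(repr=False)  # (R, N, degree) int32 slot ids
    inits: np.ndarray = field(repr=False)  # (R, N) uint8
    targets: np.ndarray = field(repr=False)  # (R,) uint8

    @property
    def R(self) -> int:
        return self.inits.shape[0]

    @property
    def N(self) -> int:
        return self.inits.shape[1]


def make_evaluation_set(
    cfg: TaskConfig, degree: int, rng: np.random.Generator
) -> EvaluationSet:
    """Draw one balanced evaluation set at the given network degree."""
    if degree % 2 != 0 or degree < 2:
        raise ValueError(f"degree must be even and >= 2, got {degree}")
    N, R = cfg.N, cfg.R
    m = cfg.majority_count
    n_swaps = swap_count(N, degree, cfg.swap_fraction)
    ring = build_ring(N, degree)

    networks = np.empty((R, N, degree), dtype=np.int32)
    inits = np.empty((R, N), dtype=np.uint8)
    targets = np.empty(R, dtype=np.uint8)
    for r in range(R):
        majority = r % 2  # alternate: R/2 of each
        positions = rng.choice(N, size=m, replace=False)
        state = np.full(N, 1 - majority, dtype=np.uint8)
        state[positions] = majority
        net = rewire_swaps(ring, n_swaps, rng)
        networks[r] = net.slots
        inits[r] = state
        targets[r] = majority
    return EvaluationSet(degree, networks, inits, targets)


def _tables_matrix(rules: list[RuleGenome], degree: int) -> np.ndarray:
    if not rules:
        raise ValueError("empty population")
    k = degree + 1
    for rule in rules:
        if rule.k != k:
            raise ValueError(
                f"rule reads {rule.k - 1} neighbors but networks have degree {degree}"
            )
    return np.stack([rule.table for rule in rules])


def evaluate_population_fitness(
    rules: list[RuleGenome],
    eval_set: EvaluationSet,
    eta: float,
    T: int,
    rng: np.random.Generator,
    engine: str = "auto",
) -> np.ndarray:
    """Fitness of every genome on the shared evaluation set.

    Returns the success fractions, exact rationals with denominator ``R``
    represented in floating point.  Deterministic given ``rng``'s state.
    """
    tables = _tables_matrix(rules, eval_set.degree)
    seeds = rng.integers(0, _SEED_MAX, size=(len(rules), eval_set.R))
    success, _ = eval_population_runs(
        tables, eval_set.networks, eval_set.inits, eval_set.targets,
        eta, T, seeds, engine=engine,
    )
    return success.mean(axis=1)


def evaluate_fitness(
    rule: RuleGenome,
    eval_set: EvaluationSet,
    eta: float,
    T: int,
    rng: np.random.Generator,
    engine: str = "auto",
) -> float:
    """Success fraction of one genome over the evaluation set."""
    return float(
        evaluate_population_fitness([rule], eval_set, eta, T, rng, engine=engine)[0]
    )
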