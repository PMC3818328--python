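"""Synchronous noisy-communication dynamics and the consensus criterion.

All agents update simultaneously from the pre-step state.  Communication
noise acts on perception: each neighbor's transmitted state is independently
flipped with probability ``eta`` per receiving agent, per slot, per time
step; an agent always reads its own state exactly.  Because noise never lets
a finite system settle into strict unanimity, the density-classification
task counts as solved at the first step after which, were the noise turned
off, a single noiseless update would bring every agent to the initial
majority state.
"""

from __future__ import annotations

import numpy as np

from .rules import RuleGenome
from .topology import AgentNetwork

__all__ = ["step", "consensus_achieved", "majority_bit", "run_task"]


def _check(state: np.ndarray, network: AgentNetwork, rule: RuleGenome) -> np.ndarray:
    state = np.ascontiguousarray(state, dtype=np.uint8)
    if state.shape != (network.N,):
        raise ValueError(f"state must have length N={network.N}")
    if rule.k - 1 != network.degree:
        raise ValueError(
            f"rule reads {rule.k - 1} neighbors but network degree is {network.degree}"
        )
    return state


def step(
    state: np.ndarray,
    network: AgentNetwork,
    rule: RuleGenome,
    eta: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One synchronous update of all agents.

    Each agent perceives its slot-ordered neighbors' pre-step states, each
    independently flipped with probability ``eta`` (fresh draws per agent
    and slot), reads its own state without noise, and looks its next state
    up in the rule table.
    """
    state = _check(state, network, rule)
    if not 0.0 <= eta <= 1.0:
        raise ValueError(f"eta must be in [0, 1], got {eta}")
    degree = network.degree
    perceived = state[network.slots].astype(np.int64)
    if eta > 0.0:
        if rng is None:
            raise ValueError("eta > 0 requires an rng")
        perceived ^= (rng.random((network.N, degree)) < eta).astype(np.int64)
    weights = 1 << np.arange(degree - 1, -1, -1, dtype=np.int64)
    idx = (state.astype(np.int64) << degree) + perceived @ weights
    return rule.table[idx]


def consensus_achieved(
    state: np.ndarray, network: AgentNetwork, rule: RuleGenome, target: int
) -> bool:
    """True iff, with the noise turned off, the system would converge to the
    all-``target`` state in the next step: one noiseless synchronous step
    from ``state`` sends every agent to ``target``, *and* the all-``target``
    state is a noiseless fixed point of the rule, so the system settles
    there rather than merely passing through.  The fixed-point clause is
    what separates genuine classifiers from oscillators that visit the
    correct consensus for a single step and leave again.
    """
    t = int(target)
    # fixed point: the unanimous-target input pattern must map to target
    unanimous = (2**rule.k - 1) if t == 1 else 0
    if int(rule.table[unanimous]) != t:
        return False
    return bool(np.all(step(state, network, rule, 0.0) == t))


def majority_bit(state: np.ndarray) -> int:
    """Strict-majority bit of a state; ties are invalid inputs."""
    state = np.asarray(state)
    ones = int(state.sum())
    if 2 * ones == state.size:
        raise ValueError("tied initial condition: majority undefined")
    return int(2 * ones > state.size)


def run_task(
    rule: RuleGenome,
    network: AgentNetwork,
    initial: np.ndarray,
    eta: float,
    T: int,
    rng: np.random.Generator | None = None,
) -> tuple[bool, int]:
    """One density-classification realization.

    Applies up to ``T`` noisy steps, checking the consensus criterion
    against the initial strict-majority bit after every step (first-passage
    semantics).  Returns ``(success, steps_used)``; success is all-or-none.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    target = majority_bit(initial)
    state = _check(initial, network, rule)
    for t in range(1, T + 1):
        state = step(state, network, rule, eta, rng)
        if consensus_achieved(state, network, rule, target):
            return True, t
    return False, T
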