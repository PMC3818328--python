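"""Boolean rule genomes: the unit of evolution in the density-classification task.

A rule genome is a Boolean function of ``k`` binary inputs — the agent's own
state plus its ``k - 1`` neighbors' states — stored as a lookup table of
``2**k`` output bits.  Table entry ``i`` is the output for the input pattern
whose binary encoding is ``i``, with the agent's own state as the most
significant bit and neighbor slot 0 occupying the next bit.  Under this
numbering the 3-input majority function is rule 232, the standard decimal
name for that Boolean function.

Promotion ("generalization") expands a ``k``-input rule to ``k + 2`` inputs
so that the two new, least-significant inputs are initially silent: the
promoted rule reproduces the base rule's output for every combination of the
new bits, so its dynamics are unchanged until mutation touches the new
entries.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RuleGenome",
    "ConservativeProfile",
    "make_majority_rule",
    "rule_decimal",
    "rule_from_decimal",
    "lookup",
    "promote",
    "mutate",
    "random_rule",
    "conservative_profile",
    "flip_thresholds",
    "read_rule",
    "write_rule",
]

# exact noisy-profile enumeration is O(4**(k-1)); beyond this we sample
_EXACT_PROFILE_K_MAX = 13


@dataclass(frozen=True)
class RuleGenome:
    """A Boolean function of ``k`` inputs as a flat lookup table.

    Parameters
    ----------
    k : int
        Number of inputs, counting the agent itself (odd, >= 1), so the
        rule reads ``k - 1`` neighbors.
    table : numpy.ndarray
        uint8 vector of length ``2**k``; entry ``i`` is the output bit for
        the input pattern with binary encoding ``i``.
    """

    k: int
    table: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.k < 1 or self.k % 2 == 0:
            raise ValueError(f"k must be odd and >= 1, got {self.k}")
        table = np.ascontiguousarray(self.table, dtype=np.uint8)
        if table.shape != (2**self.k,):
            raise ValueError(
                f"table must have length 2**k = {2**self.k}, got shape {table.shape}"
            )
        if table.size and table.max() > 1:
            raise ValueError("table entries must be 0 or 1")
        table.setflags(write=False)
        object.__setattr__(self, "table", table)

    @property
    def n_neighbors(self) -> int:
        return self.k - 1

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RuleGenome):
            return NotImplemented
        return self.k == other.k and bool(np.array_equal(self.table, other.table))

    def __hash__(self) -> int:
        return hash((self.k, self.table.tobytes()))


def make_majority_rule(k: int) -> RuleGenome:
    """Majority rule on ``k`` inputs: output 1 iff more than half the input
    bits (own state included) are 1.  For ``k = 3`` this is rule 232; for
    ``k = 1`` it degenerates to copying the agent's own state.
    """
    if k < 1 or k % 2 == 0:
        raise ValueError(f"k must be odd and >= 1, got {k}")
    idx = np.arange(2**k, dtype=np.uint64)
    popcount = np.zeros(2**k, dtype=np.int64)
    for b in range(k):
        popcount += (idx >> np.uint64(b)).astype(np.int64) & 1
    return RuleGenome(k, (popcount > k // 2).astype(np.uint8))


def rule_decimal(rule: RuleGenome) -> int:
    """Decimal name of the rule: ``sum_i table[i] * 2**i`` as an exact
    arbitrary-precision integer (a k=11 table needs 2048 bits)."""
    bits = rule.table[::-1]  # most significant index first
    return int("".join("1" if b else "0" for b in bits), 2)


def rule_from_decimal(k: int, d: int) -> RuleGenome:
    """Inverse of :func:`rule_decimal`."""
    if d < 0 or d >= 2 ** (2**k):
        raise ValueError(f"decimal id {d} out of range for k={k}")
    n = 2**k
    table = np.frombuffer(
        format(d, f"0{n}b").encode("ascii"), dtype=np.uint8
    ) - ord("0")
    return RuleGenome(k, table[::-1].astype(np.uint8))


def _index(k: int, own: int, neighbors) -> int:
    neighbors = list(neighbors)
    if len(neighbors) != k - 1:
        raise ValueError(
            f"expected {k - 1} neighbor bits, got {len(neighbors)}"
        )
    idx = int(own) << (k - 1)
    for j, bit in enumerate(neighbors):
        idx |= int(bit) << (k - 2 - j)
    return idx


def lookup(rule: RuleGenome, own: int, neighbors) -> int:
    """Output bit for one input: own state (most significant index bit) and
    the ordered neighbor-slot bits.  Promotion appends new neighbors at the
    least significant end, so slot order is stable across promotions."""
    return int(rule.table[_index(rule.k, own, neighbors)])


def promote(rule: RuleGenome) -> RuleGenome:
    """Expand the rule to read two extra neighbors, keeping the base output
    for every combination of the two new (least-significant) input bits.

    The promoted table is a 4-fold tiling of the base table, so the new
    inputs are silent: a promoted rule's dynamics on a degree-(k+1) network
    are identical to the base rule's as long as the new entries are
    unmutated.
    """
    return RuleGenome(rule.k + 2, np.repeat(rule.table, 4))


def mutate(
    rule: RuleGenome, per_bit_rate: float, rng: np.random.Generator
) -> RuleGenome:
    """Flip each table bit independently with probability ``per_bit_rate``."""
    if not 0.0 <= per_bit_rate <= 1.0:
        raise ValueError(f"per_bit_rate must be in [0, 1], got {per_bit_rate}")
    flips = rng.random(rule.table.size) < per_bit_rate
    return RuleGenome(rule.k, rule.table ^ flips.astype(np.uint8))


def random_rule(k: int, rng: np.random.Generator) -> RuleGenome:
    """A rule with uniformly random table bits."""
    return RuleGenome(k, rng.integers(0, 2, size=2**k, dtype=np.uint8))


@dataclass(frozen=True)
class ConservativeProfile:
    """Average updated state by input class.

    ``p_one[s, c]`` is the probability that the updated state is 1 given the
    agent's own state ``s`` and exactly ``c`` of its ``k - 1`` neighbors in
    state 1, with each neighbor's transmitted state independently flipped
    with probability ``eta`` before lookup (the agent's own state is read
    without noise).  Within the class, the neighbor pattern is uniform over
    the ``C(k-1, c)`` arrangements.
    """

    k: int
    eta: float
    p_one: np.ndarray  # shape (2, k): [own_state, ones_count]

    def __post_init__(self) -> None:
        p = np.asarray(self.p_one, dtype=float)
        if p.shape != (2, self.k):
            raise ValueError(f"p_one must have shape (2, {self.k})")
        if np.any(p < -1e-12) or np.any(p > 1 + 1e-12):
            raise ValueError("profile probabilities must lie in [0, 1]")
        object.__setattr__(self, "p_one", p)


def conservative_profile(
    rule: RuleGenome,
    eta: float = 0.0,
    rng: np.random.Generator | None = None,
    mc_samples: int = 100_000,
) -> ConservativeProfile:
    """Average updated state of an agent by (own state, #neighbors in 1).

    At ``eta = 0`` this is the fraction of neighbor patterns in each class
    whose output is 1.  At ``eta > 0`` the exact expectation over independent
    per-neighbor flips is computed by enumerating all perceived patterns,
    exactly for ``k <= 13``; beyond that a seeded Monte Carlo estimate with
    ``mc_samples`` draws per class is used.
    """
    if not 0.0 <= eta <= 1.0:
        raise ValueError(f"eta must be in [0, 1], got {eta}")
    m = rule.k - 1  # number of neighbors
    patterns = np.arange(2**m, dtype=np.int64)
    pop = np.zeros(2**m, dtype=np.int64)
    for b in range(m):
        pop += (patterns >> b) & 1

    # out[s, v]: output when own state is s and perceived neighbor pattern is v
    out = np.empty((2, 2**m), dtype=np.float64)
    for s in (0, 1):
        out[s] = rule.table[(s << m) + patterns]

    p_one = np.empty((2, rule.k), dtype=float)
    if eta == 0.0:
        for s in (0, 1):
            for c in range(rule.k):
                p_one[s, c] = out[s, pop == c].mean() if m else out[s, 0]
    elif rule.k <= _EXACT_PROFILE_K_MAX:
        # transition[v, u] = P(perceive u | true pattern v) under iid flips
        ham = pop[patterns[:, None] ^ patterns[None, :]]
        trans = eta**ham * (1.0 - eta) ** (m - ham)
        p_true = trans @ out.T  # (2**m, 2): P(output 1 | true v, own s)
        for s in (0, 1):
            for c in range(rule.k):
                p_one[s, c] = p_true[pop == c, s].mean()
    else:
        if rng is None:
            rng = np.random.default_rng(0)
        for s in (0, 1):
            for c in range(rule.k):
                members = patterns[pop == c]
                v = rng.choice(members, size=mc_samples)
                flips = (rng.random((mc_samples, m)) < eta).astype(np.int64)
                flip_mask = (flips << np.arange(m)).sum(axis=1)
                p_one[s, c] = out[s, v ^ flip_mask].mean()
    return ConservativeProfile(rule.k, eta, p_one)


def flip_thresholds(profile: ConservativeProfile) -> dict[int, int]:
    """Minimal number of opposing neighbors at which the agent flips.

    For each own state ``s``, the smallest count of neighbors in state
    ``1 - s`` for which the probability of switching away from ``s``
    exceeds 1/2; ``k`` (more neighbors than exist) if the rule never flips.
    A more conservative rule has larger thresholds: it demands a larger
    opposing majority before abandoning its own state.
    """
    m = profile.k - 1
    thresholds: dict[int, int] = {}
    for s in (0, 1):
        thresholds[s] = profile.k
        for opposing in range(m + 1):
            c_ones = opposing if s == 0 else m - opposing
            p_flip = profile.p_one[0, c_ones] if s == 0 else 1.0 - profile.p_one[1, c_ones]
            if p_flip > 0.5:
                thresholds[s] = opposing
                break
    return thresholds


def write_rule(rule: RuleGenome, path) -> None:
    """Write the plain-text rule format: ``k=<int>`` then the table as a
    binary string, leftmost character = output for index ``2**k - 1`` (the
    k=3 majority rule reads ``11101000``)."""
    bits = "".join(str(int(b)) for b in rule.table[::-1])
    with open(path, "w") as fh:
        fh.write(f"k={rule.k}\n{bits}\n")


def read_rule(path) -> RuleGenome:
    """Read a rule file written by :func:`write_rule`; rejects tables whose
    length does not equal ``2**k``."""
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if len(lines) < 2 or not lines[0].startswith("k="):
        raise ValueError(f"malformed rule file {path!r}: expected 'k=<int>' header")
    k = int(lines[0][2:])
    bits = lines[1]
    if len(bits) != 2**k or set(bits) - {"0", "1"}:
        raise ValueError(
            f"malformed rule file {path!r}: table must be {2**k} binary digits"
        )
    table = np.frombuffer(bits.encode("ascii"), dtype=np.uint8) - ord("0")
    return RuleGenome(k, table[::-1].astype(np.uint8))
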