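"""Ring networks with degree-preserving small-world rewiring.

Agents sit on a ring and are initially wired to their ``degree`` nearest
neighbors.  Rewiring swaps the endpoints of randomly chosen pairs of edges
(a double-edge swap), which preserves every agent's degree exactly while
introducing long-range shortcuts — the degree-regular small-world
construction.  Neighbor *slots* are ordered (ring offsets
``-degree/2 .. -1, +1 .. +degree/2``) and a swapped-in neighbor takes the
slot of the neighbor it replaced, so rule lookup slot order is well defined
on rewired networks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AgentNetwork",
    "RewiringError",
    "build_ring",
    "rewire_swaps",
    "swap_count",
    "write_edgelist",
]


class RewiringError(RuntimeError):
    """Raised when valid edge swaps cannot be sampled (pathologically small
    or dense network)."""


@dataclass(frozen=True)
class AgentNetwork:
    """``N`` agents, each with an ordered list of ``degree`` neighbor slots.

    ``slots[i, j]`` is the id of agent *i*'s neighbor in slot *j*.  The
    neighbor relation is symmetric and free of self-loops and duplicates.
    """

    N: int
    degree: int
    slots: np.ndarray = field(repr=False)  # (N, degree) int32

    def __post_init__(self) -> None:
        slots = np.ascontiguousarray(self.slots, dtype=np.int32)
        if slots.shape != (self.N, self.degree):
            raise ValueError(f"slots must have shape ({self.N}, {self.degree})")
        object.__setattr__(self, "slots", slots)

    def edges(self) -> set[tuple[int, int]]:
        """Undirected edge set as sorted (i, j) pairs."""
        out: set[tuple[int, int]] = set()
        for i in range(self.N):
            for j in self.slots[i]:
                out.add((min(i, int(j)), max(i, int(j))))
        return out

    def validate(self) -> None:
        """Check degree-regularity, symmetry, and absence of self-loops and
        duplicate neighbors; raises ``ValueError`` on violation."""
        for i in range(self.N):
            row = self.slots[i]
            if len(set(row.tolist())) != self.degree:
                raise ValueError(f"agent {i} has duplicate neighbors")
            if i in row:
                raise ValueError(f"agent {i} has a self-loop")
            for j in row:
                if i not in self.slots[j]:
                    raise ValueError(f"edge ({i}, {j}) is not symmetric")


def build_ring(N: int, degree: int) -> AgentNetwork:
    """Ring lattice: agent ``i`` is wired to ``i +- 1, ..., i +- degree/2``
    (mod N), slots ordered ``-degree/2 .. -1, +1 .. +degree/2``."""
    if degree < 2 or degree % 2 != 0:
        raise ValueError(f"degree must be even and >= 2, got {degree}")
    if N <= degree:
        raise ValueError(f"need N > degree, got N={N}, degree={degree}")
    half = degree // 2
    offsets = np.array(
        [o for o in range(-half, 0)] + [o for o in range(1, half + 1)],
        dtype=np.int64,
    )
    slots = (np.arange(N)[:, None] + offsets[None, :]) % N
    return AgentNetwork(N, degree, slots.astype(np.int32))


def swap_count(N: int, degree: int, swap_fraction: float) -> int:
    """Number of double-edge swaps for rewiring intensity ``swap_fraction``:
    ``ceil(swap_fraction * N * degree / 2)``, i.e. a fraction of the edge
    count."""
    if swap_fraction < 0:
        raise ValueError("swap_fraction must be >= 0")
    return math.ceil(swap_fraction * N * degree / 2)


def _replace_slot(slots: np.ndarray, agent: int, old: int, new: int) -> None:
    row = slots[agent]
    j = int(np.nonzero(row == old)[0][0])
    row[j] = new


def rewire_swaps(
    network: AgentNetwork, n_swaps: int, rng: np.random.Generator
) -> AgentNetwork:
    """Apply ``n_swaps`` accepted double-edge swaps and return a new network.

    A swap picks two distinct edges (a, b) and (c, d) (orientation
    randomized) and replaces them with (a, d) and (c, b).  Proposals that
    would create a self-loop or a duplicate edge are rejected and resampled;
    after ``100 * n_swaps`` failed proposals a :class:`RewiringError` is
    raised.  Degrees are preserved by construction, and each new neighbor
    occupies the slot of the neighbor it replaced.
    """
    if n_swaps < 0:
        raise ValueError("n_swaps must be >= 0")
    if n_swaps == 0:
        return network
    slots = network.slots.copy()
    edge_list = np.array(sorted(network.edges()), dtype=np.int64)
    n_edges = len(edge_list)
    accepted = 0
    proposals = 0
    cap = 100 * n_swaps
    while accepted < n_swaps:
        if proposals >= cap:
            raise RewiringError(
                f"exceeded {cap} proposals after {accepted}/{n_swaps} swaps"
            )
        proposals += 1
        e1, e2 = rng.choice(n_edges, size=2, replace=False)
        a, b = edge_list[e1]
        c, d = edge_list[e2]
        if rng.random() < 0.5:
            a, b = b, a
        if rng.random() < 0.5:
            c, d = d, c
        # new edges (a, d) and (c, b)
        if a == d or c == b:
            continue
        if d in slots[a] or b in slots[c]:
            continue
        _replace_slot(slots, a, b, d)
        _replace_slot(slots, d, c, a)
        _replace_slot(slots, c, d, b)
        _replace_slot(slots, b, a, c)
        edge_list[e1] = (min(a, d), max(a, d))
        edge_list[e2] = (min(c, b), max(c, b))
        accepted += 1
    return AgentNetwork(network.N, network.degree, slots)


def write_edgelist(network: AgentNetwork, path) -> None:
    """Dump the undirected edge list, one tab-separated pair per line."""
    with open(path, "w") as fh:
        for i, j in sorted(network.edges()):
            fh.write(f"{i}\t{j}\n")
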