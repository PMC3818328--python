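"""Batch simulation kernels for fitness evaluation.

Evaluating a population means running every (genome, initial-condition)
pair to completion — up to ``G * R`` independent realizations per
generation.  The hot path is a per-run scalar loop JIT-compiled with numba;
a vectorized numpy fallback (stepping all unfinished runs in lockstep) is
used when numba is unavailable.  At ``eta = 0`` both paths are
deterministic and produce identical results; at ``eta > 0`` they draw from
different RNG streams and agree only statistically.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a declared dependency
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        if args and callable(args[0]):
            return args[0]
        return wrap

__all__ = ["eval_population_runs", "HAVE_NUMBA"]


@njit(cache=True)
def _eval_kernel(tables, nbrs, inits, targets, eta, T, seeds):  # pragma: no cover
    G = tables.shape[0]
    R, N, D = nbrs.shape
    succ = np.zeros((G, R), dtype=np.bool_)
    steps = np.full((G, R), T, dtype=np.int32)
    cur = np.empty(N, dtype=np.uint8)
    nxt = np.empty(N, dtype=np.uint8)
    # per-step perception-flip mask over the N*D (agent, slot) channels;
    # flips are iid Bernoulli(eta), drawn by geometric skip-sampling so the
    # cost scales with the number of flips, not the number of channels
    nd = N * D
    flip = np.zeros(nd, dtype=np.uint8)
    nflip_buf = np.empty(nd, dtype=np.int64)
    skip_noise = 0.0 < eta < 1.0
    log_keep = np.log(1.0 - eta) if skip_noise else 0.0
    for g in range(G):
        table = tables[g]
        for r in range(R):
            target = targets[r]
            # consensus requires the all-target state to be a noiseless
            # fixed point; a rule violating that can never succeed here
            unanimous = (1 << (D + 1)) - 1 if target == 1 else 0
            if table[unanimous] != target:
                continue
            np.random.seed(seeds[g, r])
            net = nbrs[r]
            for i in range(N):
                cur[i] = inits[r, i]
            for t in range(1, T + 1):
                # draw this step's perception flips
                nf = 0
                if skip_noise:
                    p = -1
                    while True:
                        u = np.random.random()
                        if u < 1e-300:
                            u = 1e-300
                        p += 1 + np.int64(np.log(u) / log_keep)
                        if p >= nd:
                            break
                        flip[p] = 1
                        nflip_buf[nf] = p
                        nf += 1
                elif eta >= 1.0:
                    for ii in range(nd):
                        flip[ii] = 1
                # noisy synchronous step from cur into nxt
                for i in range(N):
                    idx = np.int64(cur[i])
                    base = i * D
                    for j in range(D):
                        s = np.int64(cur[net[i, j]]) ^ np.int64(flip[base + j])
                        idx = (idx << 1) | s
                    nxt[i] = table[idx]
                for ii in range(nf):
                    flip[nflip_buf[ii]] = 0
                # consensus criterion: one noiseless step from nxt
                ok = True
                for i in range(N):
                    idx = np.int64(nxt[i])
                    for j in range(D):
                        idx = (idx << 1) | np.int64(nxt[net[i, j]])
                    if table[idx] != target:
                        ok = False
                        break
                if ok:
                    succ[g, r] = True
                    steps[g, r] = t
                    break
                tmp = cur
                cur = nxt
                nxt = tmp
    return succ, steps


def _eval_numpy(tables, nbrs, inits, targets, eta, T, seeds):
    G = tables.shape[0]
    R, N, D = nbrs.shape
    rng = np.random.default_rng(seeds.ravel())
    total = G * R
    run_g = np.repeat(np.arange(G), R)
    run_r = np.tile(np.arange(R), G)
    S = inits[run_r].astype(np.uint8)
    succ = np.zeros(total, dtype=bool)
    steps = np.full(total, T, dtype=np.int32)
    # runs whose all-target state is not a noiseless fixed point of the
    # genome can never meet the consensus criterion: skip them outright
    tgt = targets[run_r].astype(np.int64)
    unanimous = np.where(tgt == 1, tables.shape[1] - 1, 0)
    viable = tables[run_g, unanimous] == tgt
    active = np.arange(total)[viable]
    weights = (1 << np.arange(D - 1, -1, -1)).astype(np.int64)
    for t in range(1, T + 1):
        if active.size == 0:
            break
        sub_r = run_r[active]
        net = nbrs[sub_r]  # (A, N, D)
        own = S[active]
        arange_a = np.arange(active.size)[:, None, None]
        perc = own[arange_a, net].astype(np.int64)
        if eta > 0.0:
            perc ^= (rng.random(perc.shape) < eta).astype(np.int64)
        idx = (own.astype(np.int64) << D) + perc @ weights
        new = tables[run_g[active][:, None], idx]
        perc0 = new[arange_a, net].astype(np.int64)
        idx0 = (new.astype(np.int64) << D) + perc0 @ weights
        noiseless = tables[run_g[active][:, None], idx0]
        done = np.all(noiseless == targets[sub_r][:, None], axis=1)
        S[active] = new
        if done.any():
            finished = active[done]
            succ[finished] = True
            steps[finished] = t
            active = active[~done]
    return succ.reshape(G, R), steps.reshape(G, R)


def eval_population_runs(
    tables: np.ndarray,
    nbrs: np.ndarray,
    inits: np.ndarray,
    targets: np.ndarray,
    eta: float,
    T: int,
    seeds: np.ndarray,
    engine: str = "auto",
) -> tuple[np.ndarray, np.ndarray]:
    """Run every (genome, realization) pair of the batch to completion.

    Parameters
    ----------
    tables : (G, 2**k) uint8
        Lookup tables, one row per genome (shared k).
    nbrs : (R, N, degree) int32
        Slot-ordered neighbor ids, one network per realization.
    inits, targets : (R, N) uint8 and (R,) uint8
        Initial states and their strict-majority bits.
    eta, T : float, int
        Communication-noise probability and step budget per realization.
    seeds : (G, R) integer array
        Per-run noise seeds (< 2**31).
    engine : {"auto", "numba", "numpy"}

    Returns
    -------
    (success, steps) : (G, R) bool and (G, R) int32
        Whether each run met the consensus criterion, and the first-passage
        step (or T on failure).
    """
    tables = np.ascontiguousarray(tables, dtype=np.uint8)
    nbrs = np.ascontiguousarray(nbrs, dtype=np.int32)
    inits = np.ascontiguousarray(inits, dtype=np.uint8)
    targets = np.ascontiguousarray(targets, dtype=np.uint8)
    seeds = np.ascontiguousarray(seeds, dtype=np.int64)
    G = tables.shape[0]
    R, N, D = nbrs.shape
    if tables.shape[1] != 1 << (D + 1):
        raise ValueError(
            f"table width {tables.shape[1]} does not match degree {D} (need 2**{D + 1})"
        )
    if inits.shape != (R, N) or targets.shape != (R,) or seeds.shape != (G, R):
        raise ValueError("shape mismatch between networks, initial states and seeds")
    if not 0.0 <= eta <= 1.0:
        raise ValueError(f"eta must be in [0, 1], got {eta}")
    if T < 1:
        raise ValueError("T must be >= 1")
    if engine == "auto":
        engine = "numba" if HAVE_NUMBA else "numpy"
    if engine == "numba":
        if not HAVE_NUMBA:
            raise RuntimeError("numba engine requested but numba is not importable")
        return _eval_kernel(tables, nbrs, inits, targets, float(eta), int(T), seeds)
    if engine == "numpy":
        return _eval_numpy(tables, nbrs, inits, targets, float(eta), int(T), seeds)
    raise ValueError(f"unknown engine {engine!r}")
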