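"""Numba kernels for the weighted-random-move Louvain sweep.

The phase-1 sweep moves single nodes between communities, sampling among the
strictly improving moves with probability proportional to the modularity
increase.  Two kernels cover the two interaction structures that occur:

* ``sweep_dense`` — a precomputed symmetric interaction matrix
  ``B = A - gamma * P`` with zeroed diagonal (used for consensus matrices and
  for aggregated levels);
* ``sweep_sparse_config`` — a sparse adjacency with the rank-one
  configuration null ``P_ij = k_i k_j / 2m``, never materialized.

Both kernels seed numba's Mersenne-Twister state explicitly, so a run is a
pure function of (matrix, initial labels, seed).
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["sweep_dense", "sweep_sparse_config"]


@njit(cache=True)
def _shuffled_order(n):
    order = np.arange(n)
    for t in range(n - 1, 0, -1):
        u = np.random.randint(0, t + 1)
        tmp = order[t]
        order[t] = order[u]
        order[u] = tmp
    return order


@njit(cache=True)
def _pick_proportional(gains, m):
    total = 0.0
    for t in range(m):
        total += gains[t]
    r = np.random.random() * total
    acc = 0.0
    for t in range(m):
        acc += gains[t]
        if r < acc:
            return t
    return m - 1


@njit(cache=True)
def sweep_dense(B, labels, seed, tol, max_sweeps):
    """In-place phase-1 sweeps on a dense interaction matrix.

    ``labels`` holds 0-based community ids in ``0..n-1``; returns the total
    number of accepted moves.  ``B`` must be symmetric with zero diagonal.
    Nonempty communities are tracked in an active list so that the candidate
    scan costs O(#communities) rather than O(n) per node.
    """
    np.random.seed(seed)
    n = B.shape[0]
    comm_size = np.zeros(n, np.int64)
    for i in range(n):
        comm_size[labels[i]] += 1
    active = np.empty(n, np.int64)
    pos = np.full(n, -1, np.int64)  # index into active, -1 if empty community
    n_active = 0
    for c in range(n):
        if comm_size[c] > 0:
            active[n_active] = c
            pos[c] = n_active
            n_active += 1
    free = np.empty(n, np.int64)
    n_free = 0
    for c in range(n - 1, -1, -1):
        if comm_size[c] == 0:
            free[n_free] = c
            n_free += 1
    S = np.zeros(n)
    gains = np.empty(n + 1)
    targets = np.empty(n + 1, np.int64)
    total_moves = 0
    for _ in range(max_sweeps):
        moved = 0
        order = _shuffled_order(n)
        for idx in range(n):
            i = order[idx]
            a = labels[i]
            for j in range(n):
                S[labels[j]] += B[i, j]
            s_a = S[a]  # diagonal is zero, so own community excludes i
            m = 0
            for t in range(n_active):
                c = active[t]
                if c != a:
                    g = 2.0 * (S[c] - s_a)
                    if g > tol:
                        gains[m] = g
                        targets[m] = c
                        m += 1
            if comm_size[a] > 1:
                g = 2.0 * (0.0 - s_a)  # move to a fresh empty community
                if g > tol:
                    gains[m] = g
                    targets[m] = -1
                    m += 1
            # reset scratch before mutating the active list
            for t in range(n_active):
                S[active[t]] = 0.0
            if m > 0:
                choice = _pick_proportional(gains, m)
                c = targets[choice]
                if c == -1:
                    n_free -= 1
                    c = free[n_free]
                    active[n_active] = c
                    pos[c] = n_active
                    n_active += 1
                comm_size[a] -= 1
                comm_size[c] += 1
                labels[i] = c
                moved += 1
                if comm_size[a] == 0:
                    # swap-remove a from the active list, recycle its id
                    last = active[n_active - 1]
                    active[pos[a]] = last
                    pos[last] = pos[a]
                    pos[a] = -1
                    n_active -= 1
                    free[n_free] = a
                    n_free += 1
        total_moves += moved
        if moved == 0:
            break
    return total_moves


@njit(cache=True)
def sweep_sparse_config(
    indptr, indices, data, degrees, twom, gamma, labels, seed, tol, max_sweeps
):
    """In-place phase-1 sweeps for sparse adjacency + configuration null.

    Candidate targets are the communities adjacent to the moving node plus a
    fresh empty community; gains use the closed form
    ``dQ = 2[(A_ic - A_ia') - gamma*k_i*(K_c - K_a')/2m]``.
    """
    np.random.seed(seed)
    n = labels.shape[0]
    comm_size = np.zeros(n, np.int64)
    comm_deg = np.zeros(n)
    for i in range(n):
        comm_size[labels[i]] += 1
        comm_deg[labels[i]] += degrees[i]
    link = np.zeros(n)  # A_ic accumulator, reset via touched list
    touched = np.empty(n, np.int64)
    is_touched = np.zeros(n, np.uint8)
    gains = np.empty(n + 2)
    targets = np.empty(n + 2, np.int64)
    total_moves = 0
    for _ in range(max_sweeps):
        moved = 0
        order = _shuffled_order(n)
        for idx in range(n):
            i = order[idx]
            a = labels[i]
            n_touched = 0
            for p in range(indptr[i], indptr[i + 1]):
                j = indices[p]
                if j == i:
                    continue  # self-loops contribute a constant
                c = labels[j]
                if is_touched[c] == 0:
                    is_touched[c] = 1
                    touched[n_touched] = c
                    n_touched += 1
                link[c] += data[p]
            k_i = degrees[i]
            rem = link[a] - gamma * k_i * (comm_deg[a] - k_i) / twom
            m = 0
            for t in range(n_touched):
                c = touched[t]
                if c == a:
                    continue
                g = 2.0 * (link[c] - gamma * k_i * comm_deg[c] / twom - rem)
                if g > tol:
                    gains[m] = g
                    targets[m] = c
                    m += 1
            if comm_size[a] > 1:
                g = 2.0 * (0.0 - rem)
                if g > tol:
                    gains[m] = g
                    targets[m] = -1
                    m += 1
            if m > 0:
                choice = _pick_proportional(gains, m)
                c = targets[choice]
                if c == -1:
                    c = 0
                    while comm_size[c] > 0:
                        c += 1
                comm_size[a] -= 1
                comm_deg[a] -= k_i
                comm_size[c] += 1
                comm_deg[c] += k_i
                labels[i] = c
                moved += 1
            for t in range(n_touched):
                link[touched[t]] = 0.0
                is_touched[touched[t]] = 0
        total_moves += moved
        if moved == 0:
            break
    return total_moves
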