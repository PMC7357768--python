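"""Numba kernels for simulated-annealing module detection.

Node indexing convention: bees first (0..n_bees-1), then plants.  The
network is held in CSR form (indptr/indices over all nodes, neighbors as
global node indices).  Modularity is Barber's bipartite form,

    Q = (1/N) * sum_{i in bees, j in plants} (A_ij - k_i d_j / N) [g_i == g_j]

which the kernels track incrementally through per-module degree sums
Db[s] (bee degrees in module s) and Dp[s] (plant degrees in module s).
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _degree_sums(labels, k, n_bees, n_nodes, L):
    Db = np.zeros(L)
    Dp = np.zeros(L)
    for i in range(n_bees):
        Db[labels[i]] += k[i]
    for j in range(n_bees, n_nodes):
        Dp[labels[j]] += k[j]
    return Db, Dp


@njit(cache=True)
def full_q(indptr, indices, labels, k, n_bees, n_nodes, N, L):
    """Barber modularity of a label assignment, computed from scratch."""
    Db, Dp = _degree_sums(labels, k, n_bees, n_nodes, L)
    E = np.zeros(L)
    for i in range(n_bees):
        li = labels[i]
        for t in range(indptr[i], indptr[i + 1]):
            if labels[indices[t]] == li:
                E[li] += 1.0
    q = 0.0
    for s in range(L):
        q += E[s] - Db[s] * Dp[s] / N
    return q / N


@njit(cache=True)
def _move_dq(indptr, indices, labels, k, Db, Dp, n_bees, N, node, new):
    """Q change from reassigning ``node`` to module ``new``."""
    old = labels[node]
    e_old = 0.0
    e_new = 0.0
    for t in range(indptr[node], indptr[node + 1]):
        lab = labels[indices[t]]
        if lab == old:
            e_old += 1.0
        elif lab == new:
            e_new += 1.0
    if node < n_bees:
        # bee moves against the plant-side degree sums
        return (e_new - e_old - k[node] * (Dp[new] - Dp[old]) / N) / N
    return (e_new - e_old - k[node] * (Db[new] - Db[old]) / N) / N


@njit(cache=True)
def _apply_move(labels, k, Db, Dp, n_bees, node, new):
    old = labels[node]
    labels[node] = new
    if node < n_bees:
        Db[old] -= k[node]
        Db[new] += k[node]
    else:
        Dp[old] -= k[node]
        Dp[new] += k[node]


@njit(cache=True)
def _module_contrib(indptr, indices, labels, Db, Dp, n_bees, N, s):
    """Contribution (E_s - Db_s * Dp_s / N) / N of one module to Q."""
    e = 0.0
    for i in range(n_bees):
        if labels[i] == s:
            for t in range(indptr[i], indptr[i + 1]):
                if labels[indices[t]] == s:
                    e += 1.0
    return (e - Db[s] * Dp[s] / N) / N


@njit(cache=True)
def _try_merge(indptr, indices, labels, k, Db, Dp, n_bees, n_nodes, N, L, q, T):
    a = np.random.randint(0, L)
    b = np.random.randint(0, L)
    if a == b or Db[a] + Dp[a] == 0.0 or Db[b] + Dp[b] == 0.0:
        return q
    e_cross = 0.0
    for i in range(n_bees):
        li = labels[i]
        if li == a or li == b:
            other = b if li == a else a
            for t in range(indptr[i], indptr[i + 1]):
                if labels[indices[t]] == other:
                    e_cross += 1.0
    dq = (e_cross - (Db[a] * Dp[b] + Db[b] * Dp[a]) / N) / N
    if dq >= 0.0 or np.random.random() < np.exp(dq / T):
        for v in range(n_nodes):
            if labels[v] == a:
                labels[v] = b
        Db[b] += Db[a]
        Dp[b] += Dp[a]
        Db[a] = 0.0
        Dp[a] = 0.0
        return q + dq
    return q


@njit(cache=True)
def _try_split(indptr, indices, labels, k, Db, Dp, n_bees, n_nodes, N, L, q, T):
    a = np.random.randint(0, L)
    if Db[a] + Dp[a] == 0.0:
        return q
    b = -1
    for s in range(L):
        if s != a and Db[s] == 0.0 and Dp[s] == 0.0:
            b = s
            break
    if b < 0:
        return q
    old_contrib = _module_contrib(indptr, indices, labels, Db, Dp, n_bees, N, a)
    moved = np.empty(n_nodes, np.int64)
    n_moved = 0
    for v in range(n_nodes):
        if labels[v] == a and np.random.random() < 0.5:
            _apply_move(labels, k, Db, Dp, n_bees, v, b)
            moved[n_moved] = v
            n_moved += 1
    new_contrib = _module_contrib(
        indptr, indices, labels, Db, Dp, n_bees, N, a
    ) + _module_contrib(indptr, indices, labels, Db, Dp, n_bees, N, b)
    dq = new_contrib - old_contrib
    if dq >= 0.0 or np.random.random() < np.exp(dq / T):
        return q + dq
    for t in range(n_moved):  # reject: restore
        _apply_move(labels, k, Db, Dp, n_bees, moved[t], a)
    return q


@njit(cache=True)
def sample_move_dq(indptr, indices, k, n_bees, n_nodes, N, L, seed, n_samples):
    """Q changes of random single-node moves from a random partition.

    Used to calibrate the initial temperature so that roughly half of the
    worsening moves are accepted at the start of the anneal.
    """
    np.random.seed(seed)
    labels = np.empty(n_nodes, np.int64)
    for v in range(n_nodes):
        labels[v] = np.random.randint(0, L)
    Db, Dp = _degree_sums(labels, k, n_bees, n_nodes, L)
    out = np.empty(n_samples)
    for i in range(n_samples):
        node = np.random.randint(0, n_nodes)
        new = np.random.randint(0, L)
        if new == labels[node]:
            out[i] = 0.0
        else:
            out[i] = _move_dq(indptr, indices, labels, k, Db, Dp, n_bees, N,
                              node, new)
    return out


@njit(cache=True)
def anneal(
    indptr, indices, k, n_bees, n_nodes, N, L,
    t0, cooling, t_min, steps_per_t, merge_split_prob, seed,
):
    """One annealing run from a random start; returns (labels, Q).

    Moves are single-node reassignments, plus occasional whole-module
    merges and random splits; acceptance follows the Metropolis criterion
    exp(dQ / T) at the current temperature.
    """
    np.random.seed(seed)
    labels = np.empty(n_nodes, np.int64)
    for v in range(n_nodes):
        labels[v] = np.random.randint(0, L)
    Db, Dp = _degree_sums(labels, k, n_bees, n_nodes, L)
    q = full_q(indptr, indices, labels, k, n_bees, n_nodes, N, L)
    T = t0
    while T > t_min:
        for _ in range(steps_per_t):
            if np.random.random() < merge_split_prob:
                if np.random.random() < 0.5:
                    q = _try_merge(indptr, indices, labels, k, Db, Dp,
                                   n_bees, n_nodes, N, L, q, T)
                else:
                    q = _try_split(indptr, indices, labels, k, Db, Dp,
                                   n_bees, n_nodes, N, L, q, T)
            else:
                node = np.random.randint(0, n_nodes)
                new = np.random.randint(0, L)
                if new == labels[node]:
                    continue
                dq = _move_dq(indptr, indices, labels, k, Db, Dp, n_bees, N,
                              node, new)
                if dq >= 0.0 or np.random.random() < np.exp(dq / T):
                    _apply_move(labels, k, Db, Dp, n_bees, node, new)
                    q += dq
        T *= cooling
    return labels, q


@njit(cache=True)
def greedy_refine(indptr, indices, labels, k, n_bees, n_nodes, N, L,
                  max_sweeps):
    """Accept only improving single-node moves until a fixed point.

    Deterministic (sweeps nodes and candidate modules in index order) and
    monotone: the returned partition never scores below the input one.
    """
    Db, Dp = _degree_sums(labels, k, n_bees, n_nodes, L)
    q = full_q(indptr, indices, labels, k, n_bees, n_nodes, N, L)
    for _ in range(max_sweeps):
        improved = False
        for node in range(n_nodes):
            best_dq = 1e-12
            best = -1
            for s in range(L):
                if s == labels[node]:
                    continue
                dq = _move_dq(indptr, indices, labels, k, Db, Dp, n_bees, N,
                              node, s)
                if dq > best_dq:
                    best_dq = dq
                    best = s
            if best >= 0:
                _apply_move(labels, k, Db, Dp, n_bees, node, best)
                q += best_dq
                improved = True
        if not improved:
            break
    return labels, q
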