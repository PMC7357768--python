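"""Degree-preserving null models and standardized effect sizes.

The null family is the independent ("checkerboard") swap: 2x2 submatrices
of the form [[1,0],[0,1]] or [[0,1],[1,0]] are flipped repeatedly, which
shuffles links while keeping the number of links of every bee and every
plant exactly constant.  Observed modularity is compared against an
ensemble of such shuffles through the standardized effect size

    SES = (M_obs - mean(M_null)) / sd(M_null),

with SES > 1.96 flagging a significantly modular structure at roughly the
5% level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numba import njit

from .metrics import RankTestResult, rank_sum_test
from .modularity import AnnealSchedule, ModulePartition, detect_modules
from .network import BipartiteNetwork

log = logging.getLogger(__name__)

#: attempted swaps per replicate, as a multiple of the edge count
DEFAULT_SWAP_FACTOR = 1000


@njit(cache=True)
def _swap_kernel(a, max_attempts, target_swaps, seed):
    """Attempt checkerboard flips in place; returns the number performed.

    Stops after ``max_attempts`` attempted draws, or earlier once
    ``target_swaps`` flips succeeded (pass -1 to disable the target).
    """
    np.random.seed(seed)
    n_b, n_p = a.shape
    done = 0
    for _ in range(max_attempts):
        i = np.random.randint(0, n_b)
        j = np.random.randint(0, n_b)
        if i == j:
            continue
        u = np.random.randint(0, n_p)
        v = np.random.randint(0, n_p)
        if u == v:
            continue
        if a[i, u] == 1 and a[j, v] == 1 and a[i, v] == 0 and a[j, u] == 0:
            a[i, u] = 0
            a[j, v] = 0
            a[i, v] = 1
            a[j, u] = 1
            done += 1
        elif a[i, v] == 1 and a[j, u] == 1 and a[i, u] == 0 and a[j, v] == 0:
            a[i, v] = 0
            a[j, u] = 0
            a[i, u] = 1
            a[j, v] = 1
            done += 1
        if target_swaps >= 0 and done >= target_swaps:
            break
    return done


def _has_checkerboard(a: np.ndarray) -> bool:
    """Exhaustive check for any swappable 2x2 submatrix."""
    n_b, n_p = a.shape
    for i in range(n_b):
        for j in range(i + 1, n_b):
            diff = a[i] != a[j]
            # a checkerboard needs columns u, v with opposite orientation
            if (diff & (a[i] == 1)).any() and (diff & (a[j] == 1)).any():
                return True
    return False


def independent_swap(
    net: BipartiteNetwork,
    n_swaps: int | None = None,
    seed: int = 0,
    swap_factor: int = DEFAULT_SWAP_FACTOR,
) -> BipartiteNetwork:
    """Degree-preserving shuffle of a binary network.

    With ``n_swaps=None`` (default) the burn-in budget is ``swap_factor``
    times the edge count in attempted swaps; otherwise swapping stops after
    ``n_swaps`` successful flips (the attempt cap still applies).  Matrices
    without any checkerboard unit (e.g. perfectly nested triangles) cannot
    be shuffled and are returned unchanged with a logged warning.
    """
    a = net.adjacency.copy()
    max_attempts = swap_factor * net.n_interactions
    target = -1 if n_swaps is None else int(n_swaps)
    done = _swap_kernel(a, max_attempts, target, int(seed) % 2**31)
    if done == 0 and not _has_checkerboard(a):
        log.warning(
            "no checkerboard submatrix exists; returning the network unchanged"
        )
        return BipartiteNetwork(net.bees, net.plants, net.adjacency.copy(),
                                net.period_label)
    return BipartiteNetwork(net.bees, net.plants, a, net.period_label)


@dataclass
class NullEnsemble:
    """Degree-preserving shuffles of one network with detected modules."""

    source: BipartiteNetwork
    replicates: list[np.ndarray]
    m_null: np.ndarray
    partitions: list[ModulePartition]
    n_reps: int
    seed: int
    swap_factor: int

    def replicate_network(self, r: int) -> BipartiteNetwork:
        return BipartiteNetwork(
            self.source.bees, self.source.plants, self.replicates[r],
            self.source.period_label,
        )


def build_null_ensemble(
    net: BipartiteNetwork,
    n_reps: int = 1000,
    seed: int = 0,
    schedule: AnnealSchedule | None = None,
    swap_factor: int = DEFAULT_SWAP_FACTOR,
    detect: bool = True,
) -> NullEnsemble:
    """Shuffle ``n_reps`` times and (optionally) detect modules per replicate.

    Each replicate burns in from the observed matrix with its own seed
    derived from ``seed``.  Module detection on replicates uses the given
    annealing schedule (the observed network's schedule by default, for
    fidelity; pass :meth:`AnnealSchedule.light` to trade accuracy for
    speed on big ensembles).
    """
    rng = np.random.default_rng(seed)
    sub = rng.integers(0, 2**31 - 1, size=(n_reps, 2))
    reps: list[np.ndarray] = []
    parts: list[ModulePartition] = []
    m_null = np.empty(n_reps)
    for r in range(n_reps):
        shuffled = independent_swap(net, seed=int(sub[r, 0]),
                                    swap_factor=swap_factor)
        reps.append(shuffled.adjacency)
        if detect:
            part = detect_modules(shuffled, schedule=schedule,
                                  seed=int(sub[r, 1]))
            parts.append(part)
            m_null[r] = part.Q
        else:
            m_null[r] = np.nan
    return NullEnsemble(
        source=net, replicates=reps, m_null=m_null, partitions=parts,
        n_reps=n_reps, seed=seed, swap_factor=swap_factor,
    )


@dataclass
class SESResult:
    SES: float
    M_obs: float
    M_null_mean: float
    M_null_sd: float
    significant: bool  # SES > 1.96, ~5% one-sided risk under normality

    #: empirical complement: fraction of null values >= observed
    empirical_p: float = float("nan")


def ses(m_obs: float, null_values: np.ndarray) -> SESResult:
    """Standardized effect size of an observed modularity against nulls."""
    nulls = np.asarray(null_values, dtype=float)
    if nulls.size < 2:
        raise ValueError("need at least 2 null values")
    if np.all(nulls == nulls[0]):
        raise ValueError("null values are constant; SES undefined")
    sd = float(nulls.std(ddof=1))
    mean = float(nulls.mean())
    val = (m_obs - mean) / sd
    emp = float((nulls >= m_obs).mean())
    return SESResult(SES=val, M_obs=float(m_obs), M_null_mean=mean,
                     M_null_sd=sd, significant=val > 1.96, empirical_p=emp)


def compare_modularity_periods(
    m_obs_a: float,
    null_a: np.ndarray,
    m_obs_b: float,
    null_b: np.ndarray,
) -> RankTestResult:
    """Rank-sum test on per-replicate (observed - null) modularity gaps.

    Controls for network size differences: each period contributes the
    distribution of its observed-minus-null differences, and the two
    difference samples are compared two-sided.
    """
    diff_a = m_obs_a - np.asarray(null_a, dtype=float)
    diff_b = m_obs_b - np.asarray(null_b, dtype=float)
    return rank_sum_test(diff_a, diff_b)


def resample_to_interaction_count(
    net: BipartiteNetwork,
    n_interactions: int,
    n_reps: int = 1000,
    seed: int = 0,
    schedule: AnnealSchedule | None = None,
) -> np.ndarray:
    """Modularity of the network subsampled to a fixed link count.

    Consistency check for comparisons between networks of unequal sampling
    depth: each replicate keeps a uniform random subset of
    ``n_interactions`` links, drops species left isolated, and re-detects
    modules.  Returns the replicate Q sample.
    """
    edges = sorted(net.edge_set())
    if not 1 <= n_interactions <= len(edges):
        raise ValueError(
            f"n_interactions must be in [1, {len(edges)}], got {n_interactions}"
        )
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=n_reps)
    out = np.empty(n_reps)
    for r in range(n_reps):
        local = np.random.default_rng(int(sub_seeds[r]))
        idx = local.choice(len(edges), size=n_interactions, replace=False)
        subnet = BipartiteNetwork.from_edges([edges[i] for i in idx],
                                             net.period_label)
        out[r] = detect_modules(subnet, schedule=schedule,
                                seed=int(sub_seeds[r])).Q
    return out
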