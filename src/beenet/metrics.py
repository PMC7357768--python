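"""Classical specialization indices: species degree and connectance.

Connectance C = N / (p * b) is the realized fraction of all possible
bee-plant links, with N the number of observed links, p the plant and b the
bee species richness.  Because C depends strongly on network size, the
between-period comparison is made on matrices rarefied to a common total
richness, with a rank-sum test on the two rarefied distributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .network import BipartiteNetwork


@dataclass
class ConnectanceResult:
    C: float
    N: int
    p: int
    b: int

    def rounded(self, ndigits: int = 3) -> float:
        return round(self.C, ndigits)


@dataclass
class RankTestResult:
    statistic: float
    pvalue: float
    degenerate: bool = False  # both samples constant and identical


def species_degree(net: BipartiteNetwork) -> pd.DataFrame:
    """Per-species partner counts (row/column sums of the binary matrix).

    Returns a tidy table with columns ``species``, ``guild`` and ``degree``.
    """
    return pd.DataFrame(
        {
            "species": net.bees + net.plants,
            "guild": ["bee"] * net.n_bees + ["plant"] * net.n_plants,
            "degree": np.concatenate([net.bee_degrees(), net.plant_degrees()]),
        }
    )


def connectance(net: BipartiteNetwork) -> ConnectanceResult:
    """C = N / (p * b) on a binary network."""
    return connectance_from_counts(
        N=net.n_interactions, p=net.n_plants, b=net.n_bees
    )


def connectance_from_counts(N: int, p: int, b: int) -> ConnectanceResult:
    """C = N / (p * b) from printed or tabulated network dimensions."""
    if p <= 0 or b <= 0:
        raise ValueError("species counts must be positive")
    if not 0 < N <= p * b:
        raise ValueError(f"interaction count {N} outside (0, {p * b}]")
    return ConnectanceResult(C=N / (p * b), N=N, p=p, b=b)


def rarefy_connectance(
    net: BipartiteNetwork,
    total_richness: int,
    n_reps: int = 1000,
    seed: int | None = None,
    guild_split: str = "proportional",
) -> np.ndarray:
    """Connectance distribution of matrices rarefied to a fixed richness.

    Each replicate draws a random species subset with bee + plant count
    equal to ``total_richness``, restricts the adjacency to it, drops
    species left without partners, and computes C on what remains.

    The guild split of the drawn subset is proportional to the observed
    guild sizes (``guild_split="proportional"``, the default, keeps the
    rarefied matrix shape comparable to the source network); each guild
    always keeps at least one species.
    """
    total = net.n_nodes
    if total_richness > total:
        raise ValueError(f"total_richness {total_richness} exceeds {total} species")
    if total_richness < 2:
        raise ValueError("total_richness must be at least 2 (one per guild)")
    if guild_split != "proportional":
        raise ValueError(f"unknown guild_split {guild_split!r}")
    n_b = int(round(total_richness * net.n_bees / total))
    n_b = min(max(n_b, 1), total_richness - 1, net.n_bees)
    n_p = total_richness - n_b
    if n_p > net.n_plants:
        n_p = net.n_plants
        n_b = total_richness - n_p
    rng = np.random.default_rng(seed)
    # draw over name-sorted positions so the sample depends only on the
    # species present and the seed, not on matrix row/column order
    order_b = np.argsort(np.asarray(net.bees))
    order_p = np.argsort(np.asarray(net.plants))
    out = np.empty(n_reps)
    for r in range(n_reps):
        bi = order_b[rng.choice(net.n_bees, size=n_b, replace=False)]
        pi = order_p[rng.choice(net.n_plants, size=n_p, replace=False)]
        sub = net.adjacency[np.ix_(bi, pi)]
        keep_b = sub.sum(axis=1) > 0
        keep_p = sub.sum(axis=0) > 0
        sub = sub[np.ix_(keep_b, keep_p)]
        if sub.size == 0:
            out[r] = np.nan
            continue
        out[r] = sub.sum() / (sub.shape[0] * sub.shape[1])
    return out


def rank_sum_test(
    sample_a: np.ndarray,
    sample_b: np.ndarray,
    alternative: str = "two-sided",
) -> RankTestResult:
    """Rank-sum (Wilcoxon-Mann-Whitney) test on two independent samples.

    Ties are handled by midranks with the usual normal approximation (exact
    distribution for small tie-free samples, per scipy's auto policy).  Two
    identical constant samples are degenerate (the rank test is undefined);
    p = 1 is returned with a flag.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("empty sample in rank test")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return RankTestResult(statistic=a.size * b.size / 2, pvalue=1.0,
                              degenerate=True)
    stat, p = stats.mannwhitneyu(a, b, alternative=alternative)
    return RankTestResult(statistic=float(stat), pvalue=float(p))


def compare_connectance(
    sample_a: np.ndarray, sample_b: np.ndarray
) -> RankTestResult:
    """Two-sided rank-sum test between two rarefied connectance samples.

    Rarefaction replicates of the two periods are independent draws, so the
    unpaired form applies.
    """
    return rank_sum_test(sample_a, sample_b, alternative="two-sided")
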