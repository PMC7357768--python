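"""Species roles in the modular network: c and z coefficients.

For a bee species i with total degree k_i and k_is links to plants of
module s, the participation coefficient

    c_i = 1 - sum_s (k_is / k_i)^2

measures how evenly its links spread across modules (0 when all links stay
in one module).  The within-module degree

    z_i = (kappa_i - mean_s(kappa)) / sd_s(kappa)

standardizes its link count into its own module, kappa_i, against the
same-guild members of that module; z is missing when the module's
within-module-degree variance is zero.

Species are classified against thresholds taken as empirical quantiles of
the pooled c and z values computed on degree-preserving null networks
(modules re-detected per replicate): peripherals (low c, low z), module
hubs (high z), connectors (high c) and network hubs (both high).
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd
from scipy import stats

from .modularity import ModulePartition
from .network import BipartiteNetwork
from .nullmodels import NullEnsemble

#: classical fixed role cutoffs from the original cartographic framework;
#: offered as a documented option only — the default thresholds are null
#: quantiles.
CLASSIC_C_STAR = 0.62
CLASSIC_Z_STAR = 2.5


def _labels(net: BipartiteNetwork, partition) -> np.ndarray:
    assignment = partition.assignment if isinstance(partition, ModulePartition) \
        else partition
    out = np.empty(net.n_nodes, dtype=np.int64)
    for idx, name in enumerate(net.node_names()):
        if name not in assignment:
            raise KeyError(f"partition missing node {name!r}")
        out[idx] = assignment[name]
    return out


def _module_link_counts(net: BipartiteNetwork, labels: np.ndarray, guild: str):
    """Per-species links into each module (rows: species of ``guild``)."""
    n_modules = int(labels.max()) + 1
    if guild == "bee":
        a = net.adjacency.astype(np.int64)
        partner_labels = labels[net.n_bees:]
        own_labels = labels[: net.n_bees]
    else:
        a = net.adjacency.T.astype(np.int64)
        partner_labels = labels[: net.n_bees]
        own_labels = labels[net.n_bees:]
    onehot = np.eye(n_modules, dtype=np.int64)[partner_labels]
    return a @ onehot, own_labels


def participation_coefficient(
    net: BipartiteNetwork, partition, species: str
) -> float:
    """c = 1 - sum_s (k_is / k_i)^2 for one species (either guild)."""
    guild = "bee" if species in net.bees else "plant"
    names = net.bees if guild == "bee" else net.plants
    if species not in names:
        raise KeyError(f"species {species!r} not in network")
    counts, _ = _module_link_counts(net, _labels(net, partition), guild)
    row = counts[names.index(species)]
    k = row.sum()
    return float(1.0 - ((row / k) ** 2).sum())


def within_module_degree(
    net: BipartiteNetwork, partition, species: str, ddof: int = 1
) -> float:
    """z of one species, or NaN when its module's variance is zero."""
    guild = "bee" if species in net.bees else "plant"
    names = net.bees if guild == "bee" else net.plants
    if species not in names:
        raise KeyError(f"species {species!r} not in network")
    table = cz_table(net, partition, guild=guild, ddof=ddof)
    return float(table.set_index("species").loc[species, "z"])


def cz_table(
    net: BipartiteNetwork,
    partition,
    guild: str = "bee",
    ddof: int = 1,
    period_label: str | None = None,
) -> pd.DataFrame:
    """Tidy per-species role-metric table for one guild.

    Columns: species, period, module, degree, c, z.  The z standardization
    pools over same-guild members of each module; ``ddof=1`` (sample SD) is
    the default convention, ``ddof=0`` switches to the population form.
    z is NaN for species in modules with zero within-module-degree variance
    (including single-member modules).
    """
    labels = _labels(net, partition)
    counts, own = _module_link_counts(net, labels, guild)
    names = net.bees if guild == "bee" else net.plants
    k = counts.sum(axis=1)
    c = 1.0 - ((counts / k[:, None]) ** 2).sum(axis=1)
    kappa = counts[np.arange(len(names)), own].astype(float)

    z = np.full(len(names), np.nan)
    for s in np.unique(own):
        members = own == s
        vals = kappa[members]
        if len(vals) < 2:
            continue
        sd = vals.std(ddof=ddof)
        if sd > 0:
            z[members] = (vals - vals.mean()) / sd
    return pd.DataFrame(
        {
            "species": names,
            "period": (period_label if period_label is not None
                       else net.period_label),
            "module": own,
            "degree": k,
            "c": c,
            "z": z,
        }
    )


@dataclass
class RoleThresholds:
    """Quantile cutoffs for 'high' c and z, with their provenance."""

    c_star: float
    z_star: float
    quantile: float
    provenance: str = ""
    n_pooled_c: int = 0
    n_pooled_z: int = 0


def role_thresholds(
    ensemble: NullEnsemble,
    quantile: float = 0.90,
    guild: str = "bee",
    ddof: int = 1,
) -> RoleThresholds:
    """Empirical null quantiles of c and z pooled over an ensemble.

    Modules are re-detected on every shuffled replicate (the shuffles
    destroy the observed structure, and the thresholds must reflect the c/z
    values such incidental structure produces); all species' c and defined
    z values are pooled across replicates and the requested quantile taken
    with linear interpolation between order statistics.
    """
    if not ensemble.partitions:
        raise ValueError("ensemble carries no detected partitions")
    pool_c: list[np.ndarray] = []
    pool_z: list[np.ndarray] = []
    for r, part in enumerate(ensemble.partitions):
        table = cz_table(ensemble.replicate_network(r), part, guild=guild,
                         ddof=ddof)
        pool_c.append(table["c"].to_numpy())
        pool_z.append(table["z"].dropna().to_numpy())
    c_all = np.concatenate(pool_c)
    z_all = np.concatenate(pool_z)
    if c_all.size == 0 or z_all.size == 0:
        raise ValueError("empty null c/z pool")
    return RoleThresholds(
        c_star=float(np.quantile(c_all, quantile)),
        z_star=float(np.quantile(z_all, quantile)),
        quantile=quantile,
        provenance=f"null ensemble seed={ensemble.seed} n={ensemble.n_reps}",
        n_pooled_c=int(c_all.size),
        n_pooled_z=int(z_all.size),
    )


def classic_thresholds() -> RoleThresholds:
    """The fixed cartographic cutoffs (c=0.62, z=2.5), for comparison only."""
    return RoleThresholds(c_star=CLASSIC_C_STAR, z_star=CLASSIC_Z_STAR,
                          quantile=float("nan"), provenance="classic fixed")


def classify_roles(
    table: pd.DataFrame, thresholds: RoleThresholds
) -> pd.DataFrame:
    """Attach a ``role`` column: peripheral / module hub / connector /
    network hub.

    'High' means strictly above the threshold.  Species with missing z
    cannot be assessed for hub status and are classified on c alone
    (connector if c is high, else peripheral).
    """
    out = table.copy()
    high_c = out["c"] > thresholds.c_star
    high_z = out["z"] > thresholds.z_star  # NaN compares False
    z_missing = out["z"].isna()
    role = np.where(
        high_c & high_z, "network hub",
        np.where(high_c, "connector",
                 np.where(high_z & ~z_missing, "module hub", "peripheral")),
    )
    out["role"] = role
    return out


@dataclass
class GroupComparison:
    statistic: float
    pvalue: float
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int
    test: str


def _one_comparison(a: np.ndarray, b: np.ndarray, pairing: str,
                    alternative: str) -> GroupComparison:
    if pairing == "paired":
        mask = ~np.isnan(a) & ~np.isnan(b)
        a, b = a[mask], b[mask]
        if a.size == 0:
            raise ValueError("no complete pairs to compare")
        if np.all(a == b):
            return GroupComparison(0.0, 1.0, float(a.mean()), float(b.mean()),
                                   a.size, b.size, "wilcoxon signed-rank")
        stat, p = stats.wilcoxon(b, a, alternative=alternative)
        return GroupComparison(float(stat), float(p), float(a.mean()),
                               float(b.mean()), a.size, b.size,
                               "wilcoxon signed-rank")
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("empty group in unpaired comparison")
    stat, p = stats.mannwhitneyu(b, a, alternative=alternative)
    return GroupComparison(float(stat), float(p), float(a.mean()),
                           float(b.mean()), a.size, b.size, "rank-sum")


def compare_groups(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    pairing: str = "paired",
    alternative: str = "greater",
) -> dict[str, GroupComparison]:
    """Compare c and z between two role tables.

    ``pairing="paired"`` uses the one-tailed signed-rank test on species
    present in both tables (e.g. bees persisting across periods, testing
    whether their coefficients became higher in table B).
    ``pairing="unpaired"`` uses the one-tailed rank-sum test between two
    disjoint groups (e.g. species that appeared vs the others of the same
    period).  ``alternative`` refers to table B relative to table A.
    """
    if table_a.empty:
        raise ValueError("table_a is empty")
    if table_b.empty:
        raise ValueError("table_b is empty")
    results: dict[str, GroupComparison] = {}
    if pairing == "paired":
        shared = sorted(set(table_a["species"]) & set(table_b["species"]))
        if not shared:
            raise ValueError("no shared species for a paired comparison")
        ia = table_a.set_index("species").loc[shared]
        ib = table_b.set_index("species").loc[shared]
        for var in ("c", "z"):
            results[var] = _one_comparison(
                ia[var].to_numpy(float), ib[var].to_numpy(float),
                "paired", alternative,
            )
    elif pairing == "unpaired":
        for var in ("c", "z"):
            results[var] = _one_comparison(
                table_a[var].to_numpy(float), table_b[var].to_numpy(float),
                "unpaired", alternative,
            )
    else:
        raise ValueError(f"unknown pairing {pairing!r}")
    return results


def degree_cz_correlation(table: pd.DataFrame) -> dict[str, tuple[float, float]]:
    """Pearson r and p of (c, degree) and (z, degree) on complete cases."""
    out: dict[str, tuple[float, float]] = {}
    for var in ("c", "z"):
        sub = table[["degree", var]].dropna()
        if len(sub) < 3:
            raise ValueError(f"need >=3 complete cases for {var}-degree")
        x = sub["degree"].to_numpy(float)
        y = sub[var].to_numpy(float)
        if x.std() == 0 or y.std() == 0:
            raise ValueError(f"zero variance in {var}-degree correlation")
        r, p = stats.pearsonr(x, y)
        out[var] = (float(r), float(p))
    return out
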