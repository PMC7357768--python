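"""Cross-period module correspondence and trait-based module profiles.

Modules detected independently in each period are matched by hierarchical
clustering of their bee-species sets (Jaccard distance, Ward linkage):
clusters that gather exactly one module per period identify functional
groups persisting through time.  Modules are then profiled by the traits
of their bees and of the plants they visit, their taxonomic homogeneity is
scored by the plant species-by-genus ratio against null expectation, and
the trait-specialization association is tested (rank tests, Kruskal-Wallis,
30% quantile regression of body size on the participation coefficient).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from statsmodels.regression.quantile_regression import QuantReg

from .modularity import ModulePartition
from .network import BipartiteNetwork
from .nullmodels import NullEnsemble

log = logging.getLogger(__name__)


# -- module correspondence across periods ---------------------------------


@dataclass
class CorrespondenceResult:
    """Cross-period module matching by clustering of bee-species sets."""

    module_ids: list[tuple[str, int]]  # (period label, module id) per leaf
    distance: np.ndarray  # condensed Jaccard distances
    linkage: np.ndarray  # Ward linkage matrix
    matched: list[tuple[tuple[str, int], ...]]  # one module per period
    newick: str

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g, group in enumerate(self.matched):
            for period, module in group:
                rows.append({"group": g, "period": period, "module": module})
        return pd.DataFrame(rows, columns=["group", "period", "module"])


def _newick(linkage: np.ndarray, leaf_names: list[str]) -> str:
    tree = hierarchy.to_tree(linkage)

    def walk(node) -> str:
        if node.is_leaf():
            return leaf_names[node.id]
        left, right = node.get_left(), node.get_right()
        bl = node.dist - left.dist
        br = node.dist - right.dist
        return f"({walk(left)}:{bl:.6f},{walk(right)}:{br:.6f})"

    return walk(tree) + ";"


def module_correspondence(
    partitions: list[ModulePartition],
    nets: list[BipartiteNetwork],
    min_bees: int = 10,
) -> CorrespondenceResult:
    """Match main modules across periods by their bee-species composition.

    Builds the binary module x bee-species incidence over all periods'
    main modules (those with at least ``min_bees`` bee species), computes
    pairwise Jaccard distances between modules as species sets, applies
    Ward-linkage agglomeration, and cuts the tree into as many groups as
    the largest per-period module count.  Groups holding exactly one
    module per period are reported as matched.
    """
    if len(partitions) < 2 or len(partitions) != len(nets):
        raise ValueError("need one partition per network for >=2 periods")
    leaves: list[tuple[str, int]] = []
    sets: list[set[str]] = []
    for part, net in zip(partitions, nets):
        main = part.main_modules(net, min_bees=min_bees)
        if not main:
            log.warning("period %r has no module with >=%d bee species",
                        net.period_label, min_bees)
        members = part.module_members(net)
        for m in main:
            leaves.append((net.period_label, m))
            sets.append(set(members[m]["bees"]))
    if len(sets) < 2:
        raise ValueError("fewer than two main modules to cluster")
    species = sorted(set().union(*sets))
    incidence = np.array(
        [[s in group for s in species] for group in sets], dtype=bool
    )
    dist = pdist(incidence, metric="jaccard")
    link = hierarchy.linkage(dist, method="ward")

    n_groups = max(
        sum(1 for p, _ in leaves if p == period)
        for period in {p for p, _ in leaves}
    )
    flat = hierarchy.fcluster(link, t=n_groups, criterion="maxclust")
    periods = [p for p, _ in leaves]
    matched = []
    for g in sorted(set(flat)):
        idx = [i for i, f in enumerate(flat) if f == g]
        group_periods = [periods[i] for i in idx]
        overlapping = all(
            sets[a] & sets[b] for x, a in enumerate(idx) for b in idx[x + 1:]
        )
        if len(set(group_periods)) == len(set(periods)) \
                and len(idx) == len(set(periods)) and overlapping:
            matched.append(tuple(leaves[i] for i in idx))
    names = [f"{p}|M{m}" for p, m in leaves]
    return CorrespondenceResult(
        module_ids=leaves,
        distance=dist,
        linkage=link,
        matched=matched,
        newick=_newick(link, names),
    )


# -- taxonomic homogeneity -------------------------------------------------


def _genus(name: str, genus_map: dict[str, str] | None) -> str:
    if genus_map and name in genus_map and genus_map[name]:
        return genus_map[name]
    return name.split()[0]


def _module_plants(net: BipartiteNetwork, partition: ModulePartition,
                   module: int) -> list[str]:
    """Plants linked to at least one bee of the module."""
    bee_rows = [i for i, b in enumerate(net.bees)
                if partition.assignment[b] == module]
    if not bee_rows:
        raise ValueError(f"module {module} has no bee species")
    mask = net.adjacency[bee_rows].sum(axis=0) > 0
    return [p for p, keep in zip(net.plants, mask) if keep]


def species_genus_ratio(
    net: BipartiteNetwork,
    partition: ModulePartition,
    module: int,
    genus_map: dict[str, str] | None = None,
) -> float:
    """Plant species-per-genus ratio of one module (>= 1 always).

    Counts the distinct plant species visited by the module's bees and the
    distinct genera among them (genus taken from ``genus_map`` or, by
    default, the first token of the binomial).  Higher values mean a more
    taxonomically homogeneous resource base.
    """
    plants = _module_plants(net, partition, module)
    if not plants:
        raise ValueError(f"module {module} reaches no plant species")
    genera = {_genus(p, genus_map) for p in plants}
    return len(plants) / len(genera)


def species_genus_ratio_null(
    ensemble: NullEnsemble,
    min_bees: int = 1,
    genus_map: dict[str, str] | None = None,
) -> np.ndarray:
    """Pooled species-by-genus ratios over the null ensemble's modules.

    For every shuffled replicate's detected partition, the ratio of each
    module with at least ``min_bees`` bee species is computed; the pooled
    sample is the reference band against which observed ratios are judged.
    """
    if not ensemble.partitions:
        raise ValueError("ensemble carries no detected partitions")
    out: list[float] = []
    for r, part in enumerate(ensemble.partitions):
        net_r = ensemble.replicate_network(r)
        for m in part.main_modules(net_r, min_bees=min_bees):
            out.append(species_genus_ratio(net_r, part, m, genus_map))
    return np.asarray(out)


# -- trait profiles --------------------------------------------------------


@dataclass
class ModuleProfile:
    """Trait composition of one module's bees and of their plants."""

    module: int
    n_bees: int
    n_plants: int
    bee_trait_proportions: dict[str, dict[str, float]]
    plant_trait_proportions: dict[str, dict[str, float]]
    mean_itd: float
    species_genus_ratio: float
    coverage: dict[str, float]  # fraction of members with the trait scored

    def modal(self, trait: str) -> tuple[str, float]:
        """Dominant category of a trait and its proportion."""
        pool = {**self.bee_trait_proportions, **self.plant_trait_proportions}
        props = pool[trait]
        cat = max(props, key=props.get)
        return cat, props[cat]


def _proportions(values: pd.Series) -> dict[str, float]:
    values = values.dropna()
    values = values[values.astype(str) != ""]
    if values.empty:
        return {}
    counts = values.value_counts()
    return (counts / counts.sum()).to_dict()


def trait_profile(
    net: BipartiteNetwork,
    partition: ModulePartition,
    module: int,
    bee_traits: pd.DataFrame,
    plant_traits: pd.DataFrame | None = None,
    plant_mode: str = "links",
    genus_map: dict[str, str] | None = None,
) -> ModuleProfile:
    """Trait composition of one module.

    Bee trait proportions are per species.  Plant trait proportions are
    link-weighted by default (``plant_mode="links"``: every bee-plant link
    of the module contributes its plant once, so commonly visited plants
    weigh more); ``plant_mode="species"`` counts each visited plant species
    once.  Missing trait values are excluded, with per-trait coverage
    reported.
    """
    members = partition.module_members(net)[module]
    bees = members["bees"]
    if not bees:
        raise ValueError(f"module {module} has no bee species")
    bt = bee_traits.set_index("species").reindex(bees)

    bee_props: dict[str, dict[str, float]] = {}
    coverage: dict[str, float] = {}
    for col in bt.columns:
        if col in ("guild", "ITD"):
            continue
        bee_props[col] = _proportions(bt[col])
        coverage[col] = float(bt[col].notna().mean())
    itd = bt["ITD"].dropna() if "ITD" in bt.columns else pd.Series(dtype=float)
    mean_itd = float(itd.mean()) if not itd.empty else float("nan")
    if "ITD" in bt.columns:
        coverage["ITD"] = float(bt["ITD"].notna().mean())

    bee_rows = [net.bees.index(b) for b in bees]
    sub = net.adjacency[bee_rows]
    plant_names = _module_plants(net, partition, module)
    plant_props: dict[str, dict[str, float]] = {}
    if plant_traits is not None:
        pt = plant_traits.set_index("species")
        if plant_mode == "links":
            link_plants = [net.plants[j]
                           for _, j in zip(*np.nonzero(sub))]
            frame = pt.reindex(link_plants)
        elif plant_mode == "species":
            frame = pt.reindex(plant_names)
        else:
            raise ValueError(f"unknown plant_mode {plant_mode!r}")
        for col in frame.columns:
            if col == "guild":
                continue
            plant_props[col] = _proportions(frame[col])
            coverage[f"plant:{col}"] = float(frame[col].notna().mean())

    return ModuleProfile(
        module=module,
        n_bees=len(bees),
        n_plants=len(plant_names),
        bee_trait_proportions=bee_props,
        plant_trait_proportions=plant_props,
        mean_itd=mean_itd,
        species_genus_ratio=species_genus_ratio(net, partition, module,
                                                genus_map),
        coverage=coverage,
    )


# -- trait vs specialization tests ----------------------------------------


@dataclass
class TraitTestResult:
    trait: str
    variable: str  # role metric tested (c or z)
    test: str
    statistic: float
    pvalue: float
    n: int
    extra: dict = field(default_factory=dict)


def quantile_fit(x: np.ndarray, y: np.ndarray, q: float = 0.3
                 ) -> tuple[float, float]:
    """Linear fit of ``y`` on ``x`` at quantile ``q`` (pinball loss).

    Returns (intercept, slope).  A constant response short-circuits to a
    flat line at that constant (the pinball loss is then minimized by any
    slope-0 line through it).
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if np.ptp(y) == 0:
        return float(y[0]), 0.0
    X = np.column_stack([np.ones_like(x), x])
    res = QuantReg(y, X).fit(q=q, p_tol=1e-8)
    return float(res.params[0]), float(res.params[1])


def trait_specialization_tests(
    role_table: pd.DataFrame,
    bee_traits: pd.DataFrame,
    variables: tuple[str, ...] = ("c", "z"),
    quantile: float = 0.3,
) -> list[TraitTestResult]:
    """Association between role metrics and bee traits.

    Two-category traits (tongue length, lecty) are tested with the
    rank-sum test, multi-category traits (sociality, flight period,
    nesting) with Kruskal-Wallis, and the continuous ITD with a linear
    quantile regression of ITD on the role metric (30% quantile by
    default, tracking the lower envelope of body size).  Categories with
    fewer than 2 species are dropped from the categorical tests with a
    log note.
    """
    merged = role_table.merge(bee_traits, on="species", how="inner")
    results: list[TraitTestResult] = []
    cat_traits = [c for c in bee_traits.columns
                  if c not in ("species", "guild", "ITD")]
    for var in variables:
        for trait in cat_traits:
            sub = merged[[var, trait]].dropna()
            sub = sub[sub[trait].astype(str) != ""]
            sizes = sub[trait].value_counts()
            small = sizes[sizes < 2].index.tolist()
            if small:
                log.info("dropping %s categories with <2 species: %s",
                         trait, small)
                sub = sub[~sub[trait].isin(small)]
            groups = [g[var].to_numpy(float)
                      for _, g in sub.groupby(trait, observed=True)]
            if len(groups) < 2:
                continue
            if len(groups) == 2:
                stat, p = stats.mannwhitneyu(groups[0], groups[1],
                                             alternative="two-sided")
                test = "rank-sum"
            else:
                stat, p = stats.kruskal(*groups)
                test = "kruskal-wallis"
            results.append(TraitTestResult(
                trait=trait, variable=var, test=test,
                statistic=float(stat), pvalue=float(p), n=len(sub),
            ))
        if "ITD" in merged.columns:
            sub = merged[[var, "ITD"]].dropna()
            if len(sub) >= 3:
                x = sub[var].to_numpy(float)
                y = sub["ITD"].to_numpy(float)
                intercept, slope = quantile_fit(x, y, q=quantile)
                r, p = stats.spearmanr(x, y)
                results.append(TraitTestResult(
                    trait="ITD", variable=var,
                    test=f"quantile-{quantile:g}-regression",
                    statistic=float(slope), pvalue=float(p), n=len(sub),
                    extra={"intercept": intercept, "slope": slope,
                           "spearman_r": float(r)},
                ))
    return results
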