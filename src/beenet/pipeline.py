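"""End-to-end orchestration of the two-period specialization study.

``run_pipeline`` chains every stage — record parsing, per-period network
construction, classical indices, module detection, null ensembles and SES,
species roles, and module characterization — under a single master seed
that spawns one named sub-stream per stochastic stage, and archives every
intermediate as delimited text so each reported statistic can be
recomputed from files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import characterization, metrics, modularity, nullmodels, records, roles
from .modularity import AnnealSchedule, ModulePartition
from .network import BipartiteNetwork

log = logging.getLogger(__name__)

#: fixed order of the named seed sub-streams spawned from the master seed
_STAGES = ("rarefy", "modules_a", "modules_b", "null_a", "null_b", "resample")


@dataclass
class RunConfig:
    """Configuration of one full two-period run."""

    records_path: str = ""
    bee_traits_path: str | None = None
    plant_traits_path: str | None = None
    column_map: dict[str, str] | None = None
    period_a: tuple[int, int] = (1930, 1969)
    period_b: tuple[int, int] = (1990, 2009)
    min_pair_count: int = 2
    exclude_species: tuple[str, ...] = records.DEFAULT_EXCLUDE
    n_null: int = 1000
    n_rarefy: int = 1000
    rarefy_richness: int | None = None  # default: min(b) + min(p)
    role_quantiles: tuple[float, ...] = (0.90, 0.95)
    main_module_min_bees: int = 10
    schedule: AnnealSchedule = field(default_factory=AnnealSchedule)
    null_schedule: AnnealSchedule | None = None  # default: same as observed
    n_resample: int = 0  # interaction-count consistency check replicates
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_null, self.n_rarefy, self.main_module_min_bees) < 1:
            raise ValueError("all counts must be positive")
        a0, a1 = self.period_a
        b0, b1 = self.period_b
        if not (a1 < b0 or b1 < a0):
            raise ValueError("period windows must not overlap")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("period_a", "period_b", "exclude_species",
                    "role_quantiles"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        for key in ("schedule", "null_schedule"):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = AnnealSchedule(**raw[key])
        return cls(**raw)


@dataclass
class RunReport:
    """All tables and statistics of one run, recomputable from the archive."""

    dimensions: pd.DataFrame
    connectance: dict[str, metrics.ConnectanceResult]
    rarefaction_test: metrics.RankTestResult
    partitions: dict[str, ModulePartition]
    ses: dict[str, nullmodels.SESResult]
    modularity_period_test: metrics.RankTestResult
    role_tables: dict[str, pd.DataFrame]
    thresholds: dict[str, dict[float, roles.RoleThresholds]]
    persisting_tests: dict[str, roles.GroupComparison]
    degree_correlations: dict[str, dict[str, tuple[float, float]]]
    key_species: pd.DataFrame
    correspondence: characterization.CorrespondenceResult | None = None
    profiles: list[characterization.ModuleProfile] = field(default_factory=list)
    trait_tests: list[characterization.TraitTestResult] = field(
        default_factory=list)
    resample_q: np.ndarray | None = None


def _stage_seeds(master: int) -> dict[str, int]:
    ss = np.random.SeedSequence(master)
    states = ss.generate_state(len(_STAGES))
    return {name: int(s % (2**31 - 1)) for name, s in zip(_STAGES, states)}


def build_periods(config: RunConfig, record_table: pd.DataFrame
                  ) -> dict[str, BipartiteNetwork]:
    """Per-period binary networks from a canonical record table."""
    nets: dict[str, BipartiteNetwork] = {}
    for window in (config.period_a, config.period_b):
        label = f"{window[0]}-{window[1]}"
        recs = records.filter_to_period(record_table, *window)
        nets[label] = records.build_network(
            recs, min_pair_count=config.min_pair_count,
            exclude_species=config.exclude_species, period_label=label,
        )
    return nets


def key_species_report(
    role_tables: dict[str, pd.DataFrame],
    nets: dict[str, BipartiteNetwork],
    top_n: int = 10,
) -> pd.DataFrame:
    """Key species (non-peripheral roles) with their main plant partners.

    For each period lists hubs and connectors, their persistence status
    across periods (kept a key role, became peripheral, disappeared from /
    appeared in the network), and their ``top_n`` partner plants ranked by
    plant degree.  The report also carries, per period, the pooled partner
    plants of all key species as a fraction of the period's plant richness.
    """
    labels = list(role_tables)
    rows = []
    for label in labels:
        table = role_tables[label]
        other = labels[1] if label == labels[0] else labels[0]
        other_table = role_tables[other].set_index("species")
        net = nets[label]
        plant_degree = dict(zip(net.plants, net.plant_degrees()))
        keys = table[table["role"] != "peripheral"]
        partner_union: set[str] = set()
        for _, rec in keys.iterrows():
            sp = rec["species"]
            i = net.bees.index(sp)
            partners = [net.plants[j] for j in np.nonzero(net.adjacency[i])[0]]
            partner_union.update(partners)
            partners = sorted(partners, key=lambda p: -plant_degree[p])[:top_n]
            if sp not in other_table.index:
                status = ("disappeared" if label == labels[0] else "appeared")
            elif other_table.loc[sp, "role"] != "peripheral":
                status = "kept key role"
            else:
                status = "peripheral in other period"
            rows.append({
                "period": label, "species": sp, "role": rec["role"],
                "c": rec["c"], "z": rec["z"], "degree": rec["degree"],
                "status": status, "top_plants": "; ".join(partners),
                "n_key_partner_plants": len(partner_union),
                "partner_plant_fraction": len(partner_union) / net.n_plants,
            })
        if keys.empty:
            rows.append({
                "period": label, "species": "", "role": "", "c": np.nan,
                "z": np.nan, "degree": 0, "status": "no key species",
                "top_plants": "", "n_key_partner_plants": 0,
                "partner_plant_fraction": 0.0,
            })
    df = pd.DataFrame(rows)
    # the union accounting is per period: keep the final (complete) value
    for label in labels:
        mask = df["period"] == label
        if mask.any():
            df.loc[mask, "n_key_partner_plants"] = \
                df.loc[mask, "n_key_partner_plants"].iloc[-1]
            df.loc[mask, "partner_plant_fraction"] = \
                df.loc[mask, "partner_plant_fraction"].iloc[-1]
    return df


def run_pipeline(config: RunConfig, out_dir=None) -> RunReport:
    """Execute the full study; optionally archive intermediates to a dir."""
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)

    log.info("stage: records")
    record_table = records.read_records(config.records_path,
                                        column_map=config.column_map)
    nets = build_periods(config, record_table)
    (label_a, net_a), (label_b, net_b) = nets.items()
    overlap = records.overlap_summary(net_a, net_b)
    dims = overlap.to_frame()
    if out is not None:
        for label, net in nets.items():
            records.write_adjacency(net, out / f"adjacency_{label}.csv")
            records.write_edge_list(net, out / f"edges_{label}.csv")
        dims.to_csv(out / "dimensions.csv")

    log.info("stage: classical indices")
    conn = {label: metrics.connectance(net) for label, net in nets.items()}
    richness = config.rarefy_richness or (
        min(net_a.n_bees, net_b.n_bees) + min(net_a.n_plants, net_b.n_plants)
    )
    rarefied = {
        label: metrics.rarefy_connectance(
            net, richness, n_reps=config.n_rarefy,
            seed=seeds["rarefy"] + i,
        )
        for i, (label, net) in enumerate(nets.items())
    }
    rarefaction_test = metrics.compare_connectance(rarefied[label_a],
                                                   rarefied[label_b])
    if out is not None:
        for label, sample in rarefied.items():
            np.savetxt(out / f"rarefied_connectance_{label}.txt", sample)

    log.info("stage: module detection")
    partitions = {
        label_a: modularity.detect_modules(net_a, config.schedule,
                                           seed=seeds["modules_a"]),
        label_b: modularity.detect_modules(net_b, config.schedule,
                                           seed=seeds["modules_b"]),
    }
    if out is not None:
        for label, part in partitions.items():
            modularity.write_partition(part, nets[label],
                                       out / f"partition_{label}.tsv")

    log.info("stage: null models (%d replicates per period)", config.n_null)
    null_schedule = config.null_schedule or config.schedule
    ensembles = {
        label_a: nullmodels.build_null_ensemble(
            net_a, n_reps=config.n_null, seed=seeds["null_a"],
            schedule=null_schedule),
        label_b: nullmodels.build_null_ensemble(
            net_b, n_reps=config.n_null, seed=seeds["null_b"],
            schedule=null_schedule),
    }
    ses_results = {
        label: nullmodels.ses(partitions[label].Q, ensembles[label].m_null)
        for label in nets
    }
    mod_test = nullmodels.compare_modularity_periods(
        partitions[label_a].Q, ensembles[label_a].m_null,
        partitions[label_b].Q, ensembles[label_b].m_null,
    )
    resample_q = None
    if config.n_resample > 0:
        denser = label_b if net_b.n_interactions >= net_a.n_interactions \
            else label_a
        target = min(net_a.n_interactions, net_b.n_interactions)
        resample_q = nullmodels.resample_to_interaction_count(
            nets[denser], target, n_reps=config.n_resample,
            seed=seeds["resample"], schedule=null_schedule,
        )
    if out is not None:
        for label, ens in ensembles.items():
            np.savetxt(out / f"null_modularity_{label}.txt", ens.m_null)
        if resample_q is not None:
            np.savetxt(out / "resampled_modularity.txt", resample_q)

    log.info("stage: species roles")
    role_tables: dict[str, pd.DataFrame] = {}
    thresholds: dict[str, dict[float, roles.RoleThresholds]] = {}
    for label in nets:
        table = roles.cz_table(nets[label], partitions[label])
        thresholds[label] = {
            q: roles.role_thresholds(ensembles[label], quantile=q)
            for q in config.role_quantiles
        }
        primary_q = config.role_quantiles[0]
        role_tables[label] = roles.classify_roles(
            table, thresholds[label][primary_q])
    persisting = roles.compare_groups(role_tables[label_a],
                                      role_tables[label_b],
                                      pairing="paired",
                                      alternative="greater")
    degree_corr = {
        label: roles.degree_cz_correlation(role_tables[label])
        for label in nets
    }
    keys = key_species_report(role_tables, nets)
    if out is not None:
        for label, table in role_tables.items():
            table.to_csv(out / f"roles_{label}.csv", index=False)
        keys.to_csv(out / "key_species.csv", index=False)

    log.info("stage: characterization")
    correspondence = None
    profiles: list[characterization.ModuleProfile] = []
    trait_tests: list[characterization.TraitTestResult] = []
    try:
        correspondence = characterization.module_correspondence(
            list(partitions.values()), list(nets.values()),
            min_bees=config.main_module_min_bees,
        )
    except ValueError as exc:
        log.warning("module correspondence skipped: %s", exc)
    bee_traits = plant_traits = None
    if config.bee_traits_path:
        bee_traits = pd.read_csv(config.bee_traits_path)
    if config.plant_traits_path:
        plant_traits = pd.read_csv(config.plant_traits_path)
    if bee_traits is not None:
        for label in nets:
            for m in partitions[label].main_modules(
                    nets[label], min_bees=config.main_module_min_bees):
                profiles.append(characterization.trait_profile(
                    nets[label], partitions[label], m, bee_traits,
                    plant_traits))
            trait_tests.extend(characterization.trait_specialization_tests(
                role_tables[label], bee_traits))
    if out is not None and correspondence is not None:
        (out / "module_dendrogram.nwk").write_text(correspondence.newick)
        correspondence.to_frame().to_csv(out / "matched_modules.csv",
                                         index=False)

    report = RunReport(
        dimensions=dims,
        connectance=conn,
        rarefaction_test=rarefaction_test,
        partitions=partitions,
        ses=ses_results,
        modularity_period_test=mod_test,
        role_tables=role_tables,
        thresholds=thresholds,
        persisting_tests=persisting,
        degree_correlations=degree_corr,
        key_species=keys,
        correspondence=correspondence,
        profiles=profiles,
        trait_tests=trait_tests,
        resample_q=resample_q,
    )
    if out is not None:
        (out / "report.json").write_text(report_summary_json(report))
    return report


def report_summary_json(report: RunReport) -> str:
    """Flat JSON digest of the headline statistics of a run."""
    payload: dict[str, object] = {}
    for label, c in report.connectance.items():
        payload[f"connectance[{label}]"] = round(c.C, 6)
    payload["rarefaction_p"] = report.rarefaction_test.pvalue
    for label, part in report.partitions.items():
        payload[f"modularity[{label}]"] = round(part.Q, 6)
        payload[f"n_modules[{label}]"] = part.n_modules
    for label, s in report.ses.items():
        payload[f"SES[{label}]"] = round(s.SES, 4)
        payload[f"SES_significant[{label}]"] = bool(s.significant)
    payload["modularity_period_p"] = report.modularity_period_test.pvalue
    for var, comp in report.persisting_tests.items():
        payload[f"persisting_{var}_p"] = comp.pvalue
        payload[f"persisting_{var}_means"] = [comp.mean_a, comp.mean_b]
    for label, table in report.role_tables.items():
        counts = table["role"].value_counts().to_dict()
        payload[f"roles[{label}]"] = counts
        payload[f"n_key_species[{label}]"] = int(
            (table["role"] != "peripheral").sum())
    return json.dumps(payload, indent=2, default=float)
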