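"""Reading and filtering opportunistic interaction records.

Records are specimen-level observations ("bee X caught on plant Y in year
Z") accumulated by naturalists without a standardized protocol.  This module
parses delimited record files, applies the period window and the
minimum-occurrence filter, builds the binary per-period networks, and
computes the between-period species/interaction overlap accounting.
"""

from __future__ import annotations

import csv
import io
import logging
import re
from dataclasses import dataclass

import pandas as pd

from .network import BipartiteNetwork, EmptyNetworkError

log = logging.getLogger(__name__)

#: canonical record columns; the first three are required.
RECORD_COLUMNS = (
    "bee",
    "plant",
    "year",
    "bee_family",
    "bee_genus",
    "plant_family",
    "plant_genus",
)

DEFAULT_EXCLUDE = ("Apis mellifera",)


def normalize_name(name: str) -> str:
    """Whitespace/case normalization of a species name.

    Collapses internal whitespace and canonicalizes case to the binomial
    convention (capitalized genus, lower-case epithet).  No fuzzy synonym
    matching is attempted: upstream records are assumed expert-validated.
    """
    name = re.sub(r"\s+", " ", str(name).strip())
    return name[:1].upper() + name[1:].lower() if name else ""


def read_records(
    path,
    column_map: dict[str, str] | None = None,
    sep: str | None = None,
    year_range: tuple[int, int] = (1800, 2100),
) -> pd.DataFrame:
    """Read a delimited record file into a canonical record table.

    Parameters
    ----------
    path
        Comma- or tab-delimited UTF-8 text file with a header row.  The
        delimiter is sniffed when ``sep`` is not given.
    column_map
        Mapping from file column name to canonical column name (``bee``,
        ``plant``, ``year``, optionally the family/genus columns).  Columns
        already canonically named need not be mapped; extra columns are
        ignored.
    year_range
        Plausibility window; rows outside it are treated as malformed.

    Returns
    -------
    DataFrame with the canonical columns present in the file.  Malformed
    rows (empty names, unparseable or implausible years) are skipped and
    reported with their line numbers through the module logger; the skip
    list is also attached as ``df.attrs["skipped_rows"]``.
    """
    with open(path, "r", encoding="utf-8", newline="") as fh:
        text = fh.read()
    if sep is None:
        try:
            sep = csv.Sniffer().sniff(text[:4096], delimiters=",\t;").delimiter
        except csv.Error:
            sep = ","
    raw = pd.read_csv(io.StringIO(text), sep=sep, dtype=str, keep_default_na=False)
    if column_map:
        raw = raw.rename(columns=column_map)
    missing = [c for c in ("bee", "plant", "year") if c not in raw.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")

    keep_cols = [c for c in RECORD_COLUMNS if c in raw.columns]
    rows: list[dict] = []
    skipped: list[tuple[int, str]] = []
    lo, hi = year_range
    for i, rec in enumerate(raw.to_dict("records")):
        line_no = i + 2  # header is line 1
        bee = normalize_name(rec["bee"])
        plant = normalize_name(rec["plant"])
        if not bee or not plant:
            skipped.append((line_no, "empty species name"))
            continue
        try:
            year = int(float(rec["year"]))
        except (TypeError, ValueError):
            skipped.append((line_no, f"unparseable year {rec['year']!r}"))
            continue
        if not lo <= year <= hi:
            skipped.append((line_no, f"implausible year {year}"))
            continue
        row = {"bee": bee, "plant": plant, "year": year}
        for c in keep_cols[3:]:
            row[c] = str(rec.get(c, "")).strip()
        rows.append(row)

    for line_no, reason in skipped:
        log.warning("skipped line %d: %s", line_no, reason)
    log.info("read %d records, skipped %d malformed rows", len(rows), len(skipped))
    df = pd.DataFrame(rows, columns=keep_cols if rows else ["bee", "plant", "year"])
    df.attrs["skipped_rows"] = skipped
    return df


def filter_to_period(
    records: pd.DataFrame, start_year: int, end_year: int
) -> pd.DataFrame:
    """Keep records with ``start_year <= year <= end_year`` (both inclusive)."""
    if start_year > end_year:
        raise ValueError(f"start_year {start_year} > end_year {end_year}")
    kept = records[(records["year"] >= start_year) & (records["year"] <= end_year)]
    return kept.reset_index(drop=True)


def build_network(
    records: pd.DataFrame,
    min_pair_count: int = 2,
    exclude_species: tuple[str, ...] = DEFAULT_EXCLUDE,
    period_label: str = "",
) -> BipartiteNetwork:
    """Build the binary network of a period from its record table.

    A link is established between a bee and a plant species iff their pair
    occurs at least ``min_pair_count`` times among the records — singleton
    observations are treated as possibly spurious and dropped at the default
    threshold of 2.  Counts are then discarded: the adjacency is binary,
    since opportunistic specimen counts reflect collector effort as much as
    interaction frequency.  Excluded species (by default the managed
    honeybee) are removed before counting.
    """
    if records.empty:
        raise EmptyNetworkError("no records supplied")
    excl = {normalize_name(s) for s in exclude_species}
    recs = records.assign(
        bee=records["bee"].map(normalize_name),
        plant=records["plant"].map(normalize_name),
    )
    recs = recs[~recs["bee"].isin(excl) & ~recs["plant"].isin(excl)]
    counts = recs.groupby(["bee", "plant"]).size()
    edges = [pair for pair, n in counts.items() if n >= min_pair_count]
    if not edges:
        raise EmptyNetworkError(
            f"no bee-plant pair observed >= {min_pair_count} times"
        )
    log.info(
        "period %s: %d records -> %d qualifying links (%d pairs below threshold)",
        period_label or "?",
        len(recs),
        len(edges),
        int((counts < min_pair_count).sum()),
    )
    return BipartiteNetwork.from_edges(edges, period_label=period_label)


@dataclass
class OverlapSummary:
    """Between-period species and interaction overlap accounting.

    ``shared_*`` counts species/links observed in both periods; ``pooled_*``
    counts unique species/links over both periods; the fractions are
    shared / pooled-unique.
    """

    shared_bees: int
    shared_plants: int
    shared_interactions: int
    bees_a: int
    bees_b: int
    plants_a: int
    plants_b: int
    interactions_a: int
    interactions_b: int
    pooled_bees: int
    pooled_plants: int
    pooled_interactions: int
    period_a: str = ""
    period_b: str = ""

    @property
    def bee_fraction(self) -> float:
        return self.shared_bees / self.pooled_bees

    @property
    def plant_fraction(self) -> float:
        return self.shared_plants / self.pooled_plants

    @property
    def interaction_fraction(self) -> float:
        return self.shared_interactions / self.pooled_interactions

    def to_frame(self) -> pd.DataFrame:
        """Dimension table: one row per quantity, one column per accounting."""
        return pd.DataFrame(
            {
                self.period_a or "period_a": [
                    self.bees_a, self.plants_a, self.interactions_a],
                self.period_b or "period_b": [
                    self.bees_b, self.plants_b, self.interactions_b],
                "both": [
                    self.shared_bees, self.shared_plants,
                    self.shared_interactions],
                "pooled_unique": [
                    self.pooled_bees, self.pooled_plants,
                    self.pooled_interactions],
                "fraction_shared": [
                    self.bee_fraction, self.plant_fraction,
                    self.interaction_fraction],
            },
            index=["bee_species", "plant_species", "interactions"],
        )


def overlap_summary(netA: BipartiteNetwork, netB: BipartiteNetwork) -> OverlapSummary:
    """Species and link overlap between two period networks."""
    bees_a, bees_b = set(netA.bees), set(netB.bees)
    plants_a, plants_b = set(netA.plants), set(netB.plants)
    edges_a, edges_b = netA.edge_set(), netB.edge_set()
    return OverlapSummary(
        shared_bees=len(bees_a & bees_b),
        shared_plants=len(plants_a & plants_b),
        shared_interactions=len(edges_a & edges_b),
        bees_a=len(bees_a),
        bees_b=len(bees_b),
        plants_a=len(plants_a),
        plants_b=len(plants_b),
        interactions_a=len(edges_a),
        interactions_b=len(edges_b),
        pooled_bees=len(bees_a | bees_b),
        pooled_plants=len(plants_a | plants_b),
        pooled_interactions=len(edges_a | edges_b),
        period_a=netA.period_label,
        period_b=netB.period_label,
    )


# -- plain-text output helpers -------------------------------------------


def write_adjacency(net: BipartiteNetwork, path) -> None:
    """Labeled adjacency matrix (rows = bees, columns = plants) as CSV."""
    pd.DataFrame(net.adjacency, index=net.bees, columns=net.plants).to_csv(path)


def write_edge_list(net: BipartiteNetwork, path) -> None:
    rows = sorted(net.edge_set())
    pd.DataFrame(rows, columns=["bee", "plant"]).to_csv(path, index=False)


def read_adjacency(path, period_label: str = "") -> BipartiteNetwork:
    df = pd.read_csv(path, index_col=0)
    return BipartiteNetwork(
        list(df.index), list(df.columns), df.to_numpy(), period_label
    )
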