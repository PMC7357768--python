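"""Published summary dimensions of the Belgian two-period study system.

The century-scale Belgian plant-bee record archive behind this analysis is
not publicly deposited, but the published per-period network dimensions
and key-species counts are.  They are carried here as plain inputs so the
desk-reproducible arithmetic (connectance, overlap fractions, key-species
plant coverage) can be recomputed from them with the package's own
functions.
"""

from __future__ import annotations

from .metrics import ConnectanceResult, connectance_from_counts
from .records import OverlapSummary

PERIOD_1 = "1930-1969"
PERIOD_2 = "1990-2009"

#: per-period network dimensions: (period 1, period 2, shared, pooled unique)
DIMENSIONS = {
    "bee_species": (132, 126, 68, 190),
    "plant_species": (202, 206, 92, 316),
    "interactions": (541, 795, 66, 1270),
}

#: bees classified as key species (hubs/connectors at the 90% thresholds)
KEY_SPECIES = {PERIOD_1: 17, PERIOD_2: 13}

#: plant species interacting with those key species
KEY_SPECIES_PLANT_PARTNERS = {PERIOD_1: 113, PERIOD_2: 172}


def published_connectance() -> dict[str, ConnectanceResult]:
    """Connectance of each period from the published dimensions."""
    b1, b2, _, _ = DIMENSIONS["bee_species"]
    p1, p2, _, _ = DIMENSIONS["plant_species"]
    n1, n2, _, _ = DIMENSIONS["interactions"]
    return {
        PERIOD_1: connectance_from_counts(N=n1, p=p1, b=b1),
        PERIOD_2: connectance_from_counts(N=n2, p=p2, b=b2),
    }


def published_overlap() -> OverlapSummary:
    """Overlap accounting rebuilt from the published dimension table."""
    b1, b2, bs, bt = DIMENSIONS["bee_species"]
    p1, p2, ps, pt = DIMENSIONS["plant_species"]
    n1, n2, ns, nt = DIMENSIONS["interactions"]
    return OverlapSummary(
        shared_bees=bs, shared_plants=ps, shared_interactions=ns,
        bees_a=b1, bees_b=b2, plants_a=p1, plants_b=p2,
        interactions_a=n1, interactions_b=n2,
        pooled_bees=bt, pooled_plants=pt, pooled_interactions=nt,
        period_a=PERIOD_1, period_b=PERIOD_2,
    )


def key_species_plant_coverage() -> dict[str, float]:
    """Fraction of each period's plant richness touched by key species."""
    p1, p2, _, _ = DIMENSIONS["plant_species"]
    return {
        PERIOD_1: KEY_SPECIES_PLANT_PARTNERS[PERIOD_1] / p1,
        PERIOD_2: KEY_SPECIES_PLANT_PARTNERS[PERIOD_2] / p2,
    }
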