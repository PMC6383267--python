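"""Gene-family preservation tiers and per-species family-size distributions.

Preservation tiers classify orthogroups by how many species lack any
member: the most-preserved families have a gene in every species; the
intermediate tier tolerates up to three missing species; the least tier up
to five.  Both the disjoint tiers (0 / 1-3 / 4-5 missing) and the
cumulative nested counts are reported, since the nested definition is the
one usually quoted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .genome_io import OrthogroupTable

TIER_MOST = "most"
TIER_INTERMEDIATE = "intermediate"
TIER_LEAST = "least"
TIER_UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class PreservationTier:
    orthogroup_id: str
    n_missing_species: int
    tier: str


def _tier_for(n_missing: int) -> str:
    if n_missing == 0:
        return TIER_MOST
    if 1 <= n_missing <= 3:
        return TIER_INTERMEDIATE
    if 4 <= n_missing <= 5:
        return TIER_LEAST
    return TIER_UNASSIGNED


def preservation_tiers(orthogroups: OrthogroupTable) -> list[PreservationTier]:
    """Assign each orthogroup a preservation tier from its missing-species count."""
    tiers = []
    for og_id in sorted(orthogroups.groups):
        members = orthogroups.groups[og_id]
        n_missing = sum(1 for genes in members.values() if not genes)
        tiers.append(PreservationTier(og_id, n_missing, _tier_for(n_missing)))
    return tiers


def tier_counts(tiers: Sequence[PreservationTier]) -> dict[str, int]:
    """Disjoint tier counts plus the cumulative nested counts.

    ``most_cumulative`` equals ``most``; ``intermediate_cumulative`` counts
    families missing in at most 3 species; ``least_cumulative`` at most 5.
    """
    out = {t: 0 for t in (TIER_MOST, TIER_INTERMEDIATE, TIER_LEAST, TIER_UNASSIGNED)}
    for tier in tiers:
        out[tier.tier] += 1
    out["most_cumulative"] = out[TIER_MOST]
    out["intermediate_cumulative"] = out[TIER_MOST] + out[TIER_INTERMEDIATE]
    out["least_cumulative"] = out["intermediate_cumulative"] + out[TIER_LEAST]
    return out


def family_size_distribution(
    orthogroups: OrthogroupTable, species_id: str
) -> dict[int, float]:
    """Percentage of a species' gene families having each size.

    Families with zero genes in the species are excluded; percentages are
    over the remaining families and sum to 100.
    """
    if species_id not in orthogroups.species:
        raise ValueError(f"species {species_id!r} absent from orthogroup table")
    sizes = [
        len(members[species_id])
        for members in orthogroups.groups.values()
        if members.get(species_id)
    ]
    if not sizes:
        raise ValueError(f"species {species_id!r} has no gene in any orthogroup")
    total = len(sizes)
    out: dict[int, float] = {}
    for size in sizes:
        out[size] = out.get(size, 0.0) + 1.0
    return {size: 100.0 * count / total for size, count in sorted(out.items())}
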