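"""Partition homologous gene pairs into five modes of duplication.

The classification is hierarchical and pair-level, applied to the set of
undirected, filtered homolog pairs of one genome:

1. **WGD** — anchor pairs of intra-genome collinear blocks.
2. **TD** (tandem) — remaining same-chromosome pairs at adjacent ranks.
3. **PD** (proximal) — remaining same-chromosome pairs separated by 1..10
   intervening genes (rank distance 2..proximal_max+1).
4. **TRD** (transposed) — remaining pairs in which exactly one gene lies at
   an ancestral locus (the parent copy); the other is the transposed copy.
5. **DSD** (dispersed) — everything else, reduced so that each gene keeps
   only its highest-similarity (lowest E-value) dispersed partner.

Ancestral loci are genes anchored in intra- or inter-genome collinear
blocks, or (for assemblies too fragmented for synteny) genes whose
orthogroup has members in at least ``min_lineages`` other species.
A fragmented-assembly WGD variant replaces block anchors with pairs whose
Ks falls in known WGD peak windows and whose genes have orthogroup support.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .collinearity import CollinearBlock, anchor_pair_set
from .genome_io import GenomeTable, HomologyHit, OrthogroupTable


class Mode(str, Enum):
    WGD = "WGD"
    TD = "TD"
    PD = "PD"
    TRD = "TRD"
    DSD = "DSD"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class DuplicatePair:
    """An unordered duplicate gene pair with its assigned mode and evidence.

    ``gene_a < gene_b`` lexically.  Evidence fields: ``rank_distance`` for
    TD/PD, ``parent_copy``/``transposed_copy`` for TRD, ``block_id`` for WGD.
    """

    gene_a: str
    gene_b: str
    mode: Mode
    e_value: float
    rank_distance: int | None = None
    parent_copy: str | None = None
    transposed_copy: str | None = None
    block_id: int | None = None

    def __post_init__(self) -> None:
        if self.gene_a >= self.gene_b:
            raise ValueError("pair genes must be stored in lexical order")

    @property
    def key(self) -> frozenset[str]:
        return frozenset((self.gene_a, self.gene_b))


@dataclass
class AncestralLocusSet:
    """Genes judged to occupy ancestral loci, with the evidence source."""

    species_id: str
    gene_ids: set[str] = field(default_factory=set)
    sources: dict[str, set[str]] = field(default_factory=dict)

    def add(self, gene_id: str, source: str) -> None:
        self.gene_ids.add(gene_id)
        self.sources.setdefault(gene_id, set()).add(source)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.gene_ids


def filter_hits(
    raw_hits: Iterable[HomologyHit], e_max: float = 1e-10, top_n: int = 5
) -> list[HomologyHit]:
    """Apply the standard homology-hit filter: E < e_max, best top_n per query.

    Self-hits are removed; duplicate (query, subject) rows collapse to the
    best record.  Per query at most ``top_n`` subjects are kept, ordered by
    ascending E-value with ties broken by descending bit score then lexical
    subject id.
    """
    best: dict[tuple[str, str], HomologyHit] = {}
    for hit in raw_hits:
        if hit.query == hit.subject or not hit.e_value < e_max:
            continue
        key = (hit.query, hit.subject)
        prev = best.get(key)
        if prev is None or (hit.e_value, -hit.bit_score) < (prev.e_value, -prev.bit_score):
            best[key] = hit
    by_query: dict[str, list[HomologyHit]] = {}
    for hit in best.values():
        by_query.setdefault(hit.query, []).append(hit)
    kept: list[HomologyHit] = []
    for query in sorted(by_query):
        hits = sorted(by_query[query], key=lambda h: (h.e_value, -h.bit_score, h.subject))
        kept.extend(hits[:top_n])
    return kept


def undirected_pairs(hits: Iterable[HomologyHit]) -> dict[frozenset[str], HomologyHit]:
    """Collapse directed hits to unordered pairs, keeping the best record."""
    pairs: dict[frozenset[str], HomologyHit] = {}
    for hit in hits:
        key = frozenset((hit.query, hit.subject))
        prev = pairs.get(key)
        if prev is None or (hit.e_value, -hit.bit_score) < (prev.e_value, -prev.bit_score):
            pairs[key] = hit
    return pairs


def build_ancestral_set(
    target: GenomeTable,
    intra_blocks: Sequence[CollinearBlock],
    outgroup_blocks_list: Sequence[Sequence[CollinearBlock]] = (),
) -> AncestralLocusSet:
    """Ancestral loci = target genes anchored in intra- or inter-genome blocks.

    ``outgroup_blocks_list`` holds one block list per outgroup comparison,
    each detected with the target genome as the A side.
    """
    result = AncestralLocusSet(target.species_id)
    for block in intra_blocks:
        for anchor in block.anchors:
            result.add(anchor.gene_a, "intra_synteny")
            result.add(anchor.gene_b, "intra_synteny")
    for blocks in outgroup_blocks_list:
        for block in blocks:
            for anchor in block.anchors:
                if anchor.gene_a in target:
                    result.add(anchor.gene_a, "inter_synteny")
    if not intra_blocks and not any(outgroup_blocks_list):
        warnings.warn(f"no collinear blocks supplied; ancestral set for "
                      f"{target.species_id} is empty")
    return result


def ancestral_from_orthogroups(
    orthogroups: OrthogroupTable, target_species: str, min_lineages: int = 2
) -> AncestralLocusSet:
    """Ancestral loci from orthogroup membership across distant lineages.

    A target gene is considered ancient when its orthogroup contains at
    least one gene in at least ``min_lineages`` non-target species.
    """
    if target_species not in orthogroups.species:
        raise ValueError(f"species {target_species!r} absent from orthogroup table")
    result = AncestralLocusSet(target_species)
    for og_id, members in orthogroups.groups.items():
        other = sum(
            1 for sp, genes in members.items() if sp != target_species and genes
        )
        if other >= min_lineages:
            for gene in members.get(target_species, []):
                result.add(gene, "orthogroup")
    return result


def _reduce_dispersed(
    pool: dict[frozenset[str], HomologyHit]
) -> dict[frozenset[str], HomologyHit]:
    """Keep, per gene, only its lowest-E-value dispersed pair, then dedupe.

    A gene's non-best pairs are discarded, so a pair survives only when it
    is the best remaining pair of both of its genes.  Ties break by higher
    bit score, then lexical partner id.
    """
    best_for_gene: dict[str, frozenset[str]] = {}
    best_rank: dict[str, tuple[float, float, str]] = {}
    for key, hit in pool.items():
        a, b = sorted(key)
        for gene, partner in ((a, b), (b, a)):
            rank = (hit.e_value, -hit.bit_score, partner)
            if gene not in best_rank or rank < best_rank[gene]:
                best_rank[gene] = rank
                best_for_gene[gene] = key
    return {
        key: hit
        for key, hit in pool.items()
        if all(best_for_gene[g] == key for g in key)
    }


def _make_pair(
    key: frozenset[str], hit: HomologyHit, mode: Mode, **evidence
) -> DuplicatePair:
    a, b = sorted(key)
    return DuplicatePair(a, b, mode, hit.e_value, **evidence)


def classify_pairs(
    genome: GenomeTable,
    hits: Iterable[HomologyHit],
    intra_blocks: Sequence[CollinearBlock],
    ancestral: AncestralLocusSet,
    proximal_max: int = 10,
    reduce_dispersed: bool = True,
) -> dict[Mode, list[DuplicatePair]]:
    """Hierarchically classify filtered homolog pairs into the five modes.

    ``reduce_dispersed=False`` skips the final best-hit reduction of DSD
    pairs, so that all input pairs appear in exactly one mode (useful for
    auditing the partition).
    """
    anchor_block: dict[frozenset[str], int] = {}
    for block_id, block in enumerate(intra_blocks):
        for anchor in block.anchors:
            anchor_block.setdefault(frozenset((anchor.gene_a, anchor.gene_b)), block_id)

    pairs = undirected_pairs(hits)
    result: dict[Mode, list[DuplicatePair]] = {mode: [] for mode in Mode}
    dsd_pool: dict[frozenset[str], HomologyHit] = {}

    for key in sorted(pairs, key=lambda k: tuple(sorted(k))):
        hit = pairs[key]
        a, b = sorted(key)
        if a not in genome or b not in genome:
            warnings.warn(f"pair ({a}, {b}) references a gene absent from the "
                          f"genome table; skipped")
            continue
        if key in anchor_block:
            result[Mode.WGD].append(
                _make_pair(key, hit, Mode.WGD, block_id=anchor_block[key])
            )
            continue
        la, lb = genome[a], genome[b]
        if la.chromosome == lb.chromosome:
            dist = abs(la.rank - lb.rank)
            if dist == 1:
                result[Mode.TD].append(_make_pair(key, hit, Mode.TD, rank_distance=dist))
                continue
            if 2 <= dist <= proximal_max + 1:
                result[Mode.PD].append(_make_pair(key, hit, Mode.PD, rank_distance=dist))
                continue
        a_anc, b_anc = a in ancestral, b in ancestral
        if a_anc != b_anc:
            parent, novel = (a, b) if a_anc else (b, a)
            result[Mode.TRD].append(
                _make_pair(key, hit, Mode.TRD, parent_copy=parent, transposed_copy=novel)
            )
            continue
        dsd_pool[key] = hit

    if reduce_dispersed:
        dsd_pool = _reduce_dispersed(dsd_pool)
    for key in sorted(dsd_pool, key=lambda k: tuple(sorted(k))):
        result[Mode.DSD].append(_make_pair(key, dsd_pool[key], Mode.DSD))
    return result


def classify_fragmented(
    genome: GenomeTable,
    hits: Iterable[HomologyHit],
    kaks_table: Mapping[frozenset[str], float],
    orthogroups: OrthogroupTable,
    target_species: str,
    related_species: Sequence[str],
    ks_windows: Sequence[tuple[float, float]] = ((0.2, 0.4), (0.75, 1.5)),
    min_lineages: int = 2,
    proximal_max: int = 10,
) -> dict[Mode, list[DuplicatePair]]:
    """Classify duplications in a fragmented assembly without synteny.

    WGD candidates are pairs whose Ks falls inside any of the supplied peak
    windows *and* whose two genes both have orthogroup support (>= 1 gene in
    >= ``min_lineages`` related species in their orthogroup).  TD/PD use the
    usual rank rules; TRD uses orthogroup-derived ancestral loci; DSD is the
    best-hit-reduced remainder.
    """
    if not ks_windows:
        raise ValueError("ks_windows must contain at least one (low, high) window")
    related = [sp for sp in related_species if sp != target_species]

    def og_support(gene: str) -> bool:
        og_id = orthogroups.orthogroup_of(gene)
        if og_id is None:
            return False
        members = orthogroups.groups[og_id]
        return sum(1 for sp in related if members.get(sp)) >= min_lineages

    def in_window(ks: float | None) -> bool:
        return ks is not None and any(lo <= ks <= hi for lo, hi in ks_windows)

    ancestral = ancestral_from_orthogroups(orthogroups, target_species, min_lineages)
    pairs = undirected_pairs(hits)
    result: dict[Mode, list[DuplicatePair]] = {mode: [] for mode in Mode}
    dsd_pool: dict[frozenset[str], HomologyHit] = {}

    for key in sorted(pairs, key=lambda k: tuple(sorted(k))):
        hit = pairs[key]
        a, b = sorted(key)
        if a not in genome or b not in genome:
            warnings.warn(f"pair ({a}, {b}) references a gene absent from the "
                          f"genome table; skipped")
            continue
        if in_window(kaks_table.get(key)) and og_support(a) and og_support(b):
            result[Mode.WGD].append(_make_pair(key, hit, Mode.WGD))
            continue
        la, lb = genome[a], genome[b]
        if la.chromosome == lb.chromosome:
            dist = abs(la.rank - lb.rank)
            if dist == 1:
                result[Mode.TD].append(_make_pair(key, hit, Mode.TD, rank_distance=dist))
                continue
            if 2 <= dist <= proximal_max + 1:
                result[Mode.PD].append(_make_pair(key, hit, Mode.PD, rank_distance=dist))
                continue
        a_anc, b_anc = a in ancestral, b in ancestral
        if a_anc != b_anc:
            parent, novel = (a, b) if a_anc else (b, a)
            result[Mode.TRD].append(
                _make_pair(key, hit, Mode.TRD, parent_copy=parent, transposed_copy=novel)
            )
            continue
        dsd_pool[key] = hit

    dsd_pool = _reduce_dispersed(dsd_pool)
    for key in sorted(dsd_pool, key=lambda k: tuple(sorted(k))):
        result[Mode.DSD].append(_make_pair(key, dsd_pool[key], Mode.DSD))
    return result


def mode_counts(pairs_by_mode: Mapping[Mode, Sequence[DuplicatePair]]) -> dict[str, int]:
    return {str(mode): len(pairs_by_mode.get(mode, [])) for mode in Mode}
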