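"""Collinear (syntenic) block detection by dynamic-programming chaining.

Homologous gene pairs between two chromosomes are plotted as match points
in rank space; runs of points that preserve gene order (ascending on both
axes, or ascending/descending for inverted segments) are chained into
collinear blocks.  Anchors of intra-genome blocks are the WGD-derived
duplicate pairs.

A chain's score is ``match_score * n_anchors + gap_penalty * total_gaps``
where ``total_gaps`` sums, over consecutive anchors, the number of skipped
ranks on both axes ((dx - 1) + (dy - 1)).  Consecutive anchors may be at
most ``max_gap`` ranks apart on either axis.  Match points are assigned to
at most one block, extracted greedily by descending chain score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .genome_io import GenomeTable, HomologyHit


@dataclass(frozen=True)
class AnchorPair:
    gene_a: str
    gene_b: str
    rank_a: int
    rank_b: int
    e_value: float


@dataclass(frozen=True)
class CollinearBlock:
    chrom_a: str
    chrom_b: str
    orientation: str  # "plus" or "minus"
    anchors: tuple[AnchorPair, ...]
    score: float

    def __len__(self) -> int:
        return len(self.anchors)

    def gene_pairs(self) -> list[tuple[str, str]]:
        return [(a.gene_a, a.gene_b) for a in self.anchors]


def _collapse_tandem(points: list[AnchorPair], axis: str) -> list[AnchorPair]:
    """Collapse consecutive-rank genes on one axis hitting the same partner.

    Within a run of points whose ranks on ``axis`` are consecutive and whose
    partner gene is identical, only the best-E-value point is kept.  This
    prevents tandem arrays from inflating blocks.
    """
    if axis == "a":
        key, partner = (lambda p: p.rank_a), (lambda p: p.gene_b)
    else:
        key, partner = (lambda p: p.rank_b), (lambda p: p.gene_a)
    by_partner: dict[str, list[AnchorPair]] = {}
    for p in points:
        by_partner.setdefault(partner(p), []).append(p)
    kept: list[AnchorPair] = []
    for plist in by_partner.values():
        plist.sort(key=key)
        run: list[AnchorPair] = []
        for p in plist:
            if run and key(p) == key(run[-1]) + 1:
                run.append(p)
            else:
                if run:
                    kept.append(min(run, key=lambda q: (q.e_value, key(q))))
                run = [p]
        if run:
            kept.append(min(run, key=lambda q: (q.e_value, key(q))))
    kept.sort(key=lambda p: (p.rank_a, p.rank_b))
    return kept


def _best_chain(
    points: Sequence[AnchorPair],
    orientation: str,
    max_gap: int,
    match_score: float,
    gap_penalty: float,
) -> tuple[float, list[int]]:
    """Best-scoring chain among ``points`` for one orientation.

    Returns (score, indices into points).  O(n^2) DP; points must be sorted
    by (rank_a, rank_b).
    """
    n = len(points)
    sign = 1 if orientation == "plus" else -1
    best = [match_score] * n
    parent = [-1] * n
    for i in range(n):
        ra_i, rb_i = points[i].rank_a, sign * points[i].rank_b
        for j in range(i):
            ra_j, rb_j = points[j].rank_a, sign * points[j].rank_b
            dx, dy = ra_i - ra_j, rb_i - rb_j
            if dx <= 0 or dy <= 0 or dx > max_gap or dy > max_gap:
                continue
            cand = best[j] + match_score + gap_penalty * ((dx - 1) + (dy - 1))
            if cand > best[i]:
                best[i], parent[i] = cand, j
    if n == 0:
        return float("-inf"), []
    end = max(range(n), key=lambda i: (best[i], -points[i].rank_a))
    chain: list[int] = []
    i = end
    while i != -1:
        chain.append(i)
        i = parent[i]
    chain.reverse()
    return best[end], chain


def _chain_score(
    chain: Sequence[AnchorPair], match_score: float, gap_penalty: float
) -> float:
    gaps = 0
    for prev, cur in zip(chain, chain[1:]):
        gaps += abs(cur.rank_a - prev.rank_a) - 1
        gaps += abs(cur.rank_b - prev.rank_b) - 1
    return match_score * len(chain) + gap_penalty * gaps


def detect_blocks(
    table_a: GenomeTable,
    table_b: GenomeTable,
    hits: Iterable[HomologyHit],
    min_anchors: int = 5,
    max_gap: int = 25,
    match_score: float = 50.0,
    gap_penalty: float = -1.0,
) -> list[CollinearBlock]:
    """Detect collinear blocks between two genomes (or within one).

    Hits should already be filtered (self-hits removed, E-value/top-N
    thresholds applied).  For an intra-genome scan pass the same table twice;
    match points are then canonicalised to one triangle so the trivial
    self-diagonal and mirror-image duplicates never form blocks, and points
    within ``max_gap`` ranks of the same-chromosome diagonal are excluded
    from chaining (the standard self-comparison convention: that band holds
    tandem/proximal pairs and a block there would overlap itself).
    """
    intra = table_a.species_id == table_b.species_id
    by_chrom_pair: dict[tuple[str, str], dict[tuple[str, str], AnchorPair]] = {}
    for hit in hits:
        if hit.query not in table_a or hit.subject not in table_b:
            warnings.warn(
                f"hit {hit.query}->{hit.subject} references a gene absent from "
                "the genome tables; skipped"
            )
            continue
        if intra and hit.query == hit.subject:
            continue
        la, lb = table_a[hit.query], table_b[hit.subject]
        gene_a, gene_b = hit.query, hit.subject
        ca, cb = la.chromosome, lb.chromosome
        ra, rb = la.rank, lb.rank
        if intra and ((ca, ra) > (cb, rb)):
            gene_a, gene_b, ca, cb, ra, rb = gene_b, gene_a, cb, ca, rb, ra
        if intra and ca == cb and rb - ra <= max_gap:
            continue  # near-diagonal band of a self-comparison
        point = AnchorPair(gene_a, gene_b, ra, rb, hit.e_value)
        bucket = by_chrom_pair.setdefault((ca, cb), {})
        key = (gene_a, gene_b)
        if key not in bucket or point.e_value < bucket[key].e_value:
            bucket[key] = point

    blocks: list[CollinearBlock] = []
    for (ca, cb) in sorted(by_chrom_pair):
        points = sorted(
            by_chrom_pair[(ca, cb)].values(), key=lambda p: (p.rank_a, p.rank_b)
        )
        points = _collapse_tandem(points, "a")
        points = _collapse_tandem(points, "b")
        while True:
            candidates: list[tuple[float, int, str, list[int]]] = []
            for orient_idx, orientation in enumerate(("plus", "minus")):
                score, chain = _best_chain(
                    points, orientation, max_gap, match_score, gap_penalty
                )
                if len(chain) >= min_anchors:
                    first = points[chain[0]].rank_a
                    candidates.append((score, -orient_idx, orientation, chain))
            if not candidates:
                break
            score, _, orientation, chain = max(
                candidates, key=lambda c: (c[0], c[1], -points[c[3][0]].rank_a)
            )
            anchors = tuple(points[i] for i in chain)
            blocks.append(CollinearBlock(ca, cb, orientation, anchors, score))
            chosen = set(chain)
            points = [p for i, p in enumerate(points) if i not in chosen]
    blocks.sort(key=lambda b: (-b.score, b.chrom_a, b.chrom_b, b.anchors[0].rank_a))
    return blocks


def anchor_pair_set(blocks: Iterable[CollinearBlock]) -> set[frozenset[str]]:
    """The set of unordered anchor gene pairs across blocks."""
    pairs: set[frozenset[str]] = set()
    for block in blocks:
        for a in block.anchors:
            pairs.add(frozenset((a.gene_a, a.gene_b)))
    return pairs


def write_collinearity(blocks: Sequence[CollinearBlock], path: str | Path) -> None:
    """Write blocks in an MCScanX-style collinearity text format."""
    with open(path, "w") as fh:
        fh.write(f"## Collinear blocks: {len(blocks)}\n")
        for k, block in enumerate(blocks):
            fh.write(
                f"## Alignment {k}: score={block.score:g} e_value=NA "
                f"N={len(block.anchors)} {block.chrom_a}&{block.chrom_b} "
                f"{block.orientation}\n"
            )
            for i, a in enumerate(block.anchors):
                fh.write(f"{k}-{i}:\t{a.gene_a}\t{a.gene_b}\t{a.e_value!r}\n")


def read_collinearity(
    path: str | Path, table_a: GenomeTable, table_b: GenomeTable
) -> list[CollinearBlock]:
    """Read blocks written by :func:`write_collinearity` (ranks re-looked-up)."""
    blocks: list[CollinearBlock] = []
    header: tuple[str, str, str, float] | None = None
    anchors: list[AnchorPair] = []

    def flush() -> None:
        nonlocal header, anchors
        if header is not None:
            ca, cb, orientation, score = header
            blocks.append(CollinearBlock(ca, cb, orientation, tuple(anchors), score))
        header, anchors = None, []

    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("## Alignment"):
                flush()
                parts = line.split()
                score = float(parts[3].split("=", 1)[1])
                ca, cb = parts[6].split("&", 1)
                header = (ca, cb, parts[7], score)
            elif line.startswith("##") or not line.strip():
                continue
            else:
                fields = line.split("\t")
                gene_a, gene_b, e_value = fields[1], fields[2], float(fields[3])
                anchors.append(
                    AnchorPair(
                        gene_a,
                        gene_b,
                        table_a[gene_a].rank,
                        table_b[gene_b].rank,
                        e_value,
                    )
                )
    flush()
    return blocks
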