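"""Gene-conversion detection from paralog-ortholog quartets.

A quartet pairs two paralogs (P1, P2) of the focal species with their
respective orthologs (O1, O2) in an outgroup that diverged *after* the
duplication.  Without conversion, the paralogs split before the speciation,
so Ks(P1,P2) exceeds the paralog-ortholog distances.  Whole-gene conversion
overwrites one paralog with the other after speciation, leaving

    Ks(P1,P2) < min(Ks(P1,O1), Ks(P2,O2)).

Support for this point criterion is assessed by resampling codon columns
with replacement (the same column indices across all pairwise comparisons,
taken from one joint quartet alignment) and recomputing the criterion;
``converted`` requires the point criterion plus bootstrap support of at
least ``support_min``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import codon_evol
from .codon_evol import (
    CodonAlignment,
    align_proteins,
    backtranslate,
    column_stats,
    kaks_from_stats,
    translate_cds,
)
from .dup_classifier import DuplicatePair


@dataclass(frozen=True)
class Quartet:
    paralog_1: str
    paralog_2: str
    ortholog_1: str
    ortholog_2: str

    @property
    def quartet_id(self) -> str:
        return f"{self.paralog_1}|{self.paralog_2}|{self.ortholog_1}|{self.ortholog_2}"

    def genes(self) -> tuple[str, str, str, str]:
        return (self.paralog_1, self.paralog_2, self.ortholog_1, self.ortholog_2)


@dataclass(frozen=True)
class ConversionEvent:
    quartet_id: str
    ks_paralog: float | None
    ks_out_1: float | None
    ks_out_2: float | None
    bootstrap_support: float | None
    converted: bool
    evaluable: bool
    status: str = "ok"
    mode: str | None = None


def find_quartets(
    focal_pairs: Iterable[DuplicatePair], ortholog_map: Mapping[str, str]
) -> tuple[list[Quartet], int]:
    """Build quartets for pairs whose both genes have a mapped ortholog.

    Returns (quartets, n_skipped).  Quartets sharing all four genes are
    collapsed to one.
    """
    quartets: list[Quartet] = []
    seen: set[tuple[str, str, str, str]] = set()
    skipped = 0
    for pair in focal_pairs:
        o1 = ortholog_map.get(pair.gene_a)
        o2 = ortholog_map.get(pair.gene_b)
        if o1 is None or o2 is None:
            skipped += 1
            continue
        genes = (pair.gene_a, pair.gene_b, o1, o2)
        if len(set(genes)) != 4:
            skipped += 1
            continue
        if genes in seen:
            continue
        seen.add(genes)
        quartets.append(Quartet(*genes))
    return quartets, skipped


@dataclass(frozen=True)
class QuartetAlignment:
    """A joint 4-row codon alignment with shared column indexing."""

    quartet: Quartet
    rows: tuple[str, str, str, str]  # gapped CDS of P1, P2, O1, O2

    @property
    def n_codons(self) -> int:
        return len(self.rows[0]) // 3

    def codon_row(self, index: int) -> list[str]:
        row = self.rows[index]
        return [row[i:i + 3] for i in range(0, len(row), 3)]


def _pairwise_against_reference(ref_prot: str, other_prot: str) -> tuple[list[str], dict[int, list[str]]]:
    """Align ``other`` to the reference; express it in reference coordinates.

    Returns (match, insertions): ``match[i]`` is the other sequence's residue
    aligned to reference residue i (or "-"); ``insertions[i]`` lists other
    residues falling immediately before reference residue i.
    """
    a, b = align_proteins(ref_prot, other_prot)
    match: list[str] = []
    insertions: dict[int, list[str]] = {}
    ref_pos = 0
    for ca, cb in zip(a, b):
        if ca == "-":
            insertions.setdefault(ref_pos, []).append(cb)
        else:
            match.append(cb)
            ref_pos += 1
    return match, insertions


def build_quartet_alignment(
    quartet: Quartet, cds: Mapping[str, str]
) -> QuartetAlignment:
    """Joint codon alignment of the four quartet genes.

    The three non-reference proteins are each aligned pairwise to P1 and
    merged on P1 coordinates; insertions relative to P1 become columns where
    the other two sequences are gapped (ordered P2, then O1, then O2).
    The merged protein alignment is then backtranslated per sequence.
    """
    genes = quartet.genes()
    prots = {g: translate_cds(cds[g], g) for g in genes}
    ref = genes[0]
    others = genes[1:]
    aligned = {g: _pairwise_against_reference(prots[ref], prots[g]) for g in others}

    ref_len = len(prots[ref])
    msa: dict[str, list[str]] = {g: [] for g in genes}
    for i in range(ref_len + 1):
        for g in others:
            for residue in aligned[g][1].get(i, []):
                msa[ref].append("-")
                for h in others:
                    msa[h].append(residue if h == g else "-")
        if i < ref_len:
            msa[ref].append(prots[ref][i])
            for g in others:
                msa[g].append(aligned[g][0][i])

    rows = []
    for g in genes:
        gapped_prot = "".join(msa[g])
        codon_aln = backtranslate(
            (gapped_prot, gapped_prot), cds[g], cds[g], pair_id=g, gene_a=g, gene_b=g
        )
        rows.append(codon_aln.cds_a)
    return QuartetAlignment(quartet, tuple(rows))


_PAIRS = ((0, 1), (0, 2), (1, 3))  # (P1,P2), (P1,O1), (P2,O2)


def _pair_column_arrays(
    qaln: QuartetAlignment, i: int, j: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-MSA-column NG86 stats for one pair (zeros at unusable columns)."""
    codons_i = qaln.codon_row(i)
    codons_j = qaln.codon_row(j)
    n = len(codons_i)
    stats = np.zeros((n, 8))
    usable = np.zeros(n, dtype=bool)
    for c, (ca, cb) in enumerate(zip(codons_i, codons_j)):
        if "-" in ca or "-" in cb:
            continue
        if not (set(ca) <= set(codon_evol.BASES) and set(cb) <= set(codon_evol.BASES)):
            continue
        if ca in codon_evol.STOP_CODONS or cb in codon_evol.STOP_CODONS:
            continue
        usable[c] = True
        stats[c] = column_stats([(ca, cb)])[0]
    return stats, usable


def _vector_jc(p: np.ndarray) -> np.ndarray:
    """Vectorised Jukes-Cantor correction; NaN where saturated."""
    out = np.full_like(p, np.nan)
    ok = (p >= 0) & (p < 0.75)
    out[ok] = -0.75 * np.log(1.0 - (4.0 / 3.0) * p[ok])
    return out


def detect_conversion(
    qaln: QuartetAlignment,
    n_bootstrap: int = 1000,
    support_min: float = 0.95,
    seed: int | None = None,
    ks_max: float = 5.0,
    mode: str | None = None,
) -> ConversionEvent:
    """Evaluate the conversion criterion on one quartet with bootstrap support.

    The point criterion Ks(P1,P2) < min(Ks(P1,O1), Ks(P2,O2)) is recomputed
    on ``n_bootstrap`` resamples of the joint alignment's codon columns
    (sampled with replacement; identical indices for all three pairwise
    comparisons).  Replicates with an undefined Ks fail the criterion.
    """
    arrays = [_pair_column_arrays(qaln, i, j) for i, j in _PAIRS]
    point_ks: list[float | None] = []
    for (stats, usable), (i, j) in zip(arrays, _PAIRS):
        if not usable.any():
            return ConversionEvent(
                qaln.quartet.quartet_id, None, None, None, None, False, False,
                status="no usable columns", mode=mode,
            )
        result = kaks_from_stats(stats[usable], f"{i}-{j}", ks_max=ks_max)
        point_ks.append(None if (result.ks is None or result.excluded) else result.ks)
    ks_p, ks_o1, ks_o2 = point_ks
    if ks_p is None or ks_o1 is None or ks_o2 is None:
        return ConversionEvent(
            qaln.quartet.quartet_id, ks_p, ks_o1, ks_o2, None, False, False,
            status="saturated", mode=mode,
        )

    n_cols = qaln.n_codons
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n_cols, size=(n_bootstrap, n_cols))
    boot_ks = []
    for stats, _usable in arrays:
        s = stats[:, 0][idx].sum(axis=1)
        sd = stats[:, 2][idx].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_s = np.where(s > 0, sd / np.maximum(s, 1e-300), np.nan)
        boot_ks.append(_vector_jc(p_s))
    b_p, b_o1, b_o2 = boot_ks
    with np.errstate(invalid="ignore"):
        ok = np.isfinite(b_p) & np.isfinite(b_o1) & np.isfinite(b_o2)
        criterion = ok & (b_p < np.minimum(b_o1, b_o2))
    support = float(criterion.sum()) / n_bootstrap
    point = ks_p < min(ks_o1, ks_o2)
    converted = bool(point and support >= support_min)
    return ConversionEvent(
        qaln.quartet.quartet_id, ks_p, ks_o1, ks_o2, support, converted, True,
        mode=mode,
    )


def conversion_rates_by_mode(
    events: Iterable[ConversionEvent],
    pairs_by_mode: Mapping[str, int] | None = None,
) -> dict[str, tuple[int, int, float | None]]:
    """Per-mode (n_converted, n_evaluable, rate over evaluable quartets).

    ``pairs_by_mode`` optionally supplies total pair counts so that modes
    with zero evaluable quartets still appear (rate None).
    """
    out: dict[str, tuple[int, int, float | None]] = {}
    grouped: dict[str, list[ConversionEvent]] = {}
    for event in events:
        grouped.setdefault(event.mode or "all", []).append(event)
    modes = set(grouped)
    if pairs_by_mode is not None:
        modes |= set(pairs_by_mode)
    for mode in sorted(modes):
        evaluable = [e for e in grouped.get(mode, []) if e.evaluable]
        n_conv = sum(1 for e in evaluable if e.converted)
        n_eval = len(evaluable)
        rate = n_conv / n_eval if n_eval else None
        out[mode] = (n_conv, n_eval, rate)
    return out
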