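"""Protein-guided codon alignment and Ka/Ks estimation.

Two coding sequences are compared by (1) globally aligning their protein
translations (BLOSUM62, affine gaps), (2) backtranslating the protein
alignment into a codon alignment, and (3) counting synonymous and
nonsynonymous sites and differences with the Nei-Gojobori (NG86) method.

NG86 counts, for each codon, the fraction of the three possible changes at
each position that are synonymous (changes creating a stop codon are
excluded from the denominator), and counts differences between codons by
averaging over all minimal substitution pathways with equal weights,
excluding pathways that pass through stop codons.  Proportions are
distance-corrected with the Jukes-Cantor formula

    d = -(3/4) * ln(1 - (4/3) * p),

which is undefined (saturated) at p >= 3/4.  Pairs with Ks above ``ks_max``
(default 5, where synonymous sites saturate) are flagged ``excluded``.

A secondary Ks correction, ``method="NG86-TN93"``, replaces Jukes-Cantor
with the Tamura-Nei 1993 distance computed from the transition /
transversion partition of the pathway-averaged difference counts and the
observed base composition of the compared sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data.CodonTable import unambiguous_dna_by_id

_CODON_TABLE = unambiguous_dna_by_id[1]  # universal code
BASES = "ACGT"
AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")

CODON_TO_AA: dict[str, str] = dict(_CODON_TABLE.forward_table)
for _stop in _CODON_TABLE.stop_codons:
    CODON_TO_AA[_stop] = "*"
STOP_CODONS = frozenset(_CODON_TABLE.stop_codons)
SENSE_CODONS = tuple(sorted(c for c in CODON_TO_AA if c not in STOP_CODONS))

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


def is_transition(base_a: str, base_b: str) -> bool:
    return (base_a in _PURINES and base_b in _PURINES) or (
        base_a in _PYRIMIDINES and base_b in _PYRIMIDINES
    )


def synonymous_neighbors(codon: str) -> list[str]:
    """Sense codons one substitution away encoding the same amino acid."""
    aa = CODON_TO_AA[codon]
    out = []
    for pos in range(3):
        for base in BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1:]
            if alt not in STOP_CODONS and CODON_TO_AA[alt] == aa:
                out.append(alt)
    return out


@lru_cache(maxsize=None)
def codon_sites(codon: str) -> tuple[float, float]:
    """NG86 (synonymous, nonsynonymous) site counts for one sense codon.

    Per position, the synonymous fraction is computed over the non-stop
    alternative codons; each position contributes one site in total, so
    S + N = 3 exactly.
    """
    if codon in STOP_CODONS or codon not in CODON_TO_AA:
        raise ValueError(f"not a sense codon: {codon}")
    aa = CODON_TO_AA[codon]
    syn = 0.0
    for pos in range(3):
        n_valid = n_syn = 0
        for base in BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1:]
            if alt in STOP_CODONS:
                continue
            n_valid += 1
            if CODON_TO_AA[alt] == aa:
                n_syn += 1
        if n_valid:
            syn += n_syn / n_valid
    return syn, 3.0 - syn


@lru_cache(maxsize=None)
def codon_differences(codon_a: str, codon_b: str) -> tuple[float, float, float, float]:
    """Pathway-averaged difference counts between two sense codons.

    Returns (syn, nonsyn, syn_transitions, nonsyn_transitions); syn + nonsyn
    equals the number of differing positions.  All orderings of the
    differing positions are enumerated; pathways whose intermediate codons
    are stops are excluded (if every pathway is excluded, all are used).
    """
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0, 0.0, 0.0

    def walk(order: tuple[int, ...]) -> tuple[float, float, float, float] | None:
        cur = codon_a
        syn = nonsyn = syn_ts = nonsyn_ts = 0.0
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                return None
            ts = is_transition(cur[pos], nxt[pos])
            if CODON_TO_AA[cur] == CODON_TO_AA[nxt]:
                syn += 1
                syn_ts += ts
            else:
                nonsyn += 1
                nonsyn_ts += ts
            cur = nxt
        return syn, nonsyn, syn_ts, nonsyn_ts

    results = [r for r in (walk(o) for o in permutations(diff_pos)) if r is not None]
    if not results:
        # every pathway crosses a stop codon: fall back to unrestricted paths
        def walk_any(order: tuple[int, ...]) -> tuple[float, float, float, float]:
            cur = codon_a
            syn = nonsyn = syn_ts = nonsyn_ts = 0.0
            for pos in order:
                nxt = cur[:pos] + codon_b[pos] + cur[pos + 1:]
                ts = is_transition(cur[pos], nxt[pos])
                same = CODON_TO_AA.get(cur, "*") == CODON_TO_AA.get(nxt, "*")
                if same:
                    syn += 1
                    syn_ts += ts
                else:
                    nonsyn += 1
                    nonsyn_ts += ts
                cur = nxt
            return syn, nonsyn, syn_ts, nonsyn_ts

        results = [walk_any(o) for o in permutations(diff_pos)]
    arr = np.asarray(results, dtype=float)
    return tuple(arr.mean(axis=0))  # type: ignore[return-value]


def translate_cds(cds: str, gene_id: str = "<cds>") -> str:
    """Translate a CDS, trimming one trailing stop codon if present."""
    if len(cds) % 3 != 0:
        raise ValueError(f"{gene_id}: CDS length {len(cds)} is not a multiple of 3")
    codons = [cds[i:i + 3].upper() for i in range(0, len(cds), 3)]
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    aas = []
    for i, codon in enumerate(codons):
        aa = CODON_TO_AA.get(codon)
        if aa == "*":
            raise ValueError(f"{gene_id}: internal stop codon at codon {i + 1}")
        aas.append(aa if aa is not None else "X")
    return "".join(aas)


def align_proteins(
    seq_a: str,
    seq_b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = -10.0,
    gap_extend: float = -0.5,
) -> tuple[str, str]:
    """Global pairwise protein alignment with affine gaps.

    A gap of length L scores ``gap_open + (L - 1) * gap_extend``.  The
    highest-scoring alignment is returned; among co-optimal alignments the
    choice is deterministic for fixed inputs.
    """
    for name, seq in (("first", seq_a), ("second", seq_b)):
        if not seq:
            raise ValueError(f"{name} protein sequence is empty")
        bad = set(seq.upper()) - AA_ALPHABET
        if bad:
            raise ValueError(f"illegal residue(s) in {name} sequence: {sorted(bad)}")
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    alignment = aligner.align(seq_a.upper(), seq_b.upper())[0]
    return str(alignment[0]), str(alignment[1])


@dataclass(frozen=True)
class CodonAlignment:
    """A pairwise codon alignment: two gapped CDS strings of equal length."""

    pair_id: str
    cds_a: str
    cds_b: str

    def __post_init__(self) -> None:
        if len(self.cds_a) != len(self.cds_b):
            raise ValueError("codon alignment rows differ in length")
        if len(self.cds_a) % 3 != 0:
            raise ValueError("codon alignment length is not a multiple of 3")

    @property
    def n_codons(self) -> int:
        return len(self.cds_a) // 3

    def columns(self) -> list[tuple[str, str]]:
        return [
            (self.cds_a[i:i + 3], self.cds_b[i:i + 3])
            for i in range(0, len(self.cds_a), 3)
        ]

    def ungapped_columns(self) -> list[tuple[str, str]]:
        """Columns usable for counting: no gaps, unambiguous, sense codons."""
        usable = []
        for ca, cb in self.columns():
            if "-" in ca or "-" in cb:
                continue
            if not (set(ca) <= set(BASES) and set(cb) <= set(BASES)):
                continue
            if ca in STOP_CODONS or cb in STOP_CODONS:
                continue
            usable.append((ca, cb))
        return usable


def backtranslate(
    protein_alignment: tuple[str, str],
    cds_a: str,
    cds_b: str,
    pair_id: str = "pair",
    gene_a: str = "gene_a",
    gene_b: str = "gene_b",
) -> CodonAlignment:
    """Thread two CDS through their protein alignment (PAL2NAL-style)."""
    rows = []
    for aligned, cds, gene in ((protein_alignment[0], cds_a, gene_a),
                               (protein_alignment[1], cds_b, gene_b)):
        cds = cds.upper()
        protein = aligned.replace("-", "")
        expected = translate_cds(cds, gene)
        if expected != protein:
            raise ValueError(
                f"{gene}: CDS does not translate to the aligned protein "
                f"(CDS gives {len(expected)} aa, alignment has {len(protein)})"
            )
        codons = iter(cds[i:i + 3] for i in range(0, 3 * len(protein), 3))
        rows.append("".join("---" if aa == "-" else next(codons) for aa in aligned))
    return CodonAlignment(pair_id, rows[0], rows[1])


@dataclass(frozen=True)
class KaKsResult:
    pair_id: str
    ka: float | None
    ks: float | None
    ratio: float | None
    sites_syn: float
    sites_nonsyn: float
    diffs_syn: float
    diffs_nonsyn: float
    method: str
    excluded: bool = False
    n_codons: int = 0


def jukes_cantor(p: float) -> float | None:
    """JC69 distance correction; None when saturated (p >= 3/4)."""
    if p < 0:
        raise ValueError("proportion must be non-negative")
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p) + 0.0  # +0.0 avoids -0.0


def tamura_nei(
    p_ag: float, p_ct: float, q: float, base_freqs: dict[str, float]
) -> float | None:
    """TN93 distance from purine/pyrimidine transition and transversion
    proportions; None when any logarithm argument is non-positive."""
    gA, gC, gG, gT = (base_freqs.get(b, 0.0) for b in "ACGT")
    gR, gY = gA + gG, gC + gT
    if min(gA, gC, gG, gT) <= 0:
        return None
    k1 = 2.0 * gA * gG / gR
    k2 = 2.0 * gC * gT / gY
    k3 = 2.0 * (gR * gY - gA * gG * gY / gR - gC * gT * gR / gY)
    w1 = 1.0 - p_ag / k1 - q / (2.0 * gR)
    w2 = 1.0 - p_ct / k2 - q / (2.0 * gY)
    w3 = 1.0 - q / (2.0 * gR * gY)
    if min(w1, w2, w3) <= 0:
        return None
    return -k1 * math.log(w1) - k2 * math.log(w2) - k3 * math.log(w3)


def column_stats(columns: list[tuple[str, str]]) -> np.ndarray:
    """Per-column NG86 statistics as an (n, 8) array.

    Columns of the array: S, N (pair-averaged site counts), Sd, Nd
    (pathway-averaged difference counts), Sd_ts, Nd_ts (transition parts of
    Sd/Nd), and the pathway-averaged purine-transition parts of Sd and Nd.
    Precomputing this per column lets bootstrap resampling reduce to sums.
    """
    out = np.zeros((len(columns), 8))
    for i, (ca, cb) in enumerate(columns):
        sa, na = codon_sites(ca)
        sb, nb = codon_sites(cb)
        sd, nd, sd_ts, nd_ts = codon_differences(ca, cb)
        # purine-vs-pyrimidine split of the transition counts, needed for TN93
        sd_ag, nd_ag = _purine_transition_split(ca, cb)
        out[i] = (
            (sa + sb) / 2.0, (na + nb) / 2.0, sd, nd, sd_ts, nd_ts, sd_ag, nd_ag
        )
    return out


@lru_cache(maxsize=None)
def _purine_transition_split(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Pathway-averaged counts of A<->G transition differences (syn, nonsyn)."""
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0
    results = []
    for order in permutations(diff_pos):
        cur = codon_a
        syn_ag = nonsyn_ag = 0.0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                blocked = True
                break
            if {cur[pos], nxt[pos]} == {"A", "G"}:
                if CODON_TO_AA[cur] == CODON_TO_AA[nxt]:
                    syn_ag += 1
                else:
                    nonsyn_ag += 1
            cur = nxt
        if not blocked:
            results.append((syn_ag, nonsyn_ag))
    if not results:
        return 0.0, 0.0
    arr = np.asarray(results, dtype=float)
    return float(arr[:, 0].mean()), float(arr[:, 1].mean())


def kaks_from_stats(
    stats: np.ndarray,
    pair_id: str,
    method: str = "NG86",
    ks_max: float = 5.0,
    base_freqs: dict[str, float] | None = None,
) -> KaKsResult:
    """Assemble a KaKsResult from per-column statistics (see column_stats)."""
    if stats.shape[0] == 0:
        raise ValueError(f"{pair_id}: no usable codon columns")
    S, N, Sd, Nd, Sd_ts, Nd_ts, Sd_ag, Nd_ag = stats.sum(axis=0)
    p_s = Sd / S if S > 0 else 0.0
    p_n = Nd / N if N > 0 else 0.0
    if method == "NG86":
        ks = jukes_cantor(p_s) if S > 0 else None
        ka = jukes_cantor(p_n) if N > 0 else None
    elif method == "NG86-TN93":
        if base_freqs is None:
            raise ValueError("NG86-TN93 requires base frequencies")
        ks = (
            tamura_nei(Sd_ag / S, (Sd_ts - Sd_ag) / S, (Sd - Sd_ts) / S, base_freqs)
            if S > 0 else None
        )
        ka = (
            tamura_nei(Nd_ag / N, (Nd_ts - Nd_ag) / N, (Nd - Nd_ts) / N, base_freqs)
            if N > 0 else None
        )
    else:
        raise ValueError(f"unknown method: {method}")
    ratio = (ka / ks) if (ka is not None and ks is not None and ks > 0) else None
    excluded = ks is not None and ks > ks_max
    return KaKsResult(
        pair_id=pair_id,
        ka=ka,
        ks=ks,
        ratio=ratio,
        sites_syn=float(S),
        sites_nonsyn=float(N),
        diffs_syn=float(Sd),
        diffs_nonsyn=float(Nd),
        method=method,
        excluded=excluded,
        n_codons=stats.shape[0],
    )


def estimate_kaks(
    codon_alignment: CodonAlignment, method: str = "NG86", ks_max: float = 5.0
) -> KaKsResult:
    """NG86 Ka/Ks for a pairwise codon alignment.

    Columns with gaps, ambiguous bases, or stop codons are skipped.  Ks is
    None when synonymous differences are saturated; results with
    Ks > ``ks_max`` carry ``excluded=True`` and should be dropped from
    downstream age distributions.
    """
    columns = codon_alignment.ungapped_columns()
    if not columns:
        raise ValueError(f"{codon_alignment.pair_id}: no usable codon columns")
    stats = column_stats(columns)
    base_freqs = None
    if method == "NG86-TN93":
        joined = "".join(ca + cb for ca, cb in columns)
        base_freqs = {b: joined.count(b) / len(joined) for b in BASES}
    return kaks_from_stats(
        stats, codon_alignment.pair_id, method=method, ks_max=ks_max,
        base_freqs=base_freqs,
    )


def kaks_for_cds_pair(
    gene_a: str,
    gene_b: str,
    cds_a: str,
    cds_b: str,
    method: str = "NG86",
    ks_max: float = 5.0,
) -> KaKsResult:
    """Convenience: align proteins, backtranslate, and estimate Ka/Ks."""
    prot_a = translate_cds(cds_a, gene_a)
    prot_b = translate_cds(cds_b, gene_b)
    aln = align_proteins(prot_a, prot_b)
    codon_aln = backtranslate(
        aln, cds_a, cds_b, pair_id=f"{gene_a}|{gene_b}", gene_a=gene_a, gene_b=gene_b
    )
    return estimate_kaks(codon_aln, method=method, ks_max=ks_max)
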