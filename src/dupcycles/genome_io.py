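"""Readers and writers for the standard files the pipeline touches.

The central coordinate system is *gene rank*: within each chromosome, genes
are numbered 0..n-1 in order of ascending start coordinate.  All adjacency
rules used by the duplicate-pair classifier (tandem, proximal) are expressed
in ranks, never in base pairs.

File dialects
-------------
* Gene positions: 4 tab-separated columns ``chrom  gene  start  end``
  (the MCScanX-style ".gff", not GFF3), no header.
* Homology hits: 12-column BLAST tabular (``-outfmt 6`` / "m8").
* Orthogroups: header row of species names; each data row is an orthogroup
  id followed by one comma-separated gene list per species.
* Expression: TSV with genes in rows and samples in columns.
* Duplicate pairs: 5 columns ``gene1  chr:rank  gene2  chr:rank  e_value``
  with one header line.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


@dataclass(frozen=True)
class GeneLocus:
    """A gene's position: 1-based inclusive bp coordinates plus its rank."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    rank: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )


class GenomeTable:
    """Ordered gene loci of one genome, indexed by gene id and by chromosome."""

    def __init__(self, species_id: str, loci: Mapping[str, GeneLocus]):
        self.species_id = species_id
        self.loci: dict[str, GeneLocus] = dict(loci)
        self._by_chrom: dict[str, list[str]] = {}
        for locus in sorted(self.loci.values(), key=lambda l: (l.chromosome, l.rank)):
            self._by_chrom.setdefault(locus.chromosome, []).append(locus.gene_id)
        for chrom, genes in self._by_chrom.items():
            ranks = sorted(self.loci[g].rank for g in genes)
            if ranks != list(range(len(genes))):
                raise ValueError(f"chromosome {chrom}: ranks are not 0..{len(genes)-1}")

    @classmethod
    def from_records(
        cls, species_id: str, records: Iterable[tuple[str, str, int, int]]
    ) -> "GenomeTable":
        """Build a table from (chrom, gene, start, end) rows, assigning ranks.

        Ranks are assigned per chromosome by ascending start, with ties
        broken by ascending end and then lexical gene id.
        """
        rows = list(records)
        seen: set[str] = set()
        for _, gene, _, _ in rows:
            if gene in seen:
                raise ValueError(f"duplicate gene id: {gene}")
            seen.add(gene)
        loci: dict[str, GeneLocus] = {}
        by_chrom: dict[str, list[tuple[str, str, int, int]]] = {}
        for chrom, gene, start, end in rows:
            by_chrom.setdefault(chrom, []).append((chrom, gene, start, end))
        for chrom, crows in by_chrom.items():
            crows.sort(key=lambda r: (r[2], r[3], r[1]))
            for rank, (_, gene, start, end) in enumerate(crows):
                loci[gene] = GeneLocus(gene, chrom, start, end, rank)
        return cls(species_id, loci)

    def chromosomes(self) -> list[str]:
        return sorted(self._by_chrom)

    def genes_on(self, chromosome: str) -> list[str]:
        """Gene ids on a chromosome in rank order."""
        return list(self._by_chrom.get(chromosome, []))

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.loci

    def __len__(self) -> int:
        return len(self.loci)

    def __getitem__(self, gene_id: str) -> GeneLocus:
        return self.loci[gene_id]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenomeTable):
            return NotImplemented
        return self.species_id == other.species_id and self.loci == other.loci


@dataclass(frozen=True)
class HomologyHit:
    """One directed query->subject similarity record (BLAST tabular row)."""

    query: str
    subject: str
    identity: float  # fraction in [0, 1]
    e_value: float
    bit_score: float

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValueError(f"negative E-value for {self.query}->{self.subject}")


class TpmMatrix:
    """A genes x samples matrix of TPM values backed by a pandas DataFrame."""

    def __init__(self, data: pd.DataFrame):
        if data.index.has_duplicates:
            raise ValueError("duplicate gene ids in TPM matrix")
        if data.columns.has_duplicates:
            raise ValueError("duplicate sample ids in TPM matrix")
        values = data.to_numpy(dtype=float)
        if values.size and np.nanmin(values) < 0:
            raise ValueError("negative TPM value in matrix")
        self.data = data.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def log10p(self) -> pd.DataFrame:
        """log10(TPM + 1), the transform used for expression correlations."""
        return np.log10(self.data + 1.0)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TpmMatrix):
            return NotImplemented
        return self.data.equals(other.data)


class OrthogroupTable:
    """Orthogroup membership: orthogroup id -> species -> gene list."""

    def __init__(self, groups: Mapping[str, Mapping[str, Sequence[str]]]):
        species: set[str] = set()
        for members in groups.values():
            species.update(members)
        self.species = sorted(species)
        self.groups: dict[str, dict[str, list[str]]] = {}
        seen: dict[str, str] = {}
        for og_id, members in groups.items():
            full = {sp: list(members.get(sp, [])) for sp in self.species}
            for sp, genes in full.items():
                for g in genes:
                    if g in seen:
                        raise ValueError(
                            f"gene {g} appears in orthogroups {seen[g]} and {og_id}"
                        )
                    seen[g] = og_id
            self.groups[og_id] = full
        self._og_of = seen

    def orthogroup_of(self, gene_id: str) -> str | None:
        return self._og_of.get(gene_id)

    def genes_of(self, og_id: str, species_id: str) -> list[str]:
        return list(self.groups[og_id].get(species_id, []))

    def __len__(self) -> int:
        return len(self.groups)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OrthogroupTable):
            return NotImplemented
        return self.groups == other.groups


@dataclass(frozen=True)
class PairRecord:
    """A row of the 5-column pair dialect (classifier output files)."""

    gene_a: str
    locus_a: str  # "chrom:rank"
    gene_b: str
    locus_b: str
    e_value: float


def read_gene_positions(path: str | Path, species_id: str) -> GenomeTable:
    """Read an MCScanX-style gene position file into a :class:`GenomeTable`."""
    rows: list[tuple[str, str, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected >=4 columns, got {len(fields)}")
            chrom, gene, start_s, end_s = fields[0], fields[1], fields[2], fields[3]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            rows.append((chrom, gene, start, end))
    return GenomeTable.from_records(species_id, rows)


def write_gene_positions(table: GenomeTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in table.chromosomes():
            for gene in table.genes_on(chrom):
                locus = table[gene]
                fh.write(f"{chrom}\t{gene}\t{locus.start}\t{locus.end}\n")


def select_longest_transcripts(
    records: Iterable[tuple[str, str, str]]
) -> dict[str, tuple[str, str]]:
    """Keep one CDS per gene: the longest, ties broken by lexical transcript id.

    ``records`` yields (gene_id, transcript_id, sequence).  Empty sequences
    are skipped with a warning.  Returns gene_id -> (transcript_id, sequence).
    """
    best: dict[str, tuple[str, str]] = {}
    for gene_id, transcript_id, seq in records:
        if not seq:
            warnings.warn(f"empty CDS for transcript {transcript_id}; skipped")
            continue
        kept = best.get(gene_id)
        if (
            kept is None
            or len(seq) > len(kept[1])
            or (len(seq) == len(kept[1]) and transcript_id < kept[0])
        ):
            best[gene_id] = (transcript_id, seq)
    return best


def read_blast_tab(path: str | Path) -> list[HomologyHit]:
    """Parse 12-column BLAST tabular output into hits (identity as fraction)."""
    hits: list[HomologyHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(f"{path}:{lineno}: expected 12 columns, got {len(fields)}")
            try:
                hits.append(
                    HomologyHit(
                        query=fields[0],
                        subject=fields[1],
                        identity=float(fields[2]) / 100.0,
                        e_value=float(fields[10]),
                        bit_score=float(fields[11]),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed hit line") from exc
    return hits


def write_blast_tab(hits: Iterable[HomologyHit], path: str | Path) -> None:
    """Write hits as 12-column BLAST tabular (alignment columns filled with 0)."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.query}\t{h.subject}\t{h.identity * 100.0:.2f}\t0\t0\t0\t0\t0\t0\t0"
                f"\t{h.e_value:.3g}\t{h.bit_score:.1f}\n"
            )


def read_tpm_matrix(path: str | Path) -> TpmMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return TpmMatrix(df)


def write_tpm_matrix(matrix: TpmMatrix, path: str | Path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="gene")


def read_orthogroups(path: str | Path) -> OrthogroupTable:
    """Read an Orthogroups.tsv-style table (comma-separated genes per species)."""
    groups: dict[str, dict[str, list[str]]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        species = header[1:]
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if not fields or not fields[0]:
                continue
            og_id = fields[0]
            cells = fields[1:] + [""] * (len(species) - len(fields) + 1)
            groups[og_id] = {
                sp: [g for g in cell.replace(", ", ",").split(",") if g]
                for sp, cell in zip(species, cells)
            }
    return OrthogroupTable(groups)


def write_orthogroups(table: OrthogroupTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("Orthogroup\t" + "\t".join(table.species) + "\n")
        for og_id in sorted(table.groups):
            cells = [", ".join(table.groups[og_id][sp]) for sp in table.species]
            fh.write(og_id + "\t" + "\t".join(cells) + "\n")


PAIR_HEADER = "gene1\tlocation1\tgene2\tlocation2\te_value"


def write_pairs(pairs: Iterable, genome: GenomeTable | None, path: str | Path) -> None:
    """Write duplicate pairs in the 5-column pair dialect.

    ``pairs`` may be classifier pairs (with gene_a/gene_b/e_value attributes)
    or :class:`PairRecord` instances.  When a genome table is given, the
    chrom:rank locations are looked up; otherwise pre-formatted locations on
    the records are used.
    """
    with open(path, "w") as fh:
        fh.write(PAIR_HEADER + "\n")
        for p in pairs:
            if isinstance(p, PairRecord):
                loc_a, loc_b = p.locus_a, p.locus_b
            elif genome is not None:
                la, lb = genome[p.gene_a], genome[p.gene_b]
                loc_a = f"{la.chromosome}:{la.rank}"
                loc_b = f"{lb.chromosome}:{lb.rank}"
            else:
                raise ValueError("a GenomeTable is required to format pair locations")
            fh.write(f"{p.gene_a}\t{loc_a}\t{p.gene_b}\t{loc_b}\t{p.e_value!r}\n")


def read_pairs(path: str | Path) -> list[PairRecord]:
    records: list[PairRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != PAIR_HEADER:
            raise ValueError(f"{path}: unexpected pair-file header: {header!r}")
        for lineno, line in enumerate(fh, 2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 5:
                raise ValueError(f"{path}:{lineno}: expected 5 columns")
            records.append(
                PairRecord(fields[0], fields[1], fields[2], fields[3], float(fields[4]))
            )
    return records


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file to an id -> sequence dict (ids must be unique)."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate FASTA id: {rec.id}")
        seqs[rec.id] = str(rec.seq)
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")
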