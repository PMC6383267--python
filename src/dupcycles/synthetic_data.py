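"""Synthetic genomes with planted duplication ground truth.

The generator builds an ancestral genome of random coding genes, applies
whole-genome duplications (each copying every surviving gene onto a
mirrored chromosome set and deleting copies at 1 - retention_rate), and
plants tandem, proximal, transposed, and dispersed single-gene duplications
with known pair identity, mode, and synonymous age.  It then fabricates the
inputs the pipeline consumes: an all-vs-all hit table, expression matrices
with pairs at planted correlations, orthogroup tables, and paralog/ortholog
quartets with and without gene conversion.

Sequence model
--------------
Ancestral CDS are drawn from the 24 codons of the six purely fourfold-
degenerate codon families (GTN, TCN, CCN, ACN, GCN, GGN).  Synonymous
divergence to a target Ks is simulated as a Poisson number of single-base
synonymous substitutions, each picking a random codon and one of its
synonymous neighbours (transitions weighted by ``ts_tv_ratio``).  Because
every synonymous site in this alphabet is a fourfold third position, the
process is a per-site 4-state Markov chain and the Jukes-Cantor-corrected
NG86 estimator is consistent for it; the transition bias introduces only a
small (few percent) downward bias at Ks near 1.  Nonsynonymous events are
added the same way at a target Ka (default 0.05 x Ks), avoiding stops.

All divergence of a planted pair is placed on the new copy's branch, so
creating a pair never perturbs the Ks of previously planted pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .codon_evol import (
    BASES,
    CODON_TO_AA,
    STOP_CODONS,
    codon_sites,
    is_transition,
    synonymous_neighbors,
)
from .gene_conversion import Quartet
from .genome_io import GenomeTable, HomologyHit, OrthogroupTable, TpmMatrix

# the six codon families whose third position is strictly fourfold degenerate
FOURFOLD_FAMILIES = ("GT", "TC", "CC", "AC", "GC", "GG")
FOURFOLD_CODONS = tuple(fam + b for fam in FOURFOLD_FAMILIES for b in BASES)


@dataclass(frozen=True)
class ExpressionParams:
    n_samples: int = 20
    rho_conserved: float = 0.9
    rho_diverged: float = 0.0
    fraction_diverged: float = 0.5

    def __post_init__(self) -> None:
        for rho in (self.rho_conserved, self.rho_diverged):
            if abs(rho) > 1:
                raise ValueError(f"invalid correlation {rho}")


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 42
    n_chromosomes: int = 4
    n_ancestral_genes: int = 2000
    wgd_events: tuple[tuple[float, float], ...] = ((0.3, 1.0),)  # (retention, Ks)
    n_tandem: int = 100
    n_proximal: int = 100
    n_transposed: int = 100
    n_dispersed: int = 100
    codon_length: int = 200
    ts_tv_ratio: float = 2.0
    ka_fraction: float = 0.05  # Ka target as a fraction of Ks
    single_ks_range: tuple[float, float] = (0.2, 1.2)
    spurious_hit_fraction: float = 0.05
    expression: ExpressionParams = field(default_factory=ExpressionParams)

    def __post_init__(self) -> None:
        ages = [age for _, age in self.wgd_events]
        if len(set(ages)) != len(ages):
            raise ValueError("WGD event Ks ages must be distinct")
        for retention, age in self.wgd_events:
            if not (0 < retention <= 1):
                raise ValueError(f"retention rate {retention} outside (0, 1]")
            if age <= 0:
                raise ValueError(f"WGD Ks age {age} must be positive")


@dataclass(frozen=True)
class TruthPair:
    gene_a: str  # parent / original copy
    gene_b: str  # new copy
    mode: str
    ks_age: float

    @property
    def key(self) -> frozenset[str]:
        return frozenset((self.gene_a, self.gene_b))


@dataclass
class TruthTable:
    pairs: list[TruthPair] = field(default_factory=list)

    def by_mode(self) -> dict[str, list[TruthPair]]:
        out: dict[str, list[TruthPair]] = {}
        for pair in self.pairs:
            out.setdefault(pair.mode, []).append(pair)
        return out

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)


@dataclass
class SimulatedGenome:
    genome: GenomeTable
    cds: dict[str, str]
    truth: TruthTable
    config: SimulationConfig


def random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """A random CDS over the fourfold-degenerate codon alphabet."""
    idx = rng.integers(0, len(FOURFOLD_CODONS), size=n_codons)
    return "".join(FOURFOLD_CODONS[i] for i in idx)


def _weighted_choice(rng: np.random.Generator, options: list[str], weights: list[float]) -> str:
    w = np.asarray(weights, dtype=float)
    return options[int(rng.choice(len(options), p=w / w.sum()))]


def evolve_sequence(
    seq: str,
    ks_branch: float,
    ka_branch: float,
    rng: np.random.Generator,
    ts_tv_ratio: float = 2.0,
) -> str:
    """Evolve a CDS by Poisson numbers of synonymous/nonsynonymous events.

    ``ks_branch`` and ``ka_branch`` are substitutions per synonymous /
    nonsynonymous site along this single branch.
    """
    codons = [seq[i:i + 3] for i in range(0, len(seq), 3)]
    n = len(codons)
    site_counts = np.array([codon_sites(c) for c in codons])
    s_sites, n_sites = site_counts[:, 0].sum(), site_counts[:, 1].sum()

    n_syn = rng.poisson(ks_branch * s_sites) if ks_branch > 0 else 0
    for _ in range(n_syn):
        for _attempt in range(100):
            i = int(rng.integers(0, n))
            neighbors = synonymous_neighbors(codons[i])
            if neighbors:
                weights = [
                    ts_tv_ratio if _single_change_is_transition(codons[i], alt) else 1.0
                    for alt in neighbors
                ]
                codons[i] = _weighted_choice(rng, neighbors, weights)
                break

    n_nonsyn = rng.poisson(ka_branch * n_sites) if ka_branch > 0 else 0
    for _ in range(n_nonsyn):
        for _attempt in range(100):
            i = int(rng.integers(0, n))
            alts = _nonsynonymous_neighbors(codons[i])
            if alts:
                weights = [
                    ts_tv_ratio if _single_change_is_transition(codons[i], alt) else 1.0
                    for alt in alts
                ]
                codons[i] = _weighted_choice(rng, alts, weights)
                break
    return "".join(codons)


def _single_change_is_transition(codon_a: str, codon_b: str) -> bool:
    for a, b in zip(codon_a, codon_b):
        if a != b:
            return is_transition(a, b)
    return False


def _nonsynonymous_neighbors(codon: str) -> list[str]:
    aa = CODON_TO_AA[codon]
    out = []
    for pos in range(3):
        for base in BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1:]
            if alt not in STOP_CODONS and CODON_TO_AA[alt] != aa:
                out.append(alt)
    return out


def evolve_copy(
    seq: str, ks_target: float, rng: np.random.Generator, config: SimulationConfig
) -> str:
    """A duplicate copy diverged from ``seq`` by the full pair distance."""
    return evolve_sequence(
        seq,
        ks_target,
        config.ka_fraction * ks_target,
        rng,
        ts_tv_ratio=config.ts_tv_ratio,
    )


def _chrom_root(chrom: str) -> str:
    return chrom.split("w", 1)[0]


def simulate_genome(
    config: SimulationConfig, species_id: str = "target"
) -> SimulatedGenome:
    """Generate a genome with planted WGD/TD/PD/TRD/DSD duplicate pairs."""
    rng = np.random.default_rng(config.seed)
    counter = 0

    def new_gene() -> str:
        nonlocal counter
        counter += 1
        return f"g{counter:06d}"

    chroms: dict[str, list[str]] = {}
    seqs: dict[str, str] = {}
    per_chrom = config.n_ancestral_genes // config.n_chromosomes
    extra = config.n_ancestral_genes - per_chrom * config.n_chromosomes
    for c in range(config.n_chromosomes):
        name = f"chr{c + 1}"
        count = per_chrom + (1 if c < extra else 0)
        genes = [new_gene() for _ in range(count)]
        chroms[name] = genes
        for g in genes:
            seqs[g] = random_cds(rng, config.codon_length)

    truth = TruthTable()

    # whole-genome duplications: mirror each chromosome, delete at 1-retention
    for event_idx, (retention, ks_age) in enumerate(config.wgd_events, start=1):
        for chrom in sorted(chroms):
            mirrored = f"{chrom}w{event_idx}"
            copies: list[str] = []
            for gene in chroms[chrom]:
                if rng.random() < retention:
                    copy = new_gene()
                    seqs[copy] = evolve_copy(seqs[gene], ks_age, rng, config)
                    copies.append(copy)
                    truth.pairs.append(TruthPair(gene, copy, "WGD", ks_age))
            if copies:
                chroms[mirrored] = copies

    wgd_parents = sorted({p.gene_a for p in truth.pairs if p.mode == "WGD"})
    paired_genes = {g for p in truth.pairs for g in (p.gene_a, p.gene_b)}
    unpaired = sorted(g for c in chroms.values() for g in c if g not in paired_genes)

    blocked: dict[str, set[int]] = {c: set() for c in chroms}
    insertions: dict[str, list[tuple[int, str]]] = {c: [] for c in chroms}
    chrom_names = sorted(chroms)
    used_sources: set[str] = set()

    def draw_single_ks() -> float:
        lo, hi = config.single_ks_range
        return float(rng.uniform(lo, hi))

    def place_local(mode: str, offset_low: int, offset_high: int) -> None:
        """Plant a tandem (offset 1) or proximal (offset 2..11) copy."""
        for _attempt in range(5000):
            chrom = chrom_names[int(rng.integers(0, len(chrom_names)))]
            genes = chroms[chrom]
            offset = int(rng.integers(offset_low, offset_high + 1))
            if len(genes) < offset + 2:
                continue
            i = int(rng.integers(0, len(genes) - offset))
            anchors = range(i, i + offset)
            if any(a in blocked[chrom] for a in anchors):
                continue
            source = genes[i]
            if source in used_sources:
                continue
            blocked[chrom].update(anchors)
            used_sources.add(source)
            copy = new_gene()
            ks = draw_single_ks()
            seqs[copy] = evolve_copy(seqs[source], ks, rng, config)
            insertions[chrom].append((i + offset - 1, copy))
            truth.pairs.append(TruthPair(source, copy, mode, ks))
            return
        raise ValueError(f"could not place a {mode} event: genome capacity exceeded")

    # membership lookup is hot; precompute gene -> chromosome
    gene_chrom = {g: c for c, genes in chroms.items() for g in genes}

    def place_remote(mode: str, sources: Sequence[str]) -> None:
        """Plant a transposed or dispersed copy on an unrelated chromosome."""
        for _attempt in range(5000):
            source = sources[int(rng.integers(0, len(sources)))]
            if source in used_sources:
                continue
            source_chrom = gene_chrom[source]
            candidates = [
                c for c in chrom_names if _chrom_root(c) != _chrom_root(source_chrom)
            ]
            if not candidates:
                continue
            target = candidates[int(rng.integers(0, len(candidates)))]
            anchor = int(rng.integers(0, len(chroms[target])))
            if anchor in blocked[target]:
                continue
            blocked[target].add(anchor)
            used_sources.add(source)
            copy = new_gene()
            ks = draw_single_ks()
            seqs[copy] = evolve_copy(seqs[source], ks, rng, config)
            insertions[target].append((anchor, copy))
            truth.pairs.append(TruthPair(source, copy, mode, ks))
            return
        raise ValueError(f"could not place a {mode} event: genome capacity exceeded")

    for _ in range(config.n_tandem):
        place_local("TD", 1, 1)
    for _ in range(config.n_proximal):
        place_local("PD", 2, 11)
    if config.n_transposed and not wgd_parents:
        raise ValueError("transposed events need at least one WGD-retained parent")
    for _ in range(config.n_transposed):
        place_remote("TRD", wgd_parents)
    if config.n_dispersed and not unpaired:
        raise ValueError("dispersed events need genes without WGD partners")
    for _ in range(config.n_dispersed):
        place_remote("DSD", unpaired)

    for chrom, ins in insertions.items():
        for anchor, gene in sorted(ins, key=lambda x: -x[0]):
            chroms[chrom].insert(anchor + 1, gene)

    records = []
    gene_len = 3 * config.codon_length
    for chrom in sorted(chroms):
        for idx, gene in enumerate(chroms[chrom]):
            start = (idx + 1) * (gene_len + 400)
            records.append((chrom, gene, start, start + gene_len - 1))
    genome = GenomeTable.from_records(species_id, records)
    return SimulatedGenome(genome, seqs, truth, config)


def fabricate_hits(
    genome: GenomeTable,
    truth: TruthTable,
    cds: Mapping[str, str],
    spurious_fraction: float = 0.05,
    seed: int | None = None,
) -> list[HomologyHit]:
    """Fabricate an all-vs-all hit table covering the planted homolog pairs.

    Every truth pair yields hits in both directions; the E-value is a
    deterministic decreasing function of ungapped sequence identity,
    ``E = 10 ** (-200 * identity + noise)`` (exponent clamped to [-300, 0]).
    A Binomial(n_truth_hits, spurious_fraction) number of spurious hits
    between random non-truth pairs is added.
    """
    rng = np.random.default_rng(seed)

    def identity(a: str, b: str) -> float:
        n = min(len(a), len(b))
        if n == 0:
            return 0.0
        return sum(1 for x, y in zip(a[:n], b[:n]) if x == y) / n

    def make_hit(q: str, s: str, ident: float, exponent: float) -> HomologyHit:
        exponent = float(np.clip(exponent, -300.0, 0.0))
        return HomologyHit(q, s, ident, 10.0 ** exponent, max(30.0, -2.0 * exponent))

    hits: list[HomologyHit] = []
    truth_keys = {p.key for p in truth}
    for pair in truth:
        ident = identity(cds[pair.gene_a], cds[pair.gene_b])
        exponent = -200.0 * ident + float(rng.normal(0.0, 2.0))
        hits.append(make_hit(pair.gene_a, pair.gene_b, ident, exponent))
        hits.append(make_hit(pair.gene_b, pair.gene_a, ident, exponent))

    genes = sorted(genome.loci)
    n_spurious = int(rng.binomial(len(hits), spurious_fraction)) if spurious_fraction else 0
    seen: set[tuple[str, str]] = set()
    added = 0
    while added < n_spurious:
        q = genes[int(rng.integers(0, len(genes)))]
        s = genes[int(rng.integers(0, len(genes)))]
        if q == s or (q, s) in seen or frozenset((q, s)) in truth_keys:
            continue
        seen.add((q, s))
        ident = identity(cds[q], cds[s])
        exponent = -200.0 * ident + float(rng.normal(0.0, 2.0))
        hits.append(make_hit(q, s, ident, exponent))
        added += 1
    return hits


def simulate_expression(
    truth: TruthTable,
    all_genes: Sequence[str],
    params: ExpressionParams,
    seed: int | None = None,
    log_mean: float = 1.0,
    log_sd: float = 0.6,
) -> tuple[TpmMatrix, dict[frozenset[str], float]]:
    """Expression matrix with duplicate pairs at planted correlations.

    Pair profiles are drawn from a bivariate normal in log10 space with
    correlation rho_conserved or rho_diverged (assigned per pair at
    ``fraction_diverged``); unpaired genes get independent profiles.  TPM is
    ``10**x - 1`` with x floored at 0.  Genes occurring in several pairs are
    planted for their first pair only.  Returns the matrix and the planted
    correlation per (planted) pair.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    m = params.n_samples
    profiles: dict[str, np.ndarray] = {}
    planted_rho: dict[frozenset[str], float] = {}
    for pair in truth:
        if pair.gene_a in profiles or pair.gene_b in profiles:
            continue
        rho = (
            params.rho_diverged
            if rng.random() < params.fraction_diverged
            else params.rho_conserved
        )
        cov = np.array([[1.0, rho], [rho, 1.0]])
        z = rng.multivariate_normal(np.zeros(2), cov, size=m)
        profiles[pair.gene_a] = z[:, 0]
        profiles[pair.gene_b] = z[:, 1]
        planted_rho[pair.key] = rho
    for gene in all_genes:
        if gene not in profiles:
            profiles[gene] = rng.normal(0.0, 1.0, size=m)

    gene_order = [g for g in all_genes]
    data = np.empty((len(gene_order), m))
    for i, gene in enumerate(gene_order):
        x = np.maximum(log_mean + log_sd * profiles[gene], 0.0)
        data[i] = 10.0 ** x - 1.0
    df = pd.DataFrame(data, index=gene_order,
                      columns=[f"sample{j + 1}" for j in range(m)])
    return TpmMatrix(df), planted_rho


@dataclass(frozen=True)
class QuartetTruth:
    quartet: Quartet
    converted: bool


def simulate_quartets(
    n: int,
    ks_speciation: float = 0.6,
    ks_duplication: float = 1.2,
    conversion_fraction: float = 0.5,
    codon_length: int = 500,
    seed: int | None = None,
    ka_fraction: float = 0.05,
    ts_tv_ratio: float = 2.0,
) -> tuple[dict[str, str], list[QuartetTruth]]:
    """Quartets evolved on ((P1,O1),(P2,O2)) with optional gene conversion.

    Duplication precedes speciation (``ks_duplication > ks_speciation``).
    Conversion overwrites the P2 lineage with the P1 lineage's sequence
    halfway along the post-speciation branch, after which both paralogs
    evolve independently; converted quartets therefore end with
    Ks(P1,P2) ~ ks_speciation / 2, well below the paralog-ortholog Ks.
    """
    if ks_duplication <= ks_speciation:
        raise ValueError("duplication must predate speciation (larger Ks)")
    rng = np.random.default_rng(seed)

    def evolve(seq: str, ks: float) -> str:
        return evolve_sequence(seq, ks, ka_fraction * ks, rng, ts_tv_ratio)

    half_dup = ks_duplication / 2.0
    half_spec = ks_speciation / 2.0
    pre = half_dup - half_spec

    cds: dict[str, str] = {}
    truths: list[QuartetTruth] = []
    for q in range(n):
        root = random_cds(rng, codon_length)
        anc1 = evolve(root, pre)  # lineage leading to P1/O1
        anc2 = evolve(root, pre)  # lineage leading to P2/O2
        o1 = evolve(anc1, half_spec)
        o2 = evolve(anc2, half_spec)
        converted = bool(rng.random() < conversion_fraction)
        if converted:
            p1_mid = evolve(anc1, half_spec / 2.0)
            p1 = evolve(p1_mid, half_spec / 2.0)
            p2 = evolve(p1_mid, half_spec / 2.0)  # P2 overwritten by P1 lineage
        else:
            p1 = evolve(anc1, half_spec)
            p2 = evolve(anc2, half_spec)
        names = (f"q{q:04d}_p1", f"q{q:04d}_p2", f"q{q:04d}_o1", f"q{q:04d}_o2")
        for name, seq in zip(names, (p1, p2, o1, o2)):
            cds[name] = seq
        truths.append(QuartetTruth(Quartet(*names), converted))
    return cds, truths


def simulate_orthogroups(
    genome: GenomeTable,
    truth: TruthTable,
    related_species: Sequence[str] = ("relA", "relB", "relC"),
    p_present: float = 0.9,
    seed: int | None = None,
) -> OrthogroupTable:
    """Orthogroup table over the target and synthetic related species.

    Target genes connected by truth pairs share an orthogroup, except
    transposed/dispersed novel copies, which are emitted as singleton
    families (emulating their divergence out of the cluster, so that
    orthogroup-based ancestral-locus calls mark only the parent as ancient).
    Each related species contributes 1 gene per family with probability
    ``p_present``.
    """
    rng = np.random.default_rng(seed)
    novel = {p.gene_b for p in truth if p.mode in ("TRD", "DSD")}

    parent: dict[str, str] = {}

    def find(g: str) -> str:
        parent.setdefault(g, g)
        while parent[g] != g:
            parent[g] = parent[parent[g]]
            g = parent[g]
        return g

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    for pair in truth:
        if pair.gene_a in novel or pair.gene_b in novel:
            continue
        union(pair.gene_a, pair.gene_b)

    components: dict[str, list[str]] = {}
    for gene in sorted(genome.loci):
        if gene in novel:
            continue
        components.setdefault(find(gene), []).append(gene)

    target = genome.species_id
    groups: dict[str, dict[str, list[str]]] = {}
    og_idx = 0
    for root in sorted(components):
        og_idx += 1
        og_id = f"OG{og_idx:06d}"
        members = {target: components[root]}
        for sp in related_species:
            members[sp] = (
                [f"{sp}_{og_idx:06d}"] if rng.random() < p_present else []
            )
        groups[og_id] = members
    for gene in sorted(novel):
        og_idx += 1
        og_id = f"OG{og_idx:06d}"
        groups[og_id] = {target: [gene], **{sp: [] for sp in related_species}}
    return OrthogroupTable(groups)
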