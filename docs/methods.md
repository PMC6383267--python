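# Methods

This note records the models implemented in `dupcycles`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions that matter for reproducing output.

## Coordinate system

All adjacency rules operate on *gene ranks*: within each chromosome, genes
are numbered 0..n−1 by ascending start coordinate (ties: ascending end,
then lexical gene id).  Base-pair coordinates are 1-based inclusive and are
never used for distance rules.  Strand is ignored throughout; the
classification rules are order-based only.

## Collinear block detection

Filtered homolog pairs between two chromosomes are match points
(rank_a, rank_b).  Within each chromosome pair, points are chained by an
O(n²) dynamic program separately in plus (both ranks ascending) and minus
(rank_b descending) orientation.  A chain scores

    score = match_score · n_anchors + gap_penalty · Σ [(Δa − 1) + (Δb − 1)]

with defaults match_score = 50, gap_penalty = −1, consecutive anchors at
most max_gap = 25 ranks apart on both axes, and min_anchors = 5 per
reported block.  These are the published defaults of the standard
collinearity tools this module reimplements; all four are exposed as
options.  Match points are assigned to at most one block: the best-scoring
chain is extracted, its points removed, and the DP repeated (ties: plus
before minus, then smaller first anchor rank).  Blocks are ranked by raw
chain score; a block-significance E-value model is deliberately not
implemented.

Two standard self-comparison conventions apply to intra-genome scans:

* **Tandem-array collapse** — among consecutive-rank genes hitting the same
  partner, only the best hit is kept as a match point, so tandem arrays do
  not inflate blocks.
* **Diagonal band exclusion** — same-chromosome match points within
  max_gap ranks of the diagonal are excluded from chaining.  That band is
  where tandem/proximal pairs live; because they fall on slope-1 diagonals,
  scattered local duplicates would otherwise chain into spurious
  "blocks" under a raw-score model.  A genuine same-chromosome segmental
  block further than max_gap from the diagonal is still found.

An exhaustive chain enumerator (independent of the DP) verifies score
optimality on random instances in the test suite.

## Duplicate-pair classification

Hits are filtered (self-hits removed, E < 1e−10 strictly, best five
subjects per query by ascending E then descending bit score) and collapsed
to undirected pairs.  The partition is hierarchical and *pair-level* — a
gene may appear in several modes through different pairs, but each pair
carries exactly one mode:

1. **WGD** — anchor pairs of intra-genome collinear blocks.
2. **TD** — remaining same-chromosome pairs at rank distance 1.
3. **PD** — remaining same-chromosome pairs at rank distance 2..11, i.e.
   1–10 intervening genes.  "Separated by 10 or fewer genes" is read as
   intervening genes so that TD and PD are disjoint.
4. **TRD** — remaining pairs with *exactly one* gene at an ancestral locus;
   that gene is the parent copy.  A pair whose genes are both ancestral is
   not transposed and falls through.
5. **DSD** — the remainder, then reduced so each gene keeps only its
   lowest-E-value dispersed pair (ties: higher bit score, then lexical
   partner); a pair survives the reduction only if it is the best pair of
   both its genes.

Ancestral loci are the union of (i) genes anchored in intra-genome blocks,
(ii) genes anchored in blocks against any number of outgroup genomes, and
(iii) optionally, genes whose orthogroup has members in ≥ 2 other lineages
(used for taxa where synteny to any outgroup is too sparse).  For
assemblies too fragmented for block detection, a variant classifier accepts
WGD candidates as pairs whose Ks falls in known WGD peak windows (defaults
0.2–0.4 and 0.75–1.5) *and* whose genes both have orthogroup support in ≥ 2
related species; TRD then uses orthogroup-derived ancestral loci.

No Ks cutoff is applied to transposed pairs; epoch-resolved transposition
dating is out of scope.

## Ka/Ks estimation

Protein sequences are aligned globally (BLOSUM62, gap open −10, extend
−0.5; a gap of length L costs open + (L−1)·extend) and the alignment is
backtranslated to codons, one trailing stop codon being trimmed.  Columns
with gaps, ambiguous bases, or stop codons are skipped.

The estimator is NG86: per codon, each position contributes a synonymous
site fraction equal to the synonymous share of its non-stop single-base
changes (so S + N = 3 × usable columns exactly); differences between codons
are averaged over all minimal substitution pathways with equal weights,
pathways through stop codons excluded (if all pathways are blocked, the
unrestricted average is used).  Proportions p_s = Sd/S and p_n = Nd/N are
corrected with Jukes–Cantor, d = −(3/4)·ln(1 − 4p/3), undefined at
p ≥ 3/4.  Ks > 5 is flagged `excluded` (synonymous saturation) and dropped
from all downstream age distributions.  Ka/Ks is reported only when Ks is
defined and positive.

NG86 with a brute-force per-codon oracle was chosen as the default because
every count it produces can be verified independently; richer
codon-substitution models are out of scope.  A secondary Ks correction,
`method="NG86-TN93"`, applies the Tamura–Nei 1993 distance to the
transition/transversion partition of the pathway-averaged counts, with base
frequencies taken from the compared columns; it reduces to ≈ JC at low
divergence and is reported in the `method` field of every result.

## Ks peaks

Peak calling uses the distribution of mean anchor Ks per collinear block
(one value per block), not raw pair Ks — block means suppress the
pair-level noise and weight each duplication segment once.  Raw-pair
fitting is available as a fallback and is what the CLI uses when fewer
than 20 blocks exist.

Mixtures of k = 1..5 Gaussians are fitted by EM with 10 restarts per k:
means start at spread quantiles of the data plus seeded Gaussian
perturbation; standard deviations are floored at sd_floor = 0.01 to block
degenerate spikes on discretised Ks values; iteration stops when the
log-likelihood gain falls below 1e−6 (max 500 iterations), and the
likelihood is asserted non-decreasing at every step.  k is chosen by
minimal BIC = −2 log L + (3k − 1) ln n; fits refuse fewer than 20 points.
The "most recent WGD" peak is the smallest component mean among components
with weight ≥ 0.05.  Inter-genome blocks put speciation peaks through the
identical code path.

Abundance–age trends are fitted as y = a + bx (least squares) or
y = a·e^{bx} (nonlinear least squares initialised from the log-linear
fit), reporting the Pearson correlation of (x, y) with its two-sided p,
and the χ² statistic Σ(obs − fit)²/fit.

## Expression divergence

Expression profiles are log10(TPM + 1); the +1 pseudo-count resolves zeros
and is recorded here as a package convention.  A gene counts as expressed
when any sample exceeds a TPM threshold — the mean over samples of the
per-sample median intergenic TPM when an intergenic matrix is supplied
(those medians sit near zero), else 1.0 TPM.

For each duplicate pair with both copies expressed, Pearson r is compared
with the empirical null of r over 10,000 random gene pairs drawn uniformly
without replacement from expressed genes, excluding self-pairs and known
duplicate pairs (both exclusions are package conventions).  The cutoff is
the 95% quantile of the null; r < cutoff ⇒ diverged, else conserved.
Pairs with an unexpressed copy, a copy absent from the matrix, or a
constant profile (r undefined) are `not_analyzed` with a reason.  Group
comparisons use two-sided Fisher's exact tests on diverged/total counts.

## Gene conversion

For WGD (or other) pairs whose duplication predates the focal–outgroup
speciation, quartets (P1, P2, O1, O2) are formed when both paralogs have a
mapped ortholog.  The four proteins are merged into one joint codon
alignment by aligning each sequence to P1 and stacking insertions, so all
pairwise comparisons share column indices.  The conversion criterion is

    Ks(P1,P2) < min(Ks(P1,O1), Ks(P2,O2))   (strict),

i.e. the paralogs are younger than the speciation although they duplicated
before it.  Support is the fraction of 1000 codon-column bootstrap
resamples (identical column indices across the three comparisons;
replicates with undefined Ks fail the criterion) in which the criterion
holds; `converted` requires the point criterion plus support ≥ 0.95.  The
0.95 support floor is a package convention.  Per-mode conversion rates are
converted/evaluable quartets; whole-gene conversion only — tract mapping
and directionality are out of scope.

## Family statistics

Orthogroups are tiered by the number of species with no member: 0 missing
= most-preserved, 1–3 = intermediate, 4–5 = least, more = unassigned.
Because the nested reading ("up to three", "up to five") is also common,
cumulative counts over the nested definition are emitted alongside the
disjoint tiers.  Family-size distributions per species exclude families
with zero members in that species and report percentages that sum to 100.

## The synthetic-data generator

`synthetic_data` builds genomes with planted truth: ancestral genes on a
configurable number of chromosomes; each WGD copies every surviving gene
onto a mirrored chromosome set and deletes copies at 1 − retention;
tandem copies insert at rank +1, proximal at offsets 2..11, transposed
copies move a WGD-anchored parent's duplicate to another chromosome, and
dispersed copies do the same from non-anchored genes.  Placement uses
per-chromosome exclusion zones so later insertions never split an earlier
pair, and remote copies land only on chromosomes with no mirror
relationship to the source, so a planted single-gene match point cannot be
absorbed into a real block.  Defaults (2000 ancestral genes, one WGD at
Ks 1.0 with 30% retention, 100 pairs per single-gene mode, seed 42) define
the standard recovery benchmark.

Sequences are drawn from the 24 codons of the six strictly fourfold-
degenerate families (GTN, TCN, CCN, ACN, GCN, GGN).  Synonymous divergence
to a target Ks is a Poisson number of single-base synonymous events
(transitions weighted κ = 2), which on this alphabet is exactly a per-site
4-state Markov chain — the process the Jukes–Cantor correction inverts —
so NG86+JC is a consistent estimator of the planted Ks (the transition
bias leaves a residual ~2% downward bias at Ks = 1).  Nonsynonymous events
are added at Ka = 0.05·Ks.  All divergence of a pair is placed on the new
copy's branch, so planting one pair never changes another's Ks.  Hit
tables cover every truth pair in both directions with
E = 10^(−200·identity + ε), plus a configurable fraction of spurious hits;
expression profiles are bivariate log-normal at planted correlations;
quartets evolve on ((P1,O1),(P2,O2)) with duplication before speciation
and conversion implemented by overwriting the P2 lineage with the P1
lineage's sequence halfway along the post-speciation branch.

What the generator does **not** emulate — and what passing recovery tests
therefore do not establish about real data: indels and alignment error
(all planted sequences are equal-length, so codon alignments are exact),
realistic codon usage (twofold-degenerate sites, where NG86 has a known
saturation bias, are absent until nonsynonymous drift creates them),
transposable elements, chromosome rearrangement beyond the planted events,
read-level expression noise, and BLAST score statistics (the E-value model
is an arbitrary fixed monotone map of identity).

## Numerical conventions and degenerate inputs

* Every stochastic routine takes an explicit seed; equal seeds give
  byte-identical outputs, including all generator files.
* Alignment tie-breaks follow the pairwise aligner's deterministic
  first-alignment order; tests assert score optimality, not a specific
  co-optimal trace.
* −0.0 distances are normalised to 0.0; r and Ks that are mathematically
  undefined are reported as missing (`None`/`NA`), never guessed.
* Empty inputs error early with the offending file, line, or gene named.

## Problem sizes used in validation

The shipped benchmarks run the default 2000-gene classification bundle,
200 random chaining instances against exhaustive enumeration, 100
replicate Ks recoveries at three true values (500 codons), 100 seeded
two-component mixture fits (n = 1000), 1000 planted pairs per expression
class (20 samples), and 200 quartets at 500 codons with 1000 bootstrap
resamples — sizes at which every check completes in a few minutes on one
CPU while keeping binomial confidence intervals well inside the asserted
margins.
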