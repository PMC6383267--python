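"""Study-condition benchmark runs used for validation and reporting.

Each function here sets up one of the package's headline synthetic-data
evaluations — classification recovery, chain-score optimality, the NG86
worked example, Ks and mixture-peak recovery, expression-divergence call
accuracy, and gene-conversion detection performance — and measures the
result by running the ordinary public API end to end.  The tests and the
reporting script both call these, so the numbers they quote are always
produced by the same computation.
"""

from __future__ import annotations

import numpy as np

from .codon_evol import kaks_for_cds_pair
from .collinearity import detect_blocks
from .dup_classifier import build_ancestral_set, classify_pairs, filter_hits
from .expression_divergence import call_divergence
from .genome_io import GenomeTable, HomologyHit
from .gene_conversion import build_quartet_alignment, detect_conversion
from .ks_peaks import fit_gmm
from .synthetic_data import (
    ExpressionParams,
    SimulationConfig,
    TruthPair,
    TruthTable,
    fabricate_hits,
    evolve_sequence,
    random_cds,
    simulate_expression,
    simulate_genome,
    simulate_quartets,
)

# the default simulation: 2000 ancestral genes, one WGD at Ks 1.0 with 30%
# retention, 100 planted pairs of each single-gene mode
DEFAULT_SIM = SimulationConfig()


def classification_recovery(config: SimulationConfig = DEFAULT_SIM) -> tuple[float, int]:
    """Fraction of planted pairs recovered with the correct mode."""
    bundle = simulate_genome(config)
    raw = fabricate_hits(
        bundle.genome, bundle.truth, bundle.cds,
        spurious_fraction=config.spurious_hit_fraction, seed=config.seed + 1,
    )
    hits = filter_hits(raw)
    blocks = detect_blocks(bundle.genome, bundle.genome, hits)
    ancestral = build_ancestral_set(bundle.genome, blocks)
    by_mode = classify_pairs(bundle.genome, hits, blocks, ancestral)
    assigned = {p.key: str(p.mode) for pairs in by_mode.values() for p in pairs}
    correct = sum(1 for t in bundle.truth if assigned.get(t.key) == t.mode)
    return correct / len(bundle.truth), len(bundle.truth)


def _oracle_best_chain_score(points, min_anchors, max_gap,
                             match_score=50.0, gap_penalty=-1.0):
    """Brute-force enumeration of every order-preserving chain."""
    best = None
    for sign in (1, -1):
        pts = [(ra, sign * rb) for ra, rb in points]
        n = len(pts)

        def extend(end, length, score):
            nonlocal best
            if length >= min_anchors and (best is None or score > best):
                best = score
            ra0, rb0 = pts[end]
            for j in range(n):
                ra, rb = pts[j]
                if ra > ra0 and rb > rb0 and ra - ra0 <= max_gap and rb - rb0 <= max_gap:
                    extend(j, length + 1, score + match_score
                           + gap_penalty * ((ra - ra0 - 1) + (rb - rb0 - 1)))

        for i in range(n):
            extend(i, 1, match_score)
    return best


def collinearity_oracle_agreement(n_instances: int = 200, seed: int = 123) -> tuple[int, int]:
    """Count instances where the DP chain score equals the brute-force optimum."""
    rng = np.random.default_rng(seed)
    table_a = GenomeTable.from_records(
        "A", [("c1", f"a{r}", (r + 1) * 100, (r + 1) * 100 + 50) for r in range(26)]
    )
    table_b = GenomeTable.from_records(
        "B", [("c1", f"b{r}", (r + 1) * 100, (r + 1) * 100 + 50) for r in range(26)]
    )
    agree = 0
    for _ in range(n_instances):
        npts = int(rng.integers(5, 13))
        ras = rng.choice(26, size=npts, replace=False)
        rbs = rng.choice(26, size=npts, replace=False)
        points = list(zip(ras.tolist(), rbs.tolist()))
        hits = [HomologyHit(f"a{ra}", f"b{rb}", 0.9, 1e-50, 100.0)
                for ra, rb in points]
        blocks = detect_blocks(table_a, table_b, hits, min_anchors=3, max_gap=25)
        got = blocks[0].score if blocks else None
        agree += got == _oracle_best_chain_score(points, 3, 25)
    return agree, n_instances


def ng86_worked_example() -> dict[str, float]:
    """The 10-codon GGT/TTT-vs-TTC example, computed through the full path."""
    r = kaks_for_cds_pair("a", "b", "GGT" * 9 + "TTT", "GGT" * 9 + "TTC")
    return {
        "S": r.sites_syn,
        "N": r.sites_nonsyn,
        "Sd": r.diffs_syn,
        "Nd": r.diffs_nonsyn,
        "Ks": r.ks,
        "Ka": r.ka,
    }


def ks_recovery(seed: int = 7, n_reps: int = 100, n_codons: int = 500,
                ks_values: tuple[float, ...] = (0.2, 0.5, 1.0)) -> dict[float, dict]:
    """Mean estimated Ks for pairs evolved synonymously to known distances."""
    rng = np.random.default_rng(seed)
    out: dict[float, dict] = {}
    for ks_true in ks_values:
        estimates, kas = [], []
        for _ in range(n_reps):
            anc = random_cds(rng, n_codons)
            a = evolve_sequence(anc, ks_true / 2, 0.0, rng)
            b = evolve_sequence(anc, ks_true / 2, 0.0, rng)
            r = kaks_for_cds_pair("a", "b", a, b)
            estimates.append(r.ks)
            kas.append(r.ka)
        mean = float(np.mean(estimates))
        out[ks_true] = {
            "mean_ks": mean,
            "rel_error": (mean - ks_true) / ks_true,
            "mean_ka": float(np.mean(kas)),
            "n": n_reps,
        }
    return out


def gmm_selection(n_runs: int = 100, seed: int = 0,
                  means=(0.3, 1.2), sd=0.1, n_per=500) -> dict:
    """How often BIC picks k=2 on two-component data, and the mean errors."""
    child_seeds = np.random.SeedSequence(seed).spawn(n_runs)
    n_correct = 0
    errors = []
    for child in child_seeds:
        rng = np.random.default_rng(child)
        x = np.concatenate([rng.normal(m, sd, n_per) for m in means])
        fit_seed = int(rng.integers(0, 2**31 - 1))
        model = fit_gmm(x, seed=fit_seed)
        if model.k == 2:
            n_correct += 1
            errors.append(abs(model.components[0].mean - means[0]))
            errors.append(abs(model.components[1].mean - means[1]))
    return {
        "n_correct": n_correct,
        "n_runs": n_runs,
        "max_mean_error": float(max(errors)) if errors else None,
    }


def expression_accuracy(seed: int = 9, n_per_class: int = 1000,
                        n_samples: int = 20) -> dict:
    """Call accuracy for planted conserved (rho=0.9) vs diverged (rho=0) pairs."""
    from .dup_classifier import DuplicatePair, Mode

    truth = TruthTable(
        [TruthPair(f"a{i:05d}", f"b{i:05d}", "WGD", 1.0)
         for i in range(2 * n_per_class)]
    )
    params = ExpressionParams(n_samples=n_samples, rho_conserved=0.9,
                              rho_diverged=0.0, fraction_diverged=0.5)
    genes = [g for p in truth for g in (p.gene_a, p.gene_b)]
    tpm, rho = simulate_expression(truth, genes, params, seed=seed)
    pairs = [DuplicatePair(p.gene_a, p.gene_b, Mode.WGD, 1e-50) for p in truth]
    calls, cutoff = call_divergence(pairs, tpm, seed=seed + 1)
    correct = {True: [0, 0], False: [0, 0]}
    for p, c in zip(truth, calls):
        if c.status == "not_analyzed":
            continue
        conserved_truth = rho[p.key] > 0.5
        correct[conserved_truth][1] += 1
        expected = "conserved" if conserved_truth else "diverged"
        correct[conserved_truth][0] += c.status == expected
    return {
        "accuracy_conserved": correct[True][0] / correct[True][1],
        "accuracy_diverged": correct[False][0] / correct[False][1],
        "cutoff": cutoff,
        "n_per_class": n_per_class,
    }


def conversion_performance(seed: int = 11, n_quartets: int = 200,
                           n_bootstrap: int = 1000) -> dict:
    """Sensitivity and false-positive rate of the quartet conversion test."""
    cds, truths = simulate_quartets(
        n_quartets, ks_speciation=0.6, ks_duplication=1.2,
        conversion_fraction=0.5, codon_length=500, seed=seed,
    )
    tp = fp = fn = tn = 0
    for i, t in enumerate(truths):
        qaln = build_quartet_alignment(t.quartet, cds)
        event = detect_conversion(qaln, n_bootstrap=n_bootstrap,
                                  support_min=0.95, seed=seed + 1000 + i)
        if t.converted:
            tp += event.converted
            fn += not event.converted
        else:
            fp += event.converted
            tn += not event.converted
    return {
        "sensitivity": tp / (tp + fn) if tp + fn else None,
        "false_positive_rate": fp / (fp + tn) if fp + tn else None,
        "n_quartets": n_quartets,
    }
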