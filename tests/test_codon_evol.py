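"""Protein alignment, codon backtranslation, and NG86 Ka/Ks estimation."""

import itertools
import math

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from dupcycles.codon_evol import (
    CodonAlignment,
    align_proteins,
    backtranslate,
    codon_differences,
    codon_sites,
    column_stats,
    estimate_kaks,
    jukes_cantor,
    kaks_for_cds_pair,
    kaks_from_stats,
    translate_cds,
    CODON_TO_AA,
    SENSE_CODONS,
    STOP_CODONS,
)
from dupcycles.synthetic_data import evolve_sequence, random_cds

BLOSUM62 = substitution_matrices.load("BLOSUM62")


def _score_alignment(row_a, row_b, gap_open=-10.0, gap_extend=-0.5):
    """Score a gapped alignment: gap of length L costs open + (L-1)*extend."""
    score = 0.0
    in_gap_a = in_gap_b = False
    for ca, cb in zip(row_a, row_b):
        if ca == "-":
            score += gap_extend if in_gap_a else gap_open
            in_gap_a, in_gap_b = True, False
        elif cb == "-":
            score += gap_extend if in_gap_b else gap_open
            in_gap_b, in_gap_a = True, False
        else:
            score += BLOSUM62[ca, cb]
            in_gap_a = in_gap_b = False
    return score


def _oracle_best_score(a, b):
    """Exhaustive enumeration of all global alignments of two short strings."""
    best = -math.inf

    def rec(i, j, row_a, row_b):
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, _score_alignment(row_a, row_b))
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, row_a + a[i], row_b + b[j])
        if i < len(a):
            rec(i + 1, j, row_a + a[i], row_b + "-")
        if j < len(b):
            rec(i, j + 1, row_a + "-", row_b + b[j])

    rec(0, 0, "", "")
    return best


class TestAlignProteins:
    def test_identical_sequences_align_without_gaps(self):
        a, b = align_proteins("MKVLW", "MKVLW")
        assert a == b == "MKVLW"

    def test_empty_sequence_errors(self):
        with pytest.raises(ValueError, match="empty"):
            align_proteins("", "MK")

    def test_illegal_residue_errors(self):
        with pytest.raises(ValueError, match="illegal"):
            align_proteins("MKZ", "MK")

    def test_single_gap_example(self):
        a, b = align_proteins("ACDE", "ACE")
        assert (a, b) == ("ACDE", "AC-E")

    def test_alignment_score_is_optimal_vs_exhaustive_enumeration(self):
        rng = np.random.default_rng(3)
        alphabet = "ARNDCQEGHILKMFPSTWYV"
        for _ in range(30):
            a = "".join(rng.choice(list(alphabet), size=rng.integers(1, 6)))
            b = "".join(rng.choice(list(alphabet), size=rng.integers(1, 6)))
            got_a, got_b = align_proteins(a, b)
            assert _score_alignment(got_a, got_b) == pytest.approx(
                _oracle_best_score(a, b)
            )


class TestBacktranslate:
    def test_mechanical_substitution_with_gap(self):
        aln = backtranslate(("M-K", "MGK"), "ATGAAA", "ATGGGTAAA")
        assert aln.cds_a == "ATG---AAA"
        assert aln.cds_b == "ATGGGTAAA"

    def test_trailing_stop_trimmed(self):
        aln = backtranslate(("MK", "MK"), "ATGAAATAA", "ATGAAA")
        assert aln.cds_a == "ATGAAA"

    def test_length_mismatch_names_gene(self):
        with pytest.raises(ValueError, match="geneX"):
            backtranslate(("MKV", "MKV"), "ATGAAA", "ATGAAAGTT", gene_a="geneX")

    def test_internal_stop_errors(self):
        with pytest.raises(ValueError, match="stop"):
            translate_cds("ATGTAAAAA", "g")


class TestNg86Counts:
    def test_fourfold_codon_has_one_synonymous_site(self):
        assert codon_sites("GGT") == (1.0, 2.0)

    def test_twofold_codon_has_third_of_a_site(self):
        s, n = codon_sites("TTT")
        assert s == pytest.approx(1 / 3)
        assert s + n == pytest.approx(3.0)

    def test_site_conservation_across_all_sense_codons(self):
        for codon in SENSE_CODONS:
            s, n = codon_sites(codon)
            assert s + n == pytest.approx(3.0, abs=1e-9)

    def test_pathway_counts_match_exhaustive_enumeration(self):
        """For every sense-codon pair, the averaged difference counts equal a
        direct enumeration over substitution orderings."""
        rng = np.random.default_rng(4)
        codons = list(SENSE_CODONS)
        for _ in range(300):
            ca, cb = rng.choice(codons, size=2)
            sd, nd, _, _ = codon_differences(ca, cb)
            diff = [i for i in range(3) if ca[i] != cb[i]]
            paths = []
            for order in itertools.permutations(diff):
                cur, syn, nonsyn, ok = ca, 0, 0, True
                for pos in order:
                    nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
                    if nxt in STOP_CODONS:
                        ok = False
                        break
                    syn += CODON_TO_AA[cur] == CODON_TO_AA[nxt]
                    nonsyn += CODON_TO_AA[cur] != CODON_TO_AA[nxt]
                    cur = nxt
                if ok:
                    paths.append((syn, nonsyn))
            if paths:
                exp_sd = sum(p[0] for p in paths) / len(paths)
                exp_nd = sum(p[1] for p in paths) / len(paths)
                assert (sd, nd) == (pytest.approx(exp_sd), pytest.approx(exp_nd))
            assert sd + nd == pytest.approx(len(diff))


class TestEstimateKaks:
    def test_worked_example(self):
        """9 shared GGT codons plus TTT vs TTC: one synonymous difference."""
        r = kaks_for_cds_pair("a", "b", "GGT" * 9 + "TTT", "GGT" * 9 + "TTC")
        assert r.sites_syn == pytest.approx(9.3333, abs=1e-4)
        assert r.sites_nonsyn == pytest.approx(20.6667, abs=1e-4)
        assert r.diffs_syn == pytest.approx(1.0)
        assert r.diffs_nonsyn == pytest.approx(0.0)
        assert r.ks == pytest.approx(0.1156, abs=1e-4)
        assert r.ka == 0.0

    def test_identical_sequences(self):
        r = kaks_for_cds_pair("a", "b", "GGTGCA" * 50, "GGTGCA" * 50)
        assert r.ka == 0.0 and r.ks == 0.0 and r.ratio is None

    def test_saturated_ks_is_undefined(self):
        assert jukes_cantor(0.8) is None

    def test_ks_above_cutoff_flagged_excluded(self):
        # p_s = 0.7495 corresponds to Ks ~ 5.5, just beyond the saturation cut
        stats = np.zeros((1, 8))
        stats[0, 0], stats[0, 1] = 10000.0, 20000.0
        stats[0, 2] = 7495.0
        r = kaks_from_stats(stats, "p", ks_max=5.0)
        assert r.ks > 5.0 and r.excluded

    def test_symmetry(self):
        rng = np.random.default_rng(5)
        anc = random_cds(rng, 80)
        other = evolve_sequence(anc, 0.3, 0.02, rng)
        ab = kaks_for_cds_pair("a", "b", anc, other)
        ba = kaks_for_cds_pair("b", "a", other, anc)
        assert ab.ks == ba.ks and ab.ka == ba.ka
        assert ab.sites_syn == ba.sites_syn

    def test_site_totals_match_column_count(self):
        rng = np.random.default_rng(6)
        anc = random_cds(rng, 120)
        other = evolve_sequence(anc, 0.4, 0.02, rng)
        r = kaks_for_cds_pair("a", "b", anc, other)
        assert r.sites_syn + r.sites_nonsyn == pytest.approx(
            3 * r.n_codons, abs=1e-9
        )

    def test_zero_usable_columns_errors(self):
        with pytest.raises(ValueError, match="usable"):
            estimate_kaks(CodonAlignment("p", "---", "ATG"))

    def test_synonymous_simulation_recovery(self):
        """Sequences evolved synonymously to Ks=0.5 are estimated near 0.5
        with Ka ~ 0."""
        rng = np.random.default_rng(7)
        estimates, kas = [], []
        for _ in range(20):
            anc = random_cds(rng, 500)
            a = evolve_sequence(anc, 0.25, 0.0, rng)
            b = evolve_sequence(anc, 0.25, 0.0, rng)
            r = kaks_for_cds_pair("a", "b", a, b)
            estimates.append(r.ks)
            kas.append(r.ka)
        assert abs(np.mean(estimates) - 0.5) / 0.5 < 0.1
        assert np.mean(kas) < 0.005

    def test_tn93_variant_close_to_jc_at_low_divergence(self):
        rng = np.random.default_rng(8)
        anc = random_cds(rng, 400)
        a = evolve_sequence(anc, 0.05, 0.005, rng)
        b = evolve_sequence(anc, 0.05, 0.005, rng)
        jc = kaks_for_cds_pair("a", "b", a, b, method="NG86")
        tn = kaks_for_cds_pair("a", "b", a, b, method="NG86-TN93")
        assert tn.method == "NG86-TN93"
        assert tn.ks == pytest.approx(jc.ks, rel=0.15)
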