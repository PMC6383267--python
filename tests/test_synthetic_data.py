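"""The planted-truth generator: conservation, determinism, recovery."""

import numpy as np
import pytest

from dupcycles.codon_evol import kaks_for_cds_pair
from dupcycles.collinearity import detect_blocks
from dupcycles.dup_classifier import build_ancestral_set, classify_pairs, filter_hits
from dupcycles.synthetic_data import (
    ExpressionParams,
    SimulationConfig,
    fabricate_hits,
    simulate_expression,
    simulate_genome,
    simulate_orthogroups,
    simulate_quartets,
)


class TestSimulateGenome:
    def test_full_retention_pairs_every_gene(self):
        config = SimulationConfig(
            seed=1, n_chromosomes=2, n_ancestral_genes=60,
            wgd_events=((1.0, 0.5),), n_tandem=0, n_proximal=0,
            n_transposed=0, n_dispersed=0, codon_length=30,
        )
        bundle = simulate_genome(config)
        assert len(bundle.truth) == 60
        partners = {g for p in bundle.truth for g in (p.gene_a, p.gene_b)}
        assert len(partners) == 120 == len(bundle.genome)

    def test_planted_tandem_pairs_are_adjacent(self):
        config = SimulationConfig(
            seed=2, n_chromosomes=3, n_ancestral_genes=400,
            wgd_events=((0.5, 0.6),), n_tandem=50, n_proximal=0,
            n_transposed=0, n_dispersed=0, codon_length=30,
        )
        bundle = simulate_genome(config)
        td = bundle.truth.by_mode()["TD"]
        assert len(td) == 50
        for pair in td:
            la = bundle.genome[pair.gene_a]
            lb = bundle.genome[pair.gene_b]
            assert la.chromosome == lb.chromosome
            assert abs(la.rank - lb.rank) == 1

    def test_planted_proximal_distances_in_window(self):
        config = SimulationConfig(
            seed=3, n_chromosomes=3, n_ancestral_genes=400,
            wgd_events=((0.5, 0.6),), n_tandem=0, n_proximal=40,
            n_transposed=0, n_dispersed=0, codon_length=30,
        )
        bundle = simulate_genome(config)
        for pair in bundle.truth.by_mode()["PD"]:
            la = bundle.genome[pair.gene_a]
            lb = bundle.genome[pair.gene_b]
            assert la.chromosome == lb.chromosome
            assert 2 <= abs(la.rank - lb.rank) <= 11

    def test_remote_copies_leave_source_chromosome_family(self, small_bundle):
        for mode in ("TRD", "DSD"):
            for pair in small_bundle.truth.by_mode()[mode]:
                ca = small_bundle.genome[pair.gene_a].chromosome
                cb = small_bundle.genome[pair.gene_b].chromosome
                assert ca.split("w")[0] != cb.split("w")[0]

    def test_deterministic_under_seed(self, small_config):
        a = simulate_genome(small_config)
        b = simulate_genome(small_config)
        assert a.cds == b.cds
        assert a.truth.pairs == b.truth.pairs
        assert a.genome == b.genome

    def test_capacity_exceeded_errors(self):
        config = SimulationConfig(
            seed=4, n_chromosomes=1, n_ancestral_genes=30,
            wgd_events=((0.5, 0.5),), n_tandem=60, n_proximal=0,
            n_transposed=0, n_dispersed=0, codon_length=10,
        )
        with pytest.raises(ValueError, match="capacity"):
            simulate_genome(config)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError, match="retention"):
            SimulationConfig(wgd_events=((1.5, 1.0),))
        with pytest.raises(ValueError, match="distinct"):
            SimulationConfig(wgd_events=((0.5, 1.0), (0.5, 1.0)))
        with pytest.raises(ValueError, match="correlation"):
            ExpressionParams(rho_conserved=1.5)

    def test_planted_ks_recovered_within_ten_percent(self, small_bundle):
        rel_errors = []
        for pair in list(small_bundle.truth)[:60]:
            r = kaks_for_cds_pair(
                pair.gene_a, pair.gene_b,
                small_bundle.cds[pair.gene_a], small_bundle.cds[pair.gene_b],
            )
            rel_errors.append((r.ks - pair.ks_age) / pair.ks_age)
        assert abs(np.mean(rel_errors)) < 0.1


class TestFabricateHits:
    def test_identical_sequences_get_minimal_e_value(self, small_bundle):
        hits = fabricate_hits(small_bundle.genome, small_bundle.truth,
                              small_bundle.cds, spurious_fraction=0.0, seed=5)
        identical = [h for h in hits if h.identity == 1.0]
        if identical:
            floor = min(h.e_value for h in hits)
            assert min(h.e_value for h in identical) == floor

    def test_no_spurious_hits_means_two_per_pair(self, small_bundle):
        hits = fabricate_hits(small_bundle.genome, small_bundle.truth,
                              small_bundle.cds, spurious_fraction=0.0, seed=5)
        assert len(hits) == 2 * len(small_bundle.truth)

    def test_spurious_fraction_within_three_sigma(self, small_bundle):
        frac = 0.1
        hits = fabricate_hits(small_bundle.genome, small_bundle.truth,
                              small_bundle.cds, spurious_fraction=frac, seed=6)
        n_truth = 2 * len(small_bundle.truth)
        extra = len(hits) - n_truth
        sigma = np.sqrt(n_truth * frac * (1 - frac))
        assert abs(extra - n_truth * frac) <= 3 * sigma


class TestExpression:
    def test_perfect_correlation_approached_at_large_n(self):
        from dupcycles.synthetic_data import TruthPair, TruthTable

        truth = TruthTable([TruthPair("a", "b", "WGD", 1.0)])
        params = ExpressionParams(n_samples=1000, rho_conserved=1.0,
                                  fraction_diverged=0.0)
        tpm, rho = simulate_expression(truth, ["a", "b"], params, seed=8)
        log = tpm.log10p().to_numpy()
        r = np.corrcoef(log[0], log[1])[0, 1]
        assert rho[frozenset(("a", "b"))] == 1.0
        assert r >= 0.99


class TestQuartets:
    def test_zero_conversion_fraction_plants_none(self):
        _, truths = simulate_quartets(10, conversion_fraction=0.0, seed=9,
                                      codon_length=50)
        assert not any(t.converted for t in truths)

    def test_full_conversion_puts_paralog_ks_below_ortholog_ks(self):
        cds, truths = simulate_quartets(5, conversion_fraction=1.0, seed=10,
                                        codon_length=300)
        for t in truths:
            q = t.quartet
            ks_p = kaks_for_cds_pair("p1", "p2", cds[q.paralog_1], cds[q.paralog_2]).ks
            ks_o1 = kaks_for_cds_pair("p1", "o1", cds[q.paralog_1], cds[q.ortholog_1]).ks
            ks_o2 = kaks_for_cds_pair("p2", "o2", cds[q.paralog_2], cds[q.ortholog_2]).ks
            assert t.converted
            assert ks_p < min(ks_o1, ks_o2)

    def test_speciation_must_postdate_duplication(self):
        with pytest.raises(ValueError, match="predate"):
            simulate_quartets(1, ks_speciation=1.2, ks_duplication=0.6, seed=1)


class TestOrthogroups:
    def test_novel_copies_are_singletons(self, small_bundle):
        table = simulate_orthogroups(small_bundle.genome, small_bundle.truth, seed=11)
        novel = {p.gene_b for p in small_bundle.truth if p.mode in ("TRD", "DSD")}
        for gene in novel:
            og = table.orthogroup_of(gene)
            members = table.groups[og]
            assert members[small_bundle.genome.species_id] == [gene]
            assert all(not members[sp] for sp in table.species
                       if sp != small_bundle.genome.species_id)

    def test_wgd_pairs_share_an_orthogroup(self, small_bundle):
        table = simulate_orthogroups(small_bundle.genome, small_bundle.truth, seed=11)
        for pair in small_bundle.truth.by_mode()["WGD"][:20]:
            assert table.orthogroup_of(pair.gene_a) == table.orthogroup_of(pair.gene_b)


def test_end_to_end_recovery_on_small_bundle(small_bundle, small_hits, small_blocks):
    """classify_pairs recovers >=95% of planted pairs on the session bundle."""
    ancestral = build_ancestral_set(small_bundle.genome, small_blocks)
    by_mode = classify_pairs(small_bundle.genome, small_hits, small_blocks, ancestral)
    assigned = {p.key: str(p.mode) for pairs in by_mode.values() for p in pairs}
    correct = sum(1 for t in small_bundle.truth if assigned.get(t.key) == t.mode)
    assert correct / len(small_bundle.truth) >= 0.95
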