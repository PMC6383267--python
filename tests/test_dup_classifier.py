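"""Hit filtering and the five-mode classification hierarchy."""

import pytest

from dupcycles.collinearity import AnchorPair, CollinearBlock
from dupcycles.dup_classifier import (
    AncestralLocusSet,
    Mode,
    ancestral_from_orthogroups,
    build_ancestral_set,
    classify_fragmented,
    classify_pairs,
    filter_hits,
    undirected_pairs,
)
from dupcycles.genome_io import GenomeTable, HomologyHit, OrthogroupTable


def _hit(q, s, e, bit=100.0):
    return HomologyHit(q, s, 0.9, e, bit)


class TestFilterHits:
    def test_top_five_smallest_e_values_kept(self):
        hits = [_hit("q", f"s{i}", 10.0 ** -(20 + i)) for i in range(7)]
        kept = filter_hits(hits)
        assert [h.subject for h in kept] == ["s6", "s5", "s4", "s3", "s2"]

    def test_threshold_is_strict(self):
        assert filter_hits([_hit("q", "s", 1e-9)]) == []
        assert filter_hits([_hit("q", "s", 9.9e-11)]) != []

    def test_only_self_hit_gives_empty(self):
        assert filter_hits([_hit("g", "g", 1e-50)]) == []

    def test_duplicate_rows_collapse_to_best(self):
        hits = [_hit("q", "s", 1e-20), _hit("q", "s", 1e-40)]
        (kept,) = filter_hits(hits)
        assert kept.e_value == 1e-40

    def test_ties_break_by_bit_score_then_subject(self):
        hits = [
            _hit("q", "sB", 1e-20, bit=100.0),
            _hit("q", "sA", 1e-20, bit=100.0),
            _hit("q", "sC", 1e-20, bit=200.0),
        ]
        kept = filter_hits(hits, top_n=2)
        assert [h.subject for h in kept] == ["sC", "sA"]


@pytest.fixture()
def toy_genome():
    # c1 carries ranks 0..19, c2 ranks 0..9
    records = [("c1", f"g{r:02d}", (r + 1) * 100, (r + 1) * 100 + 50) for r in range(20)]
    records += [("c2", f"h{r:02d}", (r + 1) * 100, (r + 1) * 100 + 50) for r in range(10)]
    return GenomeTable.from_records("sp", records)


def _ancestral(species, genes):
    out = AncestralLocusSet(species)
    for g in genes:
        out.add(g, "intra_synteny")
    return out


class TestClassifyPairs:
    def test_adjacent_same_chromosome_is_tandem(self, toy_genome):
        by_mode = classify_pairs(
            toy_genome, [_hit("g07", "g08", 1e-50)], [], _ancestral("sp", [])
        )
        (pair,) = by_mode[Mode.TD]
        assert pair.rank_distance == 1

    def test_five_intervening_genes_is_proximal(self, toy_genome):
        by_mode = classify_pairs(
            toy_genome, [_hit("g07", "g13", 1e-50)], [], _ancestral("sp", [])
        )
        (pair,) = by_mode[Mode.PD]
        assert pair.rank_distance == 6

    def test_proximal_window_boundary(self, toy_genome):
        # 10 intervening genes (distance 11) is proximal; 11 (distance 12) is not
        by_mode = classify_pairs(
            toy_genome, [_hit("g00", "g11", 1e-50)], [], _ancestral("sp", [])
        )
        assert len(by_mode[Mode.PD]) == 1
        by_mode = classify_pairs(
            toy_genome, [_hit("g00", "g12", 1e-50)], [], _ancestral("sp", [])
        )
        assert len(by_mode[Mode.PD]) == 0

    def test_one_ancestral_gene_is_transposed(self, toy_genome):
        by_mode = classify_pairs(
            toy_genome, [_hit("g00", "h05", 1e-50)], [], _ancestral("sp", ["g00"])
        )
        (pair,) = by_mode[Mode.TRD]
        assert pair.parent_copy == "g00" and pair.transposed_copy == "h05"

    def test_both_ancestral_falls_to_dispersed(self, toy_genome):
        by_mode = classify_pairs(
            toy_genome, [_hit("g00", "h05", 1e-50)], [],
            _ancestral("sp", ["g00", "h05"]),
        )
        assert len(by_mode[Mode.TRD]) == 0 and len(by_mode[Mode.DSD]) == 1

    def test_anchor_pair_is_wgd(self, toy_genome):
        anchors = tuple(
            AnchorPair(f"g{r:02d}", f"h{r:02d}", r, r, 1e-50) for r in range(5)
        )
        block = CollinearBlock("c1", "c2", "plus", anchors, 250.0)
        hits = [_hit(f"g{r:02d}", f"h{r:02d}", 1e-50) for r in range(5)]
        by_mode = classify_pairs(toy_genome, hits, [block], _ancestral("sp", []))
        assert len(by_mode[Mode.WGD]) == 5
        assert all(p.block_id == 0 for p in by_mode[Mode.WGD])

    def test_dispersed_best_hit_reduction(self, toy_genome):
        hits = [
            _hit("g00", "h00", 1e-80),
            _hit("g00", "h03", 1e-40),
            _hit("g00", "h06", 1e-20),
        ]
        by_mode = classify_pairs(toy_genome, hits, [], _ancestral("sp", []))
        partners = {p.gene_b for p in by_mode[Mode.DSD]}
        assert partners == {"h00"}

    def test_partition_is_exact_without_reduction(self, small_bundle, small_hits,
                                                  small_blocks):
        ancestral = build_ancestral_set(small_bundle.genome, small_blocks)
        by_mode = classify_pairs(
            small_bundle.genome, small_hits, small_blocks, ancestral,
            reduce_dispersed=False,
        )
        n_assigned = sum(len(v) for v in by_mode.values())
        n_pairs = len(undirected_pairs(small_hits))
        assert n_assigned == n_pairs
        keys = [p.key for v in by_mode.values() for p in v]
        assert len(keys) == len(set(keys))  # no pair carries two modes

    def test_determinism(self, small_bundle, small_hits, small_blocks):
        ancestral = build_ancestral_set(small_bundle.genome, small_blocks)
        a = classify_pairs(small_bundle.genome, small_hits, small_blocks, ancestral)
        b = classify_pairs(small_bundle.genome, small_hits, small_blocks, ancestral)
        assert a == b


class TestAncestralSets:
    def test_union_of_intra_and_inter_tags(self, toy_genome):
        intra = [CollinearBlock("c1", "c2", "plus",
                                (AnchorPair("g00", "h00", 0, 0, 1e-50),), 50.0)]
        inter = [[CollinearBlock("c1", "o1", "plus",
                                 (AnchorPair("g00", "x1", 0, 0, 1e-50),
                                  AnchorPair("g01", "x2", 1, 1, 1e-50)), 100.0)]]
        out = build_ancestral_set(toy_genome, intra, inter)
        assert out.sources["g00"] == {"intra_synteny", "inter_synteny"}
        assert out.sources["g01"] == {"inter_synteny"}
        assert "g05" not in out

    def test_empty_blocks_warn(self, toy_genome):
        with pytest.warns(UserWarning, match="empty"):
            out = build_ancestral_set(toy_genome, [], [])
        assert not out.gene_ids

    def test_orthogroup_ancestry_needs_two_other_lineages(self):
        table = OrthogroupTable(
            {
                "OG1": {"t": ["t1"], "o1": ["a"], "o2": ["b"], "o3": ["c"]},
                "OG2": {"t": ["t2"], "o1": ["d"], "o2": [], "o3": []},
                "OG3": {"t": ["t3"], "o1": [], "o2": [], "o3": []},
            }
        )
        out = ancestral_from_orthogroups(table, "t")
        assert "t1" in out and "t2" not in out and "t3" not in out

    def test_missing_target_species_errors(self):
        table = OrthogroupTable({"OG1": {"a": ["x"]}})
        with pytest.raises(ValueError, match="absent"):
            ancestral_from_orthogroups(table, "nope")


class TestClassifyFragmented:
    @pytest.fixture()
    def orthogroups(self):
        return OrthogroupTable(
            {
                "OG1": {"sp": ["g00", "h00"], "r1": ["a"], "r2": ["b"], "r3": []},
                "OG2": {"sp": ["g05", "h05"], "r1": [], "r2": [], "r3": []},
            }
        )

    def test_ks_window_with_support_is_wgd(self, toy_genome, orthogroups):
        kaks = {frozenset(("g00", "h00")): 0.3}
        by_mode = classify_fragmented(
            toy_genome, [_hit("g00", "h00", 1e-50)], kaks, orthogroups,
            "sp", ["r1", "r2", "r3"],
        )
        assert len(by_mode[Mode.WGD]) == 1

    def test_no_orthogroup_support_falls_through(self, toy_genome, orthogroups):
        kaks = {frozenset(("g05", "h05")): 0.3}
        by_mode = classify_fragmented(
            toy_genome, [_hit("g05", "h05", 1e-50)], kaks, orthogroups,
            "sp", ["r1", "r2", "r3"],
        )
        assert len(by_mode[Mode.WGD]) == 0 and len(by_mode[Mode.DSD]) == 1

    def test_ks_between_windows_is_not_wgd(self, toy_genome, orthogroups):
        kaks = {frozenset(("g00", "h00")): 0.6}
        by_mode = classify_fragmented(
            toy_genome, [_hit("g00", "h00", 1e-50)], kaks, orthogroups,
            "sp", ["r1", "r2", "r3"],
        )
        assert len(by_mode[Mode.WGD]) == 0

    def test_empty_windows_error(self, toy_genome, orthogroups):
        with pytest.raises(ValueError, match="window"):
            classify_fragmented(
                toy_genome, [], {}, orthogroups, "sp", ["r1"], ks_windows=(),
            )
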