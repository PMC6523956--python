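"""Duplication typing: hit graph, collinear-block chaining, MCScanX-style
class priorities and the per-species percentage summaries."""

import pytest

from soxkit import homology
from soxkit.duplication import (
    build_hit_graph,
    classify_duplications,
    detect_collinear_blocks,
    summarize_dup_table,
    species_summary_table,
)
from soxkit.seqio import GeneModel, ProteinRecord

# Sox duplication-class counts reported for seven galliform genomes
SOX_COUNTS = {
    "C_japonica": {"singleton": 0, "dispersed": 13, "proximal": 0,
                   "tandem": 4, "wgd_segmental": 1},
    "G_gallus": {"singleton": 0, "dispersed": 12, "proximal": 1,
                 "tandem": 3, "wgd_segmental": 2},
    "C_virginianus": {"singleton": 0, "dispersed": 13, "proximal": 1,
                      "tandem": 0, "wgd_segmental": 0},
    "C_squamata": {"singleton": 0, "dispersed": 14, "proximal": 0,
                   "tandem": 0, "wgd_segmental": 0},
    "N_meleagris": {"singleton": 0, "dispersed": 9, "proximal": 1,
                    "tandem": 5, "wgd_segmental": 0},
    "B_thoracicus": {"singleton": 0, "dispersed": 13, "proximal": 0,
                     "tandem": 0, "wgd_segmental": 0},
    "M_gallopavo": {"singleton": 0, "dispersed": 9, "proximal": 0,
                    "tandem": 4, "wgd_segmental": 0},
}


def _genes(spec):
    """spec: {gene_id: (chrom, rank)} -> GeneModel map."""
    return {
        gid: GeneModel(gid, chrom, 1 + rank * 100, 50 + rank * 100, "+", rank)
        for gid, (chrom, rank) in spec.items()
    }


def _graph(pairs):
    return {frozenset(p): 1e-30 for p in pairs}


class TestHitGraph:
    def test_identical_duplicates_linked_and_symmetric(self):
        prots = [
            ProteinRecord("pA", "gA", "MKVLAWGRETKVNDWLHH" * 10),
            ProteinRecord("pB", "gB", "MKVLAWGRETKVNDWLHH" * 10),
            ProteinRecord("pC", "gC", "QQPSDENNYTCS" * 12),
        ]
        scores = homology.all_vs_all_scores(prots)
        graph = build_hit_graph(scores, evalue_max=1e-5)
        assert frozenset(("pA", "pB")) in graph
        assert frozenset(("pA", "pC")) not in graph

    def test_unrelated_random_proteins_unlinked(self, default_sim, sim_scores):
        family_prot = {g + ".p1" for g in default_sim.truth.family_gene_ids}
        graph = build_hit_graph(sim_scores, evalue_max=1e-10)
        background_edges = [
            p for p in graph if not (set(p) & family_prot)
        ]
        # only the planted background duplicate pairs remain
        planted_bg = 6 + 3 + 2  # collinear segment + flankers of both blocks
        assert len(background_edges) == planted_bg


class TestCollinearBlocks:
    def test_planted_run_of_six_detected(self):
        spec = {f"a{i}": ("c1", 10 + i) for i in range(6)}
        spec.update({f"b{i}": ("c2", 20 + i) for i in range(6)})
        graph = _graph([(f"a{i}", f"b{i}") for i in range(6)])
        blocks = detect_collinear_blocks(graph, _genes(spec), min_block_size=5)
        assert len(blocks) == 1 and blocks[0].size == 6

    def test_four_pairs_below_min_size_ignored(self):
        spec = {f"a{i}": ("c1", i) for i in range(4)}
        spec.update({f"b{i}": ("c2", i) for i in range(4)})
        graph = _graph([(f"a{i}", f"b{i}") for i in range(4)])
        assert detect_collinear_blocks(graph, _genes(spec), min_block_size=5) == []

    def test_antiparallel_chain_detected(self):
        spec = {f"a{i}": ("c1", i) for i in range(5)}
        spec.update({f"b{i}": ("c2", 40 - i) for i in range(5)})
        graph = _graph([(f"a{i}", f"b{i}") for i in range(5)])
        blocks = detect_collinear_blocks(graph, _genes(spec), min_block_size=5)
        assert len(blocks) == 1 and blocks[0].size == 5

    def test_gap_limit_breaks_chain(self):
        spec = {f"a{i}": ("c1", i * 30) for i in range(5)}
        spec.update({f"b{i}": ("c2", i * 30) for i in range(5)})
        graph = _graph([(f"a{i}", f"b{i}") for i in range(5)])
        assert detect_collinear_blocks(graph, _genes(spec), max_gap=25) == []


class TestClassifyPriorities:
    def test_lone_gene_is_singleton(self):
        genes = _genes({"g1": ("c1", 0)})
        assert classify_duplications(["g1"], {}, genes) == {"g1": "singleton"}

    def test_adjacent_homologs_are_tandem(self):
        genes = _genes({"g1": ("c1", 4), "g2": ("c1", 5)})
        classes = classify_duplications(["g1", "g2"], _graph([("g1", "g2")]), genes)
        assert classes == {"g1": "tandem", "g2": "tandem"}

    def test_near_homologs_are_proximal(self):
        genes = _genes({"g1": ("c1", 0), "g2": ("c1", 7)})
        classes = classify_duplications(["g1", "g2"], _graph([("g1", "g2")]), genes)
        assert classes == {"g1": "proximal", "g2": "proximal"}

    def test_distant_homologs_are_dispersed(self):
        genes = _genes({"g1": ("c1", 0), "g2": ("c2", 0)})
        classes = classify_duplications(["g1", "g2"], _graph([("g1", "g2")]), genes)
        assert classes == {"g1": "dispersed", "g2": "dispersed"}

    def test_block_membership_outranks_tandem(self):
        spec = {f"a{i}": ("c1", i) for i in range(5)}
        spec.update({f"b{i}": ("c2", i) for i in range(5)})
        genes = _genes(spec)
        graph = _graph([(f"a{i}", f"b{i}") for i in range(5)] + [("a0", "a1")])
        blocks = detect_collinear_blocks(graph, genes, min_block_size=5)
        classes = classify_duplications(["a0", "a1"], graph, genes, blocks)
        assert classes == {"a0": "wgd_segmental", "a1": "wgd_segmental"}

    def test_missing_gene_raises(self):
        with pytest.raises(KeyError, match="gX"):
            classify_duplications(["gX"], {}, {})

    def test_input_order_never_changes_classes(self):
        spec = {"g1": ("c1", 0), "g2": ("c1", 1), "g3": ("c2", 0)}
        genes = _genes(spec)
        graph = _graph([("g1", "g2"), ("g1", "g3")])
        a = classify_duplications(["g1", "g2", "g3"], graph, genes)
        b = classify_duplications(["g3", "g2", "g1"], graph, genes)
        assert a == b

    def test_planted_truth_recovered_exactly(self, default_sim, sim_scores,
                                             sim_ranks, sim_gene_map):
        graph = build_hit_graph(sim_scores)
        blocks = detect_collinear_blocks(graph, sim_ranks,
                                         gene_of_protein=sim_gene_map)
        classes = classify_duplications(
            default_sim.truth.family_gene_ids, graph, sim_ranks, blocks,
            gene_of_protein=sim_gene_map,
        )
        assert classes == default_sim.truth.dup_class_of


class TestSummaries:
    @pytest.mark.parametrize(
        "species,expected",
        [
            ("C_japonica", 72.2), ("G_gallus", 66.7), ("M_gallopavo", 69.2),
            ("N_meleagris", 60.0), ("C_virginianus", 92.9),
            ("C_squamata", 100.0), ("B_thoracicus", 100.0),
        ],
    )
    def test_reported_percent_dispersed(self, species, expected):
        assert summarize_dup_table(SOX_COUNTS[species])["percent_dispersed"] == expected

    def test_counts_partition_the_family(self):
        s = summarize_dup_table(SOX_COUNTS["C_japonica"])
        assert s["dispersed"] + s["proximal"] + s["tandem"] + \
            s["wgd_segmental"] + s["singleton"] == s["total"] == 18

    def test_single_class_gets_hundred_percent(self):
        s = summarize_dup_table({"g1": "dispersed", "g2": "dispersed"})
        assert s["percent_dispersed"] == 100.0 and s["tandem"] == 0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            summarize_dup_table({})

    def test_species_table_layout(self):
        df = species_summary_table(SOX_COUNTS)
        assert list(df.columns) == list(SOX_COUNTS)
        assert df.loc["percent_dispersed", "C_japonica"] == 72.2
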