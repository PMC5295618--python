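import pytest
from Bio.Seq import Seq

from orfweaver import synthetic_data as synth
from orfweaver.config import RunConfig
from orfweaver.exon_mapper import ExonPlacement, PlacementClassification
from orfweaver.io_formats import SeqRecord
from orfweaver.metrics import nxx, split_at_gaps
from orfweaver.pipeline import run_pipeline
from orfweaver.scaffolder import (
    ScaffoldError,
    ScaffoldPlan,
    build_scaffold_graph,
    emit_scaffolds,
    rescue_missing_exons,
    resolve_conflicts,
)

CFG = RunConfig()


def _cls(orf_id, category, contigs):
    return PlacementClassification(orf_id=orf_id, category=category,
                                   contigs_used=list(contigs))


def _chosen(orf_id, path):
    """path: [(contig, strand), ...] one exon per contig, ascending ordinals."""
    return {
        i: ExonPlacement(orf_id, i, contig, 100 * i, 100 * i + 50, strand, 100.0)
        for i, (contig, strand) in enumerate(path, start=1)
    }


class TestGraph:
    def test_two_contig_orf_yields_one_edge(self):
        cls = {"o1": _cls("o1", 2, "AB")}
        chosen = {"o1": _chosen("o1", [("A", "+"), ("B", "+")])}
        edges, pal = build_scaffold_graph(cls, chosen)
        (e,) = edges
        assert (e.contig_a, e.orient_a, e.contig_b, e.orient_b) == ("A", "+", "B", "+")
        assert e.supporting_orfs == ["o1"] and not pal

    def test_identical_adjacency_from_two_orfs_merges_support(self):
        cls = {"o1": _cls("o1", 2, "AB"), "o2": _cls("o2", 2, "AB")}
        chosen = {
            "o1": _chosen("o1", [("A", "+"), ("B", "+")]),
            # o2 sees the junction from the other side: B- then A-
            "o2": _chosen("o2", [("B", "-"), ("A", "-")]),
        }
        edges, _ = build_scaffold_graph(cls, chosen)
        (e,) = edges
        assert e.support == 2

    def test_palindromic_path_is_flagged_not_used(self):
        cls = {"o1": _cls("o1", 2, "AB")}
        chosen = {"o1": _chosen("o1", [("A", "+"), ("B", "+"), ("A", "+")])}
        edges, pal = build_scaffold_graph(cls, chosen)
        assert pal == ["o1"] and edges == []

    def test_category_1_and_3_orfs_contribute_no_edges(self):
        cls = {"o1": _cls("o1", 1, "A"), "o2": _cls("o2", 3, "AB")}
        chosen = {"o1": _chosen("o1", [("A", "+")]),
                  "o2": _chosen("o2", [("A", "+"), ("B", "+")])}
        edges, _ = build_scaffold_graph(cls, chosen)
        assert edges == []


def _edge(a, oa, b, ob, orfs):
    from orfweaver.scaffolder import AdjacencyEdge, _normalize

    key = _normalize(a, oa, b, ob)
    return AdjacencyEdge(*key, supporting_orfs=list(orfs))


class TestConflicts:
    def test_chain_is_assembled_into_one_path(self):
        edges = [_edge("A", "+", "B", "+", ["o1", "o2", "o3"]),
                 _edge("B", "+", "C", "+", ["o4", "o5"])]
        plans, review = resolve_conflicts(edges)
        (plan,) = plans
        assert [c for c, _ in plan.components] == ["A", "B", "C"]
        assert review == []
        assert plan.provenance == [["o1", "o2", "o3"], ["o4", "o5"]]

    def test_competing_edge_for_same_end_goes_to_review(self):
        edges = [_edge("A", "+", "B", "+", ["o1", "o2", "o3"]),
                 _edge("A", "+", "X", "+", ["o9"])]
        plans, review = resolve_conflicts(edges)
        (plan,) = plans
        assert [c for c, _ in plan.components] == ["A", "B"]
        assert [e.support for e in review] == [1]

    def test_cycle_closing_edge_reviewed(self):
        edges = [_edge("A", "+", "B", "+", ["o1", "o2"]),
                 _edge("B", "+", "C", "+", ["o3", "o4"]),
                 _edge("C", "+", "A", "+", ["o5"])]
        plans, review = resolve_conflicts(edges)
        assert len(plans) == 1 and len(review) == 1
        assert review[0].contig_a == "A" and review[0].contig_b == "C"

    def test_conflict_free_graph_has_empty_review_set(self):
        edges = [_edge("A", "+", "B", "-", ["o1"])]
        plans, review = resolve_conflicts(edges)
        assert review == []
        (plan,) = plans
        assert len(plan.components) == 2


class TestEmission:
    def test_junction_is_exactly_100_n(self):
        contigs = [SeqRecord("A", "A" * 1000), SeqRecord("B", "C" * 500)]
        plan = ScaffoldPlan("s1", [("A", "+"), ("B", "-")])
        (sc,) = emit_scaffolds([plan], contigs)
        assert len(sc.seq) == 1600
        assert sc.seq[1000:1100] == "N" * 100
        assert "N" not in sc.seq[:1000] and "N" not in sc.seq[1100:]

    def test_reverse_component_is_reverse_complemented(self):
        contigs = [SeqRecord("A", "AACCGGTT"), SeqRecord("B", "ACGTAAAA")]
        plan = ScaffoldPlan("s1", [("A", "+"), ("B", "-")])
        (sc,) = emit_scaffolds([plan], contigs, CFG)
        assert sc.seq.endswith(str(Seq("ACGTAAAA").reverse_complement()))

    def test_empty_plan_set_passes_assembly_through(self):
        contigs = [SeqRecord("A", "ACGT"), SeqRecord("B", "GGCC")]
        out = emit_scaffolds([], contigs)
        assert [(r.id, r.seq) for r in out] == [(r.id, r.seq) for r in contigs]

    def test_contig_in_two_plans_is_an_error(self):
        contigs = [SeqRecord("A", "ACGT"), SeqRecord("B", "GGCC")]
        plans = [ScaffoldPlan("s1", [("A", "+"), ("B", "+")]),
                 ScaffoldPlan("s2", [("B", "+")])]
        with pytest.raises(ScaffoldError, match="two plans"):
            emit_scaffolds(plans, contigs)

    def test_sequence_conservation(self, truth6, frag_within, transcripts6):
        comps, hits = transcripts6
        res = run_pipeline(comps, hits, truth6.reference_proteins,
                           truth6.exon_models, frag_within.contigs,
                           truth6.gene_of_protein)
        in_bases = sum(len(c.seq) for c in frag_within.contigs)
        out_bases = sum(len(r.seq.replace("N", "")) for r in res.scaffolds)
        assert out_bases == in_bases


class TestRescue:
    def _setup(self, truth):
        """Drop the contig piece bearing exon 2 of one gene.

        The host contig is cut in the flanking introns and the middle piece
        discarded, so exon 2 survives only in a secondary assembly — the
        situation the rescue step exists for.
        """
        frag = synth.fragment_assembly(truth, "between_genes", flip_prob=0.0, seed=21)
        gene = truth.genes[2]
        target = next(
            s for s in frag.contig_map
            if s.genome_start <= gene.genome_start < s.genome_end
        )
        cut1 = (gene.exons[0][1] + gene.exons[1][0]) // 2 - target.genome_start
        cut2 = (gene.exons[1][1] + gene.exons[2][0]) // 2 - target.genome_start
        contigs = []
        for rec in frag.contigs:
            if rec.id == target.contig_id:
                contigs.append(SeqRecord(f"{rec.id}.left", rec.seq[:cut1]))
                contigs.append(SeqRecord(f"{rec.id}.right", rec.seq[cut2:]))
            else:
                contigs.append(rec)
        return gene, contigs

    def test_missing_exon_found_in_secondary_reclassifies_orf(self, truth6, transcripts6):
        gene, primary = self._setup(truth6)
        comps, hits = transcripts6
        secondary = [("unused_reads", [SeqRecord("genome_copy", truth6.genome)])]
        res = run_pipeline(comps, hits, truth6.reference_proteins,
                           truth6.exon_models, primary,
                           truth6.gene_of_protein, secondary)
        orf_id = f"{gene.gene_symbol}_orf"
        assert res.classifications[orf_id].category == 2
        assert [seg.exon_index for seg in res.imported] == [2]
        assert res.imported[0].source_assembly == "unused_reads"

    def test_exon_absent_everywhere_stays_category_3(self, truth6, transcripts6):
        gene, primary = self._setup(truth6)
        comps, hits = transcripts6
        res = run_pipeline(comps, hits, truth6.reference_proteins,
                           truth6.exon_models, primary,
                           truth6.gene_of_protein, [("empty", [SeqRecord("x", "ACGT" * 10)])])
        orf_id = f"{gene.gene_symbol}_orf"
        assert res.classifications[orf_id].category == 3
        assert 2 in res.classifications[orf_id].missing_exons

    def test_first_secondary_source_wins_and_duplicate_noted(self, truth6, transcripts6):
        gene, primary = self._setup(truth6)
        comps, hits = transcripts6
        secondary = [
            ("unused_reads", [SeqRecord("copy1", truth6.genome)]),
            ("short_read_asm", [SeqRecord("copy2", truth6.genome)]),
        ]
        res = run_pipeline(comps, hits, truth6.reference_proteins,
                           truth6.exon_models, primary,
                           truth6.gene_of_protein, secondary)
        (seg,) = res.imported
        assert seg.source_assembly == "unused_reads"
        assert seg.duplicate_sources == ["short_read_asm"]


class TestRecoveryProperties:
    @pytest.mark.parametrize("seed", range(20))
    def test_true_order_and_orientation_recovered(self, seed):
        truth = synth.simulate_genome(n_genes=5, seed=300 + seed)
        frag = synth.fragment_assembly(truth, "within_genes", within_genes=2,
                                       seed=400 + seed)
        comps, hits = synth.simulate_transcripts(truth, seed=500 + seed)
        res = run_pipeline(comps, hits, truth.reference_proteins,
                           truth.exon_models, frag.contigs,
                           truth.gene_of_protein)
        chain = frag.true_chain()
        true_adj = set()
        for (a, oa), (b, ob) in zip(chain, chain[1:]):
            true_adj.add((a, oa, b, ob))
            flip = {"+": "-", "-": "+"}
            true_adj.add((b, flip[ob], a, flip[oa]))
        applied = 0
        for plan in res.plans:
            for pair in zip(plan.components, plan.components[1:]):
                (a, oa), (b, ob) = pair
                assert (a, oa, b, ob) in true_adj
                applied += 1
        assert applied >= 1  # the within-gene splits produce joinable junctions

    def test_scaffolding_never_decreases_n50_and_reduces_contig_count(
        self, truth6, frag_within, transcripts6
    ):
        comps, hits = transcripts6
        res = run_pipeline(comps, hits, truth6.reference_proteins,
                           truth6.exon_models, frag_within.contigs,
                           truth6.gene_of_protein)
        before = [len(c.seq) for c in frag_within.contigs]
        after_scaffolds = [len(r.seq) for r in res.scaffolds]
        assert nxx(after_scaffolds, 50) >= nxx(before, 50)
        junctions = res.report["junctions_applied"]
        assert len(res.scaffolds) == len(before) - junctions
        # splitting the gapped output back at N-runs recovers the input pieces
        assert sorted(split_at_gaps(res.scaffolds)) == sorted(before)
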