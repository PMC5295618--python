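import pytest
from Bio.Seq import Seq

from orfweaver import synthetic_data as synth
from orfweaver.config import RunConfig
from orfweaver.exon_mapper import (
    ExonPlacement,
    classify_all,
    classify_placement,
    filter_exon_hits,
    map_exons,
    resolve_placements,
    spared,
)
from orfweaver.exon_model import align_translations, emit_exon_fasta, project_exons
from orfweaver.io_formats import SeqRecord, TabularHit
from orfweaver.orf_builder import OrfRecord

CFG = RunConfig()


def _hit(identity, q=(1, 100), s=(201, 300), exon="orf1|exon1|100", contig="tigA"):
    return TabularHit(
        query_id=exon, subject_id=contig, percent_identity=identity,
        alignment_length=q[1] - q[0] + 1, mismatches=0, gap_opens=0,
        q_start=q[0], q_end=q[1], s_start=s[0], s_end=s[1],
        e_value=1e-40, bit_score=180.0,
    )


class TestFilter:
    def test_full_length_hit_above_threshold_accepted(self):
        (p,) = filter_exon_hits([_hit(98.5)], exon_length=100)
        assert p.percent_identity == 98.5
        assert (p.start, p.end) == (200, 300)

    def test_hit_below_strict_threshold_rejected(self):
        assert filter_exon_hits([_hit(97.9)], exon_length=100) == []

    def test_exactly_98_rejected_under_strict_greater_than(self):
        assert filter_exon_hits([_hit(98.0)], exon_length=100) == []
        lax = CFG.replace(exon_identity_strict=False)
        assert len(filter_exon_hits([_hit(98.0)], 100, lax)) == 1

    def test_boundary_slack_up_to_10_per_end(self):
        (p,) = filter_exon_hits([_hit(99.0, q=(11, 90))], exon_length=100)
        assert (p.boundary_slack_left, p.boundary_slack_right) == (10, 10)
        assert filter_exon_hits([_hit(99.0, q=(12, 100))], exon_length=100) == []

    def test_sixteen_bp_exon_is_spared(self):
        assert spared(16) and not spared(17)


class TestResolver:
    def _placement(self, ordinal, contig, identity=100.0, start=0):
        return ExonPlacement("orf1", ordinal, contig, start, start + 50, "+", identity)

    def test_shared_exon_assigned_to_the_common_contig(self):
        cands = {
            1: [self._placement(1, "A", start=0)],
            2: [self._placement(2, "A", start=100), self._placement(2, "B")],
            3: [self._placement(3, "A", start=200)],
        }
        chosen, tie, mode = resolve_placements(cands)
        assert chosen[2].contig_id == "A"
        assert not tie and mode == "exhaustive"

    def test_single_hit_exons_resolved_by_identity(self):
        cands = {1: [self._placement(1, "A", identity=99.1),
                     self._placement(1, "B", identity=99.9)]}
        chosen, _, _ = resolve_placements(cands)
        assert chosen[1].contig_id == "B"

    def test_exact_tie_flagged_and_broken_to_lower_contig_set(self):
        cands = {1: [self._placement(1, "B"), self._placement(1, "A")]}
        chosen, tie, _ = resolve_placements(cands)
        assert chosen[1].contig_id == "A"
        assert tie

    def test_large_candidate_space_uses_greedy(self):
        cfg = CFG.replace(resolver_exhaustive_limit=4)
        cands = {
            o: [self._placement(o, c, start=o * 60) for c in "ABC"]
            for o in range(1, 4)
        }
        chosen, tie, mode = resolve_placements(cands, cfg)
        assert mode == "greedy"
        assert len({p.contig_id for p in chosen.values()}) == 1


class TestClassification:
    def _p(self, ordinal, contig, start, strand="+"):
        return ExonPlacement("orf1", ordinal, contig, start, start + 50, strand, 100.0)

    def test_single_contig_ordered_is_category_1(self):
        chosen = {i: self._p(i, "A", i * 100) for i in range(1, 6)}
        cls = classify_placement("orf1", list(range(1, 6)), chosen)
        assert cls.category == 1 and not cls.missing_exons

    def test_two_contigs_with_internal_order_is_category_2(self):
        chosen = {i: self._p(i, "A", i * 100) for i in (1, 2, 3)}
        # minus-strand contig: transcript order means descending coordinates
        chosen |= {i: self._p(i, "B", (7 - i) * 100, "-") for i in (4, 5, 6)}
        cls = classify_placement("orf1", list(range(1, 7)), chosen)
        assert cls.category == 2
        assert cls.contigs_used == ["A", "B"]

    def test_unplaced_exon_gives_category_3_with_missing_list(self):
        chosen = {i: self._p(i, "A", i * 100) for i in (1, 2, 3, 5)}
        cls = classify_placement("orf1", [1, 2, 3, 4, 5], chosen)
        assert cls.category == 3 and cls.missing_exons == [4]

    def test_spared_exon_alone_never_causes_category_3(self):
        chosen = {i: self._p(i, "A", i * 100) for i in (1, 3)}
        cls = classify_placement("orf1", [1, 3], chosen, spared_ordinals=[2])
        assert cls.category == 1
        assert cls.spared_exons == [2]

    def test_wrong_order_on_contig_is_category_3(self):
        chosen = {1: self._p(1, "A", 500), 2: self._p(2, "A", 100),
                  3: self._p(3, "A", 900)}
        cls = classify_placement("orf1", [1, 2, 3], chosen)
        assert cls.category == 3 and cls.misordered

    def test_mixed_strands_on_contig_is_category_3(self):
        chosen = {1: self._p(1, "A", 100), 2: self._p(2, "A", 200, "-")}
        cls = classify_placement("orf1", [1, 2], chosen)
        assert cls.category == 3 and cls.misoriented

    def test_revisiting_a_contig_is_category_3(self):
        chosen = {1: self._p(1, "A", 100), 2: self._p(2, "B", 100),
                  3: self._p(3, "A", 300)}
        cls = classify_placement("orf1", [1, 2, 3], chosen)
        assert cls.category == 3 and cls.misordered


def _exon_records_for(truth):
    records = []
    for gene in truth.genes:
        orf = OrfRecord(orf_id=f"{gene.gene_symbol}_orf", gene_symbol=gene.gene_symbol,
                        cdna=gene.cds, status="FL",
                        reference_protein_id=gene.protein_id)
        aa = orf.translation()[:-1]
        model = project_exons(orf, gene.exon_model, (aa, aa))
        records.extend(emit_exon_fasta(model, orf))
    return records


class TestOnSyntheticAssemblies:
    def test_between_gene_fragmentation_gives_all_category_1(self, truth6, frag_between):
        records = _exon_records_for(truth6)
        classifications, _ = classify_all(records, frag_between.contigs)
        assert {c.category for c in classifications.values()} == {1}

    def test_within_gene_fragmentation_moves_exactly_those_genes_to_category_2(
        self, truth6, frag_within
    ):
        records = _exon_records_for(truth6)
        classifications, _ = classify_all(records, frag_within.contigs)
        cat2 = {o for o, c in classifications.items() if c.category == 2}
        # the two extra breakpoints relative to between-gene cuts split genes
        assert len(cat2) == 2
        assert all(c.category in (1, 2) for c in classifications.values())

    def test_reverse_complemented_contig_yields_minus_placements(self, truth6):
        frag = synth.fragment_assembly(truth6, "between_genes", flip_prob=1.0, seed=5)
        records = _exon_records_for(truth6)
        classifications, chosen = classify_all(records, frag.contigs)
        assert {c.category for c in classifications.values()} == {1}
        strands = {p.strand for ch in chosen.values() for p in ch.values()}
        assert strands == {"-"}

    def test_categories_are_exhaustive_and_exclusive(self, truth6, frag_within):
        records = _exon_records_for(truth6)
        classifications, _ = classify_all(records, frag_within.contigs)
        assert len(classifications) == len(truth6.genes)
        for c in classifications.values():
            assert c.category in (1, 2, 3)


def test_internal_aligner_finds_slightly_diverged_exon():
    # one substitution in a 200-bp exon: 99.5% identity, still accepted
    import random

    rng = random.Random(9)
    exon_seq = "".join(rng.choices("ACGT", k=200))
    mid = "A" if exon_seq[100] != "A" else "C"
    diverged = exon_seq[:100] + mid + exon_seq[101:]
    contig = SeqRecord(
        "tigA",
        "".join(rng.choices("ACGT", k=300)) + diverged + "".join(rng.choices("ACGT", k=300)),
    )
    rec = SeqRecord("orf1|exon1|200", exon_seq)
    cands, _ = map_exons([rec], [contig])
    placements = cands["orf1"][1]
    assert placements
    assert placements[0].percent_identity > 98.0
    assert placements[0].start == 300 and placements[0].end == 500
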