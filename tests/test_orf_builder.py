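import random

import pytest

from orfweaver import synthetic_data as synth
from orfweaver.config import RunConfig
from orfweaver.io_formats import TabularHit
from orfweaver.orf_builder import (
    MergeError,
    OrfRecord,
    OrthologAssignment,
    TranscriptComponent,
    assign_ortholog,
    assign_terminal_codons,
    build_orfs,
    can_merge,
    classify_orf,
    merge_components,
    select_isoforms,
)

CFG = RunConfig()


def _hit(species, protein, e, bits=100.0, q=(1, 50), s=(1, 50)):
    return TabularHit(
        query_id="c1", subject_id=f"{species}|{protein}", percent_identity=95.0,
        alignment_length=q[1] - q[0] + 1, mismatches=0, gap_opens=0,
        q_start=q[0], q_end=q[1], s_start=s[0], s_end=s[1],
        e_value=e, bit_score=bits,
    )


class TestAssignOrtholog:
    def test_panel_fallback_prefers_first_species_with_significant_hit(self):
        # mouse hit misses the cutoff, rat qualifies -> rat wins despite order
        hits = [_hit("mouse", "P1", 1e-8), _hit("rat", "P2", 1e-20)]
        oa = assign_ortholog(hits, e_cutoff=1e-10)
        assert oa.reference_species == "rat"
        assert oa.reference_protein_id == "rat|P2"

    def test_mouse_preferred_when_both_qualify(self):
        hits = [_hit("rat", "P2", 1e-30), _hit("mouse", "P1", 1e-12)]
        assert assign_ortholog(hits).reference_species == "mouse"

    def test_empty_hit_set_returns_none(self):
        assert assign_ortholog([]) is None
        assert assign_ortholog([_hit("mouse", "P1", 1e-3)]) is None  # none qualify

    def test_evalue_tie_broken_by_bit_score(self):
        hits = [
            _hit("mouse", "P1", 1e-12, bits=200.0),
            _hit("mouse", "P2", 1e-12, bits=300.0),
        ]
        assert assign_ortholog(hits).reference_protein_id == "mouse|P2"


def _component_pair(cds, a_span, b_span):
    """Two codon-aligned fragments of one CDS with exact assignments."""
    ref_aa_len = len(cds) // 3 - 1
    comps, oas = [], []
    for name, (s, e) in (("a", a_span), ("b", b_span)):
        comp = TranscriptComponent(id=name, cdna=cds[s:e])
        s_aa, e_aa = s // 3 + 1, min(e // 3, ref_aa_len)
        oas.append(
            OrthologAssignment(
                component_id=name, reference_protein_id="mouse|PROTg",
                reference_species="mouse", e_value=1e-40, bit_score=2.0 * (e_aa - s_aa + 1),
                match_q_start=1, match_q_end=e_aa - s_aa + 1,
                match_s_start=s_aa, match_s_end=e_aa,
            )
        )
        comps.append(comp)
    return comps, oas


@pytest.fixture(scope="module")
def cds120():
    rng = random.Random(7)
    return synth._random_cds(rng, 40)  # 120 nt incl. stop


class TestMerging:
    def test_all_four_conditions_met_allows_merge(self, cds120):
        (a, b), (oa, ob) = _component_pair(cds120, (0, 66), (48, 120))
        ref = {"mouse|PROTg": str(__import__("Bio.Seq", fromlist=["Seq"]).Seq(cds120).translate())[:-1]}
        d = can_merge(a, b, oa, ob, CFG, ref)
        assert d.conditions == (True, True, True, True)
        assert d.ok and d.overlap_len == 18

    def test_fourteen_base_overlap_fails_condition_three(self, cds120):
        (a, b), (oa, ob) = _component_pair(cds120, (0, 60), (46, 120 - 2))
        # overlap is 60-46 = 14 identical bases: one short of the threshold
        d = can_merge(a, b, oa, ob, CFG)
        assert not d.overlap_found
        assert not d.ok

    def test_fifteen_base_overlap_passes_condition_three(self, cds120):
        (a, b), (oa, ob) = _component_pair(cds120, (0, 60), (45, 120))
        d = can_merge(a, b, oa, ob, CFG)
        assert d.overlap_found and d.overlap_len == 15

    def test_different_reference_fails_condition_one_not_error(self, cds120):
        (a, b), (oa, ob) = _component_pair(cds120, (0, 66), (48, 120))
        ob.reference_protein_id = "rat|OTHER"
        d = can_merge(a, b, oa, ob, CFG)
        assert not d.same_reference and not d.ok

    def test_merge_reconstructs_generator_cds(self, cds120):
        (a, b), (oa, ob) = _component_pair(cds120, (0, 66), (48, 120))
        d = can_merge(a, b, oa, ob, CFG)
        merged = merge_components(a, b, d)
        assert merged.cdna == cds120
        assert merged.parents == ("a", "b")

    def test_identical_components_merge_is_idempotent(self, cds120):
        (a, b), (oa, ob) = _component_pair(cds120, (0, 120), (0, 120))
        d = can_merge(a, b, oa, ob, CFG)
        assert d.ok
        assert merge_components(a, b, d).cdna == a.cdna

    def test_containment_merge_yields_container(self, cds120):
        (a, b), (oa, ob) = _component_pair(cds120, (0, 120), (30, 90))
        d = can_merge(a, b, oa, ob, CFG)
        assert d.containment is not None
        assert merge_components(a, b, d).cdna == cds120

    def test_overlap_mismatch_refused_with_positions(self, cds120):
        (a, b), (oa, ob) = _component_pair(cds120, (0, 66), (48, 120))
        d = can_merge(a, b, oa, ob, CFG)
        # corrupt one base inside the agreed overlap, then force the merge
        pos = 50
        bad = b.cdna[: pos - 48] + ("A" if b.cdna[pos - 48] != "A" else "C") + b.cdna[pos - 48 + 1 :]
        b_bad = TranscriptComponent(id="b", cdna=bad)
        with pytest.raises(MergeError, match="disagree"):
            merge_components(a, b_bad, d)

    def test_interval_difference_above_threshold_fails_condition_two(self, cds120):
        (a, b), (oa, ob) = _component_pair(cds120, (0, 120), (60, 120))
        # subject spans 39 vs 19 aa: ~51% difference
        d = can_merge(a, b, oa, ob, CFG)
        assert not d.interval_compatible


class TestTerminalCodons:
    def _component(self, upstream_nt, cds_tail="GGGCCCTTTAAA"):
        """Match region preceded by ``upstream_nt`` bases; ATG at position 0."""
        cdna = "ATG" + "CCC" * ((upstream_nt - 3) // 3) + cds_tail
        q_start = upstream_nt // 3 + 1
        oa = OrthologAssignment(
            component_id="c", reference_protein_id="mouse|P", reference_species="mouse",
            e_value=1e-30, bit_score=80.0,
            match_q_start=q_start, match_q_end=q_start + len(cds_tail) // 3 - 1,
            match_s_start=5, match_s_end=4 + len(cds_tail) // 3,
        )
        return TranscriptComponent(id="c", cdna=cdna), oa

    def test_atg_exactly_30_nt_upstream_is_provisional(self):
        c, oa = self._component(30)
        st = assign_terminal_codons(c, oa, ref_length=100)
        assert st.start_provenance == "provisional_upstream"
        assert st.coding_start == 0

    def test_atg_33_nt_upstream_is_absent(self):
        c, oa = self._component(33)
        st = assign_terminal_codons(c, oa, ref_length=100)
        assert st.start_provenance == "absent"

    def test_aligned_start_when_match_covers_reference_residue_one(self):
        cdna = "ATGAAACCCGGG" + "TAA"
        oa = OrthologAssignment(
            component_id="c", reference_protein_id="mouse|P", reference_species="mouse",
            e_value=1e-30, bit_score=80.0,
            match_q_start=1, match_q_end=4, match_s_start=1, match_s_end=4,
        )
        c = TranscriptComponent(id="c", cdna=cdna)
        st = assign_terminal_codons(c, oa, ref_length=4)
        assert st.start_provenance == "aligned"
        assert st.stop_provenance == "aligned"
        assert (st.coding_start, st.coding_end) == (0, 15)

    def test_stop_found_downstream_is_provisional(self):
        cdna = "ATGAAACCCGGG" + "CCCTGA"
        oa = OrthologAssignment(
            component_id="c", reference_protein_id="mouse|P", reference_species="mouse",
            e_value=1e-30, bit_score=80.0,
            match_q_start=1, match_q_end=4, match_s_start=1, match_s_end=4,
        )
        c = TranscriptComponent(id="c", cdna=cdna)
        st = assign_terminal_codons(c, oa, ref_length=10)  # match does not reach end
        assert st.stop_provenance == "provisional_downstream"
        assert st.coding_end == 18


class TestClassification:
    def test_full_length_component_is_fl(self, truth6, transcripts6):
        comps, hits = transcripts6
        result = build_orfs(comps, hits, truth6.reference_proteins,
                            truth6.gene_of_protein)
        assert all(o.status == "FL" for o in result.orfs)
        by_gene = {o.gene_symbol: o for o in result.orfs}
        for gene in truth6.genes:
            assert by_gene[gene.gene_symbol].cdna == gene.cds

    def test_truncated_component_is_pl_missing_start(self, truth6):
        gene = truth6.genes[0]
        # drop the first 60 nt (20 codons): no ATG upstream of the match
        cdna = gene.cds[60:]
        comp = TranscriptComponent(id="t", cdna=cdna)
        ref_aa = len(gene.cds) // 3 - 1
        hits = {"t": [TabularHit(
            "t", gene.protein_id, 100.0, ref_aa - 20, 0, 0,
            1, ref_aa - 20, 21, ref_aa, 1e-80, 300.0,
        )]}
        result = build_orfs([comp], hits, truth6.reference_proteins,
                            truth6.gene_of_protein)
        (orf,) = result.orfs
        assert orf.status == "PL" and orf.pl_reason == "missing_start"

    def test_non_overlapping_fragments_stay_two_pl_records(self, truth6):
        gene = truth6.genes[1]
        L = len(gene.cds)
        a = TranscriptComponent(id="a", cdna=gene.cds[: (L // 2) // 3 * 3 - 30])
        b_start = (L // 2) // 3 * 3 + 30
        b = TranscriptComponent(id="b", cdna=gene.cds[b_start:])
        ref_aa = L // 3 - 1
        hits = {
            "a": [TabularHit("a", gene.protein_id, 100.0, len(a.cdna) // 3, 0, 0,
                             1, len(a.cdna) // 3, 1, len(a.cdna) // 3, 1e-60, 200.0)],
            "b": [TabularHit("b", gene.protein_id, 100.0, ref_aa - b_start // 3, 0, 0,
                             1, ref_aa - b_start // 3, b_start // 3 + 1, ref_aa,
                             1e-60, 200.0)],
        }
        result = build_orfs([a, b], hits, truth6.reference_proteins,
                            truth6.gene_of_protein)
        assert len(result.orfs) == 2
        assert {o.status for o in result.orfs} == {"PL"}
        assert {o.pl_reason for o in result.orfs} == {"missing_start", "missing_end"}


class TestIsoformSelection:
    def _orf(self, oid, gene, n_nt, status="FL"):
        return OrfRecord(orf_id=oid, gene_symbol=gene, cdna="A" * n_nt, status=status)

    def test_longest_fl_is_representative(self):
        reps, sec = select_isoforms([
            self._orf("o1", "g", 900), self._orf("o2", "g", 1200),
        ])
        assert reps["g"].orf_id == "o2"
        assert [o.orf_id for o in sec] == ["o1"] and sec[0].secondary

    def test_equal_length_tie_breaks_to_lower_id(self):
        reps, sec = select_isoforms([
            self._orf("o2", "g", 900), self._orf("o1", "g", 900),
        ])
        assert reps["g"].orf_id == "o1"

    def test_pl_only_gene_flagged_non_fl_representative(self):
        reps, _ = select_isoforms([
            self._orf("o1", "g", 300, "PL"), self._orf("o2", "g", 600, "PL"),
        ])
        assert reps["g"].orf_id == "o2"
        assert reps["g"].non_fl_representative


class TestPipelineProperties:
    @pytest.mark.parametrize("seed", range(5))
    def test_fragmented_genes_recover_exactly_one_fl_orf_each(self, seed):
        truth = synth.simulate_genome(n_genes=4, seed=100 + seed)
        comps, hits = synth.simulate_transcripts(truth, fragments_per_gene=3,
                                                 overlap_nt=18, seed=seed)
        result = build_orfs(comps, hits, truth.reference_proteins,
                            truth.gene_of_protein)
        assert len(result.orfs) == len(truth.genes)
        for gene in truth.genes:
            orf = next(o for o in result.orfs if o.gene_symbol == gene.gene_symbol)
            assert orf.status == "FL"
            assert orf.cdna == gene.cds

    def test_no_fl_orf_contains_internal_stop(self, truth6, transcripts6):
        comps, hits = transcripts6
        result = build_orfs(comps, hits, truth6.reference_proteins,
                            truth6.gene_of_protein)
        for orf in result.orfs:
            if orf.status == "FL":
                aa = orf.translation()
                assert "*" not in aa[:-1]

    def test_merge_order_independence(self, cds120):
        # three mutually compatible fragments: any input order gives the CDS
        from Bio.Seq import Seq

        spans = {"a": (0, 60), "b": (30, 90), "c": (60, 120)}
        ref_aa_len = len(cds120) // 3 - 1
        comps = {}
        hits = {}
        for name, (s, e) in spans.items():
            comps[name] = TranscriptComponent(id=name, cdna=cds120[s:e])
            s_aa, e_aa = s // 3 + 1, min(e // 3, ref_aa_len)
            hits[name] = [TabularHit(
                name, "mouse|PROTg", 100.0, e_aa - s_aa + 1, 0, 0,
                1, e_aa - s_aa + 1, s_aa, e_aa, 1e-40, 2.0 * (e_aa - s_aa + 1),
            )]
        ref = {"mouse|PROTg": str(Seq(cds120).translate())[:-1]}
        for order in (("a", "b", "c"), ("c", "b", "a"), ("b", "a", "c")):
            result = build_orfs([comps[n] for n in order], hits, ref,
                                {"mouse|PROTg": "g"})
            assert len(result.orfs) == 1
            assert result.orfs[0].cdna == cds120
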