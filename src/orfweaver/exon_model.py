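"""Projection of reference exon–gene models onto reconstructed ORF cDNAs.

Each reference protein carries an ordered exon model expressed in CDS
coordinates.  To predict where the exon boundaries fall on a reconstructed
ORF, each boundary is walked through a pairwise alignment of the ORF
translation against the reference protein, so that insertions and deletions
shift downstream boundaries by their net offset.  Boundaries are kept at
exact reference phase (a boundary that splits a codon stays split); the
downstream exon mapper's 10-bp boundary flexibility absorbs split-codon
effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align

from .io_formats import ReferenceExonModel, SeqRecord
from .orf_builder import OrfRecord


class ProjectionError(ValueError):
    pass


@dataclass
class OrfExonModel:
    """Predicted exon structure of one ORF (0-based half-open on the cdna).

    Exon ordinals are the reference ordinals that survive projection; exons
    wholly deleted in the ORF keep their ordinal vacant in ``dropped``.
    """

    orf_id: str
    exons: list[tuple[int, int, int]] = field(default_factory=list)
    dropped: list[int] = field(default_factory=list)

    def exon_length(self, ordinal: int) -> int:
        for idx, start, end in self.exons:
            if idx == ordinal:
                return end - start
        raise KeyError(ordinal)


def align_translations(orf_aa: str, ref_aa: str) -> tuple[str, str]:
    """Global alignment of ORF translation vs reference protein.

    Returns the two gapped rows.  Scoring favours contiguous indels (affine
    gaps) so codon-sized indels stay as single events.
    """
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -4
    aligner.extend_gap_score = -0.5
    aligner.end_gap_score = 0.0  # PL-ORFs legitimately miss reference termini
    aln = aligner.align(orf_aa, ref_aa)[0]
    return str(aln[0]), str(aln[1])


def _ref_to_orf_map(orf_row: str, ref_row: str) -> list[int | None]:
    """Map each reference aa position to its ORF aa position (None = deleted).

    Walks alignment columns once; for a reference residue aligned to a gap,
    the entry is None.
    """
    mapping: list[int | None] = []
    oi = ri = 0
    for oc, rc in zip(orf_row, ref_row):
        if rc != "-":
            mapping.append(oi if oc != "-" else None)
            ri += 1
        if oc != "-":
            oi += 1
    return mapping


def project_exons(
    orf: OrfRecord,
    ref_model: ReferenceExonModel,
    alignment: tuple[str, str] | None = None,
) -> OrfExonModel:
    """Project the reference exon boundaries onto the ORF cdna.

    ``alignment`` is a pair of gapped rows (ORF translation, reference
    protein); when omitted it is computed.  A reference boundary at CDS
    position ``b`` (aa index b//3, phase b%3) maps to ORF nt position
    ``3*j + phase`` where ``j`` is the ORF residue aligned to that reference
    residue.  Exons wholly deleted in the ORF are dropped and recorded.
    """
    orf_aa = orf.translation()
    if orf_aa.endswith("*"):
        orf_aa = orf_aa[:-1]
    ref_model.validate()
    if alignment is None:
        raise ProjectionError(
            f"{orf.orf_id}: an ORF-vs-reference alignment is required "
            "(see align_translations)"
        )
    orf_row, ref_row = alignment
    if len(orf_row) != len(ref_row):
        raise ProjectionError(f"{orf.orf_id}: alignment rows differ in length")
    mapping = _ref_to_orf_map(orf_row, ref_row)
    orf_nt_len = len(orf_aa) * 3

    def map_boundary(b: int, *, is_end: bool) -> int | None:
        """ORF nt position for reference CDS position b (None if deleted)."""
        if b == 0:
            return 0
        if b >= len(mapping) * 3:
            return orf_nt_len
        aa_i, phase = divmod(b, 3)
        # anchor on the residue containing the boundary; for a phase-0
        # boundary anchor on the residue to the left so a deletion just
        # after it does not lose the boundary
        anchor = aa_i if phase else aa_i - 1
        j = mapping[anchor]
        if j is None:
            # nearest surviving residue: leftward for exon ends, rightward
            # for exon starts, so deleted spans collapse to a point
            step = -1 if is_end else 1
            k = anchor + step
            while 0 <= k < len(mapping) and mapping[k] is None:
                k += step
            if not (0 <= k < len(mapping)):
                return orf_nt_len if is_end else 0
            j = mapping[k]
            return (j + 1) * 3 if is_end else j * 3
        return j * 3 + phase if phase else (j + 1) * 3

    model = OrfExonModel(orf_id=orf.orf_id)
    for ordinal, cds_start, cds_end in ref_model.exons:
        start = map_boundary(cds_start, is_end=False) if cds_start else 0
        end = map_boundary(cds_end, is_end=True)
        if start is None or end is None or end <= start:
            model.dropped.append(ordinal)
            continue
        if not (0 <= start < end <= orf_nt_len + 3):
            raise ProjectionError(
                f"{orf.orf_id}: exon {ordinal} maps outside the cdna "
                f"([{start},{end}) vs length {orf_nt_len})"
            )
        model.exons.append((ordinal, start, end))

    # the final exon absorbs the stop codon if the ORF carries one
    if model.exons and len(orf.cdna) == orf_nt_len + 3:
        ordinal, start, end = model.exons[-1]
        if end == orf_nt_len:
            model.exons[-1] = (ordinal, start, end + 3)
    _check_tiling(model, orf)
    return model


def _check_tiling(model: OrfExonModel, orf: OrfRecord) -> None:
    pos = 0
    for ordinal, start, end in model.exons:
        if start != pos:
            raise ProjectionError(
                f"{orf.orf_id}: projected exons do not tile the coding region "
                f"(exon {ordinal} starts at {start}, expected {pos})"
            )
        pos = end
    if model.exons and pos != len(orf.cdna):
        raise ProjectionError(
            f"{orf.orf_id}: projected exons cover {pos} of {len(orf.cdna)} nt"
        )


def emit_exon_fasta(
    model: OrfExonModel, orf: OrfRecord, min_length: int = 17
) -> list[SeqRecord]:
    """One record per projected exon; ids ``{orf_id}|exon{i}|{length}``.

    The concatenation of the emitted sequences equals the ORF coding
    sequence.  Exons shorter than ``min_length`` are still emitted but
    tagged ``below_min_length`` so the mapper can spare them.
    """
    records = []
    for ordinal, start, end in model.exons:
        length = end - start
        desc = "below_min_length" if length < min_length else ""
        records.append(
            SeqRecord(
                id=f"{orf.orf_id}|exon{ordinal}|{length}",
                seq=orf.cdna[start:end],
                description=desc,
            )
        )
    return records


def parse_exon_id(record_id: str) -> tuple[str, int, int]:
    """Inverse of the exon record id: (orf_id, ordinal, predicted_length)."""
    orf_id, exon_tok, length = record_id.rsplit("|", 2)
    return orf_id, int(exon_tok.removeprefix("exon")), int(length)
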