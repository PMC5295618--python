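"""Reconstruction of full- and partial-length ORFs from transcript components.

A *transcript component* is one fragment of a de-novo transcriptome assembly
carrying a candidate coding region.  Components are assigned a reference
ortholog by best protein hit (with a species fallback panel), merged into
longer coding sequences when four conditions hold simultaneously, given
provisional terminal codons by an in-frame scan near the reference match,
and finally classified as full-length (FL) or partial-length (PL) ORFs.

The four merge conditions:

1. both components name the same reference protein as best (or near-best) hit;
2. their reference-protein match intervals differ by <= 15% in length;
3. they share >= 15 identical overlapping nucleotide bases;
4. the merged reading frame keeps similarity to the reference (no in-frame
   stop is introduced and identity over the merge window stays high).

Components meeting some but not all conditions are routed to a manual-review
queue, never merged automatically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq

from .config import DEFAULT_CONFIG, RunConfig
from .io_formats import TabularHit

STOP_CODONS = {"TAA", "TAG", "TGA"}


class MergeError(ValueError):
    pass


@dataclass
class TranscriptComponent:
    """An assembled transcript fragment with its candidate coding region."""

    id: str
    cdna: str
    frame: int = 0
    coding_start: int = 0
    coding_end: int | None = None
    parents: tuple[str, ...] = ()
    internal_gap: bool = False

    def __post_init__(self) -> None:
        if self.coding_end is None:
            self.coding_end = len(self.cdna)
        span = self.coding_end - self.coding_start
        if span % 3 != 0:
            raise ValueError(
                f"{self.id}: coding span {span} not divisible by 3"
            )
        if not (0 <= self.coding_start <= self.coding_end <= len(self.cdna)):
            raise ValueError(f"{self.id}: coding interval outside cdna")

    @property
    def coding(self) -> str:
        return self.cdna[self.coding_start : self.coding_end]

    def translation(self) -> str:
        return str(Seq(self.coding).translate())


@dataclass
class OrthologAssignment:
    """Best reference-protein hit for one component.

    Match intervals are 1-based inclusive amino-acid coordinates: ``q`` on the
    translated coding region of the component, ``s`` on the reference protein.
    """

    component_id: str
    reference_protein_id: str
    reference_species: str
    e_value: float
    bit_score: float
    match_q_start: int
    match_q_end: int
    match_s_start: int
    match_s_end: int
    percent_identity: float = 100.0
    #: subject intervals of the original components folded into this
    #: assignment; merged assignments accumulate them so later merge checks
    #: can compare like with like (the interval adjacent to the junction)
    constituents: tuple[tuple[int, int], ...] = ()

    def constituent_intervals(self) -> tuple[tuple[int, int], ...]:
        return self.constituents or ((self.match_s_start, self.match_s_end),)

    @property
    def subject_span(self) -> int:
        return self.match_s_end - self.match_s_start + 1

    @property
    def query_span(self) -> int:
        return self.match_q_end - self.match_q_start + 1


@dataclass
class TerminalStatus:
    start_provenance: str  # aligned | provisional_upstream | absent
    stop_provenance: str   # aligned | provisional_downstream | absent
    coding_start: int
    coding_end: int


@dataclass
class OrfRecord:
    orf_id: str
    gene_symbol: str
    cdna: str
    status: str                      # FL | PL
    pl_reason: str | None = None     # missing_start | missing_end | missing_internal
    start_codon_provenance: str = "absent"
    stop_codon_provenance: str = "absent"
    source_component_ids: tuple[str, ...] = ()
    reference_protein_id: str = ""
    secondary: bool = False
    non_fl_representative: bool = False

    def translation(self) -> str:
        return str(Seq(self.cdna).translate())


@dataclass
class MergeDecision:
    ok: bool
    same_reference: bool
    interval_compatible: bool
    overlap_found: bool
    frame_preserved: bool
    a_first: bool = True
    overlap_len: int = 0
    containment: str | None = None   # "a_in_b" | "b_in_a"
    notes: str = ""

    @property
    def conditions(self) -> tuple[bool, bool, bool, bool]:
        return (
            self.same_reference,
            self.interval_compatible,
            self.overlap_found,
            self.frame_preserved,
        )

    @property
    def partial(self) -> bool:
        """Some but not all conditions met: a manual-curation case."""
        return any(self.conditions) and not all(self.conditions)


def _species_of(subject_id: str) -> str:
    """Species of a reference protein id of the form ``species|protein``."""
    return subject_id.split("|", 1)[0] if "|" in subject_id else ""


def assign_ortholog(
    hits: Sequence[TabularHit],
    panel_order: Sequence[str] | None = None,
    e_cutoff: float = DEFAULT_CONFIG.e_cutoff,
    species_of=None,
) -> OrthologAssignment | None:
    """Pick the best reference hit for one component.

    The first species in ``panel_order`` with any hit at ``e <= e_cutoff``
    supplies the assignment; within that species the hit with the lowest
    e-value wins, ties broken by bit score then subject id.  Returns ``None``
    when no species qualifies.
    """
    if panel_order is None:
        panel_order = DEFAULT_CONFIG.panel_order
    if species_of is None:
        species_of = _species_of
    if not hits:
        return None
    by_species: dict[str, list[TabularHit]] = {}
    for h in hits:
        if h.e_value <= e_cutoff:
            by_species.setdefault(species_of(h.subject_id), []).append(h)
    for species in panel_order:
        pool = by_species.get(species)
        if not pool:
            continue
        best = min(pool, key=lambda h: (h.e_value, -h.bit_score, h.subject_id))
        return OrthologAssignment(
            component_id=best.query_id,
            reference_protein_id=best.subject_id,
            reference_species=species,
            e_value=best.e_value,
            bit_score=best.bit_score,
            match_q_start=best.q_start,
            match_q_end=best.q_end,
            match_s_start=best.s_start,
            match_s_end=best.s_end,
            percent_identity=best.percent_identity,
        )
    return None


def _find_overlap(left: str, right: str, cfg: RunConfig) -> int:
    """Longest suffix(left)/prefix(right) overlap >= min_overlap_nt, else 0.

    Exact by default; with ``allow_overlap_mismatch`` up to one mismatch per
    50 nt of overlap is tolerated.
    """
    max_l = min(len(left), len(right))
    for length in range(max_l, cfg.min_overlap_nt - 1, -1):
        a, b = left[-length:], right[:length]
        if a == b:
            return length
        if cfg.allow_overlap_mismatch:
            mm = sum(x != y for x, y in zip(a, b))
            if mm <= length // 50:
                return length
    return 0


def _near_best(hits: Sequence[TabularHit] | None, protein_id: str, frac: float) -> bool:
    """Is ``protein_id`` within ``frac`` of the component's best bit score?"""
    if not hits:
        return True  # without the full hit list, trust the assignment
    best_bits = max(h.bit_score for h in hits)
    mine = max((h.bit_score for h in hits if h.subject_id == protein_id), default=None)
    return mine is not None and mine >= best_bits * (1.0 - frac)


def can_merge(
    a: TranscriptComponent,
    b: TranscriptComponent,
    oa: OrthologAssignment,
    ob: OrthologAssignment,
    cfg: RunConfig = DEFAULT_CONFIG,
    reference_proteins: Mapping[str, str] | None = None,
    hits_a: Sequence[TabularHit] | None = None,
    hits_b: Sequence[TabularHit] | None = None,
) -> MergeDecision:
    """Evaluate the four merge conditions for a pair of components.

    ``reference_proteins`` (protein id -> amino-acid sequence) enables the
    identity half of condition 4; without it only the stop-codon check runs.
    """
    # condition 1: same reference protein, best or near-best for both
    same_ref = (
        oa.reference_protein_id == ob.reference_protein_id
        and _near_best(hits_a, oa.reference_protein_id, cfg.near_best_bits)
        and _near_best(hits_b, ob.reference_protein_id, cfg.near_best_bits)
    )

    a_first = (oa.match_s_start, oa.match_s_end, a.id) <= (
        ob.match_s_start,
        ob.match_s_end,
        b.id,
    )
    up, down = (a, b) if a_first else (b, a)
    up_oa, down_oa = (oa, ob) if a_first else (ob, oa)

    # condition 2: match intervals differ by <= max_interval_diff.  For a
    # previously merged component, compare the constituent interval adjacent
    # to the prospective junction, not the accumulated union
    if cfg.interval_diff_on == "query":
        la, lb = oa.query_span, ob.query_span
    else:
        iv_up = max(up_oa.constituent_intervals(), key=lambda t: t[1])
        iv_down = min(down_oa.constituent_intervals(), key=lambda t: t[0])
        la = iv_up[1] - iv_up[0] + 1
        lb = iv_down[1] - iv_down[0] + 1
    interval_ok = abs(la - lb) / max(la, lb) <= cfg.max_interval_diff

    # condition 3: >= 15 identical overlapping bases
    containment = None
    if down.coding in up.coding:
        containment = "b_in_a" if a_first else "a_in_b"
        overlap_len = len(down.coding)
    elif up.coding in down.coding:
        containment = "a_in_b" if a_first else "b_in_a"
        overlap_len = len(up.coding)
    else:
        overlap_len = _find_overlap(up.coding, down.coding, cfg)
    overlap_ok = overlap_len >= cfg.min_overlap_nt

    # condition 4: the merged frame keeps similarity to the reference
    frame_ok = False
    if overlap_ok:
        if containment:
            merged_coding = (
                up.coding if len(up.coding) >= len(down.coding) else down.coding
            )
        else:
            merged_coding = up.coding + down.coding[overlap_len:]
        if len(merged_coding) % 3 == 0:
            aa = str(Seq(merged_coding).translate())
            frame_ok = "*" not in aa[:-1] if aa.endswith("*") else "*" not in aa
            if frame_ok and reference_proteins is not None:
                ref = reference_proteins.get(oa.reference_protein_id)
                if ref is not None:
                    up_oa = oa if a_first else ob
                    # merge window: the overlap region, in merged aa coords
                    w0 = (len(up.coding) - overlap_len) // 3
                    w1 = -(-len(up.coding) // 3)
                    offset = up_oa.match_s_start - up_oa.match_q_start
                    matches = total = 0
                    for p in range(w0, min(w1, len(aa))):
                        rp = p + offset
                        if 0 <= rp < len(ref) and aa[p] != "*":
                            total += 1
                            matches += aa[p] == ref[rp]
                    if total:
                        frame_ok = matches / total >= cfg.min_merge_identity

    ok = same_ref and interval_ok and overlap_ok and frame_ok
    return MergeDecision(
        ok=ok,
        same_reference=same_ref,
        interval_compatible=interval_ok,
        overlap_found=overlap_ok,
        frame_preserved=frame_ok,
        a_first=a_first,
        overlap_len=overlap_len,
        containment=containment,
    )


def merge_components(
    a: TranscriptComponent,
    b: TranscriptComponent,
    decision: MergeDecision,
) -> TranscriptComponent:
    """Merge two components along the overlap found by :func:`can_merge`.

    The merged cdna is upstream-prefix + shared overlap + downstream-suffix.
    Disagreeing overlap bases refuse the merge, reporting mismatch positions.
    """
    if not decision.overlap_found:
        raise MergeError(f"no qualifying overlap between {a.id} and {b.id}")
    up, down = (a, b) if decision.a_first else (b, a)
    if decision.containment:
        keep = up if len(up.coding) >= len(down.coding) else down
        return TranscriptComponent(
            id=f"{up.id}+{down.id}",
            cdna=keep.coding,
            parents=(a.id, b.id),
        )
    left = up.coding[-decision.overlap_len:]
    right = down.coding[: decision.overlap_len]
    mismatches = [i for i, (x, y) in enumerate(zip(left, right)) if x != y]
    if mismatches:
        raise MergeError(
            f"overlap bases disagree between {up.id} and {down.id} at "
            f"overlap positions {mismatches}"
        )
    merged = up.coding + down.coding[decision.overlap_len :]
    return TranscriptComponent(
        id=f"{up.id}+{down.id}",
        cdna=merged,
        parents=(a.id, b.id),
    )


def merge_assignments(
    oa: OrthologAssignment, ob: OrthologAssignment, merged: TranscriptComponent
) -> OrthologAssignment:
    """Combined assignment for a merged component (union of match intervals)."""
    s_start = min(oa.match_s_start, ob.match_s_start)
    s_end = max(oa.match_s_end, ob.match_s_end)
    return OrthologAssignment(
        component_id=merged.id,
        reference_protein_id=oa.reference_protein_id,
        reference_species=oa.reference_species,
        e_value=min(oa.e_value, ob.e_value),
        bit_score=oa.bit_score + ob.bit_score,
        match_q_start=1,
        match_q_end=min(len(merged.coding) // 3, s_end - s_start + 1),
        match_s_start=s_start,
        match_s_end=s_end,
        percent_identity=min(oa.percent_identity, ob.percent_identity),
        constituents=oa.constituent_intervals() + ob.constituent_intervals(),
    )


def assign_terminal_codons(
    c: TranscriptComponent,
    oa: OrthologAssignment,
    ref_length: int,
    cfg: RunConfig = DEFAULT_CONFIG,
) -> TerminalStatus:
    """Assign start/stop codon provenance and adjust the coding interval.

    A start is *aligned* when the match covers reference residue 1 and the
    aligned codon is ATG; otherwise an in-frame ATG at most 30 nt upstream of
    the match region becomes a *provisional_upstream* start (nearest to the
    match start wins).  Stops are handled symmetrically downstream.
    """
    cdna = c.cdna
    match_nt_start = c.coding_start + 3 * (oa.match_q_start - 1)
    match_nt_end = c.coding_start + 3 * oa.match_q_end

    start_prov, start_pos = "absent", match_nt_start
    if oa.match_s_start == 1 and cdna[match_nt_start : match_nt_start + 3] == "ATG":
        start_prov, start_pos = "aligned", match_nt_start
    else:
        for off in range(3, cfg.upstream_scan_nt + 1, 3):
            j = match_nt_start - off
            if j < 0:
                break
            if cdna[j : j + 3] == "ATG":
                start_prov, start_pos = "provisional_upstream", j
                break

    stop_prov, stop_pos = "absent", match_nt_end
    tail = cdna[match_nt_end : match_nt_end + 3]
    if oa.match_s_end == ref_length and tail in STOP_CODONS:
        stop_prov, stop_pos = "aligned", match_nt_end + 3
    else:
        for off in range(0, cfg.downstream_scan_nt - 2, 3):
            j = match_nt_end + off
            if j + 3 > len(cdna):
                break
            if cdna[j : j + 3] in STOP_CODONS:
                stop_prov, stop_pos = "provisional_downstream", j + 3
                break

    return TerminalStatus(start_prov, stop_prov, start_pos, stop_pos)


def classify_orf(
    c: TranscriptComponent,
    status: TerminalStatus,
    oa: OrthologAssignment,
    gene_symbol: str,
    orf_id: str | None = None,
) -> OrfRecord:
    """Classify a component as FL or PL and cut its reconstructed cdna.

    FL requires both terminal codons present and a contiguous reading frame
    (no internal stop, no recorded internal gap); everything else is PL with
    a reason: missing_start, missing_end, or missing_internal.
    """
    cdna = c.cdna[status.coding_start : status.coding_end]
    aa = str(Seq(cdna).translate()) if len(cdna) % 3 == 0 else ""
    body = aa[:-1] if aa.endswith("*") else aa
    internal_stop = "*" in body

    pl_reason = None
    if c.internal_gap or internal_stop:
        pl_reason = "missing_internal"
    elif status.start_provenance == "absent":
        pl_reason = "missing_start"
    elif status.stop_provenance == "absent":
        pl_reason = "missing_end"

    return OrfRecord(
        orf_id=orf_id or c.id,
        gene_symbol=gene_symbol,
        cdna=cdna,
        status="FL" if pl_reason is None else "PL",
        pl_reason=pl_reason,
        start_codon_provenance=status.start_provenance,
        stop_codon_provenance=status.stop_provenance,
        source_component_ids=c.parents or (c.id,),
        reference_protein_id=oa.reference_protein_id,
    )


def select_isoforms(
    orfs: Iterable[OrfRecord],
) -> tuple[dict[str, OrfRecord], list[OrfRecord]]:
    """One representative per gene symbol: the longest FL-ORF.

    Ties break by lexicographic orf_id.  Genes with only PL records get their
    longest PL as representative, flagged ``non_fl_representative``.  All
    other isoforms are marked secondary and returned in the secondary bin.
    """
    by_gene: dict[str, list[OrfRecord]] = {}
    for orf in orfs:
        by_gene.setdefault(orf.gene_symbol, []).append(orf)
    representatives: dict[str, OrfRecord] = {}
    secondary: list[OrfRecord] = []
    for gene, group in sorted(by_gene.items()):
        fl = [o for o in group if o.status == "FL"]
        pool = fl or group
        rep = min(pool, key=lambda o: (-len(o.cdna), o.orf_id))
        rep.non_fl_representative = not fl
        representatives[gene] = rep
        for o in group:
            if o is not rep:
                o.secondary = True
                secondary.append(o)
    return representatives, secondary


@dataclass
class BuildResult:
    orfs: list[OrfRecord]
    representatives: dict[str, OrfRecord]
    secondary: list[OrfRecord]
    review: list[tuple[str, str, MergeDecision]]
    unassigned: list[str]


def build_orfs(
    components: Sequence[TranscriptComponent],
    hits_by_component: Mapping[str, Sequence[TabularHit]],
    reference_proteins: Mapping[str, str],
    gene_of_protein: Mapping[str, str] | None = None,
    cfg: RunConfig = DEFAULT_CONFIG,
) -> BuildResult:
    """Full reconstruction: assign, merge to fixpoint, terminate, classify.

    ``reference_proteins`` maps reference protein id to amino-acid sequence;
    ``gene_of_protein`` maps protein id to gene symbol (defaults to the part
    of the protein id after the species prefix).
    """
    if gene_of_protein is None:
        gene_of_protein = {}

    assignments: dict[str, OrthologAssignment] = {}
    unassigned: list[str] = []
    for comp in components:
        oa = assign_ortholog(
            hits_by_component.get(comp.id, ()), cfg.panel_order, cfg.e_cutoff
        )
        if oa is None:
            unassigned.append(comp.id)
        else:
            assignments[comp.id] = oa

    groups: dict[str, list[TranscriptComponent]] = {}
    for comp in components:
        oa = assignments.get(comp.id)
        if oa is not None:
            groups.setdefault(oa.reference_protein_id, []).append(comp)

    review: list[tuple[str, str, MergeDecision]] = []
    orfs: list[OrfRecord] = []
    for protein_id in sorted(groups):
        pool = sorted(
            groups[protein_id],
            key=lambda c: (assignments[c.id].match_s_start, c.id),
        )
        merged_any = True
        while merged_any and len(pool) > 1:
            merged_any = False
            for i in range(len(pool) - 1):
                a, b = pool[i], pool[i + 1]
                decision = can_merge(
                    a, b, assignments[a.id], assignments[b.id], cfg,
                    reference_proteins,
                )
                if decision.ok:
                    merged = merge_components(a, b, decision)
                    assignments[merged.id] = merge_assignments(
                        assignments[a.id], assignments[b.id], merged
                    )
                    pool[i : i + 2] = [merged]
                    merged_any = True
                    break

        # after the fixpoint, adjacent pairs meeting only some conditions
        # are manual-curation cases
        for a, b in zip(pool, pool[1:]):
            decision = can_merge(
                a, b, assignments[a.id], assignments[b.id], cfg, reference_proteins
            )
            if decision.partial:
                review.append((a.id, b.id, decision))

        ref_len = len(reference_proteins[protein_id])
        gene = gene_of_protein.get(protein_id) or _gene_from_protein_id(protein_id)
        for n, comp in enumerate(pool, start=1):
            oa = assignments[comp.id]
            status = assign_terminal_codons(comp, oa, ref_len, cfg)
            orf_id = f"{gene}_orf{n}" if len(pool) > 1 else f"{gene}_orf"
            orfs.append(classify_orf(comp, status, oa, gene, orf_id))

    representatives, secondary = select_isoforms(orfs)
    return BuildResult(orfs, representatives, secondary, review, unassigned)


def _gene_from_protein_id(protein_id: str) -> str:
    tail = protein_id.split("|")[-1]
    return tail[4:] if tail.startswith("PROT") and len(tail) > 4 else tail
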