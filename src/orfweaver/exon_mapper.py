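"""Mapping predicted exons onto assembly contigs and congruency classification.

Each predicted exon is searched against the assembly; hits are accepted only
at > 98% identity over the entire exon length, with up to 10 bp of slack at
each predicted boundary (split codons and minor splice-site differences).
Exons predicted shorter than 17 bp sit below the sensitivity threshold of
the search and are spared: noted, never searched, and never held against an
ORF.  Accepted placements are resolved so that each ORF places the maximum
number of exons on as few contigs as possible with the best identity, then
every ORF falls into one of three congruency categories:

* category 1 — all searchable exons on a single contig, in order, in one
  orientation (an accuracy endorsement for that contig);
* category 2 — same congruence, but spread over two or more contigs (the
  scaffolding signal);
* category 3 — one or more exons missing, out of order, or misoriented.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio import Align
from Bio.Seq import Seq

from .config import DEFAULT_CONFIG, RunConfig
from .exon_model import OrfExonModel, parse_exon_id
from .io_formats import SeqRecord, TabularHit


@dataclass
class ExonPlacement:
    """One accepted location of one exon on one contig (0-based half-open)."""

    orf_id: str
    exon_index: int
    contig_id: str
    start: int
    end: int
    strand: str
    percent_identity: float
    boundary_slack_left: int = 0
    boundary_slack_right: int = 0


@dataclass
class PlacementClassification:
    orf_id: str
    category: int
    contigs_used: list[str] = field(default_factory=list)
    missing_exons: list[int] = field(default_factory=list)
    spared_exons: list[int] = field(default_factory=list)
    misordered: bool = False
    misoriented: bool = False
    tie_flagged: bool = False
    search_mode: str = "exhaustive"


# ---------------------------------------------------------------------------
# Hit acceptance


def filter_exon_hits(
    hits: Sequence[TabularHit],
    exon_length: int,
    cfg: RunConfig = DEFAULT_CONFIG,
) -> list[ExonPlacement]:
    """Apply the acceptance rule to the hits of a single exon query.

    Keeps hits whose identity exceeds the threshold (strictly, by default)
    and whose query coverage reaches the exon ends within ``boundary_slack``
    bp on each side.  Exons shorter than ``spared_exon_lt`` should not be
    searched at all (see :func:`spared`).
    """
    accepted: list[ExonPlacement] = []
    for h in hits:
        if cfg.exon_identity_strict:
            if not h.percent_identity > cfg.exon_min_identity:
                continue
        elif not h.percent_identity >= cfg.exon_min_identity:
            continue
        slack_left = h.q_start - 1
        slack_right = exon_length - h.q_end
        if slack_left > cfg.boundary_slack or slack_right > cfg.boundary_slack:
            continue
        if slack_left < 0 or slack_right < 0:
            continue
        orf_id, ordinal, _ = parse_exon_id(h.query_id)
        accepted.append(
            ExonPlacement(
                orf_id=orf_id,
                exon_index=ordinal,
                contig_id=h.subject_id,
                start=h.s_start - 1,
                end=h.s_end,
                strand=h.strand,
                percent_identity=h.percent_identity,
                boundary_slack_left=slack_left,
                boundary_slack_right=slack_right,
            )
        )
    return accepted


def spared(exon_length: int, cfg: RunConfig = DEFAULT_CONFIG) -> bool:
    """Exons below the search sensitivity threshold are noted but spared."""
    return exon_length < cfg.spared_exon_lt


# ---------------------------------------------------------------------------
# Internal aligner (so the toolkit runs without an external search tool)


def _local_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -4
    aligner.extend_gap_score = -1
    return aligner


def _exact_hits(exon: str, contig: SeqRecord) -> list[tuple[int, int, str, float, int, int]]:
    out = []
    for strand, hay in (("+", contig.seq), ("-", str(Seq(contig.seq).reverse_complement()))):
        pos = hay.find(exon)
        while pos != -1:
            if strand == "+":
                out.append((pos, pos + len(exon), "+", 100.0, 0, 0))
            else:
                start = len(hay) - (pos + len(exon))
                out.append((start, start + len(exon), "-", 100.0, 0, 0))
            pos = hay.find(exon, pos + 1)
    return out


def _aligned_hit(
    exon: str, contig: SeqRecord, cfg: RunConfig
) -> list[tuple[int, int, str, float, int, int]]:
    """Best local alignment of the exon on each strand of the contig."""
    aligner = _local_aligner()
    out = []
    rc = str(Seq(contig.seq).reverse_complement())
    for strand, hay in (("+", contig.seq), ("-", rc)):
        alns = aligner.align(exon, hay)
        if not len(alns):
            continue
        aln = alns[0]
        q_blocks, s_blocks = aln.aligned
        if not len(q_blocks):
            continue
        q0, q1 = int(q_blocks[0][0]), int(q_blocks[-1][1])
        s0, s1 = int(s_blocks[0][0]), int(s_blocks[-1][1])
        matches = sum(
            1
            for (qa, qb), (sa, sb) in zip(q_blocks, s_blocks)
            for i in range(qb - qa)
            if exon[qa + i] == hay[sa + i]
        )
        span = max(q1 - q0, s1 - s0)  # aligned span including gaps
        identity = 100.0 * matches / span if span else 0.0
        slack_left, slack_right = q0, len(exon) - q1
        if strand == "+":
            start, end = s0, s1
        else:
            start, end = len(hay) - s1, len(hay) - s0
        out.append((start, end, strand, identity, slack_left, slack_right))
    return out


def map_exons(
    exon_records: Sequence[SeqRecord],
    contigs: Sequence[SeqRecord],
    cfg: RunConfig = DEFAULT_CONFIG,
) -> tuple[dict[str, dict[int, list[ExonPlacement]]], dict[str, list[int]]]:
    """Search every exon record against every contig.

    Returns (candidates, spared): candidates[orf_id][ordinal] lists accepted
    placements; spared[orf_id] lists ordinals below the length threshold.
    Exact substring search is tried first; the affine-gap aligner only runs
    for exons with no exact hit anywhere.
    """
    candidates: dict[str, dict[int, list[ExonPlacement]]] = {}
    spared_map: dict[str, list[int]] = {}
    for rec in exon_records:
        orf_id, ordinal, predicted_len = parse_exon_id(rec.id)
        candidates.setdefault(orf_id, {})
        if spared(predicted_len, cfg):
            spared_map.setdefault(orf_id, []).append(ordinal)
            continue
        raw: list[tuple[str, tuple]] = []
        for contig in contigs:
            for hit in _exact_hits(rec.seq, contig):
                raw.append((contig.id, hit))
        if not raw:
            for contig in contigs:
                for hit in _aligned_hit(rec.seq, contig, cfg):
                    raw.append((contig.id, hit))
        accepted = []
        for contig_id, (start, end, strand, identity, sl, sr) in raw:
            if cfg.exon_identity_strict and not identity > cfg.exon_min_identity:
                continue
            if not cfg.exon_identity_strict and identity < cfg.exon_min_identity:
                continue
            if sl > cfg.boundary_slack or sr > cfg.boundary_slack:
                continue
            accepted.append(
                ExonPlacement(
                    orf_id=orf_id,
                    exon_index=ordinal,
                    contig_id=contig_id,
                    start=start,
                    end=end,
                    strand=strand,
                    percent_identity=identity,
                    boundary_slack_left=sl,
                    boundary_slack_right=sr,
                )
            )
        if accepted:
            candidates[orf_id][ordinal] = accepted
    return candidates, spared_map


# ---------------------------------------------------------------------------
# Placement resolution


def _combo_key(combo: Sequence[ExonPlacement]) -> tuple:
    contigs = tuple(sorted({p.contig_id for p in combo}))
    mean_ident = sum(p.percent_identity for p in combo) / len(combo)
    return (len(contigs), -mean_ident, contigs, tuple((p.contig_id, p.start) for p in combo))


def resolve_placements(
    candidates: Mapping[int, Sequence[ExonPlacement]],
    cfg: RunConfig = DEFAULT_CONFIG,
) -> tuple[dict[int, ExonPlacement], bool, str]:
    """Choose one placement per exon.

    Objective, lexicographic: (1) maximum exons placed (every exon with a
    candidate is placed), (2) fewest distinct contigs, (3) best mean
    identity.  Exhaustive search when the candidate product is small enough,
    greedy per-contig grouping otherwise.  Exactly tied optima are resolved
    toward the lexicographically lower contig-id set and flagged.
    """
    ordinals = sorted(candidates)
    if not ordinals:
        return {}, False, "exhaustive"
    n_combos = 1
    for o in ordinals:
        n_combos *= len(candidates[o])
        if n_combos > cfg.resolver_exhaustive_limit:
            break
    if n_combos <= cfg.resolver_exhaustive_limit:
        best: tuple | None = None
        best_combo = None
        tie = False
        for combo in itertools.product(*(candidates[o] for o in ordinals)):
            key = _combo_key(combo)
            if best is None or key < best:
                tie = best is not None and key[:2] == best[:2]
                best, best_combo = key, combo
            elif key[:2] == best[:2]:
                tie = True
        assert best_combo is not None
        return dict(zip(ordinals, best_combo)), tie, "exhaustive"

    # greedy: prefer contigs that can host the most exons, then identity
    host_count: dict[str, int] = {}
    for o in ordinals:
        for p in candidates[o]:
            host_count[p.contig_id] = host_count.get(p.contig_id, 0) + 1
    chosen: dict[int, ExonPlacement] = {}
    for o in ordinals:
        chosen[o] = min(
            candidates[o],
            key=lambda p: (
                -host_count[p.contig_id],
                -p.percent_identity,
                p.contig_id,
                p.start,
            ),
        )
    return chosen, False, "greedy"


# ---------------------------------------------------------------------------
# Congruency classification


def classify_placement(
    orf_id: str,
    searchable_ordinals: Sequence[int],
    chosen: Mapping[int, ExonPlacement],
    spared_ordinals: Sequence[int] = (),
    tie_flagged: bool = False,
    search_mode: str = "exhaustive",
) -> PlacementClassification:
    """Sort one ORF into the three congruency categories.

    ``searchable_ordinals`` are the predicted exons that were searched
    (spared exons excluded); ``chosen`` maps ordinals to their resolved
    placements.
    """
    missing = sorted(o for o in searchable_ordinals if o not in chosen)
    placed = [chosen[o] for o in sorted(chosen)]

    contigs_used: list[str] = []
    for p in placed:
        if p.contig_id not in contigs_used:
            contigs_used.append(p.contig_id)

    misordered = False
    misoriented = False
    # walking exons in transcript order, each contig must be one contiguous
    # visit: revisiting a contig after leaving it (A..B..A) is misordered
    seen_done: set[str] = set()
    prev = None
    for p in placed:
        if p.contig_id != prev:
            if p.contig_id in seen_done:
                misordered = True
            if prev is not None:
                seen_done.add(prev)
            prev = p.contig_id
    # within a contig: one strand, coordinates monotone under that strand
    for contig in contigs_used:
        members = [p for p in placed if p.contig_id == contig]
        strands = {p.strand for p in members}
        if len(strands) > 1:
            misoriented = True
            continue
        strand = members[0].strand
        starts = [p.start for p in sorted(members, key=lambda p: p.exon_index)]
        if strand == "+":
            if starts != sorted(starts):
                misordered = True
        elif starts != sorted(starts, reverse=True):
            misordered = True

    if missing or misordered or misoriented or not placed:
        category = 3
    elif len(contigs_used) == 1:
        category = 1
    else:
        category = 2
    return PlacementClassification(
        orf_id=orf_id,
        category=category,
        contigs_used=contigs_used,
        missing_exons=missing,
        spared_exons=sorted(spared_ordinals),
        misordered=misordered,
        misoriented=misoriented,
        tie_flagged=tie_flagged,
        search_mode=search_mode,
    )


def write_placements_tsv(
    chosen_by_orf: Mapping[str, Mapping[int, ExonPlacement]], path
) -> None:
    cols = (
        "orf_id exon_index contig_id start end strand percent_identity "
        "slack_left slack_right"
    ).split()
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for orf_id in sorted(chosen_by_orf):
            for ordinal in sorted(chosen_by_orf[orf_id]):
                p = chosen_by_orf[orf_id][ordinal]
                fh.write(
                    "\t".join(
                        str(x)
                        for x in (
                            p.orf_id, p.exon_index, p.contig_id, p.start, p.end,
                            p.strand, f"{p.percent_identity:.3f}",
                            p.boundary_slack_left, p.boundary_slack_right,
                        )
                    )
                    + "\n"
                )


def read_placements_tsv(path) -> dict[str, dict[int, ExonPlacement]]:
    out: dict[str, dict[int, ExonPlacement]] = {}
    with open(path) as fh:
        next(fh)
        for line in fh:
            c = line.rstrip("\n").split("\t")
            p = ExonPlacement(
                orf_id=c[0], exon_index=int(c[1]), contig_id=c[2],
                start=int(c[3]), end=int(c[4]), strand=c[5],
                percent_identity=float(c[6]),
                boundary_slack_left=int(c[7]), boundary_slack_right=int(c[8]),
            )
            out.setdefault(p.orf_id, {})[p.exon_index] = p
    return out


def write_classifications_tsv(
    classifications: Mapping[str, PlacementClassification], path
) -> None:
    cols = (
        "orf_id category contigs_used missing_exons spared_exons "
        "misordered misoriented tie_flagged search_mode"
    ).split()
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for orf_id in sorted(classifications):
            c = classifications[orf_id]
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        c.orf_id, c.category, ",".join(c.contigs_used),
                        ",".join(map(str, c.missing_exons)),
                        ",".join(map(str, c.spared_exons)),
                        int(c.misordered), int(c.misoriented),
                        int(c.tie_flagged), c.search_mode,
                    )
                )
                + "\n"
            )


def read_classifications_tsv(path) -> dict[str, PlacementClassification]:
    out: dict[str, PlacementClassification] = {}
    with open(path) as fh:
        next(fh)
        for line in fh:
            c = line.rstrip("\n").split("\t")
            out[c[0]] = PlacementClassification(
                orf_id=c[0],
                category=int(c[1]),
                contigs_used=c[2].split(",") if c[2] else [],
                missing_exons=[int(x) for x in c[3].split(",") if x],
                spared_exons=[int(x) for x in c[4].split(",") if x],
                misordered=bool(int(c[5])),
                misoriented=bool(int(c[6])),
                tie_flagged=bool(int(c[7])),
                search_mode=c[8],
            )
    return out


def classify_all(
    exon_records: Sequence[SeqRecord],
    contigs: Sequence[SeqRecord],
    cfg: RunConfig = DEFAULT_CONFIG,
) -> tuple[dict[str, PlacementClassification], dict[str, dict[int, ExonPlacement]]]:
    """Map, resolve, and classify every ORF found in ``exon_records``."""
    searchable: dict[str, list[int]] = {}
    for rec in exon_records:
        orf_id, ordinal, predicted_len = parse_exon_id(rec.id)
        searchable.setdefault(orf_id, [])
        if not spared(predicted_len, cfg):
            searchable[orf_id].append(ordinal)
    candidates, spared_map = map_exons(exon_records, contigs, cfg)
    classifications: dict[str, PlacementClassification] = {}
    chosen_all: dict[str, dict[int, ExonPlacement]] = {}
    for orf_id in sorted(searchable):
        chosen, tie, mode = resolve_placements(candidates.get(orf_id, {}), cfg)
        chosen_all[orf_id] = chosen
        classifications[orf_id] = classify_placement(
            orf_id,
            searchable[orf_id],
            chosen,
            spared_map.get(orf_id, ()),
            tie,
            mode,
        )
    return classifications, chosen_all
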