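"""Reconciliation of a long-read assembly against a short-read assembly.

Contigs of an independent short-read assembly are aligned to the long-read
assembly.  A short-read contig whose terminus stops aligning well before the
contig's own end (a clipped terminus) marks a potential misassembly at the
clip point; clip points within a 500-bp window on the same target merge into
one discordant site.  A site spanned end-to-end by at least one long read is
considered supported and left alone; unsupported sites are broken at the
window midpoint, erring on the side of accuracy at the expense of
contiguity.  No sequence is ever discarded by a break.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .config import DEFAULT_CONFIG, RunConfig
from .io_formats import ReadAlignment, SeqRecord, TabularHit


@dataclass
class DiscordantSite:
    """A candidate misassembly window on a long-read-assembly contig."""

    contig_id: str
    window_start: int
    window_end: int
    evidence: list[str] = field(default_factory=list)
    supported: bool = False
    support_reads: list[str] = field(default_factory=list)

    @property
    def midpoint(self) -> int:
        return (self.window_start + self.window_end) // 2


def find_discordant_sites(
    ab_hits: Sequence[TabularHit],
    ab_contig_lengths: Mapping[str, int],
    cfg: RunConfig = DEFAULT_CONFIG,
) -> list[DiscordantSite]:
    """Locate clipped short-read-contig termini on the long-read assembly.

    For each short-read contig, only alignments at ``e <= clip_e_cutoff``
    anchor it.  A terminus with more than ``min_clip`` unaligned bases marks
    a clip point at the corresponding end of the anchoring alignment on the
    target.  Clip points within ``window`` bp on the same target contig are
    merged into one site.
    """
    points: dict[str, list[tuple[int, str]]] = {}
    by_query: dict[str, list[TabularHit]] = {}
    for h in ab_hits:
        if h.e_value <= cfg.clip_e_cutoff:
            by_query.setdefault(h.query_id, []).append(h)
    for query_id in sorted(by_query):
        hits = by_query[query_id]
        qlen = ab_contig_lengths.get(query_id)
        if qlen is None:
            raise KeyError(f"no length known for short-read contig {query_id!r}")
        aligned_lo = min(h.q_start for h in hits)
        aligned_hi = max(h.q_end for h in hits)
        if aligned_lo - 1 > cfg.min_clip:
            # left terminus of the contig is clipped; the clip point sits at
            # the target-side end of the alignment that reaches aligned_lo
            h = min(hits, key=lambda h: (h.q_start, h.e_value))
            pos = h.s_start - 1 if h.strand == "+" else h.s_end
            points.setdefault(h.subject_id, []).append((pos, query_id))
        if qlen - aligned_hi > cfg.min_clip:
            h = max(hits, key=lambda h: (h.q_end, -h.e_value))
            pos = h.s_end if h.strand == "+" else h.s_start - 1
            points.setdefault(h.subject_id, []).append((pos, query_id))

    sites: list[DiscordantSite] = []
    for contig_id in sorted(points):
        pts = sorted(points[contig_id])
        cluster: list[tuple[int, str]] = []
        for pt in pts:
            if cluster and pt[0] - cluster[0][0] > cfg.window:
                sites.append(_site_from_cluster(contig_id, cluster))
                cluster = []
            cluster.append(pt)
        if cluster:
            sites.append(_site_from_cluster(contig_id, cluster))
    return sites


def _site_from_cluster(contig_id: str, cluster: list[tuple[int, str]]) -> DiscordantSite:
    lo = cluster[0][0]
    hi = max(p for p, _ in cluster)
    return DiscordantSite(
        contig_id=contig_id,
        window_start=lo,
        window_end=max(hi, lo + 1),
        evidence=sorted({q for _, q in cluster}),
    )


def check_read_support(
    sites: Sequence[DiscordantSite],
    read_alignments: Sequence[ReadAlignment],
    cfg: RunConfig = DEFAULT_CONFIG,
) -> list[DiscordantSite]:
    """Flag each site supported iff >= 1 read alignment spans it entirely.

    A single alignment must cover ``[window_start - margin, window_end +
    margin]`` contiguously on the same target.
    """
    by_target: dict[str, list[ReadAlignment]] = {}
    for aln in read_alignments:
        by_target.setdefault(aln.target_id, []).append(aln)
    for site in sites:
        lo = site.window_start - cfg.support_margin
        hi = site.window_end + cfg.support_margin
        site.support_reads = sorted(
            a.read_id
            for a in by_target.get(site.contig_id, ())
            if a.target_start <= lo and a.target_end >= hi
        )
        site.supported = bool(site.support_reads)
    return list(sites)


@dataclass
class BreakReport:
    contig_id: str
    window_start: int
    window_end: int
    action: str  # "broken" | "supported" | "near_terminus" | "flagged"
    evidence: list[str] = field(default_factory=list)
    support_reads: list[str] = field(default_factory=list)
    break_position: int | None = None


def break_assembly(
    assembly: Sequence[SeqRecord],
    sites: Sequence[DiscordantSite],
    cfg: RunConfig = DEFAULT_CONFIG,
) -> tuple[list[SeqRecord], list[BreakReport]]:
    """Break every unsupported site at its window midpoint.

    Fragments are suffixed ``.1``, ``.2``, ... along the contig; supported
    sites and sites within ``window`` bp of a contig terminus are left
    untouched (a terminus cannot be broken).  With ``cfg.conservative`` no
    break is applied, everything is only flagged.  Total bases are conserved.
    """
    by_contig: dict[str, list[DiscordantSite]] = {}
    reports: list[BreakReport] = []
    lengths = {rec.id: len(rec.seq) for rec in assembly}
    for site in sites:
        if site.contig_id not in lengths:
            raise ValueError(f"site on unknown contig {site.contig_id!r}")
        clen = lengths[site.contig_id]
        if not (0 <= site.window_start <= site.window_end <= clen):
            raise ValueError(
                f"site [{site.window_start},{site.window_end}) outside "
                f"contig {site.contig_id!r} (length {clen})"
            )
        report = BreakReport(
            site.contig_id,
            site.window_start,
            site.window_end,
            "supported",
            site.evidence,
            site.support_reads,
        )
        if site.supported:
            reports.append(report)
            continue
        if site.midpoint < cfg.window or clen - site.midpoint < cfg.window:
            report.action = "near_terminus"
            reports.append(report)
            continue
        if cfg.conservative:
            report.action = "flagged"
            reports.append(report)
            continue
        report.action = "broken"
        report.break_position = site.midpoint
        reports.append(report)
        by_contig.setdefault(site.contig_id, []).append(site)

    out: list[SeqRecord] = []
    for rec in assembly:
        cuts = sorted({s.midpoint for s in by_contig.get(rec.id, ())})
        if not cuts:
            out.append(rec)
            continue
        bounds = [0] + cuts + [len(rec.seq)]
        for i, (lo, hi) in enumerate(zip(bounds, bounds[1:]), start=1):
            out.append(
                SeqRecord(
                    id=f"{rec.id}.{i}",
                    seq=rec.seq[lo:hi],
                    description=f"fragment {i} of {rec.id}",
                )
            )
    return out, reports


def reconcile(
    assembly: Sequence[SeqRecord],
    ab_hits: Sequence[TabularHit],
    ab_contig_lengths: Mapping[str, int],
    read_alignments: Sequence[ReadAlignment],
    cfg: RunConfig = DEFAULT_CONFIG,
) -> tuple[list[SeqRecord], list[BreakReport]]:
    """Full reconciliation pass: find sites, check read support, break."""
    sites = find_discordant_sites(ab_hits, ab_contig_lengths, cfg)
    sites = check_read_support(sites, read_alignments, cfg)
    return break_assembly(assembly, sites, cfg)
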