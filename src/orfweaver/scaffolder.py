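"""Transcript-guided scaffolding of an assembly.

ORFs whose exon complement is congruent but spans two or more contigs
(category 2) imply adjacencies between those contigs: consecutive
exon-bearing contigs in transcript order become edges of a scaffold graph,
with orientations taken from the placement strands.  Edges are applied
greedily by support into simple paths; anything that would give a contig
more than two neighbours, close a cycle, or contradict a better-supported
orientation goes to a manual-review set instead of being applied.  Exons
missing from the primary assembly may be rescued from secondary assemblies
and imported as scaffold components.  Emitted scaffolds join oriented
contig sequences with a fixed 100-N gap; the gap length encodes the joint,
not an estimate of the true genomic distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
from Bio.Seq import Seq

from .config import DEFAULT_CONFIG, RunConfig
from .exon_mapper import (
    ExonPlacement,
    PlacementClassification,
    classify_placement,
    map_exons,
    resolve_placements,
    spared,
)
from .exon_model import parse_exon_id
from .io_formats import SeqRecord


class ScaffoldError(ValueError):
    pass


@dataclass
class AdjacencyEdge:
    """One transcript-implied adjacency between two oriented contigs.

    Stored in a normalized form: ``contig_a`` is the lexicographically
    smaller id, and the orientation pair is flipped accordingly (joining
    A+ then B+ is the same junction as B- then A-).
    """

    contig_a: str
    contig_b: str
    orient_a: str
    orient_b: str
    supporting_orfs: list[str] = field(default_factory=list)
    implied_gap_rank: int = 0

    @property
    def key(self) -> tuple[str, str, str, str]:
        return (self.contig_a, self.contig_b, self.orient_a, self.orient_b)

    @property
    def support(self) -> int:
        return len(self.supporting_orfs)


@dataclass
class ScaffoldPlan:
    """Ordered, oriented contig chain; junctions carry their supporting ORFs."""

    scaffold_id: str
    components: list[tuple[str, str]] = field(default_factory=list)
    provenance: list[list[str]] = field(default_factory=list)


@dataclass
class ImportedSegment:
    segment: SeqRecord
    source_assembly: str
    orf_id: str
    exon_index: int
    duplicate_sources: list[str] = field(default_factory=list)


def _flip(orient: str) -> str:
    return "-" if orient == "+" else "+"


def _normalize(a: str, oa: str, b: str, ob: str) -> tuple[str, str, str, str]:
    if a <= b:
        return a, b, oa, ob
    return b, a, _flip(ob), _flip(oa)


def contig_chain_of_orf(
    chosen: Mapping[int, ExonPlacement]
) -> list[tuple[str, str]]:
    """Contigs visited by an ORF in transcript order, with orientations."""
    chain: list[tuple[str, str]] = []
    for ordinal in sorted(chosen):
        p = chosen[ordinal]
        entry = (p.contig_id, p.strand)
        if not chain or chain[-1][0] != p.contig_id:
            chain.append(entry)
    return chain


def build_scaffold_graph(
    classifications: Mapping[str, PlacementClassification],
    chosen_by_orf: Mapping[str, Mapping[int, ExonPlacement]],
) -> tuple[list[AdjacencyEdge], list[str]]:
    """Adjacency edges implied by category-2 ORFs.

    Identical edges are merged with accumulated support.  An ORF whose
    exon path revisits a contig (A..B..A) yields a palindromic conflict and
    is reported, not used.
    """
    merged: dict[tuple, AdjacencyEdge] = {}
    palindromic: list[str] = []
    for orf_id in sorted(classifications):
        cls = classifications[orf_id]
        if cls.category != 2:
            continue
        chain = contig_chain_of_orf(chosen_by_orf[orf_id])
        if len({c for c, _ in chain}) != len(chain):
            palindromic.append(orf_id)
            continue
        for rank, ((ca, oa), (cb, ob)) in enumerate(zip(chain, chain[1:])):
            key = _normalize(ca, oa, cb, ob)
            edge = merged.get(key)
            if edge is None:
                edge = AdjacencyEdge(*key, implied_gap_rank=rank)
                merged[key] = edge
            edge.supporting_orfs.append(orf_id)
    return [merged[k] for k in sorted(merged)], palindromic


def _edge_ends(edge: AdjacencyEdge) -> tuple[tuple[str, str], tuple[str, str]]:
    """The contig ends an edge occupies: (contig, 'L'|'R') for each side."""
    end_a = (edge.contig_a, "R" if edge.orient_a == "+" else "L")
    end_b = (edge.contig_b, "L" if edge.orient_b == "+" else "R")
    return end_a, end_b


def resolve_conflicts(
    edges: Sequence[AdjacencyEdge],
    cfg: RunConfig = DEFAULT_CONFIG,
) -> tuple[list[ScaffoldPlan], list[AdjacencyEdge]]:
    """Greedy maximum-support decomposition of the graph into simple paths.

    Edges are applied in decreasing support order; an edge that needs an
    already-occupied contig end, or that would close a cycle, moves to the
    review set.  Nothing in the review set is applied.
    """
    order = sorted(edges, key=lambda e: (-e.support, e.key))
    occupied: dict[tuple[str, str], AdjacencyEdge] = {}
    uf = nx.utils.UnionFind()
    applied: list[AdjacencyEdge] = []
    review: list[AdjacencyEdge] = []
    for edge in order:
        if edge.support < cfg.min_junction_support:
            review.append(edge)
            continue
        end_a, end_b = _edge_ends(edge)
        if end_a in occupied or end_b in occupied:
            review.append(edge)
            continue
        if uf[edge.contig_a] == uf[edge.contig_b]:
            review.append(edge)  # would close a cycle
            continue
        occupied[end_a] = edge
        occupied[end_b] = edge
        uf.union(edge.contig_a, edge.contig_b)
        applied.append(edge)

    # walk the applied edges into oriented chains
    link: dict[tuple[str, str], tuple[str, str, AdjacencyEdge]] = {}
    contigs_in_plans: set[str] = set()
    for edge in applied:
        end_a, end_b = _edge_ends(edge)
        link[end_a] = (*end_b, edge)
        link[end_b] = (*end_a, edge)
        contigs_in_plans.update((edge.contig_a, edge.contig_b))

    def degree(contig: str) -> int:
        return ((contig, "L") in link) + ((contig, "R") in link)

    plans: list[ScaffoldPlan] = []
    visited: set[str] = set()
    for start in sorted(contigs_in_plans):
        if start in visited or degree(start) != 1:
            continue
        free_end = "L" if (start, "R") in link else "R"
        # enter the first contig through its free end
        entry = free_end
        contig = start
        components: list[tuple[str, str]] = []
        provenance: list[list[str]] = []
        while True:
            visited.add(contig)
            orient = "+" if entry == "L" else "-"
            components.append((contig, orient))
            exit_end = "R" if entry == "L" else "L"
            nxt = link.get((contig, exit_end))
            if nxt is None:
                break
            nxt_contig, nxt_end, edge = nxt
            provenance.append(sorted(edge.supporting_orfs))
            contig, entry = nxt_contig, nxt_end
        if components[0][0] > components[-1][0]:
            components = [(c, _flip(o)) for c, o in reversed(components)]
            provenance = list(reversed(provenance))
        plans.append(ScaffoldPlan("", components, provenance))
    plans.sort(key=lambda p: p.components[0][0])
    for i, plan in enumerate(plans, start=1):
        plan.scaffold_id = f"scaffold_{i}"
    return plans, review


def rescue_missing_exons(
    exon_records: Sequence[SeqRecord],
    classifications: dict[str, PlacementClassification],
    chosen_by_orf: dict[str, dict[int, ExonPlacement]],
    primary_contigs: Sequence[SeqRecord],
    secondary_assemblies: Sequence[tuple[str, Sequence[SeqRecord]]],
    cfg: RunConfig = DEFAULT_CONFIG,
) -> tuple[dict[str, PlacementClassification], list[ImportedSegment]]:
    """Search secondary assemblies for missing exons and import the bearers.

    Secondary assemblies are tried in the given priority order; the first
    source with an accepted hit supplies the imported segment (the bearing
    sequence trimmed to the hit plus ``rescue_flank`` bp on each side), and
    later sources are noted as duplicates.  Affected ORFs are re-mapped
    against the primary contigs plus their imported segments and
    re-classified.
    """
    by_orf: dict[str, list[SeqRecord]] = {}
    for rec in exon_records:
        orf_id, _, _ = parse_exon_id(rec.id)
        by_orf.setdefault(orf_id, []).append(rec)

    new_classifications = dict(classifications)
    imported: list[ImportedSegment] = []
    for orf_id in sorted(classifications):
        cls = classifications[orf_id]
        if cls.category != 3 or not cls.missing_exons:
            continue
        orf_imports: list[SeqRecord] = []
        for ordinal in cls.missing_exons:
            rec = next(
                (r for r in by_orf.get(orf_id, ()) if parse_exon_id(r.id)[1] == ordinal),
                None,
            )
            if rec is None:
                continue
            found: ImportedSegment | None = None
            for source_name, contigs in secondary_assemblies:
                cands, _ = map_exons([rec], contigs, cfg)
                placements = cands.get(orf_id, {}).get(ordinal, [])
                if not placements:
                    continue
                best = min(
                    placements,
                    key=lambda p: (-p.percent_identity, p.contig_id, p.start),
                )
                if found is None:
                    host = next(c for c in contigs if c.id == best.contig_id)
                    lo = max(0, best.start - cfg.rescue_flank)
                    hi = min(len(host.seq), best.end + cfg.rescue_flank)
                    segment = SeqRecord(
                        id=f"{source_name}:{best.contig_id}:{lo}-{hi}",
                        seq=host.seq[lo:hi],
                        description=f"rescued {orf_id} exon{ordinal}",
                    )
                    found = ImportedSegment(segment, source_name, orf_id, ordinal)
                else:
                    found.duplicate_sources.append(source_name)
            if found is not None:
                imported.append(found)
                orf_imports.append(found.segment)
        if not orf_imports:
            continue
        searchable = [
            parse_exon_id(r.id)[1]
            for r in by_orf[orf_id]
            if not spared(parse_exon_id(r.id)[2], cfg)
        ]
        contigs = list(primary_contigs) + orf_imports
        cands, spared_map = map_exons(by_orf[orf_id], contigs, cfg)
        chosen, tie, mode = resolve_placements(cands.get(orf_id, {}), cfg)
        chosen_by_orf[orf_id] = chosen
        new_classifications[orf_id] = classify_placement(
            orf_id, searchable, chosen, spared_map.get(orf_id, ()), tie, mode
        )
    return new_classifications, imported


def emit_scaffolds(
    plans: Sequence[ScaffoldPlan],
    contigs: Sequence[SeqRecord],
    cfg: RunConfig = DEFAULT_CONFIG,
) -> list[SeqRecord]:
    """Render plans as gapped sequences; unscaffolded contigs pass through.

    Each junction is exactly ``cfg.gap_n`` Ns.  Reverse-oriented components
    contribute their reverse complement.  A contig claimed by two plans is a
    validation error.
    """
    by_id = {c.id: c for c in contigs}
    used: set[str] = set()
    out: list[SeqRecord] = []
    for plan in plans:
        parts: list[str] = []
        for contig_id, orient in plan.components:
            if contig_id in used:
                raise ScaffoldError(f"contig {contig_id!r} appears in two plans")
            used.add(contig_id)
            if contig_id in by_id:
                seq = by_id[contig_id].seq
            else:
                raise ScaffoldError(f"unknown contig {contig_id!r} in plan")
            if orient == "-":
                seq = str(Seq(seq).reverse_complement())
            parts.append(seq)
        out.append(
            SeqRecord(
                id=plan.scaffold_id,
                seq=("N" * cfg.gap_n).join(parts),
                description=f"components={len(plan.components)}",
            )
        )
    for contig in contigs:
        if contig.id not in used:
            out.append(contig)
    return out
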