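"""End-to-end wiring of the transcriptome-guided scaffolding workflow.

Stage order: ORF reconstruction -> exon-model projection -> exon mapping and
congruency classification -> (optional secondary-assembly rescue) ->
scaffolding.  Reconciliation and the mitochondrial tools are independent
entry points.  Every stage is deterministic, so re-running with identical
inputs and configuration is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .config import DEFAULT_CONFIG, RunConfig
from .exon_mapper import ExonPlacement, PlacementClassification, classify_all
from .exon_model import OrfExonModel, align_translations, emit_exon_fasta, project_exons
from .io_formats import ReferenceExonModel, SeqRecord, TabularHit
from .metrics import assembly_stats, scaffold_and_contig_stats
from .orf_builder import BuildResult, OrfRecord, TranscriptComponent, build_orfs
from .scaffolder import (
    ImportedSegment,
    ScaffoldPlan,
    build_scaffold_graph,
    emit_scaffolds,
    rescue_missing_exons,
    resolve_conflicts,
)


@dataclass
class PipelineResult:
    build: BuildResult
    exon_models: dict[str, OrfExonModel]
    exon_records: list[SeqRecord]
    classifications: dict[str, PlacementClassification]
    placements: dict[str, dict[int, ExonPlacement]]
    plans: list[ScaffoldPlan]
    review_edges: list
    palindromic: list[str]
    imported: list[ImportedSegment]
    scaffolds: list[SeqRecord]
    report: dict = field(default_factory=dict)


def category_report(
    classifications: Mapping[str, PlacementClassification]
) -> dict:
    counts = {1: 0, 2: 0, 3: 0}
    for cls in classifications.values():
        counts[cls.category] += 1
    total = sum(counts.values())
    return {
        "total_orfs": total,
        "category_counts": {str(k): v for k, v in counts.items()},
        "category_percent": {
            str(k): (100.0 * v / total if total else 0.0) for k, v in counts.items()
        },
    }


def run_pipeline(
    components: Sequence[TranscriptComponent],
    hits_by_component: Mapping[str, Sequence[TabularHit]],
    reference_proteins: Mapping[str, str],
    reference_models: Mapping[str, ReferenceExonModel],
    contigs: Sequence[SeqRecord],
    gene_of_protein: Mapping[str, str] | None = None,
    secondary_assemblies: Sequence[tuple[str, Sequence[SeqRecord]]] = (),
    cfg: RunConfig = DEFAULT_CONFIG,
) -> PipelineResult:
    """Run reconstruction through scaffolding and assemble the run report."""
    build = build_orfs(
        components, hits_by_component, reference_proteins, gene_of_protein, cfg
    )

    orf_models: dict[str, OrfExonModel] = {}
    exon_records: list[SeqRecord] = []
    for gene in sorted(build.representatives):
        orf = build.representatives[gene]
        ref_model = reference_models.get(orf.reference_protein_id)
        if ref_model is None:
            continue
        orf_aa = orf.translation()
        if orf_aa.endswith("*"):
            orf_aa = orf_aa[:-1]
        alignment = align_translations(orf_aa, reference_proteins[orf.reference_protein_id])
        model = project_exons(orf, ref_model, alignment)
        orf_models[orf.orf_id] = model
        exon_records.extend(emit_exon_fasta(model, orf, cfg.spared_exon_lt))

    classifications, placements = classify_all(exon_records, contigs, cfg)

    imported: list[ImportedSegment] = []
    if secondary_assemblies:
        classifications, imported = rescue_missing_exons(
            exon_records, classifications, placements, contigs,
            secondary_assemblies, cfg,
        )

    edges, palindromic = build_scaffold_graph(classifications, placements)
    plans, review_edges = resolve_conflicts(edges, cfg)
    scaffold_contigs = list(contigs) + [seg.segment for seg in imported]
    scaffolds = emit_scaffolds(plans, scaffold_contigs, cfg)

    report = category_report(classifications)
    report["before"] = assembly_stats([len(c.seq) for c in contigs]).as_dict()
    report["after"] = scaffold_and_contig_stats(scaffolds)
    report["junctions_applied"] = sum(len(p.components) - 1 for p in plans)
    report["review_edges"] = len(review_edges)
    report["imported_segments"] = len(imported)
    report["fl_orfs"] = sum(1 for o in build.orfs if o.status == "FL")
    report["pl_orfs"] = sum(1 for o in build.orfs if o.status == "PL")
    return PipelineResult(
        build=build,
        exon_models=orf_models,
        exon_records=exon_records,
        classifications=classifications,
        placements=placements,
        plans=plans,
        review_edges=review_edges,
        palindromic=palindromic,
        imported=imported,
        scaffolds=scaffolds,
        report=report,
    )
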