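"""Deterministic synthetic fixtures with recorded ground truth.

One seeded :class:`random.Random` drives everything; regenerating with the
same parameters and seed is bit-identical.  The generator emulates the
inputs of the genome/transcriptome workflow:

* a toy genome carrying non-overlapping multi-exon genes (CDS divisible by
  3, no in-frame internal stops), with the matching reference proteome and
  exon models;
* fragmentation of that genome into contigs with known order, orientation
  and breakpoints — between genes, inside chosen genes, or with chimeric
  joins;
* overlapping transcript components per gene with their protein-hit tables;
* long-read support alignments for chosen junctions;
* a circular mitochondrial molecule with an embedded tandem array, emitted
  as rotated overlapping reads, plus injected variants between haplotypes.

Substitution is the only error model: upstream read correction is assumed,
as in the workflow this emulates.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Sequence

from Bio.Seq import Seq

from .io_formats import ReferenceExonModel, SeqRecord, TabularHit, VariantRecord
from .orf_builder import STOP_CODONS, TranscriptComponent

_BASES = "ACGT"


class PackingError(ValueError):
    pass


@dataclass
class SyntheticGene:
    gene_symbol: str
    protein_id: str
    genome_start: int
    exons: list[tuple[int, int]]      # genome coordinates, 0-based half-open
    cds: str                          # incl. stop codon
    exon_model: ReferenceExonModel    # CDS coordinates, incl. stop codon

    @property
    def protein(self) -> str:
        return str(Seq(self.cds).translate())[:-1]


@dataclass
class ContigSpan:
    contig_id: str
    genome_start: int
    genome_end: int
    orientation: str                  # emitted orientation relative to genome


@dataclass
class FragmentedAssembly:
    contigs: list[SeqRecord]
    contig_map: list[ContigSpan]      # in genome order
    breakpoints: list[int]            # genome positions cut
    chimera_junctions: list[tuple[str, int]] = field(default_factory=list)

    def true_chain(self) -> list[tuple[str, str]]:
        """Genome-order chain of (contig_id, orientation) — the scaffold truth."""
        return [(s.contig_id, s.orientation) for s in self.contig_map]


@dataclass
class GroundTruth:
    genome: str
    genes: list[SyntheticGene]
    seed: int
    mito_circle: str = ""
    mito_unit: str = ""
    mito_copies: int = 0
    injected_variants: list[VariantRecord] = field(default_factory=list)

    @property
    def reference_proteins(self) -> dict[str, str]:
        return {g.protein_id: g.protein for g in self.genes}

    @property
    def gene_of_protein(self) -> dict[str, str]:
        return {g.protein_id: g.gene_symbol for g in self.genes}

    @property
    def exon_models(self) -> dict[str, ReferenceExonModel]:
        return {g.protein_id: g.exon_model for g in self.genes}


def _random_seq(rng: random.Random, length: int, gc: float = 0.42) -> str:
    w = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choices(_BASES, weights=w, k=length))


def _random_cds(rng: random.Random, n_codons: int) -> str:
    """ATG + (n_codons - 2) random non-stop codons + a stop codon."""
    codons = ["ATG"]
    for _ in range(n_codons - 2):
        while True:
            c = "".join(rng.choices(_BASES, k=3))
            if c not in STOP_CODONS:
                break
        codons.append(c)
    codons.append(rng.choice(sorted(STOP_CODONS)))
    return "".join(codons)


def simulate_genome(
    n_genes: int = 10,
    exons_per_gene: tuple[int, int] = (3, 8),
    exon_len: tuple[int, int] = (60, 300),
    intron_len: tuple[int, int] = (150, 400),
    intergenic_len: tuple[int, int] = (300, 800),
    gc: float = 0.42,
    genome_length: int | None = None,
    seed: int = 0,
) -> GroundTruth:
    """Toy genome with non-overlapping multi-exon genes on the forward strand.

    Raises :class:`PackingError` when ``genome_length`` is given and the
    layout cannot fit.
    """
    if min(exons_per_gene) < 1 or min(exon_len) < 3 or min(intron_len) < 1:
        raise ValueError("ranges must be positive (exons >= 3 bp)")
    rng = random.Random(seed)
    parts: list[str] = []
    genes: list[SyntheticGene] = []
    pos = 0

    def emit(seq: str) -> None:
        nonlocal pos
        parts.append(seq)
        pos += len(seq)

    for gi in range(n_genes):
        emit(_random_seq(rng, rng.randint(*intergenic_len), gc))
        n_ex = rng.randint(*exons_per_gene)
        lens = [rng.randint(*exon_len) for _ in range(n_ex)]
        excess = sum(lens) % 3
        lens[-1] += (3 - excess) % 3
        cds = _random_cds(rng, sum(lens) // 3)
        symbol = f"g{gi + 1:03d}"
        gene = SyntheticGene(
            gene_symbol=symbol,
            protein_id=f"mouse|PROT{symbol}",
            genome_start=pos,
            exons=[],
            cds=cds,
            exon_model=ReferenceExonModel(symbol, f"mouse|PROT{symbol}"),
        )
        cds_pos = 0
        for ei, length in enumerate(lens):
            if ei > 0:
                emit(_random_seq(rng, rng.randint(*intron_len), gc))
            gene.exons.append((pos, pos + length))
            gene.exon_model.exons.append((ei + 1, cds_pos, cds_pos + length))
            emit(cds[cds_pos : cds_pos + length])
            cds_pos += length
        gene.exon_model.validate()
        genes.append(gene)
    emit(_random_seq(rng, rng.randint(*intergenic_len), gc))

    genome = "".join(parts)
    if genome_length is not None:
        if len(genome) > genome_length:
            raise PackingError(
                f"{n_genes} genes need {len(genome)} bp, only "
                f"{genome_length} available"
            )
        genome += _random_seq(rng, genome_length - len(genome), gc)
    return GroundTruth(genome=genome, genes=genes, seed=seed)


# ---------------------------------------------------------------------------
# Fragmentation


def fragment_assembly(
    truth: GroundTruth,
    break_policy: str = "between_genes",
    within_genes: int = 0,
    chimeric_joins: int = 0,
    flip_prob: float = 0.5,
    seed: int = 0,
) -> FragmentedAssembly:
    """Cut the genome into contigs with recorded order and orientation.

    ``between_genes`` cuts at intergenic midpoints only, leaving every
    gene's exons on one contig.  ``within_genes`` additionally cuts inside
    an intron of that many genes (chosen deterministically by the seeded
    generator), splitting those genes across two contigs.
    ``chimeric_joins`` concatenates that many non-adjacent contig pairs into
    chimeras, recording each junction offset.  Each contig is emitted
    reverse-complemented with probability ``flip_prob``.
    """
    if break_policy not in ("between_genes", "within_genes", "chimeric_joins"):
        raise ValueError(f"unknown break policy {break_policy!r}")
    if break_policy == "within_genes" and within_genes == 0:
        within_genes = 1
    if break_policy == "chimeric_joins" and chimeric_joins == 0:
        chimeric_joins = 1
    rng = random.Random(seed)
    genome = truth.genome
    cuts: list[int] = []
    for a, b in zip(truth.genes, truth.genes[1:]):
        gap_lo = a.exons[-1][1]
        gap_hi = b.exons[0][0]
        cuts.append((gap_lo + gap_hi) // 2)
    if within_genes:
        eligible = [g for g in truth.genes if len(g.exons) >= 2]
        chosen = rng.sample(eligible, min(within_genes, len(eligible)))
        for gene in chosen:
            i = rng.randrange(len(gene.exons) - 1)
            lo = gene.exons[i][1]
            hi = gene.exons[i + 1][0]
            cuts.append((lo + hi) // 2)
    cuts = sorted(set(cuts))

    bounds = [0] + cuts + [len(genome)]
    spans = list(zip(bounds, bounds[1:]))
    contigs: list[SeqRecord] = []
    contig_map: list[ContigSpan] = []
    for i, (lo, hi) in enumerate(spans, start=1):
        cid = f"tig{i:05d}"
        seq = genome[lo:hi]
        orient = "-" if rng.random() < flip_prob else "+"
        if orient == "-":
            seq = str(Seq(seq).reverse_complement())
        contigs.append(SeqRecord(cid, seq))
        contig_map.append(ContigSpan(cid, lo, hi, orient))

    chimera_junctions: list[tuple[str, int]] = []
    if chimeric_joins:
        if len(contigs) < 2 * chimeric_joins:
            raise ValueError("not enough contigs for the requested chimeric joins")
        order = list(range(len(contigs)))
        rng.shuffle(order)
        paired = order[: 2 * chimeric_joins]
        keep = [contigs[k] for k in range(len(contigs)) if k not in paired]
        chimeras: list[SeqRecord] = []
        for j in range(chimeric_joins):
            a = contigs[paired[2 * j]]
            b = contigs[paired[2 * j + 1]]
            chimera = SeqRecord(f"chimera{j + 1:03d}", a.seq + b.seq)
            chimera_junctions.append((chimera.id, len(a.seq)))
            chimeras.append(chimera)
        contigs = keep + chimeras
    return FragmentedAssembly(
        contigs=contigs,
        contig_map=contig_map,
        breakpoints=cuts,
        chimera_junctions=chimera_junctions,
    )


# ---------------------------------------------------------------------------
# Transcript components and their protein hits


def simulate_transcripts(
    truth: GroundTruth,
    fragments_per_gene: int = 2,
    overlap_nt: int = 30,
    error_rate: float = 0.0,
    seed: int = 0,
) -> tuple[list[TranscriptComponent], dict[str, list[TabularHit]]]:
    """Overlapping codon-aligned fragments of each CDS plus matching hits.

    Fragments jointly cover the CDS with pairwise overlaps of at least
    ``overlap_nt`` (rounded up to whole codons); substitution errors are
    injected at ``error_rate`` per base, avoiding stop-codon creation.
    Hit records mirror what a protein search would report for each fragment
    against its true reference protein.
    """
    if overlap_nt < 15:
        raise ValueError("overlap must be >= 15 nt")
    rng = random.Random(seed)
    ov = -(-overlap_nt // 3) * 3
    components: list[TranscriptComponent] = []
    hits: dict[str, list[TabularHit]] = {}
    for gene in truth.genes:
        cds = gene.cds
        L = len(cds)
        f = fragments_per_gene
        if f < 2 or L // 3 < f + ov // 3:
            starts_ends = [(0, L)]
        else:
            step = (L - ov) // f
            step -= step % 3
            starts_ends = []
            for i in range(f):
                s = i * step
                e = L if i == f - 1 else min(L, s + step + ov)
                starts_ends.append((s, e))
        ref_aa_len = L // 3 - 1  # protein length excludes the stop
        for fi, (s, e) in enumerate(starts_ends, start=1):
            frag = list(cds[s:e])
            if error_rate > 0:
                for k in range(len(frag)):
                    if rng.random() < error_rate:
                        codon_start = k - (k % 3)
                        for alt in rng.sample(_BASES, 4):
                            if alt == frag[k]:
                                continue
                            trial = frag[codon_start : codon_start + 3]
                            trial[k % 3] = alt
                            if "".join(trial) not in STOP_CODONS:
                                frag[k] = alt
                                break
            comp_id = f"{gene.gene_symbol}_c{fi}"
            comp = TranscriptComponent(id=comp_id, cdna="".join(frag))
            components.append(comp)
            s_aa = s // 3 + 1
            e_aa = min(e // 3, ref_aa_len)
            aa_len = e_aa - s_aa + 1
            hits[comp_id] = [
                TabularHit(
                    query_id=comp_id,
                    subject_id=gene.protein_id,
                    percent_identity=100.0,
                    alignment_length=aa_len,
                    mismatches=0,
                    gap_opens=0,
                    q_start=1,
                    q_end=aa_len,
                    s_start=s_aa,
                    s_end=e_aa,
                    e_value=10.0 ** -min(180, aa_len),
                    bit_score=2.0 * aa_len,
                )
            ]
    return components, hits


# ---------------------------------------------------------------------------
# Long-read support and the mitochondrial circle


def simulate_read_support(
    contigs: Sequence[SeqRecord],
    supported: Sequence[tuple[str, int]],
    read_len: int = 2000,
    seed: int = 0,
) -> list["ReadAlignment"]:
    """Alignments of long reads spanning exactly the given (contig, pos) sites.

    Positions not listed get no spanning read, so a reconciler will treat
    them as unsupported.
    """
    from .io_formats import ReadAlignment

    lengths = {c.id: len(c.seq) for c in contigs}
    out: list[ReadAlignment] = []
    for i, (contig_id, pos) in enumerate(sorted(supported), start=1):
        clen = lengths[contig_id]
        lo = max(0, pos - read_len // 2)
        hi = min(clen, pos + read_len // 2)
        out.append(
            ReadAlignment(
                read_id=f"read{i:05d}",
                read_len=read_len,
                read_start=0,
                read_end=hi - lo,
                strand="+",
                target_id=contig_id,
                target_len=clen,
                target_start=lo,
                target_end=hi,
                matches=hi - lo,
                block_len=hi - lo,
            )
        )
    return out


def embed_tandem_array(
    unit: str,
    copies: int,
    flank: int = 200,
    gc: float = 0.42,
    seed: int = 0,
) -> tuple[str, int]:
    """A perfect ``unit x copies`` array embedded in random flanks.

    The flank bases adjacent to the array are forced to break its
    periodicity, so the embedded array is exactly the maximal one.  Returns
    (sequence, array start).
    """
    rng = random.Random(seed)
    array = unit * copies
    left = list(_random_seq(rng, flank, gc))
    right = list(_random_seq(rng, flank, gc))
    p = len(unit)
    if left and left[-1] == array[p - 1]:
        left[-1] = next(b for b in _BASES if b != array[p - 1])
    if right and right[0] == array[-p]:
        right[0] = next(b for b in _BASES if b != array[-p])
    return "".join(left) + array + "".join(right), flank


def simulate_mito(
    length: int = 16767,
    unit: str = "ACACGTAT",
    copies: int = 40,
    array_start: int | None = None,
    n_reads: int = 4,
    read_overlap: int = 1000,
    gc: float = 0.40,
    seed: int = 0,
) -> tuple[str, list[SeqRecord]]:
    """A circular molecule with an embedded tandem array, emitted as reads.

    The reads are rotations of the circle with ``read_overlap`` bp pairwise
    overlaps (and the last read wrapping past the origin), emulating chance
    linearizations of a circular genome.  Returns (circle, reads).
    """
    rng = random.Random(seed)
    span = len(unit) * copies
    if span + 2 > length:
        raise ValueError("array does not fit in the molecule")
    if array_start is None:
        array_start = length - span - 400
    circle = list(_random_seq(rng, length, gc))
    circle[array_start : array_start + span] = unit * copies
    p = len(unit)
    i = (array_start - 1) % length
    if circle[i] == unit[-1]:
        circle[i] = next(b for b in _BASES if b != unit[-1])
    j = (array_start + span) % length
    if circle[j] == unit[0]:
        circle[j] = next(b for b in _BASES if b != unit[0])
    circle_s = "".join(circle)

    reads: list[SeqRecord] = []
    step = length // n_reads
    doubled = circle_s + circle_s
    for r in range(n_reads):
        start = r * step
        end = start + step + read_overlap
        reads.append(SeqRecord(f"mito_read{r + 1}", doubled[start:end]))
    return circle_s, reads


def inject_variants(
    seq: str,
    n_transitions: int = 5,
    n_transversions: int = 2,
    n_indels: int = 1,
    seed: int = 0,
) -> tuple[str, list[VariantRecord]]:
    """Mutate a sequence and return the variant records describing the edits.

    Positions are distinct and reported against the original coordinates
    (1-based), so summaries over the returned records can be checked against
    the requested counts.
    """
    rng = random.Random(seed)
    transitions = {"A": "G", "G": "A", "C": "T", "T": "C"}
    n_total = n_transitions + n_transversions + n_indels
    positions = sorted(rng.sample(range(10, len(seq) - 10), n_total))
    rng.shuffle(positions)
    records: list[VariantRecord] = []
    edits: list[tuple[int, str, str]] = []  # (0-based pos, old, new) subs only
    kinds = (
        ["ts"] * n_transitions + ["tv"] * n_transversions + ["indel"] * n_indels
    )
    for pos, kind in zip(positions, kinds):
        ref = seq[pos]
        if kind == "ts":
            alt = transitions[ref]
            edits.append((pos, ref, alt))
            records.append(
                VariantRecord(pos + 1, pos + 1, 1, f"{ref}→{alt}",
                              stated_type="SNP (transition)")
            )
        elif kind == "tv":
            # transversion: cross the purine/pyrimidine divide
            alt = rng.choice(sorted({"C", "T"} if ref in {"A", "G"} else {"A", "G"}))
            edits.append((pos, ref, alt))
            records.append(
                VariantRecord(pos + 1, pos + 1, 1, f"{ref}→{alt}",
                              stated_type="SNP (transversion)")
            )
        else:
            ins = "".join(rng.choices(_BASES, k=rng.randint(1, 3)))
            records.append(
                VariantRecord(pos + 1, pos, 0, f"+{ins}", stated_type="Insertion")
            )
    mutated = list(seq)
    for pos, _, alt in edits:
        mutated[pos] = alt
    records.sort(key=lambda r: r.start)
    return "".join(mutated), records
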