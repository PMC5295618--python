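# Methods

## ORF reconstruction from transcript components

A transcript component is one fragment of a de-novo transcriptome assembly
whose candidate coding region has protein-level hits against one or more
reference proteomes. Ortholog assignment walks a fallback panel of
reference species in fixed order (mouse, rat, kangaroo rat, prairie vole,
chinchilla, deer mouse, marmot, ground squirrel, then human and chimpanzee
as outgroups) and takes, from the first species with any hit at
e ≤ `e_cutoff` (default 1e−10), the hit with the lowest e-value — ties by
bit score, then subject id, so assignment is deterministic.

Two components merge only when four conditions hold simultaneously:

1. **Same reference.** Both components name the same reference protein as
   best or near-best hit. "Near-best" is a bit score within 5% of the
   component's best (`near_best_bits`); the margin tolerates
   fragment-length effects while keeping paralogs apart.
2. **Compatible match intervals.** The reference-protein match intervals of
   the two components differ by ≤ 15% in length (`max_interval_diff`),
   measured on subject intervals (a switch allows query intervals). For a
   component that is itself the product of earlier merges, the comparison
   uses the constituent interval adjacent to the prospective junction
   rather than the accumulated union — otherwise chains of three or more
   fragments could never assemble, since a growing merged interval soon
   exceeds any fixed tolerance against the next fragment.
3. **Sequence overlap.** ≥ 15 identical overlapping bases
   (`min_overlap_nt`), found as the longest exact suffix/prefix match;
   containment of one coding region in the other also qualifies. A
   mismatch-tolerant mode (≤ 1 mismatch per 50 nt) exists but is off by
   default, because inputs are assumed error-corrected upstream.
4. **Frame preservation.** The merged frame introduces no internal stop
   codon, and amino-acid identity to the reference across the merge window
   is ≥ 80% (`min_merge_identity`).

Pairs meeting some but not all conditions are written to a review queue and
never merged automatically. Merging iterates to a fixpoint over components
sorted by reference match start, so the result is order-independent for
mutually compatible fragment sets.

Terminal codons: if the match covers reference residue 1 and the aligned
codon is ATG, the start is *aligned*; otherwise the nearest in-frame ATG at
most 30 nt (`upstream_scan_nt`, 10 codons) upstream of the match region
becomes a *provisional* start. Stops are handled symmetrically with a
30-nt downstream scan for TAA/TAG/TGA. An ORF is full-length (FL) iff both
terminal codons are present and the frame is contiguous (no internal stop,
no recorded internal gap); otherwise it is partial-length (PL) with reason
`missing_start`, `missing_end`, or `missing_internal`. Per gene, the
longest FL-ORF (ties by id) represents the locus; other isoforms are binned
as secondary, and a gene with only PL records gets its longest PL, flagged.

## Exon projection

Reference exon models are CDS-relative (the ORFs are coding-only by
construction); the model's last exon includes the stop codon. Boundaries
are mapped through a global protein alignment (match 1, mismatch −1, gap
open −4, extend −0.5, free end gaps so PL-ORFs align without penalty): a
CDS boundary at position *b* (residue *b*//3, phase *b*%3) maps to the ORF
residue aligned with that reference residue, scaled back to nucleotides at
the same phase. Reference residues deleted in the ORF defer to the nearest
surviving residue — leftward for exon ends, rightward for starts — so a
wholly deleted exon collapses to an empty interval and is dropped with its
ordinal recorded (ordinals are never renumbered, keeping congruency
comparisons aligned with the reference). Boundaries stay at exact reference
phase; the mapper's ±10 bp flexibility absorbs split-codon effects.

## Exon mapping and congruency classification

Acceptance of an exon placement requires identity strictly greater than 98%
over the whole exon with at most 10 bp of slack at each boundary
(independently per end, in either direction). Exons predicted shorter than
17 bp are spared: noted, not searched, and never counted against an ORF.
Identity is computed over the aligned span including gaps, the convention
of tabular search output. An internal exact-match/affine-gap aligner
(match 1, mismatch −2, gap open −4, extend −1) lets the toolkit run
self-contained; precomputed tabular hits are accepted for scale.

Placement resolution maximizes, lexicographically: exons placed, fewer
distinct contigs, higher mean identity. The search is exhaustive when the
candidate product is ≤ 10⁵ combinations and greedy (prefer contigs hosting
the most exons) beyond that, with the mode recorded. Exact ties resolve to
the lexicographically smaller contig-id set and are flagged rather than
silently chosen — tandem duplications surface this way.

Category 1 requires one contig, no missing searchable exons, coordinates
monotone under the placement strand, and a single strand; category 2 is the
same congruence across ≥ 2 contigs; category 3 is everything else,
including transcript paths that revisit a contig (A…B…A).

## Scaffolding

Each category-2 ORF contributes edges between consecutive exon-bearing
contigs in transcript order, with orientations from placement strands;
identical edges merge and accumulate support. Edges apply greedily by
decreasing support; an edge that would occupy an already-used contig end,
close a cycle, or fall below `min_junction_support` (default 1, as
single-ORF joins are legitimate) moves to the review set. Accepted edges
are walked into oriented chains, canonicalized so the lexicographically
smaller terminal contig comes first. Joints are exactly 100 N — a joint
marker, not a gap-length estimate (`gap_n` can be changed but that changes
the declared dialect). Contigs are never trimmed at junctions; overlapping
terminal placements are emitted with the standard gap and flagged.

Missing exons of category-3 ORFs are searched in secondary assemblies in
caller-given priority order under the same acceptance rule; the first
source wins (later ones are noted as duplicates) and the bearing sequence,
trimmed to the hit ± 1 kb (`rescue_flank`), is imported as a scaffold
component, after which the ORF is re-mapped and re-classified.

## Reconciliation

Short-read contigs anchor on the long-read assembly through alignments at
e ≤ 1e−10; a terminus with > 100 bp unaligned (`min_clip`) marks a clip
point at the corresponding target coordinate, and clip points within 500 bp
(`window`) on one target merge into a discordant site. A site is supported
iff one read alignment covers the whole window (± `support_margin`,
default 0). Unsupported sites are broken at the window midpoint — the
procedure errs on the side of accuracy; `conservative` only flags.
Windows within 500 bp of a contig terminus are ignored (a terminus cannot
be broken), and total bases are conserved by construction. Breaking can
only increase contig count and decrease or preserve N50; scaffolding does
the reverse — these direction-preserving properties are tested in place of
full-scale assembly statistics.

## Mitochondrial analytics

Variant classes come from the change string alone: single-base X→Y is a
transition when both bases share a purine/pyrimidine class, otherwise a
transversion; `+SEQ`/`−SEQ` are insertions/deletions; `(unit)m→(unit)n`
with a single-base unit classifies as a plain indel by copy-number
direction, with a multi-base unit as a tandem-repeat change (pooled with
indels in summaries); any other multi-base replacement is a complex
substitution. A printed label that disagrees with the computed class is
reported as a mismatch, never overridden — the packaged table contains one
such row (a two-base replacement labelled as a deletion), and reporting
rather than suppressing it is what makes the summary arithmetic
(60 SNVs + 6 indels + 2 complex = 68) come out.

Circularity: reads are chained by best suffix/prefix overlaps (≥ 100 bp at
≥ 95% identity); a terminal self-overlap marks the molecule circular, the
duplicated overlap is collapsed, and the sequence is rotated to its least
rotation (Booth's algorithm) so every rotation of one circle canonicalizes
identically.

Tandem arrays: unit lengths 2–100 are scanned by the `seq[i] == seq[i−u]`
periodicity test; the longest periodic stretch wins (ties: leftmost,
smallest unit). The reported unit is the minimal period of the stretch
(KMP failure function); the span counts whole copies of that unit, a
trailing partial copy is reported separately, and every composite unit
tiling the span exactly is listed as an alternative decomposition (so a
320-bp array reads both as 8 × 40 and 32 × 10). Arrays need ≥ 3 complete
copies and ≥ 12 bp (`min_span`) — the floor keeps the 6-bp dinucleotide
runs expected by chance in any few-hundred-bp sequence from counting as
arrays. NUMT loci are significant hits (e ≤ 1e−5) of the mitochondrial
genome against the nuclear assembly, projected to intervals and merged
within `numt_merge_gap` (default 0, i.e. overlap only).

## Metrics and rounding

N50 uses the standard cumulative-sum convention. Percentages (stage loss,
heterozygosity, residual error) round half-up at the displayed precision —
one decimal for stage accounting, two by default for rates — so printed
figures are exactly reproducible; `decimal.Decimal` avoids binary-float
rounding surprises.

## Synthetic data: what it does and does not show

One seeded `random.Random` drives each generator; identical parameters and
seed are bit-identical. Defaults: 3–8 exons per gene, exons 60–300 bp,
introns 150–400 bp, intergenic spacers 300–800 bp, GC 0.42, two transcript
fragments per gene overlapping by ≥ 30 nt, substitution-only transcript
errors (off by default; read correction is assumed upstream), contig
orientation flipped with probability 0.5, mitochondrial circles of
16,767 bp with a 320-bp control-region array emitted as four rotated reads
overlapping by 1 kb. Flank bases adjacent to an embedded tandem array are
forced to break its periodicity, so the embedded array is exactly the
maximal one regardless of seed. Acceptance and closure runs use 3–6 genes
— large enough to exercise every code path, small enough that the whole
suite runs in seconds on one CPU.

Passing on these fixtures demonstrates the machinery — exact
reconstruction, correct congruency sorting, recovery of true contig order
and orientation, conservation laws — but not performance on real data:
the generator has no paralogous gene families beyond what tests construct
explicitly, no sequencing-error model beyond substitutions, no repeats
long enough to confound exon placement, and identity-level reference
proteomes (a real cross-species reference adds divergence that mainly
stresses the provisional-codon and identity thresholds).

## Known limitations

- Exon placement is exact-first with a pairwise-aligner fallback; for
  genome-scale inputs, precomputed tabular hits are the intended path.
- The scaffold-graph resolver is greedy by support; it will not find a
  globally optimal path decomposition in adversarial graphs (those edges
  end up in the review set, which is the designed behaviour).
- `detect_circular` chains reads by exact-ish overlap and is meant for the
  handful-of-long-reads case, not as a general assembler.
- Variant classification trusts the change-string syntax; records with an
  open-ended end coordinate are carried with an unknown-end flag rather
  than a guessed length.
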