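"""Readers and writers for the external formats the toolkit touches.

All in-memory coordinates are 0-based half-open on the forward strand.
External dialects are converted at the boundary:

* FASTA            — plain text, 80-column wrap on write.
* BLAST tabular    — outfmt-6, 12 columns, 1-based inclusive; minus-strand
                     nucleotide hits arrive with ``s_start > s_end`` and are
                     normalized to a strand flag with ``s_start < s_end``.
* PAF              — minimap2 dialect, first 12 mandatory columns, already
                     0-based half-open.
* AGP v2.1         — 1-based inclusive; scaffold joints are 100-N gap lines.
* Variant TSV      — mitochondrial variant tables (start/end 1-based
                     inclusive, textual change strings).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

_IUPAC_NT = set("ACGTUMRWSYKVHDBNacgtumrwsykvhdbn")
_IUPAC_AA = set("ACDEFGHIKLMNPQRSTVWYXBZJUO*acdefghiklmnpqrstvwyxbzjuo")
_LEGAL_CHARS = _IUPAC_NT | _IUPAC_AA | {"-", "."}


class FormatError(ValueError):
    """Raised when an external file violates its declared dialect."""


@dataclass
class SeqRecord:
    """One FASTA record (nucleotide or amino acid)."""

    id: str
    seq: str
    description: str = ""

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.seq)


@dataclass
class TabularHit:
    """One row of 12-column BLAST-style tabular output.

    Coordinates are kept in the external convention (1-based inclusive on
    both query and subject); minus-strand nucleotide hits are normalized so
    ``s_start < s_end`` and ``strand`` is '-'.
    """

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    e_value: float
    bit_score: float
    strand: str = "+"


@dataclass
class ReadAlignment:
    """One PAF alignment record (0-based half-open on read and target)."""

    read_id: str
    read_len: int
    read_start: int
    read_end: int
    strand: str
    target_id: str
    target_len: int
    target_start: int
    target_end: int
    matches: int
    block_len: int
    mapq: int = 255


@dataclass
class VariantRecord:
    """One row of a mitochondrial variant table.

    ``start``/``end`` are 1-based inclusive as printed; a pure insertion is
    encoded with ``end = start - 1`` and ``length`` 0.  An open-ended end
    coordinate (printed as e.g. ``> 15817``) is stored with
    ``end_unknown=True`` and ``end`` holding the printed lower bound.
    """

    start: int
    end: int
    length: int | None
    change: str
    aa_change: str = ""
    cds_position: int | None = None
    codon_change: str = ""
    stated_type: str = ""
    end_unknown: bool = False
    length_unknown: bool = False


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Parse a FASTA file, preserving record order.

    Wrapped sequence lines are concatenated.  Malformed headers, illegal
    characters, and duplicate ids raise :class:`FormatError` naming the
    offending line number.
    """
    records: list[SeqRecord] = []
    seen: set[str] = set()
    cur_id: str | None = None
    cur_desc = ""
    cur_seq: list[str] = []

    def _flush() -> None:
        if cur_id is None:
            return
        records.append(SeqRecord(cur_id, "".join(cur_seq), cur_desc))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            if line.startswith(">"):
                header = line[1:].strip()
                if not header:
                    raise FormatError(f"{path}: empty FASTA header at line {lineno}")
                _flush()
                parts = header.split(None, 1)
                cur_id = parts[0]
                cur_desc = parts[1] if len(parts) > 1 else ""
                cur_seq = []
                if cur_id in seen:
                    raise FormatError(
                        f"{path}: duplicate record id {cur_id!r} at line {lineno}"
                    )
                seen.add(cur_id)
            else:
                if cur_id is None:
                    raise FormatError(
                        f"{path}: sequence before first header at line {lineno}"
                    )
                bad = set(line) - _LEGAL_CHARS
                if bad:
                    raise FormatError(
                        f"{path}: illegal character(s) {sorted(bad)} at line {lineno}"
                    )
                cur_seq.append(line)
    _flush()
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, wrap: int = 80) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}"
            if rec.description:
                header += f" {rec.description}"
            fh.write(header + "\n")
            seq = rec.seq
            for i in range(0, max(len(seq), 1), wrap):
                fh.write(seq[i : i + wrap] + "\n")


# ---------------------------------------------------------------------------
# BLAST tabular (outfmt 6)


def parse_hits_tabular(path: str | Path, mode: str = "nucleotide") -> list[TabularHit]:
    """Parse 12-column tab-separated hits.

    ``mode`` is ``"protein"`` or ``"nucleotide"``; in nucleotide mode a row
    with ``s_start > s_end`` encodes a minus-strand hit and is normalized.
    """
    if mode not in ("protein", "nucleotide"):
        raise ValueError(f"unknown mode {mode!r}")
    hits: list[TabularHit] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 12:
                raise FormatError(
                    f"{path}: expected 12 columns, found {len(cols)} at line {lineno}"
                )
            try:
                hit = TabularHit(
                    query_id=cols[0],
                    subject_id=cols[1],
                    percent_identity=float(cols[2]),
                    alignment_length=int(cols[3]),
                    mismatches=int(cols[4]),
                    gap_opens=int(cols[5]),
                    q_start=int(cols[6]),
                    q_end=int(cols[7]),
                    s_start=int(cols[8]),
                    s_end=int(cols[9]),
                    e_value=float(cols[10]),
                    bit_score=float(cols[11]),
                )
            except ValueError as exc:
                raise FormatError(f"{path}: bad numeric field at line {lineno}: {exc}")
            if hit.q_start > hit.q_end:
                raise FormatError(
                    f"{path}: q_start > q_end at line {lineno} (query coordinates "
                    "must be ascending)"
                )
            if hit.s_start > hit.s_end:
                if mode == "protein":
                    raise FormatError(
                        f"{path}: s_start > s_end in protein mode at line {lineno}"
                    )
                hit.strand = "-"
                hit.s_start, hit.s_end = hit.s_end, hit.s_start
            hits.append(hit)
    return hits


def write_hits_tabular(hits: Iterable[TabularHit], path: str | Path) -> None:
    """Write hits back in the 12-column dialect (minus strand re-encoded)."""
    with open(path, "w") as fh:
        for h in hits:
            s1, s2 = (h.s_end, h.s_start) if h.strand == "-" else (h.s_start, h.s_end)
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        h.query_id,
                        h.subject_id,
                        f"{h.percent_identity:.2f}",
                        h.alignment_length,
                        h.mismatches,
                        h.gap_opens,
                        h.q_start,
                        h.q_end,
                        s1,
                        s2,
                        f"{h.e_value:.2e}",
                        f"{h.bit_score:.1f}",
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# PAF


def parse_paf(path: str | Path) -> list[ReadAlignment]:
    alns: list[ReadAlignment] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise FormatError(
                    f"{path}: expected >= 12 PAF columns, found {len(cols)} "
                    f"at line {lineno}"
                )
            aln = ReadAlignment(
                read_id=cols[0],
                read_len=int(cols[1]),
                read_start=int(cols[2]),
                read_end=int(cols[3]),
                strand=cols[4],
                target_id=cols[5],
                target_len=int(cols[6]),
                target_start=int(cols[7]),
                target_end=int(cols[8]),
                matches=int(cols[9]),
                block_len=int(cols[10]),
                mapq=int(cols[11]),
            )
            if not (0 <= aln.read_start < aln.read_end <= aln.read_len):
                raise FormatError(f"{path}: bad read interval at line {lineno}")
            if not aln.target_start < aln.target_end:
                raise FormatError(f"{path}: bad target interval at line {lineno}")
            alns.append(aln)
    return alns


def write_paf(alns: Iterable[ReadAlignment], path: str | Path) -> None:
    with open(path, "w") as fh:
        for a in alns:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        a.read_id,
                        a.read_len,
                        a.read_start,
                        a.read_end,
                        a.strand,
                        a.target_id,
                        a.target_len,
                        a.target_start,
                        a.target_end,
                        a.matches,
                        a.block_len,
                        a.mapq,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# AGP v2.1

GAP_LENGTH = 100  # scaffold joints are a fixed 100-N run


def write_agp(plans, contig_lengths: dict[str, int], path: str | Path) -> None:
    """Serialize scaffold plans as AGP v2.1.

    ``plans`` is an iterable of :class:`~orfweaver.scaffolder.ScaffoldPlan`.
    Gap lines have length 100, gap_type ``scaffold``, linkage ``yes`` and
    evidence ``align_trnscpt``.  Raises :class:`FormatError` if object
    coordinates would not be conserved.
    """
    with open(path, "w") as fh:
        fh.write("##agp-version 2.1\n")
        for plan in plans:
            pos = 0  # 0-based cursor on the object
            part = 0
            for i, (contig_id, orient) in enumerate(plan.components):
                if i > 0:
                    part += 1
                    fh.write(
                        "\t".join(
                            str(x)
                            for x in (
                                plan.scaffold_id,
                                pos + 1,
                                pos + GAP_LENGTH,
                                part,
                                "N",
                                GAP_LENGTH,
                                "scaffold",
                                "yes",
                                "align_trnscpt",
                            )
                        )
                        + "\n"
                    )
                    pos += GAP_LENGTH
                if contig_id not in contig_lengths:
                    raise FormatError(f"unknown component {contig_id!r} in AGP plan")
                clen = contig_lengths[contig_id]
                if clen <= 0:
                    raise FormatError(f"component {contig_id!r} has length {clen}")
                part += 1
                fh.write(
                    "\t".join(
                        str(x)
                        for x in (
                            plan.scaffold_id,
                            pos + 1,
                            pos + clen,
                            part,
                            "W",
                            contig_id,
                            1,
                            clen,
                            orient,
                        )
                    )
                    + "\n"
                )
                pos += clen


def read_agp(path: str | Path) -> dict[str, list[tuple]]:
    """Read AGP back as {object_id: [(kind, id_or_len, orient), ...]}.

    Component rows yield ``("W", contig_id, orient)`` and gap rows
    ``("N", gap_length, None)``.  Object-coordinate conservation is checked.
    """
    objects: dict[str, list[tuple]] = {}
    cursors: dict[str, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}: expected 9 AGP columns at line {lineno}")
            obj, beg, end = cols[0], int(cols[1]), int(cols[2])
            expected = cursors.get(obj, 0) + 1
            if beg != expected:
                raise FormatError(
                    f"{path}: object coordinates not contiguous at line {lineno} "
                    f"(expected start {expected}, found {beg})"
                )
            cursors[obj] = end
            if cols[4] == "N":
                objects.setdefault(obj, []).append(("N", int(cols[5]), None))
            else:
                span = int(cols[7]) - int(cols[6]) + 1
                if span != end - beg + 1:
                    raise FormatError(
                        f"{path}: component span disagrees with object span "
                        f"at line {lineno}"
                    )
                objects.setdefault(obj, []).append(("W", cols[5], cols[8]))
    return objects


# ---------------------------------------------------------------------------
# Variant tables (mitochondrial variant TSV)

_ARROW = "→"
_OPEN_END = re.compile(r"^>\s*([\d,]+)$")


def _parse_pos(tok: str) -> int:
    return int(tok.replace(",", ""))


def normalize_change(change: str) -> str:
    """Accept both ``->`` and ``→`` arrows; emit ``→``."""
    return change.replace("->", _ARROW).strip()


VARIANT_COLUMNS = [
    "Variant Start",
    "Variant End",
    "Length",
    "Amino Acid Change",
    "CDS Position",
    "Change",
    "Codon Change",
    "Polymorphism Type",
]


def parse_variant_table(path: str | Path) -> list[VariantRecord]:
    """Parse a variant TSV with the 8-column mitochondrial table schema."""
    records: list[VariantRecord] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        return records
    start_idx = 0
    first = lines[0].split("\t")
    if first and not first[0].replace(",", "").strip().isdigit():
        start_idx = 1  # header row
    for lineno, line in enumerate(lines[start_idx:], start=start_idx + 1):
        if not line.strip():
            continue
        cols = line.split("\t")
        if len(cols) < 8:
            cols += [""] * (8 - len(cols))
        try:
            start = _parse_pos(cols[0])
            end_tok = cols[1].strip()
            end_unknown = False
            m = _OPEN_END.match(end_tok)
            if m:
                end = _parse_pos(m.group(1))
                end_unknown = True
            else:
                end = _parse_pos(end_tok)
            len_tok = cols[2].strip()
            length_unknown = len_tok.startswith(">")
            length = None if length_unknown else (int(len_tok) if len_tok else None)
            change = normalize_change(cols[5])
            if not change:
                raise ValueError("empty change string")
            cds_tok = cols[4].strip()
            cds_position = int(cds_tok) if cds_tok else None
        except ValueError as exc:
            raise FormatError(f"{path}: unparseable variant row {lineno}: {exc}")
        records.append(
            VariantRecord(
                start=start,
                end=end,
                length=length,
                change=change,
                aa_change=cols[3].strip(),
                cds_position=cds_position,
                codon_change=normalize_change(cols[6]),
                stated_type=cols[7].strip(),
                end_unknown=end_unknown,
                length_unknown=length_unknown,
            )
        )
    return records


def write_variant_table(records: Iterable[VariantRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(VARIANT_COLUMNS) + "\n")
        for r in records:
            end = f"> {r.end}" if r.end_unknown else str(r.end)
            length = f"> {r.length}" if r.length_unknown else (
                "" if r.length is None else str(r.length)
            )
            if r.length_unknown:
                length = "> 1"
            fh.write(
                "\t".join(
                    [
                        str(r.start),
                        end,
                        length,
                        r.aa_change,
                        "" if r.cds_position is None else str(r.cds_position),
                        r.change,
                        r.codon_change,
                        r.stated_type,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Exon models (GFF3 CDS features or a simple 4-column TSV)


@dataclass
class ReferenceExonModel:
    """Ordered exon intervals of a reference coding sequence.

    ``exons`` are (ordinal, cds_start, cds_end) with 1-based ordinals and
    0-based half-open coordinates on the reference CDS; their concatenation
    covers the CDS exactly.
    """

    gene_symbol: str
    protein_id: str
    exons: list[tuple[int, int, int]] = field(default_factory=list)

    def validate(self) -> None:
        pos = 0
        for ordinal, start, end in self.exons:
            if start != pos or end <= start:
                raise ValueError(
                    f"{self.protein_id}: exon {ordinal} [{start},{end}) does not "
                    f"tile the CDS (expected start {pos})"
                )
            pos = end

    @property
    def cds_length(self) -> int:
        return self.exons[-1][2] if self.exons else 0


def read_exon_models_tsv(path: str | Path) -> dict[str, ReferenceExonModel]:
    """Read models from a TSV: protein_id, gene_symbol, cds_start, cds_end.

    Rows for one protein must appear in exon order.
    """
    models: dict[str, ReferenceExonModel] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 4:
                raise FormatError(f"{path}: expected 4 columns at line {lineno}")
            pid, gene, start, end = cols[0], cols[1], int(cols[2]), int(cols[3])
            model = models.setdefault(pid, ReferenceExonModel(gene, pid))
            model.exons.append((len(model.exons) + 1, start, end))
    for model in models.values():
        model.validate()
    return models


def write_exon_models_tsv(models: Iterable[ReferenceExonModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in models:
            for _, start, end in m.exons:
                fh.write(f"{m.protein_id}\t{m.gene_symbol}\t{start}\t{end}\n")


def read_exon_models_gff3(path: str | Path) -> dict[str, ReferenceExonModel]:
    """Read CDS features from GFF3 grouped by protein_id attribute.

    CDS features for one protein are sorted by coordinate and converted to
    CDS-relative intervals (strand-aware).
    """
    raw: dict[str, list[tuple[int, int, str, str]]] = {}
    genes: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}: expected 9 GFF3 columns at line {lineno}")
            if cols[2] != "CDS":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
            )
            pid = attrs.get("protein_id") or attrs.get("Parent") or attrs.get("ID")
            if pid is None:
                raise FormatError(f"{path}: CDS without protein_id at line {lineno}")
            genes.setdefault(pid, attrs.get("gene", pid))
            raw.setdefault(pid, []).append(
                (int(cols[3]) - 1, int(cols[4]), cols[6], cols[0])
            )
    models: dict[str, ReferenceExonModel] = {}
    for pid, feats in raw.items():
        strand = feats[0][2]
        feats.sort(key=lambda f: f[0], reverse=(strand == "-"))
        model = ReferenceExonModel(genes[pid], pid)
        pos = 0
        for i, (start, end, _, _) in enumerate(feats, start=1):
            length = end - start
            model.exons.append((i, pos, pos + length))
            pos += length
        models[pid] = model
    return models
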