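"""Circular-genome utilities and mitochondrial variant analytics.

Variant change strings are classified from their own text: single-base
substitutions split into transitions (purine<->purine, pyrimidine<->
pyrimidine) and transversions; ``+SEQ``/``-SEQ`` are insertions/deletions;
``(unit)m→(unit)n`` with a multi-base unit is a tandem-repeat copy-number
change (pooled with indels in summaries, single-base units classify as plain
indels); any other multi-base replacement is a complex substitution.  The
stated label printed alongside a record is compared against the computed
class and disagreements are reported, never overridden.

Circular molecules assembled from linear reads carry a duplicated
suffix/prefix overlap; :func:`detect_circular` collapses it and rotates the
molecule to its lexicographically smallest rotation so any rotation of the
same circle yields one canonical form.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .config import DEFAULT_CONFIG, RunConfig
from .io_formats import SeqRecord, TabularHit, VariantRecord

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}

_SINGLE = re.compile(r"^([ACGT])→([ACGT])$")
_INS = re.compile(r"^\+([ACGTN]+)$")
_DEL = re.compile(r"^-([ACGTN]+)$")
_TANDEM = re.compile(r"^\(([ACGT]+)\)(\d+)→\(([ACGT]+)\)(\d+)$")
_MULTI = re.compile(r"^([ACGT]+)→([ACGT]+)$")


class ChangeStringError(ValueError):
    pass


@dataclass
class VariantClass:
    record: VariantRecord
    klass: str  # transition | transversion | insertion | deletion |
    #             complex_substitution | tandem_repeat_change
    stated_agrees: bool = True


@dataclass
class VariantSummary:
    counts: dict[str, int] = field(default_factory=dict)
    total: int = 0
    snv: int = 0
    indel_pool: int = 0           # insertions + deletions + tandem changes
    complex: int = 0
    label_mismatches: list[tuple[int, str, str]] = field(default_factory=list)


def _is_transition(a: str, b: str) -> bool:
    return (a in PURINES and b in PURINES) or (a in PYRIMIDINES and b in PYRIMIDINES)


def classify_variant(v: VariantRecord) -> VariantClass:
    """Classify one variant from its change string.

    Raises :class:`ChangeStringError` naming the record when the change
    string fits no known pattern.
    """
    change = v.change
    m = _SINGLE.match(change)
    if m:
        a, b = m.groups()
        klass = "transition" if _is_transition(a, b) else "transversion"
        return VariantClass(v, klass, _stated_agrees(v.stated_type, klass))
    if _INS.match(change):
        return VariantClass(v, "insertion", _stated_agrees(v.stated_type, "insertion"))
    if _DEL.match(change):
        return VariantClass(v, "deletion", _stated_agrees(v.stated_type, "deletion"))
    m = _TANDEM.match(change)
    if m:
        unit_a, copies_a, unit_b, copies_b = m.groups()
        if unit_a != unit_b:
            raise ChangeStringError(
                f"variant at {v.start}: tandem units differ ({unit_a!r} vs {unit_b!r})"
            )
        if len(unit_a) == 1:
            klass = "insertion" if int(copies_b) > int(copies_a) else "deletion"
        else:
            klass = "tandem_repeat_change"
        return VariantClass(v, klass, _stated_agrees(v.stated_type, klass))
    m = _MULTI.match(change)
    if m:
        klass = "complex_substitution"
        return VariantClass(v, klass, _stated_agrees(v.stated_type, klass))
    raise ChangeStringError(
        f"variant at {v.start}: unparseable change string {change!r}"
    )


_STATED_COMPAT = {
    "SNP (transition)": {"transition"},
    "SNP (transversion)": {"transversion"},
    "Insertion": {"insertion"},
    "Deletion": {"deletion"},
    "Insertion (tandem repeat)": {"insertion", "tandem_repeat_change"},
    "Deletion (tandem repeat)": {"deletion", "tandem_repeat_change"},
    "Substitution": {"complex_substitution"},
}


def _stated_agrees(stated: str, klass: str) -> bool:
    if not stated:
        return True
    return klass in _STATED_COMPAT.get(stated, set())


def summarize_variants(records: Iterable[VariantRecord]) -> VariantSummary:
    """Counts per class plus the SNV / indel-pool / complex subtotals."""
    summary = VariantSummary()
    for v in records:
        vc = classify_variant(v)
        summary.counts[vc.klass] = summary.counts.get(vc.klass, 0) + 1
        summary.total += 1
        if not vc.stated_agrees:
            summary.label_mismatches.append((v.start, v.stated_type, vc.klass))
    c = summary.counts
    summary.snv = c.get("transition", 0) + c.get("transversion", 0)
    summary.indel_pool = (
        c.get("insertion", 0) + c.get("deletion", 0) + c.get("tandem_repeat_change", 0)
    )
    summary.complex = c.get("complex_substitution", 0)
    return summary


# ---------------------------------------------------------------------------
# Circular molecules


def least_rotation(s: str) -> int:
    """Index of the lexicographically smallest rotation (Booth's algorithm)."""
    ss = s + s
    f = [-1] * len(ss)
    k = 0
    for j in range(1, len(ss)):
        sj = ss[j]
        i = f[j - k - 1]
        while i != -1 and sj != ss[k + i + 1]:
            if sj < ss[k + i + 1]:
                k = j - i - 1
            i = f[i]
        if sj != ss[k + i + 1]:
            if sj < ss[k]:
                k = j
            f[j - k] = -1
        else:
            f[j - k] = i + 1
    return k


def _overlap_identity(a: str, b: str) -> float:
    if len(a) != len(b):
        return 0.0
    if a == b:
        return 1.0
    return sum(x == y for x, y in zip(a, b)) / len(a)


def _best_suffix_prefix(left: str, right: str, min_overlap: int, min_identity: float) -> int:
    """Longest suffix(left)/prefix(right) overlap at >= min_identity, else 0."""
    for length in range(min(len(left), len(right)), min_overlap - 1, -1):
        if _overlap_identity(left[-length:], right[:length]) >= min_identity:
            return length
    return 0


@dataclass
class CircularResult:
    sequence: str          # canonical linear form (collapsed, least rotation)
    circular: bool
    length: int
    n_reads_used: int = 1


def detect_circular(
    seqs: str | SeqRecord | Sequence[SeqRecord],
    min_overlap: int | None = None,
    min_identity: float | None = None,
    cfg: RunConfig = DEFAULT_CONFIG,
) -> CircularResult:
    """Detect and canonicalize a circular molecule.

    Accepts one sequence or a set of reads.  Reads are first chained by
    suffix/prefix overlaps; a terminal self-overlap of at least
    ``min_overlap`` bp (default 100) at ``min_identity`` (default 0.95)
    marks the molecule circular, the duplicated overlap is collapsed, and
    the result is rotated to its lexicographically smallest rotation.
    """
    if min_overlap is None:
        min_overlap = cfg.circular_min_overlap
    if min_identity is None:
        min_identity = cfg.circular_min_identity
    if isinstance(seqs, str):
        reads = [seqs]
    elif isinstance(seqs, SeqRecord):
        reads = [seqs.seq]
    else:
        reads = [r.seq if isinstance(r, SeqRecord) else str(r) for r in seqs]

    current = reads[0]
    remaining = list(reads[1:])
    used = 1
    while remaining:
        best_len, best_idx = 0, -1
        for i, read in enumerate(remaining):
            ov = _best_suffix_prefix(current, read, min_overlap, min_identity)
            if ov > best_len:
                best_len, best_idx = ov, i
        if best_idx == -1:
            break
        nxt = remaining.pop(best_idx)
        if best_len >= len(nxt):  # fully contained
            used += 1
            continue
        current = current + nxt[best_len:]
        used += 1

    self_ov = 0
    max_self = len(current) // 2
    for length in range(max_self, min_overlap - 1, -1):
        if _overlap_identity(current[:length], current[-length:]) >= min_identity:
            self_ov = length
            break
    if self_ov:
        collapsed = current[:-self_ov]
        k = least_rotation(collapsed)
        canonical = collapsed[k:] + collapsed[:k]
        return CircularResult(canonical, True, len(collapsed), used)
    return CircularResult(current, False, len(current), used)


# ---------------------------------------------------------------------------
# Tandem arrays


@dataclass
class TandemArray:
    """A maximal perfect tandem array (0-based half-open on the host).

    ``span`` counts complete copies of the minimal unit only; a trailing
    partial copy is recorded separately.  ``decompositions`` lists every
    (unit_length, copies) pair whose composite unit tiles the span exactly.
    """

    start: int
    end: int
    minimal_unit: str
    minimal_copies: int
    span: int
    partial_tail: int = 0
    decompositions: list[tuple[int, int]] = field(default_factory=list)


def _minimal_period(block: str) -> int:
    """Smallest period of an exactly periodic string (KMP failure function)."""
    n = len(block)
    fail = [0] * (n + 1)
    k = 0
    for i in range(1, n):
        while k and block[i] != block[k]:
            k = fail[k]
        if block[i] == block[k]:
            k += 1
        fail[i + 1] = k
    p = n - fail[n]
    return p if n % p == 0 else n


def tandem_array(
    seq: str,
    region: tuple[int, int] | None = None,
    unit_range: tuple[int, int] = (2, 100),
    min_copies: int = 3,
    min_span: int = 12,
) -> TandemArray | None:
    """Find the maximal perfect tandem array in ``seq`` (or a region of it).

    Periodicities are scanned for every unit length in ``unit_range``; the
    longest periodic stretch wins (ties: leftmost, then smallest unit).  The
    reported unit is the minimal period of the array; composite units that
    also tile the span exactly are listed as alternative decompositions.
    Returns ``None`` when no array reaches ``min_copies`` complete copies
    and ``min_span`` bases.
    """
    offset = 0
    if region is not None:
        offset = region[0]
        seq = seq[region[0] : region[1]]
    n = len(seq)
    lo_u, hi_u = unit_range
    best: tuple[int, int, int] | None = None  # (-total, start, unit)
    for u in range(lo_u, min(hi_u, n // 2) + 1):
        i = u
        while i < n:
            if seq[i] != seq[i - u]:
                i += 1
                continue
            j = i
            while j < n and seq[j] == seq[j - u]:
                j += 1
            total = (j - i) + u  # periodic stretch [i-u, j)
            if total // u >= min_copies and total >= min_span:
                cand = (-total, i - u, u)
                if best is None or cand < best:
                    best = cand
            i = j + 1
    if best is None:
        return None
    total, start, u = -best[0], best[1], best[2]
    copies_raw = total // u
    block = seq[start : start + copies_raw * u]
    p = _minimal_period(block)
    # re-measure the run in terms of the minimal period
    full_copies = 0
    pos = start
    while pos + p <= start + total and seq[pos : pos + p] == seq[start : start + p]:
        full_copies += 1
        pos += p
    span = full_copies * p
    partial = total - span
    decomps = [
        (k, span // k)
        for k in range(p, span // 2 + 1, p)
        if span % k == 0
    ]
    return TandemArray(
        start=offset + start,
        end=offset + start + span,
        minimal_unit=seq[start : start + p],
        minimal_copies=full_copies,
        span=span,
        partial_tail=partial,
        decompositions=decomps,
    )


# ---------------------------------------------------------------------------
# NUMT loci


def numt_loci(
    hits: Sequence[TabularHit],
    e_cutoff: float | None = None,
    merge_gap: int | None = None,
    cfg: RunConfig = DEFAULT_CONFIG,
) -> tuple[int, list[tuple[str, int, int]]]:
    """Count nuclear-mitochondrial (NUMT) loci from mito-vs-nuclear hits.

    Hits at ``e <= e_cutoff`` (default 1e-5) are projected to assembly
    intervals (0-based half-open); intervals within ``merge_gap`` bp merge
    into one locus.  Returns the locus count and the merged intervals in
    BED order.
    """
    if e_cutoff is None:
        e_cutoff = cfg.numt_e_cutoff
    if merge_gap is None:
        merge_gap = cfg.numt_merge_gap
    intervals = sorted(
        (h.subject_id, h.s_start - 1, h.s_end)
        for h in hits
        if h.e_value <= e_cutoff
    )
    merged: list[tuple[str, int, int]] = []
    for contig, start, end in intervals:
        if merged and merged[-1][0] == contig and start <= merged[-1][2] + merge_gap:
            prev = merged[-1]
            merged[-1] = (contig, prev[1], max(prev[2], end))
        else:
            merged.append((contig, start, end))
    return len(merged), merged


def write_bed(loci: Iterable[tuple[str, int, int]], path) -> None:
    with open(path, "w") as fh:
        for i, (contig, start, end) in enumerate(loci, start=1):
            fh.write(f"{contig}\t{start}\t{end}\tnumt_{i}\n")
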