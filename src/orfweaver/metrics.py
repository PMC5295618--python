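"""Assembly contiguity metrics and accounting arithmetic.

N50 follows the standard cumulative-sum convention: the smallest length L
such that contigs of length >= L together contain at least half the
assembly.  Rates and percentages are rounded half-up at the displayed
precision so printed figures are reproducible exactly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

from .io_formats import SeqRecord

_N_RUN = re.compile(r"[Nn]{10,}")


@dataclass
class AssemblyStats:
    n_contigs: int
    total_bp: int
    n50: int
    max_len: int
    mean_len: float

    def as_dict(self) -> dict:
        return {
            "n_contigs": self.n_contigs,
            "total_bp": self.total_bp,
            "n50": self.n50,
            "max_len": self.max_len,
            "mean_len": self.mean_len,
        }


def nxx(lengths: Sequence[int], x: float = 50) -> int:
    """Smallest length L such that sequences >= L sum to >= x% of the total."""
    if not lengths:
        raise ValueError("nxx of an empty length set is undefined")
    if any(l <= 0 for l in lengths):
        raise ValueError("lengths must be positive")
    target = sum(lengths) * x / 100.0
    acc = 0
    for l in sorted(lengths, reverse=True):
        acc += l
        if acc >= target:
            return l
    return min(lengths)  # unreachable for x <= 100


def assembly_stats(lengths: Sequence[int]) -> AssemblyStats:
    if not lengths:
        raise ValueError("no sequences")
    total = sum(lengths)
    return AssemblyStats(
        n_contigs=len(lengths),
        total_bp=total,
        n50=nxx(lengths, 50),
        max_len=max(lengths),
        mean_len=total / len(lengths),
    )


def split_at_gaps(records: Iterable[SeqRecord], min_n_run: int = 10) -> list[int]:
    """Contig lengths of a (possibly gapped) assembly: split at N-runs >= 10."""
    lengths: list[int] = []
    for rec in records:
        for piece in _N_RUN.split(rec.seq):
            if piece:
                lengths.append(len(piece))
    return lengths


def scaffold_and_contig_stats(records: Sequence[SeqRecord]) -> dict:
    """Stats at scaffold granularity and, after gap splitting, contig granularity."""
    scaffold_lengths = [len(r.seq) for r in records]
    contig_lengths = split_at_gaps(records)
    return {
        "scaffolds": assembly_stats(scaffold_lengths).as_dict(),
        "contigs": assembly_stats(contig_lengths).as_dict(),
    }


def _round_half_up(value: float, decimals: int) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def stage_accounting(
    stage_totals: Sequence[tuple[str, float]]
) -> list[tuple[str, float, float | None, bool]]:
    """Per-stage percent lost relative to the input total.

    ``stage_totals`` is an ordered (label, total) sequence whose first entry
    is the input; each later stage reports (input - stage) / input * 100 to
    one decimal.  A stage gaining material over the input is flagged (last
    tuple element False) since bases cannot be created.
    """
    if not stage_totals:
        raise ValueError("no stages")
    label0, input_total = stage_totals[0]
    if input_total <= 0:
        raise ValueError("input total must be positive")
    out: list[tuple[str, float, float | None, bool]] = [
        (label0, input_total, None, True)
    ]
    for label, total in stage_totals[1:]:
        if total <= 0:
            raise ValueError(f"stage {label!r} total must be positive")
        lost = _round_half_up((input_total - total) / input_total * 100.0, 1)
        out.append((label, total, lost, total <= input_total))
    return out


def rate(numerator_count: int, denominator_bp: float, decimals: int = 2) -> float:
    """Percentage numerator/denominator, rounded half-up to ``decimals``."""
    if denominator_bp <= 0:
        raise ValueError("denominator must be positive")
    if numerator_count < 0:
        raise ValueError("numerator must be non-negative")
    return _round_half_up(numerator_count / denominator_bp * 100.0, decimals)
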