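"""Pipeline configuration.

Every numeric threshold used across the toolkit lives here with its default.
The defaults are the operating points of the published workflow this package
generalizes: ortholog assignment at e <= 1e-10 with a rodent-first reference
panel, component merging requiring >= 15 identical overlapping bases and
reference-interval agreement within 15%, a 30-nt in-frame scan window for
provisional terminal codons, exon mapping at > 98% identity with 10 bp of
boundary slack (exons < 17 bp spared), a 500-bp discordance window for
assembly reconciliation, 100-N scaffold joints, and a 1e-5 cutoff for
nuclear-mitochondrial (NUMT) locus scanning.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

#: Reference-proteome fallback order: rodents nearest the target clade first,
#: then two outgroup primates.
DEFAULT_PANEL: tuple[str, ...] = (
    "mouse",
    "rat",
    "kangaroo_rat",
    "prairie_vole",
    "chinchilla",
    "deer_mouse",
    "marmot",
    "ground_squirrel",
    "human",
    "chimpanzee",
)


@dataclass
class RunConfig:
    # --- ortholog assignment / ORF merging -------------------------------
    e_cutoff: float = 1e-10            # BLASTp significance cutoff
    panel_order: tuple[str, ...] = DEFAULT_PANEL
    min_overlap_nt: int = 15           # identical overlapping bases to merge
    max_interval_diff: float = 0.15    # reference-interval length tolerance
    interval_diff_on: str = "subject"  # or "query"
    near_best_bits: float = 0.05       # "near-best" = within 5% of best bits
    min_merge_identity: float = 0.80   # aa identity over the merge window
    allow_overlap_mismatch: bool = False  # tolerant overlap (<=1 mm / 50 nt)
    upstream_scan_nt: int = 30         # provisional start-codon window
    downstream_scan_nt: int = 30       # provisional stop-codon window

    # --- exon mapping -----------------------------------------------------
    exon_min_identity: float = 98.0    # percent identity threshold
    exon_identity_strict: bool = True  # strictly greater than the threshold
    boundary_slack: int = 10           # bp flexibility per exon boundary
    spared_exon_lt: int = 17           # exons below this length are spared
    resolver_exhaustive_limit: int = 100_000

    # --- scaffolding ------------------------------------------------------
    gap_n: int = 100                   # N-run length at scaffold joints
    min_junction_support: int = 1      # ORFs required to apply a junction
    rescue_flank: int = 1000           # bp imported around a rescued exon

    # --- reconciliation ---------------------------------------------------
    window: int = 500                  # discordance merge window (bp)
    min_clip: int = 100                # unaligned terminus that counts as a clip
    clip_e_cutoff: float = 1e-10       # alignments above this do not anchor
    support_margin: int = 0            # extra bp a spanning read must cover
    conservative: bool = False         # do not break, only flag

    # --- mitochondrial tools ----------------------------------------------
    numt_e_cutoff: float = 1e-5
    numt_merge_gap: int = 0
    circular_min_overlap: int = 100
    circular_min_identity: float = 0.95

    seed: int = 0

    def replace(self, **kw) -> "RunConfig":
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d.update(kw)
        return RunConfig(**d)


DEFAULT_CONFIG = RunConfig()

_BOOL = {"true": True, "false": False, "yes": True, "no": False, "1": True, "0": False}


def load_config(path: str | Path) -> RunConfig:
    """Load a flat ``key = value`` text file over the defaults."""
    cfg = RunConfig()
    types = {f.name: f.type for f in fields(RunConfig)}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, value = (tok.strip() for tok in line.split("=", 1))
            if key not in types:
                raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
            current = getattr(cfg, key)
            if isinstance(current, bool):
                setattr(cfg, key, _BOOL[value.lower()])
            elif isinstance(current, int):
                setattr(cfg, key, int(value))
            elif isinstance(current, float):
                setattr(cfg, key, float(value))
            elif isinstance(current, tuple):
                setattr(cfg, key, tuple(tok.strip() for tok in value.split(",")))
            else:
                setattr(cfg, key, value)
    return cfg
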