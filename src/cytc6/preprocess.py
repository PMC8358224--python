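"""Validity filtering and N-terminal targeting-peptide trimming.

Candidate homologs are filtered on precursor length (80–200 residues,
inclusive, applied before trimming) and must carry an appropriately
located haem-binding motif CXXCH on the mature sequence. Putative
targeting peptides are removed by alignment-overhang trimming against a
mature class-agnostic reference — the query is globally aligned to the
cyanobacterial c6 reference and any query residues aligned before the
first query/reference residue pair are cut. This keeps trimming
deterministic and self-contained (no signal-peptide predictor).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .reference_align import (
    AlignmentResult,
    DEFAULT_GAP_EXTEND,
    DEFAULT_GAP_OPEN,
    DEFAULT_MATRIX,
    ReferenceProfile,
    global_align,
)
from .sequence_io import SequenceRecord


class UntrimmableError(ValueError):
    """Alignment to the mature reference covered too little of it to trim."""


@dataclass(frozen=True)
class FilterConfig:
    """Validity-filter settings.

    ``min_len``/``max_len`` bound the precursor (untrimmed) length; the
    interval is inclusive, so lengths of exactly 80 or 200 pass.
    ``motif_window`` is the 1-based inclusive interval on the mature
    sequence within which the first cysteine of CXXCH must fall for the
    motif to count as "appropriately located". ``post_trim_min_len`` guards
    against degenerate trims. ``motif_pattern`` uses X as a wildcard.
    """

    min_len: int = 80
    max_len: int = 200
    motif_window: tuple[int, int] = (5, 40)
    post_trim_min_len: int = 60
    motif_pattern: str = "CXXCH"

    def __post_init__(self) -> None:
        if not 0 < self.min_len <= self.max_len:
            raise ValueError("require 0 < min_len <= max_len")
        lo, hi = self.motif_window
        if not (1 <= lo <= hi <= self.max_len):
            raise ValueError("motif_window must lie within [1, max_len]")

    @property
    def motif_regex(self) -> re.Pattern[str]:
        return re.compile(self.motif_pattern.replace("X", "."))


@dataclass(frozen=True)
class FilterResult:
    passed: bool
    reason: str = ""


@dataclass(frozen=True)
class MotifScan:
    """Result of the haem-motif search.

    ``position`` is the 1-based start of the first in-window CXXCH, or
    ``None`` when no occurrence qualifies; out-of-window occurrences are
    listed in ``out_of_window`` for diagnostics but never qualify.
    """

    position: int | None
    out_of_window: tuple[int, ...] = ()

    @property
    def found(self) -> bool:
        return self.position is not None


@dataclass(frozen=True)
class MaturedSequence:
    """A sequence with its putative targeting peptide removed.

    ``residues`` is a suffix of the source record's residues starting at
    offset ``trim_offset`` (0 when nothing was trimmed).
    """

    source_id: str
    residues: str
    trim_offset: int = 0


def length_filter(record: SequenceRecord, cfg: FilterConfig = FilterConfig()) -> FilterResult:
    """Pass/fail the precursor length window (applied before trimming)."""
    n = len(record.residues)
    if n < cfg.min_len:
        return FilterResult(False, f"below {cfg.min_len} ({n} aa)")
    if n > cfg.max_len:
        return FilterResult(False, f"above {cfg.max_len} ({n} aa)")
    return FilterResult(True)


def find_haem_motif(seq: str, cfg: FilterConfig = FilterConfig()) -> MotifScan:
    """Locate the first appropriately located CXXCH haem-binding motif.

    Occurrences may overlap; all starts are collected with a lookahead
    scan. Ties between several in-window occurrences resolve to the
    left-most (haem attachment is N-proximal across the family).
    """
    pattern = re.compile(f"(?=({cfg.motif_regex.pattern}))")
    lo, hi = cfg.motif_window
    in_window: list[int] = []
    outside: list[int] = []
    for m in pattern.finditer(seq):
        pos = m.start() + 1
        (in_window if lo <= pos <= hi else outside).append(pos)
    return MotifScan(
        position=in_window[0] if in_window else None,
        out_of_window=tuple(outside),
    )


#: Minimum run of consecutive aligned residue pairs taken as the start of
#: the mature region. A single chance pairing between a targeting-peptide
#: residue and the reference N-terminus must not anchor the trim.
MIN_ANCHOR_RUN = 5


def _leading_overhang(aln: AlignmentResult) -> int:
    """Query residues preceding the extrapolated reference start.

    The mature region is anchored at the first block of at least
    :data:`MIN_ANCHOR_RUN` consecutive query/reference residue pairs
    (falling back to the first pair for references shorter than the run
    length); reference coordinate 1 is then back-extrapolated gaplessly
    from that block, so a chance pairing between one or two
    targeting-peptide residues and the reference N-terminus cannot skew
    the trim.
    """
    run_start: tuple[int, int] | None = None
    run_len = 0
    first_pair: tuple[int, int] | None = None
    for qpos, rpos in aln.column_map:
        if qpos is not None and rpos is not None:
            if first_pair is None:
                first_pair = (qpos, rpos)
            if run_start is None:
                run_start = (qpos, rpos)
            run_len += 1
            if run_len >= min(MIN_ANCHOR_RUN, len(aln.ref)):
                return max(0, run_start[0] - run_start[1])
        else:
            run_start = None
            run_len = 0
    if first_pair is not None:
        return max(0, first_pair[0] - first_pair[1])
    return len(aln.query)


def _reference_coverage(aln: AlignmentResult) -> float:
    paired = sum(1 for q, r in aln.column_map if q is not None and r is not None)
    return paired / len(aln.ref)


def trim_signal_peptide(
    record: SequenceRecord,
    refs: ReferenceProfile,
    matrix: str | tuple[float, float] | object = DEFAULT_MATRIX,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
    min_coverage: float = 0.5,
) -> MaturedSequence:
    """Trim an N-terminal targeting peptide by alignment overhang.

    The record is globally aligned to the mature c6 reference; the trim
    offset is the number of query residues aligned before the first
    query/reference residue pair. Idempotent: trimming a matured sequence
    again yields offset 0.

    Raises
    ------
    UntrimmableError
        If fewer than ``min_coverage`` of the reference residues are
        aligned to query residues; such records are routed to UNTRIMMABLE
        by the pipeline rather than trimmed blindly.
    """
    aln = global_align(record.residues, refs.c6.residues, matrix, gap_open, gap_extend)
    coverage = _reference_coverage(aln)
    if coverage < min_coverage:
        raise UntrimmableError(
            f"record {record.id!r}: alignment covers only {coverage:.0%} of the "
            f"mature reference (<{min_coverage:.0%}); refusing to trim"
        )
    offset = _leading_overhang(aln)
    return MaturedSequence(
        source_id=record.id,
        residues=record.residues[offset:],
        trim_offset=offset,
    )
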