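"""Global pairwise alignment and reference-frame coordinate mapping.

Classification of cytochrome c6 homologs is anchored to two mature
reference sequences: a plant-type c6A (which fixes the diagnostic residue
position, 52 in the A. thaliana mature frame) and a cyanobacterial c6
(which fixes the loop window where the LIP insertion opens). All
coordinates are 1-based and inclusive on mature sequences.

The aligner is an exact global (Needleman–Wunsch) affine-gap alignment via
Bio.Align.PairwiseAligner; traceback is deterministic (the aligner's first
optimal traceback is always taken).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .sequence_io import SequenceRecord

#: Gap character used in aligned strings.
GAP = "-"

#: Default gap penalties (BLAST-style protein defaults): the first residue
#: of a gap scores ``gap_open``, each further residue ``gap_extend``.
DEFAULT_GAP_OPEN = -11.0
DEFAULT_GAP_EXTEND = -1.0
DEFAULT_MATRIX = "BLOSUM62"

_MOTIF_RE = re.compile(r"C..CH")


class AlignmentError(ValueError):
    """Invalid alignment input (empty sequence, gap characters, ...)."""


@dataclass(frozen=True)
class ReferenceProfile:
    """Mature reference sequences plus the coordinates anchoring classification.

    Parameters
    ----------
    c6a:
        Mature plant-type cytochrome c6A reference. The canonical choice is
        A. thaliana (accession Q93VA3.1); synthetic stand-ins are accepted.
    c6:
        Mature cyanobacterial cytochrome c6 reference (canonically
        Synechococcus sp. PCC 7002, accession O30881.1).
    diagnostic_position:
        1-based coordinate on the mature c6a reference whose residue
        separates high-potential (Gln) from low-potential (Val/Leu/Ile)
        family members. Default 52, the A. thaliana mature numbering.
    loop_window:
        1-based inclusive interval on the mature c6 reference within which a
        loop insertion must open to count as a LIP.
    """

    c6a: SequenceRecord
    c6: SequenceRecord
    diagnostic_position: int = 52
    loop_window: tuple[int, int] = (35, 50)

    def __post_init__(self) -> None:
        if not 1 <= self.diagnostic_position <= len(self.c6a.residues):
            raise ValueError(
                f"diagnostic_position {self.diagnostic_position} outside mature "
                f"c6a reference (length {len(self.c6a.residues)})"
            )
        lo, hi = self.loop_window
        if not (1 <= lo <= hi <= len(self.c6.residues)):
            raise ValueError(
                f"loop_window {self.loop_window} outside mature c6 reference "
                f"(length {len(self.c6.residues)})"
            )
        for rec in (self.c6a, self.c6):
            # N-proximal CXXCH is a validity requirement for any c6-family
            # reference; checked on the first 44 residues (the default
            # "appropriately located" window, positions 5-40).
            if not _MOTIF_RE.search(rec.residues[:44]):
                raise ValueError(
                    f"reference {rec.id!r} lacks an N-proximal CXXCH haem motif"
                )


@dataclass(frozen=True)
class AlignmentResult:
    """A global pairwise alignment of a query against a reference.

    ``column_map`` lists, per alignment column, the pair of 1-based
    coordinates ``(query position or None, reference position or None)``
    where ``None`` marks a gap in that row.
    """

    aligned_query: str
    aligned_ref: str
    score: float
    column_map: tuple[tuple[int | None, int | None], ...]

    @property
    def query(self) -> str:
        return self.aligned_query.replace(GAP, "")

    @property
    def ref(self) -> str:
        return self.aligned_ref.replace(GAP, "")


@dataclass(frozen=True)
class InsertionSpan:
    """A maximal run of reference-gap columns (an insertion in the query).

    ``ref_anchor`` is the 1-based reference position after which the
    insertion opens (0 if the insertion precedes the reference start).
    """

    query_start: int
    query_end: int
    ref_anchor: int

    @property
    def length(self) -> int:
        return self.query_end - self.query_start + 1


def _build_aligner(matrix, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    if isinstance(matrix, str):
        aligner.substitution_matrix = substitution_matrices.load(matrix)
    elif isinstance(matrix, tuple):
        aligner.match_score, aligner.mismatch_score = matrix
    else:
        aligner.substitution_matrix = matrix
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def _column_map(aligned_query: str, aligned_ref: str) -> tuple[tuple[int | None, int | None], ...]:
    cols: list[tuple[int | None, int | None]] = []
    q = r = 0
    for cq, cr in zip(aligned_query, aligned_ref):
        qpos = rpos = None
        if cq != GAP:
            q += 1
            qpos = q
        if cr != GAP:
            r += 1
            rpos = r
        cols.append((qpos, rpos))
    return tuple(cols)


def global_align(
    query: str,
    ref: str,
    matrix: str | tuple[float, float] | object = DEFAULT_MATRIX,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> AlignmentResult:
    """Optimal global affine-gap alignment of ``query`` against ``ref``.

    ``matrix`` may be a named substitution matrix (``"BLOSUM62"``), a
    ``(match, mismatch)`` score pair, or a substitution-matrix array. A gap
    of length L scores ``gap_open + (L-1)*gap_extend``; terminal gaps are
    penalized (true global alignment). The score is the maximum attainable;
    the traceback is deterministic.
    """
    if not query or not ref:
        raise AlignmentError("global_align requires two non-empty sequences")
    if GAP in query or GAP in ref:
        raise AlignmentError("input sequences must not contain gap characters")
    aligner = _build_aligner(matrix, gap_open, gap_extend)
    aln = aligner.align(query, ref)[0]
    aligned_query, aligned_ref = aln[0], aln[1]
    return AlignmentResult(
        aligned_query=aligned_query,
        aligned_ref=aligned_ref,
        score=float(aln.score),
        column_map=_column_map(aligned_query, aligned_ref),
    )


def alignment_from_strings(
    aligned_query: str, aligned_ref: str, score: float = 0.0
) -> AlignmentResult:
    """Build an :class:`AlignmentResult` from two equal-length gapped strings."""
    if len(aligned_query) != len(aligned_ref):
        raise AlignmentError("aligned strings must have equal length")
    return AlignmentResult(
        aligned_query=aligned_query,
        aligned_ref=aligned_ref,
        score=score,
        column_map=_column_map(aligned_query, aligned_ref),
    )


def map_position(aln: AlignmentResult, ref_pos: int) -> int | None:
    """Map a 1-based reference coordinate to the query frame.

    Returns the query coordinate aligned to ``ref_pos``, or ``None`` when
    the query carries a gap there. Raises ``ValueError`` if ``ref_pos``
    falls outside the ungapped reference.
    """
    ref_len = len(aln.ref)
    if not 1 <= ref_pos <= ref_len:
        raise ValueError(f"ref_pos {ref_pos} outside reference of length {ref_len}")
    for qpos, rpos in aln.column_map:
        if rpos == ref_pos:
            return qpos
    raise AssertionError("unreachable: every reference position occurs in column_map")


def find_insertions(aln: AlignmentResult) -> list[InsertionSpan]:
    """Maximal runs of reference-gap columns, reported left to right."""
    spans: list[InsertionSpan] = []
    run_start: int | None = None
    run_end: int | None = None
    last_ref = 0
    anchor = 0
    for qpos, rpos in aln.column_map:
        if rpos is None:
            if qpos is None:  # cannot happen in a pairwise alignment
                continue
            if run_start is None:
                run_start = qpos
                anchor = last_ref
            run_end = qpos
        else:
            if run_start is not None:
                spans.append(InsertionSpan(run_start, run_end, anchor))
                run_start = run_end = None
            last_ref = rpos
    if run_start is not None:
        spans.append(InsertionSpan(run_start, run_end, anchor))
    return spans


def write_alignment_fasta(aln: AlignmentResult, query_id: str, ref_id: str, path: str | Path) -> None:
    """Export an aligned pair as gapped FASTA (for external tree tools)."""
    with Path(path).open("w") as fh:
        for name, seq in ((query_id, aln.aligned_query), (ref_id, aln.aligned_ref)):
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def write_alignment_phylip(aln: AlignmentResult, query_id: str, ref_id: str, path: str | Path) -> None:
    """Export an aligned pair in sequential PHYLIP format."""
    with Path(path).open("w") as fh:
        fh.write(f" 2 {len(aln.aligned_query)}\n")
        for name, seq in ((query_id, aln.aligned_query), (ref_id, aln.aligned_ref)):
            fh.write(f"{name[:10]:<10}{seq}\n")
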