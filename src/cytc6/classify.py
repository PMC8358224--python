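"""Diagnostic-feature extraction and rule-based class assignment.

The cytochrome c6 family splits on two sequence features, read off a
reference-anchored alignment of each mature candidate:

* the residue at the equivalent of mature position 52 of the plant c6A
  reference — glutamine marks the high-potential cytochrome c6, while a
  hydrophobic valine/leucine/isoleucine marks the low-potential homologs;
* the loop insertion peptide (LIP) — a ~12-residue insertion opening in a
  defined loop window of the c6 reference and carrying two cysteines
  (operationalized as a cysteine count; no structural verification of the
  disulfide bridge is attempted).

Labels: Q → C6; V/L/I with a LIP → C6A; V/L/I without → C6B; everything
else (missing motif, gapped or ambiguous diagnostic site, other residues)
→ UNCLASSIFIED with a machine-readable reason. The historical c6B/c6C
split is deliberately collapsed into the single label C6B: the two are
orthologs distinguishable only by taxon sampling, not by any sequence
rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .preprocess import FilterConfig, MaturedSequence, find_haem_motif
from .reference_align import (
    DEFAULT_GAP_EXTEND,
    DEFAULT_GAP_OPEN,
    DEFAULT_MATRIX,
    AlignmentResult,
    ReferenceProfile,
    find_insertions,
    global_align,
    map_position,
)

C6 = "C6"
C6A = "C6A"
C6B = "C6B"
UNCLASSIFIED = "UNCLASSIFIED"
CLASSES = (C6, C6A, C6B)

#: Flag value used for a diagnostic site covered by an alignment gap.
GAP_FLAG = "-"


@dataclass(frozen=True)
class ClassRule:
    """Residue sets separating high- from low-potential family members."""

    high_potential: frozenset[str] = frozenset("Q")
    low_potential: frozenset[str] = frozenset("VLI")

    def __post_init__(self) -> None:
        if not self.high_potential or not self.low_potential:
            raise ValueError("rule residue sets must be non-empty")
        if self.high_potential & self.low_potential:
            raise ValueError("rule residue sets must be disjoint")


@dataclass(frozen=True)
class LipSpec:
    """Acceptance window for a loop insertion peptide.

    The exemplar LIP is 12 residues with two cysteines; the length window
    [8, 20] tolerates indel noise without admitting unrelated insertions.
    """

    min_len: int = 8
    max_len: int = 20
    min_cys: int = 2

    def __post_init__(self) -> None:
        if self.min_len > self.max_len:
            raise ValueError("require min_len <= max_len")
        if self.min_cys < 0:
            raise ValueError("min_cys must be >= 0")


@dataclass(frozen=True)
class LipHit:
    """A detected loop insertion peptide on the query."""

    query_start: int
    query_end: int
    ref_anchor: int
    cys_count: int

    @property
    def length(self) -> int:
        return self.query_end - self.query_start + 1


@dataclass(frozen=True)
class FeatureProfile:
    """Evidence extracted from one matured candidate.

    Missing evidence is encoded explicitly (``None`` / :data:`GAP_FLAG`),
    never silently defaulted; the class label is a pure function of this
    profile.
    """

    motif_position: int | None
    diagnostic_residue: str
    lip: LipHit | None
    low_cys_insertion: bool = False
    alignment_scores: Mapping[str, float] = field(default_factory=dict)

    @property
    def lip_cys_count(self) -> int:
        return self.lip.cys_count if self.lip else 0


@dataclass(frozen=True)
class ClassLabel:
    label: str
    reason: str
    flags: tuple[str, ...] = ()


def detect_lip(
    aln_to_c6: AlignmentResult,
    spec: LipSpec,
    loop_window: tuple[int, int],
) -> tuple[LipHit | None, bool]:
    """Find a qualifying LIP among the query's insertions against c6.

    Qualifying: opens after a reference position inside ``loop_window``,
    length within ``[min_len, max_len]`` and at least ``min_cys`` cysteines
    (left-most if several qualify). Returns ``(hit or None, saw_low_cys)``
    where the second element records an otherwise-qualifying insertion that
    failed only the cysteine count — the ambiguous one-cysteine case that
    is surfaced as a warning flag on C6B calls.
    """
    lo, hi = loop_window
    query = aln_to_c6.query
    saw_low_cys = False
    for span in find_insertions(aln_to_c6):
        if span.ref_anchor == 0 or not lo <= span.ref_anchor <= hi:
            continue
        if not spec.min_len <= span.length <= spec.max_len:
            continue
        cys = query[span.query_start - 1 : span.query_end].count("C")
        if cys >= spec.min_cys:
            return LipHit(span.query_start, span.query_end, span.ref_anchor, cys), saw_low_cys
        saw_low_cys = True
    return None, saw_low_cys


def extract_features(
    matured: MaturedSequence,
    refs: ReferenceProfile,
    lip_spec: LipSpec = LipSpec(),
    filter_cfg: FilterConfig = FilterConfig(),
    matrix: str | tuple[float, float] | object = DEFAULT_MATRIX,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> FeatureProfile:
    """Extract motif, diagnostic residue, and LIP evidence for one candidate."""
    scan = find_haem_motif(matured.residues, filter_cfg)
    aln_c6a = global_align(matured.residues, refs.c6a.residues, matrix, gap_open, gap_extend)
    qpos = map_position(aln_c6a, refs.diagnostic_position)
    diagnostic = matured.residues[qpos - 1] if qpos is not None else GAP_FLAG
    aln_c6 = global_align(matured.residues, refs.c6.residues, matrix, gap_open, gap_extend)
    lip, saw_low_cys = detect_lip(aln_c6, lip_spec, refs.loop_window)
    return FeatureProfile(
        motif_position=scan.position,
        diagnostic_residue=diagnostic,
        lip=lip,
        low_cys_insertion=saw_low_cys,
        alignment_scores={"c6a": aln_c6a.score, "c6": aln_c6.score},
    )


def assign_class(features: FeatureProfile, rule: ClassRule = ClassRule()) -> ClassLabel:
    """Assign C6 / C6A / C6B / UNCLASSIFIED from an evidence profile.

    Pure function: identical profiles always yield identical labels.
    Motif failure dominates all other evidence (the motif is a validity
    criterion, not a class feature). Residues outside {Q} ∪ {V,L,I} — and
    gapped or ambiguous (X) diagnostic sites — are refused rather than
    extrapolated, so distribution counts are never silently inflated.
    """
    if features.motif_position is None:
        return ClassLabel(UNCLASSIFIED, "no haem motif")
    d = features.diagnostic_residue
    if d == GAP_FLAG:
        return ClassLabel(UNCLASSIFIED, "diagnostic site gapped in alignment")
    if d == "X":
        return ClassLabel(UNCLASSIFIED, "diagnostic residue ambiguous (X)")
    if d in rule.high_potential:
        return ClassLabel(C6, f"diagnostic residue {d} (high potential)")
    if d in rule.low_potential:
        if features.lip is not None:
            return ClassLabel(
                C6A,
                f"diagnostic residue {d} (low potential) with LIP "
                f"(length {features.lip.length}, {features.lip.cys_count} Cys)",
            )
        flags = ("low_cys_insertion",) if features.low_cys_insertion else ()
        return ClassLabel(
            C6B, f"diagnostic residue {d} (low potential), no LIP", flags
        )
    return ClassLabel(UNCLASSIFIED, f"diagnostic residue {d} outside rule sets")
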