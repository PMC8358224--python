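"""Protein FASTA and taxon→clade map I/O.

Sequence records carry upper-case residues over the 20 standard amino
acids plus ``X`` (unknown residue, as produced by database translations).
Ambiguity is counted per record so that downstream classification can
refuse to guess at decision-relevant sites instead of silently defaulting.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

log = logging.getLogger(__name__)

#: The 20 standard amino acids.
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")
#: Residue alphabet accepted on input: standard amino acids plus X (unknown).
ALPHABET = AMINO_ACIDS | frozenset("X")

_BRACKET_TAXON = re.compile(r"\[([^\[\]]+)\]")


class SequenceError(ValueError):
    """Invalid sequence content (alphabet violation, empty residues, ...)."""


class FastaParseError(SequenceError):
    """Structurally malformed FASTA input."""


class CladeMapError(ValueError):
    """Malformed or inconsistent taxon→clade mapping."""


@dataclass(frozen=True)
class SequenceRecord:
    """A single protein sequence flowing through the pipeline.

    Parameters
    ----------
    id:
        Unique identifier (FASTA header token before the first whitespace).
    residues:
        Upper-case amino-acid string; letters restricted to :data:`ALPHABET`.
    taxon:
        Organism name, possibly empty when the header carries none.
    description:
        Free-text remainder of the FASTA header.
    """

    id: str
    residues: str
    taxon: str = ""
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceError("sequence record requires a non-empty id")
        if not self.residues:
            raise SequenceError(f"record {self.id!r}: empty residue string")
        bad = set(self.residues) - ALPHABET
        if bad:
            raise SequenceError(
                f"record {self.id!r}: disallowed residue(s) "
                f"{', '.join(sorted(bad))!s}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def n_ambiguous(self) -> int:
        """Number of X (unknown) residues."""
        return self.residues.count("X")


def _taxon_from_description(description: str) -> str:
    """Extract a bracketed organism name ``[...]`` if present, else ``""``.

    Matches the common protein-database header dialect where the organism
    is appended in square brackets.
    """
    m = _BRACKET_TAXON.search(description)
    return m.group(1).strip() if m else ""


def read_fasta(path: str | Path, *, taxon_from_brackets: bool = True) -> list[SequenceRecord]:
    """Read a protein FASTA file into a list of :class:`SequenceRecord`.

    Order is preserved. The header token before the first whitespace becomes
    the record id; with ``taxon_from_brackets`` the taxon is parsed from a
    bracketed organism name in the description, else left empty.

    Raises
    ------
    FastaParseError
        If sequence data precedes the first header (naming the line), or on
        duplicate ids.
    SequenceError
        If a record contains a residue outside the allowed alphabet.
    """
    path = Path(path)
    text = path.read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if not stripped.startswith(">"):
            raise FastaParseError(
                f"{path}: line {lineno}: sequence data before first FASTA header"
            )
        break
    else:
        log.warning("%s: empty FASTA file, no records read", path)
        return []

    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with path.open() as handle:
        for bio_rec in SeqIO.parse(handle, "fasta"):
            if bio_rec.id in seen:
                raise FastaParseError(f"{path}: duplicate sequence id {bio_rec.id!r}")
            seen.add(bio_rec.id)
            description = bio_rec.description
            if description.startswith(bio_rec.id):
                description = description[len(bio_rec.id):].strip()
            taxon = _taxon_from_description(description) if taxon_from_brackets else ""
            records.append(
                SequenceRecord(
                    id=bio_rec.id,
                    residues=str(bio_rec.seq).upper(),
                    taxon=taxon,
                    description=description,
                )
            )
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as FASTA (bodies wrapped at 60 columns).

    Round-trip property: ``read_fasta`` on the output reproduces ids and
    residues exactly; two consecutive writes are byte-identical.
    """
    path = Path(path)
    bio_records = []
    for rec in records:
        header = rec.description
        if rec.taxon and f"[{rec.taxon}]" not in header:
            header = f"{header} [{rec.taxon}]".strip()
        bio_records.append(
            _BioSeqRecord(Seq(rec.residues), id=rec.id, description=header)
        )
    with path.open("w") as handle:
        SeqIO.write(bio_records, handle, "fasta")


def read_clade_map(path: str | Path) -> dict[str, str]:
    """Read a two-column tab-separated taxon→clade mapping.

    A header row ``taxon<TAB>clade`` (case-insensitive) is skipped if
    present. Duplicate rows are tolerated when consistent (with a warning);
    conflicting duplicates or rows with fewer than two columns raise
    :class:`CladeMapError` naming the line.
    """
    path = Path(path)
    mapping: dict[str, str] = {}
    with path.open() as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = [p.strip() for p in line.split("\t")]
            if len(parts) < 2 or not parts[0] or not parts[1]:
                raise CladeMapError(
                    f"{path}: line {lineno}: expected two tab-separated columns"
                )
            taxon, clade = parts[0], parts[1]
            if lineno == 1 and (taxon.lower(), clade.lower()) == ("taxon", "clade"):
                continue
            if taxon in mapping:
                if mapping[taxon] != clade:
                    raise CladeMapError(
                        f"{path}: line {lineno}: taxon {taxon!r} mapped to both "
                        f"{mapping[taxon]!r} and {clade!r}"
                    )
                log.warning("%s: line %d: duplicate row for taxon %r", path, lineno, taxon)
                continue
            mapping[taxon] = clade
    return mapping


def write_clade_map(mapping: Mapping[str, str], path: str | Path) -> None:
    """Write a taxon→clade mapping as TSV with a header row."""
    path = Path(path)
    with path.open("w") as handle:
        handle.write("taxon\tclade\n")
        for taxon in sorted(mapping):
            handle.write(f"{taxon}\t{mapping[taxon]}\n")
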