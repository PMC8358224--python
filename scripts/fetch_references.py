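#!/usr/bin/env python
"""Fetch the canonical cytochrome c6A/c6 reference sequences from NCBI.

The package does not bundle the canonical accessions (A. thaliana
cytochrome c6A, Q93VA3.1, and Synechococcus sp. PCC 7002 cytochrome c6,
O30881.1); this one-time helper retrieves them and writes a reference
FASTA with the ids the pipeline expects (``ref_c6a``, ``ref_c6``).

The downloaded entries are precursor sequences. Classification is
anchored to mature coordinates (position 52 counts from the mature
A. thaliana c6A N-terminus), so remove the N-terminal targeting peptides
before use — e.g. with the annotated mature start from UniProt — and
verify that ``ref_c6a`` then carries V at position 52 and both entries an
N-proximal CXXCH motif. Requires network access.

Usage:
    python scripts/fetch_references.py --out references.fasta
"""

from __future__ import annotations

import argparse
import sys
import urllib.parse
import urllib.request

EFETCH = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
ACCESSIONS = {"ref_c6a": "Q93VA3.1", "ref_c6": "O30881.1"}


def fetch(accession: str) -> str:
    query = urllib.parse.urlencode(
        {"db": "protein", "id": accession, "rettype": "fasta", "retmode": "text"}
    )
    with urllib.request.urlopen(f"{EFETCH}?{query}", timeout=30) as response:
        return response.read().decode()


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", default="references.fasta")
    args = parser.parse_args()

    entries = []
    for ref_id, accession in ACCESSIONS.items():
        text = fetch(accession).strip()
        header, _, body = text.partition("\n")
        entries.append(f">{ref_id} {header.lstrip('>')}\n{body}\n")
        print(f"fetched {accession} as {ref_id}", file=sys.stderr)
    with open(args.out, "w") as handle:
        handle.writelines(entries)
    print(
        f"wrote {args.out} — trim the targeting peptides to mature "
        "coordinates before classification (see module docstring)",
        file=sys.stderr,
    )


if __name__ == "__main__":
    main()
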