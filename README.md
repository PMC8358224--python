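# cytc6

Rule-based classification of cytochrome *c*6-family proteins and
reconstruction of the family's gain/loss history on species trees.

## The problem

Cytochrome *c*6 carries electrons between the cytochrome *b*6*f* complex
and photosystem I in cyanobacteria and many algae (plastocyanin does the
same job with copper). The family has low-redox-midpoint-potential
homologs of unknown function: cytochrome *c*6A in plants and green algae
and cytochrome *c*6B in cyanobacteria (the historical *c*6B/*c*6C split
reflects taxon sampling, not function, so a single C6B label is used).
Two sequence features separate the classes:

* **Diagnostic residue** — the residue at the equivalent of mature
  position 52 of *A. thaliana* cytochrome *c*6A: Gln marks the
  high-potential cytochrome *c*6, a hydrophobic Val/Leu/Ile marks the
  low-potential homologs.
* **LIP (loop insertion peptide)** — a ~12-residue insertion in a loop
  region, carrying two disulfide-forming cysteines; present in *c*6A,
  absent in *c*6B.

The classification rule, applied to mature sequences carrying an
appropriately located haem-binding motif CXXCH:

| motif | residue @52 | LIP | label |
|---|---|---|---|
| present | Q | — | C6 |
| present | V/L/I | present | C6A |
| present | V/L/I | absent | C6B |
| present | other / X / gap | — | UNCLASSIFIED |
| absent | — | — | UNCLASSIFIED |

Candidates are pre-filtered on precursor length (80–200 residues,
inclusive) and N-terminal targeting peptides are removed by
alignment-overhang trimming against the mature *c*6 reference. Features
are read off exact global (Needleman–Wunsch, affine-gap, BLOSUM62)
alignments against two mature references: a plant-type *c*6A (fixes the
diagnostic coordinate, default 52) and a cyanobacterial *c*6 (fixes the
loop window where a LIP must open, default positions 35–50).

Downstream, per-taxon labels become a presence matrix (taxa ×
{C6, C6A, C6B} copy counts), per-clade summaries, and a Dollo-parsimony
event reconstruction on a user-supplied rooted species tree: each family
is gained once (at the MRCA of the taxa carrying it) and lost any number
of times; C6A is modelled as C6B-with-LIP, with one or more irreversible
LIP-insertion branches placed by event minimization. More than one
required insertion flags independent LIP origins (as in peridinin
dinoflagellates).

A seeded synthetic-data module generates labelled sequences with planted
features and simulates gain/loss/insertion scenarios on random trees, so
the whole pipeline is testable without any database access.

## Worked example

Simulate a 10-taxon scenario, classify the sequences, and map the labels
back onto the tree:

```sh
cytc6 simulate --out demo/sim --seed 11 --n-taxa 10
# simulated 15 sequences over 10 taxa -> demo/sim
cytc6 classify --fasta demo/sim/sequences.fasta \
               --references demo/sim/references.fasta --out demo/cls
cytc6 map --report demo/cls/classification.tsv \
          --newick demo/sim/tree.nwk \
          --clade-map demo/sim/clade_map.tsv --out demo/map
# presence matrix 9 taxa; 6 reconstructed events -> demo/map
```

`demo/cls/classification.tsv` holds one row per surviving sequence
(label, rule trace, motif position, diagnostic residue, LIP length and
cysteine count, trim offset, per-reference alignment scores), e.g.:

```
id       taxon  label  reason                                        motif_position  diagnostic_residue  lip_length  lip_cys_count
T01|C6   T01    C6     diagnostic residue Q (high potential)         24              Q                   0           0
T01|C6B  T01    C6B    diagnostic residue L (low potential), no LIP  24              L                   0           0
```

`demo/map/events.tsv` lists the reconstructed history — one gain per
family, losses at maximal all-absent subtrees, and the LIP-insertion
branch converting C6B to C6A (with equally parsimonious tied placements
when a sister lineage retains no C6B evidence):

```
family   event          branch  tied_branches
C6       gain           N3
C6       loss           T10
C6B/C6A  gain           N1
C6B/C6A  loss           T05
C6B/C6A  loss           T06
C6B/C6A  lip_insertion  N2      N2;T08
```

and `demo/map/clade_summary.md` is a per-clade presence table (organisms
searched, taxa with each cytochrome, sequence counts):

| clade | n_taxa | C6_taxa | C6_seqs | C6A_taxa | C6A_seqs | C6B_taxa | C6B_seqs |
| --- | --- | --- | --- | --- | --- | --- | --- |
| clade1 | 1 | 0 | 0 | 1 | 1 | 0 | 0 |
| clade2 | 8 | 7 | 7 | 0 | 0 | 7 | 7 |

To classify real sequences, supply a reference FASTA with entries
`ref_c6a` and `ref_c6` (mature coordinates); `scripts/fetch_references.py`
retrieves the canonical accessions from NCBI.

## Layout

- `src/cytc6/sequence_io.py` — FASTA / clade-map I/O, residue alphabet
- `src/cytc6/preprocess.py` — length filter, CXXCH motif, signal trimming
- `src/cytc6/reference_align.py` — global alignment, coordinate mapping,
  insertion detection
- `src/cytc6/classify.py` — feature extraction and the rule engine
- `src/cytc6/distribution.py` — presence matrix, clade summaries, Dollo
  and C6B→C6A transition reconstruction
- `src/cytc6/synthetic_data.py` — sequence generator and scenario simulator
- `src/cytc6/pipeline.py`, `src/cytc6/cli.py` — workflows and the `cytc6`
  command

See `docs/methods.md` for the model, parameter defaults, and known
limitations.
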