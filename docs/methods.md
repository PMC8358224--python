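# Methods

## Classification model

The pipeline classifies cytochrome *c*6-family candidates from sequence
alone, using two features with a known functional reading: the residue at
the equivalent of mature position 52 of *A. thaliana* cytochrome *c*6A
(Gln in the high-potential *c*6; Val, Leu or Ile in the low-potential
homologs, where the hydrophobic residue accounts for most of the ~200 mV
drop in redox midpoint potential) and the loop insertion peptide (LIP), a
~12-residue two-cysteine insertion distinguishing *c*6A from *c*6B. The
historical *c*6B/*c*6C distinction is collapsed into a single C6B label:
the two are orthologs separable only by taxon sampling, and no sequence
rule exists to split them.

Assumptions worth stating explicitly:

* **Mature-frame coordinates.** "Position 52" counts from the mature
  (signal-trimmed) *c*6A N-terminus. All coordinates in the package are
  1-based and inclusive on mature sequences.
* **The disulfide is not verified.** "Two cysteines" is operationalized
  as a cysteine count within the detected insertion; no structural
  modelling is attempted.
* **Refuse rather than guess.** A gapped or ambiguous (X) diagnostic
  site, or any residue outside {Q} ∪ {V, L, I}, routes a sequence to
  UNCLASSIFIED with a machine-readable reason. Extrapolating (e.g.,
  calling Met "hydrophobic enough") would silently change distribution
  counts. A V/L/I sequence whose loop insertion carries only one cysteine
  is labelled C6B with a `low_cys_insertion` warning flag — there is no
  evidence such proteins form the bridge, and no counter-rule exists.
* **Motif precedence.** Absence of an appropriately located CXXCH is a
  validity failure, not a class feature; it dominates all other evidence.

## Pipeline stages and tunable parameters

| parameter | default | units | role |
|---|---|---|---|
| `min_len` / `max_len` | 80 / 200 | residues | precursor length window, inclusive, applied before trimming |
| `motif_window` | [5, 40] | mature position | where the first Cys of CXXCH must fall ("appropriately located"); the haem site is N-proximal across the family |
| `post_trim_min_len` | 60 | residues | guards degenerate trims |
| `diagnostic_position` | 52 | mature c6A position | the Q-vs-V/L/I site |
| `loop_window` | [35, 50] | mature c6 position | where a LIP must open |
| LIP length window | [8, 20] | residues | tolerance around the 12-residue exemplar; wide enough for indel noise, narrow enough to exclude unrelated insertions |
| LIP `min_cys` | 2 | count | the disulfide pair, as a count |
| matrix / gap open / gap extend | BLOSUM62 / −11 / −1 | score | community defaults for protein global alignment; a gap of length L scores open + (L−1)·extend |

Whether the 80/200 length bounds are inclusive is not decidable from the
rule's plain statement ("less than 80 and more than 200 … deleted");
lengths of exactly 80 or 200 pass here.

**Alignment.** Classification needs only pairwise anchoring to two
references, so an exact global affine-gap aligner
(Bio.Align.PairwiseAligner) is used rather than a progressive multiple
alignment; the first optimal traceback is always taken, making every
run deterministic. The aligner's scores are verified against an
independent oracle that enumerates every global alignment explicitly
(test suite and acceptance script). Gapped pairs can be exported as
FASTA/PHYLIP for external tree inference; no tree inference, bootstrap,
or split-network analysis is performed here.

**Trimming.** Targeting peptides are removed by alignment overhang: the
precursor is globally aligned to the mature *c*6 reference
(class-agnostic; using the best-scoring of both references would leak
class information into preprocessing), the first sustained block of ≥5
consecutive residue pairs anchors the mature region, and reference
coordinate 1 is back-extrapolated gaplessly from that block. The
extrapolation step matters: anchoring on the *first* aligned pair is
fragile to a chance pairing between one or two targeting-peptide
residues and the reference N-terminus. Alignments covering <50% of the
reference are refused (UNTRIMMABLE) rather than trimmed blindly. No
HMM or neural signal-peptide predictor is used, keeping the pipeline
deterministic and self-contained.

## Ancestry reconstruction

Gains and losses are formalized as Dollo parsimony — our modelling
choice for narratives of single origins: each family is gained exactly
once, at the MRCA of the taxa carrying it, and lost any number of times,
with losses placed at the maximal all-absent subtrees below the origin.
This placement is provably minimal among single-origin reconstructions;
the test suite and acceptance script verify the event count against an
exhaustive enumeration of every origin placement on every rooted binary
tree shape up to 8 leaves (and polytomy spot-checks — the convention is
shape-agnostic).

C6A is modelled as C6B-with-LIP: one family origin, plus irreversible
insertion events each converting C6B→C6A in a subtree. Insertions are
placed at the maximal subtrees whose surviving members are exclusively
C6A. When a sister lineage retains no C6B, ancestral and more recent
placements tie exactly in event count and are genuinely
indistinguishable from presence data; the most ancestral branch is
reported as primary and the tied path (down to the MRCA of surviving
C6A leaves) as `insertion_alternatives`. Requiring more than one
insertion is reported, not resolved: it is evidence of independent LIP
origins (the peridinin-dinoflagellate situation), and lateral gene
transfer is deliberately not modelled.

Input trees are taken as rooted at their written root (polytomies
allowed); explicitly unrooted trees (`[&U]`) are rejected rather than
midpoint-rooted, since rooting is a scientific decision.

## Synthetic data: what it emulates, and what it does not

The generator emulates exactly the anatomy the rules read: one in-window
CXXCH, the class's diagnostic residue at the reference-mapped site, an
optional LIP (length uniform on [10, 16], exactly two cysteines), an
optional random targeting peptide (length uniform on [0, 40]), i.i.d.
per-residue substitution noise (default 2%), all on a mature backbone of
85–120 residues drawn uniformly over the 20 standard amino acids. All
sequences of one run share the backbone so that reference-anchored
mapping is meaningful, and the run's own reference pair is emitted as a
synthetic stand-in profile.

Three generator guards exist purely to keep planted coordinates
identifiable, and are documented because they shape what the tests mean:

* LIP boundary residues differ from the flanking backbone residues that
  an alignment-gap slide would have to match, so the optimal alignment
  cannot shift the insertion at zero noise.
* Planted anchors keep a 2-residue margin inside the loop window and ≥2
  matching residues before the diagnostic site, so small noise-induced
  slides cannot cross a decision boundary.
* The loop flanks exclude Cys/Trp (the highest-scoring identities), so a
  chance coincidence with LIP interior residues cannot pay the gap-open
  cost of splitting the insertion run.

What the generator does *not* emulate: real cytochrome composition,
homology-detection difficulty, phylogenetically correlated substitutions
(no substitution-model simulation along branches), indels outside the
LIP, or signal peptides with real targeting-sequence statistics. Passing
recovery tests therefore demonstrates that the rules and coordinate
machinery are correct and noise-robust — not that the pipeline would
retrieve homologs from a database, which is out of scope by design.

Scenarios propagate a root gene set (default {C6, C6B}) down a random
bifurcating tree (default 24 taxa), with per-branch, per-gene loss
probability (default 0.1, chosen to mirror the observed density of
independent c6/c6B losses across photosynthetic lineages) and a
designated insertion branch (by default an internal branch subtending
25–75% of the leaves). Family loss is suppressed on branches ancestral
to the insertion branch so the designated event actually occurs —
scenarios are conditioned on containing their insertion. Explicit loss
branches (`loss_branches`) replace random losses when a fully
identifiable history is wanted: randomly stacked losses (two sibling
subtrees losing the gene independently) are correctly but non-uniquely
reconstructed as a single parental loss, so only non-stacking histories
can be recovered event-for-event.

**Identifiability ceiling for the insertion branch.** If the sister
lineage of the true insertion branch loses the family entirely (a single
stem-edge loss suffices, probability ≈ the per-branch loss rate), the
ancestral and true placements tie exactly and no method can tell them
apart. Expected recovery of the exact branch is therefore capped near
1 − p_loss regardless of tree size; at the default p = 0.1 the measured
rate over 500 replicates is ~89–93% depending on seed. The tied
alternatives are always reported alongside the primary placement.

## Numerical and degenerate-input conventions

* Ties among in-window motif occurrences: left-most wins.
* Ties among qualifying LIP insertions: left-most wins.
* All-absent leaf vectors give an empty reconstruction (no origin), not
  an error; empty FASTA inputs give empty outputs with a warning.
* Taxa present in the classification report but missing from the tree
  are warned about and excluded; tree leaves without sequences count as
  absent. A taxon carrying both C6A and C6B (never observed in nature)
  is treated as C6A for placement and flagged.
* Per-sequence random substreams are derived by stable hashing (CRC-32)
  of record ids, so generated output is independent of generation order;
  identical seeds give byte-identical FASTA and histories.

## Problem sizes used in the checks

The shipped checks run at desk scale by choice: exhaustive alignment
oracles at sequence lengths ≤ 6 (enumeration beyond that adds cost, not
coverage), Dollo oracles over all 47 rooted binary shapes with ≤ 8
leaves × all 2^n leaf vectors, 1,000 sequences per label-recovery
measurement, 500 trimming replicates, and 500 scenario replicates of 24
taxa for insertion-branch recovery.

## Known limitations

* Database searching (BLAST), multiple alignment, ML tree inference,
  bootstrap support, and split networks are out of scope; export hooks
  are provided instead.
* The canonical reference accessions are not bundled; users fetch them
  once (`scripts/fetch_references.py`) or use synthetic stand-ins for
  testing. Classification quality on real data depends on supplying
  mature-coordinate references.
* Redox midpoint potentials are not predicted; the diagnostic residue is
  a proxy, not a measurement.
* Dollo parsimony cannot represent lateral transfer or regain; where the
  data demand multiple insertions, interpretation is left to the user.
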