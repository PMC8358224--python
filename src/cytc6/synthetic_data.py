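"""Labelled synthetic cytochrome c6-family sequences and evolutionary scenarios.

The generator emulates the anatomy the classification rules read: mature
sequences with a single N-proximal CXXCH haem motif, a diagnostic site
carrying Gln (C6) or Val/Leu/Ile (C6A/C6B), and — for C6A — a ~12-residue
two-cysteine loop insertion peptide (LIP) opening in the reference loop
window, optionally prefixed with a cleavable random targeting peptide.
Background residues are uniform over the 20 standard amino acids: the
point is to exercise the rules, not to mimic real cytochrome composition
or homology detection.

All sequences within one generator run share a random mature backbone, so
that reference-anchored coordinate mapping is meaningful; the generator's
own reference pair (``ref_c6``, ``ref_c6a``) is emitted as a synthetic
stand-in :class:`~cytc6.reference_align.ReferenceProfile`.

Scenarios propagate a root gene set down a random birth-only species
tree with per-branch loss probabilities and designated C6B→C6A LIP
insertion branches, emitting per-taxon sequence sets plus the full true
event history.
"""

from __future__ import annotations

import json
import re
import zlib
from dataclasses import asdict, dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .classify import C6, C6A, C6B
from .distribution import STATE_NONE, index_tree, node_name, read_newick
from .preprocess import FilterConfig
from .reference_align import ReferenceProfile
from .sequence_io import SequenceRecord

AA = "ACDEFGHIKLMNPQRSTVWY"
_LOW_POTENTIAL = "VLI"
_MOTIF_SCAN = re.compile(r"(?=(C..CH))")

_SEED_MASK = 0x7FFFFFFF


class GeneratorConfigError(ValueError):
    """Impossible generator or scenario configuration."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the sequence generator.

    Ranges are inclusive. The diagnostic position is expressed on the c6A
    reference frame (default 52, the A. thaliana mature numbering); the
    reference LIP is 12 residues, so the diagnostic site sits at position
    40 on the LIP-less c6 backbone. Substitution noise is a per-residue
    replacement probability that never touches the motif, the diagnostic
    site, or the LIP cysteines unless ``adversarial`` is set (used to test
    UNCLASSIFIED routing, not clean recovery).
    """

    seed: int = 0
    mature_len_range: tuple[int, int] = (85, 120)
    motif_position_range: tuple[int, int] = (10, 25)
    lip_len_range: tuple[int, int] = (10, 16)
    lip_cys_count: int = 2
    signal_len_range: tuple[int, int] = (0, 40)
    substitution_noise: float = 0.02
    diagnostic_position: int = 52
    reference_lip_len: int = 12
    loop_window: tuple[int, int] = (35, 50)
    adversarial: bool = False

    def __post_init__(self) -> None:
        for name in ("mature_len_range", "motif_position_range",
                     "lip_len_range", "signal_len_range", "loop_window"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0:
                raise GeneratorConfigError(f"invalid {name}: {(lo, hi)}")
        if not 0.0 <= self.substitution_noise <= 1.0:
            raise GeneratorConfigError("substitution_noise must be in [0, 1]")
        d_c6 = self.diagnostic_position - self.reference_lip_len
        if self.motif_position_range[1] + 5 >= min(d_c6, self.loop_window[0]):
            raise GeneratorConfigError(
                "motif window overlaps the diagnostic site or loop window"
            )
        if d_c6 <= self.loop_window[0]:
            raise GeneratorConfigError(
                "diagnostic site (c6 frame) must lie beyond the loop window start"
            )
        if self.mature_len_range[0] <= max(self.loop_window[1], d_c6):
            raise GeneratorConfigError(
                "mature sequences too short to carry the planted features"
            )
        if self.lip_cys_count < 2:
            raise GeneratorConfigError("LIP must carry at least 2 cysteines")


@dataclass(frozen=True)
class GroundTruth:
    """Every planted feature coordinate for one generated sequence.

    Coordinates are 1-based on the *mature* sequence (signal peptide
    excluded).
    """

    label: str
    signal_len: int
    motif_position: int
    diagnostic_position: int
    diagnostic_residue: str
    lip_start: int | None = None
    lip_end: int | None = None
    lip_cys_positions: tuple[int, ...] = ()

    @property
    def lip_length(self) -> int:
        if self.lip_start is None:
            return 0
        return self.lip_end - self.lip_start + 1


def _rand_residues(rng: np.random.Generator, n: int, exclude: str = "") -> list[str]:
    pool = [a for a in AA if a not in exclude]
    return [pool[i] for i in rng.integers(0, len(pool), size=n)]


def _derive_rng(seed: int, tag: str) -> np.random.Generator:
    return np.random.default_rng([seed & _SEED_MASK, zlib.crc32(tag.encode()) & _SEED_MASK])


class SequenceGenerator:
    """Deterministic, per-id-seeded generator of labelled family sequences.

    One global stream (from ``cfg.seed``) fixes the shared backbone and the
    reference pair; each sequence draws from a substream derived by stable
    hashing of its record id, so generated output is independent of
    insertion order.
    """

    def __init__(self, cfg: GeneratorConfig = GeneratorConfig()):
        self.cfg = cfg
        rng = _derive_rng(cfg.seed, "backbone")
        lo, hi = cfg.mature_len_range
        self.backbone_len = int(rng.integers(lo, hi + 1))
        self.d_c6 = cfg.diagnostic_position - cfg.reference_lip_len
        m_lo, m_hi = cfg.motif_position_range
        self.motif_position = int(rng.integers(m_lo, m_hi + 1))  # 1-based
        # Planted insertions keep a 2-residue margin inside the loop window
        # so that a 1-2 column alignment slide under substitution noise
        # cannot push the detected anchor out of the window, and >=1
        # matching backbone residue separates the insertion from the
        # diagnostic site so the alignment cannot trade the diagnostic
        # mismatch into the gap run (the real loop also ends short of 52).
        # Planted insertions keep a 2-residue margin inside the loop window
        # (a 1-2 column alignment slide under substitution noise must not
        # cross the boundary) and >=2 matching backbone residues before the
        # diagnostic site (so the alignment cannot trade the diagnostic
        # mismatch into the gap run; the real loop also ends short of 52).
        a_lo = max(cfg.loop_window[0] + 2, self.motif_position + 5)
        a_hi = min(cfg.loop_window[1] - 2, self.d_c6 - 3, self.backbone_len - 1)
        if a_lo > a_hi:
            raise GeneratorConfigError("no admissible LIP anchor position")
        self.lip_anchor = int(rng.integers(a_lo, a_hi + 1))  # insertion opens after this

        backbone = _rand_residues(rng, self.backbone_len)
        # Loop flanks free of high self-scoring residues (C, W) so chance
        # coincidences with LIP interiors cannot pay for splitting the
        # insertion gap; H excluded too so flanks can never seed a motif.
        a0 = self.lip_anchor
        for i in range(max(0, a0 - 3), min(self.backbone_len, a0 + 3)):
            if backbone[i] in "CWH":
                backbone[i] = _rand_residues(rng, 1, exclude="CWH")[0]
        m0 = self.motif_position - 1
        backbone[m0] = "C"
        backbone[m0 + 1], backbone[m0 + 2] = _rand_residues(rng, 2, exclude="CH")
        backbone[m0 + 3] = "C"
        backbone[m0 + 4] = "H"
        backbone[self.d_c6 - 1] = "Q"
        protected = set(range(m0, m0 + 5)) | {self.d_c6 - 1}
        self._scrub(backbone, keep_start0=m0, protected=protected, rng=rng)
        self.backbone = "".join(backbone)

        ref_lip = self._make_lip(
            rng, cfg.reference_lip_len,
            left=self.backbone[self.lip_anchor - 1],
            right=self.backbone[self.lip_anchor],
        )
        c6a = self._with_lip(list(self.backbone), ref_lip)
        c6a[self.d_c6 - 1 + cfg.reference_lip_len] = "V"
        self._scrub(
            c6a, keep_start0=m0,
            protected=self._protected_c6a(cfg.reference_lip_len, ref_lip), rng=rng,
        )
        self.profile = ReferenceProfile(
            c6a=SequenceRecord(
                "ref_c6a", "".join(c6a),
                description="synthetic stand-in mature cytochrome c6A reference",
            ),
            c6=SequenceRecord(
                "ref_c6", self.backbone,
                description="synthetic stand-in mature cytochrome c6 reference",
            ),
            diagnostic_position=cfg.diagnostic_position,
            loop_window=cfg.loop_window,
        )

    # -- construction helpers ------------------------------------------------

    def _cys_offsets(self, length: int) -> tuple[int, int]:
        # 0-based offsets of the two planted cysteines inside the LIP;
        # spacing of exactly 3 is avoided so the pair can never seed a
        # CXXCH with a downstream histidine.
        first, second = 2, length - 3
        if second - first == 3:
            first = 1
        if second <= first:
            first, second = 0, length - 1
        return first, second

    def _make_lip(self, rng: np.random.Generator, length: int, left: str, right: str) -> str:
        lip = _rand_residues(rng, length, exclude="CH")
        c1, c2 = self._cys_offsets(length)
        lip[c1] = lip[c2] = "C"
        # Boundary guards prevent the insertion gap from sliding in an
        # optimal alignment: a left slide of the gap run requires the LIP
        # suffix to match the left flank (so lip[-1] must differ from the
        # residue before the anchor), a right slide requires the LIP prefix
        # to match the right flank.
        if c1 != 0:
            lip[0] = _rand_residues(rng, 1, exclude="CH" + right)[0]
        if c2 != length - 1:
            lip[-1] = _rand_residues(rng, 1, exclude="CH" + left)[0]
        return "".join(lip)

    def _with_lip(self, backbone: list[str], lip: str) -> list[str]:
        a = self.lip_anchor
        return backbone[:a] + list(lip) + backbone[a:]

    def _protected_c6a(self, lip_len: int, lip: str) -> set[int]:
        m0 = self.motif_position - 1
        a = self.lip_anchor
        c1, c2 = self._cys_offsets(lip_len)
        return (set(range(m0, m0 + 5))
                | {self.d_c6 - 1 + lip_len}
                | {a + c1, a + c2})

    def _scrub(
        self,
        seq: list[str],
        keep_start0: int,
        protected: set[int],
        rng: np.random.Generator,
        window: tuple[int, int] = FilterConfig().motif_window,
    ) -> None:
        """Mutate away spurious in-window CXXCH occurrences (in place)."""
        lo0, hi0 = window[0] - 1, window[1] - 1
        for _ in range(100):
            spurious = [
                m.start() for m in _MOTIF_SCAN.finditer("".join(seq))
                if m.start() != keep_start0 and lo0 <= m.start() <= hi0
            ]
            if not spurious:
                return
            s = spurious[0]
            for off in (4, 0, 3):  # breaking cells: H, C1, C2 (wildcards can't break it)
                if s + off not in protected:
                    seq[s + off] = _rand_residues(rng, 1, exclude="CH")[0]
                    break
            else:  # pragma: no cover - planted features cannot cover all three
                raise RuntimeError("cannot scrub spurious motif")
        raise RuntimeError("motif scrub did not converge")  # pragma: no cover

    # -- generation ----------------------------------------------------------

    @property
    def reference_profile(self) -> ReferenceProfile:
        return self.profile

    def generate(
        self, label: str, seq_id: str, taxon: str = ""
    ) -> tuple[SequenceRecord, GroundTruth]:
        """Generate one labelled sequence plus its ground-truth annotation.

        The mature body carries exactly one in-window CXXCH, the class's
        diagnostic residue at the reference-mapped site, and (for C6A) a
        LIP with exactly two cysteines; a random targeting peptide of
        configured length is prepended. Same id, label and config →
        byte-identical output.
        """
        if label not in (C6, C6A, C6B):
            raise GeneratorConfigError(f"unknown class label {label!r}")
        cfg = self.cfg
        rng = _derive_rng(cfg.seed, f"seq:{label}:{seq_id}")
        mature = list(self.backbone)
        m0 = self.motif_position - 1
        protected = set(range(m0, m0 + 5))

        diag_idx = self.d_c6 - 1
        lip_start = lip_end = None
        cys_positions: tuple[int, ...] = ()
        if label == C6A:
            lip_len = int(rng.integers(cfg.lip_len_range[0], cfg.lip_len_range[1] + 1))
            lip = self._make_lip(
                rng, lip_len,
                left=self.backbone[self.lip_anchor - 1],
                right=self.backbone[self.lip_anchor],
            )
            mature = self._with_lip(mature, lip)
            diag_idx += lip_len
            c1, c2 = self._cys_offsets(lip_len)
            cys_positions = (self.lip_anchor + c1 + 1, self.lip_anchor + c2 + 1)
            lip_start, lip_end = self.lip_anchor + 1, self.lip_anchor + lip_len
            protected |= {self.lip_anchor + c1, self.lip_anchor + c2}
        diag_residue = "Q" if label == C6 else _LOW_POTENTIAL[int(rng.integers(3))]
        mature[diag_idx] = diag_residue
        protected.add(diag_idx)

        if cfg.substitution_noise > 0:
            hits = np.flatnonzero(rng.random(len(mature)) < cfg.substitution_noise)
            for i in hits:
                if not cfg.adversarial and int(i) in protected:
                    continue
                current = mature[int(i)]
                mature[int(i)] = _rand_residues(rng, 1, exclude=current)[0]
        self._scrub(mature, keep_start0=m0, protected=protected, rng=rng)

        s_lo, s_hi = cfg.signal_len_range
        signal_len = int(rng.integers(s_lo, s_hi + 1))
        signal = "".join(_rand_residues(rng, signal_len))
        record = SequenceRecord(
            id=seq_id,
            residues=signal + "".join(mature),
            taxon=taxon,
            description=f"synthetic {label} sequence",
        )
        truth = GroundTruth(
            label=label,
            signal_len=signal_len,
            motif_position=self.motif_position,
            diagnostic_position=diag_idx + 1,
            diagnostic_residue=diag_residue,
            lip_start=lip_start,
            lip_end=lip_end,
            lip_cys_positions=cys_positions,
        )
        return record, truth

    def generate_many(
        self, labels: Sequence[str], prefix: str = "syn", taxon: str = ""
    ) -> list[tuple[SequenceRecord, GroundTruth]]:
        return [
            self.generate(label, f"{prefix}{i:04d}", taxon=taxon)
            for i, label in enumerate(labels)
        ]


# ---------------------------------------------------------------------------
# Evolutionary scenarios
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of a simulated gain/loss/insertion scenario.

    Genes propagate from ``root_genes`` down a random bifurcating species
    tree of ``n_taxa`` leaves; each gene is lost with probability
    ``loss_prob`` per branch (independently), and on the designated
    ``insertion`` branch a surviving C6B is converted irreversibly to C6A.
    ``insertion="auto"`` picks a seeded internal branch subtending between
    a quarter and three quarters of the leaves; family loss is suppressed
    on branches ancestral to the insertion branch so the designated event
    actually occurs. ``loss_branches`` (gene → branch labels) replaces the
    random losses with an explicit, fully identifiable history.
    """

    seed: int = 0
    n_taxa: int = 24
    root_genes: tuple[str, ...] = (C6, C6B)
    loss_prob: float = 0.1
    insertion: str | None = "auto"
    loss_branches: Mapping[str, tuple[str, ...]] | None = None
    generator: GeneratorConfig | None = None

    def __post_init__(self) -> None:
        if self.n_taxa < 2:
            raise GeneratorConfigError("n_taxa must be >= 2")
        if not 0.0 <= self.loss_prob <= 1.0:
            raise GeneratorConfigError("loss_prob must be in [0, 1]")
        for gene in self.root_genes:
            if gene not in (C6, C6B):
                raise GeneratorConfigError(f"root gene must be C6 or C6B, got {gene!r}")


@dataclass(frozen=True)
class Event:
    family: str
    event: str  # "gain" | "loss" | "lip_insertion"
    branch: str


@dataclass
class Scenario:
    """A simulated scenario: tree, sequences, and the true event history."""

    config: ScenarioConfig
    tree: dendropy.Tree
    newick: str
    generator: SequenceGenerator
    sequences: list[SequenceRecord]
    truths: dict[str, GroundTruth]
    events: list[Event]
    leaf_states: dict[str, dict[str, str]]  # taxon -> {family: state}
    presence: pd.DataFrame  # taxa x (C6, C6A, C6B) counts
    insertion_branch: str | None
    clade_map: dict[str, str]


def random_topology(n_taxa: int, rng: np.random.Generator) -> str:
    """Random bifurcating rooted topology over taxa T01..Tnn (Newick)."""
    nodes = [f"T{i + 1:02d}" for i in range(n_taxa)]
    while len(nodes) > 1:
        i = int(rng.integers(len(nodes)))
        a = nodes.pop(i)
        j = int(rng.integers(len(nodes)))
        b = nodes.pop(j)
        nodes.append(f"({a},{b})")
    return nodes[0] + ";"


def _auto_insertion_branch(tree: dendropy.Tree, n_taxa: int, rng: np.random.Generator) -> str:
    lo = max(2, n_taxa // 4)
    hi = max(lo, (3 * n_taxa) // 4)
    candidates = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        n_leaves = sum(1 for _ in node.leaf_iter())
        if lo <= n_leaves <= hi:
            candidates.append(node_name(node))
    if not candidates:  # tiny trees: fall back to any internal branch
        candidates = [
            node_name(n) for n in tree.preorder_node_iter()
            if n.parent_node is not None and not n.is_leaf()
        ]
    if not candidates:
        raise GeneratorConfigError("tree has no internal branch for an insertion")
    return candidates[int(rng.integers(len(candidates)))]


def simulate_scenario(cfg: ScenarioConfig = ScenarioConfig()) -> Scenario:
    """Simulate gene propagation, losses and LIP insertion on a random tree."""
    rng = _derive_rng(cfg.seed, "scenario")
    newick = random_topology(cfg.n_taxa, rng)
    tree = read_newick(newick)
    names = {node_name(n): n for n in tree.preorder_node_iter()}

    insertion_branch: str | None = None
    if cfg.insertion == "auto":
        insertion_branch = _auto_insertion_branch(tree, cfg.n_taxa, rng)
    elif cfg.insertion is not None:
        if cfg.insertion not in names:
            raise GeneratorConfigError(
                f"insertion branch {cfg.insertion!r} not in tree"
            )
        insertion_branch = cfg.insertion
    if insertion_branch is not None and C6B not in cfg.root_genes:
        raise GeneratorConfigError("an insertion branch requires C6B at the root")

    protected_path: set[int] = set()
    if insertion_branch is not None:
        n = names[insertion_branch]
        while n is not None:
            protected_path.add(id(n))
            n = n.parent_node

    events: list[Event] = []
    root_label = node_name(tree.seed_node)
    for gene in cfg.root_genes:
        events.append(Event(gene, "gain", root_label))

    explicit = {
        gene: set(branches) for gene, branches in (cfg.loss_branches or {}).items()
    }
    gene_sets: dict[int, list[str]] = {id(tree.seed_node): list(cfg.root_genes)}
    leaf_states: dict[str, dict[str, str]] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            genes = gene_sets[id(node)]
        else:
            genes = list(gene_sets[id(node.parent_node)])
            branch = node_name(node)
            survivors = []
            for gene in genes:
                if cfg.loss_branches is not None:
                    lost = branch in explicit.get(gene, set())
                else:
                    family_protected = (
                        gene in (C6B, C6A) and id(node) in protected_path
                    )
                    lost = (not family_protected) and rng.random() < cfg.loss_prob
                if lost:
                    events.append(Event(gene, "loss", branch))
                else:
                    survivors.append(gene)
            genes = survivors
            if branch == insertion_branch and C6B in genes:
                genes[genes.index(C6B)] = C6A
                events.append(Event(C6B, "lip_insertion", branch))
            gene_sets[id(node)] = genes
        if node.is_leaf():
            taxon = node.taxon.label
            state = {C6: STATE_NONE, "family": STATE_NONE}
            if C6 in genes:
                state[C6] = "present"
            if C6A in genes:
                state["family"] = C6A
            elif C6B in genes:
                state["family"] = C6B
            leaf_states[taxon] = state

    gen_cfg = cfg.generator or GeneratorConfig(seed=(cfg.seed * 1000003 + 17) & _SEED_MASK)
    generator = SequenceGenerator(gen_cfg)
    sequences: list[SequenceRecord] = []
    truths: dict[str, GroundTruth] = {}
    taxa = sorted(leaf_states)
    counts = pd.DataFrame(0, index=taxa, columns=[C6, C6A, C6B])
    counts.index.name = "taxon"
    for taxon in taxa:
        state = leaf_states[taxon]
        present_genes = []
        if state[C6] == "present":
            present_genes.append(C6)
        if state["family"] != STATE_NONE:
            present_genes.append(state["family"])
        for gene in present_genes:
            rec, truth = generator.generate(gene, f"{taxon}|{gene}", taxon=taxon)
            sequences.append(rec)
            truths[rec.id] = truth
            counts.loc[taxon, gene] += 1

    clade_map: dict[str, str] = {}
    for i, child in enumerate(tree.seed_node.child_nodes(), start=1):
        for leaf in child.leaf_iter():
            clade_map[leaf.taxon.label] = f"clade{i}"

    return Scenario(
        config=cfg,
        tree=tree,
        newick=newick,
        generator=generator,
        sequences=sequences,
        truths=truths,
        events=events,
        leaf_states=leaf_states,
        presence=counts,
        insertion_branch=insertion_branch,
        clade_map=clade_map,
    )
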