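"""Presence/absence aggregation and gain/loss ancestry reconstruction.

Per-taxon class labels are aggregated into a presence matrix (taxa ×
{C6, C6A, C6B} copy counts), summarized per clade, and mapped onto a
rooted species tree. Ancestry is reconstructed under Dollo parsimony:
each gene family is gained exactly once — at the most recent common
ancestor of the taxa carrying it — and lost any number of times, with
losses placed at the maximal all-absent subtrees below the origin. The
plant-type C6A is modelled as C6B-with-LIP: a single family origin plus
one or more irreversible LIP-insertion events converting C6B→C6A in
subtrees. More than one required insertion is reported as evidence of
independent origins (as seen for the peridinin dinoflagellates), not
resolved automatically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd

from .classify import C6, C6A, C6B, CLASSES, UNCLASSIFIED

log = logging.getLogger(__name__)

#: Leaf states recognized by the C6B→C6A transition reconstruction.
STATE_NONE = "none"
STATE_BOTH = "both"


class NewickError(ValueError):
    """Malformed or unsupported species-tree input."""


class PresenceError(ValueError):
    """Invalid classification report for presence aggregation."""


# ---------------------------------------------------------------------------
# Species trees
# ---------------------------------------------------------------------------

def node_name(node: dendropy.Node) -> str:
    """Stable display name of a node (taxon label for leaves)."""
    if node.taxon is not None:
        return node.taxon.label
    return node.label or ""


def index_tree(tree: dendropy.Tree) -> dendropy.Tree:
    """Assign unique labels (N1, N2, ... in preorder) to unlabelled internal nodes."""
    used = {node_name(n) for n in tree if node_name(n)}
    counter = 1
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        if not node_name(node):
            while f"N{counter}" in used:
                counter += 1
            node.label = f"N{counter}"
            used.add(node.label)
    return tree


def read_newick(source: str | Path) -> dendropy.Tree:
    """Read a single rooted Newick tree; polytomies are allowed.

    The tree is rooted at the written root. Explicitly unrooted trees
    (``[&U]``) are rejected rather than midpoint-rooted silently — rooting
    is the user's scientific decision. Duplicate leaf labels and unbalanced
    parentheses raise :class:`NewickError`.
    """
    path = Path(source)
    text = path.read_text() if path.exists() else str(source)
    if "[&U]" in text.upper().replace(" ", ""):
        raise NewickError("explicitly unrooted tree ([&U]); supply a rooted tree")
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            rooting="force-rooted",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickError(f"could not parse Newick tree: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dupes = {t for t in labels if labels.count(t) > 1}
    if dupes:
        raise NewickError(f"duplicate leaf label(s): {', '.join(sorted(dupes))}")
    return index_tree(tree)


def _leaf_map(tree: dendropy.Tree) -> dict[str, dendropy.Node]:
    return {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}


def _mrca(nodes: Sequence[dendropy.Node]) -> dendropy.Node:
    paths = []
    for node in nodes:
        path = []
        n = node
        while n is not None:
            path.append(n)
            n = n.parent_node
        paths.append(path[::-1])
    mrca = paths[0][0]
    for depth in range(min(len(p) for p in paths)):
        candidate = paths[0][depth]
        if all(p[depth] is candidate for p in paths):
            mrca = candidate
        else:
            break
    return mrca


# ---------------------------------------------------------------------------
# Presence matrix and clade summaries
# ---------------------------------------------------------------------------

def build_presence_matrix(
    report: pd.DataFrame | Iterable[tuple[str, str, str]],
) -> tuple[pd.DataFrame, pd.Series]:
    """Aggregate a classification report into per-taxon copy counts.

    ``report`` provides columns ``id``, ``taxon``, ``label`` (or an
    iterable of such triples). Returns ``(matrix, unclassified)`` where
    ``matrix`` is taxa × (C6, C6A, C6B) sequence counts — a count above 1
    marks a potential paralog — and ``unclassified`` tallies refused
    records per taxon (excluded from the matrix, never discarded
    silently). Records without a taxon are an error listing the ids.
    """
    if not isinstance(report, pd.DataFrame):
        report = pd.DataFrame(report, columns=["id", "taxon", "label"])
    if report.empty:
        matrix = pd.DataFrame(columns=list(CLASSES)).astype(int)
        matrix.index.name = "taxon"
        return matrix, pd.Series(dtype=int, name="unclassified")
    missing = report.loc[
        report["taxon"].isna() | (report["taxon"].astype(str).str.strip() == ""), "id"
    ]
    if len(missing):
        raise PresenceError(
            f"records without taxon: {', '.join(str(i) for i in missing)}"
        )
    taxa = list(dict.fromkeys(report["taxon"]))
    classified = report[report["label"].isin(CLASSES)]
    matrix = (
        pd.crosstab(classified["taxon"], classified["label"])
        .reindex(index=taxa, columns=list(CLASSES), fill_value=0)
        .fillna(0)
        .astype(int)
    )
    matrix.index.name = "taxon"
    matrix.columns.name = None
    unclassified = (
        report[report["label"] == UNCLASSIFIED]
        .groupby("taxon")
        .size()
        .reindex(taxa, fill_value=0)
        .astype(int)
        .rename("unclassified")
    )
    return matrix, unclassified


def summarize_by_clade(
    matrix: pd.DataFrame,
    clade_map: Mapping[str, str],
) -> pd.DataFrame:
    """Per-clade presence summary (one row per clade).

    Columns: ``n_taxa`` (organisms searched) and, per class, the number of
    taxa with at least one sequence (``*_taxa``) and the total sequence
    count (``*_seqs``). Taxa missing from ``clade_map`` are grouped under
    ``unassigned`` with a warning. Summing ``*_seqs`` over clades
    reproduces the matrix totals exactly.
    """
    if matrix.empty:
        return pd.DataFrame(
            columns=["n_taxa"] + [f"{c}_{k}" for c in CLASSES for k in ("taxa", "seqs")]
        )
    clades = []
    for taxon in matrix.index:
        clade = clade_map.get(taxon)
        if clade is None:
            log.warning("taxon %r missing from clade map; grouped as 'unassigned'", taxon)
            clade = "unassigned"
        clades.append(clade)
    grouped = matrix.groupby(pd.Series(clades, index=matrix.index, name="clade"))
    out = pd.DataFrame({"n_taxa": grouped.size()})
    for cls in CLASSES:
        out[f"{cls}_taxa"] = grouped[cls].apply(lambda col: int((col > 0).sum()))
        out[f"{cls}_seqs"] = grouped[cls].sum().astype(int)
    out.index.name = "clade"
    return out


def summary_to_markdown(summary: pd.DataFrame) -> str:
    """Render a clade summary as a Markdown table."""
    header = ["clade"] + list(summary.columns)
    lines = ["| " + " | ".join(header) + " |",
             "| " + " | ".join("---" for _ in header) + " |"]
    for clade, row in summary.iterrows():
        lines.append("| " + " | ".join([str(clade)] + [str(v) for v in row]) + " |")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Dollo reconstruction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EventReconstruction:
    """Gain/loss/insertion events for one gene family on a species tree.

    Branches are identified by their child-node label. ``origin`` is the
    node where the single gain is placed (``None`` for an all-absent
    family). For the C6B→C6A transition, ``insertions`` lists the primary
    (most ancestral) placement of each independent LIP insertion and
    ``insertion_alternatives`` the equally parsimonious placements tied
    with each primary, ordered root-ward to leaf-ward.
    """

    family: str
    origin: str | None
    losses: tuple[str, ...] = ()
    insertions: tuple[str, ...] = ()
    insertion_alternatives: tuple[tuple[str, ...], ...] = ()
    event_count: int = 0


def _validate_leaf_states(tree: dendropy.Tree, states: Mapping[str, object]) -> None:
    leaves = set(_leaf_map(tree))
    missing = leaves - set(states)
    if missing:
        raise PresenceError(f"no state for leaf taxa: {', '.join(sorted(missing))}")


def dollo_reconstruct(
    tree: dendropy.Tree,
    presence: Mapping[str, int],
    family: str = "gene",
) -> EventReconstruction:
    """Single-gain (Dollo) reconstruction of one family's presence pattern.

    The origin is placed at the MRCA of all present leaves (the minimal
    single-origin placement); losses at the maximal subtrees below the
    origin containing only absent leaves. Event count = 1 + number of
    losses. An all-absent vector yields an empty reconstruction.
    """
    _validate_leaf_states(tree, presence)
    leaf_map = _leaf_map(tree)
    present_leaves = [leaf_map[t] for t in sorted(leaf_map) if presence[t]]
    if not present_leaves:
        return EventReconstruction(family=family, origin=None, event_count=0)

    subtree_absent: dict[int, bool] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            subtree_absent[id(node)] = not presence[node.taxon.label]
        else:
            subtree_absent[id(node)] = all(
                subtree_absent[id(c)] for c in node.child_nodes()
            )

    origin = _mrca(present_leaves)
    losses: list[str] = []
    stack = list(origin.child_nodes())
    while stack:
        node = stack.pop()
        if subtree_absent[id(node)]:
            losses.append(node_name(node))
        else:
            stack.extend(node.child_nodes())
    losses.sort()
    return EventReconstruction(
        family=family,
        origin=node_name(origin),
        losses=tuple(losses),
        event_count=1 + len(losses),
    )


def reconstruct_c6a_transition(
    tree: dendropy.Tree,
    states: Mapping[str, str],
    family: str = "C6B/C6A",
) -> EventReconstruction:
    """Reconstruct the C6B family with irreversible C6B→C6A LIP insertions.

    Leaf states are ``"none"``, ``"C6B"``, ``"C6A"`` (or ``"both"``, which
    is treated as C6A for placement and logged — no species is expected to
    carry both). The family gets one Dollo origin and losses as in
    :func:`dollo_reconstruct`; insertions are placed at the maximal
    subtrees (below the origin) whose surviving leaves are exclusively
    C6A. When deeper and shallower placements are tied (a sister lineage
    retains no C6B evidence), the most ancestral branch is reported as the
    primary placement and the tied path down to the MRCA of surviving C6A
    leaves is reported in ``insertion_alternatives``. More than one
    insertion signals independent LIP origins.
    """
    _validate_leaf_states(tree, states)
    norm: dict[str, str] = {}
    for taxon, state in states.items():
        s = str(state)
        if s == STATE_BOTH:
            log.warning(
                "taxon %r carries both C6A and C6B; treated as C6A for "
                "transition placement", taxon
            )
            s = C6A
        if s not in (STATE_NONE, C6B, C6A):
            raise PresenceError(f"taxon {taxon!r}: unknown state {state!r}")
        norm[taxon] = s

    presence = {t: int(s != STATE_NONE) for t, s in norm.items()}
    base = dollo_reconstruct(tree, presence, family=family)
    if base.origin is None:
        return base

    leaf_map = _leaf_map(tree)
    origin = next(
        n for n in tree.preorder_node_iter() if node_name(n) == base.origin
    )

    has_present: dict[int, bool] = {}
    all_c6a: dict[int, bool] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            s = norm[node.taxon.label]
            has_present[id(node)] = s != STATE_NONE
            all_c6a[id(node)] = s != C6B
        else:
            kids = node.child_nodes()
            has_present[id(node)] = any(has_present[id(c)] for c in kids)
            all_c6a[id(node)] = all(all_c6a[id(c)] for c in kids)

    def qualifies(node: dendropy.Node) -> bool:
        return has_present[id(node)] and all_c6a[id(node)]

    insertions: list[str] = []
    alternatives: list[tuple[str, ...]] = []
    stack = [origin]
    while stack:
        node = stack.pop()
        if qualifies(node):
            # Primary placement: most ancestral qualifying branch. The tied
            # placements run down to the MRCA of the surviving C6A leaves.
            c6a_leaves = [
                leaf_map[t]
                for t in sorted(leaf_map)
                if norm[t] == C6A and _is_descendant_or_self(leaf_map[t], node)
            ]
            mrca = _mrca(c6a_leaves)
            path = [node_name(node)]
            walker = mrca
            tail: list[str] = []
            while walker is not node:
                tail.append(node_name(walker))
                walker = walker.parent_node
            path.extend(reversed(tail))
            insertions.append(node_name(node))
            alternatives.append(tuple(path))
        else:
            stack.extend(node.child_nodes())
    order = sorted(range(len(insertions)), key=lambda i: insertions[i])
    insertions = [insertions[i] for i in order]
    alternatives = [alternatives[i] for i in order]
    return EventReconstruction(
        family=family,
        origin=base.origin,
        losses=base.losses,
        insertions=tuple(insertions),
        insertion_alternatives=tuple(alternatives),
        event_count=base.event_count + len(insertions),
    )


def _is_descendant_or_self(node: dendropy.Node, ancestor: dendropy.Node) -> bool:
    n = node
    while n is not None:
        if n is ancestor:
            return True
        n = n.parent_node
    return False


def replay_events(
    tree: dendropy.Tree,
    rec: EventReconstruction,
    transition: bool | None = None,
) -> dict[str, str]:
    """Simulate a reconstruction forward and return the implied leaf states.

    For a plain Dollo reconstruction the states are ``"none"``/``"present"``;
    with ``transition`` semantics (inferred from the presence of insertion
    events, or forced explicitly) they are ``"none"``/``"C6B"``/``"C6A"``.
    Used to verify that reconstructed events reproduce the observations
    exactly.
    """
    names = {node_name(n): n for n in tree.preorder_node_iter()}
    out: dict[str, str] = {}
    if rec.origin is None:
        return {leaf.taxon.label: STATE_NONE for leaf in tree.leaf_node_iter()}
    origin = names[rec.origin]
    losses = {rec_loss for rec_loss in rec.losses}
    insertions = set(rec.insertions)
    has_insertions = bool(insertions) if transition is None else transition

    def walk(node: dendropy.Node, present: bool, inserted: bool) -> None:
        name = node_name(node)
        if present and name in losses:
            present = False
        if present and name in insertions:
            inserted = True
        if node.is_leaf():
            if not present:
                out[node.taxon.label] = STATE_NONE
            elif has_insertions or inserted:
                out[node.taxon.label] = C6A if inserted else C6B
            else:
                out[node.taxon.label] = "present"
            return
        for child in node.child_nodes():
            walk(child, present, inserted)

    for leaf in tree.leaf_node_iter():
        out[leaf.taxon.label] = STATE_NONE
    walk(origin, True, False)
    return out


def transition_states(matrix: pd.DataFrame) -> tuple[dict[str, str], list[str]]:
    """Derive per-taxon {none, C6B, C6A, both} states from a presence matrix.

    Returns the states plus the list of taxa flagged for carrying both a
    C6A and a C6B sequence (unexpected across the family).
    """
    states: dict[str, str] = {}
    flagged: list[str] = []
    for taxon, row in matrix.iterrows():
        has_a, has_b = row.get(C6A, 0) > 0, row.get(C6B, 0) > 0
        if has_a and has_b:
            states[taxon] = STATE_BOTH
            flagged.append(taxon)
        elif has_a:
            states[taxon] = C6A
        elif has_b:
            states[taxon] = C6B
        else:
            states[taxon] = STATE_NONE
    return states, flagged


# ---------------------------------------------------------------------------
# Output rendering
# ---------------------------------------------------------------------------

def events_to_frame(recs: Iterable[EventReconstruction]) -> pd.DataFrame:
    """Tabulate reconstructions as (family, event, branch) rows."""
    rows = []
    for rec in recs:
        if rec.origin is None:
            continue
        rows.append({"family": rec.family, "event": "gain", "branch": rec.origin})
        for loss in rec.losses:
            rows.append({"family": rec.family, "event": "loss", "branch": loss})
        for ins, alts in zip(rec.insertions, rec.insertion_alternatives or
                             [()] * len(rec.insertions)):
            rows.append({
                "family": rec.family,
                "event": "lip_insertion",
                "branch": ins,
                "tied_branches": ";".join(alts) if len(alts) > 1 else "",
            })
    return pd.DataFrame(rows, columns=["family", "event", "branch", "tied_branches"])


def annotated_newick(tree: dendropy.Tree, recs: Iterable[EventReconstruction]) -> str:
    """Newick string with per-branch event comments (``[&events=...]``)."""
    tags: dict[str, list[str]] = {}
    for rec in recs:
        if rec.origin is None:
            continue
        tags.setdefault(rec.origin, []).append(f"gain:{rec.family}")
        for loss in rec.losses:
            tags.setdefault(loss, []).append(f"loss:{rec.family}")
        for ins in rec.insertions:
            tags.setdefault(ins, []).append(f"lip_insertion:{rec.family}")

    def render(node: dendropy.Node) -> str:
        name = node_name(node)
        comment = f"[&events={'|'.join(tags[name])}]" if name in tags else ""
        if node.is_leaf():
            return f"{name}{comment}"
        inner = ",".join(render(c) for c in node.child_nodes())
        return f"({inner}){name}{comment}"

    return render(tree.seed_node) + ";"
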