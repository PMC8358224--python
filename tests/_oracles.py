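"""Independent oracles used to cross-check the implementation.

These deliberately avoid the code paths they verify: the alignment oracle
enumerates every global alignment explicitly (with a memoized affine DP as
a second, larger-scale check), and the Dollo oracle enumerates every
admissible single-origin placement.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import dendropy


# ---------------------------------------------------------------------------
# Alignment oracles
# ---------------------------------------------------------------------------

def enumerate_alignment_score(
    a: str,
    b: str,
    score_fn,
    gap_open: float,
    gap_extend: float,
) -> float:
    """Max score over an explicit enumeration of all global alignments.

    Affine convention: a gap of length L costs ``gap_open + (L-1)*gap_extend``
    (per sequence; switching the gapped sequence reopens).
    """
    best = float("-inf")

    def rec(i: int, j: int, prev: str, acc: float) -> None:
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, acc)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, "M", acc + score_fn(a[i], b[j]))
        if i < len(a):
            rec(i + 1, j, "I", acc + (gap_extend if prev == "I" else gap_open))
        if j < len(b):
            rec(i, j + 1, "D", acc + (gap_extend if prev == "D" else gap_open))

    rec(0, 0, "", 0.0)
    return best


def dp_alignment_score(
    a: str,
    b: str,
    score_fn,
    gap_open: float,
    gap_extend: float,
) -> float:
    """Memoized recursive affine-gap score (independent of the package DP)."""

    @lru_cache(maxsize=None)
    def rec(i: int, j: int, prev: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        options = []
        if i < len(a) and j < len(b):
            options.append(score_fn(a[i], b[j]) + rec(i + 1, j + 1, "M"))
        if i < len(a):
            options.append((gap_extend if prev == "I" else gap_open) + rec(i + 1, j, "I"))
        if j < len(b):
            options.append((gap_extend if prev == "D" else gap_open) + rec(i, j + 1, "D"))
        return max(options)

    return rec(0, 0, "")


# ---------------------------------------------------------------------------
# Dollo oracle
# ---------------------------------------------------------------------------

def dollo_min_events(tree: dendropy.Tree, presence: dict[str, int]) -> int:
    """Minimal event count over every single-origin placement.

    For each candidate origin (any node whose subtree contains all present
    leaves) the losses are forced: one per maximal all-absent subtree below
    the origin. Returns 0 for an all-absent vector.
    """
    present = {t for t, v in presence.items() if v}
    if not present:
        return 0

    leafsets: dict[int, frozenset[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            leafsets[id(node)] = frozenset([node.taxon.label])
        else:
            leafsets[id(node)] = frozenset().union(
                *(leafsets[id(c)] for c in node.child_nodes())
            )

    def forced_losses(origin) -> int:
        losses = 0
        stack = list(origin.child_nodes())
        while stack:
            node = stack.pop()
            if not (leafsets[id(node)] & present):
                losses += 1
            else:
                stack.extend(node.child_nodes())
        return losses

    best = None
    for node in tree.preorder_node_iter():
        if present <= leafsets[id(node)]:
            events = 1 + forced_losses(node)
            best = events if best is None else min(best, events)
    return best


# ---------------------------------------------------------------------------
# Rooted binary tree shapes
# ---------------------------------------------------------------------------

def binary_tree_shapes(n: int) -> list[str]:
    """All rooted binary tree shapes with ``n`` leaves, as Newick strings.

    Leaves are labelled A, B, ... in left-to-right order. The number of
    shapes follows the Wedderburn–Etherington sequence (1, 1, 2, 3, 6, 11,
    23 for n = 2..8).
    """

    def shapes(k: int):
        if k == 1:
            return ["L"]
        out = []
        for i in range(1, k // 2 + 1):
            lefts, rights = shapes(i), shapes(k - i)
            if i == k - i:
                for x in range(len(lefts)):
                    for y in range(x, len(rights)):
                        out.append((lefts[x], rights[y]))
            else:
                for left in lefts:
                    for right in rights:
                        out.append((left, right))
        return out

    def label(shape, counter) -> str:
        if shape == "L":
            name = chr(ord("A") + counter[0])
            counter[0] += 1
            return name
        left, right = shape
        return f"({label(left, counter)},{label(right, counter)})"

    return [label(s, [0]) + ";" for s in shapes(n)]
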