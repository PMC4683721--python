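"""Generalized rooted subtree-prune-and-regraft (rSPR) operations.

Trees here may be multifurcating, so the classical (binary) rSPR move is
generalized: after pruning the arc ``(u, v)`` the subtree rooted at ``v``
can be regrafted either directly onto an existing internal node ``w``
(*node* variant, which can raise the out-degree of ``w``) or onto a fresh
node spliced in above ``w`` (*arc* variant).  The former parent ``u`` is
suppressed if it has become elementary.

Only the distance-1 question is handled here (is ``b`` reachable from ``a``
by a single move?), by brute-force enumeration of all moves; general rSPR
distance is NP-hard and out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Literal

from .trees import PhyloTree, TreeError, trees_equal


@dataclass(frozen=True)
class RSPROperation:
    """A single rSPR move on a given tree.

    ``pruned`` is the head ``v`` of the removed arc ``(u, v)``;
    ``regraft`` is the node ``w`` receiving the subtree; ``kind`` selects
    the node or arc variant.  Node identifiers refer to the tree the
    operation is applied to.
    """

    pruned: int
    regraft: int
    kind: Literal["node", "arc"]


@dataclass(frozen=True)
class RSPRWitness:
    """An rSPR move taking one tree to another, together with whether its
    regraft point ``w`` is neither an ancestor of the pruned node ``h`` nor
    a descendant of the parent of ``h`` -- the placement requirement under
    which the move corresponds to a secondary arc of a restricted LGT
    network."""

    op: RSPROperation
    placement_ok: bool


def apply_rspr(tree: PhyloTree, op: RSPROperation) -> PhyloTree:
    """Apply one rSPR operation, returning a new phylogenetic tree.

    Raises :class:`TreeError` if the operation is invalid for ``tree``:
    the regraft point may not be a descendant of the pruned node, and the
    node variant requires an internal regraft point other than the pruned
    node's parent.
    """
    v, w, kind = op.pruned, op.regraft, op.kind
    if v not in tree.nodes or w not in tree.nodes:
        raise TreeError("operation refers to nodes outside the tree")
    if v == tree.root:
        raise TreeError("cannot prune the root")
    u = tree.parent(v)
    if w in tree.subtree_nodes(v):
        raise TreeError("regraft point is a descendant of the pruned node")
    if kind == "node":
        if tree.is_leaf(w) or w == u:
            raise TreeError("node variant requires an internal regraft point != parent")
    elif kind != "arc":
        raise TreeError(f"unknown rSPR kind {kind!r}")

    children = {x: list(cs) for x, cs in tree._children.items()}
    labels = dict(tree.leaf_labels)
    root = tree.root

    children[u].remove(v)

    if kind == "node":
        children[w].append(v)
    else:
        new = max(children) + 1
        if w == root:
            children[new] = [v, w]
            root = new
        else:
            wp = tree.parent(w)
            children[wp][children[wp].index(w)] = new
            children[new] = [v, w]

    # suppress u if it has become elementary
    if len(children[u]) == 1:
        (c,) = children[u]
        if u == root:
            del children[u]
            root = c
        else:
            up = next(x for x, cs in children.items() if u in cs)
            children[up][children[up].index(u)] = c
            del children[u]

    return PhyloTree(children, labels, root)


def enumerate_rspr_operations(tree: PhyloTree) -> Iterator[RSPROperation]:
    """All syntactically valid rSPR operations on a tree (including ones
    that reproduce the tree itself)."""
    for v in sorted(tree.nodes):
        if v == tree.root:
            continue
        u = tree.parent(v)
        below = tree.subtree_nodes(v)
        for w in sorted(tree.nodes):
            if w in below:
                continue
            yield RSPROperation(v, w, "arc")
            if not tree.is_leaf(w) and w != u:
                yield RSPROperation(v, w, "node")


def enumerate_rspr_neighbors(tree: PhyloTree) -> list[PhyloTree]:
    """All trees at rSPR distance exactly 1 from ``tree``, one per
    isomorphism class (deduplicated by cluster set)."""
    own = tree.cluster_set()
    seen = {own}
    out: list[PhyloTree] = []
    for op in enumerate_rspr_operations(tree):
        result = apply_rspr(tree, op)
        cs = result.cluster_set()
        if cs not in seen:
            seen.add(cs)
            out.append(result)
    return out


def rspr_distance_leq_one(a: PhyloTree, b: PhyloTree) -> int | str:
    """0 if the trees are equal, 1 if one move apart, ``"more"`` otherwise."""
    if a.label_set != b.label_set:
        raise TreeError("trees are on different label sets")
    if trees_equal(a, b):
        return 0
    target = b.cluster_set()
    for t in enumerate_rspr_neighbors(a):
        if t.cluster_set() == target:
            return 1
    return "more"


def witness_rspr(a: PhyloTree, b: PhyloTree) -> RSPRWitness | None:
    """An rSPR operation transforming ``a`` into ``b``, if one exists.

    If several moves work, one whose regraft placement satisfies the
    restricted-network requirement (see :class:`RSPRWitness`) is preferred.
    Returns ``None`` when no single move transforms ``a`` into ``b`` --
    in particular when the trees are equal.
    """
    if a.label_set != b.label_set:
        raise TreeError("trees are on different label sets")
    if trees_equal(a, b):
        return None
    target = b.cluster_set()
    fallback: RSPROperation | None = None
    for op in enumerate_rspr_operations(a):
        if apply_rspr(a, op).cluster_set() != target:
            continue
        h, w = op.pruned, op.regraft
        u = a.parent(h)
        ok = (not a.is_ancestor(w, h)) and (w not in a.subtree_nodes(u))
        if ok:
            return RSPRWitness(op, True)
        if fallback is None:
            fallback = op
    if fallback is not None:
        return RSPRWitness(fallback, False)
    return None
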