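"""Rooted-tree data model: Newick I/O, clusters, triples, restriction, reduction.

Two kinds of trees appear throughout the package:

* :class:`PartialTree` -- a rooted tree that may contain *elementary*
  (out-degree-1) nodes and unlabelled leaves.  These arise naturally as the
  principal and secondary subtrees of an LGT network before reduction, and
  as the literal parse of a Newick string with redundant parentheses.
* :class:`PhyloTree` -- a phylogenetic tree proper: no elementary nodes and
  a bijection between leaves and the taxon set.

Node identifiers are opaque integers local to each tree; the only meaningful
notion of identity between trees is label-preserving isomorphism, which for
phylogenetic trees is equivalent to equality of cluster sets (and to equality
of the induced sets of rooted triples).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Iterator

import dendropy


class TreeError(ValueError):
    """A tree (or an operation on one) violates a structural requirement."""


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------

class PartialTree:
    """Rooted tree, possibly with elementary nodes and unlabelled leaves.

    Parameters
    ----------
    children : mapping of node -> sequence of child nodes
        Every node reachable from ``root`` must appear (nodes without
        children may be omitted as keys; they are filled in).
    labels : mapping of node -> str
        Leaf labels.  Labelled nodes must be leaves and labels must be
        pairwise distinct.  The map may be partial (unlabelled leaves).
    root : node
        The single in-degree-0 node.
    """

    __slots__ = ("_children", "_parent", "_labels", "root")

    def __init__(self, children, labels, root):
        ch: dict[int, tuple[int, ...]] = {u: tuple(cs) for u, cs in children.items()}
        for u in list(ch):
            for c in ch[u]:
                ch.setdefault(c, ())
        ch.setdefault(root, ())
        self._children = ch
        self._labels = dict(labels)
        self.root = root
        parent: dict[int, int] = {}
        for u, cs in ch.items():
            for c in cs:
                if c in parent:
                    raise TreeError(f"node {c} has more than one parent")
                parent[c] = u
        self._parent = parent
        self._validate()

    def _validate(self) -> None:
        if self.root in self._parent:
            raise TreeError("root has a parent")
        seen: set[int] = set()
        stack = [self.root]
        while stack:
            u = stack.pop()
            seen.add(u)
            stack.extend(self._children[u])
        if seen != set(self._children):
            raise TreeError("tree is not connected (unreachable nodes)")
        for u in self._labels:
            if self._children[u]:
                raise TreeError(f"labelled node {u} is not a leaf")
        labs = list(self._labels.values())
        if len(set(labs)) != len(labs):
            raise TreeError("duplicate leaf labels")
        for lab in labs:
            if not isinstance(lab, str) or not lab:
                raise TreeError("labels must be non-empty strings")

    # -- basic accessors ----------------------------------------------------

    @property
    def nodes(self) -> frozenset[int]:
        return frozenset(self._children)

    def children(self, u: int) -> tuple[int, ...]:
        return self._children[u]

    def parent(self, u: int) -> int | None:
        return self._parent.get(u)

    def is_leaf(self, u: int) -> bool:
        return not self._children[u]

    def is_elementary(self, u: int) -> bool:
        return len(self._children[u]) == 1

    def label(self, u: int) -> str | None:
        return self._labels.get(u)

    @property
    def leaf_labels(self) -> dict[int, str]:
        return dict(self._labels)

    @property
    def label_set(self) -> frozenset[str]:
        return frozenset(self._labels.values())

    @property
    def leaves(self) -> list[int]:
        return [u for u in sorted(self._children) if not self._children[u]]

    def arcs(self) -> list[tuple[int, int]]:
        return [(u, c) for u in sorted(self._children) for c in self._children[u]]

    def node_with_label(self, lab: str) -> int:
        for u, l in self._labels.items():
            if l == lab:
                return u
        raise KeyError(lab)

    # -- traversal ----------------------------------------------------------

    def preorder(self) -> Iterator[int]:
        stack = [self.root]
        while stack:
            u = stack.pop()
            yield u
            stack.extend(reversed(self._children[u]))

    def postorder(self) -> Iterator[int]:
        out: list[int] = []
        stack = [self.root]
        while stack:
            u = stack.pop()
            out.append(u)
            stack.extend(self._children[u])
        return reversed(out)

    # -- clusters and ancestry ----------------------------------------------

    def node_clusters(self) -> dict[int, frozenset[str]]:
        """Cluster of every node: the labels of its leaf descendants."""
        clus: dict[int, frozenset[str]] = {}
        for u in self.postorder():
            if self.is_leaf(u):
                lab = self._labels.get(u)
                clus[u] = frozenset([lab]) if lab is not None else frozenset()
            else:
                clus[u] = frozenset().union(*(clus[c] for c in self._children[u]))
        return clus

    def cluster_set(self) -> frozenset[frozenset[str]]:
        """The set of non-empty clusters (unlabelled leaves contribute none)."""
        return frozenset(c for c in self.node_clusters().values() if c)

    def node_with_cluster(self, cluster: frozenset[str]) -> int:
        """A node whose cluster equals ``cluster`` (deepest one if several
        coincide along an elementary chain)."""
        cluster = frozenset(cluster)
        best = None
        for u, c in self.node_clusters().items():
            if c == cluster and (best is None or self.is_strict_descendant(u, best)):
                best = u
        if best is None:
            raise KeyError(f"no node with cluster {sorted(cluster)}")
        return best

    def ancestors(self, u: int) -> list[int]:
        """Ancestors of ``u`` from ``u`` itself up to the root (inclusive)."""
        out = [u]
        while (p := self._parent.get(out[-1])) is not None:
            out.append(p)
        return out

    def is_ancestor(self, a: int, d: int) -> bool:
        """True iff ``a`` lies on the path root -> ``d`` (reflexive)."""
        return a in self.ancestors(d)

    def is_strict_descendant(self, d: int, a: int) -> bool:
        return d != a and self.is_ancestor(a, d)

    def subtree_nodes(self, u: int) -> set[int]:
        out: set[int] = set()
        stack = [u]
        while stack:
            v = stack.pop()
            out.add(v)
            stack.extend(self._children[v])
        return out

    def lca(self, u: int, v: int) -> int:
        """Lowest common ancestor: the common ancestor that is a descendant
        of every other common ancestor."""
        anc_u = self.ancestors(u)
        anc_u_set = set(anc_u)
        for w in self.ancestors(v):
            if w in anc_u_set:
                return w
        raise TreeError("nodes have no common ancestor")  # pragma: no cover

    # -- misc ---------------------------------------------------------------

    def copy(self) -> "PartialTree":
        return type(self)(self._children, self._labels, self.root)

    def __repr__(self) -> str:
        return f"<{type(self).__name__} {write_newick(self)!r}>"


class PhyloTree(PartialTree):
    """Phylogenetic tree on a label set S: no elementary nodes and leaves
    bijectively labelled by S (with |S| >= 2)."""

    __slots__ = ()

    def _validate(self) -> None:
        super()._validate()
        n_leaves = 0
        for u in self._children:
            k = len(self._children[u])
            if k == 1:
                raise TreeError(f"elementary node {u} in phylogenetic tree")
            if k == 0:
                n_leaves += 1
                if u not in self._labels:
                    raise TreeError(f"unlabelled leaf {u} in phylogenetic tree")
        if n_leaves < 2:
            raise TreeError("a phylogenetic tree needs at least 2 leaves")


# ---------------------------------------------------------------------------
# rooted triples
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Triple:
    """Shape of a phylogenetic tree restricted to three labels.

    ``cherry`` holds the 2-element frozenset forming the proper 2-cluster,
    or ``None`` for the star (unresolved) triple.  For a fixed 3-set there
    are exactly four possible triples: three cherries and the star.
    """

    labels: frozenset[str]
    cherry: frozenset[str] | None

    def __post_init__(self):
        if len(self.labels) != 3:
            raise TreeError("a triple needs exactly 3 labels")
        if self.cherry is not None and (
            len(self.cherry) != 2 or not self.cherry <= self.labels
        ):
            raise TreeError("cherry must be a 2-subset of the triple's labels")

    @property
    def outgroup(self) -> str | None:
        if self.cherry is None:
            return None
        (out,) = self.labels - self.cherry
        return out

    def newick(self) -> str:
        if self.cherry is None:
            return "(%s);" % ",".join(sorted(self.labels))
        a, b = sorted(self.cherry)
        return f"(({a},{b}),{self.outgroup});"


def cherry(a: str, b: str, out: str) -> Triple:
    """The triple ((a,b),out)."""
    return Triple(frozenset({a, b, out}), frozenset({a, b}))


def star(a: str, b: str, c: str) -> Triple:
    """The unresolved triple (a,b,c)."""
    return Triple(frozenset({a, b, c}), None)


def triple_of(tree: PartialTree, three_labels: Iterable[str]) -> Triple:
    """The triple defined by ``tree`` on three of its labels.

    Computed from the cluster set: the triple is a cherry on pair ``p`` iff
    some cluster meets the 3-set exactly in ``p`` (all such clusters agree,
    by laminarity).  This coincides with the shape of the restriction of the
    tree to the three labels.
    """
    three = frozenset(three_labels)
    if len(three) != 3:
        raise TreeError("exactly three distinct labels required")
    if not three <= tree.label_set:
        missing = sorted(three - tree.label_set)
        raise TreeError(f"labels not in tree: {missing}")
    for c in tree.cluster_set():
        inter = c & three
        if len(inter) == 2:
            return Triple(three, inter)
    return Triple(three, None)


def triples(tree: PartialTree) -> frozenset[Triple]:
    """Gamma(T): the set of all triples defined by the tree."""
    labs = sorted(tree.label_set)
    return frozenset(
        triple_of(tree, combo) for combo in itertools.combinations(labs, 3)
    )


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def parse_newick(text: str) -> PartialTree:
    """Parse a rooted Newick string literally.

    Redundant parentheses (as in ``((x));``) become elementary nodes, which
    are *retained*; call :func:`reduce_tree` (or :func:`parse_phylo`) to
    obtain a phylogenetic tree.  Branch lengths are ignored and internal
    labels discarded: the model is topology-only.
    """
    if text is None or not text.strip():
        raise TreeError("empty Newick input")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise TreeError(f"malformed Newick string: {exc}") from exc
    ids: dict[int, int] = {}
    for i, nd in enumerate(dtree.preorder_node_iter()):
        ids[id(nd)] = i
    children: dict[int, list[int]] = {}
    labels: dict[int, str] = {}
    for nd in dtree.preorder_node_iter():
        u = ids[id(nd)]
        children[u] = [ids[id(c)] for c in nd.child_nodes()]
        if not nd.child_nodes():
            lab = nd.taxon.label if nd.taxon is not None else nd.label
            if lab:
                labels[u] = lab
    t = PartialTree(children, labels, root=0)  # duplicate labels rejected here
    return t


def parse_phylo(text: str) -> PhyloTree:
    """Parse a Newick string and reduce it to a phylogenetic tree.

    Convenience path: elementary nodes from redundant parentheses are
    suppressed and unlabelled leaves removed.
    """
    return reduce_tree(parse_newick(text))


def write_newick(tree: PartialTree, canonical: bool = True) -> str:
    """Serialize a tree as Newick.

    With ``canonical=True`` (default) children are ordered by the smallest
    label contained in their cluster, so isomorphic trees serialize to the
    same string and ``parse -> write`` round-trips up to isomorphism.
    """
    clus = tree.node_clusters()

    def render(u: int) -> str:
        if tree.is_leaf(u):
            return tree.label(u) or ""
        cs = list(tree.children(u))
        if canonical:
            cs.sort(key=lambda c: (min(clus[c]) if clus[c] else "",))
        return "(" + ",".join(render(c) for c in cs) + ")"

    return render(tree.root) + ";"


# ---------------------------------------------------------------------------
# reduction, restriction, equality
# ---------------------------------------------------------------------------

def reduce_tree(tree: PartialTree) -> PhyloTree:
    """Reduce a partially leaf-labelled tree to a phylogenetic tree.

    Recursively removes unlabelled leaves (with their incoming arcs), then
    recursively suppresses elementary nodes; an elementary root is removed
    together with its incident arc.  The label set is preserved and so is
    every induced triple.
    """
    children = {u: list(cs) for u, cs in tree._children.items()}
    parent = dict(tree._parent)
    labels = dict(tree._labels)
    root = tree.root

    # 1. strip unlabelled leaves to a fixpoint
    changed = True
    while changed:
        changed = False
        for u in [n for n in list(children) if not children[n] and n not in labels]:
            if u == root:
                continue
            p = parent.pop(u)
            children[p].remove(u)
            del children[u]
            changed = True

    if len(labels) < 2:
        raise TreeError("fewer than 2 labelled leaves survive reduction")

    # 2. remove elementary root chain
    while len(children[root]) == 1:
        new_root = children[root][0]
        del children[root]
        del parent[new_root]
        root = new_root

    # 3. splice interior elementary nodes
    pending = [u for u in children if u != root and len(children[u]) == 1]
    while pending:
        u = pending.pop()
        if u not in children or len(children[u]) != 1:
            continue
        p = parent[u]
        (c,) = children[u]
        children[p][children[p].index(u)] = c
        parent[c] = p
        del children[u]
        del parent[u]

    return PhyloTree(children, labels, root)


def restrict(tree: PhyloTree, subset: Iterable[str]) -> PhyloTree:
    """Restriction T|_{S0}: the subtree spanned by the kept leaves, with
    elementary nodes suppressed."""
    subset = frozenset(subset)
    if not subset:
        raise TreeError("restriction subset must be non-empty")
    if not subset <= tree.label_set:
        raise TreeError(f"labels not in tree: {sorted(subset - tree.label_set)}")
    if len(subset) < 2:
        raise TreeError("restriction to fewer than 2 labels is not a phylogenetic tree")
    kept = {u: lab for u, lab in tree._labels.items() if lab in subset}
    return reduce_tree(PartialTree(tree._children, kept, tree.root))


def trees_equal(a: PartialTree, b: PartialTree) -> bool:
    """Label-preserving isomorphism, via equality of cluster sets."""
    return a.label_set == b.label_set and a.cluster_set() == b.cluster_set()


# ---------------------------------------------------------------------------
# building and enumerating trees from cluster sets
# ---------------------------------------------------------------------------

def tree_from_clusters(clusters: Iterable[frozenset[str]]) -> PhyloTree:
    """Build the phylogenetic tree with the given cluster set.

    Trivial clusters (singletons and the full label set) are added if
    missing.  Raises :class:`TreeError` if the family is not laminar
    (pairwise nested or disjoint), i.e. realized by no tree.
    """
    cl = {frozenset(c) for c in clusters}
    if not cl or frozenset() in cl:
        raise TreeError("clusters must be non-empty")
    labels = frozenset().union(*cl)
    cl |= {frozenset([x]) for x in labels}
    cl.add(labels)
    ordered = sorted(cl, key=lambda c: (-len(c), sorted(c)))
    for c1, c2 in itertools.combinations(ordered, 2):
        if not (c1 <= c2 or c2 <= c1 or not (c1 & c2)):
            raise TreeError(
                f"clusters {sorted(c1)} and {sorted(c2)} overlap: not laminar"
            )
    ids = {c: i for i, c in enumerate(ordered)}
    children: dict[int, list[int]] = {i: [] for i in ids.values()}
    for c in ordered[1:]:
        # parent: the smallest cluster strictly containing c
        parent_c = min(
            (d for d in cl if c < d), key=len
        )
        children[ids[parent_c]].append(ids[c])
    node_labels = {ids[c]: next(iter(c)) for c in cl if len(c) == 1}
    return PhyloTree(children, node_labels, root=0)


def _set_partitions(items: list) -> Iterator[list[list]]:
    """All partitions of ``items`` into unordered non-empty blocks."""
    if len(items) == 1:
        yield [items]
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def _cluster_sets(labs: frozenset[str], cache: dict) -> list[frozenset]:
    if labs in cache:
        return cache[labs]
    if len(labs) == 1:
        res = [frozenset({labs})]
    else:
        res = []
        for part in _set_partitions(sorted(labs)):
            if len(part) < 2:
                continue
            block_sets = [_cluster_sets(frozenset(b), cache) for b in part]
            for combo in itertools.product(*block_sets):
                res.append(frozenset().union(*combo) | {labs})
    cache[labs] = res
    return res


def enumerate_trees(labels: Iterable[str]) -> Iterator[PhyloTree]:
    """All phylogenetic trees (multifurcations included) on a label set,
    one per isomorphism class, in a deterministic order.

    Counts grow as 1, 4, 26, 236, 2752, ... for 2, 3, 4, 5, 6 labels; meant
    for exhaustive checks on small label sets.
    """
    labs = frozenset(labels)
    if len(labs) < 2:
        raise TreeError("need at least 2 labels")
    for cs in _cluster_sets(labs, cache={}):
        yield tree_from_clusters(cs)
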