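"""LGT networks: the principal/secondary arc partition and its invariants.

An LGT network models a set of lateral gene transfers on top of a species
tree: the *principal* arcs form a rooted tree spanning every node, with
leaves bijectively labelled by the taxa (the principal subtree ``T0``), and
each *secondary* arc represents one transfer, pointing from the donor
lineage to the principal parent's position of the recipient.  The full
digraph must be acyclic and free of elementary nodes, and every
reticulation receives exactly one principal arc.

Swapping the principal arc into a secondary arc's target for that secondary
arc yields the *secondary subtree* associated with the transfer; reducing
the principal and secondary subtrees gives the phylogenetic trees that the
reconstruction machinery works with.

The *restricted* subclass adds four conditions (checked by
:meth:`LGTNetwork.is_restricted`) that make the reduced subtrees pairwise
distinct and the network uniquely reconstructable from them.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .trees import PartialTree, PhyloTree, TreeError, reduce_tree

Arc = tuple[int, int]


class NetworkError(ValueError):
    """The arc sets do not form a valid LGT network."""


@dataclass(frozen=True)
class RestrictedViolation:
    """One violated restrictedness condition with its witness.

    Conditions:
      ``a`` -- a principally elementary node has a principally elementary
               principal child;
      ``b`` -- a secondary arc targets a principally elementary node;
      ``c`` -- a secondary arc (u, h) with a principal path from u to h;
      ``d`` -- a secondary arc (u, h) whose principal path from
               LCA(u, h) to h has no non-principally-elementary strict
               intermediate node.
    """

    condition: str
    witness: Arc


class LGTNetwork:
    """An LGT network given by its principal and secondary arc sets.

    Construction eagerly validates the basic structural invariants:
    the principal arcs form a spanning rooted tree with bijectively
    labelled leaves, the full digraph is acyclic, no node is elementary in
    the full digraph, and no secondary arc leaves a labelled leaf.
    Restrictedness is a separate, opt-in check.
    """

    __slots__ = ("principal_arcs", "secondary_arcs", "_labels", "root",
                 "_pchildren", "_pparent")

    def __init__(self, principal_arcs, secondary_arcs, leaf_labels):
        p = frozenset((int(a), int(b)) for a, b in principal_arcs)
        s = frozenset((int(a), int(b)) for a, b in secondary_arcs)
        if p & s:
            raise NetworkError("an arc cannot be both principal and secondary")
        for a, b in p | s:
            if a == b:
                raise NetworkError("self-loop arc")
        nodes = {x for arc in p | s for x in arc}
        if not nodes:
            raise NetworkError("empty network")

        pchildren: dict[int, list[int]] = {u: [] for u in nodes}
        pparent: dict[int, int] = {}
        for a, b in sorted(p):
            if b in pparent:
                raise NetworkError(f"node {b} has two principal parents")
            pparent[b] = a
            pchildren[a].append(b)
        roots = [u for u in nodes if u not in pparent]
        if len(roots) != 1:
            raise NetworkError(f"principal arcs must have a single root, got {roots}")
        self.root = roots[0]

        # principal tree spans all nodes
        seen: set[int] = set()
        stack = [self.root]
        while stack:
            u = stack.pop()
            seen.add(u)
            stack.extend(pchildren[u])
        if seen != nodes:
            raise NetworkError("principal arcs do not span all nodes from the root")

        self.principal_arcs = p
        self.secondary_arcs = s
        self._pchildren = {u: tuple(cs) for u, cs in pchildren.items()}
        self._pparent = pparent

        leaves = {u for u in nodes if not pchildren[u]}
        labels = {int(u): str(v) for u, v in leaf_labels.items()}
        if set(labels) != leaves:
            raise NetworkError("leaf labelling must cover exactly the principal leaves")
        if len(set(labels.values())) != len(labels):
            raise NetworkError("duplicate leaf labels")
        self._labels = labels

        sec_out: dict[int, int] = {u: 0 for u in nodes}
        for a, b in s:
            sec_out[a] += 1
        for u, h in s:
            if u in leaves:
                raise NetworkError(f"secondary arc leaves the labelled leaf {u}")
        for u in nodes:
            if len(pchildren[u]) + sec_out[u] == 1:
                raise NetworkError(f"elementary node {u} in the full digraph")

        g = nx.DiGraph()
        g.add_nodes_from(nodes)
        g.add_edges_from(p | s)
        if not nx.is_directed_acyclic_graph(g):
            raise NetworkError("the full digraph contains a cycle")

    # -- basic accessors ----------------------------------------------------

    @property
    def nodes(self) -> frozenset[int]:
        return frozenset(self._pchildren)

    @property
    def leaf_labels(self) -> dict[int, str]:
        return dict(self._labels)

    @property
    def label_set(self) -> frozenset[str]:
        return frozenset(self._labels.values())

    def principal_children(self, u: int) -> tuple[int, ...]:
        return self._pchildren[u]

    def principal_parent(self, u: int) -> int | None:
        return self._pparent.get(u)

    def is_principally_elementary(self, u: int) -> bool:
        """Out-degree 1 counting principal arcs only."""
        return len(self._pchildren[u]) == 1

    def principal_clusters(self) -> dict[int, frozenset[str]]:
        return self.principal_subtree().node_clusters()

    # -- subtrees -----------------------------------------------------------

    def principal_subtree(self) -> PartialTree:
        """T0: the tree formed by the principal arcs (elementary nodes kept)."""
        return PartialTree(self._pchildren, self._labels, self.root)

    def secondary_subtree(self, e: Arc) -> PartialTree:
        """T_e: T0 with the principal arc into e's target replaced by e.

        May contain unlabelled leaves (the former parent of the target, if
        it has no other child) and elementary nodes.
        """
        e = (int(e[0]), int(e[1]))
        if e not in self.secondary_arcs:
            raise NetworkError(f"{e} is not a secondary arc of this network")
        u, h = e
        old_parent = self._pparent[h]
        children = {x: list(cs) for x, cs in self._pchildren.items()}
        children[old_parent].remove(h)
        children[u].append(h)
        return PartialTree(children, self._labels, self.root)

    def sorted_secondary_arcs(self) -> list[Arc]:
        """Secondary arcs in canonical order (by source cluster, then
        target cluster, with node ids as a final tie-break)."""
        clus = self.principal_clusters()
        return sorted(
            self.secondary_arcs,
            key=lambda e: (sorted(clus[e[0]]), sorted(clus[e[1]]), e),
        )

    def reduced_subtrees(self) -> tuple[PhyloTree, list[PhyloTree]]:
        """The reduced principal subtree and the reduced secondary subtrees
        (one per secondary arc, in canonical arc order)."""
        principal = reduce_tree(self.principal_subtree())
        secondaries = [
            reduce_tree(self.secondary_subtree(e))
            for e in self.sorted_secondary_arcs()
        ]
        return principal, secondaries

    # -- restrictedness -----------------------------------------------------

    def is_restricted(self) -> list[RestrictedViolation]:
        """Check the four restrictedness conditions; empty list iff all hold."""
        violations: list[RestrictedViolation] = []
        pe = self.is_principally_elementary
        t0 = self.principal_subtree()
        for u in sorted(self.nodes):
            if pe(u):
                (v,) = self._pchildren[u]
                if pe(v):
                    violations.append(RestrictedViolation("a", (u, v)))
        for u, h in sorted(self.secondary_arcs):
            if pe(h):
                violations.append(RestrictedViolation("b", (u, h)))
            if t0.is_ancestor(u, h):
                violations.append(RestrictedViolation("c", (u, h)))
                continue  # condition (d) is about transfers across the tree
            z = t0.lca(u, h)
            path = [x for x in t0.ancestors(h) if t0.is_ancestor(z, x)]
            intermediates = [x for x in path if x not in (z, h)]
            if not any(not pe(x) for x in intermediates):
                violations.append(RestrictedViolation("d", (u, h)))
        return violations

    # -- isomorphism and serialization --------------------------------------

    def canonical_form(self):
        """A complete isomorphism invariant.

        Node ids are renumbered by a DFS of the principal tree with
        children ordered by the smallest label in their principal cluster
        (sibling clusters are disjoint and non-empty, so this order is
        total); an S-tree has no non-trivial label-preserving automorphism,
        so the renumbering is canonical.
        """
        clus = self.principal_clusters()
        ids: dict[int, int] = {}
        stack = [self.root]
        while stack:
            u = stack.pop()
            ids[u] = len(ids)
            for c in sorted(self._pchildren[u],
                            key=lambda c: min(clus[c]), reverse=True):
                stack.append(c)
        return (
            tuple(sorted((ids[a], ids[b]) for a, b in self.principal_arcs)),
            tuple(sorted((ids[a], ids[b]) for a, b in self.secondary_arcs)),
            tuple(sorted((ids[u], lab) for u, lab in self._labels.items())),
        )

    def to_text(self) -> str:
        """Serialize in the arc-list format (canonical, bit-exact).

        Header ``#lgt v1``; one ``src<TAB>tgt<TAB>P|S`` line per arc; one
        ``node<TAB>LEAF<TAB>label`` line per leaf.
        """
        principal, secondary, leaves = self.canonical_form()
        lines = ["#lgt v1"]
        lines += [f"{a}\t{b}\tP" for a, b in principal]
        lines += [f"{a}\t{b}\tS" for a, b in secondary]
        lines += [f"{u}\tLEAF\t{lab}" for u, lab in leaves]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "LGTNetwork":
        principal: list[Arc] = []
        secondary: list[Arc] = []
        labels: dict[int, str] = {}
        lines = [ln for ln in text.splitlines() if ln.strip()]
        if not lines or lines[0].strip() != "#lgt v1":
            raise NetworkError("missing '#lgt v1' header")
        for ln in lines[1:]:
            parts = ln.split("\t")
            if len(parts) != 3:
                raise NetworkError(f"malformed line: {ln!r}")
            if parts[1] == "LEAF":
                labels[int(parts[0])] = parts[2]
            elif parts[2] == "P":
                principal.append((int(parts[0]), int(parts[1])))
            elif parts[2] == "S":
                secondary.append((int(parts[0]), int(parts[1])))
            else:
                raise NetworkError(f"unknown arc type in line: {ln!r}")
        return cls(principal, secondary, labels)

    def __repr__(self) -> str:
        return (f"<LGTNetwork {len(self.nodes)} nodes, "
                f"{len(self.principal_arcs)}P/{len(self.secondary_arcs)}S arcs, "
                f"{len(self._labels)} leaves>")


def networks_isomorphic(a: LGTNetwork, b: LGTNetwork) -> bool:
    """Label-preserving isomorphism mapping principal arcs to principal
    arcs and secondary arcs to secondary arcs."""
    return a.canonical_form() == b.canonical_form()
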