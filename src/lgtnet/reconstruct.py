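"""Reconstruction of a restricted LGT network from its reduced subtrees.

The single-pair case places one secondary arc on the principal tree as
dictated by the segment decomposition of the cluster differences.  The
multi-tree case computes one placement per secondary tree, merges
placements that share a source (all arc-regraft placements on the same arc
of the principal tree share a single subdivision node -- never two stacked
subdivision nodes), adds all secondary arcs, and finally tests the
assembled digraph for acyclicity: a directed cycle proves that no
restricted network with the given subtrees exists.  The output is unique
up to isomorphism and independent of the order of the secondary trees.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .conditions import (
    ConditionFailure,
    SegmentDecomposition,
    check_cluster_condition,
)
from .network import Arc, LGTNetwork
from .trees import PhyloTree, TreeError, trees_equal

Cluster = frozenset[str]


@dataclass(frozen=True)
class ArcPlacement:
    """Where one secondary arc attaches on the principal tree.

    ``target_cluster`` (B) names the node of T receiving the transfer;
    ``source_cluster`` (C_l) names the node of T under the source.  With
    ``source_is_new`` the source is a fresh node subdividing the arc of T
    ending at the C_l node; otherwise it is the C_l node itself.
    """

    source_cluster: Cluster
    source_is_new: bool
    target_cluster: Cluster

    def __post_init__(self):
        if self.source_cluster & self.target_cluster:
            raise ValueError("source and target clusters must be disjoint")


def placement_of(dec: SegmentDecomposition) -> ArcPlacement:
    """The arc placement derived from a segment decomposition."""
    return ArcPlacement(dec.C_l, dec.source_is_new, dec.B)


@dataclass(frozen=True)
class ReconstructionResult:
    """Outcome of the multi-tree reconstruction: exactly one of ``network``,
    ``pair_failure`` (index of the offending secondary tree and the failed
    condition) or ``cycle`` (arcs of a directed cycle) is set."""

    network: LGTNetwork | None = None
    pair_failure: tuple[int, ConditionFailure] | None = None
    cycle: tuple[Arc, ...] | None = None

    def __post_init__(self):
        populated = sum(
            x is not None for x in (self.network, self.pair_failure, self.cycle)
        )
        if populated != 1:
            raise ValueError("exactly one outcome variant must be populated")

    @property
    def ok(self) -> bool:
        return self.network is not None


def _assemble(T0: PhyloTree, placements: list[ArcPlacement]):
    """Lay the secondary arcs onto a copy of T0, sharing one subdivision
    node per subdivided arc.  Returns (principal_arcs, secondary_arcs,
    leaf_labels) without any validity check."""
    children = {u: list(cs) for u, cs in T0._children.items()}
    clus = T0.node_clusters()
    node_of = {clus[u]: u for u in T0.nodes}
    parent = {c: u for u, cs in children.items() for c in cs}
    next_id = max(T0.nodes) + 1
    subdivision: dict[int, int] = {}
    secondary: list[Arc] = []
    seen: set[tuple[Cluster, bool, Cluster]] = set()
    for pl in sorted(placements,
                     key=lambda p: (sorted(p.source_cluster), p.source_is_new,
                                    sorted(p.target_cluster))):
        key = (pl.source_cluster, pl.source_is_new, pl.target_cluster)
        if key in seen:  # distinct input trees cannot induce equal placements
            raise TreeError("duplicate arc placement: inputs are not pairwise different")
        seen.add(key)
        c_node = node_of[pl.source_cluster]
        h = node_of[pl.target_cluster]
        if pl.source_is_new:
            if c_node in subdivision:
                u = subdivision[c_node]
            else:
                p = parent[c_node]  # C_l is a proper subset of S, never the root
                u = next_id
                next_id += 1
                children[p][children[p].index(c_node)] = u
                children[u] = [c_node]
                subdivision[c_node] = u
        else:
            u = c_node
        secondary.append((u, h))
    principal = [(u, c) for u, cs in children.items() for c in cs]
    return principal, secondary, dict(T0.leaf_labels)


def _find_cycle(principal, secondary) -> tuple[Arc, ...] | None:
    g = nx.DiGraph()
    g.add_edges_from(principal)
    g.add_edges_from(secondary)
    try:
        cyc = nx.find_cycle(g, orientation="original")
    except nx.NetworkXNoCycle:
        return None
    return tuple((a, b) for a, b, _ in cyc)


def build_single_arc_network(
    T: PhyloTree, Tp: PhyloTree
) -> LGTNetwork | ConditionFailure:
    """N(T, T'): the unique restricted LGT network with one secondary arc
    whose reduced principal subtree is T and reduced secondary subtree is
    T', or the condition failure explaining why none exists."""
    dec = check_cluster_condition(T, Tp)
    if isinstance(dec, ConditionFailure):
        return dec
    principal, secondary, labels = _assemble(T, [placement_of(dec)])
    return LGTNetwork(principal, secondary, labels)


def reconstruct(
    T0: PhyloTree, secondaries: list[PhyloTree], verify: bool = True
) -> ReconstructionResult:
    """Reconstruct the restricted LGT network with reduced principal
    subtree ``T0`` and reduced secondary subtrees ``secondaries``.

    The input trees must be on a common label set and pairwise different.
    On success the returned network is restricted, acyclic, unique up to
    isomorphism, and (with ``verify``, on by default) re-extraction of its
    reduced subtrees is checked against the inputs.
    """
    all_trees = [T0, *secondaries]
    for t in all_trees[1:]:
        if t.label_set != T0.label_set:
            raise TreeError("all trees must be on the same label set")
    for i, a in enumerate(all_trees):
        for b in all_trees[i + 1:]:
            if trees_equal(a, b):
                raise TreeError("input trees must be pairwise different")

    placements: list[ArcPlacement] = []
    for i, Tp in enumerate(secondaries):
        dec = check_cluster_condition(T0, Tp)
        if isinstance(dec, ConditionFailure):
            return ReconstructionResult(pair_failure=(i, dec))
        placements.append(placement_of(dec))

    principal, secondary, labels = _assemble(T0, placements)
    cycle = _find_cycle(principal, secondary)
    if cycle is not None:
        return ReconstructionResult(cycle=cycle)

    net = LGTNetwork(principal, secondary, labels)
    violations = net.is_restricted()
    if violations:  # unreachable for placements produced above
        raise RuntimeError(f"assembled network is not restricted: {violations}")
    if verify:
        principal_back, secondaries_back = net.reduced_subtrees()
        if not trees_equal(principal_back, T0):
            raise RuntimeError("re-extracted principal subtree differs from input")
        remaining = list(secondaries_back)
        for t in secondaries:
            match = next((s for s in remaining if trees_equal(s, t)), None)
            if match is None:
                raise RuntimeError("re-extracted secondary subtrees differ from inputs")
            remaining.remove(match)
    return ReconstructionResult(network=net)


def strip_to_single_arc(net: LGTNetwork, e: Arc) -> LGTNetwork:
    """Remove every secondary arc except ``e`` and suppress the nodes made
    elementary by the removals.  For a restricted network the result equals
    N(T, T') for the corresponding reduced pair (minimality of the
    single-arc network)."""
    e = (int(e[0]), int(e[1]))
    if e not in net.secondary_arcs:
        raise TreeError(f"{e} is not a secondary arc of the network")
    children = {u: list(cs) for u in net.nodes
                for cs in [list(net.principal_children(u))]}
    parent = {c: u for u, cs in children.items() for c in cs}
    root = net.root
    keep_secondary = {e}

    def total_outdeg(u: int) -> int:
        return len(children[u]) + sum(1 for a, _ in keep_secondary if a == u)

    changed = True
    while changed:
        changed = False
        for u in list(children):
            if u in e:  # endpoints of the kept arc are never elementary here
                continue
            if total_outdeg(u) != 1 or not children[u]:
                continue
            (c,) = children[u]
            if u == root:
                del children[u]
                del parent[c]
                root = c
            else:
                p = parent[u]
                children[p][children[p].index(u)] = c
                parent[c] = p
                del children[u]
                del parent[u]
            changed = True
    principal = [(u, c) for u, cs in children.items() for c in cs]
    return LGTNetwork(principal, keep_secondary, net.leaf_labels)
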