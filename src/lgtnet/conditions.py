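"""The principal--secondary compatibility conditions.

Given a candidate principal tree ``T`` and a candidate secondary tree
``T'`` on the same taxa, these checks decide whether a single lateral
transfer arc can explain their difference (i.e. whether some restricted LGT
network has ``T`` as reduced principal subtree and ``T'`` as reduced
secondary subtree), and if so where the transfer attaches.

Two equivalent formulations are implemented:

* the *cluster* condition (:func:`check_cluster_condition`): the symmetric
  difference of the cluster sets must decompose into at most two maximal
  disjoint segments (chains in the inclusion poset) on each side, whose
  extremes satisfy a small list of set-algebra identities.  This is the
  fast, O(n^2) route, and it directly yields the transfer placement: the
  target is the node of ``T`` whose cluster is the common intersection
  ``B``, and the source is either the node with cluster ``C_l`` or a fresh
  node subdividing the arc above it.
* the *triple* condition (:func:`triple_condition`): every rooted triple of
  ``T`` and ``T'`` must follow one of five patterns determined by a derived
  partition of the taxa.  This is the O(n^3)+ verification route, used to
  cross-check the cluster decomposition.

The decomposition, when it exists, is unique: both assignments of the
difference segments to the two chain roles are tried, and exactly one may
pass.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

from .trees import PhyloTree, Triple, TreeError, trees_equal, triple_of

Cluster = frozenset[str]

_LETTERS = "abcdef"


@dataclass(frozen=True)
class ConditionFailure:
    """First violated condition (letter ``a``..``f``) with a witness note."""

    condition: str
    witness: str

    def report(self) -> str:
        return f"FAIL {self.condition} {self.witness}"


@dataclass(frozen=True)
class SegmentDecomposition:
    """The chains into which the cluster symmetric difference decomposes.

    ``U_chain`` (U_1 ⊋ ... ⊋ U_k) and ``W_chain`` (W_1 ⊋ ... ⊋ W_{l0}) are
    the segments of C(T) \\ C(T'); ``Uprime_chain`` and ``Wprime_chain``
    the segments of C(T') \\ C(T).  All chains are stored largest-first;
    ``W_chain`` and ``Uprime_chain`` may be empty.

    Derived placement: ``B`` is the cluster of the transfer target in T;
    ``C_l`` locates the source.  ``source_is_new`` is True when the source
    is a fresh node subdividing the arc of T ending at the ``C_l`` node
    (the arc-regraft case, C_l in C(T')), and False when the source is the
    existing ``C_l`` node itself (the node-regraft case).
    """

    U_chain: tuple[Cluster, ...]
    W_chain: tuple[Cluster, ...]
    Uprime_chain: tuple[Cluster, ...]
    Wprime_chain: tuple[Cluster, ...]
    B: Cluster
    A_k: Cluster
    C_l: Cluster
    source_is_new: bool

    @property
    def k(self) -> int:
        return len(self.U_chain)

    @property
    def l(self) -> int:
        return len(self.Wprime_chain)

    @property
    def k0(self) -> int:
        return len(self.Uprime_chain)

    @property
    def l0(self) -> int:
        return len(self.W_chain)

    @property
    def source_kind(self) -> str:
        return "subdivide_arc" if self.source_is_new else "existing_node"

    def summary(self) -> str:
        fmt = lambda c: "{%s}" % ",".join(sorted(c))
        return (f"B={fmt(self.B)} C_l={fmt(self.C_l)} {self.source_kind}")


@dataclass(frozen=True)
class TriplePartition:
    """The taxon blocks A_1..A_k, B, C_1..C_{l-1}, C_{l,1}..C_{l,m} driving
    the triple-level patterns.  Blocks are non-empty and pairwise disjoint;
    their union need not be all of S."""

    A_parts: tuple[Cluster, ...]
    B: Cluster
    C_parts: tuple[Cluster, ...]
    C_l_parts: tuple[Cluster, ...]


class AmbiguousDecompositionError(RuntimeError):
    """Both role assignments passed: contradicts uniqueness and indicates
    an internal inconsistency."""


# ---------------------------------------------------------------------------
# segment extraction
# ---------------------------------------------------------------------------

def _maximal_segments(diff: set[Cluster], tree: PhyloTree) -> list[list[Cluster]] | None:
    """Decompose ``diff`` (a subset of the tree's clusters) into maximal
    segments of the cluster poset of ``tree``.

    In a phylogenetic tree the cluster poset *is* the tree, so a segment is
    a run of clusters along a root-ward path with no gaps.  Clusters are
    linked when they are parent/child in the tree and both in ``diff``;
    returns ``None`` when some component branches (not a chain).
    """
    if not diff:
        return []
    clus = tree.node_clusters()
    node_of = {clus[u]: u for u in tree.nodes}
    child_link: dict[Cluster, list[Cluster]] = {}
    parent_in_diff: dict[Cluster, Cluster] = {}
    for c in diff:
        p = tree.parent(node_of[c])
        if p is not None and clus[p] in diff:
            child_link.setdefault(clus[p], []).append(c)
            parent_in_diff[c] = clus[p]
    if any(len(v) > 1 for v in child_link.values()):
        return None
    heads = sorted((c for c in diff if c not in parent_in_diff),
                   key=lambda c: (-len(c), sorted(c)))
    segments = []
    for head in heads:
        chain = [head]
        while chain[-1] in child_link:
            chain.append(child_link[chain[-1]][0])
        segments.append(chain)
    return segments


# ---------------------------------------------------------------------------
# the cluster condition
# ---------------------------------------------------------------------------

def _fmt(c: Cluster) -> str:
    return "{%s}" % ",".join(sorted(c))


def _try_assignment(CT, CTp, U, W, Uq, Wq):
    """Check conditions (a)-(f) for one role assignment of the segments.

    Returns a SegmentDecomposition on success, a ConditionFailure naming
    the first violated condition otherwise.
    """
    k, l0, k0, l = len(U), len(W), len(Uq), len(Wq)
    if k < 1 or l < 1:
        return ConditionFailure("a", f"k={k}, l={l}: both a U and a W' segment are required")
    if not (l - 1 <= l0 <= l):
        return ConditionFailure("a", f"l={l} but W segment has length {l0}")
    if not (k - 1 <= k0 <= k):
        return ConditionFailure("a", f"k={k} but U' segment has length {k0}")
    if W and U[0] & W[0]:
        return ConditionFailure("b", f"U_1={_fmt(U[0])} meets W_1={_fmt(W[0])}")
    if Uq and Uq[0] & Wq[0]:
        return ConditionFailure("b", f"U'_1={_fmt(Uq[0])} meets W'_1={_fmt(Wq[0])}")
    B = U[-1] & Wq[-1]
    if B not in CT or B not in CTp:
        return ConditionFailure("c", f"U_k ∩ W'_l = {_fmt(B)} is not a common cluster")
    A_k = U[-1] - B
    if A_k not in CTp:
        return ConditionFailure("d", f"A_k={_fmt(A_k)} not a cluster of T'")
    if k0 == k - 1 and A_k not in CT:
        return ConditionFailure("d", f"A_k={_fmt(A_k)} not a cluster of T")
    if k0 == k and not (Uq[-1] == A_k and A_k not in CT):
        return ConditionFailure("d", f"U'_k should equal A_k={_fmt(A_k)} and be new in T'")
    C_l = Wq[-1] - B
    if C_l not in CT:
        return ConditionFailure("e", f"C_l={_fmt(C_l)} not a cluster of T")
    if l0 == l - 1 and C_l not in CTp:
        return ConditionFailure("e", f"C_l={_fmt(C_l)} not a cluster of T'")
    if l0 == l and not (W[-1] == C_l and C_l not in CTp):
        return ConditionFailure("e", f"W_l should equal C_l={_fmt(C_l)} and be absent from T'")
    if k > 1:
        if not A_k < Uq[k - 2]:
            return ConditionFailure("f", f"A_k={_fmt(A_k)} not strictly inside U'_{k-1}")
        Uq_ext = list(Uq) + ([A_k] if k0 == k - 1 else [])
        for i in range(k - 1):
            if U[i] - U[i + 1] != Uq_ext[i] - Uq_ext[i + 1]:
                return ConditionFailure(
                    "f", f"U_{i+1}\\U_{i+2} differs from U'_{i+1}\\U'_{i+2}")
    if l > 1:
        if not C_l < W[l - 2]:
            return ConditionFailure("f", f"C_l={_fmt(C_l)} not strictly inside W_{l-1}")
        W_ext = list(W) + ([C_l] if l0 == l - 1 else [])
        for i in range(l - 1):
            if W_ext[i] - W_ext[i + 1] != Wq[i] - Wq[i + 1]:
                return ConditionFailure(
                    "f", f"W_{i+1}\\W_{i+2} differs from W'_{i+1}\\W'_{i+2}")
    return SegmentDecomposition(
        U_chain=tuple(U), W_chain=tuple(W),
        Uprime_chain=tuple(Uq), Wprime_chain=tuple(Wq),
        B=B, A_k=A_k, C_l=C_l,
        source_is_new=(l0 == l - 1),
    )


def check_cluster_condition(
    T: PhyloTree, Tp: PhyloTree
) -> SegmentDecomposition | ConditionFailure:
    """Decide the principal--secondary condition on clusters.

    Returns the (unique) :class:`SegmentDecomposition` when ``T`` and
    ``Tp`` can be the reduced principal and secondary subtrees of a
    restricted LGT network with one secondary arc, or a
    :class:`ConditionFailure` naming the first violated condition.

    Raises :class:`TreeError` when the trees are on different label sets or
    are equal (the condition presupposes differing trees), and
    :class:`AmbiguousDecompositionError` if both role assignments were to
    pass (impossible for correct inputs; uniqueness of the decomposition).
    """
    if T.label_set != Tp.label_set:
        raise TreeError("trees are on different label sets")
    if trees_equal(T, Tp):
        raise TreeError("trees are equal: empty cluster symmetric difference")
    CT, CTp = T.cluster_set(), Tp.cluster_set()
    D, Dp = set(CT - CTp), set(CTp - CT)

    segs = _maximal_segments(D, T)
    if segs is None or len(segs) > 2:
        return ConditionFailure(
            "a", "C(T)\\C(T') is not a union of at most two disjoint segments")
    segs_p = _maximal_segments(Dp, Tp)
    if segs_p is None or len(segs_p) > 2:
        return ConditionFailure(
            "a", "C(T')\\C(T) is not a union of at most two disjoint segments")

    # the U chain and the W' chain are mandatory; when a side has two
    # segments, either may play either role -- try all assignments
    if len(segs) == 0:
        return ConditionFailure("a", "C(T)\\C(T') is empty: no U segment")
    if len(segs_p) == 0:
        return ConditionFailure("a", "C(T')\\C(T) is empty: no W' segment")
    uw_options = [(segs[0], [])] if len(segs) == 1 else [
        (segs[0], segs[1]), (segs[1], segs[0])]
    wq_options = [([], segs_p[0])] if len(segs_p) == 1 else [
        (segs_p[0], segs_p[1]), (segs_p[1], segs_p[0])]

    successes: list[SegmentDecomposition] = []
    failures: list[ConditionFailure] = []
    for U, W in uw_options:
        for Uq, Wq in wq_options:
            res = _try_assignment(CT, CTp, U, W, Uq, Wq)
            if isinstance(res, SegmentDecomposition):
                successes.append(res)
            else:
                failures.append(res)
    if len(successes) == 1:
        return successes[0]
    if len(successes) > 1:
        raise AmbiguousDecompositionError(
            "more than one segment assignment satisfies the condition")
    return max(failures, key=lambda f: _LETTERS.index(f.condition))


def cluster_condition(T: PhyloTree, Tp: PhyloTree) -> SegmentDecomposition:
    """Like :func:`check_cluster_condition` but raises on failure."""
    res = check_cluster_condition(T, Tp)
    if isinstance(res, ConditionFailure):
        raise TreeError(res.report())
    return res


# ---------------------------------------------------------------------------
# the triple condition
# ---------------------------------------------------------------------------

def derive_triple_partition(dec: SegmentDecomposition, T: PhyloTree) -> TriplePartition:
    """The taxon blocks determined by a segment decomposition.

    ``A_i = U_i \\ U_{i+1}`` (with ``A_k = U_k \\ B``) descend the path to
    the transfer target; ``C_i = W'_i \\ W'_{i+1}`` (with ``C_l = W'_l \\ B``)
    descend the path to the source.  When the source is an existing node of
    ``T``, ``C_l`` splits further into the clusters of that node's children.
    """
    U, Wq = dec.U_chain, dec.Wprime_chain
    A = [U[i] - U[i + 1] for i in range(len(U) - 1)] + [dec.A_k]
    C = [Wq[i] - Wq[i + 1] for i in range(len(Wq) - 1)]
    if dec.source_is_new:
        C_l_parts: tuple[Cluster, ...] = (dec.C_l,)
    else:
        src = T.node_with_cluster(dec.C_l)
        clus = T.node_clusters()
        C_l_parts = tuple(sorted((clus[c] for c in T.children(src)),
                                 key=lambda c: sorted(c)))
    return TriplePartition(tuple(A), dec.B, tuple(C), C_l_parts)


def _label_regions(dec: SegmentDecomposition, T: PhyloTree) -> dict[str, tuple]:
    """Assign each taxon its position relative to the transfer paths in T.

    Let h be the B node, ``src`` the C_l node, and v their LCA (the lowest
    node above both attachment points).  Regions are

    * ``("B", 0, 0)`` -- inside the transferred subtree;
    * ``("A", i, j)`` -- in the j-th off-path child subtree of the i-th
      node on the path v -> h (i = 1 topmost);
    * ``("C", i, j)`` -- likewise on the path v -> src, where position l
      is src itself: its child subtrees are separate blocks when the
      source is the existing node, one single block when the source
      subdivides the arc above src (the subtree then moves wholesale);
    * ``("J", 0, 0)`` -- under another child of the junction v;
    * ``("O", 0, 0)`` -- outside the subtree of v (unaffected).
    """
    clus = T.node_clusters()
    h = T.node_with_cluster(dec.B)
    src = T.node_with_cluster(dec.C_l)
    v = T.lca(h, src)
    # path v -> h, strict intermediates top-down: clusters must match U_chain
    u_path = [x for x in reversed(T.ancestors(h)[1:]) if T.is_strict_descendant(x, v)]
    if tuple(clus[x] for x in u_path) != dec.U_chain:  # pragma: no cover
        raise AmbiguousDecompositionError("U chain does not match the tree path")
    # path v -> src inclusive of src: positions 1..l
    w_path = [x for x in reversed(T.ancestors(src)) if T.is_strict_descendant(x, v)]
    w_clusters = (dec.W_chain if dec.l0 == dec.l
                  else dec.W_chain + (dec.C_l,))
    if tuple(clus[x] for x in w_path) != w_clusters:  # pragma: no cover
        raise AmbiguousDecompositionError("W chain does not match the tree path")

    region: dict[str, tuple] = {}
    for x in T.label_set:
        region[x] = ("O", 0, 0)
    for x in clus[v]:
        region[x] = ("J", 0, 0)
    for i, node in enumerate(u_path, start=1):
        on_path = u_path[i] if i < len(u_path) else h
        for j, c in enumerate(T.children(node), start=1):
            if c == on_path:
                continue
            for x in clus[c]:
                region[x] = ("A", i, j)
    for i, node in enumerate(w_path, start=1):
        if i < len(w_path):
            on_path = w_path[i]
            for j, c in enumerate(T.children(node), start=1):
                if c == on_path:
                    continue
                for x in clus[c]:
                    region[x] = ("C", i, j)
        elif dec.source_is_new:
            for x in clus[node]:
                region[x] = ("C", len(w_path), 0)
        else:
            for j, c in enumerate(T.children(node), start=1):
                for x in clus[c]:
                    region[x] = ("C", len(w_path), j)
    for x in dec.B:
        region[x] = ("B", 0, 0)
    return region


def _expected_pair(region, labs: tuple[str, str, str]
                   ) -> tuple[Triple, Triple] | None:
    """Expected (T, T') triples for one 3-set, or None when they must
    simply agree.

    A single transfer moves the B subtree from below the last node of the
    target path to the source; only triples with exactly one taxon inside
    B and at least one taxon hanging off the two paths (or the junction)
    can change.  The catalogue below covers the multifurcating case: two
    taxa at the *same* path position but in different child subtrees see
    their triple switch between a cherry and the star, and a taxon under a
    third child of the junction resolves against B on exactly one side.
    """
    three = frozenset(labs)
    b_labs = [x for x in labs if region[x][0] == "B"]
    if len(b_labs) != 1:
        return None
    (b,) = b_labs
    x, y = (t for t in labs if t != b)
    (kx, px, bx), (ky, py, by) = region[x], region[y]
    if {kx, ky} == {"A", "C"}:
        a_lab, c_lab = (x, y) if kx == "A" else (y, x)
        return (Triple(three, frozenset({a_lab, b})),
                Triple(three, frozenset({c_lab, b})))
    if kx == ky == "A":
        if px != py:
            deep, shallow = (x, y) if px > py else (y, x)
            return (Triple(three, frozenset({deep, b})),
                    Triple(three, frozenset({x, y})))
        if bx != by:
            return (Triple(three, None), Triple(three, frozenset({x, y})))
        return None
    if kx == ky == "C":
        if px != py:
            deep = x if px > py else y
            return (Triple(three, frozenset({x, y})),
                    Triple(three, frozenset({deep, b})))
        if bx != by:
            return (Triple(three, frozenset({x, y})), Triple(three, None))
        return None
    if {kx, ky} == {"A", "J"}:
        a_lab = x if kx == "A" else y
        return (Triple(three, frozenset({a_lab, b})), Triple(three, None))
    if {kx, ky} == {"C", "J"}:
        c_lab = x if kx == "C" else y
        return (Triple(three, None), Triple(three, frozenset({c_lab, b})))
    return None


def triple_condition(T: PhyloTree, Tp: PhyloTree) -> bool:
    """Decide the principal--secondary condition on triples.

    True iff the cluster condition holds *and* every rooted triple of the
    two trees follows the pattern dictated by the taxon regions around the
    two transfer paths (all other triples coinciding).  Equal trees yield
    False.  Equivalent to :func:`check_cluster_condition` succeeding and
    to the existence of a placement-compliant rSPR witness.
    """
    if T.label_set != Tp.label_set:
        raise TreeError("trees are on different label sets")
    if trees_equal(T, Tp):
        return False
    dec = check_cluster_condition(T, Tp)
    if isinstance(dec, ConditionFailure):
        return False
    region = _label_regions(dec, T)
    for labs in itertools.combinations(sorted(T.label_set), 3):
        got_T = triple_of(T, labs)
        got_Tp = triple_of(Tp, labs)
        expected = _expected_pair(region, labs)
        if expected is None:
            if got_T != got_Tp:
                return False
        elif (got_T, got_Tp) != expected:
            return False
    return True
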