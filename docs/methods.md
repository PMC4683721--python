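# Methods

## Model

An LGT network on a taxon set `S` is a rooted DAG `N = (V, E)` without
elementary (out-degree-1) nodes, with its leaves bijectively labelled by
`S`, together with a partition `E = E_p ⊔ E_s` such that the principal
arcs `(V, E_p)` form a rooted tree `T₀(N)` spanning `V` whose leaves are
exactly the leaves of `N`. Every reticulation therefore has exactly one
principal parent; a secondary arc `(u, h)` models a transfer from the
lineage of `u` into the lineage entering `h`. Nodes are species: the model
is topology-only (no branch lengths, no times), and elementary nodes are
excluded because a species with a single descendant is indistinguishable
from that descendant on topological evidence alone. Within the principal
tree, however, elementary nodes are allowed and meaningful — they are the
donor positions created on an arc (*subdivision nodes*), and each must
source at least one secondary arc (otherwise it would be elementary in the
full digraph).

A secondary subtree `T_e(N)` re-parents the target of `e` under its donor;
*reduction* (recursively deleting unlabelled leaves, then suppressing
elementary nodes, an elementary root being deleted with its arc) turns the
principal and secondary subtrees into phylogenetic trees. Reduction
preserves the induced rooted triples, so trees are compared throughout by
their cluster sets (equivalently, their triple sets).

## Restrictedness

Four conditions define the *restricted* class on which reconstruction is
well posed:

(a) no principal child of a principally elementary node is principally
elementary (no stacked subdivision nodes); (b) the target of a secondary
arc is never principally elementary; (c) no secondary arc runs to a
principal descendant of its source; (d) for a secondary arc `(u, h)`, the
principal path from `LCA_{T₀}(u, h)` to `h` contains a strict intermediate
node that is not principally elementary. "Intermediate" excludes both
endpoints — condition (d) in particular rules out transfers whose target
hangs directly under the junction, which would be unrecoverable from the
reduced trees. Under (a)–(d) the reduced subtrees are pairwise different
and determine the network up to isomorphism; both facts are exercised as
properties of the generator output rather than assumed.

## Deciding one pair

Given candidate principal tree `T` and secondary tree `T'` (same taxa,
different trees), three equivalent characterizations of "one transfer
apart" are implemented:

1. **Clusters** (`check_cluster_condition`, the O(n²) route used by the
   reconstruction). Since the cluster poset of a phylogenetic tree *is*
   the tree, the difference `C(T) \ C(T')` must decompose into at most two
   maximal segments (runs of parent–child clusters); likewise
   `C(T') \ C(T)`. One segment per side is mandatory (the `U` chain of
   length `k ≥ 1` and the `W'` chain of length `l ≥ 1`), the other two are
   optional with lengths `l₀ ∈ {l−1, l}` and `k₀ ∈ {k−1, k}`. The chain
   extremes must satisfy a short list of set identities: `B = U_k ∩ W'_l`
   is a common cluster (the transfer target's cluster), `A_k = U_k \ B`
   and `C_l = W'_l \ B` locate the flanks, and consecutive chain
   differences must agree between the two sides. `l₀ = l−1` means the
   source is a fresh node subdividing the arc of `T` above the `C_l` node
   (the donor is an unsampled position on that branch); `l₀ = l` means the
   source is the `C_l` node itself.
2. **rSPR** (`witness_rspr`): `T'` is reachable from `T` by a single
   generalized rooted subtree-prune-and-regraft move — generalized because
   trees may be multifurcating, so regrafting may target an existing
   internal node (raising its degree) or splice a new node above any node.
   The witness must additionally have its regraft point neither an
   ancestor of the pruned node nor a descendant of the pruned node's
   parent; a move violating this corresponds to a network breaking (c) or
   (d). The distance-1 decision is by brute-force enumeration of all
   O(n²) moves with deduplication by cluster set; general rSPR distance is
   NP-hard and out of scope.
3. **Triples** (`triple_condition`, the O(n³) verification route). Each
   taxon is assigned a region relative to the two attachment paths in `T`:
   inside the transferred clade `B`; in the j-th off-path subtree of the
   i-th node on the path junction→target (`A` regions); likewise on the
   path junction→source (`C` regions, the source node's own child subtrees
   forming separate blocks exactly when the source is an existing node);
   under another child of the junction; or outside the junction's subtree.
   Only triples containing exactly one `B` taxon can change, and the
   catalogue of changes is fully determined by the two non-`B` regions.
   Two points deserve emphasis because a naive catalogue misses them on
   multifurcating trees: two taxa at the *same* path position but in
   different child subtrees see their triple with a `B` taxon flip between
   the star and a cherry, and a taxon under a third child of the junction
   resolves against `B` on exactly one side of the move. With these
   patterns included, the triple condition agrees with the cluster
   condition and the compliant-witness criterion on every pair tested
   (hundreds of seeded random pairs, mixed independent and one-move-apart,
   up to 8 taxa).

When the cluster difference admits two segments on a side, which segment
plays which role is not known a priori; all (at most four) assignments are
tried and exactly one may pass — uniqueness of the decomposition is a
theorem for correct inputs, and the implementation raises
`AmbiguousDecompositionError` rather than picking silently if it were ever
violated. On failure the report names the first violated condition of the
assignment that progressed furthest (letters `a`–`f` in the order the
conditions are stated), which matches the natural diagnosis on the bundled
negative example.

## Multi-tree reconstruction

Each secondary tree contributes one placement (target cluster `B`, source
cluster `C_l`, subdivide-or-existing flag). Placements are merged:
all subdivide-placements on the same arc of `T₀` share a single
subdivision node — never two stacked nodes, enforcing (a) by construction
— while existing-node placements attach where they point. After adding all
secondary arcs the full digraph is tested for acyclicity; a directed cycle
is returned as the outcome (no restricted network exists), otherwise the
network is validated against the full invariant set and, by default,
verified by re-extracting its reduced subtrees and comparing them with the
inputs (`verify=False` disables this self-check). Placements are processed
in a canonical order and the result is independent of the input order of
the secondary trees, which the tests check over all permutations.

Minimality: deleting all secondary arcs but one and suppressing the nodes
so orphaned (`strip_to_single_arc`) yields exactly the single-arc network
built directly from the corresponding reduced pair; this is checked on all
generated (network, arc) samples.

## Determinism and canonical forms

All serialization is canonical: children are ordered by the smallest label
in their (principal) cluster — well defined because sibling clusters in an
S-tree are disjoint and non-empty — and network node ids are assigned by a
DFS in that order, so isomorphic networks print identically and
isomorphism is a tuple comparison of canonical forms (an S-tree has no
non-trivial label-preserving automorphism). Newick input is parsed
literally (dendropy): redundant parentheses become elementary nodes that
survive until an explicit reduction, which is how the bundled secondary
tree `T₃` (printed with an extra parenthesis pair) is handled; branch
lengths are ignored and internal labels discarded.

## Synthetic generator

`random_restricted_network(GeneratorConfig(n_leaves, n_secondary, seed))`
draws the principal tree by sequential random leaf attachment onto a
uniformly chosen arc or internal node — deliberately producing
multifurcations, since the condition machinery has branches that binary
trees never exercise. Secondary arcs are then placed by rejection
sampling: a candidate source (a new subdivision of a random arc, or a
random internal node, including re-use of an existing donor node) and a
random target are accepted only if the whole network remains a valid,
acyclic, restricted LGT network. A drawn tree may admit no valid placement
at all (a star tree admits none), so rejection extends to redrawing the
tree; `max_attempts` (default 2000) bounds the tree draws with 50
placement attempts per arc within each draw, and exhaustion raises
`GenerationError`. Generation is a pure function of the config.

The generator emulates topology only: uniform attachment is not a
biological branching model, there are no branch lengths, no time
consistency between donor and recipient, and no calibrated transfer rate.
Passing tests therefore demonstrate the combinatorial correctness of the
reconstruction on its intended domain, not inference accuracy on real gene
trees, where estimation error and rooting uncertainty would dominate.

## Problem sizes in the test suite

The default suite runs the nine-taxon worked example exactly as printed;
round-trip reconstruction on 200 seeded random restricted networks with up
to 12 leaves and up to 3 secondary arcs, under every permutation of the
secondary trees; and the three-way equivalence on 500 random pairs with up
to 8 leaves plus strip-vs-direct minimality on 40 generated networks.
These sizes keep the full suite in the tens of seconds while covering both
source kinds, multifurcations and all failure modes.

## Limitations

- Inputs must be rooted, on identical taxon sets, and pairwise different;
  relaxations (partial taxon overlap, equal secondary trees, minimizing
  transfers when the restricted problem fails) are out of scope.
- Only the distance-≤1 rSPR question is answered.
- The arc-list network format and the Newick dialect are deliberately
  minimal: no branch lengths, no support values, no extended-Newick hybrid
  syntax.
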