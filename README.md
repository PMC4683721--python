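# lgtnet

Reconstruction of **restricted LGT networks** — phylogenetic networks with
lateral (horizontal) gene transfers — from a set of incongruent rooted
phylogenetic trees.

## The problem

Lateral gene transfer (LGT) is an asymmetric event: the recipient species
inherits most of its genome from its *principal* parent and acquires some
genes from a donor. An **LGT network** makes this asymmetry explicit: it is
a rooted DAG `N = (V, E)` whose arcs are partitioned into *principal* arcs
`E_p`, forming a rooted tree `T₀(N)` spanning every node with leaves
bijectively labelled by the taxa, and *secondary* arcs `E_s`, one per
transfer, pointing from the donor lineage towards the recipient. Each
secondary arc `e = (u, h)` defines a *secondary subtree* `T_e(N)` by
swapping `e` for the principal arc into `h`; suppressing out-degree-1 nodes
and unlabelled leaves (*reduction*, written `T̃`) turns the principal and
secondary subtrees into ordinary phylogenetic trees — the evolutionary
history of most genes and the histories seen by horizontally transferred
genes.

The reconstruction problem runs the other way: given pairwise different
phylogenetic trees `T₀, T₁, …, T_k` on the same taxa, find an LGT network
whose reduced principal subtree is `T₀` and whose reduced secondary
subtrees are exactly `T₁, …, T_k`. In general the solution is neither
unique nor well behaved, so the search is restricted to networks obeying
four structural conditions (no stacked out-degree-1 nodes on the principal
tree, no transfer into an out-degree-1 node, no transfer to a principal
descendant, and a non-trivial path between the attachment points). For this
*restricted* class the reduced subtrees are pairwise different and
determine the network **uniquely up to isomorphism**.

The algorithm decides each pair `(T₀, Tᵢ)` by a segment decomposition of
the symmetric difference of their cluster sets `C(T₀) Δ C(Tᵢ)`: at most two
maximal chain segments per side whose extremes yield the transfer target
(the node of `T₀` with cluster `B`) and source (the node with cluster
`C_l`, or a new node subdividing the arc above it). Equivalently, the pair
must be one generalized rooted subtree-prune-and-regraft (rSPR) move apart,
with the regraft point neither an ancestor of the pruned node nor a
descendant of its parent; a third, triple-level characterization is also
implemented and all three are cross-checked in the test suite. Placements
are then merged (transfers from a common origin share one subdivision
node) and the assembled digraph is tested for acyclicity — a directed
cycle proves that no restricted network exists for the input.

## Worked example

A nine-taxon example of Rhodobacterales gene trees (taxa 1–9 are
Roseobacter, Ruegeria, Dinoroseobacter, Paracoccus and four *Rhodobacter
sphaeroides* strains; see `lgtnet.examples.RHODOBACTER_ORGANISMS`) ships
with the package. With the four trees in Newick files:

```sh
$ lgt check-pair T0.nwk T1.nwk
B={3} C_l={2} subdivide_arc
```

— the pair is explainable by a single transfer whose target is taxon 3 and
whose source is a new node subdividing the arc above taxon 2.

```sh
$ lgt reconstruct T0.nwk T1.nwk T2.nwk T3.nwk -o net.lgt
$ lgt extract net.lgt
(((1,2),(3,4)),(5,(6,(7,(8,9)))));
((((1,3),2),4),(5,(6,(7,(8,9)))));
(((1,(2,3)),4),(5,(6,(7,(8,9)))));
(((1,2),3),(4,(5,(6,(7,(8,9))))));
```

`net.lgt` holds the unique restricted LGT network for these trees: the
principal tree plus three secondary arcs (from subdivision nodes above
leaves 1 and 2, both targeting leaf 3, and from a subdivision node above
the *Rhodobacter* clade {5,…,9} targeting leaf 4). The extracted lines are
the reduced principal subtree followed by the three reduced secondary
subtrees — the four input trees, re-derived from the network.

Failure modes are reported with stable exit codes: a pair violating the
compatibility conditions exits 2 (`FAIL <condition> <witness>`), and
transfers that force a directed cycle exit 3. `lgt simulate` draws seeded
random restricted networks for experimentation, `lgt validate` and
`lgt isomorphic` inspect network files.

The same operations are available as library functions
(`lgtnet.reconstruct`, `lgtnet.check_cluster_condition`,
`lgtnet.rspr_distance_leq_one`, …).

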