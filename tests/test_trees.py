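"""Core tree model: Newick I/O, clusters, triples, restriction, reduction."""

import itertools
import random
import string

import pytest
from hypothesis import given, settings, strategies as st

from lgtnet import (
    PartialTree,
    TreeError,
    enumerate_trees,
    parse_newick,
    parse_phylo,
    reduce_tree,
    restrict,
    tree_from_clusters,
    trees_equal,
    triple_of,
    triples,
    write_newick,
)
from lgtnet.synthetic import random_phylo_tree

T0_NEWICK = "(((((9,8),7),6),5),((4,3),(1,2)));"


def f(*labels):
    return frozenset(str(x) for x in labels)


class TestParseNewick:
    def test_simple_cherry_clusters(self):
        t = parse_newick("((x,y),z);")
        nontrivial = {c for c in t.cluster_set() if len(c) > 1}
        assert nontrivial == {f("x", "y"), f("x", "y", "z")}

    def test_nine_leaf_tree_root_children(self):
        t = parse_newick(T0_NEWICK)
        clus = t.node_clusters()
        kids = {clus[c] for c in t.children(t.root)}
        assert kids == {f(5, 6, 7, 8, 9), f(1, 2, 3, 4)}

    def test_redundant_parentheses_kept_as_elementary_nodes(self):
        t = parse_newick("((x));")
        # root -> elementary node -> leaf x
        assert len(t.nodes) == 3
        assert t.is_elementary(t.root)
        (mid,) = t.children(t.root)
        assert t.is_elementary(mid)

    @pytest.mark.parametrize("bad", ["", "   ", "((a,b);", "(a,(b,c);"])
    def test_malformed_input_rejected(self, bad):
        with pytest.raises(TreeError):
            parse_newick(bad)

    def test_duplicate_labels_rejected(self):
        with pytest.raises(TreeError):
            parse_newick("((a,b),a);")

    def test_branch_lengths_and_internal_labels_ignored(self):
        t = parse_phylo("((a:1.5,b:0.2)inner:3,c:1);")
        assert trees_equal(t, parse_phylo("((a,b),c);"))


class TestWriteNewick:
    def test_canonical_cherry(self):
        assert write_newick(parse_phylo("(z,(y,x));")) == "((x,y),z);"

    def test_cherry_fixed_point(self):
        assert write_newick(parse_phylo("(a,b);")) == "(a,b);"

    def test_round_trip_preserves_clusters(self):
        t = parse_phylo(T0_NEWICK)
        back = parse_phylo(write_newick(t))
        assert back.cluster_set() == t.cluster_set()

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(st.integers(0, 10**6), st.integers(3, 9))
    def test_round_trip_random_trees(self, seed, n):
        t = random_phylo_tree(random.Random(seed), list(string.ascii_lowercase[:n]))
        assert trees_equal(parse_phylo(write_newick(t)), t)


class TestClusters:
    def test_application_tree_nonsingleton_clusters(self):
        t = parse_phylo(T0_NEWICK)
        nontrivial = {c for c in t.cluster_set() if len(c) > 1}
        assert nontrivial == {
            f(8, 9), f(7, 8, 9), f(6, 7, 8, 9), f(5, 6, 7, 8, 9),
            f(3, 4), f(1, 2), f(1, 2, 3, 4), f(1, 2, 3, 4, 5, 6, 7, 8, 9),
        }

    def test_cherry_clusters_include_singletons(self):
        t = parse_phylo("(a,b);")
        assert t.cluster_set() == {f("a"), f("b"), f("a", "b")}

    def test_elementary_chain_clusters_collapse(self):
        t = parse_newick("((x));")
        assert t.cluster_set() == {f("x")}


class TestRestrictAndTriples:
    def test_identity_restriction(self):
        t = parse_phylo(T0_NEWICK)
        assert trees_equal(restrict(t, t.label_set), t)

    def test_restriction_to_three_labels(self):
        t = parse_phylo(T0_NEWICK)
        r = restrict(t, {"1", "2", "3"})
        assert {c for c in r.cluster_set() if len(c) > 1} == {f(1, 2), f(1, 2, 3)}

    def test_triples_of_application_tree(self):
        t = parse_phylo(T0_NEWICK)
        assert triple_of(t, {"1", "2", "3"}).cherry == f(1, 2)
        assert triple_of(t, {"3", "4", "5"}).cherry == f(3, 4)

    def test_star_triple(self):
        assert triple_of(parse_phylo("(x,y,z);"), "xyz").cherry is None

    def test_triple_matches_restriction_shape(self):
        t = parse_phylo(T0_NEWICK)
        for labs in itertools.combinations(sorted(t.label_set), 3):
            r = restrict(t, labs)
            two = {c for c in r.cluster_set() if len(c) == 2}
            expect = next(iter(two)) if two else None
            assert triple_of(t, labs).cherry == expect

    def test_restriction_errors(self):
        t = parse_phylo(T0_NEWICK)
        with pytest.raises(TreeError):
            restrict(t, set())
        with pytest.raises(TreeError):
            restrict(t, {"1", "nope"})


class TestReduce:
    def test_idempotent_on_phylogenetic_tree(self):
        t = parse_phylo(T0_NEWICK)
        assert trees_equal(reduce_tree(t), t)

    def test_elementary_root_chain_suppressed(self):
        assert write_newick(parse_phylo("(((a,b)));")) == "(a,b);"

    def test_unlabelled_leaf_removed(self):
        t0 = parse_newick(T0_NEWICK)
        # hang t0 and an unlabelled leaf under a fresh root
        shift = {u: u + 1 for u in t0.nodes}
        children = {shift[u]: [shift[c] for c in t0.children(u)] for u in t0.nodes}
        unlabelled = max(shift.values()) + 1
        children[0] = [shift[t0.root], unlabelled]
        labels = {shift[u]: lab for u, lab in t0.leaf_labels.items()}
        t = PartialTree(children, labels, root=0)
        assert trees_equal(reduce_tree(t), parse_phylo(T0_NEWICK))

    def test_too_few_labelled_leaves(self):
        with pytest.raises(TreeError):
            reduce_tree(parse_newick("((x));"))

    def test_reduction_preserves_every_triple(self):
        raw = parse_newick("(((a,b)),((c),(d,(e))));")
        red = reduce_tree(raw)
        for labs in itertools.combinations(sorted(red.label_set), 3):
            assert triple_of(raw, labs) == triple_of(red, labs)


class TestEquality:
    def test_reflexive(self):
        t = parse_phylo(T0_NEWICK)
        assert trees_equal(t, t)

    def test_application_trees_differ(self, app_trees):
        t0, secs = app_trees
        for s in secs:
            assert not trees_equal(t0, s)

    def test_child_order_irrelevant(self):
        assert trees_equal(parse_phylo("((x,y),z);"), parse_phylo("(z,(y,x));"))

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(st.integers(0, 10**6))
    def test_equality_iff_same_triples(self, seed):
        rng = random.Random(seed)
        n = rng.randint(3, 7)
        labels = list(string.ascii_lowercase[:n])
        a = random_phylo_tree(rng, labels)
        b = random_phylo_tree(rng, labels)
        assert trees_equal(a, b) == (triples(a) == triples(b))


class TestLCA:
    def test_self(self):
        t = parse_phylo(T0_NEWICK)
        u = t.node_with_label("7")
        assert t.lca(u, u) == u

    def test_application_example(self):
        t = parse_phylo(T0_NEWICK)
        z = t.lca(t.node_with_label("1"), t.node_with_label("4"))
        assert t.node_clusters()[z] == f(1, 2, 3, 4)

    def test_root_dominates(self):
        t = parse_phylo(T0_NEWICK)
        assert t.lca(t.root, t.node_with_label("5")) == t.root


class TestClusterTripleDuality:
    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(0, 10**6))
    def test_cluster_iff_all_triples_resolved(self, seed):
        """A non-empty C is a cluster of T iff ((c,c'),x) is a triple of T
        for every c, c' in C and x outside C (brute force both sides)."""
        rng = random.Random(seed)
        n = rng.randint(3, 6)
        labels = list(string.ascii_lowercase[:n])
        t = random_phylo_tree(rng, labels)
        gamma = triples(t)
        clusters = t.cluster_set()
        for r in range(1, n):
            for combo in itertools.combinations(labels, r):
                c = frozenset(combo)
                holds = all(
                    triple_of(t, {a, b, x}).cherry == frozenset({a, b})
                    for a, b in itertools.combinations(sorted(c), 2)
                    for x in set(labels) - c
                )
                # vacuously true for singletons (always clusters)
                assert holds == (c in clusters)


class TestEnumerationAndClusters:
    @pytest.mark.parametrize("n,count", [(2, 1), (3, 4), (4, 26)])
    def test_tree_counts(self, n, count):
        labs = string.ascii_lowercase[:n]
        trees = list(enumerate_trees(labs))
        assert len(trees) == count
        # pairwise distinct
        seen = {t.cluster_set() for t in trees}
        assert len(seen) == count

    def test_tree_from_clusters_round_trip(self):
        t = parse_phylo(T0_NEWICK)
        assert trees_equal(tree_from_clusters(t.cluster_set()), t)

    def test_non_laminar_rejected(self):
        with pytest.raises(TreeError):
            tree_from_clusters({f("a", "b"), f("b", "c")})
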