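"""LGT network model: validation, subtree extraction, restrictedness,
isomorphism, serialization."""

import itertools

import pytest

from lgtnet import (
    GeneratorConfig,
    LGTNetwork,
    NetworkError,
    networks_isomorphic,
    parse_phylo,
    random_restricted_network,
    reduce_tree,
    rspr_distance_leq_one,
    trees_equal,
)


def plain_tree_network():
    # ((a,b),c) with no transfers
    return LGTNetwork(
        principal_arcs=[(0, 1), (0, 4), (1, 2), (1, 3)],
        secondary_arcs=[],
        leaf_labels={2: "a", 3: "b", 4: "c"},
    )


def one_arc_network():
    # ((a,b),(c,d)) with a subdivision node 5 above a and a transfer 5 -> c
    return LGTNetwork(
        principal_arcs=[(0, 1), (1, 5), (5, 2), (1, 3), (0, 6), (6, 4), (6, 7)],
        secondary_arcs=[(5, 4)],
        leaf_labels={2: "a", 3: "b", 4: "c", 7: "d"},
    )


class TestValidation:
    def test_plain_tree_is_valid(self):
        net = plain_tree_network()
        assert net.label_set == {"a", "b", "c"}

    def test_elementary_node_rejected(self):
        with pytest.raises(NetworkError, match="elementary"):
            LGTNetwork(
                principal_arcs=[(0, 1), (0, 4), (1, 5), (5, 2), (1, 3)],
                secondary_arcs=[],
                leaf_labels={2: "a", 3: "b", 4: "c"},
            )

    def test_two_principal_parents_rejected(self):
        with pytest.raises(NetworkError):
            LGTNetwork(
                principal_arcs=[(0, 1), (0, 2), (1, 2), (1, 3)],
                secondary_arcs=[],
                leaf_labels={2: "a", 3: "b"},
            )

    def test_cycle_rejected(self):
        with pytest.raises(NetworkError, match="cycle"):
            LGTNetwork(
                principal_arcs=[(0, 1), (0, 6), (1, 2), (1, 5), (2, 3), (2, 4),
                                (6, 7), (6, 8)],
                secondary_arcs=[(2, 6), (6, 2)],
                leaf_labels={3: "a", 4: "b", 5: "c", 7: "d", 8: "e"},
            )

    def test_secondary_arc_from_labelled_leaf_rejected(self):
        with pytest.raises(NetworkError, match="leaf"):
            LGTNetwork(
                principal_arcs=[(0, 1), (0, 4), (1, 5), (5, 2), (1, 3)],
                secondary_arcs=[(2, 4)],
                leaf_labels={2: "a", 3: "b", 4: "c"},
            )

    def test_arc_in_both_partitions_rejected(self):
        with pytest.raises(NetworkError):
            LGTNetwork(
                principal_arcs=[(0, 1), (0, 4), (1, 5), (5, 2), (1, 3)],
                secondary_arcs=[(1, 3)],
                leaf_labels={2: "a", 3: "b", 4: "c"},
            )


class TestSubtrees:
    def test_plain_tree_principal_subtree(self):
        net = plain_tree_network()
        t0 = net.principal_subtree()
        assert sorted(t0.arcs()) == sorted(net.principal_arcs)
        principal, secondaries = net.reduced_subtrees()
        assert trees_equal(principal, parse_phylo("((a,b),c);"))
        assert secondaries == []

    def test_principal_subtree_keeps_elementary_nodes(self):
        net = one_arc_network()
        t0 = net.principal_subtree()
        assert any(t0.is_elementary(u) for u in t0.nodes)
        assert trees_equal(reduce_tree(t0), parse_phylo("((a,b),(c,d));"))

    def test_secondary_subtree_is_arc_swap(self):
        net = one_arc_network()
        te = net.secondary_subtree((5, 4))
        assert len(te.nodes) == len(net.nodes)
        assert len(te.arcs()) == len(net.principal_arcs)
        assert trees_equal(reduce_tree(te), parse_phylo("(((a,c),b),d);"))

    def test_secondary_subtree_requires_secondary_arc(self):
        with pytest.raises(NetworkError):
            one_arc_network().secondary_subtree((0, 1))

    def test_leaves_of_principal_subtree_are_network_leaves(self):
        net = one_arc_network()
        t0 = net.principal_subtree()
        assert set(t0.leaves) == set(net.leaf_labels)


class TestRestricted:
    def test_plain_tree_vacuously_restricted(self):
        assert plain_tree_network().is_restricted() == []

    def test_one_arc_network_restricted(self):
        assert one_arc_network().is_restricted() == []

    def test_transfer_to_descendant_violates_c(self):
        # (((a,b),c),d): secondary arc from the {a,b,c} node down to leaf a
        net = LGTNetwork(
            principal_arcs=[(0, 1), (1, 6), (6, 2), (6, 3), (1, 4), (0, 5)],
            secondary_arcs=[(1, 2)],
            leaf_labels={2: "a", 3: "b", 4: "c", 5: "d"},
        )
        assert {v.condition for v in net.is_restricted()} == {"c"}

    def test_transfer_within_cherry_violates_d(self):
        # ((a,b),c): subdivision above a, transfer to sibling b: the path
        # from the LCA to the target has no intermediate node at all
        net = LGTNetwork(
            principal_arcs=[(0, 1), (0, 4), (1, 5), (5, 2), (1, 3)],
            secondary_arcs=[(5, 3)],
            leaf_labels={2: "a", 3: "b", 4: "c"},
        )
        assert {v.condition for v in net.is_restricted()} == {"d"}

    def test_stacked_subdivisions_violate_a(self):
        # ((a,b),c,d) with two stacked subdivision nodes above a
        net = LGTNetwork(
            principal_arcs=[(0, 1), (0, 4), (0, 7), (1, 5), (5, 6), (6, 2), (1, 3)],
            secondary_arcs=[(5, 4), (6, 7)],
            leaf_labels={2: "a", 3: "b", 4: "c", 7: "d"},
        )
        assert "a" in {v.condition for v in net.is_restricted()}

    def test_target_on_subdivision_node_violates_b(self):
        # (((a,b),c),(d,e)): node 5 subdivides the arc above the (a,b)
        # cherry; the transfer (9, 5) targets that principally elementary node
        net = LGTNetwork(
            principal_arcs=[(0, 1), (0, 9), (1, 5), (5, 6), (6, 2), (6, 3),
                            (1, 4), (9, 7), (9, 8)],
            secondary_arcs=[(5, 7), (9, 5)],
            leaf_labels={2: "a", 3: "b", 4: "c", 7: "d", 8: "e"},
        )
        assert {v.condition for v in net.is_restricted()} == {"b"}


class TestDistanceInvariant:
    def test_reduced_secondary_subtrees_one_move_from_principal(self):
        for seed in range(25):
            net = random_restricted_network(GeneratorConfig(7, 2, seed))
            principal, secondaries = net.reduced_subtrees()
            for t in secondaries:
                assert rspr_distance_leq_one(principal, t) == 1

    def test_reduced_subtrees_pairwise_distinct(self):
        for seed in range(40):
            net = random_restricted_network(GeneratorConfig(6 + seed % 5, 2, seed))
            principal, secondaries = net.reduced_subtrees()
            trees = [principal, *secondaries]
            for a, b in itertools.combinations(trees, 2):
                assert not trees_equal(a, b)


class TestIsomorphism:
    def test_reflexive(self):
        net = one_arc_network()
        assert networks_isomorphic(net, net)

    def test_invariant_under_id_renaming(self):
        net = one_arc_network()
        shift = {u: u + 100 for u in net.nodes}
        renamed = LGTNetwork(
            [(shift[a], shift[b]) for a, b in net.principal_arcs],
            [(shift[a], shift[b]) for a, b in net.secondary_arcs],
            {shift[u]: lab for u, lab in net.leaf_labels.items()},
        )
        assert networks_isomorphic(net, renamed)

    def test_different_secondary_placement_not_isomorphic(self):
        a = one_arc_network()
        # same principal tree, transfer from subdivision above b instead
        b = LGTNetwork(
            principal_arcs=[(0, 1), (1, 2), (1, 5), (5, 3), (0, 6), (6, 4), (6, 7)],
            secondary_arcs=[(5, 4)],
            leaf_labels={2: "a", 3: "b", 4: "c", 7: "d"},
        )
        assert not networks_isomorphic(a, b)

    def test_equivalence_on_generated_samples(self):
        nets = [random_restricted_network(GeneratorConfig(6, 2, s)) for s in range(6)]
        for x, y in itertools.product(nets, nets):
            assert networks_isomorphic(x, y) == (
                x.canonical_form() == y.canonical_form()
            )


class TestSerialization:
    def test_text_round_trip(self):
        for seed in range(10):
            net = random_restricted_network(GeneratorConfig(7, 2, seed))
            back = LGTNetwork.from_text(net.to_text())
            assert networks_isomorphic(net, back)

    def test_writer_is_canonical(self):
        net = one_arc_network()
        shift = {u: 50 - u for u in net.nodes}
        renamed = LGTNetwork(
            [(shift[a], shift[b]) for a, b in net.principal_arcs],
            [(shift[a], shift[b]) for a, b in net.secondary_arcs],
            {shift[u]: lab for u, lab in net.leaf_labels.items()},
        )
        assert net.to_text() == renamed.to_text()

    def test_header_required(self):
        with pytest.raises(NetworkError):
            LGTNetwork.from_text("0\t1\tP\n")
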