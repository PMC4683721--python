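"""Seeded random generation of restricted LGT networks.

Principal trees are drawn by sequential random leaf attachment, where each
new leaf joins either an existing arc (creating a new bifurcation) or an
existing internal node (creating or widening a multifurcation) -- so the
generator exercises the multifurcating branches of the condition machinery,
not just binary trees.  Secondary arcs are then added one at a time by
rejection sampling over candidate (source, target) placements, keeping only
additions under which the whole network remains a valid, acyclic,
*restricted* LGT network.  Generation is a pure function of the
configuration (same config, isomorphic output).
"""

from __future__ import annotations

import random
import string
from dataclasses import dataclass

from .network import LGTNetwork, NetworkError
from .trees import PhyloTree


class GenerationError(RuntimeError):
    """Rejection sampling exhausted its attempt budget."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of one random restricted network draw.

    ``n_leaves`` taxa (labelled a, b, c, ...; at least 3), ``n_secondary``
    transfer arcs, and a deterministic ``seed``.  ``max_attempts`` bounds
    the rejection sampling per secondary arc; exhausting it raises
    :class:`GenerationError` rather than silently degrading.
    """

    n_leaves: int
    n_secondary: int
    seed: int
    max_attempts: int = 2000

    def __post_init__(self):
        if self.n_leaves < 3:
            raise ValueError("need at least 3 leaves")
        if self.n_secondary < 0:
            raise ValueError("n_secondary must be non-negative")
        if self.n_leaves > len(string.ascii_lowercase):
            raise ValueError("at most 26 leaves supported by the label alphabet")


def random_phylo_tree(rng: random.Random, labels: list[str]) -> PhyloTree:
    """A random (possibly multifurcating) phylogenetic tree by sequential
    leaf attachment."""
    if len(labels) < 2:
        raise ValueError("need at least 2 labels")
    children: dict[int, list[int]] = {0: [1, 2]}
    node_labels = {1: labels[0], 2: labels[1]}
    next_id = 3
    for lab in labels[2:]:
        arcs = [(u, c) for u, cs in children.items() for c in cs]
        internals = [u for u in children if children[u]]
        choices = [("arc", a) for a in arcs] + [("node", u) for u in internals]
        kind, where = rng.choice(choices)
        leaf = next_id
        next_id += 1
        node_labels[leaf] = lab
        if kind == "node":
            children[where].append(leaf)
        else:
            u, c = where
            mid = next_id
            next_id += 1
            children[u][children[u].index(c)] = mid
            children[mid] = [c, leaf]
        children[leaf] = []
    return PhyloTree(children, node_labels, root=0)


def random_restricted_network(cfg: GeneratorConfig) -> LGTNetwork:
    """Draw a random restricted LGT network.

    The output passes all structural invariants and the restrictedness
    check.  Secondary-arc placement mixes both source kinds: subdividing a
    principal arc (the arc-regraft case) and reusing an existing internal
    node (the node-regraft case, including additional arcs from an already
    principally elementary subdivision node).
    """
    rng = random.Random(cfg.seed)
    labels = list(string.ascii_lowercase[: cfg.n_leaves])
    per_arc_budget = 50

    # a drawn tree may admit no valid placement at all (e.g. a near-star
    # tree, where every candidate arc violates the LCA-path condition), so
    # rejection extends to redrawing the principal tree
    for _draw in range(cfg.max_attempts):
        tree = random_phylo_tree(rng, labels)
        children = {u: list(cs) for u, cs in tree._children.items()}
        leaf_labels = dict(tree.leaf_labels)
        secondary: list[tuple[int, int]] = []
        next_id = max(tree.nodes) + 1
        placed = 0
        for _ in range(cfg.n_secondary):
            for _attempt in range(per_arc_budget):
                arcs = [(u, c) for u, cs in children.items() for c in cs]
                internals = [u for u in children if children[u]]
                target = rng.choice(sorted(u for u in children if u != tree.root))
                cand_children = {x: list(cs) for x, cs in children.items()}
                if rng.random() < 0.5:
                    # subdivide a principal arc to create the source
                    u0, c0 = rng.choice(sorted(arcs))
                    mid = next_id
                    cand_children[u0][cand_children[u0].index(c0)] = mid
                    cand_children[mid] = [c0]
                    source = mid
                    consumed_id = True
                else:
                    source = rng.choice(sorted(internals))
                    consumed_id = False
                if (source, target) in secondary:
                    continue
                cand_secondary = secondary + [(source, target)]
                principal = [(u, c) for u, cs in cand_children.items() for c in cs]
                try:
                    net = LGTNetwork(principal, cand_secondary, leaf_labels)
                except NetworkError:
                    continue
                if net.is_restricted():
                    continue
                children = cand_children
                secondary = cand_secondary
                if consumed_id:
                    next_id += 1
                placed += 1
                break
            else:
                break  # stuck on this tree; redraw
        if placed == cfg.n_secondary:
            principal = [(u, c) for u, cs in children.items() for c in cs]
            return LGTNetwork(principal, secondary, leaf_labels)
    raise GenerationError(
        f"no valid network found after {cfg.max_attempts} tree draws"
    )
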