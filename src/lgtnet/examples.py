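"""Bundled worked examples.

Three small inputs exercise the full reconstruction pipeline without any
external data:

* a nine-taxon example of Rhodobacterales gene trees (Roseobacter,
  Ruegeria, Dinoroseobacter, Paracoccus and four Rhodobacter sphaeroides
  strains) in which three lateral transfers explain the incongruence
  between a principal tree and three secondary gene trees;
* a six-taxon pair of secondary trees whose inferred transfers force a
  directed cycle, so no restricted LGT network exists for them;
* a six-taxon principal/secondary pair explainable by a (non-restricted)
  LGT network but failing the restricted-network cluster condition.

The six-taxon trees are specified by their cluster-set differences from the
principal tree; concrete realizations are recovered by exhaustive search
over all phylogenetic trees on six labels (any realization yields the same
reconstruction outcome, since placements depend only on the differences).
"""

from __future__ import annotations

from functools import lru_cache

from .trees import PhyloTree, enumerate_trees, parse_phylo, tree_from_clusters

RHODOBACTER_NEWICKS = {
    "T0": "(((((9,8),7),6),5),((4,3),(1,2)));",
    "T1": "(((((9,8),7),6),5),(((2,3),1),4));",
    "T2": "(((((9,8),7),6),5),(((1,3),2),4));",
    # the extra parenthesis pair around (3,(1,2)) parses as an elementary
    # node and is suppressed on reduction
    "T3": "((((((9,8),7),6),5),4),((3,(1,2))));",
}

RHODOBACTER_ORGANISMS = {
    "1": "Roseobacter_denitrificans_OCh_114",
    "2": "Ruegeria_pomeroyi_DSS-3",
    "3": "Ruegeria_sp._TM1040",
    "4": "Dinoroseobacter_shibae_DFL_12",
    "5": "Paracoccus_denitrificans_PD1222",
    "6": "Rhodobacter_sphaeroides_ATCC_17025",
    "7": "Rhodobacter_sphaeroides_KD131",
    "8": "Rhodobacter_sphaeroides_ATCC_17029",
    "9": "Rhodobacter_sphaeroides_2.4.1",
}


def _f(*labels: str) -> frozenset[str]:
    return frozenset(labels)


# cluster-set differences C(T) \ C(T_i') and C(T_i') \ C(T) defining the
# six-taxon examples (labels "1".."6")
CYCLE_EXAMPLE_DIFFS = [
    (
        {_f("1", "2"), _f("1", "2", "3"), _f("4", "5", "6")},
        {_f("1", "5", "6"), _f("1", "2", "5", "6"), _f("1", "2", "3", "5", "6")},
    ),
    (
        {_f("1", "2", "3"), _f("5", "6"), _f("4", "5", "6")},
        {_f("1", "2", "6"), _f("1", "2", "5", "6"), _f("1", "2", "4", "5", "6")},
    ),
]

NONRESTRICTED_EXAMPLE_DIFFS = (
    {_f("3", "4", "5"), _f("2", "3", "4", "5")},
    {_f("2", "3"), _f("2", "3", "6")},
)


@lru_cache(maxsize=None)
def rhodobacter_example() -> tuple[PhyloTree, list[PhyloTree]]:
    """The nine-taxon example: principal tree and three secondary trees."""
    t0 = parse_phylo(RHODOBACTER_NEWICKS["T0"])
    secondaries = [parse_phylo(RHODOBACTER_NEWICKS[k]) for k in ("T1", "T2", "T3")]
    return t0, secondaries


def _realize(
    diffs: list[tuple[set[frozenset[str]], set[frozenset[str]]]],
    labels: tuple[str, ...],
) -> tuple[PhyloTree, ...]:
    """Find, by exhaustive search, a principal tree T and trees T_i' whose
    cluster differences with T equal the given (removed, added) sets."""
    for T in enumerate_trees(labels):
        CT = T.cluster_set()
        found: list[PhyloTree] = []
        for removed, added in diffs:
            if not (removed <= CT) or (added & CT):
                break
            try:
                Tp = tree_from_clusters((CT - removed) | added)
            except Exception:
                break
            found.append(Tp)
        else:
            return (T, *found)
    raise RuntimeError("no tree realizes the required cluster differences")


@lru_cache(maxsize=None)
def cycle_example() -> tuple[PhyloTree, PhyloTree, PhyloTree]:
    """Six-taxon (T, T1', T2') whose two inferred transfers form a directed
    cycle: reconstruction must fail with a cycle."""
    return _realize(CYCLE_EXAMPLE_DIFFS, ("1", "2", "3", "4", "5", "6"))


@lru_cache(maxsize=None)
def nonrestricted_example() -> tuple[PhyloTree, PhyloTree]:
    """Six-taxon (T, T1') explainable only by a non-restricted network:
    the cluster condition fails at the segment decomposition."""
    return _realize([NONRESTRICTED_EXAMPLE_DIFFS], ("1", "2", "3", "4", "5", "6"))
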