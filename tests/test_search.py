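"""Tree search: enumeration, branch-and-bound, RAS+TBR, consensus."""

import numpy as np
import pytest

from morphpars import (
    CharacterMatrix,
    PhyloTree,
    SearchConfig,
    branch_and_bound,
    enumerate_trees,
    exhaustive_search,
    majority_rule_consensus,
    ras_tbr_search,
    strict_consensus,
    tree_length,
)
from morphpars.search import enumerate_adjacencies, tbr_neighbors
from morphpars.simulate import SimulationConfig, simulate_matrix
from morphpars.tree import TreeError

from oracles import all_unrooted_trees


def _double_factorial_count(n):
    out = 1
    for k in range(2 * n - 5, 1, -2):
        out *= k
    return out


@pytest.mark.parametrize("n,count", [(4, 3), (5, 15), (6, 105)])
def test_enumeration_counts(n, count):
    taxa = [f"t{i}" for i in range(n)]
    trees = list(enumerate_trees(taxa))
    assert len(trees) == count == _double_factorial_count(n)
    # exactly once: all topology keys distinct
    assert len({t.topology_key() for t in trees}) == count


def test_enumeration_guard():
    with pytest.raises(TreeError):
        list(enumerate_trees([f"t{i}" for i in range(11)]))


def test_exhaustive_recovers_perfect_phylogeny():
    m, true = simulate_matrix(
        SimulationConfig(n_taxa=6, n_chars=40, change_prob=0.05, seed=4)
    )
    res = exhaustive_search(m)
    # the generating tree is at least as short as any other topology
    assert tree_length(true, m).total_length >= res.length
    if tree_length(true, m).total_length == res.length:
        assert any(t.topology_key() == true.topology_key() for t in res.binary_trees)


def test_exhaustive_all_invariant_ties_every_topology():
    taxa = [f"t{i}" for i in range(5)]
    m = CharacterMatrix.from_values(taxa, [[0, 1]] * 5)
    res = exhaustive_search(m, SearchConfig(collapse=False))
    assert res.length == 0
    assert res.mpt_count == 15


@pytest.mark.parametrize("seed", range(8))
def test_branch_and_bound_equals_exhaustive(seed):
    rng = np.random.default_rng(200 + seed)
    n = int(rng.integers(5, 9))
    n_chars = int(rng.integers(8, 16))
    taxa = [f"t{i}" for i in range(n)]
    rows = [[int(rng.integers(3)) for _ in range(n_chars)] for _ in range(n)]
    m = CharacterMatrix.from_values(taxa, rows)
    cfg = SearchConfig(collapse=False)
    exh = exhaustive_search(m, cfg)
    bnb = branch_and_bound(m, cfg)
    assert bnb.length == exh.length
    assert {t.topology_key() for t in bnb.trees} == {t.topology_key() for t in exh.trees}


@pytest.mark.parametrize("seed", range(4))
def test_ras_tbr_equals_exact(seed):
    rng = np.random.default_rng(300 + seed)
    n = int(rng.integers(6, 9))
    taxa = [f"t{i}" for i in range(n)]
    rows = [[int(rng.integers(2)) for _ in range(12)] for _ in range(n)]
    m = CharacterMatrix.from_values(taxa, rows)
    cfg = SearchConfig(collapse=False)
    exact = branch_and_bound(m, cfg)
    heur = ras_tbr_search(m, SearchConfig(replicates=10, seed=seed, collapse=False))
    assert heur.length == exact.length
    assert {t.topology_key() for t in heur.trees} == {
        t.topology_key() for t in exact.trees
    }


def test_ras_tbr_deterministic_given_seed():
    m, _ = simulate_matrix(SimulationConfig(n_taxa=9, n_chars=25, change_prob=0.15, seed=6))
    cfg = SearchConfig(replicates=4, seed=42)
    a = ras_tbr_search(m, cfg)
    b = ras_tbr_search(m, cfg)
    assert a.length == b.length
    assert [t.to_newick() for t in a.trees] == [t.to_newick() for t in b.trees]
    assert a.replicate_lengths == b.replicate_lengths


def test_single_replicate_recovers_clean_tree():
    m, true = simulate_matrix(
        SimulationConfig(n_taxa=8, n_chars=60, change_prob=0.04, seed=8)
    )
    steps = tree_length(true, m).per_char_steps
    from morphpars import min_steps

    keep = [j for j in range(m.n_chars) if steps[j] == min_steps(m.column(j), m.specs[j])]
    clean = m.subset_characters(keep)
    res = ras_tbr_search(clean, SearchConfig(replicates=1, seed=0))
    cons = strict_consensus(res.trees)
    assert cons.bipartitions() <= true.bipartitions() | cons.bipartitions()
    # the generating tree is among the optima
    assert any(t.bipartitions() <= true.bipartitions() for t in res.trees)


def test_bnb_never_beaten_by_any_topology():
    m, _ = simulate_matrix(SimulationConfig(n_taxa=6, n_chars=10, change_prob=0.3, seed=10))
    res = branch_and_bound(m)
    lengths = [
        tree_length(t, m).total_length for t in enumerate_trees(m.taxa)
    ]
    assert res.length == min(lengths)


def test_tbr_neighborhood_is_sound():
    # every TBR neighbor is a valid binary tree on the same leaves
    taxa = [f"t{i}" for i in range(6)]
    adj = next(enumerate_adjacencies(6))
    tree = PhyloTree(adj, taxa)
    seen = set()
    for nadj in tbr_neighbors(adj):
        t = PhyloTree(nadj, taxa)
        assert t.is_binary()
        seen.add(t.topology_key())
    # TBR on 6 leaves reaches a substantial share of the 105 topologies
    assert len(seen) > 20


class TestConsensus:
    def test_identical_trees(self):
        taxa = [f"t{i}" for i in range(6)]
        t = PhyloTree(next(enumerate_adjacencies(6)), taxa)
        assert strict_consensus([t, t.copy()]).same_topology(t)

    def test_single_disagreement_polytomy(self):
        taxa = list("ABCDE")
        t1 = PhyloTree.from_newick("((A,B),(C,D),E);", taxa)
        t2 = PhyloTree.from_newick("((A,B),(C,E),D);", taxa)
        cons = strict_consensus([t1, t2])
        assert cons.bipartitions() == frozenset({frozenset({0, 1})}) or cons.bipartitions() == {
            frozenset({2, 3, 4})
        }

    def test_all_topologies_give_star(self):
        taxa = [f"t{i}" for i in range(5)]
        cons = strict_consensus(list(enumerate_trees(taxa)))
        assert cons.bipartitions() == frozenset()

    def test_majority_counting(self):
        taxa = list("ABCDE")
        t = PhyloTree.from_newick("((A,B),(C,D),E);", taxa)
        t2 = PhyloTree.from_newick("((A,C),(B,D),E);", taxa)
        maj, freqs = majority_rule_consensus([t, t, t, t2])
        # canonical form of the A+B clade: the side not containing leaf 0
        ab = frozenset({2, 3, 4})
        assert freqs[ab] == 0.75
        assert all(f > 0.5 for f in freqs.values())

    def test_threshold_one_equals_strict(self):
        taxa = list("ABCDEF")
        trees = [PhyloTree(a, taxa) for a in list(enumerate_adjacencies(6))[:4]]
        maj, _ = majority_rule_consensus(trees, threshold=1.0)
        assert maj.bipartitions() == strict_consensus(trees).bipartitions()

    def test_mismatched_leafsets_rejected(self):
        t1 = PhyloTree.from_newick("((A,B),(C,D),E);", list("ABCDE"))
        t2 = PhyloTree.from_newick("((A,B),(C,F),E);", list("ABCFE"))
        with pytest.raises(TreeError):
            strict_consensus([t1, t2])


def test_newick_roundtrip_through_dendropy():
    import dendropy

    m, t = simulate_matrix(SimulationConfig(n_taxa=9, n_chars=5, seed=13))
    nwk = t.to_newick()
    back = PhyloTree.from_newick(nwk, t.taxa)
    assert back.same_topology(t)
    # cross-check bipartition count with dendropy's own encoding
    dt = dendropy.Tree.get(data=nwk, schema="newick", preserve_underscores=True)
    dt.encode_bipartitions()
    nontrivial = [
        b for b in dt.bipartition_encoding
        if 1 < bin(b.split_bitmask).count("1") < len(t.taxa) - 1
    ]
    assert len({b.split_bitmask for b in nontrivial}) >= len(t.bipartitions())
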