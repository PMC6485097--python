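"""Fitch/Wagner scoring, m/g bounds, and CI/RI against brute-force oracles."""

import itertools

import numpy as np
import pytest

from morphpars import (
    CharacterMatrix,
    PhyloTree,
    StateSet,
    ensemble_stats,
    fitch_steps,
    max_steps,
    min_steps,
    tree_length,
    wagner_steps,
)
from morphpars.matrix import CharacterSpec
from morphpars.optimization import char_diagnostics, min_branch_lengths, sankoff_length
from morphpars.search import branch_and_bound, enumerate_adjacencies
from morphpars.simulate import SimulationConfig, simulate_matrix

from oracles import (
    all_unrooted_trees,
    brute_force_steps,
    brute_max_steps,
    brute_min_steps,
    column_sets,
)


def _cells(values):
    out = []
    for v in values:
        if v is None:
            out.append(StateSet.missing())
        elif isinstance(v, tuple):
            out.append(StateSet.poly(v))
        else:
            out.append(StateSet.single(v))
    return out


class TestFitchExamples:
    def test_single_internal_change(self, quartet_tree):
        steps, down = fitch_steps(quartet_tree, _cells([0, 0, 1, 1]))
        assert steps == 1

    def test_two_changes(self, quartet_tree):
        # brute force over all 3^2 internal assignments gives 2
        assert fitch_steps(quartet_tree, _cells([0, 1, 0, 1]))[0] == 2

    def test_invariant_column(self, quartet_tree):
        assert fitch_steps(quartet_tree, _cells([2, 2, 2, 2]))[0] == 0

    def test_missing_leaves_free(self, quartet_tree):
        assert fitch_steps(quartet_tree, _cells([0, None, 1, None]))[0] == 1


class TestWagnerExamples:
    def test_range_cost(self, quartet_tree):
        assert wagner_steps(quartet_tree, _cells([0, 0, 2, 2])) == 2

    def test_spanning_lower_bound(self, quartet_tree):
        assert wagner_steps(quartet_tree, _cells([0, 1, 2, 2])) >= 2

    def test_invariant(self, quartet_tree):
        assert wagner_steps(quartet_tree, _cells([1, 1, 1, 1])) == 0


def _adj_from_edges(edges):
    adj = {}
    for (u, v) in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    return adj


def _random_column(rng, n, n_states):
    col = []
    for _ in range(n):
        r = rng.random()
        if r < 0.1:
            col.append(None)
        elif r < 0.2:
            a = int(rng.integers(n_states - 1))
            col.append((a, a + 1))
        else:
            col.append(int(rng.integers(n_states)))
    return col


@pytest.mark.parametrize("n_leaves", [4, 5, 6])
def test_steps_equal_bruteforce_on_all_trees(n_leaves):
    """Fitch and Wagner equal exhaustive assignment minimization on every
    topology with <= 6 leaves, for random columns over <= 3 states."""
    rng = np.random.default_rng(100 + n_leaves)
    taxa = [f"t{i}" for i in range(n_leaves)]
    columns = [_random_column(rng, n_leaves, 3) for _ in range(8)]
    oracle_trees = all_unrooted_trees(n_leaves)
    assert len(oracle_trees) == len(list(enumerate_adjacencies(n_leaves)))
    for edges in oracle_trees:
        tree = PhyloTree(_adj_from_edges(edges), taxa)
        for col in columns:
            sets = column_sets(col, 3)
            expect_f = brute_force_steps(edges, sets, n_leaves, 3, ordered=False)
            expect_w = brute_force_steps(edges, sets, n_leaves, 3, ordered=True)
            assert fitch_steps(tree, _cells(col), max_state=2)[0] == expect_f
            assert wagner_steps(tree, _cells(col)) == expect_w


def test_length_invariant_under_leaf_permutation():
    m, t = simulate_matrix(SimulationConfig(n_taxa=7, n_chars=15, seed=5))
    base = tree_length(t, m).total_length
    # relabel leaves by a permutation applied consistently to matrix and tree
    rng = np.random.default_rng(0)
    perm = list(rng.permutation(m.n_taxa))
    taxa2 = [m.taxa[i] for i in perm]
    rows2 = [[c for c in m.cells[i]] for i in perm]
    m2 = CharacterMatrix.from_values(taxa2, rows2)
    mapping = {old: new for new, old in enumerate(perm)}
    adj2 = {
        (mapping.get(k, k)): [mapping.get(x, x) for x in v] for k, v in t.adj.items()
    }
    t2 = PhyloTree(adj2, taxa2)
    assert tree_length(t2, m2).total_length == base


def test_tree_length_matches_bruteforce_oracle():
    rng = np.random.default_rng(7)
    n, n_chars = 6, 12
    taxa = [f"t{i}" for i in range(n)]
    rows = [[int(rng.integers(2)) for _ in range(n_chars)] for _ in range(n)]
    m = CharacterMatrix.from_values(taxa, rows)
    edges = all_unrooted_trees(n)[42]
    tree = PhyloTree(_adj_from_edges(edges), taxa)
    cols = [column_sets([rows[i][j] for i in range(n)], 2) for j in range(n_chars)]
    expected = sum(brute_force_steps(edges, c, n, 2) for c in cols)
    res = tree_length(tree, m)
    assert res.total_length == expected
    assert sum(res.per_char_steps) == expected


def test_weights_scale_length():
    m, t = simulate_matrix(SimulationConfig(n_taxa=6, n_chars=10, seed=9))
    base = tree_length(t, m).total_length
    m2 = m.copy()
    from dataclasses import replace

    m2.specs = [replace(s, weight=2.0) for s in m2.specs]
    assert tree_length(t, m2).total_length == 2 * base


class TestMinMaxSteps:
    def test_min_unordered_examples(self):
        spec = CharacterSpec(0, 2)
        assert min_steps(_cells([0, 1, 2]), spec) == 2
        assert min_steps(_cells([0, (0, 1), 1]), spec) == 1
        assert min_steps(_cells([0, (0, 1)]), spec) == 0

    def test_min_ordered_range(self):
        spec = CharacterSpec(0, 2, ordered=True)
        assert min_steps(_cells([0, 2]), spec) == 2

    def test_max_examples(self):
        spec = CharacterSpec(0, 1)
        assert max_steps(_cells([0, 0, 0, 0, 1, 1, 1]), spec) == 3
        assert max_steps(_cells([1, 1, 1]), spec) == 0
        assert max_steps(_cells([None, None, 1]), spec) == 0

    @pytest.mark.parametrize("ordered", [False, True])
    def test_bounds_match_enumeration(self, ordered):
        rng = np.random.default_rng(3 if ordered else 4)
        spec = CharacterSpec(0, 2, ordered=ordered)
        for trial in range(12):
            n = int(rng.integers(4, 7))
            col = _random_column(rng, n, 3)
            sets = column_sets(col, 3)
            assert min_steps(_cells(col), spec) == brute_min_steps(sets, n, 3, ordered)
            assert max_steps(_cells(col), spec) == brute_max_steps(sets, n, 3, ordered)


def test_m_le_s_le_g_over_random_matrices():
    for seed in range(5):
        m, t = simulate_matrix(
            SimulationConfig(n_taxa=7, n_chars=20, change_prob=0.2, missing_frac=0.1, seed=seed)
        )
        diag = char_diagnostics(m, t)
        assert (diag["min_steps"] <= diag["steps"]).all()
        assert (diag["steps"] <= diag["max_steps"]).all()


def test_all_missing_character_changes_nothing(small_matrix):
    res = branch_and_bound(small_matrix)
    stats = ensemble_stats(small_matrix, res.trees[0])
    widened = CharacterMatrix.from_values(
        small_matrix.taxa,
        [row + [None] for row in small_matrix.cells],
    )
    res2 = branch_and_bound(widened)
    stats2 = ensemble_stats(widened, res2.trees[0])
    assert (stats2.M, stats2.S, stats2.G) == (stats.M, stats.S, stats.G)
    assert res2.length == res.length


class TestEnsembleStats:
    def test_homoplasy_free_ci_ri_one(self):
        m, t = simulate_matrix(
            SimulationConfig(n_taxa=8, n_chars=25, change_prob=0.04, seed=12)
        )
        # keep only characters that fit the true tree perfectly
        steps = tree_length(t, m).per_char_steps
        keep = [j for j in range(m.n_chars) if steps[j] == min_steps(m.column(j), m.specs[j])]
        assert keep, "simulation produced no clean characters"
        clean = m.subset_characters(keep)
        st = ensemble_stats(clean, t)
        assert st.CI == 1.0 and st.RI == 1.0

    def test_fixture_values_from_oracle(self, small_matrix):
        """CI/RI frozen from exhaustive enumeration: CI=0.75, RI=2/3."""
        res = branch_and_bound(small_matrix)
        assert res.length == 8
        st = ensemble_stats(small_matrix, res.binary_trees[0])
        assert (st.M, st.S, st.G) == (6, 8, 12)
        assert st.CI == pytest.approx(0.75)
        assert st.RI == pytest.approx(2 / 3)
        assert st.rounded() == (0.75, 0.67)

    def test_single_char_worst_tree(self):
        # one informative binary character on its worst tree: ci = m/g
        taxa = list("ABCD")
        m = CharacterMatrix.from_values(taxa, [[0], [1], [0], [1]])
        worst = None
        for adj in enumerate_adjacencies(4):
            t = PhyloTree(adj, taxa)
            s = tree_length(t, m).total_length
            if worst is None or s > worst[0]:
                worst = (s, t)
        st = ensemble_stats(m, worst[1])
        g = max_steps(m.column(0), m.specs[0])
        assert st.CI == min_steps(m.column(0), m.specs[0]) / g
        assert worst[0] == g


@pytest.mark.parametrize("seed", [3, 17, 31])
def test_tree_length_agrees_with_dendropy_fitch(seed):
    """Independent library route: dendropy's Fitch downpass scores our
    serialized matrix/tree to the same length (unordered characters,
    polymorphism and missing data included)."""
    import dendropy
    from dendropy.model import parsimony

    m, t = simulate_matrix(
        SimulationConfig(n_taxa=8, n_chars=25, change_prob=0.15,
                         missing_frac=0.1, polymorphic_frac=0.05, seed=seed)
    )
    from morphpars import write_nexus

    dm = dendropy.StandardCharacterMatrix.get(data=write_nexus(m), schema="nexus")
    dtree = dendropy.Tree.get(
        data=t.to_newick(), schema="newick",
        taxon_namespace=dm.taxon_namespace, preserve_underscores=True,
    )
    score = parsimony.fitch_down_pass(
        dtree.postorder_node_iter(),
        taxon_state_sets_map=dm.taxon_state_sets_map(gaps_as_missing=True),
    )
    assert score == tree_length(t, m).total_length


def test_sankoff_agrees_with_tree_length():
    m, t = simulate_matrix(SimulationConfig(n_taxa=7, n_chars=15, change_prob=0.15, seed=21))
    assert sankoff_length(t.adj, m) == tree_length(t, m).total_length


def test_min_branch_lengths_zero_iff_collapsible(small_matrix):
    res = branch_and_bound(small_matrix)
    tree = res.binary_trees[0]
    mins = min_branch_lengths(tree, small_matrix)
    # the fixture's single MPT survives collapse intact (frozen observation:
    # every internal branch carries at least one change in every MPR)
    assert all(v >= 0 for v in mins.values())
    # a star-like invariant matrix collapses everything
    taxa = list("ABCDE")
    inv = CharacterMatrix.from_values(taxa, [[0, 0]] * 5)
    for adj in itertools.islice(enumerate_adjacencies(5), 1):
        t = PhyloTree(adj, taxa)
        assert set(min_branch_lengths(t, inv).values()) == {0}
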