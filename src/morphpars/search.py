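"""Most-parsimonious tree search and consensus.

Three search strategies are provided:

* ``exhaustive``        — score every unrooted binary topology (guard n <= 10);
* ``branch_and_bound``  — exact DFS over stepwise-addition space, pruning any
  partial tree already longer than the best complete tree found (parsimony
  length never decreases as taxa are added, so pruning is safe);
* ``heuristic``         — random-addition-sequence (RAS) Wagner trees refined
  by tree-bisection-reconnection (TBR) branch swapping, the strategy used for
  matrices too large for exact search.

Ties during stepwise addition are broken by canonical branch order, and the
TBR neighborhood is enumerated canonically with first-improvement
acceptance, so results are bit-stable under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, FrozenSet, Iterable, Iterator, List, Optional, Sequence, Tuple

import numpy as np

from .matrix import CharacterMatrix
from .optimization import TreeScorer, min_branch_lengths
from .tree import (
    PhyloTree,
    TreeError,
    add_leaf_on_edge,
    adj_bipartitions,
    adj_edges,
    copy_adj,
    suppress_degree2,
)

__all__ = [
    "SearchConfig",
    "SearchResult",
    "enumerate_trees",
    "enumerate_adjacencies",
    "exhaustive_search",
    "branch_and_bound",
    "ras_tbr_search",
    "search",
    "strict_consensus",
    "majority_rule_consensus",
    "collapse_tree",
]


@dataclass(frozen=True)
class SearchConfig:
    """Settings for tree search.

    ``replicates`` and ``hold_per_step`` apply to the heuristic strategy
    (random stepwise addition holding ``hold_per_step`` trees at each step,
    then TBR).  ``collapse`` applies the zero-minimum-length branch rule to
    the final tree set; ``collect_all`` closes the optimal set over
    equal-length TBR neighbors so that heuristic runs can report the full
    set of most-parsimonious trees.
    """

    method: str = "auto"
    replicates: int = 1000
    hold_per_step: int = 1
    seed: int = 0
    max_trees: int = 10000
    collapse: bool = True
    collect_all: bool = True

    def __post_init__(self):
        if self.replicates < 1 or self.hold_per_step < 1:
            raise ValueError("replicates and hold_per_step must be >= 1")


@dataclass
class SearchResult:
    trees: List[PhyloTree]          # post-collapse, canonical, deduplicated
    binary_trees: List[PhyloTree]   # the underlying binary MPTs
    length: float
    evaluated: int
    method: str
    config: SearchConfig
    replicate_lengths: List[float] = field(default_factory=list)

    @property
    def mpt_count(self) -> int:
        return len(self.trees)


# ---------------------------------------------------------------------------
# topology enumeration
# ---------------------------------------------------------------------------

def enumerate_adjacencies(n: int) -> Iterator[Dict[int, List[int]]]:
    """Every unrooted binary topology on leaves 0..n-1, exactly once.

    Built by stepwise insertion: the tree count is (2n-5)!!.
    """
    if n < 3:
        raise TreeError("enumeration needs at least 3 leaves")
    base = {0: [n], 1: [n], 2: [n], n: [0, 1, 2]}

    def rec(adj, k):
        if k == n:
            yield adj
            return
        for edge in adj_edges(adj):
            nxt = copy_adj(adj)
            add_leaf_on_edge(nxt, k, edge, n + k - 2)
            yield from rec(nxt, k + 1)

    yield from rec(base, 3)


def enumerate_trees(taxa: Sequence[str]) -> Iterator[PhyloTree]:
    """All unrooted binary topologies over ``taxa`` (guard: 3 <= n <= 10)."""
    n = len(taxa)
    if not 3 <= n <= 10:
        raise TreeError(f"exhaustive enumeration guarded to 3..10 taxa, got {n}")
    for adj in enumerate_adjacencies(n):
        yield PhyloTree(adj, taxa)


# ---------------------------------------------------------------------------
# shared helpers
# ---------------------------------------------------------------------------

def _canonical_sort_key(tree: PhyloTree):
    return tuple(sorted(tuple(sorted(s)) for s in tree.topology_key()))


def _dedup(adjs: Iterable[Dict], taxa) -> List[PhyloTree]:
    seen = set()
    out = []
    for adj in adjs:
        t = PhyloTree(adj, taxa)
        key = t.topology_key()
        if key not in seen:
            seen.add(key)
            out.append(t)
    out.sort(key=_canonical_sort_key)
    return out


def collapse_tree(tree: PhyloTree, matrix: CharacterMatrix) -> PhyloTree:
    """Contract every internal branch whose minimum optimized length is zero."""
    mins = min_branch_lengths(tree, matrix)
    zero = [e for e, v in mins.items() if v == 0]
    if not zero:
        return tree
    adj = copy_adj(tree.adj)
    for (u, v) in zero:
        if u not in adj or v not in adj or v not in adj[u]:
            # endpoint already merged away; map to surviving representative
            continue
        adj[u] = [x for x in adj[u] if x != v] + [x for x in adj[v] if x != u]
        for x in adj.pop(v):
            if x != u:
                adj[x] = [u if y == v else y for y in adj[x]]
    return PhyloTree(adj, tree.taxa)


def _finalize(matrix, adjs, length, method, config, evaluated, rep_lengths=None):
    binary = _dedup(adjs, matrix.taxa)[: config.max_trees]
    if config.collapse:
        seen = set()
        trees = []
        for t in binary:
            ct = collapse_tree(t, matrix)
            key = ct.topology_key()
            if key not in seen:
                seen.add(key)
                trees.append(ct)
        trees.sort(key=_canonical_sort_key)
    else:
        trees = list(binary)
    return SearchResult(
        trees=trees,
        binary_trees=binary,
        length=length,
        evaluated=evaluated,
        method=method,
        config=config,
        replicate_lengths=list(rep_lengths or []),
    )


def _trivial_result(matrix, config, method):
    n = matrix.n_taxa
    if n == 3:
        adj = {0: [3], 1: [3], 2: [3], 3: [0, 1, 2]}
    elif n == 2:
        adj = {0: [1], 1: [0]}
    else:
        raise TreeError("search needs at least 2 taxa")
    scorer = TreeScorer(matrix)
    L = scorer.score(adj) if n == 3 else _two_taxon_length(matrix)
    return _finalize(matrix, [adj], L, method, config, evaluated=1)


def _two_taxon_length(matrix):
    from .optimization import tree_length

    t = PhyloTree({0: [1], 1: [0]}, matrix.taxa)
    # a two-leaf "tree" is a single edge; score columns directly
    total = 0
    for j in range(matrix.n_chars):
        a, b = matrix.cells[0][j], matrix.cells[1][j]
        spec = matrix.specs[j]
        ra, rb = a.resolved(spec.max_state), b.resolved(spec.max_state)
        if spec.ordered:
            d = max(0, max(min(ra), min(rb)) - min(max(ra), max(rb)))
        else:
            d = 0 if ra & rb else 1
        total += spec.weight * d
    return total


# ---------------------------------------------------------------------------
# exact searches
# ---------------------------------------------------------------------------

def exhaustive_search(matrix: CharacterMatrix, config: SearchConfig = SearchConfig()) -> SearchResult:
    """Score every topology; the ground-truth oracle for small matrices."""
    n = matrix.n_taxa
    if n <= 3:
        return _trivial_result(matrix, config, "exhaustive")
    if n > 10:
        raise TreeError(f"exhaustive search guarded to <= 10 taxa, got {n}")
    scorer = TreeScorer(matrix)
    best = None
    best_adjs: List[Dict] = []
    evaluated = 0
    for adj in enumerate_adjacencies(n):
        L = scorer.score(adj)
        evaluated += 1
        if best is None or L < best:
            best, best_adjs = L, [adj]
        elif L == best and len(best_adjs) < config.max_trees:
            best_adjs.append(adj)
    return _finalize(matrix, best_adjs, best, "exhaustive", config, evaluated)


def _stepwise_addition(matrix, scorer, order, hold=1):
    """Greedy Wagner-tree construction; returns list of (adj, length) held."""
    n = matrix.n_taxa
    a, b, c = order[0], order[1], order[2]
    hub = n
    held = [{a: [hub], b: [hub], c: [hub], hub: [a, b, c]}]
    next_id = n + 1
    evaluated = 0
    for leaf in order[3:]:
        candidates = []
        for adj in held:
            for edge in adj_edges(adj):
                nxt = copy_adj(adj)
                add_leaf_on_edge(nxt, leaf, edge, next_id)
                candidates.append((scorer.score(nxt), len(candidates), nxt))
                evaluated += 1
        candidates.sort(key=lambda t: (t[0], t[1]))  # ties: first canonical
        held = []
        seen = set()
        for L, _, adj in candidates:
            key = frozenset(adj_bipartitions(adj, n))
            if key in seen:
                continue
            seen.add(key)
            held.append(adj)
            if len(held) >= hold:
                break
        next_id += 1
    return held, evaluated


def branch_and_bound(
    matrix: CharacterMatrix,
    config: SearchConfig = SearchConfig(),
    reject=None,
    initial_bound: Optional[float] = None,
) -> SearchResult:
    """Exact search by DFS over the stepwise-addition tree with pruning.

    ``reject`` is an optional predicate on complete adjacency maps; trees
    for which it returns True are excluded from the optimum (used for
    converse-constraint Bremer searches).  The upper bound is initialized
    from a greedy addition tree (when admissible).
    """
    n = matrix.n_taxa
    if n <= 3:
        return _trivial_result(matrix, config, "branch_and_bound")
    scorer = TreeScorer(matrix)
    evaluated = 0

    held, ev = _stepwise_addition(matrix, scorer, list(range(n)), hold=1)
    evaluated += ev
    bound = initial_bound
    best_adjs: List[Dict] = []
    greedy = held[0]
    if reject is None or not reject(greedy):
        g_len = scorer.score(greedy)
        if bound is None or g_len <= bound:
            bound, best_adjs = g_len, [greedy]

    base = {0: [n], 1: [n], 2: [n], n: [0, 1, 2]}
    stack = [(base, 3)]
    while stack:
        adj, k = stack.pop()
        if k == n:
            L = scorer.score(adj)
            evaluated += 1
            if reject is not None and reject(adj):
                continue
            if bound is None or L < bound:
                bound, best_adjs = L, [adj]
            elif L == bound and len(best_adjs) < config.max_trees:
                best_adjs.append(adj)
            continue
        for edge in adj_edges(adj):
            nxt = copy_adj(adj)
            add_leaf_on_edge(nxt, k, edge, n + k - 2)
            evaluated += 1
            if bound is not None and scorer.score(nxt) > bound:
                continue
            stack.append((nxt, k + 1))
    if not best_adjs:
        raise TreeError("constrained search excluded every topology")
    return _finalize(matrix, best_adjs, bound, "branch_and_bound", config, evaluated)


# ---------------------------------------------------------------------------
# heuristic search: RAS + TBR
# ---------------------------------------------------------------------------

def tbr_neighbors(adj: Dict[int, List[int]]) -> Iterator[Dict[int, List[int]]]:
    """Canonical enumeration of the tree-bisection-reconnection neighborhood."""
    next_id = max(adj) + 1
    for (u, v) in adj_edges(adj):
        cut = copy_adj(adj)
        cut[u] = [x for x in cut[u] if x != v]
        cut[v] = [x for x in cut[v] if x != u]
        # component containing u
        comp_u = {u}
        stack = [u]
        while stack:
            x = stack.pop()
            for y in cut[x]:
                if y not in comp_u:
                    comp_u.add(y)
                    stack.append(y)
        suppress_degree2(cut, u)
        suppress_degree2(cut, v)
        side_u = {k: cut[k] for k in cut if k in comp_u}
        side_v = {k: cut[k] for k in cut if k not in comp_u}
        att_u = adj_edges(side_u) if len(side_u) > 1 else [None]
        att_v = adj_edges(side_v) if len(side_v) > 1 else [None]
        for ea in att_u:
            for eb in att_v:
                if ea is None and eb is None:
                    continue  # only reconnection is the original edge
                nxt = copy_adj(cut)
                nid = next_id
                if ea is None:
                    pa = u if u in comp_u else v
                else:
                    x, y = ea
                    pa = nid
                    nid += 1
                    nxt[x] = [pa if z == y else z for z in nxt[x]]
                    nxt[y] = [pa if z == x else z for z in nxt[y]]
                    nxt[pa] = [x, y]
                if eb is None:
                    pb = v if v not in comp_u else u
                else:
                    x, y = eb
                    pb = nid
                    nid += 1
                    nxt[x] = [pb if z == y else z for z in nxt[x]]
                    nxt[y] = [pb if z == x else z for z in nxt[y]]
                    nxt[pb] = [x, y]
                nxt[pa].append(pb)
                nxt[pb].append(pa)
                yield nxt


def _tbr_descent(adj, scorer, penalty=None, collect_equal=False):
    """First-improvement TBR to a local optimum.

    Returns (local optimum, its length, equal-length neighbors seen in the
    final non-improving sweep).  ``penalty`` is an optional function added
    to the raw length (used for constrained searches).
    """

    def cost(a):
        c = scorer.score(a)
        if penalty is not None:
            c += penalty(a)
        return c

    L = cost(adj)
    evaluated = 1
    while True:
        improved = False
        equals = []
        for nadj in tbr_neighbors(adj):
            c = cost(nadj)
            evaluated += 1
            if c < L:
                adj, L = nadj, c
                improved = True
                break
            if collect_equal and c == L:
                equals.append(nadj)
        if not improved:
            return adj, L, equals, evaluated


def ras_tbr_search(
    matrix: CharacterMatrix,
    config: SearchConfig = SearchConfig(),
    penalty=None,
) -> SearchResult:
    """Heuristic search: random stepwise addition + TBR, seeded and bit-stable.

    With ``collect_all`` the best-score set is closed over equal-length TBR
    neighbors (bounded by ``max_trees``), so on well-behaved matrices the
    full most-parsimonious set is recovered.
    """
    n = matrix.n_taxa
    if n <= 3:
        return _trivial_result(matrix, config, "heuristic")
    scorer = TreeScorer(matrix)
    rng = np.random.default_rng(config.seed)
    best: Optional[float] = None
    best_adjs: List[Dict] = []
    best_keys = set()
    evaluated = 0
    rep_lengths = []

    def cost(a):
        c = scorer.score(a)
        return c if penalty is None else c + penalty(a)

    for _ in range(config.replicates):
        order = [int(x) for x in rng.permutation(n)]
        held, ev = _stepwise_addition(matrix, scorer, order, hold=config.hold_per_step)
        evaluated += ev
        rep_best = None
        for start in held:
            opt, L, equals, ev = _tbr_descent(
                start, scorer, penalty=penalty, collect_equal=config.collect_all
            )
            evaluated += ev
            rep_best = L if rep_best is None else min(rep_best, L)
            for cand in [opt] + equals:
                Lc = L
                if best is None or Lc < best:
                    best = Lc
                    best_adjs, best_keys = [], set()
                if Lc == best:
                    key = frozenset(adj_bipartitions(cand, n))
                    if key not in best_keys and len(best_adjs) < config.max_trees:
                        best_keys.add(key)
                        best_adjs.append(cand)
        rep_lengths.append(rep_best)

    if config.collect_all:
        # close the optimal set over equal-length TBR neighbors
        queue = list(best_adjs)
        while queue and len(best_adjs) < config.max_trees:
            cur = queue.pop(0)
            for nadj in tbr_neighbors(cur):
                if cost(nadj) != best:
                    continue
                key = frozenset(adj_bipartitions(nadj, n))
                if key not in best_keys:
                    best_keys.add(key)
                    best_adjs.append(nadj)
                    queue.append(nadj)
                    if len(best_adjs) >= config.max_trees:
                        break

    raw_best = min(scorer.score(a) for a in best_adjs)
    return _finalize(
        matrix, best_adjs, raw_best, "heuristic", config, evaluated, rep_lengths
    )


def search(matrix: CharacterMatrix, config: SearchConfig = SearchConfig()) -> SearchResult:
    """Dispatch by ``config.method`` (``auto``: exact when feasible)."""
    method = config.method
    if method == "auto":
        method = "branch_and_bound" if matrix.n_taxa <= 10 else "heuristic"
    if method == "exhaustive":
        return exhaustive_search(matrix, config)
    if method == "branch_and_bound":
        return branch_and_bound(matrix, config)
    if method == "heuristic":
        return ras_tbr_search(matrix, config)
    raise ValueError(f"unknown search method {config.method!r}")


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------

def strict_consensus(trees: Sequence[PhyloTree]) -> PhyloTree:
    """Tree displaying exactly the splits shared by every input tree."""
    if not trees:
        raise TreeError("strict_consensus of an empty tree set")
    taxa = trees[0].taxa
    for t in trees[1:]:
        if t.taxa != taxa:
            raise TreeError("consensus requires identical leaf sets")
    shared = frozenset.intersection(*(t.bipartitions() for t in trees))
    return PhyloTree.from_bipartitions(taxa, shared)


def majority_rule_consensus(
    trees: Sequence[PhyloTree], threshold: float = 0.5
) -> Tuple[PhyloTree, Dict[FrozenSet[int], float]]:
    """Majority-rule consensus; returns (tree, split -> frequency in [0, 1]).

    A split is retained when its frequency exceeds ``threshold`` (or equals
    1.0 when ``threshold`` is 1.0, which reproduces the strict consensus).
    ``threshold`` must be >= 0.5 so retained splits are compatible.
    """
    if not trees:
        raise TreeError("majority_rule_consensus of an empty tree set")
    if threshold < 0.5:
        raise ValueError("threshold below 0.5 can retain incompatible splits")
    taxa = trees[0].taxa
    counts: Dict[FrozenSet[int], int] = {}
    for t in trees:
        if t.taxa != taxa:
            raise TreeError("consensus requires identical leaf sets")
        for s in t.bipartitions():
            counts[s] = counts.get(s, 0) + 1
    freqs = {s: c / len(trees) for s, c in counts.items()}
    if threshold >= 1.0:
        keep = [s for s, f in freqs.items() if f >= 1.0]
    else:
        keep = [s for s, f in freqs.items() if f > threshold]
    tree = PhyloTree.from_bipartitions(taxa, keep)
    return tree, {s: freqs[s] for s in keep}
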