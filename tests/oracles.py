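"""Independent brute-force oracles used by the test suite.

Deliberately separate from the package implementation: trees are plain
edge lists, parsimony lengths are found by exhaustive minimization over
every ancestral state assignment, and tree enumeration is by stepwise
insertion on edge lists.  Slow but unarguable for small inputs.
"""

import itertools

INF = float("inf")


def all_unrooted_trees(n):
    """Edge lists of every unrooted binary topology over leaves 0..n-1."""
    assert n >= 3
    trees = [[(0, n), (1, n), (2, n)]]
    for leaf in range(3, n):
        new_internal = n + leaf - 2
        grown = []
        for edges in trees:
            for i, (u, v) in enumerate(edges):
                cur = edges[:i] + edges[i + 1:]
                grown.append(cur + [(u, new_internal), (new_internal, v), (new_internal, leaf)])
        trees = grown
    return trees


def edge_cost(a, b, ordered):
    return abs(a - b) if ordered else (0 if a == b else 1)


def brute_force_steps(edges, leaf_sets, n_leaves, n_states, ordered=False):
    """Minimum changes over every ancestral assignment and leaf resolution.

    ``leaf_sets[i]`` is the set of states taxon i may take (full range for
    missing data).
    """
    internals = sorted({x for e in edges for x in e if x >= n_leaves})
    best = INF
    for combo in itertools.product(range(n_states), repeat=len(internals)):
        assign = dict(zip(internals, combo))
        total = 0
        for (u, v) in edges:
            su = [assign[u]] if u >= n_leaves else sorted(leaf_sets[u])
            sv = [assign[v]] if v >= n_leaves else sorted(leaf_sets[v])
            total += min(edge_cost(a, b, ordered) for a in su for b in sv)
            if total >= best:
                break
        best = min(best, total)
    return best


def brute_matrix_length(edges, columns, n_leaves, n_states, ordered_flags=None):
    if ordered_flags is None:
        ordered_flags = [False] * len(columns)
    return sum(
        brute_force_steps(edges, col, n_leaves, n_states, ordered=o)
        for col, o in zip(columns, ordered_flags)
    )


def brute_min_steps(col, n_leaves, n_states, ordered=False):
    """min over all topologies (= classical m_i) by full enumeration."""
    return min(
        brute_force_steps(e, col, n_leaves, n_states, ordered)
        for e in all_unrooted_trees(n_leaves)
    )


def brute_max_steps(col, n_leaves, n_states, ordered=False):
    """max over all topologies (= classical g_i) by full enumeration."""
    return max(
        brute_force_steps(e, col, n_leaves, n_states, ordered)
        for e in all_unrooted_trees(n_leaves)
    )


def splits_of(edges, n_leaves):
    """Non-trivial bipartitions of an edge-list tree, canonical side without leaf 0."""
    adj = {}
    for (u, v) in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    out = set()
    for (u, v) in edges:
        # leaves on v's side when edge removed
        seen = {v}
        stack = [v]
        while stack:
            x = stack.pop()
            for y in adj[x]:
                if y != u and y not in seen:
                    seen.add(y)
                    stack.append(y)
        side = frozenset(x for x in seen if x < n_leaves)
        if 0 in side:
            side = frozenset(range(n_leaves)) - side
        if 1 < len(side) < n_leaves - 1:
            out.add(side)
    return frozenset(out)


def column_sets(cells, n_states):
    """Cells (int / tuple / None for missing) -> list of state sets."""
    out = []
    for c in cells:
        if c is None:
            out.append(set(range(n_states)))
        elif isinstance(c, int):
            out.append({c})
        else:
            out.append(set(c))
    return out
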