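"""Parsimony optimization and homoplasy statistics.

Tree length is the weighted sum over characters of the minimum number of
state changes needed on the tree.  Unordered characters are scored with
Fitch set operations (any state may change to any other at cost 1);
ordered characters with the Farris interval method (a change from state i
to j costs |i - j|).  Polymorphic cells are treated as uncertainty: the
reconstruction may pick whichever member is cheapest.  Missing cells match
any state for free.

Homoplasy statistics follow the classical definitions:

* ``m_i`` — minimum conceivable steps of character i on any tree,
* ``s_i`` — observed steps on the tree under study,
* ``g_i`` — maximum conceivable steps (star-tree worst case),
* ensemble consistency index  CI = M / S  with M = sum m_i, S = sum s_i,
* ensemble retention index    RI = (G - S) / (G - M).

CI = 1 means the matrix fits the tree with no homoplasy.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .matrix import CharacterMatrix, CharacterSpec, MatrixError, StateSet
from .tree import PhyloTree, rooted_children

__all__ = [
    "fitch_steps",
    "wagner_steps",
    "tree_length",
    "min_steps",
    "max_steps",
    "is_informative",
    "ensemble_stats",
    "char_diagnostics",
    "min_branch_lengths",
    "OptimizationResult",
    "EnsembleStats",
    "TreeScorer",
]


# ---------------------------------------------------------------------------
# single-character reference implementations
# ---------------------------------------------------------------------------

def _column_masks(column: Sequence[StateSet], max_state: int) -> List[int]:
    return [cell.bitmask(max_state) for cell in column]


def fitch_steps(
    tree: PhyloTree, column: Sequence[StateSet], max_state: Optional[int] = None
) -> Tuple[int, Dict[int, frozenset]]:
    """Minimum changes of one unordered character on ``tree`` (Fitch).

    Returns ``(steps, downpass_sets)`` where ``downpass_sets`` maps each
    node id to its Fitch downpass state set (the tree is rooted on the
    edge to leaf 0 for the pass; leaf sets are the resolved cell sets).
    """
    n = tree.n_leaves
    if len(column) != n:
        raise MatrixError(f"column has {len(column)} cells for {n} leaves")
    if max_state is None:
        max_state = max((max(c.members) for c in column if not c.is_missing), default=1)
    masks = _column_masks(column, max_state)
    children, order, root = tree.rooted(0)
    down: Dict[int, int] = {}
    steps = 0
    for node in order:
        if node < n:
            down[node] = masks[node]
        else:
            kids = children[node]
            m = down[kids[0]]
            for c in kids[1:]:
                inter = m & down[c]
                if inter:
                    m = inter
                else:
                    m = m | down[c]
                    steps += 1
            down[node] = m
    sets = {
        k: frozenset(s for s in range(max_state + 1) if v >> s & 1)
        for k, v in down.items()
    }
    return steps, sets


def wagner_steps(tree: PhyloTree, column: Sequence[StateSet]) -> int:
    """Minimum total |state difference| of one ordered character (Farris)."""
    n = tree.n_leaves
    if len(column) != n:
        raise MatrixError(f"column has {len(column)} cells for {n} leaves")
    max_state = max((max(c.members) for c in column if not c.is_missing), default=1)
    iv = [cell.interval(max_state) for cell in column]
    children, order, root = tree.rooted(0)
    lo: Dict[int, int] = {}
    hi: Dict[int, int] = {}
    steps = 0
    for node in order:
        if node < n:
            lo[node], hi[node] = iv[node]
        else:
            kids = children[node]
            a, b = lo[kids[0]], hi[kids[0]]
            for c in kids[1:]:
                A = max(a, lo[c])
                B = min(b, hi[c])
                steps += max(A - B, 0)
                a, b = min(A, B), max(A, B)
            lo[node], hi[node] = a, b
    return steps


# ---------------------------------------------------------------------------
# vectorized scorer (the hot path for tree search)
# ---------------------------------------------------------------------------

class TreeScorer:
    """Scores adjacency-map trees against a fixed matrix.

    Characters are split by type: unordered columns become bitmask arrays,
    ordered columns become [lo, hi] interval arrays, both vectorized across
    characters.  With ``compress=True`` identical columns are pooled into
    weighted site patterns, which speeds up bootstrap and simulation work
    dramatically.  Partial trees (leaf subsets, as grown during stepwise
    addition) are scored on the same arrays.
    """

    def __init__(self, matrix: CharacterMatrix, compress: bool = True):
        self.n_taxa = matrix.n_taxa
        self.unord_idx = [j for j, s in enumerate(matrix.specs) if not s.ordered]
        self.ord_idx = [j for j, s in enumerate(matrix.specs) if s.ordered]
        wu = np.array([matrix.specs[j].weight for j in self.unord_idx])
        wo = np.array([matrix.specs[j].weight for j in self.ord_idx])
        self.masks = matrix.bitmask_array(self.unord_idx)
        self.lo, self.hi = matrix.interval_arrays(self.ord_idx)
        if compress:
            self.masks, self.w_u = _pool_columns(self.masks, wu)
            pair = np.concatenate([self.lo, self.hi], axis=0)
            pooled, self.w_o = _pool_columns(pair, wo)
            self.lo, self.hi = pooled[: self.n_taxa], pooled[self.n_taxa:]
        else:
            self.w_u, self.w_o = wu, wo
        self._int_weights = (
            float(self.w_u.sum() + self.w_o.sum()).is_integer()
            and np.all(self.w_u == np.round(self.w_u))
            and np.all(self.w_o == np.round(self.w_o))
        )

    def score(self, adj, bound: Optional[float] = None) -> float:
        """Weighted parsimony length of the (possibly partial) binary tree."""
        per_u, per_o = self._per_pattern(adj)
        total = float(per_u @ self.w_u) + float(per_o @ self.w_o)
        return int(total) if self._int_weights else total

    def per_pattern_steps(self, adj):
        return self._per_pattern(adj)

    def _per_pattern(self, adj):
        n = self.n_taxa
        ref = min(k for k in adj if k < n)
        children, order = rooted_children(adj, ref)
        have_u = self.masks.shape[1] > 0
        have_o = self.lo.shape[1] > 0
        steps_u = np.zeros(self.masks.shape[1], dtype=np.int64)
        steps_o = np.zeros(self.lo.shape[1], dtype=np.int64)
        mk: Dict[int, np.ndarray] = {}
        lo: Dict[int, np.ndarray] = {}
        hi: Dict[int, np.ndarray] = {}
        for node in order:
            if node == ref:
                break
            if node < n:
                if have_u:
                    mk[node] = self.masks[node]
                if have_o:
                    lo[node], hi[node] = self.lo[node], self.hi[node]
            else:
                kids = children[node]
                if have_u:
                    m = mk[kids[0]]
                    for c in kids[1:]:
                        inter = m & mk[c]
                        zero = inter == 0
                        steps_u += zero
                        m = np.where(zero, m | mk[c], inter)
                    mk[node] = m
                if have_o:
                    a, b = lo[kids[0]], hi[kids[0]]
                    for c in kids[1:]:
                        A = np.maximum(a, lo[c])
                        B = np.minimum(b, hi[c])
                        steps_o += np.maximum(A - B, 0)
                        a, b = np.minimum(A, B), np.maximum(A, B)
                    lo[node], hi[node] = a, b
        top = children[ref][0]
        if have_u:
            steps_u += (mk[top] & self.masks[ref]) == 0
        if have_o:
            A = np.maximum(lo[top], self.lo[ref])
            B = np.minimum(hi[top], self.hi[ref])
            steps_o += np.maximum(A - B, 0)
        return steps_u, steps_o


def _pool_columns(arr: np.ndarray, weights: np.ndarray):
    """Pool identical columns of ``arr``, summing their weights."""
    if arr.shape[1] == 0:
        return arr, weights
    seen: Dict[bytes, int] = {}
    keep: List[int] = []
    w: List[float] = []
    cols = np.ascontiguousarray(arr.T)
    for j in range(arr.shape[1]):
        key = cols[j].tobytes()
        if key in seen:
            w[seen[key]] += weights[j]
        else:
            seen[key] = len(keep)
            keep.append(j)
            w.append(float(weights[j]))
    return arr[:, keep], np.array(w)


# ---------------------------------------------------------------------------
# tree length and per-character statistics
# ---------------------------------------------------------------------------

@dataclass
class OptimizationResult:
    per_char_steps: List[int]
    total_length: float
    downpass_sets: Optional[Dict] = None  # (node, char) -> frozenset, on request


def tree_length(
    tree: PhyloTree, matrix: CharacterMatrix, store_sets: bool = False
) -> OptimizationResult:
    """Parsimony length of ``tree``: per-character steps and weighted total."""
    if tree.n_leaves != matrix.n_taxa or tree.taxa != matrix.taxa:
        extra = sorted(set(tree.taxa) ^ set(matrix.taxa))
        raise MatrixError(f"tree/matrix taxa mismatch: {extra or 'ordering differs'}")
    scorer = TreeScorer(matrix, compress=False)
    su, so = scorer.per_pattern_steps(tree.adj)
    per_char = [0] * matrix.n_chars
    for k, j in enumerate(scorer.unord_idx):
        per_char[j] = int(su[k])
    for k, j in enumerate(scorer.ord_idx):
        per_char[j] = int(so[k])
    total = sum(matrix.specs[j].weight * per_char[j] for j in range(matrix.n_chars))
    if float(total).is_integer():
        total = int(total)
    sets = None
    if store_sets:
        sets = {}
        for j in range(matrix.n_chars):
            spec = matrix.specs[j]
            if spec.ordered:
                continue
            _, down = fitch_steps(tree, matrix.column(j), spec.max_state)
            for node, s in down.items():
                sets[(node, j)] = s
    return OptimizationResult(per_char_steps=per_char, total_length=total, downpass_sets=sets)


def min_steps(column: Sequence[StateSet], spec: CharacterSpec) -> int:
    """Minimum conceivable steps of a character on any tree (``m_i``).

    Unordered: one less than the smallest number of states that can cover
    every non-missing cell (minimizing over polymorphic resolutions).
    Ordered: the smallest achievable state range.
    """
    cells = [c for c in column if not c.is_missing]
    if not cells:
        return 0
    if spec.ordered:
        lo = max(min(c.members) for c in cells)
        hi = min(max(c.members) for c in cells)
        return max(0, lo - hi)
    universe = sorted(set().union(*(c.members for c in cells)))
    for size in range(1, len(universe) + 1):
        for combo in itertools.combinations(universe, size):
            s = set(combo)
            if all(c.members & s for c in cells):
                return size - 1
    return len(universe) - 1  # unreachable


def max_steps(column: Sequence[StateSet], spec: CharacterSpec) -> Optional[int]:
    """Maximum conceivable steps on any tree (``g_i``, star-tree worst case).

    Unordered: ``n_eff`` minus the largest count any single state can reach
    over polymorphic resolutions.  Ordered: computed by explicit topology
    enumeration for up to 8 effective cells, else ``None`` (unsupported).
    """
    cells = [c for c in column if not c.is_missing]
    n_eff = len(cells)
    if n_eff <= 1:
        return 0
    if not spec.ordered:
        universe = set().union(*(c.members for c in cells))
        best = max(sum(1 for c in cells if s in c.members) for s in universe)
        return n_eff - best
    if n_eff == 2:
        (a0, b0), (a1, b1) = (c.interval(spec.max_state) for c in cells)
        return max(0, max(a0, a1) - min(b0, b1))
    if n_eff > 8:
        return None
    # enumerate all topologies on the effective cells
    from .search import enumerate_adjacencies

    sub = CharacterMatrix.from_values(
        taxa=[f"t{i}" for i in range(n_eff)],
        rows=[[c] for c in cells],
        ordered=[True],
    )
    worst = 0
    for adj in enumerate_adjacencies(n_eff):
        t = PhyloTree(adj, sub.taxa)
        worst = max(worst, wagner_steps(t, sub.column(0)))
    return worst


def is_informative(column: Sequence[StateSet], spec: CharacterSpec) -> bool:
    """Parsimony-informative: the character can add steps beyond its minimum."""
    g = max_steps(column, spec)
    m = min_steps(column, spec)
    if g is not None:
        return g > m
    # ordered with too many cells to enumerate: two states each in >= 2 cells
    cells = [c for c in column if not c.is_missing]
    counts: Dict[int, int] = {}
    for c in cells:
        for s in c.members:
            counts[s] = counts.get(s, 0) + 1
    return sum(1 for v in counts.values() if v >= 2) >= 2


@dataclass
class EnsembleStats:
    """Ensemble homoplasy summary over a character set on one tree."""

    M: int
    S: int
    G: Optional[int]
    CI: Optional[float]
    RI: Optional[float]
    include_uninformative: bool = True
    warning: Optional[str] = None

    def rounded(self, ndigits: int = 2):
        ci = None if self.CI is None else round(self.CI, ndigits)
        ri = None if self.RI is None else round(self.RI, ndigits)
        return ci, ri


def char_diagnostics(
    matrix: CharacterMatrix, tree: PhyloTree
) -> pd.DataFrame:
    """Per-character table: steps ``s``, bounds ``m``/``g``, ci, ri.

    Character indices in the table are 1-based, matching published usage.
    Per-character ci = m/s is defined as 1.0 for invariant characters
    (s = 0); ri = (g - s) / (g - m) is NaN when g = m.
    """
    res = tree_length(tree, matrix)
    rows = []
    for j in range(matrix.n_chars):
        col, spec = matrix.column(j), matrix.specs[j]
        s = res.per_char_steps[j]
        m = min_steps(col, spec)
        g = max_steps(col, spec)
        ci = 1.0 if s == 0 else m / s
        if g is None or g == m:
            ri = np.nan
        else:
            ri = (g - s) / (g - m)
        rows.append(
            {
                "char": j + 1,
                "steps": s,
                "min_steps": m,
                "max_steps": np.nan if g is None else g,
                "ci": ci,
                "ri": ri,
                "informative": is_informative(col, spec),
            }
        )
    return pd.DataFrame(rows)


def ensemble_stats(
    matrix: CharacterMatrix,
    tree_or_trees,
    include_uninformative: bool = True,
) -> EnsembleStats:
    """Ensemble CI and RI of a tree (or of a set of equally long trees).

    All most-parsimonious trees share S, so for a tree set the first tree
    is scored.  With ``include_uninformative=False``, characters that
    cannot contribute homoplasy are dropped before summing (conventions
    differ between programs; both modes are exact).
    """
    tree = tree_or_trees[0] if isinstance(tree_or_trees, (list, tuple)) else tree_or_trees
    diag = char_diagnostics(matrix, tree)
    if not include_uninformative:
        diag = diag[diag["informative"]]
    M = int(diag["min_steps"].sum())
    S = int(diag["steps"].sum())
    g_missing = diag["max_steps"].isna().any()
    G = None if g_missing else int(diag["max_steps"].sum())
    CI = None if S == 0 else M / S
    warning = None
    if G is None:
        RI = None
        warning = "G unavailable (ordered character too large to enumerate)"
    elif G == M:
        RI = None if S > M else 1.0
        if RI is None:
            warning = "RI undefined: G = M with S > M"
    else:
        RI = (G - S) / (G - M)
    return EnsembleStats(
        M=M, S=S, G=G, CI=CI, RI=RI,
        include_uninformative=include_uninformative, warning=warning,
    )


# ---------------------------------------------------------------------------
# exact Sankoff DP (polytomy-safe) and the zero-length-branch rule
# ---------------------------------------------------------------------------

def _char_cost_matrix(spec: CharacterSpec) -> np.ndarray:
    k = spec.max_state + 1
    if spec.ordered:
        return np.abs(np.subtract.outer(np.arange(k), np.arange(k))).astype(float)
    return 1.0 - np.eye(k)


def _leaf_cost(cell: StateSet, max_state: int) -> np.ndarray:
    v = np.full(max_state + 1, np.inf)
    for s in cell.resolved(max_state):
        v[s] = 0.0
    return v


def sankoff_length(adj, matrix: CharacterMatrix) -> float:
    """Exact minimum length of an arbitrary (possibly multifurcating) tree."""
    n = matrix.n_taxa
    ref = min(k for k in adj if k < n)
    children, order = rooted_children(adj, ref)
    total = 0.0
    for j in range(matrix.n_chars):
        spec = matrix.specs[j]
        C = _char_cost_matrix(spec)
        cost: Dict[int, np.ndarray] = {}
        for node in order:
            if node < n:
                cost[node] = _leaf_cost(matrix.cells[node][j], spec.max_state)
            else:
                acc = np.zeros(spec.max_state + 1)
                for c in children[node]:
                    acc = acc + np.min(cost[c][None, :] + C, axis=1)
                cost[node] = acc
        top = children[ref][0]
        root_cost = cost[top] + np.min(cost[ref][None, :] + C, axis=1)
        total += spec.weight * float(np.min(root_cost))
    return int(total) if float(total).is_integer() else total


def min_branch_lengths(tree: PhyloTree, matrix: CharacterMatrix) -> Dict[Tuple[int, int], int]:
    """Minimum possible length of each internal branch over all optimizations.

    A branch has minimum length zero exactly when contracting it leaves the
    tree length unchanged; such branches are unsupported by any character
    under every most-parsimonious reconstruction and are candidates for
    collapse.
    """
    base = tree_length(tree, matrix).total_length
    out: Dict[Tuple[int, int], int] = {}
    n = tree.n_leaves
    for (u, v) in tree.edges():
        if u < n or v < n:
            continue  # external branches are never collapsed
        adj = {k: list(nbrs) for k, nbrs in tree.adj.items()}
        # contract (u, v): merge v into u
        adj[u] = [x for x in adj[u] if x != v] + [x for x in adj[v] if x != u]
        for x in adj.pop(v):
            if x != u:
                adj[x] = [u if y == v else y for y in adj[x]]
        contracted = sankoff_length(adj, matrix)
        out[(u, v)] = int(round(contracted - base)) if contracted > base else 0
    return out
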