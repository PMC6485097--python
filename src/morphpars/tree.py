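"""Unrooted phylogenetic trees over the taxa of a character matrix.

Trees are stored as an adjacency map over integer node ids: leaf ids are
the 0-based indices into the ``taxa`` list, internal nodes get ids >= the
leaf count.  Trees are unrooted; for display and for ancestral-state
polarity they are rooted on the edge leading to a designated outgroup
taxon.  Consensus trees may be multifurcating; search and optimization
operate on strictly binary trees (every internal node of degree 3).
"""

from __future__ import annotations

import io
import re
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Tuple

import dendropy

__all__ = ["PhyloTree", "TreeError"]

Split = FrozenSet[int]


class TreeError(ValueError):
    pass


# ---------------------------------------------------------------------------
# low-level adjacency helpers (shared with the search module)
# ---------------------------------------------------------------------------

def copy_adj(adj: Dict[int, List[int]]) -> Dict[int, List[int]]:
    return {k: list(v) for k, v in adj.items()}


def adj_edges(adj) -> List[Tuple[int, int]]:
    """Edges as sorted (u, v) tuples with u < v, in deterministic order."""
    return sorted(
        {(u, v) if u < v else (v, u) for u in adj for v in adj[u]}
    )


def add_leaf_on_edge(adj, leaf: int, edge: Tuple[int, int], new_internal: int) -> None:
    """Subdivide ``edge`` with ``new_internal`` and hang ``leaf`` off it."""
    u, v = edge
    adj[u] = [new_internal if x == v else x for x in adj[u]]
    adj[v] = [new_internal if x == u else x for x in adj[v]]
    adj[new_internal] = [u, v, leaf]
    adj[leaf] = [new_internal]


def remove_leaf(adj, leaf: int) -> Tuple[int, int]:
    """Remove ``leaf`` and smooth its attachment node; returns restored edge."""
    (p,) = adj.pop(leaf)
    adj[p] = [x for x in adj[p] if x != leaf]
    if len(adj[p]) == 2:
        a, b = adj[p]
        adj[a] = [b if x == p else x for x in adj[a]]
        adj[b] = [a if x == p else x for x in adj[b]]
        del adj[p]
        return (a, b) if a < b else (b, a)
    return (p, p)


def suppress_degree2(adj, node: int) -> None:
    if node in adj and len(adj[node]) == 2:
        a, b = adj[node]
        adj[a] = [b if x == node else x for x in adj[a]]
        adj[b] = [a if x == node else x for x in adj[b]]
        del adj[node]


def rooted_children(adj, root: int) -> Tuple[Dict[int, List[int]], List[int]]:
    """Orient the tree away from ``root``; returns (children map, postorder).

    ``root`` may be any node (typically a leaf).  The postorder list ends
    with ``root``; children lists preserve deterministic (sorted-id) order.
    """
    children: Dict[int, List[int]] = {}
    order: List[int] = []
    stack = [(root, -1, False)]
    while stack:
        node, parent, done = stack.pop()
        if done:
            order.append(node)
            continue
        kids = sorted(x for x in adj[node] if x != parent)
        children[node] = kids
        stack.append((node, parent, True))
        for k in reversed(kids):
            stack.append((k, node, False))
    return children, order


def adj_bipartitions(adj, n_leaves: int) -> FrozenSet[Split]:
    """Non-trivial splits, each canonicalized as the side not containing leaf 0."""
    ref = min(k for k in adj if k < n_leaves)
    children, order = rooted_children(adj, ref)
    below: Dict[int, frozenset] = {}
    splits = set()
    all_leaves = frozenset(k for k in adj if k < n_leaves)
    for node in order:
        if node < n_leaves:
            below[node] = frozenset([node])
        else:
            below[node] = frozenset().union(*(below[c] for c in children[node]))
        if node != ref and 1 < len(below[node]) < len(all_leaves) - 1:
            splits.add(below[node])
    return frozenset(splits)


# ---------------------------------------------------------------------------
# PhyloTree
# ---------------------------------------------------------------------------

class PhyloTree:
    """An unrooted tree whose leaves are the taxa of a matrix.

    Parameters
    ----------
    adj
        Adjacency map; keys 0..n-1 must be the leaves (degree 1), matching
        positions in ``taxa``.
    taxa
        Leaf labels, in matrix order.
    """

    __slots__ = ("taxa", "adj")

    def __init__(self, adj: Dict[int, List[int]], taxa: Sequence[str]):
        self.taxa = list(taxa)
        self.adj = {k: list(v) for k, v in adj.items()}
        n = len(self.taxa)
        leaves = {k for k in self.adj if k < n}
        if leaves != set(range(n)):
            raise TreeError(
                f"tree leaves {sorted(leaves)} do not cover taxa 0..{n - 1}"
            )
        for k in range(n):
            if len(self.adj[k]) != 1 and n > 2:
                raise TreeError(f"leaf {self.taxa[k]!r} has degree {len(self.adj[k])}")

    # -- constructors ----------------------------------------------------
    @classmethod
    def from_newick(cls, text: str, taxa: Optional[Sequence[str]] = None) -> "PhyloTree":
        tree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True
        )
        leaf_labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
        norm = [re.sub(r"\s+", "_", l.strip().strip("'\"")) for l in leaf_labels]
        if taxa is None:
            taxa = norm
        index = {t: i for i, t in enumerate(taxa)}
        missing = [l for l in norm if l not in index]
        if missing:
            raise TreeError(f"newick leaves not in taxon set: {missing}")
        n = len(taxa)
        adj: Dict[int, List[int]] = {}
        next_id = n
        ids = {}
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                lbl = re.sub(r"\s+", "_", node.taxon.label.strip().strip("'\""))
                ids[node] = index[lbl]
            else:
                ids[node] = next_id
                next_id += 1
            adj.setdefault(ids[node], [])
        for node in tree.preorder_node_iter():
            for child in node.child_nodes():
                adj[ids[node]].append(ids[child])
                adj[ids[child]].append(ids[node])
        # unroot: suppress a degree-2 root left by rooted newick
        suppress_degree2(adj, ids[tree.seed_node])
        return cls(adj, taxa)

    @classmethod
    def from_bipartitions(
        cls, taxa: Sequence[str], splits: Iterable[Split]
    ) -> "PhyloTree":
        """Build the (possibly multifurcating) tree displaying exactly ``splits``.

        Splits must be pairwise compatible and canonicalized to the side not
        containing leaf 0 (as produced by :meth:`bipartitions`).
        """
        n = len(taxa)
        splits = sorted(set(splits), key=lambda s: (-len(s), sorted(s)))
        for a in splits:
            for b in splits:
                if a & b and not (a <= b or b <= a):
                    raise TreeError("incompatible splits passed to from_bipartitions")
        next_id = n
        root = next_id
        next_id += 1
        adj: Dict[int, List[int]] = {root: []}
        # parent of each cluster = smallest strictly containing cluster (or root)
        node_of: Dict[Split, int] = {}
        parent_of: Dict[int, int] = {}
        for s in splits:
            node_of[s] = next_id
            adj[next_id] = []
            enclosing = [t for t in splits if len(t) > len(s) and s < t]
            parent = node_of[min(enclosing, key=len)] if enclosing else root
            parent_of[next_id] = parent
            next_id += 1
        for s, v in node_of.items():
            p = parent_of[v]
            adj[p].append(v)
            adj[v].append(p)
        for leaf in range(n):
            enclosing = [t for t in splits if leaf in t]
            parent = node_of[min(enclosing, key=len)] if enclosing else root
            adj.setdefault(leaf, []).append(parent)
            adj[parent].append(leaf)
        suppress_degree2(adj, root)
        return cls(adj, taxa)

    @classmethod
    def random(cls, taxa: Sequence[str], rng) -> "PhyloTree":
        """Uniform-addition random binary topology (not uniform over trees)."""
        n = len(taxa)
        if n < 3:
            raise TreeError("need at least 3 taxa for an unrooted tree")
        order = list(rng.permutation(n))
        a, b, c = order[:3]
        hub = n
        adj = {a: [hub], b: [hub], c: [hub], hub: [a, b, c]}
        next_id = n + 1
        for leaf in order[3:]:
            edges = adj_edges(adj)
            u, v = edges[int(rng.integers(len(edges)))]
            add_leaf_on_edge(adj, int(leaf), (u, v), next_id)
            next_id += 1
        return cls(adj, taxa)

    # -- basics ----------------------------------------------------------
    @property
    def n_leaves(self) -> int:
        return len(self.taxa)

    def copy(self) -> "PhyloTree":
        return PhyloTree(self.adj, self.taxa)

    def edges(self) -> List[Tuple[int, int]]:
        return adj_edges(self.adj)

    def internal_nodes(self) -> List[int]:
        return sorted(k for k in self.adj if k >= self.n_leaves)

    def is_binary(self) -> bool:
        n = self.n_leaves
        return all(len(self.adj[k]) == 3 for k in self.adj if k >= n)

    def bipartitions(self) -> FrozenSet[Split]:
        return adj_bipartitions(self.adj, self.n_leaves)

    def topology_key(self) -> FrozenSet[Split]:
        return self.bipartitions()

    def same_topology(self, other: "PhyloTree") -> bool:
        return self.taxa == other.taxa and self.topology_key() == other.topology_key()

    def clade_leafset(self, split: Split) -> List[str]:
        return [self.taxa[i] for i in sorted(split)]

    # -- rooting and serialization ----------------------------------------
    def rooted(self, outgroup: int = 0):
        """Root on the edge to ``outgroup``; returns (children, postorder, root).

        The virtual root is a fresh node with two children: the outgroup
        leaf and the rest of the tree.
        """
        if outgroup not in self.adj:
            raise TreeError(f"outgroup id {outgroup} not in tree")
        adj = copy_adj(self.adj)
        (nbr,) = adj[outgroup] if len(adj[outgroup]) == 1 else (None,)
        if nbr is None:
            raise TreeError("outgroup must be a leaf")
        root = max(adj) + 1
        adj[outgroup] = [root]
        adj[nbr] = [root if x == outgroup else x for x in adj[nbr]]
        adj[root] = [outgroup, nbr]
        children, order = rooted_children(adj, root)
        return children, order, root

    def to_newick(
        self,
        outgroup: int = 0,
        support: Optional[Dict[Split, object]] = None,
        quote_spaces: bool = True,
    ) -> str:
        """Newick string, displayed rooted on the ``outgroup`` leaf edge.

        ``support`` maps canonical splits to values rendered as internal
        node labels (e.g. bootstrap percentages).
        """
        children, order, root = self.rooted(outgroup)
        below: Dict[int, frozenset] = {}
        n = self.n_leaves
        parts: Dict[int, str] = {}
        for node in order:
            if node < n:
                below[node] = frozenset([node])
                label = self.taxa[node]
                if "'" not in label and (" " in label) and quote_spaces:
                    label = f"'{label}'"
                parts[node] = label
            else:
                kids = children[node]
                below[node] = frozenset().union(*(below[c] for c in kids))
                inner = ",".join(parts[c] for c in kids)
                label = ""
                if support is not None and node != root:
                    split = below[node]
                    if 0 in split:  # canonical side excludes leaf 0
                        split = frozenset(range(n)) - split
                    val = support.get(frozenset(split))
                    if val is not None:
                        label = str(val)
                parts[node] = f"({inner}){label}"
        return parts[root] + ";"

    def __repr__(self):
        return f"PhyloTree({self.to_newick()})"
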