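"""Ancestral-state reconstruction and synapomorphy mapping.

States are reconstructed on a tree rooted on an outgroup taxon by exact
dynamic programming (0/1 change costs for unordered characters, |i - j|
for ordered ones), then resolved to a single state per node under one of
two conventions: ACCTRAN places changes as close to the root as possible
(favoring reversals over parallelisms), DELTRAN delays them toward the
tips.  Both are minimum reconstructions, so for every character the
changes summed over branches equal its tree length.  A change is flagged
*unambiguous* when both conventions place it on the same branch with the
same states.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .matrix import CharacterMatrix, MatrixError
from .optimization import _char_cost_matrix, _leaf_cost, char_diagnostics
from .tree import PhyloTree, TreeError

__all__ = [
    "Apomorphy",
    "ApomorphyList",
    "acctran_states",
    "ancestral_states",
    "synapomorphy_map",
    "per_character_ci",
]

Split = FrozenSet[int]


@dataclass(frozen=True)
class Apomorphy:
    """One state change on one branch.

    ``clade`` lists the taxa below the branch (a single taxon for terminal
    branches); ``char`` is 1-based.
    """

    clade: Tuple[str, ...]
    char: int
    from_state: int
    to_state: int
    unambiguous: bool = False
    ci: Optional[float] = None


@dataclass
class ApomorphyList:
    tree: PhyloTree
    outgroup: str
    entries: List[Apomorphy] = field(default_factory=list)

    def on_clade(self, taxa: Sequence[str]) -> List[Apomorphy]:
        key = tuple(sorted(taxa))
        return [e for e in self.entries if tuple(sorted(e.clade)) == key]

    def annotated_newick(self) -> str:
        """Newick with per-node labels listing the changes on each internal
        branch as ``char[state]`` tokens (terminal-branch changes appear in
        the table only)."""
        taxa = self.tree.taxa
        n = len(taxa)
        idx = {t: i for i, t in enumerate(taxa)}
        by_split: Dict[FrozenSet[int], List[str]] = {}
        for e in self.entries:
            if len(e.clade) < 2:
                continue
            split = frozenset(idx[x] for x in e.clade)
            if 0 in split:
                split = frozenset(range(n)) - split
            by_split.setdefault(split, []).append(f"{e.char}[{e.to_state}]")
        labels = {s: "'" + " ".join(v) + "'" for s, v in by_split.items()}
        return self.tree.to_newick(outgroup=idx[self.outgroup], support=labels)

    def to_dataframe(self) -> pd.DataFrame:
        recs = [
            {
                "clade": " ".join(e.clade),
                "char": e.char,
                "from": e.from_state,
                "to": e.to_state,
                "unambiguous": e.unambiguous,
                "ci": np.nan if e.ci is None else e.ci,
            }
            for e in sorted(self.entries, key=lambda e: (len(e.clade), e.clade, e.char))
        ]
        return pd.DataFrame(
            recs, columns=["clade", "char", "from", "to", "unambiguous", "ci"]
        )


def _resolve_outgroup(tree: PhyloTree, outgroup) -> int:
    if outgroup is None:
        return 0
    if isinstance(outgroup, str):
        try:
            return tree.taxa.index(outgroup)
        except ValueError:
            raise TreeError(f"outgroup {outgroup!r} is not a leaf of the tree") from None
    return int(outgroup)


def ancestral_states(
    tree: PhyloTree,
    matrix: CharacterMatrix,
    outgroup=None,
    convention: str = "acctran",
) -> Dict[int, List[int]]:
    """One reconstructed state per node per character.

    Returns a map from node id (leaves included; the virtual root under
    key ``-1``) to the per-character state list.  ``convention`` is
    ``"acctran"`` or ``"deltran"``; ties at equal cost are broken toward a
    change (ACCTRAN) or away from one (DELTRAN), then toward the smallest
    state.  The root state prefers states observed in the outgroup.
    """
    if convention not in ("acctran", "deltran"):
        raise ValueError(f"unknown convention {convention!r}")
    if tree.taxa != matrix.taxa:
        raise MatrixError("tree/matrix taxa mismatch")
    og = _resolve_outgroup(tree, outgroup)
    children, order, root = tree.rooted(og)
    n = tree.n_leaves
    assign: Dict[int, List[int]] = {node: [] for node in order}
    assign[-1] = assign.pop(root)  # stable key for the virtual root

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
        # root choice: minimal cost, preferring a state shown by the outgroup
        root_cost = cost[root]
        best = root_cost.min()
        candidates = [s for s in range(len(root_cost)) if root_cost[s] == best]
        og_states = matrix.cells[og][j].resolved(spec.max_state)
        preferred = [s for s in candidates if s in og_states]
        root_state = (preferred or candidates)[0]
        assign[-1].append(root_state)
        # preorder resolution
        stack = [(c, root_state) for c in reversed(children[root])]
        while stack:
            node, p = stack.pop()
            tot = cost[node] + C[p]
            best = tot.min()
            candidates = [s for s in range(len(tot)) if tot[s] == best]
            if convention == "acctran":
                moved = [s for s in candidates if s != p]
                state = moved[0] if moved else candidates[0]
            else:
                state = p if p in candidates else candidates[0]
            assign[node].append(state)
            for c in reversed(children.get(node, [])):
                stack.append((c, state))
    return assign


def acctran_states(tree: PhyloTree, matrix: CharacterMatrix, outgroup=None):
    """ACCTRAN reconstruction (changes placed as early as possible)."""
    return ancestral_states(tree, matrix, outgroup=outgroup, convention="acctran")


def _changes(
    tree: PhyloTree, matrix: CharacterMatrix, assign: Dict[int, List[int]], outgroup: int
):
    """Per-branch change set: {(clade leaf frozenset, char, from, to), ...}."""
    children, order, root = tree.rooted(outgroup)
    n = tree.n_leaves
    below: Dict[int, frozenset] = {}
    for node in order:
        if node < n:
            below[node] = frozenset([node])
        else:
            below[node] = frozenset().union(*(below[c] for c in children[node]))
    out = set()
    for node in order:
        kids = children[node]
        pstates = assign[-1 if node == root else node]
        for c in kids:
            cstates = assign[c]
            for j, (a, b) in enumerate(zip(pstates, cstates)):
                if a != b:
                    out.add((below[c], j + 1, a, b))
    return out


def synapomorphy_map(
    tree: PhyloTree, matrix: CharacterMatrix, outgroup=None
) -> ApomorphyList:
    """Per-branch character-state changes with per-character CI attached.

    Changes are reported under ACCTRAN; the ``unambiguous`` flag marks
    changes that DELTRAN places identically.  A change onto a polymorphic
    terminal is reported only when no member of the terminal's state set
    matches the reconstructed parent state (the reconstruction picks the
    cheapest member, so a matching member yields no change).
    """
    og = _resolve_outgroup(tree, outgroup)
    acc = ancestral_states(tree, matrix, outgroup=og, convention="acctran")
    dlt = ancestral_states(tree, matrix, outgroup=og, convention="deltran")
    acc_changes = _changes(tree, matrix, acc, og)
    dlt_changes = _changes(tree, matrix, dlt, og)
    diag = char_diagnostics(matrix, tree)
    ci_of = dict(zip(diag["char"], diag["ci"]))
    entries = [
        Apomorphy(
            clade=tuple(matrix.taxa[i] for i in sorted(clade)),
            char=char,
            from_state=a,
            to_state=b,
            unambiguous=(clade, char, a, b) in dlt_changes,
            ci=float(ci_of[char]),
        )
        for (clade, char, a, b) in acc_changes
    ]
    entries.sort(key=lambda e: (len(e.clade), e.clade, e.char))
    return ApomorphyList(tree=tree, outgroup=matrix.taxa[og], entries=entries)


def per_character_ci(matrix: CharacterMatrix, tree: PhyloTree) -> pd.DataFrame:
    """Per-character consistency index table (char 1-based, ci = m/s)."""
    diag = char_diagnostics(matrix, tree)
    return diag[["char", "steps", "min_steps", "ci"]].copy()
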