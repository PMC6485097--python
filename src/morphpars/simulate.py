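"""Synthetic morphological matrices with a known generating tree.

Characters evolve on a random (or supplied) binary tree by a per-branch
Bernoulli jump process: along each branch, with probability
``change_prob`` the state jumps to a uniformly chosen different state
(ordered variant: one step up or down).  All branch lengths are one; this
matches parsimony's change-counting view of morphology and avoids any
rate/branch-length entanglement.  After simulation a fraction of cells is
masked to missing and a fraction widened to polymorphic by adding an
adjacent state, emulating the look of published matrices (a few percent
of ``?`` and ``(0/1)`` cells).  The defaults mirror a typical published
morphological dataset: 30 taxa, 103 characters, 2-4 states.

``degrade_to_teeth_taxa`` emulates fossil taxa known only from isolated
teeth: for chosen taxa, every character outside a small dental subset
(22 of 103 by default, i.e. about 80% of cells missing) is masked.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .matrix import CharacterMatrix, StateSet
from .tree import PhyloTree

__all__ = ["SimulationConfig", "simulate_matrix", "degrade_to_teeth_taxa"]


@dataclass(frozen=True)
class SimulationConfig:
    n_taxa: int = 30
    n_chars: int = 103
    n_states: int = 3
    change_prob: float = 0.1
    missing_frac: float = 0.05
    polymorphic_frac: float = 0.02
    ordered: bool = False
    seed: int = 0
    true_tree: Optional[PhyloTree] = None
    taxa: Optional[Tuple[str, ...]] = None

    def __post_init__(self):
        if self.n_chars < 1:
            raise ValueError("n_chars must be >= 1")
        if self.n_states < 2:
            raise ValueError("n_states must be >= 2")
        if not 0.0 <= self.change_prob <= 1.0:
            raise ValueError("change_prob must be in [0, 1]")
        if min(self.missing_frac, self.polymorphic_frac) < 0 or (
            self.missing_frac + self.polymorphic_frac >= 1
        ):
            raise ValueError("missing_frac + polymorphic_frac must be < 1")


def simulate_matrix(config: SimulationConfig) -> Tuple[CharacterMatrix, PhyloTree]:
    """Simulate a matrix; returns ``(matrix, true_tree)``, reproducible per seed."""
    rng = np.random.default_rng(config.seed)
    if config.true_tree is not None:
        tree = config.true_tree
        taxa = tree.taxa
    else:
        taxa = list(config.taxa) if config.taxa else [
            f"T{i + 1:02d}" for i in range(config.n_taxa)
        ]
        tree = PhyloTree.random(taxa, rng)
    n = len(taxa)
    max_state = config.n_states - 1
    children, order, root = tree.rooted(0)
    preorder = list(reversed(order))  # root first

    states = np.empty((max(tree.adj) + 2, config.n_chars), dtype=np.int64)
    node_rows = {node: node for node in tree.adj}
    node_rows[root] = max(tree.adj) + 1
    states[node_rows[root]] = rng.integers(0, config.n_states, size=config.n_chars)
    parent_of = {}
    for p in preorder:
        for c in children.get(p, []):
            parent_of[c] = p
    for node in preorder:
        if node == root:
            continue
        ps = states[node_rows[parent_of[node]]]
        jump = rng.random(config.n_chars) < config.change_prob
        new = ps.copy()
        if config.ordered:
            step = np.where(rng.random(config.n_chars) < 0.5, -1, 1)
            # reflect at the state boundaries
            cand = ps + step
            cand = np.where(cand < 0, 1, cand)
            cand = np.where(cand > max_state, max_state - 1, cand)
            new[jump] = cand[jump]
        else:
            shift = rng.integers(1, config.n_states, size=config.n_chars)
            new[jump] = (ps[jump] + shift[jump]) % config.n_states
        states[node_rows[node]] = new

    cells: List[List[StateSet]] = [
        [StateSet.single(int(states[node_rows[i], j])) for j in range(config.n_chars)]
        for i in range(n)
    ]

    # mask and widen cells
    n_cells = n * config.n_chars
    k_miss = int(round(config.missing_frac * n_cells))
    k_poly = int(round(config.polymorphic_frac * n_cells))
    flat = rng.permutation(n_cells)
    for idx in flat[:k_miss]:
        i, j = divmod(int(idx), config.n_chars)
        cells[i][j] = StateSet.missing()
    for idx in flat[k_miss: k_miss + k_poly]:
        i, j = divmod(int(idx), config.n_chars)
        s = next(iter(cells[i][j].members))
        adjacent = s + 1 if s < max_state else s - 1
        cells[i][j] = StateSet.poly([s, adjacent])

    # state ceilings are inferred from the observed states, matching the
    # behavior of the matrix readers, so simulated matrices round-trip
    matrix = CharacterMatrix.from_values(
        taxa,
        cells,
        ordered=[config.ordered] * config.n_chars,
    )
    return matrix, tree


def degrade_to_teeth_taxa(
    matrix: CharacterMatrix,
    taxa_subset: Sequence[str],
    keep_chars: Optional[Sequence[int]] = None,
    seed: int = 0,
) -> CharacterMatrix:
    """Mask all characters outside ``keep_chars`` (0-based) for chosen taxa.

    With ``keep_chars=None`` a random dental-sized subset is drawn: 22
    characters when the matrix has 103, else the same proportion, so a
    degraded taxon is ~80% missing.
    """
    if keep_chars is None:
        k = 22 if matrix.n_chars == 103 else max(1, round(matrix.n_chars * 22 / 103))
        rng = np.random.default_rng(seed)
        keep_chars = sorted(int(x) for x in rng.choice(matrix.n_chars, size=k, replace=False))
    keep = set(int(j) for j in keep_chars)
    bad = [j for j in keep if not 0 <= j < matrix.n_chars]
    if bad:
        raise ValueError(f"keep_chars out of range: {bad}")
    out = matrix.copy()
    for label in taxa_subset:
        i = out.taxon_index(label)
        out.cells[i] = [
            cell if j in keep else StateSet.missing()
            for j, cell in enumerate(out.cells[i])
        ]
    out.validate()
    return out
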