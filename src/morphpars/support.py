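"""Clade support: Bremer decay indices and nonparametric bootstrap.

The Bremer (decay) value of a clade is the number of extra steps needed
before the clade disappears from the optimal set: the length of the best
tree *not* containing the clade minus the best overall length.  It is
computed by converse-constraint search — exact branch-and-bound with
clade-containing trees rejected when the taxon count is small, otherwise
a penalized RAS+TBR search whose objective adds a large constant to any
tree displaying the clade.

Bootstrap support is the fraction of character-resampling pseudoreplicates
whose optimal trees (summarized by their strict consensus) contain the
clade; each pseudoreplicate draws characters with replacement up to the
original character count and is analyzed with a reduced heuristic search.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .matrix import CharacterMatrix
from .search import (
    SearchConfig,
    SearchResult,
    branch_and_bound,
    majority_rule_consensus,
    ras_tbr_search,
    strict_consensus,
)
from .tree import PhyloTree, TreeError, adj_bipartitions

__all__ = [
    "BremerConfig",
    "BootstrapConfig",
    "SupportRow",
    "SupportTable",
    "bremer_supports",
    "bootstrap_supports",
    "merge_support_tables",
]

Split = FrozenSet[int]
_PENALTY = 10**6


@dataclass(frozen=True)
class BremerConfig:
    exact_max_taxa: int = 10   # converse branch-and-bound up to this size
    cap: int = 20              # heuristic decay values above this are censored
    heuristic_replicates: int = 20
    hold_per_step: int = 1
    seed: int = 0


@dataclass(frozen=True)
class BootstrapConfig:
    replicates: int = 1000
    ras_replicates: int = 10   # reduced search per pseudoreplicate
    hold_per_step: int = 1
    max_trees_per_replicate: int = 16
    seed: int = 0


@dataclass
class SupportRow:
    split: Split
    clade: Tuple[str, ...]
    bremer: Optional[int] = None
    bremer_censored: bool = False
    bootstrap_pct: Optional[float] = None


@dataclass
class SupportTable:
    taxa: List[str]
    rows: List[SupportRow]
    majority_tree: Optional[PhyloTree] = None

    def row_for(self, split: Split) -> Optional[SupportRow]:
        for r in self.rows:
            if r.split == split:
                return r
        return None

    def to_dataframe(self) -> pd.DataFrame:
        recs = []
        for r in sorted(self.rows, key=lambda r: (len(r.split), r.clade)):
            brm = "" if r.bremer is None else (f">{r.bremer}" if r.bremer_censored else r.bremer)
            recs.append(
                {
                    "clade": " ".join(r.clade),
                    "bremer": brm,
                    "bootstrap_pct": "" if r.bootstrap_pct is None else round(r.bootstrap_pct, 1),
                }
            )
        return pd.DataFrame(recs, columns=["clade", "bremer", "bootstrap_pct"])


# ---------------------------------------------------------------------------
# Bremer decay
# ---------------------------------------------------------------------------

def _contains_split(adj, n_leaves: int, split: Split) -> bool:
    return split in adj_bipartitions(adj, n_leaves)


def min_length_lacking(
    matrix: CharacterMatrix, split: Split, config: BremerConfig, l_min: float
) -> Tuple[Optional[float], bool]:
    """Best length over trees not displaying ``split``; (length, censored)."""
    n = matrix.n_taxa
    if n <= config.exact_max_taxa:
        res = branch_and_bound(
            matrix,
            SearchConfig(collapse=False, max_trees=1, collect_all=False),
            reject=lambda adj: _contains_split(adj, n, split),
        )
        return res.length, False
    # penalized heuristic: any tree displaying the split costs an extra 1e6
    penalty = lambda adj: _PENALTY if _contains_split(adj, n, split) else 0
    res = ras_tbr_search(
        matrix,
        SearchConfig(
            replicates=config.heuristic_replicates,
            hold_per_step=config.hold_per_step,
            seed=config.seed,
            collapse=False,
            collect_all=False,
        ),
        penalty=penalty,
    )
    ok = [t for t in res.binary_trees if split not in t.bipartitions()]
    if not ok:
        return None, True
    best = res.length
    if best - l_min > config.cap:
        return best, True
    return best, False


def bremer_supports(
    matrix: CharacterMatrix,
    search_result: SearchResult,
    config: BremerConfig = BremerConfig(),
) -> SupportTable:
    """Bremer decay value for every strict-consensus clade of the MPT set.

    Clades absent from the strict consensus have decay 0 by definition (a
    shortest tree already lacks them) and are not listed.
    """
    trees = search_result.trees
    cons = strict_consensus(trees)
    rows = []
    for split in sorted(cons.bipartitions(), key=lambda s: (len(s), sorted(s))):
        best, censored = min_length_lacking(matrix, split, config, search_result.length)
        if best is None:
            bremer, censored = config.cap, True
        else:
            bremer = int(round(best - search_result.length))
        rows.append(
            SupportRow(
                split=split,
                clade=tuple(cons.clade_leafset(split)),
                bremer=bremer,
                bremer_censored=censored,
            )
        )
    return SupportTable(taxa=list(matrix.taxa), rows=rows)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def bootstrap_supports(
    matrix: CharacterMatrix, config: BootstrapConfig = BootstrapConfig()
) -> SupportTable:
    """Character-resampling bootstrap frequencies per clade.

    Returns a table of every clade seen in any pseudoreplicate consensus
    (frequency in percent) and the majority-rule consensus tree with
    frequencies attached.
    """
    rng = np.random.default_rng(config.seed)
    n_chars = matrix.n_chars
    counts: Dict[Split, int] = {}
    rep_seeds = [int(s) for s in rng.integers(0, 2**31 - 1, size=config.replicates)]
    for seed in rep_seeds:
        local = np.random.default_rng(seed)
        idx = [int(x) for x in local.integers(0, n_chars, size=n_chars)]
        sub = matrix.subset_characters(idx)
        res = ras_tbr_search(
            sub,
            SearchConfig(
                replicates=config.ras_replicates,
                hold_per_step=config.hold_per_step,
                seed=seed,
                collapse=False,
                collect_all=True,
                max_trees=config.max_trees_per_replicate,
            ),
        )
        cons = strict_consensus(res.binary_trees)
        for split in cons.bipartitions():
            counts[split] = counts.get(split, 0) + 1

    rows = []
    freqs: Dict[Split, float] = {}
    for split, c in counts.items():
        pct = 100.0 * c / config.replicates
        freqs[split] = pct
        rows.append(
            SupportRow(
                split=split,
                clade=tuple(matrix.taxa[i] for i in sorted(split)),
                bootstrap_pct=pct,
            )
        )
    majority = [s for s, p in freqs.items() if p > 50.0]
    maj_tree = PhyloTree.from_bipartitions(matrix.taxa, majority)
    return SupportTable(taxa=list(matrix.taxa), rows=rows, majority_tree=maj_tree)


def merge_support_tables(
    bremer: Optional[SupportTable], bootstrap: Optional[SupportTable]
) -> SupportTable:
    """Join Bremer and bootstrap tables on the canonical split."""
    if bremer is None and bootstrap is None:
        raise ValueError("nothing to merge")
    taxa = (bremer or bootstrap).taxa
    by_split: Dict[Split, SupportRow] = {}
    for table in (bremer, bootstrap):
        if table is None:
            continue
        for r in table.rows:
            tgt = by_split.setdefault(r.split, SupportRow(split=r.split, clade=r.clade))
            if r.bremer is not None:
                tgt.bremer, tgt.bremer_censored = r.bremer, r.bremer_censored
            if r.bootstrap_pct is not None:
                tgt.bootstrap_pct = r.bootstrap_pct
    return SupportTable(
        taxa=taxa,
        rows=list(by_split.values()),
        majority_tree=None if bootstrap is None else bootstrap.majority_tree,
    )
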