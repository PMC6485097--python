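"""End-to-end analysis: read -> recode -> search -> consensus -> supports
-> synapomorphies -> report.

All randomness flows from one top-level seed, split deterministically per
stage, so the JSON report is byte-identical across runs with the same
inputs.  Every default that fills a gap left by the analysis settings
(e.g. an unspecified outgroup) is logged once at WARN level and echoed in
the report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional

import numpy as np

from .apomorphies import ApomorphyList, synapomorphy_map
from .matrix import CharacterMatrix
from .matrix_io import RecodingLedger, apply_recodings, read_nexus, read_tnt
from .optimization import char_diagnostics, ensemble_stats
from .search import (
    SearchConfig,
    majority_rule_consensus,
    search,
    strict_consensus,
)
from .support import (
    BootstrapConfig,
    BremerConfig,
    SupportTable,
    bootstrap_supports,
    bremer_supports,
    merge_support_tables,
)
from .tree import PhyloTree

logger = logging.getLogger("morphpars")

__all__ = ["AnalysisConfig", "AnalysisReport", "run_analysis", "variant_ordered", "read_matrix"]


@dataclass(frozen=True)
class AnalysisConfig:
    """Flat configuration mirroring the search settings plus toggles."""

    method: str = "auto"
    replicates: int = 1000
    hold_per_step: int = 1
    seed: int = 0
    max_trees: int = 10000
    collapse: bool = True
    ordered_all: bool = False
    ci_include_uninformative: bool = True
    outgroup: Optional[str] = None
    do_bremer: bool = True
    do_bootstrap: bool = True
    bootstrap_replicates: int = 1000
    bootstrap_ras_replicates: int = 10
    bremer_cap: int = 20
    bremer_heuristic_replicates: int = 20
    format: str = "nexus"
    recodings: Optional[str] = None  # path to a ledger TSV

    @classmethod
    def from_json(cls, text: str) -> "AnalysisConfig":
        return cls(**json.loads(text))

    def to_dict(self) -> Dict:
        return dataclasses.asdict(self)


def variant_ordered(config: AnalysisConfig) -> AnalysisConfig:
    """The all-characters-ordered variant of a configuration (idempotent)."""
    return replace(config, ordered_all=True)


@dataclass
class AnalysisReport:
    length: float
    mpt_count: int
    ci: Optional[float]
    ri: Optional[float]
    ci_informative_only: Optional[float]
    ri_informative_only: Optional[float]
    mpt_newicks: List[str]
    strict_consensus_newick: str
    bootstrap_majority_newick: Optional[str]
    supports: Optional[SupportTable]
    apomorphies: Optional[ApomorphyList]
    settings: Dict
    warnings: List[str]
    method_used: str

    def to_json(self) -> str:
        sup = None
        if self.supports is not None:
            sup = [
                {
                    "clade": list(r.clade),
                    "bremer": r.bremer,
                    "bremer_censored": r.bremer_censored,
                    "bootstrap_pct": r.bootstrap_pct,
                }
                for r in sorted(self.supports.rows, key=lambda r: (len(r.clade), r.clade))
            ]
        apo = None
        if self.apomorphies is not None:
            apo = [
                {
                    "clade": list(e.clade),
                    "char": e.char,
                    "from": e.from_state,
                    "to": e.to_state,
                    "unambiguous": e.unambiguous,
                    "ci": e.ci,
                }
                for e in self.apomorphies.entries
            ]
        payload = {
            "length": self.length,
            "mpt_count": self.mpt_count,
            "ci": self.ci,
            "ri": self.ri,
            "ci_informative_only": self.ci_informative_only,
            "ri_informative_only": self.ri_informative_only,
            "mpt_newicks": self.mpt_newicks,
            "strict_consensus": self.strict_consensus_newick,
            "bootstrap_majority": self.bootstrap_majority_newick,
            "supports": sup,
            "apomorphies": apo,
            "settings": self.settings,
            "warnings": self.warnings,
            "method_used": self.method_used,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def read_matrix(path_or_text: str, fmt: str = "nexus") -> CharacterMatrix:
    """Read a matrix from a path or literal text in either dialect."""
    text = path_or_text
    if os.path.exists(path_or_text):
        with open(path_or_text) as fh:
            text = fh.read()
    if fmt == "tnt":
        return read_tnt(text)
    return read_nexus(text)


def _stage_seeds(seed: int, n: int) -> List[int]:
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1)[0] % (2**31 - 1)) for child in ss.spawn(n)]


def run_analysis(
    matrix,
    config: AnalysisConfig = AnalysisConfig(),
    out_dir: Optional[str] = None,
) -> AnalysisReport:
    """Run the full workflow on a matrix (object, path, or document text)."""
    warnings: List[str] = []
    if isinstance(matrix, str):
        matrix = read_matrix(matrix, fmt=config.format)
    if config.recodings:
        with open(config.recodings) as fh:
            ledger = RecodingLedger.from_tsv(fh.read())
        matrix, diff = apply_recodings(matrix, ledger)
    else:
        diff = None
    if config.ordered_all:
        matrix = matrix.with_ordered_all(True)

    outgroup = config.outgroup
    if outgroup is None:
        outgroup = matrix.taxa[0]
        msg = f"no outgroup specified; defaulting to first taxon {outgroup!r}"
        logger.warning(msg)
        warnings.append(msg)

    seed_search, seed_bremer, seed_boot = _stage_seeds(config.seed, 3)
    sconf = SearchConfig(
        method=config.method,
        replicates=config.replicates,
        hold_per_step=config.hold_per_step,
        seed=seed_search,
        max_trees=config.max_trees,
        collapse=config.collapse,
    )
    result = search(matrix, sconf)
    cons = strict_consensus(result.trees)

    stats_all = ensemble_stats(matrix, result.binary_trees, include_uninformative=True)
    stats_inf = ensemble_stats(matrix, result.binary_trees, include_uninformative=False)
    for s in (stats_all, stats_inf):
        if s.warning:
            warnings.append(s.warning)

    og_idx = matrix.taxon_index(outgroup)
    supports = None
    boot_maj_newick = None
    if config.do_bremer:
        brm = bremer_supports(
            matrix,
            result,
            BremerConfig(
                cap=config.bremer_cap,
                heuristic_replicates=config.bremer_heuristic_replicates,
                seed=seed_bremer,
            ),
        )
        supports = brm
    if config.do_bootstrap:
        boot = bootstrap_supports(
            matrix,
            BootstrapConfig(
                replicates=config.bootstrap_replicates,
                ras_replicates=config.bootstrap_ras_replicates,
                seed=seed_boot,
            ),
        )
        supports = merge_support_tables(supports, boot)
        freq = {
            r.split: round(r.bootstrap_pct)
            for r in boot.rows
            if r.bootstrap_pct is not None and r.bootstrap_pct > 50.0
        }
        boot_maj_newick = boot.majority_tree.to_newick(outgroup=og_idx, support=freq)

    apoms = synapomorphy_map(result.binary_trees[0], matrix, outgroup=og_idx)

    report = AnalysisReport(
        length=result.length,
        mpt_count=result.mpt_count,
        ci=stats_all.CI,
        ri=stats_all.RI,
        ci_informative_only=stats_inf.CI,
        ri_informative_only=stats_inf.RI,
        mpt_newicks=[t.to_newick(outgroup=og_idx) for t in result.trees],
        strict_consensus_newick=cons.to_newick(outgroup=og_idx),
        bootstrap_majority_newick=boot_maj_newick,
        supports=supports,
        apomorphies=apoms,
        settings={
            **config.to_dict(),
            "outgroup_used": outgroup,
            "stage_seeds": [seed_search, seed_bremer, seed_boot],
        },
        warnings=warnings,
        method_used=result.method,
    )

    if out_dir:
        os.makedirs(out_dir, exist_ok=True)
        with open(os.path.join(out_dir, "report.json"), "w") as fh:
            fh.write(report.to_json())
        with open(os.path.join(out_dir, "mpts.nwk"), "w") as fh:
            fh.write("\n".join(report.mpt_newicks) + "\n")
        with open(os.path.join(out_dir, "strict_consensus.nwk"), "w") as fh:
            fh.write(report.strict_consensus_newick + "\n")
        if boot_maj_newick:
            with open(os.path.join(out_dir, "bootstrap_majority.nwk"), "w") as fh:
                fh.write(boot_maj_newick + "\n")
        char_diagnostics(matrix, result.binary_trees[0]).to_csv(
            os.path.join(out_dir, "char_stats.tsv"), sep="\t", index=False
        )
        if supports is not None:
            supports.to_dataframe().to_csv(
                os.path.join(out_dir, "supports.tsv"), sep="\t", index=False
            )
        apoms.to_dataframe().to_csv(
            os.path.join(out_dir, "apomorphies.tsv"), sep="\t", index=False
        )
        if diff is not None:
            diff.to_csv(os.path.join(out_dir, "recoding_diff.tsv"), sep="\t", index=False)
    return report
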