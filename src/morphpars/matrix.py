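"""Discrete morphological character matrices.

The central container is :class:`CharacterMatrix`: an ordered list of taxa,
one :class:`CharacterSpec` per character (state range, ordered flag, weight)
and a rectangular grid of :class:`StateSet` cells.  States are small
non-negative integers; a cell may be a single state, a polymorphic /
uncertain set of states (treated as uncertainty: an ancestor matching any
member costs nothing), or missing (``?``), which resolves to the full state
range of its character.  Inapplicable (``-``) cells are treated as missing
for all computations; the original symbol is preserved for round-tripping.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "StateSet",
    "CharacterSpec",
    "CharacterMatrix",
    "MatrixError",
]


class MatrixError(ValueError):
    """Raised for malformed matrices or state assignments."""


def _normalize_label(label: str) -> str:
    """Strip quotes and collapse internal whitespace to underscores."""
    label = label.strip().strip("'\"")
    return re.sub(r"\s+", "_", label)


@dataclass(frozen=True)
class StateSet:
    """A cell value: a set of candidate states, or missing data.

    ``members`` is empty exactly when ``is_missing`` is true; a missing cell
    resolves to the full state range of its character at computation time.
    ``was_gap`` records whether the cell was coded inapplicable (``-``)
    rather than unknown (``?``); both behave identically in computations.
    """

    members: frozenset = frozenset()
    is_missing: bool = False
    was_gap: bool = False

    def __post_init__(self):
        object.__setattr__(self, "members", frozenset(self.members))
        if self.is_missing and self.members:
            raise MatrixError("missing StateSet must have empty members")
        if not self.is_missing and not self.members:
            raise MatrixError("non-missing StateSet must be non-empty")
        if any((not isinstance(s, (int, np.integer))) or s < 0 for s in self.members):
            raise MatrixError(f"states must be non-negative integers: {self.members}")

    # -- constructors ---------------------------------------------------
    @classmethod
    def single(cls, state: int) -> "StateSet":
        return cls(members=frozenset([int(state)]))

    @classmethod
    def poly(cls, states: Iterable[int]) -> "StateSet":
        return cls(members=frozenset(int(s) for s in states))

    @classmethod
    def missing(cls, was_gap: bool = False) -> "StateSet":
        return cls(members=frozenset(), is_missing=True, was_gap=was_gap)

    # -- queries --------------------------------------------------------
    @property
    def is_polymorphic(self) -> bool:
        return len(self.members) > 1

    def resolved(self, max_state: int) -> frozenset:
        """Member set with missing resolved to the full declared range."""
        if self.is_missing:
            return frozenset(range(max_state + 1))
        return self.members

    def bitmask(self, max_state: int) -> int:
        if self.is_missing:
            return (1 << (max_state + 1)) - 1
        return sum(1 << s for s in self.members)

    def interval(self, max_state: int) -> tuple:
        """[lo, hi] bounds for ordered (Wagner) characters."""
        if self.is_missing:
            return (0, max_state)
        return (min(self.members), max(self.members))

    def token(self, poly_style: str = "nexus") -> str:
        """Render as a matrix token (``0``, ``{0 1}``/``[01]``, ``?``/``-``)."""
        if self.is_missing:
            return "-" if self.was_gap else "?"
        if len(self.members) == 1:
            return str(next(iter(self.members)))
        inner = sorted(self.members)
        if poly_style == "tnt":
            return "[" + "".join(str(s) for s in inner) + "]"
        return "{" + " ".join(str(s) for s in inner) + "}"

    def __repr__(self):  # compact: useful in assertion diffs
        return f"StateSet({self.token()!r})"

    def content_key(self):
        """Equality key ignoring the gap-vs-question provenance flag."""
        return (self.members, self.is_missing)


@dataclass(frozen=True)
class CharacterSpec:
    """Per-character metadata: 0-based index, state ceiling, model, weight."""

    index: int
    max_state: int
    ordered: bool = False
    weight: float = 1.0

    def __post_init__(self):
        if self.max_state < 0:
            raise MatrixError("max_state must be >= 0")
        if self.weight <= 0:
            raise MatrixError("character weight must be positive")


@dataclass
class CharacterMatrix:
    """Taxa x characters grid of :class:`StateSet` cells.

    ``cells[i][j]`` is the state set of taxon ``i`` for character ``j``.
    Character indices are 0-based internally; all user-facing reports use
    1-based indices (matching the convention of published matrices).
    """

    taxa: list
    specs: list
    cells: list  # list (per taxon) of list (per character) of StateSet

    def __post_init__(self):
        self.taxa = [_normalize_label(t) for t in self.taxa]
        self.validate()

    # -- construction helpers -------------------------------------------
    @classmethod
    def from_values(
        cls,
        taxa: Sequence,
        rows: Sequence,
        ordered=None,
        weights=None,
        max_states=None,
    ) -> "CharacterMatrix":
        """Build from per-taxon rows of ints / iterables / ``None`` (missing)."""
        cells = []
        for row in rows:
            crow = []
            for v in row:
                if v is None:
                    crow.append(StateSet.missing())
                elif isinstance(v, StateSet):
                    crow.append(v)
                elif isinstance(v, (int, np.integer)):
                    crow.append(StateSet.single(v))
                else:
                    crow.append(StateSet.poly(v))
            cells.append(crow)
        nchar = len(cells[0]) if cells else 0
        specs = []
        for j in range(nchar):
            observed = [s for row in cells for s in row[j].members]
            mx = max(observed, default=1)
            if max_states is not None:
                mx = max(mx, max_states[j] if hasattr(max_states, "__len__") else max_states)
            specs.append(
                CharacterSpec(
                    index=j,
                    max_state=max(mx, 1),
                    ordered=bool(ordered[j]) if ordered is not None else False,
                    weight=float(weights[j]) if weights is not None else 1.0,
                )
            )
        return cls(taxa=list(taxa), specs=specs, cells=cells)

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        if len(set(self.taxa)) != len(self.taxa):
            dupes = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise MatrixError(f"duplicate taxon labels after normalization: {dupes}")
        if len(self.cells) != len(self.taxa):
            raise MatrixError(
                f"matrix has {len(self.cells)} rows for {len(self.taxa)} taxa"
            )
        nchar = len(self.specs)
        for i, row in enumerate(self.cells):
            if len(row) != nchar:
                raise MatrixError(
                    f"row for taxon {self.taxa[i]!r} has {len(row)} cells, expected {nchar}"
                )
            for j, cell in enumerate(row):
                if not cell.is_missing and max(cell.members) > self.specs[j].max_state:
                    raise MatrixError(
                        f"taxon {self.taxa[i]!r} char {j + 1}: state(s) {sorted(cell.members)} "
                        f"exceed declared max state {self.specs[j].max_state}"
                    )

    # -- basic properties -------------------------------------------------
    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_chars(self) -> int:
        return len(self.specs)

    def taxon_index(self, label: str) -> int:
        label = _normalize_label(label)
        try:
            return self.taxa.index(label)
        except ValueError:
            raise MatrixError(f"unknown taxon {label!r}") from None

    def column(self, j: int) -> list:
        """Column ``j`` (0-based) as a list of StateSet, one per taxon."""
        return [row[j] for row in self.cells]

    def copy(self) -> "CharacterMatrix":
        return CharacterMatrix(
            taxa=list(self.taxa),
            specs=list(self.specs),
            cells=[list(row) for row in self.cells],
        )

    def equal_cells(self, other: "CharacterMatrix") -> bool:
        """Content equality: taxa, specs, and cell state sets (gap flag ignored)."""
        if self.taxa != other.taxa or self.specs != other.specs:
            return False
        return all(
            a.content_key() == b.content_key()
            for ra, rb in zip(self.cells, other.cells)
            for a, b in zip(ra, rb)
        )

    # -- numeric views ----------------------------------------------------
    def bitmask_array(self, char_indices=None) -> np.ndarray:
        """(n_taxa, n_chars) uint32 of state bitmasks; missing = full range."""
        idx = list(range(self.n_chars)) if char_indices is None else list(char_indices)
        out = np.empty((self.n_taxa, len(idx)), dtype=np.uint32)
        for jj, j in enumerate(idx):
            mx = self.specs[j].max_state
            for i in range(self.n_taxa):
                out[i, jj] = self.cells[i][j].bitmask(mx)
        return out

    def interval_arrays(self, char_indices=None):
        """(lo, hi) int16 arrays for ordered scoring; missing = full range."""
        idx = list(range(self.n_chars)) if char_indices is None else list(char_indices)
        lo = np.empty((self.n_taxa, len(idx)), dtype=np.int16)
        hi = np.empty_like(lo)
        for jj, j in enumerate(idx):
            mx = self.specs[j].max_state
            for i in range(self.n_taxa):
                a, b = self.cells[i][j].interval(mx)
                lo[i, jj], hi[i, jj] = a, b
        return lo, hi

    # -- transforms --------------------------------------------------------
    def with_ordered_all(self, ordered: bool = True) -> "CharacterMatrix":
        m = self.copy()
        m.specs = [replace(s, ordered=ordered) for s in m.specs]
        return m

    def subset_characters(self, char_indices) -> "CharacterMatrix":
        char_indices = list(char_indices)
        specs = [
            replace(self.specs[j], index=k) for k, j in enumerate(char_indices)
        ]
        cells = [[row[j] for j in char_indices] for row in self.cells]
        return CharacterMatrix(taxa=list(self.taxa), specs=specs, cells=cells)

    def missing_fraction(self, taxon=None) -> float:
        """Fraction of missing cells, overall or for one taxon."""
        if taxon is None:
            rows = self.cells
        else:
            rows = [self.cells[self.taxon_index(taxon)]]
        total = sum(len(r) for r in rows)
        miss = sum(1 for r in rows for c in r if c.is_missing)
        return miss / total if total else 0.0
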