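"""Reading, writing and recoding of morphological matrices.

Two dialects are supported: NEXUS ``CHARACTERS``/``DATA`` blocks (parsed
with dendropy) and the TNT ``xread`` format.  Both map onto the same
:class:`~morphpars.matrix.CharacterMatrix`; writing then re-reading in
either dialect reproduces the taxa, character specs and cell state sets.

A :class:`RecodingLedger` documents cell-level edits to a published base
matrix (taxon, 1-based character, old state, new state, source note) and
applies them idempotently, raising a conflict when the matrix does not
show the expected old state.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import List, Optional, Tuple

import dendropy
import pandas as pd

from .matrix import CharacterMatrix, CharacterSpec, MatrixError, StateSet

__all__ = [
    "read_nexus",
    "write_nexus",
    "read_tnt",
    "write_tnt",
    "RecodingEntry",
    "RecodingLedger",
    "apply_recodings",
    "published_recodings",
]


# ---------------------------------------------------------------------------
# NEXUS
# ---------------------------------------------------------------------------

def read_nexus(text: str) -> CharacterMatrix:
    """Parse a NEXUS standard-character matrix.

    ``?`` and the gap symbol both become missing cells (the gap origin is
    remembered for round-tripping); ``{..}``/``(..)`` become polymorphic
    state sets.  An ``ASSUMPTIONS`` ``TYPESET`` with ``ord:`` ranges marks
    ordered characters.
    """
    try:
        dm = dendropy.StandardCharacterMatrix.get(data=text, schema="nexus")
    except Exception as exc:  # dendropy raises schema-specific errors
        raise MatrixError(f"NEXUS parse error: {exc}") from exc
    taxa = [t.label for t in dm.taxon_namespace]
    cells: List[List[StateSet]] = []
    for taxon in dm.taxon_namespace:
        row = []
        for st in dm[taxon]:
            sym = st.symbol
            if sym == "?":
                row.append(StateSet.missing())
            elif sym == "-":
                row.append(StateSet.missing(was_gap=True))
            else:
                members = set()
                for f in st.fundamental_states:
                    if f.symbol in "?-":
                        continue
                    try:
                        members.add(int(f.symbol))
                    except ValueError:
                        raise MatrixError(
                            f"non-integer state symbol {f.symbol!r} for taxon {taxon.label!r}"
                        ) from None
                if not members:
                    row.append(StateSet.missing())
                else:
                    row.append(StateSet.poly(members))
        cells.append(row)
    if not cells or not cells[0]:
        raise MatrixError("NEXUS document contains no character data")
    nchar = len(cells[0])
    for t, row in zip(taxa, cells):
        if len(row) != nchar:
            raise MatrixError(
                f"taxon {t!r} has {len(row)} characters, expected {nchar}"
            )
    ordered = _parse_typeset(text, nchar)
    return CharacterMatrix.from_values(taxa, cells, ordered=ordered)


def _parse_typeset(text: str, nchar: int) -> List[bool]:
    """Extract ordered flags from an optional ASSUMPTIONS TYPESET command."""
    ordered = [False] * nchar
    m = re.search(r"typeset[^=;]*=\s*([^;]+);", text, flags=re.I | re.S)
    if not m:
        return ordered
    for part in m.group(1).split(","):
        if ":" not in part:
            continue
        style, ranges = part.split(":", 1)
        is_ord = style.strip().lower() in ("ord", "ordered")
        for tok in ranges.split():
            tok = tok.strip()
            if not tok:
                continue
            if "-" in tok:
                a, b = tok.split("-")
                idx = range(int(a) - 1, int(b))
            else:
                idx = [int(tok) - 1]
            for j in idx:
                if not 0 <= j < nchar:
                    raise MatrixError(f"TYPESET character {j + 1} out of range")
                ordered[j] = is_ord
    return ordered


def write_nexus(matrix: CharacterMatrix, poly_style: str = "nexus") -> str:
    """Serialize to a NEXUS DATA block (plus TYPESET when characters are ordered)."""
    max_sym = max((s.max_state for s in matrix.specs), default=1)
    symbols = " ".join(str(i) for i in range(max_sym + 1))
    out = io.StringIO()
    out.write("#NEXUS\n\nBEGIN DATA;\n")
    out.write(f"    DIMENSIONS NTAX={matrix.n_taxa} NCHAR={matrix.n_chars};\n")
    out.write(f'    FORMAT DATATYPE=STANDARD SYMBOLS="{symbols}" MISSING=? GAP=-;\n')
    out.write("    MATRIX\n")
    width = max((len(t) for t in matrix.taxa), default=4) + 2
    for i, taxon in enumerate(matrix.taxa):
        tokens = "".join(_nexus_token(c) for c in matrix.cells[i])
        out.write(f"        {taxon:<{width}}{tokens}\n")
    out.write("    ;\nEND;\n")
    ord_idx = [j + 1 for j, s in enumerate(matrix.specs) if s.ordered]
    if ord_idx:
        ranges = " ".join(str(j) for j in ord_idx)
        out.write(
            "\nBEGIN ASSUMPTIONS;\n"
            f"    TYPESET * default = ord: {ranges};\n"
            "END;\n"
        )
    return out.getvalue()


def _nexus_token(cell: StateSet) -> str:
    if cell.is_missing:
        return "-" if cell.was_gap else "?"
    if len(cell.members) == 1:
        return str(next(iter(cell.members)))
    return "{" + "".join(str(s) for s in sorted(cell.members)) + "}"


# ---------------------------------------------------------------------------
# TNT xread
# ---------------------------------------------------------------------------

_TNT_COMMENT = re.compile(r"'[^']*'")


def read_tnt(text: str) -> CharacterMatrix:
    """Parse a TNT ``xread`` document (``[..]`` polymorphism, ``?``/``-`` missing).

    An optional ``ccode`` command with ``+`` marks ordered (additive)
    characters by 0-based index or ``a.b`` range, mirroring TNT usage.
    """
    m = re.search(r"\bxread\b", text, flags=re.I)
    if not m:
        raise MatrixError("no xread command found")
    body = text[m.end():]
    body = _TNT_COMMENT.sub(" ", body)  # drop quoted title
    end = body.find(";")
    if end == -1:
        raise MatrixError("xread block not terminated by ';'")
    rest_cmds = body[end + 1:]
    body = body[:end]
    tokens = body.split()
    if len(tokens) < 2:
        raise MatrixError("xread header must give nchar and ntax")
    try:
        nchar, ntax = int(tokens[0]), int(tokens[1])
    except ValueError:
        raise MatrixError(f"bad xread dimensions: {tokens[:2]}") from None
    stream = iter(tokens[2:])
    taxa: List[str] = []
    rows: List[List[StateSet]] = []
    for tok in stream:
        label = tok
        row: List[StateSet] = []
        while len(row) < nchar:
            try:
                chunk = next(stream)
            except StopIteration:
                raise MatrixError(
                    f"taxon {label!r}: row ended after {len(row)}/{nchar} characters"
                ) from None
            row.extend(_parse_tnt_chunk(chunk, label))
        if len(row) != nchar:
            raise MatrixError(
                f"taxon {label!r} has {len(row)} characters, expected {nchar}"
            )
        taxa.append(label)
        rows.append(row)
    if len(taxa) != ntax:
        raise MatrixError(f"xread declares {ntax} taxa but {len(taxa)} rows found")
    ordered = _parse_ccode(rest_cmds, nchar)
    return CharacterMatrix.from_values(taxa, rows, ordered=ordered)


def _parse_tnt_chunk(chunk: str, label: str) -> List[StateSet]:
    out: List[StateSet] = []
    i = 0
    while i < len(chunk):
        ch = chunk[i]
        if ch == "?":
            out.append(StateSet.missing())
            i += 1
        elif ch == "-":
            out.append(StateSet.missing(was_gap=True))
            i += 1
        elif ch == "[":
            j = chunk.find("]", i)
            if j == -1:
                raise MatrixError(f"taxon {label!r}: unterminated '[' token")
            members = {int(c) for c in chunk[i + 1: j] if not c.isspace()}
            if not members:
                raise MatrixError(f"taxon {label!r}: empty polymorphism token")
            out.append(StateSet.poly(members))
            i = j + 1
        elif ch.isdigit():
            out.append(StateSet.single(int(ch)))
            i += 1
        else:
            raise MatrixError(f"taxon {label!r}: undeclared symbol {ch!r}")
    return out


def _parse_ccode(text: str, nchar: int) -> List[bool]:
    ordered = [False] * nchar
    for m in re.finditer(r"\bccode\s*([^;]*);", text, flags=re.I):
        spec = m.group(1)
        mode = None
        for tok in spec.split():
            if tok in "+-":
                mode = tok
                continue
            if tok.startswith("+") or tok.startswith("-"):
                mode, tok = tok[0], tok[1:]
            if not tok:
                continue
            if "." in tok:
                a, b = tok.split(".")
                idx = range(int(a), int(b) + 1)
            else:
                idx = [int(tok)]
            for j in idx:
                if not 0 <= j < nchar:
                    raise MatrixError(f"ccode character {j} out of range")
                if mode is not None:
                    ordered[j] = mode == "+"
    return ordered


def write_tnt(matrix: CharacterMatrix) -> str:
    out = io.StringIO()
    out.write("xread\n")
    out.write(f"{matrix.n_chars} {matrix.n_taxa}\n")
    width = max((len(t) for t in matrix.taxa), default=4) + 2
    for i, taxon in enumerate(matrix.taxa):
        tokens = "".join(c.token("tnt") for c in matrix.cells[i])
        out.write(f"{taxon:<{width}}{tokens}\n")
    out.write(";\n")
    ord_idx = [j for j, s in enumerate(matrix.specs) if s.ordered]
    if ord_idx:
        out.write("ccode + " + " ".join(str(j) for j in ord_idx) + ";\n")
    return out.getvalue()


# ---------------------------------------------------------------------------
# recoding ledger
# ---------------------------------------------------------------------------

def _parse_state_token(tok: str) -> Optional[StateSet]:
    """``1`` / ``0/1`` / ``{0 1}`` / ``?`` / ``*`` (wildcard -> None)."""
    tok = tok.strip()
    if tok in ("*", ""):
        return None
    if tok == "?":
        return StateSet.missing()
    if tok == "-":
        return StateSet.missing(was_gap=True)
    digits = re.findall(r"\d+", tok)
    if not digits:
        raise MatrixError(f"cannot parse state token {tok!r}")
    return StateSet.poly(int(d) for d in digits)


@dataclass(frozen=True)
class RecodingEntry:
    """One documented edit: (taxon, 1-based character, old, new, note).

    ``old=None`` is a wildcard: the edit applies whatever the current
    state (used when the source documents only the new coding).
    """

    taxon: str
    char: int  # 1-based, as printed in publications
    old: Optional[StateSet]
    new: StateSet
    note: str = ""


@dataclass
class RecodingLedger:
    entries: List[RecodingEntry] = field(default_factory=list)

    @classmethod
    def from_tsv(cls, text: str) -> "RecodingLedger":
        entries = []
        for lineno, line in enumerate(text.splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0].lower() == "taxon":
                continue  # header
            if len(parts) < 4:
                raise MatrixError(f"ledger line {lineno}: expected >= 4 columns")
            taxon, char, old, new = parts[:4]
            note = parts[4] if len(parts) > 4 else ""
            newset = _parse_state_token(new)
            if newset is None:
                raise MatrixError(f"ledger line {lineno}: new state may not be a wildcard")
            entries.append(
                RecodingEntry(
                    taxon=taxon.strip(),
                    char=int(char),
                    old=_parse_state_token(old),
                    new=newset,
                    note=note.strip(),
                )
            )
        return cls(entries)

    def to_tsv(self) -> str:
        lines = ["taxon\tchar\told\tnew\tnote"]
        for e in self.entries:
            old = "*" if e.old is None else e.old.token()
            lines.append(f"{e.taxon}\t{e.char}\t{old}\t{e.new.token()}\t{e.note}")
        return "\n".join(lines) + "\n"


def apply_recodings(
    matrix: CharacterMatrix, ledger: RecodingLedger
) -> Tuple[CharacterMatrix, pd.DataFrame]:
    """Apply ledger entries; returns (new matrix, machine-readable diff).

    Application is idempotent: entries whose cell already shows the new
    state are recorded as no-ops.  An entry whose old state disagrees with
    the current cell raises a conflict naming taxon and character.
    """
    out = matrix.copy()
    diff_rows = []
    for e in ledger.entries:
        i = out.taxon_index(e.taxon)
        j = e.char - 1
        if not 0 <= j < out.n_chars:
            raise MatrixError(f"recoding of {e.taxon!r}: character {e.char} out of range")
        current = out.cells[i][j]
        if current.content_key() == e.new.content_key():
            diff_rows.append((e.taxon, e.char, current.token(), e.new.token(), "noop", e.note))
            continue
        if e.old is not None and current.content_key() != e.old.content_key():
            raise MatrixError(
                f"recoding conflict for {e.taxon!r} ch. {e.char}: "
                f"found {current.token()!r}, expected {e.old.token()!r}"
            )
        row = list(out.cells[i])
        row[j] = e.new
        out.cells[i] = row
        diff_rows.append((e.taxon, e.char, current.token(), e.new.token(), "applied", e.note))
    # widen specs if a recoded state exceeds the declared range
    for j, spec in enumerate(out.specs):
        observed = max(
            (max(c.members) for row in out.cells for c in [row[j]] if not c.is_missing),
            default=spec.max_state,
        )
        if observed > spec.max_state:
            from dataclasses import replace

            out.specs[j] = replace(spec, max_state=observed)
    out.validate()
    diff = pd.DataFrame(
        diff_rows, columns=["taxon", "char", "old", "new", "status", "note"]
    )
    return out, diff


def published_recodings() -> RecodingLedger:
    """The documented recoding ledger shipped with the package."""
    text = (
        resources.files("morphpars")
        .joinpath("data/promyliobatis_recodings.tsv")
        .read_text()
    )
    return RecodingLedger.from_tsv(text)
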