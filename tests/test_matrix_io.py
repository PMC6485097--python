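"""Matrix parsing, writing, and the recoding ledger."""

import pytest

from morphpars import (
    CharacterMatrix,
    MatrixError,
    RecodingEntry,
    RecodingLedger,
    StateSet,
    apply_recodings,
    published_recodings,
    read_nexus,
    read_tnt,
    write_nexus,
    write_tnt,
)
from morphpars.simulate import SimulationConfig, simulate_matrix

MINIMAL_NEXUS = """#NEXUS
BEGIN DATA;
DIMENSIONS NTAX=2 NCHAR=1;
FORMAT DATATYPE=STANDARD SYMBOLS="0 1" MISSING=? GAP=-;
MATRIX
A 0
B 1
;
END;
"""

POLY_NEXUS = """#NEXUS
BEGIN DATA;
DIMENSIONS NTAX=3 NCHAR=3;
FORMAT DATATYPE=STANDARD SYMBOLS="0 1 2" MISSING=? GAP=-;
MATRIX
A 0{01}?
B 11-
C 202
;
END;
"""


class TestReadNexus:
    def test_minimal_block(self):
        m = read_nexus(MINIMAL_NEXUS)
        assert m.taxa == ["A", "B"]
        assert m.cells[0][0].members == frozenset([0])
        assert m.cells[1][0].members == frozenset([1])

    def test_polymorphism_missing_and_gap(self):
        m = read_nexus(POLY_NEXUS)
        assert m.cells[0][1].members == frozenset([0, 1])
        assert not m.cells[0][1].is_missing
        missing = m.cells[0][2]
        assert missing.is_missing
        # missing resolves to the full declared range of its character
        assert missing.resolved(m.specs[2].max_state) == frozenset([0, 1, 2])
        # inapplicable '-' behaves as missing but remembers its symbol
        gap = m.cells[1][2]
        assert gap.is_missing and gap.was_gap

    def test_bad_document_raises(self):
        with pytest.raises(MatrixError):
            read_nexus("#NEXUS\nBEGIN DATA;\nDIMENSIONS NTAX=2;\nEND;")

    def test_keyword_case_insensitive(self):
        m = read_nexus(MINIMAL_NEXUS.lower().replace("#nexus", "#NEXUS"))
        assert m.taxa == ["a", "b"]


class TestReadTnt:
    def test_minimal(self):
        m = read_tnt("xread\n1 2\nA 0\nB 1\n;\n")
        assert m.taxa == ["A", "B"]
        assert m.cells[1][0].members == frozenset([1])

    def test_bracket_polymorphism(self):
        m = read_tnt("xread\n2 2\nA [01]1\nB 0?\n;\n")
        assert m.cells[0][0].members == frozenset([0, 1])
        assert m.cells[1][1].is_missing

    def test_ntax_mismatch(self):
        with pytest.raises(MatrixError):
            read_tnt("xread\n1 3\nA 0\nB 1\n;\n")

    def test_matches_nexus_reading(self):
        nex = read_nexus(POLY_NEXUS)
        tnt = read_tnt(write_tnt(nex))
        assert nex.equal_cells(tnt)


@pytest.mark.parametrize("seed", [0, 1, 2])
@pytest.mark.parametrize("dialect", ["nexus", "tnt"])
def test_roundtrip_simulated(seed, dialect):
    m, _ = simulate_matrix(
        SimulationConfig(
            n_taxa=10, n_chars=20, n_states=4, missing_frac=0.1,
            polymorphic_frac=0.05, seed=seed,
        )
    )
    if dialect == "nexus":
        back = read_nexus(write_nexus(m))
    else:
        back = read_tnt(write_tnt(m))
    assert back.taxa == m.taxa
    assert back.specs == m.specs
    assert back.equal_cells(m)


def test_ordered_flags_roundtrip():
    m, _ = simulate_matrix(SimulationConfig(n_taxa=6, n_chars=8, ordered=True, seed=3))
    assert all(s.ordered for s in read_nexus(write_nexus(m)).specs)
    assert all(s.ordered for s in read_tnt(write_tnt(m)).specs)


try:
    from hypothesis import given, settings, strategies as st

    cell = st.one_of(
        st.integers(0, 3),
        st.just(None),
        st.frozensets(st.integers(0, 3), min_size=2, max_size=3).map(tuple),
    )

    @given(
        data=st.data(),
        n_taxa=st.integers(3, 8),
        n_chars=st.integers(1, 10),
    )
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_roundtrip_property(data, n_taxa, n_chars):
        """Any well-formed matrix survives write->read in both dialects."""
        rows = [
            [data.draw(cell) for _ in range(n_chars)] for _ in range(n_taxa)
        ]
        if all(v is None for row in rows for v in row):
            rows[0][0] = 0  # dendropy needs at least one observed state
        taxa = [f"tx{i}" for i in range(n_taxa)]
        m = CharacterMatrix.from_values(taxa, rows)
        assert read_nexus(write_nexus(m)).equal_cells(m)
        assert read_tnt(write_tnt(m)).equal_cells(m)

except ImportError:  # pragma: no cover - hypothesis is an optional test dep
    pass


def test_duplicate_taxon_rejected():
    bad = MINIMAL_NEXUS.replace("B 1", "A 1")
    with pytest.raises(MatrixError):
        read_nexus(bad)


def test_label_normalization():
    m = CharacterMatrix.from_values(["'Taxon one'", "Taxon_two"], [[0], [1]])
    assert m.taxa == ["Taxon_one", "Taxon_two"]


class TestRecodings:
    @pytest.fixture
    def base(self):
        taxa = ["Aetomylaeus", "Rhinoptera", "Myliobatis"]
        rows = [[1, 1, 0], [1, 1, 1], [0, 1, 1]]
        return CharacterMatrix.from_values(taxa, rows, max_states=2)

    def test_documented_edits_apply(self, base):
        # the edit style of the published ledger: singleton swaps and
        # polymorphic widenings, with 1-based character indices
        ledger = RecodingLedger(
            [
                RecodingEntry("Aetomylaeus", 1, StateSet.single(1), StateSet.single(2)),
                RecodingEntry("Rhinoptera", 2, StateSet.single(1), StateSet.single(0)),
                RecodingEntry("Myliobatis", 3, None, StateSet.poly([0, 1])),
            ]
        )
        out, diff = apply_recodings(base, ledger)
        assert out.cells[0][0].members == frozenset([2])
        assert out.cells[1][1].members == frozenset([0])
        assert out.cells[2][2].members == frozenset([0, 1])
        assert list(diff["status"]) == ["applied"] * 3
        # untouched cells unchanged
        assert out.cells[0][1].members == base.cells[0][1].members

    def test_idempotent(self, base):
        ledger = RecodingLedger(
            [RecodingEntry("Aetomylaeus", 1, StateSet.single(1), StateSet.single(2))]
        )
        once, _ = apply_recodings(base, ledger)
        twice, diff = apply_recodings(once, ledger)
        assert once.equal_cells(twice)
        assert list(diff["status"]) == ["noop"]

    def test_conflict_on_unexpected_old_state(self, base):
        ledger = RecodingLedger(
            [RecodingEntry("Myliobatis", 1, StateSet.single(1), StateSet.single(2))]
        )
        with pytest.raises(MatrixError, match="Myliobatis.*ch. 1"):
            apply_recodings(base, ledger)

    def test_changes_exactly_entry_cells(self, base):
        ledger = RecodingLedger(
            [RecodingEntry("Rhinoptera", 2, StateSet.single(1), StateSet.single(0))]
        )
        out, _ = apply_recodings(base, ledger)
        changed = [
            (i, j)
            for i in range(base.n_taxa)
            for j in range(base.n_chars)
            if base.cells[i][j].content_key() != out.cells[i][j].content_key()
        ]
        assert changed == [(1, 1)]
        assert out.specs == base.specs

    def test_ledger_tsv_roundtrip(self, base):
        ledger = RecodingLedger(
            [
                RecodingEntry("Aetomylaeus", 1, StateSet.single(1), StateSet.single(2), "note a"),
                RecodingEntry("Myliobatis", 3, None, StateSet.poly([0, 1]), "note b"),
            ]
        )
        back = RecodingLedger.from_tsv(ledger.to_tsv())
        assert back == ledger

    def test_published_ledger_loads(self):
        ledger = published_recodings()
        by_key = {(e.taxon, e.char): e for e in ledger.entries}
        # the three concretely documented singleton edits
        assert by_key[("Aetomylaeus", 27)].old == StateSet.single(1)
        assert by_key[("Aetomylaeus", 27)].new == StateSet.single(2)
        assert by_key[("Rhinoptera", 50)].new == StateSet.single(0)
        assert by_key[("Myliobatis", 16)].new == StateSet.poly([0, 1])
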