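"""One-hot encodings, variable meanings, thresholding, cleaning."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sitelogic.encoding import (
    EncodedDataset,
    binarize_continuous,
    clean_dataset,
    decode_dna,
    decode_protein,
    encode_dna,
    encode_protein,
    variable_index,
    variable_meaning,
)


class TestDnaEncoding:
    def test_defining_codes(self):
        assert str(encode_dna("A")) == "1000"
        assert str(encode_dna("C")) == "0100"
        assert str(encode_dna("G")) == "0010"
        assert str(encode_dna("T")) == "0001"

    def test_concatenation(self):
        assert str(encode_dna("ACGT")) == "1000010000100001"

    def test_binding_site_window_width(self):
        assert encode_dna("ACGTACGTACGTAC").width == 56

    def test_case_insensitive(self):
        assert encode_dna("acgt") == encode_dna("ACGT")

    def test_invalid_base_reports_position(self):
        with pytest.raises(ValueError, match="position 3"):
            encode_dna("ACNT")

    @given(st.text("ACGT", min_size=1, max_size=30))
    @settings(max_examples=100, derandomize=True)
    def test_round_trip_and_one_hot_blocks(self, seq):
        bv = encode_dna(seq)
        assert decode_dna(bv) == seq
        arr = bv.to_array().reshape(-1, 4)
        assert (arr.sum(axis=1) == 1).all()


class TestProteinEncoding:
    def test_window_width(self):
        assert encode_protein("ARNDFTSTWYV").width == 231

    def test_first_rank_first_block(self):
        bv = encode_protein("AAAAATAAAAA")
        assert bv[0] == 1

    def test_threonine_before_center_sets_bit_101(self):
        # slot 5 (position −1) holding T lights variable 101 = 4*21 + 17
        window = "AAAAT" + "S" + "AAAAA"
        bv = encode_protein(window)
        assert bv[100] == 1

    def test_unknown_residue_rank_21(self):
        bv = encode_protein("XAAAATAAAAA")
        assert bv[20] == 1

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError, match="11 residues"):
            encode_protein("AAAA")

    def test_unrecognized_symbol_rejected(self):
        with pytest.raises(ValueError, match="slot 2"):
            encode_protein("ABAAATAAAAA")  # B is not a residue code here

    @given(st.text("ARNDCQEGHILKMFPSTWYVX", min_size=11, max_size=11))
    @settings(max_examples=100, derandomize=True)
    def test_round_trip_and_one_hot_blocks(self, window):
        bv = encode_protein(window)
        assert decode_protein(bv) == window
        arr = bv.to_array().reshape(-1, 21)
        assert (arr.sum(axis=1) == 1).all()


class TestVariableMeaning:
    @pytest.mark.parametrize(
        "index,pos,symbol",
        [
            (26, 7, "C"),
            (33, 9, "A"),
            (29, 8, "A"),
            (40, 10, "T"),
            (23, 6, "G"),
            (39, 10, "G"),
            (25, 7, "A"),
            (1, 1, "A"),
            (56, 14, "T"),
        ],
    )
    def test_dna_layout(self, index, pos, symbol):
        m = variable_meaning(index, "dna")
        assert (m.window_position, m.symbol) == (pos, symbol)
        assert m.description == f"Nucleotide {pos} is/is not {symbol}"

    @pytest.mark.parametrize(
        "index,pos,symbol",
        [
            (183, 3, "P"),
            (101, -1, "T"),
            (143, 1, "T"),
            (204, 4, "P"),
            (99, -1, "P"),
            (185, 3, "T"),
            (206, 4, "T"),
            (163, 2, "S"),
            (88, -1, "D"),
            (36, -4, "P"),
            (180, 3, "K"),
            (100, -1, "S"),
            (2, -5, "R"),
            (162, 2, "P"),
            (227, 5, "T"),
            (78, -2, "P"),
            (142, 1, "S"),
            (164, 2, "T"),
            (74, -2, "L"),
            (148, 2, "A"),
            (15, -5, "P"),
            (38, -4, "T"),
            (80, -2, "T"),
        ],
    )
    def test_protein_layout(self, index, pos, symbol):
        m = variable_meaning(index, "protein")
        assert (m.window_position, m.symbol) == (pos, symbol)
        assert m.description == f"Amino Acid in Position {pos} is/is not {symbol}"

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            variable_meaning(0, "dna")
        with pytest.raises(ValueError):
            variable_meaning(232, "protein")

    @pytest.mark.parametrize("kind,width", [("dna", 56), ("protein", 231)])
    def test_inverse_of_index_formula(self, kind, width):
        for idx in range(1, width + 1):
            m = variable_meaning(idx, kind)
            assert variable_index(m.window_position, m.symbol, kind) == idx

    def test_render_is_and_is_not(self):
        m = variable_meaning(39, "dna")
        assert m.render(1) == "Nucleotide 10 is G"
        assert m.render(0) == "Nucleotide 10 is not G"


class TestBinarizeContinuous:
    def test_single_threshold_produces_contradiction(self):
        # two observations that collapse onto the same bit pattern
        ds = binarize_continuous(
            np.array([[0.8, 0.9], [0.7, 0.8]]),
            thresholds=[[0.5], [0.5]],
            labels=[1, 0],
        )
        assert ds.pattern_strings() == ["11", "11"]
        cleaned, report = clean_dataset(ds)
        assert cleaned.n == 0
        assert len(report.removed_contradictions) == 1

    def test_moved_threshold_resolves_contradiction(self):
        ds = binarize_continuous(
            np.array([[0.8, 0.9], [0.7, 0.8]]),
            thresholds=[[0.7], [0.5]],
            labels=[1, 0],
        )
        assert ds.pattern_strings() == ["11", "01"]
        cleaned, report = clean_dataset(ds)
        assert cleaned.n == 2 and not report.removed_contradictions

    def test_three_interval_membership(self):
        ds = binarize_continuous(
            np.array([[0.1], [0.5], [0.9], [0.25], [0.75]]),
            thresholds=[[0.25, 0.75]],
        )
        assert ds.pattern_strings() == ["100", "010", "001", "010", "010"]

    def test_strictly_increasing_thresholds_required(self):
        with pytest.raises(ValueError, match="increasing"):
            binarize_continuous(np.array([[0.5]]), thresholds=[[0.7, 0.3]])


class TestCleanDataset:
    def _ds(self, rows, labels):
        return EncodedDataset(
            patterns=np.array([[int(c) for c in r] for r in rows]),
            labels=np.array(labels),
            meanings=[],
        )

    def test_clean_input_unchanged(self):
        ds = self._ds(["01", "10"], [1, 0])
        cleaned, report = clean_dataset(ds)
        assert cleaned.pattern_strings() == ["01", "10"]
        assert list(cleaned.multiplicity) == [1, 1]
        assert not report.removed_contradictions

    def test_duplicates_collapse_with_multiplicity(self):
        ds = self._ds(["11"] * 4, [1] * 4)
        cleaned, report = clean_dataset(ds)
        assert cleaned.n == 1
        assert cleaned.multiplicity[0] == 4
        assert report.merged_duplicates == [("11", 1, 4)]

    def test_drop_policy_removes_contradictions(self):
        ds = self._ds(["11", "11"], [1, 0])
        cleaned, report = clean_dataset(ds, "drop")
        assert cleaned.n == 0 and report.empty_output
        assert report.removed_contradictions == [("11", {1: 1, 0: 1})]

    def test_majority_policy_keeps_winner(self):
        ds = self._ds(["11", "11", "11"], [1, 1, 0])
        cleaned, report = clean_dataset(ds, "majority")
        assert cleaned.pattern_strings() == ["11"]
        assert cleaned.labels[0] == 1 and cleaned.multiplicity[0] == 2
        assert report.resolved_majority == [("11", 1, {1: 2, 0: 1})]

    def test_majority_tie_removed(self):
        ds = self._ds(["11", "11"], [1, 0])
        cleaned, _ = clean_dataset(ds, "majority")
        assert cleaned.n == 0

    def test_output_has_no_equal_patterns(self):
        rng = np.random.default_rng(0)
        rows = ["".join(map(str, rng.integers(0, 2, 3))) for _ in range(40)]
        ds = self._ds(rows, rng.integers(0, 2, 40))
        cleaned, _ = clean_dataset(ds)
        pats = cleaned.pattern_strings()
        assert len(pats) == len(set(pats))
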