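import pytest

from dtsb.alignment import AlignedSet
from dtsb.barcode import (
    SNPBarcode,
    UNKNOWN,
    barcodes_to_json,
    extract_barcodes,
    match_barcode,
    read_barcode_table,
    sort_and_dedup,
    write_barcode_table,
)
from dtsb.errors import AmbiguousBarcodeError, DTSBError
from dtsb.tree import build_tree, classify


@pytest.fixture(scope="module")
def fig3_tree(fig3):
    return build_tree(fig3)


@pytest.fixture(scope="module")
def fig3_barcodes(fig3, fig3_tree):
    return extract_barcodes(fig3_tree, fig3)


class TestExtractBarcodes:
    def test_two_species_single_entry(self):
        a = AlignedSet(labels=("a", "b"), rows=("ACGT", "ACGA"))
        barcodes = extract_barcodes(build_tree(a), a)
        assert [b.species for b in barcodes] == ["a", "b"]
        for b, own in zip(barcodes, ("T", "A")):
            assert b.entries == ((1, 4, own),)

    def test_entry_count_equals_leaf_depth(self, fig3, fig3_tree, fig3_barcodes):
        depth_by_species = {l.species: l.level - 1 for l in fig3_tree.leaves()}
        for b in fig3_barcodes:
            assert len(b.entries) == depth_by_species[b.species]
            assert len(b.entries) <= fig3.n_species - 1

    def test_entries_are_species_own_nucleotides(self, fig3, fig3_barcodes):
        rows = dict(zip(fig3.labels, fig3.rows))
        for b in fig3_barcodes:
            for _level, position, base in b.entries:
                assert rows[b.species][position - 1] == base

    def test_levels_strictly_increase(self, fig3_barcodes):
        for b in fig3_barcodes:
            levels = [level for level, _, _ in b.entries]
            assert levels == sorted(set(levels))

    def test_all_barcode_strings_distinct(self, fig3_barcodes):
        strings = [b.barcode_string for b in fig3_barcodes]
        assert len(set(strings)) == len(strings)


class TestSortAndDedup:
    def test_repeated_position_collapsed_and_sorted(self):
        b = SNPBarcode(species="x", entries=((1, 8, "T"), (2, 3, "C"), (3, 8, "T")))
        assert sort_and_dedup(b).sorted_entries == ((3, "C"), (8, "T"))

    def test_idempotent_on_sorted_unique(self):
        b = SNPBarcode(species="x", entries=((1, 2, "A"), (2, 5, "G")))
        assert sort_and_dedup(sort_and_dedup(b)).sorted_entries == ((2, "A"), (5, "G"))

    def test_empty_entries(self):
        assert sort_and_dedup(SNPBarcode(species="x", entries=())).sorted_entries == ()

    def test_conflicting_duplicate_rejected(self):
        b = SNPBarcode(species="x", entries=((1, 8, "T"), (2, 8, "C")))
        with pytest.raises(DTSBError, match="conflicting"):
            sort_and_dedup(b)


class TestMatchBarcode:
    def test_training_rows_self_consistent(self, fig3, fig3_barcodes):
        for lab, row in zip(fig3.labels, fig3.rows):
            assert match_barcode(fig3_barcodes, row) == lab

    def test_agrees_with_tree_classification(self, fig3, fig3_tree, fig3_barcodes):
        for row in fig3.rows:
            assert match_barcode(fig3_barcodes, row) == classify(fig3_tree, row)

    def test_mutation_outside_barcode_positions_ignored(self, fig3, fig3_barcodes):
        used = {pos for b in fig3_barcodes for pos, _ in b.sorted_entries}
        free = next(p for p in range(1, fig3.length + 1) if p not in used)
        row = fig3.rows[2]
        mutated = row[: free - 1] + "G" + row[free:]
        assert match_barcode(fig3_barcodes, mutated) == fig3.labels[2]

    def test_all_gap_row_unknown(self, fig3, fig3_barcodes):
        assert match_barcode(fig3_barcodes, "-" * fig3.length) == UNKNOWN

    def test_overlapping_barcodes_flagged_ambiguous(self):
        corrupt = [
            SNPBarcode(species="x", entries=((1, 1, "A"),)),
            SNPBarcode(species="y", entries=((1, 1, "A"),)),
        ]
        with pytest.raises(AmbiguousBarcodeError):
            match_barcode(corrupt, "ACGT")


class TestBarcodeTable:
    def test_tsv_shape_and_round_trip(self, fig3_barcodes, tmp_path):
        path = tmp_path / "barcodes.tsv"
        write_barcode_table(fig3_barcodes, path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 1 + len(fig3_barcodes)
        assert lines[0].split("\t") == [
            "species", "n_positions", "positions", "nucleotides", "barcode_string",
        ]
        back = read_barcode_table(path)
        assert [b.species for b in back] == [b.species for b in fig3_barcodes]
        for got, want in zip(back, fig3_barcodes):
            assert got.sorted_entries == want.sorted_entries

    def test_empty_list_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            write_barcode_table([], tmp_path / "x.tsv")

    def test_json_export(self, fig3_barcodes, tmp_path):
        import json

        path = tmp_path / "barcodes.json"
        barcodes_to_json(fig3_barcodes, path)
        doc = json.loads(path.read_text())
        assert len(doc) == len(fig3_barcodes)
        assert doc[0].keys() == {"species", "entries", "sorted_entries", "barcode_string"}
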