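import warnings

import pytest

from mtqsar.chemio import (
    PairRecord,
    curate_pairs,
    dataset_composition,
    parse_smiles,
    read_pair_table,
    read_smiles_batch,
)
from mtqsar.errors import (
    ConflictError,
    FormatError,
    MalformedSmilesError,
    TruncationWarning,
)


class TestParseSmiles:
    @pytest.mark.parametrize(
        "smiles,n_atoms,n_bonds",
        [("CCO", 3, 2), ("C1CC1", 3, 3), ("c1ccccc1", 6, 6), ("CC(C)(C)C", 5, 4)],
    )
    def test_heavy_atom_skeletons(self, smiles, n_atoms, n_bonds):
        g = parse_smiles(smiles)
        assert (g.n_atoms, g.n_bonds) == (n_atoms, n_bonds)

    @pytest.mark.parametrize("bad", ["C(C", "C1CC", "notasmiles(", "", "   "])
    def test_malformed_raises(self, bad):
        with pytest.raises(MalformedSmilesError):
            parse_smiles(bad)

    def test_aromatic_bond_order(self):
        g = parse_smiles("c1ccccc1")
        assert all(order == 1.5 for _, _, order in g.bonds)


class TestSmilesBatch:
    def _write(self, tmp_path, rows, header="id\tSMILE", name="batch.tsv"):
        path = tmp_path / name
        path.write_text("\n".join([header] + rows) + "\n")
        return path

    def test_order_preserved(self, tmp_path):
        path = self._write(tmp_path, ["a\tCCO", "b\tCCC", "c\tCCN"])
        batch = read_smiles_batch(path)
        assert batch.rows == [("a", "CCO"), ("b", "CCC"), ("c", "CCN")]

    def test_cap_at_100_with_warning(self, tmp_path):
        rows = [f"m{i}\tCCO" for i in range(150)]
        path = self._write(tmp_path, rows)
        with pytest.warns(TruncationWarning):
            batch = read_smiles_batch(path)
        assert len(batch) == 100
        assert batch.rows[0][0] == "m0" and batch.rows[-1][0] == "m99"
        assert any("100" in w for w in batch.warnings)

    def test_missing_id_column(self, tmp_path):
        path = self._write(tmp_path, ["CCO"], header="SMILE")
        with pytest.raises(FormatError):
            read_smiles_batch(path)

    def test_csv_extension_rejected_unless_forced(self, tmp_path):
        path = self._write(tmp_path, ["a\tCCO"], name="batch.csv")
        with pytest.raises(FormatError):
            read_smiles_batch(path)
        assert len(read_smiles_batch(path, force_format=True)) == 1

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        batch = read_smiles_batch(path)
        assert len(batch) == 0 and batch.warnings


class TestPairTable:
    def test_four_row_fixture(self, tmp_path):
        path = tmp_path / "pairs.tsv"
        path.write_text(
            "drug_id\tsmiles\tec_family\tlabel\n"
            "d1\tCCO\t1.1\t1\nd2\tCCC\t1.1\t0\nd3\tCCN\t2.7\tactive\nd4\tCCO\t3.2\tinactive\n"
        )
        records, errors = read_pair_table(path)
        assert len(records) == 4 and not errors
        assert [r.label for r in records] == [1, 0, 1, 0]

    def test_invalid_ec_collected_not_fatal(self, tmp_path):
        path = tmp_path / "pairs.tsv"
        path.write_text(
            "drug_id\tsmiles\tec_family\tlabel\nd1\tCCO\tabc\t1\nd2\tCCC\t1.1\t0\n"
        )
        records, errors = read_pair_table(path)
        assert len(records) == 1 and len(errors) == 1

    def test_unmappable_column_raises(self, tmp_path):
        path = tmp_path / "pairs.tsv"
        path.write_text("foo\tbar\n1\t2\n")
        with pytest.raises(FormatError):
            read_pair_table(path)

    def test_empty_table_warns(self, tmp_path):
        path = tmp_path / "pairs.tsv"
        path.write_text("drug_id\tsmiles\tec_family\tlabel\n")
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            records, _ = read_pair_table(path)
        assert records == [] and caught


class TestCuration:
    def test_duplicates_collapse(self):
        recs = [
            PairRecord("a", "CCO", "1.1", 1),
            PairRecord("b", "OCC", "1.1", 1),  # alternative writing of ethanol
        ]
        assert len(curate_pairs(recs)) == 1

    def test_same_compound_other_subclass_retained(self):
        recs = [PairRecord("a", "CCO", "1.1", 1), PairRecord("a", "CCO", "3.2", 1)]
        assert len(curate_pairs(recs)) == 2

    def test_salt_form_collapses(self):
        recs = [
            PairRecord("a", "CCN", "1.1", 1),
            PairRecord("b", "CC[NH3+].[Cl-]", "1.1", 1),  # hydrochloride salt
        ]
        assert len(curate_pairs(recs)) == 1

    def test_conflicting_labels_raise(self):
        recs = [PairRecord("a", "CCO", "1.1", 1), PairRecord("b", "CCO", "1.1", 0)]
        with pytest.raises(ConflictError):
            curate_pairs(recs)

    def test_malformed_rows_dropped(self):
        recs = [PairRecord("a", "C(C", "1.1", 1), PairRecord("b", "CCO", "1.1", 1)]
        assert len(curate_pairs(recs)) == 1

    def test_idempotent(self):
        recs = [
            PairRecord("a", "CCO", "1.1", 1),
            PairRecord("b", "OCC", "1.1", 1),
            PairRecord("c", "CCO", "2.7", 0),
        ]
        once = curate_pairs(recs)
        assert curate_pairs(once) == once

    def test_empty_input(self):
        assert curate_pairs([]) == []


def test_dataset_composition_counts():
    recs = [PairRecord("a", "CCO", "1.1", 1)] * 3 + [PairRecord("b", "CCC", "1.2", 0)] * 2
    comp = dataset_composition(recs)
    assert comp == {"total": 5, "interacting": 3, "non_interacting": 2}
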