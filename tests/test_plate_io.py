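"""Triplet IO, metadata schema handling and screen assembly."""

import gzip

import numpy as np
import pandas as pd
import pytest

from httrscreen.plate_io import (
    CountMatrix,
    FormatError,
    PlateMetadata,
    SchemaError,
    assemble_screen,
    canonical_well,
    read_count_triplet,
    read_metadata,
    validate_metadata,
    well_is_valid,
    write_count_triplet,
    write_metadata,
)
from httrscreen.sim import SimConfig, TreatmentSpec, simulate_screen


def _write_triplet(directory, mtx_body, features, barcodes):
    (directory / "matrix.mtx").write_text(mtx_body)
    (directory / "features.tsv").write_text(features)
    (directory / "barcodes.tsv").write_text(barcodes)


MTX_2X2 = "%%MatrixMarket matrix coordinate integer general\n2 2 2\n1 1 5\n2 2 3\n"
FEATURES_2 = "ENSG1\tTP53\tGene Expression\nENSG2\tMYC\tGene Expression\n"
BARCODES_2 = "BC01\nBC02\n"


class TestReadCountTriplet:
    def test_direct_transcription(self, tmp_path):
        _write_triplet(tmp_path, MTX_2X2, FEATURES_2, BARCODES_2)
        cm = read_count_triplet(tmp_path)
        np.testing.assert_array_equal(cm.values, [[5, 0], [0, 3]])
        assert list(cm.gene_names) == ["TP53", "MYC"]
        assert list(cm.barcodes) == ["BC01", "BC02"]

    def test_empty_entry_list_gives_zero_matrix(self, tmp_path):
        body = "%%MatrixMarket matrix coordinate integer general\n2 2 0\n"
        _write_triplet(tmp_path, body, FEATURES_2, BARCODES_2)
        cm = read_count_triplet(tmp_path)
        np.testing.assert_array_equal(cm.values, np.zeros((2, 2)))

    def test_two_column_features_accepted(self, tmp_path):
        _write_triplet(tmp_path, MTX_2X2, "ENSG1\tTP53\nENSG2\tMYC\n", BARCODES_2)
        cm = read_count_triplet(tmp_path)
        assert list(cm.gene_ids) == ["ENSG1", "ENSG2"]

    def test_missing_file_names_the_file(self, tmp_path):
        (tmp_path / "matrix.mtx").write_text(MTX_2X2)
        (tmp_path / "features.tsv").write_text(FEATURES_2)
        with pytest.raises(FileNotFoundError, match="barcodes"):
            read_count_triplet(tmp_path)

    def test_dimension_mismatch_is_format_error(self, tmp_path):
        _write_triplet(tmp_path, MTX_2X2, FEATURES_2, "BC01\nBC02\nBC03\n")
        with pytest.raises(FormatError, match="barcodes"):
            read_count_triplet(tmp_path)

    def test_non_integer_value_is_format_error(self, tmp_path):
        body = "%%MatrixMarket matrix coordinate real general\n2 2 1\n1 1 2.5\n"
        _write_triplet(tmp_path, body, FEATURES_2, BARCODES_2)
        with pytest.raises(FormatError, match="non-integer"):
            read_count_triplet(tmp_path)

    def test_gzipped_triplet(self, tmp_path):
        for name, content in (
            ("matrix.mtx.gz", MTX_2X2),
            ("features.tsv.gz", FEATURES_2),
            ("barcodes.tsv.gz", BARCODES_2),
        ):
            with gzip.open(tmp_path / name, "wt") as fh:
                fh.write(content)
        cm = read_count_triplet(tmp_path, gzipped=True)
        np.testing.assert_array_equal(cm.values, [[5, 0], [0, 3]])

    def test_round_trip_simulated_matrix(self, tmp_path):
        rng = np.random.default_rng(5)
        values = rng.negative_binomial(2, 0.05, size=(500, 96))
        cm = CountMatrix(
            values,
            np.array([f"G{i}" for i in range(500)], dtype=object),
            np.array([f"sym{i}" for i in range(500)], dtype=object),
            np.array([f"BC{j}" for j in range(96)], dtype=object),
        )
        write_count_triplet(cm, tmp_path / "out")
        back = read_count_triplet(tmp_path / "out")
        np.testing.assert_array_equal(back.values, cm.values)
        assert list(back.gene_ids) == list(cm.gene_ids)
        assert list(back.barcodes) == list(cm.barcodes)


def _sheet(**overrides):
    base = pd.DataFrame(
        {
            "barcode": ["B1", "B2", "B3", "B4"],
            "well": ["A1", "A2", "B1", "B2"],
            "treatment": ["drugA", "drugA", "DMSO", "DMSO"],
            "concentration": [1.0, 1.0, 0.0, 0.0],
            "unit": ["uM"] * 4,
            "sample_type": ["treatment", "treatment", "vehicle", "vehicle"],
            "replicate": [1, 2, 1, 2],
            "plate": ["p1"] * 4,
        }
    )
    for key, value in overrides.items():
        base[key] = value
    return base


class TestMetadata:
    def test_read_all_required_columns(self, tmp_path):
        path = tmp_path / "meta.tsv"
        _sheet().to_csv(path, sep="\t", index=False)
        meta = read_metadata(path)
        assert len(meta) == 4
        assert validate_metadata(meta).passed

    def test_missing_treatment_column_named_in_error(self, tmp_path):
        path = tmp_path / "meta.tsv"
        _sheet().drop(columns=["treatment"]).to_csv(path, sep="\t", index=False)
        with pytest.raises(SchemaError, match="treatment"):
            read_metadata(path)

    def test_declared_synonym_mapped(self, tmp_path):
        sheet = _sheet().rename(columns={"concentration": "Concentration_uM"})
        path = tmp_path / "meta.csv"
        sheet.to_csv(path, index=False)
        meta = read_metadata(
            path, dialect="csv", synonyms={"Concentration_uM": "concentration"}
        )
        assert "concentration" in meta.table.columns

    def test_duplicate_barcode_is_schema_error(self, tmp_path):
        path = tmp_path / "meta.tsv"
        _sheet(barcode=["B1", "B1", "B3", "B4"]).to_csv(path, sep="\t", index=False)
        with pytest.raises(SchemaError, match="duplicate"):
            read_metadata(path)

    def test_metadata_roundtrip(self, tmp_path):
        meta = PlateMetadata(_sheet())
        write_metadata(meta, tmp_path / "m.tsv")
        back = read_metadata(tmp_path / "m.tsv")
        pd.testing.assert_frame_equal(back.table, meta.table, check_dtype=False)


class TestValidateMetadata:
    def test_special_characters_flagged(self):
        meta = PlateMetadata(_sheet(treatment=["DMSO 0.1%", "drugA", "DMSO", "DMSO"]))
        report = validate_metadata(meta)
        rules = [e[2] for e in report.errors]
        assert rules == ["special_characters"]
        assert not report.passed

    def test_invalid_well_row_beyond_plate(self):
        meta = PlateMetadata(_sheet(well=["Q5", "A2", "B1", "B2"]))
        report = validate_metadata(meta)
        assert [e[2] for e in report.errors] == ["invalid_well"]

    def test_96_well_bounds(self):
        assert well_is_valid("H12", 96)
        assert not well_is_valid("I1", 96)
        assert not well_is_valid("A13", 96)
        assert well_is_valid("P24", 384)
        assert not well_is_valid("A25", 384)

    def test_negative_concentration_and_duplicate_well(self):
        meta = PlateMetadata(
            _sheet(concentration=[1.0, -2.0, 0.0, 0.0], well=["A1", "A2", "B1", "B01"])
        )
        rules = {e[2] for e in validate_metadata(meta).errors}
        assert rules == {"negative_concentration", "duplicate_plate_well"}

    def test_missing_value_flagged(self):
        meta = PlateMetadata(_sheet(unit=["uM", None, "uM", "uM"]))
        assert [e[2] for e in validate_metadata(meta).errors] == ["missing_value"]

    def test_single_replicate_warning(self):
        meta = PlateMetadata(
            _sheet(
                treatment=["drugA", "drugB", "DMSO", "DMSO"],
                replicate=[1, 1, 1, 2],
            )
        )
        report = validate_metadata(meta)
        assert report.passed
        assert any(w[2] == "single_replicate" for w in report.warnings)

    def test_simulator_metadata_always_passes(self):
        cfg = SimConfig(
            n_genes=50, treatments=(TreatmentSpec("drugA"),), seed=3
        )
        screen, _ = simulate_screen(cfg)
        assert validate_metadata(screen.metadata).passed


class TestCanonicalWell:
    @pytest.mark.parametrize(
        "raw,canon", [("A1", "A1"), ("A01", "A1"), ("p24", "P24"), ("b09", "B9")]
    )
    def test_padding_and_case(self, raw, canon):
        assert canonical_well(raw) == canon

    def test_unparseable(self):
        with pytest.raises(ValueError):
            canonical_well("11A")


class TestAssembleScreen:
    def _pair(self):
        meta = PlateMetadata(_sheet())
        values = np.arange(8).reshape(2, 4)
        cm = CountMatrix(
            values,
            np.array(["g1", "g2"], dtype=object),
            np.array(["g1", "g2"], dtype=object),
            np.array(["B3", "B1", "B4", "B2"], dtype=object),
        )
        return cm, meta

    def test_reorders_to_metadata_order(self):
        cm, meta = self._pair()
        screen = assemble_screen(cm, meta)
        assert list(screen.counts.barcodes) == ["B1", "B2", "B3", "B4"]
        # column for B1 was index 1 in the shuffled matrix
        np.testing.assert_array_equal(screen.counts.values[:, 0], cm.values[:, 1])

    def test_shuffle_invariance(self):
        cm, meta = self._pair()
        screen1 = assemble_screen(cm, meta)
        perm = [2, 0, 3, 1]
        screen2 = assemble_screen(cm.reorder_wells(perm), meta)
        np.testing.assert_array_equal(screen1.counts.values, screen2.counts.values)

    def test_drop_unmatched_keeps_intersection_with_warning(self):
        cm, meta = self._pair()
        extra = CountMatrix(
            np.hstack([cm.values, [[9], [9]]]),
            cm.gene_ids,
            cm.gene_names,
            np.append(cm.barcodes, "B99"),
        )
        screen = assemble_screen(extra, meta, drop_unmatched=True)
        assert screen.n_wells == 4
        assert any("warning" in p for p in screen.provenance)

    def test_mismatch_without_flag_is_error(self):
        cm, meta = self._pair()
        trimmed = CountMatrix(
            cm.values[:, :3], cm.gene_ids, cm.gene_names, cm.barcodes[:3]
        )
        with pytest.raises(ValueError, match="mismatch"):
            assemble_screen(trimmed, meta)

    def test_disjoint_barcodes_error(self):
        cm, meta = self._pair()
        renamed = CountMatrix(
            cm.values, cm.gene_ids, cm.gene_names,
            np.array(["X1", "X2", "X3", "X4"], dtype=object),
        )
        with pytest.raises(ValueError, match="no barcodes"):
            assemble_screen(renamed, meta)
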