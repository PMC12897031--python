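"""Dialect contracts: strict parsing, line-numbered errors, lossless round trips."""

from __future__ import annotations

import numpy as np
import pytest

from kbhb_atlas import formats_io as fio
from kbhb_atlas.formats_io import (PDBFormatError, SampleDesign, SchemaError,
                                   ValidationError, two_group_design)

HEADER = "Protein\tPosition\tLocalization prob\tSequence window\t" + "\t".join(
    [f"GA_C{i}" for i in range(1, 5)] + [f"GA_S{i}" for i in range(1, 5)])
GOOD_ROW = "P1\t10\t0.95\tACDEFGHKIKLMNPQ\t" + "\t".join(["1000.0"] * 8)


def _write_table(tmp_path, *rows):
    path = tmp_path / "sites.tsv"
    path.write_text("\n".join([HEADER, *rows]) + "\n")
    return path


class TestSiteTable:
    def test_well_formed_rows_parsed(self, tmp_path, design):
        path = _write_table(tmp_path, GOOD_ROW,
                            GOOD_ROW.replace("P1\t10", "P2\t20"),
                            GOOD_ROW.replace("P1\t10", "P3\t30"))
        records = fio.read_site_table(path, design)
        assert len(records) == 3
        assert records[0].site_id == "P1_K10"

    def test_missing_required_column_names_it(self, tmp_path, design):
        path = tmp_path / "sites.tsv"
        path.write_text(HEADER.replace("Sequence window\t", "") + "\n")
        with pytest.raises(SchemaError, match="Sequence window"):
            fio.read_site_table(path, design)

    @pytest.mark.parametrize("mutation, message", [
        (("0.95", "1.2"), "localization"),          # probability out of range
        (("ACDEFGHKIKLMNPQ", "ACDEFGHRIKLMNPQ"), "centre must be K"),
        (("\t10\t", "\t0\t"), "position"),
    ])
    def test_malformed_row_cites_line_number(self, tmp_path, design, mutation, message):
        bad = GOOD_ROW.replace(*mutation)
        path = _write_table(tmp_path, GOOD_ROW, bad)
        with pytest.raises(ValidationError, match="line 3"):
            fio.read_site_table(path, design)

    @pytest.mark.parametrize("token", ["0", "", "NaN"])
    def test_missing_intensity_encodings(self, tmp_path, design, token):
        row = GOOD_ROW.rsplit("\t", 1)[0] + f"\t{token}"
        path = _write_table(tmp_path, row)
        rec = fio.read_site_table(path, design)[0]
        assert rec.intensities["GA_S4"] is None
        assert rec.intensities["GA_C1"] == 1000.0

    def test_shared_peptide_assigned_to_first_accession(self, tmp_path, design, caplog):
        path = _write_table(tmp_path, GOOD_ROW.replace("P1\t", "P1;P9\t"))
        with caplog.at_level("WARNING"):
            records = fio.read_site_table(path, design)
        assert records[0].protein == "P1"
        assert "first accession" in caplog.text


def test_design_requires_two_nonempty_groups():
    with pytest.raises(ValueError):
        SampleDesign({"a": "control", "b": "control"})
    design = two_group_design(2)
    assert design.group_names == ("control", "starved")
    assert design.replicate_index("GA_S2") == 2


def test_fasta_round_trip(tmp_path):
    seqs = {"P1": "MKTAYIAK", "P2 extra ignored".split()[0]: "GGKCC"}
    path = tmp_path / "x.fasta"
    fio.write_fasta(seqs, path)
    assert fio.read_fasta(path) == seqs


def test_fasta_accession_is_first_token(tmp_path):
    path = tmp_path / "x.fasta"
    path.write_text(">sp|P999|NAME description here\nMKV\n>Q1\nAAA\n")
    out = fio.read_fasta(path)
    assert set(out) == {"sp|P999|NAME", "Q1"}


def test_gmt_parse_and_round_trip(tmp_path):
    path = tmp_path / "x.gmt"
    path.write_text("TCA\tdesc\tP1\tP2\n")
    assert fio.read_gmt(path) == {"TCA": {"P1", "P2"}}
    fio.write_gmt({"TCA": {"P1", "P2"}, "B": {"P3"}}, path)
    assert fio.read_gmt(path) == {"TCA": {"P1", "P2"}, "B": {"P3"}}


def test_annotation_round_trip(tmp_path):
    ann = {"P1": ["cytoplasm"], "P2": ["nucleus", "mitochondria"]}
    path = tmp_path / "ann.tsv"
    fio.write_annotation(ann, path)
    assert fio.read_annotation(path) == ann


class TestPDB:
    def test_single_atom_coordinates(self, tmp_path):
        path = tmp_path / "one.pdb"
        path.write_text(
            "ATOM      1  CA  GLY A   1       1.000   2.000   3.000  1.00  0.00           C\n"
            "END\n")
        geometry = fio.read_pdb(path)
        assert geometry.resnums == [1]
        np.testing.assert_allclose(geometry.residue(1).coords, [[1.0, 2.0, 3.0]])

    def test_round_trip_preserves_coordinates(self, tmp_path, small_dataset):
        acc, geometry = next(iter(small_dataset.structures.items()))
        path = tmp_path / "toy.pdb"
        fio.write_pdb(geometry, path)
        back = fio.read_pdb(path)
        assert back.resnums == geometry.resnums
        for res in geometry.residues:
            np.testing.assert_allclose(back.residue(res.resnum).coords, res.coords,
                                       atol=1e-3)

    def test_skips_altloc_b_hydrogens_and_hetatm(self, tmp_path):
        path = tmp_path / "mix.pdb"
        path.write_text(
            "ATOM      1  CA AGLY A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      2  CA BGLY A   1       9.000   9.000   9.000  1.00  0.00           C\n"
            "ATOM      3  H   GLY A   1       5.000   5.000   5.000  1.00  0.00           H\n"
            "HETATM    4  O   HOH A  99       7.000   7.000   7.000  1.00  0.00           O\n"
            "END\n")
        geometry = fio.read_pdb(path)
        assert geometry.resnums == [1]
        assert geometry.residue(1).coords.shape == (1, 3)

    def test_first_model_only(self, tmp_path):
        path = tmp_path / "models.pdb"
        path.write_text(
            "MODEL        1\n"
            "ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "ENDMDL\n"
            "MODEL        2\n"
            "ATOM      2  CA  GLY A   2       9.000   0.000   0.000  1.00  0.00           C\n"
            "ENDMDL\n")
        assert fio.read_pdb(path).resnums == [1]

    def test_unparseable_line_cites_number(self, tmp_path):
        path = tmp_path / "bad.pdb"
        path.write_text(
            "ATOM      1  CA  GLY A   1       1.000   2.000   3.000  1.00  0.00           C\n"
            "ATOM      2  CA  GLY A   2       x.xxx   2.000   3.000  1.00  0.00           C\n")
        with pytest.raises(PDBFormatError, match="line 2"):
            fio.read_pdb(path)

    def test_written_files_parse_with_gemmi(self, tmp_path, small_dataset):
        gemmi = pytest.importorskip("gemmi")
        acc, geometry = next(iter(small_dataset.structures.items()))
        path = tmp_path / "toy.pdb"
        fio.write_pdb(geometry, path)
        st = gemmi.read_structure(str(path))
        got = {res.seqid.num: [(a.pos.x, a.pos.y, a.pos.z) for a in res]
               for res in st[0]["A"]}
        assert sorted(got) == sorted(geometry.resnums)
        for res in geometry.residues:
            np.testing.assert_allclose(np.array(got[res.resnum]), res.coords, atol=1e-3)


def test_structure_labels_round_trip(tmp_path):
    labels = {"kbhb": {10, 20}, "functional": {5}, "ptm": {10}}
    path = tmp_path / "labels.tsv"
    fio.write_structure_labels(labels, path)
    assert fio.read_structure_labels(path) == labels
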