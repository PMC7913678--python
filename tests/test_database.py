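"""Workbook import, filtering, archive round-trip, summary and reports."""

import json

import numpy as np
import pandas as pd
import pytest

from g4kit import database as dbmod
from g4kit import synthgen
from g4kit.seqcore import Oligonucleotide


@pytest.fixture(scope="module")
def panel_db():
    return dbmod.load_reference_panel()


@pytest.fixture(scope="module")
def panel_workbook(tmp_path_factory):
    path = tmp_path_factory.mktemp("wb") / "panel.xlsx"
    return dbmod.write_template_workbook(path)


@pytest.fixture()
def rich_db():
    """Two oligos with synthetic datasets attached, one data-free oligo."""
    db = dbmod.Database(buffers=dict(dbmod.PRESET_BUFFERS))
    db.add_oligo(Oligonucleotide(
        "2GKU", "TTGGGTTAGGGTTAGGGTTAGGGA",
        origin="Human telomere", family="human-telomeric-and-variants",
        rating="two-star",
    ))
    db.add_oligo(Oligonucleotide(
        "1XAV", "TGAGGGTGGGTAGGGTGGGTAA", origin="c-MYC", family="parallel",
        rating="two-star",
    ))
    db.add_oligo(Oligonucleotide("21G", "GGGTTAGGGTTAGGGTTAGGG",
                                 family="human-telomeric-and-variants"))
    rec = db.record_for("2GKU", "TMAA-1K")
    rec.datasets["melting"] = synthgen.make_melting_curve(
        Tm_K=314.15, sigma=0.002, seed=1, buffer="TMAA-1K", oligo="2GKU")
    rec.datasets["cd"] = synthgen.make_cd_spectrum("hybrid-typeII", sigma=0.2, seed=2)
    rec.datasets["ms"] = synthgen.make_mass_spectrum(
        "TTGGGTTAGGGTTAGGGTTAGGGA", abundances={(2, 5): 100.0},
        noise_floor=0.002, seed=3)
    rec.datasets["nmr"] = synthgen.make_nmr_trace(
        [(10.9, 1.0, 0.02), (11.3, 0.8, 0.02)], sigma=0.005, seed=4)
    rec.datasets["ims"] = synthgen.make_atd([33.0], [1.5], [1.0], mz_center=1450.0)
    rec2 = db.record_for("1XAV", "TMAA-1K")
    rec2.datasets["cd"] = synthgen.make_cd_spectrum("parallel-typeI", sigma=0.2, seed=5)
    return db


class TestImportWorkbook:
    def test_panel_workbook_has_28_entries(self, panel_workbook):
        db = dbmod.import_workbook(panel_workbook)
        assert len(db) == 28
        assert not db.import_errors

    def test_sequences_validated_on_import(self, panel_workbook):
        db = dbmod.import_workbook(panel_workbook)
        assert db.oligos["2GKU"].sequence == "TTGGGTTAGGGTTAGGGTTAGGGA"
        assert db.oligos["2KF8"].topology.quartet_count == 2
        assert db.oligos["1XAV"].rating == "two-star"

    def test_empty_workbook_warns(self, tmp_path):
        from openpyxl import Workbook

        wb = Workbook()
        wb.remove(wb.active)
        for sheet, cols in dbmod.SHEET_COLUMNS.items():
            ws = wb.create_sheet(sheet)
            ws.append(cols)
        path = tmp_path / "empty.xlsx"
        wb.save(path)
        with pytest.warns(UserWarning, match="no oligonucleotide"):
            db = dbmod.import_workbook(path)
        assert len(db) == 0

    def test_missing_metadata_sheet_errors(self, tmp_path):
        from openpyxl import Workbook

        wb = Workbook()
        wb.active.title = "cd"
        path = tmp_path / "bad.xlsx"
        wb.save(path)
        with pytest.raises(ValueError, match="oligos"):
            dbmod.import_workbook(path)

    def test_bad_sequence_row_rejected_others_kept(self, tmp_path):
        from openpyxl import load_workbook

        src = dbmod.write_template_workbook(tmp_path / "panel.xlsx")
        wb = load_workbook(src)
        ws = wb["oligos"]
        ws.cell(row=3, column=2, value="ACGUX")  # plant an invalid sequence
        broken = tmp_path / "broken.xlsx"
        wb.save(broken)
        db = dbmod.import_workbook(broken)
        assert len(db) == 27
        assert len(db.import_errors) == 1
        assert "row 3" in db.import_errors[0]

    def test_unknown_oligo_in_technique_sheet_errors(self, tmp_path):
        from openpyxl import load_workbook

        src = dbmod.write_template_workbook(tmp_path / "panel.xlsx")
        wb = load_workbook(src)
        wb["cd"].append(["NOSUCH", "TMAA-1K", 260.0, 1.0, 1e-5, 0.2, "mdeg"])
        bad = tmp_path / "badref.xlsx"
        wb.save(bad)
        with pytest.raises(ValueError, match="NOSUCH"):
            dbmod.import_workbook(bad)

    def test_import_is_deterministic(self, panel_workbook, tmp_path):
        import hashlib

        digests = []
        for i in range(2):
            db = dbmod.import_workbook(panel_workbook)
            root = dbmod.save_db(db, tmp_path / f"d{i}")
            payload = b"".join(
                sorted((root / f).read_bytes()
                       for f in ("oligos.csv", "buffers.csv", "records.csv"))
            )
            digests.append(hashlib.sha256(payload).hexdigest())
        assert digests[0] == digests[1]


class TestFilter:
    def test_human_telomeric_family_count(self, panel_db):
        sub = dbmod.filter_records(panel_db, family="human-telomeric-and-variants")
        assert len(sub) == 10

    def test_no_predicates_is_identity(self, panel_db):
        sub = dbmod.filter_records(panel_db)
        assert set(sub.oligos) == set(panel_db.oligos)
        assert len(sub.records) == len(panel_db.records)

    def test_impossible_predicate_empty(self, panel_db):
        assert len(dbmod.filter_records(panel_db, name="NOPE")) == 0

    def test_filter_is_projection(self, panel_db):
        once = dbmod.filter_records(panel_db, family="parallel")
        twice = dbmod.filter_records(once, family="parallel")
        assert set(once.oligos) == set(twice.oligos)

    def test_original_untouched(self, panel_db):
        n = len(panel_db)
        dbmod.filter_records(panel_db, family="parallel")
        assert len(panel_db) == n

    def test_filter_by_sequence_substring(self, panel_db):
        sub = dbmod.filter_records(panel_db, sequence="GGGTTAGGGTTAGGGTTAGGG")
        assert "21G" in sub.oligos

    def test_filter_by_topology(self, panel_db):
        sub = dbmod.filter_records(panel_db, topology="antiparallel")
        assert {"5YEY", "2KF8", "2KM3", "5LQG", "HIV-PRO1", "6GZN"} <= set(sub.oligos)

    def test_filter_by_cation(self, panel_db):
        sub = dbmod.filter_records(panel_db, cation=("K", 50.0))
        assert set(sub.buffers) == {"KPi-KCl"}

    def test_unknown_field_errors(self, panel_db):
        with pytest.raises(ValueError, match="unknown filter"):
            dbmod.filter_records(panel_db, color="blue")


class TestArchiveRoundTrip:
    def test_numeric_arrays_bit_faithful(self, rich_db, tmp_path):
        root = dbmod.save_db(rich_db, tmp_path / "db")
        back = dbmod.load_db(root)
        assert set(back.oligos) == set(rich_db.oligos)
        rec_a = rich_db.record_for("2GKU", "TMAA-1K")
        rec_b = back.record_for("2GKU", "TMAA-1K")
        assert np.allclose(rec_a.datasets["melting"].absorbance,
                           rec_b.datasets["melting"].absorbance, atol=1e-15)
        assert np.allclose(rec_a.datasets["cd"].signal,
                           rec_b.datasets["cd"].signal, atol=1e-15)
        assert np.allclose(rec_a.datasets["ms"].intensity,
                           rec_b.datasets["ms"].intensity, atol=1e-15)
        assert np.allclose(np.asarray(rec_a.datasets["ims"]),
                           np.asarray(rec_b.datasets["ims"]), atol=1e-15)

    def test_metadata_round_trip(self, rich_db, tmp_path):
        back = dbmod.load_db(dbmod.save_db(rich_db, tmp_path / "db"))
        o_a, o_b = rich_db.oligos["2GKU"], back.oligos["2GKU"]
        assert (o_a.sequence, o_a.family, o_a.rating) == (
            o_b.sequence, o_b.family, o_b.rating)
        assert back.buffers["TMAA-1K"].k_mM == 1.0
        assert back.record_for("2GKU", "TMAA-1K").datasets["cd"].unit == \
            rich_db.record_for("2GKU", "TMAA-1K").datasets["cd"].unit

    def test_load_missing_path_errors(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            dbmod.load_db(tmp_path / "nowhere")

    def test_old_schema_version_refused(self, rich_db, tmp_path):
        root = dbmod.save_db(rich_db, tmp_path / "db")
        manifest = json.loads((root / "manifest.json").read_text())
        manifest["schema_version"] = 0  # plant an outdated archive
        (root / "manifest.json").write_text(json.dumps(manifest))
        with pytest.raises(ValueError, match="schema version"):
            dbmod.load_db(root)


class TestSummaryTable:
    def test_column_completeness(self, rich_db):
        table = dbmod.summary_table(rich_db)
        for col in ("oligo", "condition", "Tm_C", "theta_25C", "cd_class",
                    "rating", "pct_2K_z5"):
            assert col in table.columns

    def test_single_record_single_row(self):
        db = dbmod.Database()
        db.add_oligo(Oligonucleotide("X1", "ACGT"))
        db.record_for("X1", "TMAA-1K").datasets["cd"] = \
            synthgen.make_cd_spectrum("parallel-typeI")
        assert len(dbmod.summary_table(db)) == 1

    def test_computed_values(self, rich_db):
        table = dbmod.summary_table(rich_db).set_index("oligo")
        assert table.loc["2GKU", "Tm_C"] == pytest.approx(41.0, abs=0.5)
        assert table.loc["2GKU", "cd_class"] == "hybrid-typeII"
        assert table.loc["1XAV", "cd_class"] == "parallel-typeI"
        assert np.isnan(table.loc["1XAV", "Tm_C"])  # no melting data: empty cell

    def test_abundances_resum_to_100(self, rich_db):
        table = dbmod.summary_table(rich_db).set_index("oligo")
        pct_cols = [c for c in table.columns if c.startswith("pct_")]
        total = table.loc["2GKU", pct_cols].sum()
        assert total == pytest.approx(100.0, abs=0.01)


class TestReports:
    def test_html_report_contains_all_panels_and_sequence(self, rich_db, tmp_path):
        path = dbmod.render_report(rich_db, "2GKU", "html", tmp_path)
        html = path.read_text()
        assert "TTGGGTTAGGGTTAGGGTTAGGGA" in html
        assert html.count("<svg") == 5
        assert "not available" not in html

    def test_markdown_report_same_content(self, rich_db, tmp_path):
        md = dbmod.render_report(rich_db, "2GKU", "md", tmp_path).read_text()
        assert "TTGGGTTAGGGTTAGGGTTAGGGA" in md
        assert "Circular dichroism" in md and "Native ESI-MS" in md

    def test_partial_data_report_has_placeholders(self, rich_db, tmp_path):
        html = dbmod.render_report(rich_db, "1XAV", "html", tmp_path).read_text()
        assert html.count("<svg") == 1  # only the CD panel has data
        assert html.count("not available") == 4

    def test_absent_oligo_errors(self, rich_db, tmp_path):
        with pytest.raises(KeyError, match="NOPE"):
            dbmod.render_report(rich_db, "NOPE", "html", tmp_path)
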