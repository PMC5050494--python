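"""Localization-table I/O, unit handling and filtering."""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from shapely.geometry import Polygon

from lama import (LocalizationTable, ReaderConfig, filter_localizations,
                  read_localizations, write_localizations)
from lama.exceptions import FormatError, ParseError, SchemaError

from conftest import DATA_DIR, table_from_xy


THUNDERSTORM_3ROW = (
    '"x [nm]","y [nm]","frame"\n'
    "100.0,200.0,1\n"
    "110.0,210.0,1\n"
    "500.0,500.0,2\n"
)


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReaders:
    def test_thunderstorm_nm_coordinates_and_frame_shift(self, tmp_path):
        path = _write(tmp_path, "t.csv", THUNDERSTORM_3ROW)
        t = read_localizations(path)
        assert len(t) == 3
        assert list(t.frames) == [0, 0, 1]  # ThunderSTORM is 1-based
        assert t.data["x"].tolist() == [100.0, 110.0, 500.0]
        assert t.region == (100.0, 200.0, 500.0, 500.0)

    def test_pixel_units_scale_by_pixel_size(self, tmp_path):
        text = THUNDERSTORM_3ROW.replace("[nm]", "[px]")
        path = _write(tmp_path, "t.csv", text)
        t = read_localizations(path, ReaderConfig(pixel_size_nm=100.0))
        assert t.data["x"].tolist() == [10000.0, 11000.0, 50000.0]

    def test_missing_x_column_is_schema_error(self, tmp_path):
        path = _write(tmp_path, "t.csv", '"y [nm]","frame"\n1.0,1\n')
        with pytest.raises(SchemaError, match="x"):
            read_localizations(path)

    def test_non_numeric_cell_reports_row(self, tmp_path):
        bad = THUNDERSTORM_3ROW.replace("110.0", "oops")
        path = _write(tmp_path, "t.csv", bad)
        with pytest.raises(ParseError) as err:
            read_localizations(path)
        assert err.value.row == 1

    def test_unknown_dialect_is_format_error(self, tmp_path):
        path = _write(tmp_path, "t.xyz", "just some text\nwithout structure\n")
        with pytest.raises(FormatError):
            read_localizations(path)

    def test_committed_thunderstorm_fixture(self):
        t = read_localizations(DATA_DIR / "thunderstorm_example.csv")
        assert len(t) == 5
        assert t.source_format == "thunderstorm"
        assert list(t.frames) == [0, 0, 1, 1, 2]
        assert t.data["photons"].iloc[0] == pytest.approx(1202.5)
        assert t.data["psf_sigma"].iloc[1] == pytest.approx(151.2)
        assert t.data["precision"].iloc[2] == pytest.approx(9.1)
        assert "id" in t.data.columns  # unknown columns preserved

    def test_committed_rapidstorm_fixture(self):
        t = read_localizations(DATA_DIR / "rapidstorm_example.txt")
        assert len(t) == 5
        assert t.source_format == "rapidstorm"
        assert list(t.frames) == [0, 0, 1, 1, 2]  # rapidSTORM already 0-based
        assert t.data["x"].tolist() == [100.0, 110.0, 500.0, 742.5, 1503.2]
        assert t.data["photons"].iloc[2] == pytest.approx(7800.1)

    def test_line_endings_do_not_matter(self, tmp_path):
        unix = read_localizations(_write(tmp_path, "u.csv", THUNDERSTORM_3ROW))
        dos = read_localizations(
            _write(tmp_path, "d.csv", THUNDERSTORM_3ROW.replace("\n", "\r\n")))
        pd.testing.assert_frame_equal(unix.data, dos.data)


class TestWriters:
    @pytest.mark.parametrize("dialect", ["thunderstorm", "lama_internal"])
    def test_round_trip_is_lossless(self, tmp_path, three_row_table, dialect):
        path = tmp_path / "out.csv"
        write_localizations(three_row_table, path, dialect=dialect)
        back = read_localizations(path)
        np.testing.assert_allclose(back.data["x"], three_row_table.data["x"], atol=1e-6)
        np.testing.assert_allclose(back.data["y"], three_row_table.data["y"], atol=1e-6)
        assert list(back.frames) == list(three_row_table.frames)

    def test_empty_table_round_trips_to_zero_records(self, tmp_path):
        empty = LocalizationTable(pd.DataFrame({"x": [], "y": [], "frame": []}))
        path = tmp_path / "empty.csv"
        write_localizations(empty, path)
        assert len(read_localizations(path)) == 0

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.tuples(
        st.floats(0, 1e5, allow_nan=False, width=32),
        st.floats(0, 1e5, allow_nan=False, width=32),
        st.integers(0, 10_000),
        st.floats(0, 1e5, allow_nan=False, width=32)), min_size=1, max_size=30))
    def test_round_trip_with_photons_randomized(self, rows):
        import tempfile

        df = pd.DataFrame(rows, columns=["x", "y", "frame", "photons"])
        table = LocalizationTable(df)
        with tempfile.TemporaryDirectory() as tmp:
            path = f"{tmp}/t.csv"
            write_localizations(table, path, dialect="thunderstorm")
            back = read_localizations(path)
        assert "photons" in back.data.columns
        for col in ("x", "y", "photons"):
            np.testing.assert_allclose(back.data[col], df[col], atol=1e-6)
        assert list(back.frames) == list(df["frame"])


class TestFilter:
    def test_rectangle_roi_containment(self, three_row_table):
        out = filter_localizations(three_row_table, roi=(0, 0, 300, 300))
        assert len(out) == 2
        assert out.region == (0.0, 0.0, 300.0, 300.0)

    def test_roi_is_half_open(self):
        t = table_from_xy([(100, 100), (300, 100)])
        assert len(filter_localizations(t, roi=(100, 0, 300, 300))) == 1

    def test_frame_range_inclusive(self, three_row_table):
        assert len(filter_localizations(three_row_table, frame_range=(0, 0))) == 2

    def test_inverted_frame_range_rejected(self, three_row_table):
        with pytest.raises(ValueError):
            filter_localizations(three_row_table, frame_range=(3, 1))

    def test_no_filters_is_identity(self, three_row_table):
        out = filter_localizations(three_row_table)
        pd.testing.assert_frame_equal(out.data, three_row_table.data)

    def test_polygon_roi(self):
        t = table_from_xy([(1, 1), (9, 9), (5, 1)])
        tri = Polygon([(0, 0), (10, 0), (0, 10)])
        out = filter_localizations(t, roi=tri)
        assert len(out) == 2

    def test_min_photons(self):
        t = table_from_xy([(0, 0), (1, 1)], photons=[50.0, 500.0])
        assert len(filter_localizations(t, min_photons=100)) == 1

    def test_filtering_is_idempotent(self, three_row_table):
        kwargs = dict(roi=(0, 0, 300, 300), frame_range=(0, 5))
        once = filter_localizations(three_row_table, **kwargs)
        twice = filter_localizations(once, **kwargs)
        pd.testing.assert_frame_equal(once.data, twice.data)
        assert once.region == twice.region


class TestInvariants:
    def test_negative_frames_rejected(self):
        with pytest.raises(ValueError):
            LocalizationTable(pd.DataFrame({"x": [1.0], "y": [1.0], "frame": [-1]}))

    def test_non_finite_coordinates_rejected(self):
        with pytest.raises(ValueError):
            LocalizationTable(pd.DataFrame({"x": [np.nan], "y": [1.0], "frame": [0]}))

    def test_region_derived_as_tight_bbox(self):
        t = table_from_xy([(10, 20), (30, 5)])
        assert t.region == (10.0, 5.0, 30.0, 20.0)
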