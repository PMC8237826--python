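import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from shapely.geometry import Polygon, box

from gapmeter import records as rec
from util import point_in_unit_square


def df(rows):
    return pd.DataFrame(rows, columns=["species", "lat", "lon", "date", "source"])


class TestDeduplicate:
    def test_same_key_keeps_one(self):
        out, removed = rec.deduplicate(
            df([("A b", "-23.512", "-46.701", "2001-01-01", "db")] * 2)
        )
        assert len(out) == 1 and removed == 1

    def test_different_species_kept(self):
        out, removed = rec.deduplicate(
            df(
                [
                    ("A b", "-23.512", "-46.701", "2001-01-01", "db"),
                    ("C d", "-23.512", "-46.701", "2001-01-01", "db"),
                ]
            )
        )
        assert len(out) == 2 and removed == 0

    def test_different_dates_kept(self):
        out, removed = rec.deduplicate(
            df(
                [
                    ("A b", "-23.512", "-46.701", "2001-01-01", "db"),
                    ("A b", "-23.512", "-46.701", "2001-01-02", "db"),
                ]
            )
        )
        assert len(out) == 2 and removed == 0

    def test_normalized_species_name_in_key(self):
        out, _ = rec.deduplicate(
            df(
                [
                    ("A b", "-23.512", "-46.701", "2001-01-01", "db"),
                    ("  a  B ", "-23.512", "-46.701", "2001-01-01", "db"),
                ]
            )
        )
        assert len(out) == 1

    def test_first_occurrence_kept(self, sample_records):
        out, removed = rec.deduplicate(sample_records)
        assert removed == 1
        assert out.index[0] == 0


class TestPrecision:
    @pytest.mark.parametrize(
        "lat,lon,kept",
        [
            ("-23.512", "-46.701", True),
            ("-23.512", "-46.7", False),
            ("-23", "-46.701", False),
            ("−23.512", "−46.701", True),  # unicode minus
            ("-23.5120", "-46.70", False),
            ("garbage", "-46.701", False),
        ],
    )
    def test_rule(self, lat, lon, kept):
        out, removed = rec.filter_precision(df([("A b", lat, lon, "", "db")]))
        assert (len(out) == 1) is kept
        assert removed == (0 if kept else 1)

    def test_count_decimals_trailing_zeros(self):
        assert rec.count_decimals("-46.700") == 3
        assert rec.count_decimals("-46.7") == 1
        assert rec.count_decimals("-46") == 0
        assert rec.count_decimals("bad") == -1

    @given(
        st.integers(-180, 180),
        st.integers(0, 8),
        st.integers(0, 10**8 - 1),
    )
    def test_count_decimals_matches_construction(self, whole, n_dec, frac):
        s = f"{whole}.{str(frac).zfill(8)[:n_dec]}" if n_dec else str(whole)
        assert rec.count_decimals(s) == n_dec


class TestExtent:
    def test_centroid_kept(self, unit_square):
        out, _ = rec.filter_extent(df([("A b", "0.5", "0.5", "", "db")]), unit_square)
        assert len(out) == 1

    def test_outside_removed(self, unit_square):
        out, removed = rec.filter_extent(df([("A b", "2.0", "2.0", "", "db")]), unit_square)
        assert len(out) == 0 and removed == 1

    def test_boundary_counts_as_inside(self, unit_square):
        # convention check vs a point-in-unit-square oracle
        for x, y in [(0.0, 0.5), (1.0, 1.0), (0.5, 0.0)]:
            assert point_in_unit_square(x, y)
            out, _ = rec.filter_extent(df([("A b", str(y), str(x), "", "db")]), unit_square)
            assert len(out) == 1, (x, y)

    def test_invalid_polygon_raises(self):
        bowtie = Polygon([(0, 0), (1, 1), (1, 0), (0, 1)])
        with pytest.raises(ValueError):
            rec.filter_extent(df([("A b", "0.5", "0.5", "", "db")]), bowtie)


class TestCentroids:
    def test_near_centroid_removed(self):
        centroids = pd.DataFrame({"x": [0.0], "y": [0.0]})
        out, removed = rec.filter_centroids(
            df([("A b", "10.0", "0.0", "", "db")]), centroids, radius=1000.0
        )
        assert removed == 1 and len(out) == 0

    def test_far_record_kept(self):
        centroids = pd.DataFrame({"x": [0.0], "y": [0.0]})
        out, removed = rec.filter_centroids(
            df([("A b", "5000.0", "0.0", "", "db")]), centroids, radius=1000.0
        )
        assert removed == 0 and len(out) == 1

    def test_empty_list_is_identity(self):
        frame = df([("A b", "10.0", "0.0", "", "db")])
        out, removed = rec.filter_centroids(frame, None)
        assert removed == 0 and len(out) == 1


class TestTaxonomy:
    valid = ["Adelpha plesaure", "Morpho helenor"]
    synonyms = {"Morpho achillaena": "Morpho helenor"}

    def test_valid_kept_unchanged(self):
        out, removed = rec.filter_taxonomy(
            df([("Adelpha plesaure", "0", "0", "", "db")]), self.valid, self.synonyms
        )
        assert removed == 0 and out["species"].iloc[0] == "Adelpha plesaure"

    def test_synonym_renamed(self):
        out, _ = rec.filter_taxonomy(
            df([("Morpho achillaena", "0", "0", "", "db")]), self.valid, self.synonyms
        )
        assert out["species"].iloc[0] == "Morpho helenor"

    def test_unknown_removed(self):
        out, removed = rec.filter_taxonomy(
            df([("Morphoo helenorr", "0", "0", "", "db")]), self.valid, self.synonyms
        )
        assert removed == 1 and len(out) == 0

    def test_bad_synonym_map_raises(self):
        with pytest.raises(ValueError):
            rec.filter_taxonomy(
                df([("A b", "0", "0", "", "db")]), self.valid, {"X y": "Not A Name"}
            )


class TestGrid:
    grid = rec.GridIndex(0.0, 0.0, 1000.0)

    def test_center_of_first_cell(self):
        assert self.grid.cell_of(500.0, 500.0) == (0, 0)

    def test_edge_goes_to_lower_cell(self):
        # half-open convention vs brute-force binning
        for v in [1000.0, 2000.0, 3000.0]:
            row, col = self.grid.cell_of(v, v)
            assert (row, col) == (int(v // 1000), int(v // 1000))
            assert v >= col * 1000.0 and v < (col + 1) * 1000.0

    def test_straddling_points_differ(self):
        a = self.grid.cell_of(999.5, 500.0)
        b = self.grid.cell_of(1000.5, 500.0)
        assert a != b

    def test_assign_partitions_records(self):
        frame = df(
            [
                ("A b", "500.0", "500.0", "", "db"),
                ("A b", "1500.0", "500.0", "", "db"),
                ("C d", "1500.0", "500.0", "", "db"),
            ]
        )
        cells = rec.assign_to_grid(frame, self.grid)
        assert set(cells) == {(0, 0), (1, 0)}
        assert sum(len(v) for v in cells.values()) == 3

    def test_out_of_extent_raises(self):
        grid = rec.GridIndex(0.0, 0.0, 1000.0, n_rows=2, n_cols=2)
        with pytest.raises(ValueError):
            rec.assign_to_grid(df([("A b", "5000.0", "500.0", "", "db")]), grid)


class TestCleanPipeline:
    def test_report_sum_identity_and_idempotence(self, small_survey, small_scenario):
        records, _ = small_survey
        cfg, scenario = small_scenario
        cleaned, report = rec.clean_records(records, scenario.polygon)
        report.check()
        assert report.surviving == len(cleaned)
        again, report2 = rec.clean_records(cleaned, scenario.polygon)
        assert len(again) == len(cleaned)
        assert report2.removed_duplicates == 0
        pd.testing.assert_frame_equal(
            again.reset_index(drop=True)[["species", "lat", "lon", "date"]],
            cleaned.reset_index(drop=True)[["species", "lat", "lon", "date"]],
        )

    def test_planted_violations_counted_exactly(self):
        """Each removal count equals the number of planted violations."""
        k = 4
        polygon = box(0.0, 0.0, 10_000.0, 10_000.0)
        good = [
            ("Adelpha plesaure", f"{3000 + 17 * i}.125", f"{4000 + 13 * i}.250", f"2001-01-{i + 1:02d}", "db")
            for i in range(6)
        ]
        dupes = [good[0]] * k
        imprecise = [("Adelpha plesaure", f"{3000 + i}.1", "4000.125", "2002-01-01", "db") for i in range(k)]
        outside = [("Adelpha plesaure", f"{90_000 + i}.125", "4000.125", "2003-01-01", "db") for i in range(k)]
        near_city = [("Adelpha plesaure", "9000.125", f"{9000 + i}.125", "2004-01-01", "db") for i in range(k)]
        bad_names = [("Nonexistens species", "3000.125", f"{5000 + 7 * i}.125", "2005-01-01", "db") for i in range(k)]
        frame = df(good + dupes + imprecise + outside + near_city + bad_names)
        centroids = pd.DataFrame({"x": [9000.125], "y": [9000.5]})
        cleaned, report = rec.clean_records(
            frame,
            polygon,
            valid_names=["Adelpha plesaure"],
            centroids=centroids,
            centroid_radius=100.0,
        )
        assert report.removed_duplicates == k
        assert report.removed_precision == k
        assert report.removed_extent == k
        assert report.removed_centroid == k
        assert report.removed_taxonomy == k
        assert report.surviving == len(good) == len(cleaned)
        report.check()
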