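import numpy as np
import pytest

from gapmeter import landscape as ls
from gapmeter.raster import Raster
from util import brute_force_distance_transform


def raster(data, cell_size=1000.0):
    return Raster(np.asarray(data, dtype=float), cell_size)


class TestProportionHabitat:
    def test_all_habitat(self):
        out = ls.proportion_habitat(raster(np.ones((5, 5))), window_m=3000.0)
        assert np.allclose(out.data, 1.0)

    def test_no_habitat(self):
        out = ls.proportion_habitat(raster(np.zeros((5, 5))), window_m=3000.0)
        assert np.allclose(out.data, 0.0)

    def test_single_cell_interior(self):
        data = np.zeros((5, 5))
        data[2, 2] = 1
        out = ls.proportion_habitat(raster(data), window_m=3000.0)
        assert out.data[2, 2] == pytest.approx(1 / 9)
        assert out.data[1, 1] == pytest.approx(1 / 9)

    def test_truncated_window_at_edge(self):
        data = np.ones((5, 5))
        out = ls.proportion_habitat(raster(data), window_m=3000.0)
        assert out.data[0, 0] == pytest.approx(1.0)  # 4-cell truncated window, all habitat

    def test_window_smaller_than_cell_raises(self):
        with pytest.raises(ValueError):
            ls.proportion_habitat(raster(np.ones((3, 3))), window_m=100.0)


class TestFragmentSizes:
    def test_three_connected_km_cells(self):
        data = np.zeros((3, 5))
        data[1, 1:4] = 1
        out, _ = ls.fragment_sizes(raster(data))  # 3 x 100 ha
        assert out.data[1, 1] == pytest.approx(np.log10(300), abs=1e-12)

    def test_isolated_km_cell(self):
        data = np.zeros((3, 3))
        data[1, 1] = 1
        out, _ = ls.fragment_sizes(raster(data))
        assert out.data[1, 1] == pytest.approx(2.0)

    def test_diagonal_cells_join_under_8_connectivity(self):
        data = np.zeros((4, 4))
        data[1, 1] = data[2, 2] = 1
        out, labels = ls.fragment_sizes(raster(data))
        assert labels[1, 1] == labels[2, 2]
        # 4-connectivity oracle would split them
        from scipy.ndimage import label as scipy_label

        labels4, n4 = scipy_label(data > 0.5)
        assert n4 == 2
        assert out.data[1, 1] == pytest.approx(np.log10(200))

    def test_non_habitat_is_nan(self):
        data = np.zeros((3, 3))
        data[0, 0] = 1
        out, _ = ls.fragment_sizes(raster(data))
        assert np.isnan(out.data[2, 2])

    def test_area_conservation(self, small_scenario):
        _, scenario = small_scenario
        out, labels = ls.fragment_sizes(scenario.habitat)
        mask = scenario.habitat.data > 0.5
        cell_ha = scenario.habitat.cell_size**2 / 1e4
        total = sum(
            10 ** out.data[mask][labels[mask] == lab][0]
            for lab in np.unique(labels[mask])
        )
        assert total == pytest.approx(mask.sum() * cell_ha)


class TestFunctionalConnectivity:
    def _two_patches(self, gap_cells: int, cell_size=50.0):
        """Two 100-ha patches (20x20 cells of 0.25 ha) separated horizontally."""
        h = 28
        w = 48 + gap_cells + 8
        data = np.zeros((h, w))
        data[4:24, 4:24] = 1
        data[4:24, 24 + gap_cells : 44 + gap_cells] = 1
        return raster(data, cell_size)

    def test_close_patches_merge(self):
        # 100 m edge gap: boundary cell centers 150 m apart <= 180 m
        hab = self._two_patches(gap_cells=2)
        out = ls.functional_connectivity(hab, gap_m=180.0)
        assert out.data[10, 10] == pytest.approx(np.log10(200 * 100), abs=1e-9)
        assert out.data[10, 30] == pytest.approx(np.log10(20_000))

    def test_distant_patches_do_not_merge(self):
        hab = self._two_patches(gap_cells=40)  # 2,000 m apart
        out = ls.functional_connectivity(hab, gap_m=180.0)
        assert out.data[10, 10] == pytest.approx(4.0)

    def test_isolated_patch_equals_fragment(self):
        data = np.zeros((5, 5))
        data[2, 2] = 1
        out = ls.functional_connectivity(raster(data), gap_m=180.0)
        assert out.data[2, 2] == pytest.approx(np.log10(100 * 100))

    def test_gap_zero_equals_fragment_areas(self, small_scenario):
        _, scenario = small_scenario
        conn = ls.functional_connectivity(scenario.habitat, gap_m=0.0)
        frag, _ = ls.fragment_sizes(scenario.habitat)
        mask = scenario.habitat.data > 0.5
        assert np.allclose(conn.data[mask], frag.data[mask] + 2.0)  # log10(ha*100)

    def test_nearby_non_habitat_inherits(self):
        hab = self._two_patches(gap_cells=2)
        out = ls.functional_connectivity(hab, gap_m=180.0)
        # cell in the 100 m gap (within 180 m of the edge) inherits
        assert out.data[10, 25] == pytest.approx(np.log10(20_000))
        # corner cell is > 180 m from any habitat cell: stays missing
        assert np.isnan(out.data[0, 0])

    def test_negative_gap_raises(self):
        with pytest.raises(ValueError):
            ls.functional_connectivity(raster(np.ones((3, 3))), gap_m=-1.0)


class TestHomogeneity:
    def test_constant_raster_is_one(self):
        out = ls.homogeneity(raster(np.full((4, 4), 3.3)))
        assert np.allclose(out.data, 1.0)

    def test_checkerboard_interior(self):
        # interior cells: 4 orthogonal neighbors differ by the full range, the
        # 4 diagonal neighbors are equal -> mean |diff| = 0.5 of the range
        data = np.indices((6, 6)).sum(axis=0) % 2
        out = ls.homogeneity(raster(data.astype(float)))
        assert np.allclose(out.data[1:-1, 1:-1], 0.5)

    def test_column_stripes_interior(self):
        # 6 of the 8 neighbors lie in the other stripe -> 1 - 6/8
        data = np.tile(np.arange(6) % 2, (6, 1)).astype(float)
        out = ls.homogeneity(raster(data))
        assert np.allclose(out.data[1:-1, 1:-1], 0.25)

    def test_bounds(self, small_scenario):
        _, scenario = small_scenario
        out = ls.homogeneity(scenario.veg_index)
        assert np.all(out.data >= 0.0) and np.all(out.data <= 1.0)


class TestDistanceTo:
    def test_mask_cell_zero(self):
        data = np.zeros((5, 5))
        data[2, 2] = 1
        out = ls.distance_to(raster(data))
        assert out.data[2, 2] == 0.0

    def test_orthogonal_and_diagonal(self):
        data = np.zeros((5, 5))
        data[2, 2] = 1
        out = ls.distance_to(raster(data))
        assert out.data[2, 3] == pytest.approx(1000.0)
        assert out.data[3, 3] == pytest.approx(1414.2, abs=0.2)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(5)
        for _ in range(3):
            mask = rng.random((12, 15)) < 0.1
            if not mask.any():
                mask[0, 0] = True
            out = ls.distance_to(raster(mask.astype(float), cell_size=250.0))
            expected = brute_force_distance_transform(mask, 250.0)
            assert np.allclose(out.data, expected)

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            ls.distance_to(raster(np.zeros((3, 3))))
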