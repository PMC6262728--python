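"""Raster data model: I/O round-trips, focal statistics, distance
transforms, component labeling, and summary statistics against brute-force
oracles."""

import math

import numpy as np
import pytest

from lynxlink.errors import (
    EmptyRegionError,
    GridFormatError,
    ParameterError,
)
from lynxlink.grids import (
    Grid,
    circular_kernel,
    distance_to,
    focal_mean,
    grid_stats,
    label_components,
    read_grid,
    write_grid,
)

from conftest import make_grid


# ----------------------------------------------------------------------
# I/O
# ----------------------------------------------------------------------


class TestAsciiGridIO:
    def test_round_trip_is_bit_exact(self, tmp_path, rng):
        g = make_grid(rng.normal(size=(7, 5)))
        g.values[2, 3] = g.nodata
        path = tmp_path / "g.asc"
        write_grid(g, path, "ascii_grid")
        back = read_grid(path, "ascii_grid")
        np.testing.assert_array_equal(back.values, g.values)
        assert back.cell_size == g.cell_size
        assert back.origin_x == g.origin_x
        assert back.origin_y == g.origin_y
        assert back.nodata == g.nodata

    def test_handwritten_header_parses(self, tmp_path):
        path = tmp_path / "g.asc"
        path.write_text(
            "ncols 3\nnrows 3\nxllcorner 0\nyllcorner 0\ncellsize 30\n"
            "NODATA_value -9999\n5 5 5\n5 5 5\n5 5 5\n"
        )
        g = read_grid(path, "ascii_grid")
        assert g.n_rows == 3 and g.cell_size == 30
        assert (g.values == 5).all()

    def test_nodata_cell_excluded_from_mean(self, tmp_path):
        path = tmp_path / "g.asc"
        path.write_text(
            "ncols 2\nnrows 1\nxllcorner 0\nyllcorner 0\ncellsize 30\n"
            "NODATA_value -9999\n4 -9999\n"
        )
        assert grid_stats(read_grid(path, "ascii_grid"))["mean"] == 4.0

    def test_malformed_header_names_the_field(self, tmp_path):
        path = tmp_path / "bad.asc"
        path.write_text("ncols 2\nnrows oops\nxllcorner 0\nyllcorner 0\ncellsize 30\n1 2\n")
        with pytest.raises(GridFormatError, match="nrows"):
            read_grid(path, "ascii_grid")

    def test_missing_header_field_raises(self, tmp_path):
        path = tmp_path / "bad.asc"
        path.write_text("ncols 2\nnrows 1\nxllcorner 0\nyllcorner 0\n1 2\n")
        with pytest.raises(GridFormatError, match="cellsize"):
            read_grid(path, "ascii_grid")

    def test_round_trip_preserves_grid_stats(self, tmp_path, rng):
        g = make_grid(rng.uniform(0, 10, size=(9, 9)))
        write_grid(g, tmp_path / "g.asc", "ascii_grid")
        back = read_grid(tmp_path / "g.asc", "ascii_grid")
        assert grid_stats(back) == grid_stats(g)


class TestGeoTiffIO:
    def test_round_trip_within_float32(self, tmp_path, rng):
        g = make_grid(rng.normal(size=(6, 8)), cell_size=250.0)
        path = tmp_path / "g.tif"
        write_grid(g, path, "geotiff")
        back = read_grid(path, "geotiff")
        np.testing.assert_allclose(back.values, g.values, rtol=1e-6)
        assert back.cell_size == g.cell_size
        assert back.origin_x == g.origin_x
        assert back.origin_y == g.origin_y

    def test_single_cell_value_survives(self, tmp_path):
        g = make_grid([[7.0]])
        write_grid(g, tmp_path / "one.tif", "geotiff")
        assert read_grid(tmp_path / "one.tif", "geotiff").values[0, 0] == 7.0

    def test_crs_label_carried_through(self, tmp_path):
        g = make_grid([[1.0, 2.0]])
        g.crs_label = "EPSG:5070"
        write_grid(g, tmp_path / "g.tif", "geotiff")
        assert read_grid(tmp_path / "g.tif", "geotiff").crs_label == "EPSG:5070"


def test_unknown_dialect_rejected(tmp_path):
    with pytest.raises(ParameterError):
        read_grid(tmp_path / "x", "netcdf")


# ----------------------------------------------------------------------
# Focal mean
# ----------------------------------------------------------------------


class TestFocalMean:
    def test_identity_on_constant_grid(self):
        g = make_grid(np.full((12, 12), 4.0), cell_size=1000.0)
        out = focal_mean(g, 12.0, shape="circle")
        np.testing.assert_allclose(out.values, 4.0)

    def test_rook_kernel_average(self):
        # pi km^2 window at 1 km cells: kernel = focal pixel + 4 rook
        # neighbors (diagonals at sqrt(2) km are outside radius 1 km)
        vals = np.zeros((5, 5))
        vals[2, 2] = 10.0
        g = make_grid(vals, cell_size=1000.0)
        out = focal_mean(g, math.pi, shape="circle")
        assert out.values[2, 2] == pytest.approx(10.0 / 5.0)

    def test_kernel_membership_matches_brute_force(self):
        # home-range-sized window on a 30 m grid
        kernel = circular_kernel(88.0, 30.0)
        r = math.sqrt(88.0e6 / math.pi)
        half = kernel.shape[0] // 2
        count = 0
        for di in range(-half, half + 1):
            for dj in range(-half, half + 1):
                if (di * di + dj * dj) * 30.0**2 <= r * r:
                    count += 1
        assert kernel.sum() == count

    def test_bounded_by_input_range(self, rng):
        g = make_grid(rng.uniform(2, 9, size=(20, 20)), cell_size=100.0)
        out = focal_mean(g, 0.25, shape="circle")
        assert out.values.min() >= 2.0 - 1e-9
        assert out.values.max() <= 9.0 + 1e-9

    def test_edge_kernel_shrinks_not_pads(self):
        g = make_grid(np.full((6, 6), 3.0), cell_size=100.0)
        out = focal_mean(g, 0.25, shape="square")
        # nodata-padding would drag edge means below 3
        np.testing.assert_allclose(out.values, 3.0)

    def test_nodata_propagates_and_is_excluded(self):
        vals = np.full((5, 5), 2.0)
        vals[0, 0] = -9999.0
        g = make_grid(vals, cell_size=100.0)
        out = focal_mean(g, 0.09, shape="square")
        assert out.values[0, 0] == g.nodata
        np.testing.assert_allclose(out.values[1:, 1:], 2.0)

    def test_window_smaller_than_pixel_rejected(self):
        g = make_grid(np.ones((5, 5)), cell_size=1000.0)
        with pytest.raises(ParameterError):
            focal_mean(g, 1e-4)


# ----------------------------------------------------------------------
# Distance transform
# ----------------------------------------------------------------------


class TestDistanceTo:
    def test_rook_and_diagonal_neighbors(self):
        m = np.zeros((3, 3), dtype=bool)
        m[1, 1] = True
        d = distance_to(make_grid(m)).values
        assert d[1, 1] == 0.0
        assert d[0, 1] == pytest.approx(30.0)
        assert d[0, 0] == pytest.approx(30.0 * math.sqrt(2))

    def test_matches_exhaustive_oracle(self, rng):
        m = rng.random((20, 20)) < 0.07
        m[4, 11] = True  # guarantee non-empty
        d = distance_to(make_grid(m)).values
        feat = np.argwhere(m)
        for r in range(20):
            for c in range(20):
                exact = min(
                    math.hypot(r - fr, c - fc) * 30.0 for fr, fc in feat
                )
                assert d[r, c] == pytest.approx(exact, abs=1e-6)

    def test_empty_mask_gives_infinity(self):
        d = distance_to(make_grid(np.zeros((4, 4), dtype=bool)))
        assert np.isinf(d.values).all()

    def test_triangle_inequality_sampled(self, rng):
        m = rng.random((25, 25)) < 0.05
        m[0, 0] = True
        d = distance_to(make_grid(m)).values
        for _ in range(200):
            r1, c1, r2, c2 = rng.integers(0, 25, size=4)
            sep = math.hypot(r1 - r2, c1 - c2) * 30.0
            assert d[r1, c1] <= d[r2, c2] + sep + 1e-6


# ----------------------------------------------------------------------
# Component labeling
# ----------------------------------------------------------------------


def _flood_fill_oracle(mask, connectivity):
    """Independent BFS labeling (unordered partition)."""
    offs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if connectivity == 8:
        offs += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    for r in range(mask.shape[0]):
        for c in range(mask.shape[1]):
            if mask[r, c] and not seen[r, c]:
                comp, stack = set(), [(r, c)]
                seen[r, c] = True
                while stack:
                    cr, cc = stack.pop()
                    comp.add((cr, cc))
                    for dr, dc in offs:
                        nr, nc = cr + dr, cc + dc
                        if (
                            0 <= nr < mask.shape[0]
                            and 0 <= nc < mask.shape[1]
                            and mask[nr, nc]
                            and not seen[nr, nc]
                        ):
                            seen[nr, nc] = True
                            stack.append((nr, nc))
                comps.append(frozenset(comp))
    return set(comps)


class TestLabelComponents:
    def test_diagonal_touch_depends_on_connectivity(self):
        m = np.zeros((2, 2), dtype=bool)
        m[0, 0] = m[1, 1] = True
        assert label_components(make_grid(m), 8).region_count == 1
        assert label_components(make_grid(m), 4).region_count == 2

    def test_empty_mask(self):
        assert label_components(make_grid(np.zeros((3, 3), dtype=bool))).region_count == 0

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_partition_matches_flood_fill_oracle(self, rng, connectivity):
        m = rng.random((15, 15)) < 0.4
        lab = label_components(make_grid(m), connectivity)
        got = set()
        for k in range(1, lab.region_count + 1):
            got.add(frozenset(map(tuple, np.argwhere(lab.labels.values == k))))
        assert got == _flood_fill_oracle(m, connectivity)

    def test_labels_ordered_by_decreasing_size(self, rng):
        m = rng.random((15, 15)) < 0.35
        lab = label_components(make_grid(m), 4)
        sizes = [
            (lab.labels.values == k).sum() for k in range(1, lab.region_count + 1)
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_every_true_pixel_labeled_once(self, rng):
        m = rng.random((12, 12)) < 0.5
        lab = label_components(make_grid(m), 8)
        labels = np.asarray(lab.labels.values)
        assert ((labels > 0) == m).all()

    def test_transpose_invariant_up_to_relabeling(self, rng):
        m = rng.random((10, 14)) < 0.4
        a = label_components(make_grid(m), 8)
        b = label_components(make_grid(m.T), 8)
        assert a.region_count == b.region_count
        parts_a = {
            frozenset(map(tuple, np.argwhere(a.labels.values == k)))
            for k in range(1, a.region_count + 1)
        }
        parts_b = {
            frozenset((c, r) for r, c in np.argwhere(b.labels.values == k))
            for k in range(1, b.region_count + 1)
        }
        assert parts_a == parts_b


# ----------------------------------------------------------------------
# Statistics
# ----------------------------------------------------------------------


class TestGridStats:
    def test_simple_mean(self):
        assert grid_stats(make_grid([[2.0, 4.0]]))["mean"] == 3.0

    def test_area_of_hundred_30m_pixels(self):
        s = grid_stats(make_grid(np.ones((10, 10)), cell_size=30.0))
        assert s["pixel_count"] == 100
        assert s["area_km2"] == pytest.approx(0.09)

    def test_matches_two_pass_oracle(self, rng):
        vals = rng.normal(5, 2, size=(17, 13))
        s = grid_stats(make_grid(vals))
        mean = vals.sum() / vals.size
        sd = math.sqrt(((vals - mean) ** 2).sum() / (vals.size - 1))
        assert s["mean"] == pytest.approx(mean, abs=1e-9)
        assert s["sd"] == pytest.approx(sd, abs=1e-9)
        assert s["min"] == vals.min() and s["max"] == vals.max()

    def test_region_restriction(self):
        g = make_grid([[1.0, 9.0], [5.0, 5.0]])
        region = make_grid(np.array([[True, False], [False, False]]))
        assert grid_stats(g, region)["mean"] == 1.0

    def test_empty_region_raises(self):
        g = make_grid([[1.0]])
        region = make_grid(np.array([[False]]))
        with pytest.raises(EmptyRegionError):
            grid_stats(g, region)

    def test_single_pixel_sd_is_zero(self):
        assert grid_stats(make_grid([[3.0]]))["sd"] == 0.0


def test_cell_center_convention():
    g = Grid(np.zeros((4, 4)), cell_size=30.0, origin_x=100.0, origin_y=400.0)
    assert g.cell_center(0, 0) == (115.0, 385.0)
    assert g.cell_center(3, 2) == (175.0, 295.0)
    # rows increase southward
    assert g.cell_center(1, 0)[1] < g.cell_center(0, 0)[1]
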