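import math

import numpy as np
import pandas as pd
import pytest

from ifquant.image_io import ImageStack
from ifquant.measurement import (
    CELL_TABLE_COLUMNS,
    BackgroundAOI,
    build_cell_table,
    chain_perimeter,
    compute_ctcf,
    measure_geometry,
    measure_intensity,
    select_background_aoi,
    shape_descriptors,
)
from ifquant.segmentation import LabelMask

from conftest import disk_mask


class TestChainPerimeter:
    def test_square_10x10(self):
        mask = np.zeros((12, 12), bool)
        mask[1:11, 1:11] = True
        # hand-enumerated boundary walk: 4 sides of 9 unit steps
        assert chain_perimeter(mask) == pytest.approx(36.0)

    def test_square_2x2(self):
        mask = np.zeros((4, 4), bool)
        mask[1:3, 1:3] = True
        assert chain_perimeter(mask) == pytest.approx(4.0)

    def test_line_1x5_out_and_back(self):
        mask = np.zeros((3, 7), bool)
        mask[1, 1:6] = True
        assert chain_perimeter(mask) == pytest.approx(8.0)

    def test_plus_shape_all_diagonal(self):
        mask = np.array([
            [0, 1, 0],
            [1, 1, 1],
            [0, 1, 0],
        ], dtype=bool)
        assert chain_perimeter(mask) == pytest.approx(4 * math.sqrt(2))

    def test_single_pixel_zero(self):
        mask = np.zeros((3, 3), bool)
        mask[1, 1] = True
        assert chain_perimeter(mask) == 0.0

    def test_rectangle(self):
        mask = np.zeros((10, 20), bool)
        mask[2:7, 3:15] = True  # 5 x 12 rectangle
        assert chain_perimeter(mask) == pytest.approx(2 * (4 + 11))


class TestMeasureGeometry:
    def test_single_pixel_centroid(self):
        labels = np.zeros((10, 10), dtype=np.int32)
        labels[7, 3] = 1
        geo = measure_geometry(LabelMask(labels))
        row = geo.iloc[0]
        assert (row.x, row.y, row.area) == (3.0, 7.0, 1.0)

    def test_square_centroid_and_area(self):
        labels = np.zeros((20, 20), dtype=np.int32)
        labels[5:15, 5:15] = 1
        row = measure_geometry(LabelMask(labels)).iloc[0]
        assert row.area == 100.0
        assert (row.x, row.y) == (9.5, 9.5)
        assert row.perimeter == pytest.approx(36.0)

    def test_pixel_size_calibration(self):
        labels = np.zeros((20, 20), dtype=np.int32)
        labels[5:15, 5:15] = 1
        row = measure_geometry(LabelMask(labels), pixel_size_um=0.5).iloc[0]
        assert row.area == pytest.approx(25.0)       # 100 px * 0.25 um^2
        assert row.perimeter == pytest.approx(18.0)  # 36 px * 0.5 um
        assert (row.x, row.y) == (9.5, 9.5)          # centroids stay in px

    def test_empty_mask_empty_table(self):
        geo = measure_geometry(LabelMask(np.zeros((5, 5), dtype=np.int32)))
        assert geo.empty


class TestShapeDescriptors:
    def test_ideal_square_circularity(self):
        circ, _, _, _ = shape_descriptors(100, 40, 10, 10, 100)
        assert circ == pytest.approx(math.pi / 4)

    def test_aspect_ratio(self):
        _, ar, _, _ = shape_descriptors(50, 30, 8, 4, 55)
        assert ar == 2.0

    def test_circle_roundness_is_one(self):
        d = 12.0
        area = math.pi * d ** 2 / 4
        _, _, rnd, _ = shape_descriptors(area, math.pi * d, d, d, area)
        assert rnd == pytest.approx(1.0)

    def test_circularity_clamped_at_one(self):
        circ, _, _, _ = shape_descriptors(1000, 10, 30, 30, 1000)
        assert circ == 1.0

    def test_undefined_flagged_as_nan(self):
        circ, ar, rnd, sol = shape_descriptors(1, 0, 0, 0, 0)
        assert all(math.isnan(v) for v in (circ, ar, rnd, sol))

    def test_digitized_disk_circularity_near_one(self):
        # with the 8-chain perimeter convention the chain length of a
        # circle overshoots pi*d by ~5%, so circularity converges to
        # ~0.90 rather than 1; assert it stays high and stable
        for r in (8, 16, 32):
            labels = disk_mask((3 * r + 20,) * 2, [((3 * r + 20) // 2,) * 2 + (r,)])
            geo = measure_geometry(LabelMask(labels)).iloc[0]
            circ, *_ = shape_descriptors(
                geo.area, geo.perimeter, geo.major_axis, geo.minor_axis,
                geo.convex_area)
            assert 0.88 <= circ <= 1.0
            # chain perimeter brackets the true circle perimeter
            assert 1.0 <= geo.perimeter / (2 * math.pi * r) <= 1.1

    def test_convex_digitized_shapes_solidity_grows_to_one(self):
        sols = []
        for r in (6, 12, 16, 24):
            labels = disk_mask((3 * r + 20,) * 2, [((3 * r + 20) // 2,) * 2 + (r,)])
            geo = measure_geometry(LabelMask(labels)).iloc[0]
            sols.append(geo.area / geo.convex_area)
        assert sols == sorted(sols)
        assert sols[-1] >= 0.95


class TestMeasureIntensity:
    def test_four_pixel_object(self):
        labels = np.zeros((4, 4), dtype=np.int32)
        labels[0, 0:2] = 1
        labels[1, 0:2] = 1
        channel = np.zeros((4, 4))
        channel[0, 0:2] = 10
        channel[1, 0:2] = 20
        row = measure_intensity(LabelMask(labels), channel, "c").iloc[0]
        assert row["mean"] == 15.0
        assert row.raw_int_den == 60.0
        assert row.int_den == 60.0

    def test_all_zero_channel(self):
        labels = disk_mask((30, 30), [(10, 10, 4), (22, 22, 4)])
        out = measure_intensity(LabelMask(labels), np.zeros((30, 30)), "c")
        assert (out["mean"] == 0).all()

    def test_against_pixel_loop_oracle(self, rng):
        labels = LabelMask.from_arbitrary(disk_mask(
            (64, 64),
            [(int(rng.integers(5, 59)), int(rng.integers(5, 59)),
              int(rng.integers(2, 6))) for _ in range(20)],
        ))
        channel = rng.integers(0, 65535, size=(64, 64)).astype(np.uint16)
        out = measure_intensity(labels, channel, "c").set_index("cell")
        for lab in range(1, labels.n_objects + 1):
            total, count = 0.0, 0
            for y in range(64):
                for x in range(64):
                    if labels.labels[y, x] == lab:
                        total += float(channel[y, x])
                        count += 1
            assert out.loc[lab, "raw_int_den"] == pytest.approx(total)
            assert out.loc[lab, "mean"] == pytest.approx(total / count)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            measure_intensity(
                LabelMask(np.zeros((4, 4), np.int32)), np.zeros((5, 5)), "c")


class TestCtcf:
    def _records(self, int_den, area, label="c"):
        return pd.DataFrame({
            "Cell": [1], "Label": [label], "Area": [area], "Mean": [int_den / area],
            "X": [0.0], "Y": [0.0], "Circ.": [1.0], "IntDen": [int_den],
            "RawIntDen": [int_den], "AR": [1.0], "Round": [1.0],
            "Solidity": [1.0], "CTCF": [np.nan],
        })

    def test_direct_formula(self):
        out = compute_ctcf(self._records(1200.0, 40.0),
                           BackgroundAOI((0, 0, 5, 5), {"c": 2.5}))
        assert out.CTCF.iloc[0] == pytest.approx(1100.0)

    def test_zero_background_gives_intden(self):
        out = compute_ctcf(self._records(777.0, 10.0),
                           BackgroundAOI((0, 0, 5, 5), {"c": 0.0}))
        assert out.CTCF.iloc[0] == out.IntDen.iloc[0]

    def test_missing_channel_listed(self):
        with pytest.raises(ValueError, match="c"):
            compute_ctcf(self._records(1.0, 1.0),
                         BackgroundAOI((0, 0, 5, 5), {"other": 1.0}))

    def test_uniform_background_cell_near_zero(self, rng):
        # cells sampled from the same uniform background level: CTCF ~ 0
        level = 50.0
        channel = rng.normal(level, 1.0, size=(60, 60))
        labels = disk_mask((60, 60), [(15, 15, 6)])
        stack = ImageStack([channel], ["c"])
        mask = LabelMask(labels)
        bg = select_background_aoi(stack, "manual-rect", rect=(35, 35, 20, 20),
                                   mask=mask)
        table = build_cell_table(mask, stack, bg)
        area = table.Area.iloc[0]
        assert abs(table.CTCF.iloc[0]) < 3 * area / math.sqrt(area)


class TestSelectBackgroundAoi:
    def test_manual_rect_zero_corner(self):
        img = np.ones((40, 40)) * 7
        img[:20, :20] = 0
        stack = ImageStack([img], ["c"])
        bg = select_background_aoi(stack, "manual-rect", rect=(0, 0, 20, 20))
        assert bg.per_channel_mean["c"] == 0.0

    def test_auto_darkest_finds_corner_exhaustively(self, rng):
        img = rng.integers(100, 200, size=(50, 50)).astype(np.float64)
        img[40:, :10] -= 100  # dark corner
        stack = ImageStack([img], ["c"])
        k = 10
        bg = select_background_aoi(stack, "auto-darkest", window_px=k)
        # exhaustive window-scan oracle
        best, best_sum = None, np.inf
        for y in range(50 - k + 1):
            for x in range(50 - k + 1):
                s = img[y:y + k, x:x + k].sum()
                if s < best_sum:
                    best, best_sum = (x, y), s
        assert bg.region[:2] == best

    def test_rect_overlapping_aoi_rejected(self):
        labels = np.zeros((30, 30), dtype=np.int32)
        labels[5:10, 5:10] = 1
        stack = ImageStack([np.ones((30, 30))], ["c"])
        with pytest.raises(ValueError, match="overlaps"):
            select_background_aoi(stack, "manual-rect", rect=(4, 4, 8, 8),
                                  mask=LabelMask(labels))

    def test_auto_avoids_labels(self):
        img = np.ones((30, 30)) * 100
        img[0:10, 0:10] = 0  # darkest, but occupied
        labels = np.zeros((30, 30), dtype=np.int32)
        labels[0:10, 0:10] = 1
        stack = ImageStack([img], ["c"])
        bg = select_background_aoi(stack, "auto-darkest", window_px=10,
                                   mask=LabelMask(labels))
        x0, y0, w, h = bg.region
        assert np.all(labels[y0:y0 + h, x0:x0 + w] == 0)

    def test_fully_occupied_advises_manual(self):
        labels = np.ones((20, 20), dtype=np.int32)
        stack = ImageStack([np.ones((20, 20))], ["c"])
        with pytest.raises(ValueError, match="manual"):
            select_background_aoi(stack, "auto-darkest", window_px=5,
                                  mask=LabelMask(labels))

    def test_window_too_large(self):
        stack = ImageStack([np.ones((20, 20))], ["c"])
        with pytest.raises(ValueError, match="window"):
            select_background_aoi(stack, "auto-darkest", window_px=25)


class TestBuildCellTable:
    def _stack_and_mask(self, rng, n_channels=2):
        channels = [
            rng.integers(0, 1000, size=(50, 50)).astype(np.uint16)
            for _ in range(n_channels)
        ]
        names = [f"ch{i + 1}" for i in range(n_channels)]
        labels = disk_mask((50, 50), [(12, 12, 5), (35, 35, 6), (12, 38, 4)])
        return ImageStack(channels, names), LabelMask(labels)

    def test_schema_and_order(self, rng):
        stack, mask = self._stack_and_mask(rng)
        table = build_cell_table(mask, stack)
        assert list(table.columns) == CELL_TABLE_COLUMNS
        assert len(table) == mask.n_objects * stack.n_channels

    def test_intden_identities(self, rng):
        stack, mask = self._stack_and_mask(rng)
        table = build_cell_table(mask, stack)
        np.testing.assert_allclose(table.IntDen, table.Area * table.Mean)
        # unit pixel size: IntDen == RawIntDen
        np.testing.assert_allclose(table.IntDen, table.RawIntDen)

    def test_raw_int_den_bounded_by_image_sum(self, rng):
        stack, mask = self._stack_and_mask(rng, n_channels=1)
        table = build_cell_table(mask, stack)
        assert table.RawIntDen.sum() <= stack.channels[0].sum()

    def test_geometry_identical_across_channels(self, rng):
        stack, mask = self._stack_and_mask(rng, n_channels=3)
        table = build_cell_table(mask, stack)
        for col in ("Area", "X", "Y", "Circ.", "AR", "Round", "Solidity"):
            pivot = table.pivot(index="Cell", columns="Label", values=col)
            assert pivot.nunique(axis=1).max() == 1
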