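"""Background subtraction, erosion partition and per-cell measurement."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from endoquant import synthetic as syn
from endoquant.segmentation import (
    compute_qd_mask,
    erode_alternating,
    measure_cell,
    partition_cell,
    segment_cells,
    subtract_background,
)

CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
SQUARE = np.ones((3, 3), dtype=bool)


def erode_once_oracle(mask, structure):
    """Brute-force neighborhood test: a pixel survives iff every structure
    neighbor is inside the mask (out-of-bounds counts as background)."""
    h, w = mask.shape
    offsets = [(i - 1, j - 1) for i in range(3) for j in range(3) if structure[i, j]]
    out = np.zeros_like(mask)
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            ok = True
            for dr, dc in offsets:
                rr, cc = r + dr, c + dc
                if rr < 0 or cc < 0 or rr >= h or cc >= w or not mask[rr, cc]:
                    ok = False
                    break
            out[r, c] = ok
    return out


class TestSubtractBackground:
    def test_constant_image_goes_to_zero(self):
        out, bg = subtract_background(np.full((8, 8), 7.0))
        assert bg == 7.0
        assert np.all(out == 0)

    def test_single_bright_pixel(self):
        img = np.full((9, 9), 5.0)
        img[4, 4] = 20.0
        out, bg = subtract_background(img, method="median")
        assert bg == 5.0
        assert out[4, 4] == 15.0
        assert out.sum() == 15.0

    def test_mean_of_region(self):
        img = np.zeros((10, 10))
        img[:5, :5] = 4.0
        out, bg = subtract_background(img, method="mean-of-region", empty_region=(0, 5, 0, 5))
        assert bg == 4.0
        with pytest.raises(ValueError):
            subtract_background(img, method="mean-of-region", empty_region=(0, 20, 0, 5))

    def test_recovers_generator_background(self):
        """The median estimate lands within 1 count of the true level."""
        noise = syn.ImagingNoiseSpec(background_level=100.0)
        hits = 0
        for seed in range(10):
            cells = [syn.generate_cell(syn.CellGeometryParams(), seed=seed, field_shape=(192, 192), cell_id="c")]
            fov, _ = syn.render_field(cells, [0.5], noise, (192, 192), seed=seed)
            _, bg = subtract_background(fov.qd)
            hits += abs(bg - 100.0) <= 1.0
        assert hits >= 9


class TestErodeAlternating:
    def test_solid_square_two_iterations(self):
        mask = np.zeros((14, 14), dtype=bool)
        mask[2:12, 2:12] = True  # solid 10x10
        out = erode_alternating(mask, 2)
        assert out.sum() == 36  # solid 6x6
        assert out[4:10, 4:10].all()

    def test_large_iterations_empty(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[3:7, 3:7] = True
        assert not erode_alternating(mask, 10).any()

    def test_invalid_iterations(self):
        with pytest.raises(ValueError):
            erode_alternating(np.ones((4, 4), bool), 0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(hnp.arrays(bool, (32, 32)), st.integers(1, 6))
    def test_matches_bruteforce_oracle(self, mask, iterations):
        got = erode_alternating(mask, iterations)
        want = mask
        for k in range(1, iterations + 1):
            want = erode_once_oracle(want, CROSS if k % 2 == 1 else SQUARE)
        assert np.array_equal(got, want)

    def test_monotone_in_iterations(self, rng):
        mask = rng.random((48, 48)) > 0.3
        prev = mask
        for it in range(1, 8):
            cur = erode_alternating(mask, it)
            assert np.all(cur <= prev)  # output shrinks, never grows
            prev = cur


class TestPartitionCell:
    def test_solid_square_arithmetic(self):
        cell = np.zeros((30, 30), dtype=bool)
        cell[5:25, 5:25] = True  # 20x20
        masks = partition_cell(cell, erosion_iterations=5, qd_mask=np.ones_like(cell))
        assert masks.pre_interior.sum() == 100  # 10x10 core after 5 peels
        assert masks.pre_membrane.sum() == 300
        assert not masks.degenerate

    def test_empty_qd_mask_gives_empty_compartments(self):
        cell = np.zeros((20, 20), dtype=bool)
        cell[4:16, 4:16] = True
        masks = partition_cell(cell, 3, qd_mask=np.zeros_like(cell))
        assert masks.membrane.sum() == 0 and masks.interior.sum() == 0

    def test_exhausted_interior_flagged_degenerate(self):
        cell = np.zeros((10, 10), dtype=bool)
        cell[4:7, 4:7] = True
        masks = partition_cell(cell, erosion_iterations=5)
        assert masks.degenerate

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(hnp.arrays(bool, (24, 24)), st.integers(1, 6))
    def test_partition_is_exact(self, cell, iterations):
        if not cell.any():
            return
        qd = np.zeros_like(cell)
        qd[::2, 1::2] = True
        masks = partition_cell(cell, iterations, qd_mask=qd)
        assert not (masks.pre_membrane & masks.pre_interior).any()
        assert np.array_equal(masks.pre_membrane | masks.pre_interior, cell)
        assert not (masks.membrane & masks.interior).any()
        assert np.array_equal(masks.membrane | masks.interior, qd & cell)

    def test_interior_shrinks_with_iterations(self):
        cell = np.zeros((40, 40), dtype=bool)
        cell[5:35, 5:35] = True
        areas = [partition_cell(cell, it).pre_interior.sum() for it in range(1, 10)]
        assert all(a >= b for a, b in zip(areas, areas[1:]))


class TestComputeQdMask:
    def test_all_zero_image(self):
        assert not compute_qd_mask(np.zeros((16, 16))).any()

    def test_single_bright_pixel(self):
        img = np.zeros((32, 32))
        img[10, 10] = 50.0
        mask = compute_qd_mask(img, k_sigma=3.0)
        assert mask.sum() == 1 and mask[10, 10]

    def test_noiseless_puncta_covered(self):
        """Pixels holding >= 10% of a punctum peak are QD-positive."""
        noise = syn.ImagingNoiseSpec(background_level=0.0, read_noise_sd=0.0, shot_noise=False)
        cells = [syn.generate_cell(syn.CellGeometryParams(), seed=4, field_shape=(192, 192), cell_id="c")]
        fov, _ = syn.render_field(cells, [0.5], noise, (192, 192), seed=4)
        mask = compute_qd_mask(fov.qd)
        peak = fov.qd.max()
        relevant = fov.qd >= 0.1 * peak
        assert (mask & relevant).sum() / relevant.sum() >= 0.99


class TestSegmentCells:
    def test_empty_field_no_cells(self):
        labels, cells = segment_cells(np.zeros((64, 64)))
        assert labels.max() == 0 and cells == []

    def test_border_cell_flagged_and_excluded(self):
        img = np.zeros((64, 64))
        img[:20, 10:30] = 100.0  # touches row 0
        labels, cells = segment_cells(img, min_area_px=50, threshold_method="fixed", threshold_value=50.0)
        assert labels.max() == 0
        assert len(cells) == 1 and cells[0]["border_touching"]

    def test_recovers_synthetic_cells(self):
        noise = syn.ImagingNoiseSpec()
        geom = syn.CellGeometryParams()
        n_found = 0
        for seed in range(5):
            cells = syn._place_cells(geom, 3, (256, 256), np.random.default_rng(seed))
            fov, _ = syn.render_field(cells, [0.5] * 3, noise, (256, 256), seed=seed)
            rec, _ = subtract_background(fov.receptor)
            labels, segs = segment_cells(rec)
            for gt in cells:
                tm = gt.mask((256, 256))
                best = max(
                    ((c["core_mask"] & tm).sum() / (c["core_mask"] | tm).sum()
                     for c in segs if c["label"] > 0),
                    default=0.0,
                )
                n_found += best > 0.8
        assert n_found == 15


class TestMeasureCell:
    def test_constant_intensity_sums(self):
        cell = np.zeros((20, 20), dtype=bool)
        cell[2:18, 2:18] = True
        masks = partition_cell(cell, 2, qd_mask=np.ones_like(cell))
        qd = np.ones((20, 20))
        rec = np.full((20, 20), 3.0)
        m = measure_cell(masks, qd, rec)
        assert m.qd_membrane_sum == masks.membrane.sum()
        assert m.qd_interior_sum == masks.interior.sum()
        assert m.syfp_mean == pytest.approx(3.0)

    def test_no_qd_signal_excluded(self):
        cell = np.zeros((20, 20), dtype=bool)
        cell[2:18, 2:18] = True
        masks = partition_cell(cell, 2, qd_mask=np.zeros_like(cell))
        m = measure_cell(masks, np.ones((20, 20)), np.ones((20, 20)))
        assert m.excluded and m.exclusion_reason == "no QD signal"
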