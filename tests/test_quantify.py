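"""Thresholding, cleaning, blob labeling, region attribution, counts, densities."""

import numpy as np
import pytest

import abquant as ab
from abquant.inference import BACKGROUND, GM, WM, GridGeometry, ConfidenceHeatmap, RegionMap
from abquant.quantify import (
    BinaryMask,
    DepositBlob,
    clean_mask,
    label_array,
    label_blobs,
)


def geom(h, w, stride=16, mpp=0.503):
    return GridGeometry(
        stride_px=stride, patch_size_px=256, slide_mpp=mpp,
        slide_shape=(h * stride, w * stride), origin_px=(stride // 2, stride // 2),
    )


def heatmap(values, channel="cored"):
    values = np.asarray(values, dtype=float)
    return ConfidenceHeatmap(values=values, channel=channel,
                             geometry=geom(*values.shape))


def mask_of(values, channel="cored"):
    values = np.asarray(values, dtype=bool)
    return BinaryMask(values=values, class_label=channel, threshold_used=0.9,
                      geometry=geom(*values.shape))


def region_map(labels):
    labels = np.asarray(labels, dtype=np.uint8)
    return RegionMap(labels=labels, geometry=geom(*labels.shape))


def flood_fill_labels(mask, connectivity):
    """Independent oracle: BFS flood fill, labels in raster-scan order."""
    h, w = mask.shape
    if connectivity == 4:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        steps = [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
                 if (dy, dx) != (0, 0)]
    out = np.zeros((h, w), dtype=int)
    nxt = 0
    for i in range(h):
        for j in range(w):
            if mask[i, j] and out[i, j] == 0:
                nxt += 1
                stack = [(i, j)]
                out[i, j] = nxt
                while stack:
                    y, x = stack.pop()
                    for dy, dx in steps:
                        yy, xx = y + dy, x + dx
                        if 0 <= yy < h and 0 <= xx < w and mask[yy, xx] and out[yy, xx] == 0:
                            out[yy, xx] = nxt
                            stack.append((yy, xx))
    return out


class TestThreshold:
    def test_all_zero_heatmap_empty_mask(self):
        m = ab.threshold_heatmap(heatmap(np.zeros((8, 8))), 0.5)
        assert not m.values.any()

    def test_equality_maps_to_one(self):
        hm = heatmap([[0.9, 0.89999], [0.90001, 0.0]])
        m = ab.threshold_heatmap(hm, 0.9)
        assert m.values.tolist() == [[True, False], [True, False]]

    def test_elementwise_against_direct_comparison(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(size=(40, 40))
        for thr in (0.1, 0.5, 0.937):
            m = ab.threshold_heatmap(heatmap(vals), thr)
            assert np.array_equal(m.values, vals >= thr)

    @pytest.mark.parametrize("bad", [0.0, -0.2, 1.2])
    def test_threshold_domain(self, bad):
        with pytest.raises(ValueError):
            ab.threshold_heatmap(heatmap(np.zeros((4, 4))), bad)


class TestCleanMask:
    def test_min_one_is_identity(self):
        rng = np.random.default_rng(2)
        vals = rng.uniform(size=(32, 32)) > 0.6
        m = mask_of(vals)
        assert np.array_equal(clean_mask(m, 1).values, vals)

    def test_small_components_removed(self):
        vals = np.zeros((8, 8), dtype=bool)
        vals[0, 0] = True  # size-1 component
        vals[4, 2:7] = True  # size-5 component
        cleaned = clean_mask(mask_of(vals), 2)
        assert not cleaned.values[0, 0]
        assert cleaned.values[4, 2:7].all()
        assert cleaned.values.sum() == 5

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(size=(48, 48)) > 0.55
        once = clean_mask(mask_of(vals), 3)
        twice = clean_mask(once, 3)
        assert np.array_equal(once.values, twice.values)


class TestLabelBlobs:
    def test_diagonal_pair_connectivity(self):
        vals = np.zeros((4, 4), dtype=bool)
        vals[1, 1] = vals[2, 2] = True
        assert len(label_blobs(mask_of(vals), connectivity=8)) == 1
        assert len(label_blobs(mask_of(vals), connectivity=4)) == 2

    def test_empty_mask_empty_list(self):
        assert label_blobs(mask_of(np.zeros((6, 6)))) == []

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_random_masks_match_flood_fill_oracle(self, connectivity):
        rng = np.random.default_rng(4)
        for _ in range(60):
            vals = rng.uniform(size=(64, 64)) > 0.65
            ours = label_array(vals, connectivity)
            oracle = flood_fill_labels(vals, connectivity)
            assert np.array_equal(ours, oracle)
            blobs = label_blobs(mask_of(vals), connectivity)
            assert len(blobs) == oracle.max()
            sizes = sorted(b.cell_count for b in blobs)
            oracle_sizes = sorted(np.bincount(oracle.ravel())[1:].tolist())
            assert sizes == oracle_sizes

    def test_ordering_row_major_by_first_cell(self):
        vals = np.zeros((6, 6), dtype=bool)
        vals[4, 0] = True
        vals[0, 5] = True
        vals[2, 2] = True
        blobs = label_blobs(mask_of(vals))
        firsts = [tuple(b.cells[0]) for b in blobs]
        assert firsts == [(0, 5), (2, 2), (4, 0)]


class TestAssignRegion:
    def _blob(self, cells):
        cells = np.asarray(cells)
        return DepositBlob(
            class_label="cored", cell_count=len(cells),
            centroid_cell=tuple(cells.mean(axis=0)),
            bounding_box=(0, 0, 1, 1), cells=cells, geometry=geom(10, 10),
        )

    def test_fully_inside_gm(self):
        labels = np.full((10, 10), GM)
        assert ab.assign_region(self._blob([[1, 1], [1, 2]]), region_map(labels)) == "GM"

    def test_majority_wm(self):
        labels = np.full((10, 10), GM)
        labels[:, 5:] = WM
        cells = [[0, c] for c in range(2, 8)] + [[1, c] for c in range(4, 8)]
        # 6 WM (cols 5-7 on both rows), 4 GM
        assert ab.assign_region(self._blob(cells), region_map(labels)) == "WM"

    def test_tie_goes_to_gm(self):
        labels = np.full((10, 10), GM)
        labels[:, 5:] = WM
        cells = [[0, c] for c in range(10)]  # 5 GM, 5 WM
        assert ab.assign_region(self._blob(cells), region_map(labels)) == "GM"

    def test_background_majority_excluded(self):
        labels = np.full((10, 10), BACKGROUND)
        labels[0, 0] = GM
        cells = [[0, 0], [0, 1], [0, 2]]
        assert ab.assign_region(self._blob(cells), region_map(labels)) == "excluded"

    def test_geometry_mismatch_rejected(self):
        blob = self._blob([[0, 0]])
        other = RegionMap(labels=np.zeros((12, 12), dtype=np.uint8),
                          geometry=geom(12, 12, stride=32))
        with pytest.raises(ValueError, match="geometry"):
            ab.assign_region(blob, other)


class TestCounting:
    def test_no_blobs_zero_vector(self):
        cv = ab.count_deposits({c: [] for c in ("cored", "diffuse", "CAA")},
                               region_map(np.full((8, 8), GM)))
        assert cv.counts == (0, 0, 0, 0, 0, 0)

    def test_count_vector_additivity(self):
        a = ab.CountVector((1, 0, 2, 0, 1, 0))
        b = ab.CountVector((0, 3, 0, 1, 0, 1))
        assert (a + b).counts == (1, 3, 2, 1, 1, 1)

    def test_end_to_end_matches_ground_truth(self, default_config):
        spec = ab.random_slide_spec(21, width_px=1024, height_px=1024, n_deposits=9)
        slide, truth = ab.render_slide(spec)
        res = ab.analyze_slide(slide, default_config)
        assert res["counts_blob"] == truth.expected_counts

    def test_sum_equals_non_excluded_blobs(self, default_config):
        spec = ab.random_slide_spec(22, width_px=1024, height_px=1024, n_deposits=8)
        slide, _ = ab.render_slide(spec)
        res = ab.analyze_slide(slide, default_config)
        n_blobs = sum(
            1 for blobs in res["blobs_by_class"].values()
            for b in blobs if b.region != "excluded"
        )
        assert res["counts_blob"].total() == n_blobs


class TestPatchVote:
    def _heatmaps(self, cored):
        zero = np.zeros_like(np.asarray(cored, dtype=float))
        return {
            "cored": heatmap(cored, "cored"),
            "diffuse": heatmap(zero, "diffuse"),
            "CAA": heatmap(zero, "CAA"),
        }

    def test_empty_heatmaps_zero_vector(self):
        hms = self._heatmaps(np.zeros((8, 8)))
        cv = ab.patchvote_count(hms, region_map(np.full((8, 8), GM)),
                                {"cored": 0.9, "diffuse": 0.9, "CAA": 0.9})
        assert cv.counts == (0, 0, 0, 0, 0, 0)

    def test_counts_cells_not_objects(self):
        vals = np.zeros((8, 8))
        vals[2:5, 2:6] = 1.0  # one 12-cell blob
        hms = self._heatmaps(vals)
        rm = region_map(np.full((8, 8), GM))
        thr = {"cored": 0.9, "diffuse": 0.9, "CAA": 0.9}
        vote = ab.patchvote_count(hms, rm, thr)
        assert vote.get("GM", "cored") == 12
        blobs = {"cored": label_blobs(ab.threshold_heatmap(hms["cored"], 0.9)),
                 "diffuse": [], "CAA": []}
        assert ab.count_deposits(blobs, rm).get("GM", "cored") == 1

    def test_total_equals_above_threshold_tissue_cells(self):
        rng = np.random.default_rng(5)
        vals = rng.uniform(size=(16, 16))
        labels = np.full((16, 16), GM)
        labels[:, :3] = BACKGROUND
        thr = {"cored": 0.6, "diffuse": 0.9, "CAA": 0.9}
        vote = ab.patchvote_count(self._heatmaps(vals), region_map(labels), thr)
        expected = int(((vals >= 0.6) & (labels == GM)).sum())
        assert vote.total() == expected

    def test_lowering_threshold_never_decreases_class_count(self):
        rng = np.random.default_rng(6)
        hms = {
            "cored": heatmap(rng.uniform(size=(20, 20)), "cored"),
            "diffuse": heatmap(rng.uniform(size=(20, 20)), "diffuse"),
            "CAA": heatmap(rng.uniform(size=(20, 20)), "CAA"),
        }
        rm = region_map(np.full((20, 20), GM))
        prev = -1
        for thr in (0.9, 0.7, 0.5, 0.3, 0.1):
            cv = ab.patchvote_count(hms, rm, {"cored": thr, "diffuse": 0.8, "CAA": 0.8})
            count = cv.get("GM", "cored")
            assert count >= prev
            prev = count


class TestAreasAndDensities:
    def test_area_arithmetic(self):
        labels = np.zeros((40, 40), dtype=np.uint8)
        labels.ravel()[:1000] = GM
        areas = ab.region_areas(region_map(labels))
        assert areas[0] == pytest.approx(1000 * (16 * 0.503) ** 2)
        assert areas[0] == pytest.approx(64770.304)
        assert areas[1] == 0.0

    def test_empty_region_map(self):
        areas = ab.region_areas(region_map(np.zeros((8, 8), dtype=np.uint8)))
        assert areas == (0.0, 0.0)

    def test_missing_mpp_is_error(self):
        g = geom(8, 8)
        g.slide_mpp = None
        rm = RegionMap(labels=np.zeros((8, 8), dtype=np.uint8), geometry=g)
        with pytest.raises(ValueError, match="microns"):
            ab.region_areas(rm)

    def test_stride_refinement_keeps_area(self, small_slide):
        slide, _ = small_slide
        g = ab.OracleRegionClassifier()
        a8 = ab.region_areas(ab.infer_region_map(slide, g, stride_px=8))
        a16 = ab.region_areas(ab.infer_region_map(slide, g, stride_px=16))
        # one boundary row of cells tolerance
        boundary = 2 * slide.shape[0] / 16 * (16 * 0.503) ** 2
        assert abs(a8[0] - a16[0]) < boundary
        assert abs(a8[1] - a16[1]) < boundary

    def test_density_division_example(self):
        cv = ab.CountVector((5, 0, 0, 0, 0, 0))
        df = ab.compute_densities(cv, (64770.304, 0.0))
        row = df[(df.region == "GM") & (df.deposit_class == "cored")].iloc[0]
        assert row.density_per_um2 == pytest.approx(5 / 64770.304)
        assert row.density_per_um2 == pytest.approx(7.7196e-5, rel=1e-4)

    def test_zero_counts_positive_area(self):
        df = ab.compute_densities(ab.CountVector(), (100.0, 100.0))
        assert (df.density_per_um2 == 0).all()

    def test_zero_area_zero_count_missing(self):
        df = ab.compute_densities(ab.CountVector(), (100.0, 0.0))
        wm = df[df.region == "WM"]
        assert wm.density_per_um2.isna().all()

    def test_zero_area_positive_count_error(self):
        cv = ab.CountVector((0, 0, 0, 1, 0, 0))
        with pytest.raises(ValueError, match="zero area"):
            ab.compute_densities(cv, (100.0, 0.0))

    def test_density_scale_invariance(self):
        a = ab.compute_densities(ab.CountVector((2, 0, 0, 0, 0, 0)), (500.0, 10.0))
        b = ab.compute_densities(ab.CountVector((4, 0, 0, 0, 0, 0)), (1000.0, 10.0))
        assert a.density_per_um2.iloc[0] == b.density_per_um2.iloc[0]

    def test_density_scales_with_mpp(self, small_slide):
        # same pixel content at doubled mpp -> areas x4, densities /4
        slide, _ = small_slide
        g = ab.OracleRegionClassifier()
        rm1 = ab.infer_region_map(slide, g)
        slide2 = ab.SlideRaster(slide.pixels, slide.microns_per_pixel * 2, "x")
        rm2 = ab.infer_region_map(slide2, g)
        a1, a2 = ab.region_areas(rm1), ab.region_areas(rm2)
        assert a2[0] == pytest.approx(4 * a1[0])
        cv = ab.CountVector((3, 0, 0, 0, 0, 0))
        d1 = ab.compute_densities(cv, a1).density_per_um2.iloc[0]
        d2 = ab.compute_densities(cv, a2).density_per_um2.iloc[0]
        assert d2 == pytest.approx(d1 / 4)
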