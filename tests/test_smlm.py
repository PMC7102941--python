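"""SMLM module: table I/O, rendering, Voronoi density, partitioning,
overlap formulas against set oracles, ROI transfer and precision."""

import io as _io
import math

import numpy as np
import pandas as pd
import pytest

from trnafret import smlm
from trnafret.smlm import (estimate_localization_precision, fractional_overlap2,
                           fractional_overlap3, local_density,
                           partition_by_density, read_localizations,
                           render_localizations, roi_transfer, threshold_8bit,
                           write_localizations)


class TestReadWrite:
    def test_thunderstorm_dialect(self, tmp_path):
        p = tmp_path / "locs.csv"
        p.write_text('id,frame,"x [nm]","y [nm]","uncertainty [nm]"\n'
                     "1,0,100.5,200.5,15\n2,0,300,400,18\n3,1,1,2,20\n")
        df = read_localizations(p)
        assert len(df) == 3
        assert {"x_nm", "y_nm", "uncertainty_nm"} <= set(df.columns)
        assert df["x_nm"].iloc[0] == 100.5

    def test_empty_file_with_header_ok(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("x [nm],y [nm]\n")
        df = read_localizations(p)
        assert len(df) == 0

    def test_missing_column_lists_headers(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("x [nm],intensity\n1,2\n")
        with pytest.raises(ValueError, match="y_nm"):
            read_localizations(p)

    def test_round_trip(self, tmp_path):
        df = pd.DataFrame({"id": [0, 1], "frame": [0, 1],
                           "x_nm": [10.0, 20.0], "y_nm": [30.0, 40.0],
                           "channel": ["a", "a"]})
        p = tmp_path / "out.csv"
        write_localizations(df, p)
        back = read_localizations(p)
        np.testing.assert_allclose(back["x_nm"], df["x_nm"])
        assert "channel" in back.columns


class TestRender:
    def test_single_point_histogram(self):
        df = pd.DataFrame({"x_nm": [105.0], "y_nm": [55.0]})
        img = render_localizations(df, 10.0, extent_nm=(200, 100))
        assert img.sum() == 1
        assert img[5, 10] == 1

    def test_mass_conservation(self, rng):
        n = 500
        df = pd.DataFrame({"x_nm": rng.uniform(0, 1000, n),
                           "y_nm": rng.uniform(0, 1000, n)})
        img = render_localizations(df, 20.0, extent_nm=(1000, 1000))
        assert img.sum() == n
        gimg = render_localizations(df, 20.0, mode="gaussian",
                                    extent_nm=(1000, 1000))
        assert gimg.sum() == pytest.approx(n, rel=0.02)

    def test_halving_pixel_size_doubles_dimensions(self):
        df = pd.DataFrame({"x_nm": [10.0, 900.0], "y_nm": [10.0, 400.0]})
        a = render_localizations(df, 20.0, extent_nm=(1000, 500))
        b = render_localizations(df, 10.0, extent_nm=(1000, 500))
        assert b.shape == (2 * a.shape[0], 2 * a.shape[1])

    def test_invalid_pixel_size(self):
        with pytest.raises(ValueError, match="pixel_size"):
            render_localizations(pd.DataFrame({"x_nm": [1.0], "y_nm": [1.0]}), 0)


class TestLocalDensity:
    def test_uniform_grid_interior_density(self):
        d = 7.0
        xs, ys = np.meshgrid(np.arange(20) * d, np.arange(20) * d)
        df = pd.DataFrame({"x_nm": xs.ravel(), "y_nm": ys.ravel()})
        res = local_density(df)
        interior = ~res["border"]
        assert interior.sum() > 200
        np.testing.assert_allclose(res.loc[interior, "density"], 1 / d ** 2,
                                   rtol=1e-6)

    def test_collinear_points_rejected(self):
        df = pd.DataFrame({"x_nm": np.arange(10.0), "y_nm": np.arange(10.0) * 2})
        with pytest.raises(ValueError, match="degenerate|collinear"):
            local_density(df)

    def test_too_few_points_rejected(self):
        df = pd.DataFrame({"x_nm": [0.0, 1.0, 2.5], "y_nm": [0.0, 1.0, 0.5]})
        with pytest.raises(ValueError, match=">= 4"):
            local_density(df)

    def test_dense_cluster_exceeds_sparse_background(self, rng):
        # quasi-uniform background (jittered grid, ~1/2500 nm^-2) with a
        # planted cluster ~100x denser; cluster-core densities must all
        # exceed every background density
        gx, gy = np.meshgrid(np.arange(25, 1000, 50), np.arange(25, 1000, 50))
        bg = np.column_stack([gx.ravel(), gy.ravel()]) + rng.uniform(-8, 8, (400, 2))
        cl = rng.uniform(450, 550, size=(400, 2))
        keep_bg = ~((bg > 430).all(axis=1) & (bg < 570).all(axis=1))
        bg = bg[keep_bg]
        df = pd.DataFrame({"x_nm": np.r_[bg[:, 0], cl[:, 0]],
                           "y_nm": np.r_[bg[:, 1], cl[:, 1]]})
        res = local_density(df)
        dens = res["density"].to_numpy()
        interior = ~res["border"].to_numpy()
        n_bg = bg.shape[0]
        core = np.zeros(len(df), bool)
        core[n_bg:] = (cl > 470).all(axis=1) & (cl < 530).all(axis=1)
        sel_bg = interior.copy()
        sel_bg[n_bg:] = False
        assert np.nanmin(dens[core & interior]) > np.nanmax(dens[sel_bg])


class TestPartition:
    def test_all_below_threshold_diffuse(self):
        df = pd.DataFrame({"density": np.full(10, 5.0),
                           "border": np.zeros(10, bool)})
        part = partition_by_density(df, threshold=40.0)
        assert (part.labels == "diffuse").all()
        assert part.threshold == 40.0

    def test_classification_rule_is_inclusive_at_threshold(self):
        df = pd.DataFrame({"density": [39.9, 40.0, 40.1],
                           "border": [False] * 3})
        part = partition_by_density(df)  # defaults to the 40 boundary
        assert list(part.labels) == ["diffuse", "clustered", "clustered"]

    def test_border_points_excluded(self):
        df = pd.DataFrame({"density": [np.nan, 50.0],
                           "border": [True, False]})
        part = partition_by_density(df, threshold=40.0)
        assert part.labels[0] == "border"

    def test_automatic_threshold_separates_bimodal(self, rng):
        lo = 10 ** rng.normal(0, 0.15, 400)
        hi = 10 ** rng.normal(2, 0.15, 400)
        df = pd.DataFrame({"density": np.r_[lo, hi],
                           "border": np.zeros(800, bool)})
        part = partition_by_density(df, threshold="auto")
        assert 1 < np.log10(part.threshold) / 1 < 2 or (1 < part.threshold < 100)
        acc = ((part.labels[:400] == "diffuse").mean()
               + (part.labels[400:] == "clustered").mean()) / 2
        assert acc >= 0.99


class TestThreshold8bit:
    def test_printed_rule(self):
        img = np.array([[0, 1], [2, 255]], dtype=np.uint8)
        np.testing.assert_array_equal(threshold_8bit(img),
                                      [[False, False], [True, True]])

    def test_all_zero_empty_mask(self):
        assert not threshold_8bit(np.zeros((4, 4), np.uint8)).any()

    def test_lo_zero_selects_all(self):
        img = np.arange(16, dtype=np.uint8).reshape(4, 4)
        assert threshold_8bit(img, lo=0).all()

    def test_float_image_rescaled(self):
        img = np.array([[0.0, 0.5, 1.0]])
        mask = threshold_8bit(img)
        np.testing.assert_array_equal(mask, [[False, True, True]])

    def test_bad_bounds(self):
        with pytest.raises(ValueError, match="lo"):
            threshold_8bit(np.zeros((2, 2)), lo=10, hi=2)


def _random_masks(rng, shape=(16, 16), p=0.3, n=3):
    return [rng.uniform(size=shape) < p for _ in range(n)]


class TestOverlapFormulas:
    def test_identical_masks_overlap_one(self, rng):
        m = _random_masks(rng)[0]
        m[0, 0] = True
        assert fractional_overlap2(m, m) == 1.0
        assert fractional_overlap3(m, m, m) == 1.0

    def test_disjoint_masks_zero(self):
        a = np.zeros((8, 8), bool)
        b = np.zeros((8, 8), bool)
        a[:2], b[4:] = True, True
        assert fractional_overlap2(a, b) == 0.0
        c = np.zeros((8, 8), bool)
        c[2:4] = True
        assert fractional_overlap3(a, b, c) == 0.0

    def test_counting_oracle_2color(self):
        # |R|=2, |G|=2, |R&G|=1 -> 1/3
        R = np.zeros((3, 3), bool)
        G = np.zeros((3, 3), bool)
        R[0, 0] = R[0, 1] = True
        G[0, 1] = G[2, 2] = True
        assert fractional_overlap2(R, G) == pytest.approx(1 / 3)

    def test_counting_oracle_3color(self):
        # |union|=4, |triple|=1 -> 1/4
        R = np.zeros((3, 3), bool)
        G = np.zeros((3, 3), bool)
        B = np.zeros((3, 3), bool)
        for m in (R, G, B):
            m[1, 1] = True
        R[0, 0] = G[0, 1] = B[0, 2] = True
        assert fractional_overlap3(R, G, B) == pytest.approx(0.25)

    def test_exhaustive_2x2_against_set_oracle(self):
        # every pair of 2x2 binary masks, checked against python sets
        masks = [np.array([[b >> 3 & 1, b >> 2 & 1], [b >> 1 & 1, b & 1]],
                          dtype=bool) for b in range(16)]
        for R in masks:
            for G in masks:
                rs = {i for i in range(4) if R.ravel()[i]}
                gs = {i for i in range(4) if G.ravel()[i]}
                if rs | gs:
                    expect = len(rs & gs) / len(rs | gs)
                    assert fractional_overlap2(R, G) == pytest.approx(expect)

    def test_empty_union_flagged(self):
        z = np.zeros((4, 4), bool)
        with pytest.warns(UserWarning, match="empty"):
            assert np.isnan(fractional_overlap2(z, z))

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            fractional_overlap2(np.zeros((2, 2), bool), np.zeros((3, 3), bool))

    def test_overlap2_equals_overlap3_with_repeated_mask(self, rng):
        for _ in range(200):
            R, G, _ = _random_masks(rng)
            f2 = fractional_overlap2(R, G)
            f3 = fractional_overlap3(R, G, G)
            if math.isnan(f2):
                assert math.isnan(f3)
            else:
                assert f3 == pytest.approx(f2)

    def test_symmetry_and_translation_invariance(self, rng):
        R, G, B = _random_masks(rng, shape=(12, 12))
        assert fractional_overlap2(R, G) == fractional_overlap2(G, R)
        assert (fractional_overlap3(R, G, B)
                == fractional_overlap3(B, R, G))
        Rs, Gs = np.roll(R, 3, axis=1), np.roll(G, 3, axis=1)
        assert fractional_overlap2(Rs, Gs) == fractional_overlap2(R, G)

    def test_triple_intersection_bounded_by_pairwise(self, rng):
        for _ in range(100):
            R, G, B = _random_masks(rng)
            t = (R & G & B).sum()
            assert t <= (R & G).sum()
            assert t <= (R & B).sum()
            assert t <= (G & B).sum()


class TestRoiTransfer:
    def _rois(self):
        lab = np.zeros((10, 10), int)
        lab[1:3, 1:3] = 1   # over empty region
        lab[6:9, 6:9] = 2   # over signal
        return lab

    def test_overlap_rule(self):
        lab = self._rois()
        ch = np.zeros((10, 10), bool)
        ch[7, 7] = True  # one positive pixel in ROI 2
        res = roi_transfer(lab, {"rpL10a": ch})
        t = res.table.set_index("id")
        assert not t.loc[1, "overlaps_rpL10a"]
        assert t.loc[2, "overlaps_rpL10a"]
        assert res.overlap_fraction["rpL10a"] == 0.5

    def test_overlapping_areas_reported(self):
        lab = self._rois()
        ch = np.ones((10, 10), bool)
        res = roi_transfer(lab, {"c": ch}, areas_nm2={1: 400.0, 2: 900.0})
        np.testing.assert_allclose(sorted(res.overlapping_areas["c"]),
                                   [400.0, 900.0])

    def test_shape_mismatch_clipped_with_warning(self):
        lab = self._rois()
        ch = np.ones((8, 8), bool)
        with pytest.warns(UserWarning, match="common region"):
            res = roi_transfer(lab, {"c": ch})
        assert res.table["overlaps_c"].iloc[0]

    def test_planted_large_puncta_overlap_more(self, rng):
        # ROIs of mixed sizes; only large ones placed over signal
        lab = np.zeros((100, 100), int)
        ch = np.zeros((100, 100), bool)
        areas = {}
        rid = 0
        for i in range(5):       # large, overlapping
            rid += 1
            r, c = 5 + 18 * i, 10
            lab[r:r + 4, c:c + 4] = rid
            ch[r:r + 4, c:c + 4] = True
            areas[rid] = 16 * 100.0
        for i in range(5):       # small, not overlapping
            rid += 1
            r, c = 5 + 18 * i, 60
            lab[r:r + 2, c:c + 2] = rid
            areas[rid] = 4 * 100.0
        res = roi_transfer(lab, {"c": ch}, areas_nm2=areas)
        over = res.overlapping_areas["c"]
        non_over_ids = res.table.loc[~res.table["overlaps_c"], "id"]
        non_over = [areas[int(i)] for i in non_over_ids]
        assert np.median(over) > np.median(non_over)


class TestPrecision:
    def test_identical_centroids_zero_sigma(self):
        pts = np.tile([5.0, 7.0], (150, 1))
        est = estimate_localization_precision(pts)
        assert est.sigma_nm == 0.0
        assert est.fwhm_nm == 0.0

    def test_gaussian_scatter_recovery(self, rng):
        pts = rng.normal(0, 19.4, size=(4000, 2))
        est = estimate_localization_precision(pts)
        assert est.sigma_nm == pytest.approx(19.4, rel=0.03)
        assert est.fwhm_nm / est.sigma_nm == pytest.approx(2.3548, abs=1e-4)

    def test_too_few_centroids(self):
        with pytest.raises(ValueError, match="100"):
            estimate_localization_precision(np.zeros((50, 2)))
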