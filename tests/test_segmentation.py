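"""Segmentation stages, ensemble voting and mask metrics."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage
from skimage.draw import disk as disk_coords

from flimcyte.exceptions import (
    ConfigError,
    DegenerateImageError,
    DimensionError,
    EmptyEnsembleError,
    MissingTruthError,
    UndefinedDiceError,
)
from flimcyte.segmentation import (
    SegmentationConfig,
    calibrate_variant,
    default_threshold_specs,
    dice_coefficient,
    dilation_sensitivity,
    ensemble_select,
    EnsembleCandidate,
    gate_lifetime,
    label_rois,
    merge_intensity_lifetime,
    refine_rois,
    run_variant,
    threshold_intensity,
)


def blob_image(shape=(64, 64), centers=((32, 32),), radius=6, fg=200.0, bg=10.0):
    img = np.full(shape, bg)
    mask = np.zeros(shape, bool)
    for c in centers:
        rr, cc = disk_coords(c, radius, shape=shape)
        img[rr, cc] = fg
        mask[rr, cc] = True
    return img, mask


class TestGate:
    def test_inclusive_bounds_and_nan(self):
        lt = np.array([[700.0, 800.0], [1300.0, 1500.0]])
        out = gate_lifetime(lt, 800, 1500)
        np.testing.assert_array_equal(out, [[False, True], [True, True]])
        assert not gate_lifetime(np.full((3, 3), np.nan), 800, 1500).any()

    def test_inverted_range_rejected(self):
        with pytest.raises(ConfigError):
            gate_lifetime(np.zeros((2, 2)), 1500, 800)


class TestThreshold:
    def test_otsu_matches_between_class_variance_oracle(self):
        img, truth = blob_image()
        # oracle: exhaustively maximise between-class variance over all
        # candidate thresholds of the two-valued histogram
        values = np.unique(img)
        best_t, best_var = None, -1.0
        for t in np.linspace(values.min(), values.max(), 512, endpoint=False):
            lo, hi = img[img <= t], img[img > t]
            if lo.size == 0 or hi.size == 0:
                continue
            w0, w1 = lo.size, hi.size
            var = w0 * w1 * (lo.mean() - hi.mean()) ** 2
            if var > best_var:
                best_var, best_t = var, t
        oracle = img > best_t
        np.testing.assert_array_equal(threshold_intensity(img, "otsu"), oracle)
        np.testing.assert_array_equal(oracle, truth)

    def test_union_is_superset_and_intersection_idempotent(self):
        img, _ = blob_image()
        otsu = threshold_intensity(img, "otsu")
        union = threshold_intensity(img, "otsu|yen")
        inter = threshold_intensity(img, "otsu&otsu")
        assert (union | otsu).sum() == union.sum()  # union ⊇ otsu
        np.testing.assert_array_equal(inter, otsu)

    def test_constant_image_degenerate(self):
        with pytest.raises(DegenerateImageError):
            threshold_intensity(np.full((16, 16), 7.0), "otsu")

    def test_unknown_method_rejected(self):
        with pytest.raises(ConfigError):
            threshold_intensity(np.zeros((4, 4)), "banana")


class TestMerge:
    def test_identity_annihilator_and_oracle(self, rng):
        ones = np.ones((8, 8), bool)
        assert merge_intensity_lifetime(ones, ones).all()
        assert not merge_intensity_lifetime(ones, ~ones).any()
        fg = rng.random((32, 32)) > 0.5
        gate = rng.random((32, 32)) > 0.5
        merged = merge_intensity_lifetime(fg, gate)
        for i in range(32):  # brute-force per-pixel conjunction
            for j in range(32):
                assert merged[i, j] == (fg[i, j] and gate[i, j])

    def test_shape_mismatch(self):
        with pytest.raises(DimensionError):
            merge_intensity_lifetime(np.ones((4, 4), bool), np.ones((4, 5), bool))


class TestLabelRois:
    def test_two_disjoint_blobs_full_support(self):
        _, mask = blob_image(centers=((16, 16), (48, 48)), radius=6)
        labels = label_rois(mask)
        assert labels.max() == 2
        assert (labels > 0).sum() == mask.sum()  # support preserved

    def test_empty_mask(self):
        assert label_rois(np.zeros((16, 16), bool)).max() == 0

    def test_connectivity_matches_flood_fill_oracle(self):
        # two 3x3 squares that touch only diagonally
        mask = np.zeros((16, 16), bool)
        mask[2:5, 2:5] = True
        mask[5:8, 5:8] = True
        for conn in (4, 8):
            labels = label_rois(mask, canny_sigma=0.5, connectivity=conn)
            structure = (np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
                         if conn == 4 else np.ones((3, 3)))
            _, n_oracle = ndimage.label(mask, structure=structure)
            assert labels.max() == n_oracle
        assert label_rois(mask, 0.5, 4).max() == 2
        assert label_rois(mask, 0.5, 8).max() == 1


class TestRefine:
    def test_dilation_grows_single_interior_disk(self):
        _, mask = blob_image(shape=(48, 48), centers=((24, 24),), radius=5)
        labels = mask.astype(np.int32)
        cfg = SegmentationConfig(struct_radius_1=1, struct_radius_2=0, min_area=1)
        out = refine_rois(labels, cfg, "dilate")
        assert out.max() == 1
        assert (out > 0).sum() > mask.sum()

    def test_border_touching_region_cleared(self):
        labels = np.zeros((32, 32), np.int32)
        labels[0:6, 10:16] = 1   # touches row 0
        labels[15:21, 15:21] = 2
        cfg = SegmentationConfig(struct_radius_1=0, struct_radius_2=0, min_area=1)
        out = refine_rois(labels, cfg, "dilate")
        assert out.max() == 1
        assert not out[0, :].any()

    def test_small_speck_filtered(self):
        labels = np.zeros((32, 32), np.int32)
        labels[5:7, 5:7] = 1      # 4 px speck, away from border
        labels[15:25, 15:25] = 2  # 100 px block
        cfg = SegmentationConfig(struct_radius_1=0, struct_radius_2=0, min_area=20)
        out = refine_rois(labels, cfg, "dilate")
        assert out.max() == 1
        areas = np.bincount(out.ravel())[1:]
        assert areas.min() >= 20

    def test_expansion_never_merges_labels(self):
        labels = np.zeros((40, 40), np.int32)
        labels[10:18, 10:14] = 1
        labels[10:18, 17:21] = 2  # 3 px apart; radius-2 dilation would overlap
        cfg = SegmentationConfig(struct_radius_1=2, struct_radius_2=1, min_area=1)
        out = refine_rois(labels, cfg, "dilate")
        assert out.max() == 2


class TestRunVariantAndEnsemble:
    def _scene(self):
        img, truth = blob_image(shape=(64, 64), centers=((20, 20), (44, 44)), radius=6)
        lt = np.where(truth, 1350.0, 500.0)
        return img, lt, truth.astype(np.int32)

    def test_determinism(self):
        img, lt, _ = self._scene()
        cfg = SegmentationConfig()
        a = run_variant(img, lt, ("otsu", "dilate"), cfg)
        b = run_variant(img, lt, ("otsu", "dilate"), cfg)
        np.testing.assert_array_equal(a.mask, b.mask)

    def test_out_of_gate_scene_yields_empty(self):
        img, _, _ = self._scene()
        lt = np.full(img.shape, 500.0)  # all red signal out of gate
        cand = run_variant(img, lt, ("otsu", "dilate"), SegmentationConfig())
        assert cand.mask.max() == 0

    def test_truth_candidate_wins_with_dice_one(self):
        img, lt, truth = self._scene()
        cfg = SegmentationConfig()
        cands = [run_variant(img, lt, ("otsu", "dilate"), cfg),
                 EnsembleCandidate(("truth", "none"), truth)]
        best, report = ensemble_select(cands, truth=truth)
        np.testing.assert_array_equal(best, truth)
        assert report.loc[report["selected"], "dice"].iloc[0] == pytest.approx(1.0)

    def test_argmax_dominates_every_candidate(self):
        img, lt, truth = self._scene()
        cfg = SegmentationConfig(threshold_methods=("otsu", "yen", "triangle"))
        cands = [run_variant(img, lt, v, cfg) for v in cfg.variants()]
        best, report = ensemble_select(cands, truth=truth)
        best_dice = report.loc[report["selected"], "dice"].iloc[0]
        assert (best_dice >= report["dice"] - 1e-12).all()

    def test_missing_truth_and_empty_ensemble(self):
        img, lt, truth = self._scene()
        cand = run_variant(img, lt, ("otsu", "dilate"), SegmentationConfig())
        with pytest.raises(MissingTruthError):
            ensemble_select([cand], truth=None, mode="per_image_argmax")
        with pytest.raises(EmptyEnsembleError):
            ensemble_select([], truth=truth)

    def test_global_calibration_is_row_mean_argmax(self):
        table = pd.DataFrame({
            "image_id": ["a", "b", "c"] * 2,
            "variant_threshold": ["otsu"] * 3 + ["yen"] * 3,
            "variant_expansion": ["dilate"] * 6,
            "dice": [0.9, 0.2, 0.4, 0.6, 0.6, 0.6],
        })
        # brute force: mean(otsu)=0.5, mean(yen)=0.6
        assert calibrate_variant(table) == ("yen", "dilate")

    def test_global_mode_applies_calibrated_variant(self):
        img, lt, truth = self._scene()
        cfg = SegmentationConfig(threshold_methods=("otsu", "yen"))
        cands = [run_variant(img, lt, v, cfg) for v in cfg.variants()]
        best, report = ensemble_select(
            cands, mode="global_calibration", calibrated_variant=("yen", "close")
        )
        sel = report[report["selected"]]
        assert tuple(sel[["variant_threshold", "variant_expansion"]].iloc[0]) == ("yen", "close")


class TestDice:
    def test_identical_disjoint_and_half(self):
        a = np.zeros((10, 10), bool)
        a[:5] = True
        assert dice_coefficient(a, a) == 1.0
        assert dice_coefficient(a, ~a) == 0.0
        b = np.zeros((10, 10), bool)
        b[2:7] = True  # |A|=|B|=50, overlap 30 -> dice 0.6
        assert dice_coefficient(a, b) == pytest.approx(0.6)

    def test_symmetry(self, rng):
        a = rng.random((16, 16)) > 0.5
        b = rng.random((16, 16)) > 0.5
        assert dice_coefficient(a, b) == dice_coefficient(b, a)

    def test_both_empty_undefined(self):
        z = np.zeros((4, 4), bool)
        with pytest.raises(UndefinedDiceError):
            dice_coefficient(z, z)


class TestDilationSensitivity:
    def _constant_maps(self, shape, value=1000.0):
        m = {k: np.full(shape, v) for k, v in
             [("tau1", 400.0), ("tau2", 2200.0), ("alpha1", 0.6),
              ("alpha2", 0.4), ("tau_m", value)]}
        return m

    def test_radius_zero_identity(self):
        mask = np.zeros((32, 32), np.int32)
        mask[8:14, 8:14] = 1
        mask[20:26, 20:26] = 2
        maps = {"nadph": self._constant_maps(mask.shape),
                "fad": self._constant_maps(mask.shape, 500.0)}
        ints = {"nadph": np.full(mask.shape, 10.0), "fad": np.full(mask.shape, 5.0)}
        rep = dilation_sensitivity(mask, maps, ints, radii=(0,))
        assert (rep["p_value"] == 1.0).all()

    def test_uniform_parameter_scene_no_shift(self):
        mask = np.zeros((32, 32), np.int32)
        mask[8:14, 8:14] = 1
        mask[20:26, 20:26] = 2
        maps = {"nadph": self._constant_maps(mask.shape),
                "fad": self._constant_maps(mask.shape, 500.0)}
        ints = {"nadph": np.full(mask.shape, 10.0), "fad": np.full(mask.shape, 5.0)}
        rep = dilation_sensitivity(mask, maps, ints, radii=(1, 2, 3))
        assert (rep["p_value"] > 0.05).all()
        assert set(rep["parameter"]) >= {"nadph_tau_m", "fad_alpha1", "redox_ratio"}

    def test_empty_mask_empty_report(self):
        rep = dilation_sensitivity(np.zeros((8, 8), np.int32), {}, {})
        assert rep.empty


class TestTumorCellPath:
    def test_plain_threshold_label(self):
        img, truth = blob_image(shape=(64, 64), centers=((20, 20), (44, 44)), radius=6)
        from flimcyte.segmentation import segment_tumor_cells
        labels = segment_tumor_cells(img)
        assert labels.max() == 2
        assert (labels > 0).sum() == truth.sum()

    def test_constant_image_yields_empty(self):
        from flimcyte.segmentation import segment_tumor_cells
        assert segment_tumor_cells(np.full((32, 32), 5.0)).max() == 0


def test_default_threshold_specs_count():
    specs = default_threshold_specs()
    assert len(specs) == 25
    assert len(set(specs)) == 25
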