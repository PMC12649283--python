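"""Dice, PTV classification, retained fractions and ROC threshold metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rtdeface.defacing import CropLandmarks
from rtdeface.geometry import GeometryError
from rtdeface.metrics import (
    DefaceReport,
    PairingDistances,
    classify_ptv,
    dice,
    match_rate,
    read_distance_file,
    retained_fraction,
    youden_threshold,
)

from conftest import make_geometry


class TestDice:
    def test_identical_nonempty_masks_score_one(self):
        m = np.zeros((4, 4, 2), dtype=bool)
        m[1:3, 1:3, 0] = True
        assert dice(m, m.copy()) == 1.0

    def test_disjoint_nonempty_masks_score_zero(self):
        a = np.zeros((4, 4, 2), dtype=bool)
        b = np.zeros((4, 4, 2), dtype=bool)
        a[0, 0, 0] = True
        b[3, 3, 1] = True
        assert dice(a, b) == 0.0

    def test_enumerated_half_overlap(self):
        """|a|=4, |b|=4, |a∩b|=2 on a 4x4 grid -> 0.5."""
        a = np.zeros((4, 4, 1), dtype=bool)
        b = np.zeros((4, 4, 1), dtype=bool)
        a[0, 0:4, 0] = True          # row 0
        b[0, 2:4, 0] = True          # overlap of 2
        b[1, 0:2, 0] = True
        assert dice(a, b) == 0.5

    def test_empty_conventions(self):
        e = np.zeros((3, 3, 1), dtype=bool)
        m = e.copy()
        m[1, 1, 0] = True
        assert dice(e, e.copy()) == 1.0
        assert dice(e, m) == 0.0
        assert dice(m, e) == 0.0

    def test_grid_mismatch_is_an_error(self):
        with pytest.raises(GeometryError):
            dice(np.zeros((2, 2, 1), dtype=bool), np.zeros((3, 3, 1), dtype=bool))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2**16 - 1), st.integers(0, 2**16 - 1))
    def test_symmetric_and_bounded(self, bits_a, bits_b):
        a = np.array([(bits_a >> i) & 1 for i in range(16)], dtype=bool).reshape(4, 4, 1)
        b = np.array([(bits_b >> i) & 1 for i in range(16)], dtype=bool).reshape(4, 4, 1)
        d = dice(a, b)
        assert d == dice(b, a)
        assert 0.0 <= d <= 1.0
        if a.any() or b.any():
            assert (d == 1.0) == np.array_equal(a, b)


class TestClassifyPtv:
    g = make_geometry(rows=8, cols=8, n_slices=8)
    lm = CropLandmarks(z_inf=4.0, y_mid=4.0)

    def mask_at(self, voxels):
        m = np.zeros(self.g.shape, dtype=bool)
        for r, c, k in voxels:
            m[r, c, k] = True
        return m

    def test_entirely_below_z_inf(self):
        assert classify_ptv(self.mask_at([(0, 0, 0), (7, 7, 3)]), self.lm, self.g) == "below"

    def test_same_slice_posterior_of_y_mid(self):
        m = self.mask_at([(5, 2, 5), (6, 2, 6)])  # y=5,6 >= 4; z >= 4
        assert classify_ptv(m, self.lm, self.g) == "same_slice_no_overlap"

    def test_any_voxel_in_crop_region_means_overlap(self):
        m = self.mask_at([(5, 2, 5), (1, 2, 6)])  # one voxel y=1 < 4, z=6 >= 4
        assert classify_ptv(m, self.lm, self.g) == "overlap"

    def test_empty_ptv_is_an_error(self):
        with pytest.raises(ValueError, match="empty PTV"):
            classify_ptv(np.zeros(self.g.shape, dtype=bool), self.lm, self.g)

    def test_phantom_modes_classify_as_declared(self, phantom_below, phantom_same_slice, phantom_overlap):
        from rtdeface.contours import rasterize_roi
        from rtdeface.defacing import compute_landmarks

        expected = {"below": phantom_below, "same_slice_no_overlap": phantom_same_slice,
                    "overlap": phantom_overlap}
        for category, (vol, ss, _) in expected.items():
            lm = compute_landmarks(ss, vol)
            ptv = rasterize_roi(ss.get("PTV70"), vol.geometry)
            assert classify_ptv(ptv, lm, vol.geometry) == category


class TestRetainedFraction:
    def test_counts_ratio(self):
        s = np.zeros((4, 4, 1), dtype=bool)
        s[0, :, 0] = True
        keep = np.zeros_like(s)
        keep[0, :3, 0] = True
        assert retained_fraction(s, keep) == 0.75

    def test_empty_structure_is_an_error(self):
        z = np.zeros((2, 2, 1), dtype=bool)
        with pytest.raises(ValueError, match="empty structure"):
            retained_fraction(z, z)

    def test_random_structures_match_voxel_counts(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            s = rng.random((6, 6, 4)) < 0.4
            if not s.any():
                continue
            keep = rng.random((6, 6, 4)) < 0.5
            expect = sum(
                1 for idx in zip(*np.nonzero(s)) if keep[idx]
            ) / s.sum()
            assert retained_fraction(s, keep) == pytest.approx(expect)


def brute_force_youden(same, different):
    """Independent exhaustive scan on a dense grid of thresholds."""
    pooled = np.unique(np.concatenate([same, different]))
    grid = np.concatenate([pooled - 1e-9, pooled, pooled + 1e-9,
                           [pooled.min() - 1, pooled.max() + 1]])
    best = -np.inf
    for t in np.sort(grid):
        j = (same <= t).mean() - (different <= t).mean()
        if j > best + 1e-12:
            best = j
    return best


class TestYoudenThreshold:
    def test_perfectly_separable_lists(self):
        thr, tpr, fpr, j = youden_threshold([0.1, 0.2], [0.5, 0.6])
        assert j == 1.0 and tpr == 1.0 and fpr == 0.0
        assert 0.2 < thr < 0.5

    def test_identical_lists_give_zero_j(self):
        same = [0.3, 0.5, 0.7]
        thr, tpr, fpr, j = youden_threshold(same, list(same))
        assert j == 0.0
        assert tpr == fpr

    def test_matches_exhaustive_scan_on_random_instances(self):
        rng = np.random.default_rng(13)
        for _ in range(60):
            same = rng.normal(0.4, 0.15, size=rng.integers(5, 40)).clip(0)
            diff = rng.normal(0.8, 0.2, size=rng.integers(5, 40)).clip(0)
            _, _, _, j = youden_threshold(same, diff)
            assert j == pytest.approx(brute_force_youden(same, diff), abs=1e-12)

    def test_agrees_with_sklearn_roc_curve(self):
        """Independent route: J from scikit-learn's ROC implementation."""
        from sklearn.metrics import roc_curve

        rng = np.random.default_rng(17)
        for _ in range(20):
            same = rng.normal(0.35, 0.1, size=30).clip(0.01)
            diff = rng.normal(0.75, 0.2, size=60).clip(0.01)
            _, _, _, j = youden_threshold(same, diff)
            y = np.concatenate([np.ones_like(same), np.zeros_like(diff)])
            scores = -np.concatenate([same, diff])  # match = small distance
            fpr, tpr, _ = roc_curve(y, scores)
            assert j == pytest.approx(np.max(tpr - fpr), abs=1e-12)

    def test_empty_list_is_an_error(self):
        with pytest.raises(ValueError):
            youden_threshold([], [0.5])
        with pytest.raises(ValueError):
            youden_threshold([0.5], [])

    def test_ties_break_to_smallest_threshold(self):
        # J = 1 for any threshold in (0.2, 0.6): smallest candidate wins
        thr, _, _, j = youden_threshold([0.1, 0.2], [0.6, 0.9])
        assert j == 1.0
        assert thr == pytest.approx(0.4)  # midpoint of 0.2 and 0.6


class TestMatchRate:
    def test_published_style_threshold_splits_list(self):
        assert match_rate([0.2, 0.4], 0.331) == 0.5

    def test_all_above_and_all_below(self):
        assert match_rate([0.5, 0.6, 0.7], 0.1) == 0.0
        assert match_rate([0.01, 0.02], 0.331) == 1.0

    def test_boundary_distance_counts_as_match(self):
        assert match_rate([0.331], 0.331) == 1.0

    def test_empty_list_is_an_error(self):
        with pytest.raises(ValueError):
            match_rate([], 0.3)


class TestPairingDistances:
    def test_rejects_negative_or_nonfinite(self):
        with pytest.raises(ValueError):
            PairingDistances(np.array([-0.1]), np.array([0.2]), np.array([0.3]))
        with pytest.raises(ValueError):
            PairingDistances(np.array([np.nan]), np.array([0.2]), np.array([0.3]))

    def test_distance_file_round_trip(self, tmp_path):
        f = tmp_path / "same.tsv"
        f.write_text("# pair_id distance\np01 0.12\np02\t0.50\np03, 0.331\n")
        assert np.allclose(read_distance_file(f), [0.12, 0.50, 0.331])


class TestDefaceReport:
    def test_report_round_trips_through_json(self, defaced_below):
        report = defaced_below.report
        back = DefaceReport.from_json(report.to_json())
        assert back == report

    def test_below_mode_report_contents(self, defaced_below):
        report = defaced_below.report
        assert report.ptv_category == "below"
        assert report.retained_fractions["PTV70"] == 1.0
        for name in ("Parotid_L", "Parotid_R", "Mandible", "PTV70", "Brain"):
            assert report.roi_dice[name] == 1.0
        assert set(report.rois_removed) == {
            "Eye_L", "Eye_R", "Lens_L", "Lens_R", "Cornea_L", "Cornea_R"
        }

    def test_removed_voxel_counts_consistent(self, phantom_below, defaced_below):
        """Image-level diff count can never exceed the mask accounting
        (voxels already at the fill value do not change)."""
        vol, _, _ = phantom_below
        changed = (vol.stored_values != defaced_below.volume.stored_values).sum()
        assert changed == defaced_below.report.voxels_removed
        assert changed <= defaced_below.mask.removed_voxels
        fill = vol.stored_value_for_hu(-1000.0)
        already_fill = (vol.stored_values[~defaced_below.mask.keep] == fill).sum()
        assert changed + already_fill == defaced_below.mask.removed_voxels
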