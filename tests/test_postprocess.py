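import numpy as np
import pytest
from scipy import ndimage

from avpseg.labels import DEFAULT_SCHEME
from avpseg.phantom import ReaderPerturbation, perturb_reader
from avpseg.postprocess import (PostprocessConfig, PostprocessReport,
                                enforce_continuity, enforce_sides,
                                interpolate_gaps, postprocess,
                                remove_clusters)
from avpseg.volume import LabelMap

STRUCT26 = np.ones((3, 3, 3), dtype=bool)
CFG = PostprocessConfig()


def _lm(arr, spacing=(1.0, 1.0, 1.0)):
    return LabelMap(np.asarray(arr, dtype=np.uint8), spacing=spacing,
                    scheme=DEFAULT_SCHEME)


def _components(mask):
    return ndimage.label(mask, structure=STRUCT26)[1]


class TestRemoveClusters:
    def test_small_component_removed(self):
        arr = np.zeros((16, 16, 16), dtype=np.uint8)
        arr[2:7, 2:7, 2:7] = 1          # 125 voxels
        arr[12:13, 12:14, 12:13] = 1    # 2 voxels
        out = remove_clusters(_lm(arr), CFG)
        assert out.data[12, 12, 12] == 0
        assert (out.data == 1).sum() == 125

    def test_single_component_input_unchanged(self, small_phantom):
        _, gt = small_phantom
        out = remove_clusters(gt, CFG)
        assert np.array_equal(out.data, gt.data)

    def test_survivor_matches_flood_fill_oracle(self):
        rng = np.random.default_rng(0)
        arr = (rng.random((16, 16, 16)) < 0.15).astype(np.uint8)
        out = remove_clusters(_lm(arr), CFG)
        comp, n = ndimage.label(arr == 1, structure=STRUCT26)
        largest = max((comp == i).sum() for i in range(1, n + 1))
        assert (out.data == 1).sum() == largest
        assert _components(out.data == 1) == 1

    def test_report_counts(self):
        arr = np.zeros((12, 12, 12), dtype=np.uint8)
        arr[1:4, 1:4, 1:4] = 2
        arr[8, 8, 8] = 2
        arr[10, 10, 10] = 2
        rep = PostprocessReport()
        remove_clusters(_lm(arr), CFG, rep)
        assert rep.components_removed[2] == 2
        assert rep.voxels_removed == 2


class TestEnforceSides:
    def _with_onc(self, arr):
        # ONC block centered at x = 7..8 -> midline x = 7.5
        arr[7:9, 6:10, 6:10] = DEFAULT_SCHEME.id_of["ONC"]
        return arr

    def test_wrong_side_component_relabeled(self):
        sch = DEFAULT_SCHEME
        arr = self._with_onc(np.zeros((16, 16, 16), dtype=np.uint8))
        # OTL belongs on the left (low x under +x-right affine): put it right
        arr[12:14, 3:5, 6:8] = sch.id_of["OTL"]
        out = enforce_sides(_lm(arr), CFG)
        assert (out.data[12:14, 3:5, 6:8] == sch.id_of["OTR"]).all()

    def test_valid_phantom_unchanged(self, small_phantom):
        _, gt = small_phantom
        out = enforce_sides(gt, CFG)
        assert np.array_equal(out.data, gt.data)

    def test_component_centered_on_midline_unchanged(self):
        sch = DEFAULT_SCHEME
        arr = self._with_onc(np.zeros((16, 16, 16), dtype=np.uint8))
        # symmetric around x = 7.5 -> centroid exactly on the midline
        arr[7:9, 2:4, 2:4] = sch.id_of["OTL"]
        out = enforce_sides(_lm(arr), CFG)
        assert (out.data[7:9, 2:4, 2:4] == sch.id_of["OTL"]).all()

    def test_missing_onc_without_midline_raises(self):
        arr = np.zeros((8, 8, 8), dtype=np.uint8)
        arr[1, 1, 1] = DEFAULT_SCHEME.id_of["OTL"]
        with pytest.raises(ValueError, match="ONC"):
            enforce_sides(_lm(arr), CFG)

    def test_explicit_midline_override(self):
        sch = DEFAULT_SCHEME
        arr = np.zeros((16, 16, 16), dtype=np.uint8)
        arr[2:4, 2:4, 2:4] = sch.id_of["OTR"]  # low x = left -> wrong
        cfg = PostprocessConfig(midline_x_vox=8.0)
        out = enforce_sides(_lm(arr), cfg)
        assert (out.data[2:4, 2:4, 2:4] == sch.id_of["OTL"]).all()


class TestInterpolateGaps:
    def test_one_voxel_gap_closed(self):
        arr = np.zeros((16, 16, 16), dtype=np.uint8)
        arr[3:13, 8, 8] = 1
        arr[7, 8, 8] = 0
        out = interpolate_gaps(_lm(arr), PostprocessConfig(closing_length_vox=5))
        assert _components(arr == 1) == 2
        assert _components(out.data == 1) == 1
        assert out.data[7, 8, 8] == 1

    def test_gap_free_input_unchanged(self, small_phantom):
        _, gt = small_phantom
        out = interpolate_gaps(gt, CFG)
        assert np.array_equal(out.data, gt.data)

    def test_fill_matches_brute_force_closing_on_background(self):
        arr = np.zeros((16, 16, 16), dtype=np.uint8)
        arr[2:8, 8, 8] = 3
        arr[10:14, 8, 8] = 3
        cfg = PostprocessConfig(closing_length_vox=5)
        out = interpolate_gaps(_lm(arr), cfg)
        # oracle: direct binary closing with the same line SE along x,
        # restricted to background voxels
        from avpseg.postprocess import _line_structure, _principal_axis
        se = _line_structure(_principal_axis(arr == 3), 5)
        closed = ndimage.binary_closing(arr == 3, structure=se)
        expected = arr.copy()
        expected[closed & (arr == 0)] = 3
        assert np.array_equal(out.data, expected)

    def test_other_labels_never_overwritten(self):
        arr = np.zeros((16, 16, 16), dtype=np.uint8)
        arr[2:7, 8, 8] = 1
        arr[9:14, 8, 8] = 1
        arr[7, 8, 8] = 2               # a different structure in the gap
        out = interpolate_gaps(_lm(arr), PostprocessConfig(closing_length_vox=7))
        assert out.data[7, 8, 8] == 2


class TestEnforceContinuity:
    def test_short_gap_bridged(self, small_phantom, scheme):
        _, gt = small_phantom
        data = gt.data.copy()
        icran = scheme.id_of["ONR_iCran"]
        onc = scheme.id_of["ONC"]
        d = ndimage.distance_transform_edt(~(data == onc),
                                           sampling=gt.spacing)
        data[(data == icran) & (d <= 1.3)] = 0  # carve a ~2-voxel gap
        out = enforce_continuity(gt.replace(data=data), CFG)
        grown = ndimage.binary_dilation(out.data == icran, structure=STRUCT26)
        assert (grown & (out.data == onc)).any()

    def test_connected_phantom_unchanged(self, small_phantom):
        _, gt = small_phantom
        out = enforce_continuity(gt, CFG)
        assert np.array_equal(out.data, gt.data)

    def test_gap_longer_than_bridge_reported_not_bridged(self):
        sch = DEFAULT_SCHEME
        arr = np.zeros((24, 8, 8), dtype=np.uint8)
        arr[0:3, 3:5, 3:5] = sch.id_of["ONR_iCran"]
        arr[20:23, 3:5, 3:5] = sch.id_of["ONC"]
        cfg = PostprocessConfig(bridge_max_mm=6.0)
        rep = PostprocessReport()
        out = enforce_continuity(_lm(arr), cfg, rep)
        assert np.array_equal(out.data, arr)
        assert len(rep.bridges_skipped) == 1
        # measured gap: nearest surfaces at x=2 and x=20 -> 18 voxels = 18 mm
        assert rep.bridges_skipped[0]["gap_mm"] == pytest.approx(18.0)

    def test_bridge_passes_only_through_background(self):
        sch = DEFAULT_SCHEME
        arr = np.zeros((12, 8, 8), dtype=np.uint8)
        arr[0:3, 3:5, 3:5] = sch.id_of["ONR_iCran"]
        arr[6:9, 3:5, 3:5] = sch.id_of["ONC"]
        arr[4, 3, 3] = sch.id_of["OTL"]    # unrelated structure nearby
        out = enforce_continuity(_lm(arr), CFG)
        assert (out.data[arr == sch.id_of["OTL"]] == sch.id_of["OTL"]).all()


class TestComposite:
    def _adversarial(self, gt, scheme, rng):
        bad = gt.data.copy()
        # speckle noise components
        for _ in range(6):
            p = tuple(rng.integers(1, np.array(bad.shape) - 1))
            if bad[p] == 0:
                bad[p] = rng.integers(1, 10)
        # swap tract sides wholesale
        otl, otr = scheme.id_of["OTL"], scheme.id_of["OTR"]
        l_mask, r_mask = bad == otl, bad == otr
        bad[l_mask], bad[r_mask] = otr, otl
        # 1-voxel transverse gap in the right intraorbital nerve
        iorb = scheme.id_of["ONR_iOrb"]
        xs = np.argwhere(bad == iorb)[:, 0]
        cut = int(np.median(xs))
        bad[cut][bad[cut] == iorb] = 0
        # ~2-voxel chiasm-tract disconnection
        onc = scheme.id_of["ONC"]
        d = ndimage.distance_transform_edt(~(bad == onc), sampling=gt.spacing)
        bad[(bad == otr) & (d <= 1.3)] = 0
        return gt.replace(data=bad)

    def test_adversarial_defects_all_corrected(self, small_phantom, scheme):
        _, gt = small_phantom
        rng = np.random.default_rng(0)
        fixed, report = postprocess(self._adversarial(gt, scheme, rng), CFG)
        # <= 1 component per label
        for lid in range(1, 10):
            assert _components(fixed.data == lid) <= 1, lid
        # no wrong-side components
        mid = np.argwhere(fixed.data == scheme.id_of["ONC"])[:, 0].mean()
        for lid in range(1, 10):
            side = scheme.side(lid)
            if side == "midline" or not (fixed.data == lid).any():
                continue
            cx = np.argwhere(fixed.data == lid)[:, 0].mean()
            assert ("right" if cx > mid else "left") == side
        # 26-connected chain per side
        for side in ("right", "left"):
            chain = scheme.chain(side)
            for a, b in zip(chain[:-1], chain[1:]):
                grown = ndimage.binary_dilation(fixed.data == a,
                                                structure=STRUCT26)
                assert (grown & (fixed.data == b)).any(), (side, a, b)

    def test_gt_phantom_is_fixpoint(self, small_phantom):
        _, gt = small_phantom
        out, report = postprocess(gt, CFG)
        assert np.array_equal(out.data, gt.data)
        assert report.voxels_removed == 0
        assert not report.side_flips

    def test_idempotent_on_random_predictions(self, small_phantom):
        _, gt = small_phantom
        for seed in range(20):
            noisy = perturb_reader(gt, ReaderPerturbation(
                dilate_prob=0.4, erode_prob=0.4, transition_jitter_mm=1.0,
                seed=seed))
            # sprinkle speckles to exercise cluster removal
            rng = np.random.default_rng(seed)
            data = noisy.data.copy()
            for _ in range(4):
                p = tuple(rng.integers(0, np.array(data.shape)))
                if data[p] == 0:
                    data[p] = rng.integers(1, 10)
            once, _ = postprocess(noisy.replace(data=data), CFG)
            twice, _ = postprocess(once, CFG)
            assert np.array_equal(once.data, twice.data), seed

    def test_foreground_growth_bounded(self, small_phantom):
        _, gt = small_phantom
        noisy = perturb_reader(gt, ReaderPerturbation(seed=1))
        out, report = postprocess(noisy, CFG)
        grown = (out.data != 0) & (noisy.data == 0)
        max_bridge_vox = int(np.ceil(CFG.bridge_max_mm / min(gt.spacing))) + 2
        budget = (sum(report.voxels_filled.values())
                  + len(report.bridges_drawn) * max_bridge_vox)
        assert int(grown.sum()) <= budget
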