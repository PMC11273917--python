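"""Rule-cascade tests: pixel thresholding, component analysis, slide
aggregation, auto-annotation."""

import numpy as np
import pytest

from pfstain import pdcs
from pfstain.pdcs import DecisionThresholds, PatchVerdict

from conftest import flood_fill_area


def uniform_patch(rgb, size=8):
    return np.full((size, size, 3), 0, dtype=np.uint8) + np.array(rgb, dtype=np.uint8)


class TestPixelDecision:
    def test_dark_foreground_is_positive(self):
        assert pdcs.pixel_decision(uniform_patch((50, 60, 120))).all()

    def test_background_is_excluded(self):
        assert not pdcs.pixel_decision(uniform_patch((250, 250, 250))).any()

    def test_boundary_is_strict_at_r_threshold(self):
        patch = np.zeros((2, 2, 3), dtype=np.uint8)
        patch[:, :, 1:] = 50
        patch[:, :, 0] = [[50, 99], [100, 200]]
        mask = pdcs.pixel_decision(patch)
        assert mask.tolist() == [[1, 1], [0, 0]]

    def test_rejects_non_rgb_input(self):
        with pytest.raises(ValueError, match="RGB"):
            pdcs.pixel_decision(np.zeros((4, 4), dtype=np.uint8))

    def test_permuting_pixels_permutes_mask(self, rng):
        patch = rng.integers(0, 256, (16, 16, 3), dtype=np.uint8)
        mask = pdcs.pixel_decision(patch)
        perm = rng.permutation(16 * 16)
        shuffled = patch.reshape(-1, 3)[perm].reshape(16, 16, 3)
        assert np.array_equal(
            pdcs.pixel_decision(shuffled), mask.reshape(-1)[perm].reshape(16, 16)
        )

    def test_raising_r_max_only_adds_positives(self, rng):
        patch = rng.integers(0, 256, (32, 32, 3), dtype=np.uint8)
        low = pdcs.pixel_decision(patch, DecisionThresholds(pixel_positive_r_max=80))
        high = pdcs.pixel_decision(patch, DecisionThresholds(pixel_positive_r_max=150))
        assert (high >= low).all()


class TestLargestComponent:
    def test_empty_mask(self):
        assert pdcs.largest_component_area(np.zeros((8, 8), dtype=np.uint8)) == 0

    def test_filled_rectangle(self):
        mask = np.zeros((20, 20), dtype=np.uint8)
        mask[2:12, 3:16] = 1  # 10 x 13
        assert pdcs.largest_component_area(mask) == 130

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_agrees_with_flood_fill_oracle(self, connectivity, rng):
        for _ in range(50):
            mask = (rng.random((32, 32)) < 0.4).astype(np.uint8)
            assert pdcs.largest_component_area(mask, connectivity) == flood_fill_area(
                mask, connectivity
            )

    def test_diagonal_touching_merges_only_under_8(self):
        mask = np.eye(5, dtype=np.uint8)
        assert pdcs.largest_component_area(mask, 8) == 5
        assert pdcs.largest_component_area(mask, 4) == 1


class TestPatchDecision:
    def test_component_above_threshold_is_positive(self):
        mask = np.zeros((30, 30), dtype=np.uint8)
        mask[0:5, 0:25] = 1  # 125 px, the typical minimal tumor footprint
        verdict = pdcs.patch_decision(mask)
        assert verdict.label == 1 and verdict.largest_component_area == 125

    def test_exactly_at_threshold_is_negative(self):
        mask = np.zeros((30, 30), dtype=np.uint8)
        mask[0:10, 0:10] = 1  # exactly 100 px; "exceeds" is strict
        assert pdcs.patch_decision(mask).label == 0

    def test_disjoint_small_components_do_not_sum(self):
        mask = np.zeros((30, 30), dtype=np.uint8)
        for c in (0, 10, 20):  # three disjoint 40-px components
            mask[0:5, c : c + 8] = 1
        verdict = pdcs.patch_decision(mask)
        assert verdict.label == 0 and verdict.largest_component_area == 40

    def test_raising_min_area_never_flips_negative_to_positive(self, rng):
        mask = (rng.random((64, 64)) < 0.45).astype(np.uint8)
        labels = [
            pdcs.patch_decision(mask, DecisionThresholds(component_min_area=a)).label
            for a in (10, 50, 100, 500)
        ]
        assert labels == sorted(labels, reverse=True)


class TestWsiDecision:
    def test_single_positive_patch_means_npc(self):
        verdicts = [PatchVerdict(l, 0, np.zeros((2, 2))) for l in (0, 0, 1, 0)]
        slide = pdcs.wsi_decision(verdicts)
        assert slide.diagnosis == "NPC" and slide.positive_patch_count == 1

    def test_all_negative_means_non_npc(self):
        verdicts = [PatchVerdict(0, 0, np.zeros((2, 2)))] * 5
        assert pdcs.wsi_decision(verdicts).diagnosis == "non-NPC"

    def test_count_threshold_above_one(self):
        verdicts = [PatchVerdict(0, 0, np.zeros((2, 2)))] * 999
        verdicts.append(PatchVerdict(1, 200, np.zeros((2, 2))))
        thr = DecisionThresholds(wsi_positive_count_min=2)
        assert pdcs.wsi_decision(verdicts, thr).diagnosis == "non-NPC"
        assert pdcs.wsi_decision(verdicts).diagnosis == "NPC"

    def test_empty_sequence_raises(self):
        with pytest.raises(ValueError, match="no foreground"):
            pdcs.wsi_decision([])

    def test_raising_count_min_never_flips_to_npc(self):
        verdicts = [PatchVerdict(1, 200, np.zeros((2, 2)))] * 3
        npc = [
            pdcs.wsi_decision(verdicts, DecisionThresholds(wsi_positive_count_min=k)).diagnosis
            == "NPC"
            for k in (1, 2, 3, 4, 5)
        ]
        assert npc == sorted(npc, reverse=True)


class TestAutoAnnotate:
    def test_negative_patches_all_labelled_zero(self):
        patches = [uniform_patch((220, 160, 170), 16) for _ in range(10)]
        manifest = pdcs.auto_annotate(patches)
        assert (manifest["label"] == 0).all()

    def test_agrees_with_generator_ground_truth(self, small_set):
        manifest = pdcs.auto_annotate(list(small_set.target_patches))
        agreement = (manifest["label"].to_numpy() == small_set.target_labels).mean()
        assert agreement >= 0.99

    def test_is_deterministic_and_order_preserving(self, small_set):
        patches = list(small_set.target_patches)
        m1 = pdcs.auto_annotate(patches)
        m2 = pdcs.auto_annotate(patches)
        assert m1.equals(m2)
        assert list(m1["path"]) == [str(i) for i in range(len(patches))]

    def test_reports_offending_patch_index(self):
        patches = [uniform_patch((220, 160, 170), 8), np.zeros((4, 4), dtype=np.uint8)]
        with pytest.raises(ValueError, match="patch 1"):
            pdcs.auto_annotate(patches)


class TestChannelHistograms:
    def test_single_uniform_patch_means_exact(self):
        out = pdcs.channel_histograms([uniform_patch((10, 20, 30))], [1])
        assert np.allclose(out[1][0], [10, 20, 30])

    def test_class_separation_in_r_channel(self, small_set):
        out = pdcs.channel_histograms(
            list(small_set.target_patches), small_set.target_labels
        )
        # negative patches: mean foreground R above 200
        assert (out[0][:, 0] > 200).all()
        # positive patches sit below negatives in R
        assert out[1][:, 0].max() < out[0][:, 0].min()

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="equal length"):
            pdcs.channel_histograms([uniform_patch((1, 2, 3))], [0, 1])


def test_threshold_invariants_enforced():
    with pytest.raises(ValueError):
        DecisionThresholds(pixel_positive_r_max=240)  # >= background cutoff
    with pytest.raises(ValueError):
        DecisionThresholds(component_min_area=0)
    with pytest.raises(ValueError):
        DecisionThresholds(connectivity=6)
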