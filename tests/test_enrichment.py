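import numpy as np
import pytest

from puncta import ChannelStack, mitochondrial_enrichment, peroxisomal_enrichment
from puncta.errors import EnrichmentError
from puncta.segment import MaskStack

from conftest import as_mask_stacks, brute_force_enrichment, random_small_case


def worked_example():
    """Single 4x4 slice: cargo 100 on a 2-px organelle mask, 10 elsewhere,
    construct 50 on the mask; whole cell is the region."""
    vox = np.zeros((1, 4, 4, 3))
    marker = np.zeros((1, 4, 4), bool)
    marker[0, 0, 0] = marker[0, 0, 1] = True
    vox[..., 2] = 10.0
    vox[0, 0, 0, 2] = vox[0, 0, 1, 2] = 100.0
    vox[0, 0, 0, 1] = vox[0, 0, 1, 1] = 50.0
    vox[..., 0] = np.where(marker, 100.0, 0.0)
    stack = ChannelStack(vox, {0: "marker", 1: "construct", 2: "cargo"})
    region = np.ones((1, 4, 4), bool)
    return stack, marker, marker.copy(), region


def test_worked_example_values_exact():
    stack, marker, analysis, region = worked_example()
    res = peroxisomal_enrichment(stack, *as_mask_stacks(marker, analysis, region))
    assert res.raw_enrichment == 90.0
    assert res.background == 10.0
    assert res.construct_intensity == 50.0
    assert res.normalized_enrichment == pytest.approx(1.8)
    assert res.n_slices_used == 1 and res.analysis_mask_px == 2


def test_uniform_cargo_gives_zero_enrichment():
    stack, marker, analysis, region = worked_example()
    stack.voxels[..., 2] = 37.0
    res = peroxisomal_enrichment(stack, *as_mask_stacks(marker, analysis, region))
    assert res.raw_enrichment == 0.0
    assert res.normalized_enrichment == 0.0


def test_slice_with_empty_analysis_mask_is_skipped():
    stack, marker, analysis, region = worked_example()
    vox2 = np.concatenate([stack.voxels, stack.voxels], axis=0)
    stack2 = ChannelStack(vox2, stack.channel_roles)
    marker2 = np.concatenate([marker, marker])
    analysis2 = np.concatenate([analysis, np.zeros_like(analysis)])
    region2 = np.concatenate([region, region])
    res = peroxisomal_enrichment(stack2, *as_mask_stacks(marker2, analysis2, region2))
    assert res.n_slices_used == 1
    assert res.raw_enrichment == 90.0


class TestErrorPaths:
    def test_all_slices_empty_analysis_mask_excludes_cell(self):
        stack, marker, analysis, region = worked_example()
        analysis[:] = False
        with pytest.raises(EnrichmentError, match="no construct-positive"):
            peroxisomal_enrichment(stack, *as_mask_stacks(marker, analysis, region))

    def test_no_cytosol_for_background(self):
        stack, marker, analysis, region = worked_example()
        region = marker.copy()  # region entirely inside the marker mask
        with pytest.raises(EnrichmentError, match="no cytosol"):
            peroxisomal_enrichment(stack, *as_mask_stacks(marker, analysis, region))

    def test_zero_construct_intensity_undefined(self):
        stack, marker, analysis, region = worked_example()
        stack.voxels[..., 1] = 0.0
        with pytest.raises(EnrichmentError, match="normalization undefined"):
            peroxisomal_enrichment(stack, *as_mask_stacks(marker, analysis, region))

    def test_analysis_mask_not_subset_rejected(self):
        stack, marker, analysis, region = worked_example()
        analysis = np.ones_like(analysis)
        with pytest.raises(EnrichmentError, match="subset"):
            peroxisomal_enrichment(stack, *as_mask_stacks(marker, analysis, region))


class TestLinearity:
    """Scaling/offset contracts of the score, on random small stacks."""

    def cases(self, n=20):
        rng = np.random.default_rng(7)
        return [random_small_case(rng) for _ in range(n)]

    def test_cargo_gain_scales_raw(self):
        for stack, marker, analysis, region in self.cases():
            masks = as_mask_stacks(marker, analysis, region)
            base = peroxisomal_enrichment(stack, *masks)
            vox = stack.voxels.copy()
            vox[..., 2] *= 3.0
            scaled = peroxisomal_enrichment(
                ChannelStack(vox, stack.channel_roles), *masks
            )
            assert scaled.raw_enrichment == pytest.approx(3.0 * base.raw_enrichment)

    def test_cargo_offset_cancels_in_raw(self):
        for stack, marker, analysis, region in self.cases():
            masks = as_mask_stacks(marker, analysis, region)
            base = peroxisomal_enrichment(stack, *masks)
            vox = stack.voxels.copy()
            vox[..., 2] += 55.0
            shifted = peroxisomal_enrichment(
                ChannelStack(vox, stack.channel_roles), *masks
            )
            assert shifted.raw_enrichment == pytest.approx(base.raw_enrichment, abs=1e-9)

    def test_construct_gain_divides_normalized(self):
        for stack, marker, analysis, region in self.cases():
            masks = as_mask_stacks(marker, analysis, region)
            base = peroxisomal_enrichment(stack, *masks)
            vox = stack.voxels.copy()
            vox[..., 1] *= 2.0
            scaled = peroxisomal_enrichment(
                ChannelStack(vox, stack.channel_roles), *masks
            )
            assert scaled.normalized_enrichment == pytest.approx(
                base.normalized_enrichment / 2.0
            )


def test_matches_brute_force_oracle_on_random_stacks():
    rng = np.random.default_rng(123)
    for _ in range(50):
        stack, marker, analysis, region = random_small_case(rng)
        res = peroxisomal_enrichment(stack, *as_mask_stacks(marker, analysis, region))
        oracle = brute_force_enrichment(stack, marker, analysis, region, 2, 1)
        assert res.raw_enrichment == oracle["raw"]
        assert res.background == oracle["background"]
        assert res.construct_intensity == oracle["construct"]
        assert res.normalized_enrichment == oracle["normalized"]
        assert res.n_slices_used == oracle["n_slices"]


class TestMitochondrial:
    def make(self, mito_val, cyt_val):
        vox = np.zeros((1, 4, 4, 2))
        mito = np.zeros((1, 4, 4), bool)
        mito[0, :2, :2] = True
        vox[..., 1] = np.where(mito, mito_val, cyt_val)
        stack = ChannelStack(vox, {0: "marker", 1: "cargo"})
        region = MaskStack(np.ones((1, 4, 4), bool), "geometry")
        return stack, MaskStack(mito, "marker"), region

    def test_fold_ratio(self):
        stack, mito, region = self.make(80.0, 20.0)
        assert mitochondrial_enrichment(stack, mito, region, cargo_channel=1) == 4.0

    def test_uniform_cargo_gives_unity(self):
        stack, mito, region = self.make(33.0, 33.0)
        assert mitochondrial_enrichment(stack, mito, region, cargo_channel=1) == 1.0

    def test_cytosol_shifted_condition_lowers_ratio(self):
        control, mito, region = self.make(80.0, 20.0)
        released, _, _ = self.make(30.0, 70.0)  # cargo moved off the organelle
        r_ctrl = mitochondrial_enrichment(control, mito, region, cargo_channel=1)
        r_rel = mitochondrial_enrichment(released, mito, region, cargo_channel=1)
        assert r_rel < r_ctrl

    def test_difference_mode(self):
        stack, mito, region = self.make(80.0, 20.0)
        assert (
            mitochondrial_enrichment(stack, mito, region, cargo_channel=1, mode="difference")
            == 60.0
        )

    def test_zero_cytosol_mean_drops_slice_with_warning(self):
        stack, mito, region = self.make(80.0, 0.0)
        with pytest.raises(EnrichmentError, match="no usable slices"):
            with pytest.warns(UserWarning, match="zero cytosolic mean"):
                mitochondrial_enrichment(stack, mito, region, cargo_channel=1)
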