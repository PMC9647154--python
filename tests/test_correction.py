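import numpy as np
import pytest

from cbctsc.correction import (
    FiltrationParams,
    MaskField,
    ScatterRatioField,
    TissueLACTable,
    build_mask,
    build_template,
    compute_scatter_ratio,
    estimate_rigid_transform,
    estimate_uniform_scatter,
    extract_tissue_lacs,
    local_filtration,
    apply_ratio,
    nearest_rank_percentile,
    segment_tissues,
    soft_cut_subtract,
    substitute_applicator,
)
from cbctsc.projector import ConeBeamGeometry, ProjectionStack
from cbctsc.tissues import TissueClass
from cbctsc.volume import VoxelVolume, make_centered_volume


def intensity_stack(values, I0=1.0):
    """Wrap a flat list of pixel values into a 1-view-like intensity stack."""
    arr = np.asarray(values, dtype=float)
    n = arr.size
    geom = ConeBeamGeometry(
        detector_pixels=(n, 1), pixel_pitch=8.0,
        view_angles_deg=np.array([0.0, 180.0]), I0=I0,
    )
    data = np.stack([arr.reshape(1, n), np.full((1, n), I0)])
    return ProjectionStack("intensity", data, geom)


def volume_of(arr, spacing=(1.0, 1.0, 1.0)):
    arr = np.asarray(arr, dtype=float)
    return VoxelVolume(arr, spacing, (0.0, 0.0, 0.0))


class TestExtractTissueLACs:
    def make_prior(self, muscle_hu=50.0):
        """Synthetic prior covering all four windows with forced modes."""
        data = np.concatenate([
            np.full(500, -1000.0),          # air
            np.full(400, -100.0),           # fat
            np.full(400, muscle_hu),        # muscle
            np.full(400, 300.0),            # bone
            np.full(300, 150.0),            # gap (no window)
        ])
        rng = np.random.default_rng(1)
        rng.shuffle(data)
        return volume_of(data.reshape(20, 10, 10))

    def test_forced_muscle_mode(self):
        table = extract_tissue_lacs(self.make_prior(50.0), mu_w=0.020)
        # 1-HU bins centred at half-integers: mode 49.5-50.5 -> 0.02*1.0495
        assert table.mu_muscle == pytest.approx(0.020 * 1.0495, abs=2e-5)

    def test_air_mode_gives_zero(self):
        table = extract_tissue_lacs(self.make_prior(), mu_w=0.020)
        assert table.mu_air == pytest.approx(0.0, abs=2e-5)

    def test_gap_voxels_do_not_matter(self):
        prior = self.make_prior()
        more_gap = volume_of(
            np.concatenate([prior.data.ravel(), np.full(1000, 120.0)]).reshape(30, 10, 10)
        )
        t1 = extract_tissue_lacs(prior)
        t2 = extract_tissue_lacs(more_gap)
        assert (t1.mu_air, t1.mu_fat, t1.mu_muscle, t1.mu_bone) == (
            t2.mu_air, t2.mu_fat, t2.mu_muscle, t2.mu_bone
        )

    def test_missing_class_raises(self):
        prior = volume_of(np.full((10, 10, 10), -1000.0))
        with pytest.raises(ValueError, match="window"):
            extract_tissue_lacs(prior)

    def test_ordering_invariant_holds(self, small_phantom):
        from cbctsc.phantom import make_planning_ct
        prior = make_planning_ct(small_phantom[1], 10.0, 4)
        t = extract_tissue_lacs(prior)
        assert t.mu_air < t.mu_fat < t.mu_muscle < t.mu_bone

    def test_table_rejects_bad_ordering(self):
        with pytest.raises(ValueError, match="ordered"):
            TissueLACTable(0.01, 0.005, 0.02, 0.03)


class TestUniformScatterEstimate:
    def test_nearest_rank_tenth_percentile(self):
        stack = intensity_stack([10, 20, 30, 40, 50, 60, 70, 80, 90, 100], I0=1000.0)
        est = estimate_uniform_scatter(stack, object_mask_rule=0.9)
        assert est.s_bar == 10.0

    def test_constant_shift_equivariance(self):
        base = np.array([10, 20, 30, 40, 50, 60, 70, 80, 90, 100.0])
        e0 = estimate_uniform_scatter(intensity_stack(base, I0=1000.0))
        e1 = estimate_uniform_scatter(intensity_stack(base + 7.0, I0=1000.0))
        assert e1.s_bar == e0.s_bar + 7.0

    def test_no_object_pixels_raises(self):
        stack = intensity_stack(np.full(10, 999.0), I0=1000.0)
        with pytest.raises(ValueError, match="object"):
            estimate_uniform_scatter(stack)

    def test_nearest_rank_convention(self):
        assert nearest_rank_percentile(np.arange(1, 11), 0.80) == 8
        assert nearest_rank_percentile(np.array([5.0]), 0.10) == 5.0


class TestSoftCutSubtract:
    def test_plain_branch(self):
        out = soft_cut_subtract(intensity_stack([100.0], I0=1000.0), 20.0, 0.05)
        assert out.data[0, 0, 0] == pytest.approx(80.0)

    def test_soft_branch_closed_form(self):
        out = soft_cut_subtract(intensity_stack([20.0], I0=1000.0), 19.5, 0.05)
        assert out.data[0, 0, 0] == pytest.approx(np.exp(-0.5), rel=1e-12)

    def test_zero_subtraction_is_identity(self):
        stack = intensity_stack([1.0, 5.0, 42.0], I0=1000.0)
        out = soft_cut_subtract(stack, 0.0)
        np.testing.assert_array_equal(out.data, stack.data)

    def test_output_positive_everywhere(self):
        stack = intensity_stack(np.linspace(0.01, 100.0, 200), I0=1000.0)
        out = soft_cut_subtract(stack, 50.0)
        assert np.all(out.data > 0.0)

    def test_c1_continuity_at_knee(self):
        s_bar, eps = 10.0, 0.05
        knee_I = s_bar / (1.0 - eps)
        h = 1e-6
        vals = [knee_I - 2 * h, knee_I - h, knee_I, knee_I + h, knee_I + 2 * h]
        out = soft_cut_subtract(intensity_stack(vals, I0=1000.0), s_bar, eps).data[0, 0]
        slopes = np.diff(out) / h
        assert np.all(np.abs(np.diff(slopes)) < 1e-3)

    def test_uniform_scatter_restored_exactly(self):
        """Injecting a constant and subtracting the same constant is lossless
        for every pixel in the plain-subtraction branch."""
        primaries = np.linspace(5.0, 100.0, 50)
        c = 30.0
        contaminated = intensity_stack(primaries + c, I0=1000.0)
        out = soft_cut_subtract(contaminated, c, 0.05)
        plain = (primaries + c) - c >= 0.05 * (primaries + c)
        np.testing.assert_allclose(out.data[0, 0][plain], primaries[plain], rtol=1e-12)


class TestSegmentation:
    def test_window_examples(self):
        vol = volume_of(np.array([[[-800.0, 50.0, 100.0]]]))
        labels, conf = segment_tissues(vol)
        assert labels.data[0, 0, 0] == TissueClass.AIR and conf.data[0, 0, 0]
        assert labels.data[0, 0, 1] == TissueClass.MUSCLE and conf.data[0, 0, 1]
        # gap value: labelled air but flagged unclassified
        assert labels.data[0, 0, 2] == TissueClass.AIR and not conf.data[0, 0, 2]

    def test_bone_threshold_strict(self):
        vol = volume_of(np.array([[[190.0, 190.5]]]))
        labels, conf = segment_tissues(vol)
        assert not conf.data[0, 0, 0]  # exactly 190 is outside the open bone window
        assert labels.data[0, 0, 1] == TissueClass.BONE


class TestBuildTemplate:
    TABLE = TissueLACTable(0.0, 0.018, 0.021, 0.024)

    def test_all_muscle_constant(self):
        labels = volume_of(np.full((3, 4, 5), int(TissueClass.MUSCLE)))
        out = build_template(labels, self.TABLE)
        assert np.all(out.data == 0.021)

    def test_at_most_five_distinct_values(self, small_phantom):
        labels, _ = small_phantom
        seg = volume_of((labels.data > 0).astype(float) * 2)  # air/muscle mix
        out = build_template(seg, self.TABLE)
        assert np.unique(out.data).size <= 5

    def test_swapping_lacs_swaps_regions(self):
        labels = volume_of(np.array([[[1, 2]]], dtype=float))
        swapped = TissueLACTable(0.0, 0.021, 0.0215, 0.024)
        a = build_template(labels, self.TABLE)
        b = build_template(labels, swapped)
        assert a.data[0, 0, 0] == self.TABLE.mu_fat and b.data[0, 0, 0] == 0.021
        assert a.data[0, 0, 1] == self.TABLE.mu_muscle and b.data[0, 0, 1] == 0.0215

    def test_unknown_label_raises(self):
        labels = volume_of(np.array([[[7.0]]]))
        with pytest.raises(ValueError, match="unknown label"):
            build_template(labels, self.TABLE)

    def test_applicator_label_requires_lac(self):
        labels = volume_of(np.array([[[4.0]]]))
        with pytest.raises(ValueError, match="applicator"):
            build_template(labels, self.TABLE)
        out = build_template(labels, self.TABLE, applicator_lac=0.07)
        assert out.data[0, 0, 0] == 0.07


class TestScatterRatio:
    def test_equal_volumes_give_unity(self):
        c = volume_of(np.full((2, 3, 4), 0.02))
        ratio = compute_scatter_ratio(c, c)
        assert np.all(ratio.r.data == 1.0)

    def test_halved_denominator_doubles(self):
        t = volume_of(np.full((2, 3, 4), 0.02))
        c = volume_of(np.full((2, 3, 4), 0.01))
        assert np.all(compute_scatter_ratio(t, c).r.data == 2.0)

    def test_zero_denominator_floored(self):
        t = volume_of(np.array([[[0.02]]]))
        c = volume_of(np.array([[[0.0]]]))
        ratio = compute_scatter_ratio(t, c, eps_floor=1e-4)
        assert ratio.r.data[0, 0, 0] == pytest.approx(200.0)
        assert ratio.n_floored == 1

    def test_grid_mismatch_rejected(self):
        t = volume_of(np.zeros((2, 2, 2)))
        c = VoxelVolume(np.zeros((2, 2, 2)), (2, 2, 2), (0, 0, 0))
        with pytest.raises(ValueError, match="grid"):
            compute_scatter_ratio(t, c)


def mask_inputs(r, confident=None, body=None):
    rvol = volume_of(r)
    ratio = ScatterRatioField(rvol, 1e-4)
    conf = volume_of(np.ones_like(rvol.data) if confident is None else confident)
    bod = volume_of(np.ones_like(rvol.data) if body is None else body)
    return ratio, conf, bod


class TestBuildMask:
    def test_constant_field_fully_kept(self):
        """Constant ratio: |r| sits exactly at r_max; ties are kept."""
        ratio, conf, body = mask_inputs(np.full((1, 8, 8), 1.3))
        mask = build_mask(ratio, conf, body)
        assert mask.r_max == pytest.approx(1.3)
        assert np.all(mask.f.data)

    def test_spike_rejected(self):
        r = np.ones((1, 5, 5))
        r[0, 2, 2] = 100.0
        ratio, conf, body = mask_inputs(r)
        mask = build_mask(ratio, conf, body)
        assert not mask.f.data[0, 2, 2]
        # direct neighbours carry the spike's gradient and are rejected too
        assert not mask.f.data[0, 2, 1] and not mask.f.data[0, 2, 3]
        assert mask.f.data[0, 0, 0]

    def test_unclassified_voxels_excluded(self):
        conf = np.ones((1, 4, 4))
        conf[0, 1, 1] = 0.0
        ratio, confv, body = mask_inputs(np.ones((1, 4, 4)), confident=conf)
        mask = build_mask(ratio, confv, body)
        assert not mask.f.data[0, 1, 1]

    def test_mask_fraction_bounded(self, small_phantom):
        rng = np.random.default_rng(3)
        r = rng.lognormal(0.0, 0.3, (4, 16, 16))
        ratio, conf, body = mask_inputs(r)
        mask = build_mask(ratio, conf, body, percentile=0.80)
        assert mask.f.data.mean() <= 0.80 + 1e-12

    def test_empty_body_raises(self):
        ratio, conf, body = mask_inputs(np.ones((1, 3, 3)), body=np.zeros((1, 3, 3)))
        with pytest.raises(ValueError, match="body"):
            build_mask(ratio, conf, body)


class TestLocalFiltration:
    def test_constant_fully_masked_is_identity(self):
        ratio, conf, body = mask_inputs(np.full((2, 9, 9), 1.7))
        mask = MaskField(volume_of(np.ones((2, 9, 9))), 2.0, 1.0)
        rf = local_filtration(ratio, mask)
        np.testing.assert_allclose(rf.data, 1.7, rtol=1e-12)

    def test_hole_interpolated_from_neighbours(self):
        r = np.full((1, 7, 7), 2.5)
        f = np.ones((1, 7, 7))
        f[0, 3, 3] = 0.0
        ratio, _, _ = mask_inputs(r)
        rf = local_filtration(ratio, MaskField(volume_of(f), 3.0, 1.0))
        assert rf.data[0, 3, 3] == pytest.approx(2.5, rel=1e-9)

    def test_empty_slice_uses_global_mean(self):
        r = np.full((2, 7, 7), 3.0)
        f = np.ones((2, 7, 7))
        f[1] = 0.0
        ratio, _, _ = mask_inputs(r)
        rf = local_filtration(ratio, MaskField(volume_of(f), 3.0, 1.0))
        np.testing.assert_allclose(rf.data[1], 3.0, rtol=1e-9)

    def test_identity_fallback(self):
        r = np.full((2, 7, 7), 3.0)
        f = np.ones((2, 7, 7))
        f[1] = 0.0
        ratio, _, _ = mask_inputs(r)
        params = FiltrationParams(fallback="identity")
        rf = local_filtration(ratio, MaskField(volume_of(f), 3.0, 1.0), params)
        np.testing.assert_allclose(rf.data[1], 1.0)

    def test_all_zero_mask_raises(self):
        ratio, _, _ = mask_inputs(np.ones((1, 4, 4)))
        with pytest.raises(ValueError, match="mask"):
            local_filtration(ratio, MaskField(volume_of(np.zeros((1, 4, 4))), 1.0, 1.0))

    def test_matches_explicit_weighted_average_oracle(self):
        """Normalised convolution equals the direct per-pixel weighted mean."""
        rng = np.random.default_rng(42)
        r = rng.uniform(0.5, 2.0, (1, 16, 16))
        f = (rng.random((1, 16, 16)) > 0.4).astype(float)
        params = FiltrationParams(sigma_mm=2.0, kernel_radius_sigmas=3.0)
        ratio, _, _ = mask_inputs(r)
        rf = local_filtration(ratio, MaskField(volume_of(f), 10.0, 10.0), params)

        # oracle: explicit truncated-Gaussian weighted average per pixel
        rad = int(3.0 * 2.0)  # kernel_radius_sigmas * sigma / spacing(1mm)
        ax = np.arange(-rad, rad + 1)
        kern = np.exp(-0.5 * (ax / 2.0) ** 2)
        k2 = np.outer(kern, kern)
        expected = np.zeros((16, 16))
        for i in range(16):
            for j in range(16):
                num = den = 0.0
                for di in range(-rad, rad + 1):
                    for dj in range(-rad, rad + 1):
                        ii, jj = i + di, j + dj
                        if 0 <= ii < 16 and 0 <= jj < 16 and f[0, ii, jj] > 0:
                            w = k2[di + rad, dj + rad]
                            num += w * r[0, ii, jj]
                            den += w
                expected[i, j] = num / den if den > 0 else r[0][f[0] > 0].mean()
        assert np.abs(rf.data[0] - expected).max() < 1e-6


class TestApplyRatio:
    def test_unit_ratio_is_identity(self):
        c = volume_of(np.full((2, 3, 4), 0.02))
        rf = volume_of(np.ones((2, 3, 4)))
        fc, fc_hu = apply_ratio(c, rf, mu_w=0.02)
        np.testing.assert_array_equal(fc.data, c.data)
        np.testing.assert_allclose(fc_hu.data, 0.0, atol=1e-9)

    def test_doubling_ratio_doubles_lac(self):
        c = volume_of(np.full((2, 3, 4), 0.015))
        rf = volume_of(np.full((2, 3, 4), 2.0))
        fc, _ = apply_ratio(c, rf)
        assert np.all(fc.data == 0.03)


class TestApplicatorSubstitution:
    def tube_volume(self, shift_mm=0.0):
        vol = make_centered_volume((24, 32, 32), (2.0, 2.0, 2.0), fill=0.0, unit="HU")
        z, y, x = vol.world_grid()
        tube = ((y - shift_mm) ** 2 + x**2 <= 4.0**2) & (np.abs(z) <= 16.0)
        vol.data[np.broadcast_to(tube, vol.shape)] = 2500.0
        return vol

    def test_identity_case(self):
        a = self.tube_volume()
        out = substitute_applicator(a, a, transform="identity")
        np.testing.assert_array_equal(out.data, a.data)

    def test_known_translation_recovered(self):
        model = self.tube_volume(0.0)
        shifted = self.tube_volume(6.0)
        out = substitute_applicator(shifted, model)
        # the transformed model must land on the shifted applicator footprint
        got = out.data > 1000.0
        want = shifted.data > 1000.0
        overlap = (got & want).sum() / want.sum()
        assert overlap > 0.9

    def test_estimated_translation_within_one_voxel(self):
        model = self.tube_volume(0.0)
        shifted = self.tube_volume(6.0)
        pts_m = np.argwhere(model.data > 1000) * 2.0 + np.asarray(model.origin)
        pts_s = np.argwhere(shifted.data > 1000) * 2.0 + np.asarray(shifted.origin)
        R, t = estimate_rigid_transform(pts_m, pts_s)
        assert np.allclose(R, np.eye(3), atol=0.05)
        assert np.abs(t - np.array([0.0, 6.0, 0.0])).max() < 2.0

    def test_empty_threshold_set_raises(self):
        empty = make_centered_volume((8, 8, 8), (2, 2, 2), fill=0.0, unit="HU")
        with pytest.raises(ValueError, match="threshold"):
            substitute_applicator(empty, self.tube_volume())


class TestNoScatterLimit:
    def test_near_idempotent_on_clean_data(
        self, small_phantom_with_applicator, small_phantom, small_geometry
    ):
        """Scatter-free input: the six-step correction neither degrades the
        first pass nor applies a far-from-unity ratio.  (The empirical
        uniform constant is nonzero even without scatter - it is a
        percentile of the darkest object pixels - so the ratio compensates
        a small first-pass bias rather than being exactly 1.)"""
        import numpy as np
        from scipy import ndimage

        from cbctsc.correction import CorrectionConfig, correct_cbct
        from cbctsc.fdk import ReconGrid, hu_to_lac, lac_to_hu
        from cbctsc.phantom import make_planning_ct
        from cbctsc.projector import add_noise, forward_project, to_intensity

        labels, hu = small_phantom_with_applicator
        _, hu0 = small_phantom
        prior = make_planning_ct(hu0, 10.0, 12)
        stack = add_noise(
            to_intensity(forward_project(hu_to_lac(hu), small_geometry)), 1e7, 13
        )
        cfg = CorrectionConfig(recon_grid=ReconGrid(hu.shape, hu.spacing))
        res = correct_cbct(stack, prior, cfg)
        body = ndimage.binary_erosion(res.body_mask.data.astype(bool), iterations=2)
        rel = np.abs(
            res.cbct_fc.data[body] / np.maximum(res.cbct_c.data[body], 1e-4) - 1.0
        )
        assert np.median(rel) < 0.03
        fc_err = np.abs(lac_to_hu(res.cbct_fc).data - hu0.data)[body]
        c_err = np.abs(lac_to_hu(res.cbct_c).data - hu0.data)[body]
        assert np.median(fc_err) <= np.median(c_err) + 2.0
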