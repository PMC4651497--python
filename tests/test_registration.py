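import dataclasses

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

import surequant as sq
from surequant.grid import DisplacementField, Volume
from surequant.registration import (
    InversionError,
    apply_displacement,
    compose,
    invert,
    random_smooth_field,
    simulate_registration,
    track_voxel,
)


@pytest.fixture
def like32():
    return Volume(np.zeros((32, 32, 32)), voxel_size_mm=(2.0, 2.0, 2.0))


@pytest.fixture
def smooth_volume():
    rng = np.random.default_rng(1)
    return Volume(gaussian_filter(rng.standard_normal((32, 32, 32)), 3.0))


class TestApplyDisplacement:
    def test_zero_field_identity(self, smooth_volume):
        z = DisplacementField.zero(smooth_volume)
        out_n = apply_displacement(smooth_volume, z, "nearest")
        assert np.array_equal(out_n.data, smooth_volume.data)
        out_l = apply_displacement(smooth_volume, z, "linear")
        assert np.allclose(out_l.data, smooth_volume.data)

    def test_one_voxel_shift_matches_index_oracle(self, smooth_volume):
        # +1 voxel along x in pull convention: out[i] = in[i+1], border filled
        f = DisplacementField.constant(smooth_volume, (2.0, 0.0, 0.0))
        out = apply_displacement(smooth_volume, f, "nearest", fill=-7.0)
        oracle = np.full_like(smooth_volume.data, -7.0)
        oracle[:-1] = smooth_volume.data[1:]
        assert np.array_equal(out.data, oracle)

    def test_out_of_domain_takes_fill(self, smooth_volume):
        f = DisplacementField.constant(smooth_volume, (-200.0, 0.0, 0.0))
        out = apply_displacement(smooth_volume, f, "linear", fill=0.0)
        assert np.all(out.data == 0.0)

    def test_linear_on_mask_rejected(self, like32):
        f = DisplacementField.zero(like32)
        with pytest.raises(ValueError, match="nearest"):
            apply_displacement(like32, f, "linear", is_mask=True)

    def test_mask_resampling_preserves_binarity_and_disjointness(self, cohort32):
        ctrl = cohort32.controls[0]
        f = random_smooth_field(ctrl.fa, 2.0, 6.0, np.random.default_rng(2))
        seg = sq.resample_segmentation(ctrl.seg, f)
        for m in (seg.wm, seg.gm, seg.csf):
            assert set(np.unique(m.data)) <= {0, 1}
        # TissueSegmentation construction itself asserts pairwise disjointness


class TestCompose:
    def test_zero_is_identity_element(self, like32):
        f = random_smooth_field(like32, 1.0, 6.0, np.random.default_rng(0))
        z = DisplacementField.zero(like32)
        assert np.allclose(compose(z, f).vectors, f.vectors)
        assert np.allclose(compose(f, z).vectors, f.vectors)

    def test_constant_shifts_add(self, like32):
        a = DisplacementField.constant(like32, (2.0, -4.0, 0.0))
        b = DisplacementField.constant(like32, (6.0, 2.0, 2.0))
        c = compose(a, b)
        assert np.allclose(c.vectors, a.vectors + b.vectors)

    def test_composite_matches_two_step_resampling(self, like32, smooth_volume):
        f = random_smooth_field(like32, 1.0, 6.0, np.random.default_rng(3))
        g = random_smooth_field(like32, 1.0, 6.0, np.random.default_rng(5))
        two_step = apply_displacement(apply_displacement(smooth_volume, g), f)
        one_step = apply_displacement(smooth_volume, compose(f, g))
        interior = (slice(4, -4),) * 3
        err = np.abs(two_step.data - one_step.data)[interior].max()
        # limited by trilinear interpolation of the inner field
        assert err < 0.02 * np.abs(smooth_volume.data).max() + 1e-3

    def test_grid_mismatch_rejected(self, like32):
        other = Volume(np.zeros((16, 16, 16)))
        with pytest.raises(Exception, match="grid"):
            compose(DisplacementField.zero(like32), DisplacementField.zero(other))


class TestInvert:
    def test_inverse_of_zero_is_zero(self, like32):
        z = DisplacementField.zero(like32)
        assert invert(z).is_zero()

    def test_inverse_of_constant_shift_is_negated(self, like32):
        d = DisplacementField.constant(like32, (2.0, 0.0, -2.0))
        inv = invert(d, tol=0.01)
        assert np.allclose(inv.vectors, -d.vectors, atol=1e-6)

    def test_smooth_field_inverts_below_tenth_voxel(self, like32):
        # 1 mm-RMS field; residual of compose(f, invert(f)) < 0.1 voxel
        interior = np.zeros((32, 32, 32), bool)
        interior[5:-5, 5:-5, 5:-5] = True
        for seed in (0, 1, 2):
            f = random_smooth_field(like32, 1.0, 6.0, np.random.default_rng(seed))
            g = invert(f, tol=0.08, max_iter=100, mask=interior)
            resid = compose(f, g).magnitude_mm()[interior].max() / 2.0
            assert resid < 0.1

    def test_non_invertible_field_raises_with_residual(self, like32):
        wild = random_smooth_field(like32, 24.0, 4.0, np.random.default_rng(0))
        with pytest.raises(InversionError, match="residual"):
            invert(wild, tol=0.01, max_iter=8)


class TestSimulateRegistration:
    def test_self_registration_with_zero_residual(self, cohort32):
        c = cohort32.controls[0]
        reg, recovered = simulate_registration(c, c, 0.0, 6.0, 0)
        brain = c.seg.brain.data.astype(bool)
        # equal up to the resampling tolerance of the truth-field inverse
        assert np.abs(reg.fa.data - c.fa.data)[brain].max() < 0.05
        mis = sq.misregistration_mask(reg.seg, c.seg.wm)
        assert mis.data.sum() == 0

    def test_zero_residual_reproduces_exact_map(self, cohort32, cache32):
        c, t = cohort32.controls[0], cohort32.template
        _, recovered = simulate_registration(
            c, t, 0.0, 6.0, 0, precomputed_exact=cache32.exact(c, t)
        )
        assert np.array_equal(recovered.vectors, cache32.exact(c, t).vectors)

    def test_seeded_runs_identical(self, cohort32, cache32):
        c, t = cohort32.controls[0], cohort32.template
        pre = cache32.exact(c, t)
        _, r1 = simulate_registration(c, t, 2.0, 6.0, 7, precomputed_exact=pre)
        _, r2 = simulate_registration(c, t, 2.0, 6.0, 7, precomputed_exact=pre)
        assert np.array_equal(r1.vectors, r2.vectors)

    def test_misregistration_grows_with_residual_amplitude(self, cohort32, cache32):
        subj, t = cohort32.subjects[0], cohort32.template
        pre = cache32.exact(subj, t)
        fracs = []
        for amp in (0.0, 1.0, 2.0):
            counts = []
            for seed in range(5):
                reg, _ = simulate_registration(
                    subj, t, amp, 6.0, seed, precomputed_exact=pre
                )
                counts.append(int(sq.misregistration_mask(reg.seg, t.seg.wm).data.sum()))
            fracs.append(np.mean(counts))
        assert fracs[0] <= fracs[1] <= fracs[2]
        assert fracs[2] > 0

    def test_missing_truth_field_names_plugin_path(self, cohort32):
        c = cohort32.controls[0]
        bare = dataclasses.replace(c, truth_field=None)
        with pytest.raises(ValueError, match="registration engine"):
            simulate_registration(bare, cohort32.template, 1.0, 6.0, 0)


class TestTrackVoxel:
    def test_zero_field_fixed_point(self, like32):
        t = track_voxel((4, 5, 6), DisplacementField.zero(like32))
        assert t.index == (4, 5, 6) and t.in_domain

    def test_constant_shift_increments_index(self, like32):
        f = DisplacementField.constant(like32, (2.0, 0.0, 0.0))
        t = track_voxel((4, 5, 6), f)
        assert t.index == (5, 5, 6)
        assert t.continuous == (5.0, 5.0, 6.0)

    def test_outside_grid_rejected(self, like32):
        with pytest.raises(ValueError, match="outside"):
            track_voxel((40, 0, 0), DisplacementField.zero(like32))

    def test_labeled_voxel_scatters_across_simulated_registrations(
        self, cohort32, cache32
    ):
        # one WM voxel tracked through 15 independently-seeded imperfect
        # registrations lands at dispersed positions around the target
        subj, t = cohort32.subjects[0], cohort32.template
        pre = cache32.exact(subj, t)
        voxel = (10, 16, 16)
        assert t.seg.wm.data[voxel] == 1
        positions = []
        for seed in range(15):
            _, recovered = simulate_registration(
                subj, t, 2.0, 6.0, seed, precomputed_exact=pre
            )
            positions.append(track_voxel(voxel, recovered).continuous)
        pos = np.array(positions)
        rms_dispersion = np.sqrt(((pos - pos.mean(axis=0)) ** 2).sum(axis=1).mean())
        assert rms_dispersion > 0.0
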