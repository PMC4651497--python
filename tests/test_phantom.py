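import dataclasses

import numpy as np
import pytest

import surequant as sq
from surequant.phantom import InvalidSpecError, make_cohort


class TestSpecValidation:
    def test_degenerate_shell_rejected(self):
        with pytest.raises(InvalidSpecError, match="degenerate"):
            sq.PhantomSpec(
                tissue_geometry=sq.TissueGeometry(brain_radii_vox=(5.0, 5.0, 5.0),
                                                  shell_thickness_vox=5.0)
            )

    def test_fa_mean_outside_unit_interval_rejected(self):
        with pytest.raises(InvalidSpecError, match="FA mean"):
            sq.PhantomSpec(fa_params={"wm": (1.2, 0.05), "gm": (0.15, 0.03), "csf": (0.05, 0.02)})

    def test_yaml_round_trip(self, tmp_path, spec32):
        path = tmp_path / "spec.yaml"
        spec32.to_yaml(path)
        assert sq.PhantomSpec.from_yaml(path) == spec32

    def test_lesion_spec_validation(self):
        with pytest.raises(InvalidSpecError):
            sq.LesionSpec((1, 1, 1), radius_mm=4.0, fa_delta=0.0)
        with pytest.raises(InvalidSpecError):
            sq.LesionSpec((1, 1, 1), radius_mm=-1.0, fa_delta=0.2)


class TestTemplate:
    def test_deterministic_given_seed(self, spec32, template32):
        again = sq.make_template_phantom(spec32)
        assert np.array_equal(again.fa.data, template32.fa.data)
        assert np.array_equal(again.seg.wm.data, template32.seg.wm.data)

    def test_tissues_partition_brain(self, template32):
        w = template32.seg.wm.data.astype(bool)
        g = template32.seg.gm.data.astype(bool)
        c = template32.seg.csf.data.astype(bool)
        assert not (w & g).any() and not (w & c).any() and not (g & c).any()
        assert np.array_equal(w | g | c, template32.seg.brain.data.astype(bool))

    def test_wm_fa_mean_matches_spec(self):
        # 64³ default: sample mean over ~50k WM voxels pins the tissue mean
        t = sq.make_template_phantom(sq.PhantomSpec())
        wm = t.seg.wm.data.astype(bool)
        assert t.fa.data[wm].mean() == pytest.approx(0.50, abs=0.01)
        assert np.all(t.fa.data >= 0) and np.all(t.fa.data <= 1)


class TestIndividuals:
    def test_zero_amplitude_is_template_up_to_noise(self, spec32, template32):
        spec0 = dataclasses.replace(spec32, variability_amplitude_mm=0.0)
        ind = sq.sample_individual(template32, spec0, seed=3)
        assert ind.truth_field.is_zero()
        assert np.array_equal(ind.seg.wm.data, template32.seg.wm.data)
        assert np.allclose(ind.fa_clean.data, template32.fa_clean.data)
        brain = ind.seg.brain.data.astype(bool)
        # fresh acquisition noise, but nothing else
        assert not np.array_equal(ind.fa.data, template32.fa.data)
        assert np.abs(ind.fa.data - ind.fa_clean.data)[brain].max() < 6 * spec32.noise_sd

    def test_distinct_seeds_give_distinct_deformations(self, spec32, template32):
        a = sq.sample_individual(template32, spec32, seed=1)
        b = sq.sample_individual(template32, spec32, seed=2)
        diff = np.abs(a.truth_field.vectors - b.truth_field.vectors).max()
        assert diff > 0

    def test_deformation_rms_near_requested_amplitude(self):
        # 2 mm amplitude, 6 mm smoothness on the 64³ default grid
        spec = sq.PhantomSpec(variability_smoothness_mm=6.0)
        t = sq.make_template_phantom(spec)
        ind = sq.sample_individual(t, spec, seed=1)
        rms = ind.truth_field.rms_mm(ind.seg.brain.data.astype(bool))
        assert abs(rms - 2.0) / 2.0 < 0.30

    def test_rms_scales_linearly_with_amplitude(self, template32):
        rms = []
        for amp in (1.0, 2.0, 3.0):
            f = sq.random_smooth_field(
                template32.fa, amp, 10.0, np.random.default_rng(5)
            )
            rms.append(f.rms_mm())
        assert rms[0] == pytest.approx(1.0) and rms[1] == pytest.approx(2.0)
        assert rms[2] == pytest.approx(3.0)

    def test_folding_amplitude_raises(self, spec32, template32):
        wild = dataclasses.replace(
            spec32, variability_amplitude_mm=30.0, variability_smoothness_mm=4.0
        )
        with pytest.raises(InvalidSpecError, match="fold"):
            sq.sample_individual(template32, wild, seed=0)


class TestLesions:
    def test_fa_drops_by_exactly_delta_inside_wm(self, template32):
        center = (10, 16, 16)
        assert template32.seg.wm.data[center] == 1
        lesioned = sq.insert_lesion(
            template32, sq.LesionSpec(center, radius_mm=4.0, fa_delta=0.2)
        )
        m = lesioned.lesion_mask.data.astype(bool)
        assert m.sum() > 0
        drop = template32.fa.data[m] - lesioned.fa.data[m]
        assert np.allclose(drop, 0.2)
        untouched = ~m
        assert np.array_equal(lesioned.fa.data[untouched], template32.fa.data[untouched])

    def test_lesion_clipped_to_wm_matches_brute_force(self, template32):
        # near cortex: sphere pokes into GM/background, mask keeps WM only
        center = (22, 16, 16)
        lesion = sq.LesionSpec(center, radius_mm=6.0, fa_delta=0.1)
        lesioned = sq.insert_lesion(template32, lesion)
        wm = template32.seg.wm.data.astype(bool)
        count = 0
        r_vox = lesion.radius_mm / template32.fa.voxel_size_mm[0]
        for i in range(32):
            for j in range(32):
                for k in range(32):
                    d2 = (i - center[0]) ** 2 + (j - center[1]) ** 2 + (k - center[2]) ** 2
                    if d2 <= r_vox**2 and wm[i, j, k]:
                        count += 1
        assert int(lesioned.lesion_mask.data.sum()) == count

    def test_sphere_outside_wm_rejected(self, template32):
        with pytest.raises(InvalidSpecError, match="white matter"):
            sq.insert_lesion(template32, sq.LesionSpec((1, 1, 1), 2.0, 0.2))


class TestCohort:
    def test_manifest_has_one_row_per_control(self, spec32, tmp_path):
        import pandas as pd

        spec0 = dataclasses.replace(spec32, variability_amplitude_mm=0.0)
        cohort = make_cohort(spec0, 48, [None], seed=9, out_dir=tmp_path / "c")
        assert len(cohort.controls) == 48
        df = pd.read_csv(tmp_path / "c" / "manifest.tsv", sep="\t")
        assert (df["role"] == "control").sum() == 48
        assert (df["role"] == "subject").sum() == 1
        assert df.loc[df["role"] == "subject", "lesion_path"].item() == "-"

    def test_reproducible_from_seed(self, spec32, tmp_path):
        a = make_cohort(spec32, 2, [None], seed=4, out_dir=tmp_path / "a")
        b = make_cohort(spec32, 2, [None], seed=4, out_dir=tmp_path / "b")
        assert (tmp_path / "a" / "manifest.tsv").read_text() == (
            tmp_path / "b" / "manifest.tsv"
        ).read_text()
        assert np.array_equal(a.controls[0].fa.data, b.controls[0].fa.data)
        assert np.array_equal(
            a.subjects[0].truth_field.vectors, b.subjects[0].truth_field.vectors
        )

    def test_too_few_controls_rejected(self, spec32):
        with pytest.raises(InvalidSpecError, match="n_controls"):
            make_cohort(spec32, 1, [], seed=0)

    def test_load_round_trip(self, spec32, tmp_path):
        lesion = sq.LesionSpec((10, 16, 16), 4.0, 0.2)
        cohort = make_cohort(spec32, 2, [lesion], seed=4, out_dir=tmp_path / "c")
        template, controls, subjects = sq.load_cohort(tmp_path / "c" / "manifest.tsv")
        assert template.id == "template" and len(controls) == 2 and len(subjects) == 1
        assert np.allclose(subjects[0].fa.data, cohort.subjects[0].fa.data, atol=1e-6)
        assert np.array_equal(
            subjects[0].lesion_mask.data, cohort.subjects[0].lesion_mask.data
        )
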