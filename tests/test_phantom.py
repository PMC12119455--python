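"""Phantom generator: geometry, noise model, cohort calibration, raters."""

from dataclasses import replace

import numpy as np
import pytest

import drgqmri.phantom as ph
from drgqmri.features import LEVELS, SIDES, compute_volume
from drgqmri.phantom import (AcquisitionProtocol, default_cohort_config,
                             make_rater_masks, make_scene, sample_cohort,
                             sigma_from_iqr, simulate_multiecho)


def _single_subject_spec(volume=405.0, t2=100.0, pd=0.9, seed=1, group="HC"):
    return ph.SubjectSpec(
        subject_id="T01", group=group, sex="F", age=40.0, height=170.0,
        weight=70.0,
        drg_volume={(lv, sd): volume for lv in LEVELS for sd in SIDES},
        drg_t2={(lv, sd): t2 for lv in LEVELS for sd in SIDES},
        drg_pd={(lv, sd): pd for lv in LEVELS for sd in SIDES},
        noise_sigma=0.0, seed=seed)


class TestSceneGeometry:
    def test_requested_volume_405_gives_100_voxels(self, protocol):
        scene = make_scene(_single_subject_spec(volume=405.0), protocol)
        lab = scene.mask.label_for("L5", "L")
        n = int(np.sum(scene.mask.labels == lab))
        assert abs(n - 100) <= 1

    def test_reported_hc_median_volume_within_one_voxel(self, protocol):
        scene = make_scene(_single_subject_spec(volume=628.4), protocol)
        for lab in scene.mask.drg_labels():
            vol = compute_volume(scene.mask, lab)
            assert abs(vol - 628.4) <= protocol.voxel_volume

    def test_random_specs_voxelize_within_one_voxel_volume(self, protocol):
        rng = np.random.default_rng(0)
        for i in range(100):
            v = rng.uniform(100.0, 4000.0)
            scene = make_scene(_single_subject_spec(volume=v, seed=i), protocol)
            for lab in scene.mask.drg_labels():
                assert abs(compute_volume(scene.mask, lab) - v) <= protocol.voxel_volume

    def test_masks_disjoint_and_nonempty_csf_intersects_drg_slices(self, protocol):
        scene = make_scene(_single_subject_spec(volume=2000.0), protocol)
        m = scene.mask
        for lab in m.drg_labels():
            sel = m.labels == lab
            assert sel.any()
            z = np.unique(np.nonzero(sel)[2])
            csf_z = np.unique(np.nonzero(m.labels == ph.CSF_LABEL)[2])
            assert np.intersect1d(z, csf_z).size > 0

    def test_pd_assignment_exact_before_noise(self, protocol):
        """m0_DRG / m0_CSF equals the spec PD to 1e-12."""
        spec = _single_subject_spec(pd=0.932)
        scene = make_scene(spec, protocol)
        m = scene.mask
        csf_mean = scene.m0_map[m.labels == ph.CSF_LABEL].mean()
        for lab in m.drg_labels():
            ratio = scene.m0_map[m.labels == lab].mean() / csf_mean
            assert abs(ratio - 0.932) < 1e-12

    def test_pd_one_matches_csf_m0(self, protocol):
        scene = make_scene(_single_subject_spec(pd=1.0), protocol)
        m = scene.mask
        drg = scene.m0_map[m.labels == m.label_for("L5", "L")].mean()
        csf = scene.m0_map[m.labels == ph.CSF_LABEL].mean()
        assert drg == pytest.approx(csf, abs=1e-15)

    def test_b1_field_within_range(self, protocol):
        scene = make_scene(_single_subject_spec(), protocol, b1_range=(0.8, 1.1))
        assert scene.b1_map.min() >= 0.8 - 1e-12
        assert scene.b1_map.max() <= 1.1 + 1e-12

    def test_too_small_volume_rejected_with_message(self, protocol):
        with pytest.raises(ValueError, match="8 voxel volumes"):
            make_scene(_single_subject_spec(volume=20.0), protocol)


class TestSimulation:
    def test_ideal_refocusing_gives_exponential_echoes(self):
        protocol = AcquisitionProtocol(grid_shape=(16, 16, 8))
        scene = make_scene(_single_subject_spec(volume=100.0, t2=100.0, pd=1.0),
                           protocol, b1_range=(1.0, 1.0))
        series = simulate_multiecho(scene, protocol, 0.0)
        m = scene.mask
        lab = m.label_for("L5", "L")
        vox = np.argwhere(m.labels == lab)[0]
        sig = series.data[tuple(vox)]
        expected = np.exp(-15.0 * np.arange(1, 11) / 100.0)
        np.testing.assert_allclose(sig, expected, atol=1e-10)

    def test_noise_free_series_bit_identical(self, protocol):
        scene = make_scene(_single_subject_spec(), protocol)
        a = simulate_multiecho(scene, protocol, 0.0)
        b = simulate_multiecho(scene, protocol, 0.0)
        np.testing.assert_array_equal(a.data, b.data)

    def test_rician_series_reproducible_for_fixed_seed(self, protocol):
        scene = make_scene(_single_subject_spec(), protocol)
        a = simulate_multiecho(scene, protocol, 0.02, seed=123)
        b = simulate_multiecho(scene, protocol, 0.02, seed=123)
        c = simulate_multiecho(scene, protocol, 0.02, seed=124)
        np.testing.assert_array_equal(a.data, b.data)
        assert not np.array_equal(a.data, c.data)

    def test_zero_signal_voxels_have_rayleigh_mean(self):
        """Where M0 = 0 the magnitude is pure Rayleigh noise with mean
        sigma*sqrt(pi/2); Monte-Carlo over >= 1e4 draws."""
        protocol = AcquisitionProtocol(grid_shape=(16, 16, 8))
        scene = make_scene(_single_subject_spec(volume=100.0), protocol)
        scene.m0_map[:] = 0.0
        sigma = 0.01
        series = simulate_multiecho(scene, protocol, sigma, seed=5)
        draws = series.data.ravel()
        assert draws.size >= 10_000
        expected = sigma * np.sqrt(np.pi / 2.0)
        assert np.mean(draws) == pytest.approx(expected, rel=0.02)


class TestCohortSampling:
    def test_default_cohort_has_48_subjects(self):
        specs = sample_cohort(default_cohort_config(seed=3))
        assert len(specs) == 48
        groups = {g: sum(s.group == g for s in specs) for g in ("HC", "NF1n", "NF1p")}
        assert groups == {"HC": 28, "NF1n": 12, "NF1p": 8}

    def test_deterministic_under_master_seed(self):
        a = sample_cohort(default_cohort_config(seed=9))
        b = sample_cohort(default_cohort_config(seed=9))
        for sa, sb in zip(a, b):
            assert sa == sb

    def test_degenerate_scale_reproduces_medians_exactly(self):
        cfg = default_cohort_config(seed=2).scaled(0.0)
        specs = sample_cohort(cfg)
        for group, gp in cfg.groups.items():
            sub = [s for s in specs if s.group == group]
            for feat, attr in (("volume", "drg_volume"), ("t2", "drg_t2"),
                               ("pd", "drg_pd")):
                target = getattr(gp, feat).median
                means = [np.mean([np.mean([getattr(s, attr)[(lv, sd)]
                                           for sd in SIDES]) for lv in LEVELS])
                         for s in sub]
                assert float(np.median(means)) == pytest.approx(target, abs=1e-9)

    def test_empirical_median_converges_to_configured(self):
        """Monte-Carlo: the median of many HC volume draws approaches the
        configured median."""
        cfg = default_cohort_config(seed=1)
        big = replace(cfg, groups={"HC": replace(cfg.groups["HC"], n=1000)})
        specs = sample_cohort(big)
        means = [np.mean([np.mean([s.drg_volume[(lv, sd)] for sd in SIDES])
                          for lv in LEVELS]) for s in specs]
        assert float(np.median(means)) == pytest.approx(628.4, rel=0.05)

    def test_sigma_from_iqr_inverts_lognormal_iqr(self):
        med, iqr = 628.4, 243.1
        sigma = sigma_from_iqr(med, iqr)
        q1 = med * np.exp(-0.6744897501960817 * sigma)
        q3 = med * np.exp(0.6744897501960817 * sigma)
        assert q3 - q1 == pytest.approx(iqr, rel=1e-12)

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ValueError):
            ph.FeatureParams(median=100.0, sigma=-0.1)


class TestRaterMasks:
    def test_zero_perturbation_identity(self, protocol):
        scene = make_scene(_single_subject_spec(volume=600.0), protocol)
        raters = make_rater_masks(scene.mask, n_raters=2, perturbation=0.0, seed=0)
        for rm in raters:
            np.testing.assert_array_equal(rm.labels, scene.mask.labels)
            assert all(info.rater_id.startswith("rater")
                       for info in rm.label_table.values())

    def test_perturbation_dice_in_expected_band(self, protocol):
        """Dice between two raters at perturbation 0.2 stays below 1 but
        above 0.5 for DRG-sized masks, over many seeds."""
        scene = make_scene(_single_subject_spec(volume=600.0), protocol)
        lab = scene.mask.label_for("L5", "L")
        dices = []
        for seed in range(100):
            r1, r2 = make_rater_masks(scene.mask, 2, 0.2, seed=seed)
            a, b = r1.labels == lab, r2.labels == lab
            dices.append(2 * np.sum(a & b) / (np.sum(a) + np.sum(b)))
        dices = np.array(dices)
        assert np.all(dices < 1.0)
        assert np.all(dices > 0.5)

    def test_rater_masks_connected(self, protocol):
        from scipy import ndimage
        scene = make_scene(_single_subject_spec(volume=600.0), protocol)
        raters = make_rater_masks(scene.mask, 2, 0.3, seed=4)
        struct = ndimage.generate_binary_structure(3, 1)
        for rm in raters:
            for lab in rm.drg_labels():
                _, n_cc = ndimage.label(rm.labels == lab, structure=struct)
                assert n_cc == 1

    def test_invalid_perturbation_rejected(self, protocol):
        scene = make_scene(_single_subject_spec(volume=600.0), protocol)
        for bad in (-0.1, 1.0, 1.5):
            with pytest.raises(ValueError):
                make_rater_masks(scene.mask, 2, bad, seed=0)
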