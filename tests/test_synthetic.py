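"""Toy atlas construction and the planted-network BOLD simulator."""

import numpy as np
import pytest
from scipy import stats

from hippofc import connectivity as conn
from hippofc.preprocessing import PreprocessConfig, bandpass_array, preprocess
from hippofc.synthetic import (
    GroupSimSpec,
    TABLE1_GROUP_PARAMS,
    ToyAtlasSpec,
    band_limited_noise,
    expected_network_correlation,
    file_checksum,
    make_toy_atlas,
    simulate_cohort,
    simulate_subject,
    simulate_volumetry,
)

from conftest import tiny_group_spec


class TestMakeToyAtlas:
    def test_mirrored_centers_give_equal_roi_sizes(self, atlas):
        assert atlas.left_roi.n_voxels == atlas.right_roi.n_voxels

    def test_roi_size_matches_brute_force_sphere(self, atlas):
        # exhaustive enumeration of grid points within Euclidean distance 2
        center = atlas.spec.roi_centers[0]
        radius = atlas.spec.roi_radius_vox
        count = sum(
            (i - center[0]) ** 2 + (j - center[1]) ** 2 + (k - center[2]) ** 2
            <= radius**2
            for i in range(32) for j in range(32) for k in range(16)
        )
        assert atlas.left_roi.n_voxels == count

    def test_deterministic(self):
        a, b = make_toy_atlas(), make_toy_atlas()
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_rois_inside_brain_and_disjoint(self, atlas):
        assert not np.any(atlas.left_roi.data & atlas.right_roi.data)
        assert np.all(atlas.brain.data[atlas.left_roi.data])
        assert np.all(atlas.brain.data[atlas.right_roi.data])

    def test_overlapping_rois_rejected(self):
        spec = ToyAtlasSpec(roi_centers=((14, 16, 8), (16, 16, 8)))
        with pytest.raises(ValueError, match="overlap"):
            make_toy_atlas(spec)

    def test_midsagittal_plane_at_x_zero(self, atlas):
        # world x of the two mirrored ROI centers must be opposite
        aff = atlas.affine
        lx = aff[0, 0] * atlas.spec.roi_centers[0][0] + aff[0, 3]
        rx = aff[0, 0] * atlas.spec.roi_centers[1][0] + aff[0, 3]
        assert lx == pytest.approx(-rx)


class TestLatentSignals:
    def test_spectral_containment(self):
        rng = np.random.default_rng(3)
        sig = band_limited_noise(rng, 50, 185, 2.0)
        spec = np.abs(np.fft.rfft(sig, axis=-1)) ** 2
        freqs = np.fft.rfftfreq(185, d=2.0)
        in_band = (freqs >= 0.01) & (freqs <= 0.08)
        assert spec[:, ~in_band].sum() < 0.01 * spec.sum()

    @pytest.mark.parametrize("T", [185, 2000])
    def test_latent_cross_correlation_recovers_rho_lr(self, atlas, T):
        spec = GroupSimSpec(rho_lr=0.4, volumes_per_run=T, runs_per_subject=1,
                            rng_seed=21)
        run = simulate_subject(atlas, spec, 0)[0]
        # hemisphere latents are recovered by averaging each ROI's voxels
        left = run.data[atlas.left_roi.data].mean(axis=0)
        right = run.data[atlas.right_roi.data].mean(axis=0)
        lf = bandpass_array(left[None], 2.0, 0.01, 0.08)[0]
        rf = bandpass_array(right[None], 2.0, 0.01, 0.08)[0]
        r = np.corrcoef(lf, rf)[0, 1]
        # ROI averaging attenuates slightly: corr(seed_L, seed_R) =
        # rho_lr * rho_L * rho_R / var(seed) under the variance decomposition
        from hippofc.preprocessing import band_dof

        m = atlas.left_roi.n_voxels
        nf = spec.noise_sd**2 * band_dof(T, 2.0) / T
        var_seed = spec.rho_ipsi_left**2 + ((1 - spec.rho_ipsi_left**2) + nf) / m
        expected = spec.rho_lr * spec.rho_ipsi_left * spec.rho_ipsi_right / var_seed
        assert abs(r - expected) < 3 / np.sqrt(T) + 0.05


class TestSimulateSubject:
    def test_deterministic_given_seed(self, atlas):
        spec = tiny_group_spec()
        a = simulate_subject(atlas, spec, 0)
        b = simulate_subject(atlas, spec, 0)
        np.testing.assert_array_equal(a[0].data, b[0].data)

    def test_different_subjects_differ(self, atlas):
        spec = tiny_group_spec()
        a = simulate_subject(atlas, spec, 0)
        b = simulate_subject(atlas, spec, 1)
        assert not np.array_equal(a[0].data, b[0].data)

    def test_null_coupling_gives_zero_mean_correlation(self, atlas):
        spec = GroupSimSpec(rho_ipsi_left=0.0, rho_ipsi_right=0.0, rho_lr=0.0,
                            runs_per_subject=1, rng_seed=5)
        run = preprocess(simulate_subject(atlas, spec, 0)[0],
                         PreprocessConfig(fwhm_mm=0.0))
        seed = conn.extract_seed(run, atlas.left_roi)
        cmap = conn.correlation_map(run, seed, brain_mask=atlas.brain)
        mean_r = np.nanmean(cmap.r[atlas.network_mask("left")])
        assert abs(mean_r) < 3 / np.sqrt(180)

    def test_mean_network_correlation_matches_closed_form(self, atlas):
        # the variance-decomposition oracle at rho=0.7, 10 runs of T=180
        spec = GroupSimSpec(rho_ipsi_left=0.7, rho_ipsi_right=0.7,
                            runs_per_subject=10, rng_seed=7)
        runs = [preprocess(r, PreprocessConfig(fwhm_mm=0.0))
                for r in simulate_subject(atlas, spec, 0)]
        rs = []
        for run in runs:
            seed = conn.extract_seed(run, atlas.left_roi)
            cmap = conn.correlation_map(run, seed, brain_mask=atlas.brain)
            rs.append(np.nanmean(cmap.r[atlas.network_mask("left")]))
        expected = expected_network_correlation(
            0.7, atlas.left_roi.n_voxels, spec.noise_sd, 180
        )
        assert np.mean(rs) == pytest.approx(expected, abs=0.05)

    def test_seed_beats_single_voxels(self, atlas):
        # averaging the ROI suppresses idiosyncratic noise, so the seed
        # correlates with network voxels better than single voxels do
        spec = GroupSimSpec(rho_ipsi_left=0.7, rho_ipsi_right=0.7,
                            runs_per_subject=2, rng_seed=13)
        runs = [preprocess(r, PreprocessConfig(fwhm_mm=0.0))
                for r in simulate_subject(atlas, spec, 0)]
        net = atlas.network_mask("left")
        seed_rs, voxel_rs = [], []
        for run in runs:
            seed = conn.extract_seed(run, atlas.left_roi)
            cmap = conn.correlation_map(run, seed, brain_mask=atlas.brain)
            seed_rs.append(np.nanmean(cmap.r[net]))
            one_vox = run.data[atlas.spec.roi_centers[0]]
            single = conn.SeedSeries("left", one_vox)
            cmap1 = conn.correlation_map(run, single, brain_mask=atlas.brain)
            voxel_rs.append(np.nanmean(cmap1.r[net]))
        assert np.mean(seed_rs) > np.mean(voxel_rs)

    def test_grid_mismatch_rejected(self, atlas, small_atlas):
        spec = tiny_group_spec()
        runs = simulate_subject(atlas, spec, 0)
        with pytest.raises(ValueError, match="grid"):
            conn.extract_seed(runs[0], small_atlas.left_roi)


class TestSimulateCohort:
    def test_file_count_and_manifest(self, small_atlas, tmp_path):
        specs = [tiny_group_spec(group_label=g, volumes_per_run=20)
                 for g in ("control", "right_mtle", "left_mtle")]
        manifest = simulate_cohort(small_atlas, specs, tmp_path)
        assert len(manifest) == 3 * 2 * 1
        for p in manifest.path:
            assert (tmp_path / p).exists()

    def test_empty_spec_list(self, small_atlas, tmp_path):
        manifest = simulate_cohort(small_atlas, [], tmp_path)
        assert len(manifest) == 0
        assert not list(tmp_path.glob("*.nii.gz"))

    def test_rerun_reproduces_identical_checksums(self, small_atlas, tmp_path):
        spec = tiny_group_spec(n_subjects=1, volumes_per_run=20)
        m1 = simulate_cohort(small_atlas, [spec], tmp_path / "a")
        m2 = simulate_cohort(small_atlas, [spec], tmp_path / "b")
        for p1, p2 in zip(m1.path, m2.path):
            assert file_checksum(tmp_path / "a" / p1) == file_checksum(tmp_path / "b" / p2)

    def test_manifest_round_trips(self, small_atlas, tmp_path):
        import pandas as pd

        spec = tiny_group_spec(n_subjects=1, volumes_per_run=20)
        manifest = simulate_cohort(small_atlas, [spec], tmp_path)
        back = pd.read_csv(tmp_path / "manifest.tsv", sep="\t")
        pd.testing.assert_frame_equal(manifest, back)


class TestSimulateVolumetry:
    def test_zero_sd_collapses_to_group_means(self):
        params = {"control": {"vlh": (4000.0, 0.0), "vrh": (5000.0, 0.0)}}
        table = simulate_volumetry(params, n_per_group=4, rng_seed=0)
        assert (table.vlh_mm3 == 4000).all() and (table.vrh_mm3 == 5000).all()
        assert table.qai.unique() == pytest.approx([1 - 4000 / 5000])

    def test_sample_means_near_published_parameters(self):
        table = simulate_volumetry(n_per_group=9, rng_seed=123)
        for group, params in TABLE1_GROUP_PARAMS.items():
            sub = table[table.group == group]
            for col, (mean, sd) in (("vlh_mm3", params["vlh"]), ("vrh_mm3", params["vrh"])):
                assert abs(sub[col].mean() - mean) < 3 * sd / np.sqrt(9)

    def test_large_sample_preserves_atrophy_sign(self):
        # control right volume exceeds right-MTLE right volume
        table = simulate_volumetry(n_per_group=1000, rng_seed=99)
        res = stats.ttest_ind(
            table.query("group == 'control'").vrh_mm3,
            table.query("group == 'right_mtle'").vrh_mm3,
        )
        assert res.statistic > 0

    def test_nonpositive_n_rejected(self):
        with pytest.raises(ValueError):
            simulate_volumetry(n_per_group=0)

    def test_volumes_positive(self):
        params = {"g": {"vlh": (50.0, 200.0), "vrh": (50.0, 200.0)}}
        table = simulate_volumetry(params, n_per_group=50, rng_seed=1)
        assert (table.vlh_mm3 > 0).all() and (table.vrh_mm3 > 0).all()
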