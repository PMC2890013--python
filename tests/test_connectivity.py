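"""Seed extraction, correlation mapping, r->t->z transformations."""

import numpy as np
import pytest
from scipy import stats

from hippofc import connectivity as conn
from hippofc.images import ROIMask, VolumeSeries
from hippofc.preprocessing import PreprocessConfig, preprocess
from hippofc.synthetic import simulate_subject

from conftest import pearson_oracle, tiny_group_spec

AFFINE = np.diag([2.0, 2.0, 2.0, 1.0])


def make_series(data):
    return VolumeSeries(np.asarray(data, dtype=float), AFFINE, 2.0)


@pytest.fixture
def toy_series():
    rng = np.random.default_rng(8)
    return make_series(rng.standard_normal((5, 5, 3, 40)))


def single_voxel_mask(shape, voxel):
    m = np.zeros(shape, dtype=bool)
    m[voxel] = True
    return ROIMask(m, AFFINE, "left")


class TestExtractSeed:
    def test_single_voxel_mask_returns_that_series(self, toy_series):
        mask = single_voxel_mask(toy_series.shape[:3], (1, 2, 0))
        seed = conn.extract_seed(toy_series, mask)
        np.testing.assert_allclose(seed.values, toy_series.data[1, 2, 0])

    def test_identical_voxels_average_to_same_series(self):
        x = np.sin(np.arange(30))
        data = np.broadcast_to(x, (4, 4, 2, 30)).copy()
        m = np.zeros((4, 4, 2), dtype=bool)
        m[:2, :2, 0] = True
        seed = conn.extract_seed(make_series(data), ROIMask(m, AFFINE))
        np.testing.assert_allclose(seed.values, x)

    def test_empty_mask_rejected(self, toy_series):
        empty = ROIMask(np.zeros(toy_series.shape[:3], dtype=bool), AFFINE)
        with pytest.raises(ValueError, match="empty"):
            conn.extract_seed(toy_series, empty)


class TestCorrelationMap:
    def test_voxel_equal_to_seed_has_r_one(self, toy_series):
        mask = single_voxel_mask(toy_series.shape[:3], (0, 0, 0))
        seed = conn.extract_seed(toy_series, mask)
        cmap = conn.correlation_map(toy_series, seed)
        assert cmap.r[0, 0, 0] == pytest.approx(1.0)

    def test_negated_seed_has_r_minus_one(self, toy_series):
        data = toy_series.data.copy()
        data[1, 1, 1] = -data[0, 0, 0]
        series = make_series(data)
        seed = conn.extract_seed(series, single_voxel_mask(series.shape[:3], (0, 0, 0)))
        cmap = conn.correlation_map(series, seed)
        assert cmap.r[1, 1, 1] == pytest.approx(-1.0)

    def test_matches_textbook_pearson(self):
        rng = np.random.default_rng(12)
        data = rng.standard_normal((3, 3, 2, 20))
        series = make_series(data)
        seed = conn.SeedSeries("left", rng.standard_normal(20))
        cmap = conn.correlation_map(series, seed)
        for idx in [(0, 0, 0), (1, 2, 1), (2, 2, 0)]:
            ref = pearson_oracle(data[idx], seed.values)
            assert cmap.r[idx] == pytest.approx(ref, abs=1e-12)

    def test_zero_variance_voxel_is_undefined(self, toy_series):
        data = toy_series.data.copy()
        data[2, 2, 2] = 5.0
        series = make_series(data)
        seed = conn.extract_seed(series, single_voxel_mask(series.shape[:3], (0, 0, 0)))
        cmap = conn.correlation_map(series, seed)
        assert np.isnan(cmap.r[2, 2, 2])

    def test_length_mismatch_rejected(self, toy_series):
        seed = conn.SeedSeries("left", np.zeros(10) + np.arange(10))
        with pytest.raises(ValueError, match="length mismatch"):
            conn.correlation_map(toy_series, seed)


class TestRToT:
    def test_zero_r_maps_to_zero(self):
        for n in (3, 50, 180):
            assert conn.r_to_t(0.0, n) == 0.0

    def test_closed_form_value(self):
        # r=0.5, n=180: t = 0.5*sqrt(178)/sqrt(0.75) = 7.7028
        expected = 0.5 * np.sqrt(178) / np.sqrt(0.75)
        assert conn.r_to_t(0.5, 180) == pytest.approx(expected, rel=1e-12)
        assert conn.r_to_t(0.5, 180) == pytest.approx(7.703, abs=5e-4)

    def test_monotone_in_r(self):
        rs = np.linspace(-0.99, 0.99, 101)
        ts = conn.r_to_t(rs, 60)
        assert np.all(np.diff(ts) > 0)

    def test_p_value_equivalence_with_correlation_test(self):
        # the t CDF at df=n-2 reproduces the standard correlation test p
        rng = np.random.default_rng(4)
        for _ in range(20):
            x, y = rng.standard_normal((2, 25))
            r, p_ref = stats.pearsonr(x, y)
            t = conn.r_to_t(r, 25)
            p = 2 * stats.t.sf(abs(t), 23)
            assert p == pytest.approx(p_ref, rel=1e-9)

    def test_saturated_r_gives_sentinel_with_warning(self):
        with pytest.warns(RuntimeWarning):
            t = conn.r_to_t(1.0, 10)
        assert t == conn.T_SENTINEL

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            conn.r_to_t(0.5, 2)


class TestPositiveThreshold:
    def _map(self, r_values):
        r = np.array(r_values, dtype=float).reshape(-1, 1, 1)
        return conn.CorrelationMap(r=r, n=180, affine=AFFINE)

    def test_all_negative_becomes_zero(self):
        out = conn.apply_positive_threshold(self._map([-0.5, -0.1, -0.9]))
        assert np.all(out.r == 0)

    def test_r_cutoff_matches_cdf_inversion(self):
        cut = conn.r_cutoff_for_p(1e-4, 180)
        # pushing the cutoff back through r->t->p recovers 1e-4
        t = conn.r_to_t(cut, 180)
        assert stats.t.sf(t, 178) == pytest.approx(1e-4, rel=1e-9)
        out = conn.apply_positive_threshold(self._map([0.1]), hard=True)
        assert out.r_threshold == pytest.approx(cut)

    def test_hard_threshold_keeps_only_significant(self):
        cut = conn.r_cutoff_for_p(1e-4, 180)
        out = conn.apply_positive_threshold(
            self._map([cut + 0.01, cut - 0.01, -0.3]), hard=True
        )
        assert out.r.ravel().tolist() == pytest.approx([cut + 0.01, 0.0, 0.0])

    def test_idempotent(self):
        m = self._map([0.4, -0.2, 0.05])
        once = conn.apply_positive_threshold(m, hard=True)
        twice = conn.apply_positive_threshold(once, hard=True)
        np.testing.assert_array_equal(once.r, twice.r)


class TestToZ:
    def test_fisher_closed_form(self):
        cmap = conn.CorrelationMap(r=np.array([[[0.5]]]), n=180, affine=AFFINE)
        out = conn.to_z(cmap, "fisher_r")
        assert out.z[0, 0, 0] == pytest.approx(0.5493, abs=5e-5)

    def test_zero_r_is_zero_z_under_both_methods(self):
        cmap = conn.CorrelationMap(r=np.array([[[0.0]]]), n=180, affine=AFFINE)
        for method in ("fisher_r", "t_to_normal"):
            assert conn.to_z(cmap, method).z[0, 0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_methods_agree_in_rank_order(self):
        rng = np.random.default_rng(2)
        # moderate |r| keeps the Gaussianized variant away from its +/-8
        # clipping range, where ties would break exact rank agreement
        r = rng.uniform(-0.55, 0.55, size=(4, 4, 2))
        cmap = conn.CorrelationMap(r=r, n=120, affine=AFFINE)
        za = conn.to_z(cmap, "fisher_r").z.ravel()
        zb = conn.to_z(cmap, "t_to_normal").z.ravel()
        rho = stats.spearmanr(za, zb).statistic
        assert rho == pytest.approx(1.0)

    def test_unknown_method_rejected(self):
        cmap = conn.CorrelationMap(r=np.zeros((2, 2, 2)), n=30, affine=AFFINE)
        with pytest.raises(ValueError, match="unknown z method"):
            conn.to_z(cmap, "zscore")


class TestSubjectMap:
    def test_single_run_equals_that_runs_z_map(self, toy_series):
        mask = single_voxel_mask(toy_series.shape[:3], (0, 0, 0))
        smap = conn.subject_map([toy_series], mask)
        seed = conn.extract_seed(toy_series, mask)
        cmap = conn.to_z(
            conn.apply_positive_threshold(conn.correlation_map(toy_series, seed))
        )
        np.testing.assert_allclose(smap.z, cmap.z)

    def test_duplicated_run_identical_to_single(self, toy_series):
        mask = single_voxel_mask(toy_series.shape[:3], (0, 0, 0))
        one = conn.subject_map([toy_series], mask)
        two = conn.subject_map([toy_series, toy_series], mask)
        np.testing.assert_allclose(one.z, two.z)

    def test_no_runs_rejected(self, toy_series):
        mask = single_voxel_mask(toy_series.shape[:3], (0, 0, 0))
        with pytest.raises(ValueError, match="at least one run"):
            conn.subject_map([], mask)

    def test_seed_self_consistency(self, atlas):
        # correlating the seed with the mask-average returns r=1 regardless
        # of aggregation settings
        spec = tiny_group_spec()
        run = preprocess(simulate_subject(atlas, spec, 0)[0], PreprocessConfig())
        for aggregation in ("mean_z", "concatenate"):
            smap = conn.subject_map([run], atlas.left_roi, brain_mask=atlas.brain,
                                    aggregation=aggregation)
            seed = conn.extract_seed(run, atlas.left_roi)
            cmap = conn.correlation_map(run, seed, brain_mask=atlas.brain)
            assert np.nanmax(cmap.r) <= 1.0
            r_seed = pearson_oracle(seed.values, run.data[atlas.left_roi.data].mean(axis=0))
            assert r_seed == pytest.approx(1.0)

    def test_monotone_chain_preserves_ranking(self, toy_series):
        mask = single_voxel_mask(toy_series.shape[:3], (0, 0, 0))
        seed = conn.extract_seed(toy_series, mask)
        cmap = conn.to_z(conn.correlation_map(toy_series, seed))
        r, t, z = cmap.r.ravel(), cmap.t.ravel(), cmap.z.ravel()
        order = np.argsort(r)
        assert np.all(np.diff(t[order]) >= 0)
        assert np.all(np.diff(z[order]) >= 0)

    def test_mirror_property(self, atlas):
        # flipping volumes and masks across the midline flips the map exactly
        spec = tiny_group_spec(volumes_per_run=53)
        raw = simulate_subject(atlas, spec, 0)[0]
        raw_flipped = VolumeSeries(raw.data[::-1].copy(), raw.affine, raw.tr_s)
        run = preprocess(raw, PreprocessConfig())
        flipped = preprocess(raw_flipped, PreprocessConfig())
        mask_f = ROIMask(atlas.left_roi.data[::-1].copy(), atlas.affine, "right")
        brain_f = ROIMask(atlas.brain.data[::-1].copy(), atlas.affine, "brain")
        orig = conn.subject_map([run], atlas.left_roi, brain_mask=atlas.brain)
        mirr = conn.subject_map([flipped], mask_f, brain_mask=brain_f)
        np.testing.assert_allclose(mirr.z[::-1], orig.z, atol=1e-10, equal_nan=True)
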