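import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

from aphasiamap import (
    StatMap,
    fwe_cluster_correction,
    threshold_and_cluster,
    voxelwise_glm,
)


def _lesion_array(masks):
    return np.asarray(masks, dtype=bool)


class TestVoxelwiseGLM:
    def test_constant_outcome_gives_zero_t(self, rng):
        L = rng.random((12, 3, 3, 3)) > 0.5
        smap = voxelwise_glm(L, np.full(12, 5.0), min_coverage=1)
        assert np.all(smap.t[smap.analysis_mask] == 0.0)

    def test_perfect_fit_reported_as_infinite_with_flag(self):
        L = np.zeros((8, 1, 1, 1), bool)
        L[:4] = True
        y = -10.0 * L[:, 0, 0, 0]
        smap = voxelwise_glm(L, y, min_coverage=1)
        assert np.isinf(smap.t[0, 0, 0])
        assert smap.perfect_fit[0, 0, 0]

    def test_equals_two_sample_t_on_single_voxel(self):
        # GLM lesion-term t == classical pooled-variance two-sample t
        L = np.zeros((8, 1, 1, 1), bool)
        L[:4] = True
        y = np.array([1, 2, 1, 2, 5, 6, 5, 6], dtype=float)
        smap = voxelwise_glm(L, y, min_coverage=1)
        expected = stats.ttest_ind(y[:4], y[4:]).statistic  # -4*sqrt(6)
        assert np.isclose(smap.t[0, 0, 0], expected, atol=1e-10)
        assert np.isclose(smap.t[0, 0, 0], -4.0 * np.sqrt(6.0), atol=1e-10)
        assert smap.df == 6

    def test_matches_per_voxel_regression_oracle(self, rng):
        # brute-force statsmodels OLS voxel by voxel on a <=100-voxel grid
        n, shape = 30, (4, 5, 5)
        L = rng.random((n,) + shape) > 0.5
        y = rng.normal(size=n)
        cov = rng.normal(size=(n, 2))
        smap = voxelwise_glm(L, y, covariates=cov, min_coverage=3)
        flat = L.reshape(n, -1)
        for v in np.flatnonzero(smap.analysis_mask.ravel()):
            X = sm.add_constant(np.column_stack([flat[:, v], cov]))
            res = sm.OLS(y, X).fit()
            assert abs(smap.t.ravel()[v] - res.tvalues[1]) < 1e-8

    def test_min_coverage_monotonicity(self, small_cohort, rng):
        y = rng.normal(size=len(small_cohort.lesions))
        sizes = []
        for cov in (2, 4, 8):
            smap = voxelwise_glm(small_cohort.lesions, y, min_coverage=cov)
            sizes.append(smap.analysis_mask.sum())
        assert sizes[0] >= sizes[1] >= sizes[2]

    def test_rank_deficient_covariates_rejected(self, rng):
        L = rng.random((20, 3, 3, 3)) > 0.5
        cov = np.ones((20, 2))
        with pytest.raises(ValueError, match="rank"):
            voxelwise_glm(L, rng.normal(size=20), covariates=cov, min_coverage=2)

    def test_empty_analysis_mask_rejected(self):
        L = np.zeros((10, 2, 2, 2), bool)  # nothing lesioned anywhere
        with pytest.raises(ValueError, match="empty"):
            voxelwise_glm(L, np.arange(10.0), min_coverage=1)


class TestThresholdAndCluster:
    def _statmap(self, t, df=30):
        mask = np.isfinite(t)
        return StatMap(t=t, df=df, analysis_mask=mask,
                       perfect_fit=np.zeros_like(mask))

    def test_all_zero_t_gives_no_clusters(self):
        cs = threshold_and_cluster(self._statmap(np.zeros((5, 5, 5))))
        assert len(cs) == 0

    def test_single_block_one_cluster_extent_27(self):
        t = np.zeros((7, 7, 7))
        t[2:5, 2:5, 2:5] = -10.0
        cs = threshold_and_cluster(self._statmap(t))
        assert len(cs) == 1 and cs.clusters[0].extent == 27

    def test_corner_touch_connectivity_contract(self):
        t = np.zeros((4, 4, 4))
        t[1, 1, 1] = -10.0
        t[2, 2, 2] = -10.0  # touch only at a corner
        c26 = threshold_and_cluster(self._statmap(t), connectivity=26)
        c6 = threshold_and_cluster(self._statmap(t), connectivity=6)
        assert len(c26) == 1 and len(c6) == 2

    def test_deficit_tail_keeps_negative_t_only(self):
        t = np.zeros((3, 3, 3))
        t[0, 0, 0] = -10.0
        t[2, 2, 2] = 10.0
        cs = threshold_and_cluster(self._statmap(t), tail="deficit")
        assert len(cs) == 1 and cs.clusters[0].peak_t == -10.0
        both = threshold_and_cluster(self._statmap(t), tail="two")
        assert len(both) == 2


class TestFWECorrection:
    def test_observed_above_all_nulls_gives_minimal_p(self, small_cohort):
        # a strong planted effect beats every permutation
        damage = small_cohort.damage.iloc[:, 0].to_numpy()
        y = -damage
        cs = fwe_cluster_correction(
            small_cohort.lesions, y, n_perm=100, rng_seed=0, min_coverage=4
        )
        assert min(c.fwe_p for c in cs.clusters) == pytest.approx(1 / 101)

    def test_permutation_p_formula_upper_extreme(self, rng):
        # outcome independent of lesions: every cluster p is (b+1)/(n_perm+1)
        L = rng.random((24, 6, 6, 6)) > 0.5
        y = rng.normal(size=24)
        cs = fwe_cluster_correction(L, y, n_perm=100, rng_seed=1, min_coverage=3)
        for c in cs.clusters:
            b = int(np.sum(cs.null_max_extent >= c.extent))
            assert c.fwe_p == pytest.approx((b + 1) / 101)

    def test_seed_reproducibility(self, small_cohort):
        y = small_cohort.behaviour.iloc[:, 0].to_numpy()
        a = fwe_cluster_correction(
            small_cohort.lesions, y, n_perm=100, rng_seed=5, min_coverage=4
        )
        b = fwe_cluster_correction(
            small_cohort.lesions, y, n_perm=100, rng_seed=5, min_coverage=4
        )
        assert np.array_equal(a.null_max_extent, b.null_max_extent)
        assert [c.fwe_p for c in a.clusters] == [c.fwe_p for c in b.clusters]

    def test_low_n_perm_warns(self, small_cohort):
        y = small_cohort.behaviour.iloc[:, 0].to_numpy()
        with pytest.warns(UserWarning, match="resolve"):
            fwe_cluster_correction(
                small_cohort.lesions, y, n_perm=100,
                alpha=0.005, rng_seed=0, min_coverage=4,
            )

    def test_relabelling_patients_preserves_null_distribution(self, small_cohort, rng):
        # exchangeability: permuting patient order leaves the null family unchanged
        y = rng.normal(size=len(small_cohort.lesions))
        a = fwe_cluster_correction(
            small_cohort.lesions, y, n_perm=200, rng_seed=3, min_coverage=4
        )
        order = rng.permutation(len(y))
        b = fwe_cluster_correction(
            small_cohort.lesions.subset(order), y[order], n_perm=200, rng_seed=3,
            min_coverage=4,
        )
        # same null distribution up to Monte-Carlo noise: compare upper quantiles
        qa = np.quantile(a.null_max_extent, [0.5, 0.9, 0.95])
        qb = np.quantile(b.null_max_extent, [0.5, 0.9, 0.95])
        assert np.all(np.abs(qa - qb) <= np.maximum(3.0, 0.5 * qa))
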