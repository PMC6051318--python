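import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

from aphasiamap import (
    assign_subtype,
    default_subtype_rules,
    generate_cohort,
    grow_lesion,
    make_hemisphere_mask,
)

GRID = (20, 24, 20)


class TestGrowLesion:
    def setup_method(self):
        self.hemi = make_hemisphere_mask(GRID)
        self.seed = tuple(np.argwhere(self.hemi.data)[100])

    def test_volume_one_is_just_the_seed(self):
        m = grow_lesion(self.seed, 1, self.hemi, rng=0)
        assert m.sum() == 1 and m[self.seed]

    def test_saturation_returns_whole_mask(self):
        total = int(self.hemi.data.sum())
        m = grow_lesion(self.seed, total, self.hemi, rng=0)
        assert np.array_equal(m, self.hemi.data)

    def test_exact_volume_and_connectedness_over_many_draws(self):
        struct = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
        for draw in range(100):
            m = grow_lesion(self.seed, 500, self.hemi, rng=draw)
            assert m.sum() == 500
            _, ncomp = ndimage.label(m, structure=struct)
            assert ncomp == 1
            assert not np.any(m & ~self.hemi.data)

    def test_seed_outside_mask_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            grow_lesion((0, 0, 0), 10, self.hemi, rng=0)

    def test_oversized_target_rejected(self):
        with pytest.raises(ValueError, match="target_volume"):
            grow_lesion(self.seed, int(self.hemi.data.sum()) + 1, self.hemi, rng=0)


class TestAssignSubtype:
    def test_no_damage_is_least_severe_and_fluent(self):
        rules = default_subtype_rules(3)
        label, fluent = assign_subtype([0, 0, 0], rules)
        assert label == "anomia" and fluent

    def test_total_damage_is_most_severe_and_nonfluent(self):
        rules = default_subtype_rules(3)
        label, fluent = assign_subtype([100, 100, 100], rules)
        assert label == "global" and not fluent

    @pytest.mark.parametrize("k", [1, 2, 3, 4])
    def test_cube_vertices_reproduce_rule_table(self, k):
        rules = default_subtype_rules(k)
        for bits in np.ndindex(*(2,) * k):
            vec = [100.0 if b else 0.0 for b in bits]
            label, fluent = assign_subtype(vec, rules)
            assert label == rules.table[tuple(bits)]
            assert fluent == (label in rules.fluent_labels)

    def test_out_of_range_damage_rejected(self):
        rules = default_subtype_rules(3)
        with pytest.raises(ValueError):
            assign_subtype([0, 101, 0], rules)


class TestGenerateCohort:
    def test_identical_seeds_give_bit_identical_cohorts(self):
        a = generate_cohort(n=8, grid_shape=GRID, rng_seed=3)
        b = generate_cohort(n=8, grid_shape=GRID, rng_seed=3)
        assert np.array_equal(a.lesions.masks, b.lesions.masks)
        pd.testing.assert_frame_equal(a.behaviour, b.behaviour)
        pd.testing.assert_frame_equal(a.demographics, b.demographics)
        assert (a.subtype == b.subtype).all()

    def test_no_damage_no_noise_gives_perfect_scores(self, small_cohort):
        truth = small_cohort.truth
        lam = truth.loading_matrix
        damage = np.zeros((5, truth.n_factors))
        intact = 1.0 - damage / 100.0
        base = 100.0 * (intact @ lam.T) / lam.sum(axis=1)
        assert np.allclose(base, 100.0)

    def test_total_damage_no_noise_gives_zero_scores(self, small_cohort):
        truth = small_cohort.truth
        lam = truth.loading_matrix
        damage = np.full((5, truth.n_factors), 100.0)
        base = 100.0 * ((1.0 - damage / 100.0) @ lam.T) / lam.sum(axis=1)
        assert np.allclose(base, 0.0)

    def test_scores_deterministic_function_of_damage_when_noise_free(self):
        c = generate_cohort(n=12, grid_shape=GRID, rng_seed=9, noise_sd=0.0,
                            age_coef=0.0)
        lam = c.truth.loading_matrix
        expected = np.clip(
            100.0 * ((1.0 - c.damage.to_numpy() / 100.0) @ lam.T) / lam.sum(axis=1),
            0.0,
            100.0,
        )
        assert np.allclose(c.behaviour.to_numpy(), expected, atol=1e-10)

    def test_within_factor_correlation_exceeds_between(self):
        c = generate_cohort(n=200, grid_shape=GRID, rng_seed=21, noise_sd=5.0)
        corr = np.corrcoef(c.behaviour.to_numpy().T)
        K = c.truth.n_factors
        groups = [np.arange(t, c.truth.n_tests, K) for t in range(K)]
        within, between = [], []
        T = c.truth.n_tests
        for i in range(T):
            for j in range(i + 1, T):
                same = any(i in g and j in g for g in groups)
                (within if same else between).append(corr[i, j])
        assert np.mean(within) > np.mean(between)

    def test_lesions_inside_hemisphere_and_scores_bounded(self, small_cohort):
        hemi = small_cohort.truth.hemisphere.data
        assert not np.any(small_cohort.lesions.masks & ~hemi)
        vals = small_cohort.behaviour.to_numpy()
        assert vals.min() >= 0.0 and vals.max() <= 100.0

    def test_fluency_flag_matches_label_partition(self, medium_cohort):
        fluent_labels = medium_cohort.truth.subtype_rules.fluent_labels
        expected = medium_cohort.subtype.isin(fluent_labels)
        assert (medium_cohort.fluency == expected).all()

    def test_lesion_volume_calibration(self):
        # sampled volumes should match the requested log-normal mean within 10%
        c = generate_cohort(n=120, grid_shape=GRID, rng_seed=2)
        hemi_size = int(c.truth.hemisphere.data.sum())
        rng = np.random.default_rng(123)
        frac = np.exp(rng.normal(np.log(0.12), 1.0, size=200_000))
        frac = np.clip(frac, 0.005, 0.7)
        expected_mean = frac.mean() * hemi_size
        observed_mean = c.lesions.volumes().mean()
        assert abs(observed_mean - expected_mean) / expected_mean < 0.10

    def test_nonpositive_dimensions_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(n=0, grid_shape=GRID)

    def test_ground_truth_regions_disjoint_nonempty(self, small_cohort):
        flat = small_cohort.truth.region_masks.reshape(
            small_cohort.truth.n_factors, -1
        )
        assert np.all(flat.sum(axis=1) > 0)
        assert flat.sum(axis=0).max() <= 1

    def test_write_round_trip(self, tmp_path):
        from aphasiamap import read_cohort, read_mask_stack

        c = generate_cohort(n=4, grid_shape=GRID, rng_seed=1)
        c.write(tmp_path)
        stack = read_mask_stack(sorted((tmp_path / "lesions").glob("*.nii.gz")))
        assert len(stack) == 4
        assert stack.masks.sum() == c.lesions.masks.sum()
        table = read_cohort(tmp_path / "cohort.csv")
        assert table.n == 4 and len(table.test_columns) == c.truth.n_tests
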