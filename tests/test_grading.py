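import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from headgrade.grading import (MERGED_STANDARD, ORIGINAL_STANDARD, PSOConfig,
                               assign_level, between_class_variance,
                               grade_pipeline, grading_accuracy,
                               otsu_threshold, population_yellowness,
                               pso_threshold, yellow_discriminant,
                               yellow_fraction)
from headgrade.synthetic import SceneParams, generate_scene


def random_histogram_values(rng):
    """Random bimodal-ish gray-value sample in [0, 255]."""
    n1, n2 = int(rng.integers(20, 200)), int(rng.integers(20, 200))
    c1, c2 = rng.integers(0, 256, size=2)
    v = np.concatenate([
        np.clip(rng.normal(c1, rng.uniform(1, 30), n1), 0, 255),
        np.clip(rng.normal(c2, rng.uniform(1, 30), n2), 0, 255),
    ])
    v = np.rint(v).astype(int)
    if np.unique(v).size < 2:
        v[0] = (v[0] + 128) % 256
    return v


class TestDiscriminant:
    def test_green_yellow_blue_ordering(self):
        img = np.zeros((1, 3, 3), dtype=np.uint8)
        img[0, 0] = (0, 255, 0)    # green
        img[0, 1] = (255, 255, 0)  # yellow
        img[0, 2] = (0, 0, 255)    # blue
        g = yellow_discriminant(img, np.ones((1, 3), dtype=np.uint8))
        assert list(g) == [191, 255, 0]

    def test_gray_pixels_map_to_midpoint(self):
        for c in (0, 77, 128, 255):
            img = np.full((2, 2, 3), c, dtype=np.uint8)
            g = yellow_discriminant(img, np.ones((2, 2), dtype=np.uint8))
            assert (g == 128).all()

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            yellow_discriminant(np.zeros((2, 2, 3), dtype=np.uint8),
                                np.zeros((2, 2), dtype=np.uint8))


class TestOtsu:
    def test_bimodal_split_partitions_classes(self):
        v = np.array([50] * 60 + [200] * 40)
        t = otsu_threshold(v)
        assert 50 <= t < 200
        assert (v[v <= t] == 50).all() and (v[v > t] == 200).all()

    def test_two_point_case(self):
        v = np.array([0, 255] * 10)
        t = otsu_threshold(v)
        assert 0 <= t < 255

    def test_shift_equivariance(self):
        rng = np.random.default_rng(0)
        v = np.rint(rng.uniform(30, 180, 200)).astype(int)
        t = otsu_threshold(v)
        for c in (5, 20, 60):
            assert otsu_threshold(v + c) == t + c

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            otsu_threshold(np.full(50, 128))


class TestPso:
    def test_matches_exhaustive_otsu_fitness_on_100_histograms(self):
        rng = np.random.default_rng(42)
        for i in range(100):
            v = random_histogram_values(rng)
            t_exh = otsu_threshold(v)
            t_pso = pso_threshold(v, PSOConfig(seed=i))
            assert between_class_variance(v, t_pso) == \
                pytest.approx(between_class_variance(v, t_exh), abs=1e-9)

    def test_bimodal_same_partition_as_otsu(self):
        v = np.array([50] * 60 + [200] * 40)
        t = pso_threshold(v, PSOConfig(seed=0))
        assert 50 <= t < 200

    def test_deterministic_per_seed(self):
        v = random_histogram_values(np.random.default_rng(1))
        assert pso_threshold(v, PSOConfig(seed=9)) == \
            pso_threshold(v, PSOConfig(seed=9))


class TestYellowFraction:
    def test_limits(self):
        assert yellow_fraction(np.array([10, 20, 30]), 40) == 0.0
        assert yellow_fraction(np.array([100, 200]), 50) == 1.0

    def test_counting(self):
        v = np.array([200] * 12 + [50] * 88)
        assert yellow_fraction(v, 128) == pytest.approx(0.12)


class TestAssignLevel:
    def test_merged_table_boundaries(self):
        assert assign_level(0.0, "merged") == 0
        assert assign_level(0.009, "merged") == 1
        assert assign_level(0.01, "merged") == 2
        assert assign_level(0.049, "merged") == 2
        assert assign_level(0.05, "merged") == 3
        assert assign_level(0.10, "merged") == 3  # level 4 starts strictly above 10%
        assert assign_level(0.101, "merged") == 4

    def test_merged_examples(self):
        assert assign_level(0.03, "merged") == 2
        assert assign_level(0.07, "merged") == 3
        assert assign_level(0.12, "merged") == 4

    def test_original_five_percent_is_level_3(self):
        assert assign_level(0.05, "original") == 3

    def test_zero_is_level_zero_in_both(self):
        assert assign_level(0.0, "merged") == 0
        assert assign_level(0.0, "original") == 0

    def test_original_scale_coverage(self):
        assert assign_level(0.005, "original") == 1
        assert assign_level(0.5, "original") == 5
        assert assign_level(0.7, "original") == 7
        assert assign_level(1.0, "original") == 9

    def test_monotone_in_fraction(self):
        grid = np.linspace(0, 1, 501)
        for std in ("merged", "original"):
            levels = [assign_level(f, std) for f in grid]
            assert all(a <= b for a, b in zip(levels, levels[1:]))

    @settings(derandomize=True, max_examples=200)
    @given(st.floats(0, 1), st.floats(0, 1))
    def test_monotone_for_arbitrary_fraction_pairs(self, a, b):
        lo, hi = sorted((a, b))
        for std in ("merged", "original"):
            assert assign_level(lo, std) <= assign_level(hi, std)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            assign_level(1.5, "merged")


class TestPopulationYellowness:
    def test_all_highest_level_gives_one(self):
        pop = population_yellowness([4, 4, 4], MERGED_STANDARD)
        assert pop.yellowness_degree == 1.0

    def test_all_level_zero_gives_zero(self):
        pop = population_yellowness([0, 0], ORIGINAL_STANDARD)
        assert pop.yellowness_degree == 0.0

    def test_worked_example(self):
        pop = population_yellowness([2, 2, 0, 0], MERGED_STANDARD)
        assert pop.yellowness_degree == pytest.approx(0.25)

    def test_order_invariance_and_range(self):
        rng = np.random.default_rng(2)
        levels = list(rng.choice(MERGED_STANDARD.levels, size=30))
        a = population_yellowness(levels, "merged").yellowness_degree
        b = population_yellowness(sorted(levels), "merged").yellowness_degree
        assert a == b and 0.0 <= a <= 1.0

    def test_mixed_standard_levels_rejected(self):
        with pytest.raises(ValueError):
            population_yellowness([0, 2, 9], "merged")

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            population_yellowness([], "merged")


class TestGradePipeline:
    def _scene(self, yf, seed):
        return generate_scene(SceneParams(height=96, width=96, n_heads=1,
                                          head_radius_range=(22, 38),
                                          yellow_fraction=yf, seed=seed))

    def test_all_green_head_is_level_zero(self):
        s = self._scene(0.0, seed=11)
        g = grade_pipeline(s.image, s.head_mask, "merged")
        assert g.level == 0 and g.yellow_fraction == 0.0

    def test_seven_percent_yellow_is_level_three(self):
        s = self._scene(0.07, seed=12)
        g = grade_pipeline(s.image, s.head_mask, "merged")
        assert g.level == 3
        assert g.yellow_fraction == pytest.approx(0.07, abs=0.01)

    def test_provenance_fields_present(self):
        s = self._scene(0.15, seed=13)
        g = grade_pipeline(s.image, s.head_mask, "merged")
        assert g.threshold_used is not None
        assert g.standard == "merged"


class TestGradingAccuracy:
    def test_identical_is_one(self):
        assert grading_accuracy([1, 2, 3], [1, 2, 3]) == 1.0

    def test_fully_mismatched_is_zero(self):
        assert grading_accuracy([0, 0], [1, 2]) == 0.0

    def test_counting(self):
        pred = [1] * 7 + [0] * 3
        true = [1] * 10
        assert grading_accuracy(pred, true) == pytest.approx(0.7)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            grading_accuracy([1], [1, 2])
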