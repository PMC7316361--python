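"""Relative activation, baselines, interpolation, initialization slopes."""

import numpy as np
import pytest

from xdream.analysis import (
    fractional_change_stats,
    initialization_slope,
    interpolation_curve,
    is_super_stimulus,
    random_sampling_baseline,
    relative_activation,
)
from xdream.fixtures import ReferenceSet, make_reference_set
from xdream.generators import PixelGenerator
from xdream.targets import MatchedFilterUnit


class TestRelativeActivation:
    def test_best_reference_image_scores_one(self):
        assert relative_activation(40.55, 40.55) == pytest.approx(1.0)

    def test_super_stimulus_ratio(self):
        """An optimized activation of 72.42 against a reference best of
        40.55 gives relative activation ~1.786 — a super stimulus."""
        rel = relative_activation(72.42, 40.55)
        assert rel == pytest.approx(72.42 / 40.55)
        assert rel == pytest.approx(1.786, abs=5e-4)
        assert is_super_stimulus(rel)

    def test_zero_activation_is_not_super(self):
        assert relative_activation(0.0, 5.0) == 0.0
        assert not is_super_stimulus(0.0)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            relative_activation(1.0, 0.0)

    def test_scale_invariance(self, rng):
        """Multiplying all activations by k > 0 leaves ratios unchanged."""
        acts = rng.uniform(0.1, 5.0, 20)
        ref = acts.max()
        for k in (0.5, 3.0):
            assert np.allclose(
                [relative_activation(a, ref) for a in acts],
                [relative_activation(k * a, k * ref) for a in acts],
            )


@pytest.fixture
def value_refset(rng):
    """Reference set whose unit activations are the first-pixel values,
    concentrated so that two groups hold all high activations."""
    images, groups = [], []
    for g in range(10):
        for i in range(20):
            high = g in (0, 1)
            value = rng.uniform(150, 250) if high else rng.uniform(5, 60)
            images.append(np.full((4, 4, 1), int(value), np.uint8))
            groups.append(f"group{g:02d}")
    return ReferenceSet(images=images, groups=groups, seed=0)


class FirstPixelUnit:
    name = "first_pixel"

    def score(self, image):
        return float(np.asarray(image).ravel()[0])


class TestBaselines:
    def test_full_set_sample_yields_exactly_one(self, value_refset):
        curve = random_sampling_baseline(
            FirstPixelUnit(), value_refset, sizes=[len(value_refset)], repeats=5, rng=0
        )
        assert np.all(curve.medians == 1.0)

    def test_medians_non_decreasing_in_sample_size(self, value_refset):
        curve = random_sampling_baseline(
            FirstPixelUnit(), value_refset, sizes=[5, 20, 80, 200], repeats=200, rng=1
        )
        assert np.all(np.diff(curve.medians) >= 0)
        assert np.all(curve.medians <= 1.0)

    def test_matches_bruteforce_resampling_oracle(self, value_refset, rng):
        """Median max relative activation agrees with a direct simulation
        over the same activation values."""
        unit = FirstPixelUnit()
        n = 20
        curve = random_sampling_baseline(
            unit, value_refset, sizes=[n], repeats=400, rng=2
        )
        acts = np.array([unit.score(img) for img in value_refset.images])
        rel = acts / acts.max()
        oracle = np.median(
            [
                rel[rng.choice(rel.size, size=n, replace=False)].max()
                for _ in range(4000)
            ]
        )
        assert curve.medians[0] == pytest.approx(oracle, abs=0.05)

    def test_group_restricted_sampling_underperforms(self, value_refset):
        """When high activations concentrate in few groups, restricting the
        draw to a random subset of groups finds worse best images."""
        unit = FirstPixelUnit()
        n = 100
        unrestricted = random_sampling_baseline(
            unit, value_refset, sizes=[n], scheme="unrestricted", repeats=300, rng=3
        )
        grouped = random_sampling_baseline(
            unit,
            value_refset,
            sizes=[n],
            scheme="grouped",
            n_groups=2,
            repeats=300,
            rng=4,
        )
        # restricting to 2 of 10 groups usually misses both high groups
        assert grouped.medians[0] < unrestricted.medians[0]

    def test_grouped_scheme_needs_enough_groups(self, value_refset):
        with pytest.raises(ValueError, match="groups"):
            random_sampling_baseline(
                FirstPixelUnit(), value_refset, sizes=[10], scheme="grouped", n_groups=99
            )


class TestInterpolationCurve:
    def test_endpoints_reproduce_activations(self, pixel_gen, gabor_unit, rng):
        c1, c2 = rng.uniform(-1, 1, 64), rng.uniform(-1, 1, 64)
        alphas, acts = interpolation_curve(gabor_unit, pixel_gen, c1, c2, n_points=5)
        assert acts[0] == pytest.approx(gabor_unit.score(pixel_gen.generate(c1)))
        assert acts[-1] == pytest.approx(gabor_unit.score(pixel_gen.generate(c2)))

    def test_normalized_curve_is_one_at_endpoints(self, pixel_gen, gabor_unit):
        rng = np.random.default_rng(3)
        # codes near the template so endpoint activations are positive
        base = pixel_gen.encode(gabor_unit.template)
        c1 = np.clip(base + rng.normal(0, 0.1, 64), -1, 1)
        c2 = np.clip(base + rng.normal(0, 0.1, 64), -1, 1)
        _, acts = interpolation_curve(
            gabor_unit, pixel_gen, c1, c2, n_points=7, normalize=True
        )
        assert acts[0] == pytest.approx(1.0)
        assert acts[-1] == pytest.approx(1.0)

    def test_linear_unit_gives_linear_curve(self, pixel_gen):
        """A unit linear in pixels traces a straight line in alpha, up to
        pixel quantization."""

        class MeanPixelUnit:
            name = "mean_pixel"

            def score(self, image):
                return float(np.asarray(image, dtype=float).mean())

        rng = np.random.default_rng(4)
        c1, c2 = rng.uniform(-0.8, 0.8, 64), rng.uniform(-0.8, 0.8, 64)
        alphas, acts = interpolation_curve(MeanPixelUnit(), pixel_gen, c1, c2, n_points=11)
        expected = acts[0] + alphas * (acts[-1] - acts[0])
        assert np.abs(acts - expected).max() <= 1.0  # quantization tolerance

    def test_zero_endpoint_normalization_rejected(self, pixel_gen, gabor_unit):
        blank = np.zeros(64)
        with pytest.raises(ValueError, match="endpoint"):
            interpolation_curve(
                gabor_unit, pixel_gen, blank, blank, n_points=3, normalize=True
            )


class TestInitializationSlope:
    def test_arithmetic_example(self):
        fit = initialization_slope([0.5, 0.6, 0.7])
        assert fit.slope == pytest.approx(0.10)

    def test_equal_medians_give_zero_slope(self):
        assert initialization_slope([0.4, 0.4, 0.4]).slope == pytest.approx(0.0)

    def test_matches_generic_least_squares_oracle(self, rng):
        """Closed form (m_best - m_worst)/2 equals the normal-equations fit."""
        for _ in range(20):
            y = rng.uniform(0, 1, 3)
            fit = initialization_slope(y)
            X = np.vstack([np.array([0.0, 1.0, 2.0]), np.ones(3)]).T
            slope_oracle = np.linalg.lstsq(X, y, rcond=None)[0][0]
            assert fit.slope == pytest.approx(slope_oracle, abs=1e-12)
            assert fit.slope == pytest.approx((y[2] - y[0]) / 2, abs=1e-12)


class TestFractionalChange:
    def test_identical_runs_have_zero_change(self):
        stats = fractional_change_stats([10.0, 10.0, 10.0], 10.0)
        assert stats.mean == 0.0 and stats.sd == 0.0

    def test_symmetric_changes_average_to_zero(self):
        stats = fractional_change_stats([9.0, 11.0], 10.0)
        assert np.allclose(stats.changes, [-0.1, 0.1])
        assert stats.mean == pytest.approx(0.0)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            fractional_change_stats([1.0], 0.0)
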