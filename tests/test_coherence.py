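"""Profile/magnitude differences, omission rule, quadrants and CIs."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tfactivity.coherence import (
    CoherenceConfig,
    CoherenceError,
    ConstantProfileError,
    classify_quadrant,
    coherence_point,
    coherence_table,
    magnitude_difference,
    profile_difference,
)

from .conftest import draws_with_abs_rho, interval_rhos, posterior_from_draws


def pearson_oracle(x, y):
    """Textbook product-moment formula, coded independently of the package."""
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxx = sum(v * v for v in x)
    syy = sum(v * v for v in y)
    sxy = sum(a * b for a, b in zip(x, y))
    num = n * sxy - sx * sy
    den = math.sqrt((n * sxx - sx * sx) * (n * syy - sy * sy))
    return num / den


# frozen from the oracle above: 1 - |pearson((1,2,3,4), (1,3,2,4))| = 0.2
ORACLE_D_1324 = 0.19999999999999996


class TestProfileDifference:
    def test_identical_profiles_give_zero(self):
        a = np.array([1.0, 2.0, 3.0])
        assert profile_difference(a, a) == 0.0

    def test_perfect_anticorrelation_gives_zero(self):
        assert profile_difference([1, 2, 3], [3, 2, 1]) == 0.0

    def test_frozen_oracle_value(self):
        a, b = [1, 2, 3, 4], [1, 3, 2, 4]
        assert 1 - abs(pearson_oracle(a, b)) == pytest.approx(ORACLE_D_1324, abs=1e-15)
        assert profile_difference(a, b) == pytest.approx(ORACLE_D_1324, abs=1e-12)

    def test_matches_oracle_on_random_pairs(self):
        rng = np.random.default_rng(123)
        for _ in range(100):
            a, b = rng.normal(size=(2, 7))
            expected = 1.0 - abs(pearson_oracle(list(a), list(b)))
            assert profile_difference(a, b) == pytest.approx(expected, abs=1e-12)

    def test_constant_profile_raises_with_reason(self):
        with pytest.raises(ConstantProfileError) as exc:
            profile_difference([1.0, 1.0, 1.0], [1, 2, 3])
        assert exc.value.reason == "constant_profile"

    def test_short_or_mismatched_profiles_rejected(self):
        with pytest.raises(CoherenceError):
            profile_difference([1, 2], [3, 4])
        with pytest.raises(CoherenceError):
            profile_difference([1, 2, 3], [1, 2, 3, 4])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.integers(0, 10_000),
        st.floats(0.1, 5.0),
        st.floats(-3.0, 3.0),
    )
    def test_affine_invariance(self, seed, alpha, beta):
        """d is invariant under v -> alpha*v + beta (alpha != 0); m is not."""
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=(2, 7))
        d0 = profile_difference(a, b)
        assert profile_difference(alpha * a + beta, b) == pytest.approx(d0, abs=1e-9)
        assert profile_difference(-alpha * a + beta, b) == pytest.approx(d0, abs=1e-9)
        assert 0.0 <= d0 <= 1.0


class TestMagnitudeDifference:
    def test_known_norms(self):
        assert magnitude_difference([3, 4], [0, 0]) == 5.0
        assert magnitude_difference([3, 4], [6, 8]) == 5.0
        assert magnitude_difference([1, 2, 3], [1, 2, 3]) == 0.0

    def test_not_affine_invariant(self):
        a, b = np.array([1.0, 2.0, 3.0]), np.array([0.5, 1.0, 2.0])
        assert magnitude_difference(2 * a, b) != pytest.approx(magnitude_difference(a, b))


class TestClassifyQuadrant:
    @pytest.mark.parametrize(
        "d,m,expected",
        [
            (0.0, 0.0, "lower-left"),
            (0.2, 5.0, "upper-left"),
            (0.8, 0.1, "lower-right"),
            (0.8, 5.0, "upper-right"),
            (0.5, 0.0, "lower-right"),  # boundary d goes to the high side
            (0.2, 1.0, "upper-left"),  # boundary m goes to the high side
        ],
    )
    def test_quadrants(self, d, m, expected):
        assert classify_quadrant(d, m, d_threshold=0.5, m_threshold=1.0) == expected

    def test_undefined_d(self):
        assert classify_quadrant(float("nan"), 1.0, 0.5, 1.0) == "undefined"


class TestCoherencePoint:
    def test_identical_draws_give_zero_width_interval(self):
        a, b = draws_with_abs_rho(np.full(41, 0.6))
        pa = posterior_from_draws(a[:, None, :])
        pb = posterior_from_draws(b[:, None, :])
        pt = coherence_point(pa, pb, "TF00", seed=0)
        assert pt.d_lo95 == pytest.approx(pt.d_hi95)
        assert not pt.omitted

    @pytest.mark.parametrize("half_width,omitted", [(0.10, False), (0.20, True)])
    def test_omission_rule_at_constructed_widths(self, half_width, omitted):
        """|rho| interval half-widths 0.10 / 0.20 are retained / omitted."""
        rhos = interval_rhos(0.5, half_width)
        a, b = draws_with_abs_rho(rhos)
        pa = posterior_from_draws(a[:, None, :])
        pb = posterior_from_draws(b[:, None, :])
        pt = coherence_point(pa, pb, "TF00", seed=0)
        assert (pt.d_hi95 - pt.d_lo95) / 2 == pytest.approx(half_width, abs=1e-12)
        assert pt.omitted is omitted

    def test_point_estimates_match_direct_functions(self):
        rng = np.random.default_rng(5)
        draws_a = rng.normal(1, 0.1, size=(100, 1, 7))
        draws_b = rng.normal(0.5, 0.1, size=(100, 1, 7))
        pa, pb = posterior_from_draws(draws_a), posterior_from_draws(draws_b)
        pt = coherence_point(pa, pb, "TF00", seed=1)
        assert pt.profile_difference == profile_difference(pa.mean[0], pb.mean[0])
        assert pt.magnitude_difference == magnitude_difference(pa.mean[0], pb.mean[0])

    def test_mismatched_grids_rejected(self):
        rng = np.random.default_rng(0)
        pa = posterior_from_draws(rng.normal(size=(50, 1, 7)))
        pb = posterior_from_draws(
            rng.normal(size=(50, 1, 6)), timepoints=(0, 2.5, 5, 10, 20, 40)
        )
        with pytest.raises(CoherenceError, match="grids"):
            coherence_point(pa, pb, "TF00")

    def test_interval_covers_truth(self):
        """95% interval for d contains the true d in >= 90% of 200 trials."""
        u_w = 7
        hits = 0
        n_trials = 200
        for trial in range(n_trials):
            rng = np.random.default_rng(1000 + trial)
            true_a = np.array([0.0, 0.4, 0.9, 1.6, 1.0, 0.5, 0.2])
            true_b = np.array([0.0, 0.1, 0.3, 0.6, 1.0, 1.4, 1.9])
            true_d = profile_difference(true_a, true_b)
            draws_a = true_a + rng.normal(0, 0.15, size=(150, u_w))
            draws_b = true_b + rng.normal(0, 0.15, size=(150, u_w))
            pa = posterior_from_draws(draws_a[:, None, :])
            pb = posterior_from_draws(draws_b[:, None, :])
            pt = coherence_point(pa, pb, "TF00", seed=trial)
            if pt.d_lo95 <= true_d <= pt.d_hi95:
                hits += 1
        assert hits / n_trials >= 0.90


class TestCoherenceTable:
    def _posteriors(self, n_tfs=3, seed=0):
        rng = np.random.default_rng(seed)
        base = np.cumsum(rng.normal(size=(n_tfs, 7)), axis=1)
        draws_a = base[None] + rng.normal(0, 0.05, size=(200, n_tfs, 7))
        draws_b = base[None] * 2 + rng.normal(0, 0.05, size=(200, n_tfs, 7))
        tfs = tuple(f"TF{i:02d}" for i in range(n_tfs))
        return (
            posterior_from_draws(draws_a, tf_ids=tfs),
            posterior_from_draws(draws_b, tf_ids=tfs),
        )

    def test_one_record_per_shared_tf(self):
        pa, pb = self._posteriors()
        points = coherence_table(pa, pb, CoherenceConfig(seed=3))
        assert [p.tf_id for p in points] == ["TF00", "TF01", "TF02"]

    def test_no_shared_tfs_is_error(self):
        pa, pb = self._posteriors()
        pb_renamed = posterior_from_draws(pb.draws, tf_ids=("X0", "X1", "X2"))
        with pytest.raises(CoherenceError, match="shared"):
            coherence_table(pa, pb_renamed, CoherenceConfig())

    def test_omitted_points_retained_in_table(self):
        rhos_wide = interval_rhos(0.5, 0.3)
        a1, b1 = draws_with_abs_rho(rhos_wide, seed=1)
        a2, b2 = draws_with_abs_rho(np.full(41, 0.9), seed=2)
        pa = posterior_from_draws(np.stack([a1, a2], axis=1), tf_ids=("TFw", "TFn"))
        pb = posterior_from_draws(np.stack([b1, b2], axis=1), tf_ids=("TFw", "TFn"))
        points = coherence_table(pa, pb, CoherenceConfig(seed=0))
        by_id = {p.tf_id: p for p in points}
        assert by_id["TFw"].omitted and not by_id["TFn"].omitted
        assert len(points) == 2

    def test_constant_profile_yields_undefined_record(self):
        draws_a = np.zeros((50, 1, 7))
        draws_b = np.tile(np.arange(7.0), (50, 1, 1))
        pa, pb = posterior_from_draws(draws_a), posterior_from_draws(draws_b)
        points = coherence_table(pa, pb, CoherenceConfig(seed=0))
        assert points[0].quadrant == "undefined"
        assert points[0].reason == "constant_profile"
        assert math.isnan(points[0].profile_difference)
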