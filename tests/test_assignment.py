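"""Density-ratio sex assignment: probabilities, thresholds, decision rules."""

import numpy as np
import pytest

from hatchsex import (
    FittedDist,
    assign_continuous,
    assign_empirical,
    assign_probabilistic,
    density_ratio_roots,
    empirical_threshold_set,
    relative_prob_male,
    solve_thresholds,
)
from hatchsex.errors import DomainError, OrientationError, SearchRangeError


def _ln(mu, sd):
    return FittedDist("lognormal", {"meanlog": mu, "sdlog": sd})


class TestRelativeProbMale:
    def test_identical_fits_give_half(self, naive_fits):
        f = naive_fits[0]
        for x in (0.5, 5.0, 37.7, 500.0):
            assert relative_prob_male(x, f, f) == pytest.approx(0.5, abs=1e-12)

    def test_published_crossing_is_near_half(self, naive_fits):
        assert relative_prob_male(37.7, *naive_fits) == pytest.approx(0.5, abs=0.02)

    def test_deep_female_tail(self, naive_fits):
        """At 10 pg/mL the pointwise log-density difference (~20.9 in favour
        of female) makes the male probability essentially zero."""
        assert relative_prob_male(10.0, *naive_fits) < 1e-8

    def test_deep_male_tail(self, naive_fits):
        assert relative_prob_male(100.0, *naive_fits) > 1 - 1e-10

    def test_vectorised_matches_scalar(self, naive_fits):
        xs = np.array([5.0, 37.7, 200.0])
        vec = relative_prob_male(xs, *naive_fits)
        assert np.allclose(vec, [relative_prob_male(x, *naive_fits) for x in xs])

    def test_nonpositive_concentration_rejected(self, naive_fits):
        with pytest.raises(DomainError):
            relative_prob_male(0.0, *naive_fits)

    def test_probabilities_sum_to_one(self, naive_fits):
        pm = relative_prob_male(55.0, *naive_fits)
        assert 0.0 <= pm <= 1.0


# Published decision thresholds per (status, certainty): (female_upper, male_lower).
# The challenged 99.99% male bound is excluded: the printed value corresponds to
# ~99.9% certainty rather than 99.99% and is not reproducible from the fits.
PUBLISHED_THRESHOLDS = {
    ("naive", 0.5): (37.7, 37.7),
    ("naive", 0.80): (35.3, 40.3),
    ("naive", 0.95): (32.7, 43.2),
    ("naive", 0.9999): (23.3, 56.5),
    ("challenged", 0.5): (129.7, 129.7),
    ("challenged", 0.80): (99.7, 167.1),
    ("challenged", 0.95): (73.2, 219.8),
}


class TestSolveThresholds:
    @pytest.mark.parametrize("key,expected", sorted(PUBLISHED_THRESHOLDS.items()))
    def test_reproduces_published_thresholds(self, key, expected, naive_fits, challenged_fits):
        status, cert = key
        fits = naive_fits if status == "naive" else challenged_fits
        ts = solve_thresholds(*fits, cert)
        assert ts.female_upper == pytest.approx(expected[0], abs=0.100001)
        assert ts.male_lower == pytest.approx(expected[1], abs=0.100001)

    def test_challenged_9999_female_bound(self, challenged_fits):
        ts = solve_thresholds(*challenged_fits, 0.9999)
        assert ts.female_upper == pytest.approx(17.5, abs=0.100001)

    def test_equal_sigma_crossing_at_log_midpoint(self):
        f, m = _ln(0.0, 1.0), _ln(2.0, 1.0)
        ts = solve_thresholds(f, m, 0.5)
        assert ts.female_upper == pytest.approx(np.e, abs=0.06)

    def test_certainty_nesting(self, naive_fits):
        """Higher certainty widens the unknown band on both sides."""
        prev = solve_thresholds(*naive_fits, 0.5)
        for cert in (0.6, 0.8, 0.95, 0.99, 0.9999):
            ts = solve_thresholds(*naive_fits, cert)
            assert ts.female_upper <= prev.female_upper
            assert ts.male_lower >= prev.male_lower
            prev = ts

    def test_spurious_low_crossing_excluded(self, naive_fits):
        """sigma_M > sigma_F creates a second density crossing at a very low
        concentration (~0.23 pg/mL for the naive fits); the solver must
        return only the crossing between the modes."""
        roots = density_ratio_roots(*naive_fits, 0.5)
        assert roots[0] == pytest.approx(0.23, abs=0.02)  # the spurious root exists
        ts = solve_thresholds(*naive_fits, 0.5)
        assert ts.female_upper > 30  # ... and is not what the solver returns

    def test_binned_crossing_matches_pointwise_root(self, challenged_fits):
        roots = density_ratio_roots(*challenged_fits, 0.5)
        ts = solve_thresholds(*challenged_fits, 0.5)
        assert ts.female_upper == pytest.approx(roots[-1], abs=0.1)

    def test_reversed_modes_rejected(self):
        with pytest.raises(OrientationError):
            solve_thresholds(_ln(5.0, 0.5), _ln(2.0, 0.3), 0.8)

    def test_unreachable_certainty_raises(self, naive_fits):
        with pytest.raises(SearchRangeError):
            solve_thresholds(*naive_fits, 0.9999, search_range=(30.0, 50.0))

    def test_invalid_certainty_rejected(self, naive_fits):
        with pytest.raises(DomainError):
            solve_thresholds(*naive_fits, 1.0)

    def test_symmetric_bin_option_agrees_within_grid_step(self, naive_fits):
        asym = solve_thresholds(*naive_fits, 0.95)
        sym = solve_thresholds(*naive_fits, 0.95, bin_above=0.05)
        assert abs(asym.female_upper - sym.female_upper) <= 0.100001
        assert abs(asym.male_lower - sym.male_lower) <= 0.100001


class TestAssignProbabilistic:
    def test_regions(self, naive_fits):
        ts = solve_thresholds(*naive_fits, 0.95)
        assert assign_probabilistic(30.0, ts).assigned == "F"
        assert assign_probabilistic(37.0, ts).assigned == "U"
        assert assign_probabilistic(50.0, ts).assigned == "M"

    def test_boundaries_inclusive(self, naive_fits):
        ts = solve_thresholds(*naive_fits, 0.95)
        assert assign_probabilistic(ts.female_upper, ts).assigned == "F"
        assert assign_probabilistic(ts.male_lower, ts).assigned == "M"

    def test_probabilities_reported_with_fits(self, naive_fits):
        ts = solve_thresholds(*naive_fits, 0.95)
        res = assign_probabilistic(30.0, ts, *naive_fits)
        assert res.prob_male + res.prob_female == pytest.approx(1.0)

    def test_nonpositive_rejected(self, naive_fits):
        ts = solve_thresholds(*naive_fits, 0.95)
        with pytest.raises(DomainError):
            assign_probabilistic(-1.0, ts)


class TestAssignContinuous:
    def test_identical_fits_are_a_fair_coin(self, naive_fits):
        f = naive_fits[0]
        rng = np.random.default_rng(5)
        males = sum(assign_continuous(20.0, f, f, rng).assigned == "M" for _ in range(10_000))
        assert males / 10_000 == pytest.approx(0.5, abs=0.01)

    def test_extreme_concentration_always_male(self, naive_fits):
        rng = np.random.default_rng(0)
        assert all(
            assign_continuous(5_000.0, *naive_fits, rng).assigned == "M" for _ in range(100)
        )

    def test_low_concentration_virtually_always_female(self, naive_fits):
        rng = np.random.default_rng(0)
        res = [assign_continuous(10.0, *naive_fits, rng) for _ in range(1_000)]
        assert all(r.assigned == "F" for r in res)
        assert res[0].prob_male < 1e-8

    def test_seeded_reproducibility(self, naive_fits):
        a = [assign_continuous(40.0, *naive_fits, np.random.default_rng(9)).assigned for _ in range(5)]
        b = [assign_continuous(40.0, *naive_fits, np.random.default_rng(9)).assigned for _ in range(5)]
        assert a == b


class TestAssignEmpirical:
    def test_naive_regions(self):
        assert assign_empirical(15.0, 20.8, 125.4).assigned == "F"
        assert assign_empirical(50.0, 20.8, 125.4).assigned == "U"
        assert assign_empirical(300.0, 20.8, 125.4).assigned == "M"

    def test_boundaries_inclusive_when_disjoint(self):
        assert assign_empirical(20.8, 20.8, 125.4).assigned == "F"
        assert assign_empirical(125.4, 20.8, 125.4).assigned == "M"

    def test_overlapping_ranges_use_strict_rule(self):
        # challenged extrema: female max 139.0 > male min 114.8
        assert assign_empirical(100.0, 139.0, 114.8).assigned == "F"
        assert assign_empirical(120.0, 139.0, 114.8).assigned == "U"
        assert assign_empirical(150.0, 139.0, 114.8).assigned == "M"

    def test_overlap_threshold_set_matches_published_bounds(self):
        ts = empirical_threshold_set(139.0, 114.8)
        assert ts.female_upper == pytest.approx(114.7)
        assert ts.male_lower == pytest.approx(139.1)

    def test_disjoint_threshold_set_keeps_extrema(self):
        ts = empirical_threshold_set(20.8, 125.4)
        assert (ts.female_upper, ts.male_lower) == (20.8, 125.4)
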