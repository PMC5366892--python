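import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from microstab import stability_metrics as sm
from microstab.domain_model import Origin, TrophicGroup

from conftest import make_series


def brute_force_variance(x):
    """Independent sample-variance oracle: direct sum of squared deviations."""
    x = list(x)
    m = sum(x) / len(x)
    return sum((v - m) ** 2 for v in x) / (len(x) - 1)


def brute_force_synchrony(matrix):
    """Recompute phi from first principles with the oracle variance."""
    totals = [sum(col) for col in zip(*matrix)]
    denom = sum(brute_force_variance(row) ** 0.5 for row in matrix) ** 2
    return brute_force_variance(totals) / denom


class TestTemporalVariability:
    def test_constant_series_has_zero_cv(self):
        assert sm.temporal_variability([3, 3, 3]) == 0.0

    def test_known_value(self):
        # mean 4, sample SD 2 (verified with the brute-force variance oracle)
        assert brute_force_variance([2, 4, 6]) == pytest.approx(4.0)
        assert sm.temporal_variability([2, 4, 6]) == pytest.approx(0.5)

    def test_scale_invariance(self):
        assert sm.temporal_variability([20, 40, 60]) == pytest.approx(0.5)

    def test_errors(self):
        with pytest.raises(sm.UndefinedMetricError, match="undefined CV"):
            sm.temporal_variability([0.0, 0.0])
        with pytest.raises(sm.UndefinedMetricError, match="2 sampling"):
            sm.temporal_variability([1.0])

    @settings(deadline=None, derandomize=True)
    @given(
        x=hnp.arrays(float, st.integers(2, 12), elements=st.floats(0.1, 1e3)),
        c=st.floats(0.1, 1e3),
    )
    def test_mean_shift_decreases_cv(self, x, c):
        if sm.temporal_variability(x) < 1e-9:  # effectively constant
            return
        assert sm.temporal_variability(x + c) < sm.temporal_variability(x)

    @settings(deadline=None, derandomize=True)
    @given(
        x=hnp.arrays(float, st.integers(2, 12), elements=st.floats(0.1, 1e3)),
        k=st.floats(1e-3, 1e3),
    )
    def test_positive_scaling_invariance(self, x, k):
        cv = sm.temporal_variability(x)
        assert sm.temporal_variability(k * x) == pytest.approx(cv, rel=1e-9)


class TestTemporalStability:
    def test_reciprocal_identity(self):
        assert sm.temporal_stability([2, 4, 6]) == pytest.approx(2.0)
        x = [1.5, 3.2, 2.4, 8.8]
        assert sm.temporal_stability(x) * sm.temporal_variability(x) == pytest.approx(1.0)

    def test_constant_series_flagged_infinite(self):
        with pytest.raises(sm.UndefinedMetricError, match="infinite"):
            sm.temporal_stability([5, 5, 5])


class TestPopulationVariability:
    def test_per_species_cv_and_undefined_marker(self):
        s = make_series([[1, 2, 3], [0, 0, 0]])
        out = sm.population_variability(s)
        assert out["sp0"] == pytest.approx(0.5)  # sample SD 1, mean 2
        assert out["sp1"] is None

    def test_single_species_equals_community_cv(self):
        s = make_series([[3.0, 7.0, 5.0, 9.0]])
        assert sm.population_variability(s)["sp0"] == pytest.approx(
            sm.temporal_variability(s.total_density())
        )


class TestSynchrony:
    def test_proportional_series_is_one(self):
        # totals [3,6,9]: Var=9; (sd 1 + sd 2)^2 = 9
        s = make_series([[1, 2, 3], [2, 4, 6]])
        assert sm.synchrony(s) == pytest.approx(1.0)

    def test_constant_total_is_zero(self):
        s = make_series([[1, 2, 1, 2], [2, 1, 2, 1]])
        assert sm.synchrony(s) == 0.0
        assert sm.asynchrony(s) == 1.0

    def test_independent_species_approach_half(self):
        # analytic limit (1+rho)/2 with rho=0 for two equal-SD species
        rng = np.random.default_rng(42)
        s = make_series(rng.standard_normal((2, 10_000)) + 50, days=range(1, 10_001))
        assert sm.synchrony(s) == pytest.approx(0.5, abs=0.02)

    def test_two_species_equal_sd_analytic_form(self):
        # phi = (1+rho)/2 when both species have equal SD
        x = np.array([3.0, 1.0, 4.0, 1.0, 5.0, 9.0])
        y = np.array([2.0, 7.0, 1.0, 8.0, 2.0, 8.0])
        y = x.mean() + (y - y.mean()) * x.std(ddof=1) / y.std(ddof=1)  # match SDs
        rho = np.corrcoef(x, y)[0, 1]
        s = make_series(np.vstack([x, y + 20]))
        assert sm.synchrony(s) == pytest.approx((1 + rho) / 2, abs=1e-9)

    def test_all_constant_is_an_error(self):
        with pytest.raises(sm.UndefinedMetricError, match="zero denominator"):
            sm.synchrony(make_series([[1, 1, 1], [2, 2, 2]]))

    def test_oracle_equivalence_on_random_matrices(self):
        # 500 random small integer matrices vs the brute-force recomputation
        rng = np.random.default_rng(7)
        checked = 0
        while checked < 500:
            m = rng.integers(0, 4, size=(3, 4)).astype(float)
            if m.std(axis=1).sum() == 0:
                continue
            s = make_series(m)
            assert sm.synchrony(s) == pytest.approx(brute_force_synchrony(m), abs=1e-12)
            checked += 1

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(
        m=hnp.arrays(float, st.tuples(st.integers(1, 6), st.integers(2, 8)),
                     elements=st.floats(0, 100)),
        k=st.floats(1e-3, 1e3),
        seed=st.integers(0, 2**16),
    )
    def test_bounds_and_invariances(self, m, k, seed):
        if m.std(axis=1, ddof=1).sum() <= 1e-6:  # (near-)degenerate denominator
            return
        s = make_series(m)
        phi = sm.synchrony(s)
        assert 0.0 <= phi <= 1.0
        # common positive scaling
        assert sm.synchrony(make_series(k * m)) == pytest.approx(phi, rel=1e-9)
        # species relabelling (row permutation)
        perm = np.random.default_rng(seed).permutation(m.shape[0])
        assert sm.synchrony(make_series(m[perm])) == pytest.approx(phi, rel=1e-9)

    def test_proportional_multiples_of_common_series(self):
        base = np.array([2.0, 5.0, 3.0, 8.0])
        m = np.vstack([0.5 * base, 1.7 * base, 3.0 * base])
        assert sm.synchrony(make_series(m)) == pytest.approx(1.0, abs=1e-12)


class TestDominance:
    def test_single_species_is_one(self):
        frac, sp = sm.dominance(make_series([[4.0, 6.0]]))
        assert frac == 1.0 and sp == "sp0"

    def test_symmetric_community_is_half(self):
        frac, sp = sm.dominance(make_series([[2, 2], [2, 2]]), species="sp0")
        assert frac == pytest.approx(0.5)

    def test_mean_of_daily_relative_abundance(self):
        # day shares 0.75 and 0.25 -> mean 0.5
        frac, _ = sm.dominance(make_series([[6, 2], [2, 6]]), species="sp0")
        assert frac == pytest.approx(0.5)

    def test_auto_picks_highest_mean_share_with_lexicographic_ties(self):
        s = make_series([[5, 5], [3, 3], [5, 5]], species=["b", "c", "a"])
        frac, sp = sm.dominance(s, "auto")
        assert sp == "a"  # tie between 'a' and 'b' broken lexicographically

    def test_zero_total_days_excluded_with_warning(self):
        s = make_series([[6, 0, 2], [2, 0, 6]])
        with pytest.warns(UserWarning, match="zero total"):
            frac, _ = sm.dominance(s, species="sp0")
        assert frac == pytest.approx(0.5)

    def test_all_days_zero_is_an_error(self):
        s = make_series([[0.0, 0.0]])
        with pytest.warns(UserWarning):
            with pytest.raises(sm.UndefinedMetricError):
                sm.dominance(s)


class TestRichness:
    def test_counts_species_detected_at_least_once(self):
        m = np.ones((5, 3))
        m[4] = 0.0
        assert sm.richness(make_series(m)) == 4

    def test_invaders_excluded_by_default(self):
        origin = {"r": Origin.RESIDENT, "i": Origin.INVADER}
        s = make_series([[1, 1], [1, 1]], species=["r", "i"], origin=origin)
        assert sm.richness(s) == 1
        assert sm.richness(s, residents_only=False) == 2
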