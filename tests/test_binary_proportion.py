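"""Wilson intervals and their exact binomial-enumeration oracles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pilotsize import (
    InvalidParameterError,
    enumerate_binomial_expectation,
    precision_gain_binary,
    summarize_binomial_cell,
    wilson_interval,
)
from pilotsize.binary_proportion import wilson_bounds

THETA_GRID = [round(0.10 + 0.05 * k, 2) for k in range(9)]


class TestWilsonInterval:
    def test_known_values(self):
        est = wilson_interval(30, 60, 0.95)
        assert est.wilson_lower == pytest.approx(0.377350, abs=1e-6)
        assert est.wilson_upper == pytest.approx(0.622650, abs=1e-6)
        assert est.width == pytest.approx(0.245300, abs=1e-6)

    def test_zero_successes(self):
        est = wilson_interval(0, 10)
        assert est.wilson_lower == 0.0
        assert est.wilson_upper == pytest.approx(0.277533, abs=1e-6)

    def test_matches_statsmodels(self):
        from statsmodels.stats.proportion import proportion_confint

        for y, n in [(0, 10), (3, 10), (30, 60), (199, 200), (50, 137)]:
            lo, hi = proportion_confint(y, n, alpha=0.05, method="wilson")
            est = wilson_interval(y, n, 0.95)
            assert est.wilson_lower == pytest.approx(lo, abs=1e-10)
            assert est.wilson_upper == pytest.approx(hi, abs=1e-10)

    @given(n=st.integers(min_value=1, max_value=300), frac=st.fractions(0, 1))
    def test_contains_point_estimate_and_stays_in_unit_interval(self, n, frac):
        y = int(frac * n)
        est = wilson_interval(y, n)
        assert 0.0 <= est.wilson_lower <= est.theta_hat <= est.wilson_upper <= 1.0

    def test_symmetry_about_half(self):
        for n, y in [(10, 2), (60, 30), (25, 0)]:
            a = wilson_interval(y, n)
            b = wilson_interval(n - y, n)
            assert a.wilson_lower == pytest.approx(1 - b.wilson_upper, abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidParameterError):
            wilson_interval(11, 10)


class TestEnumeration:
    def test_mean_theta_hat_is_theta(self):
        # E[Y/n] = theta exactly, for any theta
        assert enumerate_binomial_expectation(0.5, 1, "theta_hat") == pytest.approx(0.5)
        assert enumerate_binomial_expectation(0.3, 20, "theta_hat") == pytest.approx(0.3, abs=1e-12)

    def test_symmetric_theta_has_zero_bias(self):
        cell = summarize_binomial_cell(0.5, 60, method="enumeration")
        assert cell.bias == pytest.approx(0.0, abs=1e-12)

    def test_coverage_by_direct_summation(self):
        # independent oracle: rebuild the coverage sum with scipy directly
        from scipy import stats

        ys = np.arange(51)
        lo, hi = wilson_bounds(ys, 50, 0.95)
        expected = stats.binom.pmf(ys, 50, 0.1)[(lo <= 0.1) & (0.1 <= hi)].sum()
        assert enumerate_binomial_expectation(0.1, 50, "coverage") == pytest.approx(expected, abs=1e-14)

    def test_unknown_quantity_rejected(self):
        with pytest.raises(InvalidParameterError):
            enumerate_binomial_expectation(0.3, 10, "median")

    def test_width_symmetry_in_theta(self):
        for n in (10, 55, 200):
            for th in (0.1, 0.25, 0.4):
                w = enumerate_binomial_expectation(th, n, "width")
                w_mirror = enumerate_binomial_expectation(1 - th, n, "width")
                assert w == pytest.approx(w_mirror, abs=1e-13)

    def test_width_maximal_at_half(self):
        for n in (10, 60, 200):
            widths = {th: enumerate_binomial_expectation(th, n, "width") for th in THETA_GRID}
            assert max(widths, key=widths.get) == 0.5


class TestMonteCarloAgreement:
    @pytest.mark.parametrize("theta", [0.1, 0.3, 0.5])
    @pytest.mark.parametrize("n", [10, 60, 200])
    def test_simulation_converges_to_enumeration(self, theta, n, seed):
        sim = summarize_binomial_cell(theta, n, method="simulation", seed=seed)
        reps = sim.n_reps
        for attr, quantity in [
            ("mean_theta_hat", "theta_hat"),
            ("mean_width", "width"),
            ("coverage", "coverage"),
        ]:
            exact = enumerate_binomial_expectation(theta, n, quantity)
            if quantity == "coverage":
                se = np.sqrt(max(exact * (1 - exact), 1e-8) / reps)
            elif quantity == "theta_hat":
                se = np.sqrt(theta * (1 - theta) / n / reps)
            else:
                # exact second moment of the width gives the exact MC SE
                from scipy import stats

                ys = np.arange(n + 1)
                lo, hi = wilson_bounds(ys, n, 0.95)
                m2 = float(np.sum(stats.binom.pmf(ys, n, theta) * (hi - lo) ** 2))
                se = np.sqrt(max(m2 - exact**2, 1e-12) / reps)
            assert abs(getattr(sim, attr) - exact) < 4 * se + 1e-9

    def test_replicate_rule_applied(self, seed):
        sim = summarize_binomial_cell(0.5, 25, method="simulation", seed=seed)
        assert sim.n_reps == 250_000
        sim_small = summarize_binomial_cell(0.1, 25, method="simulation", seed=seed)
        assert sim_small.n_reps == 90_000  # above the 10,000 floor already


class TestPrecisionGain:
    def test_no_change_is_zero(self):
        assert precision_gain_binary(0.3, 0.3) == 0.0

    def test_thresholds_from_enumeration(self):
        for theta in THETA_GRID:
            w60 = enumerate_binomial_expectation(theta, 60, "width")
            w65 = enumerate_binomial_expectation(theta, 65, "width")
            assert precision_gain_binary(w60, w65) < 5.0
            w100 = enumerate_binomial_expectation(theta, 100, "width")
            w105 = enumerate_binomial_expectation(theta, 105, "width")
            assert precision_gain_binary(w100, w105) <= 3.0

    def test_gain_positive_and_tends_down(self):
        widths = [enumerate_binomial_expectation(0.5, n, "width") for n in range(10, 201, 5)]
        gains = [precision_gain_binary(a, b) for a, b in zip(widths, widths[1:])]
        assert all(g > 0 for g in gains)
        # decreasing trend, allowing discreteness fluctuations at small n
        assert gains[0] > gains[len(gains) // 2] > gains[-1]


class TestCoverage:
    def test_near_nominal_but_oscillating(self):
        covers = [
            enumerate_binomial_expectation(th, n, "coverage")
            for th in THETA_GRID
            for n in range(10, 201, 5)
        ]
        assert all(0.90 <= c <= 0.99 for c in covers)
        assert max(covers) - min(covers) > 0.01  # genuinely oscillates
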