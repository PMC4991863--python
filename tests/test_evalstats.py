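"""Deviation statistics, Thompson τ rejection, regression diagnostics."""

import math

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from isopka import (
    load_amine_benchmark,
    mad,
    max_ad,
    regression_stats,
    run_benchmark,
    thompson_tau_critical,
    thompson_tau_filter,
)
from isopka.errors import StatisticsError
from isopka.evalstats import load_compound1_predictions, load_sastre_experimental

vectors = st.lists(
    st.floats(-20, 20, allow_nan=False, allow_infinity=False), min_size=1, max_size=30
)


class TestDeviationStats:
    def test_identical_vectors(self):
        assert mad([1.0, 2.0], [1.0, 2.0]) == 0.0
        assert max_ad([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_arithmetic(self):
        assert mad([1.0, 3.0], [2.0, 1.0]) == pytest.approx(1.5)
        assert max_ad([5.0], [4.1]) == pytest.approx(0.9)

    def test_length_mismatch(self):
        with pytest.raises(StatisticsError, match="equal-length"):
            mad([1.0], [1.0, 2.0])
        with pytest.raises(StatisticsError, match="equal-length"):
            max_ad([1.0], [1.0, 2.0])

    @given(pairs=st.lists(st.tuples(st.floats(-20, 20), st.floats(-20, 20)),
                          min_size=1, max_size=30),
           shift=st.floats(-5, 5), seed=st.integers(0, 10))
    def test_mad_below_max_ad_and_invariances(self, pairs, shift, seed):
        pred = [p for p, _ in pairs]
        exp = [e for _, e in pairs]
        assert mad(pred, exp) <= max_ad(pred, exp) + 1e-12
        # shift invariance under adding a constant to both vectors
        assert mad([p + shift for p in pred], [e + shift for e in exp]) == (
            pytest.approx(mad(pred, exp), abs=1e-9)
        )
        # permutation invariance
        rng = np.random.default_rng(seed)
        perm = rng.permutation(len(pred))
        assert max_ad(np.array(pred)[perm], np.array(exp)[perm]) == (
            pytest.approx(max_ad(pred, exp))
        )


def _hand_tau(n, alpha=0.05):
    # independent evaluation of the rejection multiplier
    t = sps.t.ppf(1 - alpha / 2, n - 2)
    return t * (n - 1) / (math.sqrt(n) * math.sqrt(n - 2 + t * t))


class TestThompsonTau:
    def test_too_few_points(self):
        with pytest.raises(StatisticsError, match="n >= 3"):
            thompson_tau_filter([0.0, 1.0])

    def test_equal_residuals_remove_nothing(self):
        kept, removed = thompson_tau_filter([2.0] * 6)
        assert removed == [] and kept == list(range(6))

    def test_single_gross_outlier_removed(self):
        kept, removed = thompson_tau_filter([0.0, 0.0, 0.0, 0.0, 100.0])
        assert removed == [4]
        assert kept == [0, 1, 2, 3]

    @pytest.mark.parametrize("n", range(3, 11))
    def test_matches_hand_evaluated_decisions(self, n):
        # constructed cases: one spike of varying size on a flat background
        base = [0.1 * i for i in range(n - 1)]
        for spike in (0.5, 5.0, 50.0):
            data = base + [spike]
            arr = np.array(data)
            kept, removed = thompson_tau_filter(data)
            # replicate the first iteration by hand
            dev = np.abs(arr - arr.mean())
            worst = int(np.argmax(dev))
            should_remove = dev[worst] > _hand_tau(n) * arr.std(ddof=1)
            if should_remove:
                assert removed and removed[0] == worst
            else:
                assert removed == []

    def test_critical_value_against_published_point(self):
        # n=5, alpha=0.05: t(0.975, 3)=3.1824 -> tau ~ 1.571
        assert thompson_tau_critical(5) == pytest.approx(1.5712, abs=1e-3)

    def test_order_determinism(self):
        data = [0.2, -0.1, 9.0, 0.05, -0.3, 0.0]
        kept_a, removed_a = thompson_tau_filter(data)
        perm = [2, 0, 5, 1, 4, 3]
        kept_b, removed_b = thompson_tau_filter([data[i] for i in perm])
        assert sorted(data[i] for i in removed_a) == sorted(
            [data[i] for i in perm][j] for j in removed_b
        )

    def test_fixed_tau_mode(self):
        data = [0.0, 0.0, 0.0, 0.0, 3.0]
        _, removed_loose = thompson_tau_filter(data, fixed_tau=10.0)
        _, removed_tight = thompson_tau_filter(data, fixed_tau=1.4)
        assert removed_loose == [] and removed_tight == [4]


class TestRegressionStats:
    def test_perfect_fit_sentinels(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        stats = regression_stats(x, x)
        assert stats.slope == pytest.approx(1.0, abs=1e-12)
        assert stats.intercept == pytest.approx(0.0, abs=1e-12)
        assert stats.r2 == 1.0
        assert stats.std_err_estimate == 0.0
        assert math.isinf(stats.f_statistic)

    def test_against_normal_equations_oracle(self):
        rng = np.random.default_rng(20160811)
        for _ in range(100):
            n = int(rng.integers(6, 40))
            x = rng.uniform(-5, 15, n)
            y = 1.05 * x - 0.2 + rng.normal(0, 0.4, n)
            stats = regression_stats(x, y, tau_alpha=1e-12)  # keep all points
            fit = sm.OLS(y, sm.add_constant(x)).fit()
            assert stats.intercept == pytest.approx(fit.params[0], abs=1e-9)
            assert stats.slope == pytest.approx(fit.params[1], abs=1e-9)
            assert stats.intercept_stderr == pytest.approx(fit.bse[0], abs=1e-9)
            assert stats.slope_stderr == pytest.approx(fit.bse[1], abs=1e-9)
            assert stats.r2 == pytest.approx(fit.rsquared, abs=1e-9)
            assert stats.f_statistic == pytest.approx(fit.fvalue, rel=1e-9)
            assert stats.std_err_estimate == pytest.approx(
                math.sqrt(fit.ssr / (n - 2)), abs=1e-9
            )

    @given(slope=st.floats(0.2, 3), intercept=st.floats(-5, 5),
           n=st.integers(4, 20))
    def test_recovers_generating_line(self, slope, intercept, n):
        x = np.linspace(0, 10, n)
        y = slope * x + intercept
        stats = regression_stats(x, y)
        assert stats.slope == pytest.approx(slope, abs=1e-9)
        assert stats.intercept == pytest.approx(intercept, abs=1e-9)
        assert stats.n_df == n - 2

    def test_degrees_of_freedom_after_outlier_removal(self):
        rng = np.random.default_rng(3)
        x = np.linspace(0, 18, 36)
        # bounded noise keeps max|dev|/SD below the tau cutoff, so exactly
        # the three planted gross outliers are rejected
        y = x + rng.uniform(-0.3, 0.3, 36)
        y[[5, 17, 29]] += np.array([8.0, -9.0, 7.5])
        stats = regression_stats(x, y)
        assert sorted(stats.removed_outliers) == [5, 17, 29]
        assert stats.n_df == 31

    def test_too_few_points_after_filtering(self):
        with pytest.raises(StatisticsError, match="at least 4"):
            regression_stats([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_degenerate_variance(self):
        with pytest.raises(StatisticsError, match="degenerate"):
            regression_stats([2.0] * 5, [1.0, 2.0, 3.0, 4.0, 5.0])


class TestPackagedTables:
    def test_amine_benchmark_shape(self):
        table = load_amine_benchmark()
        assert len(table.names) == 12
        assert set(table.groups) == {"secondary_amine", "tertiary_amine"}
        assert set(table.predictions) == {
            "PM6-D3H+/SMD", "PM6-D3H+/SMD*", "PM6/SMD*", "PM6/COSMO*"
        }

    def test_experimental_compilation_reference_rows(self):
        df = load_sastre_experimental()
        refs = df[df["is_reference"] == 1]
        assert dict(zip(refs["name"], refs["exp"])) == {
            "Pyridine": 5.2, "Ethanol": 15.9, "Acetic acid": 4.8
        }

    def test_compound1_table_aligned(self):
        df = load_compound1_predictions()
        assert list(df["reference"]) == [
            "Tri-ethylamine", "Benzylpyrrolidene", "Heliotridane"
        ]
        assert (df["exp"] == 4.2).all()

    def test_unknown_method_label_rejected(self):
        with pytest.raises(StatisticsError, match="unknown method"):
            run_benchmark(load_amine_benchmark(), methods=["AM1/SMD"])

    def test_empty_correction_map_is_identity(self):
        table = load_amine_benchmark()
        assert run_benchmark(table, corrections={}) == run_benchmark(table)
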