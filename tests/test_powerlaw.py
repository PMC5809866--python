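import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from plawcorrect import (
    expected_sigma,
    fit_segment,
    intra_sample_scale,
    pareto_moments,
    pareto_tail,
    sample_pareto,
    segment_by_decade,
    segment_report,
    replicate_report,
)
from plawcorrect.powerlaw import PowerLawError, decade_ranges


class TestParetoTail:
    def test_small_example(self):
        curve = pareto_tail(np.array([1.0, 1.0, 0.6, 0.2]))
        assert curve.x.tolist() == [1.0, 0.6, 0.2]
        assert curve.f.tolist() == [1, 2, 3]
        assert curve.f_max == 3

    def test_fmax_counts_unique_values(self, rng):
        values = rng.permutation(np.arange(1, 633) / 632.0)
        assert pareto_tail(values).f_max == 632

    def test_zeros_dropped_and_too_few_values(self):
        curve = pareto_tail(np.array([0.0, 0.5, 1.0, 0.1, 0.0]))
        assert curve.f_max == 3
        with pytest.raises(PowerLawError):
            pareto_tail(np.array([1.0, 1.0, 0.5]))

    @given(seed=st.integers(0, 500))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.integers(0, 50, 60) / 50.0
        if len(set(v[v > 0])) < 3:
            v = np.array([0.1, 0.5, 1.0])
        curve = pareto_tail(v)
        expected = sorted(set(x for x in v if x > 0), reverse=True)
        assert curve.x.tolist() == expected
        assert curve.f.tolist() == list(range(1, len(expected) + 1))
        # rank-frequency and Pareto views are mutually inverse:
        # value at rank f is exactly the f-th largest unique value
        for f in (1, curve.f_max // 2 + 1, curve.f_max):
            assert curve.x[f - 1] == expected[f - 1]


class TestFitSegment:
    @pytest.mark.parametrize(
        "k, m", [(10.0, -1.0), (4.0, -0.5)]
    )
    def test_exact_power_law(self, k, m):
        # choose x so that rank r satisfies r = k * x**m exactly
        r = np.arange(1, 21)
        x = (r / k) ** (1.0 / m)
        curve = pareto_tail(x)
        fit = fit_segment(curve, 0, len(x))
        assert fit.m == pytest.approx(m, abs=1e-12)
        assert fit.log10_k == pytest.approx(np.log10(k), abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.sigma_obs == pytest.approx(0.0, abs=1e-12)
        # derived exponents
        assert fit.s == -fit.m
        assert fit.b == pytest.approx(1.0 / fit.s)

    def test_requires_three_points_and_spread(self):
        curve = pareto_tail(np.array([1.0, 0.5, 0.25, 0.125]))
        with pytest.raises(PowerLawError):
            fit_segment(curve, 0, 2)

    def test_noisy_slope_recovery(self):
        """Fitted slope lands within 3 standard errors of truth almost always."""
        hits = 0
        r = np.arange(1, 41)
        for seed in range(100):
            rng = np.random.default_rng(seed)
            x = (r / 10.0) ** (-1.0) * 10 ** rng.normal(0, 0.02, len(r))
            curve = pareto_tail(x)
            fit = fit_segment(curve, 0, len(curve))
            se = stats.linregress(curve.log10_x, curve.log10_f).stderr
            hits += abs(fit.m - (-1.0)) < 3 * se
        assert hits >= 97


class TestSegmentByDecade:
    def test_three_decades(self):
        x = np.geomspace(1.0, 1e-3, 40)
        segs = segment_by_decade(pareto_tail(x))
        assert len(segs) == 3
        # boundaries at 0.1 and 0.01: each segment stays inside its decade
        for seg, (hi, lo) in zip(segs, [(1.0, 0.1), (0.1, 0.01), (0.01, 1e-3)]):
            xs = x[seg.start : seg.stop]
            assert xs.max() <= hi and xs.min() >= lo

    def test_ideal_zipf_slopes(self):
        x = 1.0 / np.arange(1, 2001)
        for seg in segment_by_decade(pareto_tail(x)):
            assert seg.m == pytest.approx(-1.0, abs=0.05)

    @given(seed=st.integers(0, 300))
    def test_partition_property(self, seed):
        rng = np.random.default_rng(seed)
        x = np.unique(rng.random(rng.integers(20, 200)))[::-1]
        if x[0] / x[-1] < 10:
            x = np.concatenate([x, [x[-1] / 20]])
        ranges = decade_ranges(pareto_tail(x))
        flat = [i for a, b in ranges for i in range(a, b)]
        assert flat == list(range(len(pareto_tail(x).x)))
        assert all(b - a >= 3 for a, b in ranges[1:])

    def test_single_exponent_sample_slopes_agree(self, rng):
        """Decade slopes of a single-exponent sample agree within sampling
        error; segments of the extreme-value tail (< 1% of points) are
        excluded, their slope being dominated by order-statistic noise."""
        draws = sample_pareto(1.0, 1.0, 10**5, rng)
        segs = segment_by_decade(pareto_tail(draws))
        slopes = [s.m for s in segs if s.n_points >= 500]
        assert len(slopes) >= 3
        assert np.ptp(slopes) < 0.1


class TestParetoMoments:
    def test_analytic_values(self):
        res = pareto_moments(3.0, 1.0)
        assert res.mu == pytest.approx(1.5)
        assert res.sigma2 == pytest.approx(0.75)

    @pytest.mark.parametrize("s, finite_mu, finite_var", [
        (0.5, False, False),
        (1.5, True, False),
        (2.0, True, False),
        (2.5, True, True),
        (3.0, True, True),
    ])
    def test_divergence_thresholds(self, s, finite_mu, finite_var):
        res = pareto_moments(s, 1.0)
        assert res.mean_is_finite is finite_mu
        assert res.variance_is_finite is finite_var

    def test_invalid_inputs(self):
        with pytest.raises(PowerLawError):
            pareto_moments(0.0, 1.0)
        with pytest.raises(PowerLawError):
            pareto_moments(1.0, -1.0)

    @pytest.mark.parametrize("s, x_min", [(3.0, 1.0), (4.0, 2.0), (2.5, 0.5)])
    def test_against_scipy_closed_form(self, s, x_min):
        mu, var = stats.pareto.stats(b=s, scale=x_min, moments="mv")
        res = pareto_moments(s, x_min)
        assert res.mu == pytest.approx(float(mu))
        assert res.sigma2 == pytest.approx(float(var))

    def test_inverse_cdf_sampler_against_scipy(self, rng):
        draws = sample_pareto(4.0, 1.0, 10**5, rng)
        ref_mu, ref_var = stats.pareto.stats(b=4.0, scale=1.0, moments="mv")
        assert np.mean(draws) == pytest.approx(float(ref_mu), rel=0.02)
        assert np.var(draws, ddof=1) == pytest.approx(float(ref_var), rel=0.15)


class TestExpectedSigma:
    def test_examples(self):
        assert expected_sigma(0.1, 1.0, 0.5) == pytest.approx(0.2)
        assert expected_sigma(0.1, 1.0, 1.0) == pytest.approx(0.1)
        with pytest.raises(PowerLawError):
            expected_sigma(0.1, -1.0, 0.5)

    def test_single_exponent_replicates_ratio_near_one(self, rng):
        """Replicates of one exponent with homoskedastic log-noise show no
        excess scatter: observed/expected sigma stays near 1 everywhere."""
        import pandas as pd
        from plawcorrect import CountMatrix

        base = np.arange(1, 2001, dtype=float) ** (-1.0) * 1e6
        cols = {
            f"r{j}": base * 10 ** rng.normal(0, 0.05, len(base))
            for j in range(4)
        }
        m = CountMatrix(pd.DataFrame(cols, index=[f"t{i}" for i in range(len(base))]),
                        require_integer=False)
        report = replicate_report(intra_sample_scale(m))
        ratios = (report["sigma_obs"] / report["sigma_exp"]).dropna()
        assert np.all(ratios < 2) and np.all(ratios > 0.5)


class TestReports:
    def test_segment_report_reference_invariant(self, dilution_series):
        mat, _ = dilution_series
        scaled = intra_sample_scale(mat)
        rep = segment_report(pareto_tail(scaled.data.iloc[:, 0].to_numpy()))
        ref = rep[rep["is_reference"]]
        assert len(ref) == 1
        assert ref["sigma_obs"].iloc[0] == pytest.approx(ref["sigma_exp"].iloc[0])

    def test_replicate_report_reference_invariant(self, dilution_series):
        mat, _ = dilution_series
        rep = replicate_report(intra_sample_scale(mat))
        ref = rep[rep["is_reference"]]
        assert ref["sigma_obs"].iloc[0] == pytest.approx(ref["sigma_exp"].iloc[0])
        assert (rep.loc[rep["slope"] < 0, "sigma_exp"].dropna() > 0).all()
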