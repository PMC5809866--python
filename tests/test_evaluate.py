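import numpy as np
import pandas as pd
import pytest

from plawcorrect import (
    CountMatrix,
    concordance,
    group_compare,
    noise_model_fit,
    normalize,
    residuals,
    roc_from_foldchanges,
    significance_cutoffs,
    significant_calls,
    snr,
)
from plawcorrect.evaluate import NORMALIZERS, EvaluationError


def matrix_from(counts: dict) -> CountMatrix:
    df = pd.DataFrame(counts)
    df.index = [f"t{i}" for i in range(len(df))]
    return CountMatrix(df, require_integer=False)


class TestNormalize:
    @pytest.mark.parametrize("method", NORMALIZERS)
    def test_identical_samples_stay_identical(self, rng, method):
        col = rng.integers(1, 1000, 50)
        m = matrix_from({"a": col, "b": col.copy()})
        out = normalize(m, method)
        assert np.allclose(out["a"], out["b"])

    def test_cpm_example(self):
        # one transcript with count 1 in both samples; library sizes 1e6, 2e6
        m = matrix_from({"a": [1, 999_999], "b": [1, 1_999_999]})
        out = normalize(m, "cpm")
        assert out.loc["t0", "a"] == pytest.approx(1.0)
        assert out.loc["t0", "b"] == pytest.approx(0.5)

    def test_median_ratio_scale_recovery(self, rng):
        a = rng.integers(10, 1000, 80)
        m = matrix_from({"a": a, "b": 2 * a})
        out = normalize(m, "median_ratio")
        # size factors in ratio 1:2 equalize the doubled sample exactly
        assert np.allclose(out["a"], out["b"])

    @pytest.mark.parametrize("method", ["cpm", "upper_quartile", "median_ratio"])
    def test_invariant_to_global_sample_scalar(self, rng, method):
        a = rng.integers(1, 500, 60)
        b = rng.integers(1, 500, 60)
        m1 = matrix_from({"a": a, "b": b})
        m2 = matrix_from({"a": a * 7, "b": b})
        out1, out2 = normalize(m1, method), normalize(m2, method)
        # column ratios unchanged up to the method's overall scale convention
        ratio = out2.to_numpy() / out1.to_numpy()
        assert np.allclose(ratio, ratio.flat[0])

    def test_quantile_ties_get_tied_means(self):
        m = matrix_from({"a": [5, 5, 1], "b": [9, 2, 3]})
        out = normalize(m, "quantile")
        assert out.loc["t0", "a"] == out.loc["t1", "a"]

    def test_unknown_method(self):
        m = matrix_from({"a": [1, 2]})
        with pytest.raises(EvaluationError, match="unknown"):
            normalize(m, "tmm")


class TestNoiseModel:
    def test_exact_line(self):
        assert noise_model_fit([1.0, 2.0], [2.0, 4.0]) == pytest.approx(2.0)

    def test_symmetric_m_gives_zero(self):
        A = np.array([1.0, 1.0, 3.0, 3.0])
        M = np.array([0.5, -0.5, 1.0, -1.0])
        assert noise_model_fit(A, M) == pytest.approx(0.0)

    def test_matches_closed_form(self, rng):
        A, M = rng.normal(5, 2, 200), rng.normal(0, 1, 200)
        assert noise_model_fit(A, M) == pytest.approx(
            float(np.sum(A * M) / np.sum(A * A))
        )

    def test_rejects_all_zero_abundance(self):
        with pytest.raises(EvaluationError):
            noise_model_fit([0.0, 0.0], [1.0, 2.0])


class TestSNR:
    def test_plug_in(self):
        # noise residuals [1, 0, -1] have sample variance exactly 1
        assert snr([2.0, -2.0], [1.0, 0.0, -1.0]) == pytest.approx(4.0)

    def test_signal_equals_noise_population(self, rng):
        res = rng.normal(0.3, 1.0, 20000)
        got = snr(res, res)
        expect = 1.0 + np.mean(res) ** 2 / np.var(res, ddof=1)
        assert got == pytest.approx(expect, rel=1e-3)

    def test_zero_noise_variance_rejected(self):
        with pytest.raises(EvaluationError):
            snr([1.0], [2.0, 2.0])


class TestCutoffs:
    def test_example(self):
        noise = pd.DataFrame({"M": [-0.5, 0.8], "p": [0.2, 0.01]})
        assert significance_cutoffs(noise) == (pytest.approx(0.8), pytest.approx(0.01))

    def test_missing_pvalues_rejected(self):
        with pytest.raises(EvaluationError):
            significance_cutoffs(pd.DataFrame({"M": [0.5]}))

    def test_calls_match_brute_force(self, rng):
        n = 300
        signal = pd.DataFrame(
            {"M": rng.normal(0, 2, n), "p": rng.random(n)},
            index=[f"t{i}" for i in range(n)],
        )
        noise = pd.DataFrame({"M": rng.normal(0, 1, 50), "p": rng.random(50) / 2})
        fc, pc = significance_cutoffs(noise)
        calls = significant_calls(signal, fc, pc)
        expected = {
            t: int(np.sign(signal.loc[t, "M"]))
            for t in signal.index
            if abs(signal.loc[t, "M"]) > fc and signal.loc[t, "p"] < pc
        }
        assert calls == expected

    def test_no_calls_when_cutoffs_exclude_everything(self):
        signal = pd.DataFrame({"M": [0.1, -0.2], "p": [0.5, 0.9]}, index=["a", "b"])
        assert significant_calls(signal, 1.0, 1e-4) == {}


class TestConcordance:
    def test_example(self):
        i, u, r = concordance([{"x": 1, "y": 1}, {"x": 1, "z": -1}])
        assert (i, u) == (1, 3)
        assert r == pytest.approx(100 / 3)

    def test_identical_sets(self):
        calls = {"a": 1, "b": -1}
        assert concordance([calls, dict(calls)])[2] == pytest.approx(100.0)

    def test_sign_conflict_excluded_from_intersect(self):
        i, u, _ = concordance([{"x": 1}, {"x": -1}])
        assert (i, u) == (0, 1)

    def test_empty_union_is_nan(self):
        assert np.isnan(concordance([{}, {}])[2])

    def test_permutation_invariant_and_monotone(self, rng):
        sets = [
            {f"t{i}": int(np.sign(rng.normal())) or 1 for i in rng.integers(0, 30, 15)}
            for _ in range(3)
        ]
        a = concordance(sets)
        b = concordance(sets[::-1])
        assert a == b
        # adding a set can only shrink the intersect and grow the union
        i2, u2, _ = concordance(sets[:2])
        i3, u3, _ = concordance(sets)
        assert i3 <= i2 and u3 >= u2


class TestROC:
    def test_perfect_separation_hits_corner(self):
        roc = roc_from_foldchanges([5.0, 6.0, 7.0], [0.5, 1.0])
        corner = roc[(roc["sensitivity"] == 1.0) & (roc["specificity"] == 1.0)]
        assert len(corner) >= 1

    def test_endpoint_sensitivity_at_full_specificity(self, rng):
        signal = rng.normal(0, 2, 200)
        noise = rng.normal(0, 1, 100)
        roc = roc_from_foldchanges(signal, noise)
        full_spec = roc[roc["specificity"] == 1.0]
        expect = np.mean(np.abs(signal) > np.abs(noise).max())
        assert full_spec["sensitivity"].max() == pytest.approx(expect)

    def test_null_auc_near_half(self):
        aucs = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            pop = rng.normal(0, 1, 400)
            roc = roc_from_foldchanges(pop[:200], pop[200:])
            roc = roc.sort_values("specificity")
            aucs.append(np.trapezoid(roc["sensitivity"], 1 - roc["specificity"]))
        assert abs(np.mean(aucs)) - 0.5 < 0.1


class TestGroupCompare:
    def test_known_fold_change(self):
        background = [100] * 50
        m = matrix_from({"a1": [400] + background, "a2": [400] + background,
                         "b1": [100] + background, "b2": [100] + background})
        df = group_compare(normalize(m, "cpm"), ["a1", "a2"], ["b1", "b2"])
        # cpm equalizes the library sizes; the planted 4x remains on t0
        assert df.loc["t0", "M"] == pytest.approx(2.0, abs=0.1)
        assert df.loc["t1", "M"] == pytest.approx(0.0, abs=0.1)

    def test_pvalues_need_replicates(self):
        m = matrix_from({"a": [1, 2], "b": [2, 1]})
        with pytest.raises(EvaluationError):
            group_compare(normalize(m, "cpm"), ["a"], ["b"], with_pvalues=True)

    def test_residuals_definition(self):
        A, M = np.array([1.0, 2.0]), np.array([3.0, 1.0])
        assert np.allclose(residuals(A, M, 0.5), M - 0.5 * A)
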