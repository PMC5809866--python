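"""Downstream evaluation: normalizers, MA-space noise model, SNR,
significance cutoffs, concordance and ROC.

The normalizers here are formula-level stand-ins for the usual panel
(CPM, upper-quartile, quantile, median-of-ratios); they exist to measure
how much a correction step helps *any* reasonable normalization, not to
reproduce a specific package's output.  Comparative statistics live in
MA space: per transcript, A is the average log2 abundance and M the log2
fold change between two samples or groups.  Within-condition comparisons
("noise") calibrate a through-origin linear noise model M = m*A, whose
residuals feed the signal-to-noise ratio E(x_signal^2) / var(noise), and
whose extremes set the fold-change and p-value significance cutoffs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .countdata import CountMatrix

__all__ = [
    "normalize",
    "group_compare",
    "noise_model_fit",
    "residuals",
    "snr",
    "significance_cutoffs",
    "significant_calls",
    "concordance",
    "roc_from_foldchanges",
    "NORMALIZERS",
]

NORMALIZERS = ("cpm", "upper_quartile", "quantile", "median_ratio")

PSEUDOCOUNT = 0.5  # added before log2 so zero-adjacent values stay finite


class EvaluationError(ValueError):
    pass


def _quantile_normalize(df: pd.DataFrame) -> pd.DataFrame:
    ranks = df.rank(method="average", axis=0)
    sorted_vals = np.sort(df.to_numpy(), axis=0)
    row_means = sorted_vals.mean(axis=1)
    positions = np.arange(1, len(df) + 1, dtype=float)
    out = {
        col: np.interp(ranks[col].to_numpy(), positions, row_means)
        for col in df.columns
    }
    return pd.DataFrame(out, index=df.index)


def normalize(m: CountMatrix, method: str) -> pd.DataFrame:
    """Normalize a count matrix with one of the built-in methods.

    cpm: counts * 1e6 / library size.
    upper_quartile: counts / per-sample 75th percentile of nonzero
        counts, rescaled to the mean library size.
    quantile: each sample's sorted values replaced by cross-sample rank
        means (ties receive the mean of the tied positions).
    median_ratio: DESeq-style size factors -- per sample the median over
        all-positive transcripts of count / geometric mean across samples.
    """
    df = m.data
    lib = df.sum(axis=0)
    if (lib <= 0).any():
        raise EvaluationError("non-positive library size")
    if method == "cpm":
        return df * 1e6 / lib
    if method == "upper_quartile":
        q75 = pd.Series(
            {c: np.percentile(df[c][df[c] > 0], 75) for c in df.columns}
        )
        return df / q75 * float(lib.mean())
    if method == "quantile":
        return _quantile_normalize(df)
    if method == "median_ratio":
        pos = (df > 0).all(axis=1)
        if not pos.any():
            raise EvaluationError("no transcript is positive in every sample")
        log_gm = np.log(df[pos]).mean(axis=1)
        factors = np.exp(np.log(df[pos]).sub(log_gm, axis=0).median(axis=0))
        return df / factors
    raise EvaluationError(f"unknown normalization method: {method!r}")


def group_compare(
    norm: pd.DataFrame,
    group1: list[str],
    group2: list[str],
    with_pvalues: bool = False,
) -> pd.DataFrame:
    """MA-space comparison of two sample groups on normalized values.

    Per transcript: A = average log2(value + 0.5) across the two groups'
    means, M = log2 fold change (group1 over group2).  With
    ``with_pvalues=True`` a two-sample t-test on the log2 values supplies
    a stand-in p-value (each group needs >= 2 samples); it exercises the
    cutoff machinery and makes no claim to replicate a count GLM.
    """
    l1 = np.log2(norm[group1] + PSEUDOCOUNT)
    l2 = np.log2(norm[group2] + PSEUDOCOUNT)
    mean1, mean2 = l1.mean(axis=1), l2.mean(axis=1)
    out = pd.DataFrame(
        {"A": 0.5 * (mean1 + mean2), "M": mean1 - mean2}, index=norm.index
    )
    if with_pvalues:
        n1, n2 = len(group1), len(group2)
        if n1 < 2 or n2 < 2:
            raise EvaluationError("p-values need >= 2 samples per group")
        # Moderated two-sample t: per-transcript pooled variance smoothed by
        # the median pooled variance across transcripts, so technical
        # replicates with near-zero spread cannot yield p -> 0.
        ss = l1.var(axis=1, ddof=1) * (n1 - 1) + l2.var(axis=1, ddof=1) * (n2 - 1)
        df_resid = n1 + n2 - 2
        s2 = ss / df_resid
        s2_floor = float(np.median(s2))
        se = np.sqrt((s2 + s2_floor) * (1.0 / n1 + 1.0 / n2))
        t = (mean1 - mean2) / se
        p = 2.0 * stats.t.sf(np.abs(t), df_resid)
        out["p"] = np.where(np.isnan(p), 1.0, p)
    return out


def noise_model_fit(A: np.ndarray, M: np.ndarray) -> float:
    """Slope of the through-origin regression M = m*A (closed form)."""
    A = np.asarray(A, dtype=float)
    M = np.asarray(M, dtype=float)
    if len(A) < 2:
        raise EvaluationError("need at least 2 points")
    denom = float(np.sum(A * A))
    if denom == 0:
        raise EvaluationError("all A values are zero")
    return float(np.sum(A * M) / denom)


def residuals(A: np.ndarray, M: np.ndarray, m_noise: float) -> np.ndarray:
    """Fold-change residuals about the noise model, M - m_noise * A."""
    return np.asarray(M, dtype=float) - m_noise * np.asarray(A, dtype=float)


def snr(signal_residuals: np.ndarray, noise_residuals: np.ndarray) -> float:
    """Signal-to-noise ratio E(x_signal^2) / var(noise)."""
    nr = np.asarray(noise_residuals, dtype=float)
    sr = np.asarray(signal_residuals, dtype=float)
    if len(nr) < 2:
        raise EvaluationError("need at least 2 noise residuals")
    var = float(np.var(nr, ddof=1))
    if var == 0:
        raise EvaluationError("noise residuals have zero variance")
    return float(np.mean(sr**2) / var)


def significance_cutoffs(noise: pd.DataFrame) -> tuple[float, float]:
    """Cutoffs that exclude everything the noise comparisons produced.

    fc_cutoff = largest |M| over the noise set; p_cutoff = smallest noise
    p-value.  A signal transcript is significant iff |M| > fc_cutoff and
    p < p_cutoff.
    """
    if noise.empty:
        raise EvaluationError("empty noise set")
    if "p" not in noise.columns or noise["p"].isna().any():
        raise EvaluationError("noise comparisons need p-values")
    return float(noise["M"].abs().max()), float(noise["p"].min())


def significant_calls(
    signal: pd.DataFrame, fc_cutoff: float, p_cutoff: float
) -> dict[str, int]:
    """Significant transcripts with their fold-change sign (+1/-1)."""
    if "p" not in signal.columns:
        raise EvaluationError("signal comparisons need p-values")
    hit = (signal["M"].abs() > fc_cutoff) & (signal["p"] < p_cutoff)
    return {t: int(np.sign(signal.loc[t, "M"])) for t in signal.index[hit]}


def concordance(call_sets: list[dict[str, int]]) -> tuple[int, int, float]:
    """Agreement of significant calls across normalizers.

    intersect = transcripts called by every set with the same fold-change
    sign; union = called by any set.  Ratio = 100 * intersect / union,
    NaN when the union is empty.
    """
    if len(call_sets) < 2:
        raise EvaluationError("need at least 2 call sets")
    union: set[str] = set()
    for cs in call_sets:
        union |= set(cs)
    inter = [
        t
        for t in call_sets[0]
        if all(t in cs and cs[t] == call_sets[0][t] for cs in call_sets[1:])
    ]
    ratio = 100.0 * len(inter) / len(union) if union else float("nan")
    return len(inter), len(union), ratio


def roc_from_foldchanges(
    signal_M: np.ndarray, noise_M: np.ndarray
) -> pd.DataFrame:
    """ROC staircase over the |fold change| thresholds of the noise set.

    For every threshold t (the sorted unique |noise M| values plus 0 and
    the maximum): sensitivity = fraction of signal with |M| > t,
    specificity = fraction of noise with |M| <= t.
    """
    s = np.abs(np.asarray(signal_M, dtype=float))
    n = np.abs(np.asarray(noise_M, dtype=float))
    if len(s) == 0 or len(n) == 0:
        raise EvaluationError("signal and noise sets must be nonempty")
    thresholds = np.unique(np.concatenate(([0.0], n, [n.max()])))
    rows = [
        {
            "threshold": t,
            "sensitivity": float(np.mean(s > t)),
            "specificity": float(np.mean(n <= t)),
        }
        for t in thresholds
    ]
    return pd.DataFrame(rows)
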