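"""Rank-frequency / Pareto-tail machinery.

The empirical distribution of scaled counts is viewed as a Pareto-tail
curve: unique scaled count values x sorted descending, paired with their
rank f = 1..U (f = 1 at the maximum).  On log-log axes a pure power law
x = C1 * f**(-b) appears as a straight line of slope m = -1/b when rank is
regressed on amplitude, log10 f = log10 k + m * log10 x, with s = -m the
Pareto tail exponent.  All fits here are ordinary least squares in base-10
log space; slopes are base-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .countdata import ScaledMatrix

__all__ = [
    "ParetoCurve",
    "SegmentFit",
    "MomentResult",
    "pareto_tail",
    "fit_segment",
    "segment_by_decade",
    "pareto_moments",
    "expected_sigma",
    "sample_pareto",
    "segment_report",
    "replicate_report",
    "worst_sigma_ratio",
]


class PowerLawError(ValueError):
    """Raised for degenerate curves or fit ranges."""


class ParetoCurve:
    """Descending unique amplitudes paired with ranks 1..U.

    ``x`` must be positive; for curves built by :func:`pareto_tail` it is
    strictly decreasing (one point per unique value).  Constructed alias
    signals may bend upward near the terminal rank, so strictness is only
    enforced when ``validate=True``.
    """

    def __init__(self, x: np.ndarray, *, validate: bool = True) -> None:
        x = np.asarray(x, dtype=float)
        if x.ndim != 1 or len(x) < 1:
            raise PowerLawError("curve needs a 1-d amplitude array")
        if (x <= 0).any():
            raise PowerLawError("curve amplitudes must be positive")
        if validate and not (np.diff(x) < 0).all():
            raise PowerLawError("curve amplitudes must be strictly decreasing")
        self.x = x
        self.f = np.arange(1, len(x) + 1)
        self.log10_x = np.log10(x)
        self.log10_f = np.log10(self.f)

    @property
    def f_max(self) -> int:
        return len(self.x)

    def __len__(self) -> int:
        return len(self.x)


@dataclass(frozen=True)
class SegmentFit:
    """OLS fit of log10 rank on log10 amplitude over a curve index range."""

    start: int
    stop: int  # half-open [start, stop)
    m: float
    log10_k: float
    n_points: int
    r_squared: float
    sigma_obs: float

    @property
    def s(self) -> float:
        """Pareto tail exponent, s = -m."""
        return -self.m

    @property
    def b(self) -> float:
        """Rank-frequency exponent, b = 1/s."""
        return 1.0 / self.s


@dataclass(frozen=True)
class MomentResult:
    s: float
    x_min: float
    mu: float
    sigma2: float

    @property
    def mean_is_finite(self) -> bool:
        return bool(np.isfinite(self.mu))

    @property
    def variance_is_finite(self) -> bool:
        return bool(np.isfinite(self.sigma2))


def pareto_tail(scaled_sample: np.ndarray) -> ParetoCurve:
    """Build the Pareto-tail curve of a scaled sample.

    Zeros are dropped; the remaining values are reduced to their unique
    set, sorted descending, and ranked 1..U.  Rank r counts the unique
    values >= x_r, so rank 1 is the maximum and log rank is defined
    everywhere.
    """
    v = np.asarray(scaled_sample, dtype=float)
    v = v[v > 0]
    uniq = np.unique(v)[::-1]
    if len(uniq) < 3:
        raise PowerLawError(
            f"need at least 3 distinct positive values, got {len(uniq)}"
        )
    return ParetoCurve(uniq)


def fit_segment(curve: ParetoCurve, start: int, stop: int) -> SegmentFit:
    """OLS of log10 f on log10 x over curve indices [start, stop)."""
    if stop - start < 3:
        raise PowerLawError("segment needs at least 3 points")
    lx = curve.log10_x[start:stop]
    lf = curve.log10_f[start:stop]
    if np.ptp(lx) == 0:
        raise PowerLawError("degenerate segment: all amplitudes equal")
    res = stats.linregress(lx, lf)
    resid = lf - (res.intercept + res.slope * lx)
    return SegmentFit(
        start=start,
        stop=stop,
        m=float(res.slope),
        log10_k=float(res.intercept),
        n_points=stop - start,
        r_squared=float(res.rvalue**2),
        sigma_obs=float(np.std(resid, ddof=0)),
    )


def _decade_index(x: np.ndarray) -> np.ndarray:
    """Decade bin d such that x in [10**(-d-1), 10**(-d)).

    The top decade is closed at 1 (a scaled sample's maximum).  Amplitudes
    above 1 fall into negative bins by the same rule.
    """
    t = -np.log10(np.asarray(x, dtype=float))
    d = np.ceil(t).astype(int) - 1
    d[t == 0] = 0  # the top decade is closed at 1
    return d


def decade_ranges(curve: ParetoCurve, min_points: int = 3) -> list[tuple[int, int]]:
    """Index ranges of the order-of-magnitude segments of a curve.

    Boundaries sit at powers of ten of the amplitude.  A decade with fewer
    than ``min_points`` points is merged into the adjacent higher-count
    segment (the leading decade, if short, merges downward instead).
    """
    if curve.x[0] / curve.x[-1] < 10:
        raise PowerLawError("curve spans less than one decade in amplitude")
    d = _decade_index(curve.x)
    ranges: list[tuple[int, int]] = []
    for dec in np.unique(d):
        idx = np.nonzero(d == dec)[0]
        ranges.append((int(idx[0]), int(idx[-1]) + 1))
    merged: list[tuple[int, int]] = [ranges[0]]
    for rng in ranges[1:]:
        if rng[1] - rng[0] < min_points:
            prev = merged.pop()
            merged.append((prev[0], rng[1]))
        else:
            merged.append(rng)
    if len(merged) > 1 and merged[0][1] - merged[0][0] < min_points:
        merged = [(merged[0][0], merged[1][1])] + merged[2:]
    return merged


def segment_by_decade(curve: ParetoCurve) -> list[SegmentFit]:
    """Fit one OLS segment per order of magnitude of the amplitude."""
    return [fit_segment(curve, a, b) for a, b in decade_ranges(curve)]


def pareto_moments(s: float, x_min: float) -> MomentResult:
    """Mean and variance of the Type I Pareto distribution.

    mu = s*x_min/(s-1) for s > 1, infinite otherwise; sigma2 =
    s*x_min**2/((s-1)**2*(s-2)) for s > 2, infinite for 0 < s <= 2.  Small
    exponents therefore carry divergent moments, which is what makes
    shallow-sloped count segments irreproducible between replicates.
    """
    if s <= 0:
        raise PowerLawError(f"exponent must be positive, got {s}")
    if x_min <= 0:
        raise PowerLawError(f"x_min must be positive, got {x_min}")
    mu = s * x_min / (s - 1.0) if s > 1 else np.inf
    sigma2 = s * x_min**2 / ((s - 1.0) ** 2 * (s - 2.0)) if s > 2 else np.inf
    return MomentResult(s=s, x_min=x_min, mu=float(mu), sigma2=float(sigma2))


def expected_sigma(sigma_ref: float, s_ref: float, s_i: float) -> float:
    """Extrapolate a segment's expected residual spread from a reference.

    sigma_exp = sigma_ref * (s_ref / s_i): a segment whose exponent is half
    the reference's is expected to scatter twice as much.
    """
    if s_ref <= 0 or s_i <= 0:
        raise PowerLawError("exponents must be positive")
    return sigma_ref * (s_ref / s_i)


def sample_pareto(s: float, x_min: float, size: int, rng: np.random.Generator) -> np.ndarray:
    """Inverse-CDF draws from the Type I Pareto distribution."""
    if s <= 0 or x_min <= 0:
        raise PowerLawError("s and x_min must be positive")
    u = rng.random(size)
    return x_min * u ** (-1.0 / s)


def segment_report(curve: ParetoCurve) -> pd.DataFrame:
    """Per-decade-segment variability report for one sample's curve.

    For each order-of-magnitude segment: the OLS slope, point count, the
    observed residual spread ``sigma_obs`` of the segment fit, and the
    expected spread ``sigma_exp`` extrapolated from the highest-count
    (reference) segment by the exponent ratio s_ref / s_i.  The reference
    segment's sigma_exp equals its sigma_obs by construction; segments
    with non-negative slope carry no exponent and get sigma_exp = NaN.
    """
    segs = segment_by_decade(curve)
    ref = segs[0]
    rows = []
    for i, seg in enumerate(segs):
        rows.append(
            {
                "segment": i,
                "x_high": curve.x[seg.start],
                "x_low": curve.x[seg.stop - 1],
                "slope": seg.m,
                "n_points": seg.n_points,
                "sigma_obs": seg.sigma_obs,
                "sigma_exp": (
                    expected_sigma(ref.sigma_obs, ref.s, seg.s)
                    if seg.m < 0
                    else np.nan
                ),
                "is_reference": i == 0,
            }
        )
    return pd.DataFrame(rows).set_index("segment")


def replicate_report(
    scaled: ScaledMatrix,
    reference: str | None = None,
) -> pd.DataFrame:
    """Per-decade-segment variability report across replicates.

    For each order-of-magnitude segment of the pooled Pareto curves:

    * ``slope`` -- OLS slope of the pooled (log10 x, log10 f) curve points
      of all samples falling in the decade;
    * ``n_points`` -- number of replicate-vs-reference scatter points;
    * ``sigma_obs`` -- standard deviation of log10(sample) - log10(reference)
      over shared transcripts whose reference value falls in the decade;
    * ``sigma_exp`` -- the reference (highest-count) segment's sigma_obs
      extrapolated by the slope ratio s_ref / s_i;
    * ``is_reference`` -- marker of the highest-count segment, whose
      sigma_exp equals its sigma_obs by construction.

    The reference sample defaults to the one with the largest library size.
    """
    if reference is None:
        reference = scaled.library_sizes.idxmax()
    # pooled curve points, binned by amplitude decade
    pts_x: list[np.ndarray] = []
    pts_f: list[np.ndarray] = []
    for sid in scaled.sample_ids:
        curve = pareto_tail(scaled.sample_values(sid))
        pts_x.append(curve.log10_x)
        pts_f.append(curve.log10_f)
    lx = np.concatenate(pts_x)
    lf = np.concatenate(pts_f)
    dec = _decade_index(10.0**lx)
    # replicate scatter residuals, binned by the reference sample's decade
    ref_vals = scaled.data[reference]
    resid_by_dec: dict[int, list[float]] = {}
    for sid in scaled.sample_ids:
        if sid == reference:
            continue
        v = scaled.data[sid]
        both = (v > 0) & (ref_vals > 0)
        r = np.log10(v[both].to_numpy()) - np.log10(ref_vals[both].to_numpy())
        d_ref = _decade_index(ref_vals[both].to_numpy())
        for dd, rr in zip(d_ref, r):
            resid_by_dec.setdefault(int(dd), []).append(float(rr))

    rows = []
    decades = sorted(set(dec.tolist()))
    for dd in decades:
        sel = dec == dd
        if sel.sum() < 3 or np.ptp(lx[sel]) == 0:
            continue
        res = stats.linregress(lx[sel], lf[sel])
        resid = resid_by_dec.get(dd, [])
        rows.append(
            {
                "decade": dd,
                "slope": float(res.slope),
                "n_points": len(resid),
                "sigma_obs": float(np.std(resid, ddof=1)) if len(resid) > 1 else np.nan,
            }
        )
    if not rows:
        raise PowerLawError("no decade segment has enough points to fit")
    report = pd.DataFrame(rows).set_index("decade").sort_index()
    ref_dec = report.index[0]
    s_ref = -report.loc[ref_dec, "slope"]
    sigma_ref = report.loc[ref_dec, "sigma_obs"]
    report["sigma_exp"] = [
        expected_sigma(sigma_ref, s_ref, -sl) if sl < 0 else np.nan
        for sl in report["slope"]
    ]
    report["is_reference"] = report.index == ref_dec
    return report


def worst_sigma_ratio(report: pd.DataFrame) -> float:
    """Largest sigma_obs / sigma_exp over the non-reference segments."""
    other = report[~report["is_reference"]]
    ratios = other["sigma_obs"] / other["sigma_exp"]
    ratios = ratios[np.isfinite(ratios)]
    if ratios.empty:
        raise PowerLawError("no non-reference segment with finite sigma ratio")
    return float(ratios.max())
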