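"""Segmented power-law correction of count data.

Each sample's Pareto-tail curve is cut into consecutive segments of a
fixed number of points (PPS, points-per-segment) starting from the
highest count.  Every segment gets its own log-log OLS fit (slope m,
intercept log10 k); the highest-count segment supplies the reference pair
(m_ref, log10 k_ref), since it is sampled from the most abundant
transcripts and converges best.  Each count is then mapped onto the
reference power law:

    x' = (k / k_ref)**(1/m_ref) * x**(m / m_ref)

which restores a single common exponent across the whole count range.
The PPS setting is chosen by a grid search that balances a first-segment
slope constraint against cross-replicate agreement (median R^2).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .countdata import CountMatrix, ScaledMatrix, intra_sample_scale
from .powerlaw import (
    ParetoCurve,
    PowerLawError,
    SegmentFit,
    fit_segment,
    pareto_tail,
    segment_by_decade,
)

__all__ = [
    "CorrectionModel",
    "PPSSearchResult",
    "CorrectionResult",
    "partition_pps",
    "fit_correction",
    "apply_correction",
    "optimize_pps",
    "correct_dataset",
    "DEFAULT_PPS_GRID",
]

logger = logging.getLogger(__name__)

DEFAULT_PPS_GRID = tuple(range(5, 101, 5))


class CorrectionError(ValueError):
    pass


def partition_pps(curve: ParetoCurve, pps: int) -> list[tuple[int, int]]:
    """Consecutive index ranges of ``pps`` points from the highest count.

    A terminal remainder of fewer than 3 points is merged into the
    previous range (3 points being the OLS minimum); larger remainders
    stand as their own segment.
    """
    if pps < 5:
        raise CorrectionError(f"pps must be >= 5, got {pps}")
    n = len(curve)
    if n < pps:
        raise CorrectionError(f"curve has {n} points, fewer than pps={pps}")
    edges = list(range(0, n, pps))
    ranges = [(a, min(a + pps, n)) for a in edges]
    if len(ranges) > 1 and ranges[-1][1] - ranges[-1][0] < 3:
        last = ranges.pop()
        prev = ranges.pop()
        ranges.append((prev[0], last[1]))
    return ranges


def apply_correction(
    x,
    segment: SegmentFit,
    m_ref: float,
    log10_k_ref: float,
):
    """Map a count through its segment's fit onto the reference power law.

    Computed in log10 space for stability:
    log10 x' = (log10 k - log10 k_ref) / m_ref + (m / m_ref) * log10 x.
    """
    if m_ref == 0:
        raise CorrectionError("reference slope must be nonzero")
    x = np.asarray(x, dtype=float)
    if (x <= 0).any():
        raise CorrectionError("corrected values are defined for positive counts only")
    log_xp = (segment.log10_k - log10_k_ref) / m_ref + (segment.m / m_ref) * np.log10(x)
    out = 10.0**log_xp
    return float(out) if out.ndim == 0 else out


@dataclass
class CorrectionModel:
    """Per-sample PPS segmentation plus the fitted unique-value mapping."""

    sample_id: str | None
    pps: int
    segments: list[SegmentFit]
    m_ref: float
    log10_k_ref: float
    curve: ParetoCurve = field(repr=False)
    corrected_x: np.ndarray = field(repr=False)

    def transform(self, values: np.ndarray) -> np.ndarray:
        """Corrected values for positive inputs (zeros pass through).

        Values are matched to the model's unique-value grid (the sample's
        own values match exactly; novel values take the segment of the
        nearest unique value).
        """
        v = np.asarray(values, dtype=float)
        out = np.zeros_like(v)
        pos = v > 0
        if not pos.any():
            return out
        asc_x = self.curve.x[::-1]              # ascending unique values
        asc_corr = self.corrected_x[::-1]
        idx = np.searchsorted(asc_x, v[pos])
        idx = np.clip(idx, 0, len(asc_x) - 1)
        lower = np.clip(idx - 1, 0, len(asc_x) - 1)
        nearer_lower = np.abs(v[pos] - asc_x[lower]) < np.abs(v[pos] - asc_x[idx])
        idx[nearer_lower] = lower[nearer_lower]
        exact = np.isclose(asc_x[idx], v[pos], rtol=1e-12, atol=0)
        corr = np.where(exact, asc_corr[idx], np.nan)
        if not exact.all():
            # novel value: re-apply its nearest neighbour's segment fit
            seg_of = np.empty(len(self.curve), dtype=int)
            for si, seg in enumerate(self.segments):
                seg_of[seg.start : seg.stop] = si
            desc_idx = len(asc_x) - 1 - idx
            for j in np.nonzero(~exact)[0]:
                seg = self.segments[seg_of[desc_idx[j]]]
                corr[j] = apply_correction(v[pos][j], seg, self.m_ref, self.log10_k_ref)
        out[pos] = corr
        return out


def fit_correction(
    scaled_sample: np.ndarray,
    pps: int,
    m_ref_override: float | None = None,
    sample_id: str | None = None,
) -> CorrectionModel:
    """Fit the segmented correction model of one scaled sample.

    The reference intercept always comes from the sample's own first
    (highest-count) segment; the reference slope is that segment's slope
    unless a series-level override is supplied, in which case every sample
    of the series is pulled onto the same common exponent.
    """
    curve = pareto_tail(scaled_sample)
    ranges = partition_pps(curve, pps)
    segments = [fit_segment(curve, a, b) for a, b in ranges]
    log10_k_ref = segments[0].log10_k
    m_ref = segments[0].m if m_ref_override is None else float(m_ref_override)
    if m_ref == 0:
        raise CorrectionError("reference slope must be nonzero")
    corrected = np.empty(len(curve))
    for seg in segments:
        corrected[seg.start : seg.stop] = apply_correction(
            curve.x[seg.start : seg.stop], seg, m_ref, log10_k_ref
        )
    violations = int(np.sum(np.diff(corrected) > 0))
    if violations:
        logger.debug(
            "correction of sample %s: %d cross-segment monotonicity violations",
            sample_id,
            violations,
        )
    return CorrectionModel(
        sample_id=sample_id,
        pps=pps,
        segments=segments,
        m_ref=m_ref,
        log10_k_ref=log10_k_ref,
        curve=curve,
        corrected_x=corrected,
    )


@dataclass
class PPSSearchResult:
    """Outcome of the points-per-segment grid search."""

    candidates: list[int]
    median_slopes: list[float]
    median_r2: list[float]
    margin: tuple[float, float]
    selected_pps: int
    selected_slope: float
    within_margin: bool

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pps": self.candidates,
                "median_first_slope": self.median_slopes,
                "median_r2": self.median_r2,
            }
        )


def _corrected_columns(
    scaled: ScaledMatrix, models: dict[str, CorrectionModel]
) -> pd.DataFrame:
    out = {}
    for sid, model in models.items():
        out[sid] = model.transform(scaled.sample_values(sid))
    return pd.DataFrame(out, index=scaled.data.index)


def optimize_pps(
    scaled: ScaledMatrix,
    grid=DEFAULT_PPS_GRID,
    reference: str | None = None,
) -> PPSSearchResult:
    """Grid-search the points-per-segment setting.

    For every candidate PPS the per-sample models are fitted and two
    series-level measures taken: the median first-segment slope across the
    N samples, and the median R^2 of the N-1 log-log regressions of each
    corrected replicate against the corrected reference replicate.  The
    acceptance margin for the slope is mean +/- 1 SD of the decade-based
    highest-count-segment slopes; within the margin, the candidate with
    the largest median R^2 wins (ties to the smallest PPS).
    """
    grid = sorted(set(int(p) for p in grid))
    if not grid:
        raise CorrectionError("empty pps grid")
    sample_ids = scaled.sample_ids
    if len(sample_ids) < 2:
        raise CorrectionError("need at least 2 samples to optimize pps")
    if reference is None:
        reference = scaled.library_sizes.idxmax()

    curves = {sid: pareto_tail(scaled.sample_values(sid)) for sid in sample_ids}
    min_len = min(len(c) for c in curves.values())
    if min_len < grid[0]:
        raise CorrectionError(
            f"shortest curve ({min_len} points) is below the smallest pps {grid[0]}"
        )
    candidates = [p for p in grid if p <= min_len]

    decade_first = [segment_by_decade(curves[sid])[0].m for sid in sample_ids]
    mean_m, sd_m = float(np.mean(decade_first)), float(np.std(decade_first, ddof=0))
    margin = (mean_m - sd_m, mean_m + sd_m)

    med_slopes: list[float] = []
    med_r2: list[float] = []
    for pps in candidates:
        models = {
            sid: fit_correction(scaled.sample_values(sid), pps, sample_id=sid)
            for sid in sample_ids
        }
        med_slopes.append(float(np.median([m.segments[0].m for m in models.values()])))
        corrected = _corrected_columns(scaled, models)
        ref_col = corrected[reference]
        r2s = []
        for sid in sample_ids:
            if sid == reference:
                continue
            col = corrected[sid]
            both = (col > 0) & (ref_col > 0)
            res = stats.linregress(
                np.log10(ref_col[both].to_numpy()), np.log10(col[both].to_numpy())
            )
            r2s.append(res.rvalue**2)
        med_r2.append(float(np.median(r2s)))

    eps = 1e-9
    eligible = [
        i
        for i in range(len(candidates))
        if margin[0] - eps <= med_slopes[i] <= margin[1] + eps
    ]
    within = bool(eligible)
    if not eligible:
        mid = 0.5 * (margin[0] + margin[1])
        dist = [abs(s - mid) for s in med_slopes]
        dmin = min(dist)
        eligible = [i for i in range(len(candidates)) if dist[i] <= dmin + 1e-12]
        warnings.warn(
            "no pps candidate inside the slope margin "
            f"[{margin[0]:.3f}, {margin[1]:.3f}]; falling back to the nearest",
            stacklevel=2,
        )
    best = eligible[0]
    for i in eligible[1:]:
        if med_r2[i] > med_r2[best] + 1e-12:
            best = i
    return PPSSearchResult(
        candidates=candidates,
        median_slopes=med_slopes,
        median_r2=med_r2,
        margin=margin,
        selected_pps=candidates[best],
        selected_slope=med_slopes[best],
        within_margin=within,
    )


@dataclass
class CorrectionResult:
    """Corrected matrix plus the per-sample models behind it."""

    matrix: CountMatrix
    models: dict[str, CorrectionModel]
    search: PPSSearchResult | None
    pps: int
    m_ref: float | None  # series reference slope; None in per-sample mode

    def model_report(self) -> pd.DataFrame:
        rows = []
        for sid, model in self.models.items():
            for i, seg in enumerate(model.segments):
                rows.append(
                    {
                        "sample": sid,
                        "segment": i,
                        "x_high": model.curve.x[seg.start],
                        "x_low": model.curve.x[seg.stop - 1],
                        "m": seg.m,
                        "log10_k": seg.log10_k,
                        "n_points": seg.n_points,
                        "r_squared": seg.r_squared,
                    }
                )
        return pd.DataFrame(rows)


def correct_dataset(
    m: CountMatrix,
    pps: int | str = "auto",
    ref_slope: str = "series",
    round_counts: bool = False,
    grid=DEFAULT_PPS_GRID,
) -> CorrectionResult:
    """Apply the segmented power-law correction to a whole count matrix.

    Scales each sample, optionally grid-searches PPS, fits per-sample
    models (with the series median first-segment slope as the common
    reference slope unless ``ref_slope='per-sample'``), maps every
    positive count through its segment's correction and rescales back to
    count units.  Corrected counts are real-valued unless
    ``round_counts=True`` (nearest integer, floor of 1 for positive
    inputs).  Zero counts pass through unchanged.
    """
    if ref_slope not in ("series", "per-sample"):
        raise CorrectionError(f"unknown ref_slope mode: {ref_slope!r}")
    scaled = intra_sample_scale(m)
    search: PPSSearchResult | None = None
    if pps == "auto":
        search = optimize_pps(scaled, grid=grid)
        pps_val = search.selected_pps
        series_slope = search.selected_slope
    else:
        pps_val = int(pps)
        first = [
            fit_correction(scaled.sample_values(sid), pps_val).segments[0].m
            for sid in scaled.sample_ids
        ]
        series_slope = float(np.median(first))

    override = series_slope if ref_slope == "series" else None
    models = {
        sid: fit_correction(
            scaled.sample_values(sid), pps_val, m_ref_override=override, sample_id=sid
        )
        for sid in scaled.sample_ids
    }
    corrected_scaled = _corrected_columns(scaled, models)
    corrected = corrected_scaled * scaled.scale_factors
    if round_counts:
        vals = corrected.to_numpy()
        pos = m.data.to_numpy() > 0
        vals = np.rint(vals)
        vals[pos] = np.maximum(vals[pos], 1.0)
        corrected = pd.DataFrame(vals, index=corrected.index, columns=corrected.columns)
    matrix = CountMatrix(
        corrected, conditions=m.conditions, require_integer=round_counts
    )
    return CorrectionResult(
        matrix=matrix,
        models=models,
        search=search,
        pps=pps_val,
        m_ref=override,
    )
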