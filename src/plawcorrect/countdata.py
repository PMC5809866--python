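"""Count-table data model: reading, validation, scaling and zero filtering.

A count table is transcripts x samples, tab-separated on disk, with the
first column holding transcript identifiers and the header row holding
sample identifiers.  All downstream modules operate on the two containers
defined here: :class:`CountMatrix` (raw, integer-valued counts) and
:class:`ScaledMatrix` (per-sample intra-sample scaled counts in (0, 1]).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "ScaledMatrix",
    "read_counts",
    "write_counts",
    "intra_sample_scale",
    "filter_nonzero",
]


class CountDataError(ValueError):
    """Raised for malformed or invalid count tables."""


@dataclass
class CountMatrix:
    """Transcript-by-sample count matrix.

    Parameters
    ----------
    data:
        DataFrame with transcript ids as index and sample ids as columns.
        Values must be non-negative; integer-valued unless
        ``require_integer=False`` (corrected counts are real-valued, and
        re-diagnosis of corrected data flows through the same container).
    conditions:
        Optional mapping of sample id to condition label.
    """

    data: pd.DataFrame
    conditions: dict[str, str] | None = None
    require_integer: bool = field(default=True, repr=False)

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise CountDataError(f"duplicate transcript id: {dup!r}")
        if df.columns.has_duplicates:
            dup = df.columns[df.columns.duplicated()][0]
            raise CountDataError(f"duplicate sample id: {dup!r}")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise CountDataError("count matrix contains non-numeric values")
        if not np.all(np.isfinite(values)):
            r, c = np.argwhere(~np.isfinite(values))[0]
            raise CountDataError(
                f"non-finite count at transcript {df.index[r]!r}, sample {df.columns[c]!r}"
            )
        if (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise CountDataError(
                f"negative count at transcript {df.index[r]!r}, sample {df.columns[c]!r}"
            )
        if self.require_integer and not np.allclose(values, np.round(values)):
            r, c = np.argwhere(~np.isclose(values, np.round(values)))[0]
            raise CountDataError(
                f"non-integer count at transcript {df.index[r]!r}, sample {df.columns[c]!r}"
            )
        self.data = df.astype(float)
        if self.conditions is not None:
            missing = set(self.conditions) - set(df.columns)
            if missing:
                raise CountDataError(f"conditions given for unknown samples: {sorted(missing)}")

    # -- convenience accessors -------------------------------------------
    @property
    def transcript_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def library_sizes(self) -> pd.Series:
        """Total counts per sample (the sample's sequencing depth)."""
        return self.data.sum(axis=0)

    def sample_counts(self, sample_id: str) -> np.ndarray:
        return self.data[sample_id].to_numpy()


@dataclass
class ScaledMatrix:
    """Intra-sample scaled counts: each sample divided by its own maximum.

    Nonzero entries lie in (0, 1] with the per-sample maximum mapped to
    exactly 1; zeros stay zero.  ``scale_factors`` holds the divisor
    (the sample's maximum count) and ``library_sizes`` the original
    per-sample totals, which downstream code uses to pick the deepest
    replicate as the surrogate original signal.
    """

    data: pd.DataFrame
    scale_factors: pd.Series
    library_sizes: pd.Series
    conditions: dict[str, str] | None = None

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def sample_values(self, sample_id: str) -> np.ndarray:
        return self.data[sample_id].to_numpy()


def read_counts(path, conditions: dict[str, str] | None = None) -> CountMatrix:
    """Read a tab-separated count table.

    First row: sample ids; first column: transcript ids; cells:
    non-negative integers.  Malformed cells, duplicate ids and negative
    values raise :class:`CountDataError` naming the offender.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, header=0)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise CountDataError(f"cannot parse count table {path}: {exc}") from exc
    if df.shape[1] == 0:
        raise CountDataError(f"count table {path} has no sample columns")
    coerced = {}
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna()
        if bad.any():
            row = df.index[bad.to_numpy().nonzero()[0][0]]
            raise CountDataError(
                f"malformed cell at transcript {row!r}, sample {col!r}"
            )
        coerced[col] = vals
    return CountMatrix(pd.DataFrame(coerced, index=df.index), conditions=conditions)


def write_counts(m: CountMatrix, path) -> None:
    """Write the same tab-separated dialect that :func:`read_counts` reads."""
    out = m.data
    if np.allclose(out.to_numpy(), np.round(out.to_numpy())):
        out = out.round().astype(int)
    out.to_csv(path, sep="\t", index=True)


def intra_sample_scale(m: CountMatrix) -> ScaledMatrix:
    """Divide every sample (column) by that sample's maximum count.

    The per-sample maximum maps to exactly 1; zero counts stay zero.  An
    all-zero sample has no defined scale and raises an error.
    """
    maxima = m.data.max(axis=0)
    zero = maxima[maxima <= 0]
    if len(zero):
        raise CountDataError(f"all-zero sample: {zero.index[0]!r}")
    scaled = m.data / maxima
    return ScaledMatrix(
        data=scaled,
        scale_factors=maxima,
        library_sizes=m.library_sizes(),
        conditions=m.conditions,
    )


def filter_nonzero(m: CountMatrix, groups: list[list[str]]) -> CountMatrix:
    """Keep transcripts with a positive count in every sample of every group.

    This is the usual pre-filter before comparative analysis: a transcript
    missing (zero) in any compared sample cannot carry a finite log fold
    change and is dropped.  Row order is preserved.
    """
    if not groups:
        raise CountDataError("no groups given")
    for g in groups:
        if not g:
            raise CountDataError("empty group in comparison")
        unknown = set(g) - set(m.data.columns)
        if unknown:
            raise CountDataError(f"unknown samples in group: {sorted(unknown)}")
    samples: list[str] = [s for g in groups for s in g]
    keep = (m.data[samples] > 0).all(axis=1)
    return CountMatrix(m.data.loc[keep], conditions=m.conditions,
                       require_integer=False)
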