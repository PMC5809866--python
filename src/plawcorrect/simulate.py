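"""Synthetic count data with the statistical structure the method assumes.

Sequencing is modelled as finite multinomial sampling from a Zipf
transcript library: species abundances p_r proportional to r**(-b)
(b = 1 for Zipf), one multinomial draw of the requested depth per
replicate.  Shallow draws reproduce the finite-size phenomenology the
correction targets: fewer unique count values, flattening low-count
segments, and an aliasing-style distortion of the rank-frequency tail.
A deterministic aliased-signal generator provides the exact test bench
for the aliasing module.

Defaults mirror the dilution design at desk scale: 1000 species, b = 1,
depths spanning 8x (1e6 down to 1.25e5), two technical replicates per
depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .countdata import CountMatrix
from .powerlaw import ParetoCurve

__all__ = [
    "LibraryModel",
    "SimSpec",
    "zipf_library",
    "sequence_sample",
    "make_series",
    "alias_signal",
    "DEFAULT_DEPTHS",
]

DEFAULT_DEPTHS = (1_000_000, 500_000, 250_000, 125_000)


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class LibraryModel:
    """A transcript library: abundance probabilities p_r ~ r**(-b)."""

    n_species: int
    b: float
    p: np.ndarray = field(repr=False)


@dataclass
class SimSpec:
    """Design of a simulated dilution / two-condition series.

    ``depths`` are the per-replicate total read counts of condition "A";
    ``depths_b`` (optional) adds a second condition "B" whose library has
    ``planted`` log2 fold changes applied multiplicatively to the
    abundances before renormalization, so library-composition effects are
    present, as in real data.
    """

    library: LibraryModel
    depths: tuple[int, ...] = DEFAULT_DEPTHS
    replicates: int = 2
    seed: int = 0
    depths_b: tuple[int, ...] | None = None
    planted: dict[int, float] | None = None  # species index -> log2 fold change


def zipf_library(n_species: int, b: float = 1.0) -> LibraryModel:
    """Zipf/power-law abundance library: p_r proportional to r**(-b)."""
    if n_species < 10:
        raise SimulationError(f"need at least 10 species, got {n_species}")
    if b < 0:
        raise SimulationError(f"exponent must be non-negative, got {b}")
    r = np.arange(1, n_species + 1, dtype=float)
    w = r ** (-b)
    return LibraryModel(n_species=n_species, b=b, p=w / w.sum())


def sequence_sample(
    lib: LibraryModel, depth: int, rng: np.random.Generator
) -> np.ndarray:
    """One multinomial sequencing draw of ``depth`` total reads."""
    if depth < 1:
        raise SimulationError(f"depth must be >= 1, got {depth}")
    return rng.multinomial(int(depth), lib.p)


def _planted_library(lib: LibraryModel, planted: dict[int, float]) -> LibraryModel:
    w = lib.p.copy()
    for idx, log2fc in planted.items():
        w[idx] *= 2.0**log2fc
    return LibraryModel(n_species=lib.n_species, b=lib.b, p=w / w.sum())


def make_series(spec: SimSpec) -> tuple[CountMatrix, dict]:
    """Simulate the full replicate series of a :class:`SimSpec`.

    Returns the count matrix (columns named ``<cond>_d<depth>_r<i>``)
    plus a ground-truth record: the library exponent, planted fold
    changes, and per-column depths.  The output is a deterministic
    function of ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    lib_a = spec.library
    ids = [f"t{i:04d}" for i in range(lib_a.n_species)]
    cols: dict[str, np.ndarray] = {}
    conditions: dict[str, str] = {}
    depths_used: dict[str, int] = {}

    def emit(cond: str, lib: LibraryModel, depths) -> None:
        for depth in depths:
            for rep in range(1, spec.replicates + 1):
                sid = f"{cond}_d{int(depth)}_r{rep}"
                cols[sid] = sequence_sample(lib, depth, rng)
                conditions[sid] = f"{cond}_{int(depth)}"
                depths_used[sid] = int(depth)

    emit("A", lib_a, spec.depths)
    if spec.depths_b is not None:
        lib_b = (
            _planted_library(lib_a, spec.planted) if spec.planted else lib_a
        )
        emit("B", lib_b, spec.depths_b)

    matrix = CountMatrix(pd.DataFrame(cols, index=ids), conditions=conditions)
    truth = {
        "b_true": lib_a.b,
        "planted": {ids[i]: fc for i, fc in (spec.planted or {}).items()},
        "depths": depths_used,
    }
    return matrix, truth


def alias_signal(S_o: float, alpha: float, f_s: float, f_max: int) -> ParetoCurve:
    """Deterministic undersampled power-law signal.

    Y(f) = S_o * f**(-alpha) + S_o * (f_s - f)**(-alpha) for f = 1..f_max.
    The returned curve skips the strict-decrease check: close to f_s the
    alias term bends the amplitude back upward, exactly as an aliased
    spectrum folds.
    """
    if f_s <= f_max:
        raise SimulationError("alias model requires f_s > f_max")
    f = np.arange(1, int(f_max) + 1, dtype=float)
    y = S_o * f ** (-alpha) + S_o * (f_s - f) ** (-alpha)
    return ParetoCurve(y, validate=False)
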