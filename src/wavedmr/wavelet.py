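"""Dyadic multiresolution decomposition of methylation signals.

Each decomposition step convolves the current scaling coefficients with a
low-pass/high-pass filter pair and downsamples by two, halving (ceil) the
coefficient count.  Two normalizations are supported:

``orthonormal``
    the raw filter-bank output; with the Haar pair it conserves energy.
``mean``
    each step's scaling output is additionally scaled by ``2**-0.5`` so
    that with the Haar pair a level-``j`` coefficient equals the plain
    average of the ``2**j`` original positions under it — detection then
    compares values that stay on the [0, 1] ratio scale at every level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from wavedmr.signal_core import MethylationSignal

__all__ = [
    "WaveletFilter",
    "TransformedSignal",
    "FILTER_BANKS",
    "get_filter",
    "dwt_step",
    "transform",
    "coefficient_span",
    "export_multiresolution",
    "max_level",
]

_SQRT2_2 = math.sqrt(2.0) / 2.0

# Decomposition banks (low-pass h, high-pass g).  The haar pair is
# h = [sqrt(2)/2, sqrt(2)/2], g = [-sqrt(2)/2, sqrt(2)/2]; the
# biorthogonal/spline banks are the standard published coefficients
# (cross-checked against PyWavelets' dec_lo/dec_hi at build time).
FILTER_BANKS: dict[str, tuple[tuple[float, ...], tuple[float, ...]]] = {
    "haar": ((_SQRT2_2, _SQRT2_2), (-_SQRT2_2, _SQRT2_2)),
    "bior3.1": (
        (-0.3535533905932738, 1.0606601717798212,
         1.0606601717798212, -0.3535533905932738),
        (-0.1767766952966369, 0.5303300858899106,
         -0.5303300858899106, 0.1767766952966369),
    ),
    "bior3.3": (
        (0.06629126073623882, -0.1988737822087165, -0.15467960838455727,
         0.9943689110435825, 0.9943689110435825, -0.15467960838455727,
         -0.1988737822087165, 0.06629126073623882),
        (0.0, 0.0, -0.1767766952966369, 0.5303300858899106,
         -0.5303300858899106, 0.1767766952966369, 0.0, 0.0),
    ),
    "bior3.5": (
        (-0.013810679320049757, 0.04143203796014927, 0.052480581416189075,
         -0.26792717880896527, -0.07181553246425873, 0.966747552403483,
         0.966747552403483, -0.07181553246425873, -0.26792717880896527,
         0.052480581416189075, 0.04143203796014927, -0.013810679320049757),
        (0.0, 0.0, 0.0, 0.0, -0.1767766952966369, 0.5303300858899106,
         -0.5303300858899106, 0.1767766952966369, 0.0, 0.0, 0.0, 0.0),
    ),
    # quadratic spline biorthogonal pair (a.k.a. bior2.2 / CDF 5/3)
    "spline2.2": (
        (0.0, -0.1767766952966369, 0.3535533905932738, 1.0606601717798212,
         0.3535533905932738, -0.1767766952966369),
        (0.0, 0.3535533905932738, -0.7071067811865476,
         0.3535533905932738, 0.0, 0.0),
    ),
}


@dataclass(frozen=True)
class WaveletFilter:
    """A decomposition filter pair: low-pass ``h`` and high-pass ``g``."""

    name: str
    h: tuple[float, ...]
    g: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.h or not self.g:
            raise ValueError("filters must be non-empty")


def get_filter(name: str) -> WaveletFilter:
    """Look up a named filter bank (haar, bior3.1/3.3/3.5, spline2.2)."""
    try:
        h, g = FILTER_BANKS[name]
    except KeyError:
        raise ValueError(
            f"unknown wavelet filter {name!r}; choose from {sorted(FILTER_BANKS)}"
        ) from None
    return WaveletFilter(name=name, h=h, g=g)


@dataclass
class TransformedSignal:
    """Level-``j`` scaling (and optionally detail) coefficients of a signal."""

    level: int
    scaling: np.ndarray
    detail: np.ndarray | None
    normalization: str
    chromosome: str
    start: int
    end: int
    sample_id: str = ""


def dwt_step(
    c: np.ndarray, wav_filter: WaveletFilter
) -> tuple[np.ndarray, np.ndarray]:
    """One decomposition-with-downsampling step.

    ``scaling[k] = sum_m h[m] * c[2k + m]`` (and likewise with ``g`` for the
    detail), with zero padding past the end of ``c``.  Both outputs have
    length ``ceil(len(c) / 2)``.
    """
    c = np.asarray(c, dtype=np.float64)
    n = len(c)
    if n == 0:
        raise ValueError("input coefficient array is empty")
    n_out = (n + 1) // 2
    h = np.asarray(wav_filter.h)
    g = np.asarray(wav_filter.g)
    taps = max(len(h), len(g))
    padded = np.zeros(2 * n_out + taps, dtype=np.float64)
    padded[:n] = c
    scaling = np.zeros(n_out, dtype=np.float64)
    detail = np.zeros(n_out, dtype=np.float64)
    for m, hm in enumerate(h):
        if hm:
            scaling += hm * padded[m : m + 2 * n_out : 2]
    for m, gm in enumerate(g):
        if gm:
            detail += gm * padded[m : m + 2 * n_out : 2]
    return scaling, detail


def max_level(n: int) -> int:
    """Largest number of dyadic steps before the signal degenerates to
    repeated length-1 arrays: ``ceil(log2(n))``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return max(0, math.ceil(math.log2(n)))


def transform(
    signal: MethylationSignal,
    wav_filter: WaveletFilter | str = "haar",
    level: int = 1,
    normalization: str = "mean",
    keep_detail: bool = False,
) -> TransformedSignal:
    """Apply ``level`` dyadic decomposition steps to a methylation signal.

    Each step's scaling output feeds the next step.  Level 0 returns the
    input values unchanged.
    """
    if isinstance(wav_filter, str):
        wav_filter = get_filter(wav_filter)
    if level < 0:
        raise ValueError("level must be >= 0")
    if normalization not in ("orthonormal", "mean"):
        raise ValueError("normalization must be orthonormal|mean")
    n = len(signal)
    if level > max_level(n):
        raise ValueError(
            f"level {level} reduces a length-{n} signal below one coefficient"
        )
    c = np.asarray(signal.values, dtype=np.float64)
    d: np.ndarray | None = None
    for _ in range(level):
        c, d = dwt_step(c, wav_filter)
        if normalization == "mean":
            c = c * (2.0 ** -0.5)
            d = d * (2.0 ** -0.5)
    return TransformedSignal(
        level=level,
        scaling=c,
        detail=d if keep_detail else None,
        normalization=normalization,
        chromosome=signal.chromosome,
        start=signal.start,
        end=signal.end,
        sample_id=signal.sample_id,
    )


def coefficient_span(level: int, index: int, signal_start: int) -> tuple[int, int]:
    """Genomic interval (1-based inclusive) summarized by one level-``j``
    coefficient: ``2**level`` consecutive positions."""
    if level < 0 or index < 0:
        raise ValueError("level and index must be >= 0")
    width = 1 << level
    lo = signal_start + index * width
    return lo, lo + width - 1


def export_multiresolution(
    signal: MethylationSignal,
    wav_filter: WaveletFilter | str = "haar",
    levels: Sequence[int] = (0,),
) -> list[tuple[int, int, int, float]]:
    """Tabulate mean-normalized scaling coefficients at several levels.

    Returns rows ``(level, genomic_start, genomic_end, value)``, one per
    coefficient per requested level — ready for stacked-panel plotting or
    TSV export.
    """
    if list(levels) != sorted(levels):
        raise ValueError("levels must be sorted ascending")
    rows: list[tuple[int, int, int, float]] = []
    for level in levels:
        t = transform(signal, wav_filter, level=level, normalization="mean")
        for idx, value in enumerate(t.scaling):
            lo, hi = coefficient_span(level, idx, signal.start)
            rows.append((level, lo, hi, float(value)))
    return rows
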