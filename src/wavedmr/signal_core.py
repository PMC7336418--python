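"""Dense per-position methylation ratio and coverage signals.

A map of sparse per-position counts becomes a dense array over a genomic
interval: ``values[k]`` is the methylation (or hydroxymethylation) ratio at
position ``start + k`` and ``coverage[k]`` is the informative read depth
there.  Positions without a record are zero-valued with zero coverage.
Reads showing a base other than C never contribute.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from wavedmr.meth_io import MethylationMap, MethylationRecord

__all__ = [
    "MethylationSignal",
    "compute_mratio",
    "compute_hmratio",
    "build_signal",
]

ANALYSIS_TYPES = ("5mC", "5hmC")


@dataclass
class MethylationSignal:
    """Ratio values in [0,1] plus informative coverage over [start, end]."""

    chromosome: str
    start: int
    end: int
    values: np.ndarray
    coverage: np.ndarray
    analysis_type: str = "5mC"
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("end < start")
        if self.analysis_type not in ANALYSIS_TYPES:
            raise ValueError(f"analysis_type must be one of {ANALYSIS_TYPES}")
        n = self.end - self.start + 1
        self.values = np.asarray(self.values, dtype=np.float64)
        self.coverage = np.asarray(self.coverage, dtype=np.int64)
        if len(self.values) != n or len(self.coverage) != n:
            raise ValueError("values/coverage length must equal end - start + 1")
        if np.any(self.values < 0.0) or np.any(self.values > 1.0):
            raise ValueError("signal values must lie in [0, 1]")
        if np.any(self.coverage < 0):
            raise ValueError("coverage must be non-negative")
        if np.any(self.values[self.coverage == 0] != 0.0):
            raise ValueError("zero-coverage positions must have value 0")

    def __len__(self) -> int:
        return self.end - self.start + 1


def compute_mratio(record: MethylationRecord) -> float:
    """Methylated-read fraction mc/(c+mc); 0 when no informative reads."""
    denom = record.c_count + record.mc_count
    if denom == 0:
        return 0.0
    return record.mc_count / denom


def compute_hmratio(record: MethylationRecord) -> float:
    """Hydroxymethylated-read fraction hmc/(c+hmc); 0 when no informative reads."""
    denom = record.c_count + record.hmc_count
    if denom == 0:
        return 0.0
    return record.hmc_count / denom


def build_signal(
    meth_map: MethylationMap,
    start: int,
    end: int,
    analysis_type: str = "5mC",
) -> MethylationSignal:
    """Fill a dense ratio/coverage array over [start, end] from a sparse map.

    Coverage is the informative depth — the ratio denominator ``c + mc``
    (``c + hmc`` for 5hmC analysis) — not the total depth; records outside
    the interval are ignored.
    """
    if end < start:
        raise ValueError(f"end ({end}) < start ({start})")
    if analysis_type not in ANALYSIS_TYPES:
        raise ValueError(f"analysis_type must be one of {ANALYSIS_TYPES}")
    n = end - start + 1
    values = np.zeros(n, dtype=np.float64)
    coverage = np.zeros(n, dtype=np.int64)
    hydroxy = analysis_type == "5hmC"
    for rec in meth_map.records:
        if rec.position < start or rec.position > end:
            continue
        k = rec.position - start
        if hydroxy:
            values[k] = compute_hmratio(rec)
            coverage[k] = rec.c_count + rec.hmc_count
        else:
            values[k] = compute_mratio(rec)
            coverage[k] = rec.c_count + rec.mc_count
    return MethylationSignal(
        chromosome=meth_map.chromosome,
        start=start,
        end=end,
        values=values,
        coverage=coverage,
        analysis_type=analysis_type,
        sample_id=meth_map.sample_id,
    )
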