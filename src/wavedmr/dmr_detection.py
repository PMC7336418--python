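"""Three-stage DMR calling on wavelet-reduced methylation signals.

Stage one averages the level-``j`` scaling coefficients of all samples in
each group; stage two marks every window whose absolute group difference
strictly exceeds the detection threshold; stage three validates each marked
window against the per-position coverage of the untransformed signals and
groups adjacent surviving windows into regions.  Validation happens after
marking — the signal itself is never zeroed by coverage filtering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from wavedmr.meth_io import GeneAnnotation, MethylationMap
from wavedmr.signal_core import MethylationSignal
from wavedmr.wavelet import TransformedSignal, coefficient_span, get_filter, transform

__all__ = [
    "DetectionConfig",
    "DMRegion",
    "SampleStats",
    "group_average",
    "mark_dm",
    "required_covered",
    "validate_coverage",
    "group_adjacent",
    "classify_direction",
    "sample_stats",
    "nearest_gene",
    "detect_dmrs",
]

COVERAGE_POOLING = ("all", "any", "per-group-mean")


@dataclass(frozen=True)
class DetectionConfig:
    """Detection parameters.

    ``level`` has no default on purpose: the best resolution level is
    dataset-dependent, so the caller must choose it explicitly.
    """

    level: int
    dmr_threshold: float = 0.25
    coverage_threshold: int = 1
    min_valid_fraction: float = 0.25
    analysis_type: str = "5mC"
    filter_name: str = "haar"
    coverage_pooling: str = "all"

    def __post_init__(self) -> None:
        if self.level < 1:
            raise ValueError("level must be >= 1")
        if not 0.0 < self.dmr_threshold <= 1.0:
            raise ValueError("dmr_threshold must be in (0, 1]")
        if self.coverage_threshold < 0:
            raise ValueError("coverage_threshold must be >= 0")
        if not 0.0 < self.min_valid_fraction <= 1.0:
            raise ValueError("min_valid_fraction must be in (0, 1]")
        if self.analysis_type not in ("5mC", "5hmC"):
            raise ValueError("analysis_type must be 5mC|5hmC")
        if self.coverage_pooling not in COVERAGE_POOLING:
            raise ValueError(f"coverage_pooling must be one of {COVERAGE_POOLING}")
        get_filter(self.filter_name)  # validates the name


@dataclass
class SampleStats:
    """Descriptive statistics for one sample inside one DMR.

    Computed over informative positions only (positions carrying a record);
    all fields are 0 when the sample has no data in the region.
    """

    sample_id: str
    n_informative: int = 0
    coverage_min: float = 0.0
    coverage_avg: float = 0.0
    coverage_max: float = 0.0
    reads_c: int = 0
    reads_mc: int = 0
    reads_hmc: int = 0
    reads_noc: int = 0
    gap_min: float = 0.0
    gap_avg: float = 0.0
    gap_max: float = 0.0


@dataclass
class DMRegion:
    """A called differentially methylated region (1-based inclusive)."""

    chromosome: str
    start: int
    end: int
    direction: str  # hyper | hypo, case relative to control
    mean_difference: float
    n_windows: int
    level: int
    closest_gene: str | None = None
    gene_distance: int | None = None
    per_sample: list[SampleStats] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.direction not in ("hyper", "hypo"):
            raise ValueError("direction must be hyper|hypo")
        if self.end - self.start + 1 != self.n_windows * (1 << self.level):
            raise ValueError("region length must equal n_windows * 2**level")


def group_average(transformed: Sequence[TransformedSignal]) -> np.ndarray:
    """Element-wise mean of the scaling coefficients of one sample group."""
    if not transformed:
        raise ValueError("empty group")
    first = transformed[0]
    for t in transformed[1:]:
        if (
            t.level != first.level
            or t.normalization != first.normalization
            or (t.chromosome, t.start, t.end) != (first.chromosome, first.start, first.end)
        ):
            raise ValueError("group members differ in level/normalization/interval")
    return np.mean([t.scaling for t in transformed], axis=0)


def mark_dm(
    avg_case: np.ndarray, avg_control: np.ndarray, dmr_threshold: float
) -> np.ndarray:
    """Windows whose absolute group difference strictly exceeds the threshold."""
    avg_case = np.asarray(avg_case, dtype=np.float64)
    avg_control = np.asarray(avg_control, dtype=np.float64)
    if avg_case.shape != avg_control.shape:
        raise ValueError("group averages differ in length")
    return np.abs(avg_case - avg_control) > dmr_threshold


def required_covered(level: int, min_valid_fraction: float) -> int:
    """Positions per 2**level window that must meet the coverage threshold:
    ``floor(fraction * 2**level)``, at least 1."""
    return max(1, math.floor(min_valid_fraction * (1 << level)))


def _positions_pass(
    coverages: Sequence[np.ndarray],
    coverage_threshold: int,
    pooling: str,
    n_case: int | None = None,
) -> np.ndarray:
    stack = np.vstack([np.asarray(c) for c in coverages])
    if pooling == "all":
        return np.all(stack >= coverage_threshold, axis=0)
    if pooling == "any":
        return np.any(stack >= coverage_threshold, axis=0)
    # per-group-mean: both group mean coverages must reach the threshold
    if n_case is None or not 0 < n_case < len(coverages):
        raise ValueError("per-group-mean pooling needs a case/control split")
    case_mean = stack[:n_case].mean(axis=0)
    ctrl_mean = stack[n_case:].mean(axis=0)
    return (case_mean >= coverage_threshold) & (ctrl_mean >= coverage_threshold)


def validate_coverage(
    mask: np.ndarray,
    coverages: Sequence[np.ndarray],
    config: DetectionConfig,
    n_case: int | None = None,
) -> np.ndarray:
    """Keep a marked window only if enough of its positions are covered.

    ``coverages`` are the level-0 per-position coverage arrays of every
    analyzed sample, aligned to the signal interval.  A position counts
    (default pooling) when every sample has coverage >= the threshold
    there; the window survives when at least
    ``required_covered(level, min_valid_fraction)`` of its ``2**level``
    positions count.
    """
    mask = np.asarray(mask, dtype=bool)
    if not coverages:
        raise ValueError("no coverage arrays supplied")
    width = 1 << config.level
    n_pos = len(coverages[0])
    if any(len(c) != n_pos for c in coverages):
        raise ValueError("coverage arrays differ in length")
    if len(mask) != -(-n_pos // width):
        raise ValueError("mask length does not match ceil(n_positions / 2**level)")
    passing = _positions_pass(
        coverages, config.coverage_threshold, config.coverage_pooling, n_case
    )
    padded = np.zeros(len(mask) * width, dtype=bool)
    padded[:n_pos] = passing
    per_window = padded.reshape(len(mask), width).sum(axis=1)
    need = required_covered(config.level, config.min_valid_fraction)
    return mask & (per_window >= need)


def group_adjacent(
    mask: np.ndarray, level: int, signal_start: int
) -> list[tuple[int, int, list[int]]]:
    """Merge maximal runs of adjacent marked windows into candidate regions.

    Returns ``(genomic_start, genomic_end, window_indices)`` triples.
    """
    mask = np.asarray(mask, dtype=bool)
    regions: list[tuple[int, int, list[int]]] = []
    run: list[int] = []
    for i, flag in enumerate(mask):
        if flag:
            run.append(i)
        elif run:
            regions.append(_close_run(run, level, signal_start))
            run = []
    if run:
        regions.append(_close_run(run, level, signal_start))
    return regions


def _close_run(run: list[int], level: int, signal_start: int):
    lo, _ = coefficient_span(level, run[0], signal_start)
    _, hi = coefficient_span(level, run[-1], signal_start)
    return lo, hi, list(run)


def classify_direction(
    window_indices: Sequence[int],
    avg_case: np.ndarray,
    avg_control: np.ndarray,
) -> tuple[str, float]:
    """Label a region hyper (case above control) or hypo, with its mean
    signed difference over the region's windows."""
    if not len(window_indices):
        raise ValueError("region has no windows")
    idx = np.asarray(window_indices, dtype=int)
    diff = float(np.mean(np.asarray(avg_case)[idx] - np.asarray(avg_control)[idx]))
    return ("hyper" if diff > 0 else "hypo"), diff


def sample_stats(
    region: tuple[int, int],
    meth_map: MethylationMap,
    analysis_type: str = "5mC",
) -> SampleStats:
    """Per-sample descriptive statistics over informative positions in a region."""
    start, end = region
    recs = [r for r in meth_map.records if start <= r.position <= end]
    stats = SampleStats(sample_id=meth_map.sample_id)
    if not recs:
        return stats
    if analysis_type == "5hmC":
        cov = np.array([r.c_count + r.hmc_count for r in recs], dtype=float)
    else:
        cov = np.array([r.c_count + r.mc_count for r in recs], dtype=float)
    stats.n_informative = len(recs)
    stats.coverage_min = float(cov.min())
    stats.coverage_avg = float(cov.mean())
    stats.coverage_max = float(cov.max())
    stats.reads_c = sum(r.c_count for r in recs)
    stats.reads_mc = sum(r.mc_count for r in recs)
    stats.reads_hmc = sum(r.hmc_count for r in recs)
    stats.reads_noc = sum(r.noc_count for r in recs)
    if len(recs) >= 2:
        gaps = np.diff([r.position for r in recs]).astype(float)
        stats.gap_min = float(gaps.min())
        stats.gap_avg = float(gaps.mean())
        stats.gap_max = float(gaps.max())
    return stats


def nearest_gene(
    region: tuple[int, int], genes: Sequence[GeneAnnotation]
) -> tuple[str | None, int | None]:
    """Closest annotated gene and its distance (0 when overlapping).

    Ties are broken in favor of the gene with the smaller start.
    """
    if not genes:
        return None, None
    start, end = region
    best: tuple[int, int, str] | None = None
    for g in genes:
        if g.end < start:
            dist = start - g.end
        elif g.start > end:
            dist = g.start - end
        else:
            dist = 0
        key = (dist, g.start, g.gene_name)
        if best is None or key < best:
            best = key
    return best[2], best[0]


def _split_by_sign(
    run: Sequence[int], diff: np.ndarray
) -> list[list[int]]:
    """A single region cannot mix hyper and hypo windows; split at sign flips."""
    parts: list[list[int]] = []
    current: list[int] = []
    sign = 0.0
    for i in run:
        s = math.copysign(1.0, diff[i]) if diff[i] != 0 else 0.0
        if current and s != sign:
            parts.append(current)
            current = []
        current.append(i)
        sign = s
    if current:
        parts.append(current)
    return parts


def detect_dmrs(
    case_signals: Sequence[MethylationSignal],
    control_signals: Sequence[MethylationSignal],
    config: DetectionConfig,
    genes: Sequence[GeneAnnotation] | None = None,
    maps: Mapping[str, MethylationMap] | None = None,
) -> list[DMRegion]:
    """End-to-end DMR caller for one chromosome interval.

    Transforms every signal to the configured level (mean normalization),
    averages each group, thresholds the absolute group difference,
    validates coverage per window, merges adjacent windows (splitting at
    hyper/hypo sign changes), and annotates each region with its direction,
    nearest gene and, when ``maps`` (sample_id -> MethylationMap) is given,
    per-sample statistics.
    """
    if not case_signals or not control_signals:
        raise ValueError("both groups must be non-empty")
    all_signals = list(case_signals) + list(control_signals)
    first = all_signals[0]
    for s in all_signals[1:]:
        if (s.chromosome, s.start, s.end) != (first.chromosome, first.start, first.end):
            raise ValueError("all signals must share chromosome and interval")

    wav = get_filter(config.filter_name)
    t_case = [
        transform(s, wav, level=config.level, normalization="mean")
        for s in case_signals
    ]
    t_ctrl = [
        transform(s, wav, level=config.level, normalization="mean")
        for s in control_signals
    ]
    avg_case = group_average(t_case)
    avg_ctrl = group_average(t_ctrl)
    return _call_regions(
        avg_case,
        avg_ctrl,
        [s.coverage for s in all_signals],
        n_case=len(case_signals),
        chromosome=first.chromosome,
        signal_start=first.start,
        config=config,
        genes=genes,
        maps=maps,
    )


def _call_regions(
    avg_case: np.ndarray,
    avg_ctrl: np.ndarray,
    coverages: Sequence[np.ndarray],
    n_case: int,
    chromosome: str,
    signal_start: int,
    config: DetectionConfig,
    genes: Sequence[GeneAnnotation] | None = None,
    maps: Mapping[str, MethylationMap] | None = None,
) -> list[DMRegion]:
    """Marking, validation, grouping and annotation on precomputed group
    averages (shared by detect_dmrs and the chunked batch path)."""
    mask = mark_dm(avg_case, avg_ctrl, config.dmr_threshold)
    mask = validate_coverage(mask, coverages, config, n_case=n_case)
    diff = np.asarray(avg_case) - np.asarray(avg_ctrl)

    regions: list[DMRegion] = []
    for _, _, run in group_adjacent(mask, config.level, signal_start):
        for part in _split_by_sign(run, diff):
            lo, _ = coefficient_span(config.level, part[0], signal_start)
            _, hi = coefficient_span(config.level, part[-1], signal_start)
            direction, mean_diff = classify_direction(part, avg_case, avg_ctrl)
            gene_name, gene_dist = (
                nearest_gene((lo, hi), genes) if genes else (None, None)
            )
            region = DMRegion(
                chromosome=chromosome,
                start=lo,
                end=hi,
                direction=direction,
                mean_difference=mean_diff,
                n_windows=len(part),
                level=config.level,
                closest_gene=gene_name,
                gene_distance=gene_dist,
            )
            if maps:
                region.per_sample = [
                    sample_stats((lo, hi), m, config.analysis_type)
                    for m in maps.values()
                ]
            regions.append(region)
    regions.sort(key=lambda r: r.start)
    return regions
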