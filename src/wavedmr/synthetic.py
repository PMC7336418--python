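"""Synthetic methylation-map generator with planted DMRs, plus truth-aware scoring.

Counts follow a beta-binomial model: read depth at each data-bearing
position is Poisson, and the methylated-read count is binomial with a
per-position, per-sample success probability drawn from a beta
distribution around the configured proportion.  Planted regions shift the
case-group proportion by a signed effect; everything else is null.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from wavedmr.meth_io import MethylationMap, MethylationRecord

__all__ = [
    "SimulationParams",
    "TruthSet",
    "generate_maps",
    "generate_dataset",
    "write_truth_bed",
    "evaluate_detection",
]


@dataclass(frozen=True)
class SimulationParams:
    """Knobs for one simulated chromosome segment."""

    n_positions: int = 100_000
    cpg_density: float = 0.1
    base_methylation: float = 0.3
    effect_size: float = 0.4
    dmr_lengths: tuple[int, ...] = (64, 128)
    n_dmrs: int = 5
    coverage_mean: float = 50.0
    overdispersion: float = 0.05
    n_case: int = 2
    n_control: int = 2
    hmc_fraction: float = 0.0
    chromosome: str = "chrS"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.base_methylation <= 1.0:
            raise ValueError("base_methylation must be in [0, 1]")
        if not 0.0 <= self.effect_size <= 1.0:
            raise ValueError("effect_size must be in [0, 1]")
        if (
            self.base_methylation + self.effect_size > 1.0
            and self.base_methylation - self.effect_size < 0.0
        ):
            raise ValueError("effect_size infeasible for base_methylation")
        if self.coverage_mean <= 0:
            raise ValueError("coverage_mean must be > 0")
        if not 0.0 <= self.overdispersion < 1.0:
            raise ValueError("overdispersion must be in [0, 1)")
        if not 0.0 < self.cpg_density <= 1.0:
            raise ValueError("cpg_density must be in (0, 1]")
        if not 0.0 <= self.hmc_fraction <= 1.0:
            raise ValueError("hmc_fraction must be in [0, 1]")


@dataclass
class TruthSet:
    """Ground truth for one simulated segment.

    ``regions`` are disjoint planted intervals (1-based inclusive) with
    their signed case-minus-control effect; ``data_positions`` are the
    positions that carry reads; truth positions (differentially methylated
    base pairs) are the data positions inside nonzero-effect regions.
    """

    regions: list[tuple[int, int, float]]
    data_positions: np.ndarray
    case_proportion: np.ndarray
    control_proportion: np.ndarray
    start: int = 1

    @property
    def truth_positions(self) -> np.ndarray:
        pos = self.data_positions
        keep = np.zeros(len(pos), dtype=bool)
        for lo, hi, eff in self.regions:
            if eff != 0.0:
                keep |= (pos >= lo) & (pos <= hi)
        return pos[keep]


def _beta_binomial(
    rng: np.random.Generator, n: np.ndarray, p: np.ndarray, rho: float
) -> np.ndarray:
    """Beta-binomial draw with mean proportion ``p`` and dispersion ``rho``;
    rho = 0 degenerates to plain binomial."""
    if rho == 0.0:
        return rng.binomial(n, p)
    scale = (1.0 - rho) / rho
    a = np.clip(p * scale, 1e-12, None)
    b = np.clip((1.0 - p) * scale, 1e-12, None)
    return rng.binomial(n, rng.beta(a, b))


def _plant_regions(
    rng: np.random.Generator, params: SimulationParams
) -> list[tuple[int, int, float]]:
    """Place disjoint regions uniformly, retrying on overlap."""
    sign = 1.0 if params.base_methylation + params.effect_size <= 1.0 else -1.0
    regions: list[tuple[int, int, float]] = []
    taken = np.zeros(params.n_positions, dtype=bool)
    attempts = 0
    while len(regions) < params.n_dmrs and attempts < 1000 * params.n_dmrs:
        attempts += 1
        length = int(rng.choice(params.dmr_lengths))
        if length > params.n_positions:
            raise ValueError("dmr length exceeds segment size")
        lo0 = int(rng.integers(0, params.n_positions - length + 1))
        if taken[lo0 : lo0 + length].any():
            continue
        # 1-position guard band keeps regions strictly disjoint
        taken[max(0, lo0 - 1) : lo0 + length + 1] = True
        regions.append((lo0 + 1, lo0 + length, sign * params.effect_size))
    if len(regions) < params.n_dmrs:
        raise ValueError("could not place disjoint planted regions")
    regions.sort()
    return regions


def generate_maps(
    params: SimulationParams,
) -> tuple[list[MethylationMap], list[MethylationMap], TruthSet]:
    """Simulate case and control methylation maps with planted DMRs."""
    rng = np.random.default_rng(params.seed)
    n = params.n_positions
    regions = _plant_regions(rng, params) if params.n_dmrs else []

    control_p = np.full(n, params.base_methylation)
    case_p = control_p.copy()
    for lo, hi, eff in regions:
        case_p[lo - 1 : hi] = params.base_methylation + eff

    data_mask = rng.random(n) < params.cpg_density
    data_pos = np.flatnonzero(data_mask) + 1  # 1-based

    truth = TruthSet(
        regions=regions,
        data_positions=data_pos,
        case_proportion=case_p,
        control_proportion=control_p,
    )

    def one_sample(group: str, idx: int, p_full: np.ndarray) -> MethylationMap:
        p = p_full[data_pos - 1]
        depth = rng.poisson(params.coverage_mean, size=len(data_pos))
        mc = _beta_binomial(rng, depth, p, params.overdispersion)
        c = depth - mc
        if params.hmc_fraction > 0.0:
            hmc = rng.binomial(mc, params.hmc_fraction)
        else:
            hmc = np.zeros_like(mc)
        records = [
            MethylationRecord(
                position=int(pos),
                c_count=int(ci),
                noc_count=0,
                mc_count=int(mi),
                hmc_count=int(hi),
            )
            for pos, ci, mi, hi in zip(data_pos, c, mc, hmc)
            if ci or mi
        ]
        return MethylationMap(
            chromosome=params.chromosome,
            strand="forward",
            sample_id=f"{group}{idx}",
            records=records,
        )

    case_maps = [one_sample("case", i, case_p) for i in range(params.n_case)]
    control_maps = [one_sample("control", i, control_p) for i in range(params.n_control)]
    return case_maps, control_maps, truth


def _write_map_csv(meth_map: MethylationMap, path: Path) -> None:
    with path.open("w", newline="\n") as fh:
        fh.write("pos,c,noc,mc,hmc\n")
        for r in meth_map.records:
            fh.write(
                f"{r.position},{r.c_count},{r.noc_count},{r.mc_count},{r.hmc_count}\n"
            )


def write_truth_bed(truth: TruthSet, chromosome: str, path: Path) -> None:
    """Write planted regions as BED-like TSV (0-based half-open + effect)."""
    with path.open("w", newline="\n") as fh:
        for lo, hi, eff in truth.regions:
            fh.write(f"{chromosome}\t{lo - 1}\t{hi}\tplanted\t{eff}\n")


def generate_dataset(
    params: SimulationParams, out_dir: str | Path
) -> tuple[list[Path], TruthSet]:
    """Simulate and write one CSV per sample plus the truth TSV.

    Case samples go to ``<out>/case<i>/<chrom>_forward.csv`` and control
    samples to ``<out>/control<i>/...`` so the tree is directly usable by
    the batch runner.  Identical seeds produce byte-identical files.
    """
    out_dir = Path(out_dir)
    case_maps, control_maps, truth = generate_maps(params)
    paths: list[Path] = []
    for m in case_maps + control_maps:
        sample_dir = out_dir / m.sample_id
        sample_dir.mkdir(parents=True, exist_ok=True)
        p = sample_dir / f"{m.chromosome}_{m.strand}.csv"
        _write_map_csv(m, p)
        paths.append(p)
    write_truth_bed(truth, params.chromosome, out_dir / "truth.tsv")
    return paths, truth


def evaluate_detection(
    found: Sequence, truth: TruthSet
) -> tuple[float, float, float]:
    """Score called regions against the planted truth.

    Returns ``(sensitivity, precision, hit_rate)``: sensitivity is the
    fraction of truth positions covered by any called region; hit_rate is
    the fraction of called regions covering at least one truth position
    (0 when nothing was called); precision is the fraction of called
    regions overlapping any planted interval.
    """
    truth_pos = truth.truth_positions
    covered = np.zeros(len(truth_pos), dtype=bool)
    n_hit = 0
    n_overlap = 0
    for r in found:
        in_region = (truth_pos >= r.start) & (truth_pos <= r.end)
        covered |= in_region
        if in_region.any():
            n_hit += 1
        if any(lo <= r.end and hi >= r.start for lo, hi, _ in truth.regions):
            n_overlap += 1
    sensitivity = float(covered.mean()) if len(truth_pos) else 0.0
    hit_rate = n_hit / len(found) if found else 0.0
    precision = n_overlap / len(found) if found else 0.0
    return sensitivity, precision, hit_rate
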