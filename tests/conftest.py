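"""Shared fixtures and the independent brute-force DMR oracle.

The oracle deliberately avoids the package's wavelet path: level-j window
values are computed as plain block means over zero-padded arrays via
reshape, and the rest of the calling logic is re-derived from first
principles so the two implementations can be compared region-for-region.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from wavedmr.meth_io import MethylationMap, MethylationRecord


def make_map(counts, chromosome="chr1", strand="forward", sample_id="s1"):
    """counts: iterable of (position, c, noc, mc, hmc) tuples."""
    records = [
        MethylationRecord(
            position=p, c_count=c, noc_count=noc, mc_count=mc, hmc_count=hmc
        )
        for p, c, noc, mc, hmc in sorted(counts)
    ]
    return MethylationMap(
        chromosome=chromosome, strand=strand, sample_id=sample_id, records=records
    )


def block_means(values: np.ndarray, level: int) -> np.ndarray:
    """Zero-pad to a multiple of 2**level and average contiguous blocks."""
    width = 1 << level
    n = len(values)
    n_blocks = -(-n // width)
    padded = np.zeros(n_blocks * width)
    padded[:n] = values
    return padded.reshape(n_blocks, width).mean(axis=1)


def brute_force_detect(case_values, control_values, coverages, config, start=1):
    """Reference DMR caller: block means + thresholding + validation + runs.

    Returns tuples (start, end, direction, mean_difference, n_windows).
    """
    width = 1 << config.level
    avg_case = np.mean([block_means(np.asarray(v, float), config.level)
                        for v in case_values], axis=0)
    avg_ctrl = np.mean([block_means(np.asarray(v, float), config.level)
                        for v in control_values], axis=0)
    diff = avg_case - avg_ctrl
    marked = np.abs(diff) > config.dmr_threshold

    n_pos = len(coverages[0])
    stack = np.vstack([np.asarray(c) for c in coverages])
    ok = np.all(stack >= config.coverage_threshold, axis=0)
    need = max(1, math.floor(config.min_valid_fraction * width))
    for w in range(len(marked)):
        lo, hi = w * width, min((w + 1) * width, n_pos)
        if lo >= n_pos or ok[lo:hi].sum() < need:
            marked[w] = False

    regions = []
    run: list[int] = []

    def flush(run):
        if not run:
            return
        # split at hyper/hypo sign changes
        part = [run[0]]
        for w in run[1:]:
            if np.sign(diff[w]) != np.sign(diff[part[-1]]):
                emit(part)
                part = []
            part.append(w)
        emit(part)

    def emit(part):
        lo = start + part[0] * width
        hi = start + (part[-1] + 1) * width - 1
        md = float(np.mean(diff[part]))
        regions.append((lo, hi, "hyper" if md > 0 else "hypo", md, len(part)))

    for w, flag in enumerate(marked):
        if flag:
            run.append(w)
        elif run:
            flush(run)
            run = []
    flush(run)
    regions.sort(key=lambda r: r[0])
    return regions


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
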