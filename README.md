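# wavedmr

Wavelet-based detection of differentially methylated regions (DMRs) from
per-base methylation count maps.

`wavedmr` reads per-chromosome CSV methylation maps (one row per cytosine
position with counts of reads showing unmethylated C, non-C, methylated C
and hydroxymethylated C), builds dense methylation-ratio signals, reduces
them with a dyadic discrete wavelet transform (Haar by default; biorthogonal
3.1/3.3/3.5 and quadratic-spline banks are also available), and calls DMRs
between a case and a control group in three stages:

1. **Group averaging** — every sample's signal is transformed to the chosen
   resolution level `j` (each level-`j` coefficient summarizes `2^j`
   positions, the minimum detectable DMR length) and averaged within each
   group.
2. **Thresholding** — a window is marked differentially methylated when the
   absolute difference of the group averages strictly exceeds the DMR
   threshold.
3. **Coverage validation and grouping** — a marked window survives only if
   enough of its positions (25% by default) meet the per-position coverage
   threshold in every analyzed sample; adjacent surviving windows are merged
   into regions labeled hyper- or hypomethylated (case relative to control),
   with nearest-gene annotation and per-sample statistics.

Validation is applied *after* marking, so low-coverage positions never
distort the signal itself. Both 5mC and 5hmC analyses are supported, and a
batch mode sweeps whole sample trees chromosome by chromosome with a
deterministic-output guarantee (results are byte-identical regardless of
worker count or chunk size).

## CLI

```sh
# single-chromosome detection
wavedmr detect \
  --case case0.csv --case case1.csv \
  --control ctrl0.csv --control ctrl1.csv \
  --level 4 --dmr-threshold 0.25 --coverage-threshold 10 \
  --genes genes.bed --out dmrs.csv

# batch mode over sample directories (one CSV per chromosome/strand each,
# named <chromosome>_<strand>.csv)
wavedmr batch \
  --case-dir samples/case0 --case-dir samples/case1 \
  --control-dir samples/ctrl0 --control-dir samples/ctrl1 \
  --level 6 --chromosomes all --workers 4 --out-dir results/

# multiresolution export for plotting (TSV: level, start, end, value)
wavedmr export-signal --input case0.csv --levels 0,2,4,6 --out multi.tsv

# synthetic dataset with planted DMRs + ground truth
wavedmr simulate --n-positions 100000 --effect-size 0.4 --n-dmrs 8 \
  --seed 7 --out-dir sim/
```

`--level` is always explicit: the best resolution level depends on the
minimum DMR length being searched. `wavedmr batch --config run.yaml` accepts
a YAML file mirroring the batch configuration.

The DMR report is a two-level CSV: one `DMR` line per region (coordinates,
closest gene and distance, hyper/hypo direction, mean group difference)
followed by one `SAMPLE` line per analyzed sample (informative positions,
min/avg/max coverage, summed C/mC/hmC/non-C read counts, min/avg/max gap
between informative positions).

## Input format

Default CSV columns are `pos,c,noc,mc,hmc` (1-based position; `mc`
includes hydroxymethylated reads). Other layouts can be adapted with a
`CsvDialect` column mapping. Gene annotations are standard BED4+
(0-based half-open; converted internally to 1-based inclusive).

## Python API

```python
from wavedmr import (read_methylation_csv, build_signal, DetectionConfig,
                     detect_dmrs, write_dmr_csv)

maps = {p: read_methylation_csv(p) for p in csv_paths}
signals = [build_signal(m, start, end, "5mC") for m in maps.values()]
regions = detect_dmrs(signals[:n_case], signals[n_case:],
                      DetectionConfig(level=4, dmr_threshold=0.25))
write_dmr_csv(regions, "dmrs.csv")
```

## Tests

```sh
python -m pytest -q tests/
```

The suite includes property-based tests (hypothesis) for the signal,
transform and detection invariants, a brute-force block-mean oracle that
the wavelet path must match region-for-region, and `tests/test_acceptance.py`
with one test per acceptance criterion.

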