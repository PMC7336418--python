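"""Readers and writers for methylation-map CSVs, gene BED files and DMR reports.

Input maps carry, for every cytosine position with data, the number of
aligned reads showing an unmethylated C, a base other than C, a methylated
C (5mC, inclusive of hydroxymethylated reads) and a hydroxymethylated C
(5hmC).  One file per chromosome, strand and sample.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "CsvDialect",
    "MethylationRecord",
    "MethylationMap",
    "GeneAnnotation",
    "read_methylation_csv",
    "read_gene_bed",
    "write_dmr_csv",
    "read_dmr_csv",
]

#: canonical record field names, in default column order
_FIELDS = ("pos", "c", "noc", "mc", "hmc")


class MethylationParseError(ValueError):
    """Raised when a methylation CSV row cannot be parsed or validated."""


@dataclass(frozen=True)
class MethylationRecord:
    """Read counts at one 1-based genomic position.

    ``mc_count`` includes hydroxymethylated reads, so ``hmc_count`` can
    never exceed it.
    """

    position: int
    c_count: int
    noc_count: int
    mc_count: int
    hmc_count: int

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        for name in ("c_count", "noc_count", "mc_count", "hmc_count"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.hmc_count > self.mc_count:
            raise ValueError(
                f"hmc_count ({self.hmc_count}) exceeds mc_count "
                f"({self.mc_count}) at position {self.position}"
            )


@dataclass
class MethylationMap:
    """Position-sorted per-position counts for one chromosome + strand + sample."""

    chromosome: str
    strand: str = "forward"
    sample_id: str = ""
    records: list[MethylationRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("forward", "reverse"):
            raise ValueError(f"strand must be forward|reverse, got {self.strand!r}")
        positions = [r.position for r in self.records]
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise ValueError("record positions must be strictly increasing")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def positions(self) -> list[int]:
        return [r.position for r in self.records]


@dataclass(frozen=True)
class GeneAnnotation:
    """A named gene interval, 1-based inclusive coordinates."""

    gene_name: str
    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_name}: start > end")


@dataclass(frozen=True)
class CsvDialect:
    """Column mapping for methylation CSVs.

    ``columns`` maps the canonical field names ``pos, c, noc, mc, hmc`` to
    0-based column indices.  ``has_header`` controls whether the first
    non-comment line is skipped (when the header names match canonical
    field names, the mapping is taken from the header instead).
    """

    delimiter: str = ","
    has_header: bool = True
    columns: dict[str, int] = field(
        default_factory=lambda: {f: i for i, f in enumerate(_FIELDS)}
    )

    def __post_init__(self) -> None:
        unknown = set(self.columns) - set(_FIELDS)
        if unknown:
            raise ValueError(f"unknown column(s) in dialect: {sorted(unknown)}")
        missing = set(_FIELDS) - set(self.columns)
        if missing:
            raise ValueError(f"dialect missing column(s): {sorted(missing)}")


def _resolve_header(header: Sequence[str], dialect: CsvDialect) -> dict[str, int]:
    names = [h.strip().lower() for h in header]
    if set(_FIELDS) <= set(names):
        return {f: names.index(f) for f in _FIELDS}
    return dict(dialect.columns)


def read_methylation_csv(
    path: str | Path,
    dialect: CsvDialect | None = None,
    *,
    chromosome: str | None = None,
    strand: str = "forward",
    sample_id: str | None = None,
) -> MethylationMap:
    """Read one per-chromosome methylation CSV into a :class:`MethylationMap`.

    Rows are sorted by position on load; rows whose counts are all zero are
    dropped.  Rows with negative counts, ``hmc > mc`` or duplicated
    positions raise :class:`MethylationParseError` naming the line.
    """
    path = Path(path)
    if dialect is None:
        dialect = CsvDialect()
    chromosome = chromosome if chromosome is not None else path.stem
    sample_id = sample_id if sample_id is not None else path.stem

    records: list[MethylationRecord] = []
    columns = dict(dialect.columns)
    header_pending = dialect.has_header
    with path.open(newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter=dialect.delimiter), 1):
            if not row or (row[0].startswith("#")):
                continue
            if header_pending:
                columns = _resolve_header(row, dialect)
                header_pending = False
                continue
            try:
                vals = {f: int(row[columns[f]]) for f in _FIELDS}
            except (ValueError, IndexError) as exc:
                raise MethylationParseError(
                    f"{path}:{lineno}: malformed row {row!r}: {exc}"
                ) from exc
            if all(vals[f] == 0 for f in ("c", "noc", "mc", "hmc")):
                continue  # no signal, no coverage
            try:
                records.append(
                    MethylationRecord(
                        position=vals["pos"],
                        c_count=vals["c"],
                        noc_count=vals["noc"],
                        mc_count=vals["mc"],
                        hmc_count=vals["hmc"],
                    )
                )
            except ValueError as exc:
                raise MethylationParseError(f"{path}:{lineno}: {exc}") from exc

    records.sort(key=lambda r: r.position)
    for a, b in zip(records, records[1:]):
        if a.position == b.position:
            raise MethylationParseError(
                f"{path}: duplicate position {a.position}"
            )
    return MethylationMap(
        chromosome=chromosome, strand=strand, sample_id=sample_id, records=records
    )


def read_gene_bed(path: str | Path) -> list[GeneAnnotation]:
    """Read a BED4+ gene annotation file.

    BED is 0-based half-open; returned annotations are 1-based inclusive,
    sorted by start.  Overlapping intervals are all retained.
    """
    path = Path(path)
    genes: list[GeneAnnotation] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                parts = line.split()
            if len(parts) < 4:
                raise MethylationParseError(
                    f"{path}:{lineno}: expected >= 4 BED columns"
                )
            chrom, start_s, end_s, name = parts[0], parts[1], parts[2], parts[3]
            try:
                start0, end0 = int(start_s), int(end_s)
            except ValueError as exc:
                raise MethylationParseError(
                    f"{path}:{lineno}: non-numeric coordinates"
                ) from exc
            genes.append(
                GeneAnnotation(
                    gene_name=name, chromosome=chrom, start=start0 + 1, end=end0
                )
            )
    genes.sort(key=lambda g: (g.chromosome, g.start, g.end))
    return genes


# --- DMR report -------------------------------------------------------------

_DMR_HEADER = (
    "# DMR report\n"
    "# DMR,chromosome,start,end,n_windows,level,closest_gene,gene_distance,"
    "direction,mean_difference\n"
    "# SAMPLE,sample_id,n_informative,coverage_min,coverage_avg,coverage_max,"
    "reads_c,reads_mc,reads_hmc,reads_noc,gap_min,gap_avg,gap_max\n"
)


def _fmt(x: float) -> str:
    # repr round-trips floats exactly through float()
    return repr(float(x))


def write_dmr_csv(regions: Sequence, path: str | Path) -> None:
    """Write the two-level DMR report.

    One ``DMR`` line per region (coordinates, nearest gene, hyper/hypo
    direction, mean group difference) followed by one ``SAMPLE`` line per
    analyzed sample with its descriptive statistics inside the region.
    """
    path = Path(path)
    chroms = {r.chromosome for r in regions}
    if len(chroms) > 1:
        raise ValueError(f"regions span multiple chromosomes: {sorted(chroms)}")
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(_DMR_HEADER)
        for r in regions:
            gene = r.closest_gene if r.closest_gene is not None else ""
            dist = "" if r.gene_distance is None else str(r.gene_distance)
            fh.write(
                f"DMR,{r.chromosome},{r.start},{r.end},{r.n_windows},{r.level},"
                f"{gene},{dist},{r.direction},{_fmt(r.mean_difference)}\n"
            )
            for s in r.per_sample:
                fh.write(
                    f"SAMPLE,{s.sample_id},{s.n_informative},"
                    f"{_fmt(s.coverage_min)},{_fmt(s.coverage_avg)},"
                    f"{_fmt(s.coverage_max)},{s.reads_c},{s.reads_mc},"
                    f"{s.reads_hmc},{s.reads_noc},{_fmt(s.gap_min)},"
                    f"{_fmt(s.gap_avg)},{_fmt(s.gap_max)}\n"
                )


def read_dmr_csv(path: str | Path) -> list:
    """Read back a DMR report written by :func:`write_dmr_csv`."""
    from wavedmr.dmr_detection import DMRegion, SampleStats

    path = Path(path)
    regions: list[DMRegion] = []
    with path.open(encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split(",")
            if parts[0] == "DMR":
                (_, chrom, start, end, n_windows, level, gene, dist, direction,
                 mean_diff) = parts
                regions.append(
                    DMRegion(
                        chromosome=chrom,
                        start=int(start),
                        end=int(end),
                        n_windows=int(n_windows),
                        level=int(level),
                        closest_gene=gene or None,
                        gene_distance=int(dist) if dist else None,
                        direction=direction,
                        mean_difference=float(mean_diff),
                        per_sample=[],
                    )
                )
            elif parts[0] == "SAMPLE":
                if not regions:
                    raise MethylationParseError(
                        f"{path}: SAMPLE line before any DMR line"
                    )
                (_, sid, n_inf, cmin, cavg, cmax, rc, rmc, rhmc, rnoc,
                 gmin, gavg, gmax) = parts
                regions[-1].per_sample.append(
                    SampleStats(
                        sample_id=sid,
                        n_informative=int(n_inf),
                        coverage_min=float(cmin),
                        coverage_avg=float(cavg),
                        coverage_max=float(cmax),
                        reads_c=int(rc),
                        reads_mc=int(rmc),
                        reads_hmc=int(rhmc),
                        reads_noc=int(rnoc),
                        gap_min=float(gmin),
                        gap_avg=float(gavg),
                        gap_max=float(gmax),
                    )
                )
            else:
                raise MethylationParseError(
                    f"{path}: unknown record type {parts[0]!r}"
                )
    return regions
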