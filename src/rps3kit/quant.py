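"""Coverage-based abundance quantification of marker-bearing scaffolds.

Scaffolds carrying a marker gene are trimmed to a window of 2 kbp flanking
the gene (the whole scaffold is kept when the window would fall below a
1 kbp minimum), reads from every sample are mapped to the trimmed
scaffolds, and per-(scaffold, sample) average coverage and breadth are
computed from the SAM alignments. Because every scaffold is genuinely
present in at least the sample it was assembled from, the breadth cutoff is
calibrated as the most stringent grid value that still retains every
cluster in at least one sample; coverage of records below the cutoff is
zeroed as presumed cross-mapping noise. Coverage is then corrected for
uneven sequencing depth (each sample scaled by largest-library bp / its
bp) and replicate extractions are averaged into site-level abundances.

All coordinates are 1-based inclusive. Only primary, mapped SAM records
contribute depth, through their match/mismatch CIGAR operations; deletions
and skips advance the reference without adding depth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .errors import ConfigError, InputError, ParseError
from .marker_screen import MarkerHit

logger = logging.getLogger(__name__)

#: CIGAR operation codes that add depth (M, =, X).
_DEPTH_OPS = {0, 7, 8}
#: CIGAR operations that advance the reference without depth (D, N).
_REF_ADVANCE_OPS = {2, 3}


@dataclass
class QuantConfig:
    """Windowing and breadth-calibration parameters (lengths in bp)."""

    flank_bp: int = 2000
    min_scaffold_bp: int = 1000
    breadth_grid_lo: float = 0.1
    breadth_grid_hi: float = 1.0
    breadth_grid_step: float = 0.01

    def __post_init__(self) -> None:
        if not 0 < self.breadth_grid_lo <= self.breadth_grid_hi <= 1:
            raise InputError("breadth grid bounds must satisfy 0 < lo <= hi <= 1")
        if self.breadth_grid_step <= 0:
            raise InputError("breadth grid step must be positive")

    def breadth_grid(self) -> np.ndarray:
        n = int(round((self.breadth_grid_hi - self.breadth_grid_lo) / self.breadth_grid_step))
        return np.round(
            self.breadth_grid_lo + self.breadth_grid_step * np.arange(n + 1), 10
        )


@dataclass
class TrimmedScaffold:
    """A scaffold window centred on a marker gene."""

    id: str
    source_scaffold: str
    window_start: int
    window_end: int
    sequence: str
    origin_sample: str
    gene_id: str = ""

    @property
    def length(self) -> int:
        return self.window_end - self.window_start + 1


@dataclass(frozen=True)
class CoverageRecord:
    """Average depth and breadth of one trimmed scaffold in one sample."""

    trimmed_scaffold_id: str
    sample_id: str
    average_coverage: float
    breadth: float


@dataclass
class AbundanceMatrix:
    """Taxa/clusters x samples (or sites) abundance values.

    ``data`` rows are cluster ids and columns sample or site ids;
    ``library_bp`` maps each column to its sequencing effort in bp (absent
    after site averaging).
    """

    data: pd.DataFrame
    library_bp: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates or self.data.columns.has_duplicates:
            raise InputError("abundance matrix labels must be unique")
        if (self.data.values < 0).any():
            raise InputError("abundance values must be non-negative")
        if self.library_bp is not None:
            self.library_bp = self.library_bp.reindex(self.data.columns)
            if self.library_bp.isna().any():
                missing = list(self.library_bp.index[self.library_bp.isna()])
                raise InputError(f"library sizes missing for columns: {missing}")

    def to_tsv(self, path: str | Path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            self.data.rename_axis("cluster_id").to_csv(fh, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path, library_bp: pd.Series | None = None) -> "AbundanceMatrix":
        df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
        return cls(df, library_bp)


def trim_to_flanks(
    scaffold: tuple[str, str], gene: MarkerHit, cfg: QuantConfig | None = None
) -> TrimmedScaffold | None:
    """Trim a scaffold to ``flank_bp`` on each side of the marker gene.

    Returns ``None`` (with a logged reason) for scaffolds at or below 1 kbp,
    which are excluded from the analysis. When the flank window is shorter
    than ``min_scaffold_bp`` the entire scaffold is kept.
    """
    cfg = cfg or QuantConfig()
    scaffold_id, sequence = scaffold
    L = len(sequence)
    if L <= 1000:
        logger.info("scaffold %s filtered: length %d <= 1000 bp", scaffold_id, L)
        return None
    if not (1 <= gene.gene_start <= gene.gene_end <= L):
        raise InputError(
            f"gene {gene.gene_id} ({gene.gene_start}-{gene.gene_end}) outside "
            f"scaffold {scaffold_id} of length {L}"
        )
    start = max(1, gene.gene_start - cfg.flank_bp)
    end = min(L, gene.gene_end + cfg.flank_bp)
    if end - start + 1 < cfg.min_scaffold_bp:
        start, end = 1, L
    return TrimmedScaffold(
        id=f"{scaffold_id}|{start}-{end}",
        source_scaffold=scaffold_id,
        window_start=start,
        window_end=end,
        sequence=sequence[start - 1 : end],
        origin_sample=gene.sample_of_origin,
        gene_id=gene.gene_id,
    )


def _depth_array(
    records: Iterable[pysam.AlignedSegment],
    region_id: str,
    region_length: int,
) -> tuple[np.ndarray, int]:
    """Per-position depth over a region; returns (depth, n_skipped)."""
    depth = np.zeros(region_length, dtype=np.int64)
    skipped = 0
    for rec in records:
        if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
            continue
        if rec.reference_name != region_id:
            skipped += 1
            continue
        cig = rec.cigartuples
        if cig is None:
            raise ParseError(f"mapped read {rec.query_name} has no CIGAR")
        pos = rec.reference_start  # 0-based
        for op, length in cig:
            if op in _DEPTH_OPS:
                lo = max(pos, 0)
                hi = min(pos + length, region_length)
                if hi > lo:
                    depth[lo:hi] += 1
                pos += length
            elif op in _REF_ADVANCE_OPS:
                pos += length
            # insertions / clips / padding do not advance the reference
    return depth, skipped


def coverage_breadth(
    alignments: Iterable[pysam.AlignedSegment],
    region: TrimmedScaffold,
) -> CoverageRecord:
    """Average coverage and breadth of one trimmed scaffold in one sample.

    Records referencing other scaffolds are skipped (counted in the log).
    The sample id is taken from the first record's file, so callers
    normally use :func:`compute_coverage_table`; this function exists for
    single-region computation and expects pre-filtered records.
    """
    if region.length <= 0:
        raise InputError(f"region {region.id} has non-positive length")
    depth, skipped = _depth_array(alignments, region.id, region.length)
    if skipped:
        logger.info("region %s: skipped %d records on other references", region.id, skipped)
    avg = float(depth.sum()) / region.length
    breadth = float((depth > 0).sum()) / region.length
    return CoverageRecord(region.id, "", avg, breadth)


def compute_coverage_table(
    sam_paths: Mapping[str, str | Path],
    regions: Sequence[TrimmedScaffold],
) -> list[CoverageRecord]:
    """Coverage/breadth of every region in every sample (one SAM per sample).

    Each SAM is scanned once; records referencing scaffolds outside
    ``regions`` are skipped with a counter. Every (region, sample) pair gets
    a record, zero-valued when no reads mapped.
    """
    region_len = {r.id: r.length for r in regions}
    records: list[CoverageRecord] = []
    for sample_id, path in sam_paths.items():
        path = Path(path)
        if not path.exists():
            raise InputError(f"SAM for sample {sample_id} not found: {path}")
        depths = {rid: np.zeros(L, dtype=np.int64) for rid, L in region_len.items()}
        skipped = 0
        with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
            for rec in sam:
                if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                    continue
                rid = rec.reference_name
                if rid not in depths:
                    skipped += 1
                    continue
                cig = rec.cigartuples
                if cig is None:
                    raise ParseError(f"mapped read {rec.query_name} has no CIGAR")
                depth = depths[rid]
                L = region_len[rid]
                pos = rec.reference_start
                for op, length in cig:
                    if op in _DEPTH_OPS:
                        lo, hi = max(pos, 0), min(pos + length, L)
                        if hi > lo:
                            depth[lo:hi] += 1
                        pos += length
                    elif op in _REF_ADVANCE_OPS:
                        pos += length
        if skipped:
            logger.info("sample %s: %d records on unknown scaffolds skipped", sample_id, skipped)
        for rid, depth in depths.items():
            L = region_len[rid]
            records.append(
                CoverageRecord(
                    rid,
                    sample_id,
                    float(depth.sum()) / L,
                    float((depth > 0).sum()) / L,
                )
            )
    return records


def calibrate_breadth_cutoff(
    records: Sequence[CoverageRecord],
    cluster_of: Mapping[str, str],
    cfg: QuantConfig | None = None,
) -> float:
    """Most stringent grid cutoff that retains every cluster somewhere.

    Retained-cluster count is non-increasing in the cutoff, so the returned
    value is the grid point just before the first cluster would be lost —
    the operational reading of scanning cutoffs from 0.1 to 1 for the value
    that keeps the number of clusters unchanged.
    """
    cfg = cfg or QuantConfig()
    max_breadth: dict[str, float] = {}
    for rec in records:
        if rec.trimmed_scaffold_id not in cluster_of:
            raise ConfigError(
                f"trimmed scaffold {rec.trimmed_scaffold_id} has no cluster"
            )
        cl = cluster_of[rec.trimmed_scaffold_id]
        max_breadth[cl] = max(max_breadth.get(cl, 0.0), rec.breadth)
    if not max_breadth:
        raise InputError("no coverage records")
    weakest = min(max_breadth, key=max_breadth.get)
    if max_breadth[weakest] <= 0:
        raise InputError(
            f"cluster {weakest} has no positive-breadth record; it must be "
            "present in at least its sample of origin"
        )
    grid = cfg.breadth_grid()
    limit = max_breadth[weakest]
    retaining = grid[grid <= limit + 1e-9]
    if retaining.size == 0:
        logger.warning(
            "weakest cluster %s max breadth %.3f below grid minimum %.3f; "
            "returning the grid minimum",
            weakest,
            limit,
            cfg.breadth_grid_lo,
        )
        return float(grid[0])
    return float(retaining[-1])


def apply_breadth_cutoff(
    records: Sequence[CoverageRecord], cutoff: float
) -> list[CoverageRecord]:
    """Zero average coverage wherever breadth < cutoff (>= is retained)."""
    if not 0 < cutoff <= 1:
        raise InputError(f"breadth cutoff must be in (0, 1], got {cutoff}")
    out = []
    for rec in records:
        if rec.breadth < cutoff:
            out.append(replace(rec, average_coverage=0.0))
        else:
            out.append(rec)
    return out


def abundance_from_records(
    records: Sequence[CoverageRecord],
    cluster_of: Mapping[str, str],
    library_bp: Mapping[str, int],
) -> AbundanceMatrix:
    """Cluster x sample abundance: summed coverage of member scaffolds."""
    rows = []
    for rec in records:
        if rec.trimmed_scaffold_id not in cluster_of:
            raise ConfigError(
                f"trimmed scaffold {rec.trimmed_scaffold_id} has no cluster"
            )
        rows.append(
            (cluster_of[rec.trimmed_scaffold_id], rec.sample_id, rec.average_coverage)
        )
    df = pd.DataFrame(rows, columns=["cluster", "sample", "cov"])
    mat = df.pivot_table(index="cluster", columns="sample", values="cov", aggfunc="sum", fill_value=0.0)
    mat.index.name = None
    mat.columns.name = None
    return AbundanceMatrix(mat, pd.Series(dict(library_bp), dtype=float))


def depth_normalize(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Scale each column by (largest library bp) / (its library bp)."""
    if matrix.library_bp is None:
        raise InputError("abundance matrix has no library sizes")
    bp = matrix.library_bp.astype(float)
    if (bp <= 0).any():
        bad = list(bp.index[bp <= 0])
        raise InputError(f"non-positive library sizes for: {bad}")
    factors = bp.max() / bp
    return AbundanceMatrix(matrix.data.mul(factors, axis=1), matrix.library_bp.copy())


def average_replicates(
    matrix: AbundanceMatrix, replicate_map: Mapping[str, str]
) -> AbundanceMatrix:
    """Average replicate sample columns into site columns (zeros included)."""
    unmapped = [c for c in matrix.data.columns if c not in replicate_map]
    if unmapped:
        raise ConfigError(f"samples missing from replicate map: {unmapped}")
    sites = pd.Series({c: replicate_map[c] for c in matrix.data.columns})
    out = matrix.data.T.groupby(sites).mean().T
    out.columns.name = None
    return AbundanceMatrix(out, None)


def write_coverage_tsv(
    records: Sequence[CoverageRecord], path: str | Path, header_comment: str | None = None
) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("trimmed_scaffold_id\tsample_id\taverage_coverage\tbreadth\n")
        for r in records:
            fh.write(
                f"{r.trimmed_scaffold_id}\t{r.sample_id}\t"
                f"{r.average_coverage:.6g}\t{r.breadth:.6g}\n"
            )
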