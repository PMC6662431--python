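"""Screening of marker-gene search hits.

Hits locating the ribosomal protein S3 (rpS3) gene on assembly scaffolds
arrive as hmmsearch-style per-domain tabular text (``domtblout`` dialect).
This module parses those tables, applies per-model bit-score minima plus a
global e-value ceiling, and assigns taxonomy to cluster representatives by
filtered top hits against a reference protein database.

Conventions
-----------
* Bit-score cutoffs are minima: a hit is kept when ``bit_score >= cutoff``.
* For hit filtering the e-value ceiling is inclusive (``e <= evalue_max``);
  for taxonomy assignment it is strict (``e < evalue_max``), matching the
  usual "top hits with e-values < 1e-5" practice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConfigError, InputError, ParseError

logger = logging.getLogger(__name__)

#: Minimum number of whitespace-separated fields in a per-domain table row.
_DOMTBL_MIN_FIELDS = 22


@dataclass(frozen=True)
class MarkerHit:
    """One search hit locating a marker gene on a scaffold.

    Coordinates are 1-based inclusive nucleotide positions on the scaffold,
    taken from the envelope columns of the per-domain table.
    """

    scaffold_id: str
    gene_id: str
    model_id: str
    bit_score: float
    e_value: float
    gene_start: int
    gene_end: int
    strand: str
    sample_of_origin: str

    def __post_init__(self) -> None:
        if self.gene_start > self.gene_end:
            raise InputError(
                f"hit {self.gene_id}: gene_start {self.gene_start} > "
                f"gene_end {self.gene_end}"
            )
        if self.e_value < 0:
            raise InputError(f"hit {self.gene_id}: negative e-value")
        if not self.sample_of_origin:
            raise InputError(f"hit {self.gene_id}: empty sample_of_origin")


@dataclass(frozen=True)
class TaxonomyAssignment:
    """Best-hit taxonomy for one query sequence.

    ``lineage`` is an ordered list of rank labels (domain first, possibly
    truncated); it is empty when no hit qualified or the subject was missing
    from the lineage map.
    """

    query_id: str
    subject_id: str | None
    e_value: float | None
    lineage: tuple[str, ...] = field(default_factory=tuple)


def _strip_suffix_scaffold(gene_id: str) -> str:
    """Scaffold id from a gene-caller id of the form ``<scaffold>_<n>``."""
    head, sep, tail = gene_id.rpartition("_")
    if sep and tail.isdigit():
        return head
    return gene_id


def parse_hit_table(path: str | Path, origin_sample: str) -> list[MarkerHit]:
    """Parse an hmmsearch per-domain tabular file into :class:`MarkerHit`.

    Gene coordinates come from the envelope columns (20 and 21, 1-based),
    the score and e-value from the per-domain score and independent e-value
    columns. The free-text description may carry ``scaffold=...`` and
    ``strand=...`` tokens; otherwise the scaffold id is derived by stripping
    a trailing ``_<n>`` gene index and the strand defaults to ``+``.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"hit table not found: {path}")
    hits: list[MarkerHit] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < _DOMTBL_MIN_FIELDS:
                raise ParseError(
                    f"{path}:{lineno}: expected >= {_DOMTBL_MIN_FIELDS} "
                    f"fields, got {len(fields)}"
                )
            gene_id = fields[0]
            model_id = fields[3]
            try:
                e_value = float(fields[12])
                bit_score = float(fields[13])
                gene_start = int(fields[19])
                gene_end = int(fields[20])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if gene_start > gene_end:
                raise ParseError(
                    f"{path}:{lineno}: envelope start {gene_start} > end {gene_end}"
                )
            desc_tokens = fields[22:]
            scaffold_id = _strip_suffix_scaffold(gene_id)
            strand = "+"
            for tok in desc_tokens:
                if tok.startswith("scaffold="):
                    scaffold_id = tok[len("scaffold="):]
                elif tok.startswith("strand="):
                    strand = tok[len("strand="):]
            hits.append(
                MarkerHit(
                    scaffold_id=scaffold_id,
                    gene_id=gene_id,
                    model_id=model_id,
                    bit_score=bit_score,
                    e_value=e_value,
                    gene_start=gene_start,
                    gene_end=gene_end,
                    strand=strand,
                    sample_of_origin=origin_sample,
                )
            )
    return hits


def filter_hits(
    hits: Sequence[MarkerHit],
    cutoffs: Mapping[str, float],
    evalue_max: float = 1e-5,
) -> list[MarkerHit]:
    """Retain hits with ``bit_score >= cutoff(model)`` and ``e <= evalue_max``.

    Relative order is preserved. Every hit's model must have a cutoff.
    """
    for h in hits:
        if h.model_id not in cutoffs:
            raise ConfigError(f"no score cutoff configured for model {h.model_id!r}")
    return [
        h
        for h in hits
        if h.bit_score >= cutoffs[h.model_id] and h.e_value <= evalue_max
    ]


def read_besthit_table(path: str | Path) -> pd.DataFrame:
    """Read a best-hit TSV with columns query, subject, bitscore, evalue."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"best-hit table not found: {path}")
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"query", "subject", "bitscore", "evalue"}
    if not required.issubset(df.columns):
        raise ParseError(
            f"{path}: missing columns {sorted(required - set(df.columns))}"
        )
    return df


def assign_taxonomy_tophit(
    search_rows: pd.DataFrame | Iterable[tuple[str, str, float, float]],
    lineage_map: Mapping[str, Sequence[str]],
    evalue_max: float = 1e-5,
    rank_by: str = "bitscore",
) -> list[TaxonomyAssignment]:
    """Assign taxonomy per query from its best qualifying database hit.

    Hits with ``e_value < evalue_max`` (strict) compete; the winner has the
    highest bit score (default) or lowest e-value when ``rank_by="evalue"``.
    Ties on the primary key fall to the secondary key (e-value or bit score
    respectively); remaining ties keep the first row. Queries with no
    qualifying hit get an empty lineage, as do subjects absent from
    ``lineage_map`` (with a logged warning).
    """
    if rank_by not in ("bitscore", "evalue"):
        raise ConfigError(f"rank_by must be 'bitscore' or 'evalue', got {rank_by!r}")
    if isinstance(search_rows, pd.DataFrame):
        rows = list(
            search_rows[["query", "subject", "bitscore", "evalue"]].itertuples(
                index=False, name=None
            )
        )
    else:
        rows = list(search_rows)

    # best row per query, preserving first-seen query order; the sort key is
    # (primary desc/asc, secondary, row index) so ties fall to earlier rows
    best: dict[str, tuple[tuple[float, float, int], str, float]] = {}
    order: list[str] = []
    seen: set[str] = set()
    for idx, (query, subject, bitscore, evalue) in enumerate(rows):
        query = str(query)
        if query not in seen:
            seen.add(query)
            order.append(query)
        if not float(evalue) < evalue_max:
            continue
        if rank_by == "bitscore":
            key = (-float(bitscore), float(evalue), idx)
        else:
            key = (float(evalue), -float(bitscore), idx)
        if query not in best or key < best[query][0]:
            best[query] = (key, str(subject), float(evalue))

    assignments: list[TaxonomyAssignment] = []
    for query in order:
        if query not in best:
            assignments.append(TaxonomyAssignment(query, None, None, ()))
            continue
        _key, subject, evalue = best[query]
        lineage = lineage_map.get(subject)
        if lineage is None:
            logger.warning(
                "subject %s (query %s) absent from lineage map; assignment "
                "retained with empty lineage",
                subject,
                query,
            )
            lineage = ()
        assignments.append(
            TaxonomyAssignment(query, subject, evalue, tuple(lineage))
        )
    return assignments


def read_lineage_map(path: str | Path) -> dict[str, tuple[str, ...]]:
    """Read a two-column TSV (subject, semicolon-joined lineage)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"subject", "lineage"}.issubset(df.columns):
        raise ParseError(f"{path}: expected columns subject, lineage")
    return {
        str(r.subject): tuple(str(r.lineage).split(";"))
        for r in df.itertuples(index=False)
    }


def write_hits_tsv(hits: Sequence[MarkerHit], path: str | Path, header_comment: str | None = None) -> None:
    """Write retained hits as TSV (one row per hit)."""
    df = pd.DataFrame(
        [
            {
                "gene_id": h.gene_id,
                "scaffold_id": h.scaffold_id,
                "model_id": h.model_id,
                "bit_score": h.bit_score,
                "e_value": h.e_value,
                "gene_start": h.gene_start,
                "gene_end": h.gene_end,
                "strand": h.strand,
                "sample_of_origin": h.sample_of_origin,
            }
            for h in hits
        ]
    )
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=False)
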