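"""Quality control of the marker protein multiple alignment.

The marker sequences are aligned externally (together with a small set of
reference sequences that anchor the alignment) and arrive as aligned FASTA.
Two cleaning steps follow:

1. columns whose gap fraction exceeds 95% are removed, and
2. sequences retaining fewer than half of the non-gap positions of the
   longest surviving non-reference sequence are dropped.

Step 2 uses an integer threshold ``T = floor(retention_fraction * N)`` where
``N`` is the non-gap count of the longest *non-reference* row after column
trimming; e.g. with ``N = 206`` and the default 50% rule, ``T = 103`` and a
102-position sequence is removed while a 103-position one is kept.
Reference rows are exempt from removal (they exist only to anchor the
alignment) and are excluded when computing ``N``; they are dropped from all
downstream outputs via :func:`drop_references`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import InputError

GAP_CHARS = ("-", ".")

#: Id prefix marking reference rows in aligned FASTA input.
DEFAULT_REFERENCE_PREFIX = "REF|"


@dataclass
class MultipleAlignment:
    """A gapped protein alignment with per-row reference flags."""

    ids: list[str]
    rows: list[str]
    is_reference: list[bool] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise InputError("ids and rows differ in length")
        if not self.is_reference:
            self.is_reference = [False] * len(self.ids)
        if len(self.is_reference) != len(self.ids):
            raise InputError("is_reference and rows differ in length")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise InputError(f"rows have unequal lengths: {sorted(lengths)}")

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def nongap_counts(self) -> list[int]:
        """Number of non-gap characters per row."""
        return [
            sum(1 for c in row if c not in GAP_CHARS) for row in self.rows
        ]

    @classmethod
    def from_fasta(
        cls, path: str | Path, reference_prefix: str = DEFAULT_REFERENCE_PREFIX
    ) -> "MultipleAlignment":
        path = Path(path)
        if not path.exists():
            raise InputError(f"alignment not found: {path}")
        ids, rows, refs = [], [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            ids.append(rec.id)
            rows.append(str(rec.seq).upper())
            refs.append(rec.id.startswith(reference_prefix))
        if not ids:
            raise InputError(f"alignment is empty: {path}")
        return cls(ids, rows, refs)

    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(row), id=sid, description="")
            for sid, row in zip(self.ids, self.rows)
        ]
        SeqIO.write(records, str(path), "fasta")


def _char_matrix(msa: MultipleAlignment) -> np.ndarray:
    return np.array([list(row.upper()) for row in msa.rows], dtype="<U1")


def trim_gappy_columns(
    msa: MultipleAlignment, max_gap_fraction: float = 0.95
) -> MultipleAlignment:
    """Remove columns whose gap fraction strictly exceeds ``max_gap_fraction``.

    A column with gap fraction exactly at the threshold is kept (removal is
    strict: only ``> max_gap_fraction`` columns go). Idempotent.
    """
    if len(msa) == 0:
        raise InputError("empty alignment")
    mat = _char_matrix(msa)
    is_gap = np.isin(mat, GAP_CHARS)
    gap_fraction = is_gap.mean(axis=0)
    keep = gap_fraction <= max_gap_fraction
    rows = ["".join(r) for r in mat[:, keep]]
    return MultipleAlignment(list(msa.ids), rows, list(msa.is_reference))


def filter_short_sequences(
    msa: MultipleAlignment, retention_fraction: float = 0.5
) -> tuple[MultipleAlignment, int]:
    """Drop non-reference rows with fewer than ``T`` non-gap positions.

    ``T = floor(retention_fraction * N)`` with ``N`` the non-gap count of
    the longest non-reference row. Reference rows are exempt and do not
    enter the computation of ``N``. Returns the surviving alignment and
    the threshold ``T``.
    """
    if len(msa) == 0:
        raise InputError("empty alignment")
    counts = msa.nongap_counts()
    nonref_counts = [
        c for c, ref in zip(counts, msa.is_reference) if not ref
    ]
    if not nonref_counts:
        raise InputError("alignment has no non-reference rows")
    threshold = math.floor(retention_fraction * max(nonref_counts))
    keep = [
        ref or c >= threshold for c, ref in zip(counts, msa.is_reference)
    ]
    out = MultipleAlignment(
        [i for i, k in zip(msa.ids, keep) if k],
        [r for r, k in zip(msa.rows, keep) if k],
        [f for f, k in zip(msa.is_reference, keep) if k],
    )
    return out, threshold


def drop_references(msa: MultipleAlignment) -> MultipleAlignment:
    """Remove reference rows (used downstream of QC)."""
    keep = [not ref for ref in msa.is_reference]
    if not any(keep):
        raise InputError("alignment has no non-reference rows")
    return MultipleAlignment(
        [i for i, k in zip(msa.ids, keep) if k],
        [r for r, k in zip(msa.rows, keep) if k],
        [False] * sum(keep),
    )


def ungapped_sequences(msa: MultipleAlignment) -> list[tuple[str, str]]:
    """(id, sequence) pairs with gap characters removed, row order kept."""
    out = []
    for sid, row in zip(msa.ids, msa.rows):
        seq = "".join(c for c in row if c not in GAP_CHARS)
        out.append((sid, seq))
    return out
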