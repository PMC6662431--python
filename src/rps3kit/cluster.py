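"""Greedy centroid clustering of marker protein sequences.

Sequences are processed in decreasing length order (ties by input order).
Each sequence joins an existing cluster when its identity to the centroid
reaches the threshold (default 99%) and the coverage constraints hold
(query coverage 1.0, target coverage 0.5 by default); otherwise it founds
a new cluster. In exhaustive mode — the default, corresponding to
unlimited accept/reject attempts in the heuristic tools this emulates —
every centroid is scored and the best-identity qualifying one wins, ties
going to the earlier-created centroid.

Identity definition
-------------------
Identity is computed from an optimal global alignment with free end gaps
under unit scoring (match +1, mismatch 0, gap −1; the scoring only selects
the alignment). Identity = matches / alignment columns, where columns that
are part of a terminal gap in either sequence are excluded; the coverage of
each sequence is the fraction of its residues inside that core region. A
query that exactly matches a window of a longer target therefore has
identity 1.0, query coverage 1.0, and target coverage = window / target
length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from Bio import Align

from .errors import InputError


@dataclass
class ClusterParams:
    """Greedy-clustering thresholds (fractions in (0, 1])."""

    identity_threshold: float = 0.99
    query_cov: float = 1.0
    target_cov: float = 0.5
    exhaustive: bool = True

    def __post_init__(self) -> None:
        for name in ("identity_threshold", "query_cov", "target_cov"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise InputError(f"{name} must be in (0, 1], got {v}")


@dataclass
class SeqCluster:
    """One cluster: centroid, ordered members, representative, identities."""

    centroid_id: str
    member_ids: list[str]
    representative_id: str
    identities: dict[str, float]


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner(
        mode="global",
        match_score=1,
        mismatch_score=0,
        open_gap_score=-1,
        extend_gap_score=-1,
    )
    # free end gaps on both sequences
    aligner.end_insertion_score = 0
    aligner.end_deletion_score = 0
    return aligner


_ALIGNER = _make_aligner()

# floating-point slack for threshold comparisons on exact rationals
_EPS = 1e-9


def pairwise_identity(query: str, target: str) -> tuple[float, float, float]:
    """Identity and mutual coverage of two ungapped protein sequences.

    Returns ``(identity, query_cov, target_cov)`` as defined in the module
    docstring.
    """
    if not query or not target:
        raise InputError("empty sequence")
    aln = _ALIGNER.align(target, query)[0]
    coords = aln.coordinates  # row 0: target, row 1: query
    dt = np.diff(coords[0])
    dq = np.diff(coords[1])
    n_steps = len(dt)
    first = 0
    last = n_steps - 1
    # terminal-gap steps: at most one leading and one trailing
    if n_steps > 1 and (dt[0] == 0 or dq[0] == 0):
        first = 1
    if n_steps > 1 and last >= first and (dt[last] == 0 or dq[last] == 0):
        last -= 1
    core = range(first, last + 1)
    core_columns = int(sum(max(dt[i], dq[i]) for i in core))
    if core_columns == 0:
        return 0.0, 0.0, 0.0
    matches = 0
    for i in core:
        if dt[i] > 0 and dq[i] > 0:  # diagonal step
            t0, q0 = coords[0][i], coords[1][i]
            t1 = coords[0][i + 1]
            a = np.frombuffer(target[t0:t1].encode(), dtype="S1")
            b = np.frombuffer(
                query[q0 : q0 + (t1 - t0)].encode(), dtype="S1"
            )
            matches += int((a == b).sum())
    q_core = int(sum(dq[i] for i in core))
    t_core = int(sum(dt[i] for i in core))
    return (
        matches / core_columns,
        q_core / len(query),
        t_core / len(target),
    )


def greedy_cluster(
    seqs: Sequence[tuple[str, str]], params: ClusterParams | None = None
) -> list[SeqCluster]:
    """Partition sequences into identity clusters by greedy centroid search.

    Every input sequence lands in exactly one cluster; each member satisfies
    identity >= threshold to its centroid with both coverage constraints.
    """
    params = params or ClusterParams()
    ids = [sid for sid, _ in seqs]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise InputError(f"duplicate sequence ids: {dupes}")
    for sid, seq in seqs:
        if not seq:
            raise InputError(f"empty sequence: {sid}")

    order = sorted(range(len(seqs)), key=lambda i: (-len(seqs[i][1]), i))
    clusters: list[SeqCluster] = []
    centroid_seqs: list[str] = []
    for i in order:
        sid, seq = seqs[i]
        best_j = -1
        best_identity = -1.0
        for j, cseq in enumerate(centroid_seqs):
            identity, qcov, tcov = pairwise_identity(seq, cseq)
            qualifies = (
                identity >= params.identity_threshold - _EPS
                and qcov >= params.query_cov - _EPS
                and tcov >= params.target_cov - _EPS
            )
            if not qualifies:
                continue
            if not params.exhaustive:
                best_j, best_identity = j, identity
                break
            if identity > best_identity + _EPS:
                best_j, best_identity = j, identity
        if best_j >= 0:
            clusters[best_j].member_ids.append(sid)
            clusters[best_j].identities[sid] = best_identity
        else:
            clusters.append(
                SeqCluster(
                    centroid_id=sid,
                    member_ids=[sid],
                    representative_id=sid,
                    identities={sid: 1.0},
                )
            )
            centroid_seqs.append(seq)

    lookup = dict(seqs)
    for cl in clusters:
        cl.representative_id = pick_representative(cl, lookup)
    return clusters


def pick_representative(cluster: SeqCluster, seqs: Mapping[str, str]) -> str:
    """Longest member's id; ties broken by member order (input order)."""
    if not cluster.member_ids:
        raise InputError("empty cluster")
    best_id = None
    best_len = -1
    for mid in cluster.member_ids:
        if mid not in seqs:
            raise InputError(f"member id missing from sequence map: {mid}")
        if len(seqs[mid]) > best_len:
            best_id, best_len = mid, len(seqs[mid])
    return best_id  # type: ignore[return-value]


def cluster_membership(clusters: Sequence[SeqCluster]) -> dict[str, str]:
    """member id -> centroid id (the cluster key used downstream)."""
    return {
        mid: cl.centroid_id for cl in clusters for mid in cl.member_ids
    }


def write_clusters_tsv(
    clusters: Sequence[SeqCluster], path, header_comment: str | None = None
) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("cluster_id\tmember_id\tidentity\tis_representative\n")
        for cl in clusters:
            for mid in cl.member_ids:
                fh.write(
                    f"{cl.centroid_id}\t{mid}\t{cl.identities[mid]:.6f}\t"
                    f"{int(mid == cl.representative_id)}\n"
                )
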