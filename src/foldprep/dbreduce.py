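"""Merge-and-reduce algorithms for clustered sequence databases, desk scale.

A clustered database maps a representative sequence to its member
sequences.  New sequence sets are merged in three steps: (1) each new
sequence is assigned to an existing cluster when it matches that cluster's
representative at >30% identity over ≥90% of its own length; (2) the
remaining sequences are greedily clustered at the same thresholds;
(3) every cluster is reduced to its ``diff`` most diverse members
(representative always kept), which collapses redundancy while preserving
cluster diversity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .msa import AMINO_ACIDS, AlignedSequence
from .filtering import maxdiv_select

__all__ = [
    "ClusteredDb",
    "assign_to_clusters",
    "cluster_remainder",
    "reduce_clusters",
    "sequence_identity_and_coverage",
]

_CODE = {c: i for i, c in enumerate(AMINO_ACIDS)}


@dataclass
class ClusteredDb:
    """representative_id → [(sequence_id, sequence), ...]; the representative
    is the first member of its own cluster."""

    clusters: Dict[str, List[Tuple[str, str]]]

    def __post_init__(self) -> None:
        seen: set = set()
        for rep_id, members in self.clusters.items():
            if not members or members[0][0] != rep_id:
                raise ValueError(
                    f"cluster {rep_id!r} must list its representative first"
                )
            for sid, _ in members:
                if sid in seen:
                    raise ValueError(f"sequence {sid!r} appears in two clusters")
                seen.add(sid)

    @property
    def n_sequences(self) -> int:
        return sum(len(m) for m in self.clusters.values())

    def to_tsv(self, path_or_buf) -> None:
        import pandas as pd

        rows = [
            {"representative_id": rep, "member_id": sid, "sequence": seq}
            for rep, members in self.clusters.items()
            for sid, seq in members
        ]
        pd.DataFrame(rows).to_csv(path_or_buf, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path_or_buf) -> "ClusteredDb":
        import pandas as pd

        df = pd.read_csv(path_or_buf, sep="\t", dtype=str)
        clusters: Dict[str, List[Tuple[str, str]]] = {}
        for rec in df.itertuples(index=False):
            clusters.setdefault(rec.representative_id, []).append(
                (rec.member_id, rec.sequence)
            )
        return cls(clusters)


def sequence_identity_and_coverage(query: str, target: str) -> Tuple[float, float]:
    """Local-alignment identity and query coverage between two raw sequences.

    Identity is identities over aligned columns; coverage is the aligned
    span's share of the query length.  Equal-length identical sequences get
    (1.0, 1.0) without alignment.
    """
    if not query or not target:
        return 0.0, 0.0
    if query == target:
        return 1.0, 1.0
    from .pipeline import naive_search

    hits = naive_search(query, [("t", target)])
    if not hits:
        return 0.0, 0.0
    hit = hits[0]
    qstart, qend, qlen = hit.query_span
    return hit.fident, (qend - qstart + 1) / qlen


def assign_to_clusters(
    new_sequences: Sequence[Tuple[str, str]],
    db: ClusteredDb,
    min_id: float = 0.3,
    min_cov: float = 0.9,
) -> Tuple[ClusteredDb, List[Tuple[str, str]]]:
    """Assign each new sequence to the best-matching existing cluster.

    A sequence joins the cluster of the representative it matches best when
    that match has identity strictly above ``min_id`` and covers at least
    ``min_cov`` of the sequence's own length; everything else is returned
    unassigned.  The input database is not modified.
    """
    from .pipeline import naive_search

    reps = [(rep_id, members[0][1]) for rep_id, members in db.clusters.items()]
    clusters = {rep: list(members) for rep, members in db.clusters.items()}
    unassigned: List[Tuple[str, str]] = []
    for sid, seq in new_sequences:
        hits = naive_search(seq, reps)
        best = None
        for hit in hits:  # ascending E-value
            qstart, qend, qlen = hit.query_span
            cov = (qend - qstart + 1) / qlen
            if hit.fident > min_id and cov >= min_cov:
                best = hit
                break
        if best is None:
            unassigned.append((sid, seq))
        else:
            clusters[best.target_id].append((sid, seq))
    return ClusteredDb(clusters), unassigned


def cluster_remainder(
    unassigned: Sequence[Tuple[str, str]],
    min_id: float = 0.3,
    min_cov: float = 0.9,
) -> ClusteredDb:
    """Greedy incremental clustering of the unassigned sequences.

    Sequences are visited longest first (ties by id); each joins the first
    existing cluster whose representative it matches at the thresholds, else
    it seeds a new cluster.
    """
    ordered = sorted(unassigned, key=lambda t: (-len(t[1]), t[0]))
    clusters: Dict[str, List[Tuple[str, str]]] = {}
    rep_order: List[Tuple[str, str]] = []
    for sid, seq in ordered:
        placed = False
        for rep_id, rep_seq in rep_order:
            ident, cov = sequence_identity_and_coverage(seq, rep_seq)
            if ident > min_id and cov >= min_cov:
                clusters[rep_id].append((sid, seq))
                placed = True
                break
        if not placed:
            clusters[sid] = [(sid, seq)]
            rep_order.append((sid, seq))
    return ClusteredDb(clusters)


def _member_rows(members: Sequence[Tuple[str, str]]) -> Optional[List[AlignedSequence]]:
    """Members as pseudo-MSA rows when they share one length (the fast path
    for the diversity selection); None if lengths differ."""
    lengths = {len(seq) for _, seq in members}
    if len(lengths) != 1:
        return None
    return [AlignedSequence(header=sid, aligned=seq) for sid, seq in members]


def reduce_clusters(db: ClusteredDb, diff: int = 10) -> ClusteredDb:
    """Keep only the ``diff`` most diverse members of every cluster.

    Uses the same deterministic farthest-point selection as the MSA filters,
    seeded at the representative so it is always retained.  Clusters at or
    below ``diff`` members pass through unchanged.
    """
    if diff < 1:
        raise ValueError("diff must be >= 1")
    out: Dict[str, List[Tuple[str, str]]] = {}
    for rep_id, members in db.clusters.items():
        if len(members) <= diff:
            out[rep_id] = list(members)
            continue
        rows = _member_rows(members)
        if rows is not None:
            selected = maxdiv_select(rows, diff)
            keep_ids = {r.header for r in selected}
        else:
            keep_ids = _maxdiv_unaligned(members, diff)
        kept = [(sid, seq) for sid, seq in members if sid in keep_ids]
        out[rep_id] = kept
    return ClusteredDb(out)


def _maxdiv_unaligned(members: Sequence[Tuple[str, str]], k: int) -> set:
    """Farthest-point selection with alignment-based identities for clusters
    of unequal-length members (slow path, desk scale only)."""
    n = len(members)
    idmat = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ident, _ = sequence_identity_and_coverage(members[i][1], members[j][1])
            idmat[i, j] = idmat[j, i] = ident
    dist = 1.0 - idmat
    selected = [0]
    min_dist = dist[0].copy()
    min_dist[0] = -np.inf
    for _ in range(k - 1):
        nxt = int(np.argmax(min_dist))
        selected.append(nxt)
        min_dist = np.minimum(min_dist, dist[nxt])
        min_dist[nxt] = -np.inf
    return {members[i][0] for i in selected}
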