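"""Diversity-aware MSA filtering.

Implements the multi-stage redundancy filters applied during MSA
construction:

* stage 1 — per-cluster maximum pairwise identity filter (95%) applied to
  each sequence-database cluster before its members join the MSA;
* stage 2 — a minimum score-per-column (qsc) filter against the query,
  active only once enough hits accumulate;
* stage 3 — the identity-bucketed diversity filter: rows are partitioned
  into query-identity buckets and each saturated bucket is independently
  reduced to its most diverse members, so redundancy removal in one bucket
  can never eliminate diversity in another.

All pairwise identities use the query length as denominator (see
:mod:`foldprep.msa`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .msa import (
    GAP_CODE,
    X_CODE,
    AlignedSequence,
    Msa,
    encode_rows,
    pairwise_identity_matrix,
    query_identity,
)

__all__ = [
    "FilterParams",
    "QSC_SCALE",
    "max_seq_id_filter",
    "qsc_filter",
    "qsc_scores",
    "maxdiv_select",
    "bucketed_diff_filter",
    "stage1_cluster_filter",
]

#: divisor applied to the raw BLOSUM62 score-per-column so the qsc threshold
#: 0.8 is meaningful: the smallest diagonal BLOSUM62 entry is 4, so any
#: query's self-score per column is >= 1.0 on this scale.
QSC_SCALE = 4.0

_BLOSUM62 = None


def _blosum62():
    global _BLOSUM62
    if _BLOSUM62 is None:
        from Bio.Align import substitution_matrices

        _BLOSUM62 = substitution_matrices.load("BLOSUM62")
    return _BLOSUM62


@dataclass
class FilterParams:
    """Parameter block for the stage-3 bucketed diversity filter.

    Defaults are the production stage-3 values: identity buckets at
    0.0/0.2/0.4/0.6/0.8/1.0, 3000 most-diverse rows kept per saturated
    bucket, 95% maximum pairwise identity, filtering enabled only in
    buckets holding at least 1000 rows.  A ``qsc`` of 0 or less disables
    the score filter.
    """

    max_seq_id: float = 0.95
    qid_buckets: Tuple[float, ...] = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)
    diff: int = 3000
    qsc: float = 0.0
    filter_min_enable: int = 1000

    def __post_init__(self) -> None:
        b = tuple(self.qid_buckets)
        if len(b) < 2 or b[0] != 0.0 or b[-1] != 1.0 or any(
            x >= y for x, y in zip(b, b[1:])
        ):
            raise ValueError(
                "qid_buckets must be strictly increasing from 0.0 to 1.0"
            )
        self.qid_buckets = b
        if self.diff < 0:
            raise ValueError("diff must be non-negative")
        if not 0.0 <= self.max_seq_id <= 1.0:
            raise ValueError("max_seq_id must lie in [0, 1]")

    def bucket_of(self, identity: float) -> int:
        """Bucket index for a query identity.

        The first bucket is closed [0, b1]; later buckets are left-open
        (b_k, b_{k+1}].
        """
        edges = self.qid_buckets
        for k in range(len(edges) - 1):
            if k == 0 and edges[0] <= identity <= edges[1]:
                return 0
            if k > 0 and edges[k] < identity <= edges[k + 1]:
                return k
        # identities below 0 or above 1 cannot occur; clamp defensively
        return 0 if identity < edges[0] else len(edges) - 2


# ---------------------------------------------------------------------------
# greedy maximum-pairwise-identity filter
# ---------------------------------------------------------------------------

def _kept_indices_max_seq_id(idmat: np.ndarray, threshold: float) -> List[int]:
    n = idmat.shape[0]
    over = idmat > threshold
    kept_mask = np.zeros(n, dtype=bool)
    kept: List[int] = []
    for i in range(n):
        if not (over[i] & kept_mask).any():
            kept.append(i)
            kept_mask[i] = True
    return kept


def max_seq_id_filter(
    rows: Sequence[AlignedSequence],
    threshold: float = 0.95,
    *,
    identity_matrix: Optional[np.ndarray] = None,
) -> List[AlignedSequence]:
    """Greedy redundancy filter: scan rows in priority (input) order and keep
    a row iff its pairwise identity to every already-kept row is at most
    ``threshold``.  The output is therefore free of pairs above the
    threshold.
    """
    rows = list(rows)
    if len(rows) <= 1:
        return rows
    if identity_matrix is None:
        identity_matrix = pairwise_identity_matrix(encode_rows(rows))
    kept = _kept_indices_max_seq_id(identity_matrix, threshold)
    return [rows[i] for i in kept]


# ---------------------------------------------------------------------------
# score-per-column (qsc) filter
# ---------------------------------------------------------------------------

def qsc_scores(rows: Sequence[AlignedSequence], query: AlignedSequence) -> np.ndarray:
    """BLOSUM62 score per query column for each row, on the QSC_SCALE scale.

    Gap and insertion columns contribute zero; the divisor is the query
    length, so partial hits score proportionally lower.
    """
    mat = _blosum62()
    codes = encode_rows([query] + list(rows))
    qcodes, rcodes = codes[0], codes[1:]
    qlen = codes.shape[1]
    from .msa import ALPHABET

    # 22x22 lookup: gap rows/columns score 0
    lut = np.zeros((22, 22), dtype=np.float64)
    letters = ALPHABET[:21]  # amino acids + X
    for i, a in enumerate(letters):
        for j, b in enumerate(letters):
            lut[i, j] = mat[a][b]
    scores = lut[qcodes[None, :], rcodes].sum(axis=1)
    return scores / (qlen * QSC_SCALE)


def qsc_filter(
    rows: Sequence[AlignedSequence],
    query: AlignedSequence,
    min_qsc: float = 0.8,
    min_enable: int = 100,
) -> List[AlignedSequence]:
    """Drop rows scoring below ``min_qsc`` per column against the query.

    The filter only activates once at least ``min_enable`` rows are present;
    below that the input passes through unchanged.  A ``min_qsc`` of 0 or
    less disables the filter entirely.
    """
    rows = list(rows)
    if min_qsc <= 0 or len(rows) < min_enable:
        return rows
    scores = qsc_scores(rows, query)
    return [r for r, s in zip(rows, scores) if s >= min_qsc]


# ---------------------------------------------------------------------------
# farthest-point diversity selection
# ---------------------------------------------------------------------------

def maxdiv_select(
    rows: Sequence[AlignedSequence],
    k: int,
    *,
    identity_matrix: Optional[np.ndarray] = None,
) -> List[AlignedSequence]:
    """Keep the ``k`` most diverse rows by deterministic farthest-point greedy.

    The first row in input order seeds the selection; each step adds the row
    whose minimum distance (1 − pairwise identity) to the selected set is
    largest, ties broken by input order.  Output preserves input order.
    """
    rows = list(rows)
    n = len(rows)
    if k >= n:
        return rows
    if k <= 0:
        return []
    if identity_matrix is None:
        identity_matrix = pairwise_identity_matrix(encode_rows(rows))
    dist = 1.0 - identity_matrix
    selected = np.zeros(n, dtype=bool)
    selected[0] = True
    min_dist = dist[0].copy()
    min_dist[0] = -np.inf
    for _ in range(k - 1):
        nxt = int(np.argmax(min_dist))  # argmax returns the first maximum: input-order ties
        selected[nxt] = True
        min_dist = np.minimum(min_dist, dist[nxt])
        min_dist[selected] = -np.inf
    return [rows[i] for i in np.flatnonzero(selected)]


# ---------------------------------------------------------------------------
# stage 3: identity-bucketed diversity filter
# ---------------------------------------------------------------------------

def bucketed_diff_filter(msa: Msa, params: Optional[FilterParams] = None) -> Msa:
    """Reduce each saturated query-identity bucket to its most diverse rows.

    Every non-query row is assigned to exactly one identity bucket.  Buckets
    holding fewer than ``params.filter_min_enable`` rows pass through
    untouched; saturated buckets are filtered within the bucket only — the
    95% maximum-pairwise-identity filter followed by farthest-point
    selection down to ``params.diff`` rows.  The query is always kept and
    output rows keep their original relative order, so redundancy removal in
    one bucket cannot affect any other.
    """
    params = params or FilterParams()
    query = msa.query
    others = msa.rows[1:]
    if not others:
        return Msa([query])

    codes = encode_rows(msa.rows)
    qcodes, rcodes = codes[0], codes[1:]
    qlen = codes.shape[1]
    matches = ((rcodes == qcodes[None, :]) & (rcodes < X_CODE)).sum(axis=1)
    identities = matches / qlen

    n_buckets = len(params.qid_buckets) - 1
    buckets: List[List[int]] = [[] for _ in range(n_buckets)]
    for i, ident in enumerate(identities):
        buckets[params.bucket_of(float(ident))].append(i)

    keep = np.zeros(len(others), dtype=bool)
    for members in buckets:
        if not members:
            continue
        if len(members) < params.filter_min_enable:
            keep[members] = True
            continue
        sub = rcodes[members]
        idmat = pairwise_identity_matrix(sub, qlen=qlen)
        kept_local = _kept_indices_max_seq_id(idmat, params.max_seq_id)
        if len(kept_local) > params.diff:
            sub_rows = [others[members[j]] for j in kept_local]
            sel = maxdiv_select(
                sub_rows,
                params.diff,
                identity_matrix=idmat[np.ix_(kept_local, kept_local)],
            )
            sel_ids = {id(r) for r in sel}
            kept_local = [j for j in kept_local if id(others[members[j]]) in sel_ids]
        keep[[members[j] for j in kept_local]] = True

    return Msa([query] + [r for r, k in zip(others, keep) if k])


# ---------------------------------------------------------------------------
# stage 1: per-cluster filter
# ---------------------------------------------------------------------------

def stage1_cluster_filter(
    cluster_rows: Sequence[Sequence[AlignedSequence]],
    threshold: float = 0.95,
) -> List[AlignedSequence]:
    """Apply the 95% maximum-pairwise-identity filter to each cluster
    independently and concatenate the survivors.

    Because filtering is per cluster, identical sequences arriving from two
    different clusters both survive.
    """
    out: List[AlignedSequence] = []
    for rows in cluster_rows:
        out.extend(max_seq_id_filter(list(rows), threshold))
    return out
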