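"""Two-database MSA construction over precomputed homology hit tables.

The workflow mirrors an expanded iterative profile search against a
clustered sequence database: hits against cluster consensus/representative
sequences are accepted by E-value, each accepted cluster is expanded to its
members by composing the stored member↔representative alignments with the
representative→query alignment, members are redundancy-filtered per cluster
(stage 1), score-filtered (stage 2), and the final MSA is reduced with the
identity-bucketed diversity filter (stage 3).

The search itself is out of scope; hit tables arrive as BLAST-tabular-like
TSV with extra columns, and :func:`naive_search` provides an exhaustive
Smith–Waterman stand-in for tests and desk-scale runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .msa import AlignedSequence, Msa
from .filtering import FilterParams, bucketed_diff_filter, max_seq_id_filter, qsc_filter

__all__ = [
    "HitRecord",
    "read_hit_table",
    "write_hit_table",
    "ClusterMember",
    "Cluster",
    "ClusterTable",
    "evalue_accept",
    "expand_cluster_hits",
    "build_msas",
    "naive_search",
]

_HIT_COLUMNS = [
    "query_id", "target_id", "fident", "evalue",
    "qstart", "qend", "qlen", "tstart", "tend", "tlen",
    "aligned_target", "cluster_id", "taxid", "accession",
]


@dataclass
class HitRecord:
    """One homology hit of the query against a database sequence.

    ``aligned_target`` is the target written in the query frame (A3M
    convention) over the query span ``qstart..qend``; expansion pads it to
    the full query length.
    """

    query_id: str
    target_id: str
    fident: float
    evalue: float
    query_span: Tuple[int, int, int]
    target_span: Tuple[int, int, int]
    aligned_target: str
    cluster_id: Optional[str] = None
    taxid: Optional[int] = None
    accession: Optional[str] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.fident <= 1.0:
            raise ValueError(f"fident {self.fident} outside [0, 1]")
        if self.evalue < 0:
            raise ValueError("negative E-value")
        for (a, b, n) in (self.query_span, self.target_span):
            if not (1 <= a <= b <= n):
                raise ValueError(f"invalid span ({a}, {b}, {n})")

    def to_aligned_sequence(self) -> AlignedSequence:
        """The hit as a full-query-width MSA row."""
        qstart, qend, qlen = self.query_span
        n_match = sum(1 for c in self.aligned_target if not c.islower())
        if n_match == qlen:
            aligned = self.aligned_target
        elif n_match == qend - qstart + 1:
            aligned = "-" * (qstart - 1) + self.aligned_target + "-" * (qlen - qend)
        else:
            raise ValueError(
                f"hit {self.target_id!r}: aligned string covers {n_match} query "
                f"columns, expected {qend - qstart + 1} or {qlen}"
            )
        return AlignedSequence(
            header=self.target_id,
            aligned=aligned,
            evalue=self.evalue,
            query_span=self.query_span,
            taxid=self.taxid,
            accession=self.accession,
        )


def read_hit_table(path_or_buf) -> List[HitRecord]:
    """Read a tab-separated hit table (header line required).

    Columns follow the BLAST outfmt-6 style plus ``aligned_target``,
    ``cluster_id``, ``taxid`` and ``accession``; empty cells in the optional
    columns become None.
    """
    import pandas as pd

    df = pd.read_csv(path_or_buf, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _HIT_COLUMNS[:11] if c not in df.columns]
    if missing:
        raise ValueError(f"hit table is missing columns: {missing}")
    hits = []
    for rec in df.itertuples(index=False):
        d = rec._asdict()
        hits.append(
            HitRecord(
                query_id=d["query_id"],
                target_id=d["target_id"],
                fident=float(d["fident"]),
                evalue=float(d["evalue"]),
                query_span=(int(d["qstart"]), int(d["qend"]), int(d["qlen"])),
                target_span=(int(d["tstart"]), int(d["tend"]), int(d["tlen"])),
                aligned_target=d["aligned_target"],
                cluster_id=d.get("cluster_id") or None,
                taxid=int(d["taxid"]) if d.get("taxid") else None,
                accession=d.get("accession") or None,
            )
        )
    return hits


def write_hit_table(hits: Sequence[HitRecord], path_or_buf) -> None:
    import pandas as pd

    rows = []
    for h in hits:
        rows.append({
            "query_id": h.query_id, "target_id": h.target_id,
            "fident": h.fident, "evalue": h.evalue,
            "qstart": h.query_span[0], "qend": h.query_span[1], "qlen": h.query_span[2],
            "tstart": h.target_span[0], "tend": h.target_span[1], "tlen": h.target_span[2],
            "aligned_target": h.aligned_target,
            "cluster_id": h.cluster_id or "",
            "taxid": "" if h.taxid is None else h.taxid,
            "accession": h.accession or "",
        })
    pd.DataFrame(rows, columns=_HIT_COLUMNS).to_csv(path_or_buf, sep="\t", index=False)


# ---------------------------------------------------------------------------
# cluster tables
# ---------------------------------------------------------------------------

@dataclass
class ClusterMember:
    member_id: str
    aligned_member: str           # member row of the member↔representative alignment
    aligned_representative: str   # representative row, same length

    def __post_init__(self) -> None:
        if len(self.aligned_member) != len(self.aligned_representative):
            raise ValueError(
                f"member {self.member_id!r}: pairwise alignment rows differ in length"
            )


@dataclass
class Cluster:
    cluster_id: str
    representative_id: str
    members: List[ClusterMember]

    def __post_init__(self) -> None:
        if self.representative_id not in {m.member_id for m in self.members}:
            raise ValueError(
                f"cluster {self.cluster_id!r}: representative "
                f"{self.representative_id!r} is not among its members"
            )


@dataclass
class ClusterTable:
    """cluster_id → representative + members with stored pairwise alignments."""

    clusters: Dict[str, Cluster]

    @classmethod
    def from_tsv(cls, path_or_buf) -> "ClusterTable":
        """Read a 4-column TSV (cluster_id, member_id, aligned_member,
        aligned_representative); the first member listed per cluster is its
        representative."""
        import pandas as pd

        df = pd.read_csv(path_or_buf, sep="\t", dtype=str, keep_default_na=False)
        clusters: Dict[str, Cluster] = {}
        for rec in df.itertuples(index=False):
            member = ClusterMember(rec.member_id, rec.aligned_member,
                                   rec.aligned_representative)
            if rec.cluster_id not in clusters:
                clusters[rec.cluster_id] = Cluster(rec.cluster_id, rec.member_id, [member])
            else:
                clusters[rec.cluster_id].members.append(member)
        return cls(clusters)

    def to_tsv(self, path_or_buf) -> None:
        import pandas as pd

        rows = []
        for c in self.clusters.values():
            for m in c.members:
                rows.append({"cluster_id": c.cluster_id, "member_id": m.member_id,
                             "aligned_member": m.aligned_member,
                             "aligned_representative": m.aligned_representative})
        pd.DataFrame(rows).to_csv(path_or_buf, sep="\t", index=False)


# ---------------------------------------------------------------------------
# hit acceptance and cluster expansion
# ---------------------------------------------------------------------------

def evalue_accept(hits: Sequence[HitRecord], max_evalue: float = 0.1) -> List[HitRecord]:
    """Keep hits with E-value strictly below ``max_evalue``, order preserved."""
    return [h for h in hits if h.evalue < max_evalue]


def _rep_to_member_map(member: ClusterMember) -> Dict[int, str]:
    """1-based representative position → member character ('-' for a gap)."""
    mapping: Dict[int, str] = {}
    pos = 0
    for rc, mc in zip(member.aligned_representative, member.aligned_member):
        if rc not in "-.":
            pos += 1
            mapping[pos] = "-" if mc in "-." else mc.upper()
    return mapping


def _compose_member_row(hit: HitRecord, member: ClusterMember) -> str:
    """Project a cluster member into the query frame through the
    representative: member→representative composed with representative→query.
    Representative insertions relative to the query are dropped."""
    mapping = _rep_to_member_map(member)
    qstart, qend, qlen = hit.query_span
    rep_pos = hit.target_span[0] - 1  # consumed so far
    out: List[str] = []
    for c in hit.aligned_target:
        if c == "-":
            out.append("-")
        elif c.islower():
            rep_pos += 1
        else:
            rep_pos += 1
            out.append(mapping.get(rep_pos, "-"))
    body = "".join(out)
    if len(body) == qlen:
        return body
    return "-" * (qstart - 1) + body + "-" * (qlen - qend)


def expand_cluster_hits(
    accepted_hits: Sequence[HitRecord],
    clusters: ClusterTable,
    max_seq_id: float = 0.95,
) -> List[AlignedSequence]:
    """Expand each accepted hit to its cluster members in the query frame.

    Member rows are produced by transitive alignment composition through the
    shared representative columns, then the stage-1 per-cluster 95% filter is
    applied before the rows join the MSA.  A cluster hit more than once is
    expanded only once.
    """
    out: List[AlignedSequence] = []
    seen: set = set()
    for hit in accepted_hits:
        cid = hit.cluster_id
        if cid is None:
            raise ValueError(f"hit {hit.target_id!r} carries no cluster_id")
        if cid in seen:
            continue
        seen.add(cid)
        try:
            cluster = clusters.clusters[cid]
        except KeyError:
            raise KeyError(f"unknown cluster_id {cid!r}") from None
        rows = []
        for member in cluster.members:
            aligned = _compose_member_row(hit, member)
            rows.append(
                AlignedSequence(
                    header=member.member_id,
                    aligned=aligned,
                    evalue=hit.evalue,
                    query_span=hit.query_span,
                    taxid=hit.taxid if member.member_id == cluster.representative_id else None,
                    accession=hit.accession if member.member_id == cluster.representative_id else None,
                )
            )
        out.extend(max_seq_id_filter(rows, max_seq_id))
    return out


def build_msas(
    query: AlignedSequence,
    uniref_hits: Sequence[HitRecord],
    env_hits: Sequence[HitRecord],
    clusters: ClusterTable,
    params: Optional[FilterParams] = None,
    max_evalue: float = 0.1,
    qsc_threshold: float = 0.8,
    qsc_min_enable: int = 100,
) -> Tuple[Msa, Msa, Msa]:
    """Run the full per-database pipeline and return
    (uniref_msa, env_msa, combined).

    Per database: E-value acceptance → cluster expansion with the per-cluster
    95% filter → qsc filter (0.8, enabled from 100 hits) → bucketed diversity
    filter.  The two database MSAs are filtered independently; the combined
    MSA is the query plus both row sets.
    """
    params = params or FilterParams()

    def one_db(hits: Sequence[HitRecord]) -> Msa:
        accepted = evalue_accept(hits, max_evalue)
        rows = expand_cluster_hits(accepted, clusters, params.max_seq_id)
        rows = qsc_filter(rows, query, qsc_threshold, qsc_min_enable)
        return bucketed_diff_filter(Msa([query] + rows), params)

    uniref_msa = one_db(uniref_hits)
    env_msa = one_db(env_hits)
    combined = Msa([query] + uniref_msa.rows[1:] + env_msa.rows[1:])
    return uniref_msa, env_msa, combined


# ---------------------------------------------------------------------------
# naive exhaustive search (test plumbing)
# ---------------------------------------------------------------------------

#: Karlin–Altschul parameters for gapped BLOSUM62 (open 11 / extend 1)
KA_LAMBDA = 0.267
KA_K = 0.041


def _aligner():
    from Bio.Align import PairwiseAligner, substitution_matrices

    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def naive_search(
    query: str,
    database: Sequence[Tuple[str, str]],
    max_hits: Optional[int] = None,
) -> List[HitRecord]:
    """Exhaustive Smith–Waterman search of ``query`` against ``database``
    ((id, sequence) pairs): BLOSUM62, affine gaps (−11/−1), E-values from the
    Karlin–Altschul formula E = K·m·n·exp(−λS) with the standard gapped
    constants.  Deterministic; hits sorted by ascending E-value, ties by
    database order.  This is desk-scale test plumbing, not a fast search.
    """
    aligner = _aligner()
    qlen = len(query)
    results: List[Tuple[float, int, HitRecord]] = []
    for order, (tid, tseq) in enumerate(database):
        if not tseq:
            continue
        alns = aligner.align(query, tseq)
        if len(alns) == 0:
            continue
        aln = alns[0]
        score = float(aln.score)
        if score <= 0:
            continue
        evalue = KA_K * qlen * len(tseq) * math.exp(-KA_LAMBDA * score)
        qblocks, tblocks = aln.aligned
        qstart, qend = int(qblocks[0][0]), int(qblocks[-1][1])
        tstart, tend = int(tblocks[0][0]), int(tblocks[-1][1])
        aligned_target, identities, columns = _a3m_from_blocks(
            query, tseq, qblocks, tblocks
        )
        fident = identities / columns if columns else 0.0
        results.append((
            evalue, order,
            HitRecord(
                query_id="query",
                target_id=tid,
                fident=fident,
                evalue=evalue,
                query_span=(qstart + 1, qend, qlen),
                target_span=(tstart + 1, tend, len(tseq)),
                aligned_target=aligned_target,
            ),
        ))
    results.sort(key=lambda t: (t[0], t[1]))
    hits = [r[2] for r in results]
    return hits[:max_hits] if max_hits is not None else hits


def _a3m_from_blocks(query, target, qblocks, tblocks):
    """A3M string of the target over the aligned query span, plus identity
    counts over aligned (residue–residue) columns."""
    out: List[str] = []
    identities = 0
    columns = 0
    prev_q = qblocks[0][0]
    prev_t = tblocks[0][0]
    for (qs, qe), (ts, te) in zip(qblocks, tblocks):
        if qs > prev_q:            # gap in target: query residues unmatched
            out.append("-" * (qs - prev_q))
        if ts > prev_t:            # gap in query: target insertion
            out.append(target[prev_t:ts].lower())
        for qi, ti in zip(range(qs, qe), range(ts, te)):
            out.append(target[ti].upper())
            columns += 1
            if query[qi].upper() == target[ti].upper() and query[qi].upper() != "X":
                identities += 1
        prev_q, prev_t = qe, te
    return "".join(out), identities, columns
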