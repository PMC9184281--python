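"""MSA containers and alignment-format I/O.

The central object is :class:`Msa`, a query-anchored multiple sequence
alignment following the A3M convention: uppercase letters and ``-`` occupy
match columns (one per query residue), lowercase letters are insertions
relative to the query and occupy no query column.  All identity and coverage
arithmetic in the package is expressed against the query's match columns.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: integer codes: 0..19 amino acids, 20 = X (unknown), 21 = gap
X_CODE = 20
GAP_CODE = 21
ALPHABET = AMINO_ACIDS + "X-"
_CODE = {c: i for i, c in enumerate(ALPHABET)}

__all__ = [
    "AMINO_ACIDS",
    "X_CODE",
    "GAP_CODE",
    "AlignedSequence",
    "Msa",
    "MsaFormatError",
    "read_a3m",
    "write_a3m",
    "read_alignment",
    "query_identity",
    "query_coverage",
    "pairwise_identity",
    "encode_rows",
    "pairwise_identity_matrix",
]


class MsaFormatError(ValueError):
    """Raised when an alignment document violates its format contract."""


@dataclass
class AlignedSequence:
    """One row of a query-anchored alignment.

    ``aligned`` uses the A3M convention; ``query_span`` is 1-based inclusive
    (qstart, qend, qlen) when the producing search reported one.
    """

    header: str
    aligned: str
    evalue: Optional[float] = None
    query_span: Optional[Tuple[int, int, int]] = None
    taxid: Optional[int] = None
    accession: Optional[str] = None

    def __post_init__(self) -> None:
        if self.evalue is not None and self.evalue < 0:
            raise ValueError(f"negative E-value on {self.identifier!r}")
        if self.query_span is not None:
            qstart, qend, qlen = self.query_span
            if not (1 <= qstart <= qend <= qlen):
                raise ValueError(
                    f"invalid query span {self.query_span} on {self.identifier!r}"
                )

    @property
    def identifier(self) -> str:
        """Header up to the first whitespace."""
        return self.header.split(None, 1)[0] if self.header else ""

    @property
    def match_string(self) -> str:
        """The row restricted to match columns (insertions removed)."""
        return "".join(c for c in self.aligned if not c.islower())

    @property
    def n_match_columns(self) -> int:
        return sum(1 for c in self.aligned if not c.islower())

    def with_aligned(self, aligned: str) -> "AlignedSequence":
        return replace(self, aligned=aligned)


@dataclass
class Msa:
    """Query-anchored MSA; ``rows[0]`` is the query."""

    rows: list

    def __post_init__(self) -> None:
        if not self.rows:
            raise MsaFormatError("an MSA needs at least a query row")
        q = self.rows[0]
        if any(c == "-" or c.islower() for c in q.aligned):
            raise MsaFormatError("query row must be ungapped with no insertions")
        qlen = len(q.aligned)
        for row in self.rows[1:]:
            n = row.n_match_columns
            if n != qlen:
                raise MsaFormatError(
                    f"row {row.identifier!r} has {n} match columns, query has {qlen}"
                )

    @property
    def query(self) -> AlignedSequence:
        return self.rows[0]

    @property
    def query_length(self) -> int:
        return len(self.rows[0].aligned)

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    def match_matrix(self) -> np.ndarray:
        """Integer-coded (n_rows, query_length) matrix of the match columns."""
        return encode_rows(self.rows)


def encode_rows(rows: Sequence[AlignedSequence]) -> np.ndarray:
    """Encode match columns of ``rows`` as an int8 matrix (X and gap included)."""
    if not rows:
        return np.zeros((0, 0), dtype=np.int8)
    mats = []
    for row in rows:
        s = row.match_string.upper()
        mats.append([_CODE.get(c, X_CODE) for c in s])
    widths = {len(m) for m in mats}
    if len(widths) != 1:
        raise MsaFormatError(f"rows have differing match-column counts: {sorted(widths)}")
    return np.asarray(mats, dtype=np.int8)


# ---------------------------------------------------------------------------
# identity / coverage primitives
# ---------------------------------------------------------------------------

def _match_codes(row: AlignedSequence) -> np.ndarray:
    return encode_rows([row])[0]


def pairwise_identity(a: AlignedSequence, b: AlignedSequence) -> float:
    """Fraction of query columns where both rows carry the same residue.

    The denominator is the query length (the number of match columns); 'X'
    and gaps never count as matches.
    """
    ca, cb = _match_codes(a), _match_codes(b)
    if ca.shape != cb.shape:
        raise MsaFormatError("rows have differing match-column counts")
    if ca.size == 0:
        return 0.0
    matches = np.count_nonzero((ca == cb) & (ca < X_CODE))
    return matches / ca.size


def query_identity(row: AlignedSequence, query: AlignedSequence) -> float:
    """Sequence identity of ``row`` to the query over the query's length."""
    return pairwise_identity(row, query)


def query_coverage(row: AlignedSequence) -> float:
    """Fraction of the query covered by ``row``.

    Uses the recorded query span when present, else the fraction of match
    columns carrying a residue.
    """
    if row.query_span is not None:
        qstart, qend, qlen = row.query_span
        return (qend - qstart + 1) / qlen
    codes = _match_codes(row)
    if codes.size == 0:
        return 0.0
    return float(np.count_nonzero(codes != GAP_CODE) / codes.size)


def pairwise_identity_matrix(codes: np.ndarray, qlen: Optional[int] = None) -> np.ndarray:
    """All-pairs identity over an encoded row matrix, vectorised.

    Match counts are accumulated per residue symbol with one rank-k update
    each, so the cost is 20 small matrix products rather than n^2 row scans.
    """
    n, width = codes.shape
    if qlen is None:
        qlen = width
    counts = np.zeros((n, n), dtype=np.float32)
    for symbol in range(X_CODE):  # X and gap never match
        hits = (codes == symbol)
        if not hits.any():
            continue
        h = hits.astype(np.float32)
        counts += h @ h.T
    return counts / float(qlen)


# ---------------------------------------------------------------------------
# A3M I/O
# ---------------------------------------------------------------------------

def _parse_fasta_records(text: str) -> list:
    records = []
    header = None
    chunks: list = []
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.rstrip()
        if not line or line.startswith(("#", ";")):
            continue
        if line.startswith(">"):
            if header is not None:
                records.append((header, "".join(chunks)))
            header = line[1:].strip()
            chunks = []
        else:
            if header is None:
                raise MsaFormatError(f"line {lineno}: sequence data before first header")
            chunks.append(line)
    if header is not None:
        records.append((header, "".join(chunks)))
    return records


def read_a3m(text: str) -> Msa:
    """Parse an A3M document into an :class:`Msa`.

    Lowercase insertion characters are preserved verbatim.  Rows whose
    match-column count differs from the query's are rejected with the
    offending record named.
    """
    records = _parse_fasta_records(text)
    if not records:
        raise MsaFormatError("empty A3M input")
    rows = [AlignedSequence(header=h, aligned=seq) for h, seq in records]
    qlen = rows[0].n_match_columns
    for row in rows[1:]:
        if row.n_match_columns != qlen:
            raise MsaFormatError(
                f"record {row.identifier!r}: {row.n_match_columns} match columns, "
                f"query {rows[0].identifier!r} has {qlen}"
            )
    return Msa(rows)


def write_a3m(msa: Msa) -> str:
    """Serialise an :class:`Msa` as an A3M document (inverse of read_a3m)."""
    out = io.StringIO()
    for row in msa.rows:
        out.write(f">{row.header}\n{row.aligned}\n")
    return out.getvalue()


# ---------------------------------------------------------------------------
# other alignment dialects
# ---------------------------------------------------------------------------

_FORMAT_ALIASES = {
    "a3m": "a3m",
    "fasta": "aligned_fasta",
    "aligned_fasta": "aligned_fasta",
    "sto": "stockholm",
    "stockholm": "stockholm",
    "clustal": "clustal",
}


def _columns_to_a3m(headers: Sequence[str], seqs: Sequence[str]) -> Msa:
    """Convert a rectangular alignment (first row = query) to A3M.

    Columns where the query holds a gap become insertions: dropped from the
    query, lowercased in every other row.
    """
    width = {len(s) for s in seqs}
    if len(width) != 1:
        raise MsaFormatError("alignment is not rectangular")
    query = seqs[0]
    rows = []
    for header, seq in zip(headers, seqs):
        chars = []
        for qc, c in zip(query, seq):
            if qc in "-.":
                if c not in "-.":
                    chars.append(c.lower())
            else:
                chars.append("-" if c == "." else c.upper())
        rows.append(AlignedSequence(header=header, aligned="".join(chars)))
    return Msa(rows)


def read_alignment(text: str, format: str) -> Msa:
    """Read an alignment in any supported dialect into the A3M convention.

    Supported formats: ``a3m``, ``aligned_fasta`` (``fasta``), ``stockholm``
    (``sto``), ``clustal``.  The first sequence is taken as the query;
    columns that are gaps in the query are converted to insertions.
    """
    try:
        fmt = _FORMAT_ALIASES[format.lower()]
    except KeyError:
        raise ValueError(
            f"unknown alignment format {format!r}; "
            f"expected one of {sorted(set(_FORMAT_ALIASES))}"
        ) from None
    if fmt == "a3m":
        return read_a3m(text)
    if fmt == "aligned_fasta":
        records = _parse_fasta_records(text)
        if not records:
            raise MsaFormatError("empty alignment input")
        return _columns_to_a3m([h for h, _ in records], [s for _, s in records])
    # Stockholm / Clustal via Biopython
    from Bio import AlignIO

    try:
        aln = AlignIO.read(io.StringIO(text), fmt)
    except ValueError as exc:
        raise MsaFormatError(f"could not parse {fmt} input: {exc}") from exc
    headers = [rec.description or rec.id for rec in aln]
    seqs = [str(rec.seq) for rec in aln]
    if not seqs:
        raise MsaFormatError("empty alignment input")
    return _columns_to_a3m(headers, seqs)
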