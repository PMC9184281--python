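"""Model-input feature assembly for single chains and complexes.

Covers the MSA layouts used for complex prediction with a single-chain
network (block-diagonal MSA copies plus optional paired rows), the
residue-index trick that encodes chain breaks through clipped relative
positional encoding, seeded MSA subsampling, and fixed-size padding used by
the compile cache.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .msa import GAP_CODE, AlignedSequence, Msa, encode_rows
from .pairing import PairedBlock

__all__ = [
    "ComplexSpec",
    "FeatureSet",
    "RESIDUE_INDEX_PAD",
    "assemble_homooligomer",
    "assemble_heterooligomer",
    "build_residue_index",
    "relative_position_bins",
    "subsample_msa",
    "make_fixed_size",
]

#: sentinel for padded residue-index positions
RESIDUE_INDEX_PAD = -1

#: relative-position clipping cap of the positional encoding
POSITION_CAP = 32


@dataclass
class ComplexSpec:
    """Stoichiometry of a complex: ordered (sequence, copy_count) chains."""

    chains: List[Tuple[str, int]]

    def __post_init__(self) -> None:
        for seq, copies in self.chains:
            if not seq:
                raise ValueError("empty chain sequence")
            if copies < 1:
                raise ValueError("copy_count must be >= 1")

    @property
    def chain_lengths(self) -> List[int]:
        return [len(seq) for seq, copies in self.chains for _ in range(copies)]

    @classmethod
    def parse(cls, text: str, sequences: dict) -> "ComplexSpec":
        """Parse 'A:2' or 'A:1,B:1' against a name→sequence mapping."""
        chains = []
        for part in text.split(","):
            name, _, count = part.partition(":")
            chains.append((sequences[name.strip()], int(count or 1)))
        return cls(chains)


@dataclass
class FeatureSet:
    """Integer-encoded model input features.

    ``msa_matrix`` holds match columns only (gap token included);
    ``chain_partition`` is a list of half-open (start, end) per chain copy.
    """

    msa_matrix: np.ndarray
    residue_index: np.ndarray
    chain_partition: List[Tuple[int, int]]
    padded_length: int
    cluster_rows: Optional[List[int]] = None
    extra_rows: Optional[List[int]] = None

    def __post_init__(self) -> None:
        if self.padded_length < self.total_length:
            raise ValueError("padded_length below total length")

    @property
    def total_length(self) -> int:
        return int(self.msa_matrix.shape[1])

    @property
    def n_rows(self) -> int:
        return int(self.msa_matrix.shape[0])

    @classmethod
    def from_msa(
        cls,
        msa: Msa,
        chain_lengths: Optional[Sequence[int]] = None,
        chain_gap: int = 200,
    ) -> "FeatureSet":
        mat = msa.match_matrix()
        lengths = list(chain_lengths) if chain_lengths else [mat.shape[1]]
        if sum(lengths) != mat.shape[1]:
            raise ValueError("chain lengths do not sum to MSA width")
        partition = []
        pos = 0
        for L in lengths:
            partition.append((pos, pos + L))
            pos += L
        return cls(
            msa_matrix=mat,
            residue_index=build_residue_index(lengths, chain_gap),
            chain_partition=partition,
            padded_length=mat.shape[1],
        )

    def to_json(self) -> str:
        return json.dumps({
            "msa_matrix": self.msa_matrix.tolist(),
            "residue_index": self.residue_index.tolist(),
            "chain_partition": [list(p) for p in self.chain_partition],
            "padded_length": self.padded_length,
            "cluster_rows": self.cluster_rows,
            "extra_rows": self.extra_rows,
        })

    @classmethod
    def from_json(cls, text: str) -> "FeatureSet":
        d = json.loads(text)
        return cls(
            msa_matrix=np.asarray(d["msa_matrix"], dtype=np.int8),
            residue_index=np.asarray(d["residue_index"], dtype=int),
            chain_partition=[tuple(p) for p in d["chain_partition"]],
            padded_length=int(d["padded_length"]),
            cluster_rows=d.get("cluster_rows"),
            extra_rows=d.get("extra_rows"),
        )


# ---------------------------------------------------------------------------
# complex MSA layouts
# ---------------------------------------------------------------------------

def assemble_homooligomer(msa: Msa, copies: int) -> Msa:
    """Lay out a homo-oligomer MSA with one gap-padded copy per subunit.

    Each non-query row appears once per copy, occupying only that copy's
    column block (all other blocks gap-filled); the query row is the query
    repeated.  This block-diagonal layout outperforms plain left-to-right
    concatenation of the rows.
    """
    if copies < 1:
        raise ValueError("copies must be >= 1")
    if copies == 1:
        return msa
    L = msa.query_length
    qseq = msa.query.aligned
    rows = [AlignedSequence(header=msa.query.header, aligned=qseq * copies)]
    for copy in range(copies):
        left = "-" * (L * copy)
        right = "-" * (L * (copies - copy - 1))
        for row in msa.rows[1:]:
            rows.append(row.with_aligned(left + row.aligned + right))
    return Msa(rows)


def assemble_heterooligomer(
    paired: Sequence[PairedBlock],
    unpaired: Sequence[Msa],
) -> Msa:
    """Lay out a hetero-oligomer MSA: paired rows first, then block-diagonal
    unpaired rows.

    Row 1 is the concatenated query.  Each paired block contributes one
    full-width row spanning every chain; each chain's unpaired rows occupy
    only that chain's column block, other blocks gap-filled.
    """
    if not unpaired:
        raise ValueError("need one unpaired MSA per chain")
    lengths = [m.query_length for m in unpaired]
    total = sum(lengths)
    query = "".join(m.query.aligned for m in unpaired)
    rows = [AlignedSequence(header="query", aligned=query)]
    for block in paired:
        if len(block.rows) != len(unpaired):
            raise ValueError(
                f"paired block for taxid {block.species_taxid} has "
                f"{len(block.rows)} rows for {len(unpaired)} chains"
            )
        parts = []
        for row, L in zip(block.rows, lengths):
            if row.n_match_columns != L:
                raise ValueError(
                    f"paired row {row.identifier!r} has {row.n_match_columns} "
                    f"match columns, chain expects {L}"
                )
            parts.append(row.aligned)
        rows.append(
            AlignedSequence(
                header=f"paired_tax{block.species_taxid}",
                aligned="".join(parts),
                evalue=block.combined_evalue,
                taxid=block.species_taxid,
            )
        )
    for c, msa in enumerate(unpaired):
        left = "-" * sum(lengths[:c])
        right = "-" * (total - sum(lengths[: c + 1]))
        for row in msa.rows[1:]:
            rows.append(row.with_aligned(left + row.aligned + right))
    return Msa(rows)


# ---------------------------------------------------------------------------
# residue index and positional encoding
# ---------------------------------------------------------------------------

def build_residue_index(
    chain_lengths: Sequence[int],
    chain_gap: int = 200,
) -> np.ndarray:
    """0-based residue index, consecutive within chains, offset between them.

    The positional encoding clips at |i−j| >= 32, so any ``chain_gap`` above
    32 makes the model treat segments as separate chains; smaller gaps are
    rejected.
    """
    if chain_gap <= POSITION_CAP:
        raise ValueError(
            f"chain_gap must exceed the positional-encoding cap "
            f"({POSITION_CAP}); got {chain_gap}"
        )
    parts = []
    start = 0
    for L in chain_lengths:
        if L < 1:
            raise ValueError("chain lengths must be positive")
        parts.append(np.arange(start, start + L))
        start += L + chain_gap
    return np.concatenate(parts)


def relative_position_bins(residue_index: np.ndarray, cap: int = POSITION_CAP) -> np.ndarray:
    """Clipped relative-position bins: clamp(i − j, −cap, cap) + cap.

    Any pair separated by ``cap`` or more shares the extreme bin, which is
    what lets a residue-index jump encode a chain break.
    """
    ri = np.asarray(residue_index)
    diff = ri[:, None] - ri[None, :]
    return np.clip(diff, -cap, cap) + cap


# ---------------------------------------------------------------------------
# subsampling and padding
# ---------------------------------------------------------------------------

def subsample_msa(
    msa_or_n,
    max_clusters: int = 512,
    max_extra: int = 1024,
    seed: int = 0,
) -> Tuple[List[int], List[int]]:
    """Subsample MSA rows into cluster-center rows and extra rows.

    The query (row 0) is always a cluster row; the remaining cluster rows are
    drawn uniformly without replacement, then up to ``max_extra`` of the rest
    become extra rows.  Deterministic for a fixed seed.  Accepts an
    :class:`~foldprep.msa.Msa` or a row count.
    """
    n = msa_or_n if isinstance(msa_or_n, int) else len(msa_or_n)
    rng = np.random.default_rng(seed)
    n_cluster = min(max_clusters, n)
    pool = np.arange(1, n)
    chosen = rng.choice(pool, size=n_cluster - 1, replace=False) if n_cluster > 1 \
        else np.array([], dtype=int)
    cluster_rows = [0] + sorted(int(i) for i in chosen)
    rest = np.setdiff1d(pool, chosen, assume_unique=False)
    n_extra = min(max_extra, rest.size)
    extra = rng.choice(rest, size=n_extra, replace=False) if n_extra else np.array([], dtype=int)
    return cluster_rows, sorted(int(i) for i in extra)


def make_fixed_size(fs: FeatureSet, pad_fraction: float = 0.1) -> FeatureSet:
    """Right-pad features to ceil(total_length × (1 + pad_fraction)).

    Padded MSA columns hold the gap token and padded residue-index entries a
    sentinel.  A compiled shape S then serves any query whose total length is
    at most S, which is what makes the compile cache effective.
    """
    if pad_fraction < 0:
        raise ValueError("pad_fraction must be non-negative")
    total = fs.total_length
    # round before ceil so e.g. 100 * 1.1 == 110.000...002 does not pad to 111
    padded = math.ceil(round(total * (1.0 + pad_fraction), 9))
    extra = padded - total
    mat = np.pad(fs.msa_matrix, ((0, 0), (0, extra)), constant_values=GAP_CODE)
    ri = np.pad(fs.residue_index, (0, extra), constant_values=RESIDUE_INDEX_PAD)
    return FeatureSet(
        msa_matrix=mat,
        residue_index=ri,
        chain_partition=list(fs.chain_partition),
        padded_length=padded,
        cluster_rows=fs.cluster_rows,
        extra_rows=fs.extra_rows,
    )
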