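"""MSA pairing for protein-complex prediction.

For a complex, each chain is searched separately; rows from different
chains are then paired so that (ideally) interacting orthologs share a row.
Two protocols are provided:

* :func:`pair_by_species` — a species contributes one paired row iff, after
  a 50% query-coverage filter, it has at least one hit for every chain; the
  smallest-E-value hit per chain is used.
* :func:`pair_by_genome_distance` — for prokaryotes, hits within a species
  are matched by proximity of their UniProt-style accession ordinals, a
  proxy for genomic distance (interacting genes tend to sit in one operon).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from .msa import AlignedSequence, query_coverage
from .pipeline import HitRecord

logger = logging.getLogger(__name__)

__all__ = [
    "PairedBlock",
    "pair_by_species",
    "pair_by_genome_distance",
    "accession_ordinal",
]


@dataclass
class PairedBlock:
    """One paired row of a complex MSA: one aligned hit per chain, all from
    the same species."""

    species_taxid: int
    rows: List[AlignedSequence]  # one per chain, chain order
    combined_evalue: float

    def __post_init__(self) -> None:
        for row in self.rows:
            if row.taxid is not None and row.taxid != self.species_taxid:
                raise ValueError(
                    f"row {row.identifier!r} taxid {row.taxid} != block "
                    f"species {self.species_taxid}"
                )


def _coverage_of(hit: HitRecord) -> float:
    qstart, qend, qlen = hit.query_span
    return (qend - qstart + 1) / qlen


def _usable(hits: Sequence[HitRecord], min_query_cov: float) -> List[HitRecord]:
    out = []
    for h in hits:
        if h.taxid is None:
            logger.warning("hit %s has no taxid; ignored for pairing", h.target_id)
            continue
        if _coverage_of(h) >= min_query_cov:
            out.append(h)
    return out


def pair_by_species(
    per_chain_hits: Sequence[Sequence[HitRecord]],
    min_query_cov: float = 0.5,
) -> List[PairedBlock]:
    """Pair the best hit per chain within each species.

    Hits covering less than ``min_query_cov`` of their query are discarded
    first.  A species yields a block iff it then still has at least one hit
    for every chain; per chain the smallest-E-value hit is chosen (ties by
    target_id).  Blocks are sorted by combined (summed) E-value ascending.
    """
    n_chains = len(per_chain_hits)
    by_species: List[Dict[int, List[HitRecord]]] = []
    for hits in per_chain_hits:
        d: Dict[int, List[HitRecord]] = {}
        for h in _usable(hits, min_query_cov):
            d.setdefault(h.taxid, []).append(h)
        by_species.append(d)

    shared = set(by_species[0])
    for d in by_species[1:]:
        shared &= set(d)

    blocks = []
    for taxid in shared:
        rows = []
        total = 0.0
        for c in range(n_chains):
            best = min(by_species[c][taxid], key=lambda h: (h.evalue, h.target_id))
            rows.append(best.to_aligned_sequence())
            total += best.evalue
        blocks.append(PairedBlock(species_taxid=taxid, rows=rows, combined_evalue=total))
    blocks.sort(key=lambda b: (b.combined_evalue, b.species_taxid))
    return blocks


# ---------------------------------------------------------------------------
# genome-distance pairing
# ---------------------------------------------------------------------------

def accession_ordinal(accession: str) -> int:
    """Map an accession to an integer ordinal.

    The alphanumeric characters of the accession are read as one base-36
    number (digits 0–9 and letters A–Z as 10–35), so accessions issued
    consecutively get consecutive ordinals: A0A001 and A0A003 differ by 2.
    """
    s = "".join(c for c in accession.upper() if c.isalnum())
    if not s:
        raise ValueError(f"accession {accession!r} has no alphanumeric characters")
    return int(s, 36)


def _ordinal_or_none(hit: HitRecord) -> Optional[int]:
    if hit.accession is None:
        logger.warning("hit %s has no accession; ignored for genome pairing",
                       hit.target_id)
        return None
    try:
        return accession_ordinal(hit.accession)
    except ValueError:
        logger.warning("hit %s has unparseable accession %r; ignored",
                       hit.target_id, hit.accession)
        return None


def _greedy_match_pairs(
    left: List[Tuple[int, HitRecord]],
    right: List[Tuple[int, HitRecord]],
    max_gap: int,
) -> List[Tuple[HitRecord, HitRecord]]:
    """Greedy bipartite matching by ordinal distance: candidate pairs are
    examined in ascending distance (ties by input order) and accepted when
    both sides are still free and the distance is within ``max_gap``."""
    candidates = []
    for (i, (oa, ha)) in enumerate(left):
        for (j, (ob, hb)) in enumerate(right):
            d = abs(oa - ob)
            if d <= max_gap:
                candidates.append((d, i, j, ha, hb))
    candidates.sort(key=lambda t: (t[0], t[1], t[2]))
    used_l: set = set()
    used_r: set = set()
    pairs = []
    for d, i, j, ha, hb in candidates:
        if i in used_l or j in used_r:
            continue
        used_l.add(i)
        used_r.add(j)
        pairs.append((ha, hb))
    return pairs


def pair_by_genome_distance(
    per_chain_hits: Sequence[Sequence[HitRecord]],
    max_gap: int = 10,
    min_query_cov: float = 0.5,
) -> List[PairedBlock]:
    """Pair hits within each species by accession-ordinal proximity.

    For two chains the matching is greedy over candidate pairs sorted by
    ordinal distance; matches farther apart than ``max_gap`` are rejected.
    With more than two chains the first chain anchors the block and every
    other chain is matched greedily against it.  A species may contribute
    several blocks (paralogous operon copies).
    """
    n_chains = len(per_chain_hits)
    if n_chains < 2:
        raise ValueError("genome-distance pairing needs at least two chains")

    per_species: Dict[int, List[List[Tuple[int, HitRecord]]]] = {}
    for c, hits in enumerate(per_chain_hits):
        for h in _usable(hits, min_query_cov):
            o = _ordinal_or_none(h)
            if o is None:
                continue
            per_species.setdefault(h.taxid, [[] for _ in range(n_chains)])[c].append((o, h))

    blocks: List[PairedBlock] = []
    for taxid in sorted(per_species):
        chains = per_species[taxid]
        if any(not ch for ch in chains):
            continue
        # match every other chain against chain 0
        partner: List[Dict[int, HitRecord]] = []
        for c in range(1, n_chains):
            pairs = _greedy_match_pairs(chains[0], chains[c], max_gap)
            partner.append({id(a): b for a, b in pairs})
        for _, anchor in chains[0]:
            selected = [anchor]
            complete = True
            for c in range(1, n_chains):
                mate = partner[c - 1].get(id(anchor))
                if mate is None:
                    complete = False
                    break
                selected.append(mate)
            if not complete:
                continue
            blocks.append(
                PairedBlock(
                    species_taxid=taxid,
                    rows=[h.to_aligned_sequence() for h in selected],
                    combined_evalue=sum(h.evalue for h in selected),
                )
            )
    blocks.sort(key=lambda b: (b.combined_evalue, b.species_taxid))
    return blocks
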