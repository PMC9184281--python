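"""Seed-deterministic synthetic inputs for every module.

Generators here construct MSAs with exact query-identity targets, species
hit layouts for pairing, block-structured PAE matrices, clustered sequence
databases and scripted mock predictors, so the whole pipeline is exercised
without any database download.  These are crude statistical stand-ins: rows
are independent point-mutation sets with no phylogeny, indels or
composition bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .msa import AMINO_ACIDS, AlignedSequence, Msa
from .pipeline import HitRecord

__all__ = [
    "make_msa",
    "make_cluster_rows",
    "make_species_hits",
    "make_pae",
    "MockScript",
    "MockPredictor",
    "make_mock_predictor",
    "make_clustered_db",
    "random_sequence",
]

_AA = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length))


def _mutate(query_codes: np.ndarray, n_mut: int, rng: np.random.Generator) -> np.ndarray:
    """Mutate exactly n_mut distinct positions to residues differing from the query."""
    row = query_codes.copy()
    if n_mut == 0:
        return row
    pos = rng.choice(row.size, size=n_mut, replace=False)
    # shift by 1..19 mod 20 guarantees a different residue
    shift = rng.integers(1, 20, size=n_mut)
    row[pos] = (row[pos] + shift) % 20
    return row


def make_msa(
    n_rows: int,
    length: int,
    qid_targets: Sequence[float],
    seed: int,
) -> Msa:
    """Build an MSA of ``n_rows`` hit rows plus a random query.

    Each hit row mutates the query at exactly ``round((1 - target) * length)``
    positions (chosen without replacement, always to a different residue), so
    its query identity equals the target exactly.  Targets are cycled over
    rows when fewer targets than rows are given.
    """
    targets = list(qid_targets)
    if not targets:
        raise ValueError("need at least one identity target")
    if any(t < 0 or t > 1 for t in targets):
        raise ValueError("identity targets must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    qcodes = rng.integers(0, 20, size=length)
    query = "".join(AMINO_ACIDS[i] for i in qcodes)
    rows = [AlignedSequence(header="query", aligned=query)]
    for i in range(n_rows):
        target = targets[i % len(targets)]
        n_mut = round((1.0 - target) * length)
        codes = _mutate(qcodes, n_mut, rng)
        rows.append(
            AlignedSequence(
                header=f"hit{i}",
                aligned="".join(AMINO_ACIDS[c] for c in codes),
            )
        )
    return Msa(rows)


def make_cluster_rows(
    n_members: int,
    length: int,
    n_groups: int,
    within_group_mut: int,
    seed: int,
    founder_mut: Optional[int] = None,
) -> List[AlignedSequence]:
    """A synthetic cluster: ``n_groups`` families of near-duplicates.

    Members of one group differ from the group founder at at most
    ``within_group_mut`` positions each, so within-group pairwise identity is
    at least 1 − 2·within_group_mut/length.  Founders are independent random
    sequences by default (between-group identity near the random baseline);
    with ``founder_mut`` set, each founder instead differs from one master
    sequence at exactly that many positions, placing between-group identity
    around 1 − 2·founder_mut/length.
    """
    rng = np.random.default_rng(seed)
    rows: List[AlignedSequence] = []
    per_group = n_members // n_groups
    extra = n_members - per_group * n_groups
    master = rng.integers(0, 20, size=length)
    idx = 0
    for g in range(n_groups):
        if founder_mut is None:
            founder = rng.integers(0, 20, size=length)
        else:
            founder = _mutate(master, founder_mut, rng)
        size = per_group + (1 if g < extra else 0)
        for m in range(size):
            n_mut = int(rng.integers(0, within_group_mut + 1)) if m else 0
            codes = _mutate(founder, n_mut, rng)
            rows.append(
                AlignedSequence(
                    header=f"g{g}m{m}",
                    aligned="".join(AMINO_ACIDS[c] for c in codes),
                )
            )
            idx += 1
    return rows


# ---------------------------------------------------------------------------
# species hit layouts for pairing
# ---------------------------------------------------------------------------

def make_species_hits(
    n_chains: int,
    layout: Sequence[dict],
    seed: int = 0,
    qlen: int = 100,
) -> List[List[HitRecord]]:
    """Realise a per-species hit layout as one hit table per chain.

    ``layout`` is a list of species entries::

        {"taxid": 9606,
         "chains": {0: [{"evalue": 1e-5, "coverage": 1.0,
                         "accession": "A0A001"}], 1: [...]}}

    Coverage controls the recorded query span; hit sequences are synthetic.
    """
    rng = np.random.default_rng(seed)
    tables: List[List[HitRecord]] = [[] for _ in range(n_chains)]
    counter = 0
    for species in layout:
        taxid = species.get("taxid")
        for chain, hits in species.get("chains", {}).items():
            for spec in hits:
                cov = float(spec.get("coverage", 1.0))
                qend = max(1, min(qlen, round(cov * qlen)))
                span_len = qend  # anchored at query start
                aligned = random_sequence(span_len, rng) + "-" * (qlen - span_len)
                tables[chain].append(
                    HitRecord(
                        query_id=f"chain{chain}",
                        target_id=spec.get("target_id", f"t{counter}"),
                        fident=float(spec.get("fident", 0.5)),
                        evalue=float(spec.get("evalue", 1e-3)),
                        query_span=(1, qend, qlen),
                        target_span=(1, span_len, span_len),
                        aligned_target=aligned,
                        taxid=spec.get("taxid", taxid),
                        accession=spec.get("accession"),
                    )
                )
                counter += 1
    return tables


# ---------------------------------------------------------------------------
# predictor outputs
# ---------------------------------------------------------------------------

def make_pae(
    n: int,
    partition: Optional[Sequence[Tuple[int, int]]],
    intra_level: float,
    inter_level: float,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Block-structured PAE matrix: ``intra_level`` within chains,
    ``inter_level`` across, plus optional seeded Gaussian noise clipped at 0.
    """
    if intra_level < 0 or inter_level < 0:
        raise ValueError("PAE levels must be non-negative")
    rng = np.random.default_rng(seed)
    pae = np.full((n, n), inter_level, dtype=float)
    if partition is None:
        partition = [(0, n)]
    for start, end in partition:
        pae[start:end, start:end] = intra_level
    if noise_sd > 0:
        pae = np.clip(pae + rng.normal(0.0, noise_sd, size=(n, n)), 0.0, None)
    return pae


#: MockScript maps (model_id, recycle_index) -> dict with keys
#: ``plddt`` (scalar or vector), optional ``pae``/``pae_level``, ``delta``
MockScript = Dict[Tuple[int, int], dict]


class MockPredictor:
    """Scripted predictor satisfying the scheduler's contract.

    Replays a :data:`MockScript`; raises ``KeyError`` for any
    (model, recycle) pair the script does not cover, which surfaces test
    bugs immediately.  Records every compile notification it receives.
    """

    def __init__(self, script: MockScript, n_residues: int = 50,
                 partition: Optional[Sequence[Tuple[int, int]]] = None):
        self.script = dict(script)
        self.n_residues = n_residues
        self.partition = list(partition) if partition else None
        self.compile_events: List[tuple] = []
        self.calls: List[tuple] = []

    def on_compile(self, key) -> None:
        self.compile_events.append(key)

    def __call__(self, features, model_id: int, recycle_index: int,
                 seed: int, is_training: bool):
        from .ranking import PredictionScores

        try:
            entry = self.script[(model_id, recycle_index)]
        except KeyError:
            raise KeyError(
                f"mock predictor has no script entry for model {model_id}, "
                f"recycle {recycle_index}"
            ) from None
        self.calls.append((model_id, recycle_index, seed, is_training))
        plddt = entry.get("plddt", 50.0)
        plddt_vec = np.full(self.n_residues, float(plddt)) if np.isscalar(plddt) \
            else np.asarray(plddt, dtype=float)
        pae = entry.get("pae")
        if pae is None and "pae_level" in entry:
            pae = np.full((plddt_vec.size, plddt_vec.size), float(entry["pae_level"]))
        scores = PredictionScores(
            plddt=plddt_vec,
            pae=None if pae is None else np.asarray(pae, dtype=float),
            partition=self.partition,
            name=f"model_{model_id}",
        )
        return scores, float(entry.get("delta", 1.0))


def make_mock_predictor(script: MockScript, **kwargs) -> MockPredictor:
    return MockPredictor(script, **kwargs)


# ---------------------------------------------------------------------------
# clustered databases
# ---------------------------------------------------------------------------

def make_clustered_db(
    n_clusters: int,
    members_per_cluster: int,
    length: int,
    seed: int,
    within_cluster_mut_frac: float = 0.3,
):
    """Synthetic clustered database: each cluster is a random representative
    plus members mutated at up to ``within_cluster_mut_frac`` of positions.
    """
    from .dbreduce import ClusteredDb

    rng = np.random.default_rng(seed)
    clusters = {}
    max_mut = max(1, int(within_cluster_mut_frac * length))
    for c in range(n_clusters):
        rep_codes = rng.integers(0, 20, size=length)
        rep_id = f"c{c}_rep"
        members = [(rep_id, "".join(AMINO_ACIDS[i] for i in rep_codes))]
        for m in range(members_per_cluster - 1):
            n_mut = int(rng.integers(1, max_mut + 1))
            codes = _mutate(rep_codes, n_mut, rng)
            members.append((f"c{c}_m{m}", "".join(AMINO_ACIDS[i] for i in codes)))
        clusters[rep_id] = members
    return ClusteredDb(clusters)
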