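"""Confidence metrics and prediction ranking.

Predictors report a per-residue pLDDT vector (0–100) and an N×N predicted
aligned error (PAE) matrix in Ångström.  Single-chain predictions are
ranked by mean pLDDT; complexes by a predicted TM-score derived from the
PAE — the interface variant (ipTM, cross-chain pairs only) when a chain
partition is available, pTM otherwise.  The mean cross-chain PAE
(inter-PAE) is exposed as an additional interaction-confidence readout.

The pTM functional form is the published upstream definition:
pTM = max_i mean_j 1 / (1 + (PAE_ij / d0(N))²) with
d0(N) = 1.24·(max(N, 19) − 15)^⅓ − 1.8 (N clamped so d0 stays positive).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "PredictionScores",
    "mean_plddt",
    "inter_pae",
    "ptm_from_pae",
    "iptm_from_pae",
    "rank_predictions",
    "read_scores_json",
]


def _chain_labels(n: int, partition: Sequence[Tuple[int, int]]) -> np.ndarray:
    labels = np.full(n, -1, dtype=int)
    for k, (start, end) in enumerate(partition):
        labels[start:end] = k
    if (labels < 0).any():
        raise ValueError("partition does not cover all residue indices")
    return labels


def mean_plddt(plddt: Sequence[float]) -> float:
    """Arithmetic mean of the per-residue pLDDT."""
    v = np.asarray(plddt, dtype=float)
    if v.size == 0:
        raise ValueError("empty pLDDT vector")
    return float(v.mean())


def inter_pae(pae: np.ndarray, partition: Sequence[Tuple[int, int]]) -> float:
    """Mean PAE over all ordered cross-chain residue pairs."""
    pae = np.asarray(pae, dtype=float)
    labels = _chain_labels(pae.shape[0], partition)
    cross = labels[:, None] != labels[None, :]
    if not cross.any():
        raise ValueError("inter-PAE is undefined for a single chain")
    return float(pae[cross].mean())


def _tm_d0(n: int) -> float:
    n = max(n, 19)
    return 1.24 * (n - 15.0) ** (1.0 / 3.0) - 1.8


def ptm_from_pae(pae: np.ndarray) -> float:
    """Predicted TM-score from a PAE matrix."""
    pae = np.asarray(pae, dtype=float)
    n = pae.shape[0]
    if n < 1:
        raise ValueError("empty PAE matrix")
    d0 = _tm_d0(n)
    terms = 1.0 / (1.0 + (pae / d0) ** 2)
    return float(terms.mean(axis=1).max())


def iptm_from_pae(pae: np.ndarray, partition: Sequence[Tuple[int, int]]) -> float:
    """Interface predicted TM-score: the pTM aggregation restricted to
    cross-chain pairs."""
    pae = np.asarray(pae, dtype=float)
    n = pae.shape[0]
    labels = _chain_labels(n, partition)
    cross = labels[:, None] != labels[None, :]
    if not cross.any():
        raise ValueError("ipTM is undefined for a single chain")
    d0 = _tm_d0(n)
    terms = 1.0 / (1.0 + (pae / d0) ** 2)
    with np.errstate(invalid="ignore"):
        per_i = np.where(cross, terms, 0.0).sum(axis=1) / cross.sum(axis=1)
    return float(np.nanmax(per_i))


@dataclass
class PredictionScores:
    """Confidence outputs of one model evaluation."""

    plddt: np.ndarray
    pae: Optional[np.ndarray] = None
    partition: Optional[List[Tuple[int, int]]] = None
    name: str = ""

    @property
    def mean_plddt(self) -> float:
        return mean_plddt(self.plddt)

    @property
    def ptm(self) -> Optional[float]:
        return None if self.pae is None else ptm_from_pae(self.pae)

    @property
    def iptm(self) -> Optional[float]:
        if self.pae is None or not self.partition or len(self.partition) < 2:
            return None
        return iptm_from_pae(self.pae, self.partition)

    @property
    def inter_pae(self) -> Optional[float]:
        if self.pae is None or not self.partition or len(self.partition) < 2:
            return None
        return inter_pae(self.pae, self.partition)

    def ranking_metric(self, mode: str) -> float:
        if mode == "single":
            return self.mean_plddt
        if mode == "complex":
            value = self.iptm if self.iptm is not None else self.ptm
            if value is None:
                raise ValueError(
                    f"prediction {self.name!r} has no PAE; cannot rank a complex"
                )
            return value
        raise ValueError(f"unknown ranking mode {mode!r}")


def rank_predictions(
    scores: Sequence[PredictionScores],
    mode: str = "single",
) -> List[PredictionScores]:
    """Order predictions by confidence, best first.

    Single chains rank by mean pLDDT; complexes by ipTM when a chain
    partition is present, else pTM.  The sort is stable, so ties keep input
    order.
    """
    return sorted(scores, key=lambda s: -s.ranking_metric(mode))


def read_scores_json(text: str, partition=None, name: str = "") -> PredictionScores:
    """Parse predictor-output JSON: {"plddt": [...], "pae": [[...]]}."""
    d = json.loads(text)
    plddt = np.asarray(d["plddt"], dtype=float)
    pae = np.asarray(d["pae"], dtype=float) if d.get("pae") is not None else None
    if pae is not None:
        if pae.ndim != 2 or pae.shape[0] != pae.shape[1]:
            raise ValueError("PAE matrix must be square")
        if (pae < 0).any():
            raise ValueError("PAE entries must be non-negative")
    return PredictionScores(plddt=plddt, pae=pae, partition=partition, name=name)
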