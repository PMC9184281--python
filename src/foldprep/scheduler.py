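"""Batch prediction scheduling with compile caching and early stopping.

Running a compiled network is cheap; compiling it for a new input shape is
expensive.  The scheduler therefore sorts queries by length, pads features
by a margin (10% by default) and reuses a compiled shape for every query
that fits inside it.  Models needing templates use a different network
configuration, so the compile cache is keyed on (configuration, padded
length, padded row count).

Early stopping halts recycling once the structure change between recycles
falls below a tolerance or the confidence score reaches a threshold, and
skips the remaining models (and samples) for that query once the threshold
is met.

The predictor is pluggable: any callable
``predictor(features, model_id, recycle_index, seed, is_training)``
returning ``(PredictionScores, structure_change)`` satisfies the contract;
an optional ``on_compile(key)`` method is notified of compile events.  The
structure-change metric is whatever the predictor chooses to report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

from .ranking import PredictionScores, rank_predictions

__all__ = [
    "RunConfig",
    "QueryJob",
    "Event",
    "BatchResult",
    "config_keys",
    "sample_seeds",
    "run_batch",
]

NUM_MODELS = 5


@dataclass
class RunConfig:
    """Scheduler settings; defaults mirror production use."""

    num_models: int = NUM_MODELS
    num_recycles: int = 3
    stop_at_score: Optional[float] = None
    recycle_tolerance: Optional[float] = None
    pad_fraction: float = 0.1
    num_samples: int = 1
    use_templates: bool = False
    is_training: bool = False
    base_seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.num_models <= NUM_MODELS:
            raise ValueError("num_models must be in 1..5")
        if self.num_recycles < 1:
            raise ValueError("num_recycles must be >= 1")
        if self.num_samples < 1:
            raise ValueError("num_samples must be >= 1")
        if self.pad_fraction < 0:
            raise ValueError("pad_fraction must be non-negative")


@dataclass
class QueryJob:
    """One prediction job: a name, its total residue length and MSA depth.

    ``payload`` is passed through to the predictor untouched (a FeatureSet,
    a sequence, anything the predictor understands).
    """

    name: str
    length: int
    n_rows: int = 1
    payload: object = None
    mode: str = "single"  # 'single' or 'complex' — selects the stop metric


@dataclass
class Event:
    kind: str  # 'compile' | 'evaluate' | 'stop_score' | 'stop_tolerance' | 'failed'
    query: str
    model_id: Optional[int] = None
    recycle: Optional[int] = None
    seed: Optional[int] = None
    detail: Optional[tuple] = None


@dataclass
class BatchResult:
    results: Dict[str, List[PredictionScores]]
    events: List[Event]
    failed: List[str]

    def events_of(self, kind: str) -> List[Event]:
        return [e for e in self.events if e.kind == kind]

    @property
    def n_compiles(self) -> int:
        return len(self.events_of("compile"))

    @property
    def n_evaluations(self) -> int:
        return len(self.events_of("evaluate"))


def config_keys(use_templates: bool, num_models: int = NUM_MODELS) -> Dict[int, str]:
    """Network configuration shared by each model id.

    Without templates all five models run under one configuration (model
    5's), so one compilation serves them all with swapped weights.  With
    templates, models 1–2 share model 1's configuration and models 3–5 share
    model 3's.
    """
    if use_templates:
        mapping = {1: "config_1", 2: "config_1", 3: "config_3", 4: "config_3", 5: "config_3"}
    else:
        mapping = {m: "config_5" for m in range(1, NUM_MODELS + 1)}
    return {m: mapping[m] for m in range(1, num_models + 1)}


def sample_seeds(num_samples: int, base_seed: int = 0) -> List[int]:
    """Deterministic seed series base, base+1, … for structure sampling."""
    if num_samples < 1:
        raise ValueError("num_samples must be >= 1")
    return list(range(base_seed, base_seed + num_samples))


class _CompileCache:
    """Compiled shapes per configuration; a shape (L, R) serves any query
    with length <= L and rows <= R."""

    def __init__(self, pad_fraction: float):
        self.pad_fraction = pad_fraction
        self.shapes: Dict[str, List[Tuple[int, int]]] = {}

    def shape_for(self, config_key: str, length: int, rows: int):
        """Return ((padded_len, padded_rows), newly_compiled)."""
        fitting = [
            s for s in self.shapes.get(config_key, ())
            if s[0] >= length and s[1] >= rows
        ]
        if fitting:
            return min(fitting), False
        shape = (
            math.ceil(round(length * (1.0 + self.pad_fraction), 9)),
            math.ceil(round(rows * (1.0 + self.pad_fraction), 9)),
        )
        self.shapes.setdefault(config_key, []).append(shape)
        return shape, True


def _as_job(query, index: int) -> QueryJob:
    if isinstance(query, QueryJob):
        return query
    if isinstance(query, str):  # bare sequence
        return QueryJob(name=f"query_{index}", length=len(query), payload=query)
    if hasattr(query, "total_length"):  # FeatureSet-like
        mode = "complex" if len(getattr(query, "chain_partition", [])) > 1 else "single"
        return QueryJob(
            name=f"query_{index}",
            length=query.total_length,
            n_rows=getattr(query, "n_rows", 1),
            payload=query,
            mode=mode,
        )
    raise TypeError(f"cannot schedule query of type {type(query).__name__}")


def run_batch(
    queries: Sequence,
    predictor: Callable,
    config: Optional[RunConfig] = None,
) -> BatchResult:
    """Run all queries through the predictor with compile caching and early
    stopping; returns per-query confidence-ranked results plus a full event
    log (every compile, evaluation and stop).

    Queries are processed in ascending total length (stable for ties).  Per
    query and sample seed, models run in fixed id order and each model
    recycles up to ``num_recycles`` times.  Recycling stops early when the
    reported structure change drops below ``recycle_tolerance`` or the score
    reaches ``stop_at_score``; once the score threshold is met the remaining
    models and samples for that query are skipped.  A predictor failure
    marks the query failed and the batch continues.
    """
    config = config or RunConfig()
    jobs = [_as_job(q, i) for i, q in enumerate(queries)]
    order = sorted(range(len(jobs)), key=lambda i: (jobs[i].length, i))
    keys = config_keys(config.use_templates, config.num_models)
    cache = _CompileCache(config.pad_fraction)
    events: List[Event] = []
    results: Dict[str, List[PredictionScores]] = {}
    failed: List[str] = []

    for i in order:
        job = jobs[i]
        collected: List[PredictionScores] = []
        reached_threshold = False
        try:
            for seed in sample_seeds(config.num_samples, config.base_seed):
                for model_id in range(1, config.num_models + 1):
                    key = keys[model_id]
                    shape, compiled = cache.shape_for(key, job.length, job.n_rows)
                    if compiled:
                        events.append(Event("compile", job.name, model_id,
                                            detail=(key, *shape)))
                        if hasattr(predictor, "on_compile"):
                            predictor.on_compile((key, *shape))
                    last: Optional[PredictionScores] = None
                    for recycle in range(1, config.num_recycles + 1):
                        scores, delta = predictor(
                            job.payload, model_id, recycle, seed, config.is_training
                        )
                        events.append(Event("evaluate", job.name, model_id,
                                            recycle, seed))
                        last = scores
                        if (
                            config.stop_at_score is not None
                            and scores.ranking_metric(job.mode) >= config.stop_at_score
                        ):
                            events.append(Event("stop_score", job.name, model_id,
                                                recycle, seed))
                            reached_threshold = True
                            break
                        if (
                            config.recycle_tolerance is not None
                            and delta is not None
                            and delta < config.recycle_tolerance
                        ):
                            events.append(Event("stop_tolerance", job.name,
                                                model_id, recycle, seed))
                            break
                    if last is not None:
                        collected.append(last)
                    if reached_threshold:
                        break
                if reached_threshold:
                    break
        except Exception as exc:  # noqa: BLE001 — predictor is third-party code
            events.append(Event("failed", job.name, detail=(repr(exc),)))
            failed.append(job.name)
            continue
        results[job.name] = rank_predictions(collected, job.mode) if collected else []
    return BatchResult(results=results, events=events, failed=failed)
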