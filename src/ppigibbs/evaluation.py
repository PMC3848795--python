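"""Evaluation metrics and experimental protocols.

The quality measure is the rank-wise TP/FP ratio: at rank *i*, TP_i
counts the queries whose *i*-th ranked predicted function is among their
true functions and FP_i the queries whose *i*-th call is not, so
TP_i + FP_i always equals the number of evaluated queries.  Every query
is counted at every evaluated rank — a query with fewer true functions
than the evaluation depth necessarily contributes false positives at the
deeper ranks.  The number of ranks evaluated follows the
floor-of-average-plus-one rule: ⌊mean functions per annotated protein⌋+1.

Two protocols are provided:

* **Leave-one-out cross-validation** — each annotated protein is held
  out in turn and re-predicted from its neighbours via the bootstrap
  (weighted-voting) step only; the iterative phase is omitted because a
  single held-out protein's label never feeds back into itself.
* **Sparsely-labeled experiments** — a fraction p of the annotated
  proteins keeps its labels, the rest are queried with the full
  burn-in + sampling algorithm; repeated with fresh seeded splits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .baselines import blast_knn_predict, majority_predict
from .containers import (
    AnnotationSet,
    EnrichedNetwork,
    RankedPrediction,
    SimilarityTable,
)
from .inference import GibbsConfig, bootstrap, gibbs_predict, rank_vector

__all__ = [
    "RankMetrics",
    "SparseExperimentReport",
    "rank_depth",
    "rank_tp_fp",
    "loocv",
    "sparse_experiment",
]


def _ratio(tp: np.ndarray, fp: np.ndarray) -> np.ndarray:
    """TP/FP with explicit sentinels: +inf when FP=0 and TP>0, NaN when
    both are 0 (the ratio is undefined there and must not be silently
    dropped)."""
    tp = np.asarray(tp, dtype=float)
    fp = np.asarray(fp, dtype=float)
    out = np.full(tp.shape, np.nan)
    np.divide(tp, fp, out=out, where=fp > 0)
    out[(fp == 0) & (tp > 0)] = np.inf
    return out


@dataclass(frozen=True)
class RankMetrics:
    """Per-rank true/false positive counts and their ratio."""

    tp: np.ndarray
    fp: np.ndarray

    @property
    def depth(self) -> int:
        return len(self.tp)

    @property
    def n_queries(self) -> int:
        return int(self.tp[0] + self.fp[0]) if self.depth else 0

    @property
    def ratios(self) -> np.ndarray:
        return _ratio(self.tp, self.fp)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, self.depth + 1),
                "tp": self.tp.astype(int),
                "fp": self.fp.astype(int),
                "ratio": self.ratios,
            }
        )


def rank_depth(ann: AnnotationSet) -> int:
    """Evaluation depth: ⌊mean functions per annotated protein⌋ + 1."""
    return math.floor(ann.mean_functions()) + 1


def rank_tp_fp(
    preds: Mapping[str, RankedPrediction],
    truth: AnnotationSet,
    depth: int,
) -> RankMetrics:
    """Count rank-wise TP/FP of predictions against true annotations.

    Every query is scored at every rank 1..depth; queries missing from
    ``truth`` or predictions shallower than ``depth`` raise.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    tp = np.zeros(depth)
    fp = np.zeros(depth)
    for q, pred in preds.items():
        true_fns = truth.functions_of(q)
        if not true_fns:
            raise ValueError(f"query {q!r} has no truth annotations")
        if len(pred.terms) < depth:
            raise ValueError(
                f"prediction for {q!r} has {len(pred.terms)} ranks, "
                f"need {depth}"
            )
        for i in range(depth):
            if pred.terms[i] in true_fns:
                tp[i] += 1
            else:
                fp[i] += 1
    return RankMetrics(tp, fp)


def _dispatch(
    method,
    net: EnrichedNetwork,
    labeled: AnnotationSet,
    queries: Sequence[str],
    cfg: GibbsConfig,
    sim: SimilarityTable | None,
    knn_k: int,
) -> Mapping[str, RankedPrediction]:
    if callable(method):
        return method(net, labeled, queries, cfg)
    if method == "gibbs":
        return gibbs_predict(net, labeled, queries, cfg)
    if method == "majority":
        return majority_predict(net.explicit, labeled, queries)
    if method == "blast-knn":
        if sim is None:
            raise ValueError("blast-knn requires a similarity table")
        return blast_knn_predict(sim, labeled, queries, knn_k)
    raise ValueError(f"unknown method {method!r}")


def loocv(
    net: EnrichedNetwork,
    ann: AnnotationSet,
    cfg: GibbsConfig = GibbsConfig(),
    method: str | Callable = "gibbs",
    sim: SimilarityTable | None = None,
    knn_k: int = 5,
    return_predictions: bool = False,
):
    """Leave-one-out cross-validation.

    Each annotated protein is removed in turn and re-predicted.  For the
    collective classifier only the bootstrap step runs (its ranking comes
    from the bootstrap distribution with a seeded random tie-break — the
    held-out protein's own label can never influence a later sweep, so
    the iterative phase would only add sampling noise).  Scored with
    :func:`rank_tp_fp` at the :func:`rank_depth` of the full annotation
    set.
    """
    if len(ann) < 2:
        raise ValueError("leave-one-out needs at least 2 annotated proteins")
    depth = rank_depth(ann)
    rng = np.random.default_rng(cfg.seed)
    preds: dict[str, RankedPrediction] = {}
    for x in sorted(ann.proteins):
        held = ann.drop([x])
        if method == "gibbs":
            dist = bootstrap(net, held, [x], cfg)[x]
            order = rank_vector(dist.probs, rng)
            preds[x] = RankedPrediction(
                x,
                tuple(dist.terms[j] for j in order),
                tuple(float(dist.probs[j]) for j in order),
                dist.is_fallback,
            )
        else:
            preds[x] = _dispatch(method, net, held, [x], cfg, sim, knn_k)[x]
    metrics = rank_tp_fp(preds, ann, depth)
    if return_predictions:
        return metrics, preds
    return metrics


@dataclass(frozen=True)
class SparseExperimentReport:
    """Results of the sparsely-labeled protocol.

    ``ratios`` has shape (n_fractions, repeats, depth); entries may be
    +inf (no false positives at that rank) or NaN (no query reached that
    rank).  ``seeds`` records the per-run seeds actually used.
    """

    fractions: tuple
    depth: int
    tp: np.ndarray  # (F, R, depth)
    fp: np.ndarray
    seeds: np.ndarray  # (F, R)

    @property
    def repeats(self) -> int:
        return self.tp.shape[1]

    @property
    def ratios(self) -> np.ndarray:
        return _ratio(self.tp, self.fp)

    @property
    def mean_ratios(self) -> np.ndarray:
        """Per-fraction mean of the per-run ratios, shape (F, depth)."""
        return self.ratios.mean(axis=1)

    @property
    def sd_ratios(self) -> np.ndarray:
        if self.repeats < 2:
            return np.zeros_like(self.mean_ratios)
        with np.errstate(invalid="ignore"):  # inf/NaN sentinel ratios
            return self.ratios.std(axis=1, ddof=1)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        mean = self.mean_ratios
        sd = self.sd_ratios
        for fi, frac in enumerate(self.fractions):
            for r in range(self.depth):
                rows.append(
                    {
                        "fraction": frac,
                        "rank": r + 1,
                        "mean_ratio": mean[fi, r],
                        "sd_ratio": sd[fi, r],
                    }
                )
        return pd.DataFrame(rows)


def sparse_experiment(
    net: EnrichedNetwork,
    ann: AnnotationSet,
    fractions: Iterable[float] = tuple(np.round(np.arange(0.1, 1.0, 0.1), 1)),
    repeats: int = 10,
    cfg: GibbsConfig = GibbsConfig(),
    method: str | Callable = "gibbs",
    sim: SimilarityTable | None = None,
    knn_k: int = 5,
) -> SparseExperimentReport:
    """Sparsely-labeled evaluation over a grid of annotated fractions.

    For each (fraction, repeat): a seeded uniform sample of the annotated
    proteins keeps its labels, every remaining annotated protein is
    queried with the full algorithm, and rank-wise TP/FP is scored
    against the held-out truth.  Per-run seeds derive from ``cfg.seed``
    via a spawned seed sequence, so the whole report is reproducible.
    """
    fractions = tuple(fractions)
    for f in fractions:
        if not (0.0 < f < 1.0):
            raise ValueError(f"fractions must lie in (0, 1), got {f}")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    proteins = sorted(ann.proteins)
    depth = rank_depth(ann)
    tp = np.zeros((len(fractions), repeats, depth))
    fp = np.zeros_like(tp)
    seeds = np.zeros((len(fractions), repeats), dtype=np.int64)
    for fi, frac in enumerate(fractions):
        n_labeled = int(round(frac * len(proteins)))
        if n_labeled < 1 or n_labeled >= len(proteins):
            raise ValueError(
                f"fraction {frac} leaves no labeled proteins or no queries"
            )
        for r in range(repeats):
            child = np.random.SeedSequence([cfg.seed, fi, r])
            run_seed = int(child.generate_state(1)[0] % (2**31))
            seeds[fi, r] = run_seed
            split_rng = np.random.default_rng(child)
            labeled_ids = split_rng.choice(proteins, size=n_labeled, replace=False)
            labeled = ann.subset(labeled_ids)
            queries = sorted(ann.proteins - set(labeled_ids))
            preds = _dispatch(
                method, net, labeled, queries,
                cfg.replace(seed=run_seed), sim, knn_k,
            )
            metrics = rank_tp_fp(preds, ann, depth)
            tp[fi, r] = metrics.tp
            fp[fi, r] = metrics.fp
    return SparseExperimentReport(fractions, depth, tp, fp, seeds)
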