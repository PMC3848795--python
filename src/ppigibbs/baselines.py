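"""Reference predictors: neighbourhood majority voting and sequence kNN.

Both return :class:`RankedPrediction` objects over the full function
universe so they plug directly into the evaluation protocols.  Support
fractions are normalized vote shares (a probability over functions), or
the fallback prior when a query has no voting evidence.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from .containers import (
    AnnotationSet,
    ExplicitNetwork,
    RankedPrediction,
    SimilarityTable,
)
from .inference import fallback_prior

__all__ = ["majority_predict", "blast_knn_predict"]


def _rank_scores(
    protein: str,
    scores: np.ndarray,
    terms: Sequence[str],
    is_fallback: bool,
) -> RankedPrediction:
    """Rank functions by descending score, ties by ascending index."""
    order = np.lexsort((np.arange(len(terms)), -scores))
    total = scores.sum()
    shares = scores / total if total > 0 else scores
    return RankedPrediction(
        protein,
        tuple(terms[j] for j in order),
        tuple(float(shares[j]) for j in order),
        is_fallback,
    )


def majority_predict(
    net: ExplicitNetwork,
    ann: AnnotationSet,
    queries: Iterable[str],
    prior_kind: str = "frequency",
) -> dict:
    """Weighted majority voting over labeled immediate PPI neighbours.

    Each candidate function is scored by the summed edge weights of the
    labeled explicit neighbours carrying it (unit weights recover the
    classic occurrence count).  Queries without labeled neighbours get the
    flagged fallback prior.
    """
    terms = ann.terms
    idx = ann.term_index()
    prior = fallback_prior(ann, prior_kind)
    out = {}
    for q in sorted(set(queries)):
        scores = np.zeros(len(terms))
        seen = False
        for nbr, w in net.neighbors(q):
            fns = ann.functions_of(nbr)
            if not fns:
                continue
            seen = True
            for t in fns:
                scores[idx[t]] += w
        if not seen:
            out[q] = _rank_scores(q, prior, terms, True)
        else:
            out[q] = _rank_scores(q, scores, terms, False)
    return out


def blast_knn_predict(
    sim: SimilarityTable,
    ann: AnnotationSet,
    queries: Iterable[str],
    k: int = 5,
) -> dict:
    """Sequence-only kNN: similarity-weighted votes of the k most similar
    *labeled* proteins.

    The PPI network plays no role.  Neighbour selection is restricted to
    labeled proteins with strictly positive similarity (an unlabeled
    near-neighbour casts no vote and would only crowd out usable ones);
    ties at the k-th rank break by ascending identifier.  Queries with no
    positively similar labeled protein get the flagged fallback prior.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    terms = ann.terms
    idx = ann.term_index()
    prior = fallback_prior(ann)
    out = {}
    for q in sorted(set(queries)):
        candidates = [
            (nbr, float(s))
            for nbr, s in sim.out_scores(q).items()
            if s > 0 and nbr in ann
        ]
        candidates.sort(key=lambda pair: (-pair[1], pair[0]))
        nearest = candidates[:k]
        if not nearest:
            out[q] = _rank_scores(q, prior, terms, True)
            continue
        scores = np.zeros(len(terms))
        for nbr, s in nearest:
            for t in ann.functions_of(nbr):
                scores[idx[t]] += s
        out[q] = _rank_scores(q, scores, terms, False)
    return out
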