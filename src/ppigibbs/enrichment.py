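"""Network enrichment: adding top-k similarity-inferred implicit edges.

For each protein x the similarity table defines a score vector
``s_x = [s_{x,1}, ..., s_{x,n}]`` over the other proteins (self-similarity
is zero).  Enrichment attaches to x the k proteins with the highest
positive scores as *implicit* neighbours, weighted by those scores, while
leaving the explicit PPI graph untouched.  ``k = 0`` reproduces the bare
network (the "Origin" configuration).
"""

from __future__ import annotations

import logging
from typing import Iterable

from .containers import EnrichedNetwork, ExplicitNetwork, SimilarityTable

logger = logging.getLogger(__name__)

__all__ = ["similarity_vector", "top_k_implicit", "enrich"]


def similarity_vector(
    sim: SimilarityTable, x: str, universe: Iterable[str]
) -> list:
    """Score vector of protein ``x`` against ``universe`` \\ {x}.

    Returns ``[(protein, score), ...]`` sorted by ascending identifier;
    absent pairs score 0 and ``x`` itself is never included.
    """
    universe = set(universe)
    if x not in universe:
        raise ValueError(f"protein {x!r} not in universe")
    row = sim.out_scores(x)
    return [(i, float(row.get(i, 0.0))) for i in sorted(universe - {x})]


def top_k_implicit(
    sim: SimilarityTable, universe: Iterable[str], k: int
) -> dict:
    """Per-protein top-k implicit neighbour lists.

    For each protein in ``universe``, the k neighbours with the highest
    strictly positive similarity scores (fewer when fewer positive scores
    exist; zero-score neighbours are never added — a zero-weight edge casts
    no vote and would only distort the normalizers).  Lists are sorted by
    descending score, ties broken by ascending identifier.  ``k = 0``
    yields empty lists everywhere.
    """
    if k < 0:
        raise ValueError(f"k must be non-negative, got {k}")
    universe = set(universe)
    out: dict[str, tuple] = {}
    for x in universe:
        if k == 0:
            out[x] = ()
            continue
        candidates = [
            (i, float(s))
            for i, s in sim.out_scores(x).items()
            if s > 0 and i != x and i in universe
        ]
        candidates.sort(key=lambda pair: (-pair[1], pair[0]))
        out[x] = tuple(candidates[:k])
    return out


def enrich(
    net: ExplicitNetwork,
    sim: SimilarityTable,
    k: int,
    reciprocal: bool = False,
) -> EnrichedNetwork:
    """Build the enriched network over the union of protein identifiers.

    The implicit channel is directed from each query's perspective: x's
    implicit neighbourhood is exactly x's own top-k.  With
    ``reciprocal=True``, x additionally gains y whenever x appears in y's
    top-k (an undirected variant; lists may then exceed k).  Implicit
    edges may duplicate explicit ones — both channels keep them, the λ
    mixture of the voting rule handles the overlap.
    """
    universe = net.proteins | sim.proteins
    implicit = top_k_implicit(sim, universe, k)
    if reciprocal:
        extra: dict[str, dict[str, float]] = {x: dict(lst) for x, lst in implicit.items()}
        for y, lst in implicit.items():
            for x, s in lst:
                extra[x].setdefault(y, sim.get(y, x))
        implicit = {
            x: tuple(sorted(row.items(), key=lambda pair: (-pair[1], pair[0])))
            for x, row in extra.items()
        }
    n_impl = sum(len(lst) for lst in implicit.values())
    logger.info(
        "enriched network: %d explicit edges, %d implicit edges (k=%d) "
        "over %d proteins",
        net.n_edges, n_impl, k, len(universe),
    )
    return EnrichedNetwork(net, implicit, k)
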