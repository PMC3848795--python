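"""Shared fixtures: small hand-built networks and random fixture factories."""

from __future__ import annotations

import numpy as np
import pytest

from ppigibbs.containers import (
    AnnotationSet,
    EnrichedNetwork,
    ExplicitNetwork,
    SimilarityTable,
)


@pytest.fixture
def vote_fixture():
    """The worked bootstrap example: query X, one implicit neighbour M1
    labeled {F1} with score 10, explicit neighbours N1 {F1} (w=1) and
    N2 {F2} (w=1).  At λ=0.5 the vote is [0.75, 0.25]."""
    net = ExplicitNetwork.from_edges([("X", "N1", 1.0), ("X", "N2", 1.0)])
    enriched = EnrichedNetwork(net, {"X": (("M1", 10.0),)}, k=1)
    ann = AnnotationSet.from_mapping({"M1": {"F1"}, "N1": {"F1"}, "N2": {"F2"}})
    return enriched, ann


@pytest.fixture
def path_network():
    """4-node path A(F1)–B(F1)–C(F2)–D(F2), unit weights, no implicit."""
    net = ExplicitNetwork.from_edges([("A", "B"), ("B", "C"), ("C", "D")])
    ann = AnnotationSet.from_mapping(
        {"A": {"F1"}, "B": {"F1"}, "C": {"F2"}, "D": {"F2"}}
    )
    enriched = EnrichedNetwork(net, {p: () for p in net.proteins}, 0)
    return enriched, ann


def random_fixture(rng: np.random.Generator, n: int = 8, m: int = 3):
    """A random enriched network + annotations for property tests.

    Roughly half the proteins are labeled; edge existence, weights,
    implicit lists and label sets are all random, deliberately including
    degenerate cases (isolated proteins, empty implicit lists).
    """
    proteins = [f"P{i}" for i in range(n)]
    terms = [f"F{j}" for j in range(m)]
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.3:
                edges.append((proteins[i], proteins[j], float(rng.uniform(0.1, 3.0))))
    net = ExplicitNetwork.from_edges(edges)
    for p in proteins:
        net.graph.add_node(p)
    implicit = {}
    for p in proteins:
        others = [q for q in proteins if q != p]
        k_p = int(rng.integers(0, 4))
        chosen = rng.choice(others, size=min(k_p, len(others)), replace=False)
        lst = sorted(
            ((q, float(rng.uniform(0.5, 20.0))) for q in chosen),
            key=lambda pair: (-pair[1], pair[0]),
        )
        implicit[p] = tuple(lst)
    enriched = EnrichedNetwork(net, implicit, 3)
    labeled = [p for p in proteins if rng.random() < 0.5]
    mapping = {
        p: set(
            np.random.default_rng(rng.integers(2**31)).choice(
                terms, size=int(rng.integers(1, m + 1)), replace=False
            )
        )
        for p in labeled
    }
    ann = AnnotationSet.from_mapping(mapping, terms=terms) if mapping else \
        AnnotationSet.from_mapping({proteins[0]: {terms[0]}}, terms=terms)
    queries = sorted(set(proteins) - ann.proteins)
    return enriched, ann, queries


@pytest.fixture
def make_annotations():
    """Factory: an AnnotationSet of ``n`` proteins with ``total``
    annotations spread as evenly as possible (mean = total / n)."""

    def _make(n: int, total: int) -> AnnotationSet:
        base, extra = divmod(total, n)
        mapping = {}
        for i in range(n):
            count = base + (1 if i < extra else 0)
            mapping[f"P{i:03d}"] = {f"F{j:02d}" for j in range(count)}
        return AnnotationSet.from_mapping(mapping)

    return _make
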