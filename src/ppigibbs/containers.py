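"""Core data containers shared across the package.

The central objects are:

* :class:`AnnotationSet` — the multi-label ground truth, a mapping from
  protein identifiers to sets of function terms (GO ids, FunCat codes, or
  any opaque strings) together with a fixed, ordered term universe.
* :class:`ExplicitNetwork` — the observed protein–protein interaction
  graph with optional confidence weights.
* :class:`SimilarityTable` — directed pairwise sequence-similarity scores
  (e.g. BLAST bit scores), with self-similarity forced to zero.
* :class:`OntologyTable` — a flat child→parent table used only by the
  informative-term filter.
* :class:`EnrichedNetwork` — the explicit graph plus, per protein, its
  top-k *implicit* (similarity-inferred) neighbours; the two edge channels
  are stored separately and never merged.
* :class:`FunctionDistribution` / :class:`RankedPrediction` — per-protein
  outputs of the voting and rank-aggregation machinery.

All identifiers are case-sensitive opaque strings.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationSet",
    "ExplicitNetwork",
    "SimilarityTable",
    "OntologyTable",
    "EnrichedNetwork",
    "FunctionDistribution",
    "RankedPrediction",
]


def _check_protein_id(pid: str) -> str:
    if not pid or any(ch.isspace() for ch in pid):
        raise ValueError(f"invalid protein identifier: {pid!r}")
    return pid


@dataclass(frozen=True)
class AnnotationSet:
    """Protein → set of function terms, with a fixed term universe.

    The term universe (``terms``) is an ordered tuple of the distinct
    function terms; its length is the label dimension *m* of the
    multi-label problem.  The universe is preserved by :meth:`drop` and
    :meth:`subset` so that label vectors keep a stable meaning when
    proteins are held out during cross-validation.

    Parameters
    ----------
    mapping
        ``protein -> frozenset of terms``; every annotated protein carries
        at least one term.
    terms
        Ordered tuple of all distinct terms.  Term *j* of a label vector
        refers to ``terms[j]``.
    """

    mapping: Mapping[str, frozenset]
    terms: tuple

    @classmethod
    def from_mapping(
        cls,
        mapping: Mapping[str, Iterable[str]],
        terms: Sequence[str] | None = None,
    ) -> "AnnotationSet":
        clean: dict[str, frozenset] = {}
        for pid, ts in mapping.items():
            _check_protein_id(pid)
            ts = frozenset(ts)
            if not ts:
                continue
            for t in ts:
                if not t:
                    raise ValueError(f"empty function term for protein {pid!r}")
            clean[pid] = ts
        observed: set[str] = set()
        for ts in clean.values():
            observed |= ts
        if terms is None:
            universe = tuple(sorted(observed))
        else:
            universe = tuple(terms)
            missing = observed - set(universe)
            if missing:
                raise ValueError(f"terms {sorted(missing)} not in supplied universe")
        return cls(dict(clean), universe)

    @property
    def m(self) -> int:
        """Number of distinct function terms."""
        return len(self.terms)

    @property
    def proteins(self) -> frozenset:
        return frozenset(self.mapping)

    def __len__(self) -> int:
        return len(self.mapping)

    def __contains__(self, pid: str) -> bool:
        return pid in self.mapping

    def functions_of(self, pid: str) -> frozenset:
        """Terms annotated to ``pid`` (empty set if unannotated)."""
        return self.mapping.get(pid, frozenset())

    def term_index(self) -> dict:
        return {t: j for j, t in enumerate(self.terms)}

    def term_counts(self) -> dict:
        """Raw annotation count per term (number of annotated proteins)."""
        counts = {t: 0 for t in self.terms}
        for ts in self.mapping.values():
            for t in ts:
                counts[t] += 1
        return counts

    def mean_functions(self) -> float:
        """Average number of functions per annotated protein."""
        if not self.mapping:
            raise ValueError("annotation set is empty")
        return sum(len(ts) for ts in self.mapping.values()) / len(self.mapping)

    def indicator_matrix(self, proteins: Sequence[str]) -> np.ndarray:
        """(len(proteins), m) 0/1 matrix of label indicators f_{i,j}."""
        idx = self.term_index()
        out = np.zeros((len(proteins), self.m), dtype=float)
        for i, pid in enumerate(proteins):
            for t in self.mapping.get(pid, ()):
                out[i, idx[t]] = 1.0
        return out

    def drop(self, proteins: Iterable[str]) -> "AnnotationSet":
        """Remove proteins' annotations, keeping the term universe fixed."""
        gone = set(proteins)
        return AnnotationSet(
            {p: ts for p, ts in self.mapping.items() if p not in gone}, self.terms
        )

    def subset(self, proteins: Iterable[str]) -> "AnnotationSet":
        """Keep only the given proteins; the term universe is unchanged."""
        keep = set(proteins)
        return AnnotationSet(
            {p: ts for p, ts in self.mapping.items() if p in keep}, self.terms
        )


@dataclass
class ExplicitNetwork:
    """Undirected weighted PPI graph (the *explicit* edge channel).

    Invariants enforced by :meth:`from_edges`: no self-loops, at most one
    edge per unordered pair (duplicates merged by maximum weight), strictly
    positive weights, defaulting to 1.0 for unweighted input.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple], default_weight: float = 1.0
    ) -> "ExplicitNetwork":
        """Build from (a, b) or (a, b, weight) tuples, applying invariants."""
        g = nx.Graph()
        n_dup = 0
        n_self = 0
        for row in edges:
            if len(row) == 2:
                a, b = row
                w = default_weight
            else:
                a, b, w = row
            _check_protein_id(a)
            _check_protein_id(b)
            w = float(w)
            if w <= 0:
                raise ValueError(f"non-positive edge weight {w} on ({a}, {b})")
            if a == b:
                n_self += 1
                continue
            if g.has_edge(a, b):
                n_dup += 1
                g[a][b]["weight"] = max(g[a][b]["weight"], w)
            else:
                g.add_edge(a, b, weight=w)
        if n_self:
            logger.warning("dropped %d self-loop(s)", n_self)
        if n_dup:
            logger.info("merged %d duplicate edge(s) by max weight", n_dup)
        return cls(g)

    @property
    def proteins(self) -> frozenset:
        return frozenset(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def neighbors(self, pid: str) -> list:
        """Sorted ``[(neighbour, weight), ...]`` of explicit neighbours."""
        if pid not in self.graph:
            return []
        return sorted(
            (nbr, float(self.graph[pid][nbr]["weight"])) for nbr in self.graph[pid]
        )

    def edges(self) -> Iterator[tuple]:
        """Canonical (min_id, max_id, weight) triples."""
        for a, b, d in self.graph.edges(data=True):
            if b < a:
                a, b = b, a
            yield (a, b, float(d["weight"]))


@dataclass
class SimilarityTable:
    """Directed pairwise similarity scores s_{x,i} (query → subject).

    Self-similarity is never stored (s_{x,x} = 0 by construction) and
    duplicate (query, subject) records collapse to their maximum score —
    the conventional pair-level summary when an aligner emits several HSPs
    for the same pair.
    """

    scores: dict = field(default_factory=dict)  # query -> {subject: score}

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple]) -> "SimilarityTable":
        table: dict[str, dict[str, float]] = {}
        n_self = 0
        for q, s, score in pairs:
            _check_protein_id(q)
            _check_protein_id(s)
            score = float(score)
            if score < 0:
                raise ValueError(f"negative similarity score {score} for ({q}, {s})")
            if q == s:
                n_self += 1  # self-similarity is not considered
                continue
            row = table.setdefault(q, {})
            if s in row:
                row[s] = max(row[s], score)
            else:
                row[s] = score
        if n_self:
            logger.info("zeroed %d self-similarity record(s)", n_self)
        return cls(table)

    @property
    def proteins(self) -> frozenset:
        ids: set[str] = set(self.scores)
        for row in self.scores.values():
            ids |= set(row)
        return frozenset(ids)

    @property
    def n_pairs(self) -> int:
        return sum(len(row) for row in self.scores.values())

    def get(self, query: str, subject: str) -> float:
        """Score for (query, subject); absent pairs and self-pairs score 0."""
        if query == subject:
            return 0.0
        return self.scores.get(query, {}).get(subject, 0.0)

    def out_scores(self, query: str) -> Mapping[str, float]:
        return self.scores.get(query, {})

    def pairs(self) -> Iterator[tuple]:
        for q, row in self.scores.items():
            for s, score in row.items():
                yield (q, s, score)


@dataclass(frozen=True)
class OntologyTable:
    """Flat child → parent(s) table for function terms.

    Only parent/child adjacency is represented; the table is validated to
    be acyclic on construction.  Terms may have multiple parents.
    """

    parents: Mapping[str, frozenset]
    children: Mapping[str, frozenset]

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple]) -> "OntologyTable":
        g = nx.DiGraph()
        for child, parent in pairs:
            if not child or not parent:
                raise ValueError("empty term in ontology pair")
            g.add_edge(child, parent)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("ontology table contains a cycle")
        parents = {t: frozenset(g.successors(t)) for t in g.nodes}
        children = {t: frozenset(g.predecessors(t)) for t in g.nodes}
        return cls(parents, children)

    def children_of(self, term: str) -> frozenset:
        return self.children.get(term, frozenset())

    def ancestors_of(self, term: str) -> frozenset:
        """All (transitive) ancestors of ``term``; empty for unknown terms."""
        seen: set[str] = set()
        stack = list(self.parents.get(term, ()))
        while stack:
            t = stack.pop()
            if t in seen:
                continue
            seen.add(t)
            stack.extend(self.parents.get(t, ()))
        return frozenset(seen)


@dataclass
class EnrichedNetwork:
    """Explicit PPI graph plus per-protein implicit neighbour lists.

    ``implicit[x]`` is protein *x*'s own top-k most similar proteins as an
    ordered tuple of ``(neighbour, score)`` pairs, descending by score with
    ties broken by ascending identifier.  The implicit channel is directed
    from the query's perspective: *x* appearing in *y*'s top-k does not add
    *y* to *x*'s list (a reciprocal variant is available at enrichment
    time).  The two channels are kept separate; dropping the implicit
    channel recovers the explicit network exactly.
    """

    explicit: ExplicitNetwork
    implicit: dict  # protein -> tuple[(neighbour, score), ...]
    k: int

    @property
    def proteins(self) -> frozenset:
        return self.explicit.proteins | frozenset(self.implicit)

    def implicit_neighbors(self, pid: str) -> tuple:
        return self.implicit.get(pid, ())

    def explicit_neighbors(self, pid: str) -> list:
        return self.explicit.neighbors(pid)

    def to_json(self) -> str:
        payload = {
            "k": self.k,
            "explicit": [[a, b, w] for a, b, w in self.explicit.edges()],
            "explicit_isolated": sorted(
                self.explicit.proteins
                - {p for e in self.explicit.edges() for p in e[:2]}
            ),
            "implicit": {
                p: [[nbr, s] for nbr, s in lst] for p, lst in self.implicit.items()
            },
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "EnrichedNetwork":
        payload = json.loads(text)
        net = ExplicitNetwork.from_edges(
            (a, b, w) for a, b, w in payload["explicit"]
        )
        for pid in payload.get("explicit_isolated", []):
            net.graph.add_node(pid)
        implicit = {
            p: tuple((nbr, float(s)) for nbr, s in lst)
            for p, lst in payload["implicit"].items()
        }
        return cls(net, implicit, int(payload["k"]))


@dataclass(frozen=True)
class FunctionDistribution:
    """Per-protein functional probability distribution a_x over m terms.

    ``probs[j]`` is the probability that the protein carries function
    ``terms[j]``; entries are non-negative and sum to one.  ``is_fallback``
    marks distributions produced from the fallback prior because no
    assigned neighbour contributed any vote.
    """

    protein: str
    probs: np.ndarray
    terms: tuple
    is_fallback: bool = False

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", p)
        if p.shape != (len(self.terms),):
            raise ValueError("probability vector length does not match terms")
        if np.any(p < 0):
            raise ValueError("negative probability")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"probabilities sum to {p.sum()!r}, not 1")

    def argmax_term(self) -> str:
        return self.terms[int(np.argmax(self.probs))]


@dataclass(frozen=True)
class RankedPrediction:
    """Final ranked function list c_x for one query protein.

    ``terms`` is an ordered tuple of distinct function terms, best first;
    ``supports[r]`` is the support fraction of the rank-(r+1) call (for
    Gibbs output, the fraction of sampling iterations whose rank-(r+1)
    entry equalled this term).
    """

    protein: str
    terms: tuple
    supports: tuple
    is_fallback: bool = False

    def __post_init__(self):
        if len(self.terms) != len(set(self.terms)):
            raise ValueError("ranked terms must be distinct")
        if len(self.supports) != len(self.terms):
            raise ValueError("supports length must match terms")
        for s in self.supports:
            if not (0.0 <= s <= 1.0):
                raise ValueError(f"support fraction {s} outside [0, 1]")

    def term_at(self, rank: int) -> str:
        """Term at 1-based rank."""
        return self.terms[rank - 1]
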