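"""Readers and writers for the tool's tabular formats.

Supported inputs: whitespace/tab-separated edge lists (2 or 3 columns),
similarity scores in either BLAST tabular ``outfmt 6`` (12 columns, bit
score in the last column) or a plain 3-column TSV, annotation TSVs
``(protein, term)``, ontology TSVs ``(child, parent)``, and — purely for
identifier cross-checking — FASTA headers.  Outputs: ranked-prediction
TSVs that round-trip losslessly.

Also implements the informative-term filter (a term is kept when it is
annotated by at least ``threshold`` proteins and no child term is) and the
``restrict_to_common`` preprocessing step that removes proteins lacking
either interaction data or sequence information.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from .containers import (
    AnnotationSet,
    ExplicitNetwork,
    OntologyTable,
    RankedPrediction,
    SimilarityTable,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "read_edge_list",
    "read_similarity",
    "read_annotations",
    "read_ontology",
    "read_fasta_ids",
    "filter_informative_terms",
    "restrict_to_common",
    "write_edge_list",
    "write_similarity",
    "write_annotations",
    "write_predictions",
    "read_predictions",
]

#: Default annotation-count threshold for the informative-term filter.
INFORMATIVE_THRESHOLD = 30


class FormatError(ValueError):
    """Raised for malformed input files; the message names the line."""


def _rows(path) -> Iterator[tuple[int, list[str]]]:
    """Yield (1-based line number, whitespace-split fields), skipping blanks
    and ``#`` comments."""
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            yield lineno, line.split()


def read_edge_list(path, has_weights: bool | None = None) -> ExplicitNetwork:
    """Read an undirected edge list TSV into an :class:`ExplicitNetwork`.

    Parameters
    ----------
    path
        TSV with 2 columns (protein_a, protein_b) or 3 columns
        (protein_a, protein_b, weight).
    has_weights
        ``True`` to require a weight column, ``False`` to forbid one,
        ``None`` (default) to infer per file from the first data row.

    Unweighted edges get weight 1.0.  Self-loops are dropped with a
    warning; duplicate pairs are merged keeping the maximum weight.
    """
    edges = []
    for lineno, fields in _rows(path):
        if has_weights is None:
            has_weights = len(fields) == 3
        want = 3 if has_weights else 2
        if len(fields) != want:
            raise FormatError(
                f"{path}:{lineno}: expected {want} columns, got {len(fields)}"
            )
        if has_weights:
            try:
                w = float(fields[2])
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: weight {fields[2]!r} is not a number"
                ) from None
            if w <= 0:
                raise FormatError(f"{path}:{lineno}: non-positive weight {w}")
            edges.append((fields[0], fields[1], w))
        else:
            edges.append((fields[0], fields[1], 1.0))
    return ExplicitNetwork.from_edges(edges)


def read_similarity(path, dialect: str = "tsv3") -> SimilarityTable:
    """Read pairwise similarity scores.

    ``dialect='blast6'`` expects 12-column BLAST tabular output and takes
    the score from column 12 (the bit score — non-negative and monotone in
    alignment quality, which is what a voting weight needs).
    ``dialect='tsv3'`` expects (query, subject, score).  Self-pairs are
    zeroed on load and duplicates collapse to the maximum score.
    """
    if dialect not in ("blast6", "tsv3"):
        raise ValueError(f"unknown similarity dialect {dialect!r}")
    ncol, score_col = (12, 11) if dialect == "blast6" else (3, 2)
    pairs = []
    for lineno, fields in _rows(path):
        if len(fields) < ncol:
            raise FormatError(
                f"{path}:{lineno}: expected ≥{ncol} columns for {dialect}, "
                f"got {len(fields)}"
            )
        try:
            score = float(fields[score_col])
        except ValueError:
            raise FormatError(
                f"{path}:{lineno}: score {fields[score_col]!r} is not a number"
            ) from None
        if score < 0:
            raise FormatError(f"{path}:{lineno}: negative score {score}")
        pairs.append((fields[0], fields[1], score))
    return SimilarityTable.from_pairs(pairs)


def read_annotations(path) -> AnnotationSet:
    """Read a (protein, term) TSV into an :class:`AnnotationSet`."""
    mapping: dict[str, set] = {}
    for lineno, fields in _rows(path):
        if len(fields) != 2:
            raise FormatError(
                f"{path}:{lineno}: expected 2 columns, got {len(fields)}"
            )
        mapping.setdefault(fields[0], set()).add(fields[1])
    if not mapping:
        raise FormatError(f"{path}: no annotations found — nothing to predict")
    return AnnotationSet.from_mapping(mapping)


def read_ontology(path) -> OntologyTable:
    """Read a (child_term, parent_term) TSV; validates acyclicity."""
    pairs = []
    for lineno, fields in _rows(path):
        if len(fields) != 2:
            raise FormatError(
                f"{path}:{lineno}: expected 2 columns, got {len(fields)}"
            )
        pairs.append((fields[0], fields[1]))
    return OntologyTable.from_pairs(pairs)


def read_fasta_ids(path) -> frozenset:
    """Identifiers from FASTA headers (first token after ``>``).

    Sequences themselves are ignored: the package never runs an aligner,
    FASTA input is accepted only so identifiers can be cross-checked
    against the network and similarity tables.
    """
    ids: set[str] = set()
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith(">"):
                header = line[1:].strip()
                if header:
                    ids.add(header.split()[0])
    return frozenset(ids)


def filter_informative_terms(
    ann: AnnotationSet,
    ont: OntologyTable | None = None,
    threshold: int = INFORMATIVE_THRESHOLD,
    propagate: bool = False,
) -> frozenset:
    """Select *informative* function terms.

    A term is informative when (1) it is annotated by at least
    ``threshold`` proteins and (2) none of its child terms is annotated by
    at least ``threshold`` proteins.  Counts are raw direct-annotation
    counts by default; set ``propagate=True`` to count each protein toward
    every ancestor of its annotated terms (true-path up-propagation, the
    GO convention) before filtering.  Terms absent from the ontology are
    treated as leaves.
    """
    if ont is None:
        ont = OntologyTable.from_pairs([])
    if propagate:
        counts: dict[str, int] = {}
        for ts in ann.mapping.values():
            covered: set[str] = set(ts)
            for t in ts:
                covered |= ont.ancestors_of(t)
            for t in covered:
                counts[t] = counts.get(t, 0) + 1
    else:
        counts = ann.term_counts()
    informative = set()
    for term, n in counts.items():
        if n < threshold:
            continue
        if any(counts.get(c, 0) >= threshold for c in ont.children_of(term)):
            continue
        informative.add(term)
    return frozenset(informative)


def restrict_to_common(
    net: ExplicitNetwork,
    sim: SimilarityTable,
    ann: AnnotationSet,
) -> tuple[ExplicitNetwork, SimilarityTable, AnnotationSet, dict]:
    """Drop proteins lacking interaction data or sequence information.

    Keeps the intersection of the network's and the similarity table's
    protein identifiers, restricts annotations to the kept proteins, and
    returns ``(net, sim, ann, report)`` where ``report`` counts what was
    removed from each input.
    """
    keep = net.proteins & sim.proteins
    net2 = ExplicitNetwork.from_edges(
        (a, b, w) for a, b, w in net.edges() if a in keep and b in keep
    )
    for pid in keep & net.proteins:
        net2.graph.add_node(pid)
    sim2 = SimilarityTable.from_pairs(
        (q, s, score) for q, s, score in sim.pairs() if q in keep and s in keep
    )
    ann2 = AnnotationSet.from_mapping(
        {p: ts for p, ts in ann.mapping.items() if p in keep}
    )
    report = {
        "kept": len(keep),
        "dropped_from_network": len(net.proteins - keep),
        "dropped_from_similarity": len(sim.proteins - keep),
        "dropped_annotated": len(ann.proteins - keep),
    }
    logger.info(
        "restrict_to_common: kept %(kept)d proteins "
        "(dropped %(dropped_from_network)d network-only, "
        "%(dropped_from_similarity)d similarity-only, "
        "%(dropped_annotated)d annotated)",
        report,
    )
    return net2, sim2, ann2, report


# ---------------------------------------------------------------------------
# writers

def write_edge_list(net: ExplicitNetwork, path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for a, b, w in sorted(net.edges()):
            fh.write(f"{a}\t{b}\t{w!r}\n")


def write_similarity(sim: SimilarityTable, path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for q, s, score in sorted(sim.pairs()):
            fh.write(f"{q}\t{s}\t{score!r}\n")


def write_annotations(ann: AnnotationSet, path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for p in sorted(ann.mapping):
            for t in sorted(ann.mapping[p]):
                fh.write(f"{p}\t{t}\n")


_PRED_HEADER = "protein\trank\tterm\tsupport"


def write_predictions(preds: Sequence[RankedPrediction], path) -> None:
    """Write ranked predictions as a TSV (protein, rank, term, support).

    Supports are written with ``repr`` so the file round-trips losslessly
    through :func:`read_predictions`.
    """
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(_PRED_HEADER + "\n")
        for pred in preds:
            for rank, (term, support) in enumerate(
                zip(pred.terms, pred.supports), start=1
            ):
                fh.write(f"{pred.protein}\t{rank}\t{term}\t{float(support)!r}\n")


def read_predictions(path) -> list[RankedPrediction]:
    """Read a prediction TSV written by :func:`write_predictions`.

    Also the entry point for externally produced predictions that should
    be scored with the evaluation protocols.
    """
    per_protein: dict[str, list[tuple[int, str, float]]] = {}
    order: list[str] = []
    for lineno, fields in _rows(path):
        if fields == _PRED_HEADER.split():
            continue
        if len(fields) != 4:
            raise FormatError(
                f"{path}:{lineno}: expected 4 columns, got {len(fields)}"
            )
        pid, rank_s, term, support_s = fields
        try:
            rank = int(rank_s)
            support = float(support_s)
        except ValueError:
            raise FormatError(f"{path}:{lineno}: bad rank or support") from None
        if pid not in per_protein:
            per_protein[pid] = []
            order.append(pid)
        per_protein[pid].append((rank, term, support))
    preds = []
    for pid in order:
        rows = sorted(per_protein[pid])
        if [r for r, _, _ in rows] != list(range(1, len(rows) + 1)):
            raise FormatError(f"{path}: ranks for {pid} are not 1..n")
        preds.append(
            RankedPrediction(
                pid,
                tuple(t for _, t, _ in rows),
                tuple(s for _, _, s in rows),
            )
        )
    return preds
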