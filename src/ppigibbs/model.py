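"""Model / Results facade over the collective classifier.

`CollectiveFunctionModel` bundles the enriched network, the annotation
set and the classifier configuration; `fit()` runs the predictor and
returns a `CollectiveFunctionResults` carrying the ranked predictions,
per-call support fractions and a summary table — the shape familiar from
statistical modelling packages.
"""

from __future__ import annotations

from io import StringIO
from typing import Iterable, Mapping

import pandas as pd

from . import io as _io
from .containers import AnnotationSet, EnrichedNetwork, ExplicitNetwork
from .enrichment import enrich
from .inference import GibbsConfig, bootstrap, gibbs_predict
from .baselines import blast_knn_predict, majority_predict

__all__ = ["CollectiveFunctionModel", "CollectiveFunctionResults"]


class CollectiveFunctionModel:
    """Ranked multi-label protein function predictor.

    Parameters
    ----------
    network
        An :class:`EnrichedNetwork`, or a bare :class:`ExplicitNetwork`
        (treated as the unenriched k=0 configuration).
    annotations
        Labeled proteins.  Queries must not appear here.
    queries
        Proteins to predict; defaults to every network protein without
        annotations.
    config
        :class:`GibbsConfig` (λ, burn-in, samples, update mode, prior).

    Examples
    --------
    >>> model = CollectiveFunctionModel(enriched, annotations)   # doctest: +SKIP
    >>> res = model.fit(seed=7)                                  # doctest: +SKIP
    >>> print(res.summary())                                     # doctest: +SKIP
    """

    def __init__(
        self,
        network: EnrichedNetwork | ExplicitNetwork,
        annotations: AnnotationSet,
        queries: Iterable[str] | None = None,
        config: GibbsConfig = GibbsConfig(),
    ):
        if isinstance(network, ExplicitNetwork):
            network = EnrichedNetwork(network, {p: () for p in network.proteins}, 0)
        self.network = network
        self.annotations = annotations
        if queries is None:
            queries = sorted(network.proteins - annotations.proteins)
        self.queries = sorted(set(queries))
        self.config = config

    @classmethod
    def from_files(
        cls,
        edges_path,
        annotations_path,
        similarity_path=None,
        dialect: str = "tsv3",
        k: int = 5,
        queries: Iterable[str] | None = None,
        config: GibbsConfig = GibbsConfig(),
    ) -> "CollectiveFunctionModel":
        """Build straight from the standard input files."""
        net = _io.read_edge_list(edges_path)
        ann = _io.read_annotations(annotations_path)
        if similarity_path is not None:
            sim = _io.read_similarity(similarity_path, dialect)
            enriched = enrich(net, sim, k)
        else:
            enriched = EnrichedNetwork(net, {p: () for p in net.proteins}, 0)
        return cls(enriched, ann, queries, config)

    def fit(
        self, seed: int | None = None, method: str = "gibbs"
    ) -> "CollectiveFunctionResults":
        """Run the predictor.

        ``method`` is ``"gibbs"`` (full collective classification),
        ``"bootstrap"`` (weighted voting over labeled neighbours only) or
        ``"majority"``.  The sequence-only kNN baseline needs the raw
        similarity table rather than the enriched network; use
        :func:`ppigibbs.baselines.blast_knn_predict` for it.
        """
        cfg = self.config if seed is None else self.config.replace(seed=seed)
        if method == "gibbs":
            preds = gibbs_predict(self.network, self.annotations, self.queries, cfg)
        elif method == "bootstrap":
            from .inference import rank_vector
            import numpy as np
            from .containers import RankedPrediction

            rng = np.random.default_rng(cfg.seed)
            dists = bootstrap(self.network, self.annotations, self.queries, cfg)
            preds = {}
            for q in self.queries:
                d = dists[q]
                order = rank_vector(d.probs, rng)
                preds[q] = RankedPrediction(
                    q,
                    tuple(d.terms[j] for j in order),
                    tuple(float(d.probs[j]) for j in order),
                    d.is_fallback,
                )
        elif method == "majority":
            preds = majority_predict(
                self.network.explicit, self.annotations, self.queries
            )
        else:
            raise ValueError(f"unknown method {method!r}")
        return CollectiveFunctionResults(self, cfg, preds, method)


class CollectiveFunctionResults:
    """Fitted predictions plus reporting helpers."""

    def __init__(self, model, config, predictions: Mapping, method: str):
        self.model = model
        self.config = config
        self.predictions = dict(predictions)
        self.method = method

    def to_frame(self, depth: int | None = None) -> pd.DataFrame:
        """Long-format table (protein, rank, term, support, fallback)."""
        rows = []
        for q in sorted(self.predictions):
            pred = self.predictions[q]
            top = len(pred.terms) if depth is None else min(depth, len(pred.terms))
            for r in range(top):
                rows.append(
                    {
                        "protein": q,
                        "rank": r + 1,
                        "term": pred.terms[r],
                        "support": pred.supports[r],
                        "fallback": pred.is_fallback,
                    }
                )
        return pd.DataFrame(rows)

    def save(self, path) -> None:
        _io.write_predictions(
            [self.predictions[q] for q in sorted(self.predictions)], path
        )

    def summary(self, top: int = 3) -> str:
        """Human-readable run summary with the top-ranked calls."""
        net = self.model.network
        ann = self.model.annotations
        n_fb = sum(p.is_fallback for p in self.predictions.values())
        buf = StringIO()
        buf.write("Collective function prediction results\n")
        buf.write("=" * 46 + "\n")
        buf.write(f"method:            {self.method}\n")
        buf.write(f"proteins:          {len(net.proteins)}\n")
        buf.write(f"explicit edges:    {net.explicit.n_edges}\n")
        n_impl = sum(len(v) for v in net.implicit.values())
        buf.write(f"implicit edges:    {n_impl} (k={net.k})\n")
        buf.write(f"functions (m):     {ann.m}\n")
        buf.write(f"labeled proteins:  {len(ann)}\n")
        buf.write(f"queries:           {len(self.predictions)}\n")
        buf.write(f"fallback queries:  {n_fb}\n")
        buf.write(
            f"lambda={self.config.lam}  burn_in={self.config.burn_in}  "
            f"samples={self.config.samples}  seed={self.config.seed}\n"
        )
        buf.write("-" * 46 + "\n")
        buf.write(f"top-{top} calls (protein: term[support] ...):\n")
        for q in sorted(self.predictions)[:10]:
            pred = self.predictions[q]
            calls = "  ".join(
                f"{t}[{s:.2f}]"
                for t, s in zip(pred.terms[:top], pred.supports[:top])
            )
            buf.write(f"  {q}: {calls}\n")
        if len(self.predictions) > 10:
            buf.write(f"  ... ({len(self.predictions) - 10} more)\n")
        return buf.getvalue()
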