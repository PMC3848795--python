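"""Small plotting helpers mirroring the evaluation axes
(rank × TP/FP ratio and annotated-fraction × TP/FP ratio)."""

from __future__ import annotations

import numpy as np

from .evaluation import RankMetrics, SparseExperimentReport

__all__ = ["plot_rank_ratios", "plot_sparse_report"]


def plot_rank_ratios(metrics: RankMetrics, label: str | None = None, ax=None):
    """Bar plot of the TP/FP ratio per prediction rank."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ranks = np.arange(1, metrics.depth + 1)
    ratios = metrics.ratios
    finite = np.where(np.isfinite(ratios), ratios, np.nan)
    ax.bar(ranks, finite, label=label)
    ax.set_xlabel("prediction rank")
    ax.set_ylabel("TP/FP ratio")
    ax.set_xticks(ranks)
    if label:
        ax.legend()
    return ax


def plot_sparse_report(report: SparseExperimentReport, rank: int = 1, ax=None):
    """Mean TP/FP ratio (± sd) at one rank versus annotated fraction."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    means = report.mean_ratios[:, rank - 1]
    sds = report.sd_ratios[:, rank - 1]
    ax.errorbar(report.fractions, means, yerr=sds, marker="o", capsize=3)
    ax.set_xlabel("fraction of annotated proteins kept labeled")
    ax.set_ylabel(f"rank-{rank} TP/FP ratio (mean over {report.repeats} runs)")
    return ax
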