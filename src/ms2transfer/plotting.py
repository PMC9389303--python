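"""Optional matplotlib figures for masking reports and presence curves."""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

from .evaluation import MaskingReport, PresenceCurve


def plot_precision_recall(reports: Iterable[MaskingReport], path: Optional[str] = None):
    """Scatter of precision vs recall, one point per stringency threshold."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for report in reports:
        ax.scatter(report.recall, report.precision, label=report.threshold_label)
        ax.annotate(report.threshold_label, (report.recall, report.precision),
                    textcoords="offset points", xytext=(4, 4), fontsize=8)
    ax.set_xlabel("recall")
    ax.set_ylabel("precision")
    ax.set_xlim(0, 1.02)
    ax.set_ylim(0, 1.02)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_presence_curves(
    curves: Sequence[PresenceCurve], labels: Sequence[str], path: Optional[str] = None
):
    """Cumulative entities found in at least n batches, one line per curve."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for curve, label in zip(curves, labels):
        ax.plot(range(1, curve.n_batches + 1), curve.counts, marker="o", label=label)
    ax.set_xlabel("minimum number of batches n")
    ax.set_ylabel("entities found in >= n batches")
    ax.legend()
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
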