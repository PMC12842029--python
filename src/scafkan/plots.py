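"""Static plots: ROC curves, attribution summaries, activation profiles.

Matplotlib is imported lazily so headless library use never touches a
display backend.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np

from .interpret import AttributionReport, LocalExplanation
from .train_eval import EvalReport

__all__ = ["plot_cv_roc", "plot_attribution_summary", "plot_local_explanation",
           "plot_activation_profiles"]


def _ax(ax):
    if ax is not None:
        return ax
    import matplotlib.pyplot as plt
    return plt.subplots(figsize=(5, 4))[1]


def plot_cv_roc(report: EvalReport, ax=None):
    """One ROC curve per fold with its AUC in the legend."""
    ax = _ax(ax)
    for f in range(report.plan.K):
        pts = report.roc_data(f)
        ax.plot(pts[:, 0], pts[:, 1],
                label=f"fold {f + 1} (AUC {report.fold_metrics[f].auc:.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(fontsize=7)
    return ax


def plot_attribution_summary(report: AttributionReport, top: int = 10, ax=None):
    """Per-feature attribution spread (jittered strip, beeswarm-style)."""
    ax = _ax(ax)
    order = [report.feature_names.index(n) for n, _ in report.ranking()[:top]]
    rng = np.random.default_rng(0)
    for row, j in enumerate(reversed(order)):
        vals = report.attributions[:, j]
        ax.scatter(vals, row + rng.uniform(-0.2, 0.2, len(vals)), s=8, alpha=0.7)
    ax.set_yticks(range(len(order)))
    ax.set_yticklabels([report.feature_names[j] for j in reversed(order)],
                       fontsize=7)
    ax.axvline(0.0, color="k", lw=0.6)
    ax.set_xlabel("attribution (probability scale)")
    return ax


def plot_local_explanation(explanation: LocalExplanation, ax=None):
    """Signed bar chart of the surrogate weights for one patient."""
    ax = _ax(ax)
    terms = explanation.top_terms()
    names = [t[0] for t in terms][::-1]
    vals = [t[1] for t in terms][::-1]
    ax.barh(names, vals, color=["tab:red" if v > 0 else "tab:blue" for v in vals])
    ax.axvline(0.0, color="k", lw=0.6)
    ax.set_xlabel("local surrogate weight")
    ax.set_title(f"patient {explanation.patient_index} "
                 f"(R²={explanation.r_squared:.2f})", fontsize=9)
    return ax


def plot_activation_profiles(profiles: dict[str, dict], max_units: int = 8,
                             out: Optional[Path] = None):
    """Grid of learned input-layer activation curves per feature."""
    import matplotlib.pyplot as plt
    n = len(profiles)
    fig, axes = plt.subplots(1, n, figsize=(3 * n, 2.5), squeeze=False)
    for ax, (feat, d) in zip(axes[0], profiles.items()):
        for curve in d["profiles"][:max_units]:
            ax.plot(d["x"], curve, lw=0.8, alpha=0.8)
        ax.set_title(feat, fontsize=8)
    fig.tight_layout()
    if out is not None:
        fig.savefig(out, dpi=120)
    return fig
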