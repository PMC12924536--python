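"""Minimal ROC and Kaplan-Meier plotting helpers (matplotlib, Agg backend)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .survival import KMSummary  # noqa: E402


def plot_roc(roc_points, path: str | Path, label: str = "", auc: float | None = None):
    fig, ax = plt.subplots(figsize=(4, 4))
    title = label + (f" (AUC = {auc:.2f})" if auc is not None else "")
    ax.plot(roc_points["fpr"], roc_points["tpr"], drawstyle="steps-post")
    ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
    ax.set(xlabel="false positive rate", ylabel="true positive rate", title=title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_km(summary: KMSummary, path: str | Path, title: str = ""):
    fig, ax = plt.subplots(figsize=(5, 4))
    for group, curve in summary.curves.items():
        ax.step(curve["time"], curve["survival"], where="post",
                label=f"{group} (n={summary.group_sizes[group]})")
    ax.set(xlabel="time (days)", ylabel="survival probability", ylim=(0, 1.02),
           title=title or f"log-rank p = {summary.logrank_p:.3g}")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
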