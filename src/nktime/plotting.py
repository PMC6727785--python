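"""Basic diagnostic plots (Kaplan-Meier curves, subtype heatmap)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .stats import SurvivalComparison
from .subtypes import SubtypeAssignment

__all__ = ["km_plot", "subtype_heatmap"]


def _step(ax, km: pd.DataFrame, label: str) -> None:
    t = np.concatenate([[0.0], km["time"].to_numpy()])
    s = np.concatenate([[1.0], km["survival"].to_numpy()])
    ax.step(t, s, where="post", label=label)


def km_plot(
    comparison: SurvivalComparison,
    path: str | Path,
    labels: tuple[str, str] = ("group 1", "group 2"),
) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    _step(ax, comparison.km1, labels[0])
    _step(ax, comparison.km2, labels[1])
    ax.set_xlabel("time (days)")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend(frameon=False)
    ax.set_title(
        f"log-rank p = {comparison.p:.3g}, HR (O/E) = {comparison.hazard_ratio:.2f}"
    )
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def subtype_heatmap(
    expr: pd.DataFrame,
    panel: list[str],
    assignment: SubtypeAssignment,
    path: str | Path,
    max_genes: int = 200,
) -> None:
    """Panel-gene heatmap with samples ordered by subtype (log10 transform)."""
    present = [g for g in panel if g in expr.index][:max_genes]
    order = assignment.labels.sort_values(kind="stable").index
    x = np.log10(expr.loc[present, order] + 1.0)
    fig, ax = plt.subplots(figsize=(8, 5))
    im = ax.imshow(x.to_numpy(), aspect="auto", cmap="RdYlGn_r")
    ax.set_xlabel("samples (grouped by subtype)")
    ax.set_ylabel("panel genes")
    fig.colorbar(im, ax=ax, label="log10(expr + 1)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
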