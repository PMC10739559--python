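"""Attribution summary plots: beeswarm-style and mean-|phi| bar charts.

The beeswarm places one point per (sample, feature) at the attribution
value on the x axis, features on the y axis sorted by mean absolute
attribution (most important on top), vertical jitter for visibility and
point colour encoding the feature's value. Near-zero attributions denote
negligible impact; negative values push toward a control call and
positive ones toward a case call.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .attribution import AttributionMatrix


def importance_order(att: AttributionMatrix) -> np.ndarray:
    """Feature indices sorted by descending mean |phi| (stable)."""
    return np.argsort(-att.mean_abs(), kind="stable")


def summary_plot(
    att: AttributionMatrix,
    X: np.ndarray,
    feature_names: list[str],
    path: str | Path,
    top_n: int | None = None,
    kind: str = "beeswarm",
    seed: int = 0,
) -> Path:
    """Write a beeswarm or bar summary of one classifier's attributions."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n_feat = att.n_features
    if top_n is None:
        top_n = min(20, n_feat)
    if top_n > n_feat:
        raise ValueError(f"top_n={top_n} exceeds {n_feat} features")
    order = importance_order(att)[:top_n]
    mean_abs = att.mean_abs()
    degenerate = mean_abs.sum() == 0

    fig, ax = plt.subplots(figsize=(8, max(2.0, 0.4 * top_n + 1)))
    if kind == "bar" or degenerate:
        ax.barh(
            np.arange(top_n)[::-1],
            mean_abs[order],
            color="#1f77b4",
        )
        ax.set_yticks(np.arange(top_n)[::-1])
        ax.set_yticklabels([feature_names[j] for j in order])
        ax.set_xlabel("mean |attribution| (case-probability units)")
        if degenerate:
            ax.text(
                0.5, 0.5, "degenerate: all attributions zero",
                transform=ax.transAxes, ha="center", va="center",
                fontsize=14, color="crimson", alpha=0.7,
            )
    elif kind == "beeswarm":
        rng = np.random.default_rng(seed)
        for row, j in enumerate(order):
            y = (top_n - 1 - row) + rng.uniform(-0.25, 0.25, size=att.n_samples)
            vals = X[:, j]
            span = vals.max() - vals.min()
            colors = (vals - vals.min()) / span if span > 0 else np.full_like(vals, 0.5)
            ax.scatter(att.phi[:, j], y, c=colors, cmap="coolwarm", s=12, alpha=0.8)
        ax.set_yticks(np.arange(top_n)[::-1])
        ax.set_yticklabels([feature_names[j] for j in order])
        ax.axvline(0.0, color="grey", lw=0.8)
        ax.set_xlabel("attribution to case probability")
        sm = plt.cm.ScalarMappable(cmap="coolwarm")
        cbar = fig.colorbar(sm, ax=ax, ticks=[0, 1])
        cbar.ax.set_yticklabels(["low", "high"])
        cbar.set_label("feature value")
    else:
        raise ValueError(f"unknown plot kind: {kind!r}")
    ax.set_title(f"{att.classifier}: attribution summary")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120, metadata={"Software": None})
    plt.close(fig)
    return path
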