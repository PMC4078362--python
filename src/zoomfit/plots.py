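"""Diagnostic figures: sensitivity bars, correlation heatmap, r2 bars, scores."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def sensitivity_bars(coefficients: pd.DataFrame, output: str, path, top: int = 20):
    """Bar chart of the largest standardized coefficients for one output."""
    s = coefficients[output].reindex(coefficients[output].abs().sort_values(ascending=False).index)
    s = s.head(top)[::-1]
    fig, ax = plt.subplots(figsize=(6, max(3, 0.3 * len(s))))
    ax.barh(np.arange(len(s)), s.values, color=np.where(s.values >= 0, "#2a6fbb", "#bb3f2a"))
    ax.set_yticks(np.arange(len(s)), s.index, fontsize=7)
    ax.set_xlabel("standardized regression coefficient")
    ax.set_title(f"sensitivity of {output}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def correlation_heatmap(R: pd.DataFrame, path):
    fig, ax = plt.subplots(figsize=(0.22 * len(R) + 2, 0.22 * len(R) + 2))
    im = ax.imshow(R.to_numpy(dtype=float), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(R.columns)), R.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(len(R.index)), R.index, fontsize=6)
    fig.colorbar(im, ax=ax, label="Pearson's R")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def identifiability_bars(r2: pd.Series, path, threshold: float = 0.7):
    fig, ax = plt.subplots(figsize=(max(4, 0.5 * len(r2)), 3.2))
    ax.bar(range(len(r2)), r2.values, color="#2a6fbb")
    ax.axhline(threshold, color="k", ls="--", lw=1, label=f"screen r$^2$ = {threshold:g}")
    ax.set_xticks(range(len(r2)), r2.index, rotation=45, ha="right", fontsize=8)
    ax.set_ylabel("test-set r$^2$ (simulated vs predicted)")
    ax.set_ylim(0, 1.05)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def score_scatter(scores: np.ndarray, target_score: np.ndarray, path, nearest=None):
    """First-two-PC view of simulations (grey), target (red), nearest (cyan)."""
    fig, ax = plt.subplots(figsize=(5, 4.5))
    ax.scatter(scores[:, 0], scores[:, 1], s=10, c="0.6", label="simulations")
    if nearest is not None:
        ax.scatter(scores[nearest, 0], scores[nearest, 1], s=28, facecolors="none",
                   edgecolors="c", label="nearest")
    ax.scatter([target_score[0]], [target_score[1]], s=50, c="r", marker="*", label="target")
    ax.set_xlabel("PC1 score")
    ax.set_ylabel("PC2 score")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
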