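"""Figure helpers: distance-matrix heatmaps, t-SNE maps, loss curves."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["distance_heatmap", "tsne_scatter", "loss_curves"]


def distance_heatmap(dm, path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(dm.values, cmap="viridis")
    ax.set_xticks(range(len(dm.labels)), dm.labels, rotation=45)
    ax.set_yticks(range(len(dm.labels)), dm.labels)
    ax.set_title(f"{dm.flavor} distances")
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def tsne_scatter(coords: pd.DataFrame, labels, path) -> None:
    """Material map with per-category covariance error ellipses."""
    labels = pd.Series(labels, index=coords.index)
    fig, ax = plt.subplots(figsize=(5, 5))
    cmap = plt.get_cmap("tab10")
    for i, cat in enumerate(np.sort(labels.unique())):
        pts = coords[labels == cat].values
        color = cmap(i % 10)
        ax.scatter(pts[:, 0], pts[:, 1], s=12, color=color, label=str(cat))
        if len(pts) > 2:
            center = pts.mean(axis=0)
            cov = np.cov(pts.T)
            vals, vecs = np.linalg.eigh(cov)
            angle = np.degrees(np.arctan2(vecs[1, -1], vecs[0, -1]))
            from matplotlib.patches import Ellipse

            ax.add_patch(Ellipse(center, vals[-1] / 2, vals[0] / 2, angle=angle,
                                 fill=False, color=color))
    ax.legend(title="category", fontsize=7)
    ax.set_xlabel("t-SNE 1")
    ax.set_ylabel("t-SNE 2")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def loss_curves(report: pd.DataFrame, path) -> None:
    fig, ax = plt.subplots(figsize=(5, 3))
    ax.plot(report["epoch"], report["train_mae"], label="train")
    if "val_mae" in report:
        ax.plot(report["epoch"], report["val_mae"], label="validation")
    ax.set_xlabel("epoch")
    ax.set_ylabel("MAE")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
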