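"""Figures for the power analysis: accuracy heatmaps and error-rate boxplots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .simulate import PowerResult


def plot_accuracy_heatmaps(result: PowerResult, path) -> None:
    """One heatmap per grid cell: average posterior probability of each
    estimated father count (rows) given the true count (columns)."""
    cells = list(result.accuracy)
    fig, axes = plt.subplots(1, len(cells), figsize=(3.2 * len(cells), 3.2),
                             squeeze=False)
    for ax, cell in zip(axes[0], cells):
        m = result.accuracy[cell]
        im = ax.imshow(m, origin="lower", vmin=0, vmax=1, cmap="viridis",
                       aspect="auto",
                       extent=(0.5, len(result.true_k_values) + 0.5,
                               0.5, m.shape[0] + 0.5))
        ax.set_xticks(range(1, len(result.true_k_values) + 1),
                      [str(k) for k in result.true_k_values])
        ax.set_xlabel("true number of fathers")
        ax.set_ylabel("estimated number of fathers")
        ax.set_title(f"cell {cell}")
    fig.colorbar(im, ax=axes[0], shrink=0.8, label="posterior probability")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def plot_error_rate_boxplots(result: PowerResult, path) -> None:
    """Posterior-mean dropout and mistyping estimates per grid cell."""
    df = result.records
    cells = sorted(df["cell"].unique())
    fig, axes = plt.subplots(1, 2, figsize=(8, 3.2))
    for ax, col, name in zip(axes, ("e1_hat", "e2_hat"),
                             ("dropout", "mistyping")):
        data = [df.loc[df["cell"] == c, col] for c in cells]
        ax.boxplot(data, tick_labels=[str(c) for c in cells])
        ax.set_xlabel("grid cell")
        ax.set_ylabel(f"posterior mean {name} rate")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
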