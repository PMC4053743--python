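"""Plain heatmap export for clustered expression matrices."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .expression import ExpressionMatrix

__all__ = ["export_heatmap"]


def export_heatmap(
    matrix: ExpressionMatrix,
    orders: dict[str, list[str]],
    image_path,
    tsv_path=None,
) -> None:
    """Write the dendrogram-ordered matrix as a green/red heatmap image and,
    optionally, the reordered values as TSV."""
    ordered = matrix.values.loc[orders["rows"], orders.get("columns", matrix.sample_ids)]
    if tsv_path is not None:
        ordered.to_csv(tsv_path, sep="\t", index_label="peak_id")
    fig, ax = plt.subplots(
        figsize=(max(4, 0.25 * ordered.shape[1]), max(4, 0.02 * ordered.shape[0]))
    )
    im = ax.imshow(ordered.to_numpy(), aspect="auto", cmap="RdYlGn_r", interpolation="nearest")
    ax.set_xticks(range(ordered.shape[1]))
    ax.set_xticklabels(ordered.columns, rotation=90, fontsize=6)
    ax.set_yticks([])
    fig.colorbar(im, ax=ax, shrink=0.5)
    fig.tight_layout()
    fig.savefig(image_path, dpi=150)
    plt.close(fig)
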