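"""Box plots of per-proband evidence yields (quartile boxes, 1.5xIQR whiskers)."""
from __future__ import annotations

from typing import Sequence

from .stats import YieldTable


def plot_yield_boxes(yield_table: YieldTable, categories: Sequence[str], ax=None):
    """Per-proband count distributions, grouped by category, one box per tool."""
    import matplotlib.pyplot as plt

    counts = yield_table.counts
    tools = sorted(counts["tool"].unique())
    if ax is None:
        _, ax = plt.subplots(figsize=(1.6 * len(categories) * max(len(tools), 1) / 2 + 2, 4))
    data, positions, labels = [], [], []
    pos = 0
    for category in categories:
        for tool in tools:
            sub = counts[(counts["tool"] == tool) & (counts["category"] == category)]
            data.append(sub["count"].to_numpy())
            positions.append(pos)
            labels.append(f"{category}\n{tool}")
            pos += 1
        pos += 1
    ax.boxplot(data, positions=positions, whis=1.5, flierprops={"markersize": 2})
    ax.set_xticks(positions)
    ax.set_xticklabels(labels, rotation=90, fontsize=7)
    ax.set_ylabel("variants per proband")
    ax.figure.tight_layout()
    return ax
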