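"""Basic figures: nuclei-per-myotube violins and size-class bar charts."""

import numpy as np

__all__ = ["violin_nuclei_per_myotube", "bar_bin_fractions"]


def violin_nuclei_per_myotube(counts_by_condition: dict, ax=None, log2: bool = True):
    """Violin plot of nuclei-per-myotube distributions per condition."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(1.2 * len(counts_by_condition) + 1.5, 3.5))
    labels, data = zip(*[
        (name, np.log2(np.asarray(c, dtype=float)) if log2 else np.asarray(c, dtype=float))
        for name, c in counts_by_condition.items() if len(c)
    ])
    ax.violinplot(data, showmedians=True)
    ax.set_xticks(range(1, len(labels) + 1), labels)
    ax.set_ylabel("log2 nuclei per myotube" if log2 else "nuclei per myotube")
    return ax


def bar_bin_fractions(fractions_by_condition: dict, ax=None):
    """Grouped bars of myotube size-class fractions (2-14, 15-49, 50+)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 3.5))
    conditions = list(fractions_by_condition)
    bins = list(next(iter(fractions_by_condition.values())))
    x = np.arange(len(bins))
    width = 0.8 / max(len(conditions), 1)
    for i, cond in enumerate(conditions):
        vals = [fractions_by_condition[cond][b] for b in bins]
        ax.bar(x + i * width, vals, width, label=cond)
    ax.set_xticks(x + width * (len(conditions) - 1) / 2, bins)
    ax.set_ylabel("fraction of myotubes")
    ax.legend()
    return ax
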