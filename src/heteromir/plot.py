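"""Minimal plotting helper: per-region expression box plots."""
from __future__ import annotations

from .io import REGIONS, ExpressionMatrix, SampleSheet


def region_boxplot(expr: ExpressionMatrix, sheet: SampleSheet, gene: str,
                   ax=None, log_scale: bool = True):
    """Box plot of one gene's relative expression across the five regions.

    Returns the matplotlib Axes.  Matplotlib is imported lazily so that
    non-plotting workflows never touch it.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    row = expr.row(gene)
    data, labels = [], []
    for region in REGIONS:
        samples = [s for s in sheet.samples_in_region(region)
                   if s in row.index]
        vals = row[samples].dropna()
        if len(vals):
            data.append(vals.to_numpy())
            labels.append(region)
    ax.boxplot(data, tick_labels=labels)
    if log_scale:
        ax.set_yscale("log", base=2)
    ax.set_xlabel("region")
    ax.set_ylabel(r"relative expression ($2^{-\Delta Ct}$)")
    ax.set_title(gene)
    return ax
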