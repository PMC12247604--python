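"""Simple visualisations of connectivity tables (violin/bar exports)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

_CLASS_ORDER = ["inter_corresponding", "intra", "inter_noncorresponding"]


def plot_pair_classes(table, ax=None, title: str = ""):
    """Violin plot of subject-level Zr values by pairing class."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    groups, labels = [], []
    for cls in _CLASS_ORDER:
        vals = table.loc[table["pair_class"] == cls, "Zr"].dropna().to_numpy()
        if vals.size:
            groups.append(vals)
            labels.append(cls.replace("_", "\n"))
    if groups:
        parts = ax.violinplot(groups, showmeans=True)
        for body in parts["bodies"]:
            body.set_alpha(0.6)
        ax.set_xticks(np.arange(1, len(labels) + 1), labels=labels, fontsize=8)
    ax.set_ylabel("Fisher Zr")
    if title:
        ax.set_title(title)
    return ax


def plot_bias_bars(bias_tests, ax=None, mode: str = "within"):
    """Bar plot of per-region mean homotopic-minus-intra differences."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    sub = bias_tests[(bias_tests["mode"] == mode)
                     & (bias_tests["comparison"] == "vs_intra_high")]
    ax.bar(sub["region"], sub["mean_diff"])
    ax.axhline(0, color="k", lw=0.8)
    ax.set_ylabel("mean inter - intra_high (Zr)")
    ax.set_title(f"{mode}-subject homotopic bias")
    return ax
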