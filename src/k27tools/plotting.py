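"""Matplotlib helpers for the profile outputs (imported lazily)."""

from __future__ import annotations

import pandas as pd

CLASS_ORDER = ["high", "medium", "low", "silent"]


def plot_tss_profile(profile: pd.DataFrame, ax=None, title: str | None = None):
    """Line plot of a :func:`k27tools.chip.tss_profile` matrix (class x position)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    for cls in CLASS_ORDER:
        if cls in profile.index:
            ax.plot(profile.columns, profile.loc[cls], label=cls)
    for cls in profile.index.difference(CLASS_ORDER):
        ax.plot(profile.columns, profile.loc[cls], label=str(cls))
    ax.axvline(0, color="grey", lw=0.5, ls="--")
    ax.set_xlabel("distance from TSS (bp)")
    ax.set_ylabel("mean log2 IP/input")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_metagene(curves: dict[str, pd.Series], ax=None):
    """Overlay per-stage TSS->TES meta-profiles from
    :func:`k27tools.chip.scaled_metagene`."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    for stage, curve in curves.items():
        ax.plot(range(len(curve)), curve.to_numpy(), label=stage)
    first = next(iter(curves.values()))
    body = [i for i, lab in enumerate(first.index) if str(lab).startswith("body")]
    if body:
        ax.axvline(body[0], color="grey", lw=0.5, ls="--")
        ax.axvline(body[-1], color="grey", lw=0.5, ls="--")
        ax.set_xticks([0, body[0], body[-1], len(first) - 1])
        ax.set_xticklabels(["-flank", "TSS", "TES", "+flank"])
    ax.set_ylabel("mean log2 IP/input")
    ax.legend(frameon=False, fontsize=8)
    return ax
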