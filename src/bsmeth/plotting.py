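"""Static matplotlib figures for profiles, compartments and quintiles."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .types import CONTEXTS


def plot_profile(profile: pd.DataFrame, path: str, title: str = "") -> None:
    """Line plot of a (possibly grouped) metagene/TE profile, one panel per context."""
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.2), sharex=True)
    groups = profile["group"].unique() if "group" in profile.columns else [None]
    for ax, ctx in zip(axes, CONTEXTS):
        sub = profile[profile["context"] == ctx]
        for group in groups:
            track = sub[sub["group"] == group] if group is not None else sub
            ax.plot(track["bin"], track["ml"], label=str(group) if group is not None else None)
        # mark segment boundaries
        for seg in sub["segment"].unique()[:-1]:
            ax.axvline(sub.loc[sub["segment"] == seg, "bin"].max() + 0.5,
                       color="grey", lw=0.5, ls=":")
        ax.set_title(ctx)
        ax.set_ylim(0, 1)
    if groups[0] is not None:
        axes[-1].legend(fontsize=7)
    fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_compartments(table: pd.DataFrame, path: str) -> None:
    """Grouped bar chart of compartment methylation levels per context."""
    fig, ax = plt.subplots(figsize=(8, 3.2))
    comps = table["compartment"].unique()
    width = 0.25
    for i, ctx in enumerate(CONTEXTS):
        sub = table[table["context"] == ctx].set_index("compartment").reindex(comps)
        ax.bar([x + i * width for x in range(len(comps))], sub["ml"], width, label=ctx)
    ax.set_xticks([x + width for x in range(len(comps))])
    ax.set_xticklabels(comps, rotation=45, ha="right")
    ax.set_ylabel("methylation level")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
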