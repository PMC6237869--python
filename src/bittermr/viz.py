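"""Forest-plot style visualisation of MR estimates."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def forest_plot(mr_df: pd.DataFrame, path, analyses=("main", "binary")) -> None:
    """Point estimates with 95% CIs per stimulus x outcome, one panel per
    analysis (linear panel on the effect scale, binary panel on the OR
    scale with a reference line at 1)."""
    panels = [a for a in analyses if (mr_df["analysis"] == a).any()]
    fig, axes = plt.subplots(
        1, max(len(panels), 1), figsize=(5.5 * max(len(panels), 1), 4.5), squeeze=False
    )
    for ax, analysis in zip(axes[0], panels):
        sub = mr_df[mr_df["analysis"] == analysis].reset_index(drop=True)
        labels = sub["stimulus"] + " → " + sub["outcome"]
        y = range(len(sub))
        ax.errorbar(
            sub["estimate"],
            y,
            xerr=[sub["estimate"] - sub["ci_low"], sub["ci_high"] - sub["estimate"]],
            fmt="o",
            color="#30506d",
            ecolor="#7b97ad",
            capsize=3,
        )
        null = 1.0 if (sub["scale"] == "odds_ratio").all() else 0.0
        ax.axvline(null, color="grey", lw=0.8, ls="--")
        ax.set_yticks(list(y))
        ax.set_yticklabels(labels, fontsize=8)
        ax.invert_yaxis()
        ax.set_title(analysis)
        ax.set_xlabel(
            "causal OR per SD bitterness"
            if null == 1.0
            else "effect per SD bitterness"
        )
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
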