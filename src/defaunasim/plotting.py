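"""Optional figure helpers (matplotlib)."""

from __future__ import annotations

import pandas as pd

__all__ = ["plot_change_vs_intensity"]


def plot_change_vs_intensity(summaries: pd.DataFrame, out_path=None):
    """Mean dAGC% vs defaunation intensity with 95% CI bands, one panel
    per scenario and one line per replacement option."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    scenarios = list(dict.fromkeys(summaries["scenario"]))
    fig, axes = plt.subplots(1, len(scenarios), figsize=(4 * len(scenarios), 3.2), sharey=True)
    if len(scenarios) == 1:
        axes = [axes]
    for ax, sc in zip(axes, scenarios):
        sub = summaries[summaries["scenario"] == sc]
        for opt, grp in sub.groupby("option"):
            grp = grp.sort_values("intensity")
            x = 100 * grp["intensity"]
            ax.plot(x, grp["mean_dagc_pct"], marker="o", label=opt)
            ax.fill_between(x, grp["ci_low"], grp["ci_high"], alpha=0.25)
        ax.axhline(0, color="grey", lw=0.8)
        ax.set_title(sc)
        ax.set_xlabel("defaunation intensity (%)")
    axes[0].set_ylabel("change in AGC (%)")
    axes[-1].legend(frameon=False)
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=150)
        plt.close(fig)
    return fig
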