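"""Per-group intake–expression scatter plots with regression lines."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd


def scatter_by_group(
    expression: pd.Series,
    intake: pd.Series,
    groups: pd.Series,
    out: str | Path,
    title: str = "",
) -> Path:
    """One scatter of expression vs intake, coloured by diet group,
    with a least-squares line per group."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    common = expression.index.intersection(intake.index).intersection(groups.index)
    for g, color in zip(sorted(groups.loc[common].unique()), ("C0", "C1", "C2")):
        idx = common[groups.loc[common] == g]
        x = intake.loc[idx].to_numpy(dtype=float)
        y = expression.loc[idx].to_numpy(dtype=float)
        ax.scatter(x, y, s=14, alpha=0.7, color=color, label=g)
        if len(idx) >= 2 and np.ptp(x) > 0:
            slope, icpt = np.polyfit(x, y, 1)
            xs = np.linspace(x.min(), x.max(), 20)
            ax.plot(xs, slope * xs + icpt, color=color, lw=1.2)
    ax.set_xlabel(str(intake.name or "intake"))
    ax.set_ylabel(str(expression.name or "normalized expression"))
    if title:
        ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    out = Path(out)
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return out
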