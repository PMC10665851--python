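"""Optional static plots: Manhattan of the Lindley process and p-value QQ.

Requires matplotlib (the ``plot`` extra); pipeline stages only call in
here when plotting is explicitly enabled.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import LindleyTrack


def _axes():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def manhattan_lindley(tracks: list[LindleyTrack], path, title: str = "") -> None:
    """Per-chromosome Lindley tracks with their significance thresholds."""
    plt = _axes()
    fig, axes = plt.subplots(
        1, len(tracks), figsize=(3 * len(tracks), 2.8), sharey=True, squeeze=False
    )
    for ax, tr in zip(axes[0], tracks):
        ax.plot(tr.pos / 1e3, tr.lindley, lw=0.6, color="steelblue")
        ax.axhline(tr.threshold, ls="--", color="firebrick", lw=0.8)
        ax.set_title(f"chr {tr.chrom}", fontsize=9)
        ax.set_xlabel("position (kb)", fontsize=8)
    axes[0][0].set_ylabel("Lindley score")
    if title:
        fig.suptitle(title, fontsize=10)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def qq_plot(scan: pd.DataFrame, path, title: str = "") -> None:
    """Observed vs expected -log10 p quantiles."""
    plt = _axes()
    p = np.sort(scan["p"].to_numpy(dtype=float))
    n = len(p)
    exp = -np.log10((np.arange(1, n + 1) - 0.5) / n)
    obs = -np.log10(np.clip(p, 1e-300, 1.0))
    fig, ax = plt.subplots(figsize=(3.2, 3.2))
    ax.plot(exp, obs, ".", ms=2, color="steelblue")
    lim = max(exp.max(), obs.max()) * 1.05
    ax.plot([0, lim], [0, lim], color="grey", lw=0.8)
    ax.set_xlabel("expected $-\\log_{10} p$")
    ax.set_ylabel("observed $-\\log_{10} p$")
    if title:
        ax.set_title(title, fontsize=10)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
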