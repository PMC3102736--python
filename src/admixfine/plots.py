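"""Minimal region plotting: -log10(p) against position."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd


def plot_region_pvalues(
    results: pd.DataFrame, path: str | Path, title: str = ""
) -> Path:
    """Scatter of -log10(p_trend) vs position for one region's scan results.

    ``results`` is the association-scan frame (needs ``pos`` and
    ``p_trend``).  Writes the figure to ``path`` and returns it.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ok = results["p_trend"].notna() & (results["p_trend"] > 0)
    x = results.loc[ok, "pos"].to_numpy() / 1e6
    y = -np.log10(results.loc[ok, "p_trend"].to_numpy())
    fig, ax = plt.subplots(figsize=(7, 3))
    ax.scatter(x, y, s=12, c="#30567d")
    ax.set_xlabel("position (Mb)")
    ax.set_ylabel(r"$-\log_{10}(p)$")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


__all__ = ["plot_region_pvalues"]
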