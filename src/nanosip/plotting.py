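"""Optional zone-scatter figure: per-cell C_net% vs N_net% with the
enrichment thresholds (dashed) and the 1:1 / 2:1 guide lines that bound the
metabolic zones."""

from __future__ import annotations

from typing import Dict

import matplotlib

matplotlib.use("Agg")  # headless-safe
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .isotope import SubstratePool
from .thresholds import ControlStats

ZONE_COLORS = {
    "INACTIVE": "0.6",
    "I_EXCL_HETERO": "tab:blue",
    "II_EXCL_AUTO": "tab:green",
    "III_PRIM_HETERO": "tab:cyan",
    "IV_PRIM_AUTO": "tab:olive",
}


def zone_figure(
    percell: pd.DataFrame,
    stats: Dict[str, ControlStats],
    pools: Dict[str, SubstratePool],
    log: bool = False,
):
    """Scatter cells in the (C_net%, N_net%) plane with zone guides."""
    fig, ax = plt.subplots(figsize=(5, 5))
    for cat, sub in percell.groupby("category"):
        ax.scatter(
            sub["c_net_pct"],
            sub["n_net_pct"],
            s=12,
            label=f"{cat} (n={len(sub)})",
            color=ZONE_COLORS.get(cat, "k"),
            alpha=0.7,
        )
    dl_c = stats["C"].detection_limit_net_pct
    dl_n = stats["N"].detection_limit_net_pct
    ax.axvline(dl_c, ls="--", color="0.4", lw=1, label="C detection limit")
    ax.axhline(dl_n, ls="--", color="0.4", lw=1, label="N detection limit")
    upper = max(
        float(percell["c_net_pct"].max() or 1.0),
        float(percell["n_net_pct"].max() or 1.0),
        dl_c,
        dl_n,
    )
    grid = np.linspace(0, 1.05 * upper, 50)
    ax.plot(grid, grid, color="0.7", lw=1)  # 1:1 (II/IV boundary)
    ax.plot(grid, 2 * grid, color="0.7", lw=1)  # 2:1 (IV/III boundary)
    if log:
        ax.set_xscale("log")
        ax.set_yscale("log")
    ax.set_xlabel(r"C$_{net}$% (from $^{13}$C-bicarbonate)")
    ax.set_ylabel(r"N$_{net}$% (from $^{15}$N-amino acids)")
    ax.legend(fontsize=7, loc="upper right")
    fig.tight_layout()
    return fig
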