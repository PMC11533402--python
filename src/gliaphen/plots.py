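"""Forest-style plots of geometric mean ratios with confidence intervals."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def forest_plot(results: pd.DataFrame, title: str = "", ax=None):
    """GMR dot + 95% CI bars per cell on a log x-axis.

    ``results`` is one FDR family (one sex x outcome) from
    :func:`gliaphen.cohort_stats.run_contrast_grid`.  Cells significant after
    FDR are drawn filled; the vertical line at 1 marks no group difference.
    """
    valid = results[np.isfinite(results["gmr"])]
    if ax is None:
        _, ax = plt.subplots(figsize=(6, max(2.5, 0.28 * len(valid) + 1)))
    labels = [f"{r.region} / {r.dpe} DPE" if r.dpe != "all" else str(r.region)
              for r in valid.itertuples()]
    y = np.arange(len(valid))[::-1]
    for yi, row in zip(y, valid.itertuples()):
        color = "tab:blue" if row.significant_fdr else "0.5"
        ax.plot([row.ci_low, row.ci_high], [yi, yi], color=color, lw=1.5)
        ax.plot(row.gmr, yi, "o", color=color, ms=5,
                mfc=color if row.significant_fdr else "white")
    ax.axvline(1.0, color="0.7", lw=1)
    ax.set_xscale("log")
    ax.set_yticks(y)
    ax.set_yticklabels(labels, fontsize=8)
    ax.set_xlabel("Geometric mean ratio (DFP / Veh)")
    if title:
        ax.set_title(title, fontsize=10)
    ax.figure.tight_layout()
    return ax
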