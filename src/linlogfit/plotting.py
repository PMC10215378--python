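"""Diagnostic plots: fitted curve with Rmax/Rmin markers, companion panel."""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .data import DoseResponseTable
from .fitting import LinLogFit, SegmentedFit
from .model import TWO_POINTS

__all__ = ["plot_fit"]


def plot_fit(
    data: DoseResponseTable,
    fit: LinLogFit,
    path,
    companion: Optional[DoseResponseTable] = None,
    companion_fit: Optional[SegmentedFit] = None,
) -> Path:
    """Plot observations, the fitted curve, and vertical Rmax/Rmin lines.

    When a companion table and its segmented fit are given, they go on a
    twin y-axis with a vertical line at the breakpoint — the layout used
    to eyeball whether the breakpoint coincides with Rmin.
    """
    path = Path(path)
    fig, ax = plt.subplots(figsize=(7, 4.5))
    grid = np.linspace(data.dose.min(), data.dose.max(), 400)
    ax.scatter(data.dose, data.response, s=20, color="k", label="primary data")
    ax.plot(grid, fit.predict(grid), color="tab:blue", label="linear-logistic fit")
    if fit.stationary.regime == TWO_POINTS:
        ax.axvline(fit.stationary.rmax, ls="--", color="tab:green",
                   label=f"Rmax = {fit.stationary.rmax:.4g}")
        ax.axvline(fit.stationary.rmin, ls="--", color="tab:red",
                   label=f"Rmin = {fit.stationary.rmin:.4g}")
    ax.set_xlabel(f"dose{f' ({data.dose_unit})' if data.dose_unit else ''}")
    ax.set_ylabel(f"response{f' ({data.response_unit})' if data.response_unit else ''}")
    if companion is not None and companion_fit is not None:
        ax2 = ax.twinx()
        ax2.scatter(companion.dose, companion.response, s=20, marker="^",
                    color="tab:orange", label="companion data")
        ax2.plot(grid, companion_fit.predict(grid), color="tab:orange", ls=":",
                 label="segmented fit")
        ax.axvline(companion_fit.breakpoint, ls="-.", color="tab:orange",
                   label=f"breakpoint = {companion_fit.breakpoint:.4g}")
        ax2.set_ylabel("companion response")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
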