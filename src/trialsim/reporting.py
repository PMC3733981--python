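"""Comparison tables and simple diagnostic plots for Monte-Carlo summaries."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .engine import MCSummary

__all__ = ["summarise_results", "method_ranges", "plot_grid"]


def _to_frame(summaries) -> pd.DataFrame:
    if isinstance(summaries, pd.DataFrame):
        return summaries.copy()
    return pd.DataFrame([s.as_dict() for s in summaries])


def summarise_results(summaries: list[MCSummary] | pd.DataFrame) -> pd.DataFrame:
    """Wide comparison table of rejection rates.

    Rows are scenarios; columns are (method, randomisation) pairs; cells
    hold the rejection rate among converged replications.  Empty input
    yields an empty table.
    """
    df = _to_frame(summaries)
    if df.empty:
        return pd.DataFrame()
    return df.pivot_table(
        index="scenario",
        columns=["method", "randomisation"],
        values="rejection_rate",
        aggfunc="first",
    )


def method_ranges(summaries: list[MCSummary] | pd.DataFrame) -> pd.DataFrame:
    """Min/max rejection rate per (scenario, method) across randomisations.

    Mirrors the way results are usually quoted: "range across randomisation
    methods x.x-y.y%".
    """
    df = _to_frame(summaries)
    if df.empty:
        return pd.DataFrame()
    g = df.groupby(["scenario", "method"])["rejection_rate"]
    out = g.agg(rate_min="min", rate_max="max", n_cells="count").reset_index()
    return out


def format_rates(summaries: list[MCSummary] | pd.DataFrame) -> str:
    """Aligned plain-text table: rate [± MC SE] per cell."""
    df = _to_frame(summaries)
    if df.empty:
        return "(no results)"
    df = df.copy()
    df["cell"] = df.apply(
        lambda r: f"{100 * r.rejection_rate:.1f}% ±{100 * r.mc_se:.1f}", axis=1
    )
    wide = df.pivot_table(
        index="scenario",
        columns=["method", "randomisation"],
        values="cell",
        aggfunc="first",
    )
    return wide.to_string()


def plot_grid(grid: pd.DataFrame, sweep: str = "beta12", ax=None):
    """Type-I error curves from :func:`trialsim.engine.run_theoretical_grids`."""
    import matplotlib.pyplot as plt

    sub = grid[grid["sweep"] == sweep]
    xcol = "beta12" if sweep == "beta12" else "p"
    if ax is None:
        _, ax = plt.subplots()
    for (method, rand), chunk in sub.groupby(["method", "randomisation"]):
        chunk = chunk.sort_values(xcol)
        ax.plot(chunk[xcol], chunk["rejection_rate"], marker="o",
                label=f"{rand} / {method}")
    ax.axhline(0.05, color="grey", lw=0.8, ls="--")
    ax.set_xlabel(xcol)
    ax.set_ylabel("type I error rate")
    ax.legend(fontsize=8)
    return ax
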