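"""Plotting helpers (cosmetic): song-type bar charts, trend scatter with
fitted line, per-season histograms.  All return the matplotlib Axes so
callers can restyle; nothing here affects any computed quantity."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .songs import Song
from .trends import TrendFit, decimal_year_of

__all__ = ["plot_type_percentages", "plot_trend", "plot_seasonal_histograms"]


def plot_type_percentages(percentages: pd.DataFrame, ax=None):
    """Stacked bars of song-type percentages per season (one location)."""
    ax = ax or plt.gca()
    pct_cols = [c for c in percentages.columns if c.startswith("pct_")]
    bottom = np.zeros(len(percentages))
    for col in pct_cols:
        ax.bar(percentages["season"], percentages[col], bottom=bottom,
               label=col.removeprefix("pct_"))
        bottom += percentages[col].to_numpy()
    ax.set_ylabel("% of songs")
    ax.legend()
    ax.tick_params(axis="x", rotation=45)
    return ax


def plot_trend(songs: list[Song], fit: TrendFit, ax=None):
    """Per-song means vs year with SD error bars and the fitted line."""
    ax = ax or plt.gca()
    sd_attr = fit.response.replace("mean_", "sd_")
    x = np.array([decimal_year_of(s.date) for s in songs])
    y = np.array([getattr(s, fit.response) for s in songs])
    err = np.array([getattr(s, sd_attr, np.nan) for s in songs])
    ok = np.isfinite(y)
    ax.errorbar(x[ok], y[ok], yerr=np.where(np.isfinite(err[ok]), err[ok], 0.0),
                fmt="o", ms=3, alpha=0.6, lw=0.8)
    grid = np.linspace(x[ok].min(), x[ok].max(), 50)
    ax.plot(grid, fit.intercept + fit.slope * grid, "k-")
    ax.set_xlabel("year")
    ax.set_ylabel(fit.response)
    ax.set_title(f"slope {fit.slope:+.3f}/yr, adj R² {fit.adj_r2:.2f}")
    return ax


def plot_seasonal_histograms(table: pd.DataFrame, ax=None):
    """Step histograms per region for one season's histogram table."""
    ax = ax or plt.gca()
    for region, grp in table.groupby("region"):
        ax.step(grp["bin_left"], grp["count"], where="post", label=str(region))
    ax.set_xlabel("value")
    ax.set_ylabel("count")
    ax.legend()
    return ax
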