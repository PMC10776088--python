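"""Multi-year linear trends of song parameters and regional histograms.

Each response variable (per-song mean INI, mean 20 Hz-note peak frequency,
mean HF-note peak frequency) is fitted by ordinary least squares against
decimal year — a Gaussian linear model with year as the only explanatory
variable, one observation per song.  Residual diagnostics (residuals vs
fitted, normal quantiles) are emitted for inspection.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .songs import Song

__all__ = ["TrendFit", "TrendFilters", "fit_trend", "seasonal_histograms", "decimal_year_of"]

RESPONSES = ("mean_ini", "mean_f20", "mean_fhf")


def decimal_year_of(date: dt.date) -> float:
    """Calendar date -> year + day-of-year / 365.25."""
    return date.year + date.timetuple().tm_yday / 365.25


@dataclass
class TrendFilters:
    """Observation filters applied before fitting."""

    year_min: Optional[float] = None
    year_max: Optional[float] = None
    instrument_allow: Optional[Sequence[str]] = None  # e.g. ("EAR",)
    exclude_regions: Sequence[str] = ()

    def apply(self, songs: list[Song]) -> tuple[list[Song], Optional[str]]:
        """Returns the surviving songs and, if the set is empty, the name
        of the first filter that emptied it."""
        out = list(songs)
        steps = [
            ("year range", lambda s: (self.year_min is None or decimal_year_of(s.date) >= self.year_min)
             and (self.year_max is None or decimal_year_of(s.date) <= self.year_max)),
            ("instrument allow-list", lambda s: self.instrument_allow is None
             or s.instrument in self.instrument_allow),
            ("region excludes", lambda s: s.location not in self.exclude_regions),
        ]
        for name, keep in steps:
            nxt = [s for s in out if keep(s)]
            if out and not nxt:
                return [], name
            out = nxt
        return out, None


@dataclass
class TrendFit:
    """An OLS year-trend for one response variable."""

    response: str
    slope: float
    intercept: float
    adj_r2: float
    slope_p: float
    slope_se: float
    n_songs: int
    year_range: tuple[float, float]
    residuals: np.ndarray = field(repr=False, default=None)
    fitted: np.ndarray = field(repr=False, default=None)

    def diagnostics(self) -> pd.DataFrame:
        """Residual-vs-fitted and normal-quantile series for model checks."""
        resid = np.asarray(self.residuals)
        order = np.argsort(resid)
        qq_theoretical = np.full(resid.size, np.nan)
        from scipy import stats

        qq_theoretical[order] = stats.norm.ppf(
            (np.arange(1, resid.size + 1) - 0.375) / (resid.size + 0.25)
        )
        return pd.DataFrame(
            {
                "fitted": np.asarray(self.fitted),
                "residual": resid,
                "qq_theoretical": qq_theoretical,
            }
        )

    def to_dict(self) -> dict:
        return dict(
            response=self.response,
            slope=self.slope,
            intercept=self.intercept,
            adj_r2=self.adj_r2,
            slope_p=self.slope_p,
            slope_se=self.slope_se,
            n_songs=self.n_songs,
            year_range=list(self.year_range),
        )


def fit_trend(
    songs: list[Song],
    response: str,
    filters: TrendFilters | None = None,
) -> TrendFit:
    """OLS of a per-song mean response on decimal year.

    Each observation is one song's mean value; songs without the response
    (e.g. no HF notes) are skipped.  Raises if fewer than 3 observations
    survive, naming the filter that emptied the set when one did.
    """
    if response not in RESPONSES:
        raise ValueError(f"response must be one of {RESPONSES}")
    filters = filters or TrendFilters()
    kept, emptied_by = filters.apply(songs)
    if emptied_by is not None:
        raise ValueError(f"no songs left after the {emptied_by} filter")
    pairs = [
        (decimal_year_of(s.date), getattr(s, response))
        for s in kept
        if np.isfinite(getattr(s, response))
    ]
    if len(pairs) < 3:
        raise ValueError(
            f"need at least 3 songs with finite {response}; have {len(pairs)}"
        )
    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    design = sm.add_constant(x)
    res = sm.OLS(y, design).fit()
    return TrendFit(
        response=response,
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        adj_r2=float(res.rsquared_adj),
        slope_p=float(res.pvalues[1]),
        slope_se=float(res.bse[1]),
        n_songs=len(pairs),
        year_range=(float(x.min()), float(x.max())),
        residuals=np.asarray(res.resid),
        fitted=np.asarray(res.fittedvalues),
    )


def write_trend_json(path: str | Path, fits: dict[str, TrendFit], filters: TrendFilters | None = None) -> None:
    payload = {name: fit.to_dict() for name, fit in fits.items()}
    if filters is not None:
        payload["_filters"] = dict(
            year_min=filters.year_min,
            year_max=filters.year_max,
            instrument_allow=list(filters.instrument_allow) if filters.instrument_allow else None,
            exclude_regions=list(filters.exclude_regions),
        )
    Path(path).write_text(json.dumps(payload, indent=2))


DEFAULT_BIN_WIDTHS = {"ini": 0.5, "fhf": 1.25}


def seasonal_histograms(
    values: pd.DataFrame,
    variable: str,
    bin_width: float | None = None,
) -> pd.DataFrame:
    """Per-season, per-region histograms of pooled note-level values.

    ``values`` needs columns season, region and value (note-level INIs or
    HF peak frequencies, not song means).  Bin edges are aligned across
    regions within each season.  Returns a long table: season, region,
    bin_left, bin_right, count.
    """
    if variable not in DEFAULT_BIN_WIDTHS:
        raise ValueError(f"variable must be one of {sorted(DEFAULT_BIN_WIDTHS)}")
    width = bin_width if bin_width is not None else DEFAULT_BIN_WIDTHS[variable]
    rows = []
    if values.empty:
        return pd.DataFrame(columns=["season", "region", "bin_left", "bin_right", "count"])
    for season, sgrp in values.groupby("season"):
        v = sgrp["value"].to_numpy(dtype=float)
        lo = np.floor(v.min() / width) * width
        hi = np.ceil(v.max() / width) * width
        edges = np.arange(lo, hi + width * 1.5, width)
        for region, rgrp in sgrp.groupby("region"):
            counts, _ = np.histogram(rgrp["value"].to_numpy(dtype=float), bins=edges)
            for left, right, c in zip(edges[:-1], edges[1:], counts):
                rows.append(
                    dict(season=season, region=region, bin_left=float(left),
                         bin_right=float(right), count=int(c))
                )
    return pd.DataFrame(rows, columns=["season", "region", "bin_left", "bin_right", "count"])
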