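"""Per-pixel trend detection: Mann-Kendall test plus OLS slope on significant pixels.

The Mann-Kendall statistic S counts concordant minus discordant year pairs;
its variance carries the standard tie correction, and the normal score Z uses
the +/-1 continuity correction. Significance defaults to the two-sided p < 0.1
level. Where a trend is significant, its magnitude is the ordinary
least-squares slope against year, reported per decade.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import xarray as xr
from scipy import stats

__all__ = ["TrendResult", "mann_kendall", "trend_slope", "trend_map", "annual_climate"]

DEFAULT_ALPHA = 0.1
MIN_YEARS = 4


@dataclass(frozen=True)
class TrendResult:
    s: int  # signed pair count
    var_s: float  # tie-corrected variance of S
    z: float  # continuity-corrected normal score
    p: float  # two-sided probability
    significant: bool  # p < alpha
    slope_per_decade: float  # OLS slope x 10; NaN unless significant
    n: int  # non-missing values used


def _mk_stats(x: np.ndarray) -> tuple[int, float]:
    n = x.size
    diff = np.sign(x[None, :] - x[:, None])
    s = int(np.triu(diff, k=1).sum())
    _, counts = np.unique(x, return_counts=True)
    ties = counts[counts > 1]
    var_s = (n * (n - 1) * (2 * n + 5) - np.sum(ties * (ties - 1) * (2 * ties + 5))) / 18.0
    return s, float(var_s)


def mann_kendall(
    x: np.ndarray, years: np.ndarray | None = None, alpha: float = DEFAULT_ALPHA
) -> TrendResult:
    """Mann-Kendall trend test on one annual series.

    Missing (NaN) entries are dropped together with their years; at least
    four values are required. The slope is computed (per decade) only when
    the test is significant at ``alpha``.
    """
    x = np.asarray(x, dtype=float)
    if years is None:
        years = np.arange(x.size)
    years = np.asarray(years, dtype=float)
    keep = np.isfinite(x)
    x, years = x[keep], years[keep]
    n = x.size
    if n < MIN_YEARS:
        raise ValueError(f"Mann-Kendall needs at least {MIN_YEARS} values, got {n}")
    s, var_s = _mk_stats(x)
    if var_s <= 0:  # all values tied
        z = 0.0
    elif s > 0:
        z = (s - 1) / math.sqrt(var_s)
    elif s < 0:
        z = (s + 1) / math.sqrt(var_s)
    else:
        z = 0.0
    p = 2.0 * stats.norm.sf(abs(z))
    significant = bool(p < alpha)
    slope = trend_slope(x, years) if significant else math.nan
    return TrendResult(s, var_s, z, float(p), significant, slope, n)


def trend_slope(x: np.ndarray, years: np.ndarray | None = None) -> float:
    """OLS slope of x against year, in input units per decade."""
    x = np.asarray(x, dtype=float)
    if years is None:
        years = np.arange(x.size)
    years = np.asarray(years, dtype=float)
    keep = np.isfinite(x)
    x, years = x[keep], years[keep]
    if x.size < 2 or np.ptp(years) == 0:
        raise ValueError("slope needs at least two distinct years")
    slope = np.polyfit(years, x, 1)[0]
    return float(slope * 10.0)


def trend_map(
    da: xr.DataArray, alpha: float = DEFAULT_ALPHA, min_years: int = MIN_YEARS
) -> xr.Dataset:
    """Apply the Mann-Kendall test per pixel of an annual (year, y, x) grid.

    Non-significant pixels keep their test statistics but carry NaN slope
    (the "gray" state in maps); pixels with too few valid years are fully
    missing. Per-pixel failures never abort the map.
    """
    arr = da.transpose("year", "y", "x").values
    years = np.asarray(da["year"].values, dtype=float)
    _, rows, cols = arr.shape
    out = {
        name: np.full((rows, cols), np.nan)
        for name in ("s", "var_s", "z", "p", "slope_per_decade", "n_valid")
    }
    sig = np.zeros((rows, cols), dtype=bool)
    for r in range(rows):
        for c in range(cols):
            series = arr[:, r, c]
            if np.isfinite(series).sum() < max(min_years, MIN_YEARS):
                continue
            res = mann_kendall(series, years, alpha=alpha)
            out["s"][r, c] = res.s
            out["var_s"][r, c] = res.var_s
            out["z"][r, c] = res.z
            out["p"][r, c] = res.p
            out["slope_per_decade"][r, c] = res.slope_per_decade
            out["n_valid"][r, c] = res.n
            sig[r, c] = res.significant
    ds = xr.Dataset(
        {name: (("y", "x"), grid) for name, grid in out.items()},
        coords={"y": da.coords["y"], "x": da.coords["x"]},
        attrs={"alpha": alpha, "variable": da.name or ""},
    )
    ds["significant"] = (("y", "x"), sig)
    return ds


def annual_climate(climate: xr.Dataset) -> xr.Dataset:
    """Annual aggregates of the monthly climate cube: mean temperature, total precipitation."""
    return xr.Dataset(
        {
            "temperature_annual_mean": climate["temperature"].mean("month"),
            "precipitation_annual_total": climate["precipitation"].sum("month"),
        }
    )
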