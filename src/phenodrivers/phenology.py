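"""NDVI-ratio phenology: event detection, exclusion filters, stage-mean NDVI.

Each pixel-year's 24 composites are rescaled to an *NDVI ratio* between a
winter baseline (the mean of the positive February--March composites, which
sidesteps snow-contaminated minima) and the annual maximum. Five event dates
are then read off the ratio curve:

* BGS (beginning of growing season): first composite whose ratio exceeds 0.2
  followed by three strictly increasing composites; SOG (start of green-up)
  is the composite before it, so the green-up phase spans exactly 2 composites.
* Maturity: first composite after BGS whose ratio exceeds 0.8.
* EGS (end of growing season): first composite after maturity whose ratio
  drops below 0.6 followed by three strictly decreasing composites; SOS
  (start of senescence) is two composites earlier, so senescence spans 3.

Pixel-years whose events are missing or out of sequence, or whose mean raw
NDVI between BGS and EGS is below a sparse-vegetation threshold (default
0.1), are flagged invalid with a reason and excluded downstream. Stage-mean
NDVI is computed over the four phases, with "two weeks" taken as one
composite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
import xarray as xr

from .calendar import COMPOSITE_START_DAYS, COMPOSITES_PER_YEAR, FEB_MAR_COMPOSITES

__all__ = [
    "InvalidReason",
    "RatioCurve",
    "PhenoRecord",
    "StageActivity",
    "compute_ratio_curve",
    "detect_bgs",
    "detect_maturity",
    "detect_egs",
    "extract_phenology",
    "stage_means",
    "phenology_grids",
]

BGS_THRESHOLD = 0.2
MATURITY_THRESHOLD = 0.8
EGS_THRESHOLD = 0.6
SPARSE_NDVI_THRESHOLD = 0.1

# BGS search range leaves room for SOG below and the 3-composite look-ahead above
_BGS_SEARCH = range(2, 21)


class InvalidReason(Enum):
    NO_MIN_REF = "no_min_ref"
    FLAT_CURVE = "flat_curve"
    EVENT_MISSING = "event_missing"
    ORDER_VIOLATION = "order_violation"
    SPARSE_VEGETATION = "sparse_vegetation"


#: stable integer codes for gridded/CSV export (0 = valid)
REASON_CODES = {None: 0, **{r: i + 1 for i, r in enumerate(InvalidReason)}}


@dataclass(frozen=True)
class RatioCurve:
    """Per pixel-year normalized seasonal curve."""

    min_ref: float  # winter baseline, NDVI units
    max_ref: float  # annual maximum, NDVI units
    ratio: np.ndarray | None  # 24 values, (ndvi - min_ref) / (max_ref - min_ref)
    invalid_reason: InvalidReason | None = None

    @property
    def valid(self) -> bool:
        return self.invalid_reason is None


@dataclass(frozen=True)
class PhenoRecord:
    """Five event composite indices (1-based) with day-of-year dates."""

    sog_idx: int | None = None
    bgs_idx: int | None = None
    mat_idx: int | None = None
    sos_idx: int | None = None
    egs_idx: int | None = None
    invalid_reason: InvalidReason | None = None

    @property
    def valid(self) -> bool:
        return self.invalid_reason is None

    def doy(self, event: str) -> float:
        idx = getattr(self, f"{event}_idx")
        return float(COMPOSITE_START_DAYS[idx - 1]) if idx is not None else math.nan


@dataclass(frozen=True)
class StageActivity:
    """Mean raw NDVI of the four growth phases; NaN where a window is empty."""

    greenup: float = math.nan
    fast_growth: float = math.nan
    mature: float = math.nan
    senescence: float = math.nan


def compute_ratio_curve(series: np.ndarray) -> RatioCurve:
    """Normalize one pixel-year of composites to the [winter, peak] range.

    The winter reference is the mean of the positive February--March
    composites; if none is positive the curve is invalid (``no_min_ref``),
    and if the annual maximum does not exceed the reference it is invalid
    (``flat_curve``).
    """
    series = np.asarray(series, dtype=float)
    if series.shape != (COMPOSITES_PER_YEAR,):
        raise ValueError(f"expected {COMPOSITES_PER_YEAR} composites, got shape {series.shape}")
    febmar = series[[i - 1 for i in FEB_MAR_COMPOSITES]]
    positive = febmar[febmar > 0]
    if positive.size == 0:
        return RatioCurve(math.nan, math.nan, None, InvalidReason.NO_MIN_REF)
    min_ref = float(positive.mean())
    max_ref = float(np.nanmax(series))
    if not max_ref > min_ref:
        return RatioCurve(min_ref, max_ref, None, InvalidReason.FLAT_CURVE)
    ratio = (series - min_ref) / (max_ref - min_ref)
    return RatioCurve(min_ref, max_ref, ratio)


def _r(curve: RatioCurve, idx: int) -> float:
    """Ratio value at a 1-based composite index."""
    return float(curve.ratio[idx - 1])


def detect_bgs(curve: RatioCurve) -> int | None:
    """First composite whose ratio exceeds 0.2 and starts a 3-step strict rise.

    Returns the 1-based BGS composite index, or None when no composite in the
    search range qualifies. Ties in the look-ahead break the run.
    """
    if not curve.valid:
        return None
    for k in _BGS_SEARCH:
        if _r(curve, k) > BGS_THRESHOLD and (
            _r(curve, k + 1) > _r(curve, k)
            and _r(curve, k + 2) > _r(curve, k + 1)
            and _r(curve, k + 3) > _r(curve, k + 2)
        ):
            return k
    return None


def detect_maturity(curve: RatioCurve, bgs: int) -> int | None:
    """First composite after BGS whose ratio strictly exceeds 0.8."""
    for m in range(bgs + 1, COMPOSITES_PER_YEAR + 1):
        if _r(curve, m) > MATURITY_THRESHOLD:
            return m
    return None


def detect_egs(curve: RatioCurve, mat: int) -> int | None:
    """First composite after maturity whose ratio drops below 0.6 and starts
    a 3-step strict decline. The look-ahead must stay within the year."""
    for e in range(mat + 1, COMPOSITES_PER_YEAR - 2):
        if _r(curve, e) < EGS_THRESHOLD and (
            _r(curve, e + 1) < _r(curve, e)
            and _r(curve, e + 2) < _r(curve, e + 1)
            and _r(curve, e + 3) < _r(curve, e + 2)
        ):
            return e
    return None


def extract_phenology(
    series: np.ndarray, sparse_threshold: float = SPARSE_NDVI_THRESHOLD
) -> PhenoRecord:
    """Full event extraction for one pixel-year, with exclusion filters."""
    curve = compute_ratio_curve(series)
    if not curve.valid:
        return PhenoRecord(invalid_reason=curve.invalid_reason)
    bgs = detect_bgs(curve)
    if bgs is None:
        return PhenoRecord(invalid_reason=InvalidReason.EVENT_MISSING)
    mat = detect_maturity(curve, bgs)
    if mat is None:
        return PhenoRecord(bgs_idx=bgs, sog_idx=bgs - 1, invalid_reason=InvalidReason.EVENT_MISSING)
    egs = detect_egs(curve, mat)
    if egs is None:
        return PhenoRecord(
            bgs_idx=bgs, sog_idx=bgs - 1, mat_idx=mat, invalid_reason=InvalidReason.EVENT_MISSING
        )
    sog, sos = bgs - 1, egs - 2
    if not sog < bgs < mat < sos < egs:
        return PhenoRecord(
            sog_idx=sog, bgs_idx=bgs, mat_idx=mat, sos_idx=sos, egs_idx=egs,
            invalid_reason=InvalidReason.ORDER_VIOLATION,
        )
    season = np.asarray(series, dtype=float)[bgs - 1 : egs]
    if np.nanmean(season) < sparse_threshold:
        return PhenoRecord(
            sog_idx=sog, bgs_idx=bgs, mat_idx=mat, sos_idx=sos, egs_idx=egs,
            invalid_reason=InvalidReason.SPARSE_VEGETATION,
        )
    return PhenoRecord(sog_idx=sog, bgs_idx=bgs, mat_idx=mat, sos_idx=sos, egs_idx=egs)


def stage_means(series: np.ndarray, record: PhenoRecord) -> StageActivity:
    """Mean raw NDVI over the four growth phases of a valid record.

    Windows in 1-based composite indices: green-up ``sog..bgs``, fast growth
    ``bgs+1..mat-1``, mature ``mat..sos-1``, senescence ``sos..egs``. An empty
    window yields NaN.
    """
    if not record.valid:
        return StageActivity()
    series = np.asarray(series, dtype=float)

    def window_mean(lo: int, hi: int) -> float:
        if hi < lo:
            return math.nan
        return float(np.nanmean(series[lo - 1 : hi]))

    return StageActivity(
        greenup=window_mean(record.sog_idx, record.bgs_idx),
        fast_growth=window_mean(record.bgs_idx + 1, record.mat_idx - 1),
        mature=window_mean(record.mat_idx, record.sos_idx - 1),
        senescence=window_mean(record.sos_idx, record.egs_idx),
    )


_EVENTS = ("sog", "bgs", "mat", "sos", "egs")
_STAGES = ("greenup", "fast_growth", "mature", "senescence")


def phenology_grids(
    cube: xr.Dataset, sparse_threshold: float = SPARSE_NDVI_THRESHOLD
) -> xr.Dataset:
    """Run event extraction and stage means over a full NDVI cube.

    Returns a Dataset with dims (year, y, x): per-event composite index and
    day-of-year grids (NaN where invalid), the four stage-mean NDVI grids, a
    ``valid`` flag and an integer ``invalid_reason`` code (0 = valid).
    """
    ndvi = cube["ndvi"].transpose("year", "composite", "y", "x").values
    ny, _, rows, cols = ndvi.shape
    idx = {e: np.full((ny, rows, cols), np.nan) for e in _EVENTS}
    doy = {e: np.full((ny, rows, cols), np.nan) for e in _EVENTS}
    stages = {s: np.full((ny, rows, cols), np.nan) for s in _STAGES}
    valid = np.zeros((ny, rows, cols), dtype=bool)
    reason = np.zeros((ny, rows, cols), dtype=np.int32)

    for iy in range(ny):
        for r in range(rows):
            for c in range(cols):
                series = ndvi[iy, :, r, c]
                rec = extract_phenology(series, sparse_threshold=sparse_threshold)
                reason[iy, r, c] = REASON_CODES[rec.invalid_reason]
                if not rec.valid:
                    continue
                valid[iy, r, c] = True
                for e in _EVENTS:
                    k = getattr(rec, f"{e}_idx")
                    idx[e][iy, r, c] = k
                    doy[e][iy, r, c] = COMPOSITE_START_DAYS[k - 1]
                act = stage_means(series, rec)
                for s in _STAGES:
                    stages[s][iy, r, c] = getattr(act, s)

    data = {}
    for e in _EVENTS:
        data[f"{e}_idx"] = (("year", "y", "x"), idx[e])
        data[f"{e}_doy"] = (("year", "y", "x"), doy[e])
    for s in _STAGES:
        data[f"ndvi_{s}"] = (("year", "y", "x"), stages[s])
    data["valid"] = (("year", "y", "x"), valid)
    data["invalid_reason"] = (("year", "y", "x"), reason)
    out = xr.Dataset(
        data,
        coords={k: cube.coords[k] for k in ("year", "y", "x")},
        attrs={"sparse_threshold": sparse_threshold},
    )
    return out
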