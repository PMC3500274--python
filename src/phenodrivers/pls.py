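"""Monthly climate drivers of phenology and vegetation activity via PLS + VIP.

For each coarse pixel, one vegetation variable (an event date or a stage-mean
NDVI) is regressed on the 24 monthly climate predictors — temperature and
precipitation for each of the 12 months preceding the event — with partial
least squares (PLS1/NIPALS, via scikit-learn). The predictor window is
anchored at the *typical* date of the event, the 75th percentile of all valid
pixel-year dates; a month is included only when the typical date falls after
its 15th. The number of latent components is the smallest count whose
(leave-one-out) cross-validated explained variance of the response reaches
90%, capped at 10. Each predictor gets a standardized model coefficient and a
variable-importance-in-the-projection (VIP) score; predictors with VIP >= 0.8
are flagged important, and maps carry a four-state rendering class
(important-positive, important-negative, unimportant/gray, insufficient/white).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import xarray as xr
from sklearn.cross_decomposition import PLSRegression

from .calendar import doy_to_month_day

__all__ = [
    "InsufficientDataError",
    "DesignMatrix",
    "PLSDriverResult",
    "typical_date",
    "month_window",
    "build_design",
    "fit_pls",
    "vip_scores",
    "driver_map",
]

VIP_THRESHOLD = 0.8
CV_TARGET = 0.90
MAX_COMPONENTS = 10
MIN_VALID_YEARS = 15

_MONTH_ABBR = ("jan", "feb", "mar", "apr", "may", "jun",
               "jul", "aug", "sep", "oct", "nov", "dec")

# rendering classes for driver maps
CLASS_INSUFFICIENT = 0  # white: too few valid years for PLS
CLASS_UNIMPORTANT = 1  # gray: VIP below threshold
CLASS_POSITIVE = 2
CLASS_NEGATIVE = 3


class InsufficientDataError(ValueError):
    """Raised when a pixel has too few valid years (or a degenerate response)."""


@dataclass(frozen=True)
class DesignMatrix:
    """Centered/scaled predictors and response for one pixel.

    ``X`` has one column per *retained* predictor (zero-variance columns are
    dropped); ``labels`` covers all 24 predictors in window order (12
    temperature then 12 precipitation) and ``kept`` marks the retained ones.
    """

    X: np.ndarray  # (k, n_kept), each column mean 0 / sd 1
    y: np.ndarray  # (k,), mean 0 / sd 1
    labels: tuple[str, ...]  # length 24
    kept: np.ndarray  # (24,) bool
    year_index: np.ndarray  # indices of the retained years


@dataclass(frozen=True)
class PLSDriverResult:
    """Per-predictor coefficients, VIP and importance, over all 24 labels."""

    coefficients: np.ndarray  # (24,), standardized scale; 0 for dropped columns
    vip: np.ndarray  # (24,); 0 for dropped columns
    important: np.ndarray  # (24,) bool: VIP >= threshold (dropped -> False)
    n_components: int
    explained_variance: float  # fitted R^2 of the response
    labels: tuple[str, ...]


def typical_date(dates: np.ndarray) -> float:
    """75th percentile (linear interpolation) of an event's valid dates."""
    dates = np.asarray(dates, dtype=float)
    dates = dates[np.isfinite(dates)]
    if dates.size == 0:
        raise ValueError("no valid dates to compute a typical date from")
    return float(np.percentile(dates, 75))


def month_window(typical: float) -> list[tuple[int, int]]:
    """The 12 (month, year-offset) predictor labels preceding a typical date.

    The last window month is the typical date's own month when the date falls
    after the 15th, otherwise the preceding month; offsets are 0 for the
    event year and -1 for the previous year. Returned oldest first.
    """
    if not 1 <= typical <= 366:
        raise ValueError(f"typical day-of-year out of range: {typical}")
    month, day = doy_to_month_day(min(typical, 365))
    last = month if day > 15 else month - 1
    window = []
    for back in range(11, -1, -1):
        m = last - back
        window.append(((m - 1) % 12 + 1, 0 if m >= 1 else -1))
    return window


def window_labels(window: list[tuple[int, int]]) -> tuple[str, ...]:
    labels = []
    for var in ("T", "P"):
        for m, off in window:
            labels.append(f"{var}_{_MONTH_ABBR[m - 1]}{'_prev' if off else ''}")
    return tuple(labels)


def build_design(
    response: np.ndarray,
    temperature: np.ndarray,
    precipitation: np.ndarray,
    window: list[tuple[int, int]],
    min_years: int = MIN_VALID_YEARS,
) -> DesignMatrix:
    """Assemble the per-pixel design matrix honoring window year-offsets.

    ``temperature`` and ``precipitation`` are (n_years, 12) monthly series
    for the pixel; ``response`` is the per-year vegetation value (NaN where
    the pixel-year was excluded). Years with any missing entry are dropped;
    all retained columns and the response are centered and scaled to unit
    variance (zero-variance predictor columns are dropped instead).
    """
    response = np.asarray(response, dtype=float)
    ny = response.size
    clim = {"T": np.asarray(temperature, dtype=float), "P": np.asarray(precipitation, dtype=float)}
    cols = []
    for var in ("T", "P"):
        for m, off in window:
            col = np.full(ny, np.nan)
            src = np.arange(ny) + off
            ok = src >= 0
            col[ok] = clim[var][src[ok], m - 1]
            cols.append(col)
    raw = np.column_stack(cols)  # (ny, 24)
    keep_rows = np.isfinite(response) & np.all(np.isfinite(raw), axis=1)
    k = int(keep_rows.sum())
    if k < min_years:
        raise InsufficientDataError(f"only {k} valid years (< {min_years})")
    y = response[keep_rows]
    X = raw[keep_rows]
    if np.std(y, ddof=1) == 0:
        raise InsufficientDataError("response has zero variance")
    sd = np.std(X, axis=0, ddof=1)
    kept = sd > 0
    X = (X[:, kept] - X[:, kept].mean(axis=0)) / sd[kept]
    y = (y - y.mean()) / np.std(y, ddof=1)
    return DesignMatrix(
        X=X,
        y=y,
        labels=window_labels(window),
        kept=kept,
        year_index=np.flatnonzero(keep_rows),
    )


def vip_scores(weights: np.ndarray, scores: np.ndarray, y_loadings: np.ndarray) -> np.ndarray:
    """Variable importance in the projection from PLS internals.

    ``weights`` W is (p, A), ``scores`` T is (n, A), ``y_loadings`` q is (A,).
    VIP_j = sqrt(p * sum_a SSY_a (w_ja/|w_a|)^2 / sum_a SSY_a) with
    SSY_a = q_a^2 t_a't_a, so mean(VIP^2) over the p predictors is 1.
    """
    W = np.asarray(weights, dtype=float)
    T = np.asarray(scores, dtype=float)
    q = np.ravel(y_loadings).astype(float)
    p, A = W.shape
    ssy = q[:A] ** 2 * np.einsum("na,na->a", T, T)
    wnorm2 = (W / np.linalg.norm(W, axis=0, keepdims=True)) ** 2
    return np.sqrt(p * (wnorm2 @ ssy) / ssy.sum())


def _fit(X: np.ndarray, y: np.ndarray, a: int) -> PLSRegression:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = PLSRegression(n_components=a, scale=False)
        model.fit(X, y.reshape(-1, 1))
    return model


def _loo_q2(X: np.ndarray, y: np.ndarray, a_max: int) -> np.ndarray:
    """Leave-one-out Q^2 = 1 - PRESS/SS for component counts 1..a_max.

    Each fold is fitted once with ``a_max`` components; predictions for all
    smaller counts come from the cumulative score-times-loading expansion.
    """
    n = X.shape[0]
    press = np.zeros(a_max)
    for i in range(n):
        mask = np.arange(n) != i
        Xi, yi = X[mask], y[mask]
        a_fold = min(a_max, Xi.shape[0] - 1, Xi.shape[1])
        model = _fit(Xi, yi, a_fold)
        x0 = X[i] - model._x_mean
        t = x0 @ model.x_rotations_  # (a_fold,)
        q = np.ravel(model.y_loadings_)
        contrib = t * q[: t.size]
        preds = model._y_mean + np.cumsum(contrib)
        preds = np.concatenate([preds, np.repeat(preds[-1], a_max - a_fold)])
        press += (y[i] - np.ravel(preds)) ** 2
    ss_tot = np.sum((y - y.mean()) ** 2)
    return 1.0 - press / ss_tot


def fit_pls(
    dm: DesignMatrix,
    max_components: int = MAX_COMPONENTS,
    cv_target: float = CV_TARGET,
    vip_threshold: float = VIP_THRESHOLD,
    selection: str = "cv",
) -> PLSDriverResult:
    """Fit PLS1 for one pixel and score predictor importance.

    ``selection`` chooses how the component count is picked against the 90%
    explained-variance criterion: ``"cv"`` (default) uses leave-one-out Q^2,
    ``"fitted"`` uses the in-sample R^2. If the criterion is never reached
    the cap (default 10, or fewer if the data cannot support it) is used.
    """
    X, y = dm.X, dm.y
    n, p_kept = X.shape
    a_cap = max(1, min(max_components, n - 2, p_kept))
    if selection == "cv":
        crit = _loo_q2(X, y, a_cap)
    elif selection == "fitted":
        crit = np.empty(a_cap)
        ss_tot = np.sum((y - y.mean()) ** 2)
        for a in range(1, a_cap + 1):
            model = _fit(X, y, a)
            resid = y - np.ravel(model.predict(X))
            crit[a - 1] = 1.0 - np.sum(resid**2) / ss_tot
    else:
        raise ValueError(f"unknown selection mode {selection!r}")
    reached = np.flatnonzero(crit >= cv_target)
    a_use = int(reached[0]) + 1 if reached.size else a_cap

    model = _fit(X, y, a_use)
    resid = y - np.ravel(model.predict(X))
    r2 = 1.0 - np.sum(resid**2) / np.sum((y - y.mean()) ** 2)
    coef_kept = np.ravel(model.coef_)
    vip_kept = vip_scores(model.x_weights_, model.x_scores_, model.y_loadings_)

    coefficients = np.zeros(len(dm.labels))
    vip = np.zeros(len(dm.labels))
    coefficients[dm.kept] = coef_kept
    vip[dm.kept] = vip_kept
    important = vip >= vip_threshold
    important[~dm.kept] = False
    return PLSDriverResult(
        coefficients=coefficients,
        vip=vip,
        important=important,
        n_components=a_use,
        explained_variance=float(r2),
        labels=dm.labels,
    )


def driver_map(
    response: xr.DataArray,
    climate: xr.Dataset,
    window: list[tuple[int, int]],
    vip_threshold: float = VIP_THRESHOLD,
    min_years: int = MIN_VALID_YEARS,
    max_components: int = MAX_COMPONENTS,
    cv_target: float = CV_TARGET,
    selection: str = "cv",
) -> xr.Dataset:
    """Per-pixel PLS over a coarse-grid response; returns coefficient/VIP maps.

    ``response`` has dims (year, y, x) on the climate grid. The output holds
    ``coefficient`` and ``vip`` with dims (predictor, y, x), a rendering
    ``driver_class`` (0 insufficient/white, 1 unimportant/gray, 2
    important-positive, 3 important-negative), per-pixel ``n_components`` and
    ``explained_variance``. Pixel-level failures yield the white class.
    """
    labels = window_labels(window)
    rows, cols = response.sizes["y"], response.sizes["x"]
    resp = response.transpose("year", "y", "x").values
    temp = climate["temperature"].transpose("year", "month", "y", "x").values
    prec = climate["precipitation"].transpose("year", "month", "y", "x").values
    coef = np.full((24, rows, cols), np.nan)
    vip = np.full((24, rows, cols), np.nan)
    klass = np.full((24, rows, cols), CLASS_INSUFFICIENT, dtype=np.int32)
    ncomp = np.full((rows, cols), -1, dtype=np.int32)
    r2 = np.full((rows, cols), np.nan)
    for r in range(rows):
        for c in range(cols):
            try:
                dm = build_design(
                    resp[:, r, c], temp[:, :, r, c], prec[:, :, r, c], window, min_years=min_years
                )
                res = fit_pls(
                    dm,
                    max_components=max_components,
                    cv_target=cv_target,
                    vip_threshold=vip_threshold,
                    selection=selection,
                )
            except InsufficientDataError:
                continue
            coef[:, r, c] = res.coefficients
            vip[:, r, c] = res.vip
            ncomp[r, c] = res.n_components
            r2[r, c] = res.explained_variance
            cls = np.where(
                res.important,
                np.where(res.coefficients >= 0, CLASS_POSITIVE, CLASS_NEGATIVE),
                CLASS_UNIMPORTANT,
            )
            klass[:, r, c] = cls
    return xr.Dataset(
        {
            "coefficient": (("predictor", "y", "x"), coef),
            "vip": (("predictor", "y", "x"), vip),
            "driver_class": (("predictor", "y", "x"), klass),
            "n_components": (("y", "x"), ncomp),
            "explained_variance": (("y", "x"), r2),
        },
        coords={
            "predictor": list(labels),
            "y": response.coords["y"],
            "x": response.coords["x"],
        },
        attrs={
            "vip_threshold": vip_threshold,
            "min_valid_years": min_years,
            "cv_target": cv_target,
            "selection": selection,
            "response": response.name or "",
        },
    )
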