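"""Synthetic NDVI and climate scenes with known phenology and driver structure.

The generator emulates the two data sources the pipeline is built for:

* a fine-grid stack of 15-day NDVI composites (24 per year) whose annual
  curves follow a double logistic — a green-up limb rising around one
  day-of-year and a senescence limb falling around another — plus Gaussian
  observation noise and winter snow contamination (negative composites);
* a coarse-grid monthly climate record (temperature in degC, precipitation in
  mm) built from a seasonal climatology, a linear trend and interannual
  anomalies, at ``agg_factor`` times coarser resolution than the NDVI grid.

The two are coupled: configured driver couplings shift each pixel-year's
green-up/senescence midpoints (or its seasonal amplitude) linearly in the
deviation of a chosen climate variable and month from its climatology, using
the *same* climate values that the climate cube reports. Ground truth —
continuous event dates, their composite indices, the injected couplings and
trends — is recorded so every downstream stage can be scored exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import xarray as xr
from scipy.special import expit

from .calendar import (
    COMPOSITE_INTERVAL,
    COMPOSITE_START_DAYS,
    COMPOSITES_PER_YEAR,
    WINTER_COMPOSITES,
)

__all__ = ["Coupling", "SimulationConfig", "GroundTruth", "generate_ndvi_cube", "generate_climate_cube"]

_LOGIT_02 = float(np.log(0.2 / 0.8))
_LOGIT_08 = float(np.log(0.8 / 0.2))
_LOGIT_04 = float(np.log(0.4 / 0.6))

#: coupling targets that shift the green-up limb, the senescence limb, or the amplitude
SPRING_TARGETS = frozenset({"sog", "bgs", "maturity"})
AUTUMN_TARGETS = frozenset({"sos", "egs"})
STAGE_TARGETS = frozenset({"greenup", "fast_growth", "mature", "senescence", "ndvi"})

# default monthly climatologies: a cold, summer-wet high-plateau grassland
_TEMP_CLIM = (-10.0, -8.0, -4.0, 1.0, 6.0, 10.0, 12.0, 11.0, 7.0, 1.0, -6.0, -9.0)
_PRECIP_CLIM = (5.0, 5.0, 10.0, 20.0, 40.0, 80.0, 100.0, 90.0, 60.0, 25.0, 8.0, 5.0)


@dataclass(frozen=True)
class Coupling:
    """Linear dependence of a phenology event or stage on one climate variable.

    ``coefficient`` is days per K (or per mm) for date targets, NDVI units per
    K (or per mm) for stage/amplitude targets. The driver is the deviation of
    the named month's value from its climatology (trend plus anomaly).
    """

    month: int  # 1..12
    variable: str  # "T" or "P"
    target: str  # one of SPRING_TARGETS | AUTUMN_TARGETS | STAGE_TARGETS
    coefficient: float

    def __post_init__(self) -> None:
        if not 1 <= self.month <= 12:
            raise ValueError(f"coupling month must be 1..12, got {self.month}")
        if self.variable not in ("T", "P"):
            raise ValueError(f"coupling variable must be 'T' or 'P', got {self.variable!r}")
        if self.target not in SPRING_TARGETS | AUTUMN_TARGETS | STAGE_TARGETS:
            raise ValueError(f"unknown coupling target {self.target!r}")


def _default_couplings() -> tuple[Coupling, ...]:
    return (
        Coupling(month=4, variable="T", target="bgs", coefficient=-3.0),
        Coupling(month=8, variable="T", target="egs", coefficient=-4.0),
        Coupling(month=6, variable="T", target="mature", coefficient=0.03),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic scene.

    Defaults describe the study conditions the pipeline targets: a 20x20 NDVI
    grid over 25 years with a 5x coarser climate grid, a ~1 K/decade warming
    trend, and modest spring/autumn temperature couplings.
    """

    n_years: int = 25
    fine_shape: tuple[int, int] = (20, 20)  # (rows, cols) of NDVI pixels
    agg_factor: int = 5
    baseline_ndvi: float = 0.1
    amplitude: float = 0.5
    green_slope: float = 0.07  # 1/day steepness of the green-up logistic
    brown_slope: float = 0.05  # 1/day steepness of the senescence logistic
    mean_sog_doy: float = 135.0  # midpoint (inflection) of the green-up limb
    mean_eos_doy: float = 290.0  # midpoint of the senescence limb
    noise_sd: float = 0.02  # NDVI observation noise
    snow_prob: float = 0.1  # chance a Dec-Mar composite is snow-contaminated
    pixel_jitter_sd: float = 5.0  # static per-pixel spread of both midpoints, days
    temp_climatology: tuple[float, ...] = _TEMP_CLIM
    precip_climatology: tuple[float, ...] = _PRECIP_CLIM
    temp_trend: float = 1.0  # K per decade
    precip_trend: float = 0.0  # mm per decade (per month)
    temp_anom_sd: float = 1.0  # K
    precip_anom_sd: float = 10.0  # mm
    couplings: tuple[Coupling, ...] = field(default_factory=_default_couplings)
    start_year: int = 1982
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if not 0.0 <= self.snow_prob <= 1.0:
            raise ValueError("snow_prob must be in [0, 1]")
        if self.n_years < 3:
            raise ValueError("n_years must be at least 3")
        if len(self.temp_climatology) != 12 or len(self.precip_climatology) != 12:
            raise ValueError("climatologies must have 12 monthly values")
        rows, cols = self.fine_shape
        if rows % self.agg_factor or cols % self.agg_factor:
            raise ValueError(
                f"fine grid {self.fine_shape} is not an exact multiple of agg_factor={self.agg_factor}"
            )

    @property
    def coarse_shape(self) -> tuple[int, int]:
        return (self.fine_shape[0] // self.agg_factor, self.fine_shape[1] // self.agg_factor)

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.start_year, self.start_year + self.n_years)

    def replace(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)

    def to_text(self) -> str:
        """Plain-text key=value serialization (couplings as month,var,target,coef;...)."""
        lines = []
        for key in (
            "n_years", "agg_factor", "baseline_ndvi", "amplitude", "green_slope",
            "brown_slope", "mean_sog_doy", "mean_eos_doy", "noise_sd", "snow_prob",
            "pixel_jitter_sd", "temp_trend", "precip_trend", "temp_anom_sd",
            "precip_anom_sd", "start_year", "seed",
        ):
            lines.append(f"{key} = {getattr(self, key)}")
        lines.append(f"fine_shape = {self.fine_shape[0]}x{self.fine_shape[1]}")
        lines.append("temp_climatology = " + ",".join(str(v) for v in self.temp_climatology))
        lines.append("precip_climatology = " + ",".join(str(v) for v in self.precip_climatology))
        lines.append(
            "couplings = "
            + ";".join(f"{c.month},{c.variable},{c.target},{c.coefficient}" for c in self.couplings)
        )
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "SimulationConfig":
        kwargs: dict = {}
        for raw in text.splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key in ("n_years", "agg_factor", "start_year", "seed"):
                kwargs[key] = int(value)
            elif key == "fine_shape":
                r, _, c = value.partition("x")
                kwargs[key] = (int(r), int(c))
            elif key in ("temp_climatology", "precip_climatology"):
                kwargs[key] = tuple(float(v) for v in value.split(","))
            elif key == "couplings":
                cpl = []
                for item in filter(None, value.split(";")):
                    m, v, t, coef = item.split(",")
                    cpl.append(Coupling(int(m), v, t, float(coef)))
                kwargs[key] = tuple(cpl)
            else:
                kwargs[key] = float(value)
        return cls(**kwargs)


@dataclass(frozen=True)
class GroundTruth:
    """Noise-free event dates and the injected structure, per pixel-year.

    ``dates`` holds continuous day-of-year variables ``true_sog`` .. ``true_egs``
    and their composite-grid counterparts ``true_*_idx`` (the composite at
    which a detector sampling the noise-free curve first sees each crossing),
    with dims (year, y, x). Couplings and trends are carried in the attrs.
    """

    dates: xr.Dataset

    def to_dataframe(self):
        return self.dates.to_dataframe().reset_index()


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed) & 0x7FFFFFFF, stream]))


_STREAM_TEMP, _STREAM_PRECIP, _STREAM_NOISE, _STREAM_SNOW, _STREAM_JITTER = range(5)


def _climate_values(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Coarse-grid monthly climate, shape (n_years, 12, R, C); precip clipped at 0."""
    ny = config.n_years
    R, C = config.coarse_shape
    yrs = np.arange(ny, dtype=float)[:, None, None, None]
    t_clim = np.asarray(config.temp_climatology, dtype=float)[None, :, None, None]
    p_clim = np.asarray(config.precip_climatology, dtype=float)[None, :, None, None]
    t_anom = _rng(config, _STREAM_TEMP).normal(0.0, config.temp_anom_sd, size=(ny, 12, R, C))
    p_anom = _rng(config, _STREAM_PRECIP).normal(0.0, config.precip_anom_sd, size=(ny, 12, R, C))
    temp = t_clim + config.temp_trend * yrs / 10.0 + t_anom
    precip = np.clip(p_clim + config.precip_trend * yrs / 10.0 + p_anom, 0.0, None)
    return temp, precip


def _deviations(config: SimulationConfig) -> dict[str, np.ndarray]:
    """Deviation of each climate value from its monthly climatology (trend + anomaly)."""
    temp, precip = _climate_values(config)
    t_clim = np.asarray(config.temp_climatology, dtype=float)[None, :, None, None]
    p_clim = np.asarray(config.precip_climatology, dtype=float)[None, :, None, None]
    return {"T": temp - t_clim, "P": precip - p_clim}


def generate_climate_cube(config: SimulationConfig) -> xr.Dataset:
    """Coarse-grid monthly temperature and precipitation as an xarray Dataset.

    Deterministic in ``config.seed``; shares its anomaly streams with
    :func:`generate_ndvi_cube` so the configured couplings are mutually
    consistent between the two cubes.
    """
    temp, precip = _climate_values(config)
    R, C = config.coarse_shape
    ds = xr.Dataset(
        {
            "temperature": (("year", "month", "y", "x"), temp),
            "precipitation": (("year", "month", "y", "x"), precip),
        },
        coords={
            "year": np.asarray(config.years, dtype=np.int32),
            "month": np.arange(1, 13, dtype=np.int32),
            "y": np.arange(R, dtype=np.int32),
            "x": np.arange(C, dtype=np.int32),
        },
        attrs={
            "temp_trend_per_decade": config.temp_trend,
            "precip_trend_per_decade": config.precip_trend,
            "agg_factor": config.agg_factor,
        },
    )
    ds["temperature"].attrs["units"] = "degC"
    ds["precipitation"].attrs["units"] = "mm"
    return ds


def _shifts(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per fine-pixel-year shifts of (green-up midpoint, senescence midpoint, amplitude)."""
    dev = _deviations(config)
    ny = config.n_years
    rows, cols = config.fine_shape
    f = config.agg_factor
    s1 = np.zeros((ny, rows, cols))
    s2 = np.zeros((ny, rows, cols))
    amp = np.zeros((ny, rows, cols))
    for c in config.couplings:
        d = dev[c.variable][:, c.month - 1, :, :]  # (ny, R, C)
        fine = np.repeat(np.repeat(d, f, axis=1), f, axis=2)
        if c.target in SPRING_TARGETS:
            s1 += c.coefficient * fine
        elif c.target in AUTUMN_TARGETS:
            s2 += c.coefficient * fine
        else:
            amp += c.coefficient * fine
    return s1, s2, amp


def generate_ndvi_cube(config: SimulationConfig) -> tuple[xr.Dataset, GroundTruth]:
    """Simulate the NDVI composite stack and its ground truth.

    Each pixel-year curve is ``base + amp * (sigmoid(g1*(t - s1)) -
    sigmoid(g2*(t - s2)))`` sampled at the 24 composite start days, plus
    Gaussian noise; December--March composites are replaced by a negative
    snow value with probability ``snow_prob``. The midpoints ``s1``/``s2``
    carry a static per-pixel jitter and the configured climate couplings.
    """
    ny = config.n_years
    rows, cols = config.fine_shape
    jit = _rng(config, _STREAM_JITTER)
    jitter1 = jit.normal(0.0, config.pixel_jitter_sd, size=(rows, cols))
    jitter2 = jit.normal(0.0, config.pixel_jitter_sd, size=(rows, cols))

    ds1, ds2, damp = _shifts(config)
    s1 = config.mean_sog_doy + jitter1[None, :, :] + ds1  # (ny, rows, cols)
    s2 = config.mean_eos_doy + jitter2[None, :, :] + ds2
    amp = np.maximum(config.amplitude + damp, 1e-3)

    t = COMPOSITE_START_DAYS.astype(float)[None, :, None, None]
    g1, g2 = config.green_slope, config.brown_slope
    clean = config.baseline_ndvi + amp[:, None] * (
        expit(g1 * (t - s1[:, None])) - expit(g2 * (t - s2[:, None]))
    )
    ndvi = clean + _rng(config, _STREAM_NOISE).normal(
        0.0, config.noise_sd, size=clean.shape
    )

    snow_rng = _rng(config, _STREAM_SNOW)
    winter = np.array([i - 1 for i in WINTER_COMPOSITES])
    mask = snow_rng.random((ny, len(winter), rows, cols)) < config.snow_prob
    snow_vals = snow_rng.uniform(-0.2, -0.01, size=mask.shape)
    for k, ci in enumerate(winter):
        ndvi[:, ci] = np.where(mask[:, k], snow_vals[:, k], ndvi[:, ci])
    ndvi = np.clip(ndvi, -1.0, 1.0)

    cube = xr.Dataset(
        {"ndvi": (("year", "composite", "y", "x"), ndvi)},
        coords={
            "year": np.asarray(config.years, dtype=np.int32),
            "composite": np.arange(1, COMPOSITES_PER_YEAR + 1, dtype=np.int32),
            "doy": ("composite", COMPOSITE_START_DAYS.astype(np.int32)),
            "y": np.arange(rows, dtype=np.int32),
            "x": np.arange(cols, dtype=np.int32),
        },
        attrs={"agg_factor": config.agg_factor, "noise_sd": config.noise_sd},
    )

    # analytic event dates: threshold crossings of the noise-free limbs
    true_bgs = s1 + _LOGIT_02 / g1
    true_mat = s1 + _LOGIT_08 / g1
    true_egs = s2 + _LOGIT_04 / g2
    true_sog = true_bgs - COMPOSITE_INTERVAL
    true_sos = true_egs - 2.0 * COMPOSITE_INTERVAL
    if not (
        np.all(true_sog < true_bgs)
        and np.all(true_bgs < true_mat)
        and np.all(true_mat < true_sos)
        and np.all(true_sos < true_egs)
    ):
        raise ValueError(
            "configured slopes/midpoints/couplings produce unordered true event dates"
        )

    def idx_after(doy: np.ndarray) -> np.ndarray:
        return (
            np.searchsorted(COMPOSITE_START_DAYS, doy.ravel(), side="right")
            .reshape(doy.shape)
            .astype(np.int32)
            + 1
        )

    bgs_idx = idx_after(true_bgs)
    egs_idx = idx_after(true_egs)
    truth = xr.Dataset(
        {
            "true_sog": (("year", "y", "x"), true_sog),
            "true_bgs": (("year", "y", "x"), true_bgs),
            "true_mat": (("year", "y", "x"), true_mat),
            "true_sos": (("year", "y", "x"), true_sos),
            "true_egs": (("year", "y", "x"), true_egs),
            "true_sog_idx": (("year", "y", "x"), bgs_idx - 1),
            "true_bgs_idx": (("year", "y", "x"), bgs_idx),
            "true_mat_idx": (("year", "y", "x"), idx_after(true_mat)),
            "true_sos_idx": (("year", "y", "x"), egs_idx - 2),
            "true_egs_idx": (("year", "y", "x"), egs_idx),
        },
        coords=cube.drop_dims("composite").coords,
        attrs={
            "couplings": json.dumps(
                [
                    {"month": c.month, "variable": c.variable, "target": c.target, "coefficient": c.coefficient}
                    for c in config.couplings
                ]
            ),
            "temp_trend_per_decade": config.temp_trend,
            "precip_trend_per_decade": config.precip_trend,
        },
    )
    return cube, GroundTruth(dates=truth)
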