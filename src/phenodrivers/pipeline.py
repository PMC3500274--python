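"""End-to-end orchestration: simulate -> phenology -> trends -> regrid -> PLS.

Every stage reads and writes NetCDF/CSV products in one output directory and
the run is summarized in a ``manifest.json`` (config hash, seed, per-stage
record counts, output checksums). Reruns with the same configuration and seed
reproduce byte-identical payloads. All named thresholds live in
:class:`RunConfig`; stage code takes them as arguments.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import xarray as xr

from ._io import load_dataset, save_dataset
from .calendar import COMPOSITE_START_DAYS
from .phenology import InvalidReason, REASON_CODES, phenology_grids
from .pls import driver_map, month_window, typical_date
from .regrid import regrid_cube
from .simulate import SimulationConfig, generate_climate_cube, generate_ndvi_cube
from .trends import annual_climate, trend_map

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "summarize_fractions"]

log = logging.getLogger("phenodrivers")

ALL_STAGES = ("simulate", "phenology", "trends", "regrid", "pls")

#: which composite marks the *end* of each NDVI stage (for window anchoring)
_STAGE_END_EVENT = {
    "ndvi_greenup": "bgs_idx",
    "ndvi_fast_growth": None,  # mat_idx - 1
    "ndvi_mature": None,  # sos_idx - 1
    "ndvi_senescence": "egs_idx",
}


class PipelineError(RuntimeError):
    """A stage could not run (missing upstream product or invalid data)."""


@dataclass(frozen=True)
class RunConfig:
    """Paths, thresholds and stage list for one reproducible run."""

    outdir: Path
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    stages: tuple[str, ...] = ALL_STAGES
    sparse_ndvi: float = 0.1  # growing-season mean NDVI exclusion threshold
    mk_alpha: float = 0.1  # Mann-Kendall significance level
    vip_threshold: float = 0.8
    cv_target: float = 0.90  # explained-variance criterion for component count
    max_components: int = 10
    min_valid_years: int = 15  # below this a coarse pixel is white
    pls_selection: str = "cv"  # or "fitted"
    pls_responses: tuple[str, ...] = ("bgs_doy", "egs_doy", "ndvi_mature")

    def __post_init__(self) -> None:
        object.__setattr__(self, "outdir", Path(self.outdir))
        for name in ("sparse_ndvi", "mk_alpha", "vip_threshold", "cv_target"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    def replace(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)

    def config_hash(self) -> str:
        payload = self.sim.to_text() + json.dumps(
            {
                k: getattr(self, k)
                for k in (
                    "stages", "sparse_ndvi", "mk_alpha", "vip_threshold", "cv_target",
                    "max_components", "min_valid_years", "pls_selection", "pls_responses",
                )
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _require(path: Path, stage: str, needed_by: str) -> Path:
    if not path.exists():
        raise PipelineError(
            f"stage '{needed_by}' needs {path.name}, which stage '{stage}' produces; "
            f"run '{stage}' first"
        )
    return path


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_simulate(cfg: RunConfig, out: Path) -> dict:
    cube, truth = generate_ndvi_cube(cfg.sim)
    climate = generate_climate_cube(cfg.sim)
    save_dataset(cube, out / "ndvi.nc")
    save_dataset(climate, out / "climate.nc")
    save_dataset(truth.dates, out / "ground_truth.nc")
    truth.to_dataframe().to_csv(out / "ground_truth.csv", index=False)
    (out / "sim_config.txt").write_text(cfg.sim.to_text())
    return {
        "pixel_years": int(np.prod(cube["ndvi"].shape) // cube.sizes["composite"]),
        "composites_per_pixel": int(cube.sizes["year"] * cube.sizes["composite"]),
    }


def _stage_phenology(cfg: RunConfig, out: Path) -> dict:
    cube = load_dataset(_require(out / "ndvi.nc", "simulate", "phenology"))
    grids = phenology_grids(cube, sparse_threshold=cfg.sparse_ndvi)
    save_dataset(grids, out / "phenology.nc")
    df = grids.to_dataframe().reset_index()
    df.to_csv(out / "phenology_records.csv", index=False)
    counts = {"valid": int(grids["valid"].sum())}
    codes = grids["invalid_reason"].values
    for reason, code in REASON_CODES.items():
        if reason is not None:
            counts[reason.value] = int((codes == code).sum())
    log.info("phenology: %s", counts)
    return counts


_VEG_TREND_VARS = (
    "sog_doy", "bgs_doy", "mat_doy", "sos_doy", "egs_doy",
    "ndvi_greenup", "ndvi_fast_growth", "ndvi_mature", "ndvi_senescence",
)


def _stage_trends(cfg: RunConfig, out: Path) -> dict:
    pheno = load_dataset(_require(out / "phenology.nc", "phenology", "trends"))
    climate = load_dataset(_require(out / "climate.nc", "simulate", "trends"))
    merged = {}
    for var in _VEG_TREND_VARS:
        tm = trend_map(pheno[var], alpha=cfg.mk_alpha)
        for name in ("slope_per_decade", "p", "significant"):
            merged[f"{var}__{name}"] = tm[name]
    save_dataset(xr.Dataset(merged), out / "trends_vegetation.nc")
    merged_c = {}
    for var, da in annual_climate(climate).items():
        tm = trend_map(da, alpha=cfg.mk_alpha)
        for name in ("slope_per_decade", "p", "significant"):
            merged_c[f"{var}__{name}"] = tm[name]
    save_dataset(xr.Dataset(merged_c), out / "trends_climate.nc")
    return {
        "vegetation_variables": len(_VEG_TREND_VARS),
        "climate_variables": 2,
    }


def _stage_regrid(cfg: RunConfig, out: Path) -> dict:
    pheno = load_dataset(_require(out / "phenology.nc", "phenology", "regrid"))
    factor = cfg.sim.agg_factor
    variables = [v for v in pheno.data_vars if v.endswith("_doy") or v.startswith("ndvi_")]
    coarse = regrid_cube(pheno, factor, variables=variables)
    save_dataset(coarse, out / "regridded.nc")
    return {"variables": len(variables), "coarse_shape": list(cfg.sim.coarse_shape)}


def _anchor_days(pheno: xr.Dataset, response: str) -> np.ndarray:
    """Day-of-year of the event (or stage end) anchoring the climate window."""
    if response.endswith("_doy"):
        return pheno[response].values
    if response in ("ndvi_greenup", "ndvi_senescence"):
        return pheno[{"ndvi_greenup": "bgs_doy", "ndvi_senescence": "egs_doy"}[response]].values
    # fast growth ends one composite before maturity; mature one before SOS
    idx_var = {"ndvi_fast_growth": "mat_idx", "ndvi_mature": "sos_idx"}[response]
    idx = pheno[idx_var].values - 1
    days = np.full(idx.shape, np.nan)
    ok = np.isfinite(idx) & (idx >= 1)
    days[ok] = COMPOSITE_START_DAYS[idx[ok].astype(int) - 1]
    return days


def _stage_pls(cfg: RunConfig, out: Path) -> dict:
    coarse = load_dataset(_require(out / "regridded.nc", "regrid", "pls"))
    pheno = load_dataset(_require(out / "phenology.nc", "phenology", "pls"))
    climate = load_dataset(_require(out / "climate.nc", "simulate", "pls"))
    info = {}
    for response in cfg.pls_responses:
        if response not in coarse:
            raise PipelineError(f"response {response!r} not present in regridded.nc")
        anchor = typical_date(_anchor_days(pheno, response))
        window = month_window(anchor)
        result = driver_map(
            coarse[response],
            climate,
            window,
            vip_threshold=cfg.vip_threshold,
            min_years=cfg.min_valid_years,
            max_components=cfg.max_components,
            cv_target=cfg.cv_target,
            selection=cfg.pls_selection,
        )
        result.attrs["typical_doy"] = float(anchor)
        save_dataset(result, out / f"pls_{response}.nc")
        # per-pixel bar-chart table (coefficient + VIP per predictor)
        result[["coefficient", "vip", "driver_class"]].to_dataframe().reset_index().to_csv(
            out / f"pls_{response}.csv", index=False
        )
        fitted = int((result["n_components"].values >= 0).sum())
        info[response] = {"typical_doy": float(anchor), "pixels_fit": fitted}
    return info


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "phenology": _stage_phenology,
    "trends": _stage_trends,
    "regrid": _stage_regrid,
    "pls": _stage_pls,
}

_STAGE_OUTPUTS = {
    "simulate": ("ndvi.nc", "climate.nc", "ground_truth.nc", "ground_truth.csv", "sim_config.txt"),
    "phenology": ("phenology.nc", "phenology_records.csv"),
    "trends": ("trends_vegetation.nc", "trends_climate.nc"),
    "regrid": ("regridded.nc",),
    "pls": (),  # depends on configured responses
}


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages in order and write the run manifest."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.sim.seed,
        "stages": {},
        "outputs": {},
    }
    for stage in ALL_STAGES:
        if stage not in cfg.stages:
            continue
        log.info("running stage %s", stage)
        manifest["stages"][stage] = _STAGE_FUNCS[stage](cfg, out)
        files = list(_STAGE_OUTPUTS[stage])
        if stage == "pls":
            files = [f"pls_{r}.nc" for r in cfg.pls_responses] + [
                f"pls_{r}.csv" for r in cfg.pls_responses
            ]
        for f in files:
            manifest["outputs"][f] = _sha256(out / f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def summarize_fractions(
    trends: xr.Dataset,
    variable: str,
    threshold_per_decade: float,
    direction: str = "advance",
) -> dict:
    """Area fraction of valid pixels with a significant trend beyond a threshold.

    ``direction="advance"`` counts slopes more negative than ``-threshold``
    (earlier dates / losses), ``"increase"`` counts slopes above ``+threshold``.
    The denominator is every pixel with a defined test result.
    """
    slope = trends[f"{variable}__slope_per_decade"].values
    p = trends[f"{variable}__p"].values
    sig = trends[f"{variable}__significant"].values.astype(bool)
    valid = np.isfinite(p)
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValueError(f"no valid pixels for {variable}")
    if direction == "advance":
        exceed = sig & (slope < -threshold_per_decade)
    elif direction == "increase":
        exceed = sig & (slope > threshold_per_decade)
    else:
        raise ValueError(f"direction must be 'advance' or 'increase', got {direction!r}")
    n_exceed = int((exceed & valid).sum())
    return {
        "variable": variable,
        "direction": direction,
        "threshold_per_decade": threshold_per_decade,
        "n_valid": n_valid,
        "n_exceed": n_exceed,
        "fraction": n_exceed / n_valid,
    }
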