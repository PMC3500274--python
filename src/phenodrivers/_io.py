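"""NetCDF I/O helpers (scipy backend, NetCDF3-safe dtypes)."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import xarray as xr


def _netcdf3_safe(ds: xr.Dataset) -> xr.Dataset:
    """Cast dtypes NetCDF3 cannot hold (int64, bool) to int32/int8."""
    ds = ds.copy()
    for name in list(ds.variables):
        var = ds[name]
        if var.dtype == np.bool_:
            ds[name] = var.astype(np.int8)
            ds[name].attrs["dtype"] = "bool"
        elif var.dtype in (np.int64, np.uint64, np.uint32):
            ds[name] = var.astype(np.int32)
    return ds


def save_dataset(ds: xr.Dataset, path: Path | str) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    _netcdf3_safe(ds).to_netcdf(path, engine="scipy")
    return path


def load_dataset(path: Path | str) -> xr.Dataset:
    ds = xr.load_dataset(path, engine="scipy")
    for name in list(ds.variables):
        if ds[name].attrs.get("dtype") == "bool":
            ds[name] = ds[name].astype(bool)
            ds[name].attrs.pop("dtype", None)
    return ds
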