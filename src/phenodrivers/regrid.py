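"""Fine-to-coarse regridding: block means followed by bilinear resampling.

Vegetation layers live on the fine NDVI grid; climate lives on a grid
``factor`` times coarser. Layers are first aggregated into factor x factor
block means (missing-aware: a block with fewer than half its cells valid is
missing) and then resampled to the target grid's cell centers by bilinear
interpolation. Grids use cell-center registration on an abstract row-major
coordinate frame: cell (i, j) of a grid with cell size ``h`` and origin
``(oy, ox)`` has center ``(oy + (i + 0.5) h, ox + (j + 0.5) h)``. Target
centers outside the source center extent are clamped to the edge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import xarray as xr
from scipy.interpolate import RegularGridInterpolator

__all__ = ["GridSpec", "block_aggregate", "bilinear_to_grid", "regrid_layer", "regrid_cube"]


@dataclass(frozen=True)
class GridSpec:
    """Cell-center registered rectangular grid in abstract units."""

    rows: int
    cols: int
    cell_size: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)  # (y, x) of the outer corner

    def centers(self) -> tuple[np.ndarray, np.ndarray]:
        oy, ox = self.origin
        ys = oy + (np.arange(self.rows) + 0.5) * self.cell_size
        xs = ox + (np.arange(self.cols) + 0.5) * self.cell_size
        return ys, xs

    def coarsen(self, factor: int) -> "GridSpec":
        if self.rows % factor or self.cols % factor:
            raise ValueError(
                f"grid {self.rows}x{self.cols} not divisible by factor {factor}"
            )
        return GridSpec(self.rows // factor, self.cols // factor, self.cell_size * factor, self.origin)


def block_aggregate(layer: np.ndarray, factor: int) -> np.ndarray:
    """Mean over factor x factor blocks, ignoring NaN; a block with fewer than
    half its cells valid is NaN."""
    layer = np.asarray(layer, dtype=float)
    rows, cols = layer.shape
    if rows % factor or cols % factor:
        raise ValueError(f"layer {layer.shape} not divisible by factor {factor}")
    blocks = layer.reshape(rows // factor, factor, cols // factor, factor)
    valid = np.isfinite(blocks)
    nvalid = valid.sum(axis=(1, 3))
    with np.errstate(invalid="ignore"):
        means = np.where(
            nvalid > 0, np.nansum(np.where(valid, blocks, 0.0), axis=(1, 3)) / np.maximum(nvalid, 1), np.nan
        )
    means[2 * nvalid < factor * factor] = np.nan
    return means


def bilinear_to_grid(layer: np.ndarray, source: GridSpec, target: GridSpec) -> np.ndarray:
    """Bilinear resampling from source cell centers onto target cell centers.

    Exact for affine fields; target centers beyond the source center extent
    are clamped to the edge (nearest-edge extrapolation). NaN source cells
    propagate to any target cell they support.
    """
    layer = np.asarray(layer, dtype=float)
    if layer.shape != (source.rows, source.cols):
        raise ValueError(f"layer shape {layer.shape} does not match source {source}")
    sy, sx = source.centers()
    ty, tx = target.centers()
    if ty[0] > sy[-1] + source.cell_size or tx[0] > sx[-1] + source.cell_size:
        raise ValueError("target grid does not overlap the source extent")
    interp = RegularGridInterpolator((sy, sx), layer, method="linear", bounds_error=False)
    yy = np.clip(ty, sy[0], sy[-1])
    xx = np.clip(tx, sx[0], sx[-1])
    pts = np.stack(np.meshgrid(yy, xx, indexing="ij"), axis=-1)
    return interp(pts.reshape(-1, 2)).reshape(target.rows, target.cols)


def regrid_layer(layer: np.ndarray, factor: int, target: GridSpec | None = None) -> np.ndarray:
    """Block-aggregate a fine layer and resample it onto the target grid.

    When ``target`` is omitted it defaults to the coarsened source grid, in
    which case the bilinear step is the identity (cell centers coincide).
    """
    layer = np.asarray(layer, dtype=float)
    fine = GridSpec(*layer.shape)
    agg = block_aggregate(layer, factor)
    agg_spec = fine.coarsen(factor)
    if target is None:
        target = agg_spec
    return bilinear_to_grid(agg, agg_spec, target)


def regrid_cube(
    ds: xr.Dataset, factor: int, variables: list[str] | None = None
) -> xr.Dataset:
    """Regrid every (year, y, x) variable of a fine-grid Dataset to the coarse grid."""
    if variables is None:
        variables = [v for v in ds.data_vars if set(ds[v].dims) == {"year", "y", "x"}]
    out = {}
    ny = ds.sizes["year"]
    R, C = ds.sizes["y"] // factor, ds.sizes["x"] // factor
    for v in variables:
        arr = ds[v].transpose("year", "y", "x").values.astype(float)
        res = np.empty((ny, R, C))
        for iy in range(ny):
            res[iy] = regrid_layer(arr[iy], factor)
        out[v] = (("year", "y", "x"), res)
    return xr.Dataset(
        out,
        coords={
            "year": ds.coords["year"],
            "y": np.arange(R, dtype=np.int32),
            "x": np.arange(C, dtype=np.int32),
        },
        attrs={"agg_factor": factor},
    )
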