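"""Gridded raster series and reef-cell grids.

A :class:`RasterSeries` is a time-stamped stack of gridded fields (daily or
monthly) over a fixed land/sea mask; a :class:`ReefGrid` is the table of
reef cells (with areas in km^2) onto which predictions are made.

Raster I/O uses CF-style NetCDF through xarray.  Row 0 is the northernmost
row (array convention); latitude decreases with row index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

KM_PER_DEG_LAT = 111.32


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular grid: origin at the center of pixel (0, 0)."""

    origin_lon: float
    origin_lat: float
    cell_size_km: float
    rows: int
    cols: int

    def __post_init__(self) -> None:
        if self.rows < 2 or self.cols < 2:
            raise ValueError(f"degenerate grid {self.rows}x{self.cols}: need at least 2x2")
        if self.cell_size_km <= 0:
            raise ValueError("cell_size_km must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.rows, self.cols)

    def lats(self) -> np.ndarray:
        """Latitude of each row center (deg); decreasing with row index."""
        step = self.cell_size_km / KM_PER_DEG_LAT
        return self.origin_lat - step * np.arange(self.rows)

    def lons(self) -> np.ndarray:
        """Longitude of each column center (deg)."""
        step = self.cell_size_km / (
            KM_PER_DEG_LAT * np.cos(np.deg2rad(self.origin_lat))
        )
        return self.origin_lon + step * np.arange(self.cols)

    def pixel_latlon(self, row: int | np.ndarray, col: int | np.ndarray):
        return self.lats()[row], self.lons()[col]

    def nearest_pixel(self, lon: float, lat: float) -> tuple[int, int]:
        row = int(np.argmin(np.abs(self.lats() - lat)))
        col = int(np.argmin(np.abs(self.lons() - lon)))
        return row, col


@dataclass
class RasterSeries:
    """Time x rows x cols gridded values over a constant sea mask.

    ``mask`` is True on sea pixels; land pixels carry NaN at every time step.
    """

    grid: GridSpec
    times: pd.DatetimeIndex
    values: np.ndarray
    mask: np.ndarray
    name: str = "var"
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != 3:
            raise ValueError("values must be (time, rows, cols)")
        if self.values.shape != (len(self.times), self.grid.rows, self.grid.cols):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"({len(self.times)}, {self.grid.rows}, {self.grid.cols})"
            )
        if self.mask.shape != self.grid.shape:
            raise ValueError("mask shape does not match grid")
        if len(self.times) > 1 and not self.times.is_monotonic_increasing:
            raise ValueError("timestamps must be strictly increasing")
        # land pixels carry no values
        self.values[:, ~self.mask] = np.nan

    @property
    def n_times(self) -> int:
        return len(self.times)

    def month_index(self) -> np.ndarray:
        """Calendar month (1..12) of each time step."""
        return self.times.month.to_numpy()

    def to_xarray(self) -> xr.DataArray:
        da = xr.DataArray(
            self.values,
            dims=("time", "lat", "lon"),
            coords={"time": self.times, "lat": self.grid.lats(), "lon": self.grid.lons()},
            name=self.name,
            attrs={"units": self.units, "cell_size_km": self.grid.cell_size_km},
        )
        return da

    def to_netcdf(self, path: str) -> None:
        ds = self.to_xarray().to_dataset()
        ds["mask"] = xr.DataArray(
            self.mask.astype(np.int8),
            dims=("lat", "lon"),
            coords={"lat": self.grid.lats(), "lon": self.grid.lons()},
        )
        ds.to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path: str, name: str | None = None) -> "RasterSeries":
        ds = xr.open_dataset(path, engine="scipy")
        if name is None:
            name = [v for v in ds.data_vars if v != "mask"][0]
        da = ds[name]
        lats, lons = ds["lat"].values, ds["lon"].values
        cell = float(da.attrs.get("cell_size_km", abs(lats[0] - lats[1]) * KM_PER_DEG_LAT))
        grid = GridSpec(float(lons[0]), float(lats[0]), cell, len(lats), len(lons))
        mask = ds["mask"].values.astype(bool) if "mask" in ds else ~np.isnan(da.values).all(0)
        return cls(
            grid=grid,
            times=pd.DatetimeIndex(ds["time"].values),
            values=da.values.astype(float),
            mask=mask,
            name=str(name),
            units=str(da.attrs.get("units", "")),
        )


def resample(series: RasterSeries, factor: float) -> RasterSeries:
    """Resample a series to a finer (factor > 1) or coarser grid.

    Bilinear for the values (land filled from the nearest sea pixel first,
    so coasts do not bleed NaN), nearest-neighbour for the mask; land is
    re-masked afterwards.
    """
    from scipy import ndimage

    if factor <= 0:
        raise ValueError("factor must be positive")
    rows = max(int(round(series.grid.rows * factor)), 2)
    cols = max(int(round(series.grid.cols * factor)), 2)
    rr = (np.arange(rows) + 0.5) / factor - 0.5
    cc = (np.arange(cols) + 0.5) / factor - 0.5
    grid_r, grid_c = np.meshgrid(rr, cc, indexing="ij")
    coords = np.stack([grid_r.ravel(), grid_c.ravel()])

    # nearest-sea fill so bilinear never touches NaN
    _, (ir, ic) = ndimage.distance_transform_edt(~series.mask, return_indices=True)
    new_mask = ndimage.map_coordinates(
        series.mask.astype(float), coords, order=0).reshape(rows, cols) > 0.5
    out = np.empty((series.n_times, rows, cols))
    for t in range(series.n_times):
        filled = series.values[t][ir, ic]
        out[t] = ndimage.map_coordinates(filled, coords, order=1,
                                         mode="nearest").reshape(rows, cols)
    new_grid = GridSpec(series.grid.origin_lon, series.grid.origin_lat,
                        series.grid.cell_size_km / factor, rows, cols)
    return RasterSeries(grid=new_grid, times=series.times, values=out,
                        mask=new_mask, name=series.name, units=series.units)


@dataclass
class ReefGrid:
    """Reef cells on the raster grid, with true areas in km^2.

    Each cell references one or more raster pixels (``pixels`` is a list of
    (row, col) tuples); ``area_km2`` may be smaller than the nominal cell
    area for partially-covered cells, never larger.
    """

    cells: pd.DataFrame = field(default_factory=pd.DataFrame)
    nominal_cell_area_km2: float | None = None

    REQUIRED = ("cell_id", "row", "col", "lon", "lat", "area_km2")

    def __post_init__(self) -> None:
        for c in self.REQUIRED:
            if c not in self.cells.columns:
                raise ValueError(f"reef grid missing column {c!r}")
        if (self.cells["area_km2"] <= 0).any():
            raise ValueError("reef cell areas must be positive")
        if self.nominal_cell_area_km2 is not None:
            if (self.cells["area_km2"] > self.nominal_cell_area_km2 + 1e-9).any():
                raise ValueError("cell area exceeds nominal cell area")
        if "pixels" not in self.cells.columns:
            self.cells = self.cells.assign(
                pixels=[[(int(r), int(c))] for r, c in zip(self.cells["row"], self.cells["col"])]
            )

    def __len__(self) -> int:
        return len(self.cells)

    @property
    def ids(self) -> np.ndarray:
        return self.cells["cell_id"].to_numpy()

    @property
    def areas(self) -> np.ndarray:
        return self.cells["area_km2"].to_numpy(dtype=float)

    def to_csv(self, path: str) -> None:
        out = self.cells.drop(columns=["pixels"], errors="ignore")
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str) -> "ReefGrid":
        return cls(cells=pd.read_csv(path))
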