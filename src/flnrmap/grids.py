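"""Gridded containers: covariate stacks, trait maps and uncertain maps.

All grids are regular lat/lon rasters at half-degree resolution with cell
centers on the half-degree offsets (…, −0.25, 0.25, …), latitude indexed
south → north.  A boolean ``mask`` marks vegetated cells; every layer
carries NaN on masked-out cells.  NetCDF I/O goes through xarray
(scipy/NetCDF3 backend) with one variable per layer and CF-style ``lat`` /
``lon`` coordinate variables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional

import numpy as np
import pandas as pd
import xarray as xr

__all__ = [
    "PFT_CLASSES",
    "CATEGORICAL_PREDICTORS",
    "CovariateGrid",
    "TraitGrid",
    "UncertainMap",
]

PFT_CLASSES = ("CRO", "DBF", "EBF", "ENF", "MF", "GRA", "SH", "WET")

#: Predictors treated as a single categorical unit in ranking/selection.
CATEGORICAL_PREDICTORS = ("pft", "koeppen")

_GRID_CONVENTION = "cell centers at half-degree offsets; latitude south to north"


def _coords(ds_like):
    return {"lat": ds_like.lat, "lon": ds_like.lon}


@dataclass
class CovariateGrid:
    """Masked stack of candidate predictors plus plant-functional-type labels.

    ``layers`` maps predictor name to a (nlat, nlon) float field.  ``pft`` is
    a string field over :data:`PFT_CLASSES` (empty string off-mask); the
    ``koeppen`` layer holds small integer climate-class codes and is treated
    as categorical downstream.
    """

    lat: np.ndarray
    lon: np.ndarray
    mask: np.ndarray
    pft: np.ndarray
    layers: Dict[str, np.ndarray]

    def __post_init__(self) -> None:
        shape = (self.lat.size, self.lon.size)
        if self.mask.shape != shape or self.pft.shape != shape:
            raise ValueError("mask/pft shape does not match coordinates")
        for name, arr in self.layers.items():
            if arr.shape != shape:
                raise ValueError(f"layer {name!r} shape {arr.shape} != {shape}")

    @property
    def shape(self):
        return self.mask.shape

    @property
    def n_vegetated(self) -> int:
        return int(self.mask.sum())

    def table(self) -> pd.DataFrame:
        """Vegetated cells as a tidy table (one row per cell).

        Columns: ``cell_row``, ``cell_col``, ``lat``, ``lon``, ``pft`` and one
        column per layer.  Row order is row-major over the grid, so tables
        from co-registered grids align.
        """
        ii, jj = np.nonzero(self.mask)
        data = {
            "cell_row": ii,
            "cell_col": jj,
            "lat": self.lat[ii],
            "lon": self.lon[jj],
            "pft": self.pft[ii, jj],
        }
        for name, arr in self.layers.items():
            data[name] = arr[ii, jj]
        return pd.DataFrame(data)

    def field_from_values(self, values: np.ndarray) -> np.ndarray:
        """Scatter per-vegetated-cell values (table row order) onto the grid."""
        out = np.full(self.shape, np.nan)
        out[self.mask] = values
        return out

    def to_dataset(self) -> xr.Dataset:
        pft_codes = np.full(self.shape, -1, dtype=np.int32)
        for code, name in enumerate(PFT_CLASSES):
            pft_codes[self.pft == name] = code
        ds = xr.Dataset(
            {name: (("lat", "lon"), arr) for name, arr in self.layers.items()},
            coords={"lat": self.lat, "lon": self.lon},
        )
        ds["mask"] = (("lat", "lon"), self.mask.astype(np.int8))
        ds["pft_code"] = (("lat", "lon"), pft_codes)
        ds["pft_code"].attrs["classes"] = " ".join(PFT_CLASSES)
        ds.attrs["grid_convention"] = _GRID_CONVENTION
        ds.lat.attrs.update(units="degrees_north", standard_name="latitude")
        ds.lon.attrs.update(units="degrees_east", standard_name="longitude")
        return ds

    def to_netcdf(self, path) -> None:
        self.to_dataset().to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path) -> "CovariateGrid":
        with xr.open_dataset(path, engine="scipy") as ds:
            ds = ds.load()
        for required in ("mask", "pft_code"):
            if required not in ds:
                raise ValueError(f"covariate file missing variable {required!r}")
        mask = ds["mask"].values.astype(bool)
        codes = ds["pft_code"].values
        pft = np.full(mask.shape, "", dtype="<U3")
        for code, name in enumerate(PFT_CLASSES):
            pft[codes == code] = name
        layers = {
            name: ds[name].values
            for name in ds.data_vars
            if name not in ("mask", "pft_code")
        }
        return cls(ds.lat.values, ds.lon.values, mask, pft, layers)


@dataclass
class TraitGrid:
    """Mass-based leaf nitrogen (mg g⁻¹) and specific leaf area (m² kg⁻¹)
    with per-cell standard deviations; LNC (g m⁻²) = lncm / sla."""

    lat: np.ndarray
    lon: np.ndarray
    mask: np.ndarray
    lncm_mean: np.ndarray
    lncm_sd: np.ndarray
    sla_mean: np.ndarray
    sla_sd: np.ndarray

    def __post_init__(self) -> None:
        on = self.mask
        if np.any(self.lncm_mean[on] <= 0) or np.any(self.sla_mean[on] <= 0):
            raise ValueError("trait means must be positive on vegetated cells")
        if np.any(self.lncm_sd[on] < 0) or np.any(self.sla_sd[on] < 0):
            raise ValueError("trait sds must be non-negative")

    def lnc_mean(self) -> np.ndarray:
        """Area-based leaf nitrogen, g m⁻²: (mg g⁻¹) / (m² kg⁻¹) = g m⁻²."""
        return self.lncm_mean / self.sla_mean

    def to_netcdf(self, path) -> None:
        ds = xr.Dataset(
            {
                "lncm_mean": (("lat", "lon"), self.lncm_mean),
                "lncm_sd": (("lat", "lon"), self.lncm_sd),
                "sla_mean": (("lat", "lon"), self.sla_mean),
                "sla_sd": (("lat", "lon"), self.sla_sd),
                "mask": (("lat", "lon"), self.mask.astype(np.int8)),
            },
            coords={"lat": self.lat, "lon": self.lon},
        )
        ds["lncm_mean"].attrs["units"] = "mg g-1"
        ds["sla_mean"].attrs["units"] = "m2 kg-1"
        ds.attrs["grid_convention"] = _GRID_CONVENTION
        ds.to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path) -> "TraitGrid":
        with xr.open_dataset(path, engine="scipy") as ds:
            ds = ds.load()
        missing = [
            v
            for v in ("lncm_mean", "lncm_sd", "sla_mean", "sla_sd", "mask")
            if v not in ds
        ]
        if missing:
            raise ValueError(f"trait file missing variables: {missing}")
        return cls(
            ds.lat.values,
            ds.lon.values,
            ds["mask"].values.astype(bool),
            ds["lncm_mean"].values,
            ds["lncm_sd"].values,
            ds["sla_mean"].values,
            ds["sla_sd"].values,
        )


@dataclass
class UncertainMap:
    """Per-cell mean and standard deviation of one gridded quantity."""

    lat: np.ndarray
    lon: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    quantity: str
    units: str

    def __post_init__(self) -> None:
        if self.mean.shape != self.sd.shape:
            raise ValueError("mean and sd shapes differ")
        present = np.isfinite(self.mean)
        if np.any(self.sd[present] < -1e-12):
            raise ValueError("sd must be non-negative where mean is present")

    @property
    def mask(self) -> np.ndarray:
        return np.isfinite(self.mean)

    def to_netcdf(self, path) -> None:
        q = self.quantity
        ds = xr.Dataset(
            {
                f"{q}_mean": (("lat", "lon"), self.mean),
                f"{q}_sd": (("lat", "lon"), self.sd),
            },
            coords={"lat": self.lat, "lon": self.lon},
        )
        for v in ds.data_vars:
            ds[v].attrs["units"] = self.units
        ds.attrs["grid_convention"] = _GRID_CONVENTION
        ds.to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path, quantity: str) -> "UncertainMap":
        with xr.open_dataset(path, engine="scipy") as ds:
            ds = ds.load()
        mv, sv = f"{quantity}_mean", f"{quantity}_sd"
        for v in (mv, sv):
            if v not in ds:
                raise ValueError(f"file missing variable {v!r}")
        units = ds[mv].attrs.get("units")
        if units is None:
            warnings.warn(f"variable {mv!r} has no units attribute")
            units = ""
        return cls(ds.lat.values, ds.lon.values, ds[mv].values, ds[sv].values, quantity, units)
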