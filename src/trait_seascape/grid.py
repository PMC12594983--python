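"""Gridded seascape container: abiotic covariate fields and predicted surfaces.

A thin wrapper around an :class:`xarray.Dataset` on a regular lon/lat
grid. Quantitative covariates are float variables; the substratum factor
is stored as an integer code with the level order in variable attrs; a
boolean sea mask marks cells eligible for prediction. NetCDF I/O uses
xarray's scipy backend (classic NetCDF).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .tables import SUBSTRATUM_LEVELS

MASK_VAR = "sea_mask"
SUBSTRATUM_VAR = "Substratum"


@dataclass
class SeascapeGrid:
    """Regular lon/lat grid of abiotic covariates and prediction layers."""

    ds: xr.Dataset

    def __post_init__(self) -> None:
        if MASK_VAR not in self.ds:
            raise ValueError(f"grid needs a boolean {MASK_VAR!r} variable")
        for v in self.ds.data_vars:
            if self.ds[v].dims != self.ds[MASK_VAR].dims:
                raise ValueError(f"variable {v!r} not congruent with the grid")

    @property
    def mask(self) -> np.ndarray:
        return self.ds[MASK_VAR].to_numpy().astype(bool)

    @property
    def shape(self) -> tuple[int, int]:
        return self.ds[MASK_VAR].shape

    @property
    def feature_names(self) -> list[str]:
        skip = {MASK_VAR}
        return [v for v in self.ds.data_vars
                if v not in skip and not str(v).startswith("pred_")]

    def cell_table(self) -> pd.DataFrame:
        """Unmasked cells as a DataFrame (one row per sea cell).

        The substratum code is decoded back to its string levels; the
        index holds flat cell ids usable to scatter predictions back.
        """
        mask = self.mask
        idx = np.flatnonzero(mask.ravel())
        cols = {}
        for v in self.feature_names:
            vals = self.ds[v].to_numpy().ravel()[idx]
            if v == SUBSTRATUM_VAR:
                levels = self.ds[v].attrs.get("levels", list(SUBSTRATUM_LEVELS))
                cols[v] = pd.Categorical.from_codes(vals.astype(int), categories=levels)
            else:
                cols[v] = vals
        return pd.DataFrame(cols, index=pd.Index(idx, name="cell"))

    def with_prediction(self, name: str, values: pd.Series) -> "SeascapeGrid":
        """Scatter per-cell predictions (indexed by flat cell id) onto the grid."""
        field = np.full(self.mask.size, np.nan)
        field[np.asarray(values.index, dtype=int)] = values.to_numpy(dtype=float)
        field = field.reshape(self.shape)
        field[~self.mask] = np.nan
        ds = self.ds.assign({f"pred_{name}": (self.ds[MASK_VAR].dims, field)})
        return SeascapeGrid(ds)

    def prediction(self, name: str) -> np.ndarray:
        return self.ds[f"pred_{name}"].to_numpy()

    def to_netcdf(self, path) -> None:
        ds = self.ds.copy()
        ds[MASK_VAR] = ds[MASK_VAR].astype(np.int8)
        if SUBSTRATUM_VAR in ds:
            # classic-NetCDF attributes cannot hold string lists
            levels = ds[SUBSTRATUM_VAR].attrs.get("levels", list(SUBSTRATUM_LEVELS))
            ds[SUBSTRATUM_VAR].attrs["levels"] = "|".join(levels)
        ds.to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path) -> "SeascapeGrid":
        ds = xr.load_dataset(path, engine="scipy")
        ds[MASK_VAR] = ds[MASK_VAR].astype(bool)
        if SUBSTRATUM_VAR in ds:
            levels = ds[SUBSTRATUM_VAR].attrs.get("levels")
            if isinstance(levels, str):
                ds[SUBSTRATUM_VAR].attrs["levels"] = levels.split("|")
        return cls(ds)
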