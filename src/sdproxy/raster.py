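"""Gridded covariate stacks and TIFF-based raster I/O.

All grids live on one shared geotransform: north-up, row-major, row 0 is
the northernmost row, pixel-center registration, half-open pixel
intervals.  Static layers (terrain, 30-year climatologies, soil texture,
land cover, lithology) are stored once; dynamic layers (5-year
precipitation/temperature, NDVI, NDTI) are stored per year.

Rasters are written as one TIFF per layer(-year) with a JSON sidecar
(``stack_meta.json``) carrying the geotransform, nodata convention and
categorical legends; reads reproduce values bit-exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "GridSpec",
    "CovariateStack",
    "STATIC_LAYERS",
    "DYNAMIC_LAYERS",
    "CATEGORICAL_LAYERS",
    "PREDICTORS",
    "write_stack",
    "read_stack",
    "write_grid",
    "read_grid",
    "resample_nearest",
]

STATIC_LAYERS = (
    "DEM",
    "PRCP30",
    "TEMP30",
    "clay",
    "sand",
    "silt",
    "coarse",
    "landcover",
    "lithology",
)
DYNAMIC_LAYERS = ("PRCP5", "TEMP5", "NDVI", "NDTI")
CATEGORICAL_LAYERS = ("landcover", "lithology")

#: model predictor set (erosion is a response ingredient, never a predictor)
PREDICTORS = (
    "DEM",
    "PRCP30",
    "PRCP5",
    "TEMP30",
    "TEMP5",
    "NDVI",
    "NDTI",
    "coarse",
    "clay",
    "sand",
    "silt",
    "lithology",
    "landcover",
)


@dataclass(frozen=True)
class GridSpec:
    """North-up grid geometry: origin is the outer corner of pixel (0, 0)."""

    origin_x: float
    origin_y: float
    pixel_size: float
    nrows: int
    ncols: int

    def pixel_center(self, row, col):
        x = self.origin_x + (np.asarray(col) + 0.5) * self.pixel_size
        y = self.origin_y - (np.asarray(row) + 0.5) * self.pixel_size
        return x, y

    def pixel_of(self, x, y):
        """Containing pixel under half-open intervals; row 0 northernmost."""
        col = np.floor((np.asarray(x) - self.origin_x) / self.pixel_size).astype(int)
        row = np.floor((self.origin_y - np.asarray(y)) / self.pixel_size).astype(int)
        return row, col

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    def to_dict(self) -> dict:
        return {
            "origin_x": self.origin_x,
            "origin_y": self.origin_y,
            "pixel_size": self.pixel_size,
            "nrows": self.nrows,
            "ncols": self.ncols,
        }


class CovariateStack:
    """Per-year predictor grids on a shared :class:`GridSpec`.

    ``static`` maps layer name → 2-D array; ``dynamic`` maps layer name →
    {year → 2-D array}.  ``valid`` is the boolean nodata mask (True =
    data).  Categorical layers are integer-coded with label legends in
    ``legends``.
    """

    def __init__(
        self,
        grid: GridSpec,
        years: Iterable[int],
        static: Mapping[str, np.ndarray],
        dynamic: Mapping[str, Mapping[int, np.ndarray]],
        valid: np.ndarray,
        legends: Mapping[str, Mapping[str, int]] | None = None,
    ):
        self.grid = grid
        self.years = list(int(y) for y in years)
        self.static = dict(static)
        self.dynamic = {k: dict(v) for k, v in dynamic.items()}
        self.valid = np.asarray(valid, dtype=bool)
        self.legends = {k: dict(v) for k, v in (legends or {}).items()}
        for name, arr in self.static.items():
            if arr.shape != grid.shape:
                raise ValueError(f"static layer {name} shape {arr.shape} != grid {grid.shape}")
        for name, per_year in self.dynamic.items():
            for year, arr in per_year.items():
                if arr.shape != grid.shape:
                    raise ValueError(f"{name}[{year}] shape {arr.shape} != grid {grid.shape}")
        if self.valid.shape != grid.shape:
            raise ValueError("valid mask shape mismatch")

    def layer(self, name: str, year: int | None = None) -> np.ndarray:
        if name in self.static:
            return self.static[name]
        if name in self.dynamic:
            if year is None:
                raise KeyError(f"layer {name} is dynamic; a year is required")
            try:
                return self.dynamic[name][int(year)]
            except KeyError:
                raise KeyError(f"missing layer-year: {name}/{year}") from None
        raise KeyError(f"unknown layer {name!r}")

    def check_years(self, years: Iterable[int]) -> None:
        gaps = [
            f"{name}/{y}"
            for y in years
            for name in self.dynamic
            if int(y) not in self.dynamic[name]
        ]
        if gaps:
            raise KeyError(f"stack is missing layer-years: {gaps}")

    def features_frame(self, year: int, predictors: Iterable[str] = PREDICTORS) -> pd.DataFrame:
        """Per-valid-pixel predictor table for one year (row-major order).

        Categorical layers are returned as labels so the frame matches
        the survey-table schema.
        """
        rows, cols = np.nonzero(self.valid)
        data = {}
        for name in predictors:
            arr = self.layer(name, year)[rows, cols]
            if name in self.legends:
                inv = {v: k for k, v in self.legends[name].items()}
                arr = np.asarray([inv[int(v)] for v in arr], dtype=object)
            data[name] = arr
        frame = pd.DataFrame(data)
        frame["row"], frame["col"] = rows, cols
        return frame

    def sample_at(self, name: str, year: int | None, rows, cols) -> np.ndarray:
        return self.layer(name, year)[np.asarray(rows), np.asarray(cols)]


# ----------------------------------------------------------------------
# TIFF I/O

_NODATA_FLOAT = float("nan")


def write_grid(path: Path, arr: np.ndarray, valid: np.ndarray | None = None) -> Path:
    """Write one grid as TIFF; invalid pixels become NaN (float) or -9999 (int)."""
    path = Path(path)
    out = np.asarray(arr)
    if valid is not None:
        if np.issubdtype(out.dtype, np.floating):
            out = np.where(valid, out, _NODATA_FLOAT)
        else:
            out = np.where(valid, out, -9999).astype(np.int32)
    tifffile.imwrite(path, out)
    return path


def read_grid(path: Path) -> np.ndarray:
    return tifffile.imread(Path(path))


def write_stack(stack: CovariateStack, directory: Path) -> dict:
    """Write a stack as one TIFF per layer(-year) plus a JSON sidecar.

    Returns a manifest mapping layer keys to file paths; a subsequent
    :func:`read_stack` reproduces every value exactly.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    for name, arr in sorted(stack.static.items()):
        p = directory / f"{name}.tif"
        write_grid(p, arr, stack.valid)
        paths[name] = p.name
    for name in sorted(stack.dynamic):
        for year in sorted(stack.dynamic[name]):
            p = directory / f"{name}_{year}.tif"
            write_grid(p, stack.dynamic[name][year], stack.valid)
            paths[f"{name}_{year}"] = p.name
    mask_path = directory / "valid_mask.tif"
    tifffile.imwrite(mask_path, stack.valid.astype(np.uint8))
    meta = {
        "grid": stack.grid.to_dict(),
        "years": stack.years,
        "static": sorted(stack.static),
        "dynamic": sorted(stack.dynamic),
        "legends": stack.legends,
        "nodata": {"float": "nan", "int": -9999},
        "files": paths,
    }
    (directory / "stack_meta.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
    return meta


def read_stack(directory: Path) -> CovariateStack:
    directory = Path(directory)
    meta = json.loads((directory / "stack_meta.json").read_text())
    grid = GridSpec(**meta["grid"])
    valid = tifffile.imread(directory / "valid_mask.tif").astype(bool)
    static = {name: tifffile.imread(directory / f"{name}.tif") for name in meta["static"]}
    dynamic = {
        name: {
            int(y): tifffile.imread(directory / f"{name}_{y}.tif") for y in meta["years"]
        }
        for name in meta["dynamic"]
    }
    legends = {k: {lbl: int(code) for lbl, code in v.items()} for k, v in meta["legends"].items()}
    return CovariateStack(grid, meta["years"], static, dynamic, valid, legends)


def resample_nearest(arr: np.ndarray, out_shape: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbor resampling convenience for user rasters on other grids."""
    nr, nc = arr.shape
    orows = (np.arange(out_shape[0]) + 0.5) * nr / out_shape[0]
    ocols = (np.arange(out_shape[1]) + 0.5) * nc / out_shape[1]
    ri = np.clip(orows.astype(int), 0, nr - 1)
    ci = np.clip(ocols.astype(int), 0, nc - 1)
    return arr[np.ix_(ri, ci)]
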