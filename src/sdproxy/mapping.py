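"""Annual SDP map prediction with ensemble percentile uncertainty.

Each ensemble member predicts every valid pixel for every requested
year; the pixel value of the SDP map is the member mean (clipped to
[0, 1] upstream) and the uncertainty map is the difference between the
95th and 5th percentiles of the member predictions (linear interpolation
between closest ranks).  Nodata propagates: a pixel invalid in any
predictor layer is invalid in every product.

Prediction can be tiled to bound memory; results are bit-identical for
any tile size because members predict row-wise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .ensemble import SdpEnsemble
from .raster import CovariateStack, write_grid

__all__ = ["SdpRasterSet", "predict_annual_maps", "uncertainty_map", "write_raster_set"]


@dataclass
class SdpRasterSet:
    years: list[int]
    sdp: dict[int, np.ndarray]  # ensemble-mean SDP per year (NaN outside mask)
    uncertainty: dict[int, np.ndarray]  # p95 - p5 member spread per year
    valid: np.ndarray


def uncertainty_map(member_predictions: np.ndarray, axis: int = -1) -> np.ndarray:
    """p95 − p5 of member predictions along ``axis``.

    Percentiles use linear interpolation between closest ranks; a single
    member yields an all-zero map with a warning.
    """
    m = np.asarray(member_predictions, dtype=float)
    if m.shape[axis] < 2:
        warnings.warn("single ensemble member: uncertainty is identically zero")
        return np.zeros(np.delete(np.array(m.shape), axis))
    p5, p95 = np.percentile(m, [5.0, 95.0], axis=axis)
    return p95 - p5


def predict_annual_maps(
    ensemble: SdpEnsemble,
    stack: CovariateStack,
    years: list[int] | None = None,
    tile_rows: int | None = None,
) -> SdpRasterSet:
    """Apply the ensemble to the covariate stack for each year.

    SDP is predicted directly from covariates (erosion is an ingredient
    of the training response, never a predictor).  ``tile_rows`` bounds
    how many pixels are predicted per batch; the output is independent
    of the tiling.
    """
    years = list(stack.years if years is None else map(int, years))
    stack.check_years(years)
    rows, cols = np.nonzero(stack.valid)
    sdp_grids: dict[int, np.ndarray] = {}
    unc_grids: dict[int, np.ndarray] = {}
    for year in years:
        feats = stack.features_frame(year, ensemble.config.predictors)
        n = len(feats)
        mean = np.empty(n)
        width = np.empty(n)
        step = n if not tile_rows else max(1, int(tile_rows))
        for start in range(0, n, step):
            chunk = feats.iloc[start : start + step]
            members = ensemble.predict_members(chunk)
            mean[start : start + step] = members.mean(axis=1)
            if members.shape[1] < 2:
                width[start : start + step] = 0.0
            else:
                width[start : start + step] = uncertainty_map(members, axis=1)
        sdp = np.full(stack.grid.shape, np.nan)
        unc = np.full(stack.grid.shape, np.nan)
        sdp[rows, cols] = mean
        unc[rows, cols] = width
        sdp_grids[year], unc_grids[year] = sdp, unc
    if ensemble.n_models < 2:
        warnings.warn("single ensemble member: uncertainty maps are identically zero")
    return SdpRasterSet(years, sdp_grids, unc_grids, stack.valid.copy())


def write_raster_set(raster_set: SdpRasterSet, directory: Path) -> dict[str, str]:
    """One TIFF per year per product (sdp_YYYY.tif, uncertainty_YYYY.tif)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for year in raster_set.years:
        p = directory / f"sdp_{year}.tif"
        write_grid(p, raster_set.sdp[year], raster_set.valid)
        paths[f"sdp_{year}"] = str(p)
        q = directory / f"uncertainty_{year}.tif"
        write_grid(q, raster_set.uncertainty[year], raster_set.valid)
        paths[f"uncertainty_{year}"] = str(q)
    return paths
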