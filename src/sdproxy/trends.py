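"""Per-pixel OLS trend detection and classification on annual SDP stacks.

For every pixel the SDP time series is regressed on calendar year by
ordinary least squares (so slopes are in SDP units per year); the
two-sided p-value of the slope comes from the t statistic with n − 2
degrees of freedom.  Significant slopes (p < 0.01 by default) are
classified by magnitude:

* negligible/masked: p ≥ α or |slope| ≤ 0.001
* moderate (signed): 0.001 < |slope| ≤ 0.003
* strong (signed):   |slope| > 0.003

The boundary slopes fall as documented: exactly 0.001 is negligible,
exactly 0.003 is moderate.  No multiple-testing correction is applied
across pixels by default (per-pixel rule); an optional
Benjamini–Hochberg FDR flag is available.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TrendRaster",
    "CATEGORY_NAMES",
    "pixel_trend",
    "classify_trend",
    "trend_stack",
    "trend_area_summary",
    "write_trend_raster",
]

#: category codes (byte band values) and names
CATEGORY_NAMES = {
    0: "not_significant_or_negligible",
    1: "moderate_decrease",
    2: "strong_decrease",
    3: "moderate_increase",
    4: "strong_increase",
}
_NODATA_CODE = 255

DEFAULT_ALPHA = 0.01
DEFAULT_T_MOD = 0.001
DEFAULT_T_STRONG = 0.003


def _ols_slope_p(t: np.ndarray, y: np.ndarray):
    """Closed-form OLS slope and two-sided p (vector y allowed as columns)."""
    n = t.size
    tc = t - t.mean()
    sxx = np.sum(tc**2)
    slope = (tc @ y) / sxx
    intercept = y.mean(axis=0) - slope * t.mean()
    resid = y - (np.outer(t, np.atleast_1d(slope)) + intercept)
    sse = np.sum(np.asarray(resid) ** 2, axis=0)
    dof = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(sse / dof / sxx)
        tstat = np.where(se > 0, slope / np.where(se > 0, se, 1.0), np.inf)
    p = 2.0 * stats.t.sf(np.abs(tstat), dof)
    p = np.where(se > 0, p, 0.0)  # zero residual variance: degenerate, p = 0
    return slope, p


def pixel_trend(values, years) -> tuple[float, float]:
    """OLS slope (per calendar year) and two-sided p for one pixel series.

    Missing values are dropped; fewer than 3 remaining pairs raises.  A
    perfectly linear series (zero residual variance) reports p = 0.
    """
    y = np.asarray(values, dtype=float)
    t = np.asarray(years, dtype=float)
    ok = np.isfinite(y) & np.isfinite(t)
    y, t = y[ok], t[ok]
    if y.size < 3:
        raise ValueError(f"need >= 3 (year, value) pairs, got {y.size}")
    slope, p = _ols_slope_p(t, y[:, None])
    return float(slope[0]), float(p[0])


def classify_trend(
    slope,
    p,
    alpha: float = DEFAULT_ALPHA,
    t_mod: float = DEFAULT_T_MOD,
    t_strong: float = DEFAULT_T_STRONG,
):
    """Categorize slopes: masked if p ≥ alpha or |slope| ≤ t_mod, else
    moderate on (t_mod, t_strong] and strong above t_strong, signed."""
    slope = np.asarray(slope, dtype=float)
    p = np.asarray(p, dtype=float)
    mag = np.abs(slope)
    code = np.zeros(slope.shape, dtype=np.uint8)
    sig = p < alpha
    moderate = sig & (mag > t_mod) & (mag <= t_strong)
    strong = sig & (mag > t_strong)
    code[moderate & (slope > 0)] = 3
    code[moderate & (slope < 0)] = 1
    code[strong & (slope > 0)] = 4
    code[strong & (slope < 0)] = 2
    if code.ndim == 0:
        return CATEGORY_NAMES[int(code)]
    return code


@dataclass
class TrendRaster:
    slope: np.ndarray  # SDP units per year
    p_value: np.ndarray
    category: np.ndarray  # uint8 codes per CATEGORY_NAMES, 255 = nodata
    valid: np.ndarray
    alpha: float = DEFAULT_ALPHA
    t_mod: float = DEFAULT_T_MOD
    t_strong: float = DEFAULT_T_STRONG


def trend_stack(
    sdp_by_year: dict[int, np.ndarray],
    valid: np.ndarray | None = None,
    alpha: float = DEFAULT_ALPHA,
    t_mod: float = DEFAULT_T_MOD,
    t_strong: float = DEFAULT_T_STRONG,
    fdr: bool = False,
) -> TrendRaster:
    """Vectorized per-pixel trend over an annual SDP raster dictionary.

    Pixels must share a grid; nodata (NaN in every year, or outside
    ``valid``) propagates.  With ``fdr=True`` the per-pixel p-values are
    Benjamini–Hochberg adjusted before classification.
    """
    years = np.array(sorted(sdp_by_year), dtype=float)
    if years.size < 3:
        raise ValueError("need at least 3 years for a trend")
    grids = [np.asarray(sdp_by_year[int(y)], dtype=float) for y in years]
    shape = grids[0].shape
    if any(g.shape != shape for g in grids):
        raise ValueError("misaligned grids in the annual stack")
    if valid is not None and valid.shape != shape:
        raise ValueError("valid mask misaligned with the annual stack")
    Y = np.stack(grids)  # (T, rows, cols)
    n_finite = np.isfinite(Y).sum(axis=0)
    complete = n_finite == years.size
    partial = (~complete) & (n_finite >= 3)  # missing years allowed if >= 3 pairs
    mask = (complete | partial) if valid is None else ((complete | partial) & valid)

    slope = np.full(shape, np.nan)
    p = np.full(shape, np.nan)
    crows, ccols = np.nonzero(complete if valid is None else (complete & valid))
    if crows.size:
        s, pv = _ols_slope_p(years, Y[:, crows, ccols])
        slope[crows, ccols] = s
        p[crows, ccols] = pv
    for r, c in zip(*np.nonzero(partial if valid is None else (partial & valid))):
        slope[r, c], p[r, c] = pixel_trend(Y[:, r, c], years)
    rows, cols = np.nonzero(mask)
    if fdr and rows.size:
        pv = p[rows, cols]
        order = np.argsort(pv)
        ranked = pv[order] * pv.size / (np.arange(pv.size) + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty_like(pv)
        out[order] = np.minimum(adj, 1.0)
        p[rows, cols] = out

    category = np.full(shape, _NODATA_CODE, dtype=np.uint8)
    category[rows, cols] = classify_trend(
        slope[rows, cols], p[rows, cols], alpha, t_mod, t_strong
    )
    return TrendRaster(slope, p, category, mask, alpha, t_mod, t_strong)


def trend_area_summary(
    trend: TrendRaster,
    landcover: np.ndarray,
    legend: dict[str, int],
) -> pd.DataFrame:
    """Fraction of each land-cover class's valid pixels in each category.

    Fractions sum to 1 within each class; empty classes are omitted.
    """
    if landcover.shape != trend.category.shape:
        raise ValueError("landcover grid misaligned with trend raster")
    rows = []
    for label, code in sorted(legend.items()):
        sel = (landcover == code) & trend.valid
        total = int(sel.sum())
        if total == 0:
            continue
        row = {"landcover": label, "n_pixels": total}
        for cat_code, cat_name in CATEGORY_NAMES.items():
            row[cat_name] = float(np.sum(trend.category[sel] == cat_code) / total)
        rows.append(row)
    return pd.DataFrame(rows)


def write_trend_raster(trend: TrendRaster, directory: Path) -> dict[str, str]:
    """Slope/p/category TIFFs plus a JSON legend sidecar."""
    from .raster import write_grid  # local import to avoid cycle at module load

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, arr in (("trend_slope", trend.slope), ("trend_p", trend.p_value)):
        p = directory / f"{name}.tif"
        write_grid(p, arr, trend.valid)
        paths[name] = str(p)
    import tifffile

    cat_path = directory / "trend_category.tif"
    tifffile.imwrite(cat_path, trend.category)
    paths["trend_category"] = str(cat_path)
    legend = {
        "categories": {str(k): v for k, v in CATEGORY_NAMES.items()},
        "nodata": _NODATA_CODE,
        "alpha": trend.alpha,
        "t_mod": trend.t_mod,
        "t_strong": trend.t_strong,
    }
    leg_path = directory / "trend_legend.json"
    leg_path.write_text(json.dumps(legend, indent=1, sort_keys=True))
    paths["trend_legend"] = str(leg_path)
    return paths
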