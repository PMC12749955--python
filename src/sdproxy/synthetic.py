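"""Seeded synthetic survey and covariate-grid generator.

Emulates a LUCAS-like topsoil point survey (two survey years) and the
annual covariate grids needed for map prediction and trend analysis,
with a known generative link so parameter recovery is testable:

* covariates are spatially autocorrelated fields (seeded white noise
  convolved with a Gaussian kernel) plus latitudinal gradients for the
  climate layers; dynamic layers drift around their 30-year baselines;
* a latent degradation field L is a linear combination of standardized
  covariates plus a land-cover offset and Gaussian noise of scale
  ``noise_sd``;
* erosion and EC increase with L (lognormal links), SOC decreases with
  L (lognormal), and pH departs from 6.5 with a magnitude that grows
  with L — so the inverse-optimum rescaling rule is exercised;
* the per-row latent L is stored in the table for recovery tests.

Erosion is generated once per pixel from a reference-year latent field
and held constant across survey years, mirroring the treatment of
modelled erosion rates as static between surveys.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .raster import (
    CATEGORICAL_LAYERS,
    DYNAMIC_LAYERS,
    STATIC_LAYERS,
    CovariateStack,
    GridSpec,
    write_stack,
)

__all__ = ["SyntheticConfig", "generate_covariate_grids", "generate_survey", "write_fixture"]

LANDCOVER_CLASSES = ("cropland", "forest", "grassland", "other")
#: class shares used to threshold the smooth land-cover field
LANDCOVER_SHARES = (0.40, 0.30, 0.20, 0.10)
N_LITHOLOGY_CLASSES = 5

DEFAULT_EFFECT_SIZES = {
    "TEMP30": 0.50,
    "PRCP30": -0.35,
    "NDVI": -0.30,
    "clay": 0.20,
    "DEM": 0.15,
    "TEMP5": 0.10,
    "PRCP5": -0.10,
    "NDTI": 0.10,
    "sand": -0.10,
    "coarse": 0.10,
}

DEFAULT_LANDCOVER_OFFSETS = {
    "cropland": 0.30,
    "forest": -0.30,
    "grassland": 0.00,
    "other": 0.10,
}


@dataclass
class SyntheticConfig:
    """Conditions of the synthetic study.

    ``noise_sd`` is the standard deviation of the Gaussian noise added to
    the latent degradation field (the indicator links themselves are
    deterministic given L, apart from the random side of the pH
    departure).  ``effect_sizes`` are the coefficients of the generative
    link on standardized covariates; ``landcover_offsets`` shift the
    latent field per class, with cropland more degraded than forest by
    default.  ``temperature_gradient`` is the north→south TEMP30 increase
    (°C) across the grid (poleward cooling when positive).
    """

    grid_rows: int = 64
    grid_cols: int = 64
    years: tuple[int, ...] = tuple(range(2000, 2023))
    n_points_per_year: int = 2500
    survey_years: tuple[int, ...] = (2015, 2018)
    seed: int = 0
    noise_sd: float = 0.1
    effect_sizes: dict = field(default_factory=lambda: dict(DEFAULT_EFFECT_SIZES))
    landcover_offsets: dict = field(default_factory=lambda: dict(DEFAULT_LANDCOVER_OFFSETS))
    temperature_gradient: float = 8.0
    smooth_sigma: float = 6.0
    nodata_fraction: float = 0.02

    def __post_init__(self) -> None:
        self.years = tuple(int(y) for y in self.years)
        self.survey_years = tuple(int(y) for y in self.survey_years)
        if self.grid_rows < 8 or self.grid_cols < 8:
            raise ValueError("grid must be at least 8x8")
        if self.n_points_per_year < 50:
            raise ValueError("n_points_per_year must be >= 50")
        if list(self.years) != list(range(min(self.years), max(self.years) + 1)):
            raise ValueError("years must be contiguous")
        if not set(self.survey_years) <= set(self.years):
            raise ValueError("survey_years must be a subset of years")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def to_dict(self) -> dict:
        return {
            "grid_rows": self.grid_rows,
            "grid_cols": self.grid_cols,
            "years": list(self.years),
            "n_points_per_year": self.n_points_per_year,
            "survey_years": list(self.survey_years),
            "seed": self.seed,
            "noise_sd": self.noise_sd,
            "effect_sizes": self.effect_sizes,
            "landcover_offsets": self.landcover_offsets,
            "temperature_gradient": self.temperature_gradient,
            "smooth_sigma": self.smooth_sigma,
            "nodata_fraction": self.nodata_fraction,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        d["years"] = tuple(d.get("years", range(2000, 2023)))
        d["survey_years"] = tuple(d.get("survey_years", (2015, 2018)))
        return cls(**d)


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Standardized spatially autocorrelated field (unit variance)."""
    z = gaussian_filter(rng.standard_normal(shape), sigma, mode="reflect")
    sd = z.std()
    return (z - z.mean()) / (sd if sd > 0 else 1.0)


def generate_covariate_grids(config: SyntheticConfig) -> CovariateStack:
    """Build the static and annual covariate grids for one seed."""
    rng = np.random.default_rng([config.seed, 101])
    shape = (config.grid_rows, config.grid_cols)
    sig = config.smooth_sigma
    # north-south coordinate: -0.5 at row 0 (north) to +0.5 at the southern edge
    ns = np.linspace(-0.5, 0.5, config.grid_rows)[:, None] * np.ones((1, config.grid_cols))

    static: dict[str, np.ndarray] = {}
    static["DEM"] = np.clip(300.0 + 350.0 * _smooth_field(rng, shape, sig), 0.0, None)
    static["TEMP30"] = 9.0 + config.temperature_gradient * ns + 2.5 * _smooth_field(rng, shape, sig)
    static["PRCP30"] = np.clip(
        750.0 - 180.0 * ns + 220.0 * _smooth_field(rng, shape, sig), 50.0, None
    )
    # texture: softmax of three smooth fields; silt closes the simplex exactly
    a = np.stack([_smooth_field(rng, shape, sig) for _ in range(3)])
    e = np.exp(a - a.max(axis=0))
    frac = e / e.sum(axis=0)
    static["clay"] = 100.0 * frac[0]
    static["sand"] = 100.0 * frac[1]
    static["silt"] = 100.0 - static["clay"] - static["sand"]
    static["coarse"] = np.clip(12.0 + 8.0 * _smooth_field(rng, shape, sig), 0.0, 60.0)

    lc_field = _smooth_field(rng, shape, sig)
    edges = np.quantile(lc_field, np.cumsum(LANDCOVER_SHARES)[:-1])
    static["landcover"] = (np.searchsorted(edges, lc_field, side="right") + 1).astype(np.int32)
    lith_field = _smooth_field(rng, shape, sig)
    lith_edges = np.quantile(lith_field, np.linspace(0, 1, N_LITHOLOGY_CLASSES + 1)[1:-1])
    static["lithology"] = (np.searchsorted(lith_edges, lith_field, side="right") + 1).astype(
        np.int32
    )

    ndvi_base = np.clip(0.45 + 0.25 * _smooth_field(rng, shape, sig), -1.0, 1.0)
    ndti_base = np.clip(0.15 + 0.10 * _smooth_field(rng, shape, sig), -1.0, 1.0)

    dynamic: dict[str, dict[int, np.ndarray]] = {name: {} for name in DYNAMIC_LAYERS}
    y0 = min(config.years)
    for year in config.years:
        yr_rng = np.random.default_rng([config.seed, 202, year])
        drift = 0.015 * (year - y0)
        dynamic["PRCP5"][year] = np.clip(
            static["PRCP30"] * (1.0 + 0.08 * _smooth_field(yr_rng, shape, sig) - 0.2 * drift / 3.0),
            10.0,
            None,
        )
        dynamic["TEMP5"][year] = (
            static["TEMP30"] + 0.6 * _smooth_field(yr_rng, shape, sig) + 0.03 * (year - y0)
        )
        dynamic["NDVI"][year] = np.clip(
            ndvi_base + 0.05 * _smooth_field(yr_rng, shape, sig) - 0.05 * drift, -1.0, 1.0
        )
        dynamic["NDTI"][year] = np.clip(
            ndti_base + 0.04 * _smooth_field(yr_rng, shape, sig) + 0.03 * drift, -1.0, 1.0
        )

    # small contiguous nodata blob (e.g. open water) to exercise propagation
    valid = np.ones(shape, dtype=bool)
    if config.nodata_fraction > 0:
        blob = _smooth_field(np.random.default_rng([config.seed, 303]), shape, sig)
        valid = blob > np.quantile(blob, config.nodata_fraction)

    grid = GridSpec(origin_x=10.0, origin_y=55.0, pixel_size=0.01, nrows=shape[0], ncols=shape[1])
    legends = {
        "landcover": {name: i + 1 for i, name in enumerate(LANDCOVER_CLASSES)},
        "lithology": {f"litho_{i + 1}": i + 1 for i in range(N_LITHOLOGY_CLASSES)},
    }
    return CovariateStack(grid, config.years, static, dynamic, valid, legends)


def _latent_field(stack: CovariateStack, config: SyntheticConfig, year: int) -> np.ndarray:
    """Deterministic latent degradation field L(pixel; year), no noise."""
    L = np.zeros(stack.grid.shape)
    for name, coef in config.effect_sizes.items():
        arr = stack.layer(name, year).astype(float)
        vals = arr[stack.valid]
        sd = vals.std()
        L += coef * (arr - vals.mean()) / (sd if sd > 0 else 1.0)
    lc = stack.static["landcover"]
    for label, code in stack.legends["landcover"].items():
        L += np.where(lc == code, config.landcover_offsets.get(label, 0.0), 0.0)
    return L


def _indicators_from_latent(L: np.ndarray, ph_sign: np.ndarray) -> dict[str, np.ndarray]:
    """Map latent degradation to the four raw indicators.

    Lognormal links keep erosion (t ha⁻¹ yr⁻¹), EC (dS m⁻¹) and SOC
    (g kg⁻¹) positive and realistically skewed; the pH departure from
    6.5 grows with L through a logistic ramp, its side given by
    ``ph_sign`` (±1).
    """
    return {
        "erosion_rate": np.exp(0.2 + 0.8 * L),
        "ec": np.exp(-1.6 + 0.6 * L),
        "soc": np.exp(3.0 - 0.7 * L),
        "ph": np.clip(6.5 + ph_sign * (0.3 + 1.6 * expit(1.5 * L)), 3.0, 11.0),
    }


def generate_survey(stack: CovariateStack, config: SyntheticConfig) -> pd.DataFrame:
    """Sample point records from the stack for each survey year.

    Points are drawn uniformly without replacement over valid pixels;
    covariate columns equal the stack values at the containing pixel for
    the row's year.  The per-row latent ``latent_l`` is retained so
    downstream recovery can be checked against ground truth.
    """
    stack.check_years(config.survey_years)
    valid_idx = np.flatnonzero(stack.valid)
    if config.n_points_per_year > valid_idx.size:
        raise ValueError(
            f"n_points_per_year={config.n_points_per_year} exceeds "
            f"{valid_idx.size} available valid pixels"
        )
    ref_year = config.survey_years[0]
    noise_rng = np.random.default_rng([config.seed, 404])
    # static per-pixel erosion: reference-year latent + pixel noise, constant across surveys
    L_ref = _latent_field(stack, config, ref_year)
    L_ref_noisy = L_ref + config.noise_sd * noise_rng.standard_normal(stack.grid.shape)
    erosion_grid = np.exp(0.2 + 0.8 * L_ref_noisy)

    inv_legend = {
        name: {v: k for k, v in legend.items()} for name, legend in stack.legends.items()
    }
    frames = []
    for year in config.survey_years:
        rng = np.random.default_rng([config.seed, 505, year])
        flat = rng.choice(valid_idx, size=config.n_points_per_year, replace=False)
        rows, cols = np.unravel_index(flat, stack.grid.shape)
        L_det = _latent_field(stack, config, year)[rows, cols]
        L = L_det + config.noise_sd * rng.standard_normal(L_det.size)
        ph_sign = rng.choice([-1.0, 1.0], size=L.size)
        ind = _indicators_from_latent(L, ph_sign)
        ind["erosion_rate"] = erosion_grid[rows, cols]
        x, y = stack.grid.pixel_center(rows, cols)
        rec = {
            "lon": x,
            "lat": y,
            "row": rows,
            "col": cols,
            "year": year,
            **ind,
            "latent_l": L,
        }
        for name in set(STATIC_LAYERS) | set(DYNAMIC_LAYERS):
            vals = stack.sample_at(name, year, rows, cols)
            if name in inv_legend:
                vals = np.asarray([inv_legend[name][int(v)] for v in vals], dtype=object)
            rec[name] = vals
        frames.append(pd.DataFrame(rec))
    table = pd.concat(frames, ignore_index=True)
    table.insert(0, "id", np.arange(len(table)))
    return table


def write_fixture(stack: CovariateStack, table: pd.DataFrame, directory: Path, config: SyntheticConfig | None = None) -> dict:
    """Persist a generated stack + survey + config snapshot to a directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = write_stack(stack, directory / "stack")
    csv_path = directory / "survey.csv"
    table.to_csv(csv_path, index=False)
    paths = {"stack": str(directory / "stack"), "survey": str(csv_path)}
    if config is not None:
        cfg_path = directory / "synthetic_config.json"
        cfg_path.write_text(json.dumps(config.to_dict(), indent=1, sort_keys=True))
        paths["config"] = str(cfg_path)
    return {"paths": paths, "stack_meta": meta}
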