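"""Survey-table CSV I/O with schema and unit sanity checks."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .raster import PREDICTORS
from .rescale import INDICATOR_COLUMNS

logger = logging.getLogger(__name__)

__all__ = ["SurveyReport", "read_survey_csv", "write_survey_csv", "validate_survey"]

REQUIRED_COLUMNS = ("id", "lon", "lat", "year") + INDICATOR_COLUMNS + PREDICTORS

PH_RANGE = (3.0, 11.0)
TEXTURE_TOL = 0.5  # clay + sand + silt must sum to 100 within this


@dataclass
class SurveyReport:
    n_read: int = 0
    n_kept: int = 0
    rejected: dict = field(default_factory=dict)  # reason -> count

    def reject(self, reason: str, count: int) -> None:
        if count:
            self.rejected[reason] = self.rejected.get(reason, 0) + int(count)


def validate_survey(table: pd.DataFrame) -> tuple[pd.DataFrame, SurveyReport]:
    """Drop rows violating indicator presence or unit sanity; report counts.

    Checks: no missing indicator, erosion/EC/SOC non-negative, pH within
    [3, 11], texture fractions summing to 100 (±0.5).
    """
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing_cols:
        raise ValueError(f"survey table is missing required columns: {missing_cols}")
    report = SurveyReport(n_read=len(table))
    keep = np.ones(len(table), dtype=bool)

    has_nan = table[list(INDICATOR_COLUMNS)].isna().any(axis=1).to_numpy()
    report.reject("missing_indicator", (keep & has_nan).sum())
    keep &= ~has_nan

    for col in ("erosion_rate", "ec", "soc"):
        bad = keep & (table[col].to_numpy(dtype=float) < 0)
        report.reject(f"negative_{col}", bad.sum())
        keep &= ~bad

    ph = table["ph"].to_numpy(dtype=float)
    bad_ph = keep & ((ph < PH_RANGE[0]) | (ph > PH_RANGE[1]))
    report.reject("ph_out_of_range", bad_ph.sum())
    keep &= ~bad_ph

    tex = (
        table["clay"].to_numpy(dtype=float)
        + table["sand"].to_numpy(dtype=float)
        + table["silt"].to_numpy(dtype=float)
    )
    bad_tex = keep & (np.abs(tex - 100.0) > TEXTURE_TOL)
    report.reject("texture_sum", bad_tex.sum())
    keep &= ~bad_tex

    out = table.loc[keep].reset_index(drop=True)
    report.n_kept = len(out)
    if report.rejected:
        logger.warning("survey validation rejected rows: %s", report.rejected)
    return out, report


def read_survey_csv(path: Path) -> tuple[pd.DataFrame, SurveyReport]:
    """Read and validate a point-survey CSV (column order is irrelevant)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    table = pd.read_csv(path, float_precision="round_trip")
    return validate_survey(table)


def write_survey_csv(table: pd.DataFrame, path: Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
    return path
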