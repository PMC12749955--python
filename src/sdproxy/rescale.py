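"""Directional empirical-CDF rescaling of soil indicators and the SDP index.

The Soil Degradation Proxy (SDP) combines four soil health indicators
(SHIs): erosion rate, electrical conductivity (EC), pH and soil organic
carbon (SOC).  Each raw indicator is rescaled to [0, 1] through its
empirical cumulative distribution function, oriented so that higher SHI
always means worse soil condition:

* erosion, EC — "more is worse": SHI = F(x)
* SOC — "less is worse": SHI = 1 − F(x)
* pH — "inverse optimum" around a pivot of 6.5: SHI = F(x) above the
  pivot, 1 − F(x) below it; soil health degrades as pH departs from the
  pivot in either direction.

The ECDF convention is F(x) = (rank − 1)/(n − 1) with mean ranks for
interior ties, so the sample minimum maps to 0 and the maximum to 1
(values tied with an extreme are pinned to that endpoint); unseen
interior values are linearly interpolated and out-of-range queries clamp
to the extremes.  The SDP is the weighted mean of the four SHIs,
equal weights (0.25 each) by default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "Direction",
    "DirectionRule",
    "EcdfRescaler",
    "SdpWeights",
    "INDICATOR_COLUMNS",
    "INDICATOR_DIRECTIONS",
    "DEFAULT_PH_PIVOT",
    "fit_rescaler",
    "fit_indicator_rescalers",
    "compute_sdp",
    "build_sdp_table",
]

DEFAULT_PH_PIVOT = 6.5

#: table column for each indicator, in SDP aggregation order
INDICATOR_COLUMNS = ("erosion_rate", "ec", "ph", "soc")

#: SHI column written by :func:`build_sdp_table` for each indicator
SHI_COLUMNS = {
    "erosion_rate": "shi_er",
    "ec": "shi_ec",
    "ph": "shi_ph",
    "soc": "shi_soc",
}


class Direction(str, Enum):
    """Orientation rule linking a raw indicator to degradation."""

    MORE_IS_WORSE = "more_is_worse"
    LESS_IS_WORSE = "less_is_worse"
    INVERSE_OPTIMUM = "inverse_optimum"


@dataclass(frozen=True)
class DirectionRule:
    kind: Direction
    pivot: float | None = None

    def __post_init__(self) -> None:
        kind = Direction(self.kind)
        object.__setattr__(self, "kind", kind)
        if kind is Direction.INVERSE_OPTIMUM:
            pivot = DEFAULT_PH_PIVOT if self.pivot is None else float(self.pivot)
            if not np.isfinite(pivot):
                raise ValueError("inverse_optimum pivot must be finite")
            object.__setattr__(self, "pivot", pivot)
        elif self.pivot is not None:
            raise ValueError(f"pivot is only meaningful for inverse_optimum, got kind={kind}")


#: fixed direction per indicator
INDICATOR_DIRECTIONS: Mapping[str, DirectionRule] = {
    "erosion_rate": DirectionRule(Direction.MORE_IS_WORSE),
    "ec": DirectionRule(Direction.MORE_IS_WORSE),
    "ph": DirectionRule(Direction.INVERSE_OPTIMUM, DEFAULT_PH_PIVOT),
    "soc": DirectionRule(Direction.LESS_IS_WORSE),
}


class EcdfRescaler:
    """Empirical-CDF rescaler with a direction rule.

    Fitted on a reference sample; maps raw indicator values to SHIs in
    [0, 1].  The base ECDF assigns F = (rank − 1)/(n − 1) with mean
    ranks for ties; queries between reference values are linearly
    interpolated and queries outside the reference range clamp to
    {0, 1} before the direction rule is applied.
    """

    def __init__(self, direction: DirectionRule, name: str = ""):
        self.direction = direction
        self.name = name
        self._x: np.ndarray | None = None  # unique sorted reference values
        self._f: np.ndarray | None = None  # ECDF at self._x
        self._reference: np.ndarray | None = None  # full sorted sample

    @property
    def is_fitted(self) -> bool:
        return self._x is not None

    def fit(self, values) -> "EcdfRescaler":
        values = np.asarray(values, dtype=float).ravel()
        if values.size < 2:
            raise ValueError(f"{self.name or 'rescaler'}: need at least 2 reference values")
        if np.isnan(values).any():
            raise ValueError(f"{self.name or 'rescaler'}: NaN in reference sample")
        if not np.isfinite(values).all():
            raise ValueError(f"{self.name or 'rescaler'}: non-finite reference values")
        if np.unique(values).size < 2:
            raise ValueError(
                f"{self.name or 'rescaler'}: degenerate distribution (all values identical)"
            )
        ranks = rankdata(values, method="average")
        f = (ranks - 1.0) / (values.size - 1.0)
        order = np.argsort(values, kind="mergesort")
        xs, fs = values[order], f[order]
        # tied values share the mean-rank F; keep one node per distinct value
        keep = np.empty(xs.size, dtype=bool)
        keep[0] = True
        keep[1:] = np.diff(xs) > 0
        xu, fu = xs[keep], fs[keep]
        # the endpoint rule (min -> 0, max -> 1) outranks mean-rank ties at
        # the extremes: a duplicated minimum or maximum is still pinned
        fu[0], fu[-1] = 0.0, 1.0
        self._x, self._f = xu, fu
        self._reference = xs
        return self

    def cdf(self, values) -> np.ndarray:
        """Base ECDF (direction not applied), clamped to [0, 1]."""
        self._check_fitted()
        q = np.asarray(values, dtype=float)
        return np.interp(q, self._x, self._f)

    def transform(self, values) -> np.ndarray:
        """Map raw values to SHIs in [0, 1] under the direction rule."""
        self._check_fitted()
        q = np.asarray(values, dtype=float)
        f = self.cdf(q)
        kind = self.direction.kind
        if kind is Direction.MORE_IS_WORSE:
            out = f
        elif kind is Direction.LESS_IS_WORSE:
            out = 1.0 - f
        else:
            pivot = self.direction.pivot
            fp = float(np.interp(pivot, self._x, self._f))
            out = np.where(q > pivot, f, 1.0 - f)
            out = np.where(q == pivot, min(fp, 1.0 - fp), out)
        return np.clip(out, 0.0, 1.0)

    def _check_fitted(self) -> None:
        if not self.is_fitted:
            raise RuntimeError(f"{self.name or 'rescaler'} is not fitted")

    # -- serialization (bit-exact via Python float repr round-trip) --------

    def to_dict(self) -> dict:
        self._check_fitted()
        return {
            "name": self.name,
            "direction": self.direction.kind.value,
            "pivot": self.direction.pivot,
            "reference": [float(v) for v in self._reference],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EcdfRescaler":
        rule = DirectionRule(
            Direction(d["direction"]),
            d["pivot"] if Direction(d["direction"]) is Direction.INVERSE_OPTIMUM else None,
        )
        return cls(rule, name=d.get("name", "")).fit(np.asarray(d["reference"], dtype=float))

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "EcdfRescaler":
        return cls.from_dict(json.loads(s))


def fit_rescaler(values, direction: DirectionRule, name: str = "") -> EcdfRescaler:
    """Fit an :class:`EcdfRescaler` on a reference sample."""
    return EcdfRescaler(direction, name=name).fit(values)


def fit_indicator_rescalers(table: pd.DataFrame) -> dict[str, EcdfRescaler]:
    """Fit the four indicator rescalers on the pooled survey table.

    Pooling all survey years keeps SDP values comparable across years;
    per-year ECDFs would rescale each year against a different reference.
    """
    missing = [c for c in INDICATOR_COLUMNS if c not in table.columns]
    if missing:
        raise KeyError(f"survey table lacks indicator columns: {missing}")
    return {
        col: fit_rescaler(table[col].to_numpy(), INDICATOR_DIRECTIONS[col], name=col)
        for col in INDICATOR_COLUMNS
    }


@dataclass(frozen=True)
class SdpWeights:
    """Non-negative SHI weights summing to one (default equal, 0.25 each)."""

    w_er: float = 0.25
    w_ec: float = 0.25
    w_ph: float = 0.25
    w_soc: float = 0.25

    def __post_init__(self) -> None:
        arr = self.as_array()
        if (arr < 0).any():
            raise ValueError("SDP weights must be non-negative")
        if not np.isclose(arr.sum(), 1.0, rtol=0, atol=1e-12):
            raise ValueError(f"SDP weights must sum to 1, got {arr.sum()!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.w_er, self.w_ec, self.w_ph, self.w_soc], dtype=float)


def compute_sdp(shis, weights: SdpWeights = SdpWeights()):
    """Aggregate SHI components into the SDP.

    ``shis`` is a length-4 sequence (erosion, EC, pH, SOC order) or an
    (n, 4) array of SHI components in [0, 1].  With default weights the
    SDP is their arithmetic mean.
    """
    arr = np.asarray(shis, dtype=float)
    if arr.shape[-1] != 4:
        raise ValueError(f"expected 4 SHI components, got shape {arr.shape}")
    if np.isnan(arr).any() or (arr < 0).any() or (arr > 1).any():
        raise ValueError("SHI components must lie in [0, 1]")
    out = arr @ weights.as_array()
    return float(out) if arr.ndim == 1 else out


def build_sdp_table(
    table: pd.DataFrame,
    rescalers: Mapping[str, EcdfRescaler] | None = None,
    weights: SdpWeights = SdpWeights(),
) -> pd.DataFrame:
    """Return a copy of ``table`` with shi_* and sdp columns appended.

    If ``rescalers`` is None they are fitted on the pooled table (all
    survey years combined).  Row count and order are preserved; the SDP
    is a row-wise function of the four indicators.
    """
    if rescalers is None:
        rescalers = fit_indicator_rescalers(table)
    missing = [c for c in INDICATOR_COLUMNS if c not in table.columns]
    if missing:
        raise KeyError(f"survey table lacks indicator columns: {missing}")
    out = table.copy()
    shis = np.empty((len(out), 4), dtype=float)
    for j, col in enumerate(INDICATOR_COLUMNS):
        shi = rescalers[col].transform(out[col].to_numpy())
        out[SHI_COLUMNS[col]] = shi
        shis[:, j] = shi
    out["sdp"] = compute_sdp(shis, weights) if len(out) else np.empty(0)
    return out
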