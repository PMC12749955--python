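"""Model interpretation: importance, sensitivity, ALE and exploratory stats.

Four views of what drives the modelled SDP:

* Gini importance — mean decrease in node impurity per predictor,
  averaged over ensemble members and normalized to sum to 1.
* One-SD sensitivity — mean change in predicted SDP when a single
  continuous predictor is raised by one training-set standard deviation,
  everything else held fixed; computable per land-cover stratum.
* First-order ALE — accumulated local effects over quantile bins,
  robust to correlated predictors, with optional 95% bootstrap bands.
* Exploratory statistics — Pearson correlations of SDP with predictors
  and SDP summaries, stratified by land cover.

All interpretation runs against the ensemble-mean predictor; any object
with a ``predict_mean(table)`` method (or a bare callable on a
DataFrame) is accepted, which lets analytic stub models serve as
oracles.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ensemble import SdpEnsemble, train_ensemble

logger = logging.getLogger(__name__)

__all__ = [
    "ALECurve",
    "variable_importance",
    "sd_sensitivity",
    "ale_curve",
    "ale_with_uncertainty",
    "correlation_by_landcover",
    "sdp_summary_by_landcover",
]


def _predict_fn(model):
    if hasattr(model, "predict_mean"):
        return model.predict_mean
    if callable(model):
        return model
    raise TypeError(f"cannot interpret {type(model).__name__}: need predict_mean or callable")


def _stratum_rows(table: pd.DataFrame, stratum: str | None) -> pd.DataFrame:
    if stratum in (None, "all"):
        return table
    out = table[table["landcover"] == stratum]
    if out.empty:
        raise ValueError(f"empty stratum {stratum!r}")
    return out


def variable_importance(ensemble: SdpEnsemble) -> pd.Series:
    """Impurity importances averaged across members, normalized to sum 1.

    One-hot encoded levels are summed back into their parent predictor.
    """
    if not ensemble.members:
        raise RuntimeError("ensemble has no fitted members")
    imp = np.mean([m.feature_importances_ for m in ensemble.members], axis=0)
    agg: dict[str, float] = {}
    for name, v in zip(ensemble.feature_names, imp):
        parent = name.split("=", 1)[0]
        agg[parent] = agg.get(parent, 0.0) + float(v)
    s = pd.Series(agg).sort_values(ascending=False)
    total = s.sum()
    return s / total if total > 0 else s


def sd_sensitivity(
    model,
    table: pd.DataFrame,
    predictor: str,
    stratum: str | None = None,
    sigma: float | None = None,
) -> float:
    """Mean ΔSDP for a one-standard-deviation increase of one predictor.

    σ is the ensemble's stored training-set standard deviation when
    available, else the evaluation table's; the sign of the result
    carries the direction of the response.
    """
    if isinstance(model, SdpEnsemble) and predictor in model.config.categorical:
        raise ValueError(f"{predictor!r} is categorical; one-SD sensitivity is undefined")
    sub = _stratum_rows(table, stratum)
    if sigma is None:
        if isinstance(model, SdpEnsemble) and predictor in model.predictor_std:
            sigma = model.predictor_std[predictor]
        else:
            sigma = float(sub[predictor].to_numpy(dtype=float).std(ddof=0))
    if not sigma > 0:
        raise ValueError(f"{predictor!r} has zero standard deviation")
    f = _predict_fn(model)
    base = np.asarray(f(sub), dtype=float)
    bumped = sub.copy()
    bumped[predictor] = bumped[predictor].to_numpy(dtype=float) + sigma
    return float(np.mean(np.asarray(f(bumped), dtype=float) - base))


@dataclass
class ALECurve:
    predictor: str
    stratum: str
    edges: np.ndarray  # z_0 .. z_K, strictly increasing
    local_effects: np.ndarray  # per-bin mean local difference (length K)
    effect: np.ndarray  # centered accumulated effect at each edge (K + 1)
    counts: np.ndarray  # rows per bin (length K)
    avg_prediction: float  # stratum mean prediction (additive offset)
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        d = {"edge": self.edges, "effect": self.effect}
        if self.ci_low is not None:
            d["ci_low"], d["ci_high"] = self.ci_low, self.ci_high
        return pd.DataFrame(d)


def _quantile_edges(x: np.ndarray, n_bins: int) -> np.ndarray:
    edges = np.unique(np.quantile(x, np.linspace(0.0, 1.0, n_bins + 1)))
    if edges.size < 2:
        raise ValueError("predictor is constant within the stratum")
    return edges


def _ale_values(f, sub: pd.DataFrame, predictor: str, edges: np.ndarray):
    """Uncentered accumulated local effects on fixed edges.

    Bin k spans (z_{k-1}, z_k]; rows at or below the first edge join bin
    1.  The local effect of bin k is the mean over its rows of
    f(x_j = z_k) − f(x_j = z_{k-1}); empty interior bins contribute a
    zero step (equivalent to merging with the left neighbor) and are
    logged.
    """
    x = sub[predictor].to_numpy(dtype=float)
    K = edges.size - 1
    which = np.clip(np.searchsorted(edges, x, side="left") - 1, 0, K - 1)
    lo_rows, hi_rows = sub.copy(), sub.copy()
    lo_rows[predictor] = edges[which]
    hi_rows[predictor] = edges[which + 1]
    delta = np.asarray(f(hi_rows), dtype=float) - np.asarray(f(lo_rows), dtype=float)
    counts = np.bincount(which, minlength=K)
    sums = np.bincount(which, weights=delta, minlength=K)
    empty = counts == 0
    if empty.any():
        logger.info(
            "ale: %d empty bin(s) for %s merged with left neighbor", int(empty.sum()), predictor
        )
    local = np.where(empty, 0.0, sums / np.maximum(counts, 1))
    acc = np.concatenate([[0.0], np.cumsum(local)])
    return acc, local, counts, which


def ale_curve(
    model,
    table: pd.DataFrame,
    predictor: str,
    n_bins: int = 20,
    stratum: str | None = None,
) -> ALECurve:
    """First-order ALE of one continuous predictor.

    Quantile bin edges over the stratum; the accumulated curve is
    centered so that, evaluated (piecewise-linearly) at the stratum's
    data points, it has mean zero — the curve then reads as the
    departure from the stratum's average prediction, which is reported
    as ``avg_prediction``.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if isinstance(model, SdpEnsemble) and predictor in model.config.categorical:
        raise ValueError(f"{predictor!r} is categorical; first-order ALE is undefined")
    sub = _stratum_rows(table, stratum)
    if len(sub) < n_bins:
        raise ValueError(f"stratum has {len(sub)} rows < n_bins={n_bins}")
    f = _predict_fn(model)
    x = sub[predictor].to_numpy(dtype=float)
    edges = _quantile_edges(x, n_bins)
    acc, local, counts, _ = _ale_values(f, sub, predictor, edges)
    center = float(np.mean(np.interp(x, edges, acc)))
    return ALECurve(
        predictor=predictor,
        stratum=stratum or "all",
        edges=edges,
        local_effects=local,
        effect=acc - center,
        counts=counts,
        avg_prediction=float(np.mean(np.asarray(f(sub), dtype=float))),
    )


def ale_with_uncertainty(
    model,
    table: pd.DataFrame,
    predictor: str,
    n_bins: int = 20,
    stratum: str | None = None,
    n_boot: int = 50,
    seed: int = 0,
    refit: bool = False,
) -> ALECurve:
    """ALE with a 95% bootstrap confidence band.

    Rows of the stratum are resampled with replacement ``n_boot`` times;
    each resample's ALE is evaluated on the edge grid fixed from the
    full sample, and the band is the per-edge 2.5th/97.5th percentile.
    By default the fitted model is re-evaluated on each resample
    (``refit=False``); ``refit=True`` retrains the ensemble per resample
    for full fidelity at much higher cost.
    """
    point = ale_curve(model, table, predictor, n_bins=n_bins, stratum=stratum)
    sub = _stratum_rows(table, stratum)
    rng = np.random.default_rng([seed, 7])
    curves = np.empty((n_boot, point.edges.size))
    for b in range(n_boot):
        idx = rng.integers(0, len(sub), size=len(sub))
        boot = sub.iloc[idx]
        if refit:
            if not isinstance(model, SdpEnsemble):
                raise TypeError("refit=True requires an SdpEnsemble")
            cfg = model.config
            boot_model = train_ensemble(boot.reset_index(drop=True), cfg)
            f = _predict_fn(boot_model)
        else:
            f = _predict_fn(model)
        acc, _, _, _ = _ale_values(f, boot, predictor, point.edges)
        xb = boot[predictor].to_numpy(dtype=float)
        curves[b] = acc - float(np.mean(np.interp(xb, point.edges, acc)))
    point.ci_low = np.percentile(curves, 2.5, axis=0)
    point.ci_high = np.percentile(curves, 97.5, axis=0)
    return point


def correlation_by_landcover(
    table: pd.DataFrame,
    predictors: list[str],
    strata: list[str] | None = None,
) -> pd.DataFrame:
    """Pearson correlation of SDP with each predictor within each stratum.

    Zero-variance predictors within a stratum yield NaN (undefined);
    strata need at least 3 rows.
    """
    if strata is None:
        strata = ["all"] + sorted(map(str, pd.unique(table["landcover"].astype(str))))
    rows = []
    for stratum in strata:
        sub = _stratum_rows(table, stratum)
        if len(sub) < 3:
            raise ValueError(f"stratum {stratum!r} has fewer than 3 rows")
        y = sub["sdp"].to_numpy(dtype=float)
        for p in predictors:
            x = sub[p].to_numpy(dtype=float)
            if x.std(ddof=0) == 0 or y.std(ddof=0) == 0:
                r = np.nan
            else:
                r = float(np.corrcoef(x, y)[0, 1])
            rows.append({"stratum": stratum, "predictor": p, "pearson_r": r, "n": len(sub)})
    return pd.DataFrame(rows)


def sdp_summary_by_landcover(table: pd.DataFrame) -> pd.DataFrame:
    """Per-land-cover count, median and quartiles of SDP."""
    if "landcover" not in table.columns:
        raise KeyError("table lacks a landcover column")
    g = table.groupby("landcover")["sdp"]
    out = g.agg(
        count="count",
        median="median",
        q25=lambda s: float(np.quantile(s, 0.25)),
        q75=lambda s: float(np.quantile(s, 0.75)),
    ).reset_index()
    return out
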