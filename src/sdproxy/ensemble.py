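"""Bootstrap ensemble of random-forest regressors for SDP prediction.

The survey is split once into fixed training and validation portions
(70/30 by default).  The ensemble consists of ``n_models`` independent
random forests (100 by default), each trained on a with-replacement
resample of the training split only; the validation rows never enter any
member's fit.  The ensemble mean is the point prediction and the
member spread carries the uncertainty (see :mod:`sdproxy.mapping`).

Forest hyperparameters: 500 trees per member and features-per-split of
p/3 (rounded) by default, both configurable; categorical predictors are
integer-coded against a level registry persisted with the ensemble
(one-hot encoding available via config).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .raster import CATEGORICAL_LAYERS, PREDICTORS

__all__ = [
    "EnsembleConfig",
    "SdpEnsemble",
    "MetricsReport",
    "split_train_validation",
    "train_ensemble",
    "predict",
    "evaluate",
    "ensemble_metrics",
    "binned_errors",
    "save_ensemble",
    "load_ensemble",
]


@dataclass
class EnsembleConfig:
    n_models: int = 100
    train_fraction: float = 0.70
    n_trees: int = 500
    seed: int = 0
    predictors: tuple[str, ...] = PREDICTORS
    categorical: tuple[str, ...] = CATEGORICAL_LAYERS
    one_hot: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.n_models < 1:
            raise ValueError("n_models must be >= 1")
        self.predictors = tuple(self.predictors)
        self.categorical = tuple(c for c in self.categorical if c in self.predictors)

    def to_dict(self) -> dict:
        return {
            "n_models": self.n_models,
            "train_fraction": self.train_fraction,
            "n_trees": self.n_trees,
            "seed": self.seed,
            "predictors": list(self.predictors),
            "categorical": list(self.categorical),
            "one_hot": self.one_hot,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EnsembleConfig":
        d = dict(d)
        d["predictors"] = tuple(d.get("predictors", PREDICTORS))
        d["categorical"] = tuple(d.get("categorical", CATEGORICAL_LAYERS))
        return cls(**d)


def split_train_validation(table: pd.DataFrame, fraction: float = 0.70, seed: int = 0):
    """Seeded uniform split into disjoint, exhaustive train/validation id sets.

    Returns positional row indices; the train size is round(n * fraction).
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    n = len(table)
    if n == 0:
        raise ValueError("table is empty")
    rng = np.random.default_rng([seed, 1])
    perm = rng.permutation(n)
    n_train = int(round(n * fraction))
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


class SdpEnsemble:
    """Fitted bootstrap RF ensemble with its schema and split bookkeeping."""

    def __init__(
        self,
        members: list[RandomForestRegressor],
        bootstrap_indices: list[np.ndarray],
        config: EnsembleConfig,
        levels: dict[str, list],
        feature_names: list[str],
        predictor_std: dict[str, float],
        train_ids: np.ndarray,
        validation_ids: np.ndarray,
    ):
        self.members = members
        self.bootstrap_indices = bootstrap_indices
        self.config = config
        self.levels = levels  # categorical predictor -> ordered level list
        self.feature_names = feature_names
        self.predictor_std = predictor_std  # training-set SD per continuous predictor
        self.train_ids = train_ids
        self.validation_ids = validation_ids

    @property
    def n_models(self) -> int:
        return len(self.members)

    def encode(self, table: pd.DataFrame) -> np.ndarray:
        """Assemble the design matrix in training column order.

        Unseen categorical levels map to the designated fallback level
        ("other" if present in training, else the modal level) with a
        warning.
        """
        cfg = self.config
        missing = [p for p in cfg.predictors if p not in table.columns]
        if missing:
            raise KeyError(f"feature table lacks predictors: {missing}")
        cols = {}
        for p in cfg.predictors:
            if p in cfg.categorical:
                levels = self.levels[p]
                code = {lvl: i for i, lvl in enumerate(levels)}
                fallback = code["other"] if "other" in code else 0
                vals = table[p].astype(str).to_numpy()
                enc = np.empty(len(vals), dtype=float)
                unseen = set()
                for i, v in enumerate(vals):
                    if v in code:
                        enc[i] = code[v]
                    else:
                        unseen.add(v)
                        enc[i] = fallback
                if unseen:
                    warnings.warn(
                        f"unseen {p} levels {sorted(map(str, unseen))} mapped to "
                        f"fallback level {levels[fallback]!r}"
                    )
                if cfg.one_hot:
                    for j, lvl in enumerate(levels):
                        cols[f"{p}={lvl}"] = (enc == j).astype(float)
                else:
                    cols[p] = enc
            else:
                cols[p] = table[p].to_numpy(dtype=float)
        return np.column_stack([cols[name] for name in self.feature_names])

    def predict_members(self, table: pd.DataFrame) -> np.ndarray:
        """(rows × n_models) member predictions, clipped to [0, 1]."""
        X = self.encode(table)
        out = np.empty((X.shape[0], self.n_models))
        for j, m in enumerate(self.members):
            out[:, j] = m.predict(X)
        return np.clip(out, 0.0, 1.0)

    def predict_mean(self, table: pd.DataFrame) -> np.ndarray:
        return self.predict_members(table).mean(axis=1)


def _level_registry(table: pd.DataFrame, categorical: Iterable[str]) -> dict[str, list]:
    return {p: sorted(map(str, pd.unique(table[p].astype(str)))) for p in categorical}


def train_ensemble(table: pd.DataFrame, config: EnsembleConfig = EnsembleConfig()) -> SdpEnsemble:
    """Train the bootstrap ensemble on a table carrying an ``sdp`` column."""
    if "sdp" not in table.columns:
        raise KeyError("table lacks the 'sdp' response column; run build_sdp_table first")
    missing = [p for p in config.predictors if p not in table.columns]
    if missing:
        raise KeyError(f"table lacks predictor columns: {missing}")
    y_all = table["sdp"].to_numpy(dtype=float)
    if np.ptp(y_all) == 0:
        warnings.warn("constant SDP response; ensemble will be degenerate")

    train_ids, val_ids = split_train_validation(table, config.train_fraction, config.seed)
    levels = _level_registry(table.iloc[train_ids], config.categorical)

    feature_names: list[str] = []
    for p in config.predictors:
        if p in config.categorical and config.one_hot:
            feature_names.extend(f"{p}={lvl}" for lvl in levels[p])
        else:
            feature_names.append(p)

    predictor_std = {
        p: float(table.iloc[train_ids][p].to_numpy(dtype=float).std(ddof=0))
        for p in config.predictors
        if p not in config.categorical
    }

    shell = SdpEnsemble([], [], config, levels, feature_names, predictor_std, train_ids, val_ids)
    X_train = shell.encode(table.iloc[train_ids])
    y_train = y_all[train_ids]

    mtry = max(1, round(X_train.shape[1] / 3))
    boot_rng = np.random.default_rng([config.seed, 2])
    members, boots = [], []
    for b in range(config.n_models):
        idx = boot_rng.integers(0, len(train_ids), size=len(train_ids))
        rf = RandomForestRegressor(
            n_estimators=config.n_trees,
            max_features=mtry,
            bootstrap=False,  # the with-replacement resample IS the bootstrap
            random_state=int(np.random.default_rng([config.seed, 3, b]).integers(2**31 - 1)),
            n_jobs=1,
        )
        rf.fit(X_train[idx], y_train[idx])
        members.append(rf)
        boots.append(train_ids[idx])
    shell.members, shell.bootstrap_indices = members, boots
    return shell


def predict(ensemble: SdpEnsemble, features: pd.DataFrame):
    """Per-member predictions and their mean for a feature table."""
    members = ensemble.predict_members(features)
    return members, members.mean(axis=1)


@dataclass
class MetricsReport:
    per_member: pd.DataFrame  # columns: member, split, r_squared, rmse, mae
    ensemble_means: pd.DataFrame  # per split means over members
    binned: pd.DataFrame  # validation binned-error summary


def evaluate(predictions, observations) -> dict[str, float]:
    """R², RMSE and MAE of predictions against observations.

    R² = 1 − SSE/SST; undefined (error) when the observations have zero
    variance.
    """
    p = np.asarray(predictions, dtype=float)
    o = np.asarray(observations, dtype=float)
    if p.shape != o.shape or p.size < 2:
        raise ValueError("predictions and observations must share length >= 2")
    sst = np.sum((o - o.mean()) ** 2)
    if sst == 0:
        raise ValueError("R-squared undefined: zero variance in observations")
    sse = np.sum((o - p) ** 2)
    return {
        "r_squared": float(1.0 - sse / sst),
        "rmse": float(np.sqrt(np.mean((p - o) ** 2))),
        "mae": float(np.mean(np.abs(p - o))),
    }


def binned_errors(predictions, observations, n_bins: int = 10) -> pd.DataFrame:
    """Error distribution of (prediction − observation) in equal SDP bins.

    Bins partition [0, 1] into ``n_bins`` equal intervals on the
    observations, [0, 0.1), ..., [0.9, 1.0]; empty bins are reported
    with count 0 and no statistics.
    """
    p = np.asarray(predictions, dtype=float)
    o = np.asarray(observations, dtype=float)
    if ((o < 0) | (o > 1)).any():
        raise ValueError("observations must lie in [0, 1]")
    err = p - o
    which = np.minimum((o * n_bins).astype(int), n_bins - 1)
    rows = []
    for k in range(n_bins):
        e = err[which == k]
        row = {"bin": k, "lo": k / n_bins, "hi": (k + 1) / n_bins, "count": int(e.size)}
        if e.size:
            row.update(
                median=float(np.median(e)),
                q25=float(np.quantile(e, 0.25)),
                q75=float(np.quantile(e, 0.75)),
                mean_abs=float(np.mean(np.abs(e))),
            )
        else:
            row.update(median=np.nan, q25=np.nan, q75=np.nan, mean_abs=np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def ensemble_metrics(ensemble: SdpEnsemble, table: pd.DataFrame) -> MetricsReport:
    """Per-member train/validation metrics plus the binned validation errors."""
    y = table["sdp"].to_numpy(dtype=float)
    splits = {"train": ensemble.train_ids, "validation": ensemble.validation_ids}
    rows = []
    val_mean_pred = None
    for split, ids in splits.items():
        members = ensemble.predict_members(table.iloc[ids])
        for j in range(members.shape[1]):
            rows.append({"member": j, "split": split, **evaluate(members[:, j], y[ids])})
        if split == "validation":
            val_mean_pred = members.mean(axis=1)
    per_member = pd.DataFrame(rows)
    means = (
        per_member.groupby("split")[["r_squared", "rmse", "mae"]].mean().reset_index()
    )
    binned = binned_errors(val_mean_pred, y[splits["validation"]])
    return MetricsReport(per_member, means, binned)


# ----------------------------------------------------------------------
# directory-bundle persistence


def save_ensemble(ensemble: SdpEnsemble, directory: Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": ensemble.config.to_dict(),
        "levels": ensemble.levels,
        "feature_names": ensemble.feature_names,
        "predictor_std": ensemble.predictor_std,
        "train_ids": ensemble.train_ids.tolist(),
        "validation_ids": ensemble.validation_ids.tolist(),
        "n_members": ensemble.n_models,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    for j, (m, idx) in enumerate(zip(ensemble.members, ensemble.bootstrap_indices)):
        joblib.dump({"model": m, "bootstrap_indices": idx}, directory / f"member_{j:03d}.joblib")
    return directory


def load_ensemble(directory: Path) -> SdpEnsemble:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    members, boots = [], []
    for j in range(manifest["n_members"]):
        blob = joblib.load(directory / f"member_{j:03d}.joblib")
        members.append(blob["model"])
        boots.append(np.asarray(blob["bootstrap_indices"]))
    return SdpEnsemble(
        members,
        boots,
        EnsembleConfig.from_dict(manifest["config"]),
        manifest["levels"],
        manifest["feature_names"],
        {k: float(v) for k, v in manifest["predictor_std"].items()},
        np.asarray(manifest["train_ids"]),
        np.asarray(manifest["validation_ids"]),
    )
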