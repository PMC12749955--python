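"""End-to-end pipeline: data → SDP → ensemble → interpretation → maps → trends.

A :class:`PipelineConfig` (loadable from YAML) fully determines a run;
one global seed drives every stochastic stage, so reruns with the same
config are bit-identical.  Each run writes its products plus a JSON
manifest with a SHA-256 checksum per file, the resolved config and the
seeds used.  A stage failure leaves a partial manifest with a
failed-stage marker.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import interpret as interp
from .ensemble import EnsembleConfig, ensemble_metrics, train_ensemble
from .mapping import predict_annual_maps, write_raster_set
from .raster import PREDICTORS, read_stack
from .rescale import EcdfRescaler, SdpWeights, build_sdp_table, fit_indicator_rescalers
from .synthetic import SyntheticConfig, generate_covariate_grids, generate_survey, write_fixture
from .tables import read_survey_csv, write_survey_csv
from .trends import trend_area_summary, trend_stack, write_trend_raster

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "demo_config"]


@dataclass
class PipelineConfig:
    """Resolved configuration of one pipeline run.

    With ``survey_csv``/``stack_dir`` unset, the synthetic generator
    supplies the data (the usual mode for experiments and tests).
    """

    seed: int = 0
    output_dir: str = "sdp_run"
    survey_csv: str | None = None
    stack_dir: str | None = None
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    weights: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    ensemble: EnsembleConfig = field(default_factory=EnsembleConfig)
    ale_predictors: tuple[str, ...] = ("TEMP30", "PRCP30", "NDVI")
    ale_bins: int = 20
    ale_n_boot: int = 50
    strata: tuple[str, ...] = ("all", "cropland", "forest")
    map_years: tuple[int, ...] | None = None
    alpha: float = 0.01
    t_mod: float = 0.001
    t_strong: float = 0.003

    def __post_init__(self) -> None:
        # the global seed drives every stochastic stage
        self.synthetic.seed = self.seed
        self.ensemble.seed = self.seed

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "output_dir": self.output_dir,
            "survey_csv": self.survey_csv,
            "stack_dir": self.stack_dir,
            "synthetic": self.synthetic.to_dict(),
            "weights": list(self.weights),
            "ensemble": self.ensemble.to_dict(),
            "ale_predictors": list(self.ale_predictors),
            "ale_bins": self.ale_bins,
            "ale_n_boot": self.ale_n_boot,
            "strata": list(self.strata),
            "map_years": None if self.map_years is None else list(self.map_years),
            "alpha": self.alpha,
            "t_mod": self.t_mod,
            "t_strong": self.t_strong,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "synthetic" in d and isinstance(d["synthetic"], dict):
            d["synthetic"] = SyntheticConfig.from_dict(d["synthetic"])
        if "ensemble" in d and isinstance(d["ensemble"], dict):
            d["ensemble"] = EnsembleConfig.from_dict(d["ensemble"])
        for key in ("weights", "ale_predictors", "strata"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        if d.get("map_years") is not None:
            d["map_years"] = tuple(d["map_years"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: Path) -> Path:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return Path(path)


def demo_config(output_dir: str = "sdp_demo", seed: int = 0) -> PipelineConfig:
    """Small, quick end-to-end configuration (minutes on one CPU)."""
    return PipelineConfig(
        seed=seed,
        output_dir=output_dir,
        synthetic=SyntheticConfig(
            grid_rows=24, grid_cols=24, n_points_per_year=200, seed=seed
        ),
        ensemble=EnsembleConfig(n_models=10, n_trees=50, seed=seed),
        ale_predictors=("TEMP30", "PRCP30"),
        ale_bins=8,
        ale_n_boot=10,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return (and write) the artifact manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "seed": config.seed, "stages": {}, "files": {}}

    def _register(*paths) -> None:
        for p in paths:
            p = Path(p)
            manifest["files"][str(p.relative_to(out))] = _sha256(p)

    def _stage(name, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:  # partial manifest with failure marker
            manifest["stages"][name] = {"status": "failed", "error": f"{type(exc).__name__}: {exc}"}
            (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
            raise
        manifest["stages"][name] = {"status": "ok", "seconds": round(time.perf_counter() - t0, 3)}
        return result

    state: dict = {}

    def stage_data():
        if config.survey_csv and config.stack_dir:
            table, report = read_survey_csv(config.survey_csv)
            stack = read_stack(config.stack_dir)
            manifest["stages"].setdefault("data_report", report.rejected)
        else:
            stack = generate_covariate_grids(config.synthetic)
            table = generate_survey(stack, config.synthetic)
            write_fixture(stack, table, out / "data", config.synthetic)
            for p in sorted((out / "data").rglob("*")):
                if p.is_file():
                    _register(p)
        state["stack"], state["table"] = stack, table
        logger.info("data: %d survey rows, grid %s", len(table), stack.grid.shape)

    def stage_sdp():
        w = config.weights
        weights = SdpWeights(*w)
        rescalers = fit_indicator_rescalers(state["table"])
        table = build_sdp_table(state["table"], rescalers, weights)
        p = write_survey_csv(table, out / "sdp_table.csv")
        rp = out / "rescalers.json"
        rp.write_text(json.dumps({k: r.to_dict() for k, r in rescalers.items()}, sort_keys=True))
        _register(p, rp)
        state["table"], state["rescalers"] = table, rescalers
        logger.info("sdp: table of %d rows, mean SDP %.3f", len(table), table["sdp"].mean())

    def stage_train():
        ens = train_ensemble(state["table"], config.ensemble)
        metrics = ensemble_metrics(ens, state["table"])
        mp = out / "metrics_per_member.csv"
        metrics.per_member.to_csv(mp, index=False)
        ep = out / "metrics_ensemble.csv"
        metrics.ensemble_means.to_csv(ep, index=False)
        bp = out / "metrics_binned.csv"
        metrics.binned.to_csv(bp, index=False)
        _register(mp, ep, bp)
        state["ensemble"], state["metrics"] = ens, metrics
        logger.info("train: %d members; %s", ens.n_models, metrics.ensemble_means.to_dict("records"))

    def stage_interpret():
        ens, table = state["ensemble"], state["table"]
        imp = interp.variable_importance(ens)
        ip = out / "importance.csv"
        imp.rename("importance").to_frame().to_csv(ip)
        sens_rows = []
        for pred in ens.config.predictors:
            if pred in ens.config.categorical:
                continue
            for stratum in config.strata:
                try:
                    d = interp.sd_sensitivity(ens, table, pred, stratum=stratum)
                except ValueError:
                    d = np.nan
                sens_rows.append({"predictor": pred, "stratum": stratum, "delta_sdp": d})
        sp = out / "sensitivity.csv"
        pd.DataFrame(sens_rows).to_csv(sp, index=False)
        ale_frames = []
        for pred in config.ale_predictors:
            for stratum in config.strata:
                try:
                    curve = interp.ale_with_uncertainty(
                        ens,
                        table,
                        pred,
                        n_bins=config.ale_bins,
                        stratum=stratum,
                        n_boot=config.ale_n_boot,
                        seed=config.seed,
                    )
                except ValueError:
                    continue
                frame = curve.to_frame()
                frame.insert(0, "predictor", pred)
                frame.insert(1, "stratum", curve.stratum)
                frame["avg_prediction"] = curve.avg_prediction
                ale_frames.append(frame)
        ap = out / "ale_curves.csv"
        pd.concat(ale_frames, ignore_index=True).to_csv(ap, index=False)
        cp = out / "correlations.csv"
        cont = [p for p in ens.config.predictors if p not in ens.config.categorical]
        interp.correlation_by_landcover(table, cont, list(config.strata)).to_csv(cp, index=False)
        up = out / "sdp_by_landcover.csv"
        interp.sdp_summary_by_landcover(table).to_csv(up, index=False)
        _register(ip, sp, ap, cp, up)

    def stage_map():
        years = list(config.map_years) if config.map_years else state["stack"].years
        raster_set = predict_annual_maps(state["ensemble"], state["stack"], years)
        paths = write_raster_set(raster_set, out / "maps")
        _register(*paths.values())
        state["raster_set"] = raster_set
        logger.info("map: %d years predicted", len(years))

    def stage_trend():
        rs = state["raster_set"]
        trend = trend_stack(
            rs.sdp, rs.valid, alpha=config.alpha, t_mod=config.t_mod, t_strong=config.t_strong
        )
        paths = write_trend_raster(trend, out / "trends")
        stack = state["stack"]
        summary = trend_area_summary(
            trend, stack.static["landcover"], stack.legends["landcover"]
        )
        sp = out / "trend_area_summary.csv"
        summary.to_csv(sp, index=False)
        _register(*paths.values(), sp)
        state["trend"], state["trend_summary"] = trend, summary
        logger.info("trend: %d categorized pixels", int(trend.valid.sum()))

    _stage("data", stage_data)
    _stage("sdp", stage_sdp)
    _stage("train", stage_train)
    _stage("interpret", stage_interpret)
    _stage("map", stage_map)
    _stage("trend", stage_trend)

    cfg_path = out / "resolved_config.yaml"
    resolved = config.to_dict()
    resolved["output_dir"] = "."  # the run directory itself; keeps reruns relocatable
    cfg_path.write_text(yaml.safe_dump(resolved, sort_keys=True))
    _register(cfg_path)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
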