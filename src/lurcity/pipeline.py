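"""End-to-end orchestration of the nine-model analysis.

Stages mirror the analysis order: synthesize (or load) the city and the
hourly series -> impute -> build PPV rasters and the design table -> fit
one model per pollutant x period (3 x annual/cooler/warmer = 9) ->
stability and spatial-autocorrelation diagnostics -> regression maps
with floor/ceiling rules -> seasonal comparison at random points.

Each stage writes its outputs under the run directory and is skipped on
re-run when they already exist, so deleting one stage's files regenerates
only that stage and those downstream.  One master seed is expanded into
per-stage seeds with a fixed affine scheme, making re-runs bit-identical.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diagnostics, impute, mapping, ppv, seasons, selection, synth
from .raster import RasterGrid

log = logging.getLogger("lurcity")

POLLUTANTS = ("no", "no2", "nox")
PERIODS = ("annual", "cooler", "warmer")

_DEFAULTS: dict = {
    "seed": 1,
    "out": "runs/demo",
    "city": {},                 # CityConfig overrides
    "stations": {"n": 10},
    "truth": None,              # None -> default_ground_truth()
    "missing": {"rate": 0.28, "mechanism": "mcar"},
    "impute": {"n_runs": 10, "log_scale": False},
    "selection": {"alpha_p": 0.1, "vif_max": 5.0, "cap": None,
                  "linearize": True},
    "seasons": {"n_points": 1000},
}


def _stage_seed(master: int, stage: int) -> int:
    return (master * 1000003 + stage) % (2 ** 31)


def load_config(source) -> dict:
    """Merge a YAML file / dict over the defaults, with schema validation
    that aggregates every bad field into one error."""
    if source is None:
        user: dict = {}
    elif isinstance(source, dict):
        user = source
    else:
        with open(source) as fh:
            user = yaml.safe_load(fh) or {}
    cfg = json.loads(json.dumps(_DEFAULTS))  # deep copy
    errors = []
    for key, val in user.items():
        if key not in cfg:
            errors.append(f"unknown config key '{key}'")
            continue
        if isinstance(cfg[key], dict) and val is not None:
            if not isinstance(val, dict):
                errors.append(f"'{key}' must be a mapping")
                continue
            cfg[key].update(val)
        else:
            cfg[key] = val
    if not isinstance(cfg["seed"], int):
        errors.append("'seed' must be an integer")
    if not (isinstance(cfg["stations"].get("n"), int)
            and cfg["stations"]["n"] >= 8):
        errors.append("'stations.n' must be an integer >= 8")
    rate = cfg["missing"].get("rate", 0.28)
    if not (isinstance(rate, (int, float)) and 0 <= rate < 1):
        errors.append("'missing.rate' must be in [0, 1)")
    if cfg["missing"].get("mechanism") not in ("mcar", "block"):
        errors.append("'missing.mechanism' must be 'mcar' or 'block'")
    if not 0 < cfg["selection"].get("alpha_p", 0.1) < 1:
        errors.append("'selection.alpha_p' must be in (0, 1)")
    if errors:
        raise ValueError("invalid configuration:\n  - " + "\n  - ".join(errors))
    return cfg


def _truth_from_config(cfg: dict) -> synth.GroundTruth:
    if cfg.get("truth") is None:
        return synth.default_ground_truth()
    t = cfg["truth"]
    shift = {
        s: synth.SeasonEffect(base=e.get("base", 1.0),
                              coef=dict(e.get("coef", {})))
        for s, e in t.get("seasonal_shift",
                          {"warmer": {}, "cooler": {}}).items()}
    return synth.GroundTruth(
        active_ppvs=dict(t["active_ppvs"]), seasonal_shift=shift,
        noise_sd=t.get("noise_sd", 0.4), base_level=t.get("base_level", 40.0))


class PipelineRun:
    """One configured run with cached stage outputs on disk."""

    def __init__(self, config=None, out: str | Path | None = None):
        self.cfg = load_config(config)
        self.out = Path(out or self.cfg["out"])
        self.out.mkdir(parents=True, exist_ok=True)
        self.seed = self.cfg["seed"]
        self._scene = None
        self._stations = None
        self._ppv_rasters: dict[str, RasterGrid] | None = None
        logging.basicConfig(level=logging.INFO,
                            format="%(levelname)s %(name)s: %(message)s")

    # -- helpers ---------------------------------------------------------
    def _timed(self, name, fn):
        t0 = time.perf_counter()
        result = fn()
        log.info("stage %-8s %6.1f s", name, time.perf_counter() - t0)
        return result

    def scene(self) -> synth.CityScene:
        if self._scene is None:
            self._scene = synth.generate_city(
                synth.CityConfig(**self.cfg["city"]),
                seed=_stage_seed(self.seed, 0))
        return self._scene

    def stations(self) -> list[tuple[float, float]]:
        if self._stations is None:
            path = self.out / "stations.csv"
            if path.exists():
                df = pd.read_csv(path)
                self._stations = list(zip(df.x, df.y))
            else:
                self._stations = synth.place_stations(
                    self.scene(), self.cfg["stations"]["n"],
                    seed=_stage_seed(self.seed, 1))
                pd.DataFrame(self._stations, columns=["x", "y"]).to_csv(
                    path, index=False)
        return self._stations

    # -- stages ----------------------------------------------------------
    def stage_synth(self) -> Path:
        path = self.out / "series.csv"
        if path.exists():
            return path

        def run():
            scene = self.scene()
            scene.write(self.out / "scene")
            truth = _truth_from_config(self.cfg)
            series = synth.simulate_concentrations(
                scene, self.stations(), truth,
                seed=_stage_seed(self.seed, 2))
            mcfg = self.cfg["missing"]
            series = [synth.apply_missingness(
                s, mcfg["rate"], mcfg["mechanism"],
                seed=_stage_seed(self.seed, 3) + i)
                for i, s in enumerate(series)]
            synth.write_series_csv(series, path)
            with open(self.out / "truth.json", "w") as fh:
                json.dump({"active_ppvs": truth.active_ppvs,
                           "noise_sd": truth.noise_sd,
                           "base_level": truth.base_level,
                           "seasonal_shift": {
                               s: asdict(e) for s, e in
                               truth.seasonal_shift.items()}}, fh, indent=1)
        self._timed("synth", run)
        return path

    def stage_impute(self) -> Path:
        path = self.out / "responses.csv"
        if path.exists():
            return path
        series_path = self.stage_synth()

        def run():
            series = synth.read_series_csv(series_path)
            icfg = self.cfg["impute"]
            frames = []
            for k, pol in enumerate(POLLUTANTS):
                mat = synth.series_to_frame(series, pol)
                res = impute.em_bootstrap_impute(
                    mat, n_runs=icfg["n_runs"],
                    seed=_stage_seed(self.seed, 4) + k,
                    log_scale=icfg["log_scale"])
                sm = impute.seasonal_means(res)
                sm.columns = [f"{pol}_{c}" for c in sm.columns]
                frames.append(sm)
            pd.concat(frames, axis=1).to_csv(path)
        self._timed("impute", run)
        return path

    def stage_ppv(self) -> Path:
        path = self.out / "design.csv"
        if path.exists() and (self.out / "catalog.json").exists():
            return path
        resp_path = self.stage_impute()

        def run():
            scene = self.scene()
            catalog = ppv.build_catalog(scene)
            ppv.write_catalog(catalog, self.out / "catalog.json")
            comp = ppv.PPVComputer(scene)
            rasters = comp.compute_all(catalog)
            self._ppv_rasters = rasters
            responses = pd.read_csv(resp_path, index_col=0)
            design = ppv.extract_station_values(rasters, self.stations(),
                                                responses)
            design.to_csv(path)
        self._timed("ppv", run)
        return path

    def _ensure_rasters(self) -> dict[str, RasterGrid]:
        if self._ppv_rasters is None:
            scene = self.scene()
            catalog = ppv.build_catalog(scene)
            self._ppv_rasters = ppv.PPVComputer(scene).compute_all(catalog)
        return self._ppv_rasters

    def _design_and_priors(self):
        design = pd.read_csv(self.stage_ppv(), index_col=0)
        priors = ppv.sign_priors()
        resp_cols = [f"{p}_{t}" for p in POLLUTANTS for t in PERIODS]
        ppv_cols = [c for c in design.columns
                    if c not in resp_cols + ["x", "y"]]
        return design, priors, ppv_cols, resp_cols

    def stage_fit(self) -> Path:
        mdir = self.out / "models"
        path = self.out / "table1.csv"
        if path.exists():
            return path
        self.stage_ppv()

        def run():
            mdir.mkdir(exist_ok=True)
            design, priors, ppv_cols, resp_cols = self._design_and_priors()
            scfg = self.cfg["selection"]
            rows = []
            for col in resp_cols:
                model = selection.fit_lur(
                    design[ppv_cols], design[col], priors,
                    alpha_p=scfg["alpha_p"], vif_max=scfg["vif_max"],
                    cap=scfg["cap"], label=col,
                    linearize=scfg["linearize"])
                model.save(mdir / f"{col}.json")
                rows.append({
                    "model": col, "equation": model.equation(),
                    "n_terms": len(model.terms), "r2": model.r2,
                    "adj_r2": model.adj_r2, "loocv_r2": model.loocv_r2,
                    "max_vif": model.max_vif[1] if model.max_vif else np.nan,
                    "max_vif_var": model.max_vif[0] if model.max_vif else "",
                    "rmse_ppb": model.rmse_ppb,
                    "shapiro_p": model.shapiro_p})
            pd.DataFrame(rows).to_csv(path, index=False)
        self._timed("fit", run)
        return path

    def _load_model(self, col: str) -> selection.LURModel:
        with open(self.out / "models" / f"{col}.json") as fh:
            d = json.load(fh)
        tspec = selection.TransformSpec(d["response_power"])
        return selection.LURModel(
            label=d["label"], transform=tspec, terms=d["terms"],
            intercept=d["intercept"], r2=d["r2"], adj_r2=d["adj_r2"],
            loocv_r2=d["loocv_r2"], rmse_ppb=d["rmse_ppb"],
            max_vif=tuple(d["max_vif"]) if d["max_vif"] else None,
            shapiro_stat=d["shapiro_stat"], shapiro_p=d["shapiro_p"],
            normality_flag=d["normality_flag"], trace=d["trace"],
            n=d["n"], cap=d["cap"], ppv_transforms=d["ppv_transforms"])

    def _model_matrix(self, model, design):
        cols = {}
        for term in model.terms:
            cols[term["name"]] = selection.apply_ppv_transform(
                design[term["name"]].to_numpy(float), term["transform"])
        return pd.DataFrame(cols, index=design.index)

    def stage_diagnose(self) -> Path:
        path = self.out / "diagnostics.csv"
        if path.exists():
            return path
        self.stage_fit()

        def run():
            design, priors, ppv_cols, resp_cols = self._design_and_priors()
            coords = design[["x", "y"]].to_numpy()
            rows = []
            for col in resp_cols:
                model = self._load_model(col)
                ty = selection.transform_response(
                    design[col].to_numpy(float), model.transform)
                tmat = self._model_matrix(model, design)
                pred = model.intercept + sum(
                    t["coef"] * tmat[t["name"]].to_numpy()
                    for t in model.terms)
                resid = ty - pred
                row = {"model": col}
                if model.terms:
                    stab = diagnostics.loocv_coefficient_stability(
                        tmat, list(tmat.columns), ty)
                    stab.table.to_csv(self.out / "models"
                                      / f"{col}_stability.csv")
                    cvs = stab.table["cv"].iloc[1:]
                    row.update(sign_consistent=stab.sign_consistent,
                               cv_min=cvs.min(), cv_max=cvs.max())
                if np.ptp(resid) > 0:
                    mi = diagnostics.morans_i(resid, coords)
                    row.update(moran_i=mi.I, moran_p=mi.p_value)
                rows.append(row)
            pd.DataFrame(rows).to_csv(path, index=False)
        self._timed("diagnose", run)
        return path

    def stage_map(self) -> Path:
        path = self.out / "table2.csv"
        if path.exists():
            return path
        self.stage_fit()

        def run():
            rasters = self._ensure_rasters()
            design, priors, ppv_cols, resp_cols = self._design_and_priors()
            (self.out / "maps").mkdir(exist_ok=True)
            rows = []
            for col in resp_cols:
                model = self._load_model(col)
                y = design[col].to_numpy(float)
                surf = mapping.predict_surface(model, rasters, y)
                res = mapping.clip_predictions(surf, y.min(), y.max())
                res.raster.write_ascii(self.out / "maps" / f"{col}.asc")
                rows.append({"model": col, **res.summary()})
            pd.DataFrame(rows).to_csv(path, index=False)
        self._timed("map", run)
        return path

    def stage_seasons(self) -> Path:
        path = self.out / "season_correlations.json"
        if path.exists():
            return path
        self.stage_map()

        def run():
            design, priors, ppv_cols, resp_cols = self._design_and_priors()
            n_pts = self.cfg["seasons"]["n_points"]
            out = {}
            for pol in POLLUTANTS:
                maps = {}
                for per, tag in (("annual", "A"), ("cooler", "C"),
                                 ("warmer", "W")):
                    maps[tag] = RasterGrid.read_ascii(
                        self.out / "maps" / f"{pol}_{per}.asc")
                pts = seasons.sample_locations(
                    maps["A"], n=min(n_pts, maps["A"].values.size),
                    seed=_stage_seed(self.seed, 7))
                corr, method, _ = seasons.correlate_predictions(maps, pts)
                out[pol] = {"correlation": corr.round(4).to_dict(),
                            "method": method.to_dict()}
            with open(path, "w") as fh:
                json.dump(out, fh, indent=1)
        self._timed("seasons", run)
        return path

    def run_all(self) -> Path:
        self.stage_synth()
        self.stage_impute()
        self.stage_ppv()
        self.stage_fit()
        self.stage_diagnose()
        self.stage_map()
        self.stage_seasons()
        return self.out


def run_pipeline(config=None, out=None) -> Path:
    """Run every stage; returns the run directory."""
    return PipelineRun(config, out).run_all()
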