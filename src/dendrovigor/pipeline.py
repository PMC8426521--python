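"""Config-driven end-to-end orchestration of the dieback analysis.

Stage order mirrors the study design: climate preparation (PET, water
balance, trends, drought thresholds) → chronology building per site × vigor
class → pointer years, resilience and vigor-group tests → bootstrapped and
moving climate-growth correlations → process-model calibration/verification
per group → limitation diagnostics → smooth seasonal-growth models. Every
stochastic stage takes its seed from the config, so a rerun reproduces the
report exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chronology as chron
from . import climate as climod
from . import climate_growth as cg
from . import disturbance as dist
from . import growth_smoothing as gs
from . import vs_model as vs
from .rwl import read_rwl

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunReport", "run", "load_config"]

DEFAULTS = {
    "latitude": 41.1,
    "elevation": 800.0,
    "span_mode": "intermediate",
    "event_years": list(dist.DEFAULT_EVENT_YEARS),
    "calib_period": [1930, 1969],
    "verif_period": [1970, 2019],
    "nboot": 1000,
    "moving_window": 30,
    "moving_nboot": 200,
    "run_moving": False,
    "run_smooth": True,
    "smooth_permutations": 99,
    "seed": 0,
    "calib_maxiter": 30,
    "calib_popsize": 6,
    "eps_threshold": 0.85,
    "alpha_levels": [0.05, 0.01],
}


@dataclass
class RunConfig:
    climate_csv: str | None = None
    rwl_file: str | None = None
    metadata_csv: str | None = None
    outdir: str = "outputs"
    options: dict = field(default_factory=dict)

    def opt(self, key):
        return self.options.get(key, DEFAULTS[key])

    @property
    def config_hash(self) -> str:
        blob = json.dumps({
            "climate_csv": self.climate_csv, "rwl_file": self.rwl_file,
            "metadata_csv": self.metadata_csv, "options": self.options,
        }, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    opts = raw.get("options", {})
    unknown = set(opts) - set(DEFAULTS)
    if unknown:
        logger.warning("config: ignoring unknown option(s): %s", sorted(unknown))
        for k in unknown:
            opts.pop(k)
    return RunConfig(climate_csv=raw.get("climate_csv"),
                     rwl_file=raw.get("rwl_file"),
                     metadata_csv=raw.get("metadata_csv"),
                     outdir=raw.get("outdir", "outputs"), options=opts)


@dataclass
class RunReport:
    stages: dict = field(default_factory=dict)
    statistics: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)
    config_hash: str = ""

    def mark(self, stage: str, status: str, reason: str = "") -> None:
        self.stages[stage] = {"status": status, "reason": reason}

    @property
    def failed(self) -> bool:
        return any(s["status"] == "failed" for s in self.stages.values())

    def to_dict(self) -> dict:
        return {"config_hash": self.config_hash, "stages": self.stages,
                "statistics": self.statistics, "outputs": self.outputs}


def _save(df: pd.DataFrame, outdir: Path, name: str, report: RunReport) -> None:
    path = outdir / name
    df.to_csv(path, index=False, float_format="%.6g")
    report.outputs.append(str(path))


def run(config: RunConfig) -> RunReport:
    """Execute the full analysis; failures mark the stage and skip dependents."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(config_hash=config.config_hash)
    seed = int(config.opt("seed"))

    # ----- climate stage -------------------------------------------------
    clim = pet = None
    try:
        if config.climate_csv is None:
            raise FileNotFoundError("no climate_csv configured")
        clim = climod.read_daily_climate(config.climate_csv,
                                         latitude=config.opt("latitude"),
                                         elevation=config.opt("elevation"))
        pet = climod.penman_monteith_pet(clim)
        annual_wb = climod.water_balance(clim, pet, "year")
        _save(annual_wb, outdir, "water_balance_annual.csv", report)
        _save(climod.water_balance(clim, pet, "month"), outdir,
              "water_balance_monthly.csv", report)
        _save(climod.seasonal_summary(clim, pet), outdir,
              "seasonal_summary.csv", report)
        trend = climod.mann_kendall_trend(annual_wb["balance"].to_numpy())
        thr = climod.anomaly_thresholds(annual_wb["balance"],
                                        tuple(config.opt("alpha_levels")))
        report.statistics["climate"] = {
            "wb_mean": float(annual_wb["balance"].mean()),
            "wb_sd": float(annual_wb["balance"].std(ddof=1)),
            "wb_tau": trend.tau, "wb_tau_p": trend.p_value,
            "wb_sen_slope": trend.sen_slope,
            "thresholds": {str(a): v for a, v in thr.items()},
        }
        report.mark("climate", "completed")
    except Exception as exc:
        logger.error("climate stage failed: %s", exc)
        logger.debug(traceback.format_exc())
        report.mark("climate", "failed", str(exc))

    # ----- chronology stage ----------------------------------------------
    groups = {}
    meta = None
    if config.rwl_file is None or config.metadata_csv is None:
        report.mark("chronology", "skipped", "no ring-width inputs configured")
    else:
        try:
            series = read_rwl(config.rwl_file)
            meta = pd.read_csv(config.metadata_csv)
            by_tree = {}
            for s in series:
                tid = s.series_id[3:-1] if len(s.series_id) > 4 else s.series_id
                by_tree[s.series_id] = tid
            meta_idx = meta.set_index("tree_id")
            for s in series:
                tid = by_tree[s.series_id]
                if tid in meta_idx.index:
                    s.tree_id = tid
                    s.site = str(meta_idx.loc[tid, "site"])
                    s.vigor = str(meta_idx.loc[tid, "vigor"])
            stats_frames, rbar_frames = [], []
            for (site, vigor), grp in _group_series(series):
                std, res, det, pw = chron.build_group_chronologies(
                    grp, span_mode=config.opt("span_mode"),
                    site=site, vigor=vigor)
                st = chron.series_statistics(grp, det)
                st.insert(0, "site", site)
                st.insert(1, "group", vigor)
                stats_frames.append(st)
                rb = chron.running_rbar_eps(
                    det, eps_threshold=config.opt("eps_threshold"))
                rb.insert(0, "site", site)
                rb.insert(1, "group", vigor)
                rbar_frames.append(rb)
                groups[(site, vigor)] = {"standard": std, "residual": res,
                                         "detrended": det, "prewhitened": pw}
                _save(pd.DataFrame({
                    "year": std.years, "standard": std.index,
                    "residual": pd.Series(res.index, index=res.years).reindex(std.years).to_numpy(),
                    "depth_trees": std.depth_trees,
                }), outdir, f"chronology_{site}_{vigor}.csv", report)
            _save(pd.concat(stats_frames, ignore_index=True), outdir,
                  "series_statistics.csv", report)
            _save(pd.concat(rbar_frames, ignore_index=True), outdir,
                  "running_rbar_eps.csv", report)
            report.statistics["chronology"] = {
                f"{site}_{vigor}": {
                    "n_series": len(g["detrended"]),
                    "max_eps": float(np.nanmax(
                        rbar_frames[i]["eps"].to_numpy())) if len(rbar_frames) > i else None,
                }
                for i, ((site, vigor), g) in enumerate(groups.items())
            }
            report.mark("chronology", "completed")
        except Exception as exc:
            logger.error("chronology stage failed: %s", exc)
            logger.debug(traceback.format_exc())
            report.mark("chronology", "failed", str(exc))

    # ----- disturbance stage ---------------------------------------------
    if not groups:
        report.mark("disturbance", "skipped", "chronology stage unavailable")
    else:
        try:
            rwi_by_tree = _tree_matrix(groups)
            cropper = rwi_by_tree.apply(dist.cropper_values)
            py = dist.pointer_years(cropper)
            _save(py.reset_index(names="year"), outdir, "pointer_years.csv", report)
            res_tab = dist.resilience_table(
                rwi_by_tree, event_years=config.opt("event_years"))
            if meta is not None and not res_tab.empty:
                res_tab = res_tab.merge(meta[["tree_id", "vigor"]], on="tree_id",
                                        how="left")
            _save(res_tab, outdir, "resilience.csv", report)
            stats = {}
            if meta is not None:
                nd = meta[meta["vigor"] == "ND"]
                d = meta[meta["vigor"] == "D"]
                if len(nd) and len(d) and "recent_rw" in meta.columns:
                    cmpres = dist.compare_groups(nd["recent_rw"], d["recent_rw"])
                    stats["recent_rw_mannwhitney"] = {
                        "u": cmpres.u, "p": cmpres.p_value,
                        "median_nd": cmpres.median_1, "median_d": cmpres.median_2}
                if "defoliation" in meta.columns and "recent_rw" in meta.columns:
                    rho, p = dist.vigor_growth_association(
                        meta["recent_rw"], meta["defoliation"])
                    stats["defoliation_spearman"] = {"rho": rho, "p": p}
            if not res_tab.empty and "vigor" in res_tab.columns:
                for idx_name in ("resistance", "recovery", "resilience"):
                    a = res_tab.loc[res_tab["vigor"] == "ND", idx_name]
                    b = res_tab.loc[res_tab["vigor"] == "D", idx_name]
                    if len(a) and len(b):
                        c = dist.compare_groups(a, b)
                        stats[f"{idx_name}_mannwhitney_p"] = c.p_value
            stats["negative_pointer_years"] = [
                int(y) for y in py.index[py["flag"] == "negative"]]
            report.statistics["disturbance"] = stats
            report.mark("disturbance", "completed")
        except Exception as exc:
            logger.error("disturbance stage failed: %s", exc)
            logger.debug(traceback.format_exc())
            report.mark("disturbance", "failed", str(exc))

    # ----- correlations stage ---------------------------------------------
    if not groups or clim is None:
        report.mark("correlations", "skipped", "inputs unavailable")
    else:
        try:
            monthly = cg.monthly_climate_table(clim, pet)
            corr_frames = []
            for (site, vigor), g in groups.items():
                res_chron = g["residual"].as_series()
                matrix = cg.build_monthly_window(monthly, res_chron.index)
                tab = cg.bootstrap_correlations(
                    res_chron, matrix, nboot=int(config.opt("nboot")), seed=seed)
                tab = tab.reset_index(names="predictor")
                tab.insert(0, "site", site)
                tab.insert(1, "group", vigor)
                corr_frames.append(tab)
                if config.opt("run_moving"):
                    mv = cg.moving_correlations(
                        res_chron, matrix, window=int(config.opt("moving_window")),
                        nboot=int(config.opt("moving_nboot")), seed=seed)
                    _save(mv, outdir, f"moving_correlations_{site}_{vigor}.csv",
                          report)
            _save(pd.concat(corr_frames, ignore_index=True), outdir,
                  "bootstrap_correlations.csv", report)
            report.statistics["correlations"] = {
                "n_tables": len(corr_frames),
                "n_significant": int(sum(f["significant"].sum() for f in corr_frames)),
            }
            report.mark("correlations", "completed")
        except Exception as exc:
            logger.error("correlations stage failed: %s", exc)
            logger.debug(traceback.format_exc())
            report.mark("correlations", "failed", str(exc))

    # ----- growth model stage ---------------------------------------------
    sims = {}
    if not groups or clim is None:
        report.mark("vs_model", "skipped", "inputs unavailable")
    else:
        try:
            calib = tuple(config.opt("calib_period"))
            verif = tuple(config.opt("verif_period"))
            vstats = {}
            for (site, vigor), g in groups.items():
                obs = g["standard"].as_series()
                result = vs.calibrate(clim, obs, calib_period=calib, seed=seed,
                                      maxiter=int(config.opt("calib_maxiter")),
                                      popsize=int(config.opt("calib_popsize")))
                result = vs.verify(result, clim, obs, verif_period=verif)
                sim = vs.simulate(clim, result.params)
                sims[(site, vigor)] = sim
                vstats[f"{site}_{vigor}"] = {
                    "r_calibration": result.r_calibration,
                    "r_verification": result.r_verification,
                    "rmse_calibration": result.rmse_calibration,
                    "rmse_verification": result.rmse_verification,
                    "params": result.params.to_dict(),
                }
                daily = sim.daily.reset_index()
                daily["date"] = daily["date"].dt.strftime("%Y-%m-%d")
                _save(daily, outdir, f"vs_daily_{site}_{vigor}.csv", report)
                lim = vs.limitation_summary(
                    sim, (calib[0], calib[1]), (verif[0], verif[1]))
                vstats[f"{site}_{vigor}"]["class_fractions"] = {
                    k: lim[p]["class_fractions"] for k, p in
                    (("calibration", "A"), ("verification", "B"))}
            report.statistics["vs_model"] = vstats
            (outdir / "vs_calibration.json").write_text(
                json.dumps(vstats, indent=1, sort_keys=True))
            report.outputs.append(str(outdir / "vs_calibration.json"))
            report.mark("vs_model", "completed")
        except Exception as exc:
            logger.error("vs_model stage failed: %s", exc)
            logger.debug(traceback.format_exc())
            report.mark("vs_model", "failed", str(exc))

    # ----- smooth stage ----------------------------------------------------
    if not sims or not config.opt("run_smooth"):
        reason = ("smoothing disabled" if sims else "no simulations available")
        report.mark("smooth", "skipped", reason)
    else:
        try:
            seas = climod.water_balance(clim, pet, "season")
            spring = seas[seas["season"] == "spring"].set_index("year")["balance"]
            by_vigor = {}
            for (site, vigor), sim in sims.items():
                by_vigor.setdefault(vigor, sim)  # one sim per vigor class
            data = gs.assemble_gr_dataset(by_vigor, spring)
            fit = gs.fit_doy_smooth_by_group(data)
            _save(fit.curves, outdir, "gr_seasonal_curves.csv", report)
            inter = gs.fit_doy_wb_interaction(
                data, n_permutations=int(config.opt("smooth_permutations")),
                seed=seed)
            _save(inter.surface, outdir, "gr_doy_wb_surface.csv", report)
            report.statistics["smooth"] = {
                "edf": fit.edf, "r_squared": fit.r_squared, "ar1": fit.ar1,
                "t_vigor": fit.t_vigor, "p_vigor": fit.p_vigor,
                "interaction_p": inter.p_interaction,
                "interaction_edf": inter.edf_interaction,
            }
            report.mark("smooth", "completed")
        except Exception as exc:
            logger.error("smooth stage failed: %s", exc)
            logger.debug(traceback.format_exc())
            report.mark("smooth", "failed", str(exc))

    path = outdir / "report.json"
    path.write_text(json.dumps(report.to_dict(), indent=1, sort_keys=True,
                               default=_json_default))
    report.outputs.append(str(path))
    return report


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _group_series(series):
    keys = sorted({(s.site, s.vigor) for s in series})
    for key in keys:
        yield key, [s for s in series if (s.site, s.vigor) == key]


def _tree_matrix(groups) -> pd.DataFrame:
    """Tree-level standard RWI matrix (years × trees) across all groups."""
    cols = {}
    for (_site, _vigor), g in groups.items():
        for tid, s in chron._tree_level(g["detrended"]).items():
            cols[tid] = s
    return pd.DataFrame(cols)
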