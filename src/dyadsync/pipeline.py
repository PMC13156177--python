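"""End-to-end orchestration: simulate -> process -> analyze from one config.

A single YAML config governs all stages; the CLI can override the seed and
output directory. Every run writes a JSON run report whose exclusion counts
reconcile with the number of dyads in.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import behavior as bhv
from . import io as dio
from . import moderation as mod
from . import simulate as sim
from . import synchrony as syn
from .rsa import EstimatorConfig, estimate_rsa_series
from .types import DyadRecord

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Config schema violation, raised before any computation."""


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "runs/out"
    task_s: int = 300

    # simulate
    sim: sim.SimConfig = field(default_factory=sim.SimConfig)

    # rsa estimation
    adult_band: tuple[float, float] = (0.12, 0.40)
    child_band: tuple[float, float] | None = None  # must be set explicitly
    resample_hz: float = 4.0
    window_s: int = 32
    taper: str = "dpss"
    n_tapers: int = 3
    rsa_outlier_sd: float = 3.0

    # synchrony
    min_overlap: int = 30
    dyad_outlier_sd: float = 3.92

    # behavior
    uncodable_max: float = 0.5

    # analysis
    outcome: str = "child_dep_T"
    covariate_cols: tuple[str, ...] = (
        "child_medication", "pubertal_status", "pandemic_cohort")

    def estimator_config(self, role: str) -> EstimatorConfig:
        if role == "child":
            if self.child_band is None:
                raise ConfigError(
                    "child_band: no default child respiration band exists; "
                    "set it explicitly in the config"
                )
            lo, hi = self.child_band
        else:
            lo, hi = self.adult_band
        return EstimatorConfig(
            resample_hz=self.resample_hz, window_s=self.window_s,
            band_lo=lo, band_hi=hi, taper=self.taper, n_tapers=self.n_tapers,
        )

    def validate(self) -> None:
        nyq = self.resample_hz / 2
        for name, band in (("adult_band", self.adult_band),
                           ("child_band", self.child_band)):
            if band is None:
                continue
            lo, hi = band
            if not (0 < lo < hi):
                raise ConfigError(f"{name}: need 0 < lo < hi, got {band}")
            if hi >= nyq:
                raise ConfigError(
                    f"{name}: band_hi {hi} must be below the Nyquist "
                    f"frequency {nyq}"
                )
        if self.min_overlap < 2:
            raise ConfigError("min_overlap: must be >= 2")
        if self.task_s < self.window_s:
            raise ConfigError("task_s: must be >= window_s")
        self.sim.validate()


def load_config(path) -> PipelineConfig:
    """Load the YAML config; unknown keys are schema errors."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = PipelineConfig()
    sim_raw = raw.pop("simulate", {}) or {}
    known_sim = {f.name for f in dataclasses.fields(sim.SimConfig)}
    for key, val in sim_raw.items():
        if key == "outcome_model":
            cfg.sim.outcome = sim.OutcomeModel(**val)
        elif key in known_sim:
            setattr(cfg.sim, key, val)
        else:
            raise ConfigError(f"simulate.{key}: unknown config key")
    known = {f.name for f in dataclasses.fields(PipelineConfig)} - {"sim"}
    for key, val in raw.items():
        if key not in known:
            raise ConfigError(f"{key}: unknown config key")
        if key in ("adult_band", "child_band") and val is not None:
            val = tuple(float(v) for v in val)
        if key == "covariate_cols":
            val = tuple(val)
        setattr(cfg, key, val)
    cfg.sim.task_s = cfg.task_s
    cfg.validate()
    return cfg


def _fit_to_dict(fit: mod.ModerationFit) -> dict:
    return {
        "outcome": fit.outcome_name,
        "family": fit.family,
        "focal": fit.focal,
        "moderator": fit.moderator,
        "n_used": fit.n_used,
        "df_resid": fit.df_resid,
        "coef": {k: float(v) for k, v in fit.coef.items()},
        "vcov": {r: {c: float(fit.vcov.loc[r, c]) for c in fit.vcov.columns}
                 for r in fit.vcov.index} if fit.vcov is not None else None,
        "centering": fit.centering,
        "moderator_sd": fit.moderator_sd,
    }


def stage_simulate(cfg: PipelineConfig, outdir: Path, seed: int) -> dict:
    """Generate a study and write it in the io-module formats."""
    rng = np.random.default_rng(seed)
    dyads = sim.simulate_study(cfg.sim, rng)

    rows = []
    for d in dyads:
        sp = bhv.shared_positive(d.parent_affect, d.child_affect, cfg.uncodable_max)
        un = bhv.unsupportive_indicator(d.parent_ersb)
        rows.append({
            "dyad_id": d.dyad_id,
            "shared_positive_any": sp.any_ind if not sp.missing else np.nan,
            "unsupportive_any": un.any_ind if not un.missing else np.nan,
            "rsa_z": sim.envelope_oracle_z(d.truth),
        })
    summaries = pd.DataFrame(rows)
    # outcomes are generated from ground-truth synchrony/behavior, which the
    # processing stages then re-estimate from the raw streams
    complete = summaries.dropna().reset_index(drop=True)
    outcome_table, truth = sim.gen_outcome_table(cfg.sim, complete, rng)
    outcome_table = summaries[["dyad_id"]].merge(outcome_table, on="dyad_id", how="left")
    sim.write_study(dyads, outcome_table, outdir, truth=truth)
    return {"n_dyads": len(dyads), "n_outcome_complete": len(complete)}


def stage_process(cfg: PipelineConfig, outdir: Path) -> dict:
    """Estimate RSA and synchrony for every dyad and derive behavior
    summaries; writes tidy per-second RSA, the synchrony table, and the
    dyad-level analysis table."""
    data = outdir / "data"
    records = dio.assemble_dyads(
        data / "manifest.csv", data / "outcomes.csv",
        task_length_s=cfg.task_s,
    )
    proc = outdir / "processed"
    proc.mkdir(parents=True, exist_ok=True)

    rsa_rows = []
    estimates: list[syn.SynchronyEstimate] = []
    dyad_rows = []
    exclusions: dict[str, int] = {}

    for rec in records:
        est = _process_dyad(cfg, rec, rsa_rows)
        estimates.append(est)
        if est.missing:
            exclusions[est.reason] = exclusions.get(est.reason, 0) + 1
        summary = bhv.behavior_summary(
            rec.parent_affect, rec.child_affect, rec.parent_ersb,
            cfg.uncodable_max,
        )
        row = {
            "dyad_id": rec.dyad_id,
            "rsa_z": est.z if not est.missing else np.nan,
            "rsa_r": est.r if not est.missing else np.nan,
            "n_pairs": est.n_pairs,
            "shared_positive_prop": summary.shared_positive_prop,
            "shared_positive_any": summary.shared_positive_any,
            "unsupportive_prop": summary.unsupportive_prop,
            "unsupportive_any": summary.unsupportive_any,
            "parent_dep_T": rec.parent_dep_T,
            "child_dep_T": rec.child_dep_T,
        }
        for cov in cfg.covariate_cols:
            row[cov] = rec.covariates.get(cov)
        dyad_rows.append(row)

    pd.DataFrame(
        rsa_rows, columns=["dyad_id", "person", "second", "rsa", "valid"],
    ).to_csv(proc / "rsa_series.csv", index=False)
    syn.synchrony_table(estimates).to_csv(proc / "synchrony.csv", index=False)
    dyads_df = pd.DataFrame(dyad_rows)
    dyads_df.to_csv(proc / "dyads.csv", index=False)

    report = {
        "n_dyads_in": len(records),
        "n_synchrony": sum(1 for e in estimates if not e.missing),
        "synchrony_exclusions": exclusions,
        "missingness": dio.missingness_report(records),
    }
    assert report["n_dyads_in"] == report["n_synchrony"] + sum(exclusions.values())
    return report


def _process_dyad(cfg: PipelineConfig, rec: DyadRecord, rsa_rows: list) -> syn.SynchronyEstimate:
    if rec.parent_ibi is None or rec.child_ibi is None:
        return syn.SynchronyEstimate(rec.dyad_id, None, None, 0, 0, True, "missing IBI")
    try:
        diffs = {}
        for role, ibi in (("parent", rec.parent_ibi), ("child", rec.child_ibi)):
            ecfg = cfg.estimator_config(role)
            rsa, diff = estimate_rsa_series(
                ibi, ecfg, task_length_s=cfg.task_s, outlier_sd=cfg.rsa_outlier_sd,
            )
            diffs[role] = diff
            for t in range(rsa.task_length_s):
                rsa_rows.append({
                    "dyad_id": rec.dyad_id, "person": role, "second": t,
                    "rsa": rsa.values[t] if rsa.valid[t] else np.nan,
                    "valid": int(rsa.valid[t]),
                })
    except ValueError as exc:
        logger.warning("%s: RSA estimation failed: %s", rec.dyad_id, exc)
        return syn.SynchronyEstimate(rec.dyad_id, None, None, 0, 0, True, "rsa estimation failed")
    return syn.rsa_synchrony(
        diffs["parent"], diffs["child"],
        min_overlap=cfg.min_overlap, dyad_id=rec.dyad_id,
    )


def stage_analyze(cfg: PipelineConfig, outdir: Path) -> dict:
    """Screen synchrony outliers and fit the affect-model and RSA-model
    interaction regressions, with probes and regions of significance."""
    proc = outdir / "processed"
    dyads = pd.read_csv(proc / "dyads.csv", dtype={"dyad_id": str})

    estimates = [
        syn.SynchronyEstimate(row.dyad_id, row.rsa_z and np.tanh(row.rsa_z), row.rsa_z,
                              int(row.n_pairs), 0,
                              missing=bool(pd.isna(row.rsa_z)))
        for row in dyads.itertuples()
    ]
    retained, excluded = syn.flag_outlier_dyads(estimates, cfg.dyad_outlier_sd)
    excluded_ids = {e.dyad_id for e in excluded}
    dyads.loc[dyads["dyad_id"].isin(excluded_ids), "rsa_z"] = np.nan

    ana = outdir / "analysis"
    ana.mkdir(parents=True, exist_ok=True)
    models: dict[str, dict] = {}
    probes: list[mod.ProbeResult] = []

    # affect model: synchrony x unsupportive ERSB (both binary)
    try:
        fit_a = mod.fit_interaction_model(
            dyads, cfg.outcome,
            focal="shared_positive_any", moderator="unsupportive_any",
            covariates=["parent_dep_T", *cfg.covariate_cols],
        )
        a_probes = mod.probe_binary_levels(fit_a)
        probes.extend(a_probes)
        models["affect"] = _fit_to_dict(fit_a)
        models["affect"]["probes"] = [dataclasses.asdict(p) for p in a_probes]
    except (ValueError, KeyError) as exc:
        models["affect"] = {"error": str(exc)}

    # RSA model: parent depression moderated by RSA synchrony (continuous)
    try:
        fit_r = mod.fit_interaction_model(
            dyads, cfg.outcome,
            focal="parent_dep_T", moderator="rsa_z",
            covariates=["unsupportive_any", *cfg.covariate_cols],
        )
        r_probes = mod.probe_at_sd_levels(fit_r)
        region = mod.region_of_significance(fit_r)
        probes.extend(r_probes)
        probes.append(region)
        models["rsa"] = _fit_to_dict(fit_r)
        models["rsa"]["probes"] = [dataclasses.asdict(p) for p in r_probes]
        models["rsa"]["region"] = dataclasses.asdict(region)
    except (ValueError, KeyError) as exc:
        models["rsa"] = {"error": str(exc)}

    with open(ana / "models.json", "w") as fh:
        json.dump(models, fh, indent=2, default=float)
    mod.probes_table(probes).to_csv(ana / "probes.csv", index=False)

    n_missing_z = int(dyads["rsa_z"].isna().sum())
    report = {
        "n_dyads_in": len(dyads),
        "n_outliers_removed": len(excluded),
        "outlier_dyads": sorted(excluded_ids),
        "n_rsa_z_missing": n_missing_z,
        "n_analyzed_rsa_model": models.get("rsa", {}).get("n_used"),
        "n_analyzed_affect_model": models.get("affect", {}).get("n_used"),
    }
    return report


def run(config_path, mode: str = "all", seed: int | None = None,
        outdir: str | None = None) -> dict:
    """Execute the requested stages and write report.json.

    Modes: simulate | process | analyze | all. Schema violations raise
    before any computation; a failing stage leaves partial artifacts plus a
    failed-stage marker in the report.
    """
    cfg = load_config(config_path)
    if seed is not None:
        cfg.seed = int(seed)
    if outdir is not None:
        cfg.outdir = outdir
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)

    stages = {"simulate": [stage_simulate], "process": [stage_process],
              "analyze": [stage_analyze],
              "all": [stage_simulate, stage_process, stage_analyze]}
    if mode not in stages:
        raise ConfigError(f"mode: unknown mode {mode!r}")

    report: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "mode": mode,
        "config": json.loads(json.dumps(dataclasses.asdict(cfg), default=str)),
        "stages": {},
    }
    for stage in stages[mode]:
        name = stage.__name__.removeprefix("stage_")
        try:
            if stage is stage_simulate:
                report["stages"][name] = stage(cfg, out, cfg.seed)
            else:
                report["stages"][name] = stage(cfg, out)
        except Exception as exc:  # noqa: BLE001 - partial artifacts + marker
            report["stages"][name] = {"failed": True, "error": str(exc)}
            logger.error("stage %s failed: %s", name, exc)
            break
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    return report
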