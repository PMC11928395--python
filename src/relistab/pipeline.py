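"""End-to-end orchestration: simulate -> screen -> measures -> fit ->
reliability -> synthesise -> stability -> report.

The run configuration is a YAML/JSON document with a mandatory master seed;
every stage derives its own child seed from it, writes plain-text outputs
(CSV/JSON) into the run directory, and can be re-run from the previous
stage's files. A manifest records per-stage outputs, seeds and warnings and
is written atomically at the end of the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import tempfile
import time
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import behaviour, reliability, rl, stability, synth, task

__all__ = ["RunConfig", "validate_config", "run_pipeline"]

log = logging.getLogger("relistab")

DEFAULT_CONFIG = {
    "seed": None,
    "outdir": "relistab_run",
    "task": {},
    "agents": {
        "n_subjects": 50,
        "model_id": "DU-2rho1a",
        "session2_gain": 0.1,
        "lapse_p": 0.0,
    },
    "screening": {"alpha_level": 0.05},
    "measures": {"names": list(behaviour.MEASURES), "method": "mean"},
    "fit": {
        "enabled": False,
        "model_ids": ["DU-2rho1a"],
        "estimator": "em",
        "max_iter": 40,
        "ibic_samples": 2000,
    },
    "synth": {
        "n_datasets": 1000,
        "n": 300,
        "noise_sds": [0.0, 0.25, 0.5, 1.0, 1.5, 2.0],
        "candidates": "fast",
    },
    "stability": {
        "n_min": 10,
        "n_max": 300,
        "step": 1,
        "widths": list(stability.DEFAULT_WIDTHS),
        "percentiles": list(stability.DEFAULT_PERCENTILES),
    },
}

_TASK_KEYS = {"n_trials", "n_reversals", "base_interval", "interval_jitter",
              "p_reward_correct", "block_len", "response_window", "seed"}
_AGENT_KEYS = {"n_subjects", "model_id", "session2_gain", "lapse_p",
               "param_dists", "rt_mu", "rt_sigma", "rt_loss_shift"}


@dataclass
class RunConfig:
    seed: int
    outdir: str
    task: dict
    agents: dict
    screening: dict
    measures: dict
    fit: dict
    synth: dict
    stability: dict

    def as_dict(self) -> dict:
        return asdict(self)


def _merge(defaults: dict, user: dict, errors: list, path: str = "") -> dict:
    out = dict(defaults)
    for key, val in user.items():
        here = f"{path}{key}"
        if key not in defaults and path not in ("task.", "agents."):
            errors.append(f"unknown key: {here}")
            continue
        if isinstance(defaults.get(key), dict) and isinstance(val, dict):
            out[key] = _merge(defaults[key], val, errors, here + ".")
        else:
            out[key] = val
    return out


def validate_config(source) -> RunConfig:
    """Parse and strictly validate a run configuration.

    ``source`` may be a path to a YAML/JSON file or a dict. All problems are
    collected and reported together in a single ValueError.
    """
    if isinstance(source, (str, os.PathLike)):
        with open(source) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = dict(source)
    errors: list[str] = []
    cfg = _merge(DEFAULT_CONFIG, user, errors)

    for key in cfg["task"]:
        if key not in _TASK_KEYS:
            errors.append(f"unknown key: task.{key}")
    for key in cfg["agents"]:
        if key not in _AGENT_KEYS:
            errors.append(f"unknown key: agents.{key}")
    if cfg["seed"] is None:
        errors.append("seed is mandatory (reproducibility)")
    if cfg["measures"]["method"] not in ("mean", "separate", "joint"):
        errors.append(f"unknown measures.method {cfg['measures']['method']!r}")
    for name in cfg["measures"]["names"]:
        if name not in behaviour.MEASURES:
            errors.append(f"unknown measure {name!r}")
    for w in cfg["stability"]["widths"]:
        if not 0 < w:
            errors.append(f"corridor half-width must be positive, got {w}")
    for p in cfg["stability"]["percentiles"]:
        if not 0 < p <= 100:
            errors.append(f"percentile out of range: {p}")
    for s in cfg["synth"]["noise_sds"]:
        if s < 0:
            errors.append(f"noise SD must be non-negative, got {s}")
    if cfg["stability"]["n_max"] > cfg["synth"]["n"]:
        errors.append("stability.n_max cannot exceed synth.n")
    try:
        task.TaskConfig(**cfg["task"])
    except (TypeError, ValueError) as exc:
        errors.append(f"task: {exc}")
    if errors:
        raise ValueError("invalid configuration:\n  " + "\n  ".join(errors))
    return RunConfig(**{k: cfg[k] for k in (
        "seed", "outdir", "task", "agents", "screening", "measures", "fit",
        "synth", "stability")})


def _child_seed(master: int, stage: str) -> np.random.SeedSequence:
    h = int(hashlib.sha256(f"{master}:{stage}".encode()).hexdigest()[:8], 16)
    return np.random.SeedSequence([master, h])


def _atomic_json(obj, path: str) -> None:
    fd, tmp = tempfile.mkstemp(dir=os.path.dirname(path) or ".")
    with os.fdopen(fd, "w") as fh:
        json.dump(obj, fh, indent=2, default=str)
    os.replace(tmp, path)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: RunConfig, outdir: str) -> pd.DataFrame:
    agents = dict(cfg.agents)
    n_subjects = agents.pop("n_subjects")
    pop = task.PopulationSpec(**{k: tuple(v) if isinstance(v, list) else v
                                 for k, v in agents.items()})
    rng = np.random.default_rng(_child_seed(cfg.seed, "simulate"))
    trials = task.simulate_cohort(pop, n_subjects, task.TaskConfig(**cfg.task), rng)
    task.write_trials(trials, os.path.join(outdir, "trials.csv"))
    return trials


def stage_screen(cfg: RunConfig, trials: pd.DataFrame, outdir: str) -> pd.DataFrame:
    rows, keep_ids = [], set(trials["subject_id"].unique())
    for (sid, sess), grp in trials.groupby(["subject_id", "session"]):
        cie = task.cie_screen(grp)
        keep = task.screen_chance(grp, cfg.screening["alpha_level"])
        rows.append({"subject_id": sid, "session": sess, "above_chance": keep,
                     **cie})
        if not keep or cie["terminated_early"] or cie["excess_missing"]:
            keep_ids.discard(sid)
    pd.DataFrame(rows).to_csv(os.path.join(outdir, "screening.csv"), index=False)
    kept = trials[trials["subject_id"].isin(keep_ids)].reset_index(drop=True)
    log.info("screening kept %d of %d subjects", len(keep_ids),
             trials["subject_id"].nunique())
    task.write_trials(kept, os.path.join(outdir, "trials_screened.csv"))
    return kept


def stage_measures(cfg: RunConfig, trials: pd.DataFrame, outdir: str) -> pd.DataFrame:
    measures = behaviour.estimate_measures(
        trials, cfg.measures["names"], cfg.measures["method"])
    measures.to_csv(os.path.join(outdir, "measures.csv"), index=False)
    return measures


def stage_fit(cfg: RunConfig, trials: pd.DataFrame, outdir: str) -> pd.DataFrame:
    """EM model fits per session; parameter estimates become measures."""
    rng = np.random.default_rng(_child_seed(cfg.seed, "fit"))
    frames, fit_json = [], {}
    for model_id in cfg.fit["model_ids"]:
        model = task.model_from_id(model_id)
        bundle = rl.fit_em(trials, model, max_iter=cfg.fit["max_iter"],
                           rng=rng, ibic_samples=cfg.fit["ibic_samples"])
        tab = bundle.params_table()
        tab["measure"] = model_id + ":" + tab["measure"]
        tab["method"] = "em"
        frames.append(tab)
        fit_json[model_id] = {
            "estimator": bundle.estimator,
            "ibic": bundle.ibic,
            "n_em_iter": bundle.n_em_iter,
            "prior_mean": bundle.prior.mean.tolist(),
            "prior_cov": bundle.prior.cov.tolist(),
            "param_names": list(model.param_names),
            "estimates": bundle.estimates.to_dict(orient="records"),
        }
    _atomic_json(fit_json, os.path.join(outdir, "fits.json"))
    out = pd.concat(frames, ignore_index=True)
    out.to_csv(os.path.join(outdir, "parameter_measures.csv"), index=False)
    return out[["subject_id", "session", "measure", "method", "value"]]


def _measure_matrix(measures: pd.DataFrame, name: str) -> pd.DataFrame:
    wide = (measures[measures["measure"] == name]
            .pivot(index="subject_id", columns="session", values="value")
            .dropna())
    wide.columns = [f"session{int(c)}" for c in wide.columns]
    return wide


def stage_reliability(cfg: RunConfig, measures: pd.DataFrame, outdir: str) -> pd.DataFrame:
    rows = []
    for name in measures["measure"].unique():
        wide = _measure_matrix(measures, name)
        try:
            vc = reliability.variance_components(wide)
            icc = reliability.icc_a1(wide)
        except ValueError as exc:
            log.warning("reliability skipped for %s: %s", name, exc)
            continue
        rows.append({
            "measure": name, "between": vc.between, "within": vc.within,
            "error": vc.error, "within_corrected": vc.within_corrected,
            "prop_between": vc.proportions[0],
            "prop_within": vc.proportions[1],
            "prop_error": vc.proportions[2],
            "icc_a1": icc.icc_a1, "ci_low": icc.ci_low, "ci_high": icc.ci_high,
            "label": icc.label, "n": vc.n,
        })
    rel = pd.DataFrame(rows)
    rel.to_csv(os.path.join(outdir, "reliability.csv"), index=False)
    return rel


def stage_synth_stability(cfg: RunConfig, measures: pd.DataFrame,
                          rel: pd.DataFrame, outdir: str) -> dict:
    """Regression-based synthesis plus the stability sweep, per measure."""
    grid = stability.default_grid(cfg.stability["n_min"], cfg.stability["n_max"],
                                  cfg.stability["step"])
    candidates = (synth.CANDIDATES_FULL if cfg.synth["candidates"] == "full"
                  else synth.CANDIDATES_FAST)
    ss = _child_seed(cfg.seed, "synth")
    pos_frames, corr_frames = [], []
    for name in rel["measure"]:
        wide = _measure_matrix(measures, name)
        x1 = wide["session1"].to_numpy()
        x2 = wide["session2"].to_numpy()
        src = rel[rel["measure"] == name].iloc[0]
        g = {"between": src["prop_between"], "within": src["prop_within"],
             "error": src["prop_error"]}
        for noise_sd in cfg.synth["noise_sds"]:
            spec = synth.build_synth_spec(
                x1, x2, measure=name, candidates=candidates,
                n_datasets=cfg.synth["n_datasets"], n=cfg.synth["n"],
                noise_sd=noise_sd)
            tag = hashlib.sha256(f"{name}:{noise_sd}".encode()).hexdigest()[:8]
            child = np.random.SeedSequence(
                entropy=ss.entropy,
                spawn_key=ss.spawn_key + (int(tag, 16),))
            ensemble = synth.generate_ensemble(spec, child)
            trajs = stability.ensemble_trajectories(ensemble, grid)
            pos = stability.pos_table(trajs, g, cfg.stability["widths"], grid)
            pos["measure"] = name
            pos["noise_sd"] = noise_sd
            pos_frames.append(pos)
            if noise_sd == 0.0:
                trajs["measure"] = name
                corr = stability.component_icc_correlation(trajs)
                corr_frames.append(corr)
            log.info("stability: measure=%s noise=%.2f done", name, noise_sd)
    pos_all = pd.concat(pos_frames, ignore_index=True)
    pos_all.to_csv(os.path.join(outdir, "pos.csv"), index=False)
    report = stability.stability_report(pos_all, cfg.stability["percentiles"],
                                        grid_max=int(grid.max()))
    report["critical_n"].to_csv(os.path.join(outdir, "critical_n.csv"), index=False)
    report["summary"].to_csv(os.path.join(outdir, "stability_summary.csv"),
                             index=False)
    if len(report["monotonicity"]):
        report["monotonicity"].to_csv(
            os.path.join(outdir, "noise_monotonicity.csv"), index=False)
    if corr_frames:
        pd.concat(corr_frames, ignore_index=True).to_csv(
            os.path.join(outdir, "component_icc_correlation.csv"), index=False)
    return report


def run_pipeline(config) -> dict:
    """Run all stages; returns the manifest (also written to the outdir)."""
    cfg = config if isinstance(config, RunConfig) else validate_config(config)
    outdir = cfg.outdir
    os.makedirs(outdir, exist_ok=True)
    manifest = {"config": cfg.as_dict(), "stages": {}, "started": time.time()}
    stage_outputs = {
        "simulate": ["trials.csv"],
        "screen": ["screening.csv", "trials_screened.csv"],
        "measures": ["measures.csv"],
        "fit": ["fits.json", "parameter_measures.csv"],
        "reliability": ["reliability.csv"],
        "stability": ["pos.csv", "critical_n.csv", "stability_summary.csv"],
    }

    def record(stage):
        manifest["stages"][stage] = {
            "outputs": [os.path.join(outdir, f) for f in stage_outputs.get(stage, [])],
            "seed": cfg.seed,
        }

    current = "simulate"
    try:
        trials = stage_simulate(cfg, outdir); record("simulate")
        current = "screen"
        kept = stage_screen(cfg, trials, outdir); record("screen")
        current = "measures"
        measures = stage_measures(cfg, kept, outdir); record("measures")
        if cfg.fit["enabled"]:
            current = "fit"
            params = stage_fit(cfg, kept, outdir); record("fit")
            measures = pd.concat([measures, params], ignore_index=True)
        current = "reliability"
        rel = stage_reliability(cfg, measures, outdir); record("reliability")
        current = "stability"
        stage_synth_stability(cfg, measures, rel, outdir); record("stability")
    except Exception as exc:
        manifest["failed_stage"] = current
        manifest["error"] = str(exc)
        _atomic_json(manifest, os.path.join(outdir, "manifest.json"))
        raise
    manifest["finished"] = time.time()
    _atomic_json(manifest, os.path.join(outdir, "manifest.json"))
    return manifest
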