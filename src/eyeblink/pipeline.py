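"""End-to-end pipeline: simulate -> score -> stats -> motor -> report.

A single YAML/JSON config drives every stage; all analysis constants (50 Hz
cutoff, 7x IQR, 0.1 NEC, latency windows, +/-50 ms timing window, 300 s
rotarod cap, alpha 0.05) are named, defaulted keys. Every stage writes its
artifacts as CSV/JSON into the output directory, alongside a QC report
(invalid-trial counts, unusable sessions, convergence flags) and a run log
(package versions, seed, config hash). Reruns with the same config and seed
produce identical numeric artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cr_metrics import aggregate_cohort, score_cohort
from .ebc_io import EBCDataset, read_ebc, write_ebc
from .motor_tasks import beam_analyze, grip_analyze, ladder_analyze, rotarod_analyze
from .simulate import MotorParams, SimParams, simulate_cohort, simulate_motor_tables
from .stats_models import FitResult, ModelSpec, fit_lmm, fit_trialwise_logistic

DEFAULT_CONFIG = {
    "seed": 0,
    "sim": {},              # SimParams overrides
    "motor": {},            # MotorParams overrides
    "input_ebc": None,      # path to an EBC-CSV file instead of simulating
    "write_traces": False,  # write the simulated cohort as EBC-CSV
    "preprocess": {"cutoff_hz": 50.0, "order": 4, "iqr_k": 7.0,
                   "ur_source": "all_us"},
    "detect": {"onset_threshold": 0.02, "sustain_ms": 10.0},
    "stats": {"enable": True, "random": "intercept"},
    "motor_stats": {"enable": True, "random": "intercept"},
    "alpha": 0.05,
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, exc: Exception):
        super().__init__(f"stage '{stage}' failed: {exc}")
        self.stage = stage


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = dict(path_or_dict or {})
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for k, v in user.items():
        if isinstance(v, dict) and isinstance(cfg.get(k), dict):
            cfg[k].update(v)
        else:
            cfg[k] = v
    return cfg


def fit_to_dict(res: FitResult) -> dict:
    out = dict(
        outcome=res.spec.outcome, family=res.spec.family,
        loglik=res.loglik, chosen_random_structure=res.chosen_random_structure,
        converged=res.converged, warnings=res.warnings,
        terms=res.terms.to_dict(orient="records"),
        coef=res.coef.to_dict(orient="records"),
        posthoc=res.posthoc.to_dict(orient="records") if len(res.posthoc) else [],
    )
    for k, v in res.extra.items():
        if isinstance(v, (int, float, str, bool)):
            out[k] = v
    return out


def run_pipeline(config, out_dir) -> Path:
    """Execute every stage and write artifacts to `out_dir`; returns it."""
    cfg = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    qc: dict = {}

    stage = "simulate"
    try:
        if cfg["input_ebc"]:
            ds = read_ebc(cfg["input_ebc"])
            trials, truth = ds.trials, None
        else:
            params = SimParams(seed=cfg["seed"], **cfg["sim"])
            trials, truth = simulate_cohort(params)
            truth.to_csv(out / "ground_truth.csv", index=False)
            if cfg["write_traces"]:
                write_ebc(EBCDataset(trials), out / "traces_wide.csv", "wide")
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    stage = "score"
    try:
        pp, det = cfg["preprocess"], cfg["detect"]
        # Nyquist guard surfaces config errors here, before any session work
        fps = trials[0].fps if trials else 0.0
        if pp["cutoff_hz"] >= fps / 2.0:
            raise ValueError(
                f"cutoff {pp['cutoff_hz']} Hz >= Nyquist {fps / 2.0} Hz")
        cr_table, summaries, session_qc = score_cohort(
            trials,
            preprocess_kwargs=dict(cutoff=pp["cutoff_hz"], order=pp["order"],
                                   k=pp["iqr_k"], ur_source=pp["ur_source"]),
            onset_threshold=det["onset_threshold"],
            sustain_ms=det["sustain_ms"])
        cr_table.to_csv(out / "cr_trials.csv", index=False)
        summaries.to_csv(out / "session_summaries.csv", index=False)
        session_qc.to_csv(out / "session_qc.csv", index=False)
        aggregate_cohort(summaries).to_csv(out / "cohort_tables.csv", index=False)
        qc["n_sessions"] = int(len(session_qc))
        qc["n_unusable_sessions"] = int((~session_qc["usable"]).sum())
        qc["n_invalid_trials"] = int(session_qc["n_invalid"].sum())
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    stage = "stats"
    fits: dict[str, dict] = {}
    if cfg["stats"]["enable"]:
        try:
            rnd = cfg["stats"]["random"]
            trial_df = cr_table.rename(columns={"mouse_id": "mouse"})
            trial_df["is_cr"] = trial_df["is_cr"].astype(int)
            sess_df = summaries.rename(columns={"mouse_id": "mouse"})
            for phase in sorted(trial_df["phase"].unique()):
                sub = trial_df[trial_df["phase"] == phase]
                if sub["is_cr"].nunique() > 1:
                    fits[f"cr_logistic_{phase}"] = fit_to_dict(
                        fit_trialwise_logistic(sub, ModelSpec(
                            outcome="is_cr", family="binomial", random=rnd)))
                ssub = sess_df[sess_df["phase"] == phase].dropna(subset=["nec_250"])
                if len(ssub):
                    fits[f"nec250_lmm_{phase}"] = fit_to_dict(fit_lmm(
                        ssub, ModelSpec(outcome="nec_250", family="gaussian",
                                        random=rnd)))
            qc["model_convergence"] = {k: v["converged"] for k, v in fits.items()}
        except Exception as exc:
            raise PipelineError(stage, exc) from exc

    stage = "motor"
    if cfg["motor_stats"]["enable"]:
        try:
            mparams = MotorParams(seed=cfg["seed"], **cfg["motor"])
            tables = simulate_motor_tables(mparams)
            for name, tab in tables.items():
                tab.to_csv(out / f"motor_{name}.csv", index=False)
            rnd = cfg["motor_stats"]["random"]
            lad_logit, lad_beta = ladder_analyze(tables["ladder"], random=rnd)
            fits["ladder_clean_sweep"] = fit_to_dict(lad_logit)
            fits["ladder_mixed_beta"] = fit_to_dict(lad_beta)
            fits["rotarod_cox"] = fit_to_dict(rotarod_analyze(tables["rotarod"]))
            fits["beam_lmm"] = fit_to_dict(beam_analyze(tables["beam"]))
            grip = grip_analyze(tables["grip"])
            d = fit_to_dict(grip)
            d["back_translated"] = grip.extra["back_translated"].to_dict(
                orient="records")
            d["difference"] = grip.extra["difference"]
            fits["grip_lmm"] = d
        except Exception as exc:
            raise PipelineError(stage, exc) from exc

    stage = "report"
    try:
        with open(out / "fits.json", "w") as fh:
            json.dump(fits, fh, indent=1, default=float)
        with open(out / "qc_report.json", "w") as fh:
            json.dump(qc, fh, indent=1)
        cfg_hash = hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]
        log = dict(package_version=__version__, numpy=np.__version__,
                   pandas=pd.__version__, seed=cfg["seed"], config_hash=cfg_hash,
                   config=cfg)
        with open(out / "run_log.json", "w") as fh:
            json.dump(log, fh, indent=1)
    except Exception as exc:
        raise PipelineError(stage, exc) from exc
    return out
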