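"""End-to-end orchestration: simulate or ingest a cohort, classify gaze if
needed, run the sequential-dependence analyses, and emit the full set of
result tables with provenance.

Outputs written to the run directory:

* ``trials.csv``       — the analysed trial-level data
* ``table2.csv``       — previous-trial conditioning statistics
* ``table3.csv``       — GLMM fixed effects (run-length model)
* ``table4.csv``       — run-length error proportions with significance stars
* ``table5.csv``       — median latencies with 95% CIs per group x event
* ``km_steps.csv``     — Kaplan-Meier step functions for plotting
* ``glmm_fit.json``    — coefficients, SEs, sigma_u (+ bootstrap CI), loglik
* ``manifest.json``    — config snapshot, seed, input/output hashes, versions
* ``run.log`` / ``warnings.jsonl`` — structured logging of the run
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .gaze import ClassifierConfig, classify_cohort
from .glmm import GlmmSpec, bootstrap_sigma_ci, fit_glmm, fit_summary_frame
from .records import cohort_to_frame, read_trials_csv
from .rtstats import km_step_frame, make_table5, welch_log_rt
from .seqstats import add_history_covariates, make_table2, make_table4, usable_trials
from .synth import SimConfig, read_gaze_csv, simulate_cohort

log = logging.getLogger(__name__)

MODES = ("simulate", "trial_csv", "gaze_csv")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunManifest:
    mode: str
    seed: int
    config: dict
    input_hashes: dict
    outputs: dict
    package_version: str
    started_utc: str
    finished_utc: str

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(
    mode: str,
    out_dir,
    config: SimConfig | None = None,
    seed: int | None = None,
    trial_csv=None,
    gaze_csv=None,
    gaze_meta_csv=None,
    classifier_config: ClassifierConfig | None = None,
    n_quad: int = 15,
    bootstrap_reps: int = 0,
    response_coding: str = "correct",
) -> RunManifest:
    """Execute the full analysis and write every result table.

    ``mode`` selects the input source: ``simulate`` generates a cohort from
    ``config`` (seed overridable); ``trial_csv`` ingests classified trials;
    ``gaze_csv`` classifies raw samples first (``gaze_meta_csv`` supplies
    per-trial target sides and groups). Any stage failure raises
    :class:`PipelineError` naming the stage.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    started = time.strftime("%Y-%m-%dT%H:%M:%SZ", time.gmtime())

    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("antiseq")
    root.addHandler(handler)
    input_hashes: dict = {}
    caught: list[dict] = []
    try:
        with warnings.catch_warnings(record=True) as wlist:
            warnings.simplefilter("always")
            manifest = _run_stages(
                mode, out, config, seed, trial_csv, gaze_csv, gaze_meta_csv,
                classifier_config, n_quad, bootstrap_reps, response_coding,
                input_hashes, started,
            )
            caught = [
                {"category": type(w.message).__name__, "message": str(w.message)}
                for w in wlist
            ]
        with open(out / "warnings.jsonl", "w") as fh:
            for item in caught:
                fh.write(json.dumps(item) + "\n")
        return manifest
    finally:
        root.removeHandler(handler)
        handler.close()


def _run_stages(mode, out, config, seed, trial_csv, gaze_csv, gaze_meta_csv,
                classifier_config, n_quad, bootstrap_reps, response_coding,
                input_hashes, started) -> RunManifest:
    # --- stage: input -----------------------------------------------------
    try:
        if mode == "simulate":
            config = config or SimConfig()
            if seed is not None:
                config = dataclasses.replace(config, seed=seed)
            df = cohort_to_frame(simulate_cohort(config))
        elif mode == "trial_csv":
            input_hashes["trial_csv"] = _sha256(trial_csv)
            df = read_trials_csv(trial_csv)
        else:
            input_hashes["gaze_csv"] = _sha256(gaze_csv)
            input_hashes["gaze_meta_csv"] = _sha256(gaze_meta_csv)
            samples = read_gaze_csv(gaze_csv)
            meta = pd.read_csv(gaze_meta_csv)
            df = classify_cohort(samples, meta, classifier_config)
        df.to_csv(out / "trials.csv", index=False)
        log.info("input: %d trials, %d participants", len(df),
                 df["participant_id"].nunique())
        n_excluded = int((df["outcome"] == "excluded").sum())
        if n_excluded:
            log.info("%d excluded trials dropped from analyses", n_excluded)
    except Exception as exc:
        raise PipelineError("input", exc) from exc

    # --- stage: sequential statistics ------------------------------------
    try:
        cov = add_history_covariates(df)
        make_table2(df).to_csv(out / "table2.csv", index=False)
        make_table4(df).to_csv(out / "table4.csv", index=False)
    except Exception as exc:
        raise PipelineError("seqstats", exc) from exc

    # --- stage: GLMM ------------------------------------------------------
    try:
        spec = GlmmSpec(fixed=("group", "n_prev_success", "n_prev_fail"),
                        response_coding=response_coding)
        fit = fit_glmm(cov, spec, n_quad=n_quad)
        if not fit.converged:
            log.warning("GLMM flagged: %s", fit.message)
        summary = fit_summary_frame(fit)
        summary.to_csv(out / "table3.csv", index=False)
        fit_json = {
            "coefficients": fit.beta.to_dict(),
            "std_errors": fit.se_beta.to_dict(),
            "sigma_u": fit.sigma_u,
            "sigma_u_se": fit.sigma_u_se,
            "loglik": fit.loglik,
            "converged": fit.converged,
            "boundary": fit.boundary,
            "n_quad": fit.n_quad,
            "n_obs": fit.n_obs,
            "n_participants": fit.n_participants,
            "response_coding": response_coding,
        }
        if bootstrap_reps > 0:
            boot = bootstrap_sigma_ci(fit, B=bootstrap_reps,
                                      seed=0 if seed is None else seed)
            fit_json["sigma_u_ci95"] = list(boot.interval)
            fit_json["bootstrap_reps"] = bootstrap_reps
            fit_json["bootstrap_failures"] = boot.n_failed
        with open(out / "glmm_fit.json", "w") as fh:
            json.dump(fit_json, fh, indent=2)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("glmm", exc) from exc

    # --- stage: reaction times -------------------------------------------
    try:
        make_table5(df).to_csv(out / "table5.csv", index=False)
        km_step_frame(df).to_csv(out / "km_steps.csv", index=False)
        u = usable_trials(df)
        welch = welch_log_rt(
            u.loc[~u["is_error"], "latency_ms"].to_numpy(),
            u.loc[u["is_error"], "latency_ms"].to_numpy(),
        )
        with open(out / "rt_welch.json", "w") as fh:
            json.dump(welch, fh, indent=2)
    except Exception as exc:
        raise PipelineError("rt_survival", exc) from exc

    outputs = {
        p.name: _sha256(p)
        for p in sorted(out.iterdir())
        if p.suffix in (".csv", ".json")
    }
    manifest = RunManifest(
        mode=mode,
        seed=config.seed if (mode == "simulate" and config) else (seed or 0),
        config=dataclasses.asdict(config) if config else {},
        input_hashes=input_hashes,
        outputs=outputs,
        package_version=__version__,
        started_utc=started,
        finished_utc=time.strftime("%Y-%m-%dT%H:%M:%SZ", time.gmtime()),
    )
    manifest.to_json(out / "manifest.json")
    return manifest
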