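"""Configuration, validation and pipeline plumbing.

The pipeline stages (simulate -> [preprocess] -> select -> fit -> report)
exchange plain-text artifacts: a long-format CSV of waveform observations,
JSON for ground truth, model structures, fitted models and traces.  Every
stage draws its randomness from a seed derived from the single global seed
and the stage name, and a manifest of input hashes lets unchanged stages be
skipped on re-runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import synthetic_data as sd
from .gamlss import FittedLSSModel, ModelStructure, fit_location_scale
from .inference import PredictionGridSpec, report
from .preprocessing import restrict_cycle_support
from .selection import build_space, select_distribution, select_structure

log = logging.getLogger("gaitspan")

REQUIRED_COLUMNS = sd.LONG_COLUMNS

DEFAULT_FAMILIES = [
    ("normal", {}),
    ("scaled_t", {"df": 4.0}),
    ("logistic", {}),
]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage


def derive_seed(global_seed: int, stage: str) -> int:
    """Per-stage seed: stable hash of (global seed, stage name), < 2^31."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


# ---------------------------------------------------------------------------
# long-format CSV
# ---------------------------------------------------------------------------


def read_long_csv(path) -> pd.DataFrame:
    """Read and validate a long-format waveform dataset.

    Checks required columns, cycle in 0..100, finite power, and strictly
    positive mass/height/speed; errors cite the first offending row number
    (1-based, excluding the header).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing column(s) {missing} in {path}")
    for col in ("age", "height", "mass", "speed", "strlen", "cycle", "power"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(vals.isna().values)
        if bad.size:
            raise ValueError(f"non-numeric {col!r} at row {bad[0] + 1} of {path}")
        df[col] = vals
    cyc = df["cycle"].values
    bad = np.flatnonzero((cyc < 0) | (cyc > 100) | (cyc != np.round(cyc)))
    if bad.size:
        raise ValueError(f"cycle out of 0..100 at row {bad[0] + 1} of {path}")
    bad = np.flatnonzero(~np.isfinite(df["power"].values))
    if bad.size:
        raise ValueError(f"non-finite power at row {bad[0] + 1} of {path}")
    for col in ("mass", "height", "speed"):
        bad = np.flatnonzero(df[col].values <= 0)
        if bad.size:
            raise ValueError(f"non-positive {col!r} at row {bad[0] + 1} of {path}")
    log.info("read %d rows, %d subjects from %s", len(df), df["subject"].nunique(), path)
    return df


def write_long_csv(df: pd.DataFrame, path) -> None:
    """Write the long dataset at full float precision (round-trips exactly)."""
    df.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# pipeline configuration
# ---------------------------------------------------------------------------

_STAGE_KEYS = {
    "simulate": {"n_subjects_per_study", "joints", "study_sd", "subject_sd",
                 "noise_sd", "subject_curve_sd"},
    "select": {"joint", "budget", "terms", "k_min", "k_max", "sigma_k",
               "fraction", "families", "lambda_updates"},
    "fit": {"sigma_k", "lambda_updates"},
    "report": {"speeds", "ages", "stride_length", "sex_setting",
               "height_setting", "peaks", "n_draws"},
    "preprocess": {"threshold"},
}
_TOP_KEYS = {"seed", "out_dir", "log_level"} | set(_STAGE_KEYS)


def validate_config(config: dict) -> dict:
    """Strict schema check: unknown keys are rejected."""
    unknown = set(config) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config key(s) {sorted(unknown)}")
    for stage, keys in _STAGE_KEYS.items():
        block = config.get(stage, {})
        if not isinstance(block, dict):
            raise ValueError(f"config section {stage!r} must be a mapping")
        bad = set(block) - keys
        if bad:
            raise ValueError(f"unknown key(s) {sorted(bad)} in section {stage!r}")
    return config


def load_config(path) -> dict:
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return validate_config(cfg)


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Manifest:
    """Input hashes per stage, for artifact-based resume."""

    def __init__(self, out_dir: Path):
        self.path = out_dir / "manifest.json"
        self.data = json.loads(self.path.read_text()) if self.path.exists() else {}

    def fresh(self, stage: str, input_hash: str, outputs: list[Path]) -> bool:
        rec = self.data.get(stage)
        return (
            rec is not None
            and rec["input_hash"] == input_hash
            and all(p.exists() for p in outputs)
        )

    def record(self, stage: str, input_hash: str) -> None:
        self.data[stage] = {"input_hash": input_hash}
        self.path.write_text(json.dumps(self.data, indent=1, sort_keys=True))


def run_pipeline(config: dict, out_dir=None) -> dict[str, Path]:
    """Run simulate -> select -> fit -> report end to end.

    Each stage logs its input hash, derived seed and duration; stages whose
    inputs are unchanged since the previous run are skipped.  Returns the
    artifact paths.  A failing stage raises PipelineError naming it.
    """
    validate_config(config)
    seed = int(config.get("seed", 0))
    out = Path(out_dir or config.get("out_dir", "gaitspan_out"))
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out)
    artifacts: dict[str, Path] = {}

    def run_stage(stage, input_hash, outputs, fn):
        t0 = time.time()
        if manifest.fresh(stage, input_hash, outputs):
            log.info("stage %s: up to date, skipped", stage)
            return
        try:
            fn()
        except Exception as e:  # noqa: BLE001 - reported with stage name
            raise PipelineError(stage, str(e)) from e
        manifest.record(stage, input_hash)
        log.info("stage %s: done in %.1fs (inputs %s)", stage, time.time() - t0,
                 input_hash[:12])

    # ---- simulate
    sim_cfg = config.get("simulate", {})
    sim_seed = derive_seed(seed, "simulate")
    cohort_csv = out / "cohort.csv"
    truth_json = out / "truth.json"
    sim_hash = hashlib.sha256(
        json.dumps({"cfg": sim_cfg, "seed": sim_seed}, sort_keys=True).encode()
    ).hexdigest()

    def do_simulate():
        cfg = sd.CohortConfig(
            n_subjects_per_study=sim_cfg.get("n_subjects_per_study", 25),
            joints=tuple(sim_cfg.get("joints", list(sd.JOINTS))),
            study_sd=sim_cfg.get("study_sd", 0.05),
            subject_sd=sim_cfg.get("subject_sd", 0.10),
            subject_curve_sd=sim_cfg.get("subject_curve_sd", 0.0),
            noise=sd.NoiseProfile(sd=sim_cfg.get("noise_sd", 0.15)),
            seed=sim_seed,
        )
        data, truth = sd.simulate_cohort(cfg)
        write_long_csv(data, cohort_csv)
        truth_json.write_text(truth.to_json())

    run_stage("simulate", sim_hash, [cohort_csv, truth_json], do_simulate)
    artifacts["cohort"] = cohort_csv
    artifacts["truth"] = truth_json

    # ---- select
    sel_cfg = config.get("select", {})
    joint = sel_cfg.get("joint", "hip")
    sel_seed = derive_seed(seed, "select")
    structure_json = out / "structure.json"
    trace_json = out / "trace.json"
    sel_hash = hashlib.sha256(
        (_file_hash(cohort_csv) + json.dumps({"cfg": sel_cfg, "seed": sel_seed},
                                             sort_keys=True)).encode()
    ).hexdigest()

    def do_select():
        data = restrict_cycle_support(read_long_csv(cohort_csv))
        terms = sel_cfg.get("terms", [["cycle"], ["age"], ["cycle", "age"]])
        space = build_space(
            [tuple(t) for t in terms],
            k_bounds=(sel_cfg.get("k_min", 4), sel_cfg.get("k_max", 8)),
        )
        fit_kwargs = {"n_lambda_updates": sel_cfg.get("lambda_updates", 1)}
        structure, trace = select_structure(
            data, joint,
            budget=sel_cfg.get("budget", 20),
            seed=sel_seed,
            space=space,
            sigma_k=sel_cfg.get("sigma_k", 8),
            fraction=sel_cfg.get("fraction", 2 / 3),
            fit_kwargs=fit_kwargs,
        )
        families = [tuple(f) if isinstance(f, (list, tuple)) else (f, {})
                    for f in sel_cfg.get("families", DEFAULT_FAMILIES)]
        families = [(n, dict(kw)) for n, kw in families]
        best_family, table = select_distribution(
            data, structure, families, seed=sel_seed, joint=joint,
            fit_kwargs=fit_kwargs,
        )
        chosen = next(kw for n, kw in families if n == best_family)
        structure.family = best_family
        structure.family_kwargs = chosen
        structure_json.write_text(json.dumps(
            {"structure": structure.to_dict(), "joint": joint,
             "family_table": table.to_dict(orient="records")},
            indent=1, sort_keys=True))
        trace_json.write_text(trace.to_json())

    run_stage("select", sel_hash, [structure_json, trace_json], do_select)
    artifacts["structure"] = structure_json
    artifacts["trace"] = trace_json

    # ---- fit
    fit_cfg = config.get("fit", {})
    model_json = out / "model.json"
    fit_hash = hashlib.sha256(
        (_file_hash(cohort_csv) + _file_hash(structure_json)
         + json.dumps({"cfg": fit_cfg}, sort_keys=True)).encode()
    ).hexdigest()

    def do_fit():
        data = restrict_cycle_support(read_long_csv(cohort_csv))
        spec = json.loads(structure_json.read_text())
        structure = ModelStructure.from_dict(spec["structure"])
        jdata = data[data["joint"] == spec["joint"]].reset_index(drop=True)
        model = fit_location_scale(
            jdata, structure, joint=spec["joint"],
            n_lambda_updates=fit_cfg.get("lambda_updates", 2),
        )
        model_json.write_text(model.to_json())

    run_stage("fit", fit_hash, [model_json], do_fit)
    artifacts["model"] = model_json

    # ---- report
    rep_cfg = config.get("report", {})
    rep_seed = derive_seed(seed, "report")
    report_dir = out / "report"
    report_json = report_dir / "report.json"
    rep_hash = hashlib.sha256(
        (_file_hash(model_json) + _file_hash(cohort_csv)
         + json.dumps({"cfg": rep_cfg, "seed": rep_seed}, sort_keys=True)).encode()
    ).hexdigest()

    def do_report():
        data = restrict_cycle_support(read_long_csv(cohort_csv))
        model = FittedLSSModel.from_json(model_json.read_text())
        grid = PredictionGridSpec(
            speeds=tuple(rep_cfg.get("speeds", (1.0, 1.5))),
            ages=tuple(rep_cfg.get("ages", (20, 30, 40, 50, 60, 70, 80))),
            stride_length=rep_cfg.get("stride_length", 1.5),
            sex_setting=rep_cfg.get("sex_setting", 0.5),
            height_setting=rep_cfg.get("height_setting"),
        )
        peaks = rep_cfg.get("peaks")
        report(
            model, data[data["joint"] == model.joint],
            grid_spec=grid,
            peaks_spec=tuple(peaks) if peaks else None,
            seed=rep_seed,
            out_dir=report_dir,
        )

    run_stage("report", rep_hash, [report_json], do_report)
    artifacts["report"] = report_json
    return artifacts
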