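"""Inference products of the fitted waveform model.

Partial age-effect curves with 95% pointwise confidence intervals,
predicted mean waveforms over an age x speed grid at fixed stride length,
the A2/H1/H3 power-burst peaks with simulation-based confidence intervals,
and overall fit statistics (relRMSE and fitted-observed correlation).

Peak confidence intervals are obtained by drawing coefficient vectors from
N(beta_mu, vcov_mu) and recomputing the windowed maximum per draw — the
maximum is a non-smooth functional, so a delta-method interval would be
unreliable.  Random effects are set to zero for all population-level
predictions, i.e. estimates are marginalized over study protocols and
subjects.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .gamlss import COLUMN_ALIASES, FittedLSSModel
from .preprocessing import ANKLE_WINDOW
from .selection import relrmse

#: default cycle windows (inclusive cycle points) for the named power bursts
PEAK_WINDOWS = {"A2": (40, 65), "H1": (0, 25), "H3": (45, 70)}

#: which joint each named burst belongs to
PEAK_JOINTS = {"A2": "ankle", "H1": "hip", "H3": "hip"}


@dataclass
class PartialEffect:
    covariate: str
    grid: np.ndarray
    effect: np.ndarray  # centered contribution to mu, W/kg
    ci_lower: np.ndarray
    ci_upper: np.ndarray


@dataclass(frozen=True)
class PredictionGridSpec:
    """Covariate grid for predicted waveforms.

    Defaults follow the reporting convention of two walking speeds and seven
    ages at a fixed stride length; sex enters at 0.5 (average over the two
    dummy levels) and height at the training mean unless overridden.
    """

    speeds: tuple[float, ...] = (1.0, 1.5)
    ages: tuple[float, ...] = (20, 30, 40, 50, 60, 70, 80)
    stride_length: float = 1.5
    sex_setting: float = 0.5
    height_setting: float | None = None  # None -> training mean


@dataclass
class PredictedWaveform:
    """A 101-point predicted mean waveform at one covariate setting.

    For the ankle, predictions are defined on cycle points 21-69 only;
    ``supported`` flags those points and values outside are zero-padded.
    """

    joint: str
    age: float
    speed: float
    stride_length: float
    cycle: np.ndarray
    mu: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    supported: np.ndarray
    design_rows: np.ndarray | None = None


@dataclass
class PeakEstimate:
    joint: str
    peak: str
    window: tuple[int, int]
    age: float
    speed: float
    value: float
    ci: tuple[float, float]
    cycle_location: int


def partial_effect(model: FittedLSSModel, covariate: str, grid) -> PartialEffect:
    """The centered univariate smooth of ``covariate`` with 95% CI.

    Evaluates the term's block at the grid values; the sum-to-zero
    constraint built into the basis makes the effect average to zero over
    the training covariate distribution.  CI = effect +/- 1.96 se from the
    block's sub-covariance.
    """
    label = f"f({covariate})"
    if label not in model.mean_design.blocks:
        raise KeyError(f"term removed: no univariate smooth of {covariate!r} in the model")
    sl = model.mean_design.blocks[label]
    basis, variables = model.mean_design.bases[label]
    grid = np.asarray(grid, dtype=float)
    B = basis.evaluate([grid])
    beta = model.beta_mu[sl]
    V = model.vcov_mu[sl, sl]
    eff = B @ beta
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", B, V, B), 0.0))
    return PartialEffect(covariate, grid, eff, eff - 1.96 * se, eff + 1.96 * se)


def marginal_age_profile(
    model: FittedLSSModel,
    age_grid,
    speed: float = 1.25,
    stride_length: float = 1.45,
    grid_spec: PredictionGridSpec | None = None,
) -> np.ndarray:
    """Cycle-marginalized age effect: mean predicted power per age, centered.

    Averages the predicted mean waveform uniformly over the cycle support at
    each grid age (other covariates fixed, random effects at population
    level) and centers the profile over the grid.  Unlike the block-based
    partial effect, this marginalizes the model's predictions, so it
    estimates the unweighted cycle-average age effect even when the age
    effect is concentrated in part of the cycle and the residual variance is
    cycle-dependent.
    """
    spec = grid_spec or PredictionGridSpec(stride_length=stride_length)
    if model.joint == "ankle":
        lo, hi = ANKLE_WINDOW
        cyc = np.arange(lo, hi + 1)
    else:
        cyc = np.arange(101)
    vals = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for a in np.asarray(age_grid, dtype=float):
            nd = _grid_frame(model, spec, a, speed, cyc)
            vals.append(float(model.predict(nd)["mu"].mean()))
    prof = np.asarray(vals)
    return prof - prof.mean()


def _grid_frame(model: FittedLSSModel, spec: PredictionGridSpec, age, speed, cycle):
    height = (
        spec.height_setting
        if spec.height_setting is not None
        else model.train_means.get("ht", 1.70)
    )
    return pd.DataFrame({
        "cycle": cycle,
        "age": age,
        "speed": speed,
        "strlen": spec.stride_length,
        COLUMN_ALIASES["ht"]: height,
        "sex": spec.sex_setting,
        "study": "population",
        "subject": "population",
    })


def predict_waveforms(
    model: FittedLSSModel, spec: PredictionGridSpec = PredictionGridSpec()
) -> list[PredictedWaveform]:
    """Predicted mean waveforms with pointwise 95% CIs over the grid.

    One waveform per (speed, age) combination at the fixed stride length,
    random effects at the population level.  Ankle waveforms carry
    predictions on cycle points 21-69 and are zero-padded (and flagged)
    outside that window.
    """
    if model.joint == "ankle":
        lo, hi = ANKLE_WINDOW
        cyc = np.arange(lo, hi + 1)
    else:
        cyc = np.arange(101)
    out = []
    full = np.arange(101)
    for speed in spec.speeds:
        for age in spec.ages:
            nd = _grid_frame(model, spec, age, speed, cyc)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # grid may extrapolate mildly
                pred = model.predict(nd, population_re=True)
                rows = model.design_rows(nd, population_re=True)
            mu = np.zeros(101)
            lo_ci = np.zeros(101)
            hi_ci = np.zeros(101)
            supported = np.isin(full, cyc)
            mu[supported] = pred["mu"].values
            lo_ci[supported] = pred["mu"].values - 1.96 * pred["se_mu"].values
            hi_ci[supported] = pred["mu"].values + 1.96 * pred["se_mu"].values
            out.append(PredictedWaveform(
                joint=model.joint or "unknown",
                age=float(age),
                speed=float(speed),
                stride_length=spec.stride_length,
                cycle=full.copy(),
                mu=mu,
                ci_lower=lo_ci,
                ci_upper=hi_ci,
                supported=supported,
                design_rows=rows,
            ))
    return out


def extract_peak(
    model: FittedLSSModel,
    waveform: PredictedWaveform,
    peak: str,
    window: tuple[int, int] | None = None,
    n_draws: int = 1000,
    seed: int = 0,
) -> PeakEstimate:
    """Windowed maximum of the predicted waveform with a simulation CI.

    The point estimate is the maximum predicted mean within the window (ties
    broken toward the earliest cycle point); the CI comes from ``n_draws``
    coefficient vectors sampled from N(beta_mu, vcov_mu), taking the
    2.5/97.5 percentiles of the per-draw windowed maxima.
    """
    if window is None:
        window = PEAK_WINDOWS[peak]
    lo, hi = window
    sup = np.flatnonzero(waveform.supported)
    win = np.arange(lo, hi + 1)
    if not np.all(np.isin(win, sup)):
        raise ValueError(f"window {window} outside the waveform support")
    mu_win = waveform.mu[win]
    arg = int(np.argmax(mu_win))
    value = float(mu_win[arg])
    location = int(win[arg])
    rows = waveform.design_rows
    row_idx = np.searchsorted(sup, win)
    Xw = rows[row_idx]
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(model.beta_mu, model.vcov_mu, size=n_draws)
    maxima = (Xw @ draws.T).max(axis=0)
    ci = (float(np.percentile(maxima, 2.5)), float(np.percentile(maxima, 97.5)))
    return PeakEstimate(
        joint=waveform.joint,
        peak=peak,
        window=(lo, hi),
        age=waveform.age,
        speed=waveform.speed,
        value=value,
        ci=ci,
        cycle_location=location,
    )


def fit_statistics(model: FittedLSSModel, data: pd.DataFrame) -> tuple[float, float]:
    """(relRMSE, Pearson correlation) of fitted vs observed power.

    relRMSE averages per-subject waveform errors normalized by the observed
    range; the correlation pools all (observed, fitted) pairs.
    """
    pred = model.predict(data, population_re=False)
    obs = np.asarray(data["power"], dtype=float)
    fit = pred["mu"].values
    rel = relrmse(obs, fit, data["subject"].values)
    corr = float(np.corrcoef(obs, fit)[0, 1])
    return rel, corr


# ---------------------------------------------------------------------------
# report bundle
# ---------------------------------------------------------------------------

REPORT_SCHEMA = {
    "required": ["provenance", "fit_statistics", "partial_effects",
                 "waveforms", "peaks"],
}


def report(
    model: FittedLSSModel,
    data: pd.DataFrame,
    grid_spec: PredictionGridSpec = PredictionGridSpec(),
    peaks_spec: tuple[str, ...] | None = None,
    seed: int = 0,
    out_dir=None,
    make_plots: bool = True,
    age_effect_grid=None,
) -> dict:
    """Machine-readable inference bundle (plus figures when requested).

    Contains the partial age effect, the predicted waveform grid, the
    requested peak estimates at every (age, speed) of the grid, fit
    statistics, and provenance (seed and model structure hash).  Re-running
    with the same inputs and seed reproduces the JSON byte for byte.
    """
    import hashlib

    joint = model.joint or "unknown"
    if peaks_spec is None:
        peaks_spec = tuple(p for p, j in PEAK_JOINTS.items() if j == joint)
    waveforms = predict_waveforms(model, grid_spec)
    rel, corr = fit_statistics(model, data[data["joint"] == joint] if "joint" in data else data)
    if age_effect_grid is None:
        lo, hi = model.train_ranges.get("age", (20.0, 80.0))
        age_effect_grid = np.linspace(lo, hi, 61)
    effects = {}
    try:
        pe = partial_effect(model, "age", age_effect_grid)
        effects["age"] = {
            "grid": pe.grid.tolist(),
            "effect": pe.effect.tolist(),
            "ci_lower": pe.ci_lower.tolist(),
            "ci_upper": pe.ci_upper.tolist(),
        }
    except KeyError:
        effects["age"] = None  # age smooth removed by selection
    peaks = []
    for p in peaks_spec:
        for wf in waveforms:
            est = extract_peak(model, wf, p, seed=seed)
            d = asdict(est)
            d["window"] = list(d["window"])
            d["ci"] = list(d["ci"])
            peaks.append(d)
    structure_hash = hashlib.sha256(
        json.dumps(model.structure.to_dict(), sort_keys=True).encode()
    ).hexdigest()[:16]
    bundle = {
        "provenance": {
            "seed": seed,
            "joint": joint,
            "family": model.structure.family,
            "structure_hash": structure_hash,
            "n_obs": model.n_obs,
        },
        "fit_statistics": {"relrmse": rel, "correlation": corr},
        "partial_effects": effects,
        "waveforms": [
            {
                "joint": wf.joint, "age": wf.age, "speed": wf.speed,
                "stride_length": wf.stride_length,
                "cycle": wf.cycle.tolist(), "mu": wf.mu.tolist(),
                "ci_lower": wf.ci_lower.tolist(),
                "ci_upper": wf.ci_upper.tolist(),
                "supported": wf.supported.astype(int).tolist(),
            }
            for wf in waveforms
        ],
        "peaks": peaks,
    }
    validate_report(bundle)
    if out_dir is not None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(bundle, indent=1, sort_keys=True))
        if make_plots:
            _plots(bundle, out)
    return bundle


def validate_report(bundle: dict) -> None:
    missing = [k for k in REPORT_SCHEMA["required"] if k not in bundle]
    if missing:
        raise ValueError(f"report bundle missing sections {missing}")


def _plots(bundle: dict, out_dir) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    joint = bundle["provenance"]["joint"]
    eff = bundle["partial_effects"].get("age")
    if eff:
        fig, ax = plt.subplots(figsize=(5, 3.5))
        g = np.asarray(eff["grid"])
        ax.fill_between(g, eff["ci_lower"], eff["ci_upper"], alpha=0.3)
        ax.plot(g, eff["effect"])
        ax.axhline(0, color="k", lw=0.5)
        ax.set_xlabel("age (years)")
        ax.set_ylabel("partial effect on power (W/kg)")
        ax.set_title(f"{joint}: partial age effect")
        fig.tight_layout()
        fig.savefig(out_dir / "partial_age_effect.png", dpi=120)
        plt.close(fig)

    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5), sharey=True)
    speeds = sorted({wf["speed"] for wf in bundle["waveforms"]})
    for ax, sp in zip(axes, speeds):
        for wf in bundle["waveforms"]:
            if wf["speed"] == sp:
                ax.plot(wf["cycle"], wf["mu"], label=f'{wf["age"]:.0f} y')
        ax.set_title(f"{joint} power, {sp} m/s")
        ax.set_xlabel("% stride cycle")
    axes[0].set_ylabel("power (W/kg)")
    axes[0].legend(fontsize=6, ncol=2)
    fig.tight_layout()
    fig.savefig(out_dir / "predicted_waveforms.png", dpi=120)
    plt.close(fig)

    if bundle["peaks"]:
        peaks = pd.DataFrame(bundle["peaks"])
        names = peaks["peak"].unique()
        fig, axes = plt.subplots(1, len(names), figsize=(4 * len(names), 3.2),
                                 squeeze=False)
        for ax, name in zip(axes[0], names):
            sub = peaks[peaks["peak"] == name]
            for sp, grp in sub.groupby("speed"):
                lo = [c[0] for c in grp["ci"]]
                hi = [c[1] for c in grp["ci"]]
                ax.fill_between(grp["age"], lo, hi, alpha=0.3)
                ax.plot(grp["age"], grp["value"], marker="o", label=f"{sp} m/s")
            ax.set_title(name)
            ax.set_xlabel("age (years)")
            ax.set_ylabel("peak power (W/kg)")
            ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(out_dir / "peaks_vs_age.png", dpi=120)
        plt.close(fig)
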