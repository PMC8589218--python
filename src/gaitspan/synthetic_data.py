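"""Synthetic multi-study gait cohorts with known ground truth.

Emulates a pooled walking dataset of four studies with heterogeneous
age/speed/stride-length distributions: per-study covariate distributions,
smooth age- and speed-dependent joint power waveform shapes, additive
study- and subject-level random intercepts, and cycle-dependent residual
noise that is largest around push-off.  Every sampled quantity is recorded
in a ground-truth object so downstream estimates can be checked against
the exact generating mechanism.

Waveform templates are sums of Gaussian bumps at the canonical power-burst
locations (e.g. ankle push-off generation A2 near 50% of the stride, hip
generation H1 near 10% and H3 near 60%), with burst amplitudes that vary
smoothly with age and walking speed.  The default amplitude settings put
the true ankle push-off peak at age 55 and scale the hip bursts with speed
at magnitudes typical of adult walking (a fraction of a W/kg to a few
W/kg).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

CYCLE = np.arange(101)
JOINTS = ("ankle", "knee", "hip")

LONG_COLUMNS = [
    "study", "subject", "joint", "sex", "age", "height", "mass",
    "speed", "strlen", "cycle", "power",
]

REFERENCE_SPEED = 1.25  # m/s; amplitude speed terms are centred here


# ---------------------------------------------------------------------------
# waveform templates
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BurstSpec:
    """One Gaussian power burst and its smooth amplitude surface.

    amplitude(age, speed) = base + speed_coef*(speed - 1.25)
                            + age_lin*(age - 50) - age_curv*(age - age_peak)^2
    in W/kg; center/width are in cycle points (percent of stride).
    """

    name: str
    center: float
    width: float
    base: float
    speed_coef: float = 0.0
    age_lin: float = 0.0
    age_curv: float = 0.0
    age_peak: float = 50.0

    def amplitude(self, age, speed):
        age = np.asarray(age, dtype=float)
        speed = np.asarray(speed, dtype=float)
        return (
            self.base
            + self.speed_coef * (speed - REFERENCE_SPEED)
            + self.age_lin * (age - 50.0)
            - self.age_curv * (age - self.age_peak) ** 2
        )

    def bump(self, cycle=CYCLE) -> np.ndarray:
        c = np.asarray(cycle, dtype=float)
        return np.exp(-0.5 * ((c - self.center) / self.width) ** 2)


@dataclass(frozen=True)
class WaveformTemplate:
    """A joint's waveform as amplitude-weighted Gaussian bursts."""

    joint: str
    bursts: tuple[BurstSpec, ...]

    @property
    def base_curve(self) -> np.ndarray:
        """The 101-point waveform at unit amplitude for every burst."""
        return np.sum([b.bump() for b in self.bursts], axis=0)

    @property
    def amplitude_functions(self) -> dict:
        return {b.name: b.amplitude for b in self.bursts}

    def waveform(self, age: float, speed: float, cycle=CYCLE) -> np.ndarray:
        vals = np.zeros(np.asarray(cycle, dtype=float).shape)
        for b in self.bursts:
            vals = vals + b.amplitude(age, speed) * b.bump(cycle)
        return vals

    def validate(self) -> None:
        if self.base_curve.shape != (101,):
            raise ValueError("base curve must have 101 values")
        ages = np.linspace(19, 86, 20)
        speeds = np.linspace(0.8, 1.8, 10)
        for b in self.bursts:
            vals = b.amplitude(ages[:, None], speeds[None, :])
            if not np.all(np.isfinite(vals)):
                raise ValueError(f"non-finite amplitude for burst {b.name}")


def default_templates() -> dict[str, WaveformTemplate]:
    """Smooth lifespan templates for ankle, knee and hip power.

    Ankle power is near zero outside 21-69% of the stride; the push-off
    burst A2 peaks at age 55 in the synthetic truth.  Hip H1 declines and
    H3 grows with age, and both scale strongly with walking speed.
    """
    return {
        "ankle": WaveformTemplate("ankle", (
            BurstSpec("A1", center=40.0, width=7.0, base=-0.9,
                      speed_coef=-0.4, age_lin=0.002),
            BurstSpec("A2", center=52.0, width=5.0, base=2.9,
                      speed_coef=0.3, age_curv=5e-4, age_peak=55.0),
        )),
        "knee": WaveformTemplate("knee", (
            BurstSpec("K1", center=8.0, width=5.0, base=0.5, speed_coef=0.5),
            BurstSpec("K2", center=18.0, width=6.0, base=-0.7, speed_coef=-0.4),
            BurstSpec("K3", center=40.0, width=7.0, base=0.3, speed_coef=0.2),
            BurstSpec("K4", center=60.0, width=6.0, base=-1.1,
                      speed_coef=-0.6, age_lin=-0.02),
        )),
        "hip": WaveformTemplate("hip", (
            BurstSpec("H1", center=10.0, width=7.0, base=0.55,
                      speed_coef=0.76, age_lin=-0.004),
            BurstSpec("H2", center=35.0, width=9.0, base=-0.75, speed_coef=-0.5),
            BurstSpec("H3", center=60.0, width=6.0, base=1.0,
                      speed_coef=1.35, age_lin=0.006),
        )),
    }


# ---------------------------------------------------------------------------
# cohort configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StudySpec:
    """Covariate distributions of one source study.

    Ages are truncated-normal within ``age_range``; mean walking speed
    follows an inverted-U over age peaking near 30 years (speed_peak at the
    peak, declining by speed_decline m/s per year of distance from it);
    stride length is linear in speed and height.  All sampled heights,
    masses, speeds and stride lengths are truncated to be strictly positive.
    """

    study_id: str
    age_range: tuple[float, float]
    age_mean_sd: tuple[float, float]
    height_mean_sd: tuple[float, float]
    mass_mean_sd: tuple[float, float]
    sex_ratio_female: float
    speed_peak: float = 1.45
    speed_peak_age: float = 30.0
    speed_decline: float = 0.003  # m/s per year away from the peak age
    speed_sd: float = 0.12
    stride_speed_coef: float = 0.5
    stride_height_coef: float = 0.45
    stride_intercept: float = 0.0
    stride_sd: float = 0.08

    def __post_init__(self):
        if not self.age_range[0] < self.age_range[1]:
            raise ValueError("age_range must satisfy min < max")
        if not 0.0 <= self.sex_ratio_female <= 1.0:
            raise ValueError("sex_ratio_female must lie in [0, 1]")

    def speed_mean(self, age) -> np.ndarray:
        return self.speed_peak - self.speed_decline * np.abs(
            np.asarray(age, dtype=float) - self.speed_peak_age
        )

    def stride_mean(self, speed, height) -> np.ndarray:
        return (
            self.stride_intercept
            + self.stride_speed_coef * np.asarray(speed, dtype=float)
            + self.stride_height_coef * np.asarray(height, dtype=float)
        )


def default_studies() -> list[StudySpec]:
    """Four studies emulating the pooled cohort's descriptive statistics."""
    return [
        StudySpec("taylor", (55, 86), (65.4, 6.5), (1.68, 0.09), (74.0, 14.9),
                  0.64, speed_peak=1.52),
        StudySpec("fukuchi", (21, 84), (39.4, 17.9), (1.67, 0.12), (67.7, 12.4),
                  0.45, speed_peak=1.28),
        StudySpec("horst", (19, 30), (23.1, 2.7), (1.74, 0.10), (67.9, 11.3),
                  0.51, speed_peak=1.47),
        StudySpec("schreiber", (19, 67), (38.2, 14.0), (1.74, 0.09), (72.0, 12.2),
                  0.48, speed_peak=1.20),
    ]


@dataclass(frozen=True)
class NoiseProfile:
    """Cycle-dependent residual scale sigma(cycle) = sd * multiplier(cycle).

    The dimensionless multiplier is largest around push-off (approximately
    50% of the stride), where between-stride power variability peaks.
    Residuals are sigma(cycle) times a standard normal draw by default, or a
    Student-t draw with ``df`` degrees of freedom when kind='scaled_t'
    (matching the scaled-t family's parameterization, where sigma multiplies
    the standard t variate).
    """

    sd: float = 0.15  # W/kg, baseline residual scale
    base: float = 0.6
    peak: float = 1.2
    center: float = 50.0
    width: float = 12.0
    kind: str = "normal"
    df: float = 3.0  # only used when kind == 'scaled_t'

    def multiplier(self, cycle=CYCLE) -> np.ndarray:
        c = np.asarray(cycle, dtype=float)
        return self.base + self.peak * np.exp(-0.5 * ((c - self.center) / self.width) ** 2)

    def sigma(self, cycle=CYCLE) -> np.ndarray:
        return self.sd * self.multiplier(cycle)

    def draw_standard(self, rng: np.random.Generator, size) -> np.ndarray:
        if self.kind == "normal":
            return rng.standard_normal(size)
        if self.kind == "scaled_t":
            return rng.standard_t(self.df, size)
        raise ValueError(f"unknown noise kind {self.kind!r}")


@dataclass(frozen=True)
class CohortConfig:
    studies: tuple[StudySpec, ...] = field(default_factory=lambda: tuple(default_studies()))
    n_subjects_per_study: int = 25
    joints: tuple[str, ...] = JOINTS
    noise: NoiseProfile = field(default_factory=NoiseProfile)
    study_sd: float = 0.05  # W/kg, study random-intercept scale
    subject_sd: float = 0.10  # W/kg, subject random-intercept scale
    subject_curve_sd: float = 0.0  # optional per-subject smooth perturbation
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects_per_study < 1:
            raise ValueError("n_subjects_per_study must be a positive integer")
        if not self.joints:
            raise ValueError("joints must be a non-empty subset of ankle/knee/hip")
        bad = set(self.joints) - set(JOINTS)
        if bad:
            raise ValueError(f"unknown joints {sorted(bad)}")
        if min(self.study_sd, self.subject_sd, self.subject_curve_sd, self.noise.sd) < 0:
            raise ValueError("standard deviations must be non-negative")


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------


@dataclass
class GroundTruth:
    """Everything needed to reconstruct each simulated observation exactly."""

    config: CohortConfig
    templates: dict[str, WaveformTemplate]
    subjects: pd.DataFrame  # study, subject, sex, age, height, mass, speed, strlen
    study_effects: dict[str, float]
    subject_effects: dict[str, float]
    subject_curves: dict[str, np.ndarray]  # per-subject smooth perturbation (101,)

    def mean_waveform(self, subject: str, joint: str) -> np.ndarray:
        """The noise-free 101-point waveform assigned to a subject/joint."""
        row = self.subjects.loc[self.subjects["subject"] == subject].iloc[0]
        wf = self.templates[joint].waveform(row["age"], row["speed"])
        wf = wf + self.study_effects[row["study"]] + self.subject_effects[subject]
        if subject in self.subject_curves:
            wf = wf + self.subject_curves[subject]
        return wf

    def sigma(self) -> np.ndarray:
        return self.config.noise.sigma()

    def to_json(self) -> str:
        payload = {
            "config": _config_to_dict(self.config),
            "templates": {
                j: [asdict(b) for b in t.bursts] for j, t in self.templates.items()
            },
            "subjects": self.subjects.to_dict(orient="list"),
            "study_effects": self.study_effects,
            "subject_effects": self.subject_effects,
            "subject_curves": {k: v.tolist() for k, v in self.subject_curves.items()},
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        templates = {
            j: WaveformTemplate(j, tuple(BurstSpec(**b) for b in bursts))
            for j, bursts in d["templates"].items()
        }
        return cls(
            config=_config_from_dict(d["config"]),
            templates=templates,
            subjects=pd.DataFrame(d["subjects"]),
            study_effects=d["study_effects"],
            subject_effects=d["subject_effects"],
            subject_curves={k: np.asarray(v) for k, v in d["subject_curves"].items()},
        )


def _config_to_dict(cfg: CohortConfig) -> dict:
    return {
        "studies": [asdict(s) for s in cfg.studies],
        "n_subjects_per_study": cfg.n_subjects_per_study,
        "joints": list(cfg.joints),
        "noise": asdict(cfg.noise),
        "study_sd": cfg.study_sd,
        "subject_sd": cfg.subject_sd,
        "subject_curve_sd": cfg.subject_curve_sd,
        "seed": cfg.seed,
    }


def _config_from_dict(d: dict) -> CohortConfig:
    studies = tuple(
        StudySpec(**{**s, "age_range": tuple(s["age_range"]),
                     "age_mean_sd": tuple(s["age_mean_sd"]),
                     "height_mean_sd": tuple(s["height_mean_sd"]),
                     "mass_mean_sd": tuple(s["mass_mean_sd"])})
        for s in d["studies"]
    )
    return CohortConfig(
        studies=studies,
        n_subjects_per_study=d["n_subjects_per_study"],
        joints=tuple(d["joints"]),
        noise=NoiseProfile(**d["noise"]),
        study_sd=d["study_sd"],
        subject_sd=d["subject_sd"],
        subject_curve_sd=d.get("subject_curve_sd", 0.0),
        seed=d["seed"],
    )


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


def _truncated_normal(rng, mean, sd, lo, hi, size):
    out = np.empty(size)
    todo = np.arange(size)
    for _ in range(1000):
        draw = rng.normal(mean, sd, todo.size)
        ok = (draw >= lo) & (draw <= hi)
        out[todo[ok]] = draw[ok]
        todo = todo[~ok]
        if todo.size == 0:
            return out
    out[todo] = np.clip(rng.normal(mean, sd, todo.size), lo, hi)
    return out


def _sample_subjects(config: CohortConfig, rng) -> pd.DataFrame:
    rows = []
    for spec in config.studies:
        n = config.n_subjects_per_study
        ages = _truncated_normal(
            rng, spec.age_mean_sd[0], spec.age_mean_sd[1],
            spec.age_range[0], spec.age_range[1], n,
        )
        heights = _truncated_normal(rng, *spec.height_mean_sd, 1e-6, np.inf, n)
        masses = _truncated_normal(rng, *spec.mass_mean_sd, 1e-6, np.inf, n)
        sexes = np.where(rng.random(n) < spec.sex_ratio_female, "F", "M")
        speeds = _truncated_normal_vec(rng, spec.speed_mean(ages), spec.speed_sd)
        strides = _truncated_normal_vec(
            rng, spec.stride_mean(speeds, heights), spec.stride_sd
        )
        for i in range(n):
            rows.append({
                "study": spec.study_id,
                "subject": f"{spec.study_id}_{i:03d}",
                "sex": sexes[i],
                "age": ages[i],
                "height": heights[i],
                "mass": masses[i],
                "speed": speeds[i],
                "strlen": strides[i],
            })
    return pd.DataFrame(rows)


def _truncated_normal_vec(rng, means, sd):
    means = np.asarray(means, dtype=float)
    out = means + sd * rng.standard_normal(means.shape)
    bad = out <= 0
    while np.any(bad):
        out[bad] = means[bad] + sd * rng.standard_normal(int(bad.sum()))
        bad = out <= 0
    return out


def simulate_cohort(
    config: CohortConfig, templates: dict[str, WaveformTemplate] | None = None
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a long-format multi-study cohort plus its ground truth.

    One row per subject x joint x cycle point with
    power = template(age, speed) + study effect + subject effect + eps,
    eps ~ N(0, sigma(cycle)^2).  Identical config (including seed) gives
    bit-identical output.
    """
    if templates is None:
        templates = default_templates()
    for j in config.joints:
        templates[j].validate()
    rng = np.random.default_rng(config.seed)
    subjects = _sample_subjects(config, rng)
    study_effects = {
        s.study_id: config.study_sd * rng.standard_normal()
        for s in config.studies
    }
    subject_effects = {
        sid: config.subject_sd * rng.standard_normal()
        for sid in subjects["subject"]
    }
    subject_curves: dict[str, np.ndarray] = {}
    if config.subject_curve_sd > 0:
        # smooth low-frequency per-subject deviation around the template
        phase = 2 * np.pi * CYCLE / 101.0
        for sid in subjects["subject"]:
            a = config.subject_curve_sd * rng.standard_normal(2)
            subject_curves[sid] = a[0] * np.sin(phase) + a[1] * np.cos(phase)

    sigma = config.noise.sigma()
    truth = GroundTruth(config, templates, subjects, study_effects,
                        subject_effects, subject_curves)
    frames = []
    for _, row in subjects.iterrows():
        for joint in config.joints:
            mean = truth.mean_waveform(row["subject"], joint)
            eps = sigma * config.noise.draw_standard(rng, 101)
            frames.append(pd.DataFrame({
                "study": row["study"],
                "subject": row["subject"],
                "joint": joint,
                "sex": row["sex"],
                "age": row["age"],
                "height": row["height"],
                "mass": row["mass"],
                "speed": row["speed"],
                "strlen": row["strlen"],
                "cycle": CYCLE,
                "power": mean + eps,
            }))
    data = pd.concat(frames, ignore_index=True)[LONG_COLUMNS]
    return data, truth


def true_partial_age_effect(
    truth: GroundTruth,
    joint: str,
    age_grid,
    speed: float = REFERENCE_SPEED,
) -> np.ndarray:
    """Cycle-marginalized true age effect on mean power, centered on the grid.

    effect(a) = mean over cycle points of the template waveform at (a, speed),
    minus its mean over the age grid — the oracle for partial-age-effect
    recovery checks.
    """
    if joint not in truth.templates:
        raise KeyError(f"unknown joint {joint!r}")
    ages = np.asarray(age_grid, dtype=float)
    vals = np.array([
        truth.templates[joint].waveform(a, speed).mean() for a in ages
    ])
    return vals - vals.mean()


# ---------------------------------------------------------------------------
# raw-stride fixtures for the preprocessing stage
# ---------------------------------------------------------------------------


@dataclass
class RawStride:
    """One stride's unnormalized-time kinetic series.

    Vertical GRF is zero during swing and between strides, so initial
    contact and toe-off are detectable at any threshold up to 50 N.
    """

    time: np.ndarray
    moment: np.ndarray  # (n, 3) N*m
    angular_velocity: np.ndarray  # (n, 3) rad/s
    vgrf: np.ndarray  # (n,) N
    sample_rate: float
    mass: float


def sample_raw_strides(
    truth: GroundTruth,
    subject: str,
    joint: str = "ankle",
    n_strides: int = 5,
    sample_rate: float = 100.0,
    seed: int = 0,
) -> list[RawStride]:
    """Per-stride (moment, angular velocity, vertical GRF) series.

    Each record covers one full stride (initial contact to the onset of the
    next initial contact): the moment's first component carries the subject's
    assigned power waveform (scaled by body mass) against a unit angular
    velocity, so the preprocessing pipeline reproduces the assigned
    mass-normalized waveform up to interpolation error.
    """
    if subject not in set(truth.subjects["subject"]):
        raise KeyError(f"subject {subject!r} not in cohort")
    row = truth.subjects.loc[truth.subjects["subject"] == subject].iloc[0]
    mass = float(row["mass"])
    target = truth.mean_waveform(subject, joint)
    rng = np.random.default_rng(seed)
    strides = []
    for _ in range(n_strides):
        duration = 1.05 + 0.1 * rng.random()  # s, between consecutive ICs
        n_cycle = int(round(duration * sample_rate))
        n = n_cycle + 5  # a few samples past the next initial contact
        t = np.arange(n) / sample_rate
        # sample 1 is initial contact; sample 1 + n_cycle is the next one
        phase = np.clip((np.arange(n) - 1) / n_cycle, 0.0, 1.0)
        power = np.interp(phase * 100.0, CYCLE, target)
        moment = np.zeros((n, 3))
        moment[:, 0] = mass * power
        omega = np.zeros((n, 3))
        omega[:, 0] = 1.0
        vgrf = np.zeros(n)
        n_stance = int(round(0.62 * n_cycle))
        idx = np.arange(1, 1 + n_stance)
        vgrf[idx] = 100.0 + 700.0 * np.sin(np.pi * (idx - 0.5) / n_stance)
        nxt = 1 + n_cycle
        vgrf[nxt:] = 100.0 + 700.0 * np.sin(
            np.pi * (np.arange(nxt, n) - nxt + 0.5) / n_stance
        )
        strides.append(RawStride(t, moment, omega, vgrf, sample_rate, mass))
    return strides
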