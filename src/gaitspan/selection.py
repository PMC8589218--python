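"""Structure and distribution selection by Bayesian optimization.

The mean predictor's smooth terms (which terms enter, and with how many
basis functions per margin) are searched by Bayesian optimization under a
hierarchy constraint — an interaction smooth is admissible only when all of
its lower-order parents are present — with held-out relative RMSE as the
objective: models are trained on a random two-thirds of the subjects
(scaled-t working distribution) and scored on the remaining third.  Given
the optimal structure, candidate distribution families are then compared on
the same criterion.

The Gaussian-process surrogate (Matern kernel on a scaled integer encoding)
and expected-improvement acquisition over sampled candidate configurations
are built on scikit-learn.  When the whole configuration space is no larger
than the evaluation budget, the optimizer simply enumerates it.
"""

from __future__ import annotations

import itertools
import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern, WhiteKernel
from scipy import stats

from .gamlss import CANDIDATE_TERMS, ModelStructure, fit_location_scale
from .smooth_basis import SmoothTermSpec


# ---------------------------------------------------------------------------
# relRMSE and splits
# ---------------------------------------------------------------------------


def relrmse(observed, predicted, waveform_ids) -> float:
    """Mean over waveforms of RMSE divided by the observed waveform's range.

    ``waveform_ids`` labels which waveform (typically the subject) each
    observation belongs to.  A constant observed waveform (zero range) is an
    error.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    ids = np.asarray(waveform_ids)
    if obs.shape != pred.shape or obs.shape != ids.shape:
        raise ValueError("observed, predicted and waveform ids must align")
    vals = []
    for uid in pd.unique(ids):
        m = ids == uid
        o, p = obs[m], pred[m]
        rng = o.max() - o.min()
        if rng <= 0:
            raise ValueError(f"constant observed waveform for id {uid!r}")
        vals.append(np.sqrt(np.mean((o - p) ** 2)) / rng)
    return float(np.mean(vals))


@dataclass(frozen=True)
class SplitPlan:
    train_subjects: frozenset
    test_subjects: frozenset
    fraction_train: float
    seed: int


def split_train_test(subject_ids, fraction: float = 2 / 3, seed: int = 0) -> SplitPlan:
    """Subject-level random partition: round(fraction * n) train, rest test."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    ids = sorted(set(subject_ids))
    if len(ids) < 3:
        raise ValueError("need at least 3 subjects to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    n_train = int(round(fraction * len(ids)))
    train = frozenset(ids[i] for i in perm[:n_train])
    test = frozenset(ids[i] for i in perm[n_train:])
    return SplitPlan(train, test, fraction, seed)


# ---------------------------------------------------------------------------
# configuration space and hierarchy
# ---------------------------------------------------------------------------


def term_label(variables: tuple[str, ...]) -> str:
    return f"f({','.join(variables)})"


@dataclass(frozen=True)
class TermOption:
    """One candidate smooth term: its margins and per-margin k bounds."""

    variables: tuple[str, ...]
    k_bounds: tuple[tuple[int, int], ...]  # (lo, hi) per margin
    removable: bool = True

    @property
    def label(self) -> str:
        return term_label(self.variables)

    def n_k_combos(self) -> int:
        return math.prod(hi - lo + 1 for lo, hi in self.k_bounds)


@dataclass(frozen=True)
class ConfigPoint:
    """A point of the search space: per-term basis dimensions or removal.

    ``terms`` maps a term label to a tuple of per-margin basis dimensions,
    or to None when the term is removed.  The family is fixed during the
    structure search (scaled-t working assumption).
    """

    terms: tuple[tuple[str, tuple[int, ...] | None], ...]
    family: str = "scaled_t"

    def as_dict(self) -> dict[str, tuple[int, ...] | None]:
        return dict(self.terms)

    @classmethod
    def from_dict(cls, d: dict, family: str = "scaled_t") -> "ConfigPoint":
        return cls(tuple(sorted((k, None if v is None else tuple(v)) for k, v in d.items())), family)

    def present(self, label: str) -> bool:
        return self.as_dict().get(label) is not None


def build_space(
    candidate_terms=CANDIDATE_TERMS,
    k_bounds: tuple[int, int] = (3, 25),
    removable: bool = True,
) -> list[TermOption]:
    """The default search space: one TermOption per candidate smooth."""
    return [
        TermOption(
            tuple(v),
            tuple((k_bounds[0], k_bounds[1]) for _ in v),
            removable=removable,
        )
        for v in candidate_terms
    ]


def _parents(variables: tuple[str, ...], labels: set[str]) -> list[str]:
    """Lower-order terms this interaction requires, restricted to the space."""
    req = []
    if len(variables) >= 2:
        for v in variables:
            lab = term_label((v,))
            if lab in labels:
                req.append(lab)
    if len(variables) == 3:
        for pair in itertools.combinations(variables, 2):
            lab = term_label(tuple(pair))
            if lab in labels:
                req.append(lab)
    return req


def check_hierarchy(config: ConfigPoint, space: list[TermOption]) -> tuple[bool, list[tuple[str, str]]]:
    """True iff every present interaction has all its parents present.

    Violations are (offending term, missing parent) pairs: a bivariate
    smooth is excluded when either univariate parent is removed, and the
    trivariate smooth when any of its univariate or bivariate parents is.
    """
    labels = {opt.label for opt in space}
    cfg = config.as_dict()
    unknown = set(cfg) - labels
    if unknown:
        raise KeyError(f"config references unknown terms {sorted(unknown)}")
    violations = []
    for opt in space:
        if not config.present(opt.label):
            continue
        for parent in _parents(opt.variables, labels):
            if not config.present(parent):
                violations.append((opt.label, parent))
    return (not violations), violations


def repair_or_reject(config: ConfigPoint, space: list[TermOption]) -> ConfigPoint:
    """Repair hierarchy violations by removing orphaned interactions.

    Terms are never added; removal cascades until the configuration passes
    check_hierarchy, so the operation is idempotent.
    """
    cfg = config.as_dict()
    labels = {opt.label for opt in space}
    by_label = {opt.label: opt for opt in space}
    changed = True
    while changed:
        changed = False
        for label, ks in list(cfg.items()):
            if ks is None:
                continue
            for parent in _parents(by_label[label].variables, labels):
                if cfg.get(parent) is None:
                    cfg[label] = None
                    changed = True
                    break
    return ConfigPoint.from_dict(cfg, config.family)


def config_to_terms(config: ConfigPoint) -> list[SmoothTermSpec]:
    """Translate a configuration into mean-predictor smooth term specs."""
    specs = []
    for label, ks in config.terms:
        if ks is None:
            continue
        variables = tuple(label[2:-1].split(","))
        kind = "univariate_crs" if len(variables) == 1 else "tensor"
        specs.append(SmoothTermSpec(variables, tuple(ks), kind))
    return specs


# ---------------------------------------------------------------------------
# Bayesian optimization
# ---------------------------------------------------------------------------


@dataclass
class BOTrace:
    """Evaluation history of one optimization run."""

    evaluated: list[tuple[ConfigPoint, float]] = field(default_factory=list)
    budget: int = 0

    @property
    def best(self) -> tuple[ConfigPoint, float]:
        """Minimum recorded objective; ties broken by earliest evaluation."""
        finite = [(c, v) for c, v in self.evaluated if np.isfinite(v)]
        if not finite:
            raise ValueError("no successful evaluations")
        return min(finite, key=lambda cv: cv[1])

    def to_json(self) -> str:
        return json.dumps({
            "budget": self.budget,
            "evaluated": [
                {"config": {k: (list(v) if v is not None else None)
                            for k, v in c.as_dict().items()},
                 "family": c.family,
                 "relrmse": (v if np.isfinite(v) else None),
                 "iteration": i}
                for i, (c, v) in enumerate(self.evaluated)
            ],
        })

    @classmethod
    def from_json(cls, text: str) -> "BOTrace":
        d = json.loads(text)
        ev = [
            (ConfigPoint.from_dict(e["config"], e.get("family", "scaled_t")),
             np.inf if e["relrmse"] is None else float(e["relrmse"]))
            for e in sorted(d["evaluated"], key=lambda e: e["iteration"])
        ]
        return cls(ev, d["budget"])


def space_size(space: list[TermOption]) -> int:
    """Number of raw per-term state combinations (before hierarchy filtering)."""
    return math.prod(opt.n_k_combos() + (1 if opt.removable else 0) for opt in space)


def enumerate_space(space: list[TermOption]) -> list[ConfigPoint]:
    """All hierarchy-valid configurations of a (small) space."""
    per_term = []
    for opt in space:
        states: list[tuple[int, ...] | None] = []
        if opt.removable:
            states.append(None)
        for combo in itertools.product(
            *[range(lo, hi + 1) for lo, hi in opt.k_bounds]
        ):
            states.append(tuple(combo))
        per_term.append([(opt.label, s) for s in states])
    configs = []
    for assignment in itertools.product(*per_term):
        cfg = ConfigPoint(tuple(sorted(assignment)))
        if check_hierarchy(cfg, space)[0]:
            configs.append(cfg)
    return configs


def _sample_config(space: list[TermOption], rng: np.random.Generator) -> ConfigPoint:
    terms = []
    for opt in space:
        if opt.removable and rng.random() < 0.5:
            terms.append((opt.label, None))
        else:
            ks = tuple(int(rng.integers(lo, hi + 1)) for lo, hi in opt.k_bounds)
            terms.append((opt.label, ks))
    return repair_or_reject(ConfigPoint(tuple(sorted(terms))), space)


def _encode(config: ConfigPoint, space: list[TermOption]) -> np.ndarray:
    """Integer-vector encoding: a removal flag plus scaled k per margin."""
    cfg = config.as_dict()
    feats = []
    for opt in space:
        ks = cfg.get(opt.label)
        feats.append(0.0 if ks is None else 1.0)
        for m, (lo, hi) in enumerate(opt.k_bounds):
            if ks is None:
                feats.append(0.5)  # neutral position for an absent term
            else:
                feats.append((ks[m] - lo) / max(hi - lo, 1))
    return np.asarray(feats)


def bayes_opt(
    objective,
    space: list[TermOption],
    budget: int = 60,
    seed: int = 0,
    n_initial: int = 20,
    n_candidates: int = 500,
) -> BOTrace:
    """Minimize a configuration objective with a GP surrogate.

    Starts from a random design of valid configurations, then iterates
    expected-improvement acquisition over freshly sampled (and
    hierarchy-repaired) candidates.  Objectives that raise are recorded as
    +inf and never chosen as the best.  Exhausts the space outright whenever
    it is no larger than the budget.  Deterministic given the seed.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    rng = np.random.default_rng(seed)
    trace = BOTrace(budget=budget)

    def evaluate(cfg: ConfigPoint) -> None:
        try:
            val = float(objective(cfg))
        except Exception:
            val = np.inf
        trace.evaluated.append((cfg, val))

    if space_size(space) <= budget:
        for cfg in enumerate_space(space):
            evaluate(cfg)
        return trace

    seen: set = set()
    init: list[ConfigPoint] = []
    attempts = 0
    while len(init) < min(n_initial, budget) and attempts < 50 * n_initial:
        cfg = _sample_config(space, rng)
        if cfg.terms not in seen:
            seen.add(cfg.terms)
            init.append(cfg)
        attempts += 1
    for cfg in init:
        evaluate(cfg)

    while len(trace.evaluated) < budget:
        X = np.array([_encode(c, space) for c, _ in trace.evaluated])
        y = np.array([v for _, v in trace.evaluated])
        finite = np.isfinite(y)
        if finite.sum() < 2:
            evaluate(_sample_config(space, rng))
            continue
        y_cap = y.copy()
        y_cap[~finite] = y[finite].max() + 1.0  # failed fits look bad, stay usable
        kernel = Matern(length_scale=np.ones(X.shape[1]), nu=2.5) + WhiteKernel(
            1e-4, noise_level_bounds=(1e-12, 1e2)
        )
        gp = GaussianProcessRegressor(
            kernel=kernel, normalize_y=True, random_state=int(rng.integers(2**31 - 1))
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # GP hyperparameters may hit bounds
            gp.fit(X, y_cap)
        best = y[finite].min()
        cands, enc = [], []
        for _ in range(n_candidates):
            c = _sample_config(space, rng)
            if c.terms not in seen:
                cands.append(c)
                enc.append(_encode(c, space))
        if not cands:
            break
        mu, sd = gp.predict(np.array(enc), return_std=True)
        sd = np.maximum(sd, 1e-12)
        u = (best - mu) / sd
        ei = sd * (u * stats.norm.cdf(u) + stats.norm.pdf(u))
        pick = cands[int(np.argmax(ei))]
        seen.add(pick.terms)
        evaluate(pick)
    return trace


# ---------------------------------------------------------------------------
# end-to-end selection
# ---------------------------------------------------------------------------


def _heldout_relrmse(
    data: pd.DataFrame,
    structure: ModelStructure,
    plan: SplitPlan,
    fit_kwargs: dict,
) -> float:
    train = data[data["subject"].isin(plan.train_subjects)]
    test = data[data["subject"].isin(plan.test_subjects)].reset_index(drop=True)
    model = fit_location_scale(train.reset_index(drop=True), structure, **fit_kwargs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # held-out subjects may extrapolate
        pred = model.predict(test, population_re=False)
    return relrmse(test["power"].values, pred["mu"].values, test["subject"].values)


def select_structure(
    data: pd.DataFrame,
    joint: str,
    budget: int = 60,
    seed: int = 0,
    space: list[TermOption] | None = None,
    fraction: float = 2 / 3,
    sigma_k: int = 8,
    working_family: str = "scaled_t",
    family_kwargs: dict | None = None,
    fit_kwargs: dict | None = None,
) -> tuple[ModelStructure, BOTrace]:
    """Search smooth-term inclusion and basis dimensions for one joint.

    The objective is the held-out relRMSE of a model fitted on the training
    two-thirds of subjects under the scaled-t working distribution; sex, the
    study random intercept and the subject random intercept are always in
    the model.  Returns the relRMSE-optimal structure and the full trace.
    """
    df = data[data["joint"] == joint]
    if df["subject"].nunique() < 6:
        raise ValueError("need at least 6 subjects for structure selection")
    if space is None:
        space = build_space()
    plan = split_train_test(df["subject"], fraction=fraction, seed=seed)
    fkw = dict(fit_kwargs or {})
    fam_kw = dict(family_kwargs or ({"df": 10.0} if working_family == "scaled_t" else {}))

    def objective(cfg: ConfigPoint) -> float:
        structure = ModelStructure(
            mean_terms=config_to_terms(cfg),
            sigma_k=sigma_k,
            family=working_family,
            family_kwargs=fam_kw,
        )
        return _heldout_relrmse(df, structure, plan, fkw)

    trace = bayes_opt(objective, space, budget=budget, seed=seed)
    best_cfg, _ = trace.best
    structure = ModelStructure(
        mean_terms=config_to_terms(best_cfg),
        sigma_k=sigma_k,
        family=working_family,
        family_kwargs=fam_kw,
    )
    return structure, trace


def select_distribution(
    data: pd.DataFrame,
    structure: ModelStructure,
    families: list[tuple[str, dict]],
    seed: int = 0,
    joint: str | None = None,
    fraction: float = 2 / 3,
    fit_kwargs: dict | None = None,
    match_lambdas: bool = True,
) -> tuple[str, pd.DataFrame]:
    """Compare distribution families at a fixed predictor structure.

    Refits the model per family on the training split and returns the family
    minimizing held-out relRMSE along with the per-family table; families
    whose fit fails are recorded as +inf and excluded from the choice.

    With ``match_lambdas`` (the default) the smoothing parameters are chosen
    once, under the structure's own working family, and reused for every
    candidate: the comparison is made at the selection-optimal predictors and
    matched smoothing, so it isolates the distributional assumption rather
    than re-running the smoothness choice per family.
    """
    if not families:
        raise ValueError("at least one candidate family required")
    df = data if joint is None else data[data["joint"] == joint]
    plan = split_train_test(df["subject"], fraction=fraction, seed=seed)
    fkw = dict(fit_kwargs or {})
    if match_lambdas:
        train = df[df["subject"].isin(plan.train_subjects)].reset_index(drop=True)
        ref = fit_location_scale(train, structure, **fkw)
        fkw["lambdas_mu"] = ref.lambdas_mu
        fkw["lambdas_sigma"] = ref.lambdas_sigma
        fkw.pop("n_lambda_updates", None)
    rows = []
    for name, kwargs in families:
        cand = ModelStructure(
            mean_terms=list(structure.mean_terms),
            include_sex=structure.include_sex,
            random_terms=structure.random_terms,
            sigma_k=structure.sigma_k,
            family=name,
            family_kwargs=dict(kwargs),
        )
        try:
            score = _heldout_relrmse(df, cand, plan, fkw)
        except Exception:
            score = np.inf
        rows.append({"family": name, "family_kwargs": json.dumps(kwargs), "relrmse": score})
    table = pd.DataFrame(rows)
    finite = table[np.isfinite(table["relrmse"])]
    if finite.empty:
        raise RuntimeError("every candidate family failed to fit")
    best = finite.loc[finite["relrmse"].idxmin(), "family"]
    return str(best), table
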