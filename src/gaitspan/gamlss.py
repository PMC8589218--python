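"""Penalized location-scale additive model for joint power waveforms.

The response y_ij (power of subject i at cycle point j, W/kg) follows

    y_ij ~ D(mu = eta_mu_ij, sigma = exp(eta_sigma_ij))

where the mean predictor eta_mu is an additive combination of an intercept,
a dummy-encoded sex effect, study- and subject-level random intercepts and
penalized smooth terms (univariate cubic regression splines and tensor
products in cycle, age, speed, height and stride length), and the scale
predictor eta_sigma is an intercept plus a cubic regression spline of the
cycle point — the cycle position dominates the residual heteroscedasticity,
with the largest spread around push-off.

Fitting follows the Rigby–Stasinopoulos backfitting scheme: the two
predictors are updated in turn by penalized Fisher-scoring (weighted least
squares on working responses), with smoothing parameters chosen by GCV on
the working model during the first outer iterations and frozen thereafter.
Once frozen, the penalized log-likelihood is required to be non-decreasing
(enforced by step-halving).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from .families import Family, get_family
from . import smooth_basis as sb
from .smooth_basis import PenalizedBasis, SmoothTermSpec

#: model term variable -> long-format CSV column
COLUMN_ALIASES = {"ht": "height"}

SIGMA_FLOOR = 1e-6

#: the candidate mean smooth terms of the waveform model
CANDIDATE_TERMS = (
    ("cycle",),
    ("age",),
    ("speed",),
    ("ht",),
    ("strlen",),
    ("cycle", "age"),
    ("cycle", "speed"),
    ("age", "speed"),
    ("cycle", "ht"),
    ("cycle", "strlen"),
    ("cycle", "age", "speed"),
)


class ConvergenceError(RuntimeError):
    def __init__(self, message, trace=None, model=None):
        super().__init__(message)
        self.trace = trace
        self.model = model


class SingularSystemError(np.linalg.LinAlgError):
    pass


@dataclass
class ModelStructure:
    """Declarative description of one candidate location-scale model.

    The variance predictor is always intercept + a cubic regression spline
    of cycle (``sigma_k`` basis functions); sex enters the mean linearly and
    study/subject random intercepts are always included.
    """

    mean_terms: list[SmoothTermSpec] = field(default_factory=list)
    include_sex: bool = True
    random_terms: tuple[str, ...] = ("study", "subject")
    sigma_k: int = 8
    family: str = "normal"
    family_kwargs: dict = field(default_factory=dict)

    def __post_init__(self):
        labels = [t.label for t in self.mean_terms]
        if len(labels) != len(set(labels)):
            raise ValueError("duplicate mean terms")

    def get_family(self) -> Family:
        return get_family(self.family, **self.family_kwargs)

    def to_dict(self) -> dict:
        return {
            "mean_terms": [t.to_dict() for t in self.mean_terms],
            "include_sex": self.include_sex,
            "random_terms": list(self.random_terms),
            "sigma_k": self.sigma_k,
            "family": self.family,
            "family_kwargs": dict(self.family_kwargs),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelStructure":
        return cls(
            mean_terms=[SmoothTermSpec.from_dict(t) for t in d["mean_terms"]],
            include_sex=d.get("include_sex", True),
            random_terms=tuple(d.get("random_terms", ("study", "subject"))),
            sigma_k=d.get("sigma_k", 8),
            family=d.get("family", "normal"),
            family_kwargs=d.get("family_kwargs", {}),
        )


def encode_sex(values) -> np.ndarray:
    """Dummy-encode sex: female 0, male 1; numeric values pass through."""
    arr = np.asarray(values)
    if arr.dtype.kind in "fiu":
        return arr.astype(float)
    mapping = {"F": 0.0, "f": 0.0, "female": 0.0, "M": 1.0, "m": 1.0, "male": 1.0}
    try:
        return np.array([mapping[str(v)] for v in arr], dtype=float)
    except KeyError as e:
        raise ValueError(f"cannot encode sex value {e}") from None


def _term_columns(data: pd.DataFrame, variables: tuple[str, ...]) -> list[np.ndarray]:
    cols = []
    for v in variables:
        col = COLUMN_ALIASES.get(v, v)
        if col not in data.columns:
            raise KeyError(f"covariate column {col!r} missing from data")
        arr = np.asarray(data[col], dtype=float) if v not in ("study", "subject") else np.asarray(data[col])
        if arr.dtype.kind == "f" and not np.all(np.isfinite(arr)):
            raise ValueError(f"non-finite values in covariate {col!r}")
        cols.append(arr)
    return cols


@dataclass
class AssembledDesign:
    """A full predictor design with block bookkeeping.

    ``penalties`` is a list of (column slice, penalty matrix, term label);
    ``blocks`` maps every block label to its column slice so partial effects
    can be extracted; ``bases`` holds the evaluators for new data.
    """

    X: np.ndarray
    penalties: list[tuple[slice, np.ndarray, str]]
    blocks: dict[str, slice]
    bases: dict[str, tuple[PenalizedBasis, tuple[str, ...]]]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def full_penalty(self, idx: int) -> np.ndarray:
        sl, S, _ = self.penalties[idx]
        P = np.zeros((self.p, self.p))
        P[sl, sl] = S
        return P

    def evaluate(self, data: pd.DataFrame, population_re: bool = True) -> np.ndarray:
        """Design rows for new data; random effects zeroed when population."""
        n = len(data)
        X = np.zeros((n, self.p))
        X[:, self.blocks["intercept"]] = 1.0
        if "sex" in self.blocks:
            X[:, self.blocks["sex"]] = encode_sex(data["sex"].values)[:, None]
        for label, (basis, variables) in self.bases.items():
            sl = self.blocks[label]
            if basis.kind == "random_intercept":
                if population_re:
                    continue
                X[:, sl] = basis.evaluate([np.asarray(data[variables[0]])])
            else:
                X[:, sl] = basis.evaluate(_term_columns(data, variables))
        return X


def assemble_design(data: pd.DataFrame, structure: ModelStructure) -> tuple[AssembledDesign, AssembledDesign]:
    """Build the mean and variance designs with their penalties.

    Mean block order: intercept, sex, random intercepts, smooth terms in
    declared order. Variance design: intercept + centered CRS of cycle.
    """
    n = len(data)
    cols: list[np.ndarray] = [np.ones((n, 1))]
    blocks: dict[str, slice] = {"intercept": slice(0, 1)}
    penalties: list[tuple[slice, np.ndarray, str]] = []
    bases: dict[str, tuple[PenalizedBasis, tuple[str, ...]]] = {}
    pos = 1
    if structure.include_sex:
        cols.append(encode_sex(data["sex"].values)[:, None])
        blocks["sex"] = slice(pos, pos + 1)
        pos += 1
    terms: list[SmoothTermSpec] = [
        SmoothTermSpec((g,), kind="random_intercept") for g in structure.random_terms
    ] + list(structure.mean_terms)
    for spec in terms:
        basis = sb.build_term(spec, _term_columns(data, spec.variables))
        sl = slice(pos, pos + basis.n_columns)
        cols.append(basis.design)
        blocks[spec.label] = sl
        bases[spec.label] = (basis, spec.variables)
        for S in basis.penalties:
            penalties.append((sl, S, spec.label))
        pos += basis.n_columns
    mean = AssembledDesign(np.hstack(cols), penalties, blocks, bases)

    sig_basis = sb.build_crs_basis(np.asarray(data["cycle"], float), structure.sigma_k)
    Xs = np.hstack([np.ones((n, 1)), sig_basis.design])
    sl = slice(1, 1 + sig_basis.n_columns)
    sigma = AssembledDesign(
        Xs,
        [(sl, sig_basis.penalties[0], "f_sigma(cycle)")],
        {"intercept": slice(0, 1), "f_sigma(cycle)": sl},
        {"f_sigma(cycle)": (sig_basis, ("cycle",))},
    )
    return mean, sigma


# ---------------------------------------------------------------------------
# penalized weighted least squares + GCV
# ---------------------------------------------------------------------------


def penalized_wls(
    X: np.ndarray,
    z: np.ndarray,
    w: np.ndarray,
    penalties: list[tuple[slice, np.ndarray, str]],
    lambdas: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Solve (X'WX + sum lambda_i S_i) beta = X'Wz.

    Returns (beta, A) where A is the penalized information matrix.
    """
    XtW = X.T * w
    A = XtW @ X
    for lam, (sl, S, _name) in zip(lambdas, penalties):
        A[sl, sl] += lam * S
    b = XtW @ z
    try:
        c, low = linalg.cho_factor(A)
        return linalg.cho_solve((c, low), b), A
    except linalg.LinAlgError:
        # smooth columns can lie in the span of penalized random-effect
        # indicators (e.g. a subject-constant covariate), leaving the system
        # positive definite but numerically on the edge; a relative jitter
        # resolves that without changing the estimand materially
        jitter = 1e-10 * np.trace(A) / A.shape[0]
        try:
            A_j = A + jitter * np.eye(A.shape[0])
            c, low = linalg.cho_factor(A_j)
            return linalg.cho_solve((c, low), b), A_j
        except linalg.LinAlgError:
            names = sorted({name for _, _, name in penalties})
            raise SingularSystemError(
                f"penalized system singular; check identifiability of blocks {names}"
            ) from None


def select_lambdas_gcv(
    X, z, w, penalties, lambdas0=None, grid=None, passes=2
) -> np.ndarray:
    """Coordinate-descent GCV over a log-spaced smoothing-parameter grid.

    The cross-products X'WX and X'Wz are formed once; each candidate only
    costs one Cholesky solve, so the search scales with p^3, not n p^2.
    """
    if grid is None:
        grid = 10.0 ** np.linspace(-2, 8, 11)
    lam = (
        np.full(len(penalties), 10.0)
        if lambdas0 is None
        else np.asarray(lambdas0, float).copy()
    )
    if len(penalties) == 0:
        return lam
    XtW = X.T * w
    A0 = XtW @ X
    b = XtW @ z
    zWz = float(np.sum(w * z**2))
    n = X.shape[0]

    def gcv(lambdas) -> float:
        A = A0.copy()
        for lv, (sl, S, _name) in zip(lambdas, penalties):
            A[sl, sl] += lv * S
        try:
            c = linalg.cho_factor(A)
        except linalg.LinAlgError:
            return np.inf
        beta = linalg.cho_solve(c, b)
        edf = np.trace(linalg.cho_solve(c, A0))
        rss = zWz - 2 * float(beta @ b) + float(beta @ A0 @ beta)
        denom = max(n - edf, 1e-8)
        return n * max(rss, 0.0) / denom**2

    best = gcv(lam)
    for _ in range(passes):
        for i in range(len(lam)):
            for cand in grid:
                trial = lam.copy()
                trial[i] = cand
                score = gcv(trial)
                if score < best - 1e-12:
                    best = score
                    lam = trial
    return lam


# ---------------------------------------------------------------------------
# the fitted model object
# ---------------------------------------------------------------------------


@dataclass
class FittedLSSModel:
    structure: ModelStructure
    mean_design: AssembledDesign
    sigma_design: AssembledDesign
    beta_mu: np.ndarray
    beta_sigma: np.ndarray
    lambdas_mu: np.ndarray
    lambdas_sigma: np.ndarray
    vcov_mu: np.ndarray
    loglik: float
    penalized_loglik: float
    n_obs: int
    train_ranges: dict[str, tuple[float, float]]
    train_means: dict[str, float]
    pll_trace: list[float] = field(default_factory=list)
    joint: str | None = None

    @property
    def family(self) -> Family:
        return self.structure.get_family()

    def fitted(self) -> tuple[np.ndarray, np.ndarray]:
        mu = self.mean_design.X @ self.beta_mu
        sigma = np.exp(np.clip(self.sigma_design.X @ self.beta_sigma, np.log(SIGMA_FLOOR), 50))
        return mu, sigma

    def predict(
        self, newdata: pd.DataFrame, population_re: bool = True
    ) -> pd.DataFrame:
        """Predict mu, sigma and se(mu) for new covariate rows.

        Random effects are set to zero ("population" level) unless
        ``population_re=False`` and the levels were seen in training.
        Covariates outside the training range are flagged, not rejected.
        """
        Xm = self.mean_design.evaluate(newdata, population_re=population_re)
        Xs = self.sigma_design.evaluate(newdata)
        mu = Xm @ self.beta_mu
        sigma = np.exp(np.clip(Xs @ self.beta_sigma, np.log(SIGMA_FLOOR), 50))
        se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", Xm, self.vcov_mu, Xm), 0.0))
        extrap = np.zeros(len(newdata), dtype=bool)
        for var, (lo, hi) in self.train_ranges.items():
            col = COLUMN_ALIASES.get(var, var)
            if col in newdata.columns:
                v = np.asarray(newdata[col], dtype=float)
                extrap |= (v < lo) | (v > hi)
        if extrap.any():
            warnings.warn(
                f"{int(extrap.sum())} prediction rows extrapolate beyond the "
                "training covariate range",
                stacklevel=2,
            )
        return pd.DataFrame(
            {"mu": mu, "sigma": sigma, "se_mu": se, "extrapolated": extrap}
        )

    def design_rows(self, newdata: pd.DataFrame, population_re: bool = True) -> np.ndarray:
        """Mean-design rows for new data (used by simulation-based CIs)."""
        return self.mean_design.evaluate(newdata, population_re=population_re)

    # -- serialization ------------------------------------------------------
    def to_json(self) -> str:
        blocks = {k: [v.start, v.stop] for k, v in self.mean_design.blocks.items()}
        bases = {
            k: {"basis": b.to_dict(), "variables": list(v)}
            for k, (b, v) in self.mean_design.bases.items()
        }
        payload = {
            "structure": self.structure.to_dict(),
            "joint": self.joint,
            "beta_mu": self.beta_mu.tolist(),
            "beta_sigma": self.beta_sigma.tolist(),
            "lambdas_mu": self.lambdas_mu.tolist(),
            "lambdas_sigma": self.lambdas_sigma.tolist(),
            "vcov_mu": {
                "shape": list(self.vcov_mu.shape),
                "data": self.vcov_mu.ravel().tolist(),
            },
            "loglik": self.loglik,
            "penalized_loglik": self.penalized_loglik,
            "n_obs": self.n_obs,
            "train_ranges": {k: list(v) for k, v in self.train_ranges.items()},
            "train_means": self.train_means,
            "mean_blocks": blocks,
            "mean_bases": bases,
            "sigma_basis": self.sigma_design.bases["f_sigma(cycle)"][0].to_dict(),
            "penalty_labels": [name for _, _, name in self.mean_design.penalties],
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "FittedLSSModel":
        d = json.loads(text)
        structure = ModelStructure.from_dict(d["structure"])
        blocks = {k: slice(a, b) for k, (a, b) in d["mean_blocks"].items()}
        bases = {}
        for k, spec in d["mean_bases"].items():
            bases[k] = (_basis_from_dict(spec["basis"]), tuple(spec["variables"]))
        p = len(d["beta_mu"])
        mean = AssembledDesign(np.zeros((0, p)), [], blocks, bases)
        sig_basis = _basis_from_dict(d["sigma_basis"])
        ps = len(d["beta_sigma"])
        sigma = AssembledDesign(
            np.zeros((0, ps)),
            [],
            {"intercept": slice(0, 1), "f_sigma(cycle)": slice(1, ps)},
            {"f_sigma(cycle)": (sig_basis, ("cycle",))},
        )
        vshape = d["vcov_mu"]["shape"]
        return cls(
            structure=structure,
            mean_design=mean,
            sigma_design=sigma,
            beta_mu=np.asarray(d["beta_mu"]),
            beta_sigma=np.asarray(d["beta_sigma"]),
            lambdas_mu=np.asarray(d["lambdas_mu"]),
            lambdas_sigma=np.asarray(d["lambdas_sigma"]),
            vcov_mu=np.asarray(d["vcov_mu"]["data"]).reshape(vshape),
            loglik=d["loglik"],
            penalized_loglik=d["penalized_loglik"],
            n_obs=d["n_obs"],
            train_ranges={k: tuple(v) for k, v in d["train_ranges"].items()},
            train_means=d["train_means"],
            joint=d.get("joint"),
        )


def _basis_from_dict(d: dict) -> PenalizedBasis:
    splines = [sb.CRSpline.from_dict(s) for s in d.get("splines", [])]
    centering = np.asarray(d["centering"]) if "centering" in d else None
    if centering is not None:
        p = centering.shape[1]
    elif "margin_transforms" in d:
        p = int(np.prod([np.asarray(m).shape[1] for m in d["margin_transforms"]]))
    elif "levels" in d:
        p = len(d["levels"])
    else:
        p = splines[0].k
    return PenalizedBasis(
        design=np.zeros((0, p)),
        penalties=[],
        kind=d["kind"],
        splines=splines,
        centering=centering,
        levels=d.get("levels"),
        margin_transforms=(
            [np.asarray(m) for m in d["margin_transforms"]]
            if "margin_transforms" in d
            else None
        ),
    )


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _penalty_quadform(beta, penalties, lambdas) -> float:
    total = 0.0
    for lam, (sl, S, _name) in zip(lambdas, penalties):
        b = beta[sl]
        total += lam * float(b @ S @ b)
    return total


def log_likelihood(model: FittedLSSModel, data: pd.DataFrame) -> float:
    """Sum of log densities under the model's family at predicted (mu, sigma).

    Random-effect levels seen in training contribute their estimated
    intercepts; unseen levels are treated at the population level (zero).
    """
    fam = model.family
    y = np.asarray(data["power"], dtype=float)
    Xm = model.mean_design.evaluate(data, population_re=False)
    Xs = model.sigma_design.evaluate(data)
    mu = Xm @ model.beta_mu
    sigma = np.exp(np.clip(Xs @ model.beta_sigma, np.log(SIGMA_FLOOR), 50))
    ld = fam.log_density(y, mu, sigma)
    if not np.all(np.isfinite(ld)):
        raise ValueError("log density not finite for some observations")
    return float(np.sum(ld))


def fit_location_scale(
    data: pd.DataFrame,
    structure: ModelStructure,
    *,
    lambdas_mu=None,
    lambdas_sigma=None,
    max_iter: int = 200,
    tol: float = 1e-6,
    n_lambda_updates: int = 2,
    joint: str | None = None,
) -> FittedLSSModel:
    """Fit the location-scale model by penalized backfitting.

    Alternates penalized Fisher-scoring updates of the mean predictor (given
    the current sigma) and of the log-scale predictor (given the current mu)
    until the penalized log-likelihood stabilizes.  Smoothing parameters are
    chosen by GCV on the working model during the first ``n_lambda_updates``
    outer iterations (pass ``lambdas_mu``/``lambdas_sigma`` to fix them), and
    are frozen afterwards; from that point the penalized log-likelihood must
    be non-decreasing, which step-halving enforces.
    """
    y = np.asarray(data["power"], dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite response values")
    if np.unique(y).size < 2:
        raise ValueError("need at least 2 distinct response values")
    fam = structure.get_family()
    mean, sigd = assemble_design(data, structure)

    lam_mu = None if lambdas_mu is None else np.asarray(lambdas_mu, dtype=float)
    lam_sig = None if lambdas_sigma is None else np.asarray(lambdas_sigma, dtype=float)
    fixed_mu, fixed_sig = lam_mu is not None, lam_sig is not None

    # initialize: unpenalized-ish mean fit under constant scale
    sigma0 = max(float(np.std(y)), 1e-3)
    w0 = np.full(y.size, 1.0 / sigma0**2)
    if lam_mu is None:
        lam_mu = np.full(len(mean.penalties), 10.0)
    if lam_sig is None:
        lam_sig = np.full(len(sigd.penalties), 10.0)
    beta_mu, A_mu = penalized_wls(mean.X, y, w0, mean.penalties, lam_mu)
    eta_mu = mean.X @ beta_mu
    resid_sd = max(float(np.std(y - eta_mu)), SIGMA_FLOOR)
    beta_sigma = np.zeros(sigd.p)
    beta_sigma[0] = np.log(resid_sd)
    eta_sigma = sigd.X @ beta_sigma
    sigma = np.exp(np.clip(eta_sigma, np.log(SIGMA_FLOOR), 50))

    def pll(bm, bs):
        m = mean.X @ bm
        es = sigd.X @ bs
        s = np.exp(np.clip(es, np.log(SIGMA_FLOOR), 50))
        ll = float(np.sum(fam.log_density(y, m, s)))
        return ll - 0.5 * (
            _penalty_quadform(bm, mean.penalties, lam_mu)
            + _penalty_quadform(bs, sigd.penalties, lam_sig)
        )

    current = pll(beta_mu, beta_sigma)
    trace = [current]
    frozen_at = None
    for it in range(max_iter):
        updating_lam = it < n_lambda_updates
        # ----- mean step
        w = np.maximum(fam.weight_mu(sigma), 1e-12)
        z = eta_mu + fam.score_mu(y, eta_mu, sigma) / w
        if updating_lam and not fixed_mu and mean.penalties:
            lam_mu = select_lambdas_gcv(mean.X, z, w, mean.penalties, lam_mu)
        beta_new, A_mu = penalized_wls(mean.X, z, w, mean.penalties, lam_mu)
        beta_mu, current = _accept_step(
            beta_new, beta_mu, lambda b: pll(b, beta_sigma), current,
            enforce=not updating_lam,
        )
        eta_mu = mean.X @ beta_mu

        # ----- scale step
        w_eta = np.full(y.size, max(fam.weight_eta_sigma, 1e-12))
        zs = eta_sigma + fam.score_eta_sigma(y, eta_mu, sigma) / w_eta
        if updating_lam and not fixed_sig and sigd.penalties:
            lam_sig = select_lambdas_gcv(sigd.X, zs, w_eta, sigd.penalties, lam_sig)
        bs_new, _ = penalized_wls(sigd.X, zs, w_eta, sigd.penalties, lam_sig)
        beta_sigma, current = _accept_step(
            bs_new, beta_sigma, lambda b: pll(beta_mu, b), current,
            enforce=not updating_lam,
        )
        eta_sigma = sigd.X @ beta_sigma
        sigma = np.exp(np.clip(eta_sigma, np.log(SIGMA_FLOOR), 50))

        if not updating_lam and frozen_at is None:
            frozen_at = it
            current = pll(beta_mu, beta_sigma)  # objective fixed from here on
        trace.append(current)
        if frozen_at is not None and it > frozen_at:
            if trace[-1] < trace[-2] - 1e-6:
                raise ConvergenceError(
                    "penalized log-likelihood decreased "
                    f"({trace[-2]:.8g} -> {trace[-1]:.8g})",
                    trace=trace,
                )
            if abs(trace[-1] - trace[-2]) < tol:
                break
    else:
        raise ConvergenceError(
            f"no convergence after {max_iter} outer iterations", trace=trace
        )

    mu_hat = mean.X @ beta_mu
    ll = float(np.sum(fam.log_density(y, mu_hat, sigma)))
    vcov = linalg.inv(A_mu)
    vcov = 0.5 * (vcov + vcov.T)
    ranges, means = {}, {}
    for var in ("cycle", "age", "speed", "ht", "strlen"):
        col = COLUMN_ALIASES.get(var, var)
        if col in data.columns:
            v = np.asarray(data[col], dtype=float)
            ranges[var] = (float(v.min()), float(v.max()))
            means[var] = float(v.mean())
    return FittedLSSModel(
        structure=structure,
        mean_design=mean,
        sigma_design=sigd,
        beta_mu=beta_mu,
        beta_sigma=beta_sigma,
        lambdas_mu=np.asarray(lam_mu, dtype=float),
        lambdas_sigma=np.asarray(lam_sig, dtype=float),
        vcov_mu=vcov,
        loglik=ll,
        penalized_loglik=trace[-1],
        n_obs=y.size,
        train_ranges=ranges,
        train_means=means,
        pll_trace=trace,
        joint=joint,
    )


def _accept_step(beta_new, beta_old, objective, current, enforce):
    """Step-halving acceptance; falls back to the old iterate if needed."""
    cand = objective(beta_new)
    if not enforce or cand >= current - 1e-10:
        return beta_new, cand
    step = beta_new - beta_old
    for _ in range(30):
        step *= 0.5
        trial = beta_old + step
        cand = objective(trial)
        if cand >= current - 1e-10:
            return trial, cand
    return beta_old, current
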