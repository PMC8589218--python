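"""Penalized spline bases for location-scale additive gait models.

Implements the three building blocks the waveform models are assembled
from:

* univariate cubic regression splines (CRS) with knots at quantiles of
  the observed covariate and an exact integrated-squared-second-derivative
  penalty,
* tensor-product smooths built from marginal CRS bases with one marginal
  penalty (and hence one smoothing parameter) per margin,
* ridge-penalized indicator designs for study- and subject-level random
  intercepts.

Smooth blocks carry a sum-to-zero identifiability constraint over the
training data, applied through an orthonormal null-space reparameterization,
so an intercept can always accompany them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg


# ---------------------------------------------------------------------------
# cubic regression spline machinery
# ---------------------------------------------------------------------------


def place_knots(x: np.ndarray, k: int) -> np.ndarray:
    """Choose ``k`` strictly increasing knots at quantiles of unique x values.

    Uses evenly spaced order statistics of the unique values, which
    guarantees strict monotonicity whenever at least ``k`` distinct
    values exist.
    """
    ux = np.unique(np.asarray(x, dtype=float))
    if ux.size < k:
        raise ValueError(
            f"need at least k={k} distinct covariate values, got {ux.size}"
        )
    idx = np.round(np.linspace(0, ux.size - 1, k)).astype(int)
    return ux[idx]


def _crs_F_and_penalty(knots: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Map knot values to knot second derivatives; curvature penalty.

    For a natural cubic spline with values beta at the knots, the second
    derivatives at the interior knots are F @ beta and the exact curvature
    penalty  integral f''(x)^2 dx  equals beta' S beta with S = D' B^-1 D.
    """
    k = len(knots)
    h = np.diff(knots)
    D = np.zeros((k - 2, k))
    B = np.zeros((k - 2, k - 2))
    for i in range(k - 2):
        D[i, i] = 1.0 / h[i]
        D[i, i + 1] = -1.0 / h[i] - 1.0 / h[i + 1]
        D[i, i + 2] = 1.0 / h[i + 1]
        B[i, i] = (h[i] + h[i + 1]) / 3.0
        if i < k - 3:
            B[i, i + 1] = h[i + 1] / 6.0
            B[i + 1, i] = h[i + 1] / 6.0
    F_int = linalg.solve(B, D, assume_a="pos")
    S = D.T @ F_int
    # pad with zero rows for the natural boundary conditions f''=0
    F = np.vstack([np.zeros(k), F_int, np.zeros(k)])
    return F, 0.5 * (S + S.T)


class CRSpline:
    """A cubic regression spline basis parameterized by its knot values.

    The j-th basis function is the natural cubic spline interpolating an
    indicator at knot j; evaluation outside the knot range extends linearly.
    """

    def __init__(self, knots: np.ndarray):
        knots = np.asarray(knots, dtype=float)
        if knots.ndim != 1 or knots.size < 3:
            raise ValueError("need at least 3 knots")
        if np.any(np.diff(knots) <= 0):
            raise ValueError("knots must be strictly increasing")
        self.knots = knots
        self._F, self._S = _crs_F_and_penalty(knots)

    @property
    def k(self) -> int:
        return self.knots.size

    def penalty(self) -> np.ndarray:
        return self._S.copy()

    def basis(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        kn, F = self.knots, self._F
        k = kn.size
        out = np.zeros((x.size, k))
        lo, hi = kn[0], kn[-1]
        inside = (x >= lo) & (x <= hi)
        xi = np.clip(x, lo, hi)
        j = np.clip(np.searchsorted(kn, xi, side="right") - 1, 0, k - 2)
        h = kn[j + 1] - kn[j]
        dl = xi - kn[j]
        dr = kn[j + 1] - xi
        am = dr / h
        ap = dl / h
        cm = (dr**3 / h - h * dr) / 6.0
        cp = (dl**3 / h - h * dl) / 6.0
        rows = np.arange(x.size)
        out[rows, j] += am
        out[rows, j + 1] += ap
        out += cm[:, None] * F[j] + cp[:, None] * F[j + 1]
        # linear extension beyond the boundary knots
        outside = ~inside
        if np.any(outside):
            for bound, edge_j in ((lo, 0), (hi, k - 2)):
                sel = outside & ((x < lo) if edge_j == 0 else (x > hi))
                if not np.any(sel):
                    continue
                hj = kn[edge_j + 1] - kn[edge_j]
                at = bound
                dl0 = at - kn[edge_j]
                dr0 = kn[edge_j + 1] - at
                deriv = np.zeros(k)
                deriv[edge_j] += -1.0 / hj
                deriv[edge_j + 1] += 1.0 / hj
                deriv += ((-3.0 * dr0**2 / hj + hj) / 6.0) * F[edge_j]
                deriv += ((3.0 * dl0**2 / hj - hj) / 6.0) * F[edge_j + 1]
                out[sel] += (x[sel] - at)[:, None] * deriv
        return out

    def to_dict(self) -> dict:
        return {"knots": self.knots.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "CRSpline":
        return cls(np.asarray(d["knots"], dtype=float))


# ---------------------------------------------------------------------------
# term specifications and evaluated bases
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SmoothTermSpec:
    """Specification of one smooth model term.

    variables: 1-3 covariate names; basis_dims: one k per variable;
    kind: 'univariate_crs', 'tensor' or 'random_intercept'.
    """

    variables: tuple[str, ...]
    basis_dims: tuple[int, ...] = ()
    kind: str = "univariate_crs"

    def __post_init__(self):
        object.__setattr__(self, "variables", tuple(self.variables))
        object.__setattr__(self, "basis_dims", tuple(self.basis_dims))
        if not 1 <= len(self.variables) <= 3:
            raise ValueError("a smooth term takes 1-3 variables")
        if self.kind in ("univariate_crs", "tensor"):
            if len(self.basis_dims) != len(self.variables):
                raise ValueError("one basis dimension per variable required")
            if any(k < 3 for k in self.basis_dims):
                raise ValueError("spline margins need k >= 3")
        if self.kind == "univariate_crs" and len(self.variables) != 1:
            raise ValueError("univariate_crs takes exactly one variable")
        if self.kind == "tensor" and len(self.variables) < 2:
            raise ValueError("tensor smooths take 2 or 3 variables")

    @property
    def label(self) -> str:
        if self.kind == "random_intercept":
            return f"re({self.variables[0]})"
        return f"f({','.join(self.variables)})"

    def to_dict(self) -> dict:
        return {
            "variables": list(self.variables),
            "basis_dims": list(self.basis_dims),
            "kind": self.kind,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SmoothTermSpec":
        return cls(tuple(d["variables"]), tuple(d["basis_dims"]), d["kind"])


@dataclass
class PenalizedBasis:
    """An evaluated, constrained basis block with its penalties.

    ``design`` has one row per training observation.  ``penalties`` act on
    the constrained coefficient space.  ``evaluate`` reproduces design rows
    for new covariate values using the stored knots/levels and the same
    centering transform.
    """

    design: np.ndarray
    penalties: list[np.ndarray]
    kind: str
    splines: list[CRSpline] = field(default_factory=list)
    centering: np.ndarray | None = None  # (p_raw, p) null-space transform
    levels: list | None = None  # random-intercept group levels
    margin_transforms: list[np.ndarray] | None = None  # tensor margins

    @property
    def n_columns(self) -> int:
        return self.design.shape[1]

    def _raw(self, columns: list[np.ndarray]) -> np.ndarray:
        if self.kind == "univariate_crs":
            return self.splines[0].basis(columns[0])
        if self.kind == "tensor":
            mats = []
            for i, (sp, c) in enumerate(zip(self.splines, columns)):
                m = sp.basis(c)
                if self.margin_transforms is not None:
                    m = m @ self.margin_transforms[i]
                mats.append(m)
            out = mats[0]
            for m in mats[1:]:
                out = (out[:, :, None] * m[:, None, :]).reshape(out.shape[0], -1)
            return out
        raise ValueError(self.kind)

    def evaluate(self, columns: list[np.ndarray]) -> np.ndarray:
        """Design rows for new covariate columns (same order as variables)."""
        if self.kind == "random_intercept":
            labels = np.asarray(columns[0])
            idx = {lev: i for i, lev in enumerate(self.levels)}
            out = np.zeros((labels.size, len(self.levels)))
            for r, lab in enumerate(labels):
                if lab in idx:  # unseen level -> population (all zeros)
                    out[r, idx[lab]] = 1.0
            return out
        raw = self._raw(columns)
        return raw @ self.centering if self.centering is not None else raw

    def to_dict(self) -> dict:
        d = {"kind": self.kind}
        if self.splines:
            d["splines"] = [sp.to_dict() for sp in self.splines]
        if self.centering is not None:
            d["centering"] = self.centering.tolist()
        if self.levels is not None:
            d["levels"] = list(self.levels)
        if self.margin_transforms is not None:
            d["margin_transforms"] = [m.tolist() for m in self.margin_transforms]
        return d


def _sum_to_zero(raw: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal transform Z with 1' (raw @ Z) = 0 over the training rows."""
    c = raw.sum(axis=0)[:, None]
    if np.allclose(c, 0):
        Z = np.eye(raw.shape[1])[:, : raw.shape[1] - 1]
        return raw @ Z, Z
    Z = linalg.null_space(c.T)
    return raw @ Z, Z


def build_crs_basis(x: np.ndarray, k: int, knots: np.ndarray | None = None) -> PenalizedBasis:
    """Centered cubic regression spline basis with curvature penalty.

    Knots are placed at quantiles of the unique covariate values unless
    given explicitly.  Returns k-1 columns after the sum-to-zero constraint.
    """
    if k < 3:
        raise ValueError("k must be >= 3")
    sp = CRSpline(place_knots(x, k) if knots is None else knots)
    raw = sp.basis(np.asarray(x, dtype=float))
    design, Z = _sum_to_zero(raw)
    S = Z.T @ sp.penalty() @ Z
    return PenalizedBasis(design, [0.5 * (S + S.T)], "univariate_crs", [sp], Z)


def build_tensor_product(
    columns: list[np.ndarray], dims: list[int]
) -> PenalizedBasis:
    """Interaction tensor-product smooth from marginal CRS bases.

    Each margin is constrained to sum to zero over the training data
    (removing its constant direction) before the row-wise Kronecker product
    is formed.  These marginal constraints centre the product block and make
    the interaction identifiable next to its univariate parent smooths,
    which the term hierarchy guarantees are present whenever the tensor is;
    an additional whole-block constraint would cut an interaction direction
    out of the span.  One penalty per margin — the marginal curvature
    penalty Kronecker-expanded with identities over the other margins — so
    each margin keeps its own smoothing parameter.
    """
    if not 2 <= len(columns) <= 3:
        raise ValueError("tensor smooths take 2 or 3 margins")
    if len({len(np.asarray(c)) for c in columns}) != 1:
        raise ValueError("margins must share row count")
    splines = [CRSpline(place_knots(c, k)) for c, k in zip(columns, dims)]
    mats, transforms, pen_margins = [], [], []
    for sp, c in zip(splines, columns):
        m = sp.basis(np.asarray(c, dtype=float))
        mc, Zm = _sum_to_zero(m)
        mats.append(mc)
        transforms.append(Zm)
        pen_margins.append(Zm.T @ sp.penalty() @ Zm)
    design = mats[0]
    for m in mats[1:]:
        design = (design[:, :, None] * m[:, None, :]).reshape(design.shape[0], -1)
    penalties = []
    for i in range(len(splines)):
        blocks = [np.eye(m.shape[1]) for m in mats]
        blocks[i] = pen_margins[i]
        P = blocks[0]
        for b in blocks[1:]:
            P = np.kron(P, b)
        penalties.append(0.5 * (P + P.T))
    return PenalizedBasis(design, penalties, "tensor", splines, None,
                          margin_transforms=transforms)


def random_effect_design(group_labels) -> PenalizedBasis:
    """Ridge-penalized indicator design: i.i.d. Gaussian random intercepts.

    One column per group, identity penalty; the smoothing parameter plays
    the role of the precision ratio sigma^2/tau^2.
    """
    labels = np.asarray(group_labels)
    if labels.size == 0:
        raise ValueError("no group labels given")
    levels = list(dict.fromkeys(labels.tolist()))  # stable order
    idx = {lev: i for i, lev in enumerate(levels)}
    design = np.zeros((labels.size, len(levels)))
    for r, lab in enumerate(labels.tolist()):
        design[r, idx[lab]] = 1.0
    return PenalizedBasis(
        design, [np.eye(len(levels))], "random_intercept", levels=levels
    )


def build_term(spec: SmoothTermSpec, columns: list[np.ndarray]) -> PenalizedBasis:
    """Evaluate a SmoothTermSpec on its covariate columns."""
    if spec.kind == "univariate_crs":
        return build_crs_basis(columns[0], spec.basis_dims[0])
    if spec.kind == "tensor":
        return build_tensor_product(columns, list(spec.basis_dims))
    if spec.kind == "random_intercept":
        return random_effect_design(columns[0])
    raise ValueError(f"unknown term kind {spec.kind!r}")
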