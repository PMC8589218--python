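"""Location-scale distribution families for the waveform model.

Each family is parameterized by a location ``mu`` and a scale ``sigma``
(modelled on the log scale, sigma = exp(eta_sigma)), with any extra shape
parameters held fixed.  Families expose the log density, the score of the
log likelihood with respect to mu and with respect to eta_sigma, and the
corresponding expected (Fisher) weights used by the penalized scoring
updates.  The expected weights per unit sigma are constants of the
standardized distribution; they are computed once by numerical integration
over the standard variate and cached.
"""

from __future__ import annotations

import numpy as np
from scipy import special, stats

_GRID = np.linspace(-14.0, 14.0, 20001)


class Family:
    name: str = "family"

    # standardized machinery: z = (y - mu) / sigma ---------------------------
    def _logpdf_std(self, z):  # log density of the standard variate
        raise NotImplementedError

    def _score_z(self, z):  # d/dz of the standard log density
        raise NotImplementedError

    # ------------------------------------------------------------------
    def log_density(self, y, mu, sigma):
        z = (np.asarray(y) - mu) / sigma
        return self._logpdf_std(z) - np.log(sigma)

    def score_mu(self, y, mu, sigma):
        z = (np.asarray(y) - mu) / sigma
        return -self._score_z(z) / sigma

    def score_eta_sigma(self, y, mu, sigma):
        """d loglik / d eta_sigma with sigma = exp(eta_sigma)."""
        z = (np.asarray(y) - mu) / sigma
        return -self._score_z(z) * z - 1.0

    def _std_weights(self):
        if not hasattr(self, "_w_cache"):
            w = np.exp(self._logpdf_std(_GRID))
            sc = self._score_z(_GRID)
            i_mu = np.trapezoid(sc**2 * w, _GRID)
            se = -sc * _GRID - 1.0
            i_eta = np.trapezoid(se**2 * w, _GRID)
            self._w_cache = (float(i_mu), float(i_eta))
        return self._w_cache

    def weight_mu(self, sigma):
        """Expected information for mu per observation."""
        return self._std_weights()[0] / sigma**2

    @property
    def weight_eta_sigma(self) -> float:
        """Expected information for eta_sigma (constant)."""
        return self._std_weights()[1]

    def sample_std(self, rng: np.random.Generator, size):
        raise NotImplementedError


class Normal(Family):
    name = "normal"

    def _logpdf_std(self, z):
        return -0.5 * np.log(2 * np.pi) - 0.5 * np.asarray(z) ** 2

    def _score_z(self, z):
        return -np.asarray(z)

    def sample_std(self, rng, size):
        return rng.standard_normal(size)


class ScaledT(Family):
    """Student t rescaled by sigma, degrees of freedom held fixed."""

    def __init__(self, df: float = 10.0):
        if df <= 0:
            raise ValueError("df must be positive")
        self.df = float(df)
        self.name = f"scaled_t(df={self.df:g})"

    def _logpdf_std(self, z):
        v = self.df
        return (
            special.gammaln((v + 1) / 2)
            - special.gammaln(v / 2)
            - 0.5 * np.log(v * np.pi)
            - (v + 1) / 2 * np.log1p(np.asarray(z) ** 2 / v)
        )

    def _score_z(self, z):
        z = np.asarray(z)
        return -(self.df + 1) * z / (self.df + z**2)

    def sample_std(self, rng, size):
        return rng.standard_t(self.df, size)


class Logistic(Family):
    """Logistic distribution; sigma is the conventional scale parameter."""

    name = "logistic"

    def _logpdf_std(self, z):
        z = np.asarray(z)
        return -z - 2 * np.log1p(np.exp(-np.clip(z, -700, None)))

    def _score_z(self, z):
        return -1.0 + 2 * special.expit(-np.asarray(z))

    def sample_std(self, rng, size):
        return rng.logistic(size=size)


class Gumbel(Family):
    """Gumbel (extreme value) with density exp(z - e^z)/sigma."""

    name = "gumbel"

    def _logpdf_std(self, z):
        z = np.asarray(z)
        return z - np.exp(np.clip(z, None, 700))

    def _score_z(self, z):
        return 1.0 - np.exp(np.clip(np.asarray(z), None, 700))

    def sample_std(self, rng, size):
        return -rng.gumbel(size=size)


class SkewNormal(Family):
    """Azzalini skew-normal with fixed shape parameter."""

    def __init__(self, shape: float = 2.0):
        self.shape = float(shape)
        self.name = f"skew_normal(shape={self.shape:g})"

    def _logpdf_std(self, z):
        z = np.asarray(z)
        return (
            np.log(2.0)
            - 0.5 * np.log(2 * np.pi)
            - 0.5 * z**2
            + special.log_ndtr(self.shape * z)
        )

    def _score_z(self, z):
        z = np.asarray(z)
        a = self.shape
        ratio = np.exp(stats.norm.logpdf(a * z) - special.log_ndtr(a * z))
        return -z + a * ratio

    def sample_std(self, rng, size):
        # additive representation of the skew-normal
        d = self.shape / np.sqrt(1 + self.shape**2)
        u0 = rng.standard_normal(size)
        u1 = rng.standard_normal(size)
        return d * np.abs(u0) + np.sqrt(1 - d**2) * u1


_REGISTRY: dict[str, type | object] = {}


def register_family(key: str, factory):
    """Register a family constructor under a key usable in ModelStructure."""
    _REGISTRY[key] = factory


register_family("normal", Normal)
register_family("scaled_t", ScaledT)
register_family("logistic", Logistic)
register_family("gumbel", Gumbel)
register_family("skew_normal", SkewNormal)


def get_family(name: str, **kwargs) -> Family:
    if name not in _REGISTRY:
        raise KeyError(f"unknown family {name!r}; known: {sorted(_REGISTRY)}")
    return _REGISTRY[name](**kwargs)


def available_families() -> list[str]:
    return sorted(_REGISTRY)
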