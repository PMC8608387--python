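"""Analytic copy-number distributions for stochastic gene expression.

The central object is the stationary distribution of the Telegraph model: a
gene switches between an active and an inactive promoter state at rates
``lam`` (on) and ``mu`` (off); in the active state mRNA is transcribed as a
Poisson process at rate ``K``; every mRNA decays at rate ``delta``.  With all
rates measured in units of the decay rate (``delta = 1``) the copy-number law
is

    p(n) = K^n * (lam)_n / (n! * (lam+mu)_n) * 1F1(lam+n, lam+mu+n, -K)

where ``(x)_n`` is the rising factorial and ``1F1`` the confluent
hypergeometric function.  Two classical limits are exposed: constitutive
expression (``mu = 0``) gives Poisson(K), and the instantaneous-burst limit
(``mu -> inf`` with burst size ``beta = K/mu`` fixed) gives the negative
binomial NegBin(lam, beta/(beta+1)).

Cell-to-cell parameter variability ("extrinsic noise") is modelled by
compounding: a hyper-distribution (:class:`NoiseSpec`) is placed on one
kinetic parameter and the fixed-parameter law is integrated against it
(:func:`compound_pmf`).

Negative binomial convention
----------------------------
Throughout, ``negbin`` distributions are parameterised as ``(r, beta)`` where
``beta`` is the mean burst size, i.e. the success probability of the textbook
``(r, p)`` convention is ``p = 1/(1+beta)`` and the mean is ``r*beta``.  This
matches the burst-size reading NegBin(r, beta/(beta+1)) and avoids the classic
success/failure flip.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.special import gammaln, logsumexp

__all__ = [
    "TelegraphParams",
    "NoiseSpec",
    "Pmf",
    "telegraph_pmf",
    "telegraph_logpmf",
    "telegraph_mean_var",
    "limit_pmf",
    "noise_moments",
    "sample_noise",
    "compound_pmf",
    "truncation_support",
]

#: absolute tail-mass tolerance used when truncating pmfs to finite support
TAIL_TOL = 1e-8
#: default absolute quadrature tolerance for compound distributions
QUAD_TOL = 1e-8

_NOISE_FAMILIES = ("point", "scaled-beta", "gamma", "scaled-beta-prime", "truncated-normal")


class ParameterError(ValueError):
    """A kinetic or hyper-parameter lies outside its domain."""


class ConfigurationError(ValueError):
    """A structurally invalid request (mismatched parameter names etc.)."""


# ---------------------------------------------------------------------------
# Telegraph model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TelegraphParams:
    """Kinetic rates of the Telegraph model.

    Rates are per unit mRNA-degradation time; any ``delta != 1`` is folded
    into the other rates on construction so downstream code always sees the
    rescaled parameter set ``(lam/delta, mu/delta, K/delta, 1)``.
    """

    lam: float
    mu: float
    K: float
    delta: float = 1.0

    def __post_init__(self) -> None:
        for name in ("lam", "mu", "K", "delta"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ParameterError(f"{name} must be finite and >= 0, got {v!r}")
        if self.lam <= 0:
            raise ParameterError(f"on-rate lam must be > 0, got {self.lam!r}")
        if self.K <= 0:
            raise ParameterError(f"transcription rate K must be > 0, got {self.K!r}")
        if self.delta <= 0:
            raise ParameterError(f"degradation rate delta must be > 0, got {self.delta!r}")

    def rescaled(self) -> "TelegraphParams":
        """Equivalent parameter set with the clock set by mRNA decay (delta=1)."""
        if self.delta == 1.0:
            return self
        d = self.delta
        return TelegraphParams(self.lam / d, self.mu / d, self.K / d, 1.0)


def telegraph_logpmf(n, params: TelegraphParams):
    """Log of the Telegraph stationary pmf, evaluated entirely in log space.

    Via Kummer's transformation ``1F1(lam+n, lam+mu+n, -K) =
    exp(-K) 1F1(mu, lam+mu+n, K)`` every contribution is a positive series,
    so the evaluation is stable for K up to ~1e3 and n well past 10x the
    mean.  Vectorised over ``n``: the series terms for all copy numbers share
    a single gammaln evaluation on the integer grid lam+mu+{0, 1, ...}.
    """
    p = params.rescaled()
    n_arr = np.atleast_1d(np.asarray(n))
    if np.any(n_arr < 0) or np.any(n_arr != np.floor(n_arr)):
        raise ParameterError("copy number n must be a non-negative integer")
    lam, mu, K = p.lam, p.mu, p.K
    ni = n_arr.astype(np.int64).ravel()
    nf = ni.astype(float)
    prefix = (
        nf * math.log(K)
        + gammaln(lam + nf) - gammaln(lam)
        - (gammaln(lam + mu + nf) - gammaln(lam + mu))
        - gammaln(nf + 1.0)
        - K
    )
    if mu > 0.0:
        # log 1F1(mu, lam+mu+n, K): positive-term series, logsumexp over j.
        # terms decay once j >> K; generous cap keeps the tail below 1e-16
        jmax = int(K + 12.0 * math.sqrt(K + 1.0) + 80)
        j = np.arange(jmax, dtype=np.int64)
        jf = j.astype(float)
        col = gammaln(mu + jf) - gammaln(mu) + jf * math.log(K) - gammaln(jf + 1.0)
        # gammaln(lam+mu+n+j) looked up on the shared integer-offset grid
        grid = gammaln(lam + mu + np.arange(int(ni.max()) + jmax, dtype=float))
        logt = col[None, :] - (grid[ni[:, None] + j[None, :]] - grid[ni][:, None])
        log1f1 = logsumexp(logt, axis=1)
    else:
        log1f1 = 0.0
    out = (prefix + log1f1).reshape(n_arr.shape)
    return out if np.ndim(n) else float(out[0])


def telegraph_pmf(n, params: TelegraphParams):
    """Stationary mRNA copy-number probability of the Telegraph model."""
    return np.exp(telegraph_logpmf(n, params))


def telegraph_mean_var(params: TelegraphParams) -> tuple[float, float]:
    """Closed-form stationary mean and variance of the Telegraph model."""
    p = params.rescaled()
    lam, mu, K = p.lam, p.mu, p.K
    mean = K * lam / (lam + mu)
    var = mean + K**2 * lam * mu / ((lam + mu) ** 2 * (lam + mu + 1.0))
    return mean, var


# ---------------------------------------------------------------------------
# Poisson / negative-binomial limits
# ---------------------------------------------------------------------------

def limit_pmf(n, family: str, *params):
    """Pmf of the constitutive (Poisson) or instantaneous-burst (NegBin) limit.

    Parameters
    ----------
    family : {"poisson", "negbin"}
        ``poisson`` takes ``K >= 0``; ``negbin`` takes ``(r, beta)`` with
        ``beta`` the mean burst size (see module docstring for the
        convention).
    """
    n_arr = np.asarray(n)
    if family == "poisson":
        (K,) = params
        if K < 0 or not math.isfinite(K):
            raise ParameterError(f"poisson rate must be finite and >= 0, got {K!r}")
        if K == 0.0:  # degenerate limit: point mass at 0
            return np.where(n_arr == 0, 1.0, 0.0) if np.ndim(n) else float(n == 0)
        return stats.poisson.pmf(n, K)
    if family == "negbin":
        r, beta = params
        if r <= 0 or beta <= 0 or not (math.isfinite(r) and math.isfinite(beta)):
            raise ParameterError(f"negbin needs r > 0 and burst size beta > 0, got {params!r}")
        return stats.nbinom.pmf(n, r, 1.0 / (1.0 + beta))
    raise ParameterError(f"unknown limit family {family!r}")


# ---------------------------------------------------------------------------
# Extrinsic-noise hyper-distributions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NoiseSpec:
    """A named hyper-distribution for a single kinetic parameter.

    Families and hyper-parameters:

    ``point``              (value,)
    ``scaled-beta``        (c, a, b)      -- c * Beta(a, b), support [0, c]
    ``gamma``              (shape, scale)
    ``scaled-beta-prime``  (b, a, b2)     -- the burst-intensity mixing law of
                           the negative-binomial representation: the excess
                           inverse intensity ``b/theta - 1`` follows
                           BetaPrime(a, b2), equivalently
                           ``theta ~ b * Beta(b2, a)`` with support (0, b).
    ``truncated-normal``   (loc, scale)   -- Normal(loc, scale) restricted
                           to [0, inf)
    """

    family: str
    params: tuple

    def __post_init__(self) -> None:
        if self.family not in _NOISE_FAMILIES:
            raise ParameterError(
                f"unknown noise family {self.family!r}; expected one of {_NOISE_FAMILIES}")
        object.__setattr__(self, "params", tuple(float(p) for p in self.params))
        n_expected = {"point": 1, "scaled-beta": 3, "gamma": 2,
                      "scaled-beta-prime": 3, "truncated-normal": 2}[self.family]
        if len(self.params) != n_expected:
            raise ParameterError(
                f"{self.family} takes {n_expected} hyperparameters, got {len(self.params)}")
        pos = {"point": (), "scaled-beta": (0, 1, 2), "gamma": (0, 1),
               "scaled-beta-prime": (0, 1, 2), "truncated-normal": (1,)}[self.family]
        for i in pos:
            if self.params[i] <= 0:
                raise ParameterError(
                    f"{self.family} hyperparameter #{i} must be > 0, got {self.params[i]!r}")
        if self.family == "point" and self.params[0] < 0:
            raise ParameterError("point value must be >= 0")

    # -- constructors -------------------------------------------------------
    @classmethod
    def point(cls, value: float) -> "NoiseSpec":
        return cls("point", (value,))

    @classmethod
    def scaled_beta(cls, c: float, a: float, b: float) -> "NoiseSpec":
        return cls("scaled-beta", (c, a, b))

    @classmethod
    def gamma(cls, shape: float, scale: float) -> "NoiseSpec":
        return cls("gamma", (shape, scale))

    @classmethod
    def scaled_beta_prime(cls, b: float, a: float, b2: float) -> "NoiseSpec":
        return cls("scaled-beta-prime", (b, a, b2))

    @classmethod
    def truncated_normal(cls, loc: float, scale: float) -> "NoiseSpec":
        return cls("truncated-normal", (loc, scale))

    # -- behaviour ----------------------------------------------------------
    def frozen(self):
        """The scipy frozen distribution behind this spec (None for point)."""
        f, p = self.family, self.params
        if f == "point":
            return None
        if f == "scaled-beta":
            c, a, b = p
            return stats.beta(a, b, scale=c)
        if f == "gamma":
            shape, scale = p
            return stats.gamma(shape, scale=scale)
        if f == "scaled-beta-prime":
            b, a, b2 = p
            # theta = b / (1 + Y), Y ~ BetaPrime(a, b2)  <=>  theta ~ b*Beta(b2, a)
            return stats.beta(b2, a, scale=b)
        # truncated-normal
        loc, scale = p
        return stats.truncnorm(-loc / scale, np.inf, loc=loc, scale=scale)

    def mean(self) -> float:
        if self.family == "point":
            return self.params[0]
        return float(self.frozen().mean())

    def cv2(self) -> float:
        """Squared coefficient of variation; inf when the variance diverges."""
        if self.family == "point":
            return 0.0
        m, v = self.frozen().stats(moments="mv")
        m, v = float(m), float(v)
        if not math.isfinite(v):
            return math.inf
        return v / m**2

    def pdf(self, x):
        if self.family == "point":
            raise ConfigurationError("a point mass has no density")
        return self.frozen().pdf(x)

    def support(self, tail: float = 1e-10) -> tuple[float, float]:
        """Effective integration support: exact when bounded, else cut at the
        1 - tail quantile (and the ``tail`` quantile on the left for
        unbounded-below-at-0 families)."""
        f, p = self.family, self.params
        if f == "point":
            return p[0], p[0]
        if f == "scaled-beta":
            return 0.0, p[0]
        if f == "scaled-beta-prime":
            return 0.0, p[0]
        fr = self.frozen()
        lo = float(fr.ppf(tail * 1e-2))
        hi = float(fr.ppf(1.0 - tail))
        return max(lo, 0.0), hi

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if n < 1:
            raise ParameterError("need n >= 1 samples")
        if self.family == "point":
            return np.full(n, self.params[0])
        # truncnorm's rvs is already restricted to [0, inf)
        return np.asarray(self.frozen().rvs(size=n, random_state=rng), dtype=float)


def noise_moments(spec: NoiseSpec) -> tuple[float, float]:
    """Exact mean and squared coefficient of variation of a hyper-distribution."""
    return spec.mean(), spec.cv2()


def sample_noise(spec: NoiseSpec, n: int, seed) -> np.ndarray:
    """``n`` independent, reproducible draws from the hyper-distribution.

    ``seed`` may be an int, a SeedSequence or a Generator.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return spec.sample(n, rng)


# ---------------------------------------------------------------------------
# Finite pmf tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Pmf:
    """A pmf truncated to support {0, ..., N} with declared tail tolerance."""

    probs: np.ndarray
    tail_tol: float = TAIL_TOL

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", p)
        if np.any(p < -1e-12) or np.any(p > 1 + 1e-12):
            raise ParameterError("probabilities must lie in [0, 1]")
        if abs(p.sum() - 1.0) > max(self.tail_tol * 10, 1e-6):
            raise ParameterError(
                f"truncated pmf mass {p.sum():.10f} differs from 1 beyond tolerance")

    @property
    def support_max(self) -> int:
        return len(self.probs) - 1

    def to_table(self) -> "np.ndarray":
        return np.column_stack([np.arange(len(self.probs)), self.probs])

    def write(self, path) -> None:
        """Two-column delimited text (n, probability), UTF-8, header line."""
        import pandas as pd

        pd.DataFrame({"n": np.arange(len(self.probs)), "probability": self.probs}
                     ).to_csv(path, index=False)


def truncation_support(mean: float, var: float, pmf_fn, tail_tol: float = TAIL_TOL) -> int:
    """Support max = mean + 10*std, extended until tail mass < tail_tol."""
    nmax = int(math.ceil(mean + 10.0 * math.sqrt(max(var, 1.0)))) + 5
    while True:
        mass = float(np.sum(pmf_fn(np.arange(nmax + 1))))
        if 1.0 - mass < tail_tol:
            return nmax
        nmax = int(nmax * 1.5) + 10


# ---------------------------------------------------------------------------
# Compound (mixture) distributions
# ---------------------------------------------------------------------------

_BASE_PARAMS = {
    "telegraph": ("lam", "mu", "K"),
    "poisson": ("K",),
    "negbin": ("r", "beta"),
}


def _base_pmf_factory(base: str, which_param: str, fixed: dict):
    """Return f(n, t) = base pmf at n with `which_param` set to t."""
    if base not in _BASE_PARAMS:
        raise ConfigurationError(f"unknown base family {base!r}")
    names = _BASE_PARAMS[base]
    if which_param not in names:
        raise ConfigurationError(
            f"base {base!r} has no parameter {which_param!r}; choose from {names}")
    missing = [p for p in names if p != which_param and p not in fixed]
    if missing:
        raise ConfigurationError(f"missing fixed parameters {missing} for base {base!r}")
    extra = [p for p in fixed if p not in names or p == which_param]
    if extra:
        raise ConfigurationError(f"unexpected fixed parameters {extra} for base {base!r}")

    if base == "telegraph":
        def f(n, t):
            kw = dict(fixed)
            kw[which_param] = t
            return telegraph_pmf(n, TelegraphParams(**kw))
    elif base == "poisson":
        def f(n, t):
            return limit_pmf(n, "poisson", t)
    else:
        def f(n, t):
            kw = dict(fixed)
            kw[which_param] = t
            return limit_pmf(n, "negbin", kw["r"], kw["beta"])
    return f


def compound_pmf(n, base: str, which_param: str, spec: NoiseSpec,
                 fixed: dict | None = None, epsabs: float = QUAD_TOL):
    """Mixture pmf  q(n) = ∫ p(n; theta) f(theta) dtheta  by adaptive quadrature.

    ``base`` is one of ``telegraph``/``poisson``/``negbin``; ``which_param``
    names the mixed parameter; ``fixed`` carries the remaining base
    parameters.  Bounded families (scaled-beta, scaled-beta-prime) integrate
    their exact finite support; unbounded families are integrated to the
    1 - 1e-10 quantile.

    The quadrature is Gauss–Legendre with node doubling: the node count is
    doubled until two successive refinements agree within ``epsabs`` in the
    uniform norm over all requested ``n`` simultaneously (the base pmf is
    vectorised over ``n``, so each node costs a single pmf-table evaluation).
    """
    fixed = dict(fixed or {})
    f = _base_pmf_factory(base, which_param, fixed)

    if spec.family == "point":
        return f(n, spec.params[0])

    n_arr = np.atleast_1d(np.asarray(n))
    lo, hi = spec.support()

    def evaluate(nodes_count: int) -> np.ndarray:
        x, w = np.polynomial.legendre.leggauss(nodes_count)
        t = 0.5 * (hi - lo) * x + 0.5 * (hi + lo)
        w = 0.5 * (hi - lo) * w * spec.pdf(t)
        acc = np.zeros(len(n_arr))
        for ti, wi in zip(t, w):
            acc += wi * f(n_arr, ti)
        return acc

    prev = evaluate(48)
    for m in (96, 192, 384, 768):
        cur = evaluate(m)
        if np.max(np.abs(cur - prev)) < epsabs:
            prev = cur
            break
        prev = cur
    out = prev
    return out if np.ndim(n) else float(out[0])
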