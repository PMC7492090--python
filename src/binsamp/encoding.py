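"""Contextual priors and efficient binary-sampling encoding rules.

A stimulus magnitude ``v`` (normalized to [0, 1]) is represented by ``n``
independent binary units, each of which reads 'high' with probability
``theta(v)``.  The shape of ``theta`` is what distinguishes the candidate
encoding strategies:

* **accuracy** — maximizes discrimination accuracy (equivalently mutual
  information at large ``n``): ``theta(v) = sin^2((pi/2) F(v))`` where ``F``
  is the prior CDF.  The induced distribution of ``theta`` under the prior is
  the arcsine (Jeffreys) distribution.
* **reward** — maximizes the expected magnitude of the chosen option:
  the CDF in the accuracy rule is replaced by the normalized integral of
  ``f(v)^(2/3)``.
* **dbs** — decision by sampling: a unit fires iff the stimulus beats one
  random draw from the contextual prior, hence ``theta(v) = F(v)`` exactly.

The contextual prior family used in the experiments is
``f(v) = (alpha + 1) (1 - v)^alpha`` on [0, 1], affinely mapped to dot
counts in [5, 55].
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np
from numpy.typing import ArrayLike, NDArray

__all__ = [
    "THETA_EPS",
    "PriorSpec",
    "EncodingRule",
    "NoiseModel",
    "prior_pdf",
    "prior_cdf",
    "prior_quantile",
    "normalize_dots",
    "denormalize_dots",
    "theta_accuracy",
    "theta_reward",
    "theta_dbs",
    "theta_general",
    "theta_general_reward",
    "make_rule",
    "optimal_noise_density",
    "discriminability",
    "clip_theta",
]

#: Activation probabilities are clipped to [eps, 1-eps] before entering any
#: binomial-variance denominator, so boundary stimuli (v=0 or v=1) never
#: produce a degenerate zero-variance term.
THETA_EPS = 1e-9

RuleKind = Literal["accuracy", "reward", "dbs", "custom"]


def clip_theta(theta: ArrayLike) -> NDArray[np.float64]:
    """Clip activation probabilities away from {0, 1} for variance terms."""
    return np.clip(np.asarray(theta, dtype=float), THETA_EPS, 1.0 - THETA_EPS)


@dataclass(frozen=True)
class PriorSpec:
    """Right-skewed contextual prior ``f(v) = (alpha+1)(1-v)^alpha`` on [0,1].

    Raw dot counts ``d`` in [dot_min, dot_max] map to normalized magnitudes
    via ``v = (d - offset) / scale``; the experiments use dot_min=5,
    dot_max=55, i.e. scale=50 and offset=5.

    Parameters
    ----------
    alpha
        Shape of the prior, > 0.  Larger alpha concentrates mass at small
        magnitudes.  The experiments used alpha=2 (and alpha=1 for the
        adaptation study).
    dot_min, dot_max
        Integer bounds of the raw numerosity range.
    """

    alpha: float = 2.0
    dot_min: int = 5
    dot_max: int = 55

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError(f"prior shape alpha must be > 0, got {self.alpha}")
        if self.dot_max <= self.dot_min:
            raise ValueError("dot_max must exceed dot_min")

    @property
    def scale(self) -> int:
        return self.dot_max - self.dot_min

    @property
    def offset(self) -> int:
        return self.dot_min

    @property
    def norm_const(self) -> float:
        """Normalizing constant c of f(v) = c(1-v)^alpha; equals alpha+1."""
        return self.alpha + 1.0

    # -- density / distribution ------------------------------------------

    def pdf(self, v: ArrayLike) -> NDArray[np.float64]:
        return prior_pdf(v, self)

    def cdf(self, v: ArrayLike) -> NDArray[np.float64]:
        return prior_cdf(v, self)

    def quantile(self, q: ArrayLike) -> NDArray[np.float64]:
        return prior_quantile(q, self)

    def sample(self, size: int, rng: np.random.Generator) -> NDArray[np.float64]:
        """Draw normalized magnitudes v ~ f by inverse-CDF sampling."""
        return self.quantile(rng.uniform(0.0, 1.0, size=size))

    # -- raw-count mapping -----------------------------------------------

    def normalize(self, dots: ArrayLike) -> NDArray[np.float64]:
        return normalize_dots(dots, self)

    def denormalize(self, v: ArrayLike) -> NDArray[np.int_]:
        return denormalize_dots(v, self)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {"alpha": self.alpha, "dot_min": self.dot_min, "dot_max": self.dot_max}

    @classmethod
    def from_dict(cls, d: dict) -> "PriorSpec":
        return cls(alpha=float(d["alpha"]),
                   dot_min=int(d.get("dot_min", 5)),
                   dot_max=int(d.get("dot_max", 55)))


def _check_unit_interval(v: NDArray[np.float64], what: str = "v") -> None:
    if np.any(v < -1e-12) or np.any(v > 1 + 1e-12):
        raise ValueError(f"{what} must lie in [0, 1]")


def prior_pdf(v: ArrayLike, prior: PriorSpec) -> NDArray[np.float64]:
    """Density (alpha+1)(1-v)^alpha of the contextual prior at v in [0,1]."""
    v = np.asarray(v, dtype=float)
    _check_unit_interval(v)
    return prior.norm_const * (1.0 - np.clip(v, 0.0, 1.0)) ** prior.alpha


def prior_cdf(v: ArrayLike, prior: PriorSpec) -> NDArray[np.float64]:
    """Cumulative distribution F(v) = 1 - (1-v)^(alpha+1)."""
    v = np.asarray(v, dtype=float)
    _check_unit_interval(v)
    return 1.0 - (1.0 - np.clip(v, 0.0, 1.0)) ** (prior.alpha + 1.0)


def prior_quantile(q: ArrayLike, prior: PriorSpec) -> NDArray[np.float64]:
    """Closed-form inverse CDF: v = 1 - (1-q)^(1/(alpha+1))."""
    q = np.asarray(q, dtype=float)
    _check_unit_interval(q, "quantile argument")
    return 1.0 - (1.0 - np.clip(q, 0.0, 1.0)) ** (1.0 / (prior.alpha + 1.0))


def normalize_dots(dots: ArrayLike, prior: PriorSpec | None = None) -> NDArray[np.float64]:
    """Map raw dot counts in [dot_min, dot_max] to v = (d - offset)/scale."""
    prior = prior or PriorSpec()
    d = np.asarray(dots, dtype=float)
    if np.any(d < prior.dot_min) or np.any(d > prior.dot_max):
        raise ValueError(
            f"dot counts must lie in [{prior.dot_min}, {prior.dot_max}]")
    return (d - prior.offset) / prior.scale


def denormalize_dots(v: ArrayLike, prior: PriorSpec | None = None) -> NDArray[np.int_]:
    """Inverse of :func:`normalize_dots`, rounding to the nearest integer."""
    prior = prior or PriorSpec()
    v = np.asarray(v, dtype=float)
    _check_unit_interval(v)
    return np.rint(v * prior.scale + prior.offset).astype(int)


# ---------------------------------------------------------------------------
# Closed-form encoding rules for the parametric prior
# ---------------------------------------------------------------------------

def theta_accuracy(v: ArrayLike, prior: PriorSpec) -> NDArray[np.float64]:
    """Accuracy-maximizing rule: sin^2((pi/2) F(v))."""
    return np.sin(0.5 * np.pi * prior_cdf(v, prior)) ** 2


def theta_reward(v: ArrayLike, prior: PriorSpec) -> NDArray[np.float64]:
    """Reward-maximizing rule.

    For the parametric prior the normalized integral of f^(2/3) has the
    closed form 1 - (1-v)^((2 alpha + 3)/3), giving
    ``theta_R(v) = sin^2((pi/2) (1 - (1-v)^((2 alpha+3)/3)))``.
    """
    v = np.asarray(v, dtype=float)
    _check_unit_interval(v)
    expo = (2.0 * prior.alpha + 3.0) / 3.0
    g = 1.0 - (1.0 - np.clip(v, 0.0, 1.0)) ** expo
    return np.sin(0.5 * np.pi * g) ** 2


def theta_dbs(v: ArrayLike, prior: PriorSpec) -> NDArray[np.float64]:
    """Decision-by-sampling rule: a unit fires iff v beats one prior draw,
    so the activation probability is exactly the prior CDF."""
    return prior_cdf(v, prior)


_CLOSED_FORMS: dict[str, Callable[[ArrayLike, PriorSpec], NDArray[np.float64]]] = {
    "accuracy": theta_accuracy,
    "reward": theta_reward,
    "dbs": theta_dbs,
}


# ---------------------------------------------------------------------------
# General-prior (tabulated) rules
# ---------------------------------------------------------------------------

def theta_general(F_values: ArrayLike,
                  objective: Literal["accuracy", "dbs"] = "accuracy",
                  ) -> NDArray[np.float64]:
    """Encoding rule from tabulated CDF values of an arbitrary prior.

    ``objective='accuracy'`` applies the arcsine map sin^2((pi/2) F);
    ``objective='dbs'`` returns F unchanged.
    """
    F = np.asarray(F_values, dtype=float)
    _check_unit_interval(F, "F")
    if F.ndim and F.size > 1 and np.any(np.diff(F) < -1e-12):
        raise ValueError("CDF values must be non-decreasing")
    if objective == "accuracy":
        return np.sin(0.5 * np.pi * F) ** 2
    if objective == "dbs":
        return F.copy()
    raise ValueError(f"unknown objective {objective!r}")


def theta_general_reward(v_grid: ArrayLike, pdf_values: ArrayLike,
                         ) -> NDArray[np.float64]:
    """Reward-maximizing rule for a tabulated prior density.

    Computes the power-2/3 transformed, renormalized CDF
    ``G(v) = c * int_0^v f(u)^(2/3) du`` with ``c = 1 / int f^(2/3)`` by
    trapezoidal quadrature on the supplied grid, then applies the arcsine map.
    """
    v = np.asarray(v_grid, dtype=float)
    f = np.asarray(pdf_values, dtype=float)
    if np.any(f < 0):
        raise ValueError("density values must be non-negative")
    g = f ** (2.0 / 3.0)
    cum = np.concatenate([[0.0], np.cumsum(0.5 * (g[1:] + g[:-1]) * np.diff(v))])
    total = cum[-1]
    if total <= 0:
        raise ValueError("density integrates to zero on the grid")
    return np.sin(0.5 * np.pi * cum / total) ** 2


# ---------------------------------------------------------------------------
# EncodingRule container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EncodingRule:
    """A monotone activation map theta: [0,1] -> [0,1] with n binary units."""

    kind: RuleKind
    n: int
    prior: PriorSpec | None = None
    theta_fn: Callable[[ArrayLike], NDArray[np.float64]] | None = field(
        default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("unit count n must be >= 1")
        if self.kind in _CLOSED_FORMS and self.prior is None:
            raise ValueError(f"rule kind {self.kind!r} requires a prior")
        if self.kind == "custom" and self.theta_fn is None:
            raise ValueError("custom rules require theta_fn")

    def theta(self, v: ArrayLike) -> NDArray[np.float64]:
        """Activation probability at normalized magnitude v."""
        if self.kind == "custom":
            return np.asarray(self.theta_fn(v), dtype=float)
        return _CLOSED_FORMS[self.kind](v, self.prior)

    def theta_clipped(self, v: ArrayLike) -> NDArray[np.float64]:
        return clip_theta(self.theta(v))

    def to_json(self) -> str:
        if self.kind == "custom":
            raise ValueError("custom rules are not JSON-serializable")
        return json.dumps({"alpha": self.prior.alpha, "rule": self.kind,
                           "n": self.n, "dot_min": self.prior.dot_min,
                           "dot_max": self.prior.dot_max})

    @classmethod
    def from_json(cls, s: str) -> "EncodingRule":
        d = json.loads(s)
        prior = PriorSpec(alpha=float(d["alpha"]), dot_min=int(d["dot_min"]),
                          dot_max=int(d["dot_max"]))
        return cls(kind=d["rule"], n=int(d["n"]), prior=prior)


def make_rule(kind: RuleKind, prior: PriorSpec, n: int) -> EncodingRule:
    """Convenience constructor for the three named rules."""
    return EncodingRule(kind=kind, n=n, prior=prior)


# ---------------------------------------------------------------------------
# Threshold-unit noise implementation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NoiseModel:
    """Additive unit noise implementing a target activation rule.

    Each unit reads 'high' iff ``v - eta > tau``.  The noise density is the
    pushforward of dtheta/dv: ``f_eta(x) = theta'(x + tau)`` on the support
    ``x + tau in [0, 1]``, so that ``P(v - eta > tau) = theta(v)`` exactly.
    The density is independent of the unit count n.
    """

    tau: float
    rule: EncodingRule = field(repr=False)

    def pdf(self, x: ArrayLike) -> NDArray[np.float64]:
        x = np.asarray(x, dtype=float)
        u = x + self.tau
        inside = (u >= 0.0) & (u <= 1.0)
        out = np.zeros_like(u)
        uu = np.clip(u, 0.0, 1.0)
        # derivative of sin^2((pi/2)F) is (pi/2) sin(pi F) f; dbs derivative is f
        prior = self.rule.prior
        if self.rule.kind == "accuracy":
            out = 0.5 * np.pi * np.sin(np.pi * prior_cdf(uu, prior)) * prior_pdf(uu, prior)
        elif self.rule.kind == "dbs":
            out = prior_pdf(uu, prior)
        else:  # numerical derivative for other monotone rules
            h = 1e-6
            lo = np.clip(uu - h, 0.0, 1.0)
            hi = np.clip(uu + h, 0.0, 1.0)
            out = (self.rule.theta(hi) - self.rule.theta(lo)) / np.maximum(hi - lo, 1e-12)
        return np.where(inside, out, 0.0)

    def cdf(self, x: ArrayLike) -> NDArray[np.float64]:
        x = np.asarray(x, dtype=float)
        u = np.clip(x + self.tau, 0.0, 1.0)
        return self.rule.theta(u)

    def activation_prob(self, v: ArrayLike) -> NDArray[np.float64]:
        """P(v - eta > tau) = F_eta(v - tau) = theta(v)."""
        return self.cdf(np.asarray(v, dtype=float) - self.tau)

    def sample(self, size: int, rng: np.random.Generator) -> NDArray[np.float64]:
        """Inverse-transform noise draws."""
        u = rng.uniform(0.0, 1.0, size=size)
        prior = self.rule.prior
        if self.rule.kind == "accuracy":
            # invert theta_A: v = F^{-1}((2/pi) asin(sqrt(u)))
            inner = (2.0 / np.pi) * np.arcsin(np.sqrt(u))
            v = prior_quantile(inner, prior)
        elif self.rule.kind == "dbs":
            v = prior_quantile(u, prior)
        else:
            # generic monotone inversion on a fine grid
            grid = np.linspace(0.0, 1.0, 20001)
            tg = self.rule.theta(grid)
            v = np.interp(u, tg, grid)
        return v - self.tau


def optimal_noise_density(prior: PriorSpec, tau: float = 0.0,
                          target: EncodingRule | None = None) -> NoiseModel:
    """Noise density under which threshold units realize the target rule.

    Defaults to the accuracy-maximizing rule (the rule whose noise density
    has the closed form (pi/2) sin(pi F) f).  The density does not depend on
    the number of units n.
    """
    if target is None:
        target = EncodingRule(kind="accuracy", n=1, prior=prior)
    if target.kind not in ("accuracy", "dbs", "custom"):
        raise ValueError("optimal_noise_density supports accuracy/dbs/custom targets")
    return NoiseModel(tau=tau, rule=target)


def discriminability(v: ArrayLike, n: int, prior: PriorSpec) -> NDArray[np.float64]:
    """Analytic discriminability threshold d = 1/(n pi f(v)).

    Under the accuracy-maximizing rule the just-discriminable increment is
    inversely proportional to the local prior density; points where f(v)=0
    return +inf.
    """
    f = prior_pdf(v, prior)
    with np.errstate(divide="ignore"):
        return np.where(f > 0, 1.0 / (n * np.pi * f), np.inf)
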