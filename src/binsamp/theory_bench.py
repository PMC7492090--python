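"""Numerical verification of the efficient-sampling theory.

Computes, for each encoding rule: the mutual information I(v; k) of the
binomial channel, the large-n average error probability of a candidate
encoder distribution over theta, the expected magnitude of the chosen
option, and simulated discriminability thresholds.  Together these check
the theory's ordering claims (information: accuracy >= reward >= DbS;
reward: highest expected chosen value under the reward rule; the arcsine
encoder distribution minimizes average error; thresholds under the accuracy
rule scale as 1/f(v)).

All prior integrals substitute u = F(v), so the prior is absorbed into a
uniform measure on (0,1) and Gauss-Legendre quadrature is well conditioned
near the thin right tail of the prior.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.typing import NDArray
from scipy.special import ndtr, xlogy
from scipy.stats import beta as beta_dist
from scipy.stats import binom

from .choice_model import choice_prob_exact, choice_prob_normal
from .encoding import EncodingRule, PriorSpec, clip_theta, prior_quantile

__all__ = [
    "QuadratureGrid", "BenchResult", "cdf_space_grid",
    "mutual_information", "avg_error_prob", "avg_error_prob_theta_dist",
    "expected_value_chosen", "simulate_threshold_curve",
    "compare_rules_finite_n",
]


@dataclass(frozen=True)
class QuadratureGrid:
    """Gauss-Legendre nodes/weights on (0,1) in prior-CDF space."""

    nodes: NDArray[np.float64]
    weights: NDArray[np.float64]

    @property
    def size(self) -> int:
        return len(self.nodes)


def cdf_space_grid(n_nodes: int = 512) -> QuadratureGrid:
    """Gauss-Legendre rule mapped from [-1,1] to [0,1]."""
    x, w = np.polynomial.legendre.leggauss(n_nodes)
    return QuadratureGrid(nodes=0.5 * (x + 1.0), weights=0.5 * w)


@dataclass(frozen=True)
class BenchResult:
    rule: str
    n: float
    metric: str
    value: float
    grid_size: int


def mutual_information(rule: EncodingRule, prior: PriorSpec | None = None,
                       n: int | None = None,
                       grid: QuadratureGrid | None = None) -> float:
    """Mutual information I(v; k) in bits of the binomial sampling channel.

    I = sum_k int f(v) p(k|v) log2[p(k|v)/p(k)] dv, with the marginal
    p(k) = int f(v) p(k|v) dv; computed by quadrature in CDF space and
    enumeration over k = 0..n.
    """
    prior = prior or rule.prior
    n = int(n if n is not None else rule.n)
    if n > 200:
        raise ValueError("mutual_information enumerates k; needs n <= 200")
    grid = grid or cdf_space_grid()
    v = prior_quantile(grid.nodes, prior)
    theta = clip_theta(rule.theta(v))
    k = np.arange(n + 1)
    pkv = binom.pmf(k[None, :], n, theta[:, None])       # nodes x (n+1)
    pk = grid.weights @ pkv                              # marginal over v
    with np.errstate(divide="ignore", invalid="ignore"):
        integrand = xlogy(pkv, pkv / np.maximum(pk[None, :], 1e-300))
    bits = float(grid.weights @ integrand.sum(axis=1)) / np.log(2.0)
    return max(bits, 0.0)


def _error_kernel_normal(t1, t2, n):
    """Large-n probability of picking the smaller-theta option."""
    t1 = clip_theta(t1); t2 = clip_theta(t2)
    se = np.sqrt((t1 * (1 - t1) + t2 * (1 - t2)) / n)
    return ndtr(-np.abs(t1 - t2) / se)


def _error_kernel_exact(t1, t2, n):
    """Exact enumeration error probability (ties contribute 1/2)."""
    p_hi = choice_prob_exact(np.maximum(t1, t2), np.minimum(t1, t2), int(n))
    return 1.0 - p_hi


def avg_error_prob(a: float, b: float, n: float,
                   grid: QuadratureGrid | None = None,
                   kernel: str = "normal") -> float:
    """Average error probability of a Beta(a, b) encoder distribution.

    Both stimuli draw theta independently from Beta(a, b); the error kernel
    is the probit large-n form ('normal') or the exact binomial enumeration
    ('exact', integer n <= 200).  The arcsine case a = b = 1/2 is the
    information- and accuracy-optimal encoder distribution; a = b = 1 is the
    uniform distribution induced by decision by sampling.
    """
    if a <= 0 or b <= 0:
        raise ValueError("Beta parameters must be positive")
    grid = grid or cdf_space_grid(256)
    theta = beta_dist.ppf(grid.nodes, a, b)
    return avg_error_prob_theta_dist(theta, grid.weights, n, kernel=kernel)


def avg_error_prob_theta_dist(theta: NDArray[np.float64],
                              weights: NDArray[np.float64], n: float,
                              kernel: str = "normal") -> float:
    """Average error for an arbitrary tabulated encoder distribution.

    ``theta``/``weights`` tabulate the distribution of theta in its own CDF
    space (equally-weighted quantiles work).  The double integral over
    independent (theta1, theta2) is a full tensor product.
    """
    t1 = theta[:, None]
    t2 = theta[None, :]
    if kernel == "normal":
        ker = _error_kernel_normal(t1, t2, n)
    elif kernel == "exact":
        tt1, tt2 = np.broadcast_arrays(t1, t2)
        ker = _error_kernel_exact(tt1.ravel(), tt2.ravel(), n).reshape(tt1.shape)
    else:
        raise ValueError(f"unknown kernel {kernel!r}")
    w2 = weights[:, None] * weights[None, :]
    return float(np.sum(w2 * ker))


def expected_value_chosen(rule: EncodingRule, prior: PriorSpec | None = None,
                          n: float | None = None,
                          grid: QuadratureGrid | None = None,
                          window: float | None = None,
                          kernel: str = "normal") -> float:
    """Expected normalized magnitude of the chosen option, E[v(chosen)].

    Stimulus pairs are independent prior draws (f x f) unless ``window``
    restricts them to the experiment's CDF-distance band.  Choice follows
    the probit kernel ('normal') or exact enumeration ('exact').
    """
    prior = prior or rule.prior
    n = float(n if n is not None else rule.n)
    grid = grid or cdf_space_grid(256)
    v = prior_quantile(grid.nodes, prior)
    theta = clip_theta(rule.theta(v))
    t1 = theta[:, None]; t2 = theta[None, :]
    if kernel == "normal":
        p1 = choice_prob_normal(t1, t2, n)
    else:
        tt1, tt2 = np.broadcast_arrays(t1, t2)
        p1 = choice_prob_exact(tt1.ravel(), tt2.ravel(), int(n)).reshape(tt1.shape)
    w2 = grid.weights[:, None] * grid.weights[None, :]
    if window is not None:
        mask = np.abs(grid.nodes[:, None] - grid.nodes[None, :]) < window
        w2 = w2 * mask
        w2 = w2 / w2.sum()
    ev = np.sum(w2 * (p1 * v[:, None] + (1.0 - p1) * v[None, :]))
    return float(ev)


def simulate_threshold_curve(rule: EncodingRule, prior: PriorSpec | None = None,
                             n: float | None = None,
                             v_grid: NDArray[np.float64] | None = None,
                             criterion: float = 0.75,
                             tol: float = 1e-6) -> pd.DataFrame:
    """Discriminability thresholds d(v): the smallest increment such that
    P(choose v + d over v) reaches the criterion, by bisection on the probit
    choice model.  Unattainable criteria at the upper boundary give +inf.
    """
    if not (0.5 < criterion < 1.0):
        raise ValueError("criterion must be in (0.5, 1)")
    prior = prior or rule.prior
    n = float(n if n is not None else rule.n)
    v_grid = v_grid if v_grid is not None else np.linspace(0.02, 0.95, 40)
    out = []
    for v in v_grid:
        t_ref = rule.theta(v)
        hi = 1.0 - v

        def p(d):
            return float(choice_prob_normal(rule.theta(v + d), t_ref, n))

        if hi <= 0 or p(hi) < criterion:
            out.append({"v": v, "threshold": np.inf})
            continue
        lo = 0.0
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            if p(mid) >= criterion:
                hi = mid
            else:
                lo = mid
        out.append({"v": v, "threshold": 0.5 * (lo + hi)})
    return pd.DataFrame(out)


def compare_rules_finite_n(prior: PriorSpec, n_list: list[int],
                           metrics: tuple[str, ...] = ("avg_error", "expected_value"),
                           grid: QuadratureGrid | None = None) -> pd.DataFrame:
    """Exact-kernel error and expected-chosen-value for the three rules.

    Uses the full binomial enumeration kernel, so n is limited to modest
    values (<= 50 recommended).
    """
    grid = grid or cdf_space_grid(128)
    rows = []
    for n in n_list:
        for kind in ("accuracy", "reward", "dbs"):
            rule = EncodingRule(kind=kind, n=int(n), prior=prior)
            v = prior_quantile(grid.nodes, prior)
            theta = clip_theta(rule.theta(v))
            if "avg_error" in metrics:
                err = avg_error_prob_theta_dist(theta, grid.weights, n,
                                                kernel="exact")
                rows.append(BenchResult(kind, n, "avg_error", err, grid.size))
            if "expected_value" in metrics:
                ev = expected_value_chosen(rule, prior, n, grid, kernel="exact")
                rows.append(BenchResult(kind, n, "expected_value", ev, grid.size))
            if "mutual_information" in metrics:
                mi = mutual_information(rule, prior, int(n), grid)
                rows.append(BenchResult(kind, n, "mutual_information", mi, grid.size))
    return pd.DataFrame([r.__dict__ for r in rows])
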