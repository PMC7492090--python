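"""Choice probabilities and likelihoods for the sampling and log models.

Each stimulus is encoded as k ~ Binomial(n, theta(v)); the observer chooses
the option with the larger count (ties broken by a fair coin).  For large n
the choice probability is well approximated by the probit form

    P(choose left) = Phi( (theta_1 - theta_2)
                          / sqrt[(theta_1(1-theta_1) + theta_2(1-theta_2))/n]
                          + beta_0 + beta_L a r + beta_Ch a )

where beta_0 is a side bias and a, r encode the previous trial's choice side
and outcome.  The logarithmic benchmark model instead uses
P = Phi((log d1 - log d2)/(sigma sqrt 2) + bias terms) on raw dot counts.
In likelihoods n is treated as continuous (the hierarchical population prior
over n is a normal); the exact enumeration form requires integer n and
serves as the approximation oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from numpy.typing import ArrayLike, NDArray
from scipy.special import ndtr
from scipy.stats import binom

from .dataset import ChoiceDataset
from .encoding import EncodingRule, PriorSpec, clip_theta, normalize_dots, theta_accuracy, theta_dbs, theta_reward

__all__ = [
    "PROB_FLOOR",
    "ENUMERATION_MAX_N",
    "DecisionParams",
    "sample_representation",
    "choice_prob_exact",
    "choice_prob_normal",
    "choice_prob_log",
    "loglik_dataset",
]

#: Bernoulli probabilities are floored at this value in log-likelihoods.
PROB_FLOOR = 1e-12

#: Largest integer n for which the exact k1-vs-k2 enumeration is attempted.
ENUMERATION_MAX_N = 200

ModelName = Literal["accuracy", "reward", "dbs", "log"]

_THETA = {"accuracy": theta_accuracy, "reward": theta_reward, "dbs": theta_dbs}


@dataclass(frozen=True)
class DecisionParams:
    """Subject-level decision parameters.

    ``n`` is the number of binary sampling units (continuous in likelihoods);
    ``sigma`` is the log-space Weber noise of the logarithmic model.  The
    betas enter the probit argument additively: ``beta0`` is a left-side
    bias, ``betaL`` weights previous choice x outcome (outcome learning) and
    ``betaCh`` weights previous choice (choice repetition).
    """

    n: float = 25.0
    beta0: float = 0.0
    betaL: float = 0.0
    betaCh: float = 0.0
    sigma: float = 0.3

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")


def sample_representation(v: ArrayLike, rule: EncodingRule,
                          rng: np.random.Generator) -> NDArray[np.int_]:
    """Draw the internal count k ~ Binomial(n, theta(v)) for each stimulus."""
    theta = rule.theta(v)
    return rng.binomial(int(rule.n), theta)


def _bias(params: DecisionParams, prev_side: ArrayLike, prev_outcome: ArrayLike
          ) -> NDArray[np.float64]:
    a = np.asarray(prev_side, dtype=float)
    r = np.asarray(prev_outcome, dtype=float)
    return params.beta0 + params.betaL * a * r + params.betaCh * a


def choice_prob_exact(theta1: ArrayLike, theta2: ArrayLike, n: int
                      ) -> NDArray[np.float64]:
    """P(choose option 1) by full enumeration of (k1, k2).

    Option 1 is chosen when k1 > k2; ties contribute 1/2 (fair coin).
    Requires integer ``n`` at most :data:`ENUMERATION_MAX_N`.
    """
    if int(n) != n or not (1 <= n <= ENUMERATION_MAX_N):
        raise ValueError(
            f"exact enumeration needs integer 1 <= n <= {ENUMERATION_MAX_N}; "
            "use choice_prob_normal for larger or non-integer n")
    n = int(n)
    t1 = np.atleast_1d(np.asarray(theta1, dtype=float))
    t2 = np.atleast_1d(np.asarray(theta2, dtype=float))
    t1, t2 = np.broadcast_arrays(t1, t2)
    k = np.arange(n + 1)
    # pmf matrices: trials x (n+1)
    p1 = binom.pmf(k[None, :], n, t1.reshape(-1, 1))
    p2 = binom.pmf(k[None, :], n, t2.reshape(-1, 1))
    cdf2 = np.cumsum(p2, axis=1)  # P(k2 <= k)
    p_less = np.concatenate([np.zeros((p2.shape[0], 1)), cdf2[:, :-1]], axis=1)
    win = np.sum(p1 * p_less, axis=1)
    tie = np.sum(p1 * p2, axis=1)
    out = win + 0.5 * tie
    return out.reshape(np.shape(np.broadcast_arrays(theta1, theta2)[0])) \
        if np.ndim(theta1) or np.ndim(theta2) else float(out[0])


def choice_prob_normal(theta1: ArrayLike, theta2: ArrayLike, n: ArrayLike,
                       params: DecisionParams | None = None,
                       prev_side: ArrayLike = 0.0,
                       prev_outcome: ArrayLike = 0.0,
                       ) -> NDArray[np.float64]:
    """Probit (large-n normal) choice probability with bias/history terms."""
    params = params or DecisionParams(n=float(np.asarray(n).flat[0]))
    t1 = clip_theta(theta1)
    t2 = clip_theta(theta2)
    n = np.asarray(n, dtype=float)
    se = np.sqrt((t1 * (1.0 - t1) + t2 * (1.0 - t2)) / n)
    z = (t1 - t2) / se + _bias(params, prev_side, prev_outcome)
    p = ndtr(z)
    return np.clip(p, PROB_FLOOR, 1.0 - PROB_FLOOR)


def choice_prob_log(dots1: ArrayLike, dots2: ArrayLike,
                    params: DecisionParams,
                    prev_side: ArrayLike = 0.0,
                    prev_outcome: ArrayLike = 0.0,
                    ) -> NDArray[np.float64]:
    """Logarithmic (Weber) model choice probability on raw dot counts."""
    d1 = np.asarray(dots1, dtype=float)
    d2 = np.asarray(dots2, dtype=float)
    if np.any(d1 <= 0) or np.any(d2 <= 0):
        raise ValueError("dot counts must be positive")
    z = (np.log(d1) - np.log(d2)) / (params.sigma * np.sqrt(2.0)) \
        + _bias(params, prev_side, prev_outcome)
    p = ndtr(z)
    return np.clip(p, PROB_FLOOR, 1.0 - PROB_FLOOR)


def trial_choice_probs(data: ChoiceDataset, model: ModelName,
                       params: DecisionParams, prior: PriorSpec,
                       alpha_t: ArrayLike | None = None,
                       ) -> NDArray[np.float64]:
    """P(choose left) for every trial of a dataset under one model.

    ``alpha_t`` optionally supplies a per-trial prior shape for the
    adaptation variant of the DbS rule (theta_D with time-varying alpha).
    """
    a, r = data.history_regressors()
    dl = data.df["dots_left"].to_numpy()
    dr = data.df["dots_right"].to_numpy()
    if model == "log":
        return choice_prob_log(dl, dr, params, a, r)
    v1 = normalize_dots(dl, prior)
    v2 = normalize_dots(dr, prior)
    if alpha_t is not None:
        if model != "dbs":
            raise ValueError("trial-wise alpha is defined for the DbS rule")
        at = np.asarray(alpha_t, dtype=float)
        t1 = 1.0 - (1.0 - v1) ** (at + 1.0)
        t2 = 1.0 - (1.0 - v2) ** (at + 1.0)
    else:
        t1 = _THETA[model](v1, prior)
        t2 = _THETA[model](v2, prior)
    return choice_prob_normal(t1, t2, params.n, params, a, r)


def loglik_dataset(data: ChoiceDataset, model: ModelName,
                   params: DecisionParams, prior: PriorSpec,
                   alpha_t: ArrayLike | None = None,
                   ) -> tuple[NDArray[np.float64], float]:
    """Per-trial Bernoulli log-likelihoods and their total.

    Probabilities are floored at :data:`PROB_FLOOR`, so the result is always
    finite.
    """
    p_left = trial_choice_probs(data, model, params, prior, alpha_t)
    y = data.df["choice"].to_numpy()
    p_obs = np.where(y == 1, p_left, 1.0 - p_left)
    ll = np.log(np.clip(p_obs, PROB_FLOOR, 1.0))
    return ll, float(ll.sum())
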