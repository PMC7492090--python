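"""Synthetic numerosity experiments: stimulus generation and choice simulation.

Stimuli reproduce the study design: dot counts are i.i.d. draws from the
contextual prior f(v) = (alpha+1)(1-v)^alpha scaled to 5-55 dots, and the
two clouds of a trial are constrained to lie within a fixed window of each
other in CDF space (so most pairs are hard, and pair difficulty is roughly
uniform across the prior's support).  Choices are then simulated from any of
the sampling rules or the log model, with the history regressors computed
from the realized simulated sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .choice_model import DecisionParams, ModelName, choice_prob_log, choice_prob_normal
from .dataset import ChoiceDataset
from .encoding import PriorSpec, normalize_dots, prior_quantile, theta_accuracy, theta_dbs, theta_reward

__all__ = [
    "ExperimentSpec", "EXPERIMENTS",
    "sample_numerosity", "generate_trial_pair", "generate_trial_set",
    "simulate_choices", "make_recovery_suite", "performance_curves",
]

_THETA = {"accuracy": theta_accuracy, "reward": theta_reward, "dbs": theta_dbs}


@dataclass(frozen=True)
class ExperimentSpec:
    """Stimulus statistics and session structure of one experiment.

    ``window`` bounds the CDF-space distance |F(v1) - F(v2)| of the two
    clouds on every trial.
    """

    alpha: float = 2.0
    window: float = 0.25
    days: int = 4
    runs_per_day: int = 8
    trials_per_run: int = 75
    condition: str = "perceptual"
    name: str = "exp1"

    def __post_init__(self) -> None:
        if not (0.0 < self.window <= 1.0):
            raise ValueError("window must lie in (0, 1]")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")

    @property
    def n_trials(self) -> int:
        return self.days * self.runs_per_day * self.trials_per_run

    @property
    def prior(self) -> PriorSpec:
        return PriorSpec(alpha=self.alpha)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.__dict__ | {}, sort_keys=False)

    @classmethod
    def from_yaml(cls, s: str) -> "ExperimentSpec":
        return cls(**yaml.safe_load(s))


#: The three experiments' stimulus statistics and session structure:
#: exp1: prior shape 2, window 0.25, 4 days x 8 runs x 75 trials (~2400);
#: exp2: prior shape 2, window 0.28, 4 days x 16 runs x 40 trials (~2560);
#: exp3: prior shape 1, window 0.23, 3 days x 16 runs x 40 trials (~1920).
EXPERIMENTS: dict[str, ExperimentSpec] = {
    "exp1": ExperimentSpec(alpha=2.0, window=0.25, days=4, runs_per_day=8,
                           trials_per_run=75, name="exp1"),
    "exp2": ExperimentSpec(alpha=2.0, window=0.28, days=4, runs_per_day=16,
                           trials_per_run=40, name="exp2"),
    "exp3": ExperimentSpec(alpha=1.0, window=0.23, days=3, runs_per_day=16,
                           trials_per_run=40, name="exp3"),
}


def sample_numerosity(prior: PriorSpec, size: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Integer dot counts: prior draws scaled by 50, offset 5, rounded."""
    v = prior.sample(size, rng)
    return prior.denormalize(v)


def _draw_pairs(alpha: float, window: float, size: int,
                rng: np.random.Generator) -> tuple[np.ndarray, ...]:
    """Vectorized draw of CDF-window pairs (continuous magnitudes + counts)."""
    prior = PriorSpec(alpha=alpha)
    F1 = rng.uniform(0.0, 1.0, size=size)
    lo = np.maximum(0.0, F1 - window)
    hi = np.minimum(1.0, F1 + window)
    F2 = rng.uniform(lo, hi)
    v1 = prior_quantile(F1, prior)
    v2 = prior_quantile(F2, prior)
    d1 = prior.denormalize(v1)
    d2 = prior.denormalize(v2)
    return v1, v2, d1, d2


def generate_trial_pair(spec: ExperimentSpec, rng: np.random.Generator,
                        max_tries: int = 100) -> dict:
    """One stimulus pair within the CDF window with unequal dot counts.

    F1 is uniform on (0,1); F2 uniform on the window clipped to (0,1); both
    are mapped through the prior quantile and rounded to dots.  Pairs whose
    rounded counts coincide are redrawn (resampling F1 as well after
    ``max_tries`` failures, which cannot stall since the window always
    contains unequal counts).
    """
    for _ in range(max_tries):
        v1, v2, d1, d2 = (x[0] for x in _draw_pairs(spec.alpha, spec.window, 1, rng))
        if d1 != d2:
            return {"v_left": float(v1), "v_right": float(v2),
                    "dots_left": int(d1), "dots_right": int(d2)}
    # extremely unlikely fallthrough; fresh F1 draws until success
    while True:
        v1, v2, d1, d2 = (x[0] for x in _draw_pairs(spec.alpha, spec.window, 1, rng))
        if d1 != d2:
            return {"v_left": float(v1), "v_right": float(v2),
                    "dots_left": int(d1), "dots_right": int(d2)}


def generate_trial_set(spec: ExperimentSpec, rng: np.random.Generator,
                       subject: int = 0) -> pd.DataFrame:
    """Full day x run x trial stimulus table for one subject.

    Returns a DataFrame with columns subject, day, run, trial, condition,
    dots_left, dots_right plus the underlying continuous magnitudes
    v_left, v_right (kept for calibration analyses that predate rounding).
    """
    total = spec.n_trials
    # oversample, then reject equal-count pairs
    v1 = np.empty(0); v2 = np.empty(0)
    d1 = np.empty(0, dtype=int); d2 = np.empty(0, dtype=int)
    while len(d1) < total:
        a1, a2, b1, b2 = _draw_pairs(spec.alpha, spec.window,
                                     int(1.3 * (total - len(d1)) + 16), rng)
        keep = b1 != b2
        v1 = np.concatenate([v1, a1[keep]]); v2 = np.concatenate([v2, a2[keep]])
        d1 = np.concatenate([d1, b1[keep]]); d2 = np.concatenate([d2, b2[keep]])
    v1, v2, d1, d2 = v1[:total], v2[:total], d1[:total], d2[:total]
    day = np.repeat(np.arange(1, spec.days + 1),
                    spec.runs_per_day * spec.trials_per_run)
    run = np.tile(np.repeat(np.arange(1, spec.runs_per_day + 1),
                            spec.trials_per_run), spec.days)
    trial = np.tile(np.arange(1, spec.trials_per_run + 1),
                    spec.days * spec.runs_per_day)
    return pd.DataFrame({
        "subject": subject, "day": day, "run": run, "trial": trial,
        "condition": spec.condition,
        "dots_left": d1, "dots_right": d2,
        "v_left": v1, "v_right": v2,
    })


def simulate_choices(trials: pd.DataFrame, model: ModelName,
                     params: DecisionParams, prior: PriorSpec,
                     rng: np.random.Generator) -> ChoiceDataset:
    """Bernoulli choice simulation with sequentially realized history terms.

    With nonzero history weights each trial's probability depends on the
    simulated previous choice and outcome, so trials are generated in order;
    with all-zero history weights the simulation is fully vectorized.
    """
    dl = trials["dots_left"].to_numpy()
    dr = trials["dots_right"].to_numpy()
    if model == "log":
        base_z = None
        t1 = t2 = None
    else:
        v1 = normalize_dots(dl, prior)
        v2 = normalize_dots(dr, prior)
        t1 = _THETA[model](v1, prior)
        t2 = _THETA[model](v2, prior)
    T = len(trials)
    has_history = (params.betaL != 0.0) or (params.betaCh != 0.0)
    if not has_history:
        if model == "log":
            p = choice_prob_log(dl, dr, params)
        else:
            p = choice_prob_normal(t1, t2, params.n, params)
        choice = (rng.uniform(size=T) < p).astype(np.int64)
    else:
        run_key = trials[["day", "run"]].to_numpy()
        choice = np.zeros(T, dtype=np.int64)
        a = r = 0.0
        correct_prev = 0.0
        for t in range(T):
            if t == 0 or (run_key[t] != run_key[t - 1]).any():
                a, r = 0.0, 0.0
            if model == "log":
                p = choice_prob_log(dl[t], dr[t], params, a, r)
            else:
                p = choice_prob_normal(t1[t], t2[t], params.n, params, a, r)
            c = int(rng.uniform() < p)
            choice[t] = c
            a = 1.0 if c == 1 else -1.0
            left_larger = dl[t] > dr[t]
            correct = (c == 1) == left_larger
            r = 1.0 if correct else -1.0
    correct = ChoiceDataset.correctness(dl, dr, choice)
    df = trials.copy()
    df["choice"] = choice
    df["correct"] = correct
    meta = {"model": model, "params": params.__dict__ | {},
            "alpha": prior.alpha}
    return ChoiceDataset(df=df, meta=meta)


def make_recovery_suite(rules: list[str], n: float, trials_per_dataset: int,
                        replicates: int, seed: int,
                        spec: ExperimentSpec | None = None,
                        ) -> list[ChoiceDataset]:
    """Labelled synthetic datasets for model-recovery studies.

    For each rule and replicate, draws a fresh trial set with the
    experiment's stimulus statistics (default: exp1), truncated to
    ``trials_per_dataset`` trials, and simulates choices under that rule.
    Deterministic given ``seed``; the generating rule and parameters are
    recorded in each dataset's metadata.
    """
    if trials_per_dataset < 100:
        raise ValueError("recovery datasets need at least 100 trials")
    spec = spec or EXPERIMENTS["exp1"]
    prior = spec.prior
    rng = np.random.default_rng(seed)
    params = DecisionParams(n=n)
    out: list[ChoiceDataset] = []
    sid = 0
    for rule in rules:
        for _ in range(replicates):
            trials = generate_trial_set(spec, rng, subject=sid)
            trials = trials.iloc[:trials_per_dataset].reset_index(drop=True)
            ds = simulate_choices(trials, rule, params, prior, rng)
            ds.meta["replicate_of"] = rule
            out.append(ds)
            sid += 1
    return out


_BIN_EDGES = {
    "sum": np.arange(10, 111, 10),
    "abs_difference": np.array([0, 2, 4, 6, 8, 10, 15, 20, 30, 50]),
    "ratio": np.array([1.0, 1.1, 1.2, 1.35, 1.5, 1.75, 2.0, 3.0, 11.0]),
}


def performance_curves(data: ChoiceDataset,
                       binning: str = "sum",
                       edges: np.ndarray | None = None) -> pd.DataFrame:
    """Accuracy binned by a trial-difficulty statistic of the raw counts.

    ``binning`` is one of 'sum' (dots_left + dots_right), 'abs_difference'
    (|dots_left - dots_right|) or 'ratio' (max/min).  Empty bins are
    reported with count 0 and missing (NaN) accuracy.
    """
    if binning not in _BIN_EDGES:
        raise ValueError(f"unknown binning {binning!r}")
    dl = data.df["dots_left"].to_numpy()
    dr = data.df["dots_right"].to_numpy()
    if binning == "sum":
        x = dl + dr
    elif binning == "abs_difference":
        x = np.abs(dl - dr)
    else:
        x = np.maximum(dl, dr) / np.minimum(dl, dr)
    edges = edges if edges is not None else _BIN_EDGES[binning]
    idx = np.digitize(x, edges) - 1
    rows = []
    for b in range(len(edges) - 1):
        mask = idx == b
        cnt = int(mask.sum())
        acc = float(data.df["correct"].to_numpy()[mask].mean()) if cnt else np.nan
        rows.append({"bin_left": edges[b], "bin_right": edges[b + 1],
                     "count": cnt, "accuracy": acc})
    return pd.DataFrame(rows)
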