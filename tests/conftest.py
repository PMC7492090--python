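import numpy as np
import pytest

from binsamp import (
    EXPERIMENTS,
    ChoiceDataset,
    DecisionParams,
    PriorSpec,
    generate_trial_set,
    simulate_choices,
)


@pytest.fixture(scope="session")
def prior2() -> PriorSpec:
    """The prior of Experiments 1-2: shape 2 on 5-55 dots."""
    return PriorSpec(alpha=2.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260101)


@pytest.fixture(scope="session")
def dbs_dataset(prior2) -> ChoiceDataset:
    """1200 trials of a synthetic decision-by-sampling subject (n=25)."""
    rng = np.random.default_rng(7)
    trials = generate_trial_set(EXPERIMENTS["exp1"], rng)
    trials = trials.iloc[:1200].reset_index(drop=True)
    return simulate_choices(trials, "dbs", DecisionParams(n=25.0), prior2, rng)


def adapting_dataset(spec, delta, alpha0, tau, n, rng, prior=None):
    """DbS choices with a within-session exponential alpha trajectory."""
    from binsamp.choice_model import choice_prob_normal
    from binsamp.inference import _within_day_index

    prior = prior or PriorSpec(alpha=2.0)
    trials = generate_trial_set(spec, rng)
    t = _within_day_index(trials)
    alpha_t = delta + (alpha0 - delta) * np.exp(-t / tau)
    v1 = prior.normalize(trials["dots_left"].to_numpy())
    v2 = prior.normalize(trials["dots_right"].to_numpy())
    t1 = 1 - (1 - v1) ** (alpha_t + 1)
    t2 = 1 - (1 - v2) ** (alpha_t + 1)
    choice = (rng.uniform(size=len(t1))
              < choice_prob_normal(t1, t2, n)).astype(int)
    df = trials.copy()
    df["choice"] = choice
    df["correct"] = ChoiceDataset.correctness(
        df["dots_left"].to_numpy(), df["dots_right"].to_numpy(), choice)
    return ChoiceDataset(df=df, meta={})


@pytest.fixture(scope="session")
def rule_datasets(prior2) -> dict[str, ChoiceDataset]:
    """One 1200-trial synthetic subject per encoding rule (n=25)."""
    out = {}
    for i, rule in enumerate(("accuracy", "reward", "dbs")):
        rng = np.random.default_rng(100 + i)
        trials = generate_trial_set(EXPERIMENTS["exp1"], rng)
        trials = trials.iloc[:1200].reset_index(drop=True)
        trials["subject"] = i
        out[rule] = simulate_choices(trials, rule, DecisionParams(n=25.0),
                                     prior2, rng)
    return out
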