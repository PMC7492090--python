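#!/usr/bin/env python
"""Latent-mixture fit to a synthetic three-subject cohort.

One subject per encoding rule (1200 Experiment-1 trials each, n = 25) is
fit jointly with the hierarchical latent-mixture model at test-scale MCMC
settings.  Writes per-subject rule attributions, population mixture
weights, convergence diagnostics and LOO/WAIC to results/.  Each subject
should attribute to their generating rule with high probability, with all
R-hat below 1.05.
"""

import json
from pathlib import Path

import numpy as np

from binsamp import (
    DecisionParams, EXPERIMENTS, LatentMixtureSpec, PriorSpec,
    attribute_models, build_model, compute_loo_waic, generate_trial_set,
    run_mcmc, simulate_choices,
)

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)
prior = PriorSpec(alpha=2.0)

datasets = []
for s, rule in enumerate(("accuracy", "reward", "dbs")):
    rng = np.random.default_rng(400 + s)
    trials = generate_trial_set(EXPERIMENTS["exp1"], rng)
    trials = trials.iloc[:1200].reset_index(drop=True)
    trials["subject"] = s
    datasets.append(simulate_choices(trials, rule, DecisionParams(n=25.0),
                                     prior, rng))

model = build_model(datasets, LatentMixtureSpec(), prior)
post = run_mcmc(model, chains=3, burn_in=2000, draws=2000, thinning=2,
                seed=17)
attr = attribute_models(post)
attr["generated"] = ["accuracy", "reward", "dbs"]
attr.to_csv(OUT / "mixture_attribution.csv", index=False)
loo = compute_loo_waic(post.pointwise_ll, n_chains=3)

finite_rhat = {k: v for k, v in post.rhat.items() if np.isfinite(v)}
summary = {
    "population_pi": attr.attrs["population_pi"],
    "posterior_n_mean": post.flat("n").mean(axis=0).round(2).tolist(),
    "worst_rhat": round(max(finite_rhat.values()), 4),
    "elpd_loo": round(loo["loo"], 1),
    "elpd_waic": round(loo["waic"], 1),
    "config": post.config,
}
with open(OUT / "mixture_summary.json", "w") as fh:
    json.dump(summary, fh, indent=2)

print(attr[["subject", "generated", "accuracy", "reward", "dbs"]])
print(f"\nposterior mean n per subject: {summary['posterior_n_mean']} "
      f"(generated with n=25)")
print(f"worst R-hat {summary['worst_rhat']} "
      f"({'converged' if summary['worst_rhat'] < 1.05 else 'FLAGGED'}); "
      f"elpd_loo {summary['elpd_loo']}")
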