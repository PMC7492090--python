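# binsamp — efficient binary-sampling models of numerosity discrimination

How precisely can people tell which of two dot clouds is more numerous,
and what does their pattern of errors reveal about how magnitudes are
encoded? This package implements and tests an efficient-coding account in
which a magnitude `v` is represented by `n` independent binary units, each
firing with probability `θ(v)`, so the percept is a binomial count
`k ~ Binomial(n, θ(v))`. Different normative goals yield different
closed-form encoders adapted to the contextual prior `f(v) = (α+1)(1−v)^α`
(its CDF `F`):

| rule | `θ(v)` | optimizes |
|---|---|---|
| accuracy | `sin²((π/2) F(v))` | discrimination accuracy / mutual information |
| reward | `sin²((π/2) G(v))`, `G ∝ ∫ f^{2/3}` | expected chosen magnitude |
| DbS | `F(v)` | memory cost: one prior sample per unit |

Choices between two clouds follow the probit rule
`P = Φ((θ₁−θ₂)/√[(θ₁(1−θ₁)+θ₂(1−θ₂))/n] + biases)`, against a
logarithmic Weber benchmark `Φ((log d₁ − log d₂)/(σ√2))`.

The package provides, as importable modules with a thin `binsamp` CLI:

* `binsamp.encoding` — priors, the three rules, tabulated-prior variants,
  the threshold-unit noise density realizing a rule, analytic
  discriminability `d = 1/(nπf(v))`;
* `binsamp.choice_model` — exact (enumeration) and probit choice
  probabilities, side-bias and choice-history terms, per-trial
  log-likelihoods, CSV round-trip of choice data;
* `binsamp.synthetic_data` — experiment generators with the study design's
  stimulus statistics (priors of shape 2 and 1 over 5–55 dots, CDF-window
  pair selection), choice simulation, recovery suites, performance curves;
* `binsamp.theory_bench` — mutual information of the binomial channel,
  average-error landscapes over Beta encoder distributions, expected
  chosen value, simulated discriminability thresholds;
* `binsamp.inference` — hierarchical Bayesian latent-mixture model
  (Metropolis-within-Gibbs), R̂ diagnostics, PSIS-LOO/WAIC, the log-to-DbS
  prior-shape calibration, and prior-adaptation dynamics
  `α_t = δ + η e^{−t/τ}`.

The numbered scripts under `analysis/` run the study pipeline end to end
and write their tables to `results/`; see `docs/methods.md` for the model
assumptions and numerical choices.

## Worked example

Simulate a decision-by-sampling subject with Experiment-1 statistics and
ask which rule a mixture fit attributes:

```python
import numpy as np
from binsamp import (EXPERIMENTS, DecisionParams, LatentMixtureSpec,
                     PriorSpec, attribute_models, build_model,
                     generate_trial_set, run_mcmc, simulate_choices)

prior = PriorSpec(alpha=2.0)               # f(v) = 3 (1-v)^2 over 5..55 dots
rng = np.random.default_rng(7)
trials = generate_trial_set(EXPERIMENTS["exp1"], rng)   # 2400 trials
data = simulate_choices(trials, "dbs", DecisionParams(n=25.0), prior, rng)
print(f"accuracy {data.accuracy:.3f}")      # accuracy 0.837

model = build_model([data], LatentMixtureSpec(), prior)
post = run_mcmc(model, chains=3, burn_in=2000, draws=2000, thinning=2, seed=5)
print(attribute_models(post))
#    subject  accuracy  reward  dbs
# 0        0       0.0     0.0  1.0
print(f"n posterior mean {post.flat('n').mean():.1f}")   # n posterior mean 24.6
```

The subject simulated with the DbS rule at `n = 25` attributes fully to
DbS, with the sensitivity recovered within a couple of units. The same
pipeline scaled to 20 replicates per rule re-identifies the generating
rule in ≥ 95% of 1000-trial datasets (`analysis/03_model_recovery.py`),
and the calibration of the initial prior shape against a logarithmic code
lands at `α₀ ≈ 2.5` (`analysis/04_prior_calibration.py`).

Equivalent shell commands:

```sh
binsamp simulate --experiment exp1 --rule dbs --n 25 --seed 7 --out data.csv
binsamp fit --data data.csv --alpha-mode fixed --alpha 2 --chains 3 --seed 11 --out posterior/
binsamp bench --prior-alpha 2 --n 25 --metrics mi,error,ev --out bench.csv
binsamp calibrate --seed 1
```

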