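"""Hierarchical Bayesian latent-mixture inference for choice data.

Each subject s is assumed to use one of three encoding rules (accuracy,
reward, or decision by sampling), indicated by a latent categorical variable
m_s drawn from a population simplex pi ~ Dirichlet(1,1,1).  Subject-level
sensitivity n_s and bias weights beta_s are drawn from normal population
distributions whose means and standard deviations carry uniform hyperpriors:

    mu_n ~ U(1, 1000),      sigma_n ~ U(0.01, 1000)
    mu_beta ~ U(-10, 10),   sigma_beta ~ U(0.01, 100)
    mu_alpha ~ U(0.01, 20), sigma_alpha ~ U(0.0001, 100)   (free-alpha mode)

Choices are Bernoulli with the probit probability of the chosen rule.
Posterior sampling is Metropolis-within-Gibbs: conjugate updates for pi and
(truncated-normal) population means, categorical Gibbs updates for m_s, and
random-walk Metropolis for subject parameters and population scales.  The
number of units n is treated as continuous and truncated to >= 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from numpy.typing import NDArray
from scipy.optimize import minimize_scalar
from scipy.stats import truncnorm

from .choice_model import PROB_FLOOR, DecisionParams, loglik_dataset
from .dataset import ChoiceDataset
from .encoding import PriorSpec, clip_theta

__all__ = [
    "LatentMixtureSpec", "AdaptationParams", "PosteriorSummary", "MixtureModel",
    "build_model", "run_mcmc", "attribute_models", "compute_loo_waic",
    "gelman_rubin", "calibrate_alpha0", "fit_adaptation", "fit_early_late",
    "fit_rule_ml", "select_rule_ml",
]

RULES = ("accuracy", "reward", "dbs")

# Hyperprior supports (uniform)
BOUNDS = {
    "mu_n": (1.0, 1000.0), "sigma_n": (0.01, 1000.0),
    "mu_beta": (-10.0, 10.0), "sigma_beta": (0.01, 100.0),
    "mu_alpha": (0.01, 20.0), "sigma_alpha": (0.0001, 100.0),
}


@dataclass
class LatentMixtureSpec:
    """Structure flags for the latent-mixture hierarchical model."""

    include_history: bool = False
    alpha_mode: Literal["fixed", "free", "adaptive"] = "fixed"
    alpha_fixed: float = 2.0
    models: tuple[str, ...] = RULES
    include_log: bool = False  # adds the logarithmic model as a 4th component

    def __post_init__(self) -> None:
        if self.include_log and "log" not in self.models:
            self.models = tuple(self.models) + ("log",)


@dataclass(frozen=True)
class AdaptationParams:
    """Exponential prior-shape trajectory alpha_t = delta + eta e^(-t/tau)."""

    delta: float
    eta: float
    tau_adapt: float

    def __post_init__(self) -> None:
        if self.tau_adapt <= 0:
            raise ValueError("tau_adapt must be > 0")

    def alpha_at(self, t: NDArray[np.float64]) -> NDArray[np.float64]:
        return self.delta + self.eta * np.exp(-np.asarray(t, float) / self.tau_adapt)


@dataclass
class PosteriorSummary:
    """MCMC output: draws, diagnostics and pointwise log-likelihoods.

    ``draws`` maps latent names to arrays of shape (chains, kept) or
    (chains, kept, subjects); ``pointwise_ll`` stacks per-trial
    log-likelihoods as (chains*kept, total_trials).
    """

    draws: dict[str, np.ndarray]
    rhat: dict[str, float]
    pointwise_ll: np.ndarray | None
    config: dict
    accept_rates: dict[str, float] = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.config["chains"]

    def flat(self, name: str) -> np.ndarray:
        d = self.draws[name]
        return d.reshape(-1, *d.shape[2:])

    def converged(self, threshold: float = 1.05) -> bool:
        vals = [v for v in self.rhat.values() if np.isfinite(v)]
        return bool(np.all(np.asarray(vals) < threshold))


# ---------------------------------------------------------------------------
# Model container
# ---------------------------------------------------------------------------

class MixtureModel:
    """Latent-mixture model bound to a collection of subject datasets.

    Per-subject stimulus arrays (normalized magnitudes, history regressors,
    observed choices) are cached at construction so the sampler's inner loop
    avoids any DataFrame work.
    """

    def __init__(self, datasets: Sequence[ChoiceDataset],
                 spec: LatentMixtureSpec, prior: PriorSpec):
        if len(datasets) < 1:
            raise ValueError("need at least one subject")
        ids = {d.subject for d in datasets}
        if len(ids) != len(datasets):
            raise ValueError("duplicate subject ids across datasets")
        self.datasets = list(datasets)
        self.spec = spec
        self.prior = prior
        self.n_subjects = len(datasets)
        self.trial_counts = [len(d) for d in datasets]
        self._cache = []
        from .encoding import normalize_dots
        for d in self.datasets:
            a, r = d.history_regressors()
            dl = d.df["dots_left"].to_numpy(float)
            dr = d.df["dots_right"].to_numpy(float)
            self._cache.append({
                "v1": normalize_dots(dl, prior), "v2": normalize_dots(dr, prior),
                "logd": np.log(dl) - np.log(dr),
                "a": a, "r": r, "y": d.df["choice"].to_numpy(),
            })

    def _theta_pair(self, s: int, model: str, alpha: float | None):
        c = self._cache[s]
        al = self.prior.alpha if alpha is None else alpha
        v1, v2 = c["v1"], c["v2"]
        if model == "accuracy":
            t1 = np.sin(0.5 * np.pi * (1 - (1 - v1) ** (al + 1))) ** 2
            t2 = np.sin(0.5 * np.pi * (1 - (1 - v2) ** (al + 1))) ** 2
        elif model == "reward":
            e = (2 * al + 3) / 3.0
            t1 = np.sin(0.5 * np.pi * (1 - (1 - v1) ** e)) ** 2
            t2 = np.sin(0.5 * np.pi * (1 - (1 - v2) ** e)) ** 2
        elif model == "dbs":
            t1 = 1 - (1 - v1) ** (al + 1)
            t2 = 1 - (1 - v2) ** (al + 1)
        else:
            raise ValueError(model)
        return clip_theta(t1), clip_theta(t2)

    def subject_loglik(self, s: int, model: str, n: float,
                       beta0: float = 0.0, betaL: float = 0.0,
                       betaCh: float = 0.0, alpha: float | None = None,
                       pointwise: bool = False):
        """Log-likelihood of subject s under one rule and parameter set.

        For the log model the sensitivity latent n is mapped to the Weber
        noise via sigma = 1/n, so one population sensitivity serves both
        model families.
        """
        from scipy.special import ndtr

        c = self._cache[s]
        n = max(float(n), 1.0)
        bias = beta0 + betaL * c["a"] * c["r"] + betaCh * c["a"]
        if model == "log":
            z = c["logd"] * (n / np.sqrt(2.0)) + bias
        else:
            t1, t2 = self._theta_pair(s, model,
                                      None if self.spec.alpha_mode == "fixed"
                                      else alpha)
            z = (t1 - t2) / np.sqrt((t1 * (1 - t1) + t2 * (1 - t2)) / n) + bias
        p_left = np.clip(ndtr(z), PROB_FLOOR, 1.0 - PROB_FLOOR)
        p_obs = np.where(c["y"] == 1, p_left, 1.0 - p_left)
        ll_vec = np.log(p_obs)
        total = float(ll_vec.sum())
        return (ll_vec, total) if pointwise else total

    def log_joint(self, state: dict) -> float:
        """Log prior + log likelihood at one latent configuration.

        Used to validate the model's density on toy data; the Gibbs sweep
        itself updates blocks in place.  ``state`` carries pi, m, n,
        mu_n/sigma_n and optionally per-subject betas with their population
        parameters.
        """
        pi = np.asarray(state["pi"], float)
        if np.any(pi <= 0) or abs(pi.sum() - 1.0) > 1e-8:
            return -np.inf
        mu_n, s_n = state["mu_n"], state["sigma_n"]
        if not (BOUNDS["mu_n"][0] <= mu_n <= BOUNDS["mu_n"][1]):
            return -np.inf
        if not (BOUNDS["sigma_n"][0] <= s_n <= BOUNDS["sigma_n"][1]):
            return -np.inf
        lp = 0.0
        zeros = np.zeros(self.n_subjects)
        b0 = np.asarray(state.get("beta0", zeros), float)
        bL = np.asarray(state.get("betaL", zeros), float)
        bCh = np.asarray(state.get("betaCh", zeros), float)
        for s in range(self.n_subjects):
            n_s = state["n"][s]
            if n_s < 1.0:
                return -np.inf
            lp += -0.5 * ((n_s - mu_n) / s_n) ** 2 \
                - 0.5 * np.log(2 * np.pi) - np.log(s_n)
            lp += np.log(pi[state["m"][s]])
            model = self.spec.models[state["m"][s]]
            lp += self.subject_loglik(s, model, n_s, b0[s], bL[s], bCh[s])
        for b, arr in (("beta0", b0), ("betaL", bL), ("betaCh", bCh)):
            if f"mu_{b}" in state:
                mu, sd = state[f"mu_{b}"], state[f"sigma_{b}"]
                if not (BOUNDS["mu_beta"][0] <= mu <= BOUNDS["mu_beta"][1]):
                    return -np.inf
                if not (BOUNDS["sigma_beta"][0] <= sd <= BOUNDS["sigma_beta"][1]):
                    return -np.inf
                z = (arr - mu) / sd
                lp += float(np.sum(-0.5 * z ** 2 - 0.5 * np.log(2 * np.pi)
                                   - np.log(sd)))
        return float(lp)


def build_model(datasets: Sequence[ChoiceDataset], spec: LatentMixtureSpec,
                prior: PriorSpec) -> MixtureModel:
    """Bind a latent-mixture specification to subject datasets."""
    return MixtureModel(datasets, spec, prior)


# ---------------------------------------------------------------------------
# Metropolis-within-Gibbs sampler
# ---------------------------------------------------------------------------

def _sample_trunc_normal(rng, mean, sd, lo, hi):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(truncnorm.rvs(a, b, loc=mean, scale=sd,
                               random_state=rng))


def run_mcmc(model: MixtureModel, chains: int = 3, burn_in: int = 2000,
             draws: int = 2000, thinning: int = 2, seed: int = 0,
             pointwise: bool = True, progress: bool = False,
             ) -> PosteriorSummary:
    """Metropolis-within-Gibbs posterior sampling.

    Paper-scale settings (3 chains, 50k burn-in, 50k draws, thin 50) and
    test-scale settings (3 chains, 2k + 2k, thin 2) are both expressible;
    the default is the test scale.  Reproducible given ``seed``.
    """
    if chains < 2:
        raise ValueError("need at least 2 chains for convergence diagnostics")
    spec = model.spec
    S = model.n_subjects
    M = len(spec.models)
    kept = draws // thinning
    free_alpha = spec.alpha_mode == "free"
    use_beta = True  # beta0 always present; history betas optional
    history = spec.include_history

    names_pop = ["mu_n", "sigma_n", "mu_beta0", "sigma_beta0"]
    if history:
        names_pop += ["mu_betaL", "sigma_betaL", "mu_betaCh", "sigma_betaCh"]
    if free_alpha:
        names_pop += ["mu_alpha", "sigma_alpha"]

    store = {nm: np.zeros((chains, kept)) for nm in names_pop}
    store["pi"] = np.zeros((chains, kept, M))
    store["m"] = np.zeros((chains, kept, S), dtype=int)
    store["n"] = np.zeros((chains, kept, S))
    store["beta0"] = np.zeros((chains, kept, S))
    if history:
        store["betaL"] = np.zeros((chains, kept, S))
        store["betaCh"] = np.zeros((chains, kept, S))
    if free_alpha:
        store["alpha_s"] = np.zeros((chains, kept, S))
    total_trials = sum(model.trial_counts)
    ll_store = np.zeros((chains, kept, total_trials)) if pointwise else None

    acc = {"n": 0, "beta": 0, "alpha": 0, "scale": 0}
    prop = {"n": 0, "beta": 0, "alpha": 0, "scale": 0}

    seed_seq = np.random.SeedSequence(seed)
    chain_seeds = seed_seq.spawn(chains)

    def subject_ll(s, m_idx, n_s, b0, bL, bCh, al):
        return model.subject_loglik(s, spec.models[m_idx], n_s, b0, bL, bCh,
                                    alpha=al)

    for c in range(chains):
        rng = np.random.default_rng(chain_seeds[c])
        # --- initialization (dispersed across chains) ---
        pi = rng.dirichlet(np.ones(M))
        m = rng.integers(0, M, size=S)
        n_s = rng.uniform(10.0, 60.0, size=S)
        b0 = rng.normal(0.0, 0.1, size=S)
        bL = np.zeros(S)
        bCh = np.zeros(S)
        if history:
            bL = rng.normal(0.0, 0.1, size=S)
            bCh = rng.normal(0.0, 0.1, size=S)
        al = np.full(S, spec.alpha_fixed, dtype=float)
        if free_alpha:
            al = rng.uniform(1.0, 4.0, size=S)
        mu_n, s_n = float(np.mean(n_s)), 20.0
        pops = {"mu_beta0": 0.0, "sigma_beta0": 0.5,
                "mu_betaL": 0.0, "sigma_betaL": 0.5,
                "mu_betaCh": 0.0, "sigma_betaCh": 0.5,
                "mu_alpha": 2.0, "sigma_alpha": 1.0}
        cur_ll = np.array([subject_ll(s, m[s], n_s[s], b0[s], bL[s], bCh[s],
                                      al[s] if free_alpha else None)
                           for s in range(S)])

        step_n = np.full(S, 3.0)
        step_b = 0.1
        step_a = 0.3

        k_idx = 0
        total_iters = burn_in + draws
        for it in range(total_iters):
            # -- m_s | rest: categorical Gibbs --
            if M > 1:
                for s in range(S):
                    lls = np.array([
                        cur_ll[s] if j == m[s] else
                        subject_ll(s, j, n_s[s], b0[s], bL[s], bCh[s],
                                   al[s] if free_alpha else None)
                        for j in range(M)])
                    logp = np.log(pi) + lls
                    logp -= logp.max()
                    p = np.exp(logp)
                    p /= p.sum()
                    new = rng.choice(M, p=p)
                    if new != m[s]:
                        m[s] = new
                        cur_ll[s] = lls[new]
                # -- pi | m: Dirichlet conjugate --
                counts = np.bincount(m, minlength=M)
                pi = rng.dirichlet(1.0 + counts)

            # -- n_s: random-walk MH (log prior: truncated normal pop) --
            for s in range(S):
                prop["n"] += 1
                cand = n_s[s] + rng.normal(0.0, step_n[s])
                if cand < 1.0:
                    continue
                ll_new = subject_ll(s, m[s], cand, b0[s], bL[s], bCh[s],
                                    al[s] if free_alpha else None)
                lp_new = -0.5 * ((cand - mu_n) / s_n) ** 2
                lp_old = -0.5 * ((n_s[s] - mu_n) / s_n) ** 2
                if np.log(rng.uniform()) < (ll_new + lp_new) - (cur_ll[s] + lp_old):
                    n_s[s] = cand
                    cur_ll[s] = ll_new
                    acc["n"] += 1

            # -- beta0 (and history betas): random-walk MH --
            beta_blocks = [("beta0", b0)]
            if history:
                beta_blocks += [("betaL", bL), ("betaCh", bCh)]
            for bname, arr in beta_blocks:
                mu_b = pops[f"mu_{bname}"]
                sd_b = pops[f"sigma_{bname}"]
                for s in range(S):
                    prop["beta"] += 1
                    cand = arr[s] + rng.normal(0.0, step_b)
                    trial_b0 = cand if bname == "beta0" else b0[s]
                    trial_bL = cand if bname == "betaL" else bL[s]
                    trial_bCh = cand if bname == "betaCh" else bCh[s]
                    ll_new = subject_ll(s, m[s], n_s[s], trial_b0, trial_bL,
                                        trial_bCh, al[s] if free_alpha else None)
                    lp_new = -0.5 * ((cand - mu_b) / sd_b) ** 2
                    lp_old = -0.5 * ((arr[s] - mu_b) / sd_b) ** 2
                    if np.log(rng.uniform()) < (ll_new + lp_new) - (cur_ll[s] + lp_old):
                        arr[s] = cand
                        cur_ll[s] = ll_new
                        acc["beta"] += 1

            # -- alpha_s (free mode): random-walk MH --
            if free_alpha:
                mu_a, sd_a = pops["mu_alpha"], pops["sigma_alpha"]
                for s in range(S):
                    prop["alpha"] += 1
                    cand = al[s] + rng.normal(0.0, step_a)
                    if not (0.01 <= cand <= 20.0):
                        continue
                    ll_new = subject_ll(s, m[s], n_s[s], b0[s], bL[s], bCh[s], cand)
                    lp_new = -0.5 * ((cand - mu_a) / sd_a) ** 2
                    lp_old = -0.5 * ((al[s] - mu_a) / sd_a) ** 2
                    if np.log(rng.uniform()) < (ll_new + lp_new) - (cur_ll[s] + lp_old):
                        al[s] = cand
                        cur_ll[s] = ll_new
                        acc["alpha"] += 1

            # -- population means: conjugate truncated-normal draws --
            mu_n = _sample_trunc_normal(rng, float(np.mean(n_s)),
                                        s_n / np.sqrt(S), *BOUNDS["mu_n"])
            for bname, arr in beta_blocks:
                pops[f"mu_{bname}"] = _sample_trunc_normal(
                    rng, float(np.mean(arr)),
                    pops[f"sigma_{bname}"] / np.sqrt(S), *BOUNDS["mu_beta"])
            if free_alpha:
                pops["mu_alpha"] = _sample_trunc_normal(
                    rng, float(np.mean(al)),
                    pops["sigma_alpha"] / np.sqrt(S), *BOUNDS["mu_alpha"])

            # -- population scales: log-space random-walk MH --
            def update_scale(cur, values, mu, lo, hi):
                prop["scale"] += 1
                cand = cur * np.exp(rng.normal(0.0, 0.8))
                if not (lo <= cand <= hi):
                    return cur
                z_new = np.sum(-0.5 * ((values - mu) / cand) ** 2) \
                    - len(values) * np.log(cand)
                z_old = np.sum(-0.5 * ((values - mu) / cur) ** 2) \
                    - len(values) * np.log(cur)
                # Jacobian of the log-space proposal
                if np.log(rng.uniform()) < (z_new - z_old) + np.log(cand / cur):
                    acc["scale"] += 1
                    return cand
                return cur

            s_n = update_scale(s_n, n_s, mu_n, *BOUNDS["sigma_n"])
            for bname, arr in beta_blocks:
                pops[f"sigma_{bname}"] = update_scale(
                    pops[f"sigma_{bname}"], arr, pops[f"mu_{bname}"],
                    *BOUNDS["sigma_beta"])
            if free_alpha:
                pops["sigma_alpha"] = update_scale(
                    pops["sigma_alpha"], al, pops["mu_alpha"],
                    *BOUNDS["sigma_alpha"])

            # -- adapt step sizes during burn-in --
            if it < burn_in and it % 200 == 199:
                rate = acc["n"] / max(prop["n"], 1)
                step_n *= np.exp(np.clip(rate - 0.35, -0.5, 0.5))

            # -- store --
            if it >= burn_in and (it - burn_in) % thinning == 0 and k_idx < kept:
                store["pi"][c, k_idx] = pi
                store["m"][c, k_idx] = m
                store["n"][c, k_idx] = n_s
                store["beta0"][c, k_idx] = b0
                if history:
                    store["betaL"][c, k_idx] = bL
                    store["betaCh"][c, k_idx] = bCh
                if free_alpha:
                    store["alpha_s"][c, k_idx] = al
                store["mu_n"][c, k_idx] = mu_n
                store["sigma_n"][c, k_idx] = s_n
                for nm in names_pop[2:]:
                    store[nm][c, k_idx] = pops[nm]
                if pointwise:
                    offs = 0
                    for s in range(S):
                        vec, _ = model.subject_loglik(
                            s, spec.models[m[s]], n_s[s], b0[s], bL[s], bCh[s],
                            alpha=al[s] if free_alpha else None, pointwise=True)
                        ll_store[c, k_idx, offs:offs + len(vec)] = vec
                        offs += len(vec)
                k_idx += 1

    rhat = {}
    for nm, arr in store.items():
        if nm == "m":
            continue
        if arr.ndim == 2:
            rhat[nm] = gelman_rubin(arr)
        else:
            for j in range(arr.shape[2]):
                rhat[f"{nm}[{j}]"] = gelman_rubin(arr[:, :, j])
    accept_rates = {k: acc[k] / max(prop[k], 1) for k in acc}
    cfg = {"chains": chains, "burn_in": burn_in, "draws": draws,
           "thinning": thinning, "kept_per_chain": kept, "seed": seed,
           "models": list(spec.models)}
    pll = ll_store.reshape(chains * kept, total_trials) if pointwise else None
    return PosteriorSummary(draws=store, rhat=rhat, pointwise_ll=pll,
                            config=cfg, accept_rates=accept_rates)


# ---------------------------------------------------------------------------
# Posterior post-processing
# ---------------------------------------------------------------------------

def attribute_models(posterior: PosteriorSummary) -> pd.DataFrame:
    """Per-subject rule attribution (posterior frequency of m_s) and the
    population mixture weights (posterior mean of pi)."""
    m = posterior.draws["m"].reshape(-1, posterior.draws["m"].shape[-1])
    models = posterior.config["models"]
    M = len(models)
    rows = []
    for s in range(m.shape[1]):
        freq = np.bincount(m[:, s], minlength=M) / m.shape[0]
        rows.append({"subject": s, **{models[j]: freq[j] for j in range(M)}})
    df = pd.DataFrame(rows)
    pi_mean = posterior.flat("pi").mean(axis=0)
    df.attrs["population_pi"] = {models[j]: float(pi_mean[j]) for j in range(M)}
    return df


def compute_loo_waic(pointwise_ll: np.ndarray, n_chains: int | None = None
                     ) -> dict:
    """PSIS-LOO and WAIC from a (draws x trials) pointwise log-likelihood.

    Wraps arviz; reports elpd totals with standard errors and flags trials
    with Pareto-k > 0.7.
    """
    import arviz as az

    ll = np.asarray(pointwise_ll, dtype=float)
    if ll.ndim != 2 or ll.shape[0] < 100:
        raise ValueError("need a (draws >= 100) x trials matrix")
    if not np.all(np.isfinite(ll)):
        raise ValueError("log-likelihood matrix must be finite")
    chains = n_chains or 1
    ll3 = ll.reshape(chains, ll.shape[0] // chains, ll.shape[1])
    # arviz requires a posterior group; the deviance is a convenient scalar
    idata = az.from_dict(posterior={"deviance": -2.0 * ll3.sum(axis=2)},
                         log_likelihood={"y": ll3})
    loo = az.loo(idata, pointwise=True)
    waic = az.waic(idata, pointwise=True)
    k = np.asarray(loo.pareto_k)
    frac_bad = float(np.mean(k > 0.7))
    return {
        "loo": float(loo.elpd_loo), "loo_se": float(loo.se),
        "p_loo": float(loo.p_loo),
        "waic": float(waic.elpd_waic), "waic_se": float(waic.se),
        "p_waic": float(waic.p_waic),
        "pareto_k": k, "frac_pareto_k_gt_0.7": frac_bad,
        "warn_pareto": frac_bad > 0.10,
    }


def gelman_rubin(chains: np.ndarray) -> float:
    """Split-R-hat potential scale reduction factor.

    ``chains`` has shape (n_chains, n_draws).  Returns inf for chains with
    (numerically) zero within-chain variance and distinct means, and nan
    when every draw is identical.
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need >= 2 chains of equal length")
    n = x.shape[1]
    if n < 4:
        raise ValueError("need >= 4 draws per chain")
    half = n // 2
    splits = np.concatenate([x[:, :half], x[:, half:2 * half]], axis=0)
    m, n = splits.shape
    chain_means = splits.mean(axis=1)
    chain_vars = splits.var(axis=1, ddof=1)
    W = chain_vars.mean()
    B = n * chain_means.var(ddof=1)
    scale = 1.0 + float(np.mean(splits)) ** 2
    if W <= 1e-24 * scale:
        # numerically constant chains: identical draws -> nan sentinel,
        # frozen-but-distinct chains -> inf
        return np.nan if B <= 1e-24 * scale else np.inf
    var_hat = (n - 1) / n * W + B / n
    return float(np.sqrt(var_hat / W))


# ---------------------------------------------------------------------------
# Maximum-likelihood rule fitting (fast route used by recovery analyses)
# ---------------------------------------------------------------------------

def fit_rule_ml(data: ChoiceDataset, model: str, prior: PriorSpec,
                n_bounds: tuple[float, float] = (1.0, 400.0)) -> dict:
    """Maximum-likelihood sensitivity fit of one rule to one dataset.

    Optimizes the single sensitivity parameter (n for sampling rules,
    1/sigma reparametrized as n for the log model) by bounded scalar search;
    bias and history weights are held at zero, matching the base generative
    model of the recovery analyses.
    """
    def neg_ll(n):
        if model == "log":
            params = DecisionParams(n=25.0, sigma=1.0 / n)
        else:
            params = DecisionParams(n=n)
        _, total = loglik_dataset(data, model, params, prior)
        return -total

    res = minimize_scalar(neg_ll, bounds=n_bounds, method="bounded",
                          options={"xatol": 1e-3})
    return {"model": model, "n": float(res.x), "loglik": float(-res.fun)}


def select_rule_ml(data: ChoiceDataset, prior: PriorSpec,
                   models: Sequence[str] = RULES) -> dict:
    """Fit each candidate rule by ML and select the best-likelihood one."""
    fits = {m: fit_rule_ml(data, m, prior) for m in models}
    best = max(fits, key=lambda m: fits[m]["loglik"])
    return {"selected": best, "fits": fits}


# ---------------------------------------------------------------------------
# Prior-shape calibration (initial alpha of the adaptation model)
# ---------------------------------------------------------------------------

def _dbs_discriminability_term(v1, v2, alpha):
    t1 = clip_theta(1.0 - (1.0 - v1) ** (alpha + 1.0))
    t2 = clip_theta(1.0 - (1.0 - v2) ** (alpha + 1.0))
    return (t1 - t2) / np.sqrt(t1 * (1.0 - t1) + t2 * (1.0 - t2))


def calibrate_alpha0(trial_sets: Sequence[pd.DataFrame],
                     bounds: tuple[float, float] = (0.1, 10.0)) -> float:
    """Prior shape at which DbS discriminability best mimics the log rule.

    Minimizes, over all pooled trials, the summed squared difference between
    the standardized DbS discriminability term (theta_D evaluated on the
    continuous pre-rounding magnitudes v in [0,1]) and the log-numerosity
    difference log(d1) - log(d2) of the integer dot counts.  Neither model's
    sensitivity parameter enters: the comparison is shape-only.

    ``trial_sets`` are stimulus tables from :func:`generate_trial_set`
    (columns v_left, v_right, dots_left, dots_right).
    """
    if not trial_sets or all(len(t) == 0 for t in trial_sets):
        raise ValueError("empty trial sets")
    v1 = np.concatenate([t["v_left"].to_numpy(float) for t in trial_sets])
    v2 = np.concatenate([t["v_right"].to_numpy(float) for t in trial_sets])
    d1 = np.concatenate([t["dots_left"].to_numpy(float) for t in trial_sets])
    d2 = np.concatenate([t["dots_right"].to_numpy(float) for t in trial_sets])
    dlog = np.log(d1) - np.log(d2)

    def objective(a):
        return float(np.sum((_dbs_discriminability_term(v1, v2, a) - dlog) ** 2))

    res = minimize_scalar(objective, bounds=bounds, method="bounded",
                          options={"xatol": 1e-5})
    return float(res.x)


# ---------------------------------------------------------------------------
# Adaptation dynamics
# ---------------------------------------------------------------------------

def _within_day_index(df: pd.DataFrame) -> np.ndarray:
    """Trial counter t restarting at each daily session (0-based)."""
    t = np.zeros(len(df), dtype=float)
    for _, idx in df.groupby("day", sort=False).indices.items():
        t[idx] = np.arange(len(idx), dtype=float)
    return t


def fit_adaptation(groups: dict[str, list[ChoiceDataset]],
                   alpha0: float = 2.58,
                   prior: PriorSpec | None = None,
                   chains: int = 3, burn_in: int = 600, draws: int = 600,
                   thinning: int = 2, seed: int = 0) -> dict:
    """Posterior over adaptation dynamics alpha_t = delta + eta e^(-t/tau).

    ``groups`` maps a group label (e.g. 'exp12', 'exp3') to that group's
    subject datasets.  Each group gets its own asymptote delta_g; the time
    constant tau is shared across groups; the amplitude is anchored at the
    calibrated initial shape, eta_g = alpha0 - delta_g; the trial index t
    restarts at each daily session.  Subject sensitivity n_s is sampled
    alongside.  Random-walk Metropolis on (delta_g, log tau, n_s) with
    uniform priors delta ~ U(0.01, 20), tau ~ U(1, 5000).

    Returns draws for each delta, tau, and the posterior probability of the
    ordering delta_first_group > delta_second_group when two groups are
    supplied.
    """
    from scipy.special import ndtr

    prior = prior or PriorSpec(alpha=2.0)
    labels = list(groups)
    G = len(labels)
    # flatten datasets, remembering each one's group
    cache = []
    for g, lab in enumerate(labels):
        for ds in groups[lab]:
            df = ds.df
            cache.append({
                "g": g,
                "v1": prior.normalize(df["dots_left"].to_numpy()),
                "v2": prior.normalize(df["dots_right"].to_numpy()),
                "t": _within_day_index(df),
                "y": df["choice"].to_numpy(),
            })
    n_ds = len(cache)
    kept = draws // thinning
    d_store = np.zeros((chains, kept, G))
    tau_store = np.zeros((chains, kept))
    n_store = np.zeros((chains, kept, n_ds))
    seeds = np.random.SeedSequence(seed).spawn(chains)

    def ll_one(j, delta_g, tau, n_j):
        c = cache[j]
        a_t = np.maximum(delta_g + (alpha0 - delta_g) * np.exp(-c["t"] / tau),
                         1e-3)
        t1 = clip_theta(1 - (1 - c["v1"]) ** (a_t + 1))
        t2 = clip_theta(1 - (1 - c["v2"]) ** (a_t + 1))
        z = (t1 - t2) / np.sqrt((t1 * (1 - t1) + t2 * (1 - t2)) / max(n_j, 1.0))
        p = np.clip(ndtr(z), PROB_FLOOR, 1 - PROB_FLOOR)
        return float(np.log(np.where(c["y"] == 1, p, 1 - p)).sum())

    for c_i in range(chains):
        rng = np.random.default_rng(seeds[c_i])
        deltas = rng.uniform(0.5, 3.0, size=G)
        tau = rng.uniform(50.0, 300.0)
        ns = rng.uniform(15.0, 40.0, size=n_ds)
        cur = np.array([ll_one(j, deltas[cache[j]["g"]], tau, ns[j])
                        for j in range(n_ds)])
        k_idx = 0
        for it in range(burn_in + draws):
            for g in range(G):
                cand = deltas[g] + rng.normal(0.0, 0.25)
                if not (0.01 <= cand <= 20.0):
                    continue
                idx = [j for j in range(n_ds) if cache[j]["g"] == g]
                new = np.array([ll_one(j, cand, tau, ns[j]) for j in idx])
                if np.log(rng.uniform()) < new.sum() - cur[idx].sum():
                    deltas[g] = cand
                    cur[idx] = new
            cand_tau = tau * np.exp(rng.normal(0.0, 0.4))
            if 1.0 <= cand_tau <= 5000.0:
                new = np.array([ll_one(j, deltas[cache[j]["g"]], cand_tau, ns[j])
                                for j in range(n_ds)])
                if np.log(rng.uniform()) < (new.sum() - cur.sum()
                                            + np.log(cand_tau / tau)):
                    tau = cand_tau
                    cur = new
            for j in range(n_ds):
                cand_n = ns[j] + rng.normal(0.0, 2.0)
                if cand_n < 1.0:
                    continue
                new = ll_one(j, deltas[cache[j]["g"]], tau, cand_n)
                if np.log(rng.uniform()) < new - cur[j]:
                    ns[j] = cand_n
                    cur[j] = new
            if it >= burn_in and (it - burn_in) % thinning == 0 and k_idx < kept:
                d_store[c_i, k_idx] = deltas
                tau_store[c_i, k_idx] = tau
                n_store[c_i, k_idx] = ns
                k_idx += 1

    out = {
        "labels": labels,
        "delta_draws": d_store,
        "tau_draws": tau_store,
        "n_draws": n_store,
        "alpha0": alpha0,
        "delta_mean": d_store.reshape(-1, G).mean(axis=0),
        "tau_mean": float(tau_store.mean()),
        "rhat": {f"delta[{labels[g]}]": gelman_rubin(d_store[:, :, g])
                 for g in range(G)} | {"tau": gelman_rubin(tau_store)},
    }
    if G == 2:
        flat = d_store.reshape(-1, G)
        # tail probability that the stated ordering delta_1 > delta_2 fails
        out["p_delta1_gt_delta2"] = float(np.mean(flat[:, 0] > flat[:, 1]))
    return out


def fit_early_late(data: ChoiceDataset, prior: PriorSpec,
                   first_k: int = 150, last_k: int = 350,
                   chains: int = 3, burn_in: int = 400, draws: int = 400,
                   thinning: int = 2, seed: int = 0) -> dict:
    """Free-but-fixed alpha fits to early vs late blocks of each session.

    Extracts the first ``first_k`` and last ``last_k`` trials of each daily
    session (sessions shorter than first_k + last_k are skipped and logged),
    then jointly samples (alpha_early, alpha_late, n) by random-walk
    Metropolis under the DbS likelihood: the sensitivity n is shared across
    blocks so that the block alphas are not confounded with overall
    performance, with uniform priors alpha ~ U(0.01, 20), n >= 1.

    Returns per-block alpha draws and the posterior probability
    P(alpha_late >= alpha_early) (small values indicate a credible
    within-session decline of the shape parameter).
    """
    from scipy.special import ndtr

    blocks = {"early": [], "late": []}
    skipped = []
    for day, g in data.df.groupby("day", sort=True):
        if len(g) < first_k + last_k:
            skipped.append(int(day))
            continue
        blocks["early"].append(g.iloc[:first_k])
        blocks["late"].append(g.iloc[-last_k:])
    if not blocks["early"]:
        raise ValueError("no session long enough for the requested blocks")
    out = {"skipped_days": skipped,
           "n_early_trials": sum(len(p) for p in blocks["early"]),
           "n_late_trials": sum(len(p) for p in blocks["late"])}
    cache = {}
    for name, parts in blocks.items():
        df = pd.concat(parts).reset_index(drop=True)
        cache[name] = {
            "v1": prior.normalize(df["dots_left"].to_numpy()),
            "v2": prior.normalize(df["dots_right"].to_numpy()),
            "y": df["choice"].to_numpy(),
        }

    def block_ll(name, alpha, n):
        c = cache[name]
        t1 = clip_theta(1 - (1 - c["v1"]) ** (alpha + 1))
        t2 = clip_theta(1 - (1 - c["v2"]) ** (alpha + 1))
        z = (t1 - t2) / np.sqrt((t1 * (1 - t1) + t2 * (1 - t2)) / n)
        p = np.clip(ndtr(z), PROB_FLOOR, 1 - PROB_FLOOR)
        return float(np.log(np.where(c["y"] == 1, p, 1 - p)).sum())

    kept = draws // thinning
    a_store = {"early": np.zeros((chains, kept)),
               "late": np.zeros((chains, kept))}
    seeds = np.random.SeedSequence(seed).spawn(chains)
    for c_i in range(chains):
        rng = np.random.default_rng(seeds[c_i])
        a_e = rng.uniform(1.0, 4.0)
        a_l = rng.uniform(1.0, 4.0)
        n = rng.uniform(15.0, 40.0)
        ll_e = block_ll("early", a_e, n)
        ll_l = block_ll("late", a_l, n)
        k_idx = 0
        for it in range(burn_in + draws):
            ca = a_e + rng.normal(0.0, 0.25)
            if 0.01 <= ca <= 20.0:
                ll = block_ll("early", ca, n)
                if np.log(rng.uniform()) < ll - ll_e:
                    a_e, ll_e = ca, ll
            ca = a_l + rng.normal(0.0, 0.25)
            if 0.01 <= ca <= 20.0:
                ll = block_ll("late", ca, n)
                if np.log(rng.uniform()) < ll - ll_l:
                    a_l, ll_l = ca, ll
            cn = n + rng.normal(0.0, 2.0)
            if cn >= 1.0:
                le = block_ll("early", a_e, cn)
                ll = block_ll("late", a_l, cn)
                if np.log(rng.uniform()) < (le + ll) - (ll_e + ll_l):
                    n, ll_e, ll_l = cn, le, ll
            if it >= burn_in and (it - burn_in) % thinning == 0 and k_idx < kept:
                a_store["early"][c_i, k_idx] = a_e
                a_store["late"][c_i, k_idx] = a_l
                k_idx += 1
    for name in ("early", "late"):
        out[f"alpha_{name}"] = a_store[name]
        out[f"alpha_{name}_mean"] = float(a_store[name].mean())
        out[f"rhat_alpha_{name}"] = gelman_rubin(a_store[name])
    early = a_store["early"].ravel()
    late = a_store["late"].ravel()
    out["p_late_ge_early"] = float(np.mean(late >= early))
    return out
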