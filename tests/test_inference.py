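"""Latent-mixture MCMC, diagnostics, calibration and adaptation analyses."""

import numpy as np
import pandas as pd
import pytest

from binsamp import (
    EXPERIMENTS,
    ChoiceDataset,
    DecisionParams,
    LatentMixtureSpec,
    PriorSpec,
    attribute_models,
    build_model,
    calibrate_alpha0,
    compute_loo_waic,
    fit_adaptation,
    fit_early_late,
    fit_rule_ml,
    gelman_rubin,
    generate_trial_set,
    run_mcmc,
    select_rule_ml,
    simulate_choices,
)
from conftest import adapting_dataset


class TestGelmanRubin:
    def test_well_mixed_chains(self):
        rng = np.random.default_rng(0)
        chains = rng.normal(size=(4, 1000))
        assert gelman_rubin(chains) < 1.01

    def test_gross_nonconvergence(self):
        rng = np.random.default_rng(0)
        chains = np.stack([rng.normal(0, 1, 500), rng.normal(10, 1, 500)])
        assert gelman_rubin(chains) > 1.05

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            gelman_rubin(np.zeros((1, 100)))

    def test_zero_variance_sentinel(self):
        assert np.isnan(gelman_rubin(np.ones((3, 100))))
        frozen = np.vstack([np.zeros((2, 100)), np.ones((1, 100))])
        assert np.isinf(gelman_rubin(frozen))


class TestModelDensity:
    def test_log_joint_matches_hand_computation(self, prior2):
        # 3-trial toy dataset, single subject, hand-assembled density
        df = pd.DataFrame({
            "subject": 0, "day": 1, "run": 1, "trial": [1, 2, 3],
            "condition": "perceptual",
            "dots_left": [10, 30, 20], "dots_right": [20, 12, 25],
            "choice": [1, 1, 0], "correct": [0, 1, 1],
        })
        ds = ChoiceDataset(df=df)
        model = build_model([ds], LatentMixtureSpec(), prior2)
        state = {"pi": np.array([0.2, 0.3, 0.5]), "m": [2], "n": [25.0],
                 "mu_n": 30.0, "sigma_n": 10.0}
        got = model.log_joint(state)

        from binsamp import loglik_dataset, theta_dbs
        _, ll = loglik_dataset(ds, "dbs", DecisionParams(n=25.0), prior2)
        expected = (np.log(0.5)                      # pi[2]
                    - 0.5 * ((25.0 - 30.0) / 10.0) ** 2
                    - 0.5 * np.log(2 * np.pi) - np.log(10.0)
                    + ll)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_out_of_support_states_rejected(self, dbs_dataset, prior2):
        model = build_model([dbs_dataset], LatentMixtureSpec(), prior2)
        base = {"pi": np.array([1 / 3] * 3), "m": [0], "n": [25.0],
                "mu_n": 30.0, "sigma_n": 10.0}
        assert np.isfinite(model.log_joint(base))
        assert model.log_joint(base | {"n": [0.5]}) == -np.inf
        assert model.log_joint(base | {"mu_n": 5000.0}) == -np.inf
        assert model.log_joint(base | {"pi": np.array([0.5, 0.5, 0.2])}) == -np.inf

    def test_structural_flags(self, dbs_dataset, prior2):
        spec = LatentMixtureSpec(alpha_mode="free")
        model = build_model([dbs_dataset], spec, prior2)
        post = run_mcmc(model, chains=2, burn_in=30, draws=30, thinning=2,
                        seed=0, pointwise=False)
        assert "mu_alpha" in post.draws and "alpha_s" in post.draws
        spec2 = LatentMixtureSpec(include_history=True)
        model2 = build_model([dbs_dataset], spec2, prior2)
        post2 = run_mcmc(model2, chains=2, burn_in=30, draws=30, thinning=2,
                         seed=0, pointwise=False)
        assert "betaL" in post2.draws and "betaCh" in post2.draws
        # fixed-alpha mode carries no alpha latents
        model3 = build_model([dbs_dataset], LatentMixtureSpec(), prior2)
        post3 = run_mcmc(model3, chains=2, burn_in=30, draws=30, thinning=2,
                         seed=0, pointwise=False)
        assert "mu_alpha" not in post3.draws

    def test_duplicate_subjects_rejected(self, dbs_dataset, prior2):
        with pytest.raises(ValueError):
            build_model([dbs_dataset, dbs_dataset], LatentMixtureSpec(), prior2)


class TestSampler:
    def test_deterministic_under_seed(self, dbs_dataset, prior2):
        model = build_model([dbs_dataset], LatentMixtureSpec(), prior2)
        a = run_mcmc(model, chains=2, burn_in=50, draws=50, thinning=2,
                     seed=3, pointwise=False)
        b = run_mcmc(model, chains=2, burn_in=50, draws=50, thinning=2,
                     seed=3, pointwise=False)
        for k in a.draws:
            assert np.array_equal(a.draws[k], b.draws[k])

    def test_bookkeeping_matches_config(self, dbs_dataset, prior2):
        model = build_model([dbs_dataset], LatentMixtureSpec(), prior2)
        post = run_mcmc(model, chains=3, burn_in=40, draws=60, thinning=3,
                        seed=1, pointwise=False)
        assert post.draws["n"].shape == (3, 20, 1)
        assert post.config["kept_per_chain"] == 20

    def test_flat_likelihood_returns_prior_mixture(self, dbs_dataset, prior2):
        # with the likelihood forced flat the Dirichlet-categorical block
        # must return its prior: each pi component marginally Beta(1, 2)
        from scipy.stats import kstest

        model = build_model([dbs_dataset], LatentMixtureSpec(), prior2)
        model.subject_loglik = lambda *a, **k: 0.0
        post = run_mcmc(model, chains=3, burn_in=200, draws=1000, thinning=2,
                        seed=4, pointwise=False)
        pi = post.flat("pi")
        for j in range(3):
            stat = kstest(pi[:, j], lambda x: 1 - (1 - x) ** 2)
            assert stat.pvalue > 0.01
        attr = attribute_models(post)
        probs = attr.loc[0, ["accuracy", "reward", "dbs"]].to_numpy(float)
        assert probs.sum() == pytest.approx(1.0)
        assert np.all(probs > 0.2)  # indicator stays near uniform

    def test_recovers_n_and_rule_single_subject(self, dbs_dataset, prior2):
        model = build_model([dbs_dataset], LatentMixtureSpec(), prior2)
        post = run_mcmc(model, chains=3, burn_in=500, draws=500, thinning=2,
                        seed=5)
        n_mean = post.flat("n").mean()
        assert abs(n_mean - 25.0) / 25.0 < 0.20
        attr = attribute_models(post)
        assert attr.loc[0, "dbs"] > 0.5
        pi = attr.attrs["population_pi"]
        assert sum(pi.values()) == pytest.approx(1.0)

    def test_attribution_improves_with_trials(self, prior2):
        # 300-trial datasets attribute the true rule no better than
        # 1200-trial datasets (monotone information growth)
        rng = np.random.default_rng(23)
        means = {}
        for n_trials in (300, 1200):
            vals = []
            for rep in range(2):
                trials = generate_trial_set(EXPERIMENTS["exp1"], rng)
                trials = trials.iloc[:n_trials].reset_index(drop=True)
                ds = simulate_choices(trials, "accuracy",
                                      DecisionParams(n=25), prior2, rng)
                model = build_model([ds], LatentMixtureSpec(), prior2)
                post = run_mcmc(model, chains=2, burn_in=300, draws=300,
                                thinning=2, seed=100 + rep, pointwise=False)
                vals.append(attribute_models(post).loc[0, "accuracy"])
            means[n_trials] = np.mean(vals)
        assert means[1200] >= means[300] - 0.05


class TestModelComparison:
    def test_identical_matrices_tie(self):
        rng = np.random.default_rng(1)
        ll = rng.normal(-0.6, 0.05, size=(300, 150))
        a = compute_loo_waic(ll, n_chains=3)
        b = compute_loo_waic(ll.copy(), n_chains=3)
        assert a["loo"] == pytest.approx(b["loo"])
        assert a["waic"] == pytest.approx(b["waic"])

    def test_dominant_model_wins(self):
        rng = np.random.default_rng(2)
        ll = rng.normal(-0.7, 0.05, size=(300, 150))
        better = compute_loo_waic(ll + 0.1, n_chains=3)
        worse = compute_loo_waic(ll, n_chains=3)
        assert better["loo"] > worse["loo"]
        assert better["waic"] > worse["waic"]

    def test_loo_prefers_generating_family(self, dbs_dataset, prior2):
        # DbS data: DbS pointwise likelihoods beat the log model's
        model = build_model([dbs_dataset], LatentMixtureSpec(models=("dbs",)),
                            prior2)
        post = run_mcmc(model, chains=3, burn_in=300, draws=300, thinning=2,
                        seed=6)
        loo_dbs = compute_loo_waic(post.pointwise_ll, n_chains=3)
        model_log = build_model([dbs_dataset],
                                LatentMixtureSpec(models=("log",)), prior2)
        post_log = run_mcmc(model_log, chains=3, burn_in=300, draws=300,
                            thinning=2, seed=6)
        loo_log = compute_loo_waic(post_log.pointwise_ll, n_chains=3)
        assert loo_dbs["loo"] > loo_log["loo"]

    def test_rejects_short_or_nonfinite_matrices(self):
        with pytest.raises(ValueError):
            compute_loo_waic(np.zeros((50, 10)))
        bad = np.zeros((200, 10))
        bad[0, 0] = np.inf
        with pytest.raises(ValueError):
            compute_loo_waic(bad)


class TestMLRecovery:
    def test_ml_fit_recovers_sensitivity(self, dbs_dataset, prior2):
        fit = fit_rule_ml(dbs_dataset, "dbs", prior2)
        assert abs(fit["n"] - 25.0) / 25.0 < 0.25

    def test_selects_generating_rule(self, rule_datasets, prior2):
        for true_rule, ds in rule_datasets.items():
            assert select_rule_ml(ds, prior2)["selected"] == true_rule


@pytest.fixture(scope="module")
def trial_sets():
    rng = np.random.default_rng(31)
    return [generate_trial_set(EXPERIMENTS[e], rng)
            for e in ("exp1", "exp2", "exp3")]


class TestCalibration:
    def test_minimizer_near_expected_value(self, trial_sets):
        alpha0 = calibrate_alpha0(trial_sets)
        assert alpha0 == pytest.approx(2.58, abs=0.1)

    def test_local_minimality(self, trial_sets):
        from binsamp.inference import _dbs_discriminability_term

        alpha0 = calibrate_alpha0(trial_sets)
        v1 = np.concatenate([t["v_left"].to_numpy() for t in trial_sets])
        v2 = np.concatenate([t["v_right"].to_numpy() for t in trial_sets])
        dlog = np.concatenate([
            np.log(t["dots_left"].to_numpy()) - np.log(t["dots_right"].to_numpy())
            for t in trial_sets])

        def obj(a):
            return np.sum((_dbs_discriminability_term(v1, v2, a) - dlog) ** 2)

        assert obj(alpha0) <= obj(alpha0 - 0.25)
        assert obj(alpha0) <= obj(alpha0 + 0.25)

    def test_stable_across_regeneration(self):
        vals = []
        for seed in (41, 42, 43):
            rng = np.random.default_rng(seed)
            sets = [generate_trial_set(EXPERIMENTS[e], rng)
                    for e in ("exp1", "exp2", "exp3")]
            vals.append(calibrate_alpha0(sets))
        assert max(vals) - min(vals) < 0.2

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            calibrate_alpha0([])


class TestAdaptation:
    def test_recovers_group_difference_and_delta(self):
        rng = np.random.default_rng(11)
        alpha0 = 2.58
        g12 = [adapting_dataset(EXPERIMENTS["exp1"], 2.0, alpha0, 100, 25, rng)]
        g3 = [adapting_dataset(EXPERIMENTS["exp3"], 1.0, alpha0, 100, 25, rng)]
        out = fit_adaptation({"exp12": g12, "exp3": g3}, alpha0=alpha0,
                             chains=3, burn_in=800, draws=800, seed=2)
        # directional claim: higher asymptote for the alpha=2 experiments
        assert out["p_delta1_gt_delta2"] > 0.95
        flat = out["delta_draws"].reshape(-1, 2)
        lo, hi = np.percentile(flat[:, 0], [2.5, 97.5])
        assert lo <= 2.0 <= hi
        lo3, hi3 = np.percentile(flat[:, 1], [2.5, 97.5])
        assert lo3 <= 1.0 <= hi3

    def test_non_adapting_data_keeps_eta_small(self, prior2):
        # constant-alpha data: the fitted trajectory stays near its target,
        # i.e. delta close to the generating alpha and no credible group gap
        rng = np.random.default_rng(12)
        trials = generate_trial_set(EXPERIMENTS["exp1"], rng)
        ds = simulate_choices(trials, "dbs", DecisionParams(n=25), prior2, rng)
        out = fit_adaptation({"only": [ds]}, alpha0=2.0, prior=prior2,
                             chains=3, burn_in=600, draws=600, seed=3)
        flat = out["delta_draws"].reshape(-1)
        lo, hi = np.percentile(flat, [2.5, 97.5])
        assert lo <= 2.0 <= hi

    def test_alpha_trajectory_helper(self):
        from binsamp import AdaptationParams

        ap = AdaptationParams(delta=2.0, eta=0.58, tau_adapt=100.0)
        t = np.array([0.0, 100.0, 1e9])
        traj = ap.alpha_at(t)
        assert traj[0] == pytest.approx(2.58)
        assert traj[1] == pytest.approx(2.0 + 0.58 / np.e)
        assert traj[2] == pytest.approx(2.0)
        with pytest.raises(ValueError):
            AdaptationParams(delta=1.0, eta=0.5, tau_adapt=-1.0)


class TestEarlyLate:
    def test_adapting_sessions_show_decline(self, prior2):
        rng = np.random.default_rng(4)
        ds = adapting_dataset(EXPERIMENTS["exp2"], 1.0, 2.58, 150, 25, rng)
        out = fit_early_late(ds, prior2, chains=3, burn_in=800, draws=800,
                             seed=0)
        assert out["alpha_late_mean"] < out["alpha_early_mean"]
        assert out["p_late_ge_early"] < 0.05

    def test_non_adapting_sessions_overlap(self, prior2):
        rng = np.random.default_rng(5)
        trials = generate_trial_set(EXPERIMENTS["exp2"], rng)
        ds = simulate_choices(trials, "dbs", DecisionParams(n=25), prior2, rng)
        out = fit_early_late(ds, prior2, chains=3, burn_in=800, draws=800,
                             seed=1)
        assert out["p_late_ge_early"] > 0.05

    def test_block_sizes(self, prior2):
        rng = np.random.default_rng(6)
        trials = generate_trial_set(EXPERIMENTS["exp2"], rng)
        ds = simulate_choices(trials, "dbs", DecisionParams(n=25), prior2, rng)
        out = fit_early_late(ds, prior2, chains=2, burn_in=50, draws=50, seed=0)
        assert out["n_early_trials"] == 150 * 4
        assert out["n_late_trials"] == 350 * 4
        assert out["skipped_days"] == []

    def test_short_sessions_skipped(self, prior2):
        rng = np.random.default_rng(7)
        spec = EXPERIMENTS["exp1"]
        trials = generate_trial_set(spec, rng)
        day3 = trials[trials["day"] == 3]
        day4 = trials[trials["day"] == 4].iloc[:100]  # < first_k + last_k
        short = pd.concat([day3, day4]).reset_index(drop=True)
        ds = simulate_choices(short, "dbs", DecisionParams(n=25), prior2, rng)
        out = fit_early_late(ds, prior2, first_k=150, last_k=350,
                             chains=2, burn_in=50, draws=50, seed=0)
        assert 4 in out["skipped_days"]
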