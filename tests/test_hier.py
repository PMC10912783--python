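import numpy as np
import pytest
from scipy.special import expit

from sborg.task import TaskConfig
from sborg.cohort import simulate_cohort
from sborg.presets import group_preset
from sborg.hier import (PriorConfig, SamplerSettings, fit_happiness_hier,
                        posterior_summary, predict_from_fit, GROUP_PARAMS)
from sborg.evaluate import fit_r2


@pytest.fixture(scope="module")
def small_fit():
    group = group_preset("ICD", "off", n_subjects=4)
    task = TaskConfig(n_trials=80, seed=21)
    sessions, _ = simulate_cohort([group], task, seed=21)
    draws, diag = fit_happiness_hier(
        sessions, settings=SamplerSettings(n_steps=800, n_burn=400, thin=4,
                                           seed=22))
    return sessions, draws, diag


def test_fit_structure_and_diagnostics(small_fit):
    sessions, draws, diag = small_fit
    assert draws.cell == "ICD-off"
    assert len(draws.subjects) == 4
    shapes = {draws.group[p].shape for p in draws.group}
    assert len(shapes) == 1  # equal retained draw counts across parameters
    gamma = draws.group_flat("gamma")
    assert np.all((gamma >= 0) & (gamma <= 1))
    assert np.all(draws.individual[:, :, 4] >= 0)
    assert np.all(draws.individual[:, :, 4] <= 1)
    assert np.all(draws.sigma_ind > 0)
    for p in GROUP_PARAMS:
        assert p in diag.rhat and p in diag.ess
        assert diag.ess[p] > 0
    assert diag.n_divergent is None
    assert 0 < diag.acceptance_fraction < 1
    text = diag.to_text()
    assert "rhat" in text and "seed" in text


def test_fit_is_deterministic_under_fixed_seed(small_fit):
    sessions, draws, _ = small_fit
    draws2, _ = fit_happiness_hier(
        sessions, settings=SamplerSettings(n_steps=800, n_burn=400, thin=4,
                                           seed=22))
    for p in draws.group:
        np.testing.assert_array_equal(draws.group[p], draws2.group[p])


def test_posterior_summary_shapes(small_fit):
    _, draws, _ = small_fit
    summary = posterior_summary(draws)
    assert list(summary["parameter"]) == list(GROUP_PARAMS)
    assert (summary["hdi_low"] <= summary["mean"]).all()
    assert (summary["mean"] <= summary["hdi_high"]).all()


def test_posterior_summary_degenerate_draws():
    from sborg.hier import PosteriorDraws
    const = np.full((4, 50), 1.3)
    draws = PosteriorDraws(
        cell="X", subjects=["a", "b"],
        group={p: const for p in GROUP_PARAMS},
        individual=np.full((10, 2, 5), 0.5), sigma_ind=np.full((10, 2), 0.4))
    summary = posterior_summary(draws)
    np.testing.assert_allclose(summary["mean"], 1.3, rtol=1e-12)
    np.testing.assert_allclose(summary["sd"], 0.0, atol=1e-12)
    assert (summary["hdi_low"] == 1.3).all()
    assert (summary["hdi_high"] == 1.3).all()


def test_predictions_track_low_noise_ratings():
    # near-noise-free agents: converged individual-level estimates should
    # reproduce the latent feelings almost perfectly (r^2 > 0.95)
    group = group_preset("non-ICD", "off", n_subjects=3,
                        rating_noise_sd=0.05)
    task = TaskConfig(n_trials=120, seed=31)
    sessions, _ = simulate_cohort([group], task, seed=31)
    draws, _ = fit_happiness_hier(
        sessions, settings=SamplerSettings(n_steps=1200, n_burn=600, thin=4,
                                           seed=32))
    pred = predict_from_fit(draws, sessions)
    assert len(pred) == sum(s.n_rated for s in sessions)
    assert fit_r2(pred["actual"], pred["predicted"]) > 0.95


def test_predict_from_fit_unknown_subject(small_fit):
    sessions, draws, _ = small_fit
    stranger = sessions[0]
    stranger = type(stranger)("nobody", stranger.group, stranger.med_state,
                              stranger.trials)
    with pytest.raises(KeyError):
        predict_from_fit(draws, [stranger])


def test_group_mean_matches_single_subject_ml_optimum():
    # two clones of one parameter set, no heterogeneity, wide priors:
    # the group-mean posterior should sit at the maximum-likelihood
    # optimum found by direct numerical optimization
    import scipy.optimize
    from scipy.special import logit
    from sborg.happiness import build_regressors, decayed_series

    group = group_preset("ICD", "off", n_subjects=2,
                        sds={k: 0.0 for k in
                             ("w0", "w1", "w2", "w3", "eta",
                              "beta0", "beta1", "beta2", "beta3")})
    task = TaskConfig(n_trials=300, seed=41)
    sessions, _ = simulate_cohort([group], task, seed=41)
    draws, _ = fit_happiness_hier(
        sessions,
        priors=PriorConfig(mu_scale=5.0, tau_scale=0.05, sigma_scale=5.0),
        settings=SamplerSettings(n_steps=1500, n_burn=800, thin=4, seed=42))

    regs = [build_regressors(s) for s in sessions]

    def neg_loglik(theta):
        w0, w1, w2, w3, eta = theta
        gamma = expit(eta)
        sse, n = 0.0, 0
        for reg in regs:
            dec = decayed_series(reg.design(), gamma)[reg.rated_idx]
            pred = w0 + dec @ np.array([w1, w2, w3])
            sse += np.sum((reg.ratings - pred) ** 2)
            n += len(reg.ratings)
        return 0.5 * n * np.log(sse / n)

    start = np.array([-0.5, 0.1, 0.1, 0.3, logit(0.2)])
    opt = scipy.optimize.minimize(neg_loglik, start, method="Nelder-Mead",
                                  options={"xatol": 1e-8, "fatol": 1e-10,
                                           "maxiter": 5000})
    ml = np.concatenate([opt.x[:4], [expit(opt.x[4])]])
    summary = posterior_summary(draws).set_index("parameter")
    for p, ml_val in zip(GROUP_PARAMS, ml):
        post_mean, post_sd = summary.loc[p, "mean"], summary.loc[p, "sd"]
        assert abs(post_mean - ml_val) < 2.5 * post_sd, (p, post_mean, ml_val)


def test_shrinkage_direction_with_tight_group_priors():
    # homogeneous cohort + tight group-sd prior: individual posterior
    # means should be pulled together relative to noisy per-subject fits
    from sborg.hier import _quick_subject_fit
    from sborg.happiness import build_regressors

    group = group_preset("ICD", "off", n_subjects=5,
                        sds={k: 0.0 for k in ("w0", "w1", "w2", "w3", "eta")})
    task = TaskConfig(n_trials=60, seed=51)
    sessions, _ = simulate_cohort([group], task, seed=51)
    draws, _ = fit_happiness_hier(
        sessions, priors=PriorConfig(tau_scale=0.02),
        settings=SamplerSettings(n_steps=800, n_burn=400, thin=4, seed=52))
    post_spread = draws.individual_means()["w1"].std(ddof=1)
    mle_spread = np.std([_quick_subject_fit(build_regressors(s))[0][1]
                         for s in sessions], ddof=1)
    assert post_spread < mle_spread


def test_prior_predictive_gamma_spans_unit_interval():
    rng = np.random.default_rng(6)
    priors = PriorConfig()
    mu = rng.normal(priors.mu_loc, priors.mu_scale, 10_000)
    tau = np.abs(rng.normal(0, priors.tau_scale, 10_000))
    gamma = expit(mu + tau * rng.standard_normal(10_000))
    assert np.all((gamma > 0) & (gamma < 1))
    assert gamma.min() < 0.1 and gamma.max() > 0.9


def test_fit_excludes_degenerate_sessions_and_needs_two_subjects():
    group = group_preset("ICD", "off", n_subjects=2)
    task = TaskConfig(n_trials=40, seed=61)
    sessions, _ = simulate_cohort([group], task, seed=61)
    # make one session's ratings constant -> excluded -> only 1 left
    bad = sessions[0].trials
    bad.loc[bad["rating"].notna(), "rating"] = 0.5
    with pytest.warns(UserWarning, match="constant ratings"):
        with pytest.raises(ValueError, match="at least 2"):
            fit_happiness_hier(sessions, standardize=True,
                               settings=SamplerSettings.smoke())
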