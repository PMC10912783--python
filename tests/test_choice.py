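import numpy as np
import pandas as pd
import pytest
import scipy.stats
from scipy.special import expit

from sborg.choice import (ChoiceParams, build_choice_table,
                          fit_logistic_choice, group_coefficient_test,
                          summarize_cell_choices, fit_cell_choices)
from tests.conftest import make_session


def rated(v):
    return v


def session_with_prompts(prompt_trials, n=10):
    """Conflict trials throughout; ratings on the listed 1-based trials."""
    rows = []
    for i in range(1, n + 1):
        rating = 0.3 if i in prompt_trials else None
        rows.append((3, 1, 6, "gamble" if i % 2 else "certain",
                     6 if i % 2 else 3, rating))
    return make_session(rows)


def test_choice_table_every_trial_rated():
    rows = [(3, 1, 6, "gamble", 6, 0.1 * i) for i in range(1, 9)]
    session = make_session(rows)
    table = build_choice_table(session, "rated_only")
    # rows for responded trials 2..T; trial 1 never included
    assert list(table["trial_index"]) == list(range(2, 9))
    np.testing.assert_allclose(table["prev_rating"],
                               [0.1 * i for i in range(1, 8)])
    assert (table["ev_gamble"] == 3.5).all()
    assert (table["ev_certain"] == 3.0).all()


def test_choice_table_no_prompts_is_empty_with_warning():
    session = session_with_prompts(set())
    with pytest.warns(UserWarning, match="no usable choice rows"):
        table = build_choice_table(session, "rated_only")
    assert table.empty


def test_choice_table_rated_only_enumeration():
    # prompts on trials 2 and 5 -> rows exactly for trials 3 and 6
    session = session_with_prompts({2, 5})
    table = build_choice_table(session, "rated_only")
    assert list(table["trial_index"]) == [3, 6]


def test_choice_table_locf_carries_forward():
    session = session_with_prompts({2, 5})
    table = build_choice_table(session, "locf")
    assert list(table["trial_index"]) == [3, 4, 5, 6, 7, 8, 9, 10]
    assert (table["prev_rating"] == 0.3).all()


def test_choice_table_timeout_trials_excluded():
    rows = [(3, 1, 6, "gamble", 6, 0.2),
            (3, 1, 6, "timeout", None, None),
            (3, 1, 6, "certain", 3, 0.1),
            (4, 2, 5, "gamble", 2, None)]
    table = build_choice_table(make_session(rows), "locf")
    assert 2 not in set(table["trial_index"])
    assert list(table["trial_index"]) == [3, 4]


def simulate_rows(beta, n, seed):
    rng = np.random.default_rng(seed)
    ev_g = rng.integers(0, 13, size=n) / 2.0
    ev_c = rng.integers(1, 7, size=n).astype(float)
    prev = rng.normal(0, 1, size=n)
    logits = beta[0] + beta[1] * ev_g + beta[2] * ev_c + beta[3] * prev
    y = (rng.random(n) < expit(logits)).astype(int)
    return pd.DataFrame({"gamble_chosen": y, "ev_gamble": ev_g,
                         "ev_certain": ev_c, "prev_rating": prev})


def test_logistic_fit_recovers_known_coefficients():
    beta = np.array([0.0, 1.9, -1.8, 0.3])
    rows = simulate_rows(beta, 5000, seed=0)
    params = fit_logistic_choice(rows)
    assert not params.separation
    # asymptotic check: within 3 standard errors from a refit's covariance
    import statsmodels.api as sm
    X = sm.add_constant(rows[["ev_gamble", "ev_certain",
                              "prev_rating"]].to_numpy())
    res = sm.Logit(rows["gamble_chosen"].to_numpy(), X).fit(disp=0)
    se = np.sqrt(np.diag(res.cov_params()))
    np.testing.assert_array_less(np.abs(params.as_array() - beta), 3 * se)


def test_logistic_fit_flags_separation():
    n = 60
    ev_g = np.concatenate([np.full(30, 6.0), np.full(30, 0.5)])
    rows = pd.DataFrame({
        "gamble_chosen": (ev_g > 3).astype(int),
        "ev_gamble": ev_g,
        "ev_certain": np.full(n, 3.0),
        "prev_rating": np.zeros(n),
    })
    params = fit_logistic_choice(rows)
    assert params.separation


def test_logistic_fit_requires_both_classes():
    rows = simulate_rows(np.array([10.0, 0, 0, 0]), 50, seed=1)
    rows["gamble_chosen"] = 1
    with pytest.raises(ValueError, match="single-class"):
        fit_logistic_choice(rows)
    with pytest.raises(ValueError, match="choice rows"):
        fit_logistic_choice(rows.head(3))


def test_beta3_null_rejection_rate():
    # with a true zero prev-rating weight, per-subject significance of
    # beta3 should appear at roughly the nominal 5% rate
    beta = np.array([0.0, 1.5, -1.4, 0.0])
    import statsmodels.api as sm
    rejections = 0
    reps = 60
    for r in range(reps):
        rows = simulate_rows(beta, 400, seed=100 + r)
        X = sm.add_constant(rows[["ev_gamble", "ev_certain",
                                  "prev_rating"]].to_numpy())
        res = sm.Logit(rows["gamble_chosen"].to_numpy(), X).fit(disp=0)
        if res.pvalues[3] < 0.05:
            rejections += 1
    # binomial 99.9% envelope around 5% of 60
    assert rejections <= 11


def test_group_coefficient_test_matches_textbook_formula():
    rng = np.random.default_rng(3)
    values = rng.normal(2.3, 0.6, size=12)
    res = group_coefficient_test(values)
    n = len(values)
    mean, sd = values.mean(), values.std(ddof=1)
    t_oracle = mean / (sd / np.sqrt(n))
    p_oracle = 2 * scipy.stats.t.sf(abs(t_oracle), df=n - 1)
    tcrit = scipy.stats.t.ppf(0.975, df=n - 1)
    assert res.t_stat == pytest.approx(t_oracle, abs=1e-10)
    assert res.p_value == pytest.approx(p_oracle, abs=1e-10)
    assert res.ci_low == pytest.approx(mean - tcrit * sd / np.sqrt(n),
                                       abs=1e-10)
    assert res.ci_high == pytest.approx(mean + tcrit * sd / np.sqrt(n),
                                        abs=1e-10)
    # cross-check the t statistic against scipy's one-sample test
    scipy_res = scipy.stats.ttest_1samp(values, 0.0)
    assert res.t_stat == pytest.approx(scipy_res.statistic, abs=1e-10)
    assert res.p_value == pytest.approx(scipy_res.pvalue, abs=1e-10)


def test_group_coefficient_test_degenerate_and_symmetric():
    res = group_coefficient_test([1.7] * 5)
    assert res.degenerate and np.isnan(res.t_stat)
    assert res.estimate == pytest.approx(1.7)
    sym = group_coefficient_test([-2.0, -1.0, 1.0, 2.0])
    assert sym.p_value == pytest.approx(1.0)
    with pytest.raises(ValueError):
        group_coefficient_test([1.0])


def test_summarize_cell_choices_shapes(small_session):
    per_subject = pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(5)],
        "separation": [False] * 4 + [True],
        "beta0": np.r_[0.1, -0.1, 0.2, 0.0, 9.0],
        "beta1": np.r_[2.0, 2.2, 1.9, 2.1, 25.0],
        "beta2": np.r_[-2.0, -1.8, -2.1, -1.9, -25.0],
        "beta3": np.r_[0.0, 0.1, -0.1, 0.05, 3.0],
    })
    summary = summarize_cell_choices(per_subject)
    assert list(summary["coefficient"]) == ["beta0", "beta1", "beta2", "beta3"]
    assert (summary["n_subjects"] == 4).all()  # separated fit dropped
    b1 = summary.set_index("coefficient").loc["beta1"]
    assert b1["ci_low"] < b1["estimate"] < b1["ci_high"]
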