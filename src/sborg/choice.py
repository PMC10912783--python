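"""Trial-level logistic gamble-choice model.

The decision to gamble on trial t is modeled through its log-odds:

    logit P(gamble_t) = b0 + b1 * EV_G(t) + b2 * EV_CR(t) + b3 * SR_H(t-1)

with EV_G the gamble's expected value (dollars), EV_CR the certain reward
(dollars), and SR_H(t-1) the subjective feeling rating associated with the
previous trial (z-units).  Models are fit separately per participant and
coefficients compared at the group level with one-sample t-tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from sborg.task import gamble_ev
from sborg.records import SessionRecord

SEPARATION_GUARD = 20.0  # |beta| beyond this flags (quasi-)separation

COEF_NAMES = ("beta0", "beta1", "beta2", "beta3")
COEF_LABELS = {
    "beta0": "Baseline",
    "beta1": "Gamble EV",
    "beta2": "Certain Reward EV",
    "beta3": "Subjective Feeling on (t-1)",
}


@dataclass
class ChoiceParams:
    """Fitted (or generative) coefficients of the gamble-choice model."""

    beta0: float
    beta1: float
    beta2: float
    beta3: float = 0.0
    separation: bool = False
    converged: bool = True

    def __post_init__(self) -> None:
        betas = (self.beta0, self.beta1, self.beta2, self.beta3)
        if not all(np.isfinite(betas)):
            raise ValueError("coefficients must be finite")
        if any(abs(b) > SEPARATION_GUARD for b in betas):
            self.separation = True

    def as_array(self) -> np.ndarray:
        return np.array([self.beta0, self.beta1, self.beta2, self.beta3])

    def gamble_logit(self, ev_gamble: float, ev_certain: float,
                     prev_rating: float) -> float:
        return (self.beta0 + self.beta1 * ev_gamble
                + self.beta2 * ev_certain + self.beta3 * prev_rating)


def build_choice_table(session: SessionRecord,
                       prev_rating_mode: str = "rated_only") -> pd.DataFrame:
    """Assemble per-trial rows for the choice model from one session.

    ``rated_only`` keeps responded trials whose immediately preceding trial
    carries an emitted rating (the previous feeling is directly observed);
    ``locf`` keeps all responded trials after the first rating, carrying
    the most recent rating forward.  Trial 1 is never included.  Returns a
    frame with columns gamble_chosen, ev_gamble, ev_certain, prev_rating.
    """
    if prev_rating_mode not in ("rated_only", "locf"):
        raise ValueError("prev_rating_mode must be 'rated_only' or 'locf'")
    t = session.trials
    rows = []
    last_rating = np.nan
    prev_trial_rating = np.nan
    for i, row in enumerate(t.itertuples(index=False)):
        if i > 0 and row.choice != "timeout":
            if prev_rating_mode == "rated_only":
                prev = prev_trial_rating
            else:
                prev = last_rating
            if not np.isnan(prev):
                rows.append({
                    "trial_index": row.trial_index,
                    "gamble_chosen": int(row.choice == "gamble"),
                    "ev_gamble": gamble_ev(row.gamble_low, row.gamble_high),
                    "ev_certain": float(row.certain_value),
                    "prev_rating": float(prev),
                })
        prev_trial_rating = row.rating if not pd.isna(row.rating) else np.nan
        if not pd.isna(row.rating):
            last_rating = row.rating
    if not rows:
        warnings.warn(
            f"no usable choice rows for {session.subject_id}/{session.cell}",
            stacklevel=2)
        return pd.DataFrame(columns=[
            "trial_index", "gamble_chosen", "ev_gamble", "ev_certain",
            "prev_rating"])
    return pd.DataFrame(rows)


def fit_logistic_choice(rows: pd.DataFrame, min_rows: int = 10) -> ChoiceParams:
    """Per-participant maximum-likelihood logistic fit (Newton/IRLS).

    Requires at least ``min_rows`` rows with both outcome classes present.
    Estimates with any |beta| > 20 are flagged as separated; outright
    perfect separation is flagged with the guard value as placeholder.
    """
    if len(rows) < min_rows:
        raise ValueError(f"need >= {min_rows} choice rows, got {len(rows)}")
    y = rows["gamble_chosen"].to_numpy(dtype=float)
    if y.min() == y.max():
        raise ValueError("single-class outcomes: logistic model not identified")
    X = sm.add_constant(
        rows[["ev_gamble", "ev_certain", "prev_rating"]].to_numpy(dtype=float),
        has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(method="newton", maxiter=200, tol=1e-8,
                                     disp=0)
        b = np.clip(res.params, -SEPARATION_GUARD - 1, SEPARATION_GUARD + 1)
        params = ChoiceParams(*b)
        params.converged = bool(res.mle_retvals.get("converged", True))
    except (PerfectSeparationError, np.linalg.LinAlgError):
        params = ChoiceParams(0.0, SEPARATION_GUARD + 1, 0.0, 0.0)
        params.converged = False
    if not params.converged:
        params.separation = True
    return params


@dataclass
class GroupCoefficientTest:
    """Group-level summary of one coefficient across subjects."""

    estimate: float
    ci_low: float
    ci_high: float
    t_stat: float
    p_value: float
    n: int
    degenerate: bool = False  # zero between-subject variance


def group_coefficient_test(values, alpha: float = 0.05) -> GroupCoefficientTest:
    """Mean, t-based 95% CI, and one-sample t-test against 0.

    The group estimate is the mean of per-subject coefficients; the CI and
    test use the t distribution with n-1 degrees of freedom.  Zero
    between-subject variance is flagged rather than reported as infinite t.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise ValueError("group test needs at least 2 subjects")
    n = len(x)
    mean = x.mean()
    sd = x.std(ddof=1)
    if sd == 0.0:
        return GroupCoefficientTest(mean, mean, mean, np.nan, np.nan, n,
                                    degenerate=True)
    se = sd / np.sqrt(n)
    tcrit = scipy.stats.t.ppf(1 - alpha / 2, df=n - 1)
    t_stat = mean / se
    p = 2 * scipy.stats.t.sf(abs(t_stat), df=n - 1)
    return GroupCoefficientTest(mean, mean - tcrit * se, mean + tcrit * se,
                                t_stat, p, n)


def fit_cell_choices(sessions: list[SessionRecord],
                     prev_rating_mode: str = "rated_only",
                     min_rows: int = 10) -> pd.DataFrame:
    """Per-subject choice fits for one condition cell (tidy table)."""
    out = []
    for s in sessions:
        rows = build_choice_table(s, prev_rating_mode)
        try:
            params = fit_logistic_choice(rows, min_rows=min_rows)
        except ValueError as err:
            warnings.warn(f"{s.subject_id}/{s.cell}: {err}", stacklevel=2)
            continue
        rec = {"subject_id": s.subject_id, "group": s.group,
               "med_state": s.med_state, "n_rows": len(rows),
               "separation": params.separation}
        rec.update(dict(zip(COEF_NAMES, params.as_array())))
        out.append(rec)
    return pd.DataFrame(out)


def summarize_cell_choices(per_subject: pd.DataFrame,
                           drop_separated: bool = True) -> pd.DataFrame:
    """Group-level coefficient table (estimate, CI, t, p) for one cell."""
    tab = per_subject
    if drop_separated and len(tab):
        clean = tab[~tab["separation"]]
        if len(clean) >= 2:
            tab = clean
        else:
            warnings.warn("fewer than 2 non-separated fits; keeping all",
                          stacklevel=2)
    if len(tab) < 2:
        return pd.DataFrame(columns=[
            "coefficient", "label", "estimate", "ci_low", "ci_high",
            "t_stat", "p_value", "n_subjects"])
    rows = []
    for name in COEF_NAMES:
        res = group_coefficient_test(tab[name].to_numpy())
        rows.append({
            "coefficient": name, "label": COEF_LABELS[name],
            "estimate": res.estimate, "ci_low": res.ci_low,
            "ci_high": res.ci_high, "t_stat": res.t_stat,
            "p_value": res.p_value, "n_subjects": res.n,
        })
    return pd.DataFrame(rows)
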