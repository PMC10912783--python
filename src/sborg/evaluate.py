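"""Descriptive behavior statistics and model-fit evaluation.

Gamble rates per session with nonparametric group comparisons, and the
squared correlation between actual and model-predicted ratings used to
judge happiness-model fit quality.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats

from sborg.records import SessionRecord


def gamble_rate(session: SessionRecord) -> float:
    """Percent of responded (non-timeout) trials on which the gamble was chosen."""
    resp = session.responded
    if len(resp) == 0:
        raise ValueError(
            f"{session.subject_id}/{session.cell}: no responded trials")
    return 100.0 * (resp["choice"] == "gamble").mean()


def compare_gamble_rates(rates_a, rates_b, paired: bool = False) -> float:
    """Two-sided nonparametric comparison of per-session gamble rates.

    Unpaired contrasts (between groups) use the Wilcoxon rank-sum
    (Mann-Whitney) test, exact when sample sizes allow; paired contrasts
    (on vs off within group, matched by subject) use the Wilcoxon
    signed-rank test.  All-zero paired differences return p = 1 (no
    evidence of any shift).
    """
    a = np.asarray(rates_a, dtype=float)
    b = np.asarray(rates_b, dtype=float)
    if paired:
        if len(a) != len(b):
            raise ValueError("paired comparison needs equal-length vectors")
        if len(a) < 2:
            raise ValueError("need at least 2 pairs")
        diffs = a - b
        if np.all(diffs == 0):
            return 1.0
        return float(scipy.stats.wilcoxon(a, b, alternative="two-sided").pvalue)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 sessions per group")
    return float(scipy.stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)


def fit_r2(actual, predicted) -> float:
    """Squared Pearson correlation between actual and predicted ratings.

    Sign-free by construction: a perfectly anticorrelated prediction also
    scores 1.  Requires at least 3 pairs with variance on both sides.
    """
    x = np.asarray(actual, dtype=float)
    y = np.asarray(predicted, dtype=float)
    if len(x) != len(y):
        raise ValueError("actual and predicted must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 rating pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance: r^2 undefined")
    r, _ = scipy.stats.pearsonr(x, y)
    return float(r ** 2)


def gamble_rate_table(sessions: list[SessionRecord]) -> pd.DataFrame:
    """Per-session gamble rates, tidy (subject, group, med_state, rate)."""
    return pd.DataFrame([
        {"subject_id": s.subject_id, "group": s.group,
         "med_state": s.med_state, "gamble_rate": gamble_rate(s)}
        for s in sessions
    ])


def gamble_rate_tests(rates: pd.DataFrame) -> pd.DataFrame:
    """The four study contrasts of gamble rates.

    Between groups within each medication state (unpaired rank-sum) and
    between medication states within each group (paired by subject,
    signed-rank).
    """
    rows = []
    for state in ("off", "on"):
        sub = rates[rates["med_state"] == state]
        a = sub.loc[sub["group"] == "ICD", "gamble_rate"].to_numpy()
        b = sub.loc[sub["group"] == "non-ICD", "gamble_rate"].to_numpy()
        rows.append({
            "contrast": f"ICD-{state} vs non-ICD-{state}", "paired": False,
            "mean_a": a.mean(), "mean_b": b.mean(),
            "p_value": compare_gamble_rates(a, b, paired=False),
        })
    for grp in ("ICD", "non-ICD"):
        sub = rates[rates["group"] == grp].pivot(
            index="subject_id", columns="med_state", values="gamble_rate")
        sub = sub.dropna()
        rows.append({
            "contrast": f"{grp}-on vs {grp}-off", "paired": True,
            "mean_a": sub["on"].mean(), "mean_b": sub["off"].mean(),
            "p_value": compare_gamble_rates(
                sub["on"].to_numpy(), sub["off"].to_numpy(), paired=True),
        })
    return pd.DataFrame(rows)
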