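"""Momentary-happiness model with exponential forgetting.

Predicted momentary feeling on trial ``t`` (on the z-scored rating scale):

    Happiness(t) = w0 + w1 * sum_{j<=t} g^(t-j) CR_j
                      + w2 * sum_{j<=t} g^(t-j) EV_j
                      + w3 * sum_{j<=t} g^(t-j) RPE_j

where CR_j is the value of a chosen certain reward (0 on gamble trials),
EV_j the expected value of a chosen gamble (0 on certain trials), RPE_j the
reward prediction error (obtained gamble outcome minus gamble EV; 0 on
certain trials), and g in [0, 1] a forgetting factor that discounts events
further back in time.  Sums run over all preceding non-timeout trials, not
just rated ones; timeout trials carry no choice or outcome and are dropped
from the history entirely.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from sborg.task import gamble_ev
from sborg.records import SessionRecord


class DegenerateRatingsError(ValueError):
    """Raised when ratings have no variance and cannot be standardized."""


@dataclass
class HappinessParams:
    """Weights of the momentary-happiness model, on the z-rating scale.

    ``w1`` and ``w2`` are per-dollar weights on the exponentially decayed
    sums of chosen certain rewards and chosen-gamble expected values;
    ``w3`` weighs decayed reward prediction errors; ``gamma`` is the
    forgetting factor (0 = only the current trial matters).
    ``rating_noise_sd`` is the observation-noise scale of emitted ratings
    around the latent prediction.
    """

    w0: float
    w1: float
    w2: float
    w3: float
    gamma: float
    rating_noise_sd: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")
        if self.rating_noise_sd <= 0:
            raise ValueError("rating_noise_sd must be positive")

    def weights(self) -> np.ndarray:
        return np.array([self.w1, self.w2, self.w3], dtype=float)


@dataclass
class RegressorSeries:
    """Per-trial (CR, EV, RPE) regressors over one session's responded trials.

    Arrays are aligned to the compacted index j = 1..T over non-timeout
    trials.  ``rated_idx`` holds 0-based positions (into these arrays) of
    trials with an emitted rating, and ``ratings`` the corresponding values.
    """

    cr: np.ndarray
    ev: np.ndarray
    rpe: np.ndarray
    rated_idx: np.ndarray
    ratings: np.ndarray
    trial_index: np.ndarray  # original 1-based trial numbers

    def __len__(self) -> int:
        return len(self.cr)

    def design(self) -> np.ndarray:
        """(T, 3) stack of the three regressor series."""
        return np.column_stack([self.cr, self.ev, self.rpe])

    def to_frame(self) -> pd.DataFrame:
        rated = np.zeros(len(self), dtype=bool)
        rated[self.rated_idx] = True
        return pd.DataFrame({
            "trial_index": self.trial_index,
            "cr": self.cr, "ev": self.ev, "rpe": self.rpe,
            "rated": rated,
        })


def build_regressors(session: SessionRecord) -> RegressorSeries:
    """Extract (CR, EV, RPE) regressors from a session.

    Certain-choice trial -> (certain_value, 0, 0); gamble-choice trial ->
    (0, gamble EV, outcome - gamble EV).  Timeout trials are removed and
    indices compacted.
    """
    resp = session.responded
    cr = np.zeros(len(resp))
    ev = np.zeros(len(resp))
    rpe = np.zeros(len(resp))
    for k, row in enumerate(resp.itertuples(index=False)):
        if pd.isna(row.outcome):
            raise ValueError(
                f"outcome missing on responded trial {row.trial_index} of "
                f"{session.subject_id}/{session.cell}")
        if row.choice == "certain":
            cr[k] = row.certain_value
        else:
            g_ev = gamble_ev(row.gamble_low, row.gamble_high)
            ev[k] = g_ev
            rpe[k] = row.outcome - g_ev
    rated_mask = resp["rating"].notna().to_numpy()
    return RegressorSeries(
        cr=cr, ev=ev, rpe=rpe,
        rated_idx=np.flatnonzero(rated_mask),
        ratings=resp["rating"].to_numpy(dtype=float)[rated_mask],
        trial_index=resp["trial_index"].to_numpy(dtype=int),
    )


def decayed_sum(series, gamma: float, t: int) -> float:
    """Exponentially decayed sum sum_{j=1..t} gamma^(t-j) * series_j.

    ``t`` is 1-based; ``0**0`` is treated as 1 so gamma=0 returns the
    current trial's value.
    """
    x = np.asarray(series, dtype=float)
    if not 1 <= t <= len(x):
        raise IndexError(f"t={t} out of range 1..{len(x)}")
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must lie in [0, 1]")
    s = 0.0
    for j in range(t):
        s = gamma * s + x[j]
    return s


def decayed_series(x: np.ndarray, gamma: float) -> np.ndarray:
    """All decayed sums S_t = gamma*S_{t-1} + x_t for t = 1..len(x).

    ``x`` may be (T,) or (T, k); the recursion runs along the first axis.
    """
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    s = np.zeros(x.shape[1:] if x.ndim > 1 else ())
    for t in range(len(x)):
        s = gamma * s + x[t]
        out[t] = s
    return out


def predict_happiness(params: HappinessParams, regressors: RegressorSeries,
                      t: int) -> float:
    """Model-predicted feeling at compacted trial index ``t`` (1-based)."""
    return (params.w0
            + params.w1 * decayed_sum(regressors.cr, params.gamma, t)
            + params.w2 * decayed_sum(regressors.ev, params.gamma, t)
            + params.w3 * decayed_sum(regressors.rpe, params.gamma, t))


def predict_series(params: HappinessParams,
                   regressors: RegressorSeries) -> np.ndarray:
    """Predicted feeling at every compacted trial, computed by recursion."""
    dec = decayed_series(regressors.design(), params.gamma)
    return params.w0 + dec @ params.weights()


def zscore_ratings(ratings) -> np.ndarray:
    """Standardize ratings to sample mean 0, sd 1 (denominator n-1)."""
    x = np.asarray(ratings, dtype=float)
    x = x[~np.isnan(x)]
    if len(np.unique(x)) < 2:
        raise DegenerateRatingsError(
            "ratings have no variance; session cannot be standardized")
    return (x - x.mean()) / x.std(ddof=1)


def standardize_session(session: SessionRecord) -> SessionRecord:
    """Return a copy of the session with ratings z-scored in place.

    Raises :class:`DegenerateRatingsError` when all ratings are identical;
    callers fitting cohorts should catch it and exclude the session.
    """
    trials = session.trials.copy()
    mask = trials["rating"].notna()
    trials.loc[mask, "rating"] = zscore_ratings(trials.loc[mask, "rating"])
    return SessionRecord(session.subject_id, session.group, session.med_state,
                         trials, rating_scale="z")
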