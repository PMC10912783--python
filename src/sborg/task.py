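"""Sure-Bet-or-Gamble trial structure and schedule generation.

Each trial offers a certain (sure-bet) dollar reward against a gamble with
two equiprobable dollar outcomes.  A random third of trials prompt the
participant for a subjective-feeling rating, and each trial carries a
response time limit drawn from a Poisson distribution (mean 6 s).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONFLICT = "conflict"
DOMINATED_CERTAIN = "dominated_certain"
DOMINATED_GAMBLE = "dominated_gamble"
DOMINANCE_CLASSES = (CONFLICT, DOMINATED_CERTAIN, DOMINATED_GAMBLE)

#: dollar grids offered by the task
DEFAULT_CERTAIN_VALUES = tuple(range(1, 7))   # $1..$6
DEFAULT_GAMBLE_VALUES = tuple(range(0, 7))    # $0..$6

SCHEDULE_COLUMNS = [
    "trial_index", "certain_value", "gamble_low", "gamble_high",
    "rating_prompt", "time_limit", "dominance_class",
]


def gamble_ev(gamble_low: float, gamble_high: float) -> float:
    """Expected value of a 50/50 two-outcome gamble."""
    if gamble_low < 0 or gamble_high < 0:
        raise ValueError("gamble outcomes must be nonnegative")
    return 0.5 * (gamble_low + gamble_high)


def classify_trial(certain_value: float, gamble_low: float,
                   gamble_high: float) -> str:
    """Dominance class of a trial's option pair.

    ``dominated_certain``: the sure bet is at least as large as both gamble
    outcomes; ``dominated_gamble``: both gamble outcomes are at least the
    sure bet; otherwise ``conflict``.  Ties count as dominated (weak
    dominance still makes one option rationally no worse).  When all three
    values coincide the trial is labelled ``dominated_certain``.
    """
    if gamble_low > gamble_high:
        raise ValueError("gamble_low must not exceed gamble_high")
    if certain_value >= gamble_high:
        return DOMINATED_CERTAIN
    if certain_value <= gamble_low:
        return DOMINATED_GAMBLE
    return CONFLICT


def draw_time_limit(rate: float, rng: np.random.Generator | int) -> int:
    """One Poisson(rate) response time limit, in whole seconds."""
    if rate < 0:
        raise ValueError("time-limit rate must be nonnegative")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    return int(rng.poisson(rate))


@dataclass(frozen=True)
class TaskConfig:
    """Design parameters of one SBORG session schedule."""

    n_trials: int = 208
    rating_prob: float = 0.33
    certain_values: tuple[int, ...] = DEFAULT_CERTAIN_VALUES
    gamble_values: tuple[int, ...] = DEFAULT_GAMBLE_VALUES
    dominated_fraction: float = 0.2
    time_limit_rate: float = 6.0  # Poisson mean, seconds
    session_minutes: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be positive")
        if not 0.0 <= self.rating_prob <= 1.0:
            raise ValueError("rating_prob must lie in [0, 1]")
        if not 0.0 <= self.dominated_fraction <= 1.0:
            raise ValueError("dominated_fraction must lie in [0, 1]")
        if self.time_limit_rate < 0:
            raise ValueError("time_limit_rate must be nonnegative")
        if self.session_minutes <= 0:
            raise ValueError("session_minutes must be positive")
        if not self.certain_values or not self.gamble_values:
            raise ValueError("value sets must be nonempty")
        if not set(self.certain_values) <= set(range(1, 7)):
            raise ValueError("certain_values must be a subset of $1..$6")
        if not set(self.gamble_values) <= set(range(0, 7)):
            raise ValueError("gamble_values must be a subset of $0..$6")


@dataclass(frozen=True)
class TrialSpec:
    """One trial's offered options, prompt flag, time limit and class."""

    trial_index: int  # 1-based
    certain_value: int
    gamble_low: int
    gamble_high: int
    rating_prompt: bool
    time_limit: int
    dominance_class: str = field(default="")

    def __post_init__(self) -> None:
        if self.trial_index < 1:
            raise ValueError("trial_index is 1-based")
        if self.gamble_low > self.gamble_high:
            raise ValueError("gamble_low must not exceed gamble_high")
        if self.time_limit < 0:
            raise ValueError("time_limit must be nonnegative")
        expected = classify_trial(self.certain_value, self.gamble_low,
                                  self.gamble_high)
        if self.dominance_class == "":
            object.__setattr__(self, "dominance_class", expected)
        elif self.dominance_class != expected:
            raise ValueError(
                f"dominance_class {self.dominance_class!r} inconsistent with "
                f"option values (expected {expected!r})")

    @property
    def gamble_ev(self) -> float:
        return gamble_ev(self.gamble_low, self.gamble_high)


def generate_schedule(config: TaskConfig,
                      rng: np.random.Generator | None = None) -> list[TrialSpec]:
    """Generate an ordered trial schedule under ``config``.

    Dominated ("control") trials are injected with probability
    ``dominated_fraction`` (split evenly between certain- and
    gamble-dominated), conflict trials otherwise; option values are drawn
    uniformly on the configured integer dollar grids by rejection within
    the requested class.  Deterministic given ``config.seed`` (or an
    explicitly supplied generator).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    certain = np.asarray(config.certain_values)
    gamble = np.asarray(config.gamble_values)
    # rejection sampling needs each class to be attainable on the grids
    trials: list[TrialSpec] = []
    for i in range(1, config.n_trials + 1):
        want_dominated = rng.random() < config.dominated_fraction
        want_class = None
        if want_dominated:
            want_class = DOMINATED_CERTAIN if rng.random() < 0.5 else DOMINATED_GAMBLE
        for _ in range(10_000):
            cv = int(rng.choice(certain))
            g1 = int(rng.choice(gamble))
            g2 = int(rng.choice(gamble))
            gl, gh = min(g1, g2), max(g1, g2)
            cls = classify_trial(cv, gl, gh)
            if want_class is None:
                if cls == CONFLICT:
                    break
            elif cls == want_class:
                break
        else:  # pragma: no cover - unreachable on the default grids
            raise RuntimeError("could not sample a trial of the requested class")
        trials.append(TrialSpec(
            trial_index=i,
            certain_value=cv,
            gamble_low=gl,
            gamble_high=gh,
            rating_prompt=bool(rng.random() < config.rating_prob),
            time_limit=draw_time_limit(config.time_limit_rate, rng),
            dominance_class=cls,
        ))
    return trials


def schedule_to_frame(schedule: list[TrialSpec]) -> pd.DataFrame:
    """Tabular view of a schedule (one row per trial)."""
    return pd.DataFrame([dataclasses.asdict(t) for t in schedule],
                        columns=SCHEDULE_COLUMNS)


def schedule_from_frame(frame: pd.DataFrame) -> list[TrialSpec]:
    missing = set(SCHEDULE_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"schedule table missing columns: {sorted(missing)}")
    return [
        TrialSpec(
            trial_index=int(r.trial_index),
            certain_value=int(r.certain_value),
            gamble_low=int(r.gamble_low),
            gamble_high=int(r.gamble_high),
            rating_prompt=bool(r.rating_prompt),
            time_limit=int(r.time_limit),
            dominance_class=str(r.dominance_class),
        )
        for r in frame.itertuples(index=False)
    ]


def write_schedule(schedule: list[TrialSpec], path) -> None:
    schedule_to_frame(schedule).to_csv(path, index=False)


def read_schedule(path) -> list[TrialSpec]:
    return schedule_from_frame(pd.read_csv(path))
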