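"""Synthetic SBORG cohorts with hierarchical ground truth.

Agents choose by the logistic gamble-choice rule and feel by the
momentary-happiness model; subject-level parameters are drawn around
group-level means so that cohorts carry a known hierarchical structure for
parameter-recovery testing.  Emitted ratings live directly on the z-scale
(the scale the happiness model is defined on); an optional slider mode maps
them affinely onto the task's -4..+4 integer slider for I/O realism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from sborg.task import TaskConfig, TrialSpec, gamble_ev, generate_schedule
from sborg.records import SessionRecord, TRIAL_COLUMNS
from sborg.happiness import HappinessParams
from sborg.choice import ChoiceParams

#: parameter names a GroupSpec must provide means for.  ``eta`` is the
#: forgetting factor on the unconstrained (logit) scale.
PARAM_NAMES = ("w0", "w1", "w2", "w3", "eta",
               "beta0", "beta1", "beta2", "beta3",
               "rating_noise_sd", "timeout_prob")

SLIDER_SCALE = 2.0  # z-units -> slider units; +/-2 z spans the +/-4 slider


@dataclass
class AgentParams:
    """One simulated subject's generative parameters."""

    happiness: HappinessParams
    choice: ChoiceParams
    timeout_prob: float = 0.03

    def __post_init__(self) -> None:
        if not 0.0 <= self.timeout_prob <= 1.0:
            raise ValueError("timeout_prob must lie in [0, 1]")


@dataclass
class GroupSpec:
    """Group-level generative distribution for one condition cell.

    ``param_means``/``param_sds`` map each name in :data:`PARAM_NAMES` to the
    mean and sd of the subject-level normal draw.  The forgetting factor is
    parameterized by ``eta`` on the unconstrained scale and mapped to (0, 1)
    by the logistic function, so heterogeneity never leaves the unit
    interval.  Unlisted sds default to 0 (no heterogeneity).
    """

    label: str
    med_state: str
    n_subjects: int
    param_means: dict[str, float]
    param_sds: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        missing = set(PARAM_NAMES) - set(self.param_means)
        if missing:
            raise ValueError(f"param_means missing entries: {sorted(missing)}")
        if any(sd < 0 for sd in self.param_sds.values()):
            raise ValueError("all param_sds must be nonnegative")

    @property
    def cell(self) -> str:
        return f"{self.label}-{self.med_state}"

    def sd(self, name: str) -> float:
        return float(self.param_sds.get(name, 0.0))


def draw_agent(group: GroupSpec, rng: np.random.Generator | int) -> AgentParams:
    """Draw one subject's parameters from the group's normal laws."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    draw = {name: group.param_means[name] + group.sd(name) * rng.standard_normal()
            for name in PARAM_NAMES}
    happiness = HappinessParams(
        w0=draw["w0"], w1=draw["w1"], w2=draw["w2"], w3=draw["w3"],
        gamma=float(expit(draw["eta"])),
        rating_noise_sd=max(draw["rating_noise_sd"], 1e-3),
    )
    choice = ChoiceParams(draw["beta0"], draw["beta1"], draw["beta2"],
                          draw["beta3"])
    return AgentParams(happiness=happiness, choice=choice,
                       timeout_prob=float(np.clip(draw["timeout_prob"], 0, 1)))


def simulate_session(agent: AgentParams, schedule: list[TrialSpec],
                     rng: np.random.Generator | int,
                     subject_id: str = "sim", group: str = "ICD",
                     med_state: str = "off",
                     slider: bool = False) -> SessionRecord:
    """Simulate one subject-visit over a trial schedule.

    Per trial: with probability ``timeout_prob`` the trial times out (no
    choice, outcome or rating); otherwise the gamble is chosen with the
    logistic-rule probability using the last emitted rating carried forward
    (0 before the first), gamble outcomes resolve 50/50, the latent feeling
    is updated on the responded-trial history, and prompted trials emit
    ``latent + Normal(0, rating_noise_sd)``.
    """
    if not schedule:
        raise ValueError("schedule must be nonempty")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    h = agent.happiness
    w = h.weights()
    dec = np.zeros(3)  # decayed (CR, EV, RPE) sums over responded trials
    last_rating = 0.0  # z-scale, carried forward into the choice rule
    rows = []
    for spec in schedule:
        rec = {"trial_index": spec.trial_index,
               "certain_value": spec.certain_value,
               "gamble_low": spec.gamble_low,
               "gamble_high": spec.gamble_high,
               "rating_prompt": spec.rating_prompt,
               "time_limit": spec.time_limit,
               "choice": "timeout", "outcome": np.nan, "rating": np.nan}
        if rng.random() >= agent.timeout_prob:
            ev_g = gamble_ev(spec.gamble_low, spec.gamble_high)
            p_gamble = expit(agent.choice.gamble_logit(
                ev_g, spec.certain_value, last_rating))
            if rng.random() < p_gamble:
                outcome = float(spec.gamble_high if rng.random() < 0.5
                                else spec.gamble_low)
                x = np.array([0.0, ev_g, outcome - ev_g])
                rec["choice"] = "gamble"
            else:
                outcome = float(spec.certain_value)
                x = np.array([float(spec.certain_value), 0.0, 0.0])
                rec["choice"] = "certain"
            rec["outcome"] = outcome
            dec = h.gamma * dec + x
            if spec.rating_prompt:
                latent = h.w0 + float(w @ dec)
                rating = latent + h.rating_noise_sd * rng.standard_normal()
                if slider:
                    rating = float(np.clip(round(SLIDER_SCALE * rating), -4, 4))
                    last_rating = rating / SLIDER_SCALE
                else:
                    last_rating = rating
                rec["rating"] = rating
        rows.append(rec)
    trials = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    return SessionRecord(subject_id, group, med_state, trials,
                         rating_scale="slider" if slider else "z")


MANIFEST_COLUMNS = ["subject_id", "group", "med_state", "seed",
                    "w0", "w1", "w2", "w3", "gamma",
                    "beta0", "beta1", "beta2", "beta3",
                    "rating_noise_sd", "timeout_prob"]


def simulate_cohort(groups: list[GroupSpec], task: TaskConfig,
                    seed: int, slider: bool = False,
                    ) -> tuple[list[SessionRecord], pd.DataFrame]:
    """Simulate one session per subject per group cell.

    Returns the session records and a ground-truth manifest joining 1:1 to
    them.  Every agent draw, schedule and session stream is derived from
    ``seed`` through spawned substreams, so the cohort is fully
    reproducible.
    """
    root = np.random.SeedSequence(seed)
    sessions: list[SessionRecord] = []
    manifest_rows = []
    for g_idx, group in enumerate(groups):
        for s_idx in range(group.n_subjects):
            child = np.random.SeedSequence(
                entropy=root.entropy, spawn_key=(g_idx, s_idx))
            agent_rng, sched_rng, sess_rng = [
                np.random.default_rng(s) for s in child.spawn(3)]
            agent = draw_agent(group, agent_rng)
            schedule = generate_schedule(task, rng=sched_rng)
            subject_id = f"{group.label}-s{s_idx + 1:02d}"
            session = simulate_session(
                agent, schedule, sess_rng, subject_id=subject_id,
                group=group.label, med_state=group.med_state, slider=slider)
            sessions.append(session)
            h, c = agent.happiness, agent.choice
            manifest_rows.append({
                "subject_id": subject_id, "group": group.label,
                "med_state": group.med_state, "seed": seed,
                "w0": h.w0, "w1": h.w1, "w2": h.w2, "w3": h.w3,
                "gamma": h.gamma,
                "beta0": c.beta0, "beta1": c.beta1, "beta2": c.beta2,
                "beta3": c.beta3,
                "rating_noise_sd": h.rating_noise_sd,
                "timeout_prob": agent.timeout_prob,
            })
    manifest = pd.DataFrame(manifest_rows, columns=MANIFEST_COLUMNS)
    return sessions, manifest


def eta_for_gamma(gamma: float) -> float:
    """Unconstrained-scale value whose logistic map equals ``gamma``."""
    if not 0.0 < gamma < 1.0:
        raise ValueError("gamma must lie strictly inside (0, 1)")
    return float(logit(gamma))
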