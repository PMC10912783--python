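"""Hierarchical Bayesian fitting of the momentary-happiness model.

One condition cell (e.g. ICD-off) is fit at a time: subject-level
parameters (w0..w3, forgetting factor, rating-noise sd) are drawn around
group-level means with group-level sds, and both levels are sampled
jointly.  The observation model is

    rating_z(t) ~ Normal(Happiness(t; w_s, gamma_s), sigma_s)

per subject s, with the forgetting factor handled on an unconstrained
(logit) scale and individual effects non-centered, which keeps the small-n
hierarchy well behaved.

Sampling uses an affine-invariant ensemble MCMC (differential-evolution
moves) over the analytic log posterior; walkers are grouped into
pseudo-chains for split-R-hat and effective-sample-size diagnostics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import arviz as az
import emcee
import numpy as np
import pandas as pd
from scipy.special import expit, logit

from sborg.records import SessionRecord
from sborg.happiness import (
    HappinessParams,
    RegressorSeries,
    build_regressors,
    decayed_series,
    predict_series,
    standardize_session,
    DegenerateRatingsError,
)

GROUP_PARAMS = ("w0", "w1", "w2", "w3", "gamma")
_NATURAL = ("w0", "w1", "w2", "w3", "eta")


@dataclass
class PriorConfig:
    """Weakly informative priors on the z-rating scale.

    Group means ~ Normal(mu_loc, mu_scale) for the weights and the
    unconstrained forgetting factor; group sds ~ half-Normal(tau_scale);
    per-subject rating noise ~ half-Normal(sigma_scale).
    """

    mu_loc: float = 0.0
    mu_scale: float = 1.0
    tau_scale: float = 0.2
    sigma_scale: float = 1.0

    def __post_init__(self) -> None:
        if min(self.mu_scale, self.tau_scale, self.sigma_scale) <= 0:
            raise ValueError("all prior scales must be positive")


@dataclass
class SamplerSettings:
    """Ensemble-sampler configuration.

    ``n_walkers`` defaults to about twice the parameter dimension (rounded
    to a multiple of ``pseudo_chains``); ``n_steps`` includes ``n_burn``
    discarded steps, and retained draws are thinned by ``thin``.
    """

    n_steps: int = 4000
    n_burn: int = 2000
    thin: int = 5
    n_walkers: int | None = None
    seed: int = 0
    pseudo_chains: int = 4
    ind_draw_cap: int = 4000  # max retained draws stored for individuals

    @classmethod
    def fast(cls, seed: int = 0) -> "SamplerSettings":
        """Reduced settings for recovery runs on a single CPU."""
        return cls(n_steps=3000, n_burn=1500, thin=5, seed=seed)

    @classmethod
    def smoke(cls, seed: int = 0) -> "SamplerSettings":
        """Tiny settings for unit tests; not converged, structurally valid."""
        return cls(n_steps=300, n_burn=150, thin=3, seed=seed)


@dataclass
class FitDiagnostics:
    """Split-R-hat, effective sample size and sampler bookkeeping."""

    rhat: dict[str, float]
    ess: dict[str, float]
    n_divergent: int | None  # not defined for ensemble moves
    seed: int
    settings: SamplerSettings
    acceptance_fraction: float
    warnings: list[str] = field(default_factory=list)

    @property
    def converged(self) -> bool:
        return bool(self.rhat) and max(self.rhat.values()) <= 1.05

    def to_text(self) -> str:
        lines = [f"seed={self.seed} acceptance={self.acceptance_fraction:.3f}",
                 f"converged={self.converged} (split R-hat threshold 1.05)"]
        for p in sorted(self.rhat):
            lines.append(f"{p}: rhat={self.rhat[p]:.4f} ess={self.ess[p]:.0f}")
        lines += [f"warning: {w}" for w in self.warnings]
        return "\n".join(lines)


@dataclass
class PosteriorDraws:
    """Retained draws for one condition cell.

    ``group`` maps parameter names (w0..w3, gamma on the natural scale,
    and group sds tau_*) to (chain, draw) arrays; ``individual`` holds
    natural-scale subject-level draws with shape (draw, subject, 5) in the
    order (w0, w1, w2, w3, gamma), and ``sigma_ind`` the per-subject
    rating-noise draws (draw, subject).
    """

    cell: str
    subjects: list[str]
    group: dict[str, np.ndarray]
    individual: np.ndarray
    sigma_ind: np.ndarray

    def group_flat(self, name: str) -> np.ndarray:
        return self.group[name].ravel()

    def group_dict_flat(self) -> dict[str, np.ndarray]:
        return {p: self.group_flat(p) for p in GROUP_PARAMS}

    def individual_means(self) -> pd.DataFrame:
        """Posterior means of subject-level parameters (one row/subject)."""
        means = self.individual.mean(axis=0)
        out = pd.DataFrame(means, columns=list(GROUP_PARAMS))
        out.insert(0, "subject_id", self.subjects)
        out["rating_noise_sd"] = self.sigma_ind.mean(axis=0)
        return out

    def to_frame(self) -> pd.DataFrame:
        """Tidy (chain, draw, parameter, value) table of group-level draws."""
        frames = []
        for name, arr in self.group.items():
            nc, nd = arr.shape
            frames.append(pd.DataFrame({
                "chain": np.repeat(np.arange(nc), nd),
                "draw": np.tile(np.arange(nd), nc),
                "parameter": name,
                "value": arr.ravel(),
            }))
        return pd.concat(frames, ignore_index=True)


class _CellData:
    """Padded, vectorization-ready arrays for one cell's sessions."""

    def __init__(self, regressors: list[RegressorSeries], subjects: list[str]):
        self.subjects = subjects
        self.n_subjects = len(subjects)
        t_max = max(len(r) for r in regressors)
        S = self.n_subjects
        self.X = np.zeros((S, t_max, 3))
        flat_idx, y, subj_of_obs = [], [], []
        for s, reg in enumerate(regressors):
            self.X[s, :len(reg), :] = reg.design()
            for i, t_idx in enumerate(reg.rated_idx):
                flat_idx.append(s * t_max + t_idx)
                y.append(reg.ratings[i])
                subj_of_obs.append(s)
        self.t_max = t_max
        self.flat_idx = np.asarray(flat_idx, dtype=int)
        self.y = np.asarray(y, dtype=float)
        self.subj_of_obs = np.asarray(subj_of_obs, dtype=int)
        self.counts = np.bincount(self.subj_of_obs, minlength=S).astype(float)


def _unpack(theta: np.ndarray, S: int):
    mu = theta[:, 0:5]
    log_tau = theta[:, 5:10]
    z = theta[:, 10:10 + 5 * S].reshape(-1, S, 5)
    log_sig = theta[:, 10 + 5 * S:10 + 6 * S]
    return mu, log_tau, z, log_sig


def _make_log_prob(data: _CellData, priors: PriorConfig):
    S = data.n_subjects
    X, y = data.X, data.y
    flat_idx, subj_of_obs, counts = data.flat_idx, data.subj_of_obs, data.counts

    def log_prob(theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        K = theta.shape[0]
        out = np.full(K, -np.inf)
        ok = np.all(np.abs(theta) < 50.0, axis=1)
        if not ok.any():
            return out
        th = theta[ok]
        mu, log_tau, z, log_sig = _unpack(th, S)
        tau = np.exp(log_tau)
        sig = np.exp(log_sig)
        # non-centered subject-level parameters
        ind = mu[:, None, :] + tau[:, None, :] * z          # (K, S, 5)
        w0 = ind[:, :, 0]
        w = ind[:, :, 1:4]
        gamma = expit(ind[:, :, 4])
        # forward recursion of decayed regressor sums, all walkers at once
        sdec = np.zeros((th.shape[0], S, 3))
        H = np.empty((th.shape[0], S, data.t_max))
        g = gamma[:, :, None]
        for t in range(data.t_max):
            sdec = g * sdec + X[:, t, :]
            H[:, :, t] = w0 + np.einsum("ksj,ksj->ks", w, sdec)
        h_obs = H.reshape(th.shape[0], -1)[:, flat_idx]
        sig_obs = sig[:, subj_of_obs]
        resid = (y[None, :] - h_obs) / sig_obs
        loglik = (-0.5 * np.einsum("kr,kr->k", resid, resid)
                  - log_sig @ counts)
        lp = (-0.5 * np.sum(((mu - priors.mu_loc) / priors.mu_scale) ** 2, axis=1)
              - 0.5 * np.sum((tau / priors.tau_scale) ** 2, axis=1)
              + np.sum(log_tau, axis=1)
              - 0.5 * np.einsum("ksj,ksj->k", z, z)
              - 0.5 * np.sum((sig / priors.sigma_scale) ** 2, axis=1)
              + np.sum(log_sig, axis=1))
        val = loglik + lp
        val[~np.isfinite(val)] = -np.inf
        out[ok] = val
        return out

    return log_prob


def _quick_subject_fit(reg: RegressorSeries) -> tuple[np.ndarray, float]:
    """Grid-over-gamma + OLS starting point for one subject.

    Returns (w0, w1, w2, w3, eta) and a residual-sd estimate.
    """
    y = reg.ratings
    best = None
    for gamma in np.linspace(0.02, 0.9, 12):
        dec = decayed_series(reg.design(), gamma)[reg.rated_idx]
        A = np.column_stack([np.ones(len(y)), dec])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        sse = float(np.sum((y - A @ coef) ** 2))
        if best is None or sse < best[0]:
            best = (sse, coef, gamma)
    sse, coef, gamma = best
    sigma = max(np.sqrt(sse / max(len(y) - 5, 1)), 0.05)
    theta = np.concatenate([coef, [logit(gamma)]])
    return theta, sigma


def _prepare_sessions(sessions: list[SessionRecord], standardize: bool,
                      min_rated: int, warns: list[str]
                      ) -> tuple[list[RegressorSeries], list[str]]:
    regressors, subjects = [], []
    for s in sessions:
        try:
            sess = standardize_session(s) if standardize else s
        except DegenerateRatingsError:
            warns.append(f"excluded {s.subject_id}/{s.cell}: constant ratings")
            continue
        reg = build_regressors(sess)
        if len(reg.rated_idx) < min_rated:
            warns.append(
                f"excluded {s.subject_id}/{s.cell}: "
                f"only {len(reg.rated_idx)} rated trials (< {min_rated})")
            continue
        regressors.append(reg)
        subjects.append(s.subject_id)
    return regressors, subjects


def _pseudo_chains(flat: np.ndarray, n_keep: int, n_walkers: int,
                   n_chains: int) -> np.ndarray:
    """(n_keep, n_walkers) draws -> (n_chains, n_keep * walkers/chain)."""
    per = n_walkers // n_chains
    arr = flat.T.reshape(n_chains, per, n_keep)
    return arr.reshape(n_chains, per * n_keep)


def fit_happiness_hier(sessions: list[SessionRecord],
                       priors: PriorConfig | None = None,
                       settings: SamplerSettings | None = None,
                       standardize: bool = False,
                       min_rated: int = 5,
                       ) -> tuple[PosteriorDraws, FitDiagnostics]:
    """Fit the happiness model hierarchically to one condition cell.

    ``sessions`` should all belong to one cell; ratings are taken as
    already z-scaled unless ``standardize`` is set (use it for raw slider
    data).  Sessions with constant ratings or fewer than ``min_rated``
    rated trials are excluded with a warning.  Returns retained posterior
    draws plus diagnostics; non-convergence (split R-hat > 1.05) is
    flagged, not fatal.
    """
    priors = priors or PriorConfig()
    settings = settings or SamplerSettings()
    warns: list[str] = []
    regressors, subjects = _prepare_sessions(sessions, standardize,
                                             min_rated, warns)
    for w in warns:
        warnings.warn(w, stacklevel=2)
    if len(subjects) < 2:
        raise ValueError("hierarchical fit needs at least 2 usable subjects")
    cell = sessions[0].cell
    data = _CellData(regressors, subjects)
    S = data.n_subjects
    ndim = 10 + 6 * S

    # starting point from per-subject grid+OLS fits
    thetas, sigmas = zip(*(_quick_subject_fit(r) for r in regressors))
    thetas = np.asarray(thetas)
    mu0 = thetas.mean(axis=0)
    tau0 = np.clip(thetas.std(axis=0), 0.02, 0.5)
    z0 = np.clip((thetas - mu0) / tau0, -2.0, 2.0)
    center = np.concatenate([mu0, np.log(tau0), z0.ravel(),
                             np.log(np.asarray(sigmas))])
    jitter = np.concatenate([
        np.full(5, 0.05), np.full(5, 0.10),
        np.full(5 * S, 0.10), np.full(S, 0.05)])

    n_chains = settings.pseudo_chains
    n_walkers = settings.n_walkers or max(2 * ndim + 4, 8 * n_chains)
    n_walkers = int(np.ceil(n_walkers / n_chains) * n_chains)

    rng = np.random.RandomState(settings.seed)
    p0 = center[None, :] + jitter[None, :] * rng.randn(n_walkers, ndim)
    log_prob = _make_log_prob(data, priors)
    sampler = emcee.EnsembleSampler(
        n_walkers, ndim, log_prob, vectorize=True,
        moves=[(emcee.moves.DEMove(), 0.8),
               (emcee.moves.DESnookerMove(), 0.2)])
    sampler.random_state = rng.get_state()
    sampler.run_mcmc(p0, settings.n_steps, progress=False)
    chain = sampler.get_chain(discard=settings.n_burn, thin=settings.thin)
    n_keep = chain.shape[0]

    # group-level draws on the reported (natural) scales
    group: dict[str, np.ndarray] = {}
    natural = {
        "w0": chain[:, :, 0], "w1": chain[:, :, 1],
        "w2": chain[:, :, 2], "w3": chain[:, :, 3],
        "gamma": expit(chain[:, :, 4]),
    }
    for i, nat in enumerate(_NATURAL):
        natural[f"tau_{nat}"] = np.exp(chain[:, :, 5 + i])
    for name, arr in natural.items():
        group[name] = _pseudo_chains(arr, n_keep, n_walkers, n_chains)

    # subject-level natural draws (capped for memory)
    flat = chain.reshape(n_keep * n_walkers, ndim)
    if len(flat) > settings.ind_draw_cap:
        sel = np.linspace(0, len(flat) - 1, settings.ind_draw_cap).astype(int)
        flat = flat[sel]
    mu, log_tau, z, log_sig = _unpack(flat, S)
    ind = mu[:, None, :] + np.exp(log_tau)[:, None, :] * z
    ind[:, :, 4] = expit(ind[:, :, 4])
    draws = PosteriorDraws(cell=cell, subjects=list(subjects), group=group,
                           individual=ind, sigma_ind=np.exp(log_sig))

    rhat, ess = {}, {}
    for p in GROUP_PARAMS:
        arr = group[p]
        rhat[p] = float(az.rhat(arr))
        ess[p] = float(az.ess(arr))
    diag = FitDiagnostics(
        rhat=rhat, ess=ess, n_divergent=None, seed=settings.seed,
        settings=settings,
        acceptance_fraction=float(np.mean(sampler.acceptance_fraction)),
        warnings=warns)
    if not diag.converged:
        diag.warnings.append(
            f"split R-hat above 1.05 (max {max(rhat.values()):.3f}); "
            "treat estimates with caution")
    return draws, diag


def posterior_summary(draws: PosteriorDraws,
                      params: tuple[str, ...] = GROUP_PARAMS,
                      mass: float = 0.95) -> pd.DataFrame:
    """Per-parameter posterior mean, sd and HDI table for one cell."""
    from sborg.compare import hdi
    rows = []
    for p in params:
        x = draws.group_flat(p)
        if x.std() == 0:
            lo = hi = float(x[0])
        else:
            lo, hi = hdi(x, mass)
        rows.append({"parameter": p, "mean": x.mean(), "sd": x.std(ddof=1),
                     "hdi_low": lo, "hdi_high": hi})
    return pd.DataFrame(rows)


def predict_from_fit(draws: PosteriorDraws,
                     sessions: list[SessionRecord]) -> pd.DataFrame:
    """Per-rated-trial predictions from individual posterior means.

    Returns a tidy frame (subject_id, trial_index, actual, predicted) over
    the rated trials of each session; sessions must belong to subjects
    covered by the fit.
    """
    means = draws.individual_means().set_index("subject_id")
    frames = []
    for s in sessions:
        if s.subject_id not in means.index:
            raise KeyError(f"subject {s.subject_id!r} not covered by the fit")
        row = means.loc[s.subject_id]
        params = HappinessParams(
            w0=row["w0"], w1=row["w1"], w2=row["w2"], w3=row["w3"],
            gamma=float(np.clip(row["gamma"], 0.0, 1.0)),
            rating_noise_sd=max(float(row["rating_noise_sd"]), 1e-6))
        reg = build_regressors(s)
        pred = predict_series(params, reg)[reg.rated_idx]
        frames.append(pd.DataFrame({
            "subject_id": s.subject_id,
            "trial_index": reg.trial_index[reg.rated_idx],
            "actual": reg.ratings,
            "predicted": pred,
        }))
    return pd.concat(frames, ignore_index=True)
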