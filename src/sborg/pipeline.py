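"""End-to-end analysis pipeline.

simulate (or read) sessions -> behavior descriptives -> per-subject choice
fits -> hierarchical happiness fits per condition cell -> posterior
comparisons -> fit-quality report.  Every artifact is a delimited text or
JSON file in the output directory, stamped with the config hash and seed;
identical config + seed reproduce the outputs byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from sborg import __version__
from sborg.task import TaskConfig
from sborg.records import SessionRecord, group_by_cell
from sborg.happiness import standardize_session, DegenerateRatingsError
from sborg.cohort import simulate_cohort
from sborg.presets import default_groups, group_preset
from sborg.hier import (PriorConfig, SamplerSettings, fit_happiness_hier,
                        posterior_summary, predict_from_fit)
from sborg.compare import compare_cells
from sborg.choice import fit_cell_choices, summarize_cell_choices
from sborg.evaluate import gamble_rate_table, gamble_rate_tests, fit_r2
from sborg import io as sborg_io

ALL_CELLS = ("ICD-off", "ICD-on", "non-ICD-off", "non-ICD-on")
COMPARE_PAIRS = (
    ("ICD-off", "non-ICD-off"),   # between groups, off medication
    ("ICD-on", "non-ICD-on"),     # between groups, on medication
    ("non-ICD-on", "non-ICD-off"),
    ("ICD-on", "ICD-off"),        # within group, on minus off
)


def load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ValueError("config must be a mapping or a path to one")
    return config


def config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _sampler_settings(config: dict, seed: int) -> SamplerSettings:
    spec = config.get("sampler", {})
    base = SamplerSettings.fast(seed=seed)
    return SamplerSettings(
        n_steps=spec.get("n_steps", base.n_steps),
        n_burn=spec.get("n_burn", base.n_burn),
        thin=spec.get("thin", base.thin),
        n_walkers=spec.get("n_walkers"),
        seed=seed,
        pseudo_chains=spec.get("pseudo_chains", base.pseudo_chains),
    )


def _get_sessions(config: dict, seed: int, out: Path
                  ) -> tuple[list[SessionRecord], pd.DataFrame | None]:
    if "input" in config and config["input"].get("file"):
        scale = config["input"].get("rating_scale", "z")
        sessions = sborg_io.read_sessions(
            config["input"]["file"],
            column_map=config["input"].get("column_map"),
            rating_scale=scale)
        return sessions, None
    sim = config.get("simulate", {})
    task = TaskConfig(
        n_trials=sim.get("n_trials", 208),
        rating_prob=sim.get("rating_prob", 0.33),
        dominated_fraction=sim.get("dominated_fraction", 0.2),
        seed=seed)
    groups = default_groups(n_icd=sim.get("n_icd", 18),
                            n_non_icd=sim.get("n_non_icd", 12))
    sessions, manifest = simulate_cohort(
        groups, task, seed=seed, slider=bool(sim.get("slider", False)))
    sborg_io.write_sessions(sessions, out / "sessions.csv")
    manifest.to_csv(out / "manifest.csv", index=False)
    return sessions, manifest


def _standardized(sessions: list[SessionRecord]) -> list[SessionRecord]:
    """z-score slider-scale sessions; pass z-scale sessions through."""
    out = []
    for s in sessions:
        if s.rating_scale == "z":
            out.append(s)
            continue
        try:
            out.append(standardize_session(s))
        except DegenerateRatingsError:
            warnings.warn(
                f"excluded {s.subject_id}/{s.cell}: constant ratings",
                stacklevel=2)
    return out


def run_pipeline(config, out_dir=None) -> dict[str, Path]:
    """Run the configured stages; return a map of artifact names to paths.

    The config must declare an integer ``seed`` (runs without one are
    refused) and may declare ``input`` (a session file) or ``simulate``
    (cohort options), ``sampler`` settings, ``cells`` to fit, and
    ``stages`` to run.
    """
    config = load_config(config)
    if "seed" not in config:
        raise ValueError("config must declare an integer seed")
    seed = int(config["seed"])
    out = Path(out_dir or config.get("out_dir", "sborg_out"))
    out.mkdir(parents=True, exist_ok=True)
    stages = config.get("stages",
                        ["simulate", "evaluate", "fit-choice",
                         "fit-happiness", "compare", "report"])
    cells_wanted = tuple(config.get("cells", ALL_CELLS))
    artifacts: dict[str, Path] = {}

    sessions, _manifest = _get_sessions(config, seed, out)
    if (out / "sessions.csv").exists():
        artifacts["sessions"] = out / "sessions.csv"
    sessions_z = _standardized(sessions)
    cells = group_by_cell(sessions_z)
    report: dict = {"n_sessions": len(sessions)}

    if "evaluate" in stages:
        rates = gamble_rate_table(sessions_z)
        rates.to_csv(out / "gamble_rates.csv", index=False)
        artifacts["gamble_rates"] = out / "gamble_rates.csv"
        if rates["group"].nunique() == 2 and rates["med_state"].nunique() == 2:
            tests = gamble_rate_tests(rates)
            tests.to_csv(out / "gamble_tests.csv", index=False)
            artifacts["gamble_tests"] = out / "gamble_tests.csv"
            report["gamble_rate_means"] = (
                rates.groupby(["group", "med_state"])["gamble_rate"]
                .mean().round(4).unstack().to_dict())

    if "fit-choice" in stages:
        per_subject, summaries = [], []
        for cell, cell_sessions in cells.items():
            tab = fit_cell_choices(
                cell_sessions,
                prev_rating_mode=config.get("prev_rating_mode", "rated_only"))
            if tab.empty:
                continue
            per_subject.append(tab)
            summ = summarize_cell_choices(tab)
            if not summ.empty:
                summ.insert(0, "cell", cell)
                summaries.append(summ)
        if per_subject:
            pd.concat(per_subject, ignore_index=True).to_csv(
                out / "choice_subjects.csv", index=False)
            artifacts["choice_subjects"] = out / "choice_subjects.csv"
        if summaries:
            pd.concat(summaries, ignore_index=True).to_csv(
                out / "choice_group.csv", index=False)
            artifacts["choice_group"] = out / "choice_group.csv"

    fits: dict[str, object] = {}
    if "fit-happiness" in stages:
        priors = PriorConfig()
        r2_rows = []
        for i, cell in enumerate(c for c in ALL_CELLS if c in cells_wanted):
            if cell not in cells:
                continue
            settings = _sampler_settings(config, seed + 1000 + i)
            draws, diag = fit_happiness_hier(
                cells[cell], priors=priors, settings=settings)
            fits[cell] = draws
            posterior_summary(draws).to_csv(
                out / f"happiness_summary_{cell}.csv", index=False)
            draws.to_frame().to_csv(out / f"draws_{cell}.csv", index=False)
            (out / f"diagnostics_{cell}.txt").write_text(diag.to_text() + "\n")
            artifacts[f"happiness_summary_{cell}"] = \
                out / f"happiness_summary_{cell}.csv"
            pred = predict_from_fit(draws, [s for s in cells[cell]
                                            if s.subject_id in draws.subjects])
            pred.to_csv(out / f"predictions_{cell}.csv", index=False)
            r2_rows.append({"cell": cell,
                            "r2": fit_r2(pred["actual"], pred["predicted"]),
                            "n_rated": len(pred)})
        if r2_rows:
            r2 = pd.DataFrame(r2_rows)
            r2.to_csv(out / "r2.csv", index=False)
            artifacts["r2"] = out / "r2.csv"
            report["r2"] = {r["cell"]: round(r["r2"], 4) for r in r2_rows}

    if "compare" in stages and fits:
        for cell_a, cell_b in COMPARE_PAIRS:
            if cell_a not in fits or cell_b not in fits:
                continue
            rep = compare_cells(fits[cell_a].group_dict_flat(),
                                fits[cell_b].group_dict_flat(),
                                cell_a=cell_a, cell_b=cell_b)
            name = f"compare_{cell_a}_vs_{cell_b}.csv"
            rep.table.to_csv(out / name, index=False)
            artifacts[f"compare_{cell_a}_vs_{cell_b}"] = out / name

    meta = {"config_hash": config_hash(config), "seed": seed,
            "version": __version__}
    (out / "run_meta.json").write_text(json.dumps(meta, indent=2,
                                                  sort_keys=True) + "\n")
    if "report" in stages:
        (out / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True, default=float) + "\n")
        artifacts["report"] = out / "report.json"
    artifacts["run_meta"] = out / "run_meta.json"
    return artifacts


def run_recovery(cell: str = "non-ICD-off", n_subjects: int = 12,
                 n_trials: int = 208, seed: int = 0,
                 settings: SamplerSettings | None = None) -> pd.DataFrame:
    """Parameter-recovery benchmark for one condition cell.

    Simulates a cohort with the published group means as ground truth,
    fits the hierarchical model, and reports per-parameter posterior mean,
    sd and the standardized error (posterior mean - truth) / posterior sd.
    """
    from scipy.special import expit

    label, med_state = cell.rsplit("-", 1)
    group = group_preset(label, med_state, n_subjects=n_subjects)
    task = TaskConfig(n_trials=n_trials, seed=seed)
    sessions, _ = simulate_cohort([group], task, seed=seed)
    settings = settings or SamplerSettings.fast(seed=seed + 1)
    draws, diag = fit_happiness_hier(sessions, settings=settings)
    summary = posterior_summary(draws)
    truth = {p: group.param_means[p] for p in ("w0", "w1", "w2", "w3")}
    truth["gamma"] = float(expit(group.param_means["eta"]))
    summary["truth"] = summary["parameter"].map(truth)
    summary["z_error"] = (summary["mean"] - summary["truth"]) / summary["sd"]
    summary["rhat"] = summary["parameter"].map(diag.rhat)
    return summary
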