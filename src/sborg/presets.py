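"""Group-level generative presets for the four study condition cells.

Means are the published group-level estimates for each cell: happiness-model
weights (w0..w3) and forgetting factor from the hierarchical fits, and
gamble-choice coefficients (beta0..beta2) from the per-participant logistic
fits.  The previous-rating choice weight beta3 was not significant in any
cell and defaults to 0 in these presets.  Between-subject sds are not
published; the defaults below are plausible scatter, not calibrated values.
"""

from __future__ import annotations

from sborg.cohort import GroupSpec, eta_for_gamma

#: per-cell group means: (w0, w1, w2, w3, gamma, beta0, beta1, beta2)
_CELL_MEANS: dict[str, tuple[float, ...]] = {
    "ICD-off":     (-0.6243, 0.1372, 0.1058, 0.3298, 0.1754,
                    0.0223, 1.9517, -1.8869),
    "ICD-on":      (-0.8422, 0.1902, 0.1657, 0.3459, 0.1434,
                    -0.1182, 2.2426, -2.0518),
    "non-ICD-off": (-1.1564, 0.2418, 0.2261, 0.4602, 0.1414,
                    -0.2368, 2.3155, -2.1320),
    "non-ICD-on":  (-1.0175, 0.2231, 0.1914, 0.4453, 0.165,
                    -0.2583, 2.1248, -1.9846),
}

#: default between-subject sds on the draw scale
DEFAULT_SDS = {
    "w0": 0.05, "w1": 0.05, "w2": 0.05, "w3": 0.05,
    "eta": 0.5,           # unconstrained (logit) scale
    "beta0": 0.3, "beta1": 0.3, "beta2": 0.3, "beta3": 0.3,
    "rating_noise_sd": 0.0, "timeout_prob": 0.0,
}

DEFAULT_RATING_NOISE_SD = 0.5
DEFAULT_TIMEOUT_PROB = 0.03  # timeouts were rare in the task (~3%)

#: study design: subjects per group, each completing on and off visits
N_ICD = 18
N_NON_ICD = 12


def group_preset(label: str, med_state: str, n_subjects: int | None = None,
                 sds: dict[str, float] | None = None,
                 rating_noise_sd: float = DEFAULT_RATING_NOISE_SD,
                 timeout_prob: float = DEFAULT_TIMEOUT_PROB) -> GroupSpec:
    """GroupSpec for one condition cell with published means as defaults."""
    cell = f"{label}-{med_state}"
    if cell not in _CELL_MEANS:
        raise KeyError(f"unknown condition cell {cell!r}")
    w0, w1, w2, w3, gamma, b0, b1, b2 = _CELL_MEANS[cell]
    if n_subjects is None:
        n_subjects = N_ICD if label == "ICD" else N_NON_ICD
    means = {
        "w0": w0, "w1": w1, "w2": w2, "w3": w3,
        "eta": eta_for_gamma(gamma),
        "beta0": b0, "beta1": b1, "beta2": b2, "beta3": 0.0,
        "rating_noise_sd": rating_noise_sd,
        "timeout_prob": timeout_prob,
    }
    merged_sds = dict(DEFAULT_SDS)
    if sds:
        merged_sds.update(sds)
    return GroupSpec(label=label, med_state=med_state, n_subjects=n_subjects,
                     param_means=means, param_sds=merged_sds)


def default_groups(n_icd: int = N_ICD, n_non_icd: int = N_NON_ICD,
                   **kwargs) -> list[GroupSpec]:
    """The full 2x2 study design: ICD/non-ICD by on/off medication."""
    return [
        group_preset("ICD", "off", n_icd, **kwargs),
        group_preset("ICD", "on", n_icd, **kwargs),
        group_preset("non-ICD", "off", n_non_icd, **kwargs),
        group_preset("non-ICD", "on", n_non_icd, **kwargs),
    ]
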