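"""Posterior-comparison statistics between condition cells.

Highest-density intervals, index-paired difference distributions, a
posterior version of Cohen's d, and credible-difference fractions, matching
the statistics reported when contrasting group-level posteriors between
ICD/non-ICD groups and on/off medication states.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

GROUP_PARAMS = ("w0", "w1", "w2", "w3", "gamma")
PARAM_LABELS = {
    "w0": "Baseline (w0)",
    "w1": "Certain Reward (w1)",
    "w2": "Gamble EV (w2)",
    "w3": "RPE (w3)",
    "gamma": "Recent Experience Weight (gamma)",
}

#: posterior mass beyond which a difference counts as credible
CREDIBLE_CUTOFF = 0.975


def hdi(samples, mass: float = 0.95) -> tuple[float, float]:
    """Narrowest contiguous interval of sorted draws holding ``mass``.

    The interval contains ceil(mass * n) draws.  For multimodal samples
    this still returns a single interval (documented limitation).
    """
    x = np.sort(np.asarray(samples, dtype=float).ravel())
    n = len(x)
    if n < 2:
        raise ValueError("hdi needs at least 2 samples")
    if not 0.0 < mass <= 1.0:
        raise ValueError("mass must lie in (0, 1]")
    k = int(np.ceil(mass * n))
    if k >= n:
        return float(x[0]), float(x[-1])
    widths = x[k - 1:] - x[:n - k + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k - 1])


def _flatten(draws) -> np.ndarray:
    x = np.asarray(draws, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty draw collection")
    return x


def difference_distribution(draws_a, draws_b) -> np.ndarray:
    """Element-wise A - B after index alignment.

    Cells are fitted independently, so any pairing of draws is valid;
    index pairing is used because it is reproducible.  If lengths differ
    the longer collection is thinned evenly to match.
    """
    a, b = _flatten(draws_a), _flatten(draws_b)
    if len(a) != len(b):
        n = min(len(a), len(b))
        a = a[np.linspace(0, len(a) - 1, n).astype(int)]
        b = b[np.linspace(0, len(b) - 1, n).astype(int)]
    return a - b


def cohens_d_posterior(draws_a, draws_b) -> float:
    """Difference of posterior means over the RMS of the two posterior sds:

        d = (mean A - mean B) / sqrt((sd_A^2 + sd_B^2) / 2)

    Undefined (NaN) when both posteriors are degenerate point masses.
    """
    a, b = _flatten(draws_a), _flatten(draws_b)
    return cohens_d_from_moments(a.mean(), a.std(ddof=1),
                                 b.mean(), b.std(ddof=1))


def cohens_d_from_moments(mean_a: float, sd_a: float,
                          mean_b: float, sd_b: float) -> float:
    """Pooled-variance posterior Cohen's d from summary moments.

    Also usable to reconstruct printed effect sizes from published
    posterior means and 95% HDIs via the normal approximation
    sd = HDI width / 3.92.
    """
    pooled = np.sqrt((sd_a ** 2 + sd_b ** 2) / 2.0)
    if pooled == 0.0:
        return float("nan") if mean_a == mean_b else float("inf") * np.sign(mean_a - mean_b)
    return float((mean_a - mean_b) / pooled)


def credible_fraction(difference_draws) -> tuple[float, float]:
    """(fraction below 0, fraction above 0) of difference draws.

    Exact zeros are split evenly between the sides, so the two fractions
    always sum to 1.
    """
    d = _flatten(difference_draws)
    n = len(d)
    below = np.count_nonzero(d < 0)
    above = np.count_nonzero(d > 0)
    ties = n - below - above
    return (below + 0.5 * ties) / n, (above + 0.5 * ties) / n


@dataclass
class ComparisonReport:
    """Per-parameter posterior comparison between two condition cells."""

    cell_a: str
    cell_b: str
    table: pd.DataFrame

    def credible(self, param: str) -> bool:
        row = self.table.set_index("parameter").loc[param]
        return max(row["frac_below_0"], row["frac_above_0"]) > CREDIBLE_CUTOFF


def compare_cells(draws_a: dict[str, np.ndarray], draws_b: dict[str, np.ndarray],
                  cell_a: str = "A", cell_b: str = "B",
                  params: tuple[str, ...] = GROUP_PARAMS,
                  mass: float = 0.95) -> ComparisonReport:
    """Assemble the per-parameter comparison report for two cells.

    ``draws_a``/``draws_b`` map parameter names to draw arrays (any shape;
    flattened).  The sign convention of differences is A - B.
    """
    missing = [p for p in params if p not in draws_a or p not in draws_b]
    if missing:
        raise KeyError(f"parameters missing from one cell: {missing}")
    rows = []
    for p in params:
        a, b = _flatten(draws_a[p]), _flatten(draws_b[p])
        diff = difference_distribution(a, b)
        lo_a, hi_a = hdi(a, mass)
        lo_b, hi_b = hdi(b, mass)
        lo_d, hi_d = hdi(diff, mass)
        below, above = credible_fraction(diff)
        rows.append({
            "parameter": p, "label": PARAM_LABELS.get(p, p),
            "mean_a": a.mean(), "hdi_low_a": lo_a, "hdi_high_a": hi_a,
            "mean_b": b.mean(), "hdi_low_b": lo_b, "hdi_high_b": hi_b,
            "cohens_d": cohens_d_posterior(a, b),
            "diff_hdi_low": lo_d, "diff_hdi_high": hi_d,
            "frac_below_0": below, "frac_above_0": above,
        })
    return ComparisonReport(cell_a, cell_b, pd.DataFrame(rows))
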