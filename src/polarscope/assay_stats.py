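"""Functional-readout numerics: chemiluminescence AUC and rank-based group tests.

These are deliberately thin: the trapezoidal integral wraps numpy, the
omnibus comparison wraps the Kruskal-Wallis test (or Friedman for paired
designs) from scipy, and Dunn's rank-based post hoc z-statistics are
computed from the pooled ranks with tie correction, with multiplicity
adjustment delegated to statsmodels.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["TimeSeries", "auc_trapezoid", "compare_groups"]


@dataclass
class TimeSeries:
    """A sampled signal: times in minutes (strictly increasing), values in RLU."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if self.times.size < 2:
            raise ValueError("a time series needs at least 2 points")
        if not (np.diff(self.times) > 0).all():
            raise ValueError("times must be strictly increasing")


def auc_trapezoid(series: TimeSeries) -> float:
    """Trapezoidal area under the curve over the recorded interval (signal*min)."""
    return float(np.trapezoid(series.values, series.times))


def _dunn_posthoc(groups: dict, adjust: str) -> pd.DataFrame:
    """Dunn's pairwise z-tests on pooled ranks, with tie correction."""
    names = list(groups)
    pooled = np.concatenate([np.asarray(groups[g], dtype=float) for g in names])
    ranks = stats.rankdata(pooled)
    n_total = len(pooled)
    # tie correction term sum(t^3 - t) over tie groups
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3) - counts).sum())
    offsets = np.cumsum([0] + [len(groups[g]) for g in names])
    mean_ranks = {
        g: ranks[offsets[i] : offsets[i + 1]].mean() for i, g in enumerate(names)
    }
    rows = []
    for a, b in itertools.combinations(names, 2):
        na, nb = len(groups[a]), len(groups[b])
        var = (n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))) * (
            1.0 / na + 1.0 / nb
        )
        z = (mean_ranks[a] - mean_ranks[b]) / np.sqrt(var) if var > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group_a": a, "group_b": b, "z": z, "p_raw": p})
    table = pd.DataFrame(rows)
    if len(table):
        table["p_adjusted"] = multipletests(table["p_raw"], method=adjust)[1]
    return table


def compare_groups(
    groups: dict, paired: bool = False, adjust: str = "bonferroni"
) -> dict:
    """Omnibus rank test plus pairwise post hoc comparisons.

    Unpaired (default): Kruskal-Wallis omnibus followed by Dunn's pairwise
    z-tests.  Paired: Friedman omnibus followed by Wilcoxon signed-rank
    pairs.  Adjusted p-values use ``adjust`` (statsmodels method name).
    Returns {"test", "statistic", "p_value", "posthoc": DataFrame}.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for name, vals in groups.items():
        if len(vals) < 3:
            raise ValueError(f"group {name!r} has fewer than 3 values")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if paired:
        stat, p = stats.friedmanchisquare(*arrays.values())
        rows = []
        for a, b in itertools.combinations(arrays, 2):
            res = stats.wilcoxon(arrays[a], arrays[b])
            rows.append(
                {"group_a": a, "group_b": b, "z": res.statistic, "p_raw": res.pvalue}
            )
        posthoc = pd.DataFrame(rows)
        if len(posthoc):
            posthoc["p_adjusted"] = multipletests(posthoc["p_raw"], method=adjust)[1]
        name = "friedman + wilcoxon"
    else:
        stat, p = stats.kruskal(*arrays.values())
        posthoc = _dunn_posthoc(arrays, adjust)
        name = "kruskal-wallis + dunn"
    return {"test": name, "statistic": float(stat), "p_value": float(p), "posthoc": posthoc}
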