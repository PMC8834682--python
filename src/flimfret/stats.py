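"""Condition-level nonparametric statistics.

The study-level reporting this module reproduces: boxplot summaries
(median, quartiles, 10-90 percentile whiskers), a Kruskal-Wallis omnibus
test across conditions, Dunn's post hoc pairwise z-tests on the pooled
ranks with tie correction and multiplicity adjustment, and a
negative-control background gate (a condition counts as a real interaction
only if its median exceeds the negative-control median AND its Dunn-adjusted
p-value against the control is significant).

All quantiles use the linear-interpolation convention of ``numpy.percentile``.
The multiplicity adjustment defaults to Holm; Bonferroni and Šidák are
selectable and the method is recorded in the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError

__all__ = [
    "BoxplotSummary",
    "GroupComparison",
    "boxplot_summary",
    "kruskal_wallis",
    "dunn_posthoc",
    "background_gate",
    "compare_groups",
    "save_boxplots",
]

_CORRECTIONS = {"holm": "holm", "bonferroni": "bonferroni", "sidak": "sidak"}


@dataclass(frozen=True)
class BoxplotSummary:
    """Five-number summary used for the study's boxplots."""

    median: float
    q1: float
    q3: float
    p10: float
    p90: float
    n: int


@dataclass
class GroupComparison:
    """Omnibus + post hoc comparison of one metric across conditions."""

    metric_name: str
    groups: dict
    h_statistic: float
    omnibus_p: float
    pairwise: pd.DataFrame
    correction: str
    alpha: float
    summaries: dict
    background_threshold: Optional[float] = None
    above_background: Optional[dict] = None


def boxplot_summary(values: Sequence[float]) -> BoxplotSummary:
    """Median, quartiles and 10th/90th percentiles (linear interpolation)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("boxplot_summary requires at least one value")
    p10, q1, med, q3, p90 = np.percentile(v, [10, 25, 50, 75, 90])
    return BoxplotSummary(
        median=float(med), q1=float(q1), q3=float(q3),
        p10=float(p10), p90=float(p90), n=int(v.size),
    )


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and chi-square p over k groups.

    Degenerate input where every value is identical returns (0, 1).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("kruskal_wallis requires at least two groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs at least two values")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = scipy.stats.kruskal(*arrays)
    return float(h), float(p)


def dunn_posthoc(
    groups: Mapping[str, Sequence[float]],
    correction: str = "holm",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Dunn's post hoc test on pooled ranks, with tie correction.

    For each pair (a, b): z = (Rbar_a - Rbar_b) / SE with
    SE^2 = (N(N+1)/12 - sum(t^3 - t)/(12(N-1))) * (1/n_a + 1/n_b),
    two-sided normal p-values, then multiplicity adjustment by the chosen
    method.  Returns a DataFrame with columns group_a, group_b, z, raw_p,
    adjusted_p, significant.
    """
    if correction not in _CORRECTIONS:
        raise ConfigError(f"unknown correction {correction!r}; "
                          f"choose from {sorted(_CORRECTIONS)}")
    names = list(groups)
    if len(names) < 2:
        raise ValueError("dunn_posthoc requires at least two groups")
    arrays = {k: np.asarray(groups[k], dtype=float) for k in names}
    pooled = np.concatenate([arrays[k] for k in names])
    n_total = pooled.size
    ranks = scipy.stats.rankdata(pooled)
    mean_rank = {}
    start = 0
    for k in names:
        n_k = arrays[k].size
        mean_rank[k] = ranks[start:start + n_k].mean()
        start += n_k
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term

    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            se = np.sqrt(base_var * (1.0 / arrays[a].size + 1.0 / arrays[b].size))
            z = (mean_rank[a] - mean_rank[b]) / se if se > 0 else 0.0
            raw_p = float(2.0 * scipy.stats.norm.sf(abs(z)))
            rows.append({"group_a": a, "group_b": b, "z": float(z), "raw_p": raw_p})
    table = pd.DataFrame(rows)
    reject, adj, _, _ = multipletests(
        table["raw_p"].to_numpy(), alpha=alpha, method=_CORRECTIONS[correction]
    )
    table["adjusted_p"] = np.minimum(adj, 1.0)
    table["significant"] = table["adjusted_p"] < alpha
    return table


def background_gate(
    condition_values: Sequence[float],
    negative_control_values: Sequence[float],
    correction: str = "holm",
    alpha: float = 0.05,
) -> tuple[float, bool, float]:
    """Gate a condition against the free-acceptor negative control.

    Returns (threshold, above_background, adjusted_p): the threshold is the
    negative-control median, and the flag is true only if the condition
    median exceeds it AND the Dunn-adjusted p against the control is below
    ``alpha``.
    """
    cond = np.asarray(condition_values, dtype=float)
    ctrl = np.asarray(negative_control_values, dtype=float)
    if cond.size == 0 or ctrl.size == 0:
        raise ValueError("background_gate requires non-empty samples")
    threshold = float(np.median(ctrl))
    table = dunn_posthoc(
        {"condition": cond, "control": ctrl}, correction=correction, alpha=alpha
    )
    p_adj = float(table["adjusted_p"].iloc[0])
    flag = bool(np.median(cond) > threshold and p_adj < alpha)
    return threshold, flag, p_adj


def compare_groups(
    groups: Mapping[str, Sequence[float]],
    metric_name: str = "",
    correction: str = "holm",
    alpha: float = 0.05,
    negative_control: Optional[str] = None,
) -> GroupComparison:
    """Full condition-level analysis of one metric.

    Kruskal-Wallis omnibus over all groups, Dunn's post hoc with the chosen
    adjustment, boxplot summaries, and — when ``negative_control`` names one
    of the groups — the background gate for every other group against it
    (using that group's Dunn-adjusted p from the pooled post hoc table).
    """
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    h, p = kruskal_wallis(list(arrays.values()))
    pairwise = dunn_posthoc(arrays, correction=correction, alpha=alpha)
    summaries = {k: boxplot_summary(v) for k, v in arrays.items()}

    threshold = None
    above = None
    if negative_control is not None:
        if negative_control not in arrays:
            raise ConfigError(
                f"negative control {negative_control!r} not among groups"
            )
        threshold = summaries[negative_control].median
        above = {}
        for _, row in pairwise.iterrows():
            pair = {row["group_a"], row["group_b"]}
            if negative_control in pair:
                other = (pair - {negative_control}).pop()
                above[other] = bool(
                    summaries[other].median > threshold
                    and row["adjusted_p"] < alpha
                )
    return GroupComparison(
        metric_name=metric_name,
        groups=arrays,
        h_statistic=h,
        omnibus_p=p,
        pairwise=pairwise,
        correction=correction,
        alpha=alpha,
        summaries=summaries,
        background_threshold=threshold,
        above_background=above,
    )


def save_boxplots(
    groups: Mapping[str, Sequence[float]],
    path,
    metric_name: str = "",
) -> None:
    """Render the study-style boxplot (median, quartiles, 10-90 whiskers)."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    names = list(groups)
    fig, ax = plt.subplots(figsize=(1.2 * max(len(names), 3) + 1, 4))
    ax.boxplot(
        [np.asarray(groups[k], dtype=float) for k in names],
        tick_labels=names,
        whis=(10, 90),
        showfliers=False,
    )
    ax.set_ylabel(metric_name or "value")
    ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
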