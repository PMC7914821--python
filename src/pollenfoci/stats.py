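"""Group comparison of per-stack aggregates and significance labelling.

The omnibus test is the Kruskal–Wallis one-way ANOVA on ranks, followed by
Dunn's pairwise multiple-comparison procedure (rank-based z tests with tie
correction, Bonferroni-adjusted by default) — the standard pairing for
"ANOVA on ranks + Dunn's method".  A parametric route (one-way ANOVA +
Holm-adjusted Welch t tests) is available behind ``parametric=True``.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)


def significance_stars(p: float) -> str:
    """Map a p-value to the figure-caption label: '***' below 0.001, '*'
    below 0.05, else 'NS'.

    The caption uses strict inequalities; the boundary values resolve as
    p = 0.001 -> '*' and p = 0.05 -> 'NS'.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value {p} outside [0, 1]")
    if p < 0.001:
        return "***"
    if p < 0.05:
        return "*"
    return "NS"


def dunn_test(
    groups: Mapping[str, Sequence[float]], adjust: bool = True
) -> pd.DataFrame:
    """Dunn's post-hoc pairwise comparisons on pooled ranks.

    For groups i, j with mean ranks R_i, R_j over the pooled sample of size
    N, the statistic is

        z = (R_i - R_j) / sqrt((N (N+1) / 12 - T) (1/n_i + 1/n_j)),

    with the tie correction T = sum(t^3 - t) / (12 (N - 1)) over tie groups
    of size t.  Two-sided normal p-values, Bonferroni-multiplied by the
    number of pairs when ``adjust`` (adjustment can only raise a p-value).
    Returns a symmetric DataFrame with ones on the diagonal.
    """
    names = list(groups)
    values = [np.asarray(groups[g], dtype=float) for g in names]
    pooled = np.concatenate(values)
    n_tot = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks, sizes = [], []
    start = 0
    for v in values:
        mean_ranks.append(ranks[start : start + v.size].mean())
        sizes.append(v.size)
        start += v.size
    _, counts = np.unique(pooled, return_counts=True)
    tie_corr = float(np.sum(counts**3 - counts)) / (12.0 * (n_tot - 1)) if n_tot > 1 else 0.0
    var_unit = n_tot * (n_tot + 1) / 12.0 - tie_corr

    k = len(names)
    pmat = pd.DataFrame(np.ones((k, k)), index=names, columns=names)
    n_pairs = k * (k - 1) // 2
    for i, j in itertools.combinations(range(k), 2):
        denom = var_unit * (1.0 / sizes[i] + 1.0 / sizes[j])
        if denom <= 0:  # complete ties: no evidence against equality
            p = 1.0
        else:
            z = (mean_ranks[i] - mean_ranks[j]) / np.sqrt(denom)
            p = 2.0 * sps.norm.sf(abs(z))
            if adjust:
                p = min(p * n_pairs, 1.0)
        pmat.iloc[i, j] = pmat.iloc[j, i] = p
    return pmat


def _holm(pvals: list[float]) -> list[float]:
    order = np.argsort(pvals)
    m = len(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adj[idx] = min(running, 1.0)
    return adj.tolist()


@dataclass
class GroupComparison:
    """Omnibus + pairwise comparison of per-stack aggregates across conditions."""

    metric: str
    groups: dict[str, list[float]]
    omnibus_test: str
    omnibus_stat: float
    omnibus_p: float
    pairwise_p: pd.DataFrame  # symmetric, unit diagonal
    labels: dict[tuple[str, str], str]
    alpha: float
    pairwise_test: str

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (a, b), lab in self.labels.items():
            rows.append(
                {
                    "metric": self.metric,
                    "group_a": a,
                    "group_b": b,
                    "p_adjusted": float(self.pairwise_p.loc[a, b]),
                    "label": lab,
                    "omnibus_test": self.omnibus_test,
                    "omnibus_p": self.omnibus_p,
                }
            )
        return pd.DataFrame(rows)


def compare_groups(
    groups: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
    metric: str = "",
    adjust: bool = True,
    parametric: bool = False,
    min_group_size: int = 25,
) -> GroupComparison:
    """Compare per-stack aggregates across >= 2 conditions.

    Default route: Kruskal–Wallis omnibus + Dunn's adjusted pairwise
    p-values.  When every value across every group is tied the omnibus is
    undefined and reported as p = 1 by convention.  Groups smaller than
    ``min_group_size`` trigger a warning (the source figures report at least
    25 imaged samples per group), not an error.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    values = {g: [float(v) for v in groups[g]] for g in names}
    for g, v in values.items():
        if len(v) < 3:
            raise ValueError(f"group {g!r} has fewer than 3 values")
        if len(v) < min_group_size:
            warnings.warn(
                f"group {g!r} has {len(v)} < {min_group_size} measurements",
                stacklevel=2,
            )

    pooled = np.concatenate([values[g] for g in names])
    all_tied = bool(np.all(pooled == pooled[0]))

    if parametric:
        omnibus_name, pairwise_name = "one-way ANOVA", "Welch t (Holm)"
        if all_tied:
            stat, p = float("nan"), 1.0
            logger.warning("all values tied across groups; omnibus p set to 1")
        else:
            stat, p = sps.f_oneway(*[values[g] for g in names])
        pairs = list(itertools.combinations(names, 2))
        raw = []
        for a, b in pairs:
            if all_tied:
                raw.append(1.0)
            else:
                raw.append(float(sps.ttest_ind(values[a], values[b], equal_var=False).pvalue))
        adj = _holm(raw) if adjust else raw
        pmat = pd.DataFrame(np.ones((len(names), len(names))), index=names, columns=names)
        for (a, b), pv in zip(pairs, adj):
            pmat.loc[a, b] = pmat.loc[b, a] = pv
    else:
        omnibus_name, pairwise_name = "Kruskal-Wallis", "Dunn (Bonferroni)" if adjust else "Dunn"
        if all_tied:
            stat, p = float("nan"), 1.0
            logger.warning("all values tied across groups; omnibus p set to 1")
        else:
            stat, p = sps.kruskal(*[values[g] for g in names])
        pmat = dunn_test(values, adjust=adjust)

    labels = {
        (a, b): significance_stars(float(pmat.loc[a, b]))
        for a, b in itertools.combinations(names, 2)
    }
    return GroupComparison(
        metric=metric,
        groups=values,
        omnibus_test=omnibus_name,
        omnibus_stat=float(stat),
        omnibus_p=float(p),
        pairwise_p=pmat,
        labels=labels,
        alpha=alpha,
        pairwise_test=pairwise_name,
    )
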