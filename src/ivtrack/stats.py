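"""Group summaries and the comparison tests used for motility cohorts.

Two groups are compared with the two-tailed unpaired t-test; three or more
with the Kruskal–Wallis rank test (tie-corrected, as motility data tie at
zero) followed by Dunn's pairwise z-tests.  Dunn p-values are adjusted for
multiplicity over all pairs — Bonferroni by default, matching the common
Prism convention; Holm or no adjustment are available.

Significance bands: ``***`` p<0.001, ``**`` p<0.01, ``*`` p<0.05, else ``ns``.
"""

from __future__ import annotations

import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DomainError, EmptyCohortError

ADJUSTMENTS = ("bonferroni", "holm", "none")


@dataclass(frozen=True)
class GroupSummary:
    group: str
    n: int
    mean: float
    sd: float
    sem: float
    sd_defined: bool  # False for a single observation (sd reported as 0)


@dataclass(frozen=True)
class ComparisonResult:
    test_name: str
    statistic: float
    pvalue: float
    pairwise: pd.DataFrame  # columns: group_a, group_b, statistic, p_raw, p_adj, band


def significance_band(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def table_to_groups(
    table: pd.DataFrame, value: str, group: str
) -> dict[str, np.ndarray]:
    """Split a long-format table into {group key: value array}."""
    return {
        str(k): g[value].dropna().to_numpy(dtype=float)
        for k, g in table.groupby(group, sort=True)
    }


def _as_groups(values: Mapping[str, Sequence[float]]) -> dict[str, np.ndarray]:
    if not values:
        raise EmptyCohortError("no groups supplied")
    return {str(k): np.asarray(v, dtype=float) for k, v in values.items()}


def summarize_groups(
    values: Mapping[str, Sequence[float]]
) -> list[GroupSummary]:
    """Mean, SD, SEM and n per group, in stable (insertion) order.

    A single observation has no sample SD; it is reported as 0 with
    ``sd_defined=False``.
    """
    groups = _as_groups(values)
    out = []
    for key, arr in groups.items():
        if len(arr) < 1:
            raise EmptyCohortError(f"group {key!r} is empty")
        n = len(arr)
        mean = float(np.mean(arr))
        if n > 1:
            sd = float(np.std(arr, ddof=1))
            defined = True
        else:
            sd, defined = 0.0, False
        out.append(
            GroupSummary(
                group=key, n=n, mean=mean, sd=sd, sem=sd / math.sqrt(n),
                sd_defined=defined,
            )
        )
    return out


def _adjust(p_raw: np.ndarray, method: str) -> np.ndarray:
    m = len(p_raw)
    if method == "none":
        return p_raw.copy()
    if method == "bonferroni":
        return np.minimum(1.0, m * p_raw)
    if method == "holm":
        order = np.argsort(p_raw)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * p_raw[idx])
            adj[idx] = min(1.0, running)
        return adj
    raise DomainError(f"unknown adjustment {method!r}; choose from {ADJUSTMENTS}")


def dunn_pairwise(
    groups: Mapping[str, np.ndarray], adjust: str = "bonferroni"
) -> pd.DataFrame:
    """Dunn's post-hoc z-tests on pooled mid-ranks with tie correction.

    For groups i, j with mean ranks R̄_i, R̄_j over the pooled sample of
    size N:  z = (R̄_i − R̄_j) / sqrt((N(N+1)/12 − T)(1/n_i + 1/n_j)),
    where T = Σ(t³ − t) / (12(N − 1)) over tie groups of size t.
    """
    keys = list(groups)
    sizes = {k: len(groups[k]) for k in keys}
    pooled = np.concatenate([groups[k] for k in keys])
    n_total = len(pooled)
    ranks = sps.rankdata(pooled)
    mean_ranks = {}
    start = 0
    for k in keys:
        stop = start + sizes[k]
        mean_ranks[k] = float(np.mean(ranks[start:stop]))
        start = stop
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term

    rows = []
    for a, b in combinations(keys, 2):
        se = math.sqrt(base_var * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append({"group_a": a, "group_b": b, "statistic": z, "p_raw": p})
    table = pd.DataFrame(rows)
    table["p_adj"] = _adjust(table["p_raw"].to_numpy(), adjust)
    table["band"] = table["p_adj"].map(significance_band)
    return table


def compare_groups(
    values: Mapping[str, Sequence[float]], adjust: str = "bonferroni"
) -> ComparisonResult:
    """Two-tailed unpaired t-test (2 groups) or Kruskal–Wallis + Dunn (≥3).

    Every group needs at least two observations.
    """
    groups = _as_groups(values)
    if len(groups) < 2:
        raise EmptyCohortError("need at least two groups to compare")
    for key, arr in groups.items():
        if len(arr) < 2:
            raise EmptyCohortError(f"group {key!r} has n < 2")
    keys = list(groups)
    if len(groups) == 2:
        a, b = (groups[k] for k in keys)
        res = sps.ttest_ind(a, b, equal_var=True)
        p = float(res.pvalue)
        pairwise = pd.DataFrame(
            [
                {
                    "group_a": keys[0],
                    "group_b": keys[1],
                    "statistic": float(res.statistic),
                    "p_raw": p,
                    "p_adj": p,
                    "band": significance_band(p),
                }
            ]
        )
        return ComparisonResult(
            test_name="two-tailed unpaired t-test",
            statistic=float(res.statistic),
            pvalue=p,
            pairwise=pairwise,
        )
    kw = sps.kruskal(*(groups[k] for k in keys))
    return ComparisonResult(
        test_name="Kruskal-Wallis + Dunn",
        statistic=float(kw.statistic),
        pvalue=float(kw.pvalue),
        pairwise=dunn_pairwise(groups, adjust=adjust),
    )


def fold_change(a: float, b: float) -> float:
    """Ratio a/b of two positive quantities (densities, velocities, …)."""
    if b <= 0:
        raise DomainError("fold change undefined: reference value must be > 0")
    if a < 0:
        raise DomainError("fold change undefined for negative numerator")
    return a / b
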