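"""Nonparametric group comparison chain.

Per feature: a Shapiro-Wilk normality gate, a Kruskal-Wallis omnibus test
with tie correction, and Dunn's pairwise post hoc z tests on pooled ranks
with Holm's step-down familywise correction. The Holm family is the set
of pairwise comparisons within one feature. Shapiro-Wilk and
Kruskal-Wallis are delegated to vetted scipy routines; the Dunn
statistics are computed here.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InvalidParameterError

__all__ = [
    "GroupComparison",
    "normality_gate",
    "kruskal_wallis",
    "dunn_holm",
    "compare_feature",
    "analyze_feature_table",
]


def _check_groups(samples: Mapping[str, np.ndarray], min_n: int = 1):
    if len(samples) < 2:
        raise InvalidParameterError("need at least 2 groups")
    out = {}
    for name, arr in samples.items():
        arr = np.asarray(arr, dtype=float)
        arr = arr[~np.isnan(arr)]
        if len(arr) < min_n:
            raise InvalidParameterError(f"group '{name}' has n < {min_n}")
        out[name] = arr
    return out


def normality_gate(samples: Mapping[str, np.ndarray], alpha: float = 0.05):
    """Shapiro-Wilk per group; returns (p-values, use_nonparametric).

    The nonparametric branch is taken when any group rejects normality
    at ``alpha``. Degenerate (constant) groups get p = NaN and force the
    nonparametric branch.
    """
    groups = _check_groups(samples, min_n=3)
    ps: dict[str, float] = {}
    flag = False
    for name, arr in groups.items():
        if np.ptp(arr) == 0:
            ps[name] = float("nan")
            flag = True
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ps[name] = float(stats.shapiro(arr).pvalue)
        if ps[name] < alpha:
            flag = True
    return ps, flag


def kruskal_wallis(samples: Mapping[str, np.ndarray]):
    """Kruskal-Wallis H with tie correction; p from chi-square (k-1 df).

    All-identical data give H = 0, p = 1 by convention.
    """
    groups = _check_groups(samples, min_n=1)
    if sum(len(a) for a in groups.values()) < 5:
        raise InvalidParameterError("total n must be >= 5")
    pooled = np.concatenate(list(groups.values()))
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    h, p = stats.kruskal(*groups.values())
    return float(h), float(p)


def dunn_holm(samples: Mapping[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's pairwise z tests on pooled ranks, Holm-adjusted.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - C) (1/n_i + 1/n_j))
    with tie correction C = sum(t^3 - t) / (12 (N - 1)). Two-sided
    normal p-values; Holm's step-down over all pairs within the feature.
    """
    groups = _check_groups(samples, min_n=1)
    names = list(groups)
    pooled = np.concatenate([groups[g] for g in names])
    n_tot = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_rank = {}
    i0 = 0
    for g in names:
        n_g = len(groups[g])
        mean_rank[g] = float(ranks[i0:i0 + n_g].mean())
        i0 += n_g
    _, counts = np.unique(pooled, return_counts=True)
    tie_c = float(((counts ** 3 - counts).sum()) / (12.0 * (n_tot - 1))) if n_tot > 1 else 0.0
    base_var = n_tot * (n_tot + 1) / 12.0 - tie_c
    rows = []
    for gi, gj in itertools.combinations(names, 2):
        var = base_var * (1.0 / len(groups[gi]) + 1.0 / len(groups[gj]))
        if var <= 0:
            z, p = 0.0, 1.0
        else:
            z = (mean_rank[gi] - mean_rank[gj]) / np.sqrt(var)
            p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group_i": gi, "group_j": gj, "z": float(z),
                     "p_raw": float(min(p, 1.0))})
    table = pd.DataFrame(rows)
    table["p_adj"] = multipletests(table["p_raw"], method="holm")[1]
    return table


@dataclass
class GroupComparison:
    feature: str
    shapiro_p: dict[str, float]
    use_nonparametric: bool
    kw_h: float
    kw_p: float
    pairwise: pd.DataFrame


def compare_feature(samples: Mapping[str, np.ndarray], feature: str = "",
                    alpha: float = 0.05) -> GroupComparison:
    """Full chain for one feature: gate, omnibus, post hoc."""
    shapiro_p, flag = normality_gate(samples, alpha=alpha)
    h, p = kruskal_wallis(samples)
    pairwise = dunn_holm(samples)
    return GroupComparison(feature=feature, shapiro_p=shapiro_p,
                           use_nonparametric=flag, kw_h=h, kw_p=p,
                           pairwise=pairwise)


def analyze_feature_table(table: pd.DataFrame, feature_cols: Sequence[str],
                          group_col: str = "group",
                          alpha: float = 0.05) -> pd.DataFrame:
    """Run the chain per feature over a feature table; tidy output.

    Returns one row per (feature, comparison): omnibus rows have
    comparison 'all' with the H statistic; pairwise rows carry Dunn z,
    raw and Holm-adjusted p.
    """
    rows = []
    for feat in feature_cols:
        samples = {g: sub[feat].to_numpy(dtype=float)
                   for g, sub in table.groupby(group_col)}
        res = compare_feature(samples, feature=feat, alpha=alpha)
        rows.append({"feature": feat, "test": "kruskal_wallis",
                     "comparison": "all", "statistic": res.kw_h,
                     "p": res.kw_p, "p_adj": np.nan})
        for _, r in res.pairwise.iterrows():
            rows.append({"feature": feat, "test": "dunn",
                         "comparison": f"{r['group_i']} vs {r['group_j']}",
                         "statistic": r["z"], "p": r["p_raw"],
                         "p_adj": r["p_adj"]})
    return pd.DataFrame(rows)
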