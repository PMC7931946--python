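"""Cohort-comparison statistics for property profiles.

For each descriptor compared across two or more compound groups the battery
reports: group summaries (n, mean, median, sample SD), one-way ANOVA,
pairwise Welch tests (unequal variances), pairwise Wilcoxon rank-sum tests
(exact enumeration when both groups have n <= 10, otherwise a tie-corrected
normal approximation), Tukey HSD pairwise p-values, and Benjamini-Hochberg
q-values at FDR 5%.  Significance calls are made on q-values.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

WILCOXON_EXACT_MAX_N = 10


@dataclass
class GroupSummary:
    n: int
    mean: float
    median: float
    sd: float
    degenerate: bool = False  # n == 1: SD defined as 0


def summarize_group(values) -> GroupSummary:
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty group")
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return GroupSummary(
        n=int(arr.size),
        mean=float(arr.mean()),
        median=float(np.median(arr)),
        sd=sd,
        degenerate=arr.size == 1,
    )


def _midranks(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


def wilcoxon_rank_sum(a, b) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact enumeration of the rank-sum distribution (with midranks for ties)
    when both groups have n <= 10; tie-corrected normal approximation
    otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    if n1 <= WILCOXON_EXACT_MAX_N and n2 <= WILCOXON_EXACT_MAX_N:
        ranks = _midranks(np.concatenate([a, b]))
        w_obs = ranks[:n1].sum()
        mu = ranks.sum() * n1 / (n1 + n2)
        dev_obs = abs(w_obs - mu)
        total = 0
        extreme = 0
        for idx in combinations(range(n1 + n2), n1):
            total += 1
            if abs(ranks[list(idx)].sum() - mu) >= dev_obs - 1e-9:
                extreme += 1
        return extreme / total
    stat = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(stat.pvalue)


def welch_test(a, b) -> float:
    """Welch's unequal-variance two-sample t-test, two-sided p-value."""
    res = sps.ttest_ind(np.asarray(a, float), np.asarray(b, float), equal_var=False)
    p = float(res.pvalue)
    return 1.0 if np.isnan(p) else p


@dataclass
class GroupComparison:
    descriptor: str
    groups: dict[str, GroupSummary]
    p_anova: float
    p_welch: dict[tuple[str, str], float]
    p_wilcoxon: dict[tuple[str, str], float]
    p_tukey: dict[tuple[str, str], float]
    q_values: dict[str, float] = field(default_factory=dict)
    significant: bool = False
    degenerate: bool = False


def compare_groups(groups: dict[str, list], descriptor: str = "value",
                   q_star: float = 0.05) -> GroupComparison:
    """Run the full comparison battery on named groups of numbers."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    names = sorted(groups)
    arrays = {g: np.asarray(groups[g], dtype=float) for g in names}
    for g, arr in arrays.items():
        if arr.size < 2:
            raise ValueError(f"group {g!r} needs n >= 2")
    summaries = {g: summarize_group(arr) for g, arr in arrays.items()}

    all_zero_var = all(arr.std(ddof=0) == 0 for arr in arrays.values())
    means = [arr.mean() for arr in arrays.values()]
    degenerate = all_zero_var and len(set(means)) == 1
    if degenerate:
        pair_one = {pair: 1.0 for pair in combinations(names, 2)}
        return GroupComparison(descriptor, summaries, 1.0, dict(pair_one),
                               dict(pair_one), dict(pair_one), degenerate=True)

    p_anova = float(sps.f_oneway(*[arrays[g] for g in names]).pvalue)
    p_welch = {}
    p_wilcoxon = {}
    for g1, g2 in combinations(names, 2):
        p_welch[(g1, g2)] = welch_test(arrays[g1], arrays[g2])
        p_wilcoxon[(g1, g2)] = wilcoxon_rank_sum(arrays[g1], arrays[g2])
    tukey = sps.tukey_hsd(*[arrays[g] for g in names])
    p_tukey = {
        (g1, g2): float(tukey.pvalue[names.index(g1), names.index(g2)])
        for g1, g2 in combinations(names, 2)
    }

    family = {"anova": p_anova}
    for (g1, g2), p in p_welch.items():
        family[f"welch:{g1}|{g2}"] = p
    for (g1, g2), p in p_wilcoxon.items():
        family[f"wilcoxon:{g1}|{g2}"] = p
    keys = sorted(family)
    qvals, flags = bh_adjust([family[k] for k in keys], q_star)
    q_map = dict(zip(keys, qvals))
    return GroupComparison(
        descriptor=descriptor,
        groups=summaries,
        p_anova=p_anova,
        p_welch=p_welch,
        p_wilcoxon=p_wilcoxon,
        p_tukey=p_tukey,
        q_values=q_map,
        significant=any(flags),
    )


def bh_adjust(pvalues, q_star: float = 0.05) -> tuple[list[float], list[bool]]:
    """Benjamini-Hochberg step-up q-values with monotonicity enforcement;
    reject when q <= q_star."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return [], []
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, alpha=q_star, method="fdr_bh")
    reject = q <= q_star
    return [float(v) for v in q], [bool(r) for r in reject]


def compare_profiles(
    frames: dict[str, pd.DataFrame], descriptors: list[str] | None = None,
    q_star: float = 0.05,
) -> pd.DataFrame:
    """Table-shaped comparison of property-profile frames by group.

    `frames` maps group name to a profile DataFrame (one row per compound);
    numeric columns shared by all groups are compared."""
    if descriptors is None:
        common = set.intersection(*(set(f.columns) for f in frames.values()))
        descriptors = sorted(
            c for c in common
            if c != "mol_id" and all(pd.api.types.is_numeric_dtype(f[c]) for f in frames.values())
        )
    rows = []
    for desc in descriptors:
        groups = {
            g: f[desc].dropna().tolist() for g, f in frames.items()
        }
        groups = {g: v for g, v in groups.items() if len(v) >= 2}
        if len(groups) < 2:
            continue
        cmp = compare_groups(groups, desc, q_star)
        row = {"descriptor": desc, "p_anova": cmp.p_anova,
               "significant_fdr5": cmp.significant, "degenerate": cmp.degenerate}
        for g, s in cmp.groups.items():
            row[f"{g}_n"] = s.n
            row[f"{g}_mean"] = s.mean
            row[f"{g}_median"] = s.median
            row[f"{g}_sd"] = s.sd
        for (g1, g2), p in cmp.p_welch.items():
            row[f"p_welch_{g1}_vs_{g2}"] = p
        for (g1, g2), p in cmp.p_wilcoxon.items():
            row[f"p_wilcoxon_{g1}_vs_{g2}"] = p
        for (g1, g2), p in cmp.p_tukey.items():
            row[f"p_tukey_{g1}_vs_{g2}"] = p
        rows.append(row)
    return pd.DataFrame(rows)


def density_summary(groups: dict[str, list], n_grid: int = 100) -> pd.DataFrame:
    """Kernel-density summary table (grid + density per group) for violin-style
    visualization; rendering is left to the caller."""
    rows = []
    for name in sorted(groups):
        arr = np.asarray(groups[name], dtype=float)
        if arr.size < 2 or arr.std(ddof=0) == 0:
            continue
        kde = sps.gaussian_kde(arr)
        grid = np.linspace(arr.min(), arr.max(), n_grid)
        dens = kde(grid)
        for g, d in zip(grid, dens):
            rows.append({"group": name, "grid": float(g), "density": float(d)})
    return pd.DataFrame(rows)
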