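"""Comparisons of plot-level responses among forest types.

One-way ANOVA with an LSD (least significant difference) post-hoc, a
Kruskal–Wallis fallback when group variances are unequal, and the compact
letter display used to annotate bar plots: groups sharing a letter do not
differ at the chosen alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupComparison",
    "one_way_anova_lsd",
    "kruskal_wallis",
    "variance_homogeneity_gate",
    "compare_groups",
    "compact_letter_display",
]


@dataclass
class GroupComparison:
    response: str
    test: str                      # "anova" | "kruskal"
    statistic: float               # F or H
    df: tuple
    p_value: float
    group_table: pd.DataFrame      # group, n, mean, se, letter
    pairwise_p: pd.DataFrame       # symmetric matrix of pairwise p-values
    letters: dict[str, str]
    alpha: float = 0.05
    transform: str | None = None
    notes: list[str] = field(default_factory=list)


def _split_groups(values, groups):
    s = pd.Series(np.asarray(values, dtype=float))
    g = pd.Series(list(groups))
    if len(s) != len(g):
        raise ValueError("values and groups must have equal length")
    by = {name: s[g.values == name].to_numpy() for name in pd.unique(g)}
    small = [name for name, v in by.items() if len(v) < 2]
    if len(by) < 2:
        raise ValueError("need at least 2 groups")
    if small:
        raise ValueError(f"groups with fewer than 2 observations: {small}")
    return by


def compact_letter_display(
    names: list, pairwise_p: pd.DataFrame, means: dict, alpha: float = 0.05
) -> dict:
    """Minimal letter assignment for a pairwise significance pattern.

    Insert-and-absorb: start from one column containing every group; for
    each significant pair split every column containing both; absorb
    columns that are subsets of another.  Groups are lettered in order of
    decreasing mean.
    """
    order = sorted(names, key=lambda n: (-means[n], str(n)))
    columns: list[set] = [set(order)]
    sig_pairs = [
        (a, b)
        for i, a in enumerate(order)
        for b in order[i + 1:]
        if pairwise_p.loc[a, b] < alpha
    ]
    for a, b in sig_pairs:
        for col in [c for c in columns if a in c and b in c]:
            columns.remove(col)
            columns.append(col - {a})
            columns.append(col - {b})
        # absorb: drop any column that is a subset of another
        columns = [
            c for c in columns
            if c and not any(c < other for other in columns)
        ]
        # deduplicate
        uniq = []
        for c in columns:
            if c not in uniq:
                uniq.append(c)
        columns = uniq
    columns.sort(key=lambda c: min(order.index(n) for n in c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {n: "" for n in order}
    for li, col in enumerate(columns):
        for n in order:
            if n in col:
                letters[n] += alphabet[li % len(alphabet)]
    return letters


def _finish(
    response, test, stat, df, p, by, pairwise, alpha, transform, notes
) -> GroupComparison:
    names = list(by)
    means = {n: float(np.mean(by[n])) for n in names}
    letters = compact_letter_display(names, pairwise, means, alpha)
    table = pd.DataFrame(
        {
            "group": names,
            "n": [len(by[n]) for n in names],
            "mean": [means[n] for n in names],
            "se": [float(np.std(by[n], ddof=1) / np.sqrt(len(by[n]))) for n in names],
            "letter": [letters[n] for n in names],
        }
    )
    return GroupComparison(
        response=response, test=test, statistic=float(stat), df=df,
        p_value=float(p), group_table=table, pairwise_p=pairwise,
        letters=letters, alpha=alpha, transform=transform, notes=notes,
    )


def one_way_anova_lsd(
    values, groups, alpha: float = 0.05, response: str = "response",
    transform: str | None = None,
) -> GroupComparison:
    """Classical one-way ANOVA with unadjusted LSD pairwise t-tests.

    The pairwise tests use the pooled mean squared error with N − k degrees
    of freedom; LSD is by definition unadjusted for multiplicity.
    """
    by = _split_groups(values, groups)
    names = list(by)
    k = len(names)
    N = sum(len(v) for v in by.values())

    F, p = stats.f_oneway(*by.values())
    if not np.isfinite(F):  # all values identical in every group
        F, p = 0.0, 1.0

    mse = sum(((v - v.mean()) ** 2).sum() for v in by.values()) / (N - k)
    pw = pd.DataFrame(np.ones((k, k)), index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            na, nb = len(by[a]), len(by[b])
            if mse == 0:
                pp = 1.0 if by[a].mean() == by[b].mean() else 0.0
            else:
                t = (by[a].mean() - by[b].mean()) / np.sqrt(mse * (1 / na + 1 / nb))
                pp = 2 * stats.t.sf(abs(t), N - k)
            pw.loc[a, b] = pw.loc[b, a] = pp
    return _finish(response, "anova", F, (k - 1, N - k), p, by, pw, alpha,
                   transform, [])


def kruskal_wallis(
    values, groups, alpha: float = 0.05, response: str = "response",
) -> GroupComparison:
    """Kruskal–Wallis H with tie correction and chi-square p (k−1 df).

    Pairwise p-values for the letter display come from unadjusted two-sided
    Mann–Whitney U tests.
    """
    by = _split_groups(values, groups)
    names = list(by)
    k = len(names)
    notes = []
    if np.ptp(np.concatenate(list(by.values()))) == 0:
        # all values identical: the tie correction divides by zero
        H, p = 0.0, 1.0
        notes.append("all values identical; H set to 0 (total ties)")
    else:
        H, p = stats.kruskal(*by.values())

    pw = pd.DataFrame(np.ones((k, k)), index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if np.ptp(np.concatenate([by[a], by[b]])) == 0:
                pp = 1.0
            else:
                pp = stats.mannwhitneyu(by[a], by[b], alternative="two-sided").pvalue
            pw.loc[a, b] = pw.loc[b, a] = pp
    return _finish(response, "kruskal", H, (k - 1,), p, by, pw, alpha, None, notes)


def variance_homogeneity_gate(
    values, groups, alpha: float = 0.05, response: str = "response",
) -> GroupComparison:
    """Test-choice gate: ANOVA when group variances are homogeneous,
    Kruskal–Wallis otherwise.

    Homogeneity is assessed with a Brown–Forsythe test (Levene on absolute
    deviations from group medians).  If raw values fail the gate and all are
    positive, a log transform is attempted first; the transformation used is
    recorded on the result.
    """
    by = _split_groups(values, groups)
    vals = np.asarray(values, dtype=float)

    def homogeneous(v) -> bool:
        arr = [np.asarray(v)[np.asarray(list(groups)) == n] for n in by]
        if all(np.ptp(a) == 0 for a in arr):
            return True
        try:
            _, p = stats.levene(*arr, center="median")
        except ValueError:
            return True
        return bool(p >= alpha)

    if homogeneous(vals):
        return one_way_anova_lsd(vals, groups, alpha=alpha, response=response)
    if (vals > 0).all():
        logged = np.log(vals)
        if homogeneous(logged):
            res = one_way_anova_lsd(logged, groups, alpha=alpha,
                                    response=response, transform="log")
            res.notes.append(
                "raw variances unequal (Brown-Forsythe); ANOVA run on log scale"
            )
            return res
    res = kruskal_wallis(vals, groups, alpha=alpha, response=response)
    res.notes.append(
        "unequal variances after transformation; Kruskal-Wallis used"
    )
    return res


def compare_groups(
    summary: pd.DataFrame,
    responses: list[str],
    group_col: str = "forest_type",
    alpha: float = 0.05,
) -> dict[str, GroupComparison]:
    """Run the gated comparison for each response column of a per-plot
    summary table; rows with missing values are dropped per response."""
    out = {}
    for resp in responses:
        sub = summary[[resp, group_col]].dropna()
        counts = sub[group_col].value_counts()
        if (counts >= 2).sum() < 2:
            # not enough data (e.g. a metric undefined for a whole stratum)
            continue
        sub = sub[sub[group_col].isin(counts.index[counts >= 2])]
        out[resp] = variance_homogeneity_gate(
            sub[resp].to_numpy(), sub[group_col].tolist(),
            alpha=alpha, response=resp,
        )
    return out
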