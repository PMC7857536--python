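"""Comparative statistics of protein features across stability groups.

Continuous features (isoelectric point, mass, percent disorder, node
connectivity, ...) are compared by one-way ANOVA with Tukey's HSD
post-hoc pairwise test (Tukey-Kramer at unequal group sizes); binary
motif features by a Pearson chi-square test of independence without
continuity correction. All p-values are Benjamini-Hochberg adjusted
across the tested features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .kinetics import bh_adjust


@dataclass
class GroupComparison:
    """ANOVA + Tukey result for one continuous feature."""

    feature: str
    group_n: dict[str, int]
    group_mean: dict[str, float]
    group_ci95: dict[str, tuple[float, float]]
    p_anova: float
    p_tukey: dict[tuple[str, str], float]
    q_anova: float | None = None


def anova_tukey(values, group_labels, feature: str = "") -> GroupComparison:
    """One-way ANOVA and Tukey HSD pairwise comparisons.

    Singleton groups are excluded with a warning (a within-group
    variance cannot be estimated from one observation). Group means
    carry normal-approximation 95% confidence intervals.
    """
    df = pd.DataFrame({"value": np.asarray(values, dtype=float),
                       "group": list(group_labels)}).dropna()
    sizes = df.groupby("group").size()
    singletons = sizes[sizes < 2].index.tolist()
    if singletons:
        warnings.warn(f"excluding singleton groups {singletons}")
        df = df[~df["group"].isin(singletons)]
    groups = sorted(df["group"].unique())
    if len(groups) < 2:
        raise ValueError("need at least two groups with >= 2 members")

    arrays = [df.loc[df["group"] == g, "value"].to_numpy() for g in groups]
    f_stat, p_anova = stats.f_oneway(*arrays)

    tukey = pairwise_tukeyhsd(df["value"].to_numpy(), df["group"].to_numpy())
    p_tukey = {}
    for (g1, g2), p in zip(
        [(tukey.groupsunique[i], tukey.groupsunique[j])
         for i, j in zip(*np.triu_indices(len(tukey.groupsunique), k=1))],
        tukey.pvalues,
    ):
        p_tukey[(str(g1), str(g2))] = float(p)

    group_n, group_mean, group_ci = {}, {}, {}
    for g, arr in zip(groups, arrays):
        m = float(arr.mean())
        sem = float(arr.std(ddof=1) / np.sqrt(len(arr)))
        group_n[g] = int(len(arr))
        group_mean[g] = m
        group_ci[g] = (m - 1.96 * sem, m + 1.96 * sem)

    return GroupComparison(
        feature=feature,
        group_n=group_n,
        group_mean=group_mean,
        group_ci95=group_ci,
        p_anova=float(p_anova),
        p_tukey=p_tukey,
    )


def chisq_binary(presence, group_labels) -> tuple[float, pd.DataFrame, bool]:
    """Pearson chi-square test of a binary feature across groups.

    Builds the 2 x k presence/absence-by-group contingency table and
    tests independence without continuity correction. Returns
    (p-value, expected-count table, degenerate flag); a table with a
    zero row or column is degenerate and yields p = 1. A warning is
    emitted when any expected count is below 5.
    """
    presence = np.asarray(presence).astype(int)
    if set(np.unique(presence)) - {0, 1}:
        raise ValueError("presence flags must be binary")
    table = pd.crosstab(presence, pd.Series(list(group_labels), name="group"))
    table = table.reindex(index=[0, 1], fill_value=0)
    obs = table.to_numpy()
    if (obs.sum(axis=1) == 0).any() or (obs.sum(axis=0) == 0).any():
        expected = pd.DataFrame(np.zeros_like(obs, dtype=float),
                                index=table.index, columns=table.columns)
        return 1.0, expected, True
    chi2, p, dof, expected = stats.chi2_contingency(obs, correction=False)
    if (expected < 5).any():
        warnings.warn("expected count below 5; chi-square approximation weak")
    expected = pd.DataFrame(expected, index=table.index, columns=table.columns)
    return float(p), expected, False


def compare_features(
    features: pd.DataFrame,
    labels,
    continuous: list[str] | None = None,
    binary: list[str] | None = None,
) -> pd.DataFrame:
    """Run the group comparisons over a feature table and BH-adjust.

    ``continuous`` features go through ANOVA+Tukey, ``binary`` features
    through the chi-square test; the omnibus p-values of all tested
    features are adjusted jointly. Returns a tidy table with one row per
    feature.
    """
    labels = list(labels)
    rows = []
    for name in continuous or []:
        cmp_ = anova_tukey(features[name], labels, feature=name)
        row = {"feature": name, "test": "anova", "p": cmp_.p_anova}
        for pair, p in cmp_.p_tukey.items():
            row[f"p_tukey_{pair[0]}_vs_{pair[1]}"] = p
        rows.append(row)
    for name in binary or []:
        p, _, degenerate = chisq_binary(features[name], labels)
        rows.append({"feature": name, "test": "chisq", "p": p,
                     "degenerate": degenerate})
    out = pd.DataFrame(rows)
    if len(out):
        out["q_bh"] = bh_adjust(out["p"].to_numpy())
    return out
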