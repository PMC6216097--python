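"""Diallel-cross comparisons and morphometrics.

The B6xD2 diallel (B6, D2, and reciprocal F1 hybrids) separates the
offspring's own genotype from parental contributions: the reciprocal F1s
B6D2F1 (B6 dam) and D2B6F1 (D2 dam) are genetically identical females-wise,
so a phenotypic difference between them points to maternal environment or
genomic imprinting, not to inherited alleles.

Group comparisons follow the study's twin-track convention: a rank-based
overall test (Kruskal-Wallis) with unadjusted pairwise Wilcoxon rank-sum
tests, alongside parametric Tukey HSD contrasts as the multiplicity-adjusted
alternative.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .io import CALL_TYPES

RECIPROCAL_F1S = ("B6D2F1", "D2B6F1")


@dataclass
class GroupComparisonResult:
    kruskal_statistic: float
    kruskal_p: float
    wilcoxon_p: pd.DataFrame  # symmetric matrix of unadjusted rank-sum p-values
    tukey_p: pd.DataFrame  # symmetric matrix of Tukey-adjusted p-values
    summary: pd.DataFrame  # per group: n, mean, sd, median


@dataclass
class ParentOfOriginResult:
    statistic: float
    p_value: float
    direction: int  # sign of mean(B6 dam) - mean(D2 dam)
    mean_b6_dam: float
    mean_d2_dam: float
    n_b6_dam: int
    n_d2_dam: int


@dataclass
class CallTypeProfile:
    per_subject: pd.DataFrame  # one row per subject: group + 10 percentages
    group_means: pd.DataFrame  # one row per group: mean percentage per type
    excluded_subjects: int


def group_comparison(
    table: pd.DataFrame, trait: str, grouping: str = "strain"
) -> GroupComparisonResult:
    """Overall and pairwise group tests on a quantitative trait.

    Wilcoxon pairwise p-values are reported unadjusted; Tukey HSD provides
    the adjusted parametric alternative. Requires >= 2 groups with >= 2
    observations each.
    """
    groups = {g: sub[trait].to_numpy(dtype=float) for g, sub in table.groupby(grouping)}
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    names = sorted(groups)
    stat, p = stats.kruskal(*(groups[g] for g in names))
    wil = pd.DataFrame(np.ones((len(names), len(names))), index=names, columns=names)
    for a, b in itertools.combinations(names, 2):
        pw = stats.mannwhitneyu(groups[a], groups[b], alternative="two-sided").pvalue
        wil.loc[a, b] = wil.loc[b, a] = pw
    tuk = pairwise_tukeyhsd(table[trait].to_numpy(dtype=float), table[grouping].to_numpy())
    tukey = pd.DataFrame(np.ones((len(names), len(names))), index=names, columns=names)
    for (a, b), padj in zip(
        itertools.combinations(tuk.groupsunique, 2), np.atleast_1d(tuk.pvalues)
    ):
        tukey.loc[a, b] = tukey.loc[b, a] = padj
    summary = (
        table.groupby(grouping)[trait]
        .agg(n="count", mean="mean", sd="std", median="median")
        .loc[names]
    )
    return GroupComparisonResult(
        kruskal_statistic=float(stat),
        kruskal_p=float(p),
        wilcoxon_p=wil,
        tukey_p=tukey,
        summary=summary,
    )


def parent_of_origin_test(
    table: pd.DataFrame, trait: str, females_only: bool = False
) -> ParentOfOriginResult:
    """Rank test between the reciprocal F1 groups.

    A significant difference between B6D2F1 and D2B6F1 (optionally females
    only, removing any Y-linked contribution) indicates a parental effect or
    imprinting. ``direction`` is the sign of the B6-dam-minus-D2-dam mean
    difference.
    """
    sub = table
    if females_only:
        sub = sub[sub["sex"] == "F"]
    a = sub.loc[sub["strain"] == "B6D2F1", trait].to_numpy(dtype=float)
    b = sub.loc[sub["strain"] == "D2B6F1", trait].to_numpy(dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("a reciprocal F1 group is absent or empty after filtering")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    diff = a.mean() - b.mean()
    return ParentOfOriginResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        direction=int(np.sign(diff)),
        mean_b6_dam=float(a.mean()),
        mean_d2_dam=float(b.mean()),
        n_b6_dam=len(a),
        n_d2_dam=len(b),
    )


def calltype_profile(
    table: pd.DataFrame, grouping: str = "strain", strict: bool = False
) -> CallTypeProfile:
    """Per-group call-category profiles as mean-of-ratios percentages.

    Each subject's ten counts are converted to percentages of that subject's
    own total, then averaged within groups (mean of ratios, not ratio of
    sums, so prolific callers do not dominate). Subjects with zero total
    calls are excluded with a warning, or raise when ``strict``.
    """
    missing = [c for c in CALL_TYPES if c not in table.columns]
    if missing:
        raise KeyError(f"call-type count columns missing: {missing}")
    counts = table[list(CALL_TYPES)].to_numpy(dtype=float)
    totals = counts.sum(axis=1)
    zero = totals == 0
    if zero.any():
        if strict:
            raise ValueError(f"{int(zero.sum())} subject(s) with zero total calls")
        warnings.warn(f"excluding {int(zero.sum())} subject(s) with zero total calls")
    keep = ~zero
    pct = 100.0 * counts[keep] / totals[keep, None]
    per_subject = pd.DataFrame(pct, columns=list(CALL_TYPES))
    per_subject.insert(0, grouping, table.loc[keep, grouping].to_numpy())
    group_means = per_subject.groupby(grouping)[list(CALL_TYPES)].mean()
    return CallTypeProfile(
        per_subject=per_subject,
        group_means=group_means,
        excluded_subjects=int(zero.sum()),
    )


def section_volume(areas: Sequence[float], spacing: float) -> float:
    """Structure volume from serial sections: sum(area_i) * spacing (mm^3).

    ``areas`` in mm^2, ``spacing`` (distance to the next section level) in mm.
    """
    areas = np.asarray(areas, dtype=float)
    if areas.size == 0:
        raise ValueError("need at least one area measurement")
    if spacing <= 0:
        raise ValueError("section spacing must be positive")
    return float(areas.sum() * spacing)
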