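"""Variance partition and heritability of vocalization traits.

Three related quantities are computed for an inbred panel:

* ``h2_full_model`` / ``H2_strain_only`` — the fraction of phenotypic sum of
  squares explained by strain in a sequential (type-I) ANOVA, with or
  without covariates. For fully inbred strains this is a broad-sense
  estimate (strain differences capture the whole genotypic value).
* ``HRIx2`` — the heritability of *strain means*,
  HRIx2 = Va / (Va + Ve/n), where Va is the between-strain variance
  component, Ve the within-strain variance, and n the number of within-line
  replicates. Because an inbred genome can be resampled, averaging n pups
  shrinks the environmental term by 1/n; this is the quantity that governs
  power to map strain-mean traits.

Va and Ve are extracted from the one-way ANOVA mean squares by the balanced
moment estimator, Va = (MS_strain - MS_within)/n_bar (floored at zero) with
n_bar the mean per-strain replicate count; Ve = MS_within.

Confidence intervals use the study's subsampling scheme: the estimator is
recomputed on many random subsets of a fixed fraction of the pups and the
2.5th/97.5th percentiles of the resampled values are reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .io import strain_means as _strain_means
from .simulate import (
    GeneticMap,
    SimConfig,
    hri2_target_strain_fraction,
    simulate_ri_genotypes,
    simulate_ri_phenotypes,
)

_CATEGORICAL = {"strain", "litter", "sex"}


@dataclass
class VarianceDecomposition:
    """Sequential ANOVA table with per-factor fractions of total SS."""

    table: pd.DataFrame  # index: factor (incl. Residual); columns sum_sq, df, mean_sq, F, p, fraction
    trait: str
    total_ss: float


@dataclass
class HeritabilityEstimate:
    estimator: str  # h2_full_model | H2_strain_only | HRIx2
    value: float
    va: float
    ve: float
    n: float
    day: int | None = None
    ci: tuple[float, float] | None = None
    subsamples: int | None = None


# ---------------------------------------------------------------------------
# ANOVA partition
# ---------------------------------------------------------------------------


def _term_for(factor: str, factors: Sequence[str], table: pd.DataFrame) -> str:
    if ":" in factor:
        return ":".join(_term_for(part, factors, table) for part in factor.split(":"))
    if factor == "litter" and "strain" in factors:
        # litters are nested within strains
        return "C(strain):C(litter)"
    if factor in _CATEGORICAL or table[factor].dtype == object:
        return f"C({factor})"
    return factor


def variance_partition(
    table: pd.DataFrame, trait: str, factors: Sequence[str]
) -> VarianceDecomposition:
    """Sequential (type-I) sums of squares in the caller's factor order.

    Categorical columns (strain, litter, sex) are treated as factors, with
    litter nested in strain when both appear; numeric columns (day, weight)
    enter as covariates. Fractions are computed against the total SS and
    sum to 1 including the residual.
    """
    y = table[trait].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("zero total variance")
    for f in factors:
        for part in f.split(":"):
            if part not in table.columns:
                raise KeyError(f"factor {part!r} not in table")
            if table[part].nunique() < 2:
                raise ValueError(f"factor {part!r} has a single level")
    data = table
    if "litter" in factors and "strain" in factors:
        # recode litters within strain so the nested term has the right df
        data = table.copy()
        data["litter"] = (
            data.groupby("strain")["litter"].transform(lambda s: pd.factorize(s)[0]).astype(str)
        )
    terms = [_term_for(f, list(factors), data) for f in factors]
    model = smf.ols(f"{trait} ~ " + " + ".join(terms), data=data).fit()
    anova = sm.stats.anova_lm(model, typ=1)
    anova = anova.rename(columns={"PR(>F)": "p"})
    anova["mean_sq"] = anova["sum_sq"] / anova["df"]
    total = float(anova["sum_sq"].sum())
    anova["fraction"] = anova["sum_sq"] / total
    anova = anova[["sum_sq", "df", "mean_sq", "F", "p", "fraction"]]
    return VarianceDecomposition(table=anova, trait=trait, total_ss=total)


def broad_h2(table: pd.DataFrame, trait: str, day: int | None = None) -> HeritabilityEstimate:
    """Broad-sense heritability H^2 = SS_strain / SS_total (strain-only ANOVA).

    Also extracts the variance components Va, Ve and the mean per-strain
    replicate count n_bar needed downstream for HRIx2. When ``day`` is None
    each pup contributes its across-day average.
    """
    sub = table if day is None else table[table["day"] == day]
    per_pup = sub.groupby(["strain", "litter", "pup"], sort=False)[trait].mean().reset_index()
    y = per_pup[trait].to_numpy(dtype=float)
    groups = per_pup["strain"].to_numpy()
    uniq, counts = np.unique(groups, return_counts=True)
    s, n_total = len(uniq), len(y)
    if s < 2:
        raise ValueError("need at least 2 strains")
    if n_total <= s:
        raise ValueError("need replicate pups within strains")
    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())
    if ss_total == 0:
        raise ValueError("zero total variance")
    means = np.array([y[groups == g].mean() for g in uniq])
    ss_strain = float((counts * (means - grand) ** 2).sum())
    ss_within = ss_total - ss_strain
    ms_strain = ss_strain / (s - 1)
    ms_within = ss_within / (n_total - s)
    n_bar = n_total / s
    va = max(0.0, (ms_strain - ms_within) / n_bar)
    return HeritabilityEstimate(
        estimator="H2_strain_only",
        value=ss_strain / ss_total,
        va=va,
        ve=ms_within,
        n=n_bar,
        day=day,
    )


def hri2(va: float, ve: float, n: float) -> float:
    """Heritability of strain means: HRIx2 = Va / (Va + Ve/n)."""
    if va < 0 or ve < 0:
        raise ValueError("variance components must be non-negative")
    if n < 1:
        raise ValueError("need at least one replicate per line")
    if va + ve == 0:
        raise ValueError("both variance components are zero")
    return va / (va + ve / n)


def hri2_estimate(table: pd.DataFrame, trait: str, day: int | None = None) -> HeritabilityEstimate:
    """HRIx2 from the one-way ANOVA moment components of a phenotype table."""
    base = broad_h2(table, trait, day=day)
    return HeritabilityEstimate(
        estimator="HRIx2",
        value=hri2(base.va, base.ve, base.n),
        va=base.va,
        ve=base.ve,
        n=base.n,
        day=day,
    )


# ---------------------------------------------------------------------------
# resampled confidence intervals and day averaging
# ---------------------------------------------------------------------------


def subsample_ci(
    table: pd.DataFrame,
    statistic: Callable[[pd.DataFrame], float],
    iterations: int = 1000,
    keep_fraction: float = 0.95,
    seed=None,
) -> tuple[float, float]:
    """Empirical CI by recomputing a statistic on random subsets of the pups.

    Each iteration draws floor(keep_fraction * N) rows uniformly without
    replacement (N = number of pup-day records) and re-evaluates the
    statistic; the 2.5th and 97.5th percentiles of the resampled values are
    returned. Deterministic under ``seed``.
    """
    if not 0.0 < keep_fraction <= 1.0:
        raise ValueError("keep_fraction must be in (0, 1]")
    if iterations < 100:
        raise ValueError("need at least 100 iterations")
    n = len(table)
    m = int(np.floor(keep_fraction * n))
    if m < 1:
        raise ValueError("subset too small for the statistic")
    rng = np.random.default_rng(seed)
    values = np.empty(iterations)
    for i in range(iterations):
        idx = rng.choice(n, size=m, replace=False)
        try:
            values[i] = statistic(table.iloc[idx])
        except ValueError as exc:
            raise ValueError(f"subset too small for the statistic: {exc}") from exc
    return float(np.percentile(values, 2.5)), float(np.percentile(values, 97.5))


def combine_across_days(
    estimates: Sequence[float], ses: Sequence[float | None]
) -> float:
    """Inverse-squared-error weighted mean of per-day heritability values.

    Entries with missing or non-positive SE are excluded.
    """
    if len(estimates) != len(ses):
        raise ValueError("estimates and ses must have equal length")
    num = den = 0.0
    for h, se in zip(estimates, ses):
        if se is None or not np.isfinite(se) or se <= 0:
            continue
        w = 1.0 / se**2
        num += h * w
        den += w
    if den == 0:
        raise ValueError("no usable entries (all SEs missing or non-positive)")
    return num / den


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------


@dataclass
class TraitDiagnostics:
    z_scores: np.ndarray
    theoretical_quantiles: np.ndarray  # ascending
    empirical_quantiles: np.ndarray  # ascending (sorted z-scores)
    max_gap: float  # largest successive empirical-quantile gap (bimodality hint)


def trait_diagnostics(values: Sequence[float]) -> TraitDiagnostics:
    """Z-scores and normal-probability-plot coordinates for strain means.

    The theoretical quantiles use the Blom plotting positions
    (i - 3/8)/(n + 1/4). The largest gap between successive sorted z-scores
    is returned as a crude bimodality indicator.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance input")
    z = (x - x.mean()) / sd
    emp = np.sort(z)
    n = len(x)
    theo = stats.norm.ppf((np.arange(1, n + 1) - 0.375) / (n + 0.25))
    return TraitDiagnostics(
        z_scores=z,
        theoretical_quantiles=theo,
        empirical_quantiles=emp,
        max_gap=float(np.diff(emp).max()),
    )


# ---------------------------------------------------------------------------
# power by simulation
# ---------------------------------------------------------------------------


@dataclass
class PowerEstimate:
    power: float
    mc_se: float
    replicates: int
    threshold_policy: str


def power_by_simulation(
    n_strains: int = 41,
    strain_mean_h2: float = 0.5,
    qtl_fraction: float = 0.5,
    alpha_policy: str | tuple[str, float] = "significant",
    replicates: int = 200,
    seed=0,
    gmap: GeneticMap | None = None,
    n_perm: int = 500,
    litters_per_strain: int = 3,
    pups_per_litter: int = 3,
    window_cm: float = 10.0,
) -> PowerEstimate:
    """Power to detect a QTL of given effect size by full-pipeline simulation.

    Each replicate simulates an RI panel (genotypes, then pup-level
    phenotypes with the causal marker carrying ``qtl_fraction`` of the
    genetic variance, the strain fraction chosen to give the target
    strain-mean heritability ``strain_mean_h2``), maps the strain means,
    and compares the causal-region maximum LRS (within ``window_cm`` of the
    planted marker) to the threshold. With ``qtl_fraction = 0`` there is no
    causal region and the genome-wide maximum is used, so the result is the
    genome-wide type-I error of the policy.

    ``alpha_policy``: "significant" (permutation genome-wide p < 0.05),
    "suggestive" (p < 0.63), or ("pointwise", alpha) using the chi-square
    1-df approximation of the pointwise null.
    """
    if not 0.0 <= strain_mean_h2 < 1.0 or not 0.0 <= qtl_fraction <= 1.0:
        raise ValueError("proportions must be in [0,1]")
    if replicates < 20:
        raise ValueError("too few replicates for a power estimate")
    if gmap is None:
        gmap = GeneticMap.regular(n_chromosomes=10, markers_per_chromosome=40, spacing_cm=2.0)
    n_reps_per_line = litters_per_strain * pups_per_litter
    f_strain = hri2_target_strain_fraction(strain_mean_h2, n_reps_per_line)
    # plant the QTL mid-chromosome 1
    chr1 = gmap.markers[gmap.markers["chrom"] == gmap.chromosomes()[0]]
    causal = chr1["marker"].iloc[len(chr1) // 2]
    causal_chrom = chr1["chrom"].iloc[0]
    causal_cm = float(chr1["cm"].iloc[len(chr1) // 2])

    from .scan import DosageGrid, _lrs_slope, _perm_max_lrs  # local import to avoid cycle

    marker_pos = gmap.markers
    in_window = (
        (marker_pos["chrom"] == causal_chrom)
        & ((marker_pos["cm"] - causal_cm).abs() <= window_cm)
    ).to_numpy()

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    hits = 0
    for child in ss.spawn(replicates):
        rngs = child.spawn(3)
        geno = simulate_ri_genotypes(n_strains, gmap, rngs[0])
        config = SimConfig(
            strain_background=f_strain,
            litter=0.0,
            maternal=0.0,
            residual=1.0 - f_strain,
            qtl=[(causal, qtl_fraction)] if qtl_fraction > 0 else [],
            litters_per_strain=litters_per_strain,
            pups_per_litter=pups_per_litter,
            days=(8,),
            day_effects=(0.0,),
            seed=rngs[1],
        )
        table = simulate_ri_phenotypes(geno, config)
        y = _strain_means(table, config.trait)
        x = geno.dosage()
        x = np.nan_to_num(x)
        yv = (
            y.set_index("strain")["value"].reindex(geno.strains).to_numpy(dtype=float)
        )
        lrs, _ = _lrs_slope(x, yv)
        if isinstance(alpha_policy, tuple):
            policy_name, alpha = alpha_policy
            if policy_name != "pointwise" or not 0 < alpha < 1:
                raise ValueError(f"bad alpha policy {alpha_policy!r}")
            threshold = float(stats.chi2.ppf(1 - alpha, 1))
        else:
            if alpha_policy not in ("significant", "suggestive"):
                raise ValueError(f"bad alpha policy {alpha_policy!r}")
            maxima = _perm_max_lrs(x, yv, n_perm, np.random.default_rng(rngs[2]))
            q = 0.95 if alpha_policy == "significant" else 0.37
            threshold = float(np.quantile(maxima, q))
        stat = lrs.max() if qtl_fraction == 0 else lrs[in_window].max()
        hits += int(stat > threshold)
    power = hits / replicates
    return PowerEstimate(
        power=power,
        mc_se=float(np.sqrt(power * (1 - power) / replicates)),
        replicates=replicates,
        threshold_policy=str(alpha_policy),
    )
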