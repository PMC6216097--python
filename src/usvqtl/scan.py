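"""Haley-Knott mapping of strain-mean traits in RI panels.

The scan regresses strain means on expected allele dosages at markers and
pseudomarkers, reports the likelihood-ratio statistic

    LRS = N * ln(RSS0 / RSS1),       LOD = LRS / 4.61,

calibrates genome-wide thresholds by permuting the strain means, delimits
1.5-LOD support intervals, locates peaks by bootstrap resampling of strains,
and offers a single-random-effect mixed model (EMMA-style spectral
decomposition of a kinship matrix) to absorb polygenic relatedness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .io import GenotypeMatrix
from .simulate import haldane_r, ri_expanded_r

#: divisor converting LRS to LOD
LRS_PER_LOD = 4.61

_MIN_STRAINS = 4


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class ScanResult:
    """Genome-scan track: one row per (pseudo)marker position.

    ``table`` columns: chrom, marker, mb, cm, lrs, lod, additive. The LOD
    column is LRS/4.61 at every position. ``thresholds`` holds the
    permutation LRS thresholds; ``peaks`` the :class:`QTLPeak` report.
    """

    table: pd.DataFrame
    thresholds: dict[str, float] | None = None
    peaks: list["QTLPeak"] | None = None

    def peak_index(self) -> int:
        """Row index of the genome-wide maximum (lowest coordinate on ties)."""
        return int(np.argmax(self.table["lrs"].to_numpy()))


@dataclass
class QTLPeak:
    chrom: str
    marker: str
    mb: float
    cm: float
    lrs: float
    lod: float
    significant: bool
    interval_mb: tuple[float, float]
    discordant_with: dict[str, int] = field(default_factory=dict)
    overlaps_sibling: bool = False
    bootstrap_counts: np.ndarray | None = None


@dataclass
class DosageGrid:
    """Expected allele dosages at markers and interpolated pseudomarkers.

    ``positions`` columns: marker, chrom, cm, mb, is_pseudo.
    ``values``: strains x positions array in [-1, +1] (B -> -1, D -> +1).
    """

    positions: pd.DataFrame
    values: np.ndarray
    strains: list[str]


@dataclass
class KinshipMatrix:
    values: np.ndarray
    strains: list[str]
    normalization: str = "centered_crossproduct_over_markers"

    def __post_init__(self) -> None:
        k = np.asarray(self.values, dtype=float)
        if k.ndim != 2 or k.shape[0] != k.shape[1] or k.shape[0] != len(self.strains):
            raise ValueError("kinship matrix must be square and match the strain list")
        if not np.allclose(k, k.T, atol=1e-8):
            raise ValueError("kinship matrix must be symmetric")
        self.values = k

    @property
    def trace(self) -> float:
        return float(np.trace(self.values))


# ---------------------------------------------------------------------------
# winsorization
# ---------------------------------------------------------------------------


def winsorize_means(means: pd.DataFrame, z_threshold: float = 2.5):
    """Winsorize outlying strain means before mapping.

    Values whose z-score (from the full set's mean and SD, ddof=1) exceeds
    the threshold in magnitude are replaced by the nearest retained value on
    the same side of the distribution. Returns the adjusted table and a
    change log of ``{"strain", "old", "new"}`` dicts.
    """
    if len(means) < 3:
        raise ValueError("need at least 3 strains to winsorize")
    values = means["value"].to_numpy(dtype=float)
    mu, sd = values.mean(), values.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance: nothing to winsorize")
    z = (values - mu) / sd
    outlier = np.abs(z) > z_threshold
    retained = values[~outlier]
    if outlier.any() and retained.size == 0:
        raise ValueError("all values flagged as outliers")
    adjusted = values.copy()
    log = []
    for i in np.flatnonzero(outlier):
        new = retained.max() if z[i] > 0 else retained.min()
        log.append({"strain": means["strain"].iloc[i], "old": float(values[i]), "new": float(new)})
        adjusted[i] = new
    out = means.copy()
    out["value"] = adjusted
    return out, log


def render_change_log(log: Sequence[dict]) -> str:
    """Render a winsorization log as 'STRAIN from OLD to NEW' clauses."""
    return "; ".join(f"{e['strain']} from {e['old']:g} to {e['new']:g}" for e in log)


# ---------------------------------------------------------------------------
# dosages
# ---------------------------------------------------------------------------


def _transition(prob_same: np.ndarray, state_is_d: np.ndarray) -> np.ndarray:
    """P(target = D | source state) for a two-state RI chain."""
    return np.where(state_is_d, prob_same, 1.0 - prob_same)


def expected_dosages(
    geno: GenotypeMatrix, step_cm: float = 1.0, method: str = "ri_markov"
) -> DosageGrid:
    """Expected allele dosage at markers and at a pseudomarker grid.

    At genotyped markers the dosage is exactly +-1 (H/U missing calls are
    mean-imputed per position). Pseudomarkers are inserted every ``step_cm``
    between flanking markers; their dosage is the conditional expectation
    given the flanks under the two-state RI chain with expanded
    recombination fractions R = 4r/(1+6r) (``method="ri_markov"``) or simple
    linear interpolation in cM (``method="interpolate"``).
    """
    if step_cm <= 0:
        raise ValueError("step must be positive")
    if method not in ("ri_markov", "interpolate"):
        raise ValueError(f"unknown method {method!r}")
    strains = geno.strains
    marker_dosage = geno.dosage()  # strains x markers with NaN for H/U
    col_mean = np.nanmean(np.where(np.isnan(marker_dosage), np.nan, marker_dosage), axis=0)
    col_mean = np.nan_to_num(col_mean)  # all-missing marker -> 0

    pos_rows = []
    cols = []
    idx = 0
    for chrom, grp in geno.markers.groupby("chrom", sort=False):
        if len(grp) < 1:
            raise ValueError(f"chromosome {chrom} has no markers")
        g_idx = grp.index.to_numpy()
        cm = grp["cm"].to_numpy()
        mb = grp["mb"].to_numpy()
        names = grp["marker"].to_numpy()
        for j in range(len(grp)):
            d = marker_dosage[:, g_idx[j]].copy()
            d[np.isnan(d)] = col_mean[g_idx[j]]
            pos_rows.append((names[j], chrom, cm[j], mb[j], False))
            cols.append(d)
            if j + 1 < len(grp):
                gap = cm[j + 1] - cm[j]
                n_pseudo = int(np.floor((gap - 1e-9) / step_cm))
                left = marker_dosage[:, g_idx[j]]
                right = marker_dosage[:, g_idx[j + 1]]
                left = np.where(np.isnan(left), col_mean[g_idx[j]], left)
                right = np.where(np.isnan(right), col_mean[g_idx[j + 1]], right)
                for k in range(1, n_pseudo + 1):
                    dcm = k * step_cm
                    frac = dcm / gap
                    pmb = mb[j] + frac * (mb[j + 1] - mb[j])
                    if method == "interpolate":
                        dose = left * (1 - frac) + right * frac
                    else:
                        dose = _ri_conditional_dosage(left, right, dcm, gap - dcm)
                    pos_rows.append((f"{names[j]}+{dcm:g}cM", chrom, cm[j] + dcm, pmb, True))
                    cols.append(dose)
            idx += 1
    positions = pd.DataFrame(pos_rows, columns=["marker", "chrom", "cm", "mb", "is_pseudo"])
    return DosageGrid(positions=positions, values=np.column_stack(cols), strains=strains)


def _ri_conditional_dosage(left: np.ndarray, right: np.ndarray, d_left: float, d_right: float) -> np.ndarray:
    """E[dosage] at a point between two flanking markers.

    Treats observed dosages as P(D) = (d+1)/2, composes the two-state chain
    with flip probabilities R(d_left), R(d_right), and conditions on both
    flanks. Works for fractional (mean-imputed) flank dosages too.
    """
    rl = float(ri_expanded_r(haldane_r(d_left)))
    rr = float(ri_expanded_r(haldane_r(d_right)))
    p_left_d = (left + 1.0) / 2.0
    p_right_d = (right + 1.0) / 2.0
    # P(mid=D | flanks): mixture over flank states weighted by their probs
    #   numerator_D = sum over l,r of P(l) P(r) P(l->D) P(D->r)
    pl_same = 1.0 - rl
    pr_same = 1.0 - rr
    num_d = (
        p_left_d * pl_same + (1 - p_left_d) * rl
    ) * (p_right_d * pr_same + (1 - p_right_d) * rr)
    num_b = (
        p_left_d * rl + (1 - p_left_d) * pl_same
    ) * (p_right_d * rr + (1 - p_right_d) * pr_same)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_d = np.where(num_d + num_b > 0, num_d / (num_d + num_b), 0.5)
    return 2.0 * p_d - 1.0


# ---------------------------------------------------------------------------
# core regression scan
# ---------------------------------------------------------------------------


def _align(dosages: DosageGrid, y: pd.DataFrame):
    """Match strain means to dosage rows; drop strains without phenotype."""
    lookup = dict(zip(y["strain"].astype(str), y["value"].astype(float)))
    keep, vals = [], []
    for i, strain in enumerate(dosages.strains):
        if strain in lookup and np.isfinite(lookup[strain]):
            keep.append(i)
            vals.append(lookup[strain])
    if len(keep) < _MIN_STRAINS:
        raise ValueError(f"need at least {_MIN_STRAINS} strains with phenotype and genotype")
    return dosages.values[keep, :], np.asarray(vals)


def _lrs_slope(x: np.ndarray, yv: np.ndarray):
    """Vectorized per-column regression statistics.

    Returns (lrs, slope) arrays; columns with (near-)zero dosage variance
    get LRS = 0 and slope = 0.
    """
    n = len(yv)
    yc = yv - yv.mean()
    syy = float(yc @ yc)
    xc = x - x.mean(axis=0, keepdims=True)
    sxx = np.einsum("ij,ij->j", xc, xc)
    sxy = yc @ xc
    ok = sxx > 1e-12
    r2 = np.zeros_like(sxx)
    slope = np.zeros_like(sxx)
    if syy > 0:
        r2[ok] = (sxy[ok] ** 2) / (sxx[ok] * syy)
    slope[ok] = sxy[ok] / sxx[ok]
    r2 = np.clip(r2, 0.0, 1.0 - 1e-12)
    lrs = -n * np.log1p(-r2)
    return lrs, slope


def hk_scan(dosages: DosageGrid, y: pd.DataFrame) -> ScanResult:
    """Haley-Knott regression of strain means on expected dosages.

    ``y`` is a strain-mean table (columns strain, value). Per position the
    statistic is LRS = N ln(RSS0/RSS1) for the intercept+slope model; the
    additive coefficient is the slope under +-1 coding, i.e. half the
    D-minus-B class difference.
    """
    x, yv = _align(dosages, y)
    lrs, slope = _lrs_slope(x, yv)
    table = dosages.positions[["chrom", "marker", "mb", "cm"]].copy()
    table["lrs"] = lrs
    table["lod"] = lrs / LRS_PER_LOD
    table["additive"] = slope
    return ScanResult(table=table[["chrom", "marker", "mb", "cm", "lrs", "lod", "additive"]])


def permutation_thresholds(
    dosages: DosageGrid, y: pd.DataFrame, n_perm: int = 5000, seed=None
) -> dict[str, float]:
    """Genome-wide LRS thresholds from permutations of the strain means.

    ``significant`` is the 95th percentile (genome-wide p < 0.05) and
    ``suggestive`` the 37th percentile (genome-wide p < 0.63, about one
    false QTL per scan) of the per-permutation maximum LRS.
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    x, yv = _align(dosages, y)
    maxima = _perm_max_lrs(x, yv, n_perm, np.random.default_rng(seed))
    return {
        "significant": float(np.quantile(maxima, 0.95)),
        "suggestive": float(np.quantile(maxima, 0.37)),
    }


def _perm_max_lrs(x: np.ndarray, yv: np.ndarray, n_perm: int, rng) -> np.ndarray:
    n = len(yv)
    order = np.argsort(rng.random((n_perm, n)), axis=1)
    yp = yv[order]
    yp_c = yp - yp.mean(axis=1, keepdims=True)
    syy = np.einsum("ij,ij->i", yp_c, yp_c)
    xc = x - x.mean(axis=0, keepdims=True)
    sxx = np.einsum("ij,ij->j", xc, xc)
    sxy = yp_c @ xc  # n_perm x positions
    ok = sxx > 1e-12
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(ok[None, :], sxy**2 / (sxx[None, :] * syy[:, None]), 0.0)
    r2 = np.clip(np.nan_to_num(r2), 0.0, 1.0 - 1e-12)
    return (-n * np.log1p(-r2)).max(axis=1)


# ---------------------------------------------------------------------------
# support intervals, bootstrap, peaks
# ---------------------------------------------------------------------------


def lod_support_interval(
    scan: ScanResult, peak: int | str, drop: float = 1.5
) -> tuple[float, float]:
    """1.5-LOD-drop support interval around a peak, in Mb.

    Walks out from the peak over contiguous positions on its chromosome
    while LOD >= peak LOD - drop; the interval is truncated at chromosome
    ends. ``peak`` is a row index or marker name.
    """
    table = scan.table
    if isinstance(peak, str):
        hits = np.flatnonzero(table["marker"].to_numpy() == peak)
        if hits.size == 0:
            raise KeyError(f"peak position {peak!r} not in scan")
        p = int(hits[0])
    else:
        p = int(peak)
        if not 0 <= p < len(table):
            raise KeyError("peak index outside scan")
    chrom = table["chrom"].iloc[p]
    on_chr = np.flatnonzero((table["chrom"] == chrom).to_numpy())
    lod = table["lod"].to_numpy()
    cutoff = lod[p] - drop
    pos_in_chr = int(np.flatnonzero(on_chr == p)[0])
    lo = pos_in_chr
    while lo - 1 >= 0 and lod[on_chr[lo - 1]] >= cutoff:
        lo -= 1
    hi = pos_in_chr
    while hi + 1 < len(on_chr) and lod[on_chr[hi + 1]] >= cutoff:
        hi += 1
    mb = table["mb"].to_numpy()
    return float(mb[on_chr[lo]]), float(mb[on_chr[hi]])


def bootstrap_peaks(
    dosages: DosageGrid, y: pd.DataFrame, n_boot: int = 2000, seed=None
) -> np.ndarray:
    """Bootstrap the genome-wide peak location.

    Strains are resampled with replacement ``n_boot`` times, the scan is
    recomputed, and the peak position index is tallied. Returns an integer
    array aligned to ``dosages.positions`` whose entries sum to ``n_boot``;
    ties go to the lowest-coordinate position.
    """
    if n_boot < 100:
        raise ValueError("need at least 100 bootstrap resamples")
    x, yv = _align(dosages, y)
    rng = np.random.default_rng(seed)
    n = len(yv)
    counts = np.zeros(x.shape[1], dtype=int)
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        lrs, _ = _lrs_slope(x[idx], yv[idx])
        counts[int(np.argmax(lrs))] += 1
    return counts


# ---------------------------------------------------------------------------
# kinship and mixed model
# ---------------------------------------------------------------------------


def kinship_matrix(geno: GenotypeMatrix) -> KinshipMatrix:
    """Centered genotype cross-product relatedness (GEMMA-style).

    Marker dosages are mean-imputed (H/U), column-centered, and the
    strains x strains cross-product is divided by the marker count —
    symmetric and positive semidefinite by construction.
    """
    if len(geno.strains) < 2 or geno.n_markers < 2:
        raise ValueError("need at least 2 strains and 2 markers")
    d = geno.dosage()
    all_missing = np.isnan(d).all(axis=0)
    if all_missing.any():
        bad = geno.markers["marker"].iloc[int(np.flatnonzero(all_missing)[0])]
        raise ValueError(f"marker {bad!r} has no genotyped strain")
    col_mean = np.nanmean(d, axis=0)
    filled = np.where(np.isnan(d), col_mean[None, :], d)
    z = filled - filled.mean(axis=0, keepdims=True)
    k = (z @ z.T) / z.shape[1]
    return KinshipMatrix(values=k, strains=geno.strains)


def kinship_lmm_scan(
    dosages: DosageGrid, y: pd.DataFrame, kinship: KinshipMatrix, per_marker_opt: bool = False
) -> ScanResult:
    """Mixed-model scan y = dosage*beta + u + e with cov(u) proportional to K.

    The variance ratio delta = Ve/Vg is estimated once under the null by
    restricted likelihood on the spectral decomposition of K, then each
    position is tested by a generalized-least-squares likelihood ratio on
    the rotated data, reported on the LRS scale. ``per_marker_opt`` re-fits
    delta under each marker's alternative model (slower, exact).
    """
    lookup = {s: i for i, s in enumerate(kinship.strains)}
    if set(dosages.strains) - set(kinship.strains):
        raise ValueError("kinship matrix does not cover all genotyped strains")
    x, yv = _align(dosages, y)
    # _align keeps dosage-strain order; select matching K rows
    ylook = dict(zip(y["strain"].astype(str), y["value"].astype(float)))
    kept = [s for s in dosages.strains if s in ylook and np.isfinite(ylook[s])]
    kidx = [lookup[s] for s in kept]
    k = kinship.values[np.ix_(kidx, kidx)]
    eigval, eigvec = np.linalg.eigh(k)
    if eigval.min() < -1e-6 * max(1.0, abs(eigval.max())):
        raise ValueError("kinship matrix is not positive semidefinite")
    eigval = np.clip(eigval, 0.0, None)
    n = len(yv)
    ystar = eigvec.T @ yv
    onestar = eigvec.T @ np.ones(n)
    xstar = eigvec.T @ x

    def reml_criterion(log_delta: float) -> float:
        w = 1.0 / (eigval + np.exp(log_delta))
        sxx = float(w @ onestar**2)
        beta = float(w @ (onestar * ystar)) / sxx
        rss = float(w @ (ystar - beta * onestar) ** 2)
        return (n - 1) * np.log(rss / (n - 1)) + float(np.log(eigval + np.exp(log_delta)).sum()) + np.log(sxx)

    res = minimize_scalar(reml_criterion, bounds=(-10.0, 10.0), method="bounded")
    delta = float(np.exp(res.x))

    def gls_stats(dlt: float):
        w = 1.0 / (eigval + dlt)
        sw = np.sqrt(w)
        a0 = sw * onestar
        yw = sw * ystar
        xw = sw[:, None] * xstar
        # residualize on the (rotated, weighted) intercept
        a0n = a0 / np.linalg.norm(a0)
        yt = yw - a0n * (a0n @ yw)
        xt = xw - np.outer(a0n, a0n @ xw)
        rss0 = float(yt @ yt)
        sxx = np.einsum("ij,ij->j", xt, xt)
        sxy = yt @ xt
        ok = sxx > 1e-12
        gain = np.zeros_like(sxx)
        gain[ok] = sxy[ok] ** 2 / sxx[ok]
        rss1 = np.maximum(rss0 - gain, 1e-12 * max(rss0, 1.0))
        slope = np.where(ok, sxy / np.where(ok, sxx, 1.0), 0.0)
        return rss0, rss1, slope

    if per_marker_opt:
        lrs = np.zeros(x.shape[1])
        slope = np.zeros(x.shape[1])
        rss0_null, _, _ = gls_stats(delta)
        for j in range(x.shape[1]):
            xj = xstar[:, j]

            def alt_crit(log_delta: float, xj=xj) -> float:
                w = 1.0 / (eigval + np.exp(log_delta))
                design = np.column_stack([onestar, xj])
                wd = w[:, None] * design
                xtx = design.T @ wd
                beta = np.linalg.lstsq(xtx, design.T @ (w * ystar), rcond=None)[0]
                resid = ystar - design @ beta
                rss = float(w @ resid**2)
                return n * np.log(rss / n) + float(np.log(eigval + np.exp(log_delta)).sum())

            rj = minimize_scalar(alt_crit, bounds=(-10.0, 10.0), method="bounded")
            _, rss1_j, slope_j = gls_stats(float(np.exp(rj.x)))
            lrs[j] = n * np.log(rss0_null / rss1_j[j])
            slope[j] = slope_j[j]
    else:
        rss0, rss1, slope = gls_stats(delta)
        lrs = n * np.log(rss0 / rss1)
    lrs = np.maximum(lrs, 0.0)
    table = dosages.positions[["chrom", "marker", "mb", "cm"]].copy()
    table["lrs"] = lrs
    table["lod"] = lrs / LRS_PER_LOD
    table["additive"] = slope
    return ScanResult(table=table[["chrom", "marker", "mb", "cm", "lrs", "lod", "additive"]])


# ---------------------------------------------------------------------------
# peak report
# ---------------------------------------------------------------------------


def peak_report(
    scan: ScanResult,
    thresholds: dict[str, float],
    geno: GenotypeMatrix | None = None,
    drop: float = 1.5,
) -> list[QTLPeak]:
    """Peaks above the suggestive threshold, with sibling-peak diagnostics.

    Contiguous supra-suggestive runs are split wherever the profile dips
    below the suggestive line; each run contributes one peak (its maximum,
    lowest coordinate on ties). For sibling peaks on one chromosome the
    count of strains carrying opposite parental alleles at the two peak
    markers is reported (the two-independent-QTL argument), and overlapping
    support intervals are flagged.
    """
    table = scan.table
    suggestive = thresholds["suggestive"]
    significant = thresholds.get("significant", np.inf)
    lrs = table["lrs"].to_numpy()
    peaks: list[QTLPeak] = []
    for chrom in dict.fromkeys(table["chrom"]):
        on_chr = np.flatnonzero((table["chrom"] == chrom).to_numpy())
        above = lrs[on_chr] >= suggestive
        i = 0
        while i < len(on_chr):
            if not above[i]:
                i += 1
                continue
            j = i
            while j + 1 < len(on_chr) and above[j + 1]:
                j += 1
            run = on_chr[i : j + 1]
            best = run[int(np.argmax(lrs[run]))]
            interval = lod_support_interval(scan, int(best), drop=drop)
            peaks.append(
                QTLPeak(
                    chrom=str(chrom),
                    marker=table["marker"].iloc[best],
                    mb=float(table["mb"].iloc[best]),
                    cm=float(table["cm"].iloc[best]),
                    lrs=float(lrs[best]),
                    lod=float(lrs[best] / LRS_PER_LOD),
                    significant=bool(lrs[best] >= significant),
                    interval_mb=interval,
                )
            )
            i = j + 1
    # sibling diagnostics per chromosome
    by_chr: dict[str, list[QTLPeak]] = {}
    for pk in peaks:
        by_chr.setdefault(pk.chrom, []).append(pk)
    for chrom, sibs in by_chr.items():
        if len(sibs) < 2:
            continue
        for a in sibs:
            for b in sibs:
                if a is b:
                    continue
                if _intervals_overlap(a.interval_mb, b.interval_mb):
                    a.overlaps_sibling = True
                if geno is not None:
                    a.discordant_with[b.marker] = _discordant_count(geno, a, b)
    return peaks


def _intervals_overlap(a: tuple[float, float], b: tuple[float, float]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def _nearest_genotyped_marker(geno: GenotypeMatrix, chrom: str, mb: float) -> str:
    grp = geno.markers[geno.markers["chrom"] == chrom]
    if grp.empty:
        raise KeyError(f"no genotyped markers on chromosome {chrom}")
    i = (grp["mb"] - mb).abs().idxmin()
    return grp.loc[i, "marker"]


def _discordant_count(geno: GenotypeMatrix, a: QTLPeak, b: QTLPeak) -> int:
    ma = _nearest_genotyped_marker(geno, a.chrom, a.mb)
    mb_ = _nearest_genotyped_marker(geno, b.chrom, b.mb)
    ca = geno.codes.loc[ma]
    cb = geno.codes.loc[mb_]
    mask = ca.isin(["B", "D"]) & cb.isin(["B", "D"])
    return int(((ca != cb) & mask).sum())
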