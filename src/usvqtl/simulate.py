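"""Synthetic data with the variance structure the analysis assumes.

Three generators stand in for the study's raw material:

* RI-panel genotypes: each strain is a homozygous mosaic of the two parental
  alleles (B/D). Along a chromosome the allele sequence follows a two-state
  chain whose adjacent-marker discordance is the Haldane-Waddington
  expansion R = 4r/(1+6r) of the Haldane recombination fraction r implied by
  the cM gap — the standard model for sib-mated recombinant inbred lines.
* RI phenotypes: pup value = grand mean + QTL additive effects + polygenic
  strain deviate + litter deviate + maternal (dam) deviate + day shift +
  residual, with each component scaled so its realized variance fraction
  matches the configuration in expectation. Litters are nested in strains
  and every pup is measured on all configured days.
* Diallel families: the four groups B6, D2 and the reciprocal hybrids
  B6D2F1 / D2B6F1. The reciprocals share their nuclear genetic value by
  construction and differ only through the dam's maternal deviation and a
  signed parent-of-origin deviation, so E[B6D2F1 - D2B6F1] =
  (maternal_B6 - maternal_D2) + 2 * parent_of_origin.

Call-type counts are multinomial draws over the ten call categories.

A single seed drives everything; sub-generators are spawned deterministically
from it via :class:`numpy.random.SeedSequence`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import CALL_TYPES, GenotypeMatrix, QUANT_TRAITS

DIALLEL_GROUPS = ("B6", "D2", "B6D2F1", "D2B6F1")

#: realistic baselines for the four quantitative traits (used to fill the
#: non-focal trait columns so tables look like real recordings)
TRAIT_BASELINES = {
    "n_calls": (90.0, 25.0),
    "duration_ms": (30.0, 8.0),
    "frequency_khz": (62.0, 4.0),
    "amplitude_db": (-30.0, 5.0),
}


def haldane_r(d_cm: np.ndarray | float) -> np.ndarray | float:
    """Recombination fraction from map distance (Haldane, no interference)."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=float) / 100.0))


def ri_expanded_r(r: np.ndarray | float) -> np.ndarray | float:
    """RI-by-sib-mating expansion R = 4r/(1+6r) of a recombination fraction."""
    r = np.asarray(r, dtype=float)
    return 4.0 * r / (1.0 + 6.0 * r)


@dataclass(frozen=True)
class GeneticMap:
    """Ordered marker coordinates (cM and Mb) per chromosome."""

    markers: pd.DataFrame  # columns: marker, chrom, cm, mb

    def __post_init__(self) -> None:
        required = {"marker", "chrom", "cm", "mb"}
        if not required.issubset(self.markers.columns):
            raise ValueError(f"map needs columns {sorted(required)}")
        if len(self.markers) == 0:
            raise ValueError("empty genetic map")
        if self.markers["marker"].duplicated().any():
            raise ValueError("marker names must be unique genome-wide")
        for _, grp in self.markers.groupby("chrom", sort=False):
            if (np.diff(grp["cm"].to_numpy()) < 0).any():
                raise ValueError("cM positions must be non-decreasing within a chromosome")

    @classmethod
    def regular(
        cls,
        n_chromosomes: int = 19,
        markers_per_chromosome: int = 53,
        spacing_cm: float = 1.5,
        mb_per_cm: float = 1.86,
        mb_offset: float = 3.0,
    ) -> "GeneticMap":
        """Evenly spaced stylized autosomal map (default ~1000 markers,
        ~78 cM per chromosome — a mouse-like genome)."""
        rows = []
        for c in range(1, n_chromosomes + 1):
            for m in range(markers_per_chromosome):
                cm = float(m * spacing_cm)
                rows.append((f"c{c}m{m:03d}", str(c), cm, mb_offset + cm * mb_per_cm))
        return cls(pd.DataFrame(rows, columns=["marker", "chrom", "cm", "mb"]))

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.markers["chrom"]))


def simulate_ri_genotypes(n_strains: int, gmap: GeneticMap, seed) -> GenotypeMatrix:
    """Simulate fully inbred RI genotypes over a genetic map.

    Per chromosome the first marker is B or D with probability 1/2 and
    adjacent markers disagree with probability R = 4r/(1+6r), r Haldane from
    the cM gap. No heterozygous or unknown calls are emitted.
    """
    if n_strains < 2:
        raise ValueError("need at least 2 strains")
    rng = np.random.default_rng(seed)
    blocks = []
    for _, grp in gmap.markers.groupby("chrom", sort=False):
        cm = grp["cm"].to_numpy()
        big_r = ri_expanded_r(haldane_r(np.diff(cm)))
        first = rng.integers(0, 2, size=n_strains)
        if len(cm) > 1:
            flips = rng.random((n_strains, len(cm) - 1)) < big_r
            states = (first[:, None] + np.cumsum(flips, axis=1)) % 2
            chrom_states = np.column_stack([first, states])
        else:
            chrom_states = first[:, None]
        blocks.append(chrom_states)
    states = np.concatenate(blocks, axis=1)  # strains x markers, 0=B 1=D
    letters = np.where(states == 1, "D", "B")
    strains = [f"SIM{i + 1:03d}" for i in range(n_strains)]
    codes = pd.DataFrame(
        letters.T,
        index=pd.Index(gmap.markers["marker"], name="marker"),
        columns=strains,
    )
    return GenotypeMatrix(markers=gmap.markers.reset_index(drop=True), codes=codes)


@dataclass
class SimConfig:
    """Variance structure and replicate design for an RI phenotype simulation.

    Fractions are of ``total_variance``; QTL fractions are of the
    strain-level (genetic) variance, i.e. nested inside ``strain_background``.
    ``day_effects`` are fixed shifts, one per recording day — the defaults
    put roughly 1% of the variance on age. ``pup_repeatability`` is the
    share of the residual that persists within a pup across days (default 0:
    no day-to-day correlation beyond strain/litter structure).
    """

    strain_background: float = 0.4
    litter: float = 0.3
    maternal: float = 0.0
    residual: float = 0.29
    qtl: list[tuple[str, float]] = field(default_factory=list)
    litters_per_strain: int = 3
    pups_per_litter: int = 3
    days: tuple[int, ...] = (7, 8, 9)
    day_effects: tuple[float, ...] | None = (-0.12, 0.0, 0.12)
    pup_repeatability: float = 0.0
    grand_mean: float = 0.0
    total_variance: float = 1.0
    trait: str = "amplitude_db"
    seed: int = 0

    def validate(self, geno: GenotypeMatrix | None = None) -> None:
        fracs = {
            "strain_background": self.strain_background,
            "litter": self.litter,
            "maternal": self.maternal,
            "residual": self.residual,
        }
        for name, val in fracs.items():
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"variance fraction {name}={val} outside [0,1]")
        if sum(fracs.values()) > 1.0 + 1e-9:
            raise ValueError("variance fractions sum to more than 1")
        qsum = 0.0
        for marker, frac in self.qtl:
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"QTL fraction {frac} outside [0,1]")
            qsum += frac
            if geno is not None and marker not in set(geno.markers["marker"]):
                raise ValueError(f"QTL marker {marker!r} absent from genotypes")
        if qsum > 1.0 + 1e-9:
            raise ValueError("QTL fractions exceed the strain-level variance")
        if self.day_effects is not None and len(self.day_effects) != len(self.days):
            raise ValueError("day_effects must match days in length")
        if not 0.0 <= self.pup_repeatability <= 1.0:
            raise ValueError("pup_repeatability outside [0,1]")


def simulate_ri_phenotypes(geno: GenotypeMatrix, config: SimConfig) -> pd.DataFrame:
    """Simulate a pup-level phenotype table on top of RI genotypes.

    Returns one row per pup per day with the focal trait generated from the
    configured variance components; the other quantitative trait columns are
    filled with baseline noise so the table is structurally complete.
    """
    config.validate(geno)
    rng = np.random.default_rng(config.seed)
    strains = geno.strains
    s = len(strains)
    v = config.total_variance
    qsum = sum(frac for _, frac in config.qtl)

    # per-strain genetic value: QTL additive effects + polygenic remainder
    genetic = np.zeros(s)
    marker_index = {m: i for i, m in enumerate(geno.markers["marker"])}
    dosage = geno.dosage()  # strains x markers, +-1
    for marker, frac in config.qtl:
        a = np.sqrt(frac * config.strain_background * v)
        d = dosage[:, marker_index[marker]]
        genetic += a * np.nan_to_num(d)
    genetic += rng.normal(0.0, np.sqrt(max(0.0, (1 - qsum) * config.strain_background * v)), s)

    day_fx = dict(zip(config.days, config.day_effects or [0.0] * len(config.days)))
    sd_litter = np.sqrt(config.litter * v)
    sd_maternal = np.sqrt(config.maternal * v)
    sd_resid = np.sqrt(config.residual * v)
    sd_pup = sd_resid * np.sqrt(config.pup_repeatability)
    sd_meas = sd_resid * np.sqrt(1.0 - config.pup_repeatability)

    rows = []
    focal = []
    for si, strain in enumerate(strains):
        for li in range(config.litters_per_strain):
            litter_dev = rng.normal(0.0, sd_litter) + rng.normal(0.0, sd_maternal)
            for pi in range(config.pups_per_litter):
                pup_dev = rng.normal(0.0, sd_pup)
                sex = "F" if pi % 2 == 0 else "M"
                weight = rng.normal(4.8, 0.4)
                for day in config.days:
                    value = (
                        config.grand_mean
                        + genetic[si]
                        + litter_dev
                        + pup_dev
                        + day_fx[day]
                        + rng.normal(0.0, sd_meas)
                    )
                    rows.append(
                        (strain, f"L{li + 1}", f"P{pi + 1}", sex, day, round(weight + 0.25 * (day - 8), 3))
                    )
                    focal.append(value)
    table = pd.DataFrame(rows, columns=["strain", "litter", "pup", "sex", "day", "weight_g"])
    n = len(table)
    for trait in QUANT_TRAITS:
        mean, sd = TRAIT_BASELINES[trait]
        col = rng.normal(mean, sd * 0.05, n)
        if trait == "n_calls":
            col = np.maximum(0, np.round(col)).astype(int)
        table[trait] = col
    values = np.asarray(focal)
    if config.trait == "n_calls":
        values = np.maximum(0, np.round(values)).astype(int)
    table[config.trait] = values
    return table


@dataclass
class DiallelConfig:
    """Design of the four-group B6xD2 diallel simulation.

    ``f1_mean`` is shared by both reciprocal hybrids (identical autosomal
    genetic value by construction); ``maternal`` gives the dam-strain
    deviations, and ``parent_of_origin`` is added to B6D2F1 pups and
    subtracted from D2B6F1 pups.
    """

    litters_per_group: int = 4
    pups_per_litter: int = 6
    group_means: dict = field(default_factory=lambda: {"B6": 0.0, "D2": 0.0})
    f1_mean: float = 0.0
    maternal: dict = field(default_factory=lambda: {"B6": 0.0, "D2": 0.0})
    parent_of_origin: float = 0.0
    litter_sd: float = 0.0
    residual_sd: float = 1.0
    days: tuple[int, ...] = (8,)
    trait: str = "amplitude_db"
    seed: int = 0

    def genetic_value(self, group: str) -> float:
        if group in ("B6D2F1", "D2B6F1"):
            return self.f1_mean
        return self.group_means[group]


_DAM = {"B6": "B6", "D2": "D2", "B6D2F1": "B6", "D2B6F1": "D2"}
_POE_SIGN = {"B6": 0.0, "D2": 0.0, "B6D2F1": 1.0, "D2B6F1": -1.0}


def simulate_diallel(config: DiallelConfig) -> pd.DataFrame:
    """Simulate the four-group diallel phenotype table.

    Sexes alternate within litters; reciprocal F1 groups share their genetic
    value and differ only via maternal and parent-of-origin deviations.
    """
    for group in DIALLEL_GROUPS:
        try:
            config.genetic_value(group)
            config.maternal[_DAM[group]]
        except KeyError as exc:
            raise ValueError(f"missing configuration for group {group}") from exc
    rng = np.random.default_rng(config.seed)
    rows = []
    focal = []
    for group in DIALLEL_GROUPS:
        base = (
            config.genetic_value(group)
            + config.maternal[_DAM[group]]
            + _POE_SIGN[group] * config.parent_of_origin
        )
        for li in range(config.litters_per_group):
            litter_dev = rng.normal(0.0, config.litter_sd)
            for pi in range(config.pups_per_litter):
                sex = "F" if pi % 2 == 0 else "M"
                weight = rng.normal(4.8, 0.4)
                for day in config.days:
                    value = base + litter_dev + rng.normal(0.0, config.residual_sd)
                    rows.append((group, f"L{li + 1}", f"P{pi + 1}", sex, day, round(weight, 3)))
                    focal.append(value)
    table = pd.DataFrame(rows, columns=["strain", "litter", "pup", "sex", "day", "weight_g"])
    n = len(table)
    for trait in QUANT_TRAITS:
        mean, sd = TRAIT_BASELINES[trait]
        col = rng.normal(mean, sd * 0.05, n)
        if trait == "n_calls":
            col = np.maximum(0, np.round(col)).astype(int)
        table[trait] = col
    table[config.trait] = np.asarray(focal)
    return table


def simulate_calltype_counts(profile: Sequence[float], total: int, seed) -> np.ndarray:
    """Multinomial call-type counts over the ten call categories."""
    profile = np.asarray(profile, dtype=float)
    if profile.shape != (len(CALL_TYPES),):
        raise ValueError(f"profile must have {len(CALL_TYPES)} probabilities")
    if (profile < 0).any() or abs(profile.sum() - 1.0) > 1e-9:
        raise ValueError("profile probabilities must be non-negative and sum to 1")
    if total < 0:
        raise ValueError("total must be non-negative")
    rng = np.random.default_rng(seed)
    return rng.multinomial(total, profile)


def attach_calltype_counts(
    table: pd.DataFrame,
    profiles: dict[str, Sequence[float]],
    mean_total: float = 60.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Attach per-row multinomial call-type counts using per-strain profiles.

    Row totals are Poisson around ``mean_total``; ``n_calls`` is overwritten
    to equal the sum of the ten counts.
    """
    rng = np.random.default_rng(seed)
    out = table.copy()
    counts = np.zeros((len(out), len(CALL_TYPES)), dtype=int)
    for i, strain in enumerate(out["strain"]):
        profile = np.asarray(profiles[strain], dtype=float)
        total = int(rng.poisson(mean_total))
        counts[i] = rng.multinomial(total, profile)
    for j, ct in enumerate(CALL_TYPES):
        out[ct] = counts[:, j]
    out["n_calls"] = counts.sum(axis=1)
    return out


def hri2_target_strain_fraction(hri2: float, n: int) -> float:
    """Strain-level variance fraction giving a target strain-mean
    heritability HRIx^2 = f*n/(f*n + 1 - f) at n replicates per line."""
    if not 0.0 <= hri2 < 1.0:
        raise ValueError("target HRIx^2 must be in [0,1)")
    return hri2 / (n - hri2 * (n - 1))
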