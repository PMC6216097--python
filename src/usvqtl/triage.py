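"""Candidate-gene triage inside QTL support intervals.

Genes overlapping a 1.5-LOD support interval are filtered to those carrying
coding variants (nsSNPs or InDels) and ranked by how many of three curated
evidence lists they appear in: a cis-eQTL in brain transcriptome data,
expression correlated with the mapped trait, and a prior phenotype
association (brain, behavior, or cranio-facial). The evidence flags are
inputs — curated upstream from expression and phenotype databases — not
recomputed here.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

EVIDENCE_FLAGS = ("cis_eqtl", "trait_correlated", "prior_phenotype")


@dataclass(frozen=True)
class GeneRecord:
    symbol: str
    chrom: str
    start_mb: float
    end_mb: float
    has_coding_variant: bool
    cis_eqtl: bool = False
    trait_correlated: bool = False
    prior_phenotype: bool = False

    def __post_init__(self) -> None:
        if self.start_mb > self.end_mb:
            raise ValueError(f"{self.symbol}: start beyond end")

    @property
    def tier(self) -> int:
        """Number of evidence flags set (0-3)."""
        return int(self.cis_eqtl) + int(self.trait_correlated) + int(self.prior_phenotype)


@dataclass
class EvidenceReport:
    tiers: dict[int, list[str]]  # tier -> sorted gene symbols
    union: list[str]  # genes with >= 1 evidence flag, sorted
    top: list[str]  # genes with all three flags, sorted

    @property
    def union_count(self) -> int:
        return len(self.union)


def read_gene_table(source) -> list[GeneRecord]:
    """Read a tab-separated gene table.

    Columns: symbol, chrom, start_mb, end_mb, coding_variant, cis_eqtl,
    trait_correlated, prior_phenotype (flags as 0/1). ``#`` lines are
    comments.
    """
    handle = source if hasattr(source, "read") else open(source, "r", encoding="utf-8")
    close = not hasattr(source, "read")
    try:
        text = "\n".join(
            ln for ln in handle.read().splitlines() if ln.strip() and not ln.startswith("#")
        )
    finally:
        if close:
            handle.close()
    table = pd.read_csv(_io.StringIO(text), sep="\t")
    records = []
    for row in table.itertuples(index=False):
        records.append(
            GeneRecord(
                symbol=str(row.symbol),
                chrom=str(row.chrom),
                start_mb=float(row.start_mb),
                end_mb=float(row.end_mb),
                has_coding_variant=bool(int(row.coding_variant)),
                cis_eqtl=bool(int(row.cis_eqtl)),
                trait_correlated=bool(int(row.trait_correlated)),
                prior_phenotype=bool(int(row.prior_phenotype)),
            )
        )
    return records


def interval_candidates(
    genes: Iterable[GeneRecord],
    chromosome: str,
    interval: tuple[float, float],
    require_coding_variant: bool = False,
) -> list[GeneRecord]:
    """Genes overlapping a [lo, hi] Mb interval on a chromosome.

    Any overlap counts and both endpoints are inclusive; optionally restrict
    to genes carrying a coding variant.
    """
    lo, hi = interval
    if lo > hi:
        raise ValueError(f"malformed interval [{lo}, {hi}]")
    out = []
    for g in genes:
        if g.chrom != str(chromosome):
            continue
        if g.start_mb <= hi and g.end_mb >= lo:
            if require_coding_variant and not g.has_coding_variant:
                continue
            out.append(g)
    return out


def evidence_rank(genes: Sequence[GeneRecord]) -> EvidenceReport:
    """Group candidates by evidence tier.

    Tier = number of evidence lists a gene appears in; the top tier (all
    three) holds the strongest candidates, and the union (tier >= 1) bounds
    how far the list can be narrowed. Order-invariant and idempotent.
    """
    tiers: dict[int, list[str]] = {0: [], 1: [], 2: [], 3: []}
    for g in genes:
        tiers[g.tier].append(g.symbol)
    for t in tiers:
        tiers[t] = sorted(set(tiers[t]))
    union = sorted(set(tiers[1]) | set(tiers[2]) | set(tiers[3]))
    return EvidenceReport(tiers=tiers, union=union, top=tiers[3])


def render_report(report: EvidenceReport) -> str:
    """Tab-separated rendering of an evidence report."""
    lines = ["tier\tn_genes\tgenes"]
    for t in (3, 2, 1, 0):
        genes = report.tiers[t]
        lines.append(f"{t}\t{len(genes)}\t{','.join(genes)}")
    lines.append(f"union(>=1)\t{report.union_count}\t{','.join(report.union)}")
    return "\n".join(lines)
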