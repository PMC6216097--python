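"""Tabular formats for the vocalization-genetics pipeline.

Covers the GeneNetwork ``.geno`` genotype dialect used for BXD-style
recombinant inbred (RI) panels, individual-level phenotype tables (one row
per pup per recording day), per-strain trait means, and genome-scan tracks.

All readers validate rather than coerce: malformed allele tokens, duplicate
markers, non-numeric coordinates and duplicated pup-day rows raise
:class:`FormatError` with enough context to find the offending line.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from typing import IO, Sequence

import numpy as np
import pandas as pd

#: canonical allele codes: B6 allele, D2 allele, heterozygous, unknown
ALLELE_CODES = ("B", "D", "H", "U")

#: the ten pup call categories used throughout (counts are inputs upstream
#: of this package; the simulator emits them multinomially)
CALL_TYPES = (
    "complex",
    "harmonics",
    "two_syllable",
    "upward",
    "downward",
    "chevron",
    "short",
    "composite",
    "frequency_steps",
    "flat",
)

#: quantitative USV traits: number of calls, mean duration (ms),
#: mean peak frequency (kHz), mean peak amplitude (dB)
QUANT_TRAITS = ("n_calls", "duration_ms", "frequency_khz", "amplitude_db")

PHENOTYPE_REQUIRED = (
    "strain",
    "litter",
    "pup",
    "sex",
    "day",
    "weight_g",
) + QUANT_TRAITS

SEX_TOKENS = ("F", "M")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Strains x markers matrix of two-letter allele codes with coordinates.

    Parameters
    ----------
    markers
        One row per marker with columns ``marker``, ``chrom``, ``cm``, ``mb``,
        ordered by chromosome then position.
    codes
        DataFrame indexed by marker name, one column per strain, values in
        ``{"B", "D", "H", "U"}``.
    """

    markers: pd.DataFrame
    codes: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"marker", "chrom", "cm", "mb"}
        if not required.issubset(self.markers.columns):
            raise ValueError(f"markers table needs columns {sorted(required)}")
        if self.markers["marker"].duplicated().any():
            dup = self.markers.loc[self.markers["marker"].duplicated(), "marker"].iloc[0]
            raise FormatError(f"duplicate marker name: {dup!r}")
        if pd.Index(self.codes.columns).duplicated().any():
            raise FormatError("strain names are not unique")
        if not self.codes.index.equals(pd.Index(self.markers["marker"])):
            raise ValueError("codes index must match marker order")
        for _, grp in self.markers.groupby("chrom", sort=False):
            if (np.diff(grp["cm"].to_numpy()) < 0).any():
                raise ValueError("cM positions must be non-decreasing per chromosome")
        bad = ~self.codes.isin(ALLELE_CODES)
        if bad.to_numpy().any():
            r, c = np.argwhere(bad.to_numpy())[0]
            raise FormatError(
                f"invalid allele code {self.codes.iat[r, c]!r} at marker "
                f"{self.codes.index[r]!r}, strain {self.codes.columns[c]!r}"
            )

    @property
    def strains(self) -> list[str]:
        return list(self.codes.columns)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def dosage(self) -> np.ndarray:
        """Signed allele dosage, strains x markers.

        B -> -1, D -> +1; heterozygous/unknown calls are returned as NaN
        (they are excluded from dosage computation and mean-imputed by the
        scan layer).
        """
        arr = self.codes.to_numpy()
        out = np.full(arr.shape, np.nan)
        out[arr == "B"] = -1.0
        out[arr == "D"] = 1.0
        return out.T


# ---------------------------------------------------------------------------
# .geno dialect
# ---------------------------------------------------------------------------


def _as_text_handle(source) -> IO[str]:
    if hasattr(source, "read"):
        return source
    return open(source, "r", encoding="utf-8")


def read_geno(source) -> GenotypeMatrix:
    """Parse a GeneNetwork ``.geno`` file.

    The dialect has ``@key: value`` metadata lines declaring the maternal
    (``@mat``), paternal (``@pat``), heterozygous (``@het``) and unknown
    (``@unk``) symbols, a header line ``Chr  Locus  cM  Mb  <strain...>``
    and tab-separated data rows. Declared symbols are mapped onto the
    canonical ``{B, D, H, U}`` codes.
    """
    handle = _as_text_handle(source)
    close = not hasattr(source, "read")
    try:
        meta = {"mat": "B", "pat": "D", "het": "H", "unk": "U"}
        header: list[str] | None = None
        rows: list[list[str]] = []
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if line.startswith("@"):
                body = line[1:]
                if ":" in body:
                    key, _, val = body.partition(":")
                else:
                    key, _, val = body.partition(" ")
                meta[key.strip().lower()] = val.strip()
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if header is None:
                if len(fields) < 5 or fields[0].lower() != "chr":
                    raise FormatError(
                        f"line {lineno}: expected header starting with 'Chr', got {fields[:4]}"
                    )
                header = fields
                continue
            if len(fields) != len(header):
                raise FormatError(
                    f"line {lineno}: {len(fields)} fields, header has {len(header)}"
                )
            rows.append([lineno, *fields])
        if header is None:
            raise FormatError("no header line found")

        strains = header[4:]
        symbol_map = {
            meta["mat"]: "B",
            meta["pat"]: "D",
            meta["het"]: "H",
            meta["unk"]: "U",
        }
        marker_rows = []
        code_rows = []
        seen: set[str] = set()
        for lineno, chrom, locus, cm, mb, *calls in rows:
            if locus in seen:
                raise FormatError(f"line {lineno}: duplicate marker name {locus!r}")
            seen.add(locus)
            try:
                cm_f, mb_f = float(cm), float(mb)
            except ValueError as exc:
                raise FormatError(f"line {lineno}: non-numeric coordinate for {locus!r}") from exc
            mapped = []
            for strain, call in zip(strains, calls):
                if call not in symbol_map:
                    raise FormatError(
                        f"line {lineno}: unknown allele token {call!r} for strain {strain!r}"
                    )
                mapped.append(symbol_map[call])
            marker_rows.append((locus, str(chrom), cm_f, mb_f))
            code_rows.append(mapped)
        markers = pd.DataFrame(marker_rows, columns=["marker", "chrom", "cm", "mb"])
        codes = pd.DataFrame(code_rows, index=pd.Index(markers["marker"], name="marker"), columns=strains)
        return GenotypeMatrix(markers=markers, codes=codes)
    finally:
        if close:
            handle.close()


def write_geno(geno: GenotypeMatrix, target, name: str = "SIM") -> None:
    """Write a :class:`GenotypeMatrix` in the ``.geno`` dialect."""
    handle = target if hasattr(target, "write") else open(target, "w", encoding="utf-8")
    close = not hasattr(target, "write")
    try:
        handle.write(f"@name: {name}\n@type: riset\n@mat: B\n@pat: D\n@het: H\n@unk: U\n")
        handle.write("Chr\tLocus\tcM\tMb\t" + "\t".join(geno.strains) + "\n")
        codes = geno.codes.to_numpy()
        for i, row in enumerate(geno.markers.itertuples(index=False)):
            handle.write(
                f"{row.chrom}\t{row.marker}\t{row.cm:g}\t{row.mb:g}\t"
                + "\t".join(codes[i])
                + "\n"
            )
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# phenotype tables
# ---------------------------------------------------------------------------


def _sniff_delimiter(header_line: str) -> str:
    if "\t" in header_line:
        return "\t"
    if "," in header_line:
        return ","
    raise FormatError("could not detect delimiter (expected tab or comma)")


def read_phenotypes(source, allowed_days: Sequence[int] | None = (7, 8, 9)) -> pd.DataFrame:
    """Read an individual-level phenotype table (one row per pup x day).

    Required columns: strain, litter, pup, sex, day, weight_g, and the four
    quantitative traits. The ten call-type count columns are optional but
    validated (non-negative integers) when present.
    """
    handle = _as_text_handle(source)
    close = not hasattr(source, "read")
    try:
        text = handle.read()
    finally:
        if close:
            handle.close()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise FormatError("empty phenotype file (no header)")
    sep = _sniff_delimiter(lines[0])
    table = pd.read_csv(_io.StringIO(text), sep=sep)
    missing = [c for c in PHENOTYPE_REQUIRED if c not in table.columns]
    if missing:
        raise FormatError(f"missing required columns: {missing}")
    if table.empty:
        return table
    table["strain"] = table["strain"].astype(str)
    table["litter"] = table["litter"].astype(str)
    table["pup"] = table["pup"].astype(str)
    bad_sex = set(table["sex"].astype(str)) - set(SEX_TOKENS)
    if bad_sex:
        raise FormatError(f"unknown sex token(s): {sorted(bad_sex)}")
    table["day"] = table["day"].astype(int)
    if allowed_days is not None:
        bad_day = set(table["day"]) - set(allowed_days)
        if bad_day:
            raise FormatError(f"day value(s) outside {tuple(allowed_days)}: {sorted(bad_day)}")
    count_cols = ["n_calls"] + [c for c in CALL_TYPES if c in table.columns]
    for col in count_cols:
        if (table[col] < 0).any():
            row = table.index[table[col] < 0][0]
            raise FormatError(f"negative count in column {col!r} (row {row})")
    key = ["strain", "litter", "pup", "day"]
    dup = table.duplicated(subset=key)
    if dup.any():
        first = table.loc[dup, key].iloc[0]
        raise FormatError(
            "duplicated pup-day row: strain={strain} litter={litter} pup={pup} day={day}".format(
                **first.to_dict()
            )
        )
    return table


def write_phenotypes(table: pd.DataFrame, target, sep: str = "\t") -> None:
    table.to_csv(target, sep=sep, index=False)


# ---------------------------------------------------------------------------
# strain means
# ---------------------------------------------------------------------------


def strain_means(
    table: pd.DataFrame, trait: str, day: int | None = None
) -> pd.DataFrame:
    """Collapse a phenotype table to per-strain means for one trait.

    Returns columns strain, value, sd, se, n; ``se = sd/sqrt(n)``. When
    ``day`` is None, each pup is first averaged over its recording days so
    that ``n`` counts pups, not measurements.
    """
    if trait not in table.columns:
        raise KeyError(f"trait {trait!r} not in table")
    sub = table if day is None else table[table["day"] == day]
    if sub.empty:
        raise ValueError("no records for requested day")
    per_pup = sub.groupby(["strain", "litter", "pup"], sort=True)[trait].mean().reset_index()
    grp = per_pup.groupby("strain")[trait]
    out = grp.agg(value="mean", sd="std", n="count").reset_index()
    out["se"] = out["sd"] / np.sqrt(out["n"])
    return out[["strain", "value", "sd", "se", "n"]]


def read_strain_means(source) -> pd.DataFrame:
    handle = _as_text_handle(source)
    close = not hasattr(source, "read")
    try:
        text = handle.read()
    finally:
        if close:
            handle.close()
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise FormatError("empty strain-mean file")
    sep = _sniff_delimiter(lines[0])
    table = pd.read_csv(_io.StringIO("\n".join(lines)), sep=sep)
    if "strain" not in table.columns or "value" not in table.columns:
        raise FormatError("strain-mean table needs columns 'strain' and 'value'")
    table["strain"] = table["strain"].astype(str)
    if "n" in table.columns and (table["n"] < 1).any():
        raise FormatError("replicate count n must be >= 1")
    if "se" not in table.columns and {"sd", "n"}.issubset(table.columns):
        table["se"] = table["sd"] / np.sqrt(table["n"])
    return table


def write_strain_means(table: pd.DataFrame, target, sep: str = "\t") -> None:
    table.to_csv(target, sep=sep, index=False)


# ---------------------------------------------------------------------------
# scan tracks
# ---------------------------------------------------------------------------


def write_scan(result, target) -> None:
    """Write a genome scan as tab-separated text.

    A ``#``-prefixed header block carries the permutation thresholds and the
    peak list; data rows carry chromosome, Mb, cM, LRS, LOD (= LRS/4.61) and
    the additive coefficient per position.
    """
    if len(result.table) == 0:
        raise ValueError("empty scan result")
    handle = target if hasattr(target, "write") else open(target, "w", encoding="utf-8")
    close = not hasattr(target, "write")
    try:
        if result.thresholds:
            for key, val in result.thresholds.items():
                handle.write(f"# threshold\t{key}\t{val:.6f}\n")
        for peak in result.peaks or []:
            handle.write(
                f"# peak\t{peak.chrom}\t{peak.marker}\t{peak.mb:.6f}\t{peak.lrs:.6f}\n"
            )
        handle.write("chrom\tmarker\tmb\tcm\tlrs\tlod\tadditive\n")
        for row in result.table.itertuples(index=False):
            handle.write(
                f"{row.chrom}\t{row.marker}\t{row.mb:.6f}\t{row.cm:.6f}\t"
                f"{row.lrs:.6f}\t{row.lod:.6f}\t{row.additive:.6f}\n"
            )
    finally:
        if close:
            handle.close()


def read_scan(source):
    """Read a scan track written by :func:`write_scan`."""
    from .scan import ScanResult  # local import: scan builds on io

    handle = _as_text_handle(source)
    close = not hasattr(source, "read")
    try:
        thresholds: dict[str, float] = {}
        data_lines = []
        for line in handle:
            if line.startswith("# threshold"):
                _, key, val = line.strip().split("\t")
                thresholds[key] = float(val)
            elif line.startswith("#"):
                continue
            elif line.strip():
                data_lines.append(line)
    finally:
        if close:
            handle.close()
    table = pd.read_csv(_io.StringIO("".join(data_lines)), sep="\t")
    table["chrom"] = table["chrom"].astype(str)
    return ScanResult(table=table, thresholds=thresholds or None)
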