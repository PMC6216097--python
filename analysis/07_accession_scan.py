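"""Optional: re-map the deposited strain-mean traits on real BXD genotypes.

Requires two files the user must download into data/external/ (no network
access is assumed here):

* ``data/external/BXD.geno`` — the January 2017 BXD genotype file
  (GeneNetwork .geno format).
* ``data/external/gn_<trait>.tsv`` — strain-mean tables for GeneNetwork
  phenotypes 16357 (peak amplitude, day 7) and 16359 (mean peak frequency,
  day 7), as tab-separated ``strain\tvalue`` tables.

Expected outcome: the 1.5-LOD support interval for 16357 falls on chr8
around 3.5-16.7 Mb, and for 16359 the chr2 interval around 179.5-180.8 Mb.
"""

from pathlib import Path

import usvqtl as u

EXT = Path(__file__).resolve().parent.parent / "data" / "external"
TRAITS = {"16357": "8", "16359": "2"}

geno_path = EXT / "BXD.geno"
if not geno_path.exists():
    raise SystemExit(
        f"{geno_path} not found - download the January 2017 BXD genotype file "
        "and the GeneNetwork strain means (see module docstring) to run this step."
    )
geno = u.read_geno(geno_path)
for trait, chrom in TRAITS.items():
    means = u.read_strain_means(EXT / f"gn_{trait}.tsv")
    means, log = u.winsorize_means(means)
    grid = u.expected_dosages(geno, step_cm=1.0)
    scan = u.hk_scan(grid, means)
    scan.thresholds = u.permutation_thresholds(grid, means, n_perm=5000, seed=2017)
    peaks = u.peak_report(scan, scan.thresholds, geno)
    on_target = [p for p in peaks if p.chrom == chrom]
    for p in on_target:
        print(f"trait {trait}: chr{p.chrom} peak {p.marker} @ {p.mb:.1f} Mb, "
              f"LOD {p.lod:.2f}, 1.5-LOD interval {p.interval_mb[0]:.1f}-{p.interval_mb[1]:.1f} Mb")
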