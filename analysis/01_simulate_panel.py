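"""Simulate the study's two designs and write them under scratch/sim/.

Creates (a) a 41-strain RI panel genotyped at ~1000 markers with a planted
QTL on chromosome 8 and pup-level recordings on postnatal days 7-9, and
(b) a four-group diallel (B6, D2, reciprocal F1s) with a planted maternal
contrast, plus per-pup call-type counts.
"""

from pathlib import Path

import numpy as np

import usvqtl as u
from usvqtl.simulate import attach_calltype_counts

OUT = Path(__file__).resolve().parent.parent / "scratch" / "sim"
OUT.mkdir(parents=True, exist_ok=True)
SEED = 20170101

gmap = u.GeneticMap.regular()
geno = u.simulate_ri_genotypes(41, gmap, SEED)
chr8 = gmap.markers[gmap.markers["chrom"] == "8"]
causal = chr8["marker"].iloc[20]
config = u.SimConfig(
    strain_background=0.35,
    litter=0.35,  # litter effects are large for these traits
    residual=0.29,
    qtl=[(causal, 0.6)],
    grand_mean=-30.0,  # dB scale for peak amplitude
    total_variance=25.0,
    seed=SEED + 1,
)
table = u.simulate_ri_phenotypes(geno, config)
u.write_geno(geno, OUT / "panel.geno", name="SIMBXD")
u.write_phenotypes(table, OUT / "panel_phenotypes.tsv")
for day in (7, 8, 9):
    u.write_strain_means(u.strain_means(table, "amplitude_db", day=day),
                         OUT / f"amplitude_day{day}_means.tsv")

diallel_cfg = u.DiallelConfig(
    litters_per_group=4, pups_per_litter=6,
    group_means={"B6": -36.0, "D2": -23.0}, f1_mean=-39.0,
    maternal={"B6": -1.0, "D2": 1.0}, parent_of_origin=0.5,
    litter_sd=1.5, residual_sd=2.5, seed=SEED + 2,
)
dia = u.simulate_diallel(diallel_cfg)
# strain-specific call-type repertoires (loosely: D2 complex/flat-heavy,
# B6 two-syllable/short-heavy, F1s complex-heavy)
profiles = {
    "B6": np.array([0.12, 0.02, 0.28, 0.04, 0.19, 0.01, 0.20, 0.03, 0.08, 0.03]),
    "D2": np.array([0.29, 0.01, 0.01, 0.23, 0.02, 0.15, 0.02, 0.00, 0.00, 0.27]),
    "B6D2F1": np.array([0.30, 0.01, 0.18, 0.09, 0.19, 0.07, 0.00, 0.00, 0.05, 0.11]),
    "D2B6F1": np.array([0.30, 0.02, 0.17, 0.08, 0.18, 0.06, 0.01, 0.01, 0.05, 0.12]),
}
dia = attach_calltype_counts(dia, profiles, mean_total=70, seed=SEED + 3)
u.write_phenotypes(dia, OUT / "diallel_phenotypes.tsv")

print(f"RI panel: {len(geno.strains)} strains x {geno.n_markers} markers, "
      f"{len(table)} pup-day records; planted QTL at {causal} "
      f"({float(chr8['mb'].iloc[20]):.1f} Mb, chr8)")
print(f"diallel: {len(dia)} pup records across {dia['strain'].nunique()} groups")
print(f"written under {OUT}")
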