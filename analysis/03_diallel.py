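"""Diallel-cross analysis: group tests, parent-of-origin, call repertoires.

Runs the four-group comparison on peak amplitude, the reciprocal-F1 rank
test (all pups and females only), the per-group call-type percentage
profiles, and a worked serial-section volume computation.
"""

from pathlib import Path

import usvqtl as u

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results"
TRAIT = "amplitude_db"

table = u.read_phenotypes(ROOT / "scratch" / "sim" / "diallel_phenotypes.tsv")

gc = u.group_comparison(table, TRAIT)
print("group summary:")
print(gc.summary.round(2).to_string())
print(f"\nKruskal-Wallis H = {gc.kruskal_statistic:.2f}, p = {gc.kruskal_p:.3g}")
print("Tukey adjusted pairwise p-values:")
print(gc.tukey_p.round(4).to_string())
gc.tukey_p.to_csv(OUT / "diallel_tukey.tsv", sep="\t")

for females_only in (False, True):
    poe = u.parent_of_origin_test(table, TRAIT, females_only=females_only)
    scope = "females only" if females_only else "all pups"
    print(f"\nparent-of-origin ({scope}): U = {poe.statistic:.0f}, p = {poe.p_value:.3g}, "
          f"B6-dam minus D2-dam direction {poe.direction:+d} "
          f"({poe.mean_b6_dam:.2f} vs {poe.mean_d2_dam:.2f} dB)")

prof = u.calltype_profile(table)
print("\nmean call-type percentages per group:")
print(prof.group_means.round(1).to_string())
prof.group_means.to_csv(OUT / "calltype_profiles.tsv", sep="\t")

# worked morphometric example: thyroid-cartilage-like series at 50 um spacing
areas_mm2 = [0.8, 1.1, 1.4, 1.3, 0.9]
vol = u.section_volume(areas_mm2, spacing=0.05)
print(f"\nserial-section volume for areas {areas_mm2} mm^2 at 0.05 mm spacing: {vol:.3f} mm^3")
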