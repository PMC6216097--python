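import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

import usvqtl as u


@pytest.fixture(scope="session")
def small_map() -> u.GeneticMap:
    return u.GeneticMap.regular(n_chromosomes=3, markers_per_chromosome=20, spacing_cm=3.0)


@pytest.fixture(scope="session")
def small_panel(small_map):
    """41-strain panel with a planted QTL mid-chromosome 2."""
    geno = u.simulate_ri_genotypes(41, small_map, seed=11)
    causal = small_map.markers.query("chrom == '2'")["marker"].iloc[10]
    config = u.SimConfig(
        strain_background=0.6,
        litter=0.1,
        residual=0.3,
        qtl=[(causal, 0.8)],
        day_effects=(0.0, 0.0, 0.0),
        seed=12,
    )
    table = u.simulate_ri_phenotypes(geno, config)
    return geno, table, causal


@pytest.fixture()
def hand_anova_table() -> pd.DataFrame:
    """Two strains x two litters x two pups, exact sums of squares by hand:
    total 40, strain 32, litter-within-strain 8, residual 0."""
    rows = []
    for strain, litters, vals in [("A", ("a1", "a2"), (1, 1, 3, 3)), ("B", ("b1", "b2"), (5, 5, 7, 7))]:
        for i, v in enumerate(vals):
            rows.append((strain, litters[i // 2], f"P{i % 2 + 1}", "F", 8, 5.0, float(v)))
    return pd.DataFrame(
        rows, columns=["strain", "litter", "pup", "sex", "day", "weight_g", "amplitude_db"]
    )


@pytest.fixture()
def six_strain_scan():
    """One marker, six strains split B/B/B/D/D/D with y = 0..5.

    Least-squares by hand: RSS0 = 17.5, RSS1 = 4, LRS = 6 ln(4.375)."""
    markers = pd.DataFrame({"marker": ["m1"], "chrom": ["1"], "cm": [0.0], "mb": [3.0]})
    codes = pd.DataFrame(
        {f"s{i}": ["B" if i < 3 else "D"] for i in range(6)},
        index=pd.Index(["m1"], name="marker"),
    )
    geno = u.GenotypeMatrix(markers=markers, codes=codes)
    y = pd.DataFrame({"strain": [f"s{i}" for i in range(6)], "value": [0.0, 1, 2, 3, 4, 5]})
    return geno, y
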