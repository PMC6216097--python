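"""Haley-Knott scan machinery against hand and brute-force oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import usvqtl as u
from usvqtl.scan import ScanResult, render_change_log


def _means(strains, values):
    return pd.DataFrame({"strain": strains, "value": values})


class TestWinsorize:
    def test_hand_example_single_high_outlier(self):
        means = _means([f"S{i}" for i in range(10)], [1.0] * 9 + [10.0])
        adj, log = u.winsorize_means(means)
        assert adj["value"].tolist() == [1.0] * 10
        assert log == [{"strain": "S9", "old": 10.0, "new": 1.0}]
        assert render_change_log(log) == "S9 from 10 to 1"

    def test_no_outliers_is_identity(self):
        means = _means(list("abcde"), [1.0, 2.0, 3.0, 4.0, 5.0])
        adj, log = u.winsorize_means(means)
        assert log == [] and adj["value"].tolist() == means["value"].tolist()

    def test_low_outlier_raised_from_below(self):
        means = _means([f"S{i}" for i in range(10)], [5.0] * 9 + [-4.0])
        adj, log = u.winsorize_means(means)
        assert log[0]["new"] == 5.0

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="zero variance"):
            u.winsorize_means(_means(list("abc"), [2.0, 2.0, 2.0]))

    @given(st.lists(st.floats(-50, 50), min_size=5, max_size=30, unique=True))
    def test_rank_order_of_retained_values_preserved(self, values):
        means = _means([f"S{i}" for i in range(len(values))], values)
        try:
            adj, log = u.winsorize_means(means)
        except ValueError:
            return  # degenerate variance
        changed = {e["strain"] for e in log}
        kept = adj[~adj["strain"].isin(changed)]
        orig = means[~means["strain"].isin(changed)]
        assert np.array_equal(np.argsort(kept["value"]), np.argsort(orig["value"]))


class TestExpectedDosages:
    def _two_marker_geno(self, gap_cm, codes):
        markers = pd.DataFrame(
            {"marker": ["a", "b"], "chrom": ["1", "1"], "cm": [0.0, gap_cm], "mb": [3.0, 4.0]}
        )
        frame = pd.DataFrame(codes, index=pd.Index(["a", "b"], name="marker"))
        return u.GenotypeMatrix(markers=markers, codes=frame)

    def test_marker_positions_are_exact(self):
        geno = self._two_marker_geno(10.0, {"s1": ["B", "D"], "s2": ["D", "B"]})
        grid = u.expected_dosages(geno, step_cm=100.0)
        np.testing.assert_array_equal(grid.values, [[-1, 1], [1, -1]])

    def test_concordant_flanks_at_tiny_gap(self):
        geno = self._two_marker_geno(0.02, {"s1": ["D", "D"], "s2": ["B", "B"]})
        grid = u.expected_dosages(geno, step_cm=0.01)
        mid = grid.values[:, grid.positions["is_pseudo"].to_numpy()][:, 0]
        assert mid[0] == pytest.approx(1.0, abs=1e-6)
        assert mid[1] == pytest.approx(-1.0, abs=1e-6)

    def test_discordant_flanks_midpoint_is_zero(self):
        geno = self._two_marker_geno(10.0, {"s1": ["B", "D"], "s2": ["D", "B"]})
        grid = u.expected_dosages(geno, step_cm=5.0)
        mid = grid.values[:, grid.positions["is_pseudo"].to_numpy()][:, 0]
        np.testing.assert_allclose(mid, 0.0, atol=1e-12)

    def test_het_and_unknown_are_mean_imputed(self):
        geno = self._two_marker_geno(5.0, {"s1": ["B", "D"], "s2": ["D", "B"], "s3": ["H", "U"]})
        grid = u.expected_dosages(geno, step_cm=100.0)
        np.testing.assert_allclose(grid.values[2], [0.0, 0.0])  # mean of -1,+1

    def test_invalid_step(self, six_strain_scan):
        with pytest.raises(ValueError):
            u.expected_dosages(six_strain_scan[0], step_cm=0.0)


class TestHKScan:
    def test_hand_computed_six_strain_example(self, six_strain_scan):
        geno, y = six_strain_scan
        res = u.hk_scan(u.expected_dosages(geno), y)
        row = res.table.iloc[0]
        assert row["lrs"] == pytest.approx(6 * np.log(17.5 / 4.0), abs=1e-9)
        assert row["lrs"] == pytest.approx(8.855, abs=1e-3)
        assert row["lod"] == pytest.approx(row["lrs"] / 4.61)
        assert row["additive"] == pytest.approx(1.5)

    def test_constant_phenotype_gives_zero_lrs(self, small_panel):
        geno, _, _ = small_panel
        grid = u.expected_dosages(geno, step_cm=100.0)
        y = _means(geno.strains, np.ones(len(geno.strains)))
        assert u.hk_scan(grid, y).table["lrs"].abs().max() == 0.0

    def test_row_reordering_invariance(self, small_panel):
        geno, table, _ = small_panel
        grid = u.expected_dosages(geno, step_cm=100.0)
        y = u.strain_means(table, "amplitude_db")
        a = u.hk_scan(grid, y)
        b = u.hk_scan(grid, y.sample(frac=1.0, random_state=1).reset_index(drop=True))
        np.testing.assert_allclose(a.table["lrs"], b.table["lrs"])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_least_squares_oracle(self, seed):
        """Brute-force two-parameter OLS at every position on small instances."""
        rng = np.random.default_rng(seed)
        n, m = rng.integers(5, 11), rng.integers(3, 21)
        gmap = u.GeneticMap.regular(n_chromosomes=1, markers_per_chromosome=int(m), spacing_cm=4.0)
        geno = u.simulate_ri_genotypes(int(n), gmap, seed=seed)
        grid = u.expected_dosages(geno, step_cm=100.0)
        yv = rng.normal(size=int(n))
        res = u.hk_scan(grid, _means(geno.strains, yv))
        rss0 = np.sum((yv - yv.mean()) ** 2)
        for j in range(grid.values.shape[1]):
            design = np.column_stack([np.ones(int(n)), grid.values[:, j]])
            if np.linalg.matrix_rank(design) < 2:
                assert res.table["lrs"].iloc[j] == 0.0
                continue
            beta, rss1, *_ = np.linalg.lstsq(design, yv, rcond=None)
            rss1 = float(rss1[0]) if len(rss1) else float(np.sum((yv - design @ beta) ** 2))
            assert res.table["lrs"].iloc[j] == pytest.approx(n * np.log(rss0 / rss1), abs=1e-8)
            assert res.table["additive"].iloc[j] == pytest.approx(beta[1], abs=1e-8)

    def test_too_few_strains(self, six_strain_scan):
        geno, y = six_strain_scan
        with pytest.raises(ValueError, match="at least 4"):
            u.hk_scan(u.expected_dosages(geno), y.iloc[:3])


class TestPermutationThresholds:
    def test_ordering_and_determinism(self, small_panel):
        geno, table, _ = small_panel
        grid = u.expected_dosages(geno, step_cm=100.0)
        y = u.strain_means(table, "amplitude_db")
        a = u.permutation_thresholds(grid, y, n_perm=500, seed=3)
        b = u.permutation_thresholds(grid, y, n_perm=500, seed=3)
        assert a == b
        assert a["significant"] >= a["suggestive"]

    def test_four_strain_exhaustive_null(self):
        """With 4 strains all 24 permutations are enumerable; the sampled
        quantiles must land inside the exhaustive null's atom range."""
        gmap = u.GeneticMap.regular(n_chromosomes=1, markers_per_chromosome=6, spacing_cm=10.0)
        geno = u.simulate_ri_genotypes(4, gmap, seed=5)
        grid = u.expected_dosages(geno, step_cm=100.0)
        yv = np.array([0.0, 1.0, 2.0, 4.0])
        maxima = []
        for perm in itertools.permutations(range(4)):
            res = u.hk_scan(grid, _means(geno.strains, yv[list(perm)]))
            maxima.append(res.table["lrs"].max())
        maxima = np.sort(maxima)
        thr = u.permutation_thresholds(grid, _means(geno.strains, yv), n_perm=2000, seed=6)
        assert np.quantile(maxima, 0.85) <= thr["significant"] <= maxima[-1]
        assert np.quantile(maxima, 0.25) <= thr["suggestive"] <= np.quantile(maxima, 0.5)

    def test_minimum_permutations(self, six_strain_scan):
        geno, y = six_strain_scan
        with pytest.raises(ValueError):
            u.permutation_thresholds(u.expected_dosages(geno), y, n_perm=50)


class TestSupportInterval:
    def _profile_scan(self, lods, mbs=None):
        n = len(lods)
        table = pd.DataFrame(
            {
                "chrom": ["1"] * n,
                "marker": [f"m{i}" for i in range(n)],
                "mb": mbs if mbs is not None else np.arange(1.0, n + 1),
                "cm": np.arange(float(n)),
                "lod": lods,
            }
        )
        table["lrs"] = table["lod"] * u.LRS_PER_LOD
        table["additive"] = 0.0
        return ScanResult(table=table)

    def test_hand_walkout(self):
        scan = self._profile_scan([0.0, 1.0, 3.0, 2.8, 1.2, 0.5])
        assert u.lod_support_interval(scan, 2) == (3.0, 4.0)
        assert u.lod_support_interval(scan, "m2") == (3.0, 4.0)

    def test_flat_profile_spans_chromosome(self):
        scan = self._profile_scan([2.0] * 5)
        assert u.lod_support_interval(scan, 0) == (1.0, 5.0)

    def test_peak_at_chromosome_edge(self):
        scan = self._profile_scan([4.0, 3.9, 1.0, 0.5])
        assert u.lod_support_interval(scan, 0)[0] == 1.0

    def test_unknown_peak(self):
        scan = self._profile_scan([1.0, 2.0, 1.0])
        with pytest.raises(KeyError):
            u.lod_support_interval(scan, "nope")


class TestBootstrapPeaks:
    def test_conservation_and_determinism(self, small_panel):
        geno, table, _ = small_panel
        grid = u.expected_dosages(geno, step_cm=100.0)
        y = u.strain_means(table, "amplitude_db")
        a = u.bootstrap_peaks(grid, y, n_boot=300, seed=7)
        b = u.bootstrap_peaks(grid, y, n_boot=300, seed=7)
        assert a.sum() == 300
        np.testing.assert_array_equal(a, b)

    def test_strong_qtl_modal_bin_near_causal(self, small_map):
        """Planted QTL at half the strain-mean variance: the bootstrap mode
        lands on or next to the causal marker in most pipeline replicates."""
        hits = 0
        reps = 20
        causal_name = small_map.markers["marker"].iloc[30]
        for i in range(reps):
            geno = u.simulate_ri_genotypes(41, small_map, seed=100 + i)
            config = u.SimConfig(
                strain_background=0.55, litter=0.0, residual=0.45,
                qtl=[(causal_name, 0.95)], day_effects=(0.0, 0.0, 0.0), seed=200 + i,
            )
            table = u.simulate_ri_phenotypes(geno, config)
            grid = u.expected_dosages(geno, step_cm=100.0)
            counts = u.bootstrap_peaks(grid, u.strain_means(table, "amplitude_db"),
                                       n_boot=200, seed=300 + i)
            mode = int(np.argmax(counts))
            hits += abs(mode - 30) <= 1
        assert hits / reps > 0.5


class TestKinship:
    def test_identical_strains_share_diagonal_value(self):
        markers = pd.DataFrame(
            {"marker": ["a", "b", "c"], "chrom": ["1"] * 3, "cm": [0.0, 5.0, 10.0],
             "mb": [3.0, 4.0, 5.0]}
        )
        codes = pd.DataFrame(
            {"s1": ["B", "D", "B"], "s2": ["B", "D", "B"], "s3": ["D", "B", "D"]},
            index=pd.Index(["a", "b", "c"], name="marker"),
        )
        k = u.kinship_matrix(u.GenotypeMatrix(markers=markers, codes=codes))
        assert k.values[0, 1] == pytest.approx(k.values[0, 0])

    def test_hand_computed_three_by_four(self):
        markers = pd.DataFrame(
            {"marker": list("abcd"), "chrom": ["1"] * 4, "cm": [0.0, 5, 10, 15],
             "mb": [3.0, 4, 5, 6]}
        )
        codes = pd.DataFrame(
            {"s1": ["B", "B", "D", "D"], "s2": ["B", "D", "B", "D"], "s3": ["D", "D", "D", "B"]},
            index=pd.Index(list("abcd"), name="marker"),
        )
        k = u.kinship_matrix(u.GenotypeMatrix(markers=markers, codes=codes))
        # dosage rows: s1=(-1,-1,1,1) s2=(-1,1,-1,1) s3=(1,1,1,-1)
        # column means (-1/3,1/3,1/3,1/3); centered Z rows:
        # s1=(-2/3,-4/3,2/3,2/3) s2=(-2/3,2/3,-4/3,2/3) s3=(4/3,2/3,2/3,-4/3)
        z = np.array([[-2, -4, 2, 2], [-2, 2, -4, 2], [4, 2, 2, -4]]) / 3.0
        np.testing.assert_allclose(k.values, z @ z.T / 4.0)
        eig = np.linalg.eigvalsh(k.values)
        assert eig.min() > -1e-12

    def test_independent_strains_near_zero_offdiagonal(self):
        # unlinked markers; large panel so the -1/(n-1) centering bias of the
        # sample-mean column centering is negligible
        gmap = u.GeneticMap.regular(n_chromosomes=2000, markers_per_chromosome=1)
        geno = u.simulate_ri_genotypes(100, gmap, seed=8)
        k = u.kinship_matrix(geno)
        off = k.values[~np.eye(100, dtype=bool)]
        assert np.abs(off).max() < 4.5 / np.sqrt(2000) + 1 / 99
        assert abs(off.mean()) < 0.02


class TestKinshipLMM:
    def test_identity_kinship_matches_plain_scan(self, small_panel):
        geno, table, _ = small_panel
        grid = u.expected_dosages(geno, step_cm=100.0)
        y = u.strain_means(table, "amplitude_db")
        hk = u.hk_scan(grid, y)
        ki = u.KinshipMatrix(values=np.eye(len(geno.strains)), strains=geno.strains)
        lmm = u.kinship_lmm_scan(grid, y, ki)
        from scipy.stats import spearmanr

        assert spearmanr(hk.table["lrs"], lmm.table["lrs"]).statistic > 0.99
        assert hk.peak_index() == lmm.peak_index()

    def test_negative_eigenvalue_rejected(self, small_panel):
        geno, table, _ = small_panel
        grid = u.expected_dosages(geno, step_cm=100.0)
        y = u.strain_means(table, "amplitude_db")
        bad = -np.eye(len(geno.strains))
        with pytest.raises(ValueError, match="positive semidefinite"):
            u.kinship_lmm_scan(grid, y, u.KinshipMatrix(values=bad, strains=geno.strains))
        with pytest.raises(ValueError, match="symmetric"):
            k = np.eye(len(geno.strains))
            k[0, 1] = 0.5
            u.KinshipMatrix(values=k, strains=geno.strains)

    def test_two_cluster_relatedness_shrinks_null_statistics(self, small_map):
        """Polygenic cluster structure inflates the plain scan; the mixed
        model absorbs it, so its mean null LRS is smaller."""
        rng = np.random.default_rng(9)
        geno = u.simulate_ri_genotypes(40, small_map, seed=10)
        grid = u.expected_dosages(geno, step_cm=100.0)
        cluster = np.repeat([0.0, 2.0], 20)
        k = u.kinship_matrix(geno).values
        k = k + 0.8 * (np.equal.outer(cluster, cluster).astype(float))
        hk_mean = []
        lmm_mean = []
        for _ in range(5):
            yv = cluster + rng.multivariate_normal(np.zeros(40), 0.5 * k + 0.2 * np.eye(40))
            y = _means(geno.strains, yv)
            hk_mean.append(u.hk_scan(grid, y).table["lrs"].mean())
            lmm_mean.append(
                u.kinship_lmm_scan(grid, y, u.KinshipMatrix(values=k, strains=geno.strains))
                .table["lrs"].mean()
            )
        assert np.mean(lmm_mean) < np.mean(hk_mean)


class TestPeakReport:
    def _geno_two_qtl(self):
        """Two marker blocks on one chromosome with exactly 8 strains
        carrying opposite parental alleles at the two peak markers."""
        n = 40
        rng = np.random.default_rng(11)
        m = 15
        markers = pd.DataFrame(
            {
                "marker": [f"m{i}" for i in range(m)],
                "chrom": ["14"] * m,
                "cm": np.arange(m) * 5.0,
                "mb": 40.0 + np.arange(m) * 2.5,
            }
        )
        left = rng.integers(0, 2, n)
        right = left.copy()
        flip = rng.choice(n, size=8, replace=False)
        right[flip] = 1 - right[flip]
        rows = []
        for j in range(m):
            if j < 5:
                src = left
            elif j >= 10:
                src = right
            else:  # uninformative middle block so the profile dips
                src = rng.integers(0, 2, n)
            rows.append(np.where(src == 1, "D", "B"))
        codes = pd.DataFrame(
            np.array(rows), index=pd.Index(markers["marker"], name="marker"),
            columns=[f"s{i}" for i in range(n)],
        )
        return u.GenotypeMatrix(markers=markers, codes=codes), left, right

    def test_empty_when_nothing_suggestive(self, six_strain_scan):
        geno, y = six_strain_scan
        scan = u.hk_scan(u.expected_dosages(geno), y)
        assert u.peak_report(scan, {"suggestive": 100.0, "significant": 200.0}) == []

    def test_two_peaks_with_eight_discordant_strains(self):
        geno, left, right = self._geno_two_qtl()
        yv = 1.0 * (2 * left - 1) + 1.0 * (2 * right - 1)
        scan = u.hk_scan(u.expected_dosages(geno, step_cm=100.0), _means(geno.strains, yv))
        lrs = scan.table["lrs"].to_numpy()
        # suggestive line chosen between the saddle and the two summits
        saddle = lrs[5:10].min()
        thresholds = {"suggestive": (saddle + lrs.max()) / 2, "significant": lrs.max() + 1}
        peaks = u.peak_report(scan, thresholds, geno)
        assert len(peaks) == 2
        assert all(p.discordant_with[q.marker] == 8 for p in peaks for q in peaks if p is not q)

    def test_overlapping_intervals_flagged(self):
        geno, left, right = self._geno_two_qtl()
        yv = 1.0 * (2 * left - 1) + 1.0 * (2 * right - 1)
        scan = u.hk_scan(u.expected_dosages(geno, step_cm=100.0), _means(geno.strains, yv))
        lrs = scan.table["lrs"].to_numpy()
        saddle = lrs[5:10].min()
        thresholds = {"suggestive": (saddle + lrs.max()) / 2, "significant": lrs.max() + 1}
        peaks = u.peak_report(scan, thresholds, geno, drop=100.0)  # huge drop -> whole chromosome
        assert all(p.overlaps_sibling for p in peaks)


def test_lod_is_lrs_over_4_61_everywhere(small_panel):
    geno, table, _ = small_panel
    grid = u.expected_dosages(geno, step_cm=1.0)
    res = u.hk_scan(grid, u.strain_means(table, "amplitude_db"))
    np.testing.assert_allclose(res.table["lod"], res.table["lrs"] / 4.61, rtol=0, atol=1e-12)
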