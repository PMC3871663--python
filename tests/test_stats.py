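"""Estimators: per-site pi, windowed pi/theta_W, Hudson F_ST, LD decay."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sweepqtl import stats
from sweepqtl.io_formats import Gene, GeneAnnotation, GenotypePanel, \
    PopulationMap

A9 = sum(1.0 / i for i in range(1, 10))  # harmonic number a_9


def make_panel(alleles, positions, chrom="chr1"):
    alleles = np.asarray(alleles, dtype=np.int8)
    n, m = alleles.shape
    sites = pd.DataFrame({
        "chrom": chrom, "pos": np.asarray(positions, dtype=np.int64),
        "ref": "A", "alt": "T", "qual": 500.0, "depth": 20.0,
        "site_class": "unknown"})
    return GenotypePanel([f"s{i}" for i in range(n)], alleles, sites)


def uniform_popmap(panel, label="pop"):
    return PopulationMap({s: label for s in panel.samples})


class TestSitePi:
    @pytest.mark.parametrize("alleles,expected", [
        ([0, 0, 1, 1], 2 / 3),   # 4 differing pairs of 6
        ([0, 0, 0, 0], 0.0),     # monomorphic
        ([0, 1], 1.0),           # the single pair differs
    ])
    def test_hand_enumerated_values(self, alleles, expected):
        assert stats.site_pi(np.array(alleles)) == pytest.approx(expected)

    def test_fewer_than_two_calls_is_undefined(self):
        assert np.isnan(stats.site_pi(np.array([0, -1, -1])))

    def test_missing_calls_equal_subsampling(self):
        # a missing call must behave exactly like removing that sample
        with_missing = np.array([0, 1, 1, -1])
        subset = np.array([0, 1, 1])
        assert stats.site_pi(with_missing) == stats.site_pi(subset)


class TestSlidingWindows:
    def test_enumerated_grid(self):
        grid = stats.sliding_windows(1_000_000, 500_000, 20_000)
        assert grid.n_windows == 50
        assert grid.starts[0] == 0 and grid.starts[-1] == 980_000
        assert np.all(grid.truncated == (grid.starts > 500_000))
        assert grid.ends[-1] == 1_000_000

    def test_short_chromosome_gives_one_truncated_window(self):
        grid = stats.sliding_windows(300, 500, 500)
        assert grid.n_windows == 1 and grid.truncated[0]
        assert grid.ends[0] == 300

    def test_step_equal_size_tiles(self):
        grid = stats.sliding_windows(1000, 100, 100)
        assert np.all(grid.starts == np.arange(0, 1000, 100))
        assert np.all(grid.ends - grid.starts == 100)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            stats.sliding_windows(1000, 100, 200)


class TestWindowDiversity:
    def test_watterson_from_segregating_count(self):
        # 16 segregating sites, n=10 everywhere, 1000 callable sites
        rng = np.random.default_rng(0)
        alleles = np.zeros((10, 16), dtype=np.int8)
        for j in range(16):
            k = rng.integers(1, 10)
            alleles[rng.choice(10, size=k, replace=False), j] = 1
        panel = make_panel(alleles, rng.choice(1000, 16, replace=False))
        grid = stats.sliding_windows(1000, 1000, 1000, "chr1")
        track = stats.window_diversity(panel, uniform_popmap(panel), grid,
                                       "pop")
        assert track["theta"].iloc[0] == pytest.approx(16 / (A9 * 1000))
        assert track["n_snps"].iloc[0] == 16

    def test_no_segregating_sites_gives_zero_theta(self):
        panel = make_panel(np.zeros((4, 0), dtype=np.int8), [])
        grid = stats.sliding_windows(100, 100, 100, "chr1")
        track = stats.window_diversity(panel, uniform_popmap(panel), grid,
                                       "pop")
        assert track["theta"].iloc[0] == 0.0
        assert track["pi"].iloc[0] == 0.0

    def test_genomewide_watterson_matches_published_scale(self):
        # S = 1,042,719 over 65,827,877 bp in n = 32 gives
        # theta_W ~ 0.39e-2, the value reported for the full rice panel
        theta = stats.watterson_theta(1_042_719, 32, 65_827_877)
        assert round(theta * 100, 2) == 0.39

    def test_missing_data_reduces_per_site_sample_size(self):
        # one missing call: site contributes 1/a_{n-2} to the theta sum
        alleles = np.array([[0], [1], [1], [-1]], dtype=np.int8)
        panel = make_panel(alleles, [5])
        grid = stats.sliding_windows(10, 10, 10, "chr1")
        track = stats.window_diversity(panel, uniform_popmap(panel), grid,
                                       "pop")
        a2 = 1.0 + 0.5
        assert track["theta"].iloc[0] == pytest.approx(1 / (a2 * 10))


class TestHudsonFst:
    def test_identical_frequencies_give_near_zero(self):
        # pairwise-difference within is the unbiased heterozygosity, so at
        # identical sample frequencies F_ST sits at -1/(2n-1), ~0 for
        # reasonable sample sizes
        n = 50
        col = np.array([0, 1] * (n // 2), dtype=np.int8)
        panel = make_panel(np.stack([col, col], axis=1)[
            np.concatenate([np.arange(n), np.arange(n)])], [10, 20])
        pm = PopulationMap({f"s{i}": ("A" if i < n else "B")
                            for i in range(2 * n)})
        assert stats.hudson_fst(panel, pm, "A", "B") == pytest.approx(
            0.0, abs=0.05)

    def test_fixed_difference_gives_one(self):
        alleles = np.array([[0]] * 4 + [[1]] * 4, dtype=np.int8)
        panel = make_panel(alleles, [10])
        pm = PopulationMap({f"s{i}": ("A" if i < 4 else "B")
                            for i in range(8)})
        assert stats.hudson_fst(panel, pm, "A", "B") == pytest.approx(1.0)

    def test_hand_enumerated_mixed_site(self):
        # popA = {A,A,T,T}, popB = {A,A,A,A}: within = 1/3, between = 1/2
        alleles = np.array([[0], [0], [1], [1],
                            [0], [0], [0], [0]], dtype=np.int8)
        panel = make_panel(alleles, [10])
        pm = PopulationMap({f"s{i}": ("A" if i < 4 else "B")
                            for i in range(8)})
        assert stats.hudson_fst(panel, pm, "A", "B") == pytest.approx(1 / 3)

    def test_zero_between_diversity_is_undefined(self):
        alleles = np.zeros((8, 1), dtype=np.int8)
        panel = make_panel(alleles, [10])
        pm = PopulationMap({f"s{i}": ("A" if i < 4 else "B")
                            for i in range(8)})
        assert np.isnan(stats.hudson_fst(panel, pm, "A", "B"))


class TestPerGeneSynonymousPi:
    def _setup(self, n_syn):
        gene = Gene("g1", "chr1", "+", 0, 20_000, cds=[(0, 18_000)],
                    exons=[(0, 20_000)])
        ann = GeneAnnotation([gene])
        ann.syn_sites["g1"] = np.arange(2, 2 + 3 * n_syn, 3)
        return ann

    def test_gene_below_threshold_excluded(self):
        ann = self._setup(999)
        panel = make_panel(np.zeros((10, 0), dtype=np.int8), [])
        out = stats.per_gene_synonymous_pi(panel, ann,
                                           uniform_popmap(panel), "pop")
        assert not out["included"].iloc[0]
        assert out["reason"].iloc[0] == "too_few_synonymous_sites"

    def test_only_first_thousand_sites_used(self):
        ann = self._setup(1500)
        used = ann.syn_sites["g1"][:1000]
        beyond = ann.syn_sites["g1"][1200]
        # SNP beyond the first 1000 synonymous sites must not count
        alleles = np.zeros((10, 2), dtype=np.int8)
        alleles[0, 0] = 1   # singleton inside the first 1000
        alleles[0, 1] = 1   # singleton beyond them
        panel = make_panel(alleles, [used[10], beyond])
        out = stats.per_gene_synonymous_pi(panel, ann,
                                           uniform_popmap(panel), "pop")
        single = 1 * 9 / (10 * 9 / 2)
        assert out["pi"].iloc[0] == pytest.approx(single / 1000)

    def test_five_singletons_hand_value(self):
        ann = self._setup(1200)
        pos = ann.syn_sites["g1"][:5]
        alleles = np.zeros((10, 5), dtype=np.int8)
        alleles[0, :] = 1
        panel = make_panel(alleles, pos)
        out = stats.per_gene_synonymous_pi(panel, ann,
                                           uniform_popmap(panel), "pop")
        assert out["pi"].iloc[0] == pytest.approx(0.001)
        assert out["n_segregating"].iloc[0] == 5

    def test_missing_annotation_is_error(self):
        ann = GeneAnnotation([])
        panel = make_panel(np.zeros((4, 0), dtype=np.int8), [])
        with pytest.raises(ValueError, match="synonymous-site map"):
            stats.per_gene_synonymous_pi(panel, ann,
                                         uniform_popmap(panel), "pop")


class TestLdDecay:
    def test_duplicated_site_has_r2_one(self):
        col = np.array([0, 0, 1, 1, 0, 1, 0, 1], dtype=np.int8)
        panel = make_panel(np.stack([col, col], axis=1), [100, 100 + 1])
        out = stats.ld_r2_decay(panel, uniform_popmap(panel), "pop",
                                max_dist=10, bin_size=10)
        assert out["mean_r2"].iloc[0] == pytest.approx(1.0)

    def test_two_by_two_haplotype_table(self):
        # haplotypes AB, AB, Ab, ab -> D = 0.125, r^2 = 1/3
        s1 = np.array([0, 0, 0, 1], dtype=np.int8)
        s2 = np.array([0, 0, 1, 1], dtype=np.int8)
        panel = make_panel(np.stack([s1, s2], axis=1), [0, 50])
        out = stats.ld_r2_decay(panel, uniform_popmap(panel), "pop",
                                max_dist=100, bin_size=100)
        assert out["mean_r2"].iloc[0] == pytest.approx(1 / 3)

    def test_unlinked_sites_mean_r2_near_reciprocal_n(self):
        rng = np.random.default_rng(42)
        n, m = 10, 60
        alleles = (rng.random((n, m)) < rng.uniform(0.3, 0.7, m)
                   ).astype(np.int8)
        panel = make_panel(alleles, np.arange(m) * 10)
        out = stats.ld_r2_decay(panel, uniform_popmap(panel), "pop",
                                max_dist=1000, bin_size=1000)
        mean = (out["mean_r2"] * out["n_pairs"]).sum() / \
            out["n_pairs"].sum()
        assert 0.05 < mean < 0.25  # E[r^2] ~ 1/n for unlinked sites

    def test_pairs_with_too_few_joint_calls_skipped(self):
        s1 = np.array([0, 1, -1, -1, -1], dtype=np.int8)
        s2 = np.array([0, 1, -1, -1, -1], dtype=np.int8)
        panel = make_panel(np.stack([s1, s2], axis=1), [0, 50])
        out = stats.ld_r2_decay(panel, uniform_popmap(panel), "pop",
                                max_dist=100, bin_size=100)
        assert out["n_pairs"].sum() == 0

    def test_subsampling_is_seed_reproducible(self):
        rng = np.random.default_rng(3)
        alleles = (rng.random((12, 30)) < 0.5).astype(np.int8)
        panel = make_panel(alleles, np.arange(30) * 100)
        a = stats.ld_r2_decay(panel, uniform_popmap(panel), "pop",
                              subsample=10, seed=5)
        b = stats.ld_r2_decay(panel, uniform_popmap(panel), "pop",
                              subsample=10, seed=5)
        pd.testing.assert_frame_equal(a, b)


@settings(deadline=None, max_examples=40, derandomize=True)
@given(st.integers(2, 12), st.integers(1, 30), st.integers(0, 10**6))
def test_estimator_invariants(n, m, seed):
    """0 <= window pi, theta_W >= 0, Hudson F_ST <= 1 on random panels."""
    rng = np.random.default_rng(seed)
    alleles = rng.choice(np.array([-1, 0, 1], dtype=np.int8),
                         size=(2 * n, m), p=[0.1, 0.5, 0.4])
    panel = make_panel(alleles, np.sort(rng.choice(10**6, m,
                                                   replace=False)))
    pm = PopulationMap({f"s{i}": ("A" if i < n else "B")
                        for i in range(2 * n)})
    grid = stats.sliding_windows(10**6, 10**6, 10**6, "chr1")
    for pop in ("A", "B"):
        tr = stats.window_diversity(panel, pm, grid, pop)
        assert tr["pi"].iloc[0] >= 0
        assert tr["theta"].iloc[0] >= 0
    fst = stats.hudson_fst(panel, pm, "A", "B")
    assert np.isnan(fst) or fst <= 1.0


def test_pi_theta_balance_on_neutral_data(neutral_panel):
    """On neutral data pi and theta_W estimate the same theta; a paired
    comparison across sub-windows should not reject their equality."""
    from scipy import stats as sps

    grid = stats.sliding_windows(300_000, 10_000, 10_000, "chr")
    track = stats.window_diversity(neutral_panel, None, grid, "wild")
    t, p = sps.ttest_rel(track["pi"], track["theta"])
    assert p > 0.001
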