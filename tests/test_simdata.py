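"""Simulator correctness: neutral expectations, sweep footprints, export."""

import numpy as np
import pytest

from sweepqtl import io_formats, simdata, stats
from sweepqtl.simdata import DemographicModel, GenomeConfig, SweepSpec


def _pi_sum(alleles):
    d, c = stats.allele_counts(alleles)
    return stats._site_pi_vec(d, c).sum()


class TestValidation:
    def test_zero_length_locus_rejected(self):
        with pytest.raises(ValueError):
            simdata.simulate_locus(simdata.default_model(), 2, 2, 0, seed=1)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            simdata.simulate_locus(simdata.default_model(), 1, 0, 100,
                                   seed=1)

    @pytest.mark.parametrize("kwargs", [
        {"N0": -1.0}, {"N1": 0.0}, {"T1": -5.0}, {"mu": -1e-9},
        {"rec": -1e-9}, {"s_wild": 1.0}, {"s_cult": -0.1},
        {"N0": float("nan")},
    ])
    def test_bad_model_parameters_rejected(self, kwargs):
        params = dict(N0=1000.0, N1=500.0, T1=100.0)
        params.update(kwargs)
        with pytest.raises(ValueError):
            DemographicModel(**params)

    def test_sweep_time_must_lie_within_bottleneck(self):
        with pytest.raises(ValueError):
            DemographicModel(N0=1000.0, N1=500.0, T1=100.0,
                             sweeps=(SweepSpec("c", 0, 1e5, t_fix=200.0),))

    def test_sweep_outside_genome_rejected(self):
        with pytest.raises(ValueError):
            GenomeConfig(chrom_lengths={"chr1": 1_000_000},
                         sweeps=(SweepSpec("chr1", 2_000_000, 1e5),))

    def test_missing_rate_one_rejected(self, neutral_panel):
        with pytest.raises(ValueError):
            simdata.degrade_panel(neutral_panel, 1.0, seed=1)


class TestNeutralExpectations:
    def test_no_mutation_means_no_sites(self):
        m = DemographicModel(N0=1000.0, N1=500.0, T1=100.0, mu=0.0)
        panel = simdata.simulate_locus(m, 4, 4, 10_000, seed=5)
        assert panel.n_sites == 0

    def test_mean_pairwise_diversity_matches_theta(self):
        # single population, n=2, theta = 4*N0*mu*L = 10 per locus
        m = DemographicModel(N0=2500.0, N1=2500.0, T1=None, mu=1e-6,
                             rec=0.0, s_wild=0.0, s_cult=0.0)
        rng = np.random.default_rng(101)
        diffs = 0
        R = 5000
        for _ in range(R):
            p = simdata.simulate_locus(m, 2, 0, 1000,
                                       seed=int(rng.integers(2**31)))
            diffs += int(np.sum(p.alleles[0] != p.alleles[1]))
        assert diffs / R == pytest.approx(10.0, rel=0.05)

    def test_pi_and_watterson_converge_to_theta(self):
        # E[pi] = E[S/a_{n-1}] = theta for a neutral constant-size locus
        theta = 10.0
        m = DemographicModel(N0=2500.0, N1=2500.0, T1=None, mu=1e-6,
                             rec=2e-6, s_wild=0.0, s_cult=0.0)
        rng = np.random.default_rng(77)
        n, R = 10, 800
        pis, ss = [], []
        for _ in range(R):
            p = simdata.simulate_locus(m, n, 0, 1000,
                                       seed=int(rng.integers(2**31)))
            pis.append(_pi_sum(p.alleles))
            ss.append(p.n_sites)
        a9 = sum(1.0 / i for i in range(1, n))
        assert np.mean(pis) == pytest.approx(theta, rel=0.07)
        assert np.mean(ss) / a9 == pytest.approx(theta, rel=0.07)

    def test_symmetric_split_fst_matches_closed_form(self):
        # tau = T / (2N) = 1  ->  Hudson F_ST = tau / (1 + tau) = 0.5
        N = 2500.0
        m = DemographicModel(N0=N, N1=N, T1=2 * N, mu=2e-6, rec=0.0,
                             s_wild=0.0, s_cult=0.0)
        rng = np.random.default_rng(11)
        w = b = 0.0
        for _ in range(800):
            p = simdata.simulate_locus(m, 10, 10, 1000,
                                       seed=int(rng.integers(2**31)))
            ws, bs, valid = stats.fst_site_components(p.alleles[:10],
                                                      p.alleles[10:])
            w += ws[valid].sum()
            b += bs[valid].sum()
        assert 1.0 - w / b == pytest.approx(0.5, abs=0.05)

    def test_agreement_with_independent_simulator(self):
        """Mean pi and the folded SFS agree with msprime on the same
        single-population parameters (within Monte-Carlo error)."""
        msprime = pytest.importorskip("msprime")
        N, mu, L, n, R = 2500.0, 1e-6, 10_000, 8, 300
        m = DemographicModel(N0=N, N1=N, T1=None, mu=mu, rec=1e-6,
                             s_wild=0.0, s_cult=0.0)
        rng = np.random.default_rng(55)
        pi_mine = np.zeros(R)
        sfs_mine = np.zeros(n - 1)
        for r in range(R):
            p = simdata.simulate_locus(m, n, 0, L,
                                       seed=int(rng.integers(2**31)))
            pi_mine[r] = _pi_sum(p.alleles)
            d, _ = stats.allele_counts(p.alleles)
            np.add.at(sfs_mine, d - 1, 1)
        pi_ms = np.zeros(R)
        sfs_ms = np.zeros(n - 1)
        reps = msprime.sim_ancestry(samples=n, ploidy=1,
                                    population_size=2 * N,
                                    recombination_rate=1e-6,
                                    sequence_length=L, num_replicates=R,
                                    random_seed=42)
        for r, ts in enumerate(reps):
            mts = msprime.sim_mutations(ts, rate=mu, random_seed=100 + r,
                                        discrete_genome=False)
            pi_ms[r] = mts.diversity(span_normalise=False)
            afs = mts.allele_frequency_spectrum(span_normalise=False,
                                                polarised=True)
            sfs_ms += afs[1:n]
        assert pi_mine.mean() == pytest.approx(pi_ms.mean(), rel=0.08)
        np.testing.assert_allclose(sfs_mine / R, sfs_ms / R, rtol=0.20)


class TestSweepOperator:
    def test_residual_diversity_at_sweep_center(self):
        """Post-sweep pairwise TMRCA at the center is the fixation time:
        per-site cultivated diversity ~ 2*mu*t_fix."""
        model = simdata.default_model(rec=0.0)
        sw = SweepSpec("c", 10_000, lam=200_000.0)
        rng = np.random.default_rng(3)
        tot = 0.0
        R, L = 2000, 20_000
        for _ in range(R):
            p = simdata.simulate_locus(model, 2, 22, L, sweep=sw,
                                       seed=int(rng.integers(2**31)))
            near = np.abs(p.positions - 10_000) < 2_000
            tot += _pi_sum(p.alleles[2:][:, near])
        expected = 2 * model.mu * model.T1  # t_fix defaults to T1
        assert tot / (R * 4000) == pytest.approx(expected, rel=0.10)

    def test_sweep_reduces_cultivated_diversity(self):
        """Paired over seeds: cultivated pi within 50 kb of the sweep is
        below the unswept background."""
        model = simdata.default_model()
        sw = SweepSpec("c", 50_000, lam=200_000.0)
        rng = np.random.default_rng(29)
        swept = neutral = 0.0
        for _ in range(40):
            seed = int(rng.integers(2**31))
            a = simdata.simulate_locus(model, 10, 22, 100_000, sweep=sw,
                                       seed=seed)
            b = simdata.simulate_locus(model, 10, 22, 100_000, seed=seed)
            swept += _pi_sum(a.alleles[10:])
            neutral += _pi_sum(b.alleles[10:])
        assert swept < neutral

    def test_sweep_requires_two_population_model(self):
        m = DemographicModel(N0=1000.0, N1=1000.0, T1=None)
        with pytest.raises(ValueError):
            simdata.simulate_locus(m, 2, 2, 1000,
                                   sweep=SweepSpec("c", 0, 1e5), seed=1)


class TestDegrade:
    def test_zero_missing_rate_keeps_calls(self, neutral_panel):
        out = simdata.degrade_panel(neutral_panel, 0.0, seed=4)
        np.testing.assert_array_equal(out.alleles, neutral_panel.alleles)
        assert out.qual is not None and out.depth is not None

    def test_missing_fraction_matches_rate(self):
        panel = simdata.HaplotypePanel(
            samples=[f"s{i}" for i in range(10)],
            populations=["wild"] * 10, L=100,
            positions=np.arange(100),
            alleles=np.tile(np.array([0, 1] * 5, dtype=np.int8)[:, None],
                            (1, 100)))
        out = simdata.degrade_panel(panel, 0.5, seed=8)
        frac = (out.alleles == io_formats.MISSING).mean()
        assert abs(frac - 0.5) < 0.05

    def test_monomorphic_sites_dropped(self):
        # one sample's derived allele at site 0: masking it leaves the
        # site monomorphic, which must remove it
        alleles = np.zeros((4, 2), dtype=np.int8)
        alleles[0, 0] = 1
        alleles[:2, 1] = 1
        panel = simdata.HaplotypePanel(["a", "b", "c", "d"], ["wild"] * 4,
                                       100, np.array([10, 20]), alleles)
        rng_hits = []
        for seed in range(50):
            out = simdata.degrade_panel(panel, 0.4, seed=seed)
            assert out.n_sites <= 2
            for j in range(out.n_sites):
                col = out.alleles[:, j]
                called = col[col >= 0]
                assert len(set(called.tolist())) == 2
            rng_hits.append(out.n_sites)
        assert min(rng_hits) < 2  # degradation does drop sites sometimes


class TestGenomeSynthesis:
    def test_truth_bookkeeping(self):
        model = simdata.default_model()
        cfg = GenomeConfig(chrom_lengths={"chr1": 400_000})
        bundle = simdata.synthesize_genome(cfg, model, seed=3)
        assert bundle.truth.sweeps == []
        sweeps = tuple(SweepSpec(f"chr{i+1}", 200_000, 1e5)
                       for i in range(3))
        cfg3 = GenomeConfig(chrom_lengths={f"chr{i+1}": 400_000
                                           for i in range(3)},
                            sweeps=sweeps)
        bundle3 = simdata.synthesize_genome(cfg3, model, seed=3)
        assert len(bundle3.truth.sweeps) == 3
        for sw in bundle3.truth.sweeps:
            assert 0 <= sw.pos < cfg3.chrom_lengths[sw.chrom]

    def test_same_seed_reproduces_identical_vcf(self, tmp_path):
        model = simdata.default_model()
        cfg = GenomeConfig(chrom_lengths={"chr1": 300_000})
        out = []
        for d in ("a", "b"):
            bundle = simdata.synthesize_genome(cfg, model, seed=99)
            paths = simdata.export_dataset(bundle, tmp_path / d)
            out.append(paths["vcf"].read_bytes())
        assert out[0] == out[1]

    def test_export_round_trip(self, small_bundle, tmp_path):
        paths = simdata.export_dataset(small_bundle, tmp_path / "ds")
        panel, popmap = io_formats.read_vcf_panel(paths["vcf"],
                                                  paths["popmap"])
        src = small_bundle.panel
        assert panel.samples == src.samples
        np.testing.assert_array_equal(panel.alleles, src.alleles)
        np.testing.assert_array_equal(panel.sites["pos"].to_numpy(),
                                      src.sites["pos"].to_numpy())
        np.testing.assert_allclose(panel.sites["qual"].to_numpy(),
                                   src.sites["qual"].to_numpy())
        np.testing.assert_allclose(panel.sites["depth"].to_numpy(),
                                   src.sites["depth"].to_numpy())
        assert popmap == small_bundle.popmap

    def test_vcf_contigs_match_fasta(self, small_bundle, tmp_path):
        paths = simdata.export_dataset(small_bundle, tmp_path / "ds")
        ref = io_formats.read_fasta(paths["fasta"])
        contigs = {}
        with open(paths["vcf"]) as fh:
            for line in fh:
                if line.startswith("##contig"):
                    name = line.split("ID=")[1].split(",")[0]
                    length = int(line.split("length=")[1].split(">")[0])
                    contigs[name] = length
                if not line.startswith("#"):
                    break
        assert contigs == {k: len(v) for k, v in ref.items()}

    def test_popmap_covers_all_vcf_samples(self, small_bundle, tmp_path):
        paths = simdata.export_dataset(small_bundle, tmp_path / "ds")
        popmap = io_formats.read_popmap(paths["popmap"])
        assert sorted(popmap.assignments) == sorted(
            small_bundle.panel.samples)

    def test_tile_engine_runs_and_is_flagged_distinct(self):
        model = simdata.default_model()
        p = simdata.simulate_locus(model, 4, 4, 30_000, seed=6,
                                   engine="tile", tile=1000)
        assert np.all(np.diff(p.positions) > 0)
        assert p.n_sites > 0
        with pytest.raises(ValueError):
            simdata.simulate_locus(model, 4, 4, 1000, seed=6,
                                   engine="nope")
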