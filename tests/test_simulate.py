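"""Simulator contracts: fork geometry, population kinetics, rendering, fixtures."""

import numpy as np
import pytest
from scipy.stats import norm

from replichron import (
    GeneAnnot,
    GenomeModel,
    Origin,
    SimConfig,
    evolve_acetylation,
    population_replication_fraction,
    render_chipseq,
    simulate_replication_timing,
    steady_state_acetylation,
    write_fixture,
)
from replichron.simulate import build_genes, build_genome, build_origins

PHI_1 = 0.8413447460685429  # standard normal CDF at 1


def plain_config(**kw):
    """Constant-turnover configuration: the closed-form kinetics apply exactly."""
    defaults = dict(
        n_chroms=1, chrom_length=30_000, origin_spacing=30_000,
        k_basal=0.0, lambda0=0.0, tss_decay_bp=None, arrest_program_tau=None,
        seed=5,
    )
    defaults.update(kw)
    return SimConfig(**defaults)


class TestReplicationTiming:
    def test_zero_distance_equals_firing_time(self):
        g = GenomeModel((("chr1", 10_000),))
        sched = simulate_replication_timing(g, [Origin("o", "chr1", 2_000, 10.0)], 1_500, 200)
        assert sched.times["chr1"][2_000 // 200] == 10.0

    def test_distance_over_speed(self):
        g = GenomeModel((("chr1", 10_000),))
        sched = simulate_replication_timing(g, [Origin("o", "chr1", 0, 10.0)], 1_500, 200)
        assert sched.times["chr1"][3_000 // 200] == pytest.approx(12.0)

    def test_two_origin_midpoint_takes_min(self):
        g = GenomeModel((("chr1", 40_000),))
        oris = [Origin("a", "chr1", 0, 10.0), Origin("b", "chr1", 30_000, 30.0)]
        sched = simulate_replication_timing(g, oris, 1_500, 200)
        # brute force over both origins at the midpoint
        assert sched.times["chr1"][15_000 // 200] == pytest.approx(min(10 + 10, 30 + 10))

    def test_piecewise_linear_slope_around_isolated_origin(self):
        g = GenomeModel((("chr1", 60_000),))
        sched = simulate_replication_timing(g, [Origin("o", "chr1", 30_000, 15.0)], 1_500, 200)
        T = sched.times["chr1"]
        diffs = np.diff(T)
        expected = 200 / 1_500
        b = 30_000 // 200
        np.testing.assert_allclose(diffs[:b], -expected)
        np.testing.assert_allclose(diffs[b:], expected)

    def test_lipschitz_bound_between_bins(self, toy_genome, toy_origins):
        sched = simulate_replication_timing(toy_genome, toy_origins, 1_500, 200)
        for c in toy_genome.names:
            assert np.all(np.abs(np.diff(sched.times[c])) <= 200 / 1_500 + 1e-12)

    def test_chromosome_without_origin_is_named(self, toy_genome):
        with pytest.raises(ValueError, match="chr2"):
            simulate_replication_timing(
                toy_genome, [Origin("o", "chr1", 100, 5.0)], 1_500, 200
            )


class TestPopulationFraction:
    @pytest.fixture
    def sched(self):
        g = GenomeModel((("chr1", 10_000),))
        return simulate_replication_timing(g, [Origin("o", "chr1", 0, 10.0)], 1_000, 200)

    def test_half_replicated_at_median_time(self, sched):
        T0 = sched.times["chr1"][0]
        F = population_replication_fraction(sched, float(T0), 4.0, "SR")
        assert F["chr1"][0] == pytest.approx(0.5)

    def test_one_sigma_after_median(self, sched):
        T = sched.times["chr1"]
        F = population_replication_fraction(sched, float(T[5]) + 4.0, 4.0, "SR")
        assert F["chr1"][5] == pytest.approx(PHI_1)

    def test_escape_fraction_is_the_late_limit(self, sched):
        F = population_replication_fraction(sched, 1e6, 4.0, "NR_IAA", escape_fraction=0.05)
        np.testing.assert_allclose(F["chr1"], 0.05)

    def test_monotone_in_time(self, sched):
        prev = None
        for t in [0, 5, 10, 20, 40]:
            F = population_replication_fraction(sched, t, 4.0, "SR")["chr1"]
            if prev is not None:
                assert np.all(F >= prev - 1e-15)
            prev = F

    def test_negative_escape_rejected(self, sched):
        with pytest.raises(ValueError):
            population_replication_fraction(sched, 10, 4.0, "NR_IAA", escape_fraction=-0.1)


class TestSteadyState:
    def test_no_turnover_reaches_ceiling(self):
        cfg = plain_config()
        g = build_genome(cfg)
        genes = [GeneAnnot("g1", "chrI", 1_000, 3_000, "+", 0.0)]
        a = steady_state_acetylation(g, genes, cfg)
        np.testing.assert_allclose(a.data["chrI"], cfg.a_max)

    def test_balance_at_equal_rates_is_half(self):
        # lambda == k_esa  =>  A_ss = a_max / 2 inside the gene
        cfg = plain_config(lambda0=0.005, k_esa=0.005, tss_decay_bp=None)
        g = build_genome(cfg)
        genes = [GeneAnnot("g1", "chrI", 10_000, 20_000, "+", 1.0)]
        a = steady_state_acetylation(g, genes, cfg)
        body = a.data["chrI"][10_000 // 200 : 20_000 // 200]
        np.testing.assert_allclose(body, cfg.a_max / 2)

    def test_non_increasing_in_expression(self):
        cfg = plain_config(lambda0=0.1)
        g = build_genome(cfg)
        genes = [
            GeneAnnot("g1", "chrI", 2_000, 6_000, "+", 1.0),
            GeneAnnot("g2", "chrI", 10_000, 14_000, "+", 10.0),
        ]
        a = steady_state_acetylation(g, genes, cfg)
        v1 = a.data["chrI"][2_000 // 200 : 6_000 // 200].mean()
        v2 = a.data["chrI"][10_000 // 200 : 14_000 // 200].mean()
        assert v1 > v2

    def test_all_zero_expression_is_uniform(self):
        cfg = plain_config()
        g = build_genome(cfg)
        genes = [GeneAnnot(f"g{i}", "chrI", 2_000 * i + 500, 2_000 * i + 1_500, "+", 0.0)
                 for i in range(3)]
        a = steady_state_acetylation(g, genes, cfg)
        assert np.ptp(a.data["chrI"]) == 0.0


class TestEvolution:
    def test_fixed_point_stays_constant(self):
        # writer on, no turnover, no background: p_sas == a_max == A_ss
        cfg = plain_config(k_esa=0.0, p_sas=0.8, a_max=0.8)
        g = build_genome(cfg)
        a_ss = steady_state_acetylation(g, [], cfg)
        sched = simulate_replication_timing(g, [Origin("o", "chrI", 15_000, 10.0)], 1_500, 200)
        for t in [0.0, 20.0, 60.0]:
            a = evolve_acetylation(a_ss, sched, cfg, "SR", True, t)
            np.testing.assert_allclose(a.data["chrI"], 0.8, atol=1e-12)

    def test_parental_dilution_halves_without_writer(self):
        # fully replicated, no kinetics: exactly half the arrest level remains
        cfg = plain_config(k_esa=0.0, a_max=0.8, firing_jitter=1e-6)
        g = build_genome(cfg)
        a_ss = steady_state_acetylation(g, [], cfg)  # 0.8 everywhere
        sched = simulate_replication_timing(g, [Origin("o", "chrI", 15_000, 0.0)], 1e9, 200)
        a = evolve_acetylation(a_ss, sched, cfg, "SR_IAA", False, 30.0)
        np.testing.assert_allclose(a.data["chrI"], 0.4, atol=1e-9)

    def test_turnover_decays_post_replication_value(self):
        # strong turnover pulls the deposition pulse back down as tau grows
        cfg = plain_config(k_esa=0.001, lambda0=0.1, firing_jitter=1e-6)
        g = build_genome(cfg)
        genes = [GeneAnnot("g1", "chrI", 0, 30_000, "+", 1.0)]
        a_ss = steady_state_acetylation(g, genes, cfg)
        sched = simulate_replication_timing(g, [Origin("o", "chrI", 15_000, 0.0)], 1e9, 200)
        early = evolve_acetylation(a_ss, sched, cfg, "SR", True, 2.0)
        late = evolve_acetylation(a_ss, sched, cfg, "SR", True, 40.0)
        assert late.data["chrI"].mean() < early.data["chrI"].mean()

    def test_stepped_integration_matches_closed_form_when_program_frozen(self):
        # arrest_program_tau = huge is numerically the constant-rate model
        base = plain_config(lambda0=0.05)
        g = build_genome(base)
        genes = [GeneAnnot("g1", "chrI", 5_000, 25_000, "+", 1.0)]
        sched = simulate_replication_timing(g, [Origin("o", "chrI", 15_000, 10.0)], 1_500, 200)
        exact_cfg = base
        stepped_cfg = SimConfig(**{**base.__dict__, "arrest_program_tau": 1e9})
        a_ss = steady_state_acetylation(g, genes, exact_cfg)
        for t in [15.0, 40.0]:
            exact = evolve_acetylation(a_ss, sched, exact_cfg, "SR", True, t)
            stepped = evolve_acetylation(a_ss, sched, stepped_cfg, "SR", True, t)
            np.testing.assert_allclose(
                stepped.data["chrI"], exact.data["chrI"], atol=5e-4
            )


class TestRendering:
    def test_zero_signal_zero_background_gives_zero_ip(self):
        cfg = plain_config(ip_background=0.0)
        g = build_genome(cfg)
        acetyl = steady_state_acetylation(g, [], cfg)
        for c in acetyl.data:
            acetyl.data[c][:] = 0.0
        ip, _, _ = render_chipseq(acetyl, cfg, "SR", 0.0, seed=1)
        assert np.all(ip.data["chrI"] == 0)

    def test_same_seed_reproduces_counts(self):
        cfg = plain_config()
        g = build_genome(cfg)
        acetyl = steady_state_acetylation(g, [], cfg)
        a = render_chipseq(acetyl, cfg, "SR", 0.0, seed=42)
        b = render_chipseq(acetyl, cfg, "SR", 0.0, seed=42)
        for c in g.names:
            np.testing.assert_array_equal(a[0].data[c], b[0].data[c])
            np.testing.assert_array_equal(a[1].data[c], b[1].data[c])
        assert a[2] == b[2]

    def test_spike_input_reads_match_admixture_expectation(self):
        # expected spike input reads = spike_fraction * expected sample input
        cfg = plain_config(
            chrom_length=2_000_000, origin_spacing=2_000_000,
            spike_fraction=0.04, read_depth=100.0,
        )
        g = build_genome(cfg)
        acetyl = steady_state_acetylation(g, [], cfg)
        _, inp, counts = render_chipseq(acetyl, cfg, "SR", 0.0, seed=3)
        expected = 0.04 * cfg.read_depth * g.n_bins("chrI", cfg.resolution)
        assert abs(counts.in_spike - expected) < 5 * np.sqrt(expected)

    def test_nonpositive_depth_rejected(self):
        with pytest.raises(ValueError):
            plain_config(read_depth=0.0)


class TestFixture:
    def test_default_grid_writes_42_bedgraphs(self, tmp_path):
        cfg = plain_config(chrom_length=20_000, origin_spacing=20_000, read_depth=5.0)
        files = write_fixture(cfg, tmp_path)
        bedgraphs = [f for f in files if f.endswith(".bedgraph")]
        assert len(bedgraphs) == 3 * 7 * 2

    def test_single_chromosome_everywhere(self, tmp_path):
        cfg = plain_config(chrom_length=20_000, origin_spacing=20_000, read_depth=5.0)
        write_fixture(cfg, tmp_path)
        assert (tmp_path / "genome.tsv").read_text().count("chrI") == 1
        beds = (tmp_path / "origins.bed").read_text() + (tmp_path / "genes.bed").read_text()
        chroms = {line.split("\t")[0] for line in beds.strip().splitlines()}
        assert chroms == {"chrI"}

    def test_same_seed_same_checksums(self, tmp_path):
        cfg = plain_config(chrom_length=20_000, origin_spacing=20_000, read_depth=5.0)
        a = write_fixture(cfg, tmp_path / "a")
        b = write_fixture(cfg, tmp_path / "b")
        assert a == b

    def test_balanced_expression_decorrelates_timing(self):
        # expression quartiles should have closely matched replication times
        cfg = SimConfig(seed=11)
        g = build_genome(cfg)
        oris = build_origins(cfg, g)
        genes = build_genes(cfg, g, oris)
        sched = simulate_replication_timing(g, oris, cfg.fork_speed, cfg.resolution)
        t_of = {
            gene.id: sched.times[gene.chrom][(gene.start + gene.end) // 2 // cfg.resolution]
            for gene in genes
        }
        by_expr = sorted(genes, key=lambda x: x.expression)
        q = len(genes) // 4
        lo = np.mean([t_of[x.id] for x in by_expr[:q]])
        hi = np.mean([t_of[x.id] for x in by_expr[-q:]])
        assert abs(lo - hi) < 1.5
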