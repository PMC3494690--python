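import numpy as np
import pytest

from poolld import pipeline, pool_sim
from poolld.pool_sim import (
    DemographicModel,
    ReadSimConfig,
    bottleneck_heterozygosity,
    generate_panel,
    pi,
    simulate_reads,
    true_r2,
    wf_equilibrium_panel,
    write_sam,
)


class TestGeneratePanel:
    def test_two_complementary_haplotypes_give_r2_one(self):
        panel = generate_panel(2, 200, 5, freq_spectrum="uniform", seed=1)
        for i in range(panel.n_sites - 1):
            assert true_r2(panel, i, i + 1) == pytest.approx(1.0)

    def test_injected_balanced_pair_has_zero_r2(self):
        panel = generate_panel(
            100, 500, 4, seed=2, injected_pairs=[(0, 1, (25, 25, 25, 25))]
        )
        assert true_r2(panel, 0, 1) == pytest.approx(0.0, abs=1e-12)

    def test_injected_pair_matches_hand_arithmetic(self):
        panel = generate_panel(
            100, 500, 4, seed=3, injected_pairs=[(0, 1, (60, 20, 10, 10))]
        )
        assert true_r2(panel, 0, 1) == pytest.approx(0.0016 / 0.0336)

    def test_bad_injection_counts_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            generate_panel(100, 500, 4, seed=4, injected_pairs=[(0, 1, (50, 20, 10, 10))])
        with pytest.raises(ValueError, match="monomorphic"):
            generate_panel(100, 500, 4, seed=4, injected_pairs=[(0, 1, (100, 0, 0, 0))])

    def test_columns_polymorphic_and_reproducible(self):
        a = generate_panel(50, 2000, 40, seed=7)
        b = generate_panel(50, 2000, 40, seed=7)
        assert np.array_equal(a.matrix, b.matrix)
        assert a.reference == b.reference
        tot = a.matrix.sum(axis=0)
        assert ((tot > 0) & (tot < a.n_hap)).all()

    def test_alt_alleles_differ_from_reference(self):
        p = generate_panel(10, 500, 20, seed=8)
        for j in range(p.n_sites):
            assert p.alt_bases[j].decode() != p.ref_base(j)


class TestPi:
    def test_monomorphic_panel(self):
        panel = generate_panel(10, 100, 2, seed=1)
        panel.matrix[:] = 0
        # bypass polymorphism invariant for the degenerate check
        assert pi(panel) == 0.0

    def test_single_site_half_frequency_two_haplotypes(self):
        panel = generate_panel(2, 100, 1, freq_spectrum="uniform", seed=2)
        assert pi(panel) == pytest.approx(1 / 100)

    def test_matches_all_pairs_hamming_oracle(self):
        panel = generate_panel(12, 300, 30, seed=5)
        m = panel.matrix.astype(int)
        total = 0
        npairs = 0
        for i in range(panel.n_hap):
            for j in range(i + 1, panel.n_hap):
                total += int(np.sum(m[i] != m[j]))
                npairs += 1
        assert pi(panel) == pytest.approx(total / npairs / panel.region_length)


class TestBottleneckHeterozygosity:
    def test_zero_duration_keeps_h0(self):
        assert bottleneck_heterozygosity(0.3, 50, 0) == 0.3

    def test_infinite_size_keeps_h0(self):
        assert bottleneck_heterozygosity(0.3, 1e12, 100) == pytest.approx(0.3)

    @pytest.mark.parametrize("nb", [47, 470])
    def test_half_size_half_duration_matches_to_first_order(self, nb):
        t = 84
        a = bottleneck_heterozygosity(0.3, nb, t)
        b = bottleneck_heterozygosity(0.3, nb / 2, t / 2)
        assert a == pytest.approx(b, rel=5 / nb)


class TestSimulateReads:
    def test_template_count_and_frequency_composition(self):
        panel = generate_panel(2, 2000, 10, freq_spectrum="uniform", seed=3)
        config = ReadSimConfig(mean_depth=200, insert_mean=300, insert_sd=20, seed=3)
        sim = simulate_reads(panel, config)
        assert sim.n_templates == round(200 * 2000 / (2 * 93))
        # 50/50 panel: pooled sampled allele frequency near 0.5 at every site
        freq = sim.truth["reads_alt"] / sim.truth["reads_total"]
        assert np.all(np.abs(freq - 0.5) < 0.15)

    def test_sam_round_trip_matches_truth_table(self, tmp_path):
        panel = generate_panel(20, 3000, 25, seed=9)
        config = ReadSimConfig(mean_depth=40, insert_mean=300, insert_sd=30,
                               error_rate=0.0, seed=9)
        sim = simulate_reads(panel, config)
        sam = tmp_path / "r.sam"
        write_sam(sim, sam)
        from poolld.pair_counting import TemplateIndex
        from poolld.variants_io import stream_templates

        index = TemplateIndex(stream_templates(sam, panel.sites(), min_baseq=20))
        for _, row in sim.truth.iterrows():
            counts = index.locus_counts(
                [s for s in panel.sites() if s.pos == row["pos"]][0]
            )
            assert counts.depth == row["reads_total"]
            assert counts.counts.get(row["alt_allele"], 0) == row["reads_alt"]

    def test_same_seed_same_sam_bytes(self, tmp_path):
        panel = generate_panel(10, 2000, 10, seed=4)
        for name in ("a.sam", "b.sam"):
            config = ReadSimConfig(mean_depth=20, insert_mean=300, insert_sd=30,
                                   error_rate=0.01, seed=11)
            write_sam(simulate_reads(panel, config), tmp_path / name)
        assert (tmp_path / "a.sam").read_bytes() == (tmp_path / "b.sam").read_bytes()

    def test_region_shorter_than_read_pair_rejected(self):
        panel = generate_panel(4, 150, 3, seed=5)
        with pytest.raises(ValueError, match="region"):
            simulate_reads(panel, ReadSimConfig(mean_depth=10, seed=0))

    def test_error_rate_perturbs_calls(self, tmp_path):
        panel = generate_panel(2, 2000, 8, freq_spectrum="uniform", seed=6)
        noisy = ReadSimConfig(mean_depth=50, insert_mean=300, insert_sd=20,
                              error_rate=0.2, seed=6)
        clean = ReadSimConfig(mean_depth=50, insert_mean=300, insert_sd=20,
                              error_rate=0.0, seed=6)
        write_sam(simulate_reads(panel, noisy), tmp_path / "n.sam")
        write_sam(simulate_reads(panel, clean), tmp_path / "c.sam")
        assert (tmp_path / "n.sam").read_text() != (tmp_path / "c.sam").read_text()


class TestWorkedExample:
    def test_partial_intersection_frequencies_through_pipeline(self, tmp_path):
        sam, tsv = pool_sim.write_worked_example(tmp_path)
        estimates, _ = pipeline.estimate_ld(
            sam, tsv, n_chrom=100, max_distance=200, min_intersecting=5
        )
        (e,) = estimates
        assert e.p_a == pytest.approx(3 / 5)
        assert e.p_a_all == pytest.approx(4 / 8)
        assert e.n == 5
        assert e.depth_a == 8


class TestWrightFisher:
    def test_equilibrium_diversity_near_theta(self):
        """Sampled π fluctuates around the neutral expectation 2·M·mu."""
        pis = [
            pi(wf_equilibrium_panel(40, 3000, theta=0.01, n0=50, seed=s,
                                    burn_in_factor=8))
            for s in range(3)
        ]
        assert 0.004 < float(np.mean(pis)) < 0.02

    def test_seed_reproducibility(self):
        a = pool_sim.wf_bottleneck_panel(
            DemographicModel(n0=30, nb=5, sample_size=10, theta=0.01), 1000, seed=2,
            burn_in_factor=5)
        b = pool_sim.wf_bottleneck_panel(
            DemographicModel(n0=30, nb=5, sample_size=10, theta=0.01), 1000, seed=2,
            burn_in_factor=5)
        assert np.array_equal(a.matrix, b.matrix)
        assert np.array_equal(a.positions, b.positions)

    def test_bottleneck_reduces_diversity(self):
        """A long, hard bottleneck loses most heterozygosity."""
        eq, bn = [], []
        for s in range(3):
            eq.append(pi(wf_equilibrium_panel(40, 3000, theta=0.01, n0=50, seed=s,
                                              burn_in_factor=8)))
            model = DemographicModel(n0=50, nb=3, t_bottleneck=2.0,
                                     sample_size=20, theta=0.01)
            bn.append(pi(pool_sim.wf_bottleneck_panel(model, 3000, seed=s,
                                                      burn_in_factor=8)))
        assert np.mean(bn) < 0.5 * np.mean(eq)

    def test_matched_trio_definitions(self):
        m = DemographicModel()
        s, mi = m.severe(), m.mild()
        assert (s.nb, s.t_bottleneck) == (m.nb / 2, m.t_bottleneck * 2)
        assert (mi.nb, mi.t_bottleneck) == (m.nb * 2, m.t_bottleneck / 2)
        # in 4·Ne units, all three bottlenecks span the same generations
        assert s.bottleneck_generations() == m.bottleneck_generations()
        assert mi.bottleneck_generations() == m.bottleneck_generations()
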