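"""The synthetic-data generator: K2P mutation process, element and genome
assembly, reads, and marker populations."""

import numpy as np
import pytest

from retroscape.dating import k2p, ltr_pair_age
from retroscape.io import revcomp
from retroscape.simulate import (PopulationTruth, build_genome,
                                 default_templates,
                                 generate_differentiated_truth,
                                 generate_population_truth, make_template,
                                 mutate_k2p, random_sequence,
                                 simulate_element, simulate_marker_population,
                                 simulate_reads)


@pytest.fixture(scope="module")
def rng():
    return np.random.default_rng(0)


class TestMutateK2P:
    def test_zero_divergence_returns_input(self, rng):
        seq = random_sequence(500, rng)
        assert mutate_k2p(seq, 0.0, seed=1) == seq

    def test_same_seed_is_deterministic(self, rng):
        seq = random_sequence(500, rng)
        assert mutate_k2p(seq, 0.04, seed=7) == mutate_k2p(seq, 0.04, seed=7)
        assert mutate_k2p(seq, 0.04, seed=7) != mutate_k2p(seq, 0.04, seed=8)

    def test_negative_divergence_rejected(self):
        with pytest.raises(ValueError):
            mutate_k2p("ACGT" * 10, -0.1)

    def test_mean_k2p_distance_matches_branch_length(self, rng):
        """Monte-Carlo: the K2P estimator applied to (input, output) is an
        unbiased estimate of the requested divergence (3-SE band)."""
        seq = random_sequence(10_000, rng)
        dists = [k2p(seq, mutate_k2p(seq, 0.04, ts_tv_ratio=2.0, seed=i)).K
                 for i in range(200)]
        se = np.std(dists) / np.sqrt(len(dists))
        assert abs(np.mean(dists) - 0.04) < 3 * se

    def test_transition_bias_follows_ts_tv_ratio(self, rng):
        """With ratio 2 the instantaneous process puts 2/3 of substitutions
        in transitions; observed P/Q at low divergence reflects that."""
        seq = random_sequence(50_000, rng)
        d = k2p(seq, mutate_k2p(seq, 0.03, ts_tv_ratio=2.0, seed=3))
        assert 1.5 < d.P / d.Q < 2.6


class TestSimulateElement:
    def test_age_zero_ltrs_identical(self, templates):
        seq, rec = simulate_element(templates[0], 0.0, seed=5)
        ltr5 = seq[rec.ltr5[0] - 1:rec.ltr5[1]]
        ltr3 = seq[rec.ltr3[0] - 1:rec.ltr3[1]]
        assert ltr5 == ltr3

    def test_negative_age_rejected(self, templates):
        with pytest.raises(ValueError):
            simulate_element(templates[0], -1.0)

    @pytest.mark.parametrize("age,expected_k", [(1.0, 0.04), (2.0, 0.08)])
    def test_expected_inter_ltr_divergence(self, templates, age, expected_k):
        """K = 2 r T: each LTR accumulates r*T substitutions per site."""
        ks = []
        for i in range(200):
            seq, rec = simulate_element(templates[0], age, seed=i)
            ks.append(k2p(seq[rec.ltr5[0] - 1:rec.ltr5[1]],
                          seq[rec.ltr3[0] - 1:rec.ltr3[1]]).K)
        se = np.std(ks) / np.sqrt(len(ks))
        assert abs(np.mean(ks) - expected_k) < 3 * se + 0.001

    def test_dating_round_trip_recovers_age(self, templates):
        ages = []
        for i in range(200):
            seq, rec = simulate_element(templates[1], 2.0, seed=3000 + i)
            ages.append(ltr_pair_age(seq[rec.ltr5[0] - 1:rec.ltr5[1]],
                                     seq[rec.ltr3[0] - 1:rec.ltr3[1]]).T)
        assert abs(np.mean(ages) - 2.0) < 0.1


class TestBuildGenome:
    def test_no_elements_genome_is_background(self, templates):
        sg = build_genome(templates, [], background_length=10_000, seed=1)
        assert sg.genome.total_length == 10_000
        assert sg.elements == [] and sg.truth_gff() == []

    def test_element_count_and_non_overlap(self, templates):
        specs = [(templates[0].lineage_name, 1.0, 25),
                 (templates[1].lineage_name, 2.0, 25)]
        sg = build_genome(templates, specs, background_length=1_500_000,
                          seed=9, nesting_fraction=0.0)
        assert len(sg.elements) == 50
        spans = sorted((r.start, r.end) for r in sg.elements)
        assert all(a[1] < b[0] for a, b in zip(spans, spans[1:]))

    def test_truth_coordinates_slice_real_ltrs(self, templates):
        """Truth conservation: the recorded LTR intervals of every element
        (ages <= 2 MYA) cut out sequences above the default 85% detection
        identity."""
        specs = [(t.lineage_name, a, 2) for t in templates for a in (1.0, 2.0)]
        sg = build_genome(templates, specs, background_length=400_000, seed=3)
        for rec in sg.elements:
            l5 = sg.genome.fetch(rec.chrom, *rec.ltr5)
            l3 = sg.genome.fetch(rec.chrom, *rec.ltr3)
            ident = 100.0 * np.mean([a == b for a, b in zip(l5, l3)])
            assert ident >= 85.0

    def test_tsd_flanks_elements(self, templates):
        specs = [(templates[0].lineage_name, 1.0, 5)]
        sg = build_genome(templates, specs, background_length=200_000, seed=4)
        chrom_seq = sg.genome.sequences["chr1"]
        for rec in sg.elements:
            d = len(rec.tsd)
            left = chrom_seq[rec.start - 1 - d:rec.start - 1]
            right = chrom_seq[rec.end:rec.end + d]
            assert left == right == rec.tsd

    def test_nesting_records_host(self, templates):
        specs = [(templates[0].lineage_name, 1.0, 10)]
        sg = build_genome(templates, specs, background_length=600_000,
                          seed=11, nesting_fraction=0.4)
        nested = [r for r in sg.elements if r.nested_in]
        assert nested
        hosts = {r.element_id: r for r in sg.elements}
        for r in nested:
            host = hosts[r.nested_in]
            assert host.start <= r.start and r.end <= host.end

    def test_determinism_same_seed_byte_identical(self, templates):
        specs = [(templates[0].lineage_name, 1.0, 3)]
        a = build_genome(templates, specs, background_length=100_000, seed=8)
        b = build_genome(templates, specs, background_length=100_000, seed=8)
        assert a.genome.sequences == b.genome.sequences
        assert [(r.element_id, r.start, r.end) for r in a.elements] == \
               [(r.element_id, r.start, r.end) for r in b.elements]

    def test_capacity_error(self, templates):
        specs = [(templates[0].lineage_name, 1.0, 40)]
        with pytest.raises(ValueError, match="background too short"):
            build_genome(templates, specs, background_length=5_000, seed=1)


class TestSimulateReads:
    def test_read_count_arithmetic(self, rng):
        from retroscape.io import Genome
        g = Genome({"c": random_sequence(85_000, rng)})
        reads = simulate_reads(g, coverage=1.0, read_length=85, seed=1)
        assert len(reads) == 1000

    def test_error_free_reads_are_genome_substrings(self, rng):
        from retroscape.io import Genome
        seq = random_sequence(5_000, rng)
        g = Genome({"c": seq})
        reads = simulate_reads(g, coverage=2.0, error_rate=0.0, seed=2)
        for _, r in reads[:200]:
            assert r in seq or revcomp(r) in seq

    def test_read_longer_than_genome_rejected(self, rng):
        from retroscape.io import Genome
        g = Genome({"c": random_sequence(50, rng)})
        with pytest.raises(ValueError):
            simulate_reads(g, coverage=1.0, read_length=85)


class TestMarkerPopulation:
    def test_fixed_presence_allele_gives_all_ones(self):
        truth = PopulationTruth(5, 1, np.ones((1, 10)), np.ones((5, 1)))
        y = simulate_marker_population(truth, seed=1)
        assert (y.to_numpy() == 1).all()

    def test_absent_allele_gives_all_zeros(self):
        truth = PopulationTruth(5, 1, np.zeros((1, 10)), np.ones((5, 1)))
        y = simulate_marker_population(truth, seed=1)
        assert (y.to_numpy() == 0).all()

    def test_invalid_q_rows_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            PopulationTruth(2, 2, np.full((2, 5), 0.5),
                            np.array([[0.6, 0.6], [0.5, 0.5]]))

    def test_band_frequency_matches_dominant_model(self):
        """P(band) = 1 - (sum_k Q_ik (1-f_kl))^2 for the diploid dominant
        marker."""
        truth = generate_population_truth(40, 2, 400, seed=5)
        y = simulate_marker_population(truth, seed=6).to_numpy()
        a = truth.Q_true @ (1 - truth.allele_freqs)
        expect = 1 - a ** 2
        assert abs(y.mean() - expect.mean()) < 0.02

    def test_differentiated_truth_patterns_are_non_constant(self):
        truth = generate_differentiated_truth(20, 3, 50, seed=2)
        f = truth.allele_freqs
        # every locus separates at least one pair of subpopulations
        assert (np.ptp(f, axis=0) > 0.3).all()
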