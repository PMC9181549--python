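"""In-silico IRAP: primer scanning, amplicon prediction, band matrices,
PCA ordination."""

import numpy as np
import pandas as pd
import pytest

from retroscape.io import Genome, revcomp
from retroscape.irap import (Amplicon, PrimerSite, band_matrix,
                             find_primer_sites, load_primers, pca,
                             polymorphic_bands, predict_amplicons)
from retroscape.simulate import random_sequence

ANG5 = "TTCAAGAATCACACCCTCTA"  # the bundled ANG 5+ forward primer


def _bg(n, seed=0):
    return random_sequence(n, np.random.default_rng(seed))


class TestFindPrimerSites:
    def test_single_planted_site_on_plus_strand(self):
        g = Genome({"c": _bg(5000) + ANG5 + _bg(5000, 1)})
        sites = find_primer_sites(g, ANG5)
        assert len(sites) == 1
        (s,) = sites
        assert (s.strand, s.mismatches) == ("+", 0)
        assert s.position == 5000 + len(ANG5)   # 3' end coordinate

    def test_reverse_complement_genome_mirrors_site(self):
        g = Genome({"c": _bg(5000) + ANG5 + _bg(5000, 1)})
        grc = Genome({"c": revcomp(g.sequences["c"])})
        sites = find_primer_sites(grc, ANG5)
        assert len(sites) == 1 and sites[0].strand == "-"
        # 3' end maps to the mirrored coordinate
        assert sites[0].position == len(grc.sequences["c"]) - (5000 + 20) + 1

    def test_planted_copy_number_is_recovered(self):
        """A primer planted n times is found exactly n times (the scan is a
        census, like the 2271-copy genome count it emulates)."""
        from retroscape.simulate import plant_primer_sites
        seq = list(_bg(400_000, seed=3))
        rng = np.random.default_rng(4)
        planted = plant_primer_sites(seq, ANG5, [("c", 1, 400_000)], 137,
                                     rng, "c")
        g = Genome({"c": "".join(seq)})
        sites = find_primer_sites(g, ANG5)
        assert len(sites) == len(planted) == 137
        assert {(s.chrom, s.position, s.strand) for s in sites} == set(planted)

    def test_one_internal_mismatch_tolerated_but_not_three_prime(self):
        site = list(ANG5)
        site[5] = "G" if site[5] != "G" else "T"       # internal mismatch
        g = Genome({"c": _bg(2000) + "".join(site) + _bg(2000, 5)})
        sites = find_primer_sites(g, ANG5, max_mismatches=1)
        assert len(sites) == 1 and sites[0].mismatches == 1
        bad = list(ANG5)
        bad[-1] = "G" if bad[-1] != "G" else "T"        # 3'-terminal mismatch
        g = Genome({"c": _bg(2000) + "".join(bad) + _bg(2000, 5)})
        assert find_primer_sites(g, ANG5, max_mismatches=1) == []

    def test_iupac_degenerate_primer_matches_both_variants(self):
        rnase = "ATGGGACTTCGWTATTCTAGTG"   # W = A or T
        for base in "AT":
            g = Genome({"c": _bg(1000) + rnase.replace("W", base)
                        + _bg(1000, 6)})
            assert len(find_primer_sites(g, rnase)) == 1

    def test_invalid_primers_rejected(self):
        g = Genome({"c": _bg(100)})
        with pytest.raises(ValueError, match="IUPAC"):
            find_primer_sites(g, "ACGTACGTACGTACGTACZ5")
        with pytest.raises(ValueError, match="length"):
            find_primer_sites(g, "ACGT")

    def test_bundled_primer_panel(self):
        primers = load_primers()
        assert len(primers) == 11
        assert (primers.loc[primers.code == "ANG_5+", "sequence"].iloc[0]
                == ANG5)


class TestPredictAmplicons:
    def _site(self, pos, strand, m=20):
        return PrimerSite("c", pos, strand, 0, m)

    def test_facing_pair_yields_one_amplicon_with_span_between_five_primes(self):
        # + site 3' end at 1020 (5' end 1001), - site 3' end at 1481
        # (5' end 1500): product = inclusive span 1001..1500 = 500 bp
        sites = [self._site(1020, "+"), self._site(1481, "-")]
        (amp,) = predict_amplicons(sites)
        assert (amp.start, amp.end, amp.length) == (1001, 1500, 500)

    def test_distant_pair_filtered_by_length(self):
        sites = [self._site(1020, "+"), self._site(6000, "-")]
        assert predict_amplicons(sites) == []
        assert len(predict_amplicons(sites, max_len=10_000)) == 1

    def test_wrong_orientation_yields_nothing(self):
        # reverse site upstream of forward site: primers point apart
        sites = [self._site(1481, "+"), self._site(1020, "-")]
        assert predict_amplicons(sites) == []

    def test_adjacent_inverted_elements_give_one_inter_element_amplicon(self):
        """Two neighbouring elements, each contributing one outward-facing
        primer site near its element-terminal LTR: the only possible product
        is the single inter-element one spanning the spacer."""
        elem_fwd = _bg(250, 7) + _bg(2000, 9) + _bg(100, 8) + ANG5 + _bg(30, 20)
        spacer = _bg(400, 10)
        genome = Genome({"c": _bg(3000, 11) + elem_fwd + spacer
                         + revcomp(elem_fwd) + _bg(3000, 12)})
        sites = find_primer_sites(genome, ANG5)
        assert {s.strand for s in sites} == {"+", "-"} and len(sites) == 2
        amps = predict_amplicons(sites)
        assert len(amps) == 1
        # the product spans the inter-element region
        amp = amps[0]
        assert amp.forward_site.strand == "+"
        assert amp.reverse_site.strand == "-"
        assert amp.length == 400 + 2 * (30 + len(ANG5))

    def test_amplicon_lengths_invariant_under_reverse_complement(self):
        seq = _bg(2000, 13) + ANG5 + _bg(700, 14) + revcomp(ANG5) \
            + _bg(500, 15) + ANG5 + _bg(900, 16) + revcomp(ANG5) + _bg(2000, 17)
        g = Genome({"c": seq})
        grc = Genome({"c": revcomp(seq)})
        lens = sorted(a.length
                      for a in predict_amplicons(find_primer_sites(g, ANG5)))
        lens_rc = sorted(a.length
                         for a in predict_amplicons(find_primer_sites(grc,
                                                                      ANG5)))
        assert lens and lens == lens_rc


class TestBandMatrix:
    def test_identical_accessions_identical_rows(self):
        amps = {"B": [500, 800, 1200], "B1": [500, 800, 1200],
                "B3": [502, 799, 1210]}  # within 2% co-binning
        m = band_matrix(amps)
        assert (m.loc["B"] == m.loc["B1"]).all()
        assert (m.loc["B"] == m.loc["B3"]).all()

    def test_private_band_is_single_one_column(self):
        m = band_matrix({"a": [500, 3000], "b": [500]})
        private = [c for c in m.columns if m[c].sum() == 1]
        assert len(private) == 1 and m.loc["a", private[0]] == 1

    def test_segregating_loci_count_recovered(self):
        """39 segregating insertion loci across a population come back as
        39 polymorphic bands (plus monomorphic shared ones)."""
        rng = np.random.default_rng(18)
        shared = [300, 2500]
        loci = sorted(rng.choice(np.arange(400, 2400, 8), size=39,
                                 replace=False))
        present = rng.random((12, 39)) < 0.5
        present[0, :] = True   # ensure every locus occurs at least once
        present[1, :] = False  # ...and is absent somewhere
        amps = {f"acc{i}": shared + [loci[j] for j in range(39)
                                     if present[i, j]]
                for i in range(12)}
        m = band_matrix(amps, size_tolerance=0.001)
        assert len(polymorphic_bands(m)) == 39

    def test_needs_two_accessions(self):
        with pytest.raises(ValueError):
            band_matrix({"only": [100]})


class TestPCA:
    def test_identical_rows_identical_coordinates(self):
        m = pd.DataFrame([[1, 0, 1], [1, 0, 1], [0, 1, 0]],
                         index=list("abc"))
        scores, _ = pca(m)
        assert np.allclose(scores.loc["a"], scores.loc["b"])

    def test_rank_one_matrix_explained_by_pc1(self):
        m = pd.DataFrame([[1, 1, 0, 0]] * 3 + [[0, 0, 1, 1]] * 3)
        scores, evr = pca(m)
        assert evr[0] == pytest.approx(1.0)

    def test_two_groups_separate_on_pc1(self):
        rng = np.random.default_rng(19)
        a = (rng.random((10, 30)) < 0.9).astype(int)
        b = (rng.random((10, 30)) < 0.1).astype(int)
        m = pd.DataFrame(np.vstack([a, b]))
        scores, _ = pca(m)
        pc1 = scores["PC1"].to_numpy()
        separation = abs(pc1[:10].mean() - pc1[10:].mean())
        assert separation > pc1[:10].std() + pc1[10:].std()

    def test_constant_matrix_rejected(self):
        m = pd.DataFrame(np.ones((4, 5), dtype=int))
        with pytest.raises(ValueError, match="variance"):
            pca(m)
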