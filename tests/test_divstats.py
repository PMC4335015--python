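import itertools
import math

import numpy as np
import pytest

from sweepwatch.divstats import (
    ChromosomeClassing,
    diversity_profile,
    haplotype_count,
    nucleotide_diversity,
    thin_variants,
)
from sweepwatch.hapio import VariantSite, Window, WindowSet
from conftest import make_matrix, random_matrix


def pi_bruteforce(hap, window, rows, denominator="bp"):
    """Independent oracle: explicit double loop over pairs and sites."""
    in_window = [
        j for j, s in enumerate(hap.sites)
        if s.chrom == window.chrom and window.start <= s.pos - 1 < window.end
    ]
    denom = (
        window.end - window.start if denominator == "bp"
        else max(len(in_window), 1)
    )
    per_pair = []
    for i, k in itertools.combinations(rows, 2):
        diff = sum(int(hap.data[i, j] != hap.data[k, j]) for j in in_window)
        per_pair.append(diff / denom)
    return sum(per_pair) / len(per_pair)


def pi_frequency_form(hap, window, rows):
    """Second independent route: pi = sum_s 2 p (1-p) n/(n-1) / length."""
    n = len(rows)
    total = 0.0
    for j, s in enumerate(hap.sites):
        if s.chrom == window.chrom and window.start <= s.pos - 1 < window.end:
            p = float(np.mean([hap.data[i, j] for i in rows]))
            total += 2 * p * (1 - p) * n / (n - 1)
    return total / (window.end - window.start)


W = Window("w", "chr1", 0, 1000)


class TestNucleotideDiversity:
    def test_identical_chromosomes(self):
        hap = make_matrix(["10101", "10101"])
        r = nucleotide_diversity(hap, W, [0, 1])
        assert r.pi == 0.0 and r.sem == 0.0

    def test_single_pair_three_differences(self):
        hap = make_matrix(["000", "111"], positions=[10, 20, 30])
        r = nucleotide_diversity(hap, W, [0, 1])
        assert r.pi == pytest.approx(0.003)
        assert r.n_pairs == 1 and r.n_sites == 3

    def test_four_chromosomes_five_sites_hand_enumeration(self):
        # pairwise differing-site counts: 1+2+5+1+4+3 = 16 over 6 pairs
        hap = make_matrix(["00000", "00001", "00011", "11111"],
                          positions=[100, 200, 300, 400, 500])
        r = nucleotide_diversity(hap, W, range(4))
        assert r.pi == pytest.approx(16 / 6 / 1000)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_both_independent_oracles(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 13))
        m = int(rng.integers(1, 51))
        hap = random_matrix(rng, n, m)
        w = Window("w", "chr1", 0, int(hap.positions.max()) + 50)
        rows = list(range(n))
        got = nucleotide_diversity(hap, w, rows).pi
        assert got == pytest.approx(pi_bruteforce(hap, w, rows), abs=1e-15)
        assert got == pytest.approx(pi_frequency_form(hap, w, rows), abs=1e-12)

    def test_invariant_to_row_order_and_label_swap(self):
        rng = np.random.default_rng(3)
        hap = random_matrix(rng, 8, 20)
        w = Window("w", "chr1", 0, 3000)
        base = nucleotide_diversity(hap, w, range(8)).pi
        perm = rng.permutation(8)
        assert nucleotide_diversity(hap, w, perm).pi == pytest.approx(base)
        flipped = hap.data.copy()
        flipped[:, 5] = 1 - flipped[:, 5]
        hap2 = make_matrix(flipped, positions=hap.positions,
                           ids=[f"c{i}" for i in range(8)])
        assert nucleotide_diversity(hap2, w, range(8)).pi == pytest.approx(base)

    def test_concatenation_of_equal_windows_averages(self):
        rng = np.random.default_rng(4)
        hap = random_matrix(rng, 6, 30)
        lo, hi = Window("a", "chr1", 0, 1500), Window("b", "chr1", 1500, 3000)
        both = Window("ab", "chr1", 0, 3000)
        pa = nucleotide_diversity(hap, lo, range(6)).pi
        pb = nucleotide_diversity(hap, hi, range(6)).pi
        pab = nucleotide_diversity(hap, both, range(6)).pi
        assert pab == pytest.approx((pa + pb) / 2)

    def test_fewer_than_two_chromosomes_raises(self):
        hap = make_matrix(["01", "10"])
        with pytest.raises(ValueError, match="at least 2"):
            nucleotide_diversity(hap, W, [0])

    def test_per_site_denominator(self):
        hap = make_matrix(["000", "111"], positions=[10, 20, 30])
        r = nucleotide_diversity(hap, W, [0, 1], denominator="sites")
        assert r.pi == pytest.approx(1.0)


class TestDiversityProfile:
    def _classing(self, hap, derived_ids, mel_samples):
        return ChromosomeClassing(
            {cid: ("derived" if cid in derived_ids else "ancestral")
             for cid in hap.chrom_ids},
            {s: ("melanistic" if s in mel_samples else "non_melanistic")
             for s in hap.sample_ids},
            [],
        )

    def test_small_class_reports_nan_not_zero(self):
        hap = make_matrix(["0011", "0011", "0101", "1111"])
        classing = self._classing(hap, {"S001_A"}, set())
        df = diversity_profile(hap, WindowSet((W,)), classing)
        derived = df[df["class"] == "derived"].iloc[0]
        assert derived["n_chrom"] == 1
        assert math.isnan(derived["pi"])
        anc = df[df["class"] == "ancestral"].iloc[0]
        assert anc["pi"] >= 0

    def test_window_permutation_permutes_rows_only(self):
        hap = make_matrix(["0011", "0111", "0101", "1111"],
                          positions=[100, 600, 1100, 1600])
        wa, wb = Window("A", "chr1", 0, 1000), Window("B", "chr1", 1000, 2000)
        classing = self._classing(hap, {"S001_A", "S001_B"}, {"S001"})
        d1 = diversity_profile(hap, WindowSet((wa, wb)), classing)
        d2 = diversity_profile(hap, WindowSet((wb, wa)), classing)
        k = ["window", "class"]
        assert (
            d1.sort_values(k).reset_index(drop=True)
            .equals(d2.sort_values(k).reset_index(drop=True))
        )

    def test_individual_class_uses_both_chromosomes(self):
        hap = make_matrix(["0011", "0111", "0101", "1111"])
        classing = self._classing(hap, {"S001_A"}, {"S001"})
        df = diversity_profile(hap, WindowSet((W,)), classing,
                               by="individual_class")
        mel = df[df["class"] == "melanistic"].iloc[0]
        assert mel["n_chrom"] == 2  # both chromosomes of the melanistic sample


class TestHaplotypeCount:
    def test_all_identical(self):
        hap = make_matrix(["0101"] * 5)
        assert haplotype_count(hap, W, range(5)) == 1

    def test_all_distinct(self):
        hap = make_matrix(["000", "001", "010", "100"])
        assert haplotype_count(hap, W, range(4)) == 4

    def test_empty_window_counts_one(self):
        hap = make_matrix(["01", "10"])
        w = Window("far", "chr1", 5000, 6000)
        assert haplotype_count(hap, w, [0, 1]) == 1

    def test_empty_subset_raises(self):
        hap = make_matrix(["01", "10"])
        with pytest.raises(ValueError, match="empty"):
            haplotype_count(hap, W, [])


class TestThinVariants:
    def s(self, pos, qual=None):
        return VariantSite("chr1", pos, "A", "T", quality=qual)

    def test_ten_sites_one_bin_keeps_one(self):
        sites = [self.s(p, 10) for p in range(10, 1001, 100)]
        assert len(thin_variants(sites)) == 1

    def test_three_bins_keep_all(self):
        sites = [self.s(500), self.s(1500), self.s(2500)]
        assert thin_variants(sites) == sites

    def test_quality_tie_keeps_smallest_position(self):
        sites = [self.s(10, 5), self.s(20, 9), self.s(30, 9)]
        kept = thin_variants(sites)
        assert [x.pos for x in kept] == [20]

    def test_missing_quality_keeps_smallest_position(self):
        sites = [self.s(10), self.s(20), self.s(30)]
        assert [x.pos for x in thin_variants(sites)] == [10]

    def test_bins_anchor_at_origin(self):
        # origin 500: bin edges at 500, 1500 -> sites 600 and 1600 both kept
        sites = [self.s(600, 1), self.s(1600, 1)]
        assert len(thin_variants(sites, origin=500)) == 2
        assert len(thin_variants(sites, origin=0)) == 2
        # but 600 and 1400 share a bin when origin=500
        sites2 = [self.s(600, 2), self.s(1400, 1)]
        assert [x.pos for x in thin_variants(sites2, origin=500)] == [600]

    def test_unsorted_input_raises(self):
        with pytest.raises(ValueError, match="sorted"):
            thin_variants([self.s(20), self.s(10)])
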