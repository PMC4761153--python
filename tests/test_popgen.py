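"""Unit oracles for the SFS statistics.

Expected values are frozen from independent derivations: exact-Fractions
recomputation of the Tajima (1989) and corrected Fu-Li (1993 p.701 /
Simonsen 1995) constants, and brute-force pairwise enumeration over
explicit haplotype matrices.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sfsweep.popgen import (
    InvalidSampleSizeError,
    SiteFrequencySpectrum,
    StatisticUndefinedError,
    fu_li_D_star,
    fu_li_constants,
    harmonic_numbers,
    nucleotide_diversity,
    sfs_from_genotypes,
    tajima_D,
    tajima_constants,
    watterson_theta,
)


def sfs(n_seq, count_dict, n_sites, site_class="unlabeled"):
    counts = np.zeros(n_seq // 2, dtype=np.int64)
    for m, c in count_dict.items():
        counts[m - 1] = c
    return SiteFrequencySpectrum(n_seq=n_seq, counts=counts, n_sites=n_sites, site_class=site_class)


def brute_force_pi(haplotypes: np.ndarray) -> float:
    """Mean pairwise Hamming distance per site over all sequence pairs."""
    n, L = haplotypes.shape
    total = sum(
        np.sum(haplotypes[i] != haplotypes[j])
        for i, j in itertools.combinations(range(n), 2)
    )
    return total / (n * (n - 1) / 2) / L


class TestHarmonicNumbers:
    @pytest.mark.parametrize(
        "n, a1, a2",
        [
            (2, 1.0, 1.0),
            (4, 11 / 6, 49 / 36),
            (16, 3.3182289932289932, 1.580440283444987),
        ],
    )
    def test_values(self, n, a1, a2):
        got_a1, got_a2 = harmonic_numbers(n)
        assert got_a1 == pytest.approx(a1, abs=1e-12)
        assert got_a2 == pytest.approx(a2, abs=1e-12)

    def test_rejects_small_n(self):
        with pytest.raises(InvalidSampleSizeError):
            harmonic_numbers(1)

    def test_a1_strictly_increasing(self):
        a1s = [harmonic_numbers(n)[0] for n in range(2, 60)]
        assert all(b > a for a, b in zip(a1s, a1s[1:]))


class TestWattersonTheta:
    def test_no_variation(self):
        assert watterson_theta(sfs(8, {}, 1000)) == 0.0

    def test_n2_a1_is_one(self):
        assert watterson_theta(sfs(2, {1: 20}, 1000)) == pytest.approx(0.02)

    def test_n4_per_locus(self):
        # S=11, a1=11/6, 1 site -> 6.0
        assert watterson_theta(sfs(4, {1: 7, 2: 4}, 11)) * 11 == pytest.approx(6.0)

    def test_empty_region(self):
        with pytest.raises(StatisticUndefinedError):
            watterson_theta(sfs(4, {}, 0))


class TestNucleotideDiversity:
    def test_zero(self):
        assert nucleotide_diversity(sfs(6, {}, 10)) == 0.0

    def test_two_sequences(self):
        assert nucleotide_diversity(sfs(2, {1: 1}, 100)) == pytest.approx(0.01)

    def test_explicit_four_haplotype_matrix(self):
        # haplotypes realizing counts {1: 2, 2: 1} on 1 informative site each
        haps = np.array(
            [
                [1, 0, 1],
                [0, 0, 1],
                [0, 1, 0],
                [0, 0, 0],
            ]
        )
        expected = brute_force_pi(haps)  # = 10/6/3 per site over 3 sites
        got = nucleotide_diversity(sfs(4, {1: 2, 2: 1}, 3))
        assert got == pytest.approx(expected, abs=1e-12)
        assert got * 3 == pytest.approx(10 / 6, abs=1e-12)

    @given(
        st.integers(min_value=2, max_value=12).flatmap(
            lambda n: st.lists(
                st.lists(st.integers(0, 1), min_size=6, max_size=6),
                min_size=n,
                max_size=n,
            )
        )
    )
    @settings(max_examples=60, deadline=None)
    def test_matches_brute_force_on_random_matrices(self, rows):
        haps = np.array(rows)
        got = nucleotide_diversity(
            sfs_from_genotypes(haps.T, ploidy=1)
        )
        assert got == pytest.approx(brute_force_pi(haps), abs=1e-12)

    def test_theta_equals_pi_for_two_sequences(self):
        s = sfs(2, {1: 7}, 50)
        assert watterson_theta(s) == pytest.approx(nucleotide_diversity(s), abs=1e-15)


class TestTajimaD:
    def test_zero_when_k_equals_theta(self):
        # n=4: a1 = 11/6; choose counts with k = S/a1:
        # counts {1: c1, 2: c2}: S = c1+c2, k = (3 c1 + 4 c2)/6
        # (3 c1 + 4 c2)/6 = (c1+c2) 6/11 -> 3 c1 = 8 c2 -> c1=8, c2=3
        s = sfs(4, {1: 8, 2: 3}, 1000)
        assert tajima_D(s) == pytest.approx(0.0, abs=1e-12)

    def test_undefined_for_no_segregating_sites(self):
        with pytest.raises(StatisticUndefinedError):
            tajima_D(sfs(10, {}, 1000))

    def test_small_samples_rejected(self):
        with pytest.raises(InvalidSampleSizeError):
            tajima_D(sfs(2, {1: 5}, 100))

    def test_frozen_n10_singletons(self):
        # 5 singletons among 10 sequences; constants recomputed with exact
        # Fractions in an independent script:
        # a1 = 2.828968253968254, e1 = 0.01906053380159183,
        # e2 = 0.004948927769896327, k = 1.0 -> D = -1.741095865207146
        got = tajima_D(sfs(10, {1: 5}, 1000))
        assert got == pytest.approx(-1.741095865207146, abs=1e-12)

    def test_constants_frozen_n10(self):
        c = tajima_constants(10)
        assert c.a1 == pytest.approx(2.828968253968254, abs=1e-12)
        assert c.a2 == pytest.approx(1.5397677311665408, abs=1e-12)
        assert c.e1 == pytest.approx(0.01906053380159183, abs=1e-12)
        assert c.e2 == pytest.approx(0.004948927769896327, abs=1e-12)

    @given(
        n=st.integers(min_value=4, max_value=40),
        singles=st.integers(min_value=0, max_value=30),
        mid=st.integers(min_value=0, max_value=30),
    )
    @settings(max_examples=80, deadline=None)
    def test_sign_matches_pi_minus_theta(self, n, singles, mid):
        counts = {1: singles}
        if n >= 5:
            counts[2] = mid
        if sum(counts.values()) == 0:
            return
        s = sfs(n, counts, 10_000)
        d = tajima_D(s)
        diff = nucleotide_diversity(s) * s.n_sites - s.S / tajima_constants(n).a1
        assert np.sign(np.round(d, 14)) == np.sign(np.round(diff, 14))


class TestFuLiDStar:
    def test_frozen_n10(self):
        # eta=10, eta_s=3; corrected constants via exact Fractions:
        # u* = 1.4729295398143674, v* = 0.4358006189157914
        # -> D* = 0.34365989628197224
        s = sfs(10, {1: 3, 2: 7}, 1000)
        assert fu_li_D_star(s) == pytest.approx(0.34365989628197224, abs=1e-12)

    def test_constants_frozen_n10(self):
        c = fu_li_constants(10)
        assert c.u_D == pytest.approx(1.4729295398143674, abs=1e-12)
        assert c.v_D == pytest.approx(0.4358006189157914, abs=1e-12)

    def test_undefined_for_no_segregating_sites(self):
        with pytest.raises(StatisticUndefinedError):
            fu_li_D_star(sfs(10, {}, 1000))

    def test_degenerate_n3_rejected(self):
        # for n=3 every folded site is a singleton and u* = v* = 0
        with pytest.raises(InvalidSampleSizeError):
            fu_li_constants(3)

    def test_zero_numerator(self):
        # n=4: (n/(n-1)) eta = a_n eta_s holds for eta=11, eta_s=8
        # since (4/3)*11 = (11/6)*8
        s = sfs(4, {1: 8, 2: 3}, 1000)
        assert fu_li_D_star(s) == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_formula(self):
        c = fu_li_constants(10)
        s = sfs(10, {1: 9, 2: 1}, 1000)
        num = (10 / 9) * 10 - c.a_n * 9
        expect = num / np.sqrt(c.u_D * 10 + c.v_D * 100)
        assert fu_li_D_star(s) == pytest.approx(expect, abs=1e-12)

    def test_variance_positive_over_n(self):
        for n in range(4, 600, 7):
            c = fu_li_constants(n)
            assert c.u_D > 0 and c.v_D > 0


class TestSfsFromGenotypes:
    def test_all_zero(self):
        s = sfs_from_genotypes(np.zeros((10, 4)), ploidy=2)
        assert s.S == 0 and s.n_sites == 10 and s.n_seq == 8

    def test_single_het_site(self):
        g = np.zeros((10, 1))
        g[3, 0] = 1
        s = sfs_from_genotypes(g, ploidy=2)
        assert s.n_seq == 2 and s.S == 1 and dict(enumerate(s.counts, 1)) == {1: 1}

    def test_missing_sites_dropped_listwise(self):
        g = np.array([[1.0, np.nan], [1.0, 0.0]])
        s = sfs_from_genotypes(g, ploidy=2)
        assert s.n_sites == 1 and s.S == 1

    def test_rejects_out_of_range_dosage(self):
        with pytest.raises(ValueError):
            sfs_from_genotypes(np.array([[3.0]]), ploidy=2)

    @given(
        st.integers(min_value=0, max_value=2**40 - 1),
    )
    @settings(max_examples=40, deadline=None)
    def test_brute_force_tally_on_random_binary_matrix(self, seed):
        rng = np.random.default_rng(seed)
        g = rng.integers(0, 2, size=(20, 50))
        s = sfs_from_genotypes(g, ploidy=1)
        assert s.n_seq == 50
        # brute-force per-column tally
        expected = np.zeros(25, dtype=int)
        for row in g:
            ones = int(row.sum())
            minor = min(ones, 50 - ones)
            if minor > 0:
                expected[minor - 1] += 1
        assert np.array_equal(s.counts, expected)


class TestSFSValidation:
    def test_counts_length_enforced(self):
        with pytest.raises(ValueError):
            SiteFrequencySpectrum(n_seq=6, counts=np.zeros(2), n_sites=10)

    def test_segregating_exceeds_sites(self):
        with pytest.raises(ValueError):
            SiteFrequencySpectrum(n_seq=4, counts=np.array([5, 0]), n_sites=3)

    def test_minimum_sample(self):
        with pytest.raises(InvalidSampleSizeError):
            SiteFrequencySpectrum(n_seq=1, counts=np.zeros(0), n_sites=3)
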