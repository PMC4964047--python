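"""Diversity, differentiation and exact-test statistics."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, strategies as st

from balnoise.haplotypes import HaplotypeMatrix
from balnoise.popgen import (
    FstResult,
    fst,
    haplogroup_pi_profile,
    hwe_exact_test,
    ld_r2,
    site_diversity,
    tajimas_d,
)


def random_matrix(rng, n, s, p_range=(0.05, 0.95)):
    while True:
        freqs = rng.uniform(*p_range, size=s)
        alleles = (rng.random((n, s)) < freqs).astype(np.int8)
        counts = alleles.sum(axis=0)
        if np.any((counts > 0) & (counts < n)):
            return HaplotypeMatrix(alleles, np.arange(s) * 10)


def brute_force_pi(matrix):
    """Mean pairwise Hamming distance over all C(n,2) haplotype pairs."""
    n = matrix.n
    total = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += int((matrix.alleles[i] != matrix.alleles[j]).sum())
    return total / (n * (n - 1) / 2)


def reference_tajima_d(alleles):
    """Independent Tajima's D implementation (explicit 1989 constants)."""
    n, s_all = alleles.shape
    counts = alleles.sum(axis=0)
    seg = counts[(counts > 0) & (counts < n)]
    S = len(seg)
    if S == 0:
        return math.nan
    pairdiff = sum(c * (n - c) for c in seg) / (n * (n - 1) / 2)
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    var = c1 / a1 * S + c2 / (a1**2 + a2) * S * (S - 1)
    return (pairdiff - S / a1) / math.sqrt(var)


class TestSiteDiversity:
    def test_single_site_printed_formula(self):
        # n=4, one site with derived count 2: pi = 4/3 * 2*0.5*0.5 = 2/3
        m = HaplotypeMatrix(np.array([[1], [1], [0], [0]]), [5])
        pi, th = site_diversity(m)
        assert pi == pytest.approx(2 / 3, abs=1e-12)
        assert th == pytest.approx(1 / (1 + 1 / 2 + 1 / 3), abs=1e-12)

    def test_no_segregating_sites(self):
        m = HaplotypeMatrix(np.ones((4, 0), dtype=np.int8), [])
        assert site_diversity(m) == (0.0, 0.0)

    @given(st.integers(0, 2**31 - 1))
    def test_pi_equals_mean_pairwise_hamming(self, seed):
        rng = np.random.default_rng(seed)
        m = random_matrix(rng, int(rng.integers(4, 21)), int(rng.integers(2, 50)))
        pi, _ = site_diversity(m)
        n = m.n
        assert pi == pytest.approx(
            n / (n - 1) * brute_force_pi(m) * (n - 1) / n, rel=1e-12
        )
        # the frequency form *is* the brute-force mean pairwise distance
        assert pi == pytest.approx(brute_force_pi(m), rel=1e-12)


class TestTajimasD:
    def test_all_singletons_negative(self, rng):
        # every derived allele a singleton: excess rare variation, D < 0
        alleles = np.zeros((10, 8), dtype=np.int8)
        for j in range(8):
            alleles[j % 10, j] = 1
        res = tajimas_d(HaplotypeMatrix(alleles, np.arange(8)))
        assert res.D < 0

    def test_undefined_when_no_sites(self):
        m = HaplotypeMatrix(np.zeros((6, 0), dtype=np.int8), [])
        res = tajimas_d(m)
        assert not res.defined and np.isnan(res.D)

    def test_sign_follows_pi_minus_theta(self, rng):
        for _ in range(20):
            m = random_matrix(rng, 15, 30)
            res = tajimas_d(m)
            assert np.sign(res.D) == np.sign(res.pi - res.theta_s)

    def test_matches_independent_reference(self, rng):
        for _ in range(50):
            m = random_matrix(rng, 15, 30)
            assert tajimas_d(m).D == pytest.approx(
                reference_tajima_d(m.alleles), abs=1e-10
            )


class TestHaplogroupProfile:
    def test_classes_identical_except_focal(self):
        # two haplogroups differing only at the focal site: between == within
        # everywhere no other site segregates
        n = 8
        base = np.tile(np.array([0, 1, 0, 1], dtype=np.int8), (n, 1))
        focal = np.array([0] * 4 + [1] * 4, dtype=np.int8)[:, None]
        alleles = np.hstack([base[:, :2], focal, base[:, 2:]])
        # base columns are monomorphic and get dropped; only focal remains
        m = HaplotypeMatrix(alleles, [100, 200, 300, 400, 500], focal_index=2)
        prof = haplogroup_pi_profile(m, window_bp=200, step=100)
        # in windows containing the focal site, every cross pair differs by 1
        assert np.all(prof.pi_between >= prof.pi_within)

    def test_balanced_simulation_between_exceeds_within(self):
        from balnoise.simulate import SimConfig, simulate_balanced_haplotypes

        cfg = SimConfig(seed=5, n_haplotypes=40, theta=5.0, class_split_time=6.0)
        rng = cfg.rng()
        wins = 0
        reps = 40
        for _ in range(reps):
            m = simulate_balanced_haplotypes(cfg, rng=rng)
            prof = haplogroup_pi_profile(m, window_bp=500, step=250)
            mid = len(prof.window_centers) // 2
            if prof.pi_between[mid] > prof.pi_within[mid]:
                wins += 1
        assert wins >= 0.95 * reps

    def test_empty_window_zero(self):
        m = HaplotypeMatrix(
            np.array([[1, 0], [0, 1], [1, 1], [0, 0]]), [0, 5000], focal_index=0
        )
        prof = haplogroup_pi_profile(m, window_bp=100, step=1000)
        assert np.all(prof.pi_between >= 0)


class TestFst:
    def test_identity(self):
        assert fst([0.5, 0.5, 0.5]).fst == pytest.approx(0.0, abs=1e-12)

    def test_fixed_difference(self):
        res = fst([1.0, 0.0])
        assert res.Hs == 0.0 and res.Ht == pytest.approx(0.5)
        assert res.fst == pytest.approx(1.0)

    def test_hand_evaluated_three_pops(self):
        res = fst([0.2, 0.5, 0.8])
        assert res.Hs == pytest.approx(0.38, abs=1e-12)
        assert res.Ht == pytest.approx(0.5, abs=1e-12)
        assert res.fst == pytest.approx(0.24, abs=1e-12)

    def test_monomorphic_flagged(self):
        assert not fst([0.0, 0.0]).defined

    @given(st.lists(st.floats(0.01, 0.99), min_size=2, max_size=6), st.integers(0, 10**6))
    def test_relabeling_invariance(self, freqs, seed):
        rng = np.random.default_rng(seed)
        perm = rng.permutation(len(freqs))
        a, b = fst(freqs), fst(np.asarray(freqs)[perm])
        assert a.fst == pytest.approx(b.fst, abs=1e-12)


class TestLdR2:
    def test_site_with_itself(self, rng):
        g = rng.integers(0, 3, size=50)
        assert ld_r2(g, g) == pytest.approx(1.0)

    def test_unlinked_sites_near_zero(self, rng):
        a = rng.binomial(2, 0.4, size=10_000)
        b = rng.binomial(2, 0.4, size=10_000)
        assert ld_r2(a, b) < 0.01

    def test_matches_haplotype_frequency_oracle(self, rng):
        # phased binary data: r^2 = D^2 / (pA qA pB qB)
        for _ in range(20):
            h = (rng.random((40, 2)) < [0.3, 0.6]).astype(int)
            pa, pb = h.mean(axis=0)
            if pa in (0, 1) or pb in (0, 1):
                continue
            pab = np.mean(h[:, 0] * h[:, 1])
            D = pab - pa * pb
            expected = D**2 / (pa * (1 - pa) * pb * (1 - pb))
            assert ld_r2(h[:, 0], h[:, 1]) == pytest.approx(expected, rel=1e-9)

    def test_monomorphic_undefined(self):
        assert np.isnan(ld_r2([1, 1, 1], [0, 1, 2]))


def hwe_enumeration_oracle(n_aa, n_ab, n_bb):
    """Exact-fraction enumeration of the conditional heterozygote distribution."""
    n = n_aa + n_ab + n_bb
    na = 2 * n_aa + n_ab
    nminor = min(na, 2 * n - na)
    denom = math.comb(2 * n, na)

    def prob(het):
        homr = (nminor - het) // 2
        homc = n - het - homr
        ways = Fraction(math.factorial(n), math.factorial(het) * math.factorial(homr) * math.factorial(homc))
        return ways * Fraction(2**het, denom)

    hets = range(nminor % 2, nminor + 1, 2)
    p_obs = prob(n_ab)
    return float(sum(p for h in hets if (p := prob(h)) <= p_obs))


class TestHweExact:
    @pytest.mark.parametrize("n", [5, 11, 17, 25, 50])
    def test_matches_full_enumeration(self, n):
        for n_aa in range(0, n + 1, max(1, n // 5)):
            for n_ab in range(0, n - n_aa + 1, max(1, n // 5)):
                n_bb = n - n_aa - n_ab
                if 2 * n_aa + n_ab in (0, 2 * n):
                    continue
                p = hwe_exact_test(n_aa, n_ab, n_bb)
                assert p == pytest.approx(hwe_enumeration_oracle(n_aa, n_ab, n_bb), rel=1e-9)

    def test_null_consistent_large_sample(self):
        # 0.25 / 0.5 / 0.25 at n=200: perfectly HWE-proportioned
        assert hwe_exact_test(50, 100, 50) > 0.5

    def test_extreme_heterozygote_excess(self):
        assert hwe_exact_test(0, 100, 0) < 1e-6

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_test(0, 0, 0)

    def test_super_uniform_under_null(self, rng):
        # p-values under random mating should be (super-)uniform
        n, reps = 100, 2000
        hits = 0
        for _ in range(reps):
            g = rng.binomial(2, 0.3, size=n)
            p = hwe_exact_test(int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum()))
            assert 0.0 < p <= 1.0
            hits += p < 0.05
        assert hits / reps <= 0.07
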