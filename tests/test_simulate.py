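"""Properties of the synthetic-data generators."""

import numpy as np
import pytest

from balnoise.haplotypes import HaplotypeMatrix
from balnoise.noise_model import NoiseModelParams, noise_decomposition, match_mean, rate_f
from balnoise.popgen import harmonic, site_diversity, tajimas_d
from balnoise.simulate import (
    SimConfig,
    balanced_d_values,
    neutral_d_values,
    simulate_allelic_reads,
    simulate_balanced_haplotypes,
    simulate_neutral_haplotypes,
    simulate_single_cell_atac,
    simulate_single_cell_expression,
)
from balnoise.singlecell import chromatin_variability


class TestNeutralCoalescent:
    def test_theta_zero_no_sites(self):
        m = simulate_neutral_haplotypes(SimConfig(seed=1, theta=1e-300))
        assert m.n_sites == 0

    def test_determinism(self):
        cfg = SimConfig(seed=42, n_haplotypes=30, theta=8.0)
        a = simulate_neutral_haplotypes(cfg)
        b = simulate_neutral_haplotypes(cfg)
        assert np.array_equal(a.alleles, b.alleles)
        assert np.array_equal(a.positions, b.positions)

    def test_too_few_haplotypes(self):
        with pytest.raises(ValueError):
            SimConfig(n_haplotypes=1)

    def test_watterson_and_pi_unbiased(self):
        # E[S] = theta * a_n and E[pi] = theta under the neutral coalescent
        cfg = SimConfig(seed=3, n_haplotypes=25, theta=6.0)
        rng = cfg.rng()
        S, pi = [], []
        for _ in range(400):
            m = simulate_neutral_haplotypes(cfg, rng=rng)
            p, _ = site_diversity(m)
            S.append(m.n_sites)
            pi.append(p)
        exp_s = cfg.theta * harmonic(cfg.n_haplotypes)
        assert np.mean(S) == pytest.approx(exp_s, rel=0.1)
        assert np.mean(pi) == pytest.approx(cfg.theta, rel=0.15)

    def test_mean_d_matches_msprime_oracle(self):
        """Neutral D distribution agrees with an independent coalescent simulator."""
        msprime = pytest.importorskip("msprime")
        from balnoise.popgen import tajima_d_from_counts

        n, theta, L, reps = 40, 8.0, 5000, 400
        cfg = SimConfig(seed=9, n_haplotypes=n, theta=theta)
        mine = neutral_d_values(cfg, reps)
        seeds = np.random.default_rng(7)
        oracle = []
        for ts in msprime.sim_ancestry(
            samples=n, ploidy=1, population_size=1.0, sequence_length=L,
            num_replicates=reps, random_seed=11,
        ):
            mts = msprime.sim_mutations(
                ts, rate=theta / 2 / L, random_seed=int(seeds.integers(1, 2**31)),
                discrete_genome=False,
            )
            counts = np.array([int((v.genotypes != 0).sum()) for v in mts.variants()])
            oracle.append(tajima_d_from_counts(n, counts).D)
        se = np.hypot(np.nanstd(mine) / np.sqrt(reps), np.nanstd(oracle) / np.sqrt(reps))
        assert abs(np.nanmean(mine) - np.nanmean(oracle)) < 4 * se


class TestBalancedCoalescent:
    def test_small_split_time_near_neutral(self):
        cfg = SimConfig(seed=2, n_haplotypes=40, theta=5.0, class_split_time=1e-9)
        d_bal = balanced_d_values(cfg, 150)
        d_neu = neutral_d_values(SimConfig(seed=3, n_haplotypes=40, theta=5.0), 150)
        # distributions indistinguishable in location (focal site adds ~nothing)
        assert abs(np.nanmedian(d_bal) - np.nanmedian(d_neu)) < 0.35

    def test_focal_column_flagged_at_center(self):
        cfg = SimConfig(seed=4, n_haplotypes=60, theta=5.0, class_split_time=5.0)
        m = simulate_balanced_haplotypes(cfg)
        assert m.focal_index is not None
        assert m.positions[m.focal_index] == cfg.window_bp // 2
        freq = m.derived_freqs()[m.focal_index]
        assert freq == pytest.approx(0.5, abs=0.01)

    def test_invalid_class_frequency(self):
        cfg = SimConfig(seed=1, balanced_freq=1.0)
        with pytest.raises(ValueError):
            simulate_balanced_haplotypes(cfg)

    def test_between_class_pi_exceeds_within_at_focal(self):
        from balnoise.popgen import haplogroup_pi_profile

        cfg = SimConfig(seed=6, n_haplotypes=40, theta=5.0, class_split_time=8.0)
        rng = cfg.rng()
        wins = 0
        for _ in range(60):
            m = simulate_balanced_haplotypes(cfg, rng=rng)
            prof = haplogroup_pi_profile(m, window_bp=1000, step=500)
            mid = np.argmin(np.abs(prof.window_centers - cfg.window_bp // 2))
            wins += prof.pi_between[mid] > prof.pi_within[mid]
        assert wins >= 57  # >= 95%

    def test_median_d_above_neutral(self):
        cfg = SimConfig(seed=8, n_haplotypes=50, theta=5.0, class_split_time=4.0)
        d_bal = balanced_d_values(cfg, 300)
        d_neu = neutral_d_values(SimConfig(seed=9, n_haplotypes=50, theta=5.0), 300)
        assert np.nanmedian(d_bal) > np.nanmedian(d_neu)


class TestAllelicReads:
    def test_symmetric_bias_zero_log_ratio(self, rng):
        cfg = SimConfig(seed=0, allele_bias=1.0, depth_mean=5000.0)
        df = simulate_allelic_reads([f"s{i}" for i in range(200)], cfg, rng=rng)
        ratio = np.log2(df.ref_reads / df.alt_reads)
        assert abs(ratio.mean()) < 0.05

    def test_twofold_bias_log_ratio_one(self, rng):
        cfg = SimConfig(seed=0, allele_bias=2.0, depth_mean=10_000.0)
        df = simulate_allelic_reads(["s"], cfg, rng=rng)
        obs = np.log2(df.ref_reads[0] / df.alt_reads[0])
        # binomial error at depth 10,000: sd(log2 ratio) ~ 0.03
        assert obs == pytest.approx(1.0, abs=0.1)

    def test_zero_depth_all_zero(self, rng):
        cfg = SimConfig(seed=0, allele_bias=1.0, depth_mean=0.0)
        df = simulate_allelic_reads(["a", "b"], cfg, rng=rng)
        assert (df.ref_reads + df.alt_reads).sum() == 0


class TestSingleCellExpression:
    def test_no_tf_fluctuation_hom_het_converge(self):
        # a -> inf with a*b fixed: extrinsic noise vanishes
        params = NoiseModelParams(lam=5.0, a=40_000.0, b=1.0 / 40_000.0)
        het = simulate_single_cell_expression(params, "het", 4000, rng=1, n_genes=8)
        hom = simulate_single_cell_expression(params, "hom", 4000, rng=2, n_genes=8)
        cv2 = lambda x: (x.std(axis=1, ddof=1) / x.mean(axis=1)) ** 2
        assert np.mean(cv2(het)) == pytest.approx(np.mean(cv2(hom)), rel=0.1)

    def test_lam_one_identity(self):
        params = NoiseModelParams(lam=1.0, a=1.0, b=1.0)
        het = simulate_single_cell_expression(params, "het", 6000, rng=3, n_genes=10)
        hom = simulate_single_cell_expression(params, "hom", 6000, rng=4, n_genes=10)
        cv2 = lambda x: (x.std(axis=1, ddof=1) / x.mean(axis=1)) ** 2
        a, b = np.mean(cv2(het)), np.mean(cv2(hom))
        se = np.hypot(np.std(cv2(het), ddof=1), np.std(cv2(hom), ddof=1)) / np.sqrt(10)
        assert abs(a - b) < 3 * se

    def test_hom_noisier_than_het_matches_analytic(self):
        """Empirical CV2 difference agrees with analytic delta-eta2 at mRNA level."""
        params = NoiseModelParams(alpha_m=400.0, lam=10.0, a=1.0, b=1.0)
        n_genes, n_cells = 150, 400
        het = simulate_single_cell_expression(params, "het", n_cells, rng=5, n_genes=n_genes)
        hom = simulate_single_cell_expression(params, "hom", n_cells, rng=6, n_genes=n_genes)
        cv2 = lambda x: (x.std(axis=1, ddof=1) / x.mean(axis=1)) ** 2
        c_het, c_hom = cv2(het), cv2(hom)
        diff = c_hom.mean() - c_het.mean()
        se = np.hypot(c_het.std(ddof=1), c_hom.std(ddof=1)) / np.sqrt(n_genes)
        rate = rate_f(params)
        lam_bar = match_mean(rate, params.lam, params.a, params.b)
        analytic = (
            noise_decomposition(params, "hom", lam_bar).eta2_g
            - noise_decomposition(params, "het").eta2_g
        )
        assert diff > 0
        assert abs(diff - analytic) < 3 * se


class TestSingleCellAtac:
    # group 0 is always a large zero-extrinsic background that pins the
    # per-cell depth, as the genome-wide peak catalog does in real data

    def test_zero_extrinsic_at_depth_baseline(self):
        cfg = SimConfig(seed=11, n_cells=200, depth_mean=20.0)
        groups = np.repeat([0, 1], [1900, 100])
        counts, groups, _ = simulate_single_cell_atac(
            cfg, n_peaks=2000, peak_groups=groups, group_extrinsic_var=[0.0, 0.0]
        )
        res = chromatin_variability(counts, groups, n_boot=100, seed=0).set_index("group")
        # depth-standardized deviations of Poisson counts have SD ~ 1
        assert res.loc["1", "variability"] == pytest.approx(1.0, abs=0.35)

    def test_planted_groups_ordered(self):
        cfg = SimConfig(seed=12, n_cells=254, depth_mean=20.0)
        groups = np.repeat([0, 1, 2], [1800, 100, 100])
        counts, groups, _ = simulate_single_cell_atac(
            cfg, n_peaks=2000, peak_groups=groups,
            group_extrinsic_var=[0.0, 0.005, 0.08],
        )
        res = chromatin_variability(counts, groups, n_boot=150, seed=1).set_index("group")
        assert res.loc["2", "variability"] > res.loc["1", "variability"]

    def test_fixed_seed_reproducible(self):
        cfg = SimConfig(seed=13, n_cells=50, depth_mean=10.0)
        a, _, _ = simulate_single_cell_atac(cfg, n_peaks=40)
        b, _, _ = simulate_single_cell_atac(cfg, n_peaks=40)
        assert np.array_equal(a, b)
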