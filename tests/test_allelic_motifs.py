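"""Allelic imbalance and PWM scanning / motif divergence."""

import itertools

import numpy as np
import pandas as pd
import pytest

from balnoise.allelic import allelic_imbalance
from balnoise.motifs import PWM, reverse_complement, scan_alleles, scan_sequence


def counts_frame(rows):
    return pd.DataFrame(rows, columns=["snp_id", "ref_reads", "alt_reads"])


class TestAllelicImbalance:
    def test_equal_counts_zero(self):
        df = counts_frame([("a", 20, 20), ("c", 15, 15)])
        out = allelic_imbalance(df, control_ids={"c"})
        assert out.loc[0, "imbalance_abs"] == 0.0

    def test_twofold_ratio_one(self):
        df = counts_frame([("a", 20, 10), ("c", 12, 12)])
        out = allelic_imbalance(df, control_ids={"c"})
        assert out.loc[0, "imbalance_abs"] == pytest.approx(1.0)

    def test_control_median_maps_to_zero(self, rng):
        rows = [(f"c{i}", int(r), int(a)) for i, (r, a) in enumerate(
            zip(rng.integers(10, 100, 50), rng.integers(10, 100, 50)))]
        df = counts_frame(rows)
        out = allelic_imbalance(df, control_ids={r[0] for r in rows})
        ok = out["excluded"] == ""
        assert np.median(out.loc[ok, "imbalance_norm"]) == pytest.approx(0.0, abs=1e-12)

    def test_depth_and_zero_count_exclusions(self):
        df = counts_frame([("low", 4, 5), ("zero", 30, 0), ("ok", 10, 5)])
        out = allelic_imbalance(df, control_ids=set()).set_index("snp_id")
        assert out.loc["low", "excluded"] == "low_depth"
        assert out.loc["zero", "excluded"] == "zero_count"
        assert out.loc["ok", "excluded"] == ""

    def test_swap_invariance(self):
        a = allelic_imbalance(counts_frame([("x", 30, 10)]), set())
        b = allelic_imbalance(counts_frame([("x", 10, 30)]), set())
        assert a.loc[0, "imbalance_abs"] == pytest.approx(b.loc[0, "imbalance_abs"])


def enumerate_threshold(pwm, p):
    """Threshold by scoring all 4^w words (uniform background)."""
    words = itertools.product("ACGT", repeat=pwm.width)
    scores = np.array([pwm.score("".join(w)) for w in words])
    uniq = np.unique(scores)
    best = np.inf
    for s in uniq[::-1]:
        if (scores >= s - 1e-12).mean() <= p * (1 + 1e-12):
            best = s
        else:
            break
    return best


class TestPwmThreshold:
    def test_width8_matches_full_enumeration(self, rng):
        counts = rng.integers(1, 60, size=(4, 8)).astype(float)
        pwm = PWM(counts, "w8")
        for p in (1e-4, 1e-3, 0.05):
            assert pwm.threshold(p) == pytest.approx(enumerate_threshold(pwm, p), abs=1e-9)

    def test_p_one_gives_minimum_score(self, rng):
        pwm = PWM(rng.integers(1, 30, size=(4, 6)).astype(float), "w6")
        assert pwm.threshold(1.0) == pytest.approx(pwm.min_score, abs=1e-9)

    def test_width4_granularity_no_hits(self):
        # best word probability 4^-4 ~ 3.9e-3 > 1e-4: no achievable threshold
        counts = np.zeros((4, 4))
        counts[0] = 100.0  # consensus AAAA
        pwm = PWM(counts, "w4")
        assert pwm.threshold(1e-4) == np.inf
        hit, _ = scan_sequence("AAAAAAAA", pwm, p=1e-4)
        assert not hit

    def test_threshold_monotone_in_p(self, rng):
        pwm = PWM(rng.integers(1, 40, size=(4, 7)).astype(float), "w7")
        ps = [1e-4, 1e-3, 1e-2, 0.1, 1.0]
        ts = [pwm.threshold(p) for p in ps]
        assert all(a >= b for a, b in zip(ts, ts[1:]))

    def test_invalid_p(self, rng):
        pwm = PWM(rng.integers(1, 10, size=(4, 5)).astype(float), "x")
        with pytest.raises(ValueError):
            pwm.threshold(0.0)


class TestScanning:
    def _strong_pwm(self, word, name):
        counts = np.full((4, len(word)), 1.0)
        for j, c in enumerate(word):
            counts["ACGT".index(c), j] = 200.0
        return PWM(counts, name)

    def test_scanner_matches_window_enumeration(self, rng):
        # every window of every strand, scored directly
        pwm = PWM(rng.integers(1, 50, size=(4, 5)).astype(float), "w5")
        seq = "".join(rng.choice(list("ACGT"), size=30))
        _, best = scan_sequence(seq, pwm, p=1.0)
        words = []
        for s in (seq, reverse_complement(seq)):
            words += [s[i : i + 5] for i in range(len(s) - 4)]
        assert best == pytest.approx(max(pwm.score(w) for w in words), abs=1e-12)

    def test_identical_alleles_no_specific_tfs(self):
        pwm = self._strong_pwm("ACGTACGTAC", "tf")
        seq = "T" * 15 + "ACGTACGTAC" + "T" * 16
        div = scan_alleles("s", seq, seq, [pwm])
        assert not div.tfs_allele1_only and not div.tfs_allele2_only
        assert div.tfs_common == {"tf"}

    def test_planted_allele_specific_motif(self):
        # consensus spans the SNP; the SNP position carries nearly all of
        # the information, so the allele-2 word falls below threshold
        # while single mismatches elsewhere would not
        seq1 = "T" * 15 + "ACGTGCGTAC" + "T" * 16
        seq2 = seq1[:20] + "A" + seq1[21:]  # SNP at index 20 (motif pos 5)
        word = seq1[15:25]
        counts = np.full((4, 10), 20.0)
        for j, c in enumerate(word):
            counts["ACGT".index(c), j] = 40.0
        counts[:, 5] = 0.0
        counts["ACGT".index(word[5]), 5] = 100.0
        pwm = PWM(counts, "spec")
        div = scan_alleles("s", seq1, seq2, [pwm])
        assert div.tfs_allele1_only == {"spec"}
        assert not div.tfs_common

    def test_four_common_four_specific_score_one(self, fixture_dataset):
        from balnoise import io

        data_dir, manifest = fixture_dataset
        flanks = io.read_fasta(f"{data_dir}/flanks.fasta")
        pwms = io.read_pfms(f"{data_dir}/motifs.pfm")
        snp = manifest["motif_snp"]
        div = scan_alleles(snp, flanks[f"{snp}_allele1"], flanks[f"{snp}_allele2"], pwms)
        assert div.tfs_common == frozenset(manifest["common_tfs"])
        assert div.tfs_allele1_only == frozenset(manifest["specific_tfs"])
        assert div.score == pytest.approx(1.0)

    def test_reverse_complement_invariance(self, fixture_dataset):
        from balnoise import io

        data_dir, manifest = fixture_dataset
        flanks = io.read_fasta(f"{data_dir}/flanks.fasta")
        pwms = io.read_pfms(f"{data_dir}/motifs.pfm")
        snp = manifest["motif_snp"]
        s1, s2 = flanks[f"{snp}_allele1"], flanks[f"{snp}_allele2"]
        a = scan_alleles(snp, s1, s2, pwms)
        b = scan_alleles(snp, reverse_complement(s1), reverse_complement(s2), pwms)
        assert a.tfs_common == b.tfs_common
        assert a.tfs_allele1_only == b.tfs_allele1_only

    def test_ambiguous_bases_skipped(self):
        pwm = self._strong_pwm("ACGT", "tf")
        hit, best = scan_sequence("NNACGTNN", pwm, p=1.0)
        assert hit and best == pytest.approx(pwm.score("ACGT"))
        hit_n, best_n = scan_sequence("NNANGTNN", pwm, p=1.0)
        assert best_n is None or best_n < best
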