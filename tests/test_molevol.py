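"""NG86 Ka/Ks engine, sliding windows, divergence dating."""
import math

import numpy as np
import pytest

from genefam import molevol
from genefam.errors import SaturationError, ValidationError
from genefam.molevol import (
    CodonAlignmentPair,
    divergence_time,
    kaks_ng86,
    ng86_sites,
    sliding_window_kaks,
)
from genefam.simulate import simulate_codon_pair

from tests import _oracles


class TestSiteCounts:
    @pytest.mark.parametrize(
        "codon,s,n",
        [
            ("TTT", 1 / 3, 8 / 3),   # Phe: only 3rd-position TTC is synonymous
            ("ATG", 0.0, 3.0),       # Met: single-codon amino acid
            ("GGG", 1.0, 2.0),       # Gly: 3rd position fully degenerate
        ],
    )
    def test_hand_enumerated_codons(self, codon, s, n):
        got_s, got_n = ng86_sites(codon)
        assert got_s == pytest.approx(s)
        assert got_n == pytest.approx(n)

    def test_all_sense_codons_match_oracle_and_sum_to_three(self):
        for codon in molevol.SENSE_CODONS:
            s, n = ng86_sites(codon)
            os, on = _oracles.oracle_codon_sites(codon)
            assert s == pytest.approx(os, abs=1e-12)
            assert s + n == pytest.approx(3.0, abs=1e-12)

    def test_stop_codon_rejected(self):
        with pytest.raises(ValidationError):
            ng86_sites("TAA")


class TestKaKs:
    def test_identical_sequences(self):
        pair = CodonAlignmentPair("a", "b", "ATGGGG", "ATGGGG")
        res = kaks_ng86(pair)
        assert res.Ka == res.Ks == 0.0
        assert res.ratio is None
        assert res.ratio_str == "NA"

    def test_single_synonymous_difference_worked_example(self):
        """TTT->TTC on a GGG background: Sd=1, Nd=0, S=7/3, Ks=-0.75 ln(3/7)."""
        pair = CodonAlignmentPair("a", "b", "TTTGGGGGG", "TTCGGGGGG")
        res = kaks_ng86(pair)
        assert res.Sd == pytest.approx(1.0)
        assert res.Nd == pytest.approx(0.0)
        assert res.S == pytest.approx(7 / 3)
        assert res.pS == pytest.approx(3 / 7)
        assert res.Ka == 0.0
        assert res.Ks == pytest.approx(-0.75 * math.log(1 - 4 / 7))
        assert res.ratio == 0.0

    def test_site_conservation_and_symmetry(self, rng):
        for _ in range(25):
            a, b = _oracles.random_mutated_pair(rng, 40, int(rng.integers(0, 25)))
            res = kaks_ng86(CodonAlignmentPair("x", "y", a, b))
            assert res.S + res.N == pytest.approx(len(a), abs=1e-9)
            swapped = kaks_ng86(CodonAlignmentPair("y", "x", b, a))
            for field in ("S", "N", "Sd", "Nd", "Ks", "Ka"):
                assert getattr(res, field) == pytest.approx(
                    getattr(swapped, field), abs=1e-12
                )

    def test_agrees_with_brute_force_oracle(self, rng):
        """Implementation equals full path-enumeration oracle to 1e-9."""
        for _ in range(60):
            a, b = _oracles.random_mutated_pair(rng, 50, int(rng.integers(0, 35)))
            res = kaks_ng86(CodonAlignmentPair("x", "y", a, b))
            S, N, Sd, Nd, ks, ka = _oracles.oracle_ng86(a, b)
            assert res.S == pytest.approx(S, abs=1e-9)
            assert res.N == pytest.approx(N, abs=1e-9)
            assert res.Sd == pytest.approx(Sd, abs=1e-9)
            assert res.Nd == pytest.approx(Nd, abs=1e-9)
            assert res.Ks == pytest.approx(ks, abs=1e-9)
            assert res.Ka == pytest.approx(ka, abs=1e-9)

    def test_ks_monotone_in_planted_synonymous_differences(self):
        """More synonymous changes (nonsynonymous fixed) never lower Ks."""
        base = "GGG" * 60  # every 3rd position synonymous for Gly
        prev = -1.0
        for k in range(0, 30, 5):
            derived = "".join(
                "GGA" if i < k else "GGG" for i in range(60)
            )
            res = kaks_ng86(CodonAlignmentPair("a", "b", base, derived))
            assert res.Ks >= prev
            prev = res.Ks

    def test_saturation_raises(self):
        # every codon differs at its synonymous 3rd position -> pS = 1
        a, b = "GGG" * 10, "GGA" * 10
        with pytest.raises(SaturationError):
            kaks_ng86(CodonAlignmentPair("a", "b", a, b))

    def test_internal_stop_rejected_and_gap_codons_dropped(self):
        with pytest.raises(ValidationError):
            kaks_ng86(CodonAlignmentPair("a", "b", "TAAGGG", "GGGGGG"))
        res = kaks_ng86(
            CodonAlignmentPair("a", "b", "---GGGGGGTTT", "GGGGGGGGGTTC")
        )
        assert res.S == pytest.approx(2 + 1 / 3)  # gapped first column dropped

    @pytest.mark.parametrize(
        "bad_a,bad_b", [("ATG", "ATGATG"), ("AT", "AT"), ("ATN", "ATG")]
    )
    def test_pair_validation(self, bad_a, bad_b):
        with pytest.raises(ValidationError):
            CodonAlignmentPair("a", "b", bad_a, bad_b)


class TestSimulationRecovery:
    def test_planted_counts_self_consistent(self):
        pair, truth = simulate_codon_pair(200, 0.3, 0.2, seed=9)
        res = kaks_ng86(pair)
        assert res.Sd == pytest.approx(truth.realized_Sd)
        assert res.Nd == pytest.approx(truth.realized_Nd)

    def test_zero_divergence_gives_identical_pair(self):
        pair, truth = simulate_codon_pair(100, 0.5, 0.0, seed=1)
        assert pair.seq_a == pair.seq_b
        assert truth.n_syn_events == truth.n_nonsyn_events == 0

    def test_determinism(self):
        p1, _ = simulate_codon_pair(150, 0.3, 0.3, seed=77)
        p2, _ = simulate_codon_pair(150, 0.3, 0.3, seed=77)
        assert (p1.seq_a, p1.seq_b) == (p2.seq_a, p2.seq_b)

    def test_omega_recovery_small_scale(self):
        """Mean estimated ratio near the planted omega (reduced replicates)."""
        ratios = [
            kaks_ng86(simulate_codon_pair(900, 0.3, 0.3, seed=500 + i)[0]).ratio
            for i in range(30)
        ]
        assert abs(float(np.mean(ratios)) - 0.3) < 0.05


class TestSlidingWindow:
    def test_identical_sequences_all_zero(self):
        seq = "ATGGGGTTTCCCAAAGGGTTTCCCAAAGGG"
        prof = sliding_window_kaks(
            CodonAlignmentPair("a", "b", seq, seq), window_bp=9, step_bp=3
        )
        assert all(w.Ka == 0.0 and w.Ks == 0.0 for w in prof.windows)
        assert all(w.flag == "undefined_ratio" for w in prof.windows)
        assert prof.windows[0].start_bp == 1
        assert all(w.start_bp % 3 == 1 for w in prof.windows)

    def test_partition_additivity_with_step_equal_window(self, rng):
        a, b = _oracles.random_mutated_pair(rng, 60, 25)
        pair = CodonAlignmentPair("a", "b", a, b)
        whole = kaks_ng86(pair)
        prof = sliding_window_kaks(pair, window_bp=45, step_bp=45)
        # re-count via sub-pairs because flagged windows carry no counts
        total_sd = total_nd = 0.0
        for w in prof.windows:
            sub = CodonAlignmentPair(
                "a", "b", a[w.start_bp - 1 : w.end_bp], b[w.start_bp - 1 : w.end_bp]
            )
            res = kaks_ng86(sub)
            total_sd += res.Sd
            total_nd += res.Nd
        assert total_sd == pytest.approx(whole.Sd, abs=1e-9)
        assert total_nd == pytest.approx(whole.Nd, abs=1e-9)

    def test_planted_high_omega_segment_is_found(self):
        """A segment evolved at omega=2 on an omega=0.2 background gives the
        max-ratio window inside/overlapping the planted segment."""
        bg1, _ = simulate_codon_pair(60, 0.2, 0.4, seed=11)
        hot, _ = simulate_codon_pair(30, 2.0, 0.4, seed=12)
        bg2, _ = simulate_codon_pair(60, 0.2, 0.4, seed=13)
        a = bg1.seq_a + hot.seq_a + bg2.seq_a
        b = bg1.seq_b + hot.seq_b + bg2.seq_b
        prof = sliding_window_kaks(
            CodonAlignmentPair("a", "b", a, b), window_bp=90, step_bp=9
        )
        scored = [w for w in prof.windows if w.ratio is not None]
        best = max(scored, key=lambda w: w.ratio)
        seg_start, seg_end = 181, 270  # planted hot segment in bp
        assert best.ratio > 1.0
        assert best.start_bp <= seg_end and best.end_bp >= seg_start

    def test_window_validation(self):
        pair = CodonAlignmentPair("a", "b", "ATGGGG", "ATGGGG")
        with pytest.raises(ValidationError):
            sliding_window_kaks(pair, window_bp=4, step_bp=3)
        with pytest.raises(ValidationError):
            sliding_window_kaks(pair, window_bp=9, step_bp=3)


class TestDivergenceTime:
    @pytest.mark.parametrize(
        "ks,expected",
        [(0.343, 18.85), (0.253, 13.90), (0.009, 0.49), (0.325, 17.86), (0.0, 0.0)],
    )
    def test_populus_clock_dates(self, ks, expected):
        assert round(divergence_time(ks).t_mya, 2) == pytest.approx(expected)

    def test_custom_rate_and_validation(self):
        assert divergence_time(0.2, 1e-8).t_mya == pytest.approx(10.0)
        with pytest.raises(ValidationError):
            divergence_time(-0.1)
        with pytest.raises(ValidationError):
            divergence_time(0.1, 0.0)
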