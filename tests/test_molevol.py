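"""NG86 Ka/Ks against an exhaustive pathway enumerator, codon-alignment
threading, sliding-window arithmetic and estimator recovery."""

import math
import random

import pytest
from hypothesis import given, strategies as st

from oracles import ng86_pathways
from soxkit.molevol import (
    SENSE_CODONS,
    CodonAlignment,
    codon_align,
    ng86,
    ng86_pair,
    pairwise_kaks_table,
    selection_call,
    sliding_window,
)
from soxkit.seqio import CdsRecord
from soxkit.simulate import simulate_codon_pair


def _aln(codons_a, codons_b):
    return CodonAlignment("a", "b", tuple(codons_a), tuple(codons_b))


class TestNg86Counts:
    def test_identical_sequences(self):
        res = ng86(_aln(["ATG", "AAA"], ["ATG", "AAA"]))
        assert res.s_diffs == res.n_diffs == 0
        assert res.ka == res.ks == 0.0
        assert math.isnan(res.ratio)

    def test_single_synonymous_third_position_change(self):
        # TTT -> TTC is Phe -> Phe: one synonymous difference, Ka = 0
        res = ng86_pair(CdsRecord("a", "TTT"), CdsRecord("b", "TTC"))
        assert (res.s_diffs, res.n_diffs) == (1.0, 0.0)
        assert res.ka == 0.0

    def test_sites_sum_to_three_per_codon_for_all_sense_pairs(self):
        for c1 in SENSE_CODONS:
            res = ng86(_aln([c1], [c1]))
            assert res.n_sites + res.s_sites == pytest.approx(3.0)

    def test_pathway_counts_match_exhaustive_enumerator(self):
        # every 61 x 61 sense-codon pair, against an independent oracle
        for c1 in SENSE_CODONS:
            for c2 in SENSE_CODONS:
                res = ng86(_aln([c1], [c2]))
                sd, nd, hamming = ng86_pathways(c1, c2)
                assert res.s_diffs + res.n_diffs == pytest.approx(hamming)
                assert res.s_diffs == pytest.approx(sd)
                assert res.n_diffs == pytest.approx(nd)

    def test_symmetric_in_sequence_order(self):
        rng = random.Random(3)
        for _ in range(25):
            a = [rng.choice(SENSE_CODONS) for _ in range(30)]
            b = [rng.choice(SENSE_CODONS) for _ in range(30)]
            r1, r2 = ng86(_aln(a, b)), ng86(_aln(b, a))
            assert r1.ka == pytest.approx(r2.ka, nan_ok=True)
            assert r1.ks == pytest.approx(r2.ks, nan_ok=True)

    def test_saturated_proportion_gives_nan_not_exception(self):
        # force pS towards saturation with many third-position changes
        a = ["TTT"] * 3
        b = ["TTC"] * 3
        res = ng86(_aln(a, b))
        assert math.isnan(res.ks) and math.isnan(res.ratio)


class TestCodonAlign:
    def test_identical_cds(self):
        cds = CdsRecord("g1", "ATGAAACCC")
        aln = codon_align("MKP", "MKP", cds, CdsRecord("g2", "ATGAAACCC"))
        assert aln.n_codons == 3

    def test_gap_column_masked(self):
        a = CdsRecord("g1", "ATGAAACCC")
        b = CdsRecord("g2", "ATGCCC")
        aln = codon_align("MKP", "M-P", a, b)
        assert aln.n_codons == 2
        assert aln.codons_a == ("ATG", "CCC")

    def test_terminal_stop_trimmed(self):
        a = CdsRecord("g1", "ATGAAATAA")
        aln = codon_align("MK", "MK", a, CdsRecord("g2", "ATGAAA"))
        assert aln.n_codons == 2

    def test_translation_mismatch_names_codon(self):
        with pytest.raises(ValueError, match="codon 2"):
            codon_align("MK", "MK", CdsRecord("g1", "ATGCCC"),
                        CdsRecord("g2", "ATGAAA"))


class TestSlidingWindow:
    def _identical(self, n_codons):
        codons = ["ATG"] * n_codons
        return _aln(codons, codons)

    def test_exact_window_count_for_168bp(self):
        # L=168, window 150, step 9 -> floor((168-150)/9)+1 = 3 windows
        points = sliding_window(self._identical(56), 150, 9)
        assert [p.start_bp for p in points] == [1, 10, 19]
        assert all(p.end_bp - p.start_bp + 1 == 150 for p in points)

    def test_single_window_when_length_equals_window(self):
        assert len(sliding_window(self._identical(50), 150, 9)) == 1

    def test_too_short_alignment_gives_empty_list(self):
        assert sliding_window(self._identical(49), 150, 9) == []

    @given(st.integers(min_value=1, max_value=400))
    def test_window_count_formula(self, n_codons):
        L = 3 * n_codons
        points = sliding_window(self._identical(n_codons), 150, 9)
        expected = 0 if L < 150 else (L - 150) // 9 + 1
        assert len(points) == expected

    def test_planted_high_omega_segment_raises_window_ratios(self):
        low_a, low_b, _ = simulate_codon_pair(100, 0.05, 0.4, seed=21)
        hot_a, hot_b, _ = simulate_codon_pair(60, 2.0, 0.4, seed=22)
        tail_a, tail_b, _ = simulate_codon_pair(100, 0.05, 0.4, seed=23)
        codons = lambda s: [s[i:i + 3] for i in range(0, len(s), 3)]
        a = codons(low_a.sequence) + codons(hot_a.sequence) + codons(tail_a.sequence)
        b = codons(low_b.sequence) + codons(hot_b.sequence) + codons(tail_b.sequence)
        points = sliding_window(_aln(a, b), 150, 9)
        hot_bp = range(301, 481)  # codons 101-160
        inside = [p.ka_ks for p in points
                  if p.start_bp >= hot_bp.start and p.end_bp <= hot_bp.stop
                  and not math.isnan(p.ka_ks)]
        outside = [p.ka_ks for p in points
                   if (p.end_bp < hot_bp.start or p.start_bp > hot_bp.stop)
                   and not math.isnan(p.ka_ks)]
        assert inside and outside
        assert (sum(inside) / len(inside)) > 2 * (sum(outside) / len(outside))


class TestEstimatorRecovery:
    def test_purifying_omega_recovered(self):
        ratios = []
        for rep in range(30):
            a, b, _ = simulate_codon_pair(300, omega=0.2, t=0.3, seed=100 + rep)
            ratios.append(ng86_pair(a, b).ratio)
        mean = sum(ratios) / len(ratios)
        assert mean == pytest.approx(0.2, abs=0.15)

    def test_omega_zero_yields_zero_ka(self):
        a, b, counts = simulate_codon_pair(200, omega=0.0, t=0.2, seed=5)
        assert counts["nonsynonymous"] == 0
        res = ng86_pair(a, b)
        assert res.n_diffs == 0 and res.ka == 0.0

    def test_zero_divergence_is_identity(self):
        a, b, counts = simulate_codon_pair(50, omega=0.5, t=0.0, seed=6)
        assert a.sequence == b.sequence
        assert counts == {"synonymous": 0, "nonsynonymous": 0}


class TestPairTable:
    def test_purifying_pairs_called_purifying(self):
        cds = {}
        pairs = []
        for i in range(3):
            a, b, _ = simulate_codon_pair(400, omega=0.3, t=0.3, seed=50 + i)
            cds[f"a{i}"] = CdsRecord(f"a{i}", a.sequence)
            cds[f"b{i}"] = CdsRecord(f"b{i}", b.sequence)
            pairs.append((f"a{i}", f"b{i}"))
        df = pairwise_kaks_table(pairs, cds)
        assert list(df["call"]) == ["purifying"] * 3

    def test_neutral_band_call(self):
        assert selection_call(1.02) == "neutral"
        assert selection_call(0.4) == "purifying"
        assert selection_call(1.6) == "positive"
        assert selection_call(float("nan")) == "undefined"

    def test_empty_pair_list_gives_empty_table(self):
        assert pairwise_kaks_table([], {}).empty

    def test_missing_cds_is_an_error_naming_the_gene(self):
        with pytest.raises(ValueError, match="gX"):
            pairwise_kaks_table([("gX", "gY")], {})
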