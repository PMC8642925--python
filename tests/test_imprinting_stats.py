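import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from imprintscan.allelic_counting import GeneAllelicSummary
from imprintscan.imprinting_stats import (
    Status,
    adjust_q,
    call_imprinting,
    chi2_two_to_one,
    classify,
    meg_fraction_threshold,
    merge_cross_pairs,
    peg_fraction_threshold,
)


def chi2_sf_oracle(x: float) -> float:
    """Survival function of chi-square(1 df) via the error function:
    P(X > x) = erfc(sqrt(x/2)). Independent of scipy."""
    return math.erfc(math.sqrt(x / 2.0))


def summary(m, p, direction="forward", gene="g"):
    return GeneAllelicSummary(gene, direction, m, p, 1)


class TestChi2TwoToOne:
    def test_exact_dosage_ratio(self):
        stat, p = chi2_two_to_one(20, 10)
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_fully_maternal(self):
        # by hand: (100 - 200/3)^2/(200/3) + (0 - 100/3)^2/(100/3) = 50
        stat, p = chi2_two_to_one(100, 0)
        assert stat == pytest.approx(50.0)
        assert p == pytest.approx(chi2_sf_oracle(50.0), rel=1e-9)
        assert p == pytest.approx(1.537e-12, rel=1e-3)

    def test_inverted_ratio(self):
        # by hand: (10-20)^2/20 + (20-10)^2/10 = 5 + 10 = 15
        stat, _ = chi2_two_to_one(10, 20)
        assert stat == pytest.approx(15.0)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            chi2_two_to_one(0, 0)

    def test_vectorised_matches_scalar(self):
        M = np.array([20, 100, 10, 7])
        P = np.array([10, 0, 20, 13])
        stats_v, p_v = chi2_two_to_one(M, P)
        for m, p, sv, pv in zip(M, P, stats_v, p_v):
            ss, ps = chi2_two_to_one(int(m), int(p))
            assert sv == pytest.approx(ss)
            assert pv == pytest.approx(ps)

    @given(m=st.integers(0, 200), p=st.integers(0, 200))
    def test_p_value_matches_erfc_oracle(self, m, p):
        if m + p == 0:
            return
        stat, pv = chi2_two_to_one(m, p)
        assert pv == pytest.approx(chi2_sf_oracle(stat), rel=1e-9, abs=1e-300)


class TestAdjustQ:
    def test_single_p_identity(self):
        assert adjust_q([0.01]) == pytest.approx([0.01])

    def test_hand_computed_bh(self):
        # q_i = min over j>=i of p_(j) * m / j = 0.04 for all four
        assert adjust_q([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_all_ones(self):
        assert adjust_q([1.0, 1.0, 1.0]) == pytest.approx([1.0] * 3)

    def test_empty(self):
        assert adjust_q([]).size == 0

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=50))
    def test_qs_dominate_ps_and_stay_in_unit_interval(self, ps):
        q = adjust_q(ps)
        assert np.all(q >= np.asarray(ps) - 1e-12)
        assert np.all((q >= 0) & (q <= 1))


class TestThresholds:
    def test_default_fold_gives_published_cutoffs(self):
        assert meg_fraction_threshold(5) == pytest.approx(10 / 11)
        assert peg_fraction_threshold(5) == pytest.approx(5 / 7)

    def test_thresholds_follow_fold_factor(self):
        # 2f/(2f+1) and f/(f+2) at f=3
        assert meg_fraction_threshold(3) == pytest.approx(6 / 7)
        assert peg_fraction_threshold(3) == pytest.approx(3 / 5)


class TestClassify:
    def test_high_stringency_meg(self):
        status = classify(summary(200, 4), summary(180, 5, "reciprocal"), 1e-6, 1e-6, "coding")
        assert status is Status.MEG

    def test_exact_dosage_is_biallelic(self):
        status = classify(summary(40, 20), summary(40, 20, "reciprocal"), 1.0, 1.0, "coding")
        assert status is Status.BIALLELIC

    def test_fraction_exactly_at_threshold_is_low_stringency_only(self):
        # maternal fraction exactly 10/11 fails the strict MEG cutoff
        status = classify(summary(100, 10), summary(110, 2, "reciprocal"), 1e-9, 1e-9, "coding")
        assert status is Status.LOW_MEG

    def test_noncoding_peg_is_pnc(self):
        status = classify(summary(3, 97), summary(5, 95, "reciprocal"), 1e-9, 1e-9, "noncoding")
        assert status is Status.PNC

    def test_opposite_directions_are_biallelic(self):
        status = classify(summary(95, 5), summary(5, 95, "reciprocal"), 1e-9, 1e-9, "coding")
        assert status is Status.BIALLELIC

    def test_one_insignificant_direction_is_biallelic(self):
        status = classify(summary(95, 5), summary(60, 40, "reciprocal"), 1e-9, 0.5, "coding")
        assert status is Status.BIALLELIC

    @given(
        mf=st.integers(0, 300), pf=st.integers(0, 300),
        mr=st.integers(0, 300), pr=st.integers(0, 300),
        qf=st.floats(0, 1), qr=st.floats(0, 1),
    )
    def test_parental_swap_symmetry(self, mf, pf, mr, pr, qf, qr):
        """Swapping M and P in both directions, together with the mirrored
        1:2 dosage null, maps every maternal-side call to its exact
        paternal-side mirror (the 2:1 null itself is what makes the two
        parental sides asymmetric at fixed dosage)."""
        if mf + pf == 0 or mr + pr == 0:
            return
        mirror = {
            Status.MEG: Status.PEG, Status.PEG: Status.MEG,
            Status.LOW_MEG: Status.LOW_PEG, Status.LOW_PEG: Status.LOW_MEG,
            Status.BIALLELIC: Status.BIALLELIC,
        }
        a = classify(summary(mf, pf), summary(mr, pr, "reciprocal"), qf, qr, "coding")
        b = classify(summary(pf, mf), summary(pr, mr, "reciprocal"), qf, qr, "coding",
                     dosage=(1, 2))
        assert b is mirror[a]

    @given(
        mf=st.integers(0, 300), pf=st.integers(0, 300),
        mr=st.integers(0, 300), pr=st.integers(0, 300),
    )
    def test_high_stringency_implies_low_stringency(self, mf, pf, mr, pr):
        if mf + pf == 0 or mr + pr == 0:
            return
        status = classify(summary(mf, pf), summary(mr, pr, "reciprocal"), 1e-9, 1e-9, "coding")
        f0 = 2 / 3
        s_f = summary(mf, pf)
        s_r = summary(mr, pr, "reciprocal")
        if status is Status.MEG:
            assert s_f.maternal_fraction > f0 and s_r.maternal_fraction > f0
        if status is Status.PEG:
            assert s_f.maternal_fraction < f0 and s_r.maternal_fraction < f0


class TestCallImprinting:
    def test_non_analyzed_below_read_threshold(self):
        fwd = {"g1": summary(5, 3, gene="g1")}
        rev = {"g1": summary(100, 2, "reciprocal", gene="g1")}
        calls = call_imprinting(fwd, rev, {"g1": "coding"})
        assert calls["g1"].status is Status.NON_ANALYZED

    def test_bh_family_is_analyzable_genes(self):
        # one strongly imprinted gene among clear biallelic ones
        fwd = {f"g{i}": summary(200, 100, gene=f"g{i}") for i in range(9)}
        rev = {f"g{i}": summary(200, 100, "reciprocal", gene=f"g{i}") for i in range(9)}
        fwd["hit"] = summary(300, 2, gene="hit")
        rev["hit"] = summary(280, 3, "reciprocal", gene="hit")
        calls = call_imprinting(fwd, rev, {g: "coding" for g in fwd})
        assert calls["hit"].status is Status.MEG
        _, p_single = chi2_two_to_one(300, 2)
        # BH with 10 tests inflates the smallest p by at most m/1
        assert calls["hit"].q_fwd <= min(1.0, p_single * 10) + 1e-12

    def test_expressed_filter_gates_analysis(self):
        fwd = {"g1": summary(300, 2, gene="g1")}
        rev = {"g1": summary(280, 3, "reciprocal", gene="g1")}
        calls = call_imprinting(fwd, rev, {"g1": "coding"}, expressed={"g1": False})
        assert calls["g1"].status is Status.NON_ANALYZED


def test_merge_cross_pairs_union_and_conflict():
    from imprintscan.imprinting_stats import ImprintingCall

    def call(gene, status):
        return ImprintingCall(gene, status, 0, 0, 0, 0, 0.5, 0.5)

    pair1 = {"a": call("a", Status.MEG), "b": call("b", Status.NON_ANALYZED),
             "c": call("c", Status.PEG)}
    pair2 = {"a": call("a", Status.BIALLELIC), "b": call("b", Status.PEG),
             "c": call("c", Status.LOW_MEG)}
    merged = merge_cross_pairs([pair1, pair2])
    assert merged["a"] is Status.MEG          # imprinted in either pair
    assert merged["b"] is Status.PEG          # analyzed only in pair 2
    assert merged["c"] is Status.BIALLELIC    # conflicting parental directions
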