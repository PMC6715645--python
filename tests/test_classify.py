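"""Levan typing, formulas and Stebbins asymmetry classification."""

from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from karyokit import (
    HeteromorphismPolicy,
    LevanThresholds,
    PairProfile,
    classify_karyotype,
    karyotype_formula,
    levan_type,
    pair_types,
    proportion_arm_ratio_above,
    stebbins_class,
)

TYPE_ORDER = {"m": 0, "sm": 1, "st": 2, "t": 3}


class TestLevanType:
    @pytest.mark.parametrize(
        "r, expected",
        [
            (1.0, "m"),
            (1.67, "m"),
            (1.70, "sm"),  # lower-inclusive boundary
            (2.17, "sm"),
            (3.00, "st"),  # lower-inclusive boundary
            (6.10, "st"),
            (7.0, "t"),
            (7.5, "t"),
            (8.0, "t"),
        ],
    )
    def test_interval_classification(self, r, expected):
        assert levan_type(r) == expected

    def test_ratio_below_one_rejected(self):
        with pytest.raises(ValueError):
            levan_type(0.8)

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            LevanThresholds(m_max=3.0, sm_max=1.7)

    @settings(deadline=None, max_examples=200)
    @given(st.floats(1.0, 20.0), st.floats(1.0, 20.0))
    def test_monotone_in_ratio(self, r1, r2):
        lo, hi = sorted((r1, r2))
        assert TYPE_ORDER[levan_type(hi)] >= TYPE_ORDER[levan_type(lo)]


def _pp(rank, ra, rb=None, rel=5.0):
    return PairProfile(
        rank=rank, rel_length_pct=rel, arm_ratio_a=ra, arm_ratio_b=rb if rb else ra
    )


class TestPairTypes:
    @pytest.mark.parametrize(
        "ra, rb, expected",
        [
            (2.17, 1.67, ("sm", "m", True)),
            (3.00, 2.09, ("st", "sm", True)),
            (4.0, 4.0, ("st", "st", False)),
        ],
    )
    def test_homologs_typed_independently(self, ra, rb, expected):
        assert pair_types(_pp(1, ra, rb)) == expected

    def test_strict_policy_flags_same_type_gap(self):
        p = _pp(1, 2.9, 2.2)
        assert pair_types(p)[2] is False
        assert pair_types(p, policy=HeteromorphismPolicy(same_type_gap=True))[2] is True


class TestKaryotypeFormula:
    def test_three_identical_metacentric_pairs(self):
        pairs = [_pp(i, 1.2) for i in (1, 2, 3)]
        typed = [
            PairProfile(
                rank=p.rank, rel_length_pct=5.0, arm_ratio_a=1.2, arm_ratio_b=1.2,
                type_a="m", type_b="m",
            )
            for p in pairs
        ]
        assert str(karyotype_formula(typed)) == "3m"

    def test_untyped_pair_rejected(self):
        with pytest.raises(ValueError, match="untyped"):
            karyotype_formula([_pp(1, 2.0)])

    def test_counts_sum_to_n_pairs_with_halves_iff_heteromorphic(self, classified):
        for acc, k in classified.items():
            assert k.formula.n_pairs == k.n_pairs
            has_half = any(c != int(c) for c in k.formula.counts.values())
            assert has_half == any(p.heteromorphic for p in k.pairs)


class TestProportionAboveTwo:
    def test_all_metacentric_is_zero(self):
        assert proportion_arm_ratio_above([_pp(1, 1.0), _pp(2, 1.0)]) == 0

    def test_one_of_two_pairs(self):
        assert proportion_arm_ratio_above([_pp(1, 3.0), _pp(2, 1.2)]) == Fraction(1, 2)

    def test_published_profile_both_conventions(self, all_profiles):
        pairs = all_profiles["S_rufescens"]
        assert proportion_arm_ratio_above(pairs) == Fraction(21, 32)  # 10.5/16
        assert proportion_arm_ratio_above(pairs, convention="pair_any") == Fraction(11, 16)
        # both conventions land in Stebbins row 3
        for conv in ("homolog", "pair_any"):
            p = proportion_arm_ratio_above(pairs, convention=conv)
            assert stebbins_class(p, 3.05).row == 3


class TestStebbinsClass:
    @pytest.mark.parametrize(
        "p, s, expected",
        [
            (Fraction(0), 1.0, "1A"),
            (Fraction(1, 2), 3.0, "2B"),  # p = 0.5 closes row 2
            (Fraction(21, 32), 3.05, "3B"),
            (Fraction(21, 32), 4.82, "3C"),
            (Fraction(1), 4.0, "4B"),  # s = 4 closes column B
            (Fraction(1), 4.01, "4C"),
            (Fraction(1, 100), 1.99, "2A"),
        ],
    )
    def test_band_boundaries(self, p, s, expected):
        assert str(stebbins_class(p, s)) == expected

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            stebbins_class(1.5, 2.0)
        with pytest.raises(ValueError):
            stebbins_class(Fraction(1, 2), 0.5)


class TestClassifyKaryotype:
    def test_order_invariance(self, all_profiles):
        pairs = all_profiles["S_campestris"]
        k1 = classify_karyotype("x", pairs)
        k2 = classify_karyotype("x", list(reversed(pairs)))
        assert str(k1.formula) == str(k2.formula)
        assert [p.arm_ratio_a for p in k1.pairs] == [p.arm_ratio_a for p in k2.pairs]

    def test_scale_invariance_of_class(self, all_profiles):
        pairs = all_profiles["S_rufescens"]
        k1 = classify_karyotype("x", pairs, largest_um=5.62, smallest_um=1.84)
        k2 = classify_karyotype("x", pairs, largest_um=56.2, smallest_um=18.4)
        assert str(k1.stebbins) == str(k2.stebbins) == "3B"

    def test_size_ratio_falls_back_to_relative_lengths(self, all_profiles):
        k = classify_karyotype("x", all_profiles["S_fluminensis_Uruana"])
        assert str(k.stebbins) == "3C"  # 15.08 / 3.33 > 4

    def test_heteromorphic_pair_detected_and_annotated(self, classified):
        k = classified["S_rufescens"]
        het = [p for p in k.pairs if p.heteromorphic]
        assert [p.rank for p in het] == [10]
        assert (het[0].type_a, het[0].type_b) == ("sm", "m")
        assert "sex" in k.metadata["heteromorphic_note"]
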