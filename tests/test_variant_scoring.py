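"""Threshold classification, damage-potential profile and class comparison."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mfnscan import (
    ClassifierThresholds,
    CodingRegion,
    InvalidScoreError,
    MissingScoreError,
    classify_pp2,
    classify_sift,
    compare_mutation_classes,
    damage_category,
    enumerate_snvs,
    position_damage_profile,
    variant_flagged_damaging,
)
from mfnscan.variant_scoring import (
    MISSING_LABEL,
    PP2_BENIGN,
    PP2_POSSIBLY,
    PP2_PROBABLY,
    SIFT_DAMAGING,
    SIFT_TOLERATED,
)

from .oracles import fisher_two_sided


class TestClassifiers:
    @pytest.mark.parametrize(
        "score,label",
        [(0.99, SIFT_DAMAGING), (0.88, SIFT_TOLERATED), (0.91, SIFT_TOLERATED),
         (0.92, SIFT_TOLERATED), (0.95, SIFT_TOLERATED), (0.951, SIFT_DAMAGING)],
    )
    def test_sift_threshold_is_strict(self, score, label):
        assert classify_sift(score) == label

    @pytest.mark.parametrize(
        "score,label",
        [(0.999, PP2_PROBABLY), (0.161, PP2_POSSIBLY), (0.02, PP2_BENIGN),
         (0.001, PP2_BENIGN), (0.15, PP2_POSSIBLY), (0.85, PP2_POSSIBLY),
         (0.1499, PP2_BENIGN), (0.8501, PP2_PROBABLY)],
    )
    def test_pp2_bands_closed_in_the_middle(self, score, label):
        assert classify_pp2(score) == label

    @pytest.mark.parametrize("bad", [-0.1, 1.1, 2.0])
    def test_out_of_range_scores_rejected(self, bad):
        with pytest.raises(InvalidScoreError):
            classify_sift(bad)
        with pytest.raises(InvalidScoreError):
            classify_pp2(bad)

    def test_missing_scores_get_sentinel(self):
        assert classify_sift(None) == MISSING_LABEL
        assert classify_pp2(float("nan")) == MISSING_LABEL

    def test_bad_thresholds_rejected(self):
        with pytest.raises(InvalidScoreError):
            ClassifierThresholds(pp2_benign_lt=0.9, pp2_probably_gt=0.1)

    @settings(max_examples=80, deadline=None)
    @given(
        lo=st.floats(0, 1, allow_nan=False),
        hi=st.floats(0, 1, allow_nan=False),
    )
    def test_pp2_monotone_in_score(self, lo, hi):
        """A higher score never moves the label toward Benign."""
        lo, hi = min(lo, hi), max(lo, hi)
        order = {PP2_BENIGN: 0, PP2_POSSIBLY: 1, PP2_PROBABLY: 2}
        assert order[classify_pp2(lo)] <= order[classify_pp2(hi)]


def _snv(codon: str, pos: int, alt: str):
    region = CodingRegion("c", codon)
    return next(
        s for s in enumerate_snvs(region) if s.pos_in_codon == pos and s.alt_nt == alt
    )


class TestDamageCategory:
    def test_nonsense_is_two_without_any_score(self):
        stop_gain = _snv("TGG", 2, "A")  # TGG -> TAG
        assert stop_gain.consequence == "nonsense"
        assert damage_category(stop_gain) == 2

    @pytest.mark.parametrize(
        "label,cat", [(PP2_BENIGN, 0), (PP2_POSSIBLY, 1), (PP2_PROBABLY, 2)]
    )
    def test_missense_maps_pp2_label(self, label, cat):
        missense = _snv("ATG", 2, "A")  # ATG -> AAG (M>K)
        assert damage_category(missense, label) == cat

    def test_synonymous_rejected(self):
        syn = _snv("CTG", 3, "A")  # CTG -> CTA, both Leu
        with pytest.raises(ValueError, match="synonymous"):
            damage_category(syn, PP2_BENIGN)

    def test_missing_score_policy(self, caplog):
        missense = _snv("ATG", 2, "A")
        with pytest.raises(MissingScoreError):
            damage_category(missense, None, missing_policy="strict")
        with caplog.at_level("WARNING"):
            assert damage_category(missense, None, missing_policy="permissive") == 0
        assert "no PolyPhen2 score" in caplog.text


def _score_table(rows):
    df = pd.DataFrame(
        rows, columns=["residue_number", "ref_aa", "alt_aa", "sift_score", "pp2_score"]
    )
    return df.drop_duplicates(subset=["residue_number", "ref_aa", "alt_aa"])


class TestPositionDamageProfile:
    def test_all_benign_missense_codon_scores_zero(self):
        # CTG (Leu): every change is missense or synonymous, no stop-gain routes
        region = CodingRegion("c", "CTG")
        rows = [
            (1, s.ref_aa, s.alt_aa, 0.5, 0.01)
            for s in enumerate_snvs(region)
            if s.consequence == "missense"
        ]
        profile = position_damage_profile(region, _score_table(rows))
        assert profile.loc[1] == 0

    def test_trp_codon_with_benign_missense_scores_four(self):
        # TGG: 7 missense (scored benign) + 2 stop-gains x category 2 = 4
        region = CodingRegion("c", "TGG")
        rows = [
            (1, s.ref_aa, s.alt_aa, 0.5, 0.01)
            for s in enumerate_snvs(region)
            if s.consequence == "missense"
        ]
        profile = position_damage_profile(region, _score_table(rows))
        assert profile.loc[1] == 4

    def test_multi_route_change_counts_per_nucleotide(self):
        # ATG: M>I is reachable via three third-position changes; scoring the
        # single M>I row as possibly damaging must add 3, not 1
        region = CodingRegion("c", "ATG")
        rows = [(1, "M", "I", 0.5, 0.5)] + [
            (1, s.ref_aa, s.alt_aa, 0.5, 0.01)
            for s in enumerate_snvs(region)
            if s.consequence == "missense" and s.alt_aa != "I"
        ]
        profile = position_damage_profile(region, _score_table(rows))
        assert profile.loc[1] == 3

    def test_additive_over_codons_and_row_order_invariant(self, rng):
        region = CodingRegion("c", "ATGTGG", first_residue_number=10)
        snvs = enumerate_snvs(region)
        rows = [
            (s.residue_number, s.ref_aa, s.alt_aa, 0.5, rng.random())
            for s in snvs
            if s.consequence == "missense"
        ]
        table = _score_table(rows).drop_duplicates(
            subset=["residue_number", "ref_aa", "alt_aa"]
        )
        profile = position_damage_profile(region, table)
        shuffled = position_damage_profile(region, table.sample(frac=1, random_state=1))
        pd.testing.assert_series_equal(profile, shuffled)
        # additivity over disjoint codon subsets
        for res, codon in zip((10, 11), ("ATG", "TGG")):
            sub_region = CodingRegion("c", codon, first_residue_number=res)
            sub = position_damage_profile(
                region=sub_region,
                scores=table[table.residue_number == res],
            )
            assert sub.loc[res] == profile.loc[res]

    def test_profile_bounded_by_18(self, hr1_like_region):
        snvs = enumerate_snvs(hr1_like_region)
        rows = [
            (s.residue_number, s.ref_aa, s.alt_aa, 1.0, 0.99)
            for s in snvs
            if s.consequence == "missense"
        ]
        table = _score_table(rows).drop_duplicates(
            subset=["residue_number", "ref_aa", "alt_aa"]
        )
        profile = position_damage_profile(hr1_like_region, table)
        assert ((profile >= 0) & (profile <= 18)).all()
        assert len(profile) == 44

    def test_missing_score_strict_names_the_change(self):
        region = CodingRegion("c", "ATG")
        with pytest.raises(MissingScoreError, match=r"M1[A-Z]"):
            position_damage_profile(
                region, _score_table([]), missing_policy="strict"
            )


class TestFlaggedDamaging:
    @pytest.mark.parametrize(
        "sift,pp2,flagged",
        [
            (0.88, 0.161, True),   # tolerated but possibly damaging
            (0.91, 0.02, False),   # benign by both
            (0.99, 0.999, True),   # damaging by both
            (0.92, 0.001, False),
            (0.99, None, True),    # SIFT alone can flag
            (None, 0.01, False),   # benign PolyPhen2 alone cannot
        ],
    )
    def test_flag_logic(self, sift, pp2, flagged):
        assert variant_flagged_damaging(sift, pp2) is flagged

    def test_both_missing_is_an_error(self):
        with pytest.raises(MissingScoreError):
            variant_flagged_damaging(None, float("nan"))


class TestTable1Fixture:
    def test_reproduces_published_predictions(self, table1):
        sift_pred = [classify_sift(s) for s in table1.sift_score]
        pp2_pred = [classify_pp2(s) for s in table1.pp2_score]
        assert sift_pred == [
            SIFT_TOLERATED, SIFT_TOLERATED, SIFT_DAMAGING, SIFT_TOLERATED,
        ]
        assert pp2_pred == [PP2_POSSIBLY, PP2_BENIGN, PP2_PROBABLY, PP2_BENIGN]

    def test_exactly_two_variants_flagged(self, table1):
        flags = [
            variant_flagged_damaging(s, p)
            for s, p in zip(table1.sift_score, table1.pp2_score)
        ]
        assert flags == [True, False, True, False]
        flagged_residues = table1.residue_number[flags].tolist()
        assert flagged_residues == [393, 400]


class TestCompareMutationClasses:
    def test_identical_groups_are_null(self):
        scores = [0.2, 0.4, 0.6]
        flags = [True, False, True]
        res = compare_mutation_classes(scores, flags, scores, flags)
        assert res.fisher_p == 1.0
        assert res.t_stat == pytest.approx(0.0)
        assert res.t_p == pytest.approx(1.0)
        assert res.frac_a == res.frac_b

    def test_fisher_matches_enumeration_oracle(self):
        res = compare_mutation_classes(
            np.linspace(0.1, 0.9, 10), [True] * 3 + [False] * 7,
            np.linspace(0.1, 0.9, 10), [True] * 9 + [False] * 1,
        )
        assert res.fisher_p == pytest.approx(0.0197666110978804, abs=1e-12)
        assert res.fisher_p == pytest.approx(fisher_two_sided(3, 7, 9, 1), abs=1e-12)

    def test_t_matches_hand_computed_pooled_t(self):
        res = compare_mutation_classes(
            [0.1, 0.2, 0.3], [False] * 3, [0.7, 0.8, 0.9], [True] * 3
        )
        # hand computation: pooled s^2 = 0.01, t = -0.6/sqrt(0.01*2/3), df = 4
        assert res.t_stat == pytest.approx(-7.348469228349536, rel=1e-12)
        assert res.t_p == pytest.approx(0.0018262606682599818, rel=1e-9)
        assert res.sem_a == pytest.approx(0.1 / math.sqrt(3), rel=1e-12)

    def test_small_group_skips_t_but_keeps_fisher(self, caplog):
        with caplog.at_level("WARNING"):
            res = compare_mutation_classes([0.5], [True], [0.1, 0.2], [False, False])
        assert math.isnan(res.t_p)
        assert 0 < res.fisher_p <= 1
        assert "t-test not computed" in caplog.text

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_mutation_classes([], [], [0.5], [True])

    def test_fisher_oracle_equivalence_on_table_sample(self, rng):
        """Implementation agrees with integer enumeration on random small tables."""
        for _ in range(300):
            a, b, c, d = rng.integers(0, 11, size=4)
            if (a + b) == 0 or (c + d) == 0:
                continue
            res = compare_mutation_classes(
                [0.1, 0.9], [True] * a + [False] * b,
                [0.1, 0.9], [True] * c + [False] * d,
            )
            assert res.fisher_p == pytest.approx(
                fisher_two_sided(a, b, c, d), abs=1e-12
            )
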