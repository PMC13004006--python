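"""Composite ultrasound score and Bishop score component maps."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import iolscore as iol
from iolscore import (
    BishopAssessment,
    RiskCategory,
    UltrasoundAssessment,
    ValidationError,
    bishop_score,
    classify_category,
    composite_score,
)
from iolscore.scoring import angulation_subscores, elastography_subscores


class TestComponentBands:
    @pytest.mark.parametrize("cl, expected", [
        (25.0, 0), (20.5, 0), (20.0, 1), (11.0, 1), (15.0, 1),
        (10.9, 2), (0.0, 2),
    ])
    def test_cervical_length_bands(self, cl, expected):
        assert iol.score_cervical_length(cl) == expected

    @pytest.mark.parametrize("pos, expected", [
        ("occiput_posterior", 0), ("occiput_transverse", 1),
        ("occiput_anterior", 2),
    ])
    def test_head_position_map(self, pos, expected):
        assert iol.score_head_position(pos) == expected

    @pytest.mark.parametrize("hpd, expected", [
        (55.0, 0), (50.0, 1), (40.0, 1), (39.9, 2), (10.0, 2),
    ])
    def test_head_perineum_distance_bands(self, hpd, expected):
        assert iol.score_head_perineum_distance(hpd) == expected

    @pytest.mark.parametrize("stiff, expected_subs, expected", [
        ((12, 9, 7), (0, 0, 0), 0),     # every third above its 0-band edge
        ((5, 4, 3), (2, 2, 2), 2),      # every third below its 2-band edge
        ((12, 7, 4), (0, 1, 2), 1),     # mixed; mean 1.0 rounds to 1
        ((9.0, 7.0, 5.5), (1, 1, 1), 1),  # middle closed bands
    ])
    def test_elastography_default(self, stiff, expected_subs, expected):
        assert elastography_subscores(*stiff) == expected_subs
        assert iol.score_elastography(*stiff) == expected

    def test_elastography_alternative_strategies(self):
        # (12, 7, 4): sub-scores (0, 1, 2) -> vote/median is 1;
        # mean stiffness 7.667 is inside [6.6, 8.0] -> 1
        assert iol.score_elastography(12, 7, 4, strategy="per_third_then_vote") == 1
        assert iol.score_elastography(
            12, 7, 4, strategy="mean_stiffness_vs_mean_thresholds") == 1
        # (11, 10, 9): subs (0, 0, 0) but the mean 10 exceeds 8 -> 0 both ways
        assert iol.score_elastography(11, 10, 9) == 0
        # rounding half-up: subs (1, 2, 2), mean 5/3 -> 2
        assert iol.score_elastography(9.0, 5.0, 4.0) == 2
        with pytest.raises(iol.ConfigurationError):
            iol.score_elastography(5, 5, 5, strategy="nope")

    @pytest.mark.parametrize("aa, pa, expected_subs, expected", [
        (110, 105, (2, 2, 2), 2),   # all above the upper edges
        (80, 80, (0, 0, 0), 0),     # all below the lower edges
        (95, 85, (1, 0, 1), 1),     # AA in band, PA below, sum 180 in band
        (104, 99, (1, 1, 2), 1),    # closed middle-band edges; sum 203 > 190
    ])
    def test_angulation_default(self, aa, pa, expected_subs, expected):
        assert angulation_subscores(aa, pa) == expected_subs
        assert iol.score_angulation(aa, pa) == expected

    def test_angulation_sum_only_strategy(self):
        assert iol.score_angulation(95, 85, strategy="sum_score_only") == 1
        assert iol.score_angulation(80, 80, strategy="sum_score_only") == 0
        with pytest.raises(iol.ConfigurationError):
            iol.score_angulation(95, 85, strategy="nope")

    @pytest.mark.parametrize("func, bad", [
        (iol.score_cervical_length, -1.0),
        (iol.score_cervical_length, float("nan")),
        (iol.score_head_perineum_distance, float("inf")),
    ])
    def test_invalid_measurements_rejected(self, func, bad):
        with pytest.raises(ValidationError):
            func(bad)

    def test_unknown_head_position_lists_accepted_labels(self):
        with pytest.raises(ValidationError, match="occiput_anterior"):
            iol.score_head_position("breech")


class TestCompositeScore:
    def test_all_favorable_scores_ten(self):
        a = UltrasoundAssessment(8, "occiput_anterior", 35, 5, 4, 3, 110, 105)
        r = composite_score(a)
        assert r.total == 10 and r.category is RiskCategory.HIGH

    def test_all_unfavorable_scores_zero(self):
        a = UltrasoundAssessment(30, "occiput_posterior", 60, 12, 9, 7, 80, 80)
        r = composite_score(a)
        assert r.total == 0 and r.category is RiskCategory.LOW

    def test_mixed_assessment_sums_components(self):
        a = UltrasoundAssessment(15, "occiput_transverse", 45, 12, 7, 4, 95, 85)
        r = composite_score(a)
        assert (r.sub_cl, r.sub_position, r.sub_hpd, r.sub_elasto,
                r.sub_angle) == (1, 1, 1, 1, 1)
        assert r.total == 5 and r.category is RiskCategory.INTERMEDIATE

    def test_missing_measurement_named(self):
        with pytest.raises(ValidationError, match="cervical_length"):
            UltrasoundAssessment(None, "occiput_anterior", 35, 5, 4, 3, 110, 105)

    @pytest.mark.parametrize("total, expected", [
        (0, RiskCategory.LOW), (3, RiskCategory.LOW),
        (4, RiskCategory.INTERMEDIATE), (6, RiskCategory.INTERMEDIATE),
        (7, RiskCategory.HIGH), (10, RiskCategory.HIGH),
    ])
    def test_category_bands(self, total, expected):
        assert classify_category(total) is expected

    def test_category_bands_exhaustive_and_exclusive(self):
        cats = [classify_category(t) for t in range(11)]
        assert all(c in RiskCategory for c in cats)
        assert [c.value for c in cats] == (
            ["low"] * 4 + ["intermediate"] * 3 + ["high"] * 4)

    @pytest.mark.parametrize("bad", [-1, 11, 5.5])
    def test_category_out_of_range(self, bad):
        with pytest.raises(ValidationError):
            classify_category(bad)


class TestBishopScore:
    @pytest.mark.parametrize("components, expected", [
        ((0, 0, -3, "firm", "posterior"), 0),     # all-minimum
        ((5, 80, 1, "soft", "anterior"), 13),     # all-maximum of original table
        ((3, 60, -1, "medium", "mid"), 8),        # 2+2+2+1+1
        ((1, 40, -2, "firm", "mid"), 4),          # 1+1+1+0+1
    ])
    def test_original_point_table(self, components, expected):
        d, e, s, c, p = components
        b = BishopAssessment(dilatation_cm=d, effacement_pct=e, station=s,
                             consistency=c, position=p)
        assert bishop_score(b) == expected

    @pytest.mark.parametrize("kwargs", [
        dict(dilatation_cm=-1, effacement_pct=0, station=0,
             consistency="firm", position="mid"),
        dict(dilatation_cm=2, effacement_pct=120, station=0,
             consistency="firm", position="mid"),
        dict(dilatation_cm=2, effacement_pct=50, station=3,
             consistency="firm", position="mid"),
        dict(dilatation_cm=2, effacement_pct=50, station=0,
             consistency="mushy", position="mid"),
    ])
    def test_out_of_range_components_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            BishopAssessment(**kwargs)


# ---------------------------------------------------------------------------
# Properties
# ---------------------------------------------------------------------------

def _brute_force_total(cl, pos, hpd, si, sm, so, aa, pa):
    """Independent re-implementation of the printed bands (kept deliberately
    naive: literal threshold chains and fraction arithmetic)."""
    if cl > 20:
        s1 = 0
    elif cl >= 11:
        s1 = 1
    else:
        s1 = 2
    s2 = {"occiput_posterior": 0, "occiput_transverse": 1,
          "occiput_anterior": 2}[pos]
    if hpd > 50:
        s3 = 0
    elif hpd >= 40:
        s3 = 1
    else:
        s3 = 2

    def down(v, hi, lo):
        return 0 if v > hi else (1 if v >= lo else 2)

    e = down(si, 10, 8.1) + down(sm, 8, 6.6) + down(so, 6, 5.1)
    s4 = math.floor(e / 3 + 0.5)

    def up(v, lo, hi):
        return 0 if v < lo else (1 if v <= hi else 2)

    g = up(aa, 90, 104) + up(pa, 90, 99) + up(aa + pa, 170, 190)
    s5 = math.floor(g / 3 + 0.5)
    return s1 + s2 + s3 + s4 + s5


def test_composite_agrees_with_brute_force_on_random_assessments():
    """10,000 random assessments: composite_score == literal band re-implementation."""
    rng = np.random.default_rng(20240202)
    positions = ("occiput_posterior", "occiput_transverse", "occiput_anterior")
    for _ in range(10_000):
        cl = rng.uniform(0, 45)
        pos = positions[rng.integers(3)]
        hpd = rng.uniform(10, 80)
        si, sm, so = rng.uniform(0, 20, 3)
        aa, pa = rng.uniform(40, 200, 2)
        a = UltrasoundAssessment(cl, pos, hpd, si, sm, so, aa, pa)
        r = composite_score(a)
        assert r.total == _brute_force_total(cl, pos, hpd, si, sm, so, aa, pa)
        assert r.total == (r.sub_cl + r.sub_position + r.sub_hpd
                           + r.sub_elasto + r.sub_angle)
        assert 0 <= r.total <= 10


@settings(derandomize=True, max_examples=200)
@given(lo=st.floats(0, 60), delta=st.floats(0, 30))
def test_cervical_length_subscore_monotone_as_cervix_shortens(lo, delta):
    assert iol.score_cervical_length(lo) >= iol.score_cervical_length(lo + delta)


@settings(derandomize=True, max_examples=200)
@given(lo=st.floats(10, 80), delta=st.floats(0, 40))
def test_hpd_subscore_monotone_as_head_descends(lo, delta):
    assert (iol.score_head_perineum_distance(lo)
            >= iol.score_head_perineum_distance(lo + delta))


@settings(derandomize=True, max_examples=200)
@given(si=st.floats(0.1, 25), sm=st.floats(0.1, 25), so=st.floats(0.1, 25),
       d=st.floats(0, 10))
def test_elastography_monotone_as_cervix_softens(si, sm, so, d):
    softer = iol.score_elastography(max(si - d, 0), max(sm - d, 0), max(so - d, 0))
    assert softer >= iol.score_elastography(si, sm, so)


@settings(derandomize=True, max_examples=200)
@given(aa=st.floats(40, 200), pa=st.floats(40, 150), d=st.floats(0, 50))
def test_angulation_monotone_as_angles_widen(aa, pa, d):
    assert iol.score_angulation(aa + d, pa + d) >= iol.score_angulation(aa, pa)
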