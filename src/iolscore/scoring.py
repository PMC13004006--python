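"""Pre-induction cervical scoring.

Two scores are computed per patient:

* the composite ultrasound induction score — five sonographic components
  (cervical length, fetal head position, head–perineum distance, cervical
  elastography, cervical angulation), each scored 0–2 in the direction of
  labor favorability, summed to a 0–10 total and banded into low (0–3),
  intermediate (4–6) and high (7–10) probability categories;
* the Bishop score in its original 1964 form (dilatation, effacement,
  station, consistency, position; maximum 13).

All component maps are total, piecewise-constant and monotone in the
clinically favorable direction.  Middle bands are closed intervals; the
0- and 2-score bands are strict inequalities.  Missing measurements are an
error — the package never imputes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from enum import Enum

from .exceptions import ConfigurationError, ValidationError

__all__ = [
    "HeadPosition",
    "Consistency",
    "CervicalPosition",
    "RiskCategory",
    "UltrasoundAssessment",
    "CompositeScoreResult",
    "BishopAssessment",
    "score_cervical_length",
    "score_head_position",
    "score_head_perineum_distance",
    "score_elastography",
    "score_angulation",
    "composite_score",
    "classify_category",
    "bishop_score",
    "ELASTOGRAPHY_STRATEGIES",
    "ANGULATION_STRATEGIES",
]


class HeadPosition(str, Enum):
    """Fetal head rotational position (occiput landmark)."""

    OCCIPUT_POSTERIOR = "occiput_posterior"
    OCCIPUT_TRANSVERSE = "occiput_transverse"
    OCCIPUT_ANTERIOR = "occiput_anterior"


class Consistency(str, Enum):
    """Digitally assessed cervical consistency (Bishop component)."""

    FIRM = "firm"
    MEDIUM = "medium"
    SOFT = "soft"


class CervicalPosition(str, Enum):
    """Digitally assessed cervical position (Bishop component)."""

    POSTERIOR = "posterior"
    MID = "mid"
    ANTERIOR = "anterior"


class RiskCategory(str, Enum):
    """Composite-score probability band for successful induction."""

    LOW = "low"
    INTERMEDIATE = "intermediate"
    HIGH = "high"


def _check_finite_nonneg(name: str, value: float, strict_positive: bool = False) -> float:
    try:
        value = float(value)
    except (TypeError, ValueError):
        raise ValidationError(f"{name} must be a number, got {value!r}") from None
    if not math.isfinite(value):
        raise ValidationError(f"{name} must be finite, got {value!r}")
    if strict_positive:
        if value <= 0:
            raise ValidationError(f"{name} must be strictly positive, got {value}")
    elif value < 0:
        raise ValidationError(f"{name} must be non-negative, got {value}")
    return value


def _coerce_enum(name: str, value, enum_cls):
    if isinstance(value, enum_cls):
        return value
    try:
        return enum_cls(value)
    except ValueError:
        accepted = ", ".join(m.value for m in enum_cls)
        raise ValidationError(
            f"{name}={value!r} is not a recognized category; accepted: {accepted}"
        ) from None


@dataclass(frozen=True)
class UltrasoundAssessment:
    """One patient's raw pre-induction sonographic measurements.

    Parameters
    ----------
    cervical_length : float
        Transvaginal cervical length, mm (>= 0).
    head_position : HeadPosition or str
        Occiput posterior / transverse / anterior.
    head_perineum_distance : float
        Transperineal head–perineum distance, mm (>= 0).
    stiffness_inner, stiffness_middle, stiffness_outer : float
        Elastographic stiffness of the inner/middle/outer cervical
        thirds, kPa (>= 0).
    anterior_angle, posterior_angle : float
        Anterior and posterior cervical angles, degrees (strictly
        positive, < 360).
    """

    cervical_length: float
    head_position: HeadPosition
    head_perineum_distance: float
    stiffness_inner: float
    stiffness_middle: float
    stiffness_outer: float
    anterior_angle: float
    posterior_angle: float

    def __post_init__(self):
        for f in fields(self):
            if getattr(self, f.name) is None:
                raise ValidationError(f"missing measurement: {f.name}")
        object.__setattr__(
            self, "cervical_length",
            _check_finite_nonneg("cervical_length", self.cervical_length))
        object.__setattr__(
            self, "head_position",
            _coerce_enum("head_position", self.head_position, HeadPosition))
        object.__setattr__(
            self, "head_perineum_distance",
            _check_finite_nonneg("head_perineum_distance", self.head_perineum_distance))
        for name in ("stiffness_inner", "stiffness_middle", "stiffness_outer"):
            object.__setattr__(self, name, _check_finite_nonneg(name, getattr(self, name)))
        for name in ("anterior_angle", "posterior_angle"):
            v = _check_finite_nonneg(name, getattr(self, name), strict_positive=True)
            if v >= 360:
                raise ValidationError(f"{name} must be below 360 degrees, got {v}")
            object.__setattr__(self, name, v)


@dataclass(frozen=True)
class CompositeScoreResult:
    """Per-component sub-scores, 0–10 total and risk category."""

    sub_cl: int
    sub_position: int
    sub_hpd: int
    sub_elasto: int
    sub_angle: int
    total: int
    category: RiskCategory

    def __post_init__(self):
        subs = (self.sub_cl, self.sub_position, self.sub_hpd,
                self.sub_elasto, self.sub_angle)
        if any(s not in (0, 1, 2) for s in subs):
            raise ValidationError(f"sub-scores must each be in {{0,1,2}}, got {subs}")
        if self.total != sum(subs):
            raise ValidationError(
                f"total {self.total} does not equal sum of sub-scores {sum(subs)}")


@dataclass(frozen=True)
class BishopAssessment:
    """Five digital-examination components of the Bishop score.

    ``station`` is the fetal station on the -3..+2 scale of the original
    1964 table.
    """

    dilatation_cm: float
    effacement_pct: float
    station: int
    consistency: Consistency
    position: CervicalPosition

    def __post_init__(self):
        for f in fields(self):
            if getattr(self, f.name) is None:
                raise ValidationError(f"missing Bishop component: {f.name}")
        object.__setattr__(
            self, "dilatation_cm",
            _check_finite_nonneg("dilatation_cm", self.dilatation_cm))
        eff = _check_finite_nonneg("effacement_pct", self.effacement_pct)
        if eff > 100:
            raise ValidationError(f"effacement_pct must be in [0, 100], got {eff}")
        object.__setattr__(self, "effacement_pct", eff)
        st = self.station
        if int(st) != st or not (-3 <= st <= 2):
            raise ValidationError(
                f"station must be an integer in [-3, +2], got {st!r}")
        object.__setattr__(self, "station", int(st))
        object.__setattr__(
            self, "consistency",
            _coerce_enum("consistency", self.consistency, Consistency))
        object.__setattr__(
            self, "position",
            _coerce_enum("position", self.position, CervicalPosition))


# ---------------------------------------------------------------------------
# Composite-score components
# ---------------------------------------------------------------------------

def score_cervical_length(cl: float) -> int:
    """Score transvaginal cervical length: >20 mm -> 0, 11-20 mm -> 1, <11 mm -> 2."""
    cl = _check_finite_nonneg("cervical_length", cl)
    if cl > 20:
        return 0
    if cl >= 11:
        return 1
    return 2


def score_head_position(pos) -> int:
    """Score fetal head position: OP -> 0, OT -> 1, OA -> 2."""
    pos = _coerce_enum("head_position", pos, HeadPosition)
    return {
        HeadPosition.OCCIPUT_POSTERIOR: 0,
        HeadPosition.OCCIPUT_TRANSVERSE: 1,
        HeadPosition.OCCIPUT_ANTERIOR: 2,
    }[pos]


def score_head_perineum_distance(hpd: float) -> int:
    """Score head–perineum distance: >50 mm -> 0, 40-50 mm -> 1, <40 mm -> 2."""
    hpd = _check_finite_nonneg("head_perineum_distance", hpd)
    if hpd > 50:
        return 0
    if hpd >= 40:
        return 1
    return 2


# Zone-specific stiffness bands (kPa): a third scores 0 above the upper
# threshold, 1 within the closed middle band, 2 below its lower edge.
_STIFFNESS_BANDS = {
    "inner": (10.0, 8.1),
    "middle": (8.0, 6.6),
    "outer": (6.0, 5.1),
}


def _band_score(value: float, upper: float, lower: float) -> int:
    """0 above ``upper``, 1 in [lower, upper], 2 below ``lower``."""
    if value > upper:
        return 0
    if value >= lower:
        return 1
    return 2


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def elastography_subscores(inner: float, middle: float, outer: float) -> tuple[int, int, int]:
    """Per-third stiffness sub-scores using the zone-specific bands."""
    inner = _check_finite_nonneg("stiffness_inner", inner)
    middle = _check_finite_nonneg("stiffness_middle", middle)
    outer = _check_finite_nonneg("stiffness_outer", outer)
    return (
        _band_score(inner, *_STIFFNESS_BANDS["inner"]),
        _band_score(middle, *_STIFFNESS_BANDS["middle"]),
        _band_score(outer, *_STIFFNESS_BANDS["outer"]),
    )


ELASTOGRAPHY_STRATEGIES = (
    "mean_of_subscores",
    "per_third_then_vote",
    "mean_stiffness_vs_mean_thresholds",
)


def score_elastography(inner: float, middle: float, outer: float,
                       strategy: str = "mean_of_subscores") -> int:
    """Reduce the three per-third stiffness values to one 0–2 component.

    Strategies
    ----------
    ``mean_of_subscores`` (default)
        Score each third with its own band, then round the arithmetic mean
        of the three sub-scores half-up.  Keeps every zone-specific
        threshold operative.
    ``per_third_then_vote``
        Median (majority vote) of the three per-third sub-scores.
    ``mean_stiffness_vs_mean_thresholds``
        Average the three stiffness readings and band the mean against the
        averaged thresholds (upper 8.0 kPa, lower 6.6 kPa).
    """
    subs = elastography_subscores(inner, middle, outer)
    if strategy == "mean_of_subscores":
        return _round_half_up(sum(subs) / 3.0)
    if strategy == "per_third_then_vote":
        return int(sorted(subs)[1])
    if strategy == "mean_stiffness_vs_mean_thresholds":
        mean_stiff = (float(inner) + float(middle) + float(outer)) / 3.0
        upper = sum(b[0] for b in _STIFFNESS_BANDS.values()) / 3.0
        lower = sum(b[1] for b in _STIFFNESS_BANDS.values()) / 3.0
        return _band_score(mean_stiff, upper, lower)
    raise ConfigurationError(
        f"unknown elastography strategy {strategy!r}; "
        f"choose one of {ELASTOGRAPHY_STRATEGIES}")


def angulation_subscores(aa: float, pa: float) -> tuple[int, int, int]:
    """Band sub-scores for the anterior angle, posterior angle and their sum.

    AA: <90 -> 0, 90-104 -> 1, >104 -> 2.  PA: <90 -> 0, 90-99 -> 1, >99 -> 2.
    AA+PA: <170 -> 0, 170-190 -> 1, >190 -> 2.  Larger angles are more
    favorable, so the bands run opposite to the stiffness bands.
    """
    aa = _check_finite_nonneg("anterior_angle", aa, strict_positive=True)
    pa = _check_finite_nonneg("posterior_angle", pa, strict_positive=True)

    def increasing_band(value: float, lower: float, upper: float) -> int:
        if value < lower:
            return 0
        if value <= upper:
            return 1
        return 2

    return (
        increasing_band(aa, 90.0, 104.0),
        increasing_band(pa, 90.0, 99.0),
        increasing_band(aa + pa, 170.0, 190.0),
    )


ANGULATION_STRATEGIES = ("mean_of_subscores", "sum_score_only")


def score_angulation(aa: float, pa: float,
                     strategy: str = "mean_of_subscores") -> int:
    """Reduce the three angle bands (AA, PA, AA+PA) to one 0–2 component.

    ``mean_of_subscores`` (default) rounds the mean of the three band
    scores half-up; ``sum_score_only`` uses only the AA+PA band.
    """
    subs = angulation_subscores(aa, pa)
    if strategy == "mean_of_subscores":
        return _round_half_up(sum(subs) / 3.0)
    if strategy == "sum_score_only":
        return subs[2]
    raise ConfigurationError(
        f"unknown angulation strategy {strategy!r}; "
        f"choose one of {ANGULATION_STRATEGIES}")


def classify_category(total: int) -> RiskCategory:
    """Band a 0–10 composite total: 0–3 low, 4–6 intermediate, 7–10 high."""
    if int(total) != total or not (0 <= total <= 10):
        raise ValidationError(f"total must be an integer in [0, 10], got {total!r}")
    total = int(total)
    if total <= 3:
        return RiskCategory.LOW
    if total <= 6:
        return RiskCategory.INTERMEDIATE
    return RiskCategory.HIGH


def composite_score(a: UltrasoundAssessment,
                    elastography_strategy: str = "mean_of_subscores",
                    angulation_strategy: str = "mean_of_subscores",
                    ) -> CompositeScoreResult:
    """Compute the composite ultrasound induction score for one assessment.

    Returns the five 0–2 sub-scores, their 0–10 sum, and the risk
    category.  Raises :class:`ValidationError` when a measurement is
    missing or invalid; nothing is imputed.
    """
    if not isinstance(a, UltrasoundAssessment):
        raise ValidationError(
            f"composite_score expects an UltrasoundAssessment, got {type(a).__name__}")
    sub_cl = score_cervical_length(a.cervical_length)
    sub_position = score_head_position(a.head_position)
    sub_hpd = score_head_perineum_distance(a.head_perineum_distance)
    sub_elasto = score_elastography(
        a.stiffness_inner, a.stiffness_middle, a.stiffness_outer,
        strategy=elastography_strategy)
    sub_angle = score_angulation(
        a.anterior_angle, a.posterior_angle, strategy=angulation_strategy)
    total = sub_cl + sub_position + sub_hpd + sub_elasto + sub_angle
    return CompositeScoreResult(
        sub_cl=sub_cl, sub_position=sub_position, sub_hpd=sub_hpd,
        sub_elasto=sub_elasto, sub_angle=sub_angle,
        total=total, category=classify_category(total))


# ---------------------------------------------------------------------------
# Bishop score (original 1964 table, maximum 13)
# ---------------------------------------------------------------------------

def bishop_score(b: BishopAssessment) -> int:
    """Total Bishop score under the original 1964 point assignment.

    Dilatation (cm): closed/<1 -> 0, 1-2 -> 1, 3-4 -> 2, >=5 -> 3.
    Effacement (%): <40 -> 0, 40-50 -> 1, 60-70 -> 2, >=80 -> 3
    (values falling between printed columns take the band they reach).
    Station: -3 -> 0, -2 -> 1, -1/0 -> 2, +1/+2 -> 3.
    Consistency: firm 0, medium 1, soft 2.
    Position: posterior 0, mid 1, anterior 2.
    """
    if not isinstance(b, BishopAssessment):
        raise ValidationError(
            f"bishop_score expects a BishopAssessment, got {type(b).__name__}")
    d = b.dilatation_cm
    if d >= 5:
        pts_dil = 3
    elif d >= 3:
        pts_dil = 2
    elif d >= 1:
        pts_dil = 1
    else:
        pts_dil = 0
    e = b.effacement_pct
    if e >= 80:
        pts_eff = 3
    elif e >= 60:
        pts_eff = 2
    elif e >= 40:
        pts_eff = 1
    else:
        pts_eff = 0
    pts_station = {-3: 0, -2: 1, -1: 2, 0: 2, 1: 3, 2: 3}[b.station]
    pts_consistency = {
        Consistency.FIRM: 0, Consistency.MEDIUM: 1, Consistency.SOFT: 2,
    }[b.consistency]
    pts_position = {
        CervicalPosition.POSTERIOR: 0, CervicalPosition.MID: 1,
        CervicalPosition.ANTERIOR: 2,
    }[b.position]
    return pts_dil + pts_eff + pts_station + pts_consistency + pts_position
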