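"""Synthetic pre-induction cohort generator.

The generator emulates the statistical structure the downstream analysis
assumes: a single latent cervical-readiness factor L ~ Normal drives every
sonographic measurement, every Bishop component, and the delivery outcome.
Cervical length, head–perineum distance and stiffness decrease in L;
cervical angles increase in L; head position and the Bishop components
arise from ordinal cutpoints on L plus component-specific noise; the
outcome follows a logistic model in L, parity and maternal age.

Demographic marginals default to the study-population values: n = 200,
56% nulliparous, induction indications 31/23/19/12/15% (post-term,
hypertensive, PROM, FGR, other), 74% induced after 36 weeks, methods
50/15/35% (dinoprostone, oxytocin, combined), maternal age 30.8 ± 5.4
years truncated to [18, 50].  The vaginal-delivery rate is not published
for the cohort; the default outcome intercept targets a rate of 0.70,
a documented assumption.

Reproducibility: one root seed; subject *i* draws only from the
substream ``SeedSequence(seed, spawn_key=(i,))``, so a cohort prefix is
bit-identical regardless of the total size requested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats
from scipy.special import expit

from .exceptions import CalibrationError, ValidationError
from .scoring import (
    BishopAssessment,
    CervicalPosition,
    Consistency,
    HeadPosition,
    UltrasoundAssessment,
)

__all__ = [
    "LinearMeasurement",
    "OrdinalComponent",
    "CohortConfig",
    "PatientRecord",
    "CalibrationResult",
    "generate_cohort",
    "generate_cohort_arrays",
    "composite_totals",
    "calibrate_category_distribution",
]

# physiologic truncation bounds (standard obstetric reference ranges)
_CL_BOUNDS = (0.0, 50.0)        # mm
_STIFF_BOUNDS = (0.0, 30.0)     # kPa
_ANGLE_BOUNDS = (40.0, 220.0)   # degrees
_HPD_BOUNDS = (10.0, 80.0)      # mm

INDICATIONS = ("post_term", "hypertensive", "prom", "fgr", "other")
METHODS = ("dinoprostone", "oxytocin", "combined")
GA_STRATA = ("34_36", "gt_36")

_HEAD_POSITIONS = (HeadPosition.OCCIPUT_POSTERIOR,
                   HeadPosition.OCCIPUT_TRANSVERSE,
                   HeadPosition.OCCIPUT_ANTERIOR)
# representative raw values per ordinal level of each Bishop component
_BISHOP_DILATATION_CM = (0.0, 1.5, 3.5, 5.0)
_BISHOP_EFFACEMENT_PCT = (20.0, 50.0, 70.0, 80.0)
_BISHOP_STATION = (-3, -2, -1, 1)
_BISHOP_CONSISTENCY = (Consistency.FIRM, Consistency.MEDIUM, Consistency.SOFT)
_BISHOP_POSITION = (CervicalPosition.POSTERIOR, CervicalPosition.MID,
                    CervicalPosition.ANTERIOR)


@dataclass(frozen=True)
class LinearMeasurement:
    """Gaussian measurement model m = intercept + slope·L + noise, truncated.

    ``slope`` carries the direction: negative for measurements that fall
    as readiness rises (cervical length, HPD, stiffness), positive for
    the angles.
    """

    intercept: float
    slope: float
    noise_sd: float
    lower: float
    upper: float

    def __post_init__(self):
        if self.noise_sd <= 0:
            raise ValidationError(f"noise_sd must be > 0, got {self.noise_sd}")
        if self.lower >= self.upper:
            raise ValidationError("lower bound must be below upper bound")

    def sample(self, latent: np.ndarray, z: np.ndarray) -> np.ndarray:
        raw = self.intercept + self.slope * latent + self.noise_sd * z
        return np.clip(raw, self.lower, self.upper)


@dataclass(frozen=True)
class OrdinalComponent:
    """Ordinal level via cutpoints on (L + noise); level = #cutpoints crossed."""

    cutpoints: tuple[float, ...]
    noise_sd: float

    def __post_init__(self):
        if self.noise_sd <= 0:
            raise ValidationError(f"noise_sd must be > 0, got {self.noise_sd}")
        if any(a >= b for a, b in zip(self.cutpoints, self.cutpoints[1:])):
            raise ValidationError("cutpoints must be strictly increasing")

    def sample(self, latent: np.ndarray, z: np.ndarray) -> np.ndarray:
        propensity = latent + self.noise_sd * z
        return np.searchsorted(np.asarray(self.cutpoints), propensity,
                               side="right")


def _check_probs(name: str, probs: dict, keys: tuple[str, ...]) -> None:
    if set(probs) != set(keys):
        raise ValidationError(f"{name} must have exactly the keys {keys}")
    total = sum(probs.values())
    if abs(total - 1.0) > 1e-9:
        raise ValidationError(f"{name} must sum to 1 (got {total!r})")
    if any(p < 0 for p in probs.values()):
        raise ValidationError(f"{name} entries must be non-negative")


@dataclass(frozen=True)
class CohortConfig:
    """Full parameterisation of the synthetic cohort.

    Demographic defaults reproduce the study-population marginals; the
    latent-measurement defaults place the composite-score distribution in
    a clinically plausible range and are the starting point for
    :func:`calibrate_category_distribution`.
    """

    n: int = 200
    p_nulliparous: float = 0.56
    indication_probs: dict = field(default_factory=lambda: {
        "post_term": 0.31, "hypertensive": 0.23, "prom": 0.19,
        "fgr": 0.12, "other": 0.15})
    p_ga_late: float = 0.74
    method_probs: dict = field(default_factory=lambda: {
        "dinoprostone": 0.50, "oxytocin": 0.15, "combined": 0.35})
    age_mean: float = 30.8
    age_sd: float = 5.4
    age_min: float = 18.0
    age_max: float = 50.0

    readiness_mean: float = 0.0
    readiness_sd: float = 1.0

    cervical_length: LinearMeasurement = LinearMeasurement(18.0, -7.0, 4.0, *_CL_BOUNDS)
    head_perineum_distance: LinearMeasurement = LinearMeasurement(45.0, -8.0, 5.0, *_HPD_BOUNDS)
    stiffness_inner: LinearMeasurement = LinearMeasurement(9.0, -2.5, 1.2, *_STIFF_BOUNDS)
    stiffness_middle: LinearMeasurement = LinearMeasurement(7.3, -2.0, 1.0, *_STIFF_BOUNDS)
    stiffness_outer: LinearMeasurement = LinearMeasurement(5.55, -1.6, 0.8, *_STIFF_BOUNDS)
    anterior_angle: LinearMeasurement = LinearMeasurement(97.0, 12.0, 8.0, *_ANGLE_BOUNDS)
    posterior_angle: LinearMeasurement = LinearMeasurement(94.5, 9.0, 7.0, *_ANGLE_BOUNDS)
    head_position: OrdinalComponent = OrdinalComponent((-0.8, 0.6), 1.2)

    bishop_dilatation: OrdinalComponent = OrdinalComponent((-1.2, 0.0, 1.2), 1.0)
    bishop_effacement: OrdinalComponent = OrdinalComponent((-1.2, 0.0, 1.2), 1.0)
    bishop_station: OrdinalComponent = OrdinalComponent((-1.2, 0.0, 1.2), 1.0)
    bishop_consistency: OrdinalComponent = OrdinalComponent((-0.7, 0.7), 1.0)
    bishop_position: OrdinalComponent = OrdinalComponent((-0.7, 0.7), 1.0)

    outcome_intercept: float = 0.95
    outcome_readiness_slope: float = 1.5
    outcome_multiparous_effect: float = 0.6
    outcome_age_effect: float = -0.02  # per year, age centered at age_mean
    target_vaginal_rate: float = 0.70  # assumption; intercept approximates it

    def __post_init__(self):
        if int(self.n) != self.n or self.n < 2:
            raise ValidationError(f"n must be an integer >= 2, got {self.n!r}")
        for name in ("p_nulliparous", "p_ga_late", "target_vaginal_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        _check_probs("indication_probs", self.indication_probs, INDICATIONS)
        _check_probs("method_probs", self.method_probs, METHODS)
        for name in ("age_sd", "readiness_sd"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if not self.age_min < self.age_max:
            raise ValidationError("age_min must be below age_max")

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        out = {}
        for f in self.__dataclass_fields__:
            v = getattr(self, f)
            if isinstance(v, LinearMeasurement):
                out[f] = {"intercept": v.intercept, "slope": v.slope,
                          "noise_sd": v.noise_sd, "lower": v.lower,
                          "upper": v.upper}
            elif isinstance(v, OrdinalComponent):
                out[f] = {"cutpoints": list(v.cutpoints), "noise_sd": v.noise_sd}
            elif isinstance(v, dict):
                out[f] = dict(v)
            else:
                out[f] = v
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        kwargs = {}
        for key, value in d.items():
            if key not in cls.__dataclass_fields__:
                raise ValidationError(f"unknown config field {key!r}")
            default = cls.__dataclass_fields__[key].default
            if isinstance(default, LinearMeasurement):
                kwargs[key] = LinearMeasurement(**value)
            elif isinstance(default, OrdinalComponent):
                kwargs[key] = OrdinalComponent(
                    cutpoints=tuple(value["cutpoints"]),
                    noise_sd=value["noise_sd"])
            else:
                kwargs[key] = value
        return cls(**kwargs)


@dataclass(frozen=True)
class PatientRecord:
    """One simulated participant row."""

    identifier: str
    age: float
    parity: str                 # nulliparous | multiparous
    indication: str
    ga_stratum: str             # 34_36 | gt_36
    method: str
    ultrasound: UltrasoundAssessment
    bishop: BishopAssessment
    outcome: str                # vaginal_delivery | cesarean


def _truncnorm_mean(loc: float, sd: float, lo: float, hi: float) -> float:
    a, b = (lo - loc) / sd, (hi - loc) / sd
    z = stats.norm.cdf(b) - stats.norm.cdf(a)
    return loc + sd * (stats.norm.pdf(a) - stats.norm.pdf(b)) / z


def _truncnorm_loc_for_mean(mean: float, sd: float, lo: float,
                            hi: float) -> float:
    """Location parameter whose [lo, hi]-truncated normal has the given mean."""
    return float(optimize.brentq(
        lambda m: _truncnorm_mean(m, sd, lo, hi) - mean,
        mean - 3 * sd, mean + 3 * sd, xtol=1e-10))


def _rngs_for(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(i,)))
            for i in range(n)]


def generate_cohort_arrays(config: CohortConfig, seed: int,
                           n: int | None = None) -> dict[str, np.ndarray]:
    """Vectorised cohort draw; columns as numpy arrays.

    Categorical columns are integer-coded (indices into the module-level
    category tuples); :func:`generate_cohort` translates them into
    :class:`PatientRecord` objects.
    """
    if not isinstance(config, CohortConfig):
        raise ValidationError("config must be a CohortConfig")
    n = int(config.n if n is None else n)
    if n < 1:
        raise ValidationError("n must be >= 1")

    # fixed per-subject draw layout: 6 uniforms + 14 standard normals
    u = np.empty((n, 6))
    z = np.empty((n, 14))
    for i, rng in enumerate(_rngs_for(int(seed), n)):
        u[i] = rng.random(6)
        z[i] = rng.standard_normal(14)

    # demographics; the location parameter is solved so the *truncated*
    # distribution has mean age_mean (truncation at [18, 50] would
    # otherwise shift the realised mean by ~0.05 years)
    loc = _truncnorm_loc_for_mean(config.age_mean, config.age_sd,
                                  config.age_min, config.age_max)
    lo = stats.norm.cdf((config.age_min - loc) / config.age_sd)
    hi = stats.norm.cdf((config.age_max - loc) / config.age_sd)
    age = loc + config.age_sd * stats.norm.ppf(lo + u[:, 0] * (hi - lo))
    nulliparous = u[:, 1] < config.p_nulliparous
    ind_cum = np.cumsum([config.indication_probs[k] for k in INDICATIONS])
    indication = np.searchsorted(ind_cum, u[:, 2], side="right").clip(0, len(INDICATIONS) - 1)
    ga_late = u[:, 3] < config.p_ga_late
    m_cum = np.cumsum([config.method_probs[k] for k in METHODS])
    method = np.searchsorted(m_cum, u[:, 4], side="right").clip(0, len(METHODS) - 1)

    # latent readiness and measurements
    latent = config.readiness_mean + config.readiness_sd * z[:, 0]
    cols = {
        "cl_mm": config.cervical_length.sample(latent, z[:, 1]),
        "hpd_mm": config.head_perineum_distance.sample(latent, z[:, 2]),
        "stiff_inner_kpa": config.stiffness_inner.sample(latent, z[:, 3]),
        "stiff_mid_kpa": config.stiffness_middle.sample(latent, z[:, 4]),
        "stiff_outer_kpa": config.stiffness_outer.sample(latent, z[:, 5]),
        "aa_deg": config.anterior_angle.sample(latent, z[:, 6]),
        "pa_deg": config.posterior_angle.sample(latent, z[:, 7]),
        "head_position": config.head_position.sample(latent, z[:, 8]),
        "bishop_dilatation": config.bishop_dilatation.sample(latent, z[:, 9]),
        "bishop_effacement": config.bishop_effacement.sample(latent, z[:, 10]),
        "bishop_station": config.bishop_station.sample(latent, z[:, 11]),
        "bishop_consistency": config.bishop_consistency.sample(latent, z[:, 12]),
        "bishop_position": config.bishop_position.sample(latent, z[:, 13]),
    }

    logit = (config.outcome_intercept
             + config.outcome_readiness_slope * latent
             + config.outcome_multiparous_effect * (~nulliparous)
             + config.outcome_age_effect * (age - config.age_mean))
    vaginal = u[:, 5] < expit(logit)

    cols.update(age=age, nulliparous=nulliparous, indication=indication,
                ga_late=ga_late, method=method, latent=latent,
                vaginal=vaginal)
    return cols


def generate_cohort(config: CohortConfig, seed: int,
                    n: int | None = None) -> list[PatientRecord]:
    """Generate a cohort of :class:`PatientRecord`.

    Same config and seed give a bit-identical cohort; subject *i* is
    identical for any requested size covering it.
    """
    a = generate_cohort_arrays(config, seed, n)
    records = []
    for i in range(a["age"].size):
        us = UltrasoundAssessment(
            cervical_length=float(a["cl_mm"][i]),
            head_position=_HEAD_POSITIONS[int(a["head_position"][i])],
            head_perineum_distance=float(a["hpd_mm"][i]),
            stiffness_inner=float(a["stiff_inner_kpa"][i]),
            stiffness_middle=float(a["stiff_mid_kpa"][i]),
            stiffness_outer=float(a["stiff_outer_kpa"][i]),
            anterior_angle=float(a["aa_deg"][i]),
            posterior_angle=float(a["pa_deg"][i]))
        bishop = BishopAssessment(
            dilatation_cm=_BISHOP_DILATATION_CM[int(a["bishop_dilatation"][i])],
            effacement_pct=_BISHOP_EFFACEMENT_PCT[int(a["bishop_effacement"][i])],
            station=_BISHOP_STATION[int(a["bishop_station"][i])],
            consistency=_BISHOP_CONSISTENCY[int(a["bishop_consistency"][i])],
            position=_BISHOP_POSITION[int(a["bishop_position"][i])])
        records.append(PatientRecord(
            identifier=f"p{i + 1:05d}",
            age=float(a["age"][i]),
            parity="nulliparous" if a["nulliparous"][i] else "multiparous",
            indication=INDICATIONS[int(a["indication"][i])],
            ga_stratum="gt_36" if a["ga_late"][i] else "34_36",
            method=METHODS[int(a["method"][i])],
            ultrasound=us, bishop=bishop,
            outcome="vaginal_delivery" if a["vaginal"][i] else "cesarean"))
    return records


def composite_totals(arrays: dict[str, np.ndarray]) -> np.ndarray:
    """Vectorised composite-score totals from a generated array table.

    Mirrors :func:`iolscore.scoring.composite_score` with the default
    (mean-of-sub-scores) strategies; equivalence is enforced by tests.
    """
    cl = arrays["cl_mm"]
    hpd = arrays["hpd_mm"]
    sub_cl = np.select([cl > 20, cl >= 11], [0, 1], default=2)
    sub_pos = arrays["head_position"].astype(int)
    sub_hpd = np.select([hpd > 50, hpd >= 40], [0, 1], default=2)

    def band(v, upper, lower):
        return np.select([v > upper, v >= lower], [0, 1], default=2)

    elasto = (band(arrays["stiff_inner_kpa"], 10.0, 8.1)
              + band(arrays["stiff_mid_kpa"], 8.0, 6.6)
              + band(arrays["stiff_outer_kpa"], 6.0, 5.1))
    sub_elasto = np.floor(elasto / 3.0 + 0.5).astype(int)

    def inc_band(v, lower, upper):
        return np.select([v < lower, v <= upper], [0, 1], default=2)

    aa, pa = arrays["aa_deg"], arrays["pa_deg"]
    angles = (inc_band(aa, 90.0, 104.0) + inc_band(pa, 90.0, 99.0)
              + inc_band(aa + pa, 170.0, 190.0))
    sub_angle = np.floor(angles / 3.0 + 0.5).astype(int)
    return sub_cl + sub_pos + sub_hpd + sub_elasto + sub_angle


def category_proportions(totals: np.ndarray) -> np.ndarray:
    """(low, intermediate, high) fractions of a vector of 0–10 totals."""
    totals = np.asarray(totals)
    n = totals.size
    return np.array([(totals <= 3).sum(), ((totals >= 4) & (totals <= 6)).sum(),
                     (totals >= 7).sum()]) / n


@dataclass(frozen=True)
class CalibrationResult:
    """Outcome of the category-distribution calibration."""

    config: CohortConfig
    achieved: tuple[float, float, float]
    targets: tuple[float, float, float]
    n_eval: int
    n_function_evals: int


def calibrate_category_distribution(config: CohortConfig, targets,
                                    seed: int, n_eval: int = 6000,
                                    tol: float = 0.02) -> CalibrationResult:
    """Tune the latent readiness mean/SD to hit target category proportions.

    Minimises the worst absolute deviation of the (low, intermediate,
    high) composite-score fractions from ``targets`` over
    (readiness_mean, log readiness_sd), using common random numbers (one
    evaluation cohort of ``n_eval`` subjects regenerated deterministically
    from ``seed``) so the search is reproducible.  Raises
    :class:`CalibrationError` carrying the best configuration when the
    tolerance cannot be reached.
    """
    targets = tuple(float(t) for t in targets)
    if len(targets) != 3 or abs(sum(targets) - 1.0) > 1e-9:
        raise ValidationError("targets must be three proportions summing to 1")
    eval_seed = (int(seed) * 69069 + 12345) % (2 ** 31)
    n_evals = 0

    def proportions_for(mean: float, sd: float) -> np.ndarray:
        cfg = replace(config, readiness_mean=float(mean), readiness_sd=float(sd))
        arrays = generate_cohort_arrays(cfg, eval_seed, n_eval)
        return category_proportions(composite_totals(arrays))

    def objective(theta) -> float:
        nonlocal n_evals
        n_evals += 1
        props = proportions_for(theta[0], math.exp(theta[1]))
        return float(np.max(np.abs(props - np.array(targets))))

    # coarse deterministic grid, a refinement grid around the best cell,
    # then a short Nelder-Mead polish
    grid_means = np.linspace(-1.5, 1.5, 13)
    grid_logsd = np.log(np.array([0.3, 0.45, 0.6, 0.9, 1.3]))
    best = min(((objective((m, s)), (m, s))
                for m in grid_means for s in grid_logsd), key=lambda t: t[0])
    m0, s0 = best[1]
    fine = min(((objective((m, s)), (m, s))
                for m in np.linspace(m0 - 0.2, m0 + 0.2, 7)
                for s in np.linspace(s0 - 0.25, s0 + 0.25, 7)),
               key=lambda t: t[0])
    best = fine if fine[0] < best[0] else best
    res = optimize.minimize(objective, x0=np.array(best[1]),
                            method="Nelder-Mead",
                            options={"xatol": 1e-3, "fatol": 1e-4,
                                     "maxfev": 120})
    x = res.x if res.fun <= best[0] else np.array(best[1])
    achieved = proportions_for(x[0], math.exp(x[1]))
    final = replace(config, readiness_mean=float(x[0]),
                    readiness_sd=float(math.exp(x[1])))
    result = CalibrationResult(
        config=final, achieved=tuple(float(p) for p in achieved),
        targets=targets, n_eval=n_eval, n_function_evals=n_evals)
    if np.max(np.abs(achieved - np.array(targets))) > tol:
        raise CalibrationError(
            f"category calibration missed tolerance {tol}: "
            f"achieved {result.achieved} vs targets {targets}",
            best_config=final, achieved=result.achieved)
    return result
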