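"""Cohort I/O and end-to-end analysis orchestration.

One row per patient in a plain CSV (lowercase snake-case categorical
tokens).  ``run_pipeline`` ingests or simulates a cohort, computes the
composite ultrasound score and the Bishop score for every complete row,
runs the ROC / paired-comparison / parity-stratified / age-adjusted
logistic analysis, and returns a fully recomputable report with
provenance (config hash, seed, software version).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from datetime import datetime, timezone

import numpy as np
import pandas as pd

from . import __version__
from .cohort import CohortConfig, PatientRecord, generate_cohort
from .exceptions import DegenerateDataError, SchemaError, ValidationError
from .inference import fit_logistic, stratified_analysis
from .roc import compare_paired_auc, roc_curve
from .scoring import (
    BishopAssessment,
    UltrasoundAssessment,
    bishop_score,
    composite_score,
)

__all__ = [
    "CSV_COLUMNS",
    "AnalysisReport",
    "read_cohort_csv",
    "write_cohort_csv",
    "records_to_frame",
    "frame_to_records",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

CSV_COLUMNS = (
    "id", "age_years", "parity", "indication", "ga_stratum",
    "induction_method", "cl_mm", "head_position", "hpd_mm",
    "stiff_inner_kpa", "stiff_mid_kpa", "stiff_outer_kpa", "aa_deg",
    "pa_deg", "bishop_dilatation_cm", "bishop_effacement_pct",
    "bishop_station", "bishop_consistency", "bishop_position", "outcome",
)

_NUMERIC_COLUMNS = (
    "age_years", "cl_mm", "hpd_mm", "stiff_inner_kpa", "stiff_mid_kpa",
    "stiff_outer_kpa", "aa_deg", "pa_deg", "bishop_dilatation_cm",
    "bishop_effacement_pct", "bishop_station",
)


def records_to_frame(records: list[PatientRecord]) -> pd.DataFrame:
    """Flatten patient records into the pipeline CSV schema."""
    rows = []
    for r in records:
        rows.append({
            "id": r.identifier, "age_years": r.age, "parity": r.parity,
            "indication": r.indication, "ga_stratum": r.ga_stratum,
            "induction_method": r.method,
            "cl_mm": r.ultrasound.cervical_length,
            "head_position": r.ultrasound.head_position.value,
            "hpd_mm": r.ultrasound.head_perineum_distance,
            "stiff_inner_kpa": r.ultrasound.stiffness_inner,
            "stiff_mid_kpa": r.ultrasound.stiffness_middle,
            "stiff_outer_kpa": r.ultrasound.stiffness_outer,
            "aa_deg": r.ultrasound.anterior_angle,
            "pa_deg": r.ultrasound.posterior_angle,
            "bishop_dilatation_cm": r.bishop.dilatation_cm,
            "bishop_effacement_pct": r.bishop.effacement_pct,
            "bishop_station": r.bishop.station,
            "bishop_consistency": r.bishop.consistency.value,
            "bishop_position": r.bishop.position.value,
            "outcome": r.outcome,
        })
    return pd.DataFrame(rows, columns=list(CSV_COLUMNS))


def frame_to_records(df: pd.DataFrame) -> list[PatientRecord]:
    """Build validated patient records from a schema-conformant frame."""
    records = []
    for _, row in df.iterrows():
        us = UltrasoundAssessment(
            cervical_length=float(row["cl_mm"]),
            head_position=str(row["head_position"]),
            head_perineum_distance=float(row["hpd_mm"]),
            stiffness_inner=float(row["stiff_inner_kpa"]),
            stiffness_middle=float(row["stiff_mid_kpa"]),
            stiffness_outer=float(row["stiff_outer_kpa"]),
            anterior_angle=float(row["aa_deg"]),
            posterior_angle=float(row["pa_deg"]))
        bishop = BishopAssessment(
            dilatation_cm=float(row["bishop_dilatation_cm"]),
            effacement_pct=float(row["bishop_effacement_pct"]),
            station=int(row["bishop_station"]),
            consistency=str(row["bishop_consistency"]),
            position=str(row["bishop_position"]))
        records.append(PatientRecord(
            identifier=str(row["id"]), age=float(row["age_years"]),
            parity=str(row["parity"]), indication=str(row["indication"]),
            ga_stratum=str(row["ga_stratum"]),
            method=str(row["induction_method"]),
            ultrasound=us, bishop=bishop, outcome=str(row["outcome"])))
    return records


def write_cohort_csv(records: list[PatientRecord], path) -> None:
    """Write patient records as CSV (full float precision round-trip)."""
    # repr gives the shortest decimal that round-trips the float exactly
    records_to_frame(records).to_csv(
        path, index=False, float_format=lambda v: repr(float(v)))


def _read_frame(path) -> tuple[pd.DataFrame, int]:
    """Read and validate the cohort CSV; drop incomplete rows.

    Returns the complete-case frame and the number of excluded rows.
    Malformed numeric cells raise :class:`SchemaError` citing row and
    column; missing required columns raise with the full schema.
    """
    try:
        df = pd.read_csv(path, dtype=str, skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        raise SchemaError(
            "empty input; required columns: " + ", ".join(CSV_COLUMNS)) from None
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"missing required column(s) {missing}; "
            f"required schema: {', '.join(CSV_COLUMNS)}")
    df = df[list(CSV_COLUMNS)]
    for col in _NUMERIC_COLUMNS:
        converted = []
        # Python float() is correctly rounded; pd.to_numeric is not
        for row, cell in enumerate(df[col]):
            if cell is None or (isinstance(cell, float) and np.isnan(cell)) \
                    or str(cell).strip() == "":
                converted.append(np.nan)
                continue
            try:
                converted.append(float(cell))
            except ValueError:
                raise SchemaError(
                    f"malformed numeric value {cell!r} in column {col!r}, "
                    f"row {row + 2} (1-based, including header)") from None
        df[col] = converted
    complete = df.dropna(subset=list(CSV_COLUMNS))
    n_excluded = len(df) - len(complete)
    if n_excluded:
        logger.warning("excluded %d row(s) with missing required fields",
                       n_excluded)
    return complete.reset_index(drop=True), n_excluded


def read_cohort_csv(path) -> list[PatientRecord]:
    """Read a cohort CSV into validated patient records (complete cases)."""
    df, _ = _read_frame(path)
    return frame_to_records(df)


@dataclass(frozen=True)
class AnalysisReport:
    """Full pre-induction prediction analysis of one cohort."""

    cohort_summary: dict
    composite_roc: dict
    bishop_roc: dict
    paired_comparison: dict
    parity_stratified: dict
    adjusted_logistic: dict
    provenance: dict

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)

    def to_text(self) -> str:
        """Human-readable report mirroring the analysis ordering."""
        s = self.cohort_summary
        lines = [
            "Pre-induction prediction analysis",
            "=" * 50,
            f"Cohort: n = {s['n']} (excluded incomplete rows: {s['n_excluded']})",
            f"Maternal age: {s['age_mean']:.1f} +/- {s['age_sd']:.1f} years",
            f"Nulliparous: {100 * s['parity_proportions']['nulliparous']:.1f}%",
            f"Vaginal delivery: {100 * s['vaginal_delivery_rate']:.1f}%",
            "Composite score categories (low/intermediate/high): "
            + "/".join(f"{100 * p:.1f}%"
                       for p in s["category_proportions"].values()),
            "",
        ]
        for name, d in (("Composite ultrasound score", self.composite_roc),
                        ("Bishop score", self.bishop_roc)):
            lines.append(
                f"{name}: AUC {d['auc']:.3f} (SE {d['se']:.3f}, "
                f"95% CI {d['ci_low']:.3f}-{d['ci_high']:.3f}, "
                f"p vs 0.5 = {d['p_vs_half']:.3g})")
        pc = self.paired_comparison
        lines.append(
            f"Paired AUC difference (composite - Bishop): {pc['delta']:.3f} "
            f"(SE {pc['se_delta']:.3f}, z = {pc['z']:.2f}, p = {pc['p_value']:.3g})")
        lines.append("")
        for stratum, d in self.parity_stratified["curves"].items():
            lines.append(
                f"Composite score, {stratum}: AUC {d['auc']:.3f} "
                f"(95% CI {d['ci_low']:.3f}-{d['ci_high']:.3f})")
        for stratum, reason in self.parity_stratified["skipped"].items():
            lines.append(f"Composite score, {stratum}: skipped ({reason})")
        lines.append("")
        lines.append("Age-adjusted logistic regression (outcome: vaginal delivery):")
        for t in self.adjusted_logistic["terms"]:
            lines.append(
                f"  {t['term']}: OR {t['or']:.2f} "
                f"(95% CI {t['ci_low']:.2f}-{t['ci_high']:.2f}, p = {t['p']:.3g})")
        return "\n".join(lines)


def _points_list(curve) -> list[dict]:
    return [{"cutoff": p.cutoff, "sensitivity": p.sensitivity,
             "one_minus_specificity": p.one_minus_specificity}
            for p in curve.points]


def _curve_dict(curve) -> dict:
    d = curve.to_dict()
    d["coordinates"] = _points_list(curve)
    return d


def run_pipeline(input=None, config: CohortConfig | None = None,
                 seed: int = 0, score_coding: str = "continuous",
                 timestamp: str | None = None) -> AnalysisReport:
    """Run the full analysis on a cohort CSV or a simulated cohort.

    Parameters
    ----------
    input : path-like, optional
        Cohort CSV; mutually exclusive with ``config``.
    config : CohortConfig, optional
        Generator configuration for a simulated cohort (uses ``seed``).
    score_coding : {"continuous", "category"}
        How the composite score enters the adjusted logistic model.
    timestamp : str, optional
        Provenance timestamp; defaults to the current UTC time.  Pass a
        fixed value for byte-identical reports.
    """
    if (input is None) == (config is None):
        raise ValidationError("provide exactly one of input or config")
    if input is not None:
        df, n_excluded = _read_frame(input)
        records = frame_to_records(df)
        source = {"type": "csv", "path": str(input)}
        hash_basis = df.to_csv(index=False)
    else:
        records = generate_cohort(config, seed)
        n_excluded = 0
        source = {"type": "simulated", "n": config.n}
        hash_basis = json.dumps(config.to_dict(), sort_keys=True)
    if not records:
        raise DegenerateDataError("no complete-case rows to analyse")

    composite = np.array([composite_score(r.ultrasound).total for r in records])
    categories = np.array(
        [composite_score(r.ultrasound).category.value for r in records])
    bishop = np.array([bishop_score(r.bishop) for r in records])
    outcome = np.array([1.0 if r.outcome == "vaginal_delivery" else 0.0
                        for r in records])
    if outcome.min() == outcome.max():
        raise DegenerateDataError(
            "outcome has a single class; ROC/regression analysis impossible")
    age = np.array([r.age for r in records])
    parity = np.array([r.parity for r in records])
    n = len(records)

    def prop_table(values, keys) -> dict:
        return {k: float((values == k).mean()) for k in keys}

    summary = {
        "n": n,
        "n_excluded": n_excluded,
        "age_mean": float(age.mean()),
        "age_sd": float(age.std(ddof=1)),
        "parity_counts": {k: int((parity == k).sum())
                          for k in ("nulliparous", "multiparous")},
        "parity_proportions": prop_table(parity, ("nulliparous", "multiparous")),
        "indication_proportions": prop_table(
            np.array([r.indication for r in records]),
            ("post_term", "hypertensive", "prom", "fgr", "other")),
        "ga_proportions": prop_table(
            np.array([r.ga_stratum for r in records]), ("34_36", "gt_36")),
        "method_proportions": prop_table(
            np.array([r.method for r in records]),
            ("dinoprostone", "oxytocin", "combined")),
        "vaginal_delivery_rate": float(outcome.mean()),
        "category_counts": {k: int((categories == k).sum())
                            for k in ("low", "intermediate", "high")},
        "category_proportions": prop_table(
            categories, ("low", "intermediate", "high")),
    }

    comp_curve = roc_curve(composite, outcome)
    bishop_curve = roc_curve(bishop, outcome)
    paired = compare_paired_auc(bishop, composite, outcome)

    curves, skipped = stratified_analysis(composite, outcome, parity)
    stratified = {
        "curves": {str(k): _curve_dict(c) for k, c in curves.items()},
        "skipped": {str(k): v for k, v in skipped.items()},
    }

    if score_coding == "continuous":
        design = np.column_stack([np.ones(n), composite, age])
        terms = ("intercept", "composite_score", "age_years")
    elif score_coding == "category":
        design = np.column_stack([np.ones(n),
                                  (categories == "intermediate").astype(float),
                                  (categories == "high").astype(float), age])
        terms = ("intercept", "category_intermediate", "category_high",
                 "age_years")
    else:
        raise ValidationError(
            "score_coding must be 'continuous' or 'category'")
    fit = fit_logistic(design, outcome, terms=terms)

    report = AnalysisReport(
        cohort_summary=summary,
        composite_roc=_curve_dict(comp_curve),
        bishop_roc=_curve_dict(bishop_curve),
        paired_comparison={
            "auc_bishop": paired.auc_a, "auc_composite": paired.auc_b,
            "delta": paired.delta, "se_delta": paired.se_delta,
            "z": paired.z, "p_value": paired.p_value},
        parity_stratified=stratified,
        adjusted_logistic={
            "score_coding": score_coding,
            "converged": fit.converged,
            "n_iterations": fit.n_iterations,
            "log_likelihood": fit.log_likelihood,
            "terms": fit.summary_records()},
        provenance={
            "source": source,
            "config_hash": hashlib.sha256(
                hash_basis.encode()).hexdigest()[:16],
            "seed": int(seed),
            "software_version": __version__,
            "timestamp": timestamp if timestamp is not None
            else datetime.now(timezone.utc).isoformat(),
        })
    return report
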