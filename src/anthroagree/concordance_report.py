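"""Nutrition-status concordance between measurement sources, and the pipeline.

Each child is classified severe/moderate/normal three ways (WHZ, HAZ, MUAC)
independently from the manual and the scan-derived measurements; the 3x3
cross-classification per indicator summarises how measurement error
propagates into screening decisions.  Scan-side WHZ uses the manually
recorded weight — the device measures only stature and MUAC.

:func:`run_pipeline` chains the full analysis (simulate or load -> link ->
quality -> agreement -> concordance) and writes all report tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .agreement import bland_altman_table, stratified_agreement, summaries_to_frame
from .growth_reference import (
    GrowthReference,
    NutritionClass,
    classify_muac,
    classify_z,
    synthetic_reference,
)
from .linkage import accuracy_exclusion_mask, build_enrollment_flow, build_pairs
from .quality_metrics import quality_report
from .synthetic_cohort import CohortConfig, load_cohort, simulate_cohort, write_cohort

logger = logging.getLogger(__name__)

__all__ = [
    "CLASSES",
    "INDICATORS",
    "ConcordanceMatrix",
    "classify_cohort",
    "concordance_matrix",
    "concordance_rate",
    "detection_fraction",
    "run_pipeline",
]

CLASSES = (NutritionClass.SEVERE.value, NutritionClass.MODERATE.value, NutritionClass.NORMAL.value)
INDICATORS = ("whz", "haz", "muac")

_CONDITIONS = {
    "wasted_by_whz": "whz",
    "stunted_by_haz": "haz",
    "wasted_by_muac": "muac",
}


@dataclass(frozen=True)
class ConcordanceMatrix:
    """3x3 cross-classification, rows = manual class, columns = scan class."""

    indicator: str
    counts: np.ndarray  # (3, 3) int, index order severe/moderate/normal

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(CLASSES), columns=list(CLASSES))


def _class_value(cls) -> str | None:
    return None if cls is None else NutritionClass(cls).value


def classify_cohort(pairs: pd.DataFrame, reference: GrowthReference) -> pd.DataFrame:
    """Per-child (manual class, scan class) per indicator, long format.

    Expects the z-score columns the linkage stage attaches (manual_whz,
    manual_haz, scan_whz, scan_haz).  MUAC is classified on raw cm.  Children
    missing the inputs for an indicator are excluded for that indicator with
    a log entry.
    """
    records = []
    dropped = {ind: 0 for ind in INDICATORS}
    for row in pairs.itertuples(index=False):
        per_ind = {
            "whz": (classify_z(row.manual_whz), classify_z(row.scan_whz)),
            "haz": (classify_z(row.manual_haz), classify_z(row.scan_haz)),
            "muac": (
                classify_muac(row.manual_muac_cm),
                classify_muac(row.scan_muac_cm) if np.isfinite(row.scan_muac_cm) and row.scan_muac_cm > 0 else None,
            ),
        }
        for ind, (mc, sc) in per_ind.items():
            if mc is None or sc is None:
                dropped[ind] += 1
                continue
            records.append((row.child_id, ind, _class_value(mc), _class_value(sc)))
    for ind, k in dropped.items():
        if k:
            logger.info("%d child(ren) excluded from %s classification (missing inputs)", k, ind)
    return pd.DataFrame(records, columns=["child_id", "indicator", "manual_class", "scan_class"])


def concordance_matrix(class_pairs: pd.DataFrame, indicator: str) -> ConcordanceMatrix:
    """Tally the 3x3 (manual, scan) classification matrix for one indicator."""
    if indicator not in INDICATORS:
        raise ValueError(f"indicator must be one of {INDICATORS}, got {indicator!r}")
    sub = class_pairs[class_pairs["indicator"] == indicator]
    if len(sub) == 0:
        raise ValueError(f"no classified children for indicator {indicator!r}")
    idx = {c: i for i, c in enumerate(CLASSES)}
    counts = np.zeros((3, 3), dtype=int)
    for mc, sc in zip(sub["manual_class"], sub["scan_class"]):
        counts[idx[mc], idx[sc]] += 1
    return ConcordanceMatrix(indicator=indicator, counts=counts)


def concordance_rate(matrix: ConcordanceMatrix) -> float:
    """Fraction of children identically classified by both sources (trace/n)."""
    if matrix.n == 0:
        raise ValueError("concordance rate undefined for an empty matrix")
    return float(np.trace(matrix.counts) / matrix.n)


def detection_fraction(matrix: ConcordanceMatrix, condition: str | None = None) -> float:
    """Of children positive (severe or moderate) by manual measurement, the
    fraction also positive by scan.  NaN when nobody is manual-positive.

    ``condition`` (wasted_by_whz / stunted_by_haz / wasted_by_muac) is an
    optional consistency check against the matrix's indicator.
    """
    if condition is not None:
        expected = _CONDITIONS.get(condition)
        if expected is None:
            raise ValueError(f"unknown condition {condition!r}")
        if expected != matrix.indicator:
            raise ValueError(
                f"condition {condition!r} does not match indicator {matrix.indicator!r}"
            )
    positive = matrix.counts[:2, :]  # manual severe + moderate rows
    manual_positive = int(positive.sum())
    if manual_positive == 0:
        return np.nan
    both_positive = int(positive[:, :2].sum())
    return both_positive / manual_positive


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def _config_hash(config: CohortConfig | None) -> str:
    if config is None:
        return "external-data"
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(
    out_dir,
    cohort_config: CohortConfig | None = None,
    data_dir=None,
    reference: GrowthReference | None = None,
    weight_threshold_kg: float = 5.0,
    sd_policy: str = "flexible",
    min_stratum_n: int = 5,
) -> dict:
    """Run the full analysis and write the report bundle under ``out_dir``.

    Exactly one of ``cohort_config`` (simulate-first mode) or ``data_dir``
    (pre-existing roster/manual/scan CSVs) must be given.  Outputs:
    matched_pairs.csv, enrollment_flow.csv, quality_report.csv,
    agreement_{measure}.csv, bland_altman_{measure}.csv, concordance.csv,
    summary.json and run_log.json.  Any stage failure aborts with the stage
    named and removes partial outputs.  Identical config + seed produce
    byte-identical outputs.
    """
    if (cohort_config is None) == (data_dir is None):
        raise ValueError("provide exactly one of cohort_config or data_dir")
    if reference is None:
        reference = synthetic_reference()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _write_csv(df: pd.DataFrame, name: str, **kw):
        path = out_dir / name
        df.to_csv(path, index=False, float_format="%.6g", **kw)
        written.append(path)
        return path

    stage = "setup"
    try:
        stage = "simulate" if cohort_config is not None else "load"
        if cohort_config is not None:
            tables = simulate_cohort(cohort_config, reference)
            write_cohort(tables, out_dir / "data")
        else:
            tables = load_cohort(data_dir)

        stage = "link"
        linked = build_pairs(tables, reference, weight_threshold_kg=weight_threshold_kg)
        pairs = linked["pairs"]
        if len(pairs) == 0:
            raise ValueError("no matched pairs — nothing to analyse")
        flow = build_enrollment_flow(
            n_manual=len(tables["manual"]),
            n_scan_sessions=len(tables["scan"]),
            n_scan_children=len(linked["scan_children"]),
            n_matched=len(pairs),
        )
        out_pairs = pairs.copy()
        for c in out_pairs.columns:
            if out_pairs[c].dtype == bool:
                out_pairs[c] = out_pairs[c].astype(int)
        _write_csv(out_pairs, "matched_pairs.csv")
        _write_csv(flow, "enrollment_flow.csv")

        stage = "quality"
        quality = quality_report(pairs, policy=sd_policy)
        path = out_dir / "quality_report.csv"
        quality.to_csv(path, float_format="%.6g")
        written.append(path)

        stage = "agreement"
        excluded = accuracy_exclusion_mask(pairs)
        agreement_tables = {}
        for measure in ("stature", "muac"):
            frames = []
            for grouping in ("overall", "team", "sex", "age_group"):
                sums = stratified_agreement(pairs, measure, grouping, min_n=min_stratum_n)
                frames.append(summaries_to_frame(sums))
            clean = pairs[~excluded]
            if len(clean) >= 2:
                sens = summaries_to_frame(
                    stratified_agreement(clean, measure, "overall", min_n=min_stratum_n)
                )
                sens["stratum"] = "overall, excluding flagged and discordant"
                frames.append(sens)
            table = pd.concat(frames, ignore_index=True)
            agreement_tables[measure] = table
            _write_csv(table, f"agreement_{measure}.csv")
            _write_csv(bland_altman_table(pairs, measure), f"bland_altman_{measure}.csv")

        stage = "concordance"
        classes = classify_cohort(pairs, reference)
        matrices = {}
        conc_rows = []
        for ind in INDICATORS:
            mat = concordance_matrix(classes, ind)
            matrices[ind] = mat
            for i, mc in enumerate(CLASSES):
                for j, sc in enumerate(CLASSES):
                    conc_rows.append((ind, mc, sc, int(mat.counts[i, j])))
        conc = pd.DataFrame(conc_rows, columns=["indicator", "manual_class", "scan_class", "count"])
        _write_csv(conc, "concordance.csv")

        stage = "summary"
        summary = {
            "n_manual": len(tables["manual"]),
            "n_scan_sessions": len(tables["scan"]),
            "n_scan_children": len(linked["scan_children"]),
            "n_matched": len(pairs),
            "n_excluded_flagged_or_discordant": int(excluded.sum()),
            "agreement": {
                m: t[t["stratum"] == "overall"].drop(columns="suppressed").iloc[0].to_dict()
                for m, t in agreement_tables.items()
            },
            "concordance_rate": {ind: concordance_rate(matrices[ind]) for ind in INDICATORS},
            "detection_fraction": {
                ind: (None if np.isnan(f := detection_fraction(matrices[ind])) else f)
                for ind in INDICATORS
            },
        }
        path = out_dir / "summary.json"
        path.write_text(json.dumps(summary, indent=2, sort_keys=True, default=float) + "\n")
        written.append(path)

        run_log = {
            "version": __version__,
            "seed": None if cohort_config is None else cohort_config.seed,
            "config_hash": _config_hash(cohort_config),
            "weight_threshold_kg": weight_threshold_kg,
            "sd_policy": sd_policy,
            "exclusion_counts": {
                c: int(pairs[c].sum())
                for c in (
                    "discordant_sex",
                    "discordant_age",
                    "discordant_weight",
                    "scan_fixed_outlier",
                    "scan_flexible_outlier",
                    "range_invalid",
                )
            },
        }
        path = out_dir / "run_log.json"
        path.write_text(json.dumps(run_log, indent=2, sort_keys=True) + "\n")
        written.append(path)
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return {
        "tables": tables,
        "pairs": pairs,
        "enrollment_flow": flow,
        "quality": quality,
        "agreement": agreement_tables,
        "classes": classes,
        "matrices": matrices,
        "summary": summary,
    }
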