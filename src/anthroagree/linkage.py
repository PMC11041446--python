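"""Session aggregation, record linkage, discordance flags, enrollment flow.

Scan and manual records are linked on the child ID alone.  Because both
teams entered age, sex and weight independently, a matched ID with
conflicting attributes signals a probable mix-up; such pairs are flagged
(not dropped) so the agreement stage can run sensitivity analyses with and
without them.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .growth_reference import GrowthReference, cohort_zscores
from .quality_metrics import fixed_exclusion_flags, flexible_exclusion_flags

logger = logging.getLogger(__name__)

__all__ = [
    "aggregate_sessions",
    "match_records",
    "flag_discordance",
    "flag_scan_outliers",
    "accuracy_exclusion_mask",
    "build_pairs",
    "enrollment_flow",
    "build_enrollment_flow",
    "add_age_group",
]

#: Default attribute-discordance thresholds: age strictly > 6 months,
#: weight strictly > 5 kg (a 10 kg variant is also in circulation for this
#: kind of field check; pass weight_threshold_kg=10 to use it).
AGE_THRESHOLD_MONTHS = 6.0
WEIGHT_THRESHOLD_KG = 5.0

FLAG_COLUMNS = (
    "discordant_sex",
    "discordant_age",
    "discordant_weight",
    "scan_fixed_outlier",
    "scan_flexible_outlier",
    "range_invalid",
)


def aggregate_sessions(sessions: pd.DataFrame) -> pd.DataFrame:
    """Collapse multi-session scans to one record per child via the median.

    Per measure, the median of the finite session values is used (midpoint of
    the two central values for even counts).  Children with no usable session
    for either measure are excluded with a logged reason.  Per-child constant
    attributes (team, sex, age, weight) are taken from the first session.
    """
    if len(sessions) == 0:
        return sessions.head(0).assign(n_sessions=pd.Series(dtype=int)).drop(columns=["session"], errors="ignore")
    rows = []
    for child_id, grp in sessions.groupby("child_id", sort=True):
        stature = float(np.nanmedian(grp["stature_cm"])) if grp["stature_cm"].notna().any() else np.nan
        muac = float(np.nanmedian(grp["muac_cm"])) if grp["muac_cm"].notna().any() else np.nan
        if np.isnan(stature) and np.isnan(muac):
            logger.info("child %s excluded: no usable scan session", child_id)
            continue
        first = grp.iloc[0]
        rows.append(
            {
                "child_id": child_id,
                "team": first.get("team", np.nan),
                "sex": first.get("sex", None),
                "age_months": first.get("age_months", np.nan),
                "weight_kg": first.get("weight_kg", np.nan),
                "stature_cm": stature,
                "muac_cm": muac,
                "n_sessions": int(len(grp)),
            }
        )
    return pd.DataFrame(rows)


def _check_unique(df: pd.DataFrame, source: str) -> None:
    dup = df["child_id"][df["child_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate child_id in {source} records: {dup.iloc[0]!r}")


def match_records(
    manual: pd.DataFrame, scan: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Inner-join aggregated scan and manual records on child ID.

    Returns (pairs, unmatched_manual, unmatched_scan).  Duplicate IDs within
    a source are an error naming the offending ID.  In the paired table the
    manual side keeps the plain column names (team, sex, age_months,
    weight_kg, manual_stature_cm, manual_muac_cm); the scan side is prefixed
    ``scan_``.
    """
    _check_unique(manual, "manual")
    _check_unique(scan, "scan")
    m = manual.rename(columns={"stature_cm": "manual_stature_cm", "muac_cm": "manual_muac_cm"})
    s = scan.rename(
        columns={
            c: f"scan_{c}"
            for c in ("sex", "age_months", "weight_kg", "stature_cm", "muac_cm", "team")
            if c in scan.columns
        }
    )
    pairs = m.merge(s, on="child_id", how="inner")
    unmatched_manual = manual[~manual["child_id"].isin(scan["child_id"])].copy()
    unmatched_scan = scan[~scan["child_id"].isin(manual["child_id"])].copy()
    return pairs, unmatched_manual, unmatched_scan


def flag_discordance(
    pairs: pd.DataFrame,
    age_threshold_months: float = AGE_THRESHOLD_MONTHS,
    weight_threshold_kg: float = WEIGHT_THRESHOLD_KG,
) -> pd.DataFrame:
    """Flag pairs whose independently recorded attributes conflict.

    discordant_sex: recorded sexes differ; discordant_age: |age difference|
    strictly exceeds the threshold (an exactly-6-month difference is NOT
    flagged); discordant_weight likewise.  Missing attributes on either side
    skip that attribute's flag (logged), leaving it False.
    """
    out = pairs.copy()
    for flag, a, b in [
        ("discordant_sex", "sex", "scan_sex"),
        ("discordant_age", "age_months", "scan_age_months"),
        ("discordant_weight", "weight_kg", "scan_weight_kg"),
    ]:
        if a not in out.columns or b not in out.columns:
            logger.warning("discordance flag %s skipped: missing column", flag)
            out[flag] = False
            continue
        if flag == "discordant_sex":
            ok = out[a].notna() & out[b].notna()
            out[flag] = ok & (out[a] != out[b])
        else:
            thr = age_threshold_months if flag == "discordant_age" else weight_threshold_kg
            diff = (out[a] - out[b]).abs()
            out[flag] = diff.notna() & (diff > thr)
        n_missing = int((~(out[a].notna() & out[b].notna())).sum())
        if n_missing:
            logger.info("%s: %d pair(s) with missing attribute skipped", flag, n_missing)
    return out


def flag_scan_outliers(
    pairs: pd.DataFrame, reference: GrowthReference, restrict_tails: bool = True
) -> pd.DataFrame:
    """Flag scan-side implausibility on z-scores computed from scan stature.

    Scan-side WHZ/HAZ use the scan stature together with the manually
    recorded weight (the device measures no weight).  Flags:
    ``scan_fixed_outlier`` (WHZ outside +/-5 or HAZ outside +/-6, strict),
    ``scan_flexible_outlier`` (beyond 3 z from the scan sample's own median),
    ``range_invalid`` (scan stature outside the generatable-z window for the
    child's age).
    """
    out = pairs.copy()
    zs = cohort_zscores(
        out, reference, stature_col="scan_stature_cm", weight_col="weight_kg",
        restrict_tails=restrict_tails,
    )
    out["scan_whz"] = zs["whz"]
    out["scan_haz"] = zs["haz"]
    fixed = fixed_exclusion_flags(zs["whz"].to_numpy(), zs["haz"].to_numpy())
    out["scan_fixed_outlier"] = fixed["whz_fixed"] | fixed["haz_fixed"]
    flex = np.zeros(len(out), bool)
    for col in ("whz", "haz"):
        z = zs[col].to_numpy(float)
        if np.isfinite(z).any():
            f, _ = flexible_exclusion_flags(z)
            flex |= f
    out["scan_flexible_outlier"] = flex
    out["range_invalid"] = ~zs["range_valid"].to_numpy(bool)
    return out


def accuracy_exclusion_mask(pairs: pd.DataFrame) -> pd.Series:
    """True for pairs dropped in the excluding-flagged-and-discordant analysis:
    out-of-range or fixed-outlier scan values, or any attribute discordance."""
    cols = ["range_invalid", "scan_fixed_outlier", "discordant_sex", "discordant_age", "discordant_weight"]
    mask = pd.Series(False, index=pairs.index)
    for c in cols:
        if c in pairs.columns:
            mask |= pairs[c].fillna(False).astype(bool)
    return mask


def build_pairs(
    tables: dict[str, pd.DataFrame],
    reference: GrowthReference,
    age_threshold_months: float = AGE_THRESHOLD_MONTHS,
    weight_threshold_kg: float = WEIGHT_THRESHOLD_KG,
) -> dict:
    """Aggregate -> match -> flag; the standard linkage pipeline.

    ``tables`` is the roster/manual/scan dict from the generator or
    :func:`anthroagree.synthetic_cohort.load_cohort`.  Returns a dict with
    the flagged pairs, both unmatched sets, and the aggregated scan table.
    """
    scan_children = aggregate_sessions(tables["scan"])
    pairs, um, us = match_records(tables["manual"], scan_children)
    pairs = flag_discordance(pairs, age_threshold_months, weight_threshold_kg)
    pairs = flag_scan_outliers(pairs, reference)
    manual_z = cohort_zscores(pairs, reference, stature_col="manual_stature_cm")
    pairs["manual_whz"] = manual_z["whz"]
    pairs["manual_haz"] = manual_z["haz"]
    pairs["manual_range_invalid"] = ~manual_z["range_valid"].to_numpy(bool)
    pairs = add_age_group(pairs)
    return {
        "pairs": pairs,
        "unmatched_manual": um,
        "unmatched_scan": us,
        "scan_children": scan_children,
    }


def add_age_group(pairs: pd.DataFrame) -> pd.DataFrame:
    """Age groups matching measurement position: 6-23 (length), 24-59 (height)."""
    out = pairs.copy()
    out["age_group"] = np.where(out["age_months"] < 24.0, "6-23", "24-59")
    return out


# ---------------------------------------------------------------------------
# Enrollment accounting
# ---------------------------------------------------------------------------

def enrollment_flow(stages, reference_label: str) -> pd.DataFrame:
    """Tabulate enrollment stages with percentages of a reference stage.

    ``stages`` is an ordered sequence of (label, count).  Percentages are of
    the count at ``reference_label``.
    """
    df = pd.DataFrame(stages, columns=["stage", "count"])
    if (df["count"] < 0).any():
        raise ValueError("stage counts must be nonnegative")
    ref = df.loc[df["stage"] == reference_label, "count"]
    if len(ref) != 1:
        raise ValueError(f"reference stage {reference_label!r} not found exactly once")
    denom = float(ref.iloc[0])
    df["percent_of_reference"] = np.where(
        denom > 0, np.round(100.0 * df["count"] / denom, 1), 0.0
    )
    return df


def build_enrollment_flow(
    n_manual: int,
    n_scan_sessions: int,
    n_scan_children: int,
    n_matched: int,
    n_refused: int = 0,
) -> pd.DataFrame:
    """Enrollment flow on the manual-measured denominator.

    Stage counts must be internally consistent: matched children are a subset
    of both the manual and the scan-derived sets.
    """
    if n_matched > n_manual:
        raise ValueError(f"matched ({n_matched}) exceeds manual-measured ({n_manual})")
    if n_matched > n_scan_children:
        raise ValueError(f"matched ({n_matched}) exceeds scan-derived children ({n_scan_children})")
    stages = [
        ("manual measurements obtained", n_manual),
        ("scan refusals recorded", n_refused),
        ("scan sessions transmitted", n_scan_sessions),
        ("children with scan-derived estimates", n_scan_children),
        ("matched to manual measurements", n_matched),
    ]
    flow = enrollment_flow(stages, "manual measurements obtained")
    # within-chain percentage the enrollment figure also reports: matched among
    # children with scan-derived estimates
    flow.attrs["matched_of_scan_children_pct"] = (
        round(100.0 * n_matched / n_scan_children, 1) if n_scan_children else 0.0
    )
    return flow
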