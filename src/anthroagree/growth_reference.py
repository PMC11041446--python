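"""LMS growth references, z-scores, and nutrition-status classification.

The LMS method summarises an age- (or stature-) conditional reference
distribution by a Box-Cox power ``L``, a median ``M`` and a coefficient of
variation ``S``.  A measurement ``x`` maps to a z-score

    z = ((x/M)**L - 1) / (L*S)      (L != 0)
    z = ln(x/M) / S                 (L == 0)

Three indicators are supported: weight-for-age (WAZ), stature-for-age (HAZ,
"stature" meaning recumbent length below 24 months and standing height
thereafter), and weight-for-stature (WHZ).  Classification follows standard
acute-malnutrition practice: z < -3 severe, -3 <= z < -2 moderate, otherwise
normal; MUAC < 11.5 cm severe, 11.5 <= MUAC < 12.5 cm moderate.

This package ships no official reference values (reproducing them is out of
scope); :func:`synthetic_reference` builds a smooth, internally consistent
stand-in table on the same schema for simulation and testing.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "DAYS_PER_MONTH",
    "Indicator",
    "NutritionClass",
    "ZScoreSet",
    "GrowthReference",
    "load_reference",
    "synthetic_reference",
    "lms_zscore",
    "lms_invert",
    "restricted_zscore",
    "compute_indicators",
    "cohort_zscores",
    "classify_z",
    "classify_muac",
    "stature_range_valid",
]

#: Age conversion used throughout: months are turned into reference-table
#: days with this constant (365.25 / 12), matching common growth-standard
#: software conventions.
DAYS_PER_MONTH = 365.25 / 12.0

#: Age (months) below which stature is interpreted as recumbent length.
LENGTH_AGE_LIMIT_MONTHS = 24.0

#: Valid stature windows (cm) for z-score generation, by measurement position.
LENGTH_RANGE_CM = (45.0, 110.0)
HEIGHT_RANGE_CM = (65.0, 120.0)


class Indicator(str, enum.Enum):
    """Reference indicators keyed by age in days or stature in cm."""

    WEIGHT_FOR_AGE = "weight-for-age"
    STATURE_FOR_AGE = "stature-for-age"
    WEIGHT_FOR_STATURE = "weight-for-stature"


class NutritionClass(str, enum.Enum):
    SEVERE = "severe"
    MODERATE = "moderate"
    NORMAL = "normal"


SEXES = ("female", "male")


@dataclass(frozen=True)
class ZScoreSet:
    """Per-child anthropometric z-scores.

    A z-score is NaN exactly when its inputs were missing or the key fell
    outside reference coverage.  ``range_valid`` records whether the stature
    lies inside the window for which z-scores are considered generatable
    (length 45-110 cm under 24 months, height 65-120 cm otherwise); z-scores
    are still computed for out-of-window stature so that filtering remains a
    downstream decision.
    """

    whz: float
    haz: float
    waz: float
    range_valid: bool


# ---------------------------------------------------------------------------
# LMS arithmetic
# ---------------------------------------------------------------------------

def lms_zscore(x: float, L: float, M: float, S: float) -> float:
    """Box-Cox (LMS) z-score of measurement ``x``.

    Raises ``ValueError`` for nonpositive ``x``, ``M`` or ``S``.
    """
    x = float(x)
    if np.isnan(x):
        return np.nan
    if x <= 0 or M <= 0 or S <= 0:
        raise ValueError(f"lms_zscore requires x, M, S > 0 (got x={x}, M={M}, S={S})")
    if L == 0:
        return float(np.log(x / M) / S)
    return float(((x / M) ** L - 1.0) / (L * S))


def lms_invert(z: float, L: float, M: float, S: float) -> float:
    """Measurement value at z-score ``z``: x = M*(1 + L*S*z)**(1/L)."""
    if M <= 0 or S <= 0:
        raise ValueError("lms_invert requires M, S > 0")
    if L == 0:
        return float(M * np.exp(S * z))
    base = 1.0 + L * S * z
    if base <= 0:
        raise ValueError(f"z={z} outside the Box-Cox domain for L={L}, S={S}")
    return float(M * base ** (1.0 / L))


def restricted_zscore(x: float, L: float, M: float, S: float, enabled: bool = True) -> float:
    """z-score with the conventional tail adjustment beyond |z| = 3.

    Inside +/-3 (or when ``enabled`` is false) this is exactly
    :func:`lms_zscore`.  Beyond, the score is linearised against the distance
    between the +/-2 and +/-3 SD values of the reference distribution:

        z > 3:  3 + (x - SD3) / (SD3 - SD2)
        z < -3: -3 + (x - SD3neg) / (SD2neg - SD3neg)

    which keeps extreme weight-based scores on an interpretable scale.
    """
    z = lms_zscore(x, L, M, S)
    if not enabled or np.isnan(z) or abs(z) <= 3.0:
        return z
    if z > 3.0:
        sd3 = lms_invert(3.0, L, M, S)
        sd2 = lms_invert(2.0, L, M, S)
        return 3.0 + (x - sd3) / (sd3 - sd2)
    sd3n = lms_invert(-3.0, L, M, S)
    sd2n = lms_invert(-2.0, L, M, S)
    return -3.0 + (x - sd3n) / (sd2n - sd3n)


# ---------------------------------------------------------------------------
# Reference table
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = ("indicator", "sex", "key", "L", "M", "S")


class GrowthReference:
    """An LMS table with interpolated (L, M, S) lookup.

    Parameters
    ----------
    table:
        DataFrame with columns indicator, sex, key, L, M, S.  Keys must be
        strictly increasing within each (indicator, sex) after sorting;
        duplicates are an error.
    interpolation:
        ``"linear"`` (default) interpolates L, M, S linearly in the key;
        ``"nearest"`` takes the nearest tabulated row.  Lookups outside the
        tabulated key range return no parameters (downstream z-scores become
        missing); the table is never extrapolated.
    """

    def __init__(self, table: pd.DataFrame, interpolation: str = "linear"):
        if interpolation not in ("linear", "nearest"):
            raise ValueError(f"unknown interpolation {interpolation!r}")
        self.interpolation = interpolation
        self.table = _validate_table(table)
        # pre-split per (indicator, sex) into numpy arrays for fast lookup
        self._grids: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
        for (ind, sex), grp in self.table.groupby(["indicator", "sex"], sort=False):
            keys = grp["key"].to_numpy(float)
            lms = grp[["L", "M", "S"]].to_numpy(float)
            self._grids[(ind, sex)] = (keys, lms)

    def indicators(self) -> set[str]:
        return {ind for ind, _ in self._grids}

    def coverage(self, indicator: Indicator | str, sex: str) -> tuple[float, float]:
        keys, _ = self._require(indicator, sex)
        return float(keys[0]), float(keys[-1])

    def _require(self, indicator: Indicator | str, sex: str):
        ind = Indicator(indicator).value
        if sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {sex!r}")
        try:
            return self._grids[(ind, sex)]
        except KeyError:
            raise ValueError(f"reference lacks indicator {ind!r} for sex {sex!r}") from None

    def lookup(self, indicator: Indicator | str, sex: str, key: float):
        """(L, M, S) at ``key``, or ``None`` outside tabulated coverage."""
        keys, lms = self._require(indicator, sex)
        key = float(key)
        if np.isnan(key) or key < keys[0] or key > keys[-1]:
            return None
        if self.interpolation == "nearest":
            i = int(np.argmin(np.abs(keys - key)))
            return tuple(lms[i])
        L = float(np.interp(key, keys, lms[:, 0]))
        M = float(np.interp(key, keys, lms[:, 1]))
        S = float(np.interp(key, keys, lms[:, 2]))
        return (L, M, S)

    def zscore(self, indicator, sex, key, x, restrict_tails: bool = False) -> float:
        """z-score of ``x`` at ``key``; NaN when inputs or coverage are missing."""
        if x is None or np.isnan(float(x)) or np.isnan(float(key)):
            return np.nan
        if float(x) <= 0:
            # a nonpositive recorded measurement is junk, not a valid input
            return np.nan
        p = self.lookup(indicator, sex, key)
        if p is None:
            return np.nan
        return restricted_zscore(float(x), *p, enabled=restrict_tails)

    def invert(self, indicator, sex, key, z) -> float:
        """Measurement value at z-score ``z``; NaN outside coverage."""
        p = self.lookup(indicator, sex, key)
        if p is None:
            return np.nan
        return lms_invert(float(z), *p)


def _validate_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"reference table missing column(s): {', '.join(missing)}")
    if len(table) == 0:
        raise ValueError("reference table has no rows")
    table = table.loc[:, list(_REQUIRED_COLUMNS)].copy()
    for col in ("key", "L", "M", "S"):
        try:
            table[col] = pd.to_numeric(table[col], errors="raise")
        except (ValueError, TypeError) as exc:
            bad = table.index[pd.to_numeric(table[col], errors="coerce").isna()].tolist()
            raise ValueError(f"non-numeric {col} in reference row(s) {bad}") from exc
    bad_ind = set(table["indicator"]) - {i.value for i in Indicator}
    if bad_ind:
        raise ValueError(f"unknown indicator value(s): {sorted(bad_ind)}")
    bad_sex = set(table["sex"]) - set(SEXES)
    if bad_sex:
        raise ValueError(f"unknown sex value(s): {sorted(bad_sex)}")
    if (table["M"] <= 0).any() or (table["S"] <= 0).any():
        raise ValueError("reference requires M > 0 and S > 0 in every row")
    table = table.sort_values(["indicator", "sex", "key"], kind="mergesort").reset_index(drop=True)
    for (ind, sex), grp in table.groupby(["indicator", "sex"], sort=False):
        keys = grp["key"].to_numpy(float)
        dup = keys[:-1][np.diff(keys) <= 0]
        if dup.size:
            raise ValueError(
                f"duplicate or non-increasing key {dup[0]:g} for ({ind}, {sex})"
            )
    return table


def load_reference(path, interpolation: str = "linear") -> GrowthReference:
    """Load an LMS reference from CSV (columns indicator,sex,key,L,M,S)."""
    table = pd.read_csv(path)
    return GrowthReference(table, interpolation=interpolation)


# ---------------------------------------------------------------------------
# Synthetic reference
# ---------------------------------------------------------------------------

def _sfa_median(age_months: np.ndarray, sex: str) -> np.ndarray:
    # smooth monotone median stature: ~66.5 cm at 6 mo to ~109 cm at 59 mo
    base = 66.5 * (age_months / 6.0) ** 0.215
    return base * (1.01 if sex == "male" else 1.0)


def _wfs_median(stature_cm: np.ndarray, sex: str) -> np.ndarray:
    # median weight given stature: ~5.9 kg at 66.5 cm to ~22 kg at 120 cm
    base = 2.45 * (stature_cm / 45.0) ** 2.26
    return base * (1.02 if sex == "male" else 1.0)


def synthetic_reference(interpolation: str = "linear") -> GrowthReference:
    """Build the package's synthetic LMS stand-in reference table.

    Covers ages ~5.5-60 months (in days) for the age-keyed indicators and
    statures 40-130 cm for weight-for-stature, with smooth power-law median
    curves of realistic scale.  Weight-for-age medians are the composition of
    the weight-for-stature and stature-for-age curves, so a child at the
    median of both HAZ and WHZ also sits at the WAZ median.  These are NOT
    official reference values.
    """
    rows = []
    age_days = np.arange(165.0, 1846.0, 15.0)  # ~5.4 to ~60.6 months
    age_months = age_days / DAYS_PER_MONTH
    stature_keys = np.arange(40.0, 130.01, 0.5)
    for sex in SEXES:
        m_sfa = _sfa_median(age_months, sex)
        for k, m in zip(age_days, m_sfa):
            rows.append((Indicator.STATURE_FOR_AGE.value, sex, k, 1.0, m, 0.035))
        m_wfa = _wfs_median(m_sfa, sex)
        for k, m in zip(age_days, m_wfa):
            rows.append((Indicator.WEIGHT_FOR_AGE.value, sex, k, 0.1, m, 0.12))
        m_wfs = _wfs_median(stature_keys, sex)
        for k, m in zip(stature_keys, m_wfs):
            rows.append((Indicator.WEIGHT_FOR_STATURE.value, sex, k, -0.35, m, 0.08))
    table = pd.DataFrame(rows, columns=list(_REQUIRED_COLUMNS))
    return GrowthReference(table, interpolation=interpolation)


# ---------------------------------------------------------------------------
# Indicator computation and classification
# ---------------------------------------------------------------------------

def stature_range_valid(stature_cm: float, age_months: float) -> bool:
    """Whether stature lies in the generatable-z window for the child's age.

    Boundaries are inclusive-valid: 45.0 cm at 18 months is in range.
    """
    if np.isnan(stature_cm) or np.isnan(age_months):
        return False
    lo, hi = (
        LENGTH_RANGE_CM if age_months < LENGTH_AGE_LIMIT_MONTHS else HEIGHT_RANGE_CM
    )
    return lo <= stature_cm <= hi


def compute_indicators(
    age_months: float,
    sex: str,
    weight_kg: float,
    stature_cm: float,
    reference: GrowthReference,
    restrict_tails: bool = True,
) -> ZScoreSet:
    """Compute WHZ, HAZ and WAZ for one child.

    Age is converted to days via :data:`DAYS_PER_MONTH`.  The tail-restricted
    z computation (``restrict_tails``) applies to the weight-based indicators
    (WHZ, WAZ) only; HAZ is always the plain LMS score.  Children outside
    6-59 months are scored with a warning, not an error.
    """
    if sex not in SEXES:
        raise ValueError(f"sex must be one of {SEXES}, got {sex!r}")
    age_months = float(age_months)
    weight = np.nan if weight_kg is None else float(weight_kg)
    stature = np.nan if stature_cm is None else float(stature_cm)
    if not np.isnan(age_months) and not (6.0 <= age_months <= 59.0):
        warnings.warn(
            f"age {age_months:.1f} months outside the 6-59 month study range",
            stacklevel=2,
        )
    age_days = age_months * DAYS_PER_MONTH
    haz = reference.zscore(Indicator.STATURE_FOR_AGE, sex, age_days, stature)
    waz = reference.zscore(
        Indicator.WEIGHT_FOR_AGE, sex, age_days, weight, restrict_tails=restrict_tails
    )
    whz = reference.zscore(
        Indicator.WEIGHT_FOR_STATURE, sex, stature, weight, restrict_tails=restrict_tails
    )
    return ZScoreSet(
        whz=whz, haz=haz, waz=waz, range_valid=stature_range_valid(stature, age_months)
    )


def cohort_zscores(
    df: pd.DataFrame,
    reference: GrowthReference,
    stature_col: str = "stature_cm",
    weight_col: str = "weight_kg",
    restrict_tails: bool = True,
) -> pd.DataFrame:
    """Vectorised wrapper: WHZ/HAZ/WAZ/range_valid for each row of ``df``.

    ``df`` must carry ``age_months``, ``sex`` and the named stature/weight
    columns.  Returns a DataFrame aligned to ``df.index``.
    """
    out = {"whz": [], "haz": [], "waz": [], "range_valid": []}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for row in df.itertuples(index=False):
            zs = compute_indicators(
                getattr(row, "age_months"),
                getattr(row, "sex"),
                getattr(row, weight_col),
                getattr(row, stature_col),
                reference,
                restrict_tails=restrict_tails,
            )
            out["whz"].append(zs.whz)
            out["haz"].append(zs.haz)
            out["waz"].append(zs.waz)
            out["range_valid"].append(zs.range_valid)
    return pd.DataFrame(out, index=df.index)


def classify_z(z: float) -> NutritionClass | None:
    """Severity class from a z-score: <-3 severe, [-3, -2) moderate, else normal.

    Missing (NaN/None) z yields ``None``.
    """
    if z is None or np.isnan(z):
        return None
    if z < -3.0:
        return NutritionClass.SEVERE
    if z < -2.0:
        return NutritionClass.MODERATE
    return NutritionClass.NORMAL


def classify_muac(muac_cm: float) -> NutritionClass | None:
    """Severity class from MUAC: <11.5 severe, [11.5, 12.5) moderate, else normal."""
    if muac_cm is None or np.isnan(muac_cm):
        return None
    muac_cm = float(muac_cm)
    if muac_cm <= 0:
        raise ValueError(f"MUAC must be positive, got {muac_cm}")
    if muac_cm < 11.5:
        return NutritionClass.SEVERE
    if muac_cm < 12.5:
        return NutritionClass.MODERATE
    return NutritionClass.NORMAL
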