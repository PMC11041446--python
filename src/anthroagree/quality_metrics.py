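"""Data-quality metrics: digit preference, outlier flags, post-exclusion SDs.

The digit preference score (DPS) follows the MONICA procedure: the
chi-square statistic of the terminal-digit distribution against uniformity,
rescaled by sample size and degrees of freedom,

    DPS = 100 * sqrt(chi2 / (9 * N)).

0 means perfectly uniform terminal digits; 100 means all mass on one digit.
Outlier flags come in two flavours used for anthropometric plausibility
screening: *fixed* windows around the reference mean (WHZ beyond +/-5, HAZ
beyond +/-6) and *flexible* windows of +/-3 z around the observed sample
median.  Stature outside the window in which z-scores are generatable
(length 45-110 cm under 24 months, height 65-120 cm after) is flagged by the
range rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .growth_reference import stature_range_valid

__all__ = [
    "DigitPreferenceResult",
    "terminal_digit_counts",
    "digit_preference_score",
    "fixed_exclusion_flags",
    "flexible_exclusion_flags",
    "range_exclusion_flags",
    "summary_sd",
    "quality_report",
]

WHZ_FIXED_WINDOW = (-5.0, 5.0)
HAZ_FIXED_WINDOW = (-6.0, 6.0)
FLEXIBLE_HALF_WIDTH = 3.0


@dataclass(frozen=True)
class DigitPreferenceResult:
    counts: tuple[int, ...]
    n: int
    chi_square: float
    dps: float


def terminal_digit_counts(values, resolution: float = 0.1) -> np.ndarray:
    """Tally terminal digits 0-9 of measurements on the given grid.

    The terminal digit of 81.4 cm at 0.1-cm resolution is 4.  Values are
    snapped to the grid first, so 80.04 counts as digit 0.
    """
    v = np.asarray(values, float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("no finite values to tally")
    digits = np.rint(v / resolution).astype(np.int64) % 10
    return np.bincount(digits, minlength=10)


def digit_preference_score(counts) -> DigitPreferenceResult:
    """MONICA digit preference score from terminal-digit counts."""
    counts = np.asarray(counts, dtype=np.int64)
    if counts.shape != (10,):
        raise ValueError("expected 10 terminal-digit counts")
    if (counts < 0).any():
        raise ValueError("counts must be nonnegative")
    n = int(counts.sum())
    if n == 0:
        raise ValueError("digit preference score undefined for n = 0")
    expected = n / 10.0
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    dps = float(100.0 * np.sqrt(chi2 / (9.0 * n)))
    return DigitPreferenceResult(tuple(int(c) for c in counts), n, chi2, dps)


def fixed_exclusion_flags(whz, haz) -> pd.DataFrame:
    """Fixed implausibility windows: WHZ outside (-5, 5), HAZ outside (-6, 6).

    Inequalities are strict — WHZ of exactly -5 is not flagged.  Missing
    z-scores are never flagged.
    """
    whz = np.asarray(whz, float)
    haz = np.asarray(haz, float)
    return pd.DataFrame(
        {
            "whz_fixed": np.isfinite(whz) & ((whz < WHZ_FIXED_WINDOW[0]) | (whz > WHZ_FIXED_WINDOW[1])),
            "haz_fixed": np.isfinite(haz) & ((haz < HAZ_FIXED_WINDOW[0]) | (haz > HAZ_FIXED_WINDOW[1])),
        }
    )


def flexible_exclusion_flags(z, half_width: float = FLEXIBLE_HALF_WIDTH):
    """Flag z-scores beyond ``half_width`` from the observed sample median.

    Returns (flags, median).  The median is computed on the finite values of
    the analysed sample — each source and indicator is its own sample.
    Strict inequalities: a value exactly at median + 3 is not flagged.
    """
    z = np.asarray(z, float)
    finite = np.isfinite(z)
    if not finite.any():
        raise ValueError("flexible exclusions need at least one finite z-score")
    med = float(np.median(z[finite]))
    flags = finite & ((z < med - half_width) | (z > med + half_width))
    return flags, med


def range_exclusion_flags(stature_cm, age_months) -> np.ndarray:
    """True where stature is outside the generatable-z window for the age.

    Boundaries are inclusive-valid (45.0 cm at 18 months passes).
    """
    stature = np.atleast_1d(np.asarray(stature_cm, float))
    age = np.atleast_1d(np.asarray(age_months, float))
    return np.array(
        [not stature_range_valid(s, a) for s, a in zip(stature, age)], dtype=bool
    )


def summary_sd(
    values,
    fixed_flags=None,
    flexible_flags=None,
    range_flags=None,
    policy: str = "none",
) -> float:
    """Sample SD (n-1 denominator) after the chosen exclusion policy.

    ``policy``: 'none' keeps everything finite; 'fixed' additionally drops
    fixed-window flags; 'flexible' drops flexible-window flags.  Range flags,
    when supplied, are dropped under either exclusion policy.  Fewer than two
    retained values is an error.
    """
    v = np.asarray(values, float)
    keep = np.isfinite(v)
    if policy not in ("none", "fixed", "flexible"):
        raise ValueError(f"unknown exclusion policy {policy!r}")
    if policy != "none":
        flags = fixed_flags if policy == "fixed" else flexible_flags
        if flags is not None:
            keep &= ~np.asarray(flags, bool)
        if range_flags is not None:
            keep &= ~np.asarray(range_flags, bool)
    if keep.sum() < 2:
        raise ValueError("summary SD needs at least 2 retained values")
    return float(np.std(v[keep], ddof=1))


def _source_quality(
    stature, muac, whz, haz, range_invalid, policy: str
) -> dict[str, float]:
    """Quality metrics for one measurement source (one sample column)."""
    out: dict[str, float] = {}
    out["dps_stature"] = digit_preference_score(terminal_digit_counts(stature)).dps
    out["dps_muac"] = digit_preference_score(terminal_digit_counts(muac)).dps
    fixed = fixed_exclusion_flags(whz, haz)
    out["n_fixed_whz"] = int(fixed["whz_fixed"].sum())
    out["n_fixed_haz"] = int(fixed["haz_fixed"].sum())
    flex = {}
    for name, z in (("whz", whz), ("haz", haz)):
        flags, _ = flexible_exclusion_flags(z)
        flex[name] = flags
        out[f"n_flexible_{name}"] = int(flags.sum())
    rng = np.asarray(range_invalid, bool)
    out["n_range_invalid"] = int(rng.sum())
    for name, z in (("whz", whz), ("haz", haz)):
        out[f"sd_{name}"] = summary_sd(
            z,
            fixed_flags=fixed[f"{name}_fixed"].to_numpy(),
            flexible_flags=flex[name],
            range_flags=rng,
            policy=policy,
        )
    out["sd_muac"] = summary_sd(muac, policy="none")
    return out


def quality_report(pairs: pd.DataFrame, policy: str = "flexible") -> pd.DataFrame:
    """Side-by-side quality table (metric x source) for linked pairs.

    ``pairs`` must carry manual_/scan_ stature and MUAC plus the z-score
    columns added by the linkage stage (manual_whz, manual_haz, scan_whz,
    scan_haz) and range_invalid.  ``policy`` selects which outlier set feeds
    the post-exclusion SDs (flexible by default).
    """
    sources = {}
    sources["manual"] = _source_quality(
        pairs["manual_stature_cm"],
        pairs["manual_muac_cm"],
        pairs["manual_whz"].to_numpy(float),
        pairs["manual_haz"].to_numpy(float),
        np.zeros(len(pairs), bool) if "manual_range_invalid" not in pairs else pairs["manual_range_invalid"],
        policy,
    )
    sources["scan"] = _source_quality(
        pairs["scan_stature_cm"],
        pairs["scan_muac_cm"],
        pairs["scan_whz"].to_numpy(float),
        pairs["scan_haz"].to_numpy(float),
        pairs["range_invalid"] if "range_invalid" in pairs else np.zeros(len(pairs), bool),
        policy,
    )
    report = pd.DataFrame(sources)
    report.index.name = "metric"
    return report
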