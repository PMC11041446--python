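"""Paired-difference agreement statistics for method comparison.

For N children each measured by the device (M_i1) and manually (M_i2), the
difference d_i = M_i1 - M_i2 (scan minus manual) carries all the agreement
information:

* mean bias  (1/N) sum d_i, with a t-based 95% CI — systematic error;
* 95% limits of agreement  bias +/- 1.96 * SD(d) — random error, the
  interval expected to contain 95% of individual differences;
* technical error of measurement  TEM = sqrt(sum d_i^2 / 2N) — the
  anthropometric error index of Ulijaszek & Kerr, in measurement units;
* the Pitman test of equal variances for paired samples, operationalised as
  the correlation of d_i with the pair mean (M_i1 + M_i2)/2: a nonzero
  correlation means error scales with the size of the child.

TEM relates to the bias/SD summary through sum d^2 = N*bias^2 + (N-1)*s^2,
so printed (bias, LoA, n) triples determine the TEM exactly; this identity
is exposed as :func:`tem_from_summary`.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LOA_MULTIPLIER",
    "AgreementSummary",
    "paired_differences",
    "mean_bias",
    "limits_of_agreement",
    "sd_from_loa",
    "technical_error",
    "tem_from_summary",
    "pitman_test",
    "pearson_correlation",
    "within_threshold_fraction",
    "summarize_agreement",
    "stratified_agreement",
    "bland_altman_table",
    "summaries_to_frame",
]

#: Conventional Bland-Altman multiplier for the 95% limits of agreement.
LOA_MULTIPLIER = 1.96

MEASURE_COLUMNS = {
    "stature": ("scan_stature_cm", "manual_stature_cm"),
    "muac": ("scan_muac_cm", "manual_muac_cm"),
}


@dataclass(frozen=True)
class AgreementSummary:
    """Agreement statistics for one stratum.

    ``suppressed`` is True for strata below the minimum size, in which case
    only ``n`` is meaningful and every statistic is NaN.
    """

    stratum: str
    n: int
    bias_cm: float
    bias_ci: tuple[float, float]
    sd_diff_cm: float
    loa: tuple[float, float]
    tem_cm: float
    pitman_r: float
    pitman_p: float
    suppressed: bool = False


def paired_differences(pairs: pd.DataFrame, measure: str) -> pd.DataFrame:
    """(diff, mean) per pair for one measure; diff is scan minus manual.

    Pairs missing either value are dropped (count retrievable by comparing
    lengths).
    """
    try:
        scan_col, manual_col = MEASURE_COLUMNS[measure]
    except KeyError:
        raise ValueError(f"measure must be one of {tuple(MEASURE_COLUMNS)}, got {measure!r}") from None
    scan = pairs[scan_col].to_numpy(float)
    manual = pairs[manual_col].to_numpy(float)
    keep = np.isfinite(scan) & np.isfinite(manual)
    out = pd.DataFrame(
        {
            "child_id": pairs.loc[keep, "child_id"].to_numpy()
            if "child_id" in pairs.columns
            else np.arange(int(keep.sum())),
            "diff": scan[keep] - manual[keep],
            "mean": (scan[keep] + manual[keep]) / 2.0,
        }
    )
    return out


def mean_bias(diffs, confidence: float = 0.95) -> tuple[float, tuple[float, float]]:
    """Mean difference with a t-interval.

    Returns (bias, (lo, hi)).  With a single difference the CI collapses to
    the point; with zero spread it is degenerate at the bias.
    """
    d = np.asarray(diffs, float)
    if d.size == 0:
        raise ValueError("mean bias undefined for empty differences")
    bias = float(d.mean())
    if d.size < 2:
        return bias, (bias, bias)
    sd = float(d.std(ddof=1))
    tcrit = float(stats.t.ppf(0.5 + confidence / 2.0, d.size - 1))
    half = tcrit * sd / np.sqrt(d.size)
    return bias, (bias - half, bias + half)


def limits_of_agreement(diffs, multiplier: float = LOA_MULTIPLIER) -> tuple[float, float]:
    """bias +/- multiplier * sample SD of the differences (n >= 2)."""
    d = np.asarray(diffs, float)
    if d.size < 2:
        raise ValueError("limits of agreement need at least 2 differences")
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return (bias - multiplier * sd, bias + multiplier * sd)


def sd_from_loa(lower: float, upper: float, multiplier: float = LOA_MULTIPLIER) -> float:
    """Recover the SD of differences from printed limits of agreement."""
    if upper < lower:
        raise ValueError("upper limit below lower limit")
    return (upper - lower) / (2.0 * multiplier)


def technical_error(diffs) -> float:
    """TEM = sqrt(sum d_i^2 / (2N)) over paired differences."""
    d = np.asarray(diffs, float)
    if d.size == 0:
        raise ValueError("TEM undefined for empty differences")
    return float(np.sqrt(np.sum(d**2) / (2.0 * d.size)))


def tem_from_summary(bias: float, sd: float, n: int) -> float:
    """TEM from a (mean difference, sample SD, n) summary.

    Uses sum d^2 = n*bias^2 + (n-1)*sd^2, i.e.
    TEM = sqrt((bias^2 + sd^2*(n-1)/n) / 2), carrying the (n-1)/n correction
    for the sample-SD denominator explicitly.
    """
    if n < 2:
        raise ValueError("summary TEM needs n >= 2")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    return float(np.sqrt((bias**2 + sd**2 * (n - 1) / n) / 2.0))


def pitman_test(diffs, means) -> tuple[float, float]:
    """Pitman test of equal variances for paired measurements.

    Operationalised as the Pearson correlation r between the paired
    differences and the pair means (equivalent to the classical
    difference-vs-sum formulation: the sum is twice the mean, which leaves r
    unchanged), with the two-sided p-value from t = r*sqrt((n-2)/(1-r^2)) on
    n-2 degrees of freedom.  Zero variance in either vector makes the test
    undefined: (nan, nan) is returned.
    """
    d = np.asarray(diffs, float)
    m = np.asarray(means, float)
    if d.size != m.size:
        raise ValueError("diffs and means must have equal length")
    if d.size < 3:
        raise ValueError("Pitman test needs n >= 3")
    if np.std(d) == 0 or np.std(m) == 0:
        return (np.nan, np.nan)
    r = float(np.corrcoef(d, m)[0, 1])
    if abs(r) >= 1.0:
        return (r, 0.0)
    n = d.size
    t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return (r, p)


def pearson_correlation(x, y) -> float:
    """Product-moment correlation; NaN when either vector has zero variance."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size:
        raise ValueError("vectors must have equal length")
    if x.size < 3:
        raise ValueError("correlation needs n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def within_threshold_fraction(diffs, threshold_cm: float) -> float:
    """Fraction of differences with |d| <= threshold (boundary inclusive)."""
    d = np.asarray(diffs, float)
    if d.size == 0:
        raise ValueError("fraction undefined for empty differences")
    if threshold_cm <= 0:
        raise ValueError("threshold must be positive")
    return float(np.mean(np.abs(d) <= threshold_cm))


def summarize_agreement(diffs, means, stratum: str = "overall") -> AgreementSummary:
    """Full AgreementSummary for one vector of paired differences."""
    d = np.asarray(diffs, float)
    bias, ci = mean_bias(d)
    loa = limits_of_agreement(d)
    r, p = pitman_test(d, means) if d.size >= 3 else (np.nan, np.nan)
    return AgreementSummary(
        stratum=stratum,
        n=int(d.size),
        bias_cm=bias,
        bias_ci=ci,
        sd_diff_cm=float(d.std(ddof=1)),
        loa=loa,
        tem_cm=technical_error(d),
        pitman_r=r,
        pitman_p=p,
    )


_GROUPINGS = {
    "overall": None,
    "team": "team",
    "sex": "sex",
    "age_group": "age_group",
}


def stratified_agreement(
    pairs: pd.DataFrame,
    measure: str,
    grouping: str = "overall",
    min_n: int = 5,
) -> list[AgreementSummary]:
    """Agreement summaries per stratum of ``grouping``.

    Strata smaller than ``min_n`` are reported with their n only and all
    statistics suppressed (NaN) rather than dropped, so small teams remain
    visible in output tables.
    """
    if grouping not in _GROUPINGS:
        raise ValueError(f"unknown grouping {grouping!r}; expected one of {tuple(_GROUPINGS)}")
    col = _GROUPINGS[grouping]
    if col is None:
        dm = paired_differences(pairs, measure)
        return [summarize_agreement(dm["diff"], dm["mean"], "overall")]
    if col not in pairs.columns:
        raise ValueError(f"pairs lack the {col!r} column required for grouping {grouping!r}")
    out = []
    for value, grp in pairs.groupby(col, sort=True):
        dm = paired_differences(grp, measure)
        label = f"{grouping}={value}"
        if len(dm) < min_n:
            out.append(
                AgreementSummary(
                    stratum=label,
                    n=len(dm),
                    bias_cm=np.nan,
                    bias_ci=(np.nan, np.nan),
                    sd_diff_cm=np.nan,
                    loa=(np.nan, np.nan),
                    tem_cm=np.nan,
                    pitman_r=np.nan,
                    pitman_p=np.nan,
                    suppressed=True,
                )
            )
        else:
            out.append(summarize_agreement(dm["diff"], dm["mean"], label))
    return out


def bland_altman_table(pairs: pd.DataFrame, measure: str) -> pd.DataFrame:
    """Tidy (child_id, mean, diff, strata) rows for Bland-Altman plotting."""
    dm = paired_differences(pairs, measure)
    if len(dm) == 0:
        return pd.DataFrame(columns=["child_id", "mean_cm", "diff_cm", "team", "sex", "age_group"])
    dm = dm.rename(columns={"mean": "mean_cm", "diff": "diff_cm"})
    strata = [c for c in ("team", "sex", "age_group") if c in pairs.columns]
    if strata and "child_id" in pairs.columns:
        dm = dm.merge(pairs[["child_id", *strata]], on="child_id", how="left")
    return dm


def summaries_to_frame(summaries: list[AgreementSummary]) -> pd.DataFrame:
    """Flatten AgreementSummary records into a tidy table (one row per stratum)."""
    rows = []
    for s in summaries:
        d = asdict(s)
        d["bias_ci_lower"], d["bias_ci_upper"] = d.pop("bias_ci")
        d["loa_lower"], d["loa_upper"] = d.pop("loa")
        rows.append(d)
    cols = [
        "stratum",
        "n",
        "tem_cm",
        "bias_cm",
        "bias_ci_lower",
        "bias_ci_upper",
        "loa_lower",
        "loa_upper",
        "sd_diff_cm",
        "pitman_r",
        "pitman_p",
        "suppressed",
    ]
    return pd.DataFrame(rows, columns=cols)
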