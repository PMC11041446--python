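"""Measurement-quality comparison: digit preference, outliers, SDs.

Computes the quality panel (DPS for stature and MUAC, fixed/flexible
outlier counts for WHZ/HAZ, post-exclusion SDs) side by side for the manual
and scan-derived sources among matched pairs.  Writes results/quality_report.csv.
"""

from pathlib import Path

from anthroagree import synthetic_reference
from anthroagree.linkage import build_pairs
from anthroagree.quality_metrics import quality_report
from anthroagree.synthetic_cohort import load_cohort

ROOT = Path(__file__).resolve().parents[1] / "results"


def main():
    tables = load_cohort(ROOT / "data")
    pairs = build_pairs(tables, synthetic_reference())["pairs"]
    report = quality_report(pairs, policy="flexible")
    report.to_csv(ROOT / "quality_report.csv", float_format="%.6g")
    print(report.round(2).to_string())
    dps_ratio = report.loc["dps_stature", "manual"] / report.loc["dps_stature", "scan"]
    print(
        f"\nmanual stature DPS is {dps_ratio:.1f}x the scan DPS "
        "(manual measurers heap terminal digits; the device does not), while every "
        "other metric favours the manual source."
    )


if __name__ == "__main__":
    main()
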