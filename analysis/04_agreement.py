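"""Agreement between scan-derived and manual measurements.

Bias with 95% CI, 95% limits of agreement, TEM, and the Pitman
size-dependence test, overall and stratified by team, sex and age group,
plus the sensitivity analysis excluding flagged and discordant pairs.
Writes results/agreement_{measure}.csv and Bland-Altman plot data.
"""

from pathlib import Path

import pandas as pd

from anthroagree import synthetic_reference
from anthroagree.agreement import (
    bland_altman_table,
    stratified_agreement,
    summaries_to_frame,
    within_threshold_fraction,
    paired_differences,
)
from anthroagree.linkage import accuracy_exclusion_mask, build_pairs
from anthroagree.synthetic_cohort import load_cohort

ROOT = Path(__file__).resolve().parents[1] / "results"


def main():
    tables = load_cohort(ROOT / "data")
    pairs = build_pairs(tables, synthetic_reference())["pairs"]
    clean = pairs[~accuracy_exclusion_mask(pairs)]

    for measure in ("stature", "muac"):
        frames = []
        for grouping in ("overall", "team", "sex", "age_group"):
            frames.append(summaries_to_frame(stratified_agreement(pairs, measure, grouping)))
        sens = summaries_to_frame(stratified_agreement(clean, measure, "overall"))
        sens["stratum"] = "overall, excluding flagged and discordant"
        table = pd.concat(frames + [sens], ignore_index=True)
        table.to_csv(ROOT / f"agreement_{measure}.csv", index=False, float_format="%.6g")
        bland_altman_table(pairs, measure).to_csv(
            ROOT / f"bland_altman_{measure}.csv", index=False, float_format="%.6g"
        )

        print(f"\n=== {measure} ===")
        print(table.drop(columns="suppressed").round(2).to_string(index=False))
        diffs = paired_differences(pairs, measure)["diff"]
        print(
            f"within 1 cm of manual: {100 * within_threshold_fraction(diffs, 1.0):.0f}% "
            f"of {len(diffs)} pairs"
        )


if __name__ == "__main__":
    main()
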