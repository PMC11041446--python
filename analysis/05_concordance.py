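"""Does measurement error change who screens positive for malnutrition?

Classifies every matched child severe/moderate/normal by WHZ, HAZ and MUAC
from each source independently, cross-tabulates the classifications, and
reports concordance and the fraction of manual-positive children the scan
also detects.  Writes results/concordance.csv.
"""

from pathlib import Path

import pandas as pd

from anthroagree import synthetic_reference
from anthroagree.concordance_report import (
    CLASSES,
    INDICATORS,
    classify_cohort,
    concordance_matrix,
    concordance_rate,
    detection_fraction,
)
from anthroagree.linkage import build_pairs
from anthroagree.synthetic_cohort import load_cohort

ROOT = Path(__file__).resolve().parents[1] / "results"


def main():
    tables = load_cohort(ROOT / "data")
    ref = synthetic_reference()
    pairs = build_pairs(tables, ref)["pairs"]
    classes = classify_cohort(pairs, ref)

    rows = []
    for ind in INDICATORS:
        mat = concordance_matrix(classes, ind)
        for i, mc in enumerate(CLASSES):
            for j, sc in enumerate(CLASSES):
                rows.append((ind, mc, sc, int(mat.counts[i, j])))
        print(f"\n=== {ind} (n={mat.n}) ===")
        print(mat.to_frame().to_string())
        print(f"concordant: {100 * concordance_rate(mat):.1f}%")
        det = detection_fraction(mat)
        print(f"manual-positive children detected by scan: {100 * det:.0f}%")
    pd.DataFrame(rows, columns=["indicator", "manual_class", "scan_class", "count"]).to_csv(
        ROOT / "concordance.csv", index=False
    )


if __name__ == "__main__":
    main()
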