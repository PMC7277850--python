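#!/usr/bin/env python
"""Penetrance fold-change biomarker calling on the normalized matrix.

Scores every antigen (individual FC vs the control mean, zeroing below
2-fold, penetrance frequencies and fold changes), applies the calling rule,
and compares the called signature against the planted ground truth.
Writes results/penetrance.tsv and results/biomarkers.tsv.
"""

from pathlib import Path

import pandas as pd

from immunoarray import read_sample_sheet, score_penetrance

ROOT = Path(__file__).resolve().parent.parent / "results"
COLS = ["freq_case", "freq_control", "freq_diff", "pfc_case", "pfc_control",
        "mean_control", "is_biomarker", "rank"]


def main() -> None:
    H = pd.read_csv(ROOT / "normalized_matrix.tsv", sep="\t", index_col=0)
    sheet = read_sample_sheet(ROOT / "study" / "samples.csv")
    result = score_penetrance(H, sheet.case_ids, sheet.control_ids)
    result.table[COLS].to_csv(ROOT / "penetrance.tsv", sep="\t")
    result.biomarkers[COLS].to_csv(ROOT / "biomarkers.tsv", sep="\t")
    print(result.biomarkers[COLS].round(2).to_string())

    truth = pd.read_csv(ROOT / "study" / "ground_truth.csv")
    planted = set(truth.probe_id)
    called = result.signature
    print(f"\ncalled {len(called)} biomarkers; planted {len(planted)}")
    print(f"sensitivity {len(called & planted) / len(planted):.2f}, "
          f"false positives {len(called - planted)} "
          f"of {len(result.table) - len(planted)} null probes")


if __name__ == "__main__":
    main()
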