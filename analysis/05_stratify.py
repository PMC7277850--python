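#!/usr/bin/env python
"""Stratification of the called signature.

Ward/Euclidean clustering of the biomarker fold-change matrix (heatmap +
newick trees), the Malay sub-cohort signature comparison (Chinese cases
removed, penetrance re-run), and disease annotation of the signature
against the packaged association table.
"""

from pathlib import Path

import pandas as pd

from immunoarray import read_sample_sheet, score_penetrance
from immunoarray.stratification import (
    annotate_disease,
    cluster_heatmap,
    disease_summary,
    linkage_to_newick,
    subcohort_signature,
)

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    H = pd.read_csv(ROOT / "normalized_matrix.tsv", sep="\t", index_col=0)
    sheet = read_sample_sheet(ROOT / "study" / "samples.csv")
    result = score_penetrance(H, sheet.case_ids, sheet.control_ids)
    marks = sorted(result.signature)

    cluster = cluster_heatmap(result.fc, biomarkers=marks,
                              image_path=ROOT / "heatmap.png")
    (ROOT / "samples.nwk").write_text(
        linkage_to_newick(cluster.sample_linkage, list(cluster.matrix.columns)) + "\n")
    (ROOT / "proteins.nwk").write_text(
        linkage_to_newick(cluster.protein_linkage, list(cluster.matrix.index)) + "\n")
    labels = cluster.cut_samples(k=2)
    print("2-cluster cut of the sample tree:")
    for c, members in labels.groupby(labels).groups.items():
        print(f"  cluster {c}: {' '.join(members)}")

    malay = [r.sample_id for r in sheet.rows
             if r.group == "case" and r.ethnicity == "Malay"]
    comp, _, _ = subcohort_signature(H, sheet.case_ids, sheet.control_ids, malay)
    print(f"\nMalay sub-cohort (n={len(malay)}): "
          f"{len(comp.signature_subcohort)} biomarkers, "
          f"{len(comp.overlap)} overlap the full signature, "
          f"{len(comp.unique_to_subcohort)} unique to the sub-cohort, "
          f"{len(comp.unique_to_full)} only in the full cohort")

    annotate_disease(marks).to_csv(ROOT / "annotation.tsv", sep="\t", index=False)
    summary = disease_summary(marks)
    print("\ndisease associations of the called signature "
          "(synthetic probes: expected none):")
    print(summary[summary.n_targets > 0].to_string(index=False)
          if summary.n_targets.any() else "  none")


if __name__ == "__main__":
    main()
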