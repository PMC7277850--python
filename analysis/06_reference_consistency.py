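#!/usr/bin/env python
"""Consistency checks across the packaged reference tables.

Counts each protein's penetrance frequency from the per-patient biomarker
lists and compares it with the published 23-protein summary; applies the
biomarker calling rule to the summary; intersects the signature with the
disease-association table.  Writes results/reference_consistency.tsv.
"""

from pathlib import Path

import pandas as pd

from immunoarray.penetrance import call_biomarkers
from immunoarray.reference_data import (
    biomarker_summary,
    discordant_proteins,
    per_patient_frequencies,
)
from immunoarray.stratification import annotate_disease, disease_summary

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    summary = biomarker_summary().set_index("protein")
    counted = per_patient_frequencies()
    table = pd.DataFrame(
        {
            "published_freq": summary.freq_case,
            "counted_freq": counted.reindex(summary.index).astype(int),
        }
    )
    table["concordant"] = table.published_freq == table.counted_freq
    table.to_csv(ROOT / "reference_consistency.tsv", sep="\t")
    disc = discordant_proteins()
    print(f"{int(table.concordant.sum())} of {len(table)} proteins concordant "
          f"between the two published tables; {len(disc)} discordant:")
    print("  " + " ".join(sorted(disc)))

    scored = summary.assign(freq_diff=summary.freq_case)  # control freqs are 0
    called = call_biomarkers(scored, n_case=9, n_control=3)
    print(f"\ncalling rule flags {int(called.is_biomarker.sum())} of "
          f"{len(called)} published rows as biomarkers")
    print(f"fold-change extrema: max {summary.pfc_case.max()} "
          f"({summary.pfc_case.idxmax()}), min {summary.pfc_case.min()} "
          f"({summary.pfc_case.idxmin()})")

    sig = set(summary.index)
    ds = disease_summary(sig).set_index("disease")
    ann = annotate_disease(sig)
    print(f"\n{ds.loc['Thalassemia', 'n_targets']} biomarkers associated with "
          f"thalassemia ({ds.loc['Thalassemia', 'targets']}); "
          f"{int((ann.n_diseases == 0).sum())} novel")


if __name__ == "__main__":
    main()
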