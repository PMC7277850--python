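"""Published reference datasets for the beta-thalassemia-major autoantibody study.

Three tables from the original 12-sample Immunome-array study (nine
beta-thalassemia major patients, three non-thalassemia controls) are packaged
verbatim as machine-readable data:

* the per-patient autoantibody biomarker lists (clinical summary table),
* the 23-protein penetrance summary (penetrance frequency among cases,
  penetrance fold change, control-group mean RFU), and
* the Open Targets disease-association table for those 23 antigens.

Two typographic artifacts in the per-patient table are transcribed with a
documented fix-up: patient 025723 lists ZNHIT3 twice (de-duplicated here) and
patient 025749 runs three gene symbols together (split as APOBEC3G, NR2E3,
KRT19).  The per-patient lists and the 23-protein summary disagree on the
penetrance frequency of 14 proteins; :func:`discordant_proteins` flags them
rather than reconciling the two tables.
"""

from __future__ import annotations

import pandas as pd

# Per-patient biomarker lists. 025723's duplicate ZNHIT3 is de-duplicated;
# 025749's run-together tokens are split as APOBEC3G, NR2E3, KRT19.
_CASE_BIOMARKERS: dict[str, tuple[str, ...]] = {
    "025757": ("MAPKAPK3", "TSPY3", "PFKFB4"),
    "025724": ("SDCCAG8", "NME7"),
    "025712": ("DBNL", "TWF2", "PDCL3", "NR2E3", "ZNHIT3"),
    "025711": ("HCLS1", "HOOK1"),
    "025740": ("HCLS1", "SDCCAG8", "HOOK1", "COPS6"),
    "025723": ("HCLS1", "SDCCAG8", "ZNHIT3", "HOOK1", "MAPKAPK3", "MOB3A", "PFKFB4"),
    "025749": (
        "SDCCAG8", "TSPY3", "PFKFB4", "APOBEC3G", "NR2E3", "KRT19",
        "FOXR2", "RPLP1", "SGSM3", "HCLS1", "DBNL", "ZNHIT3", "NME7",
    ),
    "025759": ("HCLS1", "DBNL", "NME7", "TWF2", "MAPKAPK3", "COPS6", "TSPY3"),
    "025750": ("PFKFB4", "PDCL3", "TPM1", "DBNL", "TSPY3", "ZNHIT3", "NME7"),
}

# 23-protein penetrance summary: (protein, penetrance frequency among the
# nine cases, penetrance fold change, mean control RFU), in published order.
_BIOMARKER_SUMMARY: tuple[tuple[str, int, float, float], ...] = (
    ("HCLS1", 5, 5.33, 157.83),
    ("DBNL", 4, 4.07, 109.26),
    ("SDCCAG8", 4, 4.01, 144.09),
    ("TSPY3", 4, 3.02, 97.43),
    ("PFKFB4", 4, 2.70, 119.35),
    ("ZNHIT3", 4, 2.46, 102.29),
    ("NME7", 4, 2.39, 95.36),
    ("TWF2", 3, 13.38, 85.86),
    ("HOOK1", 3, 9.21, 163.31),
    ("MAPKAPK3", 3, 7.21, 104.63),
    ("COPS6", 3, 7.08, 103.80),
    ("MED22", 3, 5.95, 103.00),
    ("PDCL3", 3, 5.89, 94.35),
    ("APOBEC3G", 3, 3.58, 102.11),
    ("NR2E3", 3, 3.49, 107.26),
    ("KRT19", 3, 3.32, 209.80),
    ("MOB3A", 3, 3.17, 130.69),
    ("FOXR2", 3, 3.00, 104.71),
    ("RPLP1", 3, 2.97, 99.18),
    ("SGSM3", 3, 2.85, 129.13),
    ("TPM1", 3, 2.79, 248.36),
    ("EPS15", 3, 2.61, 115.74),
    ("TRAF1", 3, 2.16, 110.63),
)

# Open Targets disease associations for the 23 antigens.
_DISEASE_ASSOCIATIONS: dict[str, frozenset[str]] = {
    "Thalassemia": frozenset({"EPS15", "HCLS1", "KRT19", "TPM1"}),
    "Beta-thal and related diseases": frozenset({"EPS15", "HCLS1", "TPM1"}),
    "Beta-thal": frozenset({"HCLS1", "TPM1"}),
    "Beta-thal intermedia": frozenset({"HCLS1"}),
    "Hereditary persistence of fetal Hb- beta-thal": frozenset({"EPS15"}),
    "Delta-beta-thal": frozenset({"EPS15"}),
    "Beta-thal associated with another Hb anomaly": frozenset({"EPS15"}),
    "Beta-thal major": frozenset({"HCLS1"}),
    "Alpha-thal": frozenset({"KRT19"}),
    "Alpha-thal and related diseases": frozenset({"KRT19"}),
}


def case_biomarker_lists() -> dict[str, set[str]]:
    """Per-patient autoantibody biomarker sets for the nine cases."""
    return {cid: set(markers) for cid, markers in _CASE_BIOMARKERS.items()}


def biomarker_summary() -> pd.DataFrame:
    """The published 23-biomarker penetrance summary.

    Columns: protein, freq_case (penetrance frequency among the nine cases),
    pfc_case (penetrance fold change), mean_control (control-group mean RFU).
    Row order is the published ranking (descending frequency, then descending
    fold change).
    """
    return pd.DataFrame(
        _BIOMARKER_SUMMARY,
        columns=["protein", "freq_case", "pfc_case", "mean_control"],
    )


def disease_associations() -> dict[str, frozenset[str]]:
    """Disease name -> associated-target set for the 23 antigens."""
    return dict(_DISEASE_ASSOCIATIONS)


def disease_targets(disease: str) -> frozenset[str]:
    """Target set for one disease; unknown disease names yield the empty set."""
    return _DISEASE_ASSOCIATIONS.get(disease, frozenset())


def per_patient_frequencies() -> pd.Series:
    """Penetrance frequency of each protein counted from the per-patient lists."""
    counts: dict[str, int] = {}
    for markers in _CASE_BIOMARKERS.values():
        for m in set(markers):
            counts[m] = counts.get(m, 0) + 1
    for protein, *_ in _BIOMARKER_SUMMARY:
        counts.setdefault(protein, 0)
    return pd.Series(counts, name="frequency").sort_index()


def discordant_proteins() -> set[str]:
    """Proteins whose counted per-patient frequency disagrees with the summary."""
    counted = per_patient_frequencies()
    return {
        protein
        for protein, freq, *_ in _BIOMARKER_SUMMARY
        if counted.get(protein, 0) != freq
    }
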