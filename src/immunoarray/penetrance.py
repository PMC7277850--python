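"""Penetrance fold-change biomarker statistic.

Serum autoantibody signals are sparse: a marker may be strongly elevated in a
subset of patients and absent in the rest, so group means wash it out.  The
penetrance statistic scores each protein by the samples in which it is
actually elevated:

* **Individual fold change** — each sample's normalized RFU divided by the
  control-group mean for that protein (the same fixed denominator for cases
  and controls; no leave-one-out).
* **Zeroing** — signals below 2-fold of the control mean are replaced with
  zero; they are treated as background.
* **Penetrance frequency** — the number of samples per group with individual
  FC >= 2 ("penetrant" samples), and the case-minus-control difference.
* **Penetrance fold change** — the mean RFU over penetrant samples only,
  divided by the control mean; 0 when a group has no penetrant sample.

A protein is called a biomarker when its case penetrance fold change exceeds
2.0 (strictly) and both the case frequency and the case-control frequency
difference reach 10% of the case count (ceiling).  Ranking is by descending
case frequency, then descending case fold change, ties broken alphabetically.

No significance testing is involved: the statistic is a thresholded
descriptive score.  An optional background floor (mean + 2 SD of buffer-spot
net intensities) can additionally zero probes whose absolute signal is
indistinguishable from empty spots.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

FOLD_THRESHOLD = 2.0  # individual-FC cut for a penetrant sample
CALL_PFC_THRESHOLD = 2.0  # strict > for the biomarker call
FREQ_FRACTION = 0.10  # of the case count, ceiling


class PenetranceError(ValueError):
    pass


@dataclass
class PenetranceResult:
    """Per-protein penetrance table plus the intermediate matrices."""

    table: pd.DataFrame  # per-protein scores, biomarker flags and ranks
    fc: pd.DataFrame  # individual fold changes (post-zeroing)
    H: pd.DataFrame  # expression matrix post-zeroing
    excluded: list[str]  # proteins dropped for zero control mean

    @property
    def biomarkers(self) -> pd.DataFrame:
        called = self.table[self.table["is_biomarker"]]
        return called.sort_values("rank")

    @property
    def signature(self) -> set[str]:
        return set(self.table.index[self.table["is_biomarker"]])


def individual_fc(
    H: pd.DataFrame, control_ids: list[str]
) -> tuple[pd.DataFrame, pd.Series, list[str]]:
    """Fold change of every sample against the control-group mean per protein.

    Proteins with a zero (or undefined) control mean cannot be scored; they
    are excluded and reported, not errored.
    Returns (FC matrix, control means, excluded protein ids).
    """
    if not control_ids:
        raise PenetranceError("at least one control sample is required")
    mean_control = H[control_ids].mean(axis=1)
    scorable = mean_control > 0
    excluded = list(H.index[~scorable])
    fc = H.loc[scorable].div(mean_control[scorable], axis=0)
    return fc, mean_control[scorable], excluded


def zero_low_signals(
    H: pd.DataFrame, fc: pd.DataFrame, threshold: float = FOLD_THRESHOLD
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replace sub-threshold signals (and their FCs) with zero."""
    low = fc < threshold
    H_z = H.loc[fc.index].where(~low, 0.0)
    fc_z = fc.where(~low, 0.0)
    return H_z, fc_z


def penetrance_frequencies(
    fc: pd.DataFrame,
    case_ids: list[str],
    control_ids: list[str],
    threshold: float = FOLD_THRESHOLD,
) -> pd.DataFrame:
    """Counts of penetrant samples (FC >= threshold) per group, per protein."""
    penetrant = fc >= threshold
    freq_case = penetrant[case_ids].sum(axis=1).astype(int)
    freq_control = penetrant[control_ids].sum(axis=1).astype(int)
    return pd.DataFrame(
        {
            "freq_case": freq_case,
            "freq_control": freq_control,
            "freq_diff": freq_case - freq_control,
        }
    )


def _penetrant_mean(H: pd.DataFrame, fc: pd.DataFrame, ids: list[str], threshold: float) -> pd.Series:
    mask = fc[ids] >= threshold
    sums = H[ids].where(mask, 0.0).sum(axis=1)
    counts = mask.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = sums / counts
    return means.fillna(0.0)


def penetrance_fold_changes(
    H: pd.DataFrame,
    fc: pd.DataFrame,
    mean_control: pd.Series,
    case_ids: list[str],
    control_ids: list[str],
    threshold: float = FOLD_THRESHOLD,
) -> pd.DataFrame:
    """Mean over penetrant samples / control mean, per group and protein.

    Reported as 0 when the group has no penetrant sample (undefined mean).
    """
    return pd.DataFrame(
        {
            "pfc_case": _penetrant_mean(H, fc, case_ids, threshold) / mean_control,
            "pfc_control": _penetrant_mean(H, fc, control_ids, threshold) / mean_control,
        }
    )


def call_biomarkers(
    table: pd.DataFrame,
    n_case: int,
    n_control: int,
    pfc_threshold: float = CALL_PFC_THRESHOLD,
    freq_fraction: float = FREQ_FRACTION,
) -> pd.DataFrame:
    """Apply the three-part biomarker calling and ranking rule.

    *table* needs columns freq_case, freq_diff, pfc_case (e.g. the output of
    :func:`score_penetrance`, or a published summary table).  A protein is a
    biomarker iff pfc_case > pfc_threshold (strict), freq_case >=
    ceil(freq_fraction * n_case) and freq_diff >= the same count.  Returns a
    copy with ``is_biomarker`` and 1-based ``rank`` columns (rank is NA for
    non-called proteins); ranking is descending freq_case, then descending
    pfc_case, ties alphabetical.
    """
    if n_case < 1:
        raise PenetranceError("n_case must be >= 1")
    if n_control < 1:
        raise PenetranceError("n_control must be >= 1")
    min_count = math.ceil(freq_fraction * n_case)
    out = table.copy()
    out["is_biomarker"] = (
        (out["pfc_case"] > pfc_threshold)
        & (out["freq_case"] >= min_count)
        & (out["freq_diff"] >= min_count)
    )
    called = out[out["is_biomarker"]].sort_values(
        by=["freq_case", "pfc_case"],
        ascending=[False, False],
        kind="mergesort",
    )
    # mergesort is stable; break residual ties alphabetically by protein id
    called = called.loc[
        sorted(
            called.index,
            key=lambda p: (-called.at[p, "freq_case"], -called.at[p, "pfc_case"], p),
        )
    ]
    out["rank"] = pd.Series(
        range(1, len(called) + 1), index=called.index, dtype="Int64"
    )
    return out


def background_floor(buffer_nets, n_sd: float = 2.0) -> float:
    """Array background floor: mean + n_sd * SD of buffer-spot net intensities."""
    arr = np.asarray(buffer_nets, dtype=float)
    if arr.size == 0:
        return 0.0
    return float(arr.mean() + n_sd * arr.std(ddof=1 if arr.size > 1 else 0))


def score_penetrance(
    H: pd.DataFrame,
    case_ids: list[str],
    control_ids: list[str],
    fold_threshold: float = FOLD_THRESHOLD,
    pfc_threshold: float = CALL_PFC_THRESHOLD,
    freq_fraction: float = FREQ_FRACTION,
    floor: float | None = None,
) -> PenetranceResult:
    """Run the full penetrance pipeline on a normalized expression matrix.

    *H* is proteins x samples (normalized RFU).  If *floor* is given, probes
    whose aggregated net RFU falls below it are zeroed before fold-change
    computation (the absolute-background interpretation of the zeroing rule;
    off by default — the relative 2-fold rule always applies).
    """
    missing = [s for s in case_ids + control_ids if s not in H.columns]
    if missing:
        raise PenetranceError(f"samples not in matrix: {missing}")
    H = H[case_ids + control_ids].astype(float)
    if floor is not None:
        H = H.where(H >= floor, 0.0)
    fc, mean_control, excluded = individual_fc(H, control_ids)
    H_z, fc_z = zero_low_signals(H.loc[fc.index], fc, threshold=fold_threshold)
    freqs = penetrance_frequencies(fc_z, case_ids, control_ids, threshold=fold_threshold)
    pfcs = penetrance_fold_changes(
        H_z, fc_z, mean_control, case_ids, control_ids, threshold=fold_threshold
    )
    table = pd.concat([freqs, pfcs], axis=1)
    table["mean_control"] = mean_control
    table = call_biomarkers(
        table,
        n_case=len(case_ids),
        n_control=len(control_ids),
        pfc_threshold=pfc_threshold,
        freq_fraction=freq_fraction,
    )
    table.index.name = "protein"
    return PenetranceResult(table=table, fc=fc_z, H=H_z, excluded=excluded)
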