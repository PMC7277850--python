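"""Composite Cy3-BSA-driven normalization.

Cy3-labelled BSA is spotted at constant concentration on every slide, so any
between-sample difference in its intensity reflects scanner/labelling drift
rather than biology.  Normalization is a two-step composite:

1. **Quantile-based reference** — all Cy3-BSA replica net intensities are
   loaded into a spots x samples matrix ``X``; each column is sorted
   independently and the row means of the sorted matrix give the reference
   profile ``<X_i>`` (Bolstad-style quantile reference restricted to the
   control probes).
2. **Intensity-based scaling** — each sample's scaling factor is
   ``k = sum(<X_i>) / sum(X_k)``, the reference total over that sample's
   Cy3-BSA total.  Multiplying every probe of sample *k* by its factor
   equalizes Cy3-BSA totals across samples.

Because sorting preserves column sums, ``sum(<X_i>)`` equals the mean of the
per-sample Cy3-BSA totals — a useful independent check, exploited in the
test-suite oracle.  The factors act on replicate-aggregated per-probe values;
no log transform is applied anywhere (the downstream statistic is
ratio-based on raw RFU).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .array_io import ProbeClass, SampleArray
from .qc import net_intensity


class NormalizationError(ValueError):
    pass


def build_cy3_matrix(samples: list[SampleArray]) -> pd.DataFrame:
    """Assemble the Cy3-BSA spots x samples matrix from slide spot tables.

    Flagged Cy3-BSA replicas are excluded and their cells imputed with the
    mean of the sample's remaining replicas so the matrix has no missing
    cells; a sample whose Cy3-BSA spots are all flagged cannot be normalized
    and raises.
    """
    columns = {}
    for sample in samples:
        spots = sorted(
            sample.spots_of_class(ProbeClass.CY3BSA_CONTROL),
            key=lambda s: (s.block, s.row, s.column),
        )
        if not spots:
            raise NormalizationError(
                f"sample {sample.sample_id}: no Cy3-BSA control spots"
            )
        nets = [
            net_intensity(s.fg_median, s.bg_median) if s.flag >= 0 else np.nan
            for s in spots
        ]
        arr = np.asarray(nets, dtype=float)
        good = ~np.isnan(arr)
        if not good.any():
            raise NormalizationError(
                f"sample {sample.sample_id}: all Cy3-BSA spots flagged; "
                "sample should fail QC instead of being normalized"
            )
        arr[~good] = arr[good].mean()
        columns[sample.sample_id] = arr
    lengths = {len(v) for v in columns.values()}
    if len(lengths) != 1:
        raise NormalizationError("samples have differing Cy3-BSA replica counts")
    return pd.DataFrame(columns)


def quantile_reference(X: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Row means of the column-wise sorted matrix (the reference profile)."""
    arr = np.asarray(X, dtype=float)
    if arr.size == 0:
        raise NormalizationError("empty Cy3-BSA matrix")
    x_sort = np.sort(arr, axis=0)
    return x_sort.mean(axis=1)


@dataclass
class NormalizationFactors:
    """Per-sample multiplicative scaling factors plus the reference profile."""

    factors: pd.Series  # index sample_id, values > 0
    reference: np.ndarray  # <X_i>, ascending


def scaling_factors(X: pd.DataFrame) -> NormalizationFactors:
    """factor_k = sum(reference) / sum of sample k's Cy3-BSA intensities."""
    totals = X.sum(axis=0)
    zero = totals.index[totals <= 0]
    if len(zero):
        raise NormalizationError(
            f"degenerate sample(s) with zero Cy3-BSA total: {list(zero)}"
        )
    ref = quantile_reference(X)
    factors = ref.sum() / totals
    return NormalizationFactors(factors=factors, reference=ref)


def apply_normalization(
    H_raw: pd.DataFrame, factors: NormalizationFactors
) -> pd.DataFrame:
    """Scale every probe value of sample k by factor_k (columns = samples)."""
    missing = [c for c in H_raw.columns if c not in factors.factors.index]
    if missing:
        raise NormalizationError(f"no scaling factor for sample(s): {missing}")
    return H_raw.mul(factors.factors[H_raw.columns], axis=1)


def expression_matrix(samples: list[SampleArray]) -> pd.DataFrame:
    """Antigen-probe x sample matrix of replicate-aggregated net RFUs.

    Requires ``qc.aggregate_replicas`` to have populated ``per_probe_net``.
    """
    antigen_ids = None
    cols = {}
    for sample in samples:
        if not sample.per_probe_net:
            raise NormalizationError(
                f"sample {sample.sample_id}: replicas not aggregated; run QC first"
            )
        ids = sorted(
            {
                s.probe_id
                for s in sample.spots_of_class(ProbeClass.ANTIGEN)
            }
        )
        if antigen_ids is None:
            antigen_ids = ids
        cols[sample.sample_id] = [sample.per_probe_net.get(pid, np.nan) for pid in ids]
    H = pd.DataFrame(cols, index=antigen_ids)
    H.index.name = "protein"
    return H


def normalize_study(samples: list[SampleArray]) -> tuple[pd.DataFrame, NormalizationFactors]:
    """Build the raw expression matrix and return its normalized form."""
    X = build_cy3_matrix(samples)
    factors = scaling_factors(X)
    H = expression_matrix(samples)
    return apply_normalization(H, factors), factors
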