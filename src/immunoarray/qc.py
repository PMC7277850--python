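"""Quality control of protein-array slides.

Three coefficient-of-variation (CV%) gates are evaluated per sample, all
against the same cut-off (15% by default):

1. **IgG dilution linearity** — six two-fold serial dilutions of IgG are
   spotted as positive controls; the observed per-level means, normalized to
   the first level, are divided by the ideal series ``(1/2)**(level-1)`` and
   the CV% of those ratios measures departure from two-fold linearity.
2. **Replicate-spot variability** — mean over probes of the CV% across a
   probe's four replicate spots.
3. **Cy3-BSA replica variability** — CV% across the constant-concentration
   Cy3-BSA control spots.

CV% is the sample (n-1) standard deviation over the mean, times 100.  Net
intensity is foreground minus background, clipped at zero.  Replicas are
aggregated by the mean over unflagged spots (median available via
``method="median"``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .array_io import ProbeClass, SampleArray


class QCError(ValueError):
    """A QC metric could not be computed from the available spots."""


DEFAULT_CV_THRESHOLD = 15.0  # percent

IDEAL_IGG_RATIOS = tuple(0.5 ** (level - 1) for level in range(1, 7))


def net_intensity(fg: float, bg: float) -> float:
    """Background-subtracted spot intensity, clipped at zero."""
    if fg < 0 or bg < 0:
        raise ValueError("intensities must be non-negative")
    return max(fg - bg, 0.0)


def cv_percent(values) -> float:
    """Coefficient of variation in percent: sample SD (n-1) / mean x 100."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("CV%% needs at least 2 values, got %d" % arr.size)
    mean = arr.mean()
    if mean == 0:
        raise QCError("CV% undefined: mean of values is zero")
    return float(arr.std(ddof=1) / mean * 100.0)


def aggregate_replicas(
    sample: SampleArray, method: str = "mean"
) -> dict[str, float]:
    """Aggregate net intensities of each probe's replicate spots.

    Flagged spots (flag < 0) are excluded; a probe whose replicas are all
    flagged is recorded as missing (NaN) rather than raising — missingness
    is data, not an error.  The result is also stored on
    ``sample.per_probe_net``.
    """
    agg = np.mean if method == "mean" else np.median
    nets: dict[str, list[float]] = {}
    seen: dict[str, None] = {}
    for s in sample.spots:
        seen.setdefault(s.probe_id, None)
        if s.flag < 0:
            continue
        nets.setdefault(s.probe_id, []).append(net_intensity(s.fg_median, s.bg_median))
    out = {
        pid: (float(agg(nets[pid])) if pid in nets else math.nan) for pid in seen
    }
    sample.per_probe_net = out
    return out


def _unflagged_nets(spots) -> list[float]:
    return [net_intensity(s.fg_median, s.bg_median) for s in spots if s.flag >= 0]


def igg_dilution_cv(sample: SampleArray) -> float:
    """CV% of the observed/ideal ratios over the six IgG dilution levels.

    The observed per-level mean net RFUs are normalized by the level-1 value,
    so the metric is invariant to overall slide brightness; 0 means a perfect
    two-fold series.
    """
    by_level: dict[int, list[float]] = {}
    for s in sample.spots_of_class(ProbeClass.IGG_CONTROL):
        if s.flag >= 0:
            by_level.setdefault(s.igg_level, []).append(
                net_intensity(s.fg_median, s.bg_median)
            )
    missing = sorted(set(range(1, 7)) - set(by_level))
    if missing:
        raise QCError(f"sample {sample.sample_id}: missing IgG levels {missing}")
    observed = np.array([np.mean(by_level[level]) for level in range(1, 7)])
    if observed[0] <= 0:
        raise QCError(f"sample {sample.sample_id}: IgG level-1 mean is zero")
    ratios = (observed / observed[0]) / np.asarray(IDEAL_IGG_RATIOS)
    return cv_percent(ratios)


def replicate_spot_cv(sample: SampleArray, min_mean: float = 0.0) -> float:
    """Mean over antigen probes of the CV% across each probe's replicas.

    Probes with fewer than two unflagged replicas or non-positive mean net
    intensity are skipped (their CV is undefined).
    """
    by_probe: dict[str, list[float]] = {}
    for s in sample.spots_of_class(ProbeClass.ANTIGEN):
        if s.flag >= 0:
            by_probe.setdefault(s.probe_id, []).append(
                net_intensity(s.fg_median, s.bg_median)
            )
    cvs = [
        cv_percent(v)
        for v in by_probe.values()
        if len(v) >= 2 and np.mean(v) > min_mean
    ]
    if not cvs:
        raise QCError(f"sample {sample.sample_id}: no probe with computable replica CV")
    return float(np.mean(cvs))


def cy3bsa_replica_cv(sample: SampleArray) -> float:
    """CV% across all unflagged Cy3-BSA control replicas of the slide."""
    nets = _unflagged_nets(sample.spots_of_class(ProbeClass.CY3BSA_CONTROL))
    if len(nets) < 2:
        raise QCError(
            f"sample {sample.sample_id}: fewer than 2 unflagged Cy3-BSA spots"
        )
    return cv_percent(nets)


METRICS = ("igg_dilution_cv", "replicate_spot_cv", "cy3bsa_replica_cv")


@dataclass
class QCReport:
    """Per-sample CV% metrics with pass/fail gates against a common threshold."""

    per_sample: pd.DataFrame  # index sample_id, columns METRICS + passed/failed_metrics
    threshold: float = DEFAULT_CV_THRESHOLD

    @property
    def study_means(self) -> pd.Series:
        return self.per_sample[list(METRICS)].mean()

    @property
    def failing_samples(self) -> list[str]:
        return list(self.per_sample.index[~self.per_sample["passed"]])

    @property
    def all_passed(self) -> bool:
        return bool(self.per_sample["passed"].all())


def qc_gate(metrics: pd.DataFrame, threshold: float = DEFAULT_CV_THRESHOLD) -> QCReport:
    """Gate each sample: pass iff every CV metric is <= threshold (percent)."""
    df = metrics.copy()
    df["passed"] = (df[list(METRICS)] <= threshold).all(axis=1)
    df["failed_metrics"] = [
        ";".join(m for m in METRICS if row[m] > threshold)
        for _, row in df.iterrows()
    ]
    return QCReport(per_sample=df, threshold=threshold)


def run_qc(
    samples: list[SampleArray],
    threshold: float = DEFAULT_CV_THRESHOLD,
    aggregation: str = "mean",
) -> QCReport:
    """Aggregate replicas and evaluate all three CV gates for every sample."""
    rows = {}
    for sample in samples:
        aggregate_replicas(sample, method=aggregation)
        rows[sample.sample_id] = {
            "igg_dilution_cv": igg_dilution_cv(sample),
            "replicate_spot_cv": replicate_spot_cv(sample),
            "cy3bsa_replica_cv": cy3bsa_replica_cv(sample),
        }
    metrics = pd.DataFrame.from_dict(rows, orient="index")
    metrics.index.name = "sample_id"
    return qc_gate(metrics, threshold=threshold)
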