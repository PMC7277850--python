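"""Synthetic Immunome-style studies with known ground truth.

Generates a complete study — GAL layout, one GPR spot table per sample, a
sample sheet and a ground-truth file — whose statistical structure emulates
a KREX Immunome slide: ~1600 antigen probes spotted once per block across 4
replicate sub-arrays (quadruplicate overall), a 6-step two-fold IgG dilution
control series, constant-concentration Cy3-BSA control replicas, and
printing-buffer spots.

The generative model, per sample *s* and antigen *p*:

* baseline_p ~ LogNormal(baseline_log_mean, baseline_log_sd), shared across
  samples (RFU distributions are right-skewed);
* scale_s ~ Uniform(sample_scale_range), a multiplicative per-sample drift
  that the Cy3-BSA normalization is supposed to remove;
* true level = baseline_p * scale_s, times the planted fold for probes where
  *s* is a penetrant case;
* each replicate spot's foreground = true * (1 + N(0, spot_noise_cv)) plus
  its own background draw N(background_mean_rfu, background_sd_rfu), floored
  at 0; the background draw is also written as the spot's background column,
  so noise-free net intensities recover the true level exactly.

IgG spots follow the exact two-fold series x * (1/2)**(level-1) (times the
sample scale); Cy3-BSA spots share the single true level cy3bsa_mean_rfu *
scale_s.  Intensities are serialized as rounded integers by default
(scanner convention); ``round_intensities=False`` keeps exact floats for
closed-form tests.

Everything is driven by one seeded generator: a fixed seed yields
byte-identical output files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .array_io import (
    ArrayLayout,
    NamingConvention,
    ProbeClass,
    SampleArray,
    SampleSheet,
    SampleSheetRow,
    SpotRecord,
    write_gal,
    write_gpr,
    write_sample_sheet,
)
from .reference_data import (  # noqa: F401  (fixture API lives here too)
    biomarker_summary,
    case_biomarker_lists,
    disease_associations,
    disease_targets,
    discordant_proteins,
    per_patient_frequencies,
)

N_BLOCKS = 4  # replicate sub-arrays per slide


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class PlantedBiomarker:
    """Ground truth for one case-specific autoantibody elevation."""

    probe_id: str
    fold: float  # case elevation multiplier, > 1
    penetrance: float  # share of cases elevated, in (0, 1]

    def __post_init__(self) -> None:
        if not self.fold > 1:
            raise ConfigError(f"{self.probe_id}: fold must be > 1")
        if not 0 < self.penetrance <= 1:
            raise ConfigError(f"{self.probe_id}: penetrance must be in (0, 1]")

    def n_penetrant(self, n_case: int) -> int:
        n = math.floor(self.penetrance * n_case + 0.5)  # round half up
        if n < 1:
            raise ConfigError(
                f"{self.probe_id}: penetrance {self.penetrance} rounds to zero "
                f"penetrant cases for n_case={n_case}"
            )
        return n


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design and noise parameters of the generator.

    Defaults mirror the original study design: 9 cases vs 3 controls on a
    1600-antigen array, ~10% replicate-spot noise, and per-sample scale
    drift in (0.7, 1.4).  ``igg_base_concentration_rfu`` is the undiluted
    IgG level (the "x" of the two-fold series).
    """

    n_case: int = 9
    n_control: int = 3
    n_antigens: int = 1600
    igg_base_concentration_rfu: float = 40000.0
    igg_replicas_per_block: int = 1
    cy3bsa_replicas_per_block: int = 4
    cy3bsa_mean_rfu: float = 20000.0
    buffer_spots_per_block: int = 4
    baseline_log_mean: float = 5.0  # log-RFU; exp(5) ~ 148 RFU median baseline
    baseline_log_sd: float = 0.8
    spot_noise_cv: float = 0.10
    sample_scale_range: tuple[float, float] = (0.7, 1.4)
    background_mean_rfu: float = 50.0
    background_sd_rfu: float = 10.0
    planted: tuple[PlantedBiomarker, ...] = ()
    round_intensities: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_case", "n_control", "n_antigens",
                     "igg_replicas_per_block", "cy3bsa_replicas_per_block"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if self.spot_noise_cv < 0:
            raise ConfigError("spot_noise_cv must be >= 0")
        lo, hi = self.sample_scale_range
        if not 0 < lo <= hi:
            raise ConfigError("sample_scale_range must satisfy 0 < low <= high")
        antigens = set(antigen_ids(self.n_antigens))
        for pb in self.planted:
            if pb.probe_id not in antigens:
                raise ConfigError(
                    f"planted probe {pb.probe_id!r} is not among the antigen probes"
                )
            pb.n_penetrant(self.n_case)


def antigen_ids(n_antigens: int) -> list[str]:
    return [f"AG{i:04d}" for i in range(1, n_antigens + 1)]


def build_layout(config: SyntheticConfig) -> ArrayLayout:
    """Construct the slide layout: every probe once per block, row-major grid."""
    per_block: list[tuple[str, str]] = [(pid, pid) for pid in antigen_ids(config.n_antigens)]
    for level in range(1, 7):
        for r in range(1, config.igg_replicas_per_block + 1):
            per_block.append((f"IgG{level}_rep{r}", f"IgG{level}_rep{r}"))
    for r in range(1, config.cy3bsa_replicas_per_block + 1):
        per_block.append((f"Cy3BSA_rep{r}", f"Cy3BSA_rep{r}"))
    for r in range(1, config.buffer_spots_per_block + 1):
        per_block.append((f"BUFFER_{r}", f"BUFFER_{r}"))

    n_spots = len(per_block)
    n_columns = math.ceil(math.sqrt(n_spots))
    n_rows = math.ceil(n_spots / n_columns)
    naming = NamingConvention()
    positions: dict[tuple[int, int, int], str] = {}
    rows_out: list[tuple[int, int, int, str, str]] = []
    for block in range(1, N_BLOCKS + 1):
        for idx, (pid, name) in enumerate(per_block):
            row, col = divmod(idx, n_columns)
            positions[(block, row + 1, col + 1)] = pid
            rows_out.append((block, row + 1, col + 1, pid, name))

    catalogue: dict[str, list] = {}
    for _, _, _, pid, name in rows_out:
        if pid not in catalogue:
            cls, level = naming.classify(name)
            catalogue[pid] = [name, cls, level, 0]
        catalogue[pid][3] += 1
    from .array_io import ProbeInfo

    layout = ArrayLayout(
        probes=[ProbeInfo(pid, *vals) for pid, vals in catalogue.items()],
        n_blocks=N_BLOCKS,
        n_rows=n_rows,
        n_columns=n_columns,
        positions=positions,
    )
    layout._gal_rows = rows_out  # type: ignore[attr-defined]
    return layout


@dataclass
class GroundTruth:
    """What was planted: per biomarker, its fold and the penetrant case ids."""

    baselines: pd.Series  # antigen baseline RFU
    sample_scales: pd.Series  # per-sample multiplicative drift
    planted: list[PlantedBiomarker]
    penetrant_cases: dict[str, list[str]]  # probe_id -> case sample ids

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "probe_id": [pb.probe_id for pb in self.planted],
                "fold": [pb.fold for pb in self.planted],
                "penetrance": [pb.penetrance for pb in self.planted],
                "baseline_rfu": [
                    self.baselines[pb.probe_id] for pb in self.planted
                ],
                "penetrant_cases": [
                    ";".join(self.penetrant_cases[pb.probe_id])
                    for pb in self.planted
                ],
            }
        )


def _sample_ids(config: SyntheticConfig) -> tuple[list[str], list[str]]:
    cases = [f"case_{i:02d}" for i in range(1, config.n_case + 1)]
    controls = [f"control_{i:02d}" for i in range(1, config.n_control + 1)]
    return cases, controls


def _case_ethnicities(n_case: int) -> list[str]:
    # Two-ethnicity cohort in a 2:1 ratio, mirroring the 6 Malay / 3 Chinese
    # split of the original cases; used by the sub-cohort analyses.
    n_minor = n_case // 3
    return ["Malay"] * (n_case - n_minor) + ["Chinese"] * n_minor


def simulate_study(
    config: SyntheticConfig,
) -> tuple[ArrayLayout, list[SampleArray], GroundTruth]:
    """Simulate a study in memory; one seeded RNG drives everything."""
    rng = np.random.default_rng(config.seed)
    layout = build_layout(config)
    cases, controls = _sample_ids(config)
    ethnicities = dict(zip(cases, _case_ethnicities(config.n_case)))

    ag_ids = antigen_ids(config.n_antigens)
    baselines = pd.Series(
        rng.lognormal(config.baseline_log_mean, config.baseline_log_sd, len(ag_ids)),
        index=ag_ids,
    )
    lo, hi = config.sample_scale_range
    all_ids = cases + controls
    scales = pd.Series(rng.uniform(lo, hi, len(all_ids)), index=all_ids)

    penetrant: dict[str, list[str]] = {}
    for pb in config.planted:
        order = list(rng.permutation(config.n_case))
        chosen = sorted(order[: pb.n_penetrant(config.n_case)])
        penetrant[pb.probe_id] = [cases[i] for i in chosen]

    fold_of: dict[str, dict[str, float]] = {
        pb.probe_id: {cid: pb.fold for cid in penetrant[pb.probe_id]}
        for pb in config.planted
    }

    gal_rows = layout._gal_rows  # type: ignore[attr-defined]
    naming = NamingConvention()
    samples: list[SampleArray] = []
    for sid in all_ids:
        scale = float(scales[sid])
        spots: list[SpotRecord] = []
        n = len(gal_rows)
        eps = rng.normal(0.0, config.spot_noise_cv, n) if config.spot_noise_cv > 0 else np.zeros(n)
        bgs = np.maximum(
            rng.normal(config.background_mean_rfu, config.background_sd_rfu, n), 0.0
        )
        for (block, row, col, pid, name), e, bg in zip(gal_rows, eps, bgs):
            cls, level = naming.classify(name)
            if cls is ProbeClass.ANTIGEN:
                true = baselines[pid] * scale * fold_of.get(pid, {}).get(sid, 1.0)
            elif cls is ProbeClass.IGG_CONTROL:
                true = config.igg_base_concentration_rfu * 0.5 ** (level - 1) * scale
            elif cls is ProbeClass.CY3BSA_CONTROL:
                true = config.cy3bsa_mean_rfu * scale
            else:  # buffer
                true = 0.0
            fg = max(true * (1.0 + e) + bg, 0.0)
            if config.round_intensities:
                fg, bg = round(fg), round(bg)
            spots.append(
                SpotRecord(
                    block=block,
                    column=col,
                    row=row,
                    probe_name=name,
                    probe_id=pid,
                    probe_class=cls,
                    igg_level=level,
                    fg_median=float(fg),
                    bg_median=float(bg),
                    flag=0,
                )
            )
        samples.append(
            SampleArray(
                sample_id=sid,
                group="case" if sid in ethnicities else "control",
                ethnicity=ethnicities.get(sid),
                spots=spots,
            )
        )

    truth = GroundTruth(
        baselines=baselines,
        sample_scales=scales,
        planted=list(config.planted),
        penetrant_cases=penetrant,
    )
    return layout, samples, truth


def generate_study(config: SyntheticConfig, out_dir: str | Path) -> SampleSheet:
    """Write a complete study (GAL, GPRs, sample sheet, ground truth) to disk."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    layout, samples, truth = simulate_study(config)
    write_gal(layout._gal_rows, out / "layout.gal")  # type: ignore[attr-defined]
    rows = []
    for sample in samples:
        gpr = f"{sample.sample_id}.gpr"
        write_gpr(sample, out / gpr)
        rows.append(
            SampleSheetRow(
                sample_id=sample.sample_id,
                gpr_path=gpr,
                group=sample.group,
                ethnicity=sample.ethnicity,
            )
        )
    sheet = SampleSheet(rows=rows)
    write_sample_sheet(sheet, out / "samples.csv")
    truth.to_frame().to_csv(out / "ground_truth.csv", index=False)
    return sheet


def with_planted(
    config: SyntheticConfig,
    n_planted: int,
    fold: float,
    penetrance: float,
    first_index: int = 1,
) -> SyntheticConfig:
    """Convenience: plant *n_planted* biomarkers on consecutive antigen probes."""
    planted = tuple(
        PlantedBiomarker(f"AG{i:04d}", fold=fold, penetrance=penetrance)
        for i in range(first_index, first_index + n_planted)
    )
    return replace(config, planted=planted)
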