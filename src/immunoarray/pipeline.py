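"""End-to-end pipeline: load -> QC -> normalize -> penetrance -> cluster/annotate.

Each stage writes its table under the run's output directory and the run
closes with a JSON manifest (tool version, configuration hash, input
checksums, per-stage outputs and timings).  By default the run halts when any
sample fails a QC gate; ``allow_qc_failures`` overrides the halt and carries
the failing samples forward.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__
from .array_io import ProbeClass, load_study, read_gal, read_sample_sheet
from .normalization import normalize_study
from .penetrance import background_floor, score_penetrance
from .qc import DEFAULT_CV_THRESHOLD, net_intensity, run_qc
from .stratification import (
    annotate_disease,
    cluster_heatmap,
    disease_summary,
    linkage_to_newick,
)

log = logging.getLogger("immunoarray")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """All knobs of a pipeline run; every published threshold is a field."""

    sample_sheet: str
    gal: str
    out_dir: str
    qc_threshold: float = DEFAULT_CV_THRESHOLD  # percent
    fold_threshold: float = 2.0  # individual-FC cut
    pfc_threshold: float = 2.0  # biomarker call, strict >
    freq_fraction: float = 0.10  # of case count, ceiling
    aggregation: str = "mean"  # replica aggregation: mean|median
    use_background_floor: bool = False
    channel: int = 532
    allow_qc_failures: bool = False
    write_heatmap: bool = True


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in order; returns (and writes) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "immunoarray",
        "version": __version__,
        "config": asdict(config),
        "config_hash": hashlib.sha256(
            json.dumps(asdict(config), sort_keys=True).encode()
        ).hexdigest(),
        "inputs": {},
        "stages": [],
    }

    def stage(name: str):
        t0 = time.perf_counter()

        def done(outputs: list[str]):
            manifest["stages"].append(
                {
                    "name": name,
                    "outputs": outputs,
                    "seconds": round(time.perf_counter() - t0, 3),
                }
            )
            log.info("stage %s done (%d outputs)", name, len(outputs))

        return done

    # load
    done = stage("load")
    sheet_path, gal_path = Path(config.sample_sheet), Path(config.gal)
    try:
        sheet = read_sample_sheet(sheet_path)
        layout = read_gal(gal_path)
        samples = load_study(
            sheet, layout, base_dir=sheet_path.parent, channel=config.channel
        )
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise PipelineError("load", str(exc)) from exc
    manifest["inputs"] = {
        "sample_sheet": _sha256(sheet_path),
        "gal": _sha256(gal_path),
        "n_samples": len(samples),
    }
    done([])

    # qc
    done = stage("qc")
    try:
        report = run_qc(
            samples, threshold=config.qc_threshold, aggregation=config.aggregation
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("qc", str(exc)) from exc
    qc_path = out / "qc_report.csv"
    report.per_sample.to_csv(qc_path)
    done([qc_path.name])
    if not report.all_passed:
        msg = f"samples failing QC gates: {report.failing_samples}"
        if not config.allow_qc_failures:
            raise PipelineError("qc", msg)
        log.warning("%s (continuing: allow_qc_failures)", msg)

    # normalize
    done = stage("normalize")
    try:
        H, factors = normalize_study(samples)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("normalize", str(exc)) from exc
    norm_path = out / "normalized_matrix.tsv"
    H.to_csv(norm_path, sep="\t")
    factors.factors.rename("scaling_factor").to_csv(out / "scaling_factors.tsv", sep="\t")
    done([norm_path.name, "scaling_factors.tsv"])

    # penetrance
    done = stage("penetrance")
    floor = None
    if config.use_background_floor:
        buffer_nets = [
            net_intensity(s.fg_median, s.bg_median)
            for sample in samples
            for s in sample.spots_of_class(ProbeClass.BUFFER)
            if s.flag >= 0
        ]
        floor = background_floor(buffer_nets)
    try:
        result = score_penetrance(
            H,
            case_ids=sheet.case_ids,
            control_ids=sheet.control_ids,
            fold_threshold=config.fold_threshold,
            pfc_threshold=config.pfc_threshold,
            freq_fraction=config.freq_fraction,
            floor=floor,
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("penetrance", str(exc)) from exc
    pen_path = out / "penetrance.tsv"
    cols = ["freq_case", "freq_control", "freq_diff", "pfc_case", "pfc_control",
            "mean_control", "is_biomarker", "rank"]
    result.table[cols].to_csv(pen_path, sep="\t")
    result.biomarkers[cols].to_csv(out / "biomarkers.tsv", sep="\t")
    done([pen_path.name, "biomarkers.tsv"])

    # cluster + annotate
    done = stage("stratify")
    outputs = []
    signature = sorted(result.signature)
    if len(signature) >= 2 and result.fc.shape[1] >= 2:
        cluster = cluster_heatmap(
            result.fc,
            biomarkers=signature,
            image_path=(out / "heatmap.png") if config.write_heatmap else None,
        )
        if cluster.sample_linkage is not None:
            (out / "samples.nwk").write_text(
                linkage_to_newick(cluster.sample_linkage, list(cluster.matrix.columns)) + "\n"
            )
            outputs.append("samples.nwk")
        if cluster.protein_linkage is not None:
            (out / "proteins.nwk").write_text(
                linkage_to_newick(cluster.protein_linkage, list(cluster.matrix.index)) + "\n"
            )
            outputs.append("proteins.nwk")
        if config.write_heatmap:
            outputs.append("heatmap.png")
    else:
        log.warning("fewer than 2 biomarkers or samples; clustering skipped")
    annotate_disease(signature).to_csv(out / "annotation.tsv", sep="\t", index=False)
    disease_summary(signature).to_csv(out / "disease_summary.tsv", sep="\t", index=False)
    outputs += ["annotation.tsv", "disease_summary.tsv"]
    done(outputs)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
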