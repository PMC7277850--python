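"""Generator determinism, closed-form recovery, and the packaged study tables."""

import hashlib
from pathlib import Path

import numpy as np
import pytest

from immunoarray import normalize_study, run_qc, score_penetrance
from immunoarray.array_io import ProbeClass
from immunoarray.qc import net_intensity
from immunoarray.reference_data import (
    biomarker_summary,
    case_biomarker_lists,
    disease_targets,
    discordant_proteins,
    per_patient_frequencies,
)
from immunoarray.synthetic_data import (
    ConfigError,
    PlantedBiomarker,
    SyntheticConfig,
    generate_study,
    simulate_study,
    with_planted,
)

from .conftest import group_ids, small_config


def _hashes(d: Path) -> dict[str, str]:
    return {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(d.iterdir())
    }


def test_seeded_generation_is_byte_identical(tmp_path):
    cfg = with_planted(small_config(seed=7), 2, fold=4.0, penetrance=0.5)
    generate_study(cfg, tmp_path / "a")
    generate_study(cfg, tmp_path / "b")
    ha, hb = _hashes(tmp_path / "a"), _hashes(tmp_path / "b")
    assert ha == hb
    assert set(ha) == {"layout.gal", "samples.csv", "ground_truth.csv"} | {
        f"case_{i:02d}.gpr" for i in range(1, 10)
    } | {f"control_{i:02d}.gpr" for i in range(1, 4)}


def test_different_seed_changes_output(tmp_path):
    generate_study(small_config(seed=1), tmp_path / "a")
    generate_study(small_config(seed=2), tmp_path / "b")
    assert _hashes(tmp_path / "a")["case_01.gpr"] != _hashes(tmp_path / "b")["case_01.gpr"]


def test_noise_free_planted_fc_is_exact(noise_free_study):
    """No noise, float serialization: pipeline FC of a planted probe = fold."""
    cfg, _, samples, truth = noise_free_study
    cases, controls = group_ids(samples)
    run_qc(samples)
    H, _ = normalize_study(samples)
    result = score_penetrance(H, cases, controls)
    for pb in truth.planted:
        fcs = result.fc.loc[pb.probe_id, cases]
        assert fcs.to_numpy() == pytest.approx(np.full(len(cases), pb.fold), rel=1e-9)
        assert result.table.loc[pb.probe_id, "pfc_case"] == pytest.approx(5.0, rel=1e-9)


def test_igg_series_is_exact_two_fold(noise_free_study):
    """Generated IgG spot levels follow x:(1/2)^(level-1); terminal ratio 1/32."""
    _, _, samples, _ = noise_free_study
    sample = samples[0]
    by_level = {}
    for s in sample.spots_of_class(ProbeClass.IGG_CONTROL):
        by_level.setdefault(s.igg_level, []).append(net_intensity(s.fg_median, s.bg_median))
    means = {lvl: np.mean(v) for lvl, v in by_level.items()}
    for lvl in range(1, 7):
        assert means[lvl] / means[1] == pytest.approx(0.5 ** (lvl - 1), rel=1e-12)
    assert means[6] / means[1] == pytest.approx(0.03125, rel=1e-12)


def test_ground_truth_consistent_with_intensities(noise_free_study):
    """Noise-free case means re-derived from spots equal baseline x scale x fold."""
    _, _, samples, truth = noise_free_study
    pb = truth.planted[0]
    for sample in samples:
        nets = [
            net_intensity(s.fg_median, s.bg_median)
            for s in sample.spots
            if s.probe_id == pb.probe_id
        ]
        fold = pb.fold if sample.sample_id in truth.penetrant_cases[pb.probe_id] else 1.0
        expected = truth.baselines[pb.probe_id] * truth.sample_scales[sample.sample_id] * fold
        assert np.mean(nets) == pytest.approx(expected, rel=1e-9)


def test_planted_probe_must_be_an_antigen():
    with pytest.raises(ConfigError, match="not among the antigen probes"):
        SyntheticConfig(
            n_antigens=5, planted=(PlantedBiomarker("AG9999", 5.0, 1.0),)
        )


def test_penetrance_must_round_to_a_case():
    with pytest.raises(ConfigError, match="rounds to zero"):
        SyntheticConfig(
            n_case=4, n_antigens=5,
            planted=(PlantedBiomarker("AG0001", 5.0, 0.05),),
        )


def test_invalid_planted_parameters():
    with pytest.raises(ConfigError, match="fold"):
        PlantedBiomarker("AG0001", fold=1.0, penetrance=0.5)
    with pytest.raises(ConfigError, match="penetrance"):
        PlantedBiomarker("AG0001", fold=3.0, penetrance=0.0)


def test_generated_study_loads_and_passes_qc(tmp_path):
    from immunoarray import load_study, read_gal, read_sample_sheet

    cfg = small_config(seed=13)
    generate_study(cfg, tmp_path)
    sheet = read_sample_sheet(tmp_path / "samples.csv")
    layout = read_gal(tmp_path / "layout.gal")
    samples = load_study(sheet, layout, base_dir=tmp_path)
    assert len(samples) == cfg.n_case + cfg.n_control
    assert run_qc(samples).all_passed


# --- packaged study tables -------------------------------------------------


def test_biomarker_summary_shape_and_rows():
    t = biomarker_summary()
    assert len(t) == 23
    hcls1 = t[t.protein == "HCLS1"].iloc[0]
    assert (hcls1.freq_case, hcls1.pfc_case, hcls1.mean_control) == (5, 5.33, 157.83)
    assert t[t.protein == "TPM1"].iloc[0].mean_control == 248.36
    assert t.pfc_case.max() == 13.38 and t.pfc_case.min() == 2.16


def test_per_patient_lists():
    lists = case_biomarker_lists()
    assert len(lists) == 9
    assert lists["025711"] == {"HCLS1", "HOOK1"}
    assert lists["025757"] == {"MAPKAPK3", "TSPY3", "PFKFB4"}
    # transcription fix-ups: no duplicates, run-together tokens split
    assert "NR2E3" in lists["025749"] and "KRT19" in lists["025749"]


def test_counted_frequencies_flag_discordance():
    freqs = per_patient_frequencies()
    assert freqs["HCLS1"] == 5
    disc = discordant_proteins()
    assert "MED22" in disc and "EPS15" in disc and "TRAF1" in disc
    assert "HCLS1" not in disc and "DBNL" not in disc
    assert len(disc) == 14


def test_disease_targets():
    assert disease_targets("Thalassemia") == {"EPS15", "HCLS1", "KRT19", "TPM1"}
    assert disease_targets("Beta-thal") == {"HCLS1", "TPM1"}
    assert disease_targets("not a disease") == frozenset()
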