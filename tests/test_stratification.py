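"""Ward clustering, sub-cohort signatures, and disease annotation."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist

from immunoarray import normalize_study, run_qc, score_penetrance
from immunoarray.reference_data import biomarker_summary
from immunoarray.stratification import (
    StratificationError,
    annotate_disease,
    cluster_heatmap,
    disease_summary,
    linkage_to_newick,
    read_association_tsv,
    subcohort_signature,
    write_association_tsv,
)
from immunoarray.synthetic_data import simulate_study, with_planted

from .conftest import group_ids, small_config


def test_identical_samples_merge_first():
    M = pd.DataFrame(
        {"a": [1.0, 2.0], "b": [1.0, 2.0], "c": [9.0, 9.0]},
        index=["p1", "p2"],
    )
    res = cluster_heatmap(M)
    first = res.sample_linkage[0]
    assert sorted(first[:2]) == [0, 1] and first[2] == 0.0  # a,b at distance 0


def test_three_point_linkage_matches_hand_computed_ward():
    """1-D points {0, 1, 5}: first merge (0,1) at 1; then Ward height for
    merging {0,1} with {5} is sqrt(2*2/3) * |0.5 - 5| = 5.1962..."""
    M = pd.DataFrame({"a": [0.0], "b": [1.0], "c": [5.0]}, index=["p"])
    # protein axis has one row; cluster samples only
    res = cluster_heatmap(pd.concat([M, M * 0]),)
    Z = res.sample_linkage
    assert Z[0][2] == pytest.approx(1.0)
    assert Z[1][2] == pytest.approx(np.sqrt(4.0 / 3.0) * 4.5)


def test_permuting_rows_leaves_heights_unchanged(noisy_study):
    _, _, samples, truth = noisy_study
    cases, controls = group_ids(samples)
    run_qc(samples)
    H, _ = normalize_study(samples)
    res = score_penetrance(H, cases, controls)
    marks = sorted(res.signature)
    a = cluster_heatmap(res.fc, biomarkers=marks)
    b = cluster_heatmap(res.fc.iloc[::-1], biomarkers=marks)
    assert np.allclose(a.sample_linkage[:, 2], b.sample_linkage[:, 2])


def test_planted_separation_splits_cases_from_controls():
    """Fold 10, penetrance 1, 5% noise: top split = case/control status."""
    cfg = with_planted(
        small_config(spot_noise_cv=0.05, seed=21), n_planted=4, fold=10.0, penetrance=1.0
    )
    _, samples, _ = simulate_study(cfg)
    cases, controls = group_ids(samples)
    run_qc(samples)
    H, _ = normalize_study(samples)
    res = score_penetrance(H, cases, controls)
    cluster = cluster_heatmap(res.fc, biomarkers=sorted(res.signature))
    labels = cluster.cut_samples(k=2)
    assert labels[cases].nunique() == 1
    assert labels[controls].nunique() == 1
    assert labels[cases[0]] != labels[controls[0]]


def test_single_axis_too_small_is_skipped():
    M = pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 1.0]}, index=["p1", "p2"])
    res = cluster_heatmap(M, biomarkers=["p1"])
    assert res.protein_linkage is None and res.protein_order == ["p1"]
    assert res.sample_linkage is not None


def test_empty_matrix_errors():
    with pytest.raises(StratificationError):
        cluster_heatmap(pd.DataFrame())


def test_heatmap_image_written(tmp_path):
    M = pd.DataFrame(np.arange(12.0).reshape(3, 4),
                     index=list("pqr"), columns=list("abcd"))
    cluster_heatmap(M, image_path=tmp_path / "h.png")
    assert (tmp_path / "h.png").stat().st_size > 0


def test_newick_serialization_round_trips_leaf_names():
    M = pd.DataFrame({"a": [0.0, 0], "b": [1.0, 0], "c": [5.0, 0]}, index=["p", "q"])
    res = cluster_heatmap(M)
    nwk = linkage_to_newick(res.sample_linkage, list(M.columns))
    assert nwk.endswith(";") and {"a", "b", "c"} <= set(nwk.replace("(", " ").replace(")", " ").replace(",", " ").replace(":", " ").split())


# --- sub-cohort signatures -------------------------------------------------


def _study_matrix(noisy_study):
    _, _, samples, truth = noisy_study
    cases, controls = group_ids(samples)
    run_qc(samples)
    H, _ = normalize_study(samples)
    return H, cases, controls, truth


def test_full_subset_reproduces_full_signature(noisy_study):
    H, cases, controls, _ = _study_matrix(noisy_study)
    comp, full, sub = subcohort_signature(H, cases, controls, cases)
    assert comp.signature_subcohort == comp.signature_full == full.signature
    assert comp.unique_to_full == comp.unique_to_subcohort == set()
    assert full.table.equals(sub.table)


def test_overlap_partition_is_a_partition(noisy_study):
    H, cases, controls, _ = _study_matrix(noisy_study)
    comp, *_ = subcohort_signature(H, cases, controls, cases[:4])
    union = comp.signature_full | comp.signature_subcohort
    parts = [comp.overlap, comp.unique_to_full, comp.unique_to_subcohort]
    assert set.union(*parts) == union
    assert not (comp.unique_to_subcohort & comp.signature_full)
    assert not (comp.overlap & comp.unique_to_full)


def test_excluding_all_penetrant_cases_moves_probe_to_unique_full():
    cfg = with_planted(small_config(seed=33), n_planted=1, fold=8.0, penetrance=0.3)
    _, samples, truth = simulate_study(cfg)
    cases, controls = group_ids(samples)
    run_qc(samples)
    H, _ = normalize_study(samples)
    probe = truth.planted[0].probe_id
    penetrant = set(truth.penetrant_cases[probe])
    remaining = [c for c in cases if c not in penetrant]
    comp, *_ = subcohort_signature(H, cases, controls, remaining)
    assert probe in comp.unique_to_full


def test_empty_subset_errors(noisy_study):
    H, cases, controls, _ = _study_matrix(noisy_study)
    with pytest.raises(StratificationError):
        subcohort_signature(H, cases, controls, [])


# --- disease annotation ----------------------------------------------------


def test_annotation_counts_against_reference_table():
    signature = set(biomarker_summary().protein)
    summary = disease_summary(signature).set_index("disease")
    assert summary.loc["Thalassemia", "n_targets"] == 4
    ann = annotate_disease(signature)
    novel = ann[ann.n_diseases == 0]
    assert len(novel) == 19


def test_annotate_empty_list():
    assert annotate_disease([]).empty


def test_association_tsv_round_trip(tmp_path):
    table = {"D1": frozenset({"A", "B"}), "D2": frozenset({"C"})}
    p = write_association_tsv(table, tmp_path / "t.tsv")
    assert read_association_tsv(p) == table
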