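"""GAL/GPR/sample-sheet IO: round-trips, name-convention parsing, errors."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from immunoarray.array_io import (
    FormatError,
    LayoutError,
    NamingConvention,
    ProbeClass,
    SampleArray,
    SampleSheet,
    SampleSheetRow,
    SpotRecord,
    read_gal,
    read_gpr,
    read_sample_sheet,
    write_gal,
    write_gpr,
    write_sample_sheet,
)
from immunoarray.synthetic_data import SyntheticConfig, build_layout, simulate_study

from .conftest import small_config


@pytest.mark.parametrize(
    "name, expected_class, expected_level",
    [
        ("IgG1", ProbeClass.IGG_CONTROL, 1),
        ("IgG3_rep2", ProbeClass.IGG_CONTROL, 3),
        ("IgG6_rep1", ProbeClass.IGG_CONTROL, 6),
        ("Cy3BSA_rep4", ProbeClass.CY3BSA_CONTROL, None),
        ("BUFFER_1", ProbeClass.BUFFER, None),
        ("EMPTY", ProbeClass.BUFFER, None),
        ("HCLS1", ProbeClass.ANTIGEN, None),
        ("IgG7ish", ProbeClass.ANTIGEN, None),  # only levels 1..6 are controls
    ],
)
def test_name_convention(name, expected_class, expected_level):
    cls, level = NamingConvention().classify(name)
    assert (cls, level) == (expected_class, expected_level)


def test_gal_round_trip_carries_layout(tmp_path):
    cfg = small_config(n_antigens=8)
    layout = build_layout(cfg)
    path = write_gal(layout._gal_rows, tmp_path / "a.gal")
    loaded = read_gal(path)
    antigens = [p for p in loaded.probes if p.probe_class is ProbeClass.ANTIGEN]
    assert len(antigens) == 8
    assert all(p.replicas == 4 for p in antigens)
    assert loaded.positions == layout.positions
    assert loaded.n_blocks == 4


def test_gal_missing_block_column(tmp_path):
    p = tmp_path / "bad.gal"
    p.write_text("ATF\t1.0\n0\t4\nColumn\tRow\tID\tName\n1\t1\tA\tA\n")
    with pytest.raises(FormatError, match="Block"):
        read_gal(p)


def test_gal_duplicate_position(tmp_path):
    p = tmp_path / "dup.gal"
    p.write_text(
        "ATF\t1.0\n0\t5\nBlock\tColumn\tRow\tID\tName\n"
        "1\t1\t1\tA\tA\n1\t1\t1\tB\tB\n"
    )
    with pytest.raises(LayoutError, match="duplicate"):
        read_gal(p)


def test_gpr_round_trip_identity(tmp_path, noisy_study):
    _, layout, samples, _ = noisy_study
    gal = write_gal(layout._gal_rows, tmp_path / "x.gal")
    loaded_layout = read_gal(gal)
    sample = samples[0]
    path = write_gpr(sample, tmp_path / "x.gpr")
    back = read_gpr(path, loaded_layout, sample_id=sample.sample_id, group=sample.group)
    assert sorted(back.spots, key=lambda s: (s.block, s.row, s.column)) == sorted(
        sample.spots, key=lambda s: (s.block, s.row, s.column)
    )


def test_gpr_row_count_matches_layout(tmp_path, noisy_study):
    _, layout, samples, _ = noisy_study
    path = write_gpr(samples[0], tmp_path / "y.gpr")
    n_rows = sum(
        1 for line in path.read_text().splitlines()[5:] if line.strip()
    )
    assert n_rows == layout.n_spots == len(samples[0].spots)


def test_reader_keeps_flagged_spots(tmp_path):
    layout_p = tmp_path / "f.gal"
    layout_p.write_text(
        "ATF\t1.0\n0\t5\nBlock\tColumn\tRow\tID\tName\nl1\t1\t1\tA\tA\n".replace("l1", "1")
    )
    layout = read_gal(layout_p)
    gpr = tmp_path / "f.gpr"
    gpr.write_text(
        "ATF\t1.0\n0\t8\nBlock\tColumn\tRow\tName\tID\t"
        "F532 Median\tB532 Median\tFlags\n1\t1\t1\tA\tA\t500\t100\t-100\n"
    )
    sample = read_gpr(gpr, layout)
    assert len(sample.spots) == 1 and sample.spots[0].flag == -100


def test_gpr_position_not_in_layout(tmp_path):
    layout_p = tmp_path / "g.gal"
    layout_p.write_text("ATF\t1.0\n0\t5\nBlock\tColumn\tRow\tID\tName\n1\t1\t1\tA\tA\n")
    layout = read_gal(layout_p)
    gpr = tmp_path / "g.gpr"
    gpr.write_text(
        "ATF\t1.0\n0\t8\nBlock\tColumn\tRow\tName\tID\t"
        "F532 Median\tB532 Median\tFlags\n2\t1\t1\tA\tA\t500\t100\t0\n"
    )
    with pytest.raises(LayoutError, match="absent from array layout"):
        read_gpr(gpr, layout)


def test_gpr_non_numeric_intensity_names_row(tmp_path):
    layout_p = tmp_path / "h.gal"
    layout_p.write_text("ATF\t1.0\n0\t5\nBlock\tColumn\tRow\tID\tName\n1\t1\t1\tA\tA\n")
    layout = read_gal(layout_p)
    gpr = tmp_path / "h.gpr"
    gpr.write_text(
        "ATF\t1.0\n0\t8\nBlock\tColumn\tRow\tName\tID\t"
        "F532 Median\tB532 Median\tFlags\n1\t1\t1\tA\tA\tnope\t100\t0\n"
    )
    with pytest.raises(FormatError, match="row 1"):
        read_gpr(gpr, layout)


def test_write_gpr_refuses_empty():
    empty = SampleArray(sample_id="s", group="case", spots=[])
    with pytest.raises(FormatError):
        write_gpr(empty, "/tmp/never.gpr")


@settings(deadline=None, max_examples=15, derandomize=True)
@given(
    n_antigens=st.integers(min_value=1, max_value=12),
    seed=st.integers(min_value=0, max_value=2**16),
    channel=st.sampled_from([532, 635]),
)
def test_round_trip_property(tmp_path_factory, n_antigens, seed, channel):
    """read_gpr(write_gpr(s)) is the identity over random layouts/intensities."""
    tmp = tmp_path_factory.mktemp("rt")
    cfg = SyntheticConfig(n_case=1, n_control=1, n_antigens=n_antigens, seed=seed)
    layout, samples, _ = simulate_study(cfg)
    path = write_gpr(samples[0], tmp / f"{seed}.gpr", channel=channel)
    back = read_gpr(path, layout, channel=channel)
    assert sorted(back.spots, key=lambda s: (s.block, s.row, s.column)) == sorted(
        samples[0].spots, key=lambda s: (s.block, s.row, s.column)
    )


def test_spot_record_rejects_negative_intensity():
    with pytest.raises(ValueError, match="negative"):
        SpotRecord(1, 1, 1, "A", "A", ProbeClass.ANTIGEN, None, -1.0, 0.0)


def test_sample_sheet_round_trip_and_validation(tmp_path):
    sheet = SampleSheet(
        rows=[
            SampleSheetRow("c1", "c1.gpr", "case", "Malay"),
            SampleSheetRow("n1", "n1.gpr", "control", None),
        ]
    )
    p = write_sample_sheet(sheet, tmp_path / "s.csv")
    back = read_sample_sheet(p)
    assert back.case_ids == ["c1"] and back.control_ids == ["n1"]
    with pytest.raises(FormatError, match="unique"):
        SampleSheet(rows=[sheet.rows[0], sheet.rows[0]])
    with pytest.raises(FormatError, match="group"):
        SampleSheet(rows=[SampleSheetRow("x", "x.gpr", "patient")])
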