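"""Reading and writing GenePix-style spot tables (GPR, GAL) and sample sheets.

Both formats are tab-separated ATF ("Axon Text File") dialects: an ``ATF 1.0``
line, a line giving the number of optional-header records and data columns,
the optional header records (quoted ``"Key=Value"`` strings), and then a
single column-header row followed by one row per spot.  A slide carries four
replicate sub-arrays ("blocks"); every probe is spotted once per block, so
antigens end up in quadruplicate.

Probe classes (antigen, IgG dilution control, Cy3-BSA control, buffer) are
not encoded in the format itself; they are inferred from probe names via a
configurable :class:`NamingConvention`.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence


class ProbeClass(str, Enum):
    ANTIGEN = "antigen"
    IGG_CONTROL = "igg_control"
    CY3BSA_CONTROL = "cy3bsa_control"
    BUFFER = "buffer"


class FormatError(ValueError):
    """Malformed GAL/GPR/sample-sheet content."""


class LayoutError(ValueError):
    """Layout inconsistency (duplicate or irreconcilable spot positions)."""


@dataclass(frozen=True)
class NamingConvention:
    """Maps probe names to probe classes.

    Defaults: names starting ``IgG1``..``IgG6`` are IgG dilution controls at
    that level, ``Cy3BSA`` marks the constant-concentration BSA control, and
    ``BUFFER``/``EMPTY`` mark printing-buffer spots.  Everything else is an
    antigen probe.
    """

    igg_prefix: str = "IgG"
    cy3bsa_prefixes: tuple[str, ...] = ("Cy3BSA",)
    buffer_prefixes: tuple[str, ...] = ("BUFFER", "EMPTY")

    def classify(self, name: str) -> tuple[ProbeClass, int | None]:
        """Return (probe class, IgG dilution level or None)."""
        m = re.match(re.escape(self.igg_prefix) + r"([1-6])(?![0-9])", name)
        if m:
            return ProbeClass.IGG_CONTROL, int(m.group(1))
        for p in self.cy3bsa_prefixes:
            if name.upper().startswith(p.upper()):
                return ProbeClass.CY3BSA_CONTROL, None
        for p in self.buffer_prefixes:
            if name.upper().startswith(p.upper()):
                return ProbeClass.BUFFER, None
        return ProbeClass.ANTIGEN, None


@dataclass(frozen=True)
class SpotRecord:
    """One probed spot on a slide.

    Coordinates are 1-based per the GenePix convention; ``block`` indexes the
    replicate sub-array.  Intensities are relative fluorescence units (RFU);
    a negative ``flag`` marks a bad spot (flag filtering happens downstream,
    never in the reader).
    """

    block: int
    column: int
    row: int
    probe_name: str
    probe_id: str
    probe_class: ProbeClass
    igg_level: int | None
    fg_median: float
    bg_median: float
    flag: int = 0

    def __post_init__(self) -> None:
        if self.fg_median < 0 or self.bg_median < 0:
            raise ValueError(
                f"negative intensity at block {self.block} "
                f"({self.row},{self.column})"
            )
        if self.probe_class is ProbeClass.IGG_CONTROL and not (
            self.igg_level is not None and 1 <= self.igg_level <= 6
        ):
            raise ValueError("IgG control spot requires a dilution level in 1..6")


@dataclass(frozen=True)
class ProbeInfo:
    probe_id: str
    probe_name: str
    probe_class: ProbeClass
    igg_level: int | None
    replicas: int


@dataclass
class ArrayLayout:
    """Array design parsed from a GAL file: probe catalogue plus grid geometry."""

    probes: list[ProbeInfo]
    n_blocks: int
    n_rows: int
    n_columns: int
    positions: dict[tuple[int, int, int], str] = field(default_factory=dict)

    def probe_ids(self, probe_class: ProbeClass | None = None) -> list[str]:
        return [
            p.probe_id
            for p in self.probes
            if probe_class is None or p.probe_class is probe_class
        ]

    @property
    def n_spots(self) -> int:
        return len(self.positions)


@dataclass
class SampleArray:
    """All spots of one sample's slide plus per-probe aggregated net RFUs."""

    sample_id: str
    group: str  # "case" or "control"
    spots: list[SpotRecord]
    ethnicity: str | None = None
    per_probe_net: dict[str, float] = field(default_factory=dict)

    def spots_of_class(self, probe_class: ProbeClass) -> list[SpotRecord]:
        return [s for s in self.spots if s.probe_class is probe_class]


@dataclass(frozen=True)
class SampleSheetRow:
    sample_id: str
    gpr_path: str
    group: str
    ethnicity: str | None = None


@dataclass
class SampleSheet:
    rows: list[SampleSheetRow]

    def __post_init__(self) -> None:
        ids = [r.sample_id for r in self.rows]
        if len(set(ids)) != len(ids):
            raise FormatError("sample_id values must be unique")
        for r in self.rows:
            if r.group not in ("case", "control"):
                raise FormatError(
                    f"sample {r.sample_id}: group must be case/control, "
                    f"got {r.group!r}"
                )

    @property
    def case_ids(self) -> list[str]:
        return [r.sample_id for r in self.rows if r.group == "case"]

    @property
    def control_ids(self) -> list[str]:
        return [r.sample_id for r in self.rows if r.group == "control"]


# --- ATF plumbing ---------------------------------------------------------


def _read_atf(path: Path) -> tuple[list[str], list[dict[str, str]]]:
    """Parse an ATF file into (optional header records, data-row dicts)."""
    with open(path, newline="") as fh:
        lines = fh.read().splitlines()
    if not lines or not lines[0].startswith("ATF"):
        raise FormatError(f"{path}: not an ATF file (missing 'ATF' signature)")
    try:
        n_header = int(lines[1].split("\t")[0])
    except (IndexError, ValueError) as exc:
        raise FormatError(f"{path}: malformed ATF record-count line") from exc
    headers = [ln.strip('"') for ln in lines[2 : 2 + n_header]]
    body = lines[2 + n_header :]
    if not body:
        raise FormatError(f"{path}: no column-header row")
    columns = [c.strip('"') for c in body[0].split("\t")]
    rows: list[dict[str, str]] = []
    for raw in body[1:]:
        if not raw.strip():
            continue
        cells = [c.strip('"') for c in raw.split("\t")]
        rows.append(dict(zip(columns, cells)))
    return headers, rows


def _require_columns(rows: list[dict[str, str]], required: Sequence[str], path: Path) -> None:
    present = set(rows[0]) if rows else set()
    for col in required:
        if col not in present:
            raise FormatError(f"{path}: required column {col!r} is missing")


# --- GAL -----------------------------------------------------------------


def read_gal(path: str | Path, naming: NamingConvention | None = None) -> ArrayLayout:
    """Read a GenePix Array List file into an :class:`ArrayLayout`.

    Probe classes are inferred from the ``Name`` column via *naming*; every
    (block, row, column) must be unique.
    """
    path = Path(path)
    naming = naming or NamingConvention()
    _, rows = _read_atf(path)
    if not rows:
        raise FormatError(f"{path}: GAL file has no data rows")
    _require_columns(rows, ("Block", "Column", "Row", "ID", "Name"), path)

    positions: dict[tuple[int, int, int], str] = {}
    catalogue: dict[str, tuple[str, ProbeClass, int | None, int]] = {}
    max_block = max_row = max_col = 0
    for r in rows:
        key = (int(r["Block"]), int(r["Row"]), int(r["Column"]))
        if key in positions:
            raise LayoutError(f"{path}: duplicate spot position {key}")
        pid, name = r["ID"], r["Name"]
        positions[key] = pid
        cls, level = naming.classify(name)
        if pid in catalogue:
            prev = catalogue[pid]
            catalogue[pid] = (prev[0], prev[1], prev[2], prev[3] + 1)
        else:
            catalogue[pid] = (name, cls, level, 1)
        max_block = max(max_block, key[0])
        max_row = max(max_row, key[1])
        max_col = max(max_col, key[2])

    probes = [
        ProbeInfo(pid, name, cls, level, reps)
        for pid, (name, cls, level, reps) in catalogue.items()
    ]
    return ArrayLayout(
        probes=probes,
        n_blocks=max_block,
        n_rows=max_row,
        n_columns=max_col,
        positions=positions,
    )


# --- GPR -----------------------------------------------------------------

_CHANNEL_COLUMNS = {
    532: ("F532 Median", "B532 Median"),
    635: ("F635 Median", "B635 Median"),
}


def read_gpr(
    path: str | Path,
    layout: ArrayLayout,
    sample_id: str | None = None,
    group: str = "case",
    ethnicity: str | None = None,
    channel: int = 532,
    naming: NamingConvention | None = None,
) -> SampleArray:
    """Read a GenePix Results file into a :class:`SampleArray`.

    Every spot position is cross-checked against *layout*; rows are never
    silently dropped (a malformed row raises with its row number).  The
    intensity channel defaults to 532 nm (Cy3); 635 selects the red channel's
    column pair.
    """
    path = Path(path)
    naming = naming or NamingConvention()
    fg_col, bg_col = _CHANNEL_COLUMNS[channel]
    _, rows = _read_atf(path)
    if not rows:
        raise FormatError(f"{path}: GPR file has no data rows")
    _require_columns(
        rows, ("Block", "Column", "Row", "Name", "ID", fg_col, bg_col, "Flags"), path
    )

    spots: list[SpotRecord] = []
    for i, r in enumerate(rows, start=1):
        key = (int(r["Block"]), int(r["Row"]), int(r["Column"]))
        if key not in layout.positions:
            raise LayoutError(
                f"{path}: spot at block/row/col {key} absent from array layout"
            )
        try:
            fg = float(r[fg_col])
            bg = float(r[bg_col])
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric intensity in data row {i}") from exc
        cls, level = naming.classify(r["Name"])
        spots.append(
            SpotRecord(
                block=key[0],
                column=key[2],
                row=key[1],
                probe_name=r["Name"],
                probe_id=r["ID"],
                probe_class=cls,
                igg_level=level,
                fg_median=fg,
                bg_median=bg,
                flag=int(float(r["Flags"])),
            )
        )
    return SampleArray(
        sample_id=sample_id or path.stem,
        group=group,
        ethnicity=ethnicity,
        spots=spots,
    )


def _format_intensity(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def write_gpr(sample: SampleArray, path: str | Path, channel: int = 532) -> Path:
    """Write a SampleArray as an ATF 1.0 GPR file.

    Integer intensities round-trip bit-exactly through :func:`read_gpr`.
    Refuses to write an empty spot set.
    """
    if not sample.spots:
        raise FormatError("refusing to write a GPR file with no spots")
    path = Path(path)
    fg_col, bg_col = _CHANNEL_COLUMNS[channel]
    headers = [
        '"Type=GenePix Results 3"',
        f'"Wavelengths={channel}"',
    ]
    cols = ["Block", "Column", "Row", "Name", "ID", fg_col, bg_col, "Flags"]
    lines = ["ATF\t1.0", f"{len(headers)}\t{len(cols)}", *headers, "\t".join(cols)]
    for s in sorted(sample.spots, key=lambda s: (s.block, s.row, s.column)):
        lines.append(
            "\t".join(
                [
                    str(s.block),
                    str(s.column),
                    str(s.row),
                    s.probe_name,
                    s.probe_id,
                    _format_intensity(s.fg_median),
                    _format_intensity(s.bg_median),
                    str(s.flag),
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def write_gal(layout_rows: Iterable[tuple[int, int, int, str, str]], path: str | Path) -> Path:
    """Write GAL rows ((block, row, column, probe_id, probe_name)) as ATF 1.0."""
    path = Path(path)
    headers = ['"Type=GenePix ArrayList V1.0"']
    cols = ["Block", "Column", "Row", "ID", "Name"]
    lines = ["ATF\t1.0", f"{len(headers)}\t{len(cols)}", *headers, "\t".join(cols)]
    for block, row, column, pid, name in layout_rows:
        lines.append("\t".join([str(block), str(column), str(row), pid, name]))
    path.write_text("\n".join(lines) + "\n")
    return path


# --- sample sheet ---------------------------------------------------------


def read_sample_sheet(path: str | Path) -> SampleSheet:
    """Read the study sample sheet (CSV: sample_id,gpr_path,group,ethnicity)."""
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {
            "sample_id",
            "gpr_path",
            "group",
        } <= set(reader.fieldnames):
            raise FormatError(
                f"{path}: sample sheet needs columns sample_id,gpr_path,group"
            )
        rows = [
            SampleSheetRow(
                sample_id=r["sample_id"],
                gpr_path=r["gpr_path"],
                group=r["group"],
                ethnicity=r.get("ethnicity") or None,
            )
            for r in reader
        ]
    return SampleSheet(rows=rows)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["sample_id", "gpr_path", "group", "ethnicity"])
        for r in sheet.rows:
            w.writerow([r.sample_id, r.gpr_path, r.group, r.ethnicity or ""])
    return path


def load_study(
    sheet: SampleSheet,
    layout: ArrayLayout,
    base_dir: str | Path = ".",
    channel: int = 532,
    naming: NamingConvention | None = None,
) -> list[SampleArray]:
    """Load every sample listed in the sheet, resolving paths against base_dir."""
    base = Path(base_dir)
    arrays = []
    for r in sheet.rows:
        p = Path(r.gpr_path)
        if not p.is_absolute():
            p = base / p
        arrays.append(
            read_gpr(
                p,
                layout,
                sample_id=r.sample_id,
                group=r.group,
                ethnicity=r.ethnicity,
                channel=channel,
                naming=naming,
            )
        )
    return arrays
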