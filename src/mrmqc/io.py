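"""Tab-delimited input/output.

Reads the three files an assay-characterization run needs — a Skyline-style
transition-results export (per-run, per-transition peak areas), an experiment
metadata file (sample type, day, replicate, calibration point / concentration
level per run), and a serial-dilution map (calibration point → theoretical
concentration) — and writes the two tabular result reports.

Header matching is case-insensitive and tolerant of space/underscore/hyphen
variants; a user-supplied column map can override it entirely (Skyline report
templates are user-customizable, so header spellings are not stable).
"""

from __future__ import annotations

import csv
import logging
import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

#: Missing-value spellings accepted on input. Output always uses "NA".
MISSING_SPELLINGS = {"", "#n/a", "na", "nan", "n/a"}

SAMPLE_TYPES = ("blank", "calibration", "qc")
CONCENTRATION_LEVELS = ("low", "medium", "high")


class FormatError(ValueError):
    """A malformed input file (missing column, bad enum, broken invariant)."""


# ---------------------------------------------------------------------------
# domain rows
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SkylineExportRow:
    """One data line of a Skyline transition-results export."""

    peptide_sequence: str
    precursor_charge: int
    fragment_ion: str
    product_charge: int
    replicate_name: str
    peak_area: float | None  # None = not detected / not reported

    def __post_init__(self) -> None:
        if not re.fullmatch(r"[A-Z][A-Z0-9\[\]().+\-]*", self.peptide_sequence):
            raise FormatError(
                f"invalid peptide sequence {self.peptide_sequence!r}"
            )
        if self.precursor_charge < 1 or self.product_charge < 1:
            raise FormatError("charges must be >= 1")
        if self.peak_area is not None and self.peak_area < 0:
            raise FormatError(f"negative peak area {self.peak_area!r}")


@dataclass(frozen=True)
class MetadataRow:
    """Experiment-design coordinates of one mass-spectrometry run."""

    replicate_name: str
    sample_type: str
    day: int | None = None
    replicate_index: int = 1
    concentration_level: str | None = None
    calibration_point: int | None = None

    def __post_init__(self) -> None:
        if self.sample_type not in SAMPLE_TYPES:
            raise FormatError(
                f"sample_type {self.sample_type!r} not one of {SAMPLE_TYPES}"
            )
        if (self.sample_type == "calibration") != (self.calibration_point is not None):
            raise FormatError(
                f"run {self.replicate_name!r}: calibration runs (and only those) "
                "must carry a calibration_point"
            )
        if (self.sample_type == "qc") != (self.concentration_level is not None):
            raise FormatError(
                f"run {self.replicate_name!r}: qc runs (and only those) "
                "must carry a concentration_level"
            )
        if self.concentration_level is not None and \
                self.concentration_level not in CONCENTRATION_LEVELS:
            raise FormatError(
                f"concentration_level {self.concentration_level!r} "
                f"not one of {CONCENTRATION_LEVELS}"
            )


@dataclass(frozen=True)
class DilutionRow:
    """One calibration point of the serial dilution."""

    calibration_point: int
    theoretical_concentration: float

    def __post_init__(self) -> None:
        if self.calibration_point < 1:
            raise FormatError("calibration_point must be >= 1")
        if self.theoretical_concentration < 0:
            raise FormatError("theoretical_concentration must be >= 0")


# ---------------------------------------------------------------------------
# header resolution
# ---------------------------------------------------------------------------

def _squash(name: str) -> str:
    return re.sub(r"[ _\-.]", "", name.strip().lower())


_SKYLINE_ALIASES: dict[str, tuple[str, ...]] = {
    "peptide_sequence": ("peptidesequence", "peptide", "peptidemodifiedsequence",
                         "modifiedsequence"),
    "precursor_charge": ("precursorcharge",),
    "fragment_ion": ("fragmention",),
    "product_charge": ("productcharge",),
    "replicate_name": ("replicatename", "replicate", "filename"),
    "peak_area": ("area", "totalarea", "peakarea"),
}

_METADATA_ALIASES: dict[str, tuple[str, ...]] = {
    "replicate_name": ("replicatename", "replicate", "runname", "run"),
    "sample_type": ("sampletype", "type"),
    "day": ("day",),
    "replicate_index": ("replicateindex", "repindex", "rep"),
    "concentration_level": ("concentrationlevel", "conclevel", "level"),
    "calibration_point": ("calibrationpoint", "calipoint", "dilutionpoint"),
}

_DILUTION_ALIASES: dict[str, tuple[str, ...]] = {
    "calibration_point": ("calibrationpoint", "calipoint", "dilutionpoint"),
    "theoretical_concentration": ("theoreticalconcentration", "concentration",
                                  "conc", "theoreticalconc"),
}


def _resolve_header(header: Sequence[str],
                    aliases: Mapping[str, tuple[str, ...]],
                    required: Iterable[str],
                    column_map: Mapping[str, str] | None = None,
                    ) -> dict[str, int]:
    """Map canonical field names to column indices in *header*."""
    squashed = [_squash(h) for h in header]
    out: dict[str, int] = {}
    for field, names in aliases.items():
        if column_map and field in column_map:
            names = (_squash(column_map[field]),)
        for name in names:
            if name in squashed:
                out[field] = squashed.index(name)
                break
    missing = [f for f in required if f not in out]
    if missing:
        raise FormatError(
            f"header is missing required column(s): {', '.join(missing)} "
            f"(got header {list(header)!r})"
        )
    return out


def _read_rows(path: str | Path) -> tuple[list[str], list[tuple[int, list[str]]]]:
    """Read a tab-delimited file: (header, [(line_number, fields), ...])."""
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        lines = [(i + 1, row) for i, row in enumerate(reader)]
    lines = [(n, row) for n, row in lines if any(f.strip() for f in row)]
    if not lines:
        raise FormatError(f"{path}: empty file (no header)")
    (_, header), data = lines[0], lines[1:]
    return header, data


def _cell(fields: list[str], idx: int) -> str:
    return fields[idx].strip() if 0 <= idx < len(fields) else ""


def _opt(fields: list[str], idx: int) -> str | None:
    v = _cell(fields, idx)
    return None if v.lower() in MISSING_SPELLINGS else v


def _opt_int(fields: list[str], idx: int, what: str, lineno: int) -> int | None:
    v = _opt(fields, idx)
    if v is None:
        return None
    try:
        return int(v)
    except ValueError:
        raise FormatError(f"line {lineno}: non-integer {what}: {v!r}") from None


# ---------------------------------------------------------------------------
# parsers
# ---------------------------------------------------------------------------

def parse_skyline_export(path: str | Path,
                         column_map: Mapping[str, str] | None = None,
                         ) -> list[SkylineExportRow]:
    """Parse a Skyline transition-results export.

    Missing or non-numeric peak areas become ``None`` (never zero); data-line
    order is preserved. Raises :class:`FormatError` if a required column is
    absent or the file is empty.
    """
    header, data = _read_rows(path)
    cols = _resolve_header(header, _SKYLINE_ALIASES, _SKYLINE_ALIASES,
                           column_map)
    rows: list[SkylineExportRow] = []
    for lineno, fields in data:
        area_raw = _opt(fields, cols["peak_area"])
        area: float | None
        if area_raw is None:
            area = None
        else:
            try:
                area = float(area_raw)
            except ValueError:
                logger.warning("%s line %d: non-numeric area %r treated as "
                               "missing", path, lineno, area_raw)
                area = None
            else:
                if math.isnan(area):
                    area = None
        try:
            rows.append(SkylineExportRow(
                peptide_sequence=_cell(fields, cols["peptide_sequence"]),
                precursor_charge=int(_cell(fields, cols["precursor_charge"])),
                fragment_ion=_cell(fields, cols["fragment_ion"]),
                product_charge=int(_cell(fields, cols["product_charge"])),
                replicate_name=_cell(fields, cols["replicate_name"]),
                peak_area=area,
            ))
        except (ValueError, FormatError) as exc:
            raise FormatError(f"{path} line {lineno}: {exc}") from None
    return rows


def parse_metadata(path: str | Path) -> list[MetadataRow]:
    """Parse the experiment-metadata file (one row per MS run)."""
    header, data = _read_rows(path)
    cols = _resolve_header(header, _METADATA_ALIASES,
                           ("replicate_name", "sample_type"))
    rows: list[MetadataRow] = []
    seen: set[str] = set()
    for lineno, fields in data:
        name = _cell(fields, cols["replicate_name"])
        if name in seen:
            raise FormatError(f"{path} line {lineno}: duplicate replicate "
                              f"name {name!r}")
        seen.add(name)
        try:
            rows.append(MetadataRow(
                replicate_name=name,
                sample_type=_cell(fields, cols["sample_type"]).lower(),
                day=_opt_int(fields, cols.get("day", -1), "day", lineno),
                replicate_index=_opt_int(fields, cols.get("replicate_index", -1),
                                         "replicate_index", lineno) or 1,
                concentration_level=(
                    v.lower() if (v := _opt(fields, cols.get(
                        "concentration_level", -1))) is not None else None),
                calibration_point=_opt_int(fields,
                                           cols.get("calibration_point", -1),
                                           "calibration_point", lineno),
            ))
        except FormatError as exc:
            raise FormatError(f"{path} line {lineno}: {exc}") from None
    return rows


def parse_dilution_map(path: str | Path) -> list[DilutionRow]:
    """Parse the serial-dilution map, sorted by calibration point.

    Theoretical concentration must strictly increase with calibration point.
    """
    header, data = _read_rows(path)
    cols = _resolve_header(header, _DILUTION_ALIASES, _DILUTION_ALIASES)
    rows: list[DilutionRow] = []
    for lineno, fields in data:
        try:
            rows.append(DilutionRow(
                calibration_point=int(_cell(fields, cols["calibration_point"])),
                theoretical_concentration=float(
                    _cell(fields, cols["theoretical_concentration"])),
            ))
        except (ValueError, FormatError) as exc:
            raise FormatError(f"{path} line {lineno}: {exc}") from None
    points = [r.calibration_point for r in rows]
    if len(set(points)) != len(points):
        raise FormatError(f"{path}: duplicate calibration points")
    rows.sort(key=lambda r: r.calibration_point)
    concs = [r.theoretical_concentration for r in rows]
    if any(b <= a for a, b in zip(concs, concs[1:])):
        raise FormatError(f"{path}: theoretical concentration must strictly "
                          "increase with calibration point")
    return rows


# ---------------------------------------------------------------------------
# report writing
# ---------------------------------------------------------------------------

# Percent-scaled quantities print at 4 decimal places; everything else at
# 6 significant figures.
_PERCENT_COLUMN = re.compile(r"(CV|\(%\)|percent|Deviation)", re.IGNORECASE)


def format_cell(column: str, value: object) -> str:
    """Render one report cell; None/NaN become "NA"."""
    if value is None:
        return "NA"
    if isinstance(value, bool):
        return "TRUE" if value else "FALSE"
    if isinstance(value, float):
        if math.isnan(value):
            return "NA"
        if _PERCENT_COLUMN.search(column):
            return f"{value:.4f}"
        return f"{value:.6g}"
    return str(value)


def write_report(rows: Sequence, path: str | Path, row_type=None) -> None:
    """Write result rows (all of one report type) as a tab-delimited table.

    Column names and order come from the row type's ``columns()``; each row
    supplies its cell values through ``to_record()``. Missing / not-applicable
    cells are written as "NA". An empty row list needs an explicit
    ``row_type`` and yields a header-only file.
    """
    types = {type(r) for r in rows}
    if len(types) > 1:
        raise ValueError(f"mixed report row types: {types}")
    if rows:
        row_type = type(rows[0])
    if row_type is None:
        raise ValueError("row_type is required for an empty report")
    columns = row_type.columns()
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        if columns:
            writer.writerow(columns)
        for row in rows:
            record = row.to_record()
            writer.writerow([format_cell(c, record[c]) for c in columns])


def read_report(path: str | Path):
    """Read back a report written by :func:`write_report` ("NA" → NaN).

    Returns a :class:`pandas.DataFrame`; numeric columns are inferred.
    """
    import pandas as pd

    return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
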