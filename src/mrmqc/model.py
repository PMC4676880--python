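"""Measurement assembly and design-aware grouping.

Parsed export rows are folded into one :class:`MeasurementSet` per monitored
transition (peptide, precursor charge, fragment ion, product charge), each
run annotated with its experiment-design coordinates from the metadata file.
The per-peptide summed-transition series is built here, as is the grouping of
measurements by calibration point (response-curve mode) or by concentration
level × day (repeatability mode).

Metadata row order is taken as acquisition order; blank runs listed after the
last run of the highest calibration point are treated as post-high blanks for
the carry-over assessment, all other blanks as pre-curve blanks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .io import MetadataRow, SkylineExportRow

logger = logging.getLogger(__name__)

SUMMED_SENTINEL = "summed"


class AssemblyError(ValueError):
    """Export and metadata files do not describe the same experiment."""


@dataclass(frozen=True)
class TransitionKey:
    """Identity of one monitored transition (or the per-peptide sum)."""

    peptide_sequence: str
    precursor_charge: int
    fragment_ion: str
    product_charge: int
    is_summed: bool = False

    @property
    def label(self) -> str:
        """Display label, e.g. "2.y4.1"; the summed series renders "summed"."""
        if self.is_summed:
            return SUMMED_SENTINEL
        return f"{self.precursor_charge}.{self.fragment_ion}.{self.product_charge}"


@dataclass(frozen=True)
class RunAnnotation:
    """Design coordinates of one run (mirrors the metadata invariants)."""

    sample_type: str
    day: int | None = None
    replicate_index: int = 1
    calibration_point: int | None = None
    concentration_level: str | None = None


@dataclass(frozen=True)
class Measurement:
    annotation: RunAnnotation
    area: float | None


@dataclass
class MeasurementSet:
    """All runs of one transition: run name → (annotation, peak area).

    Insertion order of ``measurements`` follows the metadata file, i.e.
    acquisition order.
    """

    key: TransitionKey
    measurements: dict[str, Measurement] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.measurements)

    def areas(self, sample_type: str | None = None) -> list[float | None]:
        return [m.area for m in self.measurements.values()
                if sample_type is None or m.annotation.sample_type == sample_type]


def _annotation(meta: MetadataRow) -> RunAnnotation:
    return RunAnnotation(
        sample_type=meta.sample_type,
        day=meta.day,
        replicate_index=meta.replicate_index,
        calibration_point=meta.calibration_point,
        concentration_level=meta.concentration_level,
    )


def assemble(export_rows: Sequence[SkylineExportRow],
             metadata: Sequence[MetadataRow]) -> list[MeasurementSet]:
    """Fold export rows into one MeasurementSet per distinct transition.

    Every run in the export must have exactly one metadata row (orphans are an
    error); metadata runs absent from the export are logged, not fatal.
    Within a set, measurements are ordered by metadata (acquisition) order.
    """
    meta_by_run = {m.replicate_name: m for m in metadata}
    run_order = {m.replicate_name: i for i, m in enumerate(metadata)}

    orphans = sorted({r.replicate_name for r in export_rows}
                     - meta_by_run.keys())
    if orphans:
        raise AssemblyError(
            "export names runs with no metadata row: " + ", ".join(orphans))

    per_key: dict[TransitionKey, dict[str, float | None]] = {}
    for row in export_rows:
        key = TransitionKey(row.peptide_sequence, row.precursor_charge,
                            row.fragment_ion, row.product_charge)
        runs = per_key.setdefault(key, {})
        if row.replicate_name in runs:
            raise AssemblyError(
                f"transition {key.peptide_sequence} {key.label} appears twice "
                f"in run {row.replicate_name!r}")
        runs[row.replicate_name] = row.peak_area

    exported_runs = {r.replicate_name for r in export_rows}
    for name in meta_by_run:
        if name not in exported_runs:
            logger.warning("metadata run %r has no rows in the export", name)

    sets = []
    for key, runs in per_key.items():
        ordered = sorted(runs, key=run_order.__getitem__)
        sets.append(MeasurementSet(key, {
            name: Measurement(_annotation(meta_by_run[name]), runs[name])
            for name in ordered}))
    return sets


def sum_transitions(sets: Sequence[MeasurementSet]) -> MeasurementSet:
    """Per-run sum over a peptide's transitions.

    Missing areas are treated as absent, not zero (zero-filling would bias the
    curve's low end, where dropout concentrates); a run in which every
    transition is missing stays missing. All sets must belong to one
    (peptide, precursor charge) and cover the same runs.
    """
    if not sets:
        raise AssemblyError("cannot sum an empty list of transitions")
    peptides = {(s.key.peptide_sequence, s.key.precursor_charge) for s in sets}
    if len(peptides) > 1:
        raise AssemblyError(f"cannot sum transitions across peptides: {peptides}")
    run_sets = {tuple(s.measurements) for s in sets}
    if len(run_sets) > 1:
        raise AssemblyError("transitions do not cover the same run set")

    first = sets[0]
    key = replace(first.key, fragment_ion=SUMMED_SENTINEL, product_charge=1,
                  is_summed=True)
    summed: dict[str, Measurement] = {}
    for run, meas in first.measurements.items():
        contributing = [s.measurements[run].area for s in sets
                        if s.measurements[run].area is not None]
        total = sum(contributing) if contributing else None
        summed[run] = Measurement(meas.annotation, total)
    return MeasurementSet(key, summed)


@dataclass
class ResponseCurveGroups:
    """Calibration replicates per point, plus the blank runs.

    ``blanks_post_high`` are blank runs acquired after the last run of the
    highest calibration point (carry-over blanks); ``blanks_pre`` is every
    other blank.
    """

    calibration: dict[int, list[float | None]]
    blanks_pre: list[float | None]
    blanks_post_high: list[float | None]

    @property
    def n_measurements(self) -> int:
        return (sum(len(v) for v in self.calibration.values())
                + len(self.blanks_pre) + len(self.blanks_post_high))


def group_by_design(mset: MeasurementSet, mode: str):
    """Group one transition's measurements by the experiment design.

    mode="response_curve" → :class:`ResponseCurveGroups`;
    mode="repeatability" → dict (concentration_level, day) → replicate areas.
    """
    if mode == "response_curve":
        calibration: dict[int, list[float | None]] = {}
        entries = list(mset.measurements.values())
        cal_positions = [i for i, m in enumerate(entries)
                         if m.annotation.sample_type == "calibration"]
        if not cal_positions:
            raise AssemblyError(
                f"{mset.key.label}: no calibration runs for response-curve mode")
        top_point = max(entries[i].annotation.calibration_point
                        for i in cal_positions)
        last_top = max(i for i in cal_positions
                       if entries[i].annotation.calibration_point == top_point)
        blanks_pre: list[float | None] = []
        blanks_post: list[float | None] = []
        for i, m in enumerate(entries):
            ann = m.annotation
            if ann.sample_type == "calibration":
                calibration.setdefault(ann.calibration_point, []).append(m.area)
            elif ann.sample_type == "blank":
                (blanks_post if i > last_top else blanks_pre).append(m.area)
        return ResponseCurveGroups(
            calibration=dict(sorted(calibration.items())),
            blanks_pre=blanks_pre, blanks_post_high=blanks_post)

    if mode == "repeatability":
        groups: dict[tuple[str, int], list[float | None]] = {}
        for m in mset.measurements.values():
            ann = m.annotation
            if ann.sample_type == "qc":
                groups.setdefault((ann.concentration_level, ann.day),
                                  []).append(m.area)
        if not groups:
            raise AssemblyError(
                f"{mset.key.label}: no qc runs for repeatability mode")
        return groups

    raise ValueError(f"unknown grouping mode {mode!r}")


def group_by_peptide(sets: Iterable[MeasurementSet]
                     ) -> dict[tuple[str, int], list[MeasurementSet]]:
    """Group transition sets by (peptide sequence, precursor charge)."""
    out: dict[tuple[str, int], list[MeasurementSet]] = {}
    for s in sets:
        out.setdefault(
            (s.key.peptide_sequence, s.key.precursor_charge), []).append(s)
    return out
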