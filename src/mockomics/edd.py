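"""Generic 5-column measurement CSV and experiment-description CSV.

This is the package's interchange layer, modelled on the generic import
format of online experiment-data repositories: every measurement is one row
of (line name, typed measurement id, time in hours, value, unit).  Measurement
ids follow the standardized choices — PubChem CIDs for metabolites, UniProt
accessions for proteins, GenBank gene ids for transcripts — and the unit
vocabulary is closed: FPKM (transcripts), proteins/cell (proteins), mg/L or
mM (metabolites), and the empty string for optical density, which has no
units.

The experiment-description file carries per-line metadata only (part id,
temperature, shaking speed, ...) and never measurement values.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

VALID_UNITS = {"FPKM", "proteins/cell", "mg/L", "mM", ""}
METABOLITE_UNITS = {"mg/L", "mM"}

#: header strings are config-exposed so exports can match any live instance
DEFAULT_HEADERS = ["Line Name", "Measurement Type", "Time", "Value", "Units"]

DESCRIPTION_LINE_COLUMN = "Line Name"
DESCRIPTION_PART_COLUMN = "Part ID"


class EddFormatError(ValueError):
    """A record or file violates the interchange format."""


def canonical_measurement_id(measurement_id: str) -> str:
    """Normalize typed ids: ``"CID: 715"`` → ``"CID:715"``."""
    mid = measurement_id.strip()
    if ":" in mid:
        prefix, rest = mid.split(":", 1)
        return f"{prefix.strip()}:{rest.strip()}"
    return mid


@dataclass
class MeasurementRecord:
    """One measurement row of the generic 5-column format."""

    line_name: str
    measurement_id: str
    time: float  # h
    value: float
    unit: str

    def __post_init__(self) -> None:
        self.measurement_id = canonical_measurement_id(self.measurement_id)
        self.time = float(self.time)
        self.value = float(self.value)

    @property
    def is_metabolite_id(self) -> bool:
        return self.measurement_id.startswith("CID:")

    def validate(self) -> None:
        if self.unit not in VALID_UNITS:
            raise EddFormatError(f"unknown unit {self.unit!r}")
        if self.time < 0:
            raise EddFormatError(f"negative time {self.time}")
        if self.is_metabolite_id and self.unit not in METABOLITE_UNITS:
            raise EddFormatError(
                f"CID-typed id {self.measurement_id!r} requires a metabolite "
                f"unit, got {self.unit!r}"
            )


def _sort_key(rec: MeasurementRecord):
    return (rec.line_name, rec.unit, rec.measurement_id, rec.time)


def _fmt(v: float) -> str:
    """Shortest exact decimal: integral values bare ("0"), others via repr."""
    if np.isfinite(v) and v == int(v):
        return str(int(v))
    return repr(float(v))


def write_edd_generic(
    records: list[MeasurementRecord],
    path,
    headers: list[str] | None = None,
) -> None:
    """Write validated records as the 5-column CSV, stably ordered.

    Rows are sorted by (line, measurement type, time); all offending records
    are reported at once on validation failure.
    """
    headers = headers or DEFAULT_HEADERS
    if len(headers) != 5:
        raise EddFormatError("generic format requires exactly five headers")
    offenders = []
    for i, rec in enumerate(records):
        try:
            rec.validate()
        except EddFormatError as exc:
            offenders.append(f"record {i}: {exc}")
    if offenders:
        raise EddFormatError("invalid records:\n" + "\n".join(offenders))
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(headers)
        for rec in sorted(records, key=_sort_key):
            writer.writerow(
                [rec.line_name, rec.measurement_id,
                 _fmt(rec.time), _fmt(rec.value), rec.unit]
            )


def read_edd_generic(path) -> list[MeasurementRecord]:
    """Strictly parse a generic 5-column CSV back into validated records."""
    records = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise EddFormatError(f"{path}: empty file") from None
        if len(header) != 5:
            raise EddFormatError(
                f"{path}: line 1: expected 5 columns, found {len(header)}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 5:
                raise EddFormatError(
                    f"{path}: line {lineno}: expected 5 columns, found {len(row)}"
                )
            line, mid, time_s, value_s, unit = row
            try:
                time = float(time_s)
                value = float(value_s)
            except ValueError as exc:
                raise EddFormatError(
                    f"{path}: line {lineno}: unparseable number: {exc}"
                ) from None
            rec = MeasurementRecord(line, mid, time, value, unit)
            try:
                rec.validate()
            except EddFormatError as exc:
                raise EddFormatError(f"{path}: line {lineno}: {exc}") from None
            records.append(rec)
    return records


# -- experiment description --------------------------------------------------


@dataclass
class ExperimentLine:
    """One line (strain × culture condition): name, part id, metadata."""

    line_name: str
    part_id: str
    metadata: dict[str, str] = field(default_factory=dict)


@dataclass
class ExperimentDescription:
    """Per-line design metadata; contains no measurement values."""

    lines: list[ExperimentLine]

    def __post_init__(self) -> None:
        names = [ln.line_name for ln in self.lines]
        if len(set(names)) != len(names):
            raise EddFormatError("duplicate line names in experiment description")

    def __len__(self) -> int:
        return len(self.lines)


def write_experiment_description(description: ExperimentDescription, path) -> None:
    """Write line name, part id, then metadata columns in sorted order."""
    meta_keys = sorted({k for ln in description.lines for k in ln.metadata})
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow([DESCRIPTION_LINE_COLUMN, DESCRIPTION_PART_COLUMN, *meta_keys])
        for ln in description.lines:
            writer.writerow(
                [ln.line_name, ln.part_id]
                + [ln.metadata.get(k, "") for k in meta_keys]
            )


def read_experiment_description(path) -> ExperimentDescription:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise EddFormatError(f"{path}: empty file") from None
        if header[:2] != [DESCRIPTION_LINE_COLUMN, DESCRIPTION_PART_COLUMN]:
            raise EddFormatError(
                f"{path}: expected leading columns "
                f"{[DESCRIPTION_LINE_COLUMN, DESCRIPTION_PART_COLUMN]}"
            )
        meta_keys = header[2:]
        lines = []
        for row in reader:
            if not row:
                continue
            metadata = {
                k: v for k, v in zip(meta_keys, row[2:]) if v != ""
            }
            lines.append(ExperimentLine(row[0], row[1], metadata))
    return ExperimentDescription(lines)


# -- adapters from simulation objects ---------------------------------------


def records_from_series(series, model, line_name: str = "WT"):
    """OD and extracellular-metabolite records from a batch time series."""
    records = [
        MeasurementRecord(line_name, "OD", float(t), float(od), "")
        for t, od in zip(series.times, series.cell_density)
    ]
    for met, values in series.concentrations.items():
        mid = model.metabolite_measurement_ids.get(met, met)
        for t, v in zip(series.times, values):
            records.append(MeasurementRecord(line_name, mid, float(t), float(v), "mM"))
    return records


def records_from_omics(table, line_name: str = "WT"):
    """Measurement records from one omics table."""
    return [
        MeasurementRecord(line_name, row.feature_id, row.time, row.value, row.unit)
        for row in table.df.itertuples(index=False)
    ]
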