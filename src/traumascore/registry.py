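"""Patient-level trauma registry: data model, inclusion rules, delimited I/O.

A registry file is one row per admission with a mandatory header. Columns:

    patient_id, age, sex, mechanism, rr, sbp, gcs, died, injuries

``injuries`` encodes the AIS injury list as semicolon-separated
``region:severity`` tokens, e.g. ``head_neck:3;chest:4``; an empty cell is an
empty injury list. ``died`` is 0/1 for the in-hospital outcome. Columns not
in this set are carried through unmodified as per-record metadata.

Validation mirrors the study's inclusion criteria: admissions aged 13 or
younger are excluded (managed by paediatric services in the source registry);
an empty injury list and any unsurvivable AIS-6 injury are flagged but kept.
Exclusions that depend on clinical context the schema cannot express
(pathological fractures, hanging, drowning, burns, isolated head injury
without compromise) are the caller's responsibility.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from os import PathLike
from typing import IO, Iterable, Union

import pandas as pd

__all__ = [
    "BodyRegion",
    "Sex",
    "Mechanism",
    "AISInjury",
    "Physiology",
    "PatientRecord",
    "ValidationIssue",
    "read_registry",
    "write_registry",
    "validate_record",
]

REQUIRED_COLUMNS = (
    "patient_id",
    "age",
    "sex",
    "mechanism",
    "rr",
    "sbp",
    "gcs",
    "died",
    "injuries",
)


class BodyRegion(str, enum.Enum):
    """The six ISS body regions."""

    HEAD_NECK = "head_neck"
    FACE = "face"
    CHEST = "chest"
    ABDOMEN = "abdomen"
    EXTREMITIES = "extremities"
    EXTERNAL = "external"


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


class Mechanism(str, enum.Enum):
    BLUNT = "blunt"
    PENETRATING = "penetrating"
    BLAST = "blast"


@dataclass(frozen=True)
class AISInjury:
    """A single injury: body region plus AIS severity grade 1 (minor) to 6
    (currently untreatable)."""

    body_region: BodyRegion
    severity: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "body_region", BodyRegion(self.body_region))
        if not 1 <= int(self.severity) <= 6:
            raise ValueError(
                f"AIS severity must be in 1..6, got {self.severity!r}"
            )
        object.__setattr__(self, "severity", int(self.severity))


@dataclass(frozen=True)
class Physiology:
    """First-recorded physiology: respiratory rate (breaths/min), systolic
    blood pressure (mmHg) and Glasgow Coma Scale."""

    respiratory_rate: int
    systolic_bp: int
    gcs: int

    def __post_init__(self) -> None:
        if self.respiratory_rate < 0:
            raise ValueError(
                f"respiratory rate must be >= 0, got {self.respiratory_rate}"
            )
        if self.systolic_bp < 0:
            raise ValueError(
                f"systolic BP must be >= 0, got {self.systolic_bp}"
            )
        if not 3 <= self.gcs <= 15:
            raise ValueError(f"GCS must be in 3..15, got {self.gcs}")


@dataclass
class PatientRecord:
    """One trauma admission."""

    patient_id: str
    age: int
    sex: Sex
    mechanism: Mechanism
    injuries: tuple[AISInjury, ...]
    physiology: Physiology
    died: bool
    extra: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sex = Sex(self.sex)
        self.mechanism = Mechanism(self.mechanism)
        self.injuries = tuple(self.injuries)
        if self.age < 0:
            raise ValueError(f"age must be >= 0, got {self.age}")


@dataclass(frozen=True)
class ValidationIssue:
    """One finding from :func:`validate_record`. ``fatal`` issues exclude the
    record from analysis; non-fatal issues are informational."""

    patient_id: str
    rule: str
    message: str
    fatal: bool


def _parse_injuries(cell: str, row_label: str) -> tuple[AISInjury, ...]:
    cell = (cell or "").strip()
    if not cell:
        return ()
    injuries = []
    for token in cell.split(";"):
        token = token.strip()
        if not token:
            continue
        try:
            region, sev = token.split(":")
            injuries.append(AISInjury(BodyRegion(region.strip()), int(sev)))
        except (ValueError, KeyError) as exc:
            raise ValueError(
                f"row {row_label}: cannot parse injury token {token!r}: {exc}"
            ) from exc
    return tuple(injuries)


def _parse_int(cell: str, column: str, row_label: str) -> int:
    try:
        return int(str(cell).strip())
    except (TypeError, ValueError) as exc:
        raise ValueError(
            f"row {row_label}: column {column!r}: "
            f"cannot parse {cell!r} as an integer"
        ) from exc


Source = Union[str, PathLike, IO[str]]


def read_registry(source: Source, *, delimiter: str = ",") -> list[PatientRecord]:
    """Read a delimited registry file into :class:`PatientRecord` objects.

    Parameters
    ----------
    source
        Path or open text stream. A header row is mandatory.
    delimiter
        Field separator; ``","`` (default) or e.g. ``"\\t"`` for TSV.

    Raises
    ------
    ValueError
        If a required column is absent, or any cell fails to parse or
        violates a field invariant (the error names the offending row).
    """
    frame = pd.read_csv(source, sep=delimiter, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"registry is missing required column(s): {missing}")
    passthrough = [c for c in frame.columns if c not in REQUIRED_COLUMNS]

    records: list[PatientRecord] = []
    for i, row in enumerate(frame.itertuples(index=False), start=2):
        row = dict(zip(frame.columns, row))
        label = f"{i} (patient_id={row['patient_id']!r})"
        try:
            physiology = Physiology(
                respiratory_rate=_parse_int(row["rr"], "rr", label),
                systolic_bp=_parse_int(row["sbp"], "sbp", label),
                gcs=_parse_int(row["gcs"], "gcs", label),
            )
            died_code = _parse_int(row["died"], "died", label)
            if died_code not in (0, 1):
                raise ValueError(f"row {label}: died must be 0 or 1, got {died_code}")
            record = PatientRecord(
                patient_id=str(row["patient_id"]),
                age=_parse_int(row["age"], "age", label),
                sex=Sex(str(row["sex"]).strip()),
                mechanism=Mechanism(str(row["mechanism"]).strip()),
                injuries=_parse_injuries(row["injuries"], label),
                physiology=physiology,
                died=bool(died_code),
                extra={c: row[c] for c in passthrough},
            )
        except ValueError as exc:
            raise ValueError(str(exc) if str(exc).startswith("row ") else f"row {label}: {exc}") from exc
        records.append(record)
    return records


def write_registry(
    records: Iterable[PatientRecord],
    sink: Union[str, PathLike, IO[str]],
    *,
    delimiter: str = ",",
) -> None:
    """Write records as delimited text; inverse of :func:`read_registry`."""
    records = list(records)
    passthrough: list[str] = []
    for rec in records:
        for key in rec.extra:
            if key not in passthrough:
                passthrough.append(key)
    rows = []
    for rec in records:
        row = {
            "patient_id": rec.patient_id,
            "age": rec.age,
            "sex": rec.sex.value,
            "mechanism": rec.mechanism.value,
            "rr": rec.physiology.respiratory_rate,
            "sbp": rec.physiology.systolic_bp,
            "gcs": rec.physiology.gcs,
            "died": int(rec.died),
            "injuries": ";".join(
                f"{inj.body_region.value}:{inj.severity}" for inj in rec.injuries
            ),
        }
        for key in passthrough:
            row[key] = rec.extra.get(key, "")
        rows.append(row)
    frame = pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS) + passthrough)
    frame.to_csv(sink, sep=delimiter, index=False)


def validate_record(record: PatientRecord) -> list[ValidationIssue]:
    """Apply the study's inclusion rules to one record.

    Returns a (possibly empty) list of issues. ``age <= 13`` is fatal (the
    study enrolled patients aged more than 13 years); an empty injury list
    and any AIS severity 6 are flagged non-fatally — AIS 6 forces ISS/NISS
    to 75 downstream rather than excluding the record.
    """
    issues: list[ValidationIssue] = []
    if record.age <= 13:
        issues.append(
            ValidationIssue(
                patient_id=record.patient_id,
                rule="age_exclusion",
                message=f"age {record.age} <= 13: outside the adult trauma cohort",
                fatal=True,
            )
        )
    if not record.injuries:
        issues.append(
            ValidationIssue(
                patient_id=record.patient_id,
                rule="no_injuries",
                message="record carries no AIS injuries; anatomic scores are 0",
                fatal=False,
            )
        )
    if any(inj.severity == 6 for inj in record.injuries):
        issues.append(
            ValidationIssue(
                patient_id=record.patient_id,
                rule="unsurvivable_ais",
                message="AIS severity 6 present; ISS/NISS forced to 75",
                fatal=False,
            )
        )
    return issues
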