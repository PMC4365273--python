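"""Longitudinal PK dataset types and NONMEM-style CSV I/O.

The dataset layout is the conventional one-row-per-event table: dosing
records (EVID=1) carry AMT (mg) and RATE (mg/day); observation records
(EVID=0) carry DV with DVID distinguishing the analyte (1 = total drug in
mg/L, 2 = free target in ng/L).  Covariates repeat on every row of a
subject.  Times are in days since first dose.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable

import pandas as pd

__all__ = [
    "Analyte",
    "Sex",
    "DoseEvent",
    "Observation",
    "PatientCovariates",
    "Subject",
    "StudyDataset",
    "read_dataset",
    "write_dataset",
    "DatasetError",
]

MINUTES_PER_DAY = 24.0 * 60.0

SNP_2578_LEVELS = ("CC", "CA", "AA")  # wild type first
SNP_1154_LEVELS = ("GG", "GA", "AA")
SNP_634_LEVELS = ("GG", "GC", "CC")


class DatasetError(ValueError):
    """Raised for malformed or invariant-violating datasets."""


class Analyte(enum.Enum):
    TOTAL_DRUG = 1  # total antibody, reported in mg/L
    FREE_TARGET = 2  # free ligand, reported in ng/L

    @property
    def reported_unit(self) -> str:
        return "mg/L" if self is Analyte.TOTAL_DRUG else "ng/L"


class Sex(enum.Enum):
    F = 0
    M = 1


@dataclass(frozen=True)
class DoseEvent:
    """An intravenous infusion: ``amount`` mg delivered at a constant rate
    over ``duration`` days starting at ``time`` days."""

    time: float
    amount: float
    duration: float

    def __post_init__(self) -> None:
        if self.time < 0:
            raise DatasetError(f"dose time must be >= 0, got {self.time}")
        if self.amount < 0:
            raise DatasetError(f"dose amount must be >= 0, got {self.amount}")
        if self.duration <= 0:
            raise DatasetError(
                f"infusion duration must be > 0, got {self.duration}"
            )

    @property
    def rate(self) -> float:
        """Infusion rate in mg/day."""
        return self.amount / self.duration

    @property
    def end(self) -> float:
        return self.time + self.duration


@dataclass(frozen=True)
class Observation:
    """A timed concentration measurement of one analyte, in its reported
    unit (mg/L for TOTAL_DRUG, ng/L for FREE_TARGET)."""

    time: float
    analyte: Analyte
    value: float | None
    missing: bool = False

    def __post_init__(self) -> None:
        if self.time < 0:
            raise DatasetError(f"observation time must be >= 0, got {self.time}")
        if not self.missing:
            if self.value is None or not self.value > 0:
                raise DatasetError(
                    f"non-missing observation must have value > 0, got {self.value}"
                )


@dataclass(frozen=True)
class PatientCovariates:
    weight: float  # kg
    age: float  # years
    sex: Sex
    snp_2578: str = "CC"
    snp_1154: str = "GG"
    snp_634: str = "GG"

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise DatasetError(f"weight must be > 0, got {self.weight}")
        if self.age <= 0:
            raise DatasetError(f"age must be > 0, got {self.age}")
        for name, value, levels in (
            ("snp_2578", self.snp_2578, SNP_2578_LEVELS),
            ("snp_1154", self.snp_1154, SNP_1154_LEVELS),
            ("snp_634", self.snp_634, SNP_634_LEVELS),
        ):
            if value not in levels:
                raise DatasetError(f"{name} must be one of {levels}, got {value!r}")

    def numeric(self, name: str) -> float:
        """Continuous covariate lookup by field name."""
        if name in ("weight", "age"):
            return float(getattr(self, name))
        raise KeyError(name)


@dataclass(frozen=True)
class Subject:
    id: str
    covariates: PatientCovariates
    doses: tuple[DoseEvent, ...]
    observations: tuple[Observation, ...]

    def __post_init__(self) -> None:
        if len(self.doses) < 1:
            raise DatasetError(f"subject {self.id}: at least one dose required")
        for seq, what in ((self.doses, "doses"), (self.observations, "observations")):
            times = [e.time for e in seq]
            if any(b < a for a, b in zip(times, times[1:])):
                raise DatasetError(f"subject {self.id}: {what} not time-sorted")

    def observations_for(self, analyte: Analyte) -> tuple[Observation, ...]:
        return tuple(o for o in self.observations if o.analyte is analyte)


@dataclass(frozen=True)
class StudyDataset:
    subjects: tuple[Subject, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        ids = [s.id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise DatasetError("subject ids must be unique")

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)

    @property
    def n_observations(self) -> int:
        return sum(len(s.observations) for s in self.subjects)

    def with_analytes(self, analytes: Iterable[Analyte]) -> "StudyDataset":
        """Dataset restricted to observations of the given analytes."""
        keep = set(analytes)
        return StudyDataset(
            tuple(
                replace(s, observations=tuple(o for o in s.observations if o.analyte in keep))
                for s in self.subjects
            )
        )


_COLUMNS = [
    "ID", "TIME", "AMT", "RATE", "EVID", "DVID", "DV", "MDV",
    "WT", "AGE", "SEX", "SNP2578", "SNP1154", "SNP634",
]


def write_dataset(dataset: StudyDataset, path) -> None:
    """Write a dataset to the NONMEM-style CSV layout (lossless round trip
    with :func:`read_dataset`; deterministic column order)."""
    rows = []
    for s in dataset.subjects:
        cov = s.covariates
        base = {
            "ID": s.id, "WT": cov.weight, "AGE": cov.age, "SEX": cov.sex.value,
            "SNP2578": cov.snp_2578, "SNP1154": cov.snp_1154, "SNP634": cov.snp_634,
        }
        events: list[tuple[float, int, dict]] = []
        for d in s.doses:
            events.append((d.time, 1, {
                **base, "TIME": d.time, "AMT": d.amount, "RATE": d.rate,
                "EVID": 1, "DVID": "", "DV": "", "MDV": 1,
            }))
        for o in s.observations:
            events.append((o.time, 0, {
                **base, "TIME": o.time, "AMT": "", "RATE": "",
                "EVID": 0, "DVID": o.analyte.value,
                "DV": "" if o.missing else o.value, "MDV": 1 if o.missing else 0,
            }))
        # stable order: time, then doses before observations at equal times
        events.sort(key=lambda e: (e[0], -e[1]))
        rows.extend(e[2] for e in events)
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, index=False)


def read_dataset(path, column_mapping: dict[str, str] | None = None) -> StudyDataset:
    """Read and validate a NONMEM-style CSV into a :class:`StudyDataset`.

    ``column_mapping`` maps the standard column names to names used in the
    file (e.g. ``{"WT": "BW"}``).
    """
    df = pd.read_csv(path, dtype={"SNP2578": str, "SNP1154": str, "SNP634": str})
    mapping = {std: std for std in _COLUMNS}
    if column_mapping:
        mapping.update(column_mapping)
    missing = [std for std, col in mapping.items() if col not in df.columns]
    if missing:
        raise DatasetError(f"missing required columns: {missing}")

    subjects = []
    for sid, grp in df.groupby(mapping["ID"], sort=False):
        doses: list[DoseEvent] = []
        observations: list[Observation] = []
        cov = None
        for idx, row in grp.iterrows():
            rowno = idx + 2  # header + 1-based
            if cov is None:
                try:
                    cov = PatientCovariates(
                        weight=float(row[mapping["WT"]]),
                        age=float(row[mapping["AGE"]]),
                        sex=Sex(int(row[mapping["SEX"]])),
                        snp_2578=str(row[mapping["SNP2578"]]),
                        snp_1154=str(row[mapping["SNP1154"]]),
                        snp_634=str(row[mapping["SNP634"]]),
                    )
                except (ValueError, DatasetError) as exc:
                    raise DatasetError(f"row {rowno}: bad covariates: {exc}") from exc
            evid = int(row[mapping["EVID"]])
            try:
                if evid == 1:
                    amount = float(row[mapping["AMT"]])
                    rate = float(row[mapping["RATE"]])
                    if rate <= 0:
                        raise DatasetError(f"RATE must be > 0 for doses, got {rate}")
                    doses.append(DoseEvent(
                        time=float(row[mapping["TIME"]]),
                        amount=amount,
                        duration=amount / rate,
                    ))
                elif evid == 0:
                    mdv = int(row[mapping["MDV"]])
                    dv = row[mapping["DV"]]
                    observations.append(Observation(
                        time=float(row[mapping["TIME"]]),
                        analyte=Analyte(int(row[mapping["DVID"]])),
                        value=None if mdv else float(dv),
                        missing=bool(mdv),
                    ))
                else:
                    raise DatasetError(f"unsupported EVID {evid}")
            except DatasetError as exc:
                raise DatasetError(f"row {rowno}: {exc}") from exc
            except (TypeError, ValueError) as exc:
                raise DatasetError(f"row {rowno}: unparseable event: {exc}") from exc
        try:
            subjects.append(Subject(str(sid), cov, tuple(doses), tuple(observations)))
        except DatasetError as exc:
            raise DatasetError(f"subject {sid}: {exc}") from exc
    return StudyDataset(tuple(subjects))
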