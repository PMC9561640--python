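"""Read, validate, and write the four-table CDM-subset bundle.

Column dictionary (comma-delimited UTF-8 with header row, ISO-8601 dates on
disk, integer day offsets from the bundle origin in memory):

* ``persons.csv`` - person_id (int), sex ("M"/"F"), birth_year (int),
  race_flag (bool; used only by the MDRD equation).
* ``drug_exposure.csv`` - person_id, ingredient, drug_class (one of ACEi,
  ARB, BB, CCB, DU, OTHER), daily_dose (mg/day), start_date, end_date.
* ``condition_occurrence.csv`` - person_id, condition_category,
  condition_date.  Categories carry diagnosis tokens (e.g. "diabetes_mellitus"),
  procedure/encounter tokens ("major_surgery", "pregnancy", "hospitalization")
  and concomitant-medication dispensing tokens prefixed "rx_"
  (e.g. "rx_antianginal").
* ``measurement.csv`` - person_id, analyte (SBP, DBP, TC, HDL, LDL, TG, AST,
  ALT, SCR, HCG), value, unit, measurement_date.

Rows are written in a stable order (person_id, then day), so two writes of
the same bundle are byte-identical.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from .errors import BundleValidationError
from .phenotypes import EXPECTED_UNITS

log = logging.getLogger(__name__)

DRUG_CLASSES = frozenset({"ACEi", "ARB", "BB", "CCB", "DU", "OTHER"})
ANALYTES = frozenset(EXPECTED_UNITS)
DEFAULT_ORIGIN = dt.date(2010, 1, 1)

PERSON_COLS = ["person_id", "sex", "birth_year", "race_flag"]
DRUG_COLS = ["person_id", "ingredient", "drug_class", "daily_dose", "start_day", "end_day"]
COND_COLS = ["person_id", "condition_category", "day"]
MEAS_COLS = ["person_id", "analyte", "value", "unit", "day"]

FILES = {
    "persons": "persons.csv",
    "drug_exposures": "drug_exposure.csv",
    "condition_occurrences": "condition_occurrence.csv",
    "measurements": "measurement.csv",
}


@dataclass
class TableBundle:
    """In-memory bundle of the four tables, dates as day offsets from ``origin``."""

    persons: pd.DataFrame
    drug_exposures: pd.DataFrame
    condition_occurrences: pd.DataFrame
    measurements: pd.DataFrame
    origin: dt.date = DEFAULT_ORIGIN

    def sorted(self) -> "TableBundle":
        return TableBundle(
            self.persons.sort_values("person_id", kind="mergesort").reset_index(drop=True),
            self.drug_exposures.sort_values(
                ["person_id", "start_day", "ingredient", "end_day"], kind="mergesort"
            ).reset_index(drop=True),
            self.condition_occurrences.sort_values(
                ["person_id", "day", "condition_category"], kind="mergesort"
            ).reset_index(drop=True),
            self.measurements.sort_values(
                ["person_id", "day", "analyte", "value"], kind="mergesort"
            ).reset_index(drop=True),
            self.origin,
        )

    def year_of(self, day: int) -> int:
        return (self.origin + dt.timedelta(days=int(day))).year


@dataclass(frozen=True)
class Violation:
    table: str
    row: int  # 0-based row index within the table; -1 for table-level problems
    message: str

    def __str__(self):
        return f"{self.table}[row {self.row}]: {self.message}"


def _day_to_iso(days: pd.Series, origin: dt.date) -> pd.Series:
    base = pd.Timestamp(origin)
    return (base + pd.to_timedelta(days.astype(int), unit="D")).dt.strftime("%Y-%m-%d")


def _iso_to_day(dates: pd.Series, origin: dt.date) -> pd.Series:
    base = pd.Timestamp(origin)
    return (pd.to_datetime(dates, format="%Y-%m-%d") - base).dt.days.astype(int)


def _select_known(df: pd.DataFrame, cols, table: str) -> pd.DataFrame:
    extra = [c for c in df.columns if c not in cols]
    if extra:
        log.warning("%s: ignoring unknown column(s) %s", table, extra)
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise BundleValidationError([Violation(table, -1, f"missing column(s) {missing}")])
    return df[cols].copy()


def read_bundle(directory, origin: dt.date = DEFAULT_ORIGIN) -> TableBundle:
    """Read and validate the four-file bundle from ``directory``.

    Raises ``FileNotFoundError`` naming a missing file and
    :class:`BundleValidationError` on enum, range, or referential-integrity
    violations (with row numbers).
    """
    directory = Path(directory)
    raw = {}
    for key, fname in FILES.items():
        path = directory / fname
        if not path.exists():
            raise FileNotFoundError(f"bundle file missing: {path}")
        raw[key] = pd.read_csv(path)

    persons = _select_known(raw["persons"], PERSON_COLS, "persons")
    persons["person_id"] = persons["person_id"].astype(int)
    persons["birth_year"] = persons["birth_year"].astype(int)
    persons["race_flag"] = persons["race_flag"].astype(bool)

    drug = _select_known(
        raw["drug_exposures"],
        ["person_id", "ingredient", "drug_class", "daily_dose", "start_date", "end_date"],
        "drug_exposure",
    )
    drug["start_day"] = _iso_to_day(drug["start_date"], origin)
    drug["end_day"] = _iso_to_day(drug["end_date"], origin)
    drug = drug.drop(columns=["start_date", "end_date"])[DRUG_COLS]
    drug["person_id"] = drug["person_id"].astype(int)
    drug["daily_dose"] = drug["daily_dose"].astype(float)

    cond = _select_known(
        raw["condition_occurrences"],
        ["person_id", "condition_category", "condition_date"],
        "condition_occurrence",
    )
    cond["day"] = _iso_to_day(cond["condition_date"], origin)
    cond = cond.drop(columns=["condition_date"])[COND_COLS]
    cond["person_id"] = cond["person_id"].astype(int)

    meas = _select_known(
        raw["measurements"],
        ["person_id", "analyte", "value", "unit", "measurement_date"],
        "measurement",
    )
    meas["day"] = _iso_to_day(meas["measurement_date"], origin)
    meas = meas.drop(columns=["measurement_date"])[MEAS_COLS]
    meas["person_id"] = meas["person_id"].astype(int)
    meas["value"] = meas["value"].astype(float)

    bundle = TableBundle(persons, drug, cond, meas, origin)
    violations = validate_bundle(bundle)
    if violations:
        raise BundleValidationError(violations)
    return bundle


def write_bundle(bundle: TableBundle, directory) -> dict:
    """Write the four delimited files; returns the mapping of table -> path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    b = bundle.sorted()
    paths = {}

    persons = b.persons[PERSON_COLS].copy()
    persons["race_flag"] = persons["race_flag"].map({True: "true", False: "false"})
    paths["persons"] = directory / FILES["persons"]
    persons.to_csv(paths["persons"], index=False)

    drug = b.drug_exposures.copy()
    drug["start_date"] = _day_to_iso(drug["start_day"], b.origin)
    drug["end_date"] = _day_to_iso(drug["end_day"], b.origin)
    drug = drug[["person_id", "ingredient", "drug_class", "daily_dose", "start_date", "end_date"]]
    paths["drug_exposures"] = directory / FILES["drug_exposures"]
    drug.to_csv(paths["drug_exposures"], index=False)

    cond = b.condition_occurrences.copy()
    cond["condition_date"] = _day_to_iso(cond["day"], b.origin)
    cond = cond[["person_id", "condition_category", "condition_date"]]
    paths["condition_occurrences"] = directory / FILES["condition_occurrences"]
    cond.to_csv(paths["condition_occurrences"], index=False)

    meas = b.measurements.copy()
    meas["measurement_date"] = _day_to_iso(meas["day"], b.origin)
    meas = meas[["person_id", "analyte", "value", "unit", "measurement_date"]]
    paths["measurements"] = directory / FILES["measurements"]
    meas.to_csv(paths["measurements"], index=False)
    return paths


def validate_bundle(bundle: TableBundle) -> list:
    """Report-only validation; returns a (possibly empty) list of violations."""
    v: list = []
    persons = bundle.persons
    dup = persons["person_id"].duplicated()
    for row in persons.index[dup]:
        v.append(Violation("persons", int(row), f"duplicate person_id {persons.at[row, 'person_id']}"))
    for row in persons.index[~persons["sex"].isin(["M", "F"])]:
        v.append(Violation("persons", int(row), f"unknown sex token {persons.at[row, 'sex']!r}"))
    known_ids = set(persons["person_id"])

    drug = bundle.drug_exposures
    for row in drug.index[~drug["drug_class"].isin(DRUG_CLASSES)]:
        v.append(Violation("drug_exposure", int(row), f"unknown drug_class {drug.at[row, 'drug_class']!r}"))
    for row in drug.index[drug["end_day"] < drug["start_day"]]:
        v.append(Violation("drug_exposure", int(row), "end_day before start_day"))
    for row in drug.index[drug["daily_dose"] < 0]:
        v.append(Violation("drug_exposure", int(row), "negative daily_dose"))
    for row in drug.index[~drug["person_id"].isin(known_ids)]:
        v.append(Violation("drug_exposure", int(row), f"orphan person_id {drug.at[row, 'person_id']}"))

    cond = bundle.condition_occurrences
    for row in cond.index[~cond["person_id"].isin(known_ids)]:
        v.append(Violation("condition_occurrence", int(row), f"orphan person_id {cond.at[row, 'person_id']}"))

    meas = bundle.measurements
    for row in meas.index[~meas["analyte"].isin(ANALYTES)]:
        v.append(Violation("measurement", int(row), f"unknown analyte {meas.at[row, 'analyte']!r}"))
    for row in meas.index[meas["value"] < 0]:
        v.append(Violation("measurement", int(row), "negative value"))
    for row in meas.index[~meas["person_id"].isin(known_ids)]:
        v.append(Violation("measurement", int(row), f"orphan person_id {meas.at[row, 'person_id']}"))
    return v


def bundles_equal(a: TableBundle, b: TableBundle) -> bool:
    """Equality up to row order (both bundles are canonically sorted first)."""
    a, b = a.sorted(), b.sorted()
    try:
        pd.testing.assert_frame_equal(a.persons, b.persons, check_dtype=False)
        pd.testing.assert_frame_equal(a.drug_exposures, b.drug_exposures, check_dtype=False)
        pd.testing.assert_frame_equal(a.condition_occurrences, b.condition_occurrences, check_dtype=False)
        pd.testing.assert_frame_equal(a.measurements, b.measurements, check_dtype=False)
    except AssertionError:
        return False
    return a.origin == b.origin
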