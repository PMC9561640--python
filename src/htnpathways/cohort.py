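"""Eligibility, exclusion, and group-assignment rules for the analysis cohort.

Cohort entry (the index date) is the first anti-hypertensive prescription
preceded by at least 365 days of recorded clinical history; exit is 1,095
days later.  Continuous treatment requires prescription coverage of >= 875
days (80% of 1,095) within the window with no drug holiday longer than 30
days between adjacent prescriptions.  Exclusions are applied in a fixed
order so attrition counts are deterministic: age < 18 at index, major
surgery, pregnancy, hCG > 5 mIU/mL between index and exit, and missing
pre-index blood-pressure measurements.

A person is *changed* if at least one medication-change event among
persisted (>= 30-day) regimens falls in (index, exit]; otherwise *unchanged*.
Baseline covariates are evaluated on the half-open window
[index - window_days, index): the index-day prescription itself belongs to
follow-up, so it cannot contaminate its own baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from . import phenotypes as ph
from . import regimens as rg
from .errors import IntegrityError
from .io import TableBundle

FOLLOWUP_DAYS = 1095
COVERAGE_FLOOR = 875
MAX_GAP_DAYS = 30
HISTORY_DAYS = 365

EXCLUSION_ORDER = (
    "no_prior_history",
    "discontinuous",
    "age_under_18",
    "major_surgery",
    "pregnancy",
    "hcg_over_5",
    "no_baseline_bp",
)

#: Diagnosis categories turned into baseline history flags (Table-1 style).
DISEASE_CATEGORIES = (
    "diabetes_mellitus",
    "dyslipidemia",
    "liver_disease",
    "renal_disease",
    "gastrointestinal_diseases",
    "insomnia",
    "mental_behavioral_diseases",
    "neoplasm",
    "arrhythmia",
    "angina_pectoris",
)

#: Concomitant-medication dispensing categories (condition tokens prefixed rx_).
MEDICATION_CATEGORIES = (
    "rx_antianginal",
    "rx_anticoagulant",
    "rx_statin",
    "rx_nsaid",
    "rx_gastrointestinal",
    "rx_sedative",
)

#: Phenotypes whose baseline flag combines labs and diagnoses.
_LAB_PHENOTYPES = {
    "dyslipidemia": "dyslipidemia",
    "liver_disease": "liver_disease",
    "renal_disease": "renal_disease",
}


@dataclass
class CohortRecord:
    person_id: int
    index_day: Optional[int] = None
    exit_day: Optional[int] = None
    eligible: bool = False
    exclusion: Optional[str] = None
    group: Optional[str] = None
    covariates: dict = field(default_factory=dict)


@dataclass
class EligibilityReport:
    """Attrition counts, reasons assigned by first-failing rule."""

    screened: int = 0
    reasons: dict = field(default_factory=dict)
    eligible: int = 0
    person_reasons: dict = field(default_factory=dict)  # person_id -> reason

    def attrition(self) -> list:
        rows = [("screened", self.screened)]
        remaining = self.screened
        for reason in EXCLUSION_ORDER:
            removed = self.reasons.get(reason, 0)
            remaining -= removed
            rows.append((f"excluded_{reason}", removed))
        rows.append(("eligible", remaining))
        if remaining != self.eligible:
            raise IntegrityError("attrition counts do not telescope")
        return rows


@dataclass
class CohortResult:
    cohort: pd.DataFrame
    report: EligibilityReport
    regimens: dict  # person_id -> list[Regimen] (persisted)
    events: dict    # person_id -> list[ChangeEvent]
    sequences: dict  # person_id -> list[str]


def find_index_date(exposure_starts: Sequence[int], history_start_day: int,
                    min_history_days: int = HISTORY_DAYS) -> Optional[int]:
    """Earliest exposure start with >= min_history_days of prior history, else None."""
    for day in sorted(exposure_starts):
        if day - history_start_day >= min_history_days:
            return int(day)
    return None


def assess_continuity(
    intervals: Sequence[tuple],
    index_day: int,
    exit_day: int,
    coverage_floor: int = COVERAGE_FLOOR,
    max_gap_allowed: int = MAX_GAP_DAYS,
):
    """Coverage and largest drug holiday over [index, exit].

    Coverage counts calendar days covered by the union of the clipped exposure
    intervals (overlaps not double-counted).  The gap between adjacent covered
    intervals is ``next.start - prev.end - 1``; only interior gaps count as
    drug holidays.  Returns (coverage_days, max_gap_days, continuous).
    """
    clipped = [
        (max(s, index_day), min(e, exit_day))
        for s, e in intervals
        if min(e, exit_day) >= max(s, index_day)
    ]
    if not clipped:
        return 0, 0, False
    merged = rg.merge_intervals(clipped, gap_tolerance=0)
    coverage = sum(e - s + 1 for s, e in merged)
    max_gap = max(
        (b[0] - a[1] - 1 for a, b in zip(merged[:-1], merged[1:])), default=0
    )
    continuous = coverage >= coverage_floor and max_gap <= max_gap_allowed
    return coverage, max_gap, continuous


def apply_exclusions(
    person: pd.Series,
    conditions: pd.DataFrame,
    measurements: pd.DataFrame,
    index_day: int,
    exit_day: int,
    index_year: int,
) -> Optional[str]:
    """First failing rule in the fixed order, or None if the person passes.

    Order: age < 18 at index, major surgery, pregnancy, hCG > 5 mIU/mL
    (strictly greater) in [index, exit], no blood-pressure measurement
    strictly before index.
    """
    if index_year - int(person["birth_year"]) < 18:
        return "age_under_18"
    in_follow = conditions[(conditions["day"] >= index_day) & (conditions["day"] <= exit_day)]
    if (in_follow["condition_category"] == "major_surgery").any():
        return "major_surgery"
    if (in_follow["condition_category"] == "pregnancy").any():
        return "pregnancy"
    hcg = measurements[
        (measurements["analyte"] == "HCG")
        & (measurements["day"] >= index_day)
        & (measurements["day"] <= exit_day)
    ]
    if (hcg["value"] > 5).any():
        return "hcg_over_5"
    bp_before = measurements[
        measurements["analyte"].isin(["SBP", "DBP"]) & (measurements["day"] < index_day)
    ]
    if bp_before.empty:
        return "no_baseline_bp"
    return None


def assign_group(change_events, index_day: int, exit_day: int) -> str:
    """'changed' iff at least one persisted change event falls in (index, exit]."""
    for ev in change_events:
        if index_day < ev.day <= exit_day:
            return "changed"
    return "unchanged"


def build_baseline_covariates(
    person: pd.Series,
    conditions: pd.DataFrame,
    measurements: pd.DataFrame,
    index_day: int,
    window_days: int,
    index_year: int,
    egfr_coefficient: float = 175.0,
) -> dict:
    """Baseline covariate map evaluated on [index - window_days, index)."""
    window = (index_day - window_days, index_day)
    cov: dict = {
        "age": index_year - int(person["birth_year"]),
        "male": int(person["sex"] == "M"),
        "index_year": index_year,
    }
    bp_before = measurements[measurements["day"] < index_day]
    for analyte, name in (("SBP", "sbp"), ("DBP", "dbp")):
        rows = bp_before[bp_before["analyte"] == analyte]
        if rows.empty:
            raise IntegrityError(
                f"person {person['person_id']}: no pre-index {analyte} after exclusions"
            )
        cov[name] = float(rows.sort_values("day").iloc[-1]["value"])

    lo, hi = window
    in_win = conditions[(conditions["day"] >= lo) & (conditions["day"] < hi)]
    cats = set(in_win["condition_category"])
    demographics = {
        "age": cov["age"],
        "female": person["sex"] == "F",
        "black": bool(person.get("race_flag", False)),
    }
    rules = ph.default_rules()
    for cat in DISEASE_CATEGORIES:
        if cat in _LAB_PHENOTYPES:
            flag = ph.evaluate_rule(
                rules[_LAB_PHENOTYPES[cat]], measurements, conditions, window,
                demographics=demographics, egfr_coefficient=egfr_coefficient,
            )
            cov[cat] = int(flag or cat in cats)
        else:
            cov[cat] = int(cat in cats)
    for cat in MEDICATION_CATEGORIES:
        cov[cat] = int(cat in cats)
    cov["hospitalization"] = int("hospitalization" in cats)
    cov["n_comorbidities"] = int(sum(cov[c] for c in DISEASE_CATEGORIES))
    cov["n_medications"] = int(sum(cov[c] for c in MEDICATION_CATEGORIES))
    return cov


def build_cohort(
    bundle: TableBundle,
    window_days: int = 365,
    gap_tolerance: int = MAX_GAP_DAYS,
    min_persist_days: int = 30,
    followup_days: int = FOLLOWUP_DAYS,
    coverage_floor: int = COVERAGE_FLOOR,
    min_history_days: int = HISTORY_DAYS,
    max_steps: int = 5,
    egfr_coefficient: float = 175.0,
) -> CohortResult:
    """Apply eligibility, exclusion, and group assignment to every person.

    Returns the cohort table (eligible persons with covariates), the attrition
    report, and the per-person persisted regimens / change events / class-label
    sequences used downstream.
    """
    drug_by_pid = dict(iter(bundle.drug_exposures.groupby("person_id")))
    cond_by_pid = dict(iter(bundle.condition_occurrences.groupby("person_id")))
    meas_by_pid = dict(iter(bundle.measurements.groupby("person_id")))
    empty_cond = bundle.condition_occurrences.iloc[0:0]
    empty_meas = bundle.measurements.iloc[0:0]

    report = EligibilityReport(screened=len(bundle.persons))
    rows = []
    regimen_store, event_store, sequence_store = {}, {}, {}

    for _, person in bundle.persons.iterrows():
        pid = int(person["person_id"])
        exposures = drug_by_pid.get(pid)
        conditions = cond_by_pid.get(pid, empty_cond)
        measurements = meas_by_pid.get(pid, empty_meas)

        record_days = []
        if exposures is not None:
            record_days.append(int(exposures["start_day"].min()))
        if not conditions.empty:
            record_days.append(int(conditions["day"].min()))
        if not measurements.empty:
            record_days.append(int(measurements["day"].min()))

        def _exclude(reason):
            report.reasons[reason] = report.reasons.get(reason, 0) + 1
            report.person_reasons[pid] = reason

        index_day = exit_day = None
        if exposures is None or not record_days:
            _exclude("no_prior_history")
            continue
        history_start = min(record_days)
        index_day = find_index_date(
            exposures["start_day"].tolist(), history_start, min_history_days
        )
        if index_day is None:
            _exclude("no_prior_history")
            continue
        exit_day = index_day + followup_days

        intervals = list(zip(exposures["start_day"], exposures["end_day"]))
        coverage, max_gap, continuous = assess_continuity(
            intervals, index_day, exit_day, coverage_floor, gap_tolerance
        )
        if not continuous:
            _exclude("discontinuous")
            continue

        index_year = bundle.year_of(index_day)
        reason = apply_exclusions(
            person, conditions, measurements, index_day, exit_day, index_year
        )
        if reason is not None:
            _exclude(reason)
            continue

        eras = rg.build_drug_eras(exposures, gap_tolerance=gap_tolerance)
        regs = rg.derive_regimens(eras, index_day, exit_day, gap_tolerance=gap_tolerance)
        persisted = rg.filter_transient_regimens(regs, min_days=min_persist_days)
        events = rg.detect_changes(persisted)
        group = assign_group(events, index_day, exit_day)
        sequence = rg.extract_sequence(persisted, max_steps=max_steps)

        cov = build_baseline_covariates(
            person, conditions, measurements, index_day, window_days, index_year,
            egfr_coefficient=egfr_coefficient,
        )
        regimen_store[pid] = persisted
        event_store[pid] = events
        sequence_store[pid] = sequence
        rows.append(
            {
                "person_id": pid,
                "index_day": index_day,
                "exit_day": exit_day,
                "eligible": True,
                "exclusion": None,
                "group": group,
                "initial_regimen": persisted[0].label if persisted else "",
                "n_changes": len(events),
                "coverage_days": coverage,
                "max_gap_days": max_gap,
                **cov,
            }
        )
        report.eligible += 1

    cohort = pd.DataFrame(rows)
    if not cohort.empty:
        cohort = cohort.sort_values("person_id").reset_index(drop=True)
    return CohortResult(cohort, report, regimen_store, event_store, sequence_store)
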