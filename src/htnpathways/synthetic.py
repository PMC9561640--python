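"""Synthetic OMOP-like tables with known ground truth.

The generator emulates the data structure the pipeline consumes: refill-style
prescription sequences for the six anti-hypertensive classes, regimen-change
events governed by a logistic model on person covariates, lab panels and
diagnosis records consistent with the phenotype thresholds, and planted
eligibility violations (continuity gaps, missing history, under-age, surgery,
pregnancy, hCG, missing baseline blood pressure).

Every planted quantity is recorded in a :class:`TruthLog` so each downstream
stage can be tested against ground truth.  Dates are integer day offsets from
the study start; conversion to ISO dates happens only at I/O.  All randomness
derives from ``rng_seed`` through one stream per table with per-person
substreams, so adding a table never perturbs another table's draws and the
same configuration always yields byte-identical output.

Default magnitudes follow the observed cohort this generator emulates: mean
age 62.5 +/- 10.8 years, 55.2% male, initial regimens of 1/2/>=3 drugs in
proportions 63.2/27.5/9.6%, class mix dominated by ARB and CCB, 30-day
refills, and comorbidity prevalences matching the baseline table.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io import DEFAULT_ORIGIN, TableBundle
from .phenotypes import EXPECTED_UNITS, mdrd_egfr
from .regimens import (
    CHANGED_TO_DIFFERENT_CLASS,
    CHANGED_WITHIN_CLASS,
    CLASS_ORDER,
    DOSE_INCREASED,
    DOSE_REDUCED,
    MEDICATION_ADDED,
    MEDICATION_REMOVED,
)

# RNG stream codes, one per output table / planting stage
_POP, _RX, _LAB, _COND, _CHANGE = 1, 2, 3, 4, 5

_INGREDIENTS_PER_CLASS = 3
_BASE_DOSE = 50.0

EXCLUSION_FRACTION_KEYS = (
    "no_prior_history",
    "discontinuous",
    "age_under_18",
    "major_surgery",
    "pregnancy",
    "hcg_over_5",
    "no_baseline_bp",
)


def _normalized(values):
    arr = np.asarray(values, dtype=float)
    return tuple(arr / arr.sum())


def _default_class_weights():
    # initial-monotherapy mix: ACEi 5, ARB 190, BB 36, CCB 167, DU 3, OTHER 1
    counts = {"ACEi": 5, "ARB": 190, "BB": 36, "CCB": 167, "DU": 3, "OTHER": 1}
    total = sum(counts.values())
    return {k: v / total for k, v in counts.items()}


@dataclass
class SimulationConfig:
    n_persons: int = 800
    origin: dt.date = DEFAULT_ORIGIN
    study_days: int = 4000  # ~11 years, so index dates spread over several years
    age_mean: float = 62.5
    age_sd: float = 10.8
    male_fraction: float = 0.552
    class_weights: dict = field(default_factory=_default_class_weights)
    initial_combo_fractions: tuple = field(
        default_factory=lambda: _normalized((0.632, 0.275, 0.096))
    )
    refill_interval_days: int = 30
    gap_days_distribution: tuple = ("uniform", 0, 5)  # or ("constant", v)
    change_intercept: float = -0.35
    covariate_effects: dict = field(
        default_factory=lambda: {"dbp_centered": 0.02, "male": 0.15, "arrhythmia": 2.3}
    )
    n_changes_poisson_mean: float = 0.8  # extra changes beyond the first
    lab_noise_sd: dict = field(
        default_factory=lambda: {"SBP": 8.0, "DBP": 6.0, "TC": 15.0}
    )
    exclusion_fractions: dict = field(
        default_factory=lambda: {
            "no_prior_history": 0.03,
            "discontinuous": 0.05,
            "age_under_18": 0.02,
            "major_surgery": 0.02,
            "pregnancy": 0.015,
            "hcg_over_5": 0.01,
            "no_baseline_bp": 0.03,
        }
    )
    disease_prevalence: dict = field(
        default_factory=lambda: {
            "diabetes_mellitus": 0.215,
            "dyslipidemia": 0.461,
            "liver_disease": 0.123,
            "renal_disease": 0.10,
            "gastrointestinal_diseases": 0.146,
            "insomnia": 0.02,
            "mental_behavioral_diseases": 0.039,
            "neoplasm": 0.077,
            "arrhythmia": 0.022,
            "angina_pectoris": 0.07,
        }
    )
    medication_prevalence: dict = field(
        default_factory=lambda: {
            "rx_antianginal": 0.086,
            "rx_anticoagulant": 0.178,
            "rx_statin": 0.468,
            "rx_nsaid": 0.374,
            "rx_gastrointestinal": 0.465,
            "rx_sedative": 0.261,
        }
    )
    hospitalization_rate: float = 0.15
    rng_seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self):
        if self.n_persons < 0:
            raise ConfigurationError("n_persons must be >= 0")
        if abs(sum(self.class_weights.values()) - 1.0) > 1e-9:
            raise ConfigurationError("class_weights must sum to 1")
        if set(self.class_weights) - set(CLASS_ORDER):
            raise ConfigurationError(f"unknown drug class in class_weights")
        if abs(sum(self.initial_combo_fractions) - 1.0) > 1e-9:
            raise ConfigurationError("initial_combo_fractions must sum to 1")
        if self.study_days <= 1460:
            raise ConfigurationError(
                "study_days must exceed 1460 (365-day history + 1095-day follow-up)"
            )
        if not 0 <= self.male_fraction <= 1:
            raise ConfigurationError("male_fraction must be a probability")
        if self.refill_interval_days < 1:
            raise ConfigurationError("refill_interval_days must be >= 1")
        kind = self.gap_days_distribution[0]
        if kind not in ("uniform", "constant"):
            raise ConfigurationError(f"unknown gap distribution kind {kind!r}")
        for key in self.exclusion_fractions:
            if key not in EXCLUSION_FRACTION_KEYS:
                raise ConfigurationError(f"unknown exclusion fraction {key!r}")
        if sum(self.exclusion_fractions.values()) > 1:
            raise ConfigurationError("exclusion fractions must sum to <= 1")


@dataclass
class PersonTruth:
    person_id: int
    exclusion: Optional[str] = None
    group: Optional[str] = None          # changed/unchanged; None when excluded
    covariates: dict = field(default_factory=dict)
    changes: list = field(default_factory=list)  # [{"day": d, "mode": m}]
    index_day: int = 0
    # internal generator state (not serialized)
    regimen: dict = field(default_factory=dict, repr=False)     # ingredient -> (class, dose)
    segments: list = field(default_factory=list, repr=False)    # (start, end, regimen dict)
    blackout: Optional[tuple] = field(default=None, repr=False)  # (start, end) planted holiday
    phenotype_via: dict = field(default_factory=dict, repr=False)  # category -> "dx"/analyte


@dataclass
class TruthLog:
    persons: dict = field(default_factory=dict)  # person_id -> PersonTruth

    def counts_by_exclusion(self) -> dict:
        out: dict = {}
        for p in self.persons.values():
            if p.exclusion:
                out[p.exclusion] = out.get(p.exclusion, 0) + 1
        return out

    def group_labels(self) -> dict:
        return {pid: p.group for pid, p in self.persons.items() if p.group is not None}

    def to_json(self, path):
        payload = {
            str(pid): {
                "exclusion": p.exclusion,
                "group": p.group,
                "index_day": p.index_day,
                "covariates": {k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
                               for k, v in p.covariates.items()},
                "changes": p.changes,
            }
            for pid, p in self.persons.items()
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def _rng(config, *key):
    return np.random.default_rng([config.rng_seed & 0x7FFFFFFF, *key])


def _invlogit(x):
    return 1.0 / (1.0 + math.exp(-x))


def _ingredient(cls: str, k: int) -> str:
    return f"{cls.lower()}_{k}"


# ---------------------------------------------------------------------------
# population
# ---------------------------------------------------------------------------

def generate_population(config: SimulationConfig):
    """Persons table plus the truth log seeded with covariates and planted exclusions."""
    n = config.n_persons
    truth = TruthLog()
    rng = _rng(config, _POP)
    if n == 0:
        persons = pd.DataFrame(columns=["person_id", "sex", "birth_year", "race_flag"])
        return persons, truth

    # index dates spread across the study window, leaving room for 365+ days of
    # history before and the 1,095-day follow-up after
    index_days = 400 + rng.integers(0, config.study_days - 1495 + 1, size=n)
    male = rng.random(n) < config.male_fraction
    ages = np.clip(np.round(rng.normal(config.age_mean, config.age_sd, size=n)), 25, 95)

    # one categorical draw per person -> planted exclusions are mutually exclusive
    keys = list(EXCLUSION_FRACTION_KEYS)
    probs = [config.exclusion_fractions.get(k, 0.0) for k in keys]
    probs.append(1.0 - sum(probs))
    excl_draw = rng.choice(len(keys) + 1, size=n, p=probs)

    dbp = rng.normal(80.0, 10.0, size=n)
    sbp = rng.normal(135.0, 15.0, size=n)
    disease = {
        cat: rng.random(n) < p for cat, p in config.disease_prevalence.items()
    }
    meds = {cat: rng.random(n) < p for cat, p in config.medication_prevalence.items()}
    hosp = rng.random(n) < config.hospitalization_rate

    rows = []
    for i in range(n):
        pid = i + 1
        excl = keys[excl_draw[i]] if excl_draw[i] < len(keys) else None
        if excl in ("pregnancy", "hcg_over_5") and male[i]:
            excl = None  # female-only exclusions
        age = 16 if excl == "age_under_18" else int(ages[i])
        index_day = int(index_days[i])
        index_year = (config.origin + dt.timedelta(days=index_day)).year
        cov = {
            "male": int(male[i]),
            "age": age,
            "sbp": round(float(sbp[i]), 1),
            "dbp": round(float(dbp[i]), 1),
            "hospitalization": int(hosp[i]),
        }
        cov["dbp_centered"] = cov["dbp"] - 80.0
        for cat, flags in disease.items():
            cov[cat] = int(flags[i])
        for cat, flags in meds.items():
            cov[cat] = int(flags[i])
        truth.persons[pid] = PersonTruth(
            person_id=pid, exclusion=excl, covariates=cov, index_day=index_day
        )
        rows.append(
            {
                "person_id": pid,
                "sex": "M" if male[i] else "F",
                "birth_year": index_year - age,
                "race_flag": False,
            }
        )
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# prescriptions
# ---------------------------------------------------------------------------

def _draw_gap(rng, config) -> int:
    kind, *params = config.gap_days_distribution
    if kind == "constant":
        return int(params[0])
    lo, hi = params
    return int(rng.integers(lo, hi + 1))


def _emit_person_rx(pid: int, truth: PersonTruth, config: SimulationConfig) -> list:
    """Refill rows for one person from their regimen segments (deterministic per person)."""
    rng = _rng(config, _RX, pid)
    rows = []
    interval = config.refill_interval_days
    blackout = truth.blackout
    for seg_start, seg_end, regimen in truth.segments:
        for ingredient in sorted(regimen):
            cls, dose = regimen[ingredient]
            t = seg_start
            while t <= seg_end:
                end = min(t + interval - 1, seg_end)
                if blackout and t < blackout[1] + 1 and end >= blackout[0]:
                    if t < blackout[0]:
                        rows.append((pid, ingredient, cls, dose, t, blackout[0] - 1))
                    t = blackout[1] + 1
                    continue
                rows.append((pid, ingredient, cls, dose, t, end))
                t = end + 1 + _draw_gap(rng, config)
    return rows


def generate_prescriptions(population: pd.DataFrame, truth: TruthLog,
                           config: SimulationConfig) -> pd.DataFrame:
    """Refill chains from each person's index date (initial regimens only)."""
    classes = sorted(config.class_weights, key=CLASS_ORDER.index)
    weights = np.array([config.class_weights[c] for c in classes])
    combo_probs = np.asarray(config.initial_combo_fractions)

    all_rows = []
    for pid in population["person_id"].astype(int):
        p = truth.persons[pid]
        rng = _rng(config, _RX, pid, 0)  # regimen-composition stream
        n_drugs = int(rng.choice([1, 2, 3], p=combo_probs))
        chosen = rng.choice(len(classes), size=min(n_drugs, len(classes)),
                            replace=False, p=weights)
        regimen = {}
        for ci in chosen:
            cls = classes[ci]
            ing = _ingredient(cls, int(rng.integers(1, _INGREDIENTS_PER_CLASS + 1)))
            regimen[ing] = (cls, _BASE_DOSE)
        p.regimen = regimen
        index, exit_ = p.index_day, p.index_day + 1095
        if p.exclusion == "no_prior_history":
            p.segments = [(index, index + 200, dict(regimen))]
        else:
            p.segments = [(index, exit_, dict(regimen))]
        if p.exclusion == "discontinuous":
            g0 = index + int(rng.integers(200, 601))
            p.blackout = (g0, g0 + int(rng.integers(35, 61)) - 1)
        all_rows.extend(_emit_person_rx(pid, p, config))
    return _rx_frame(all_rows)


def _rx_frame(rows) -> pd.DataFrame:
    df = pd.DataFrame(
        rows,
        columns=["person_id", "ingredient", "drug_class", "daily_dose", "start_day", "end_day"],
    )
    return df.sort_values(
        ["person_id", "start_day", "ingredient", "end_day"], kind="mergesort"
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# planted change events
# ---------------------------------------------------------------------------

def _resolve_covariate(cov: dict, name: str) -> float:
    if ":" in name:
        a, b = name.split(":")
        return _resolve_covariate(cov, a) * _resolve_covariate(cov, b)
    if name not in cov:
        raise ConfigurationError(f"unknown covariate {name!r} in covariate_effects")
    return float(cov[name])


def _feasible_modes(regimen: dict) -> list:
    modes = [DOSE_INCREASED, MEDICATION_ADDED, CHANGED_WITHIN_CLASS]
    if any(dose > 25 for _, dose in regimen.values()):
        modes.append(DOSE_REDUCED)
    if len(regimen) >= 2:
        modes.append(MEDICATION_REMOVED)
    used = {cls for cls, _ in regimen.values()}
    if len(used) < len(CLASS_ORDER):
        modes.append(CHANGED_TO_DIFFERENT_CLASS)
    return modes


def _apply_edit(regimen: dict, mode: str, rng) -> dict:
    new = dict(regimen)
    ingredients = sorted(new)
    if mode == DOSE_INCREASED:
        ing = ingredients[int(rng.integers(len(ingredients)))]
        cls, dose = new[ing]
        new[ing] = (cls, dose * 2)
    elif mode == DOSE_REDUCED:
        cands = [i for i in ingredients if new[i][1] > 25]
        ing = cands[int(rng.integers(len(cands)))]
        cls, dose = new[ing]
        new[ing] = (cls, dose / 2)
    elif mode == MEDICATION_ADDED:
        used = {cls for cls, _ in new.values()}
        avail = [c for c in CLASS_ORDER if c not in used]
        cls = avail[int(rng.integers(len(avail)))]
        new[_ingredient(cls, int(rng.integers(1, _INGREDIENTS_PER_CLASS + 1)))] = (cls, _BASE_DOSE)
    elif mode == MEDICATION_REMOVED:
        ing = ingredients[int(rng.integers(len(ingredients)))]
        del new[ing]
    elif mode == CHANGED_WITHIN_CLASS:
        ing = ingredients[int(rng.integers(len(ingredients)))]
        cls, dose = new[ing]
        k_old = int(ing.rsplit("_", 1)[1])
        options = [k for k in range(1, _INGREDIENTS_PER_CLASS + 1) if k != k_old]
        del new[ing]
        new[_ingredient(cls, options[int(rng.integers(len(options)))])] = (cls, dose)
    elif mode == CHANGED_TO_DIFFERENT_CLASS:
        ing = ingredients[int(rng.integers(len(ingredients)))]
        _, dose = new[ing]
        used = {cls for cls, _ in new.values()}
        avail = [c for c in CLASS_ORDER if c not in used]
        cls = avail[int(rng.integers(len(avail)))]
        del new[ing]
        new[_ingredient(cls, int(rng.integers(1, _INGREDIENTS_PER_CLASS + 1)))] = (cls, dose)
    else:
        raise ValueError(f"unknown mode {mode}")
    return new


def plant_change_events(population: pd.DataFrame, truth: TruthLog,
                        config: SimulationConfig) -> pd.DataFrame:
    """Plant logistic-model-driven regimen edits; returns the updated exposure table.

    P(changed) = inverse-logit(change_intercept + sum effects * covariates);
    each planted edit starts at a refill boundary and the resulting regimen
    persists at least 30 days.  Persons with a planted exclusion keep their
    initial regimen and receive no group label.
    """
    interval = config.refill_interval_days
    # validate covariate names once against the covariate dictionary
    if truth.persons:
        first = next(iter(truth.persons.values()))
        for name in config.covariate_effects:
            _resolve_covariate(first.covariates, name)

    for pid in population["person_id"].astype(int):
        p = truth.persons[pid]
        if p.exclusion is not None:
            continue
        rng = _rng(config, _CHANGE, pid)
        eta = config.change_intercept + sum(
            beta * _resolve_covariate(p.covariates, name)
            for name, beta in config.covariate_effects.items()
        )
        changed = rng.random() < _invlogit(eta)
        p.group = "changed" if changed else "unchanged"
        if not changed:
            continue
        k = 1 + min(int(rng.poisson(config.n_changes_poisson_mean)), 3)
        # candidate refill boundaries between day index+90 and index+870
        candidates = [p.index_day + interval * m for m in range(3, 30)]
        rng.shuffle(candidates)
        days: list = []
        for day in candidates:
            if len(days) == k:
                break
            if all(abs(day - d) >= 60 for d in days):
                days.append(day)
        days.sort()
        index, exit_ = p.index_day, p.index_day + 1095
        state = dict(p.regimen)
        boundaries = [index] + days + [exit_ + 1]
        segments = []
        for j, day in enumerate(days):
            segments.append((boundaries[j], day - 1, dict(state)))
            mode = str(rng.choice(_feasible_modes(state)))
            state = _apply_edit(state, mode, rng)
            p.changes.append({"day": int(day), "mode": mode})
        segments.append((days[-1], exit_, dict(state)))
        p.segments = segments

    all_rows = []
    for pid in population["person_id"].astype(int):
        all_rows.extend(_emit_person_rx(pid, truth.persons[pid], config))
    return _rx_frame(all_rows)


# ---------------------------------------------------------------------------
# labs and conditions
# ---------------------------------------------------------------------------

def _scr_at_egfr(target: float, age: float, female: bool) -> float:
    """Serum creatinine at which the MDRD eGFR equals ``target``."""
    base = 175.0 * age ** -0.203 * (0.742 if female else 1.0)
    return (base / target) ** (1.0 / 1.154)


def generate_labs_and_conditions(population: pd.DataFrame, truth: TruthLog,
                                 config: SimulationConfig):
    """Measurement and condition tables consistent with the planted covariates.

    Persons flagged with a lab phenotype receive at least one value crossing
    the corresponding threshold inside the baseline window (labs pinned at
    index - 60 days so both the 365- and 183-day windows see them); unflagged
    persons receive values safely inside the normal range, including a
    creatinine bounded away from both the 1.4 mg/dL and the person-specific
    eGFR-60 thresholds.
    """
    meas_rows, cond_rows = [], []
    noise = config.lab_noise_sd

    def add_meas(pid, analyte, value, day):
        meas_rows.append((pid, analyte, round(float(value), 2), EXPECTED_UNITS[analyte], int(day)))

    for pid in population["person_id"].astype(int):
        p = truth.persons[pid]
        rng = _rng(config, _LAB, pid)
        crng = _rng(config, _COND, pid)
        cov = p.covariates
        index = p.index_day
        lab_day = index - 60

        # clinical-history anchor >= 365 days before index (non-BP)
        if p.exclusion != "no_prior_history":
            add_meas(pid, "TC", np.clip(rng.normal(190, noise.get("TC", 15.0)), 120, 235),
                     index - 400)

        # blood pressure: the index-7 reading is the planted covariate value
        if p.exclusion == "no_baseline_bp":
            add_meas(pid, "SBP", cov["sbp"], index + 10)
            add_meas(pid, "DBP", cov["dbp"], index + 10)
        else:
            add_meas(pid, "SBP", cov["sbp"] + rng.normal(0, noise.get("SBP", 8.0)), index - 30)
            add_meas(pid, "DBP", cov["dbp"] + rng.normal(0, noise.get("DBP", 6.0)), index - 30)
            add_meas(pid, "SBP", cov["sbp"], index - 7)
            add_meas(pid, "DBP", cov["dbp"], index - 7)

        # persons planted without prior history get no further records: nothing
        # may predate their first exposure far enough to create qualifying history
        if p.exclusion == "no_prior_history":
            continue

        # lipid panel
        vals = {
            "TC": np.clip(rng.normal(190, 20), 120, 235),
            "HDL": np.clip(rng.normal(55, 8), 45, 90),
            "LDL": np.clip(rng.normal(120, 15), 70, 155),
            "TG": np.clip(rng.normal(130, 30), 60, 195),
        }
        if cov.get("dyslipidemia"):
            via = str(rng.choice(["TC", "HDL", "LDL", "TG", "dx"]))
            p.phenotype_via["dyslipidemia"] = via
            if via == "TC":
                vals["TC"] = rng.uniform(245, 320)
            elif via == "HDL":
                vals["HDL"] = rng.uniform(25, 38)
            elif via == "LDL":
                vals["LDL"] = rng.uniform(165, 220)
            elif via == "TG":
                vals["TG"] = rng.uniform(210, 400)
            else:
                cond_rows.append((pid, "dyslipidemia", index - int(crng.integers(30, 300))))
        for analyte, v in vals.items():
            add_meas(pid, analyte, v, lab_day)

        # liver enzymes
        ast = np.clip(rng.normal(25, 8), 8, 110)
        alt = np.clip(rng.normal(25, 8), 8, 110)
        if cov.get("liver_disease"):
            via = str(rng.choice(["AST", "ALT", "dx"]))
            p.phenotype_via["liver_disease"] = via
            if via == "AST":
                ast = rng.uniform(130, 300)
            elif via == "ALT":
                alt = rng.uniform(130, 300)
            else:
                cond_rows.append(
                    (pid, str(crng.choice(["steatosis_of_liver", "cirrhosis", "hepatitis"])),
                     index - int(crng.integers(30, 300)))
                )
        add_meas(pid, "AST", ast, lab_day)
        add_meas(pid, "ALT", alt, lab_day)

        # creatinine, bounded away from both renal thresholds when unflagged
        female = not cov["male"]
        safe_upper = min(1.35, 0.95 * _scr_at_egfr(60.0, cov["age"], female))
        if cov.get("renal_disease"):
            via = str(rng.choice(["SCR", "dx"]))
            p.phenotype_via["renal_disease"] = via
            if via == "SCR":
                add_meas(pid, "SCR", rng.uniform(1.5, 2.5), lab_day)
            else:
                add_meas(pid, "SCR", rng.uniform(0.5, max(0.55, safe_upper)), lab_day)
                cond_rows.append(
                    (pid, str(crng.choice(["renal_failure", "chronic_kidney_disease"])),
                     index - int(crng.integers(30, 300)))
                )
        else:
            add_meas(pid, "SCR", rng.uniform(0.5, max(0.55, safe_upper)), lab_day)

        if p.exclusion == "hcg_over_5":
            add_meas(pid, "HCG", rng.uniform(10, 100), index + 200)
        if p.exclusion == "major_surgery":
            cond_rows.append((pid, "major_surgery", index + int(crng.integers(50, 400))))
        if p.exclusion == "pregnancy":
            cond_rows.append((pid, "pregnancy", index + int(crng.integers(50, 400))))

        # pure-diagnosis history categories
        for cat in config.disease_prevalence:
            if cat in ("dyslipidemia", "liver_disease", "renal_disease"):
                continue
            if cov.get(cat):
                cond_rows.append((pid, cat, index - int(crng.integers(30, 300))))
        for cat in config.medication_prevalence:
            if cov.get(cat):
                cond_rows.append((pid, cat, index - int(crng.integers(10, 300))))
        if cov.get("hospitalization"):
            cond_rows.append((pid, "hospitalization", index - int(crng.integers(10, 300))))

    meas = pd.DataFrame(meas_rows, columns=["person_id", "analyte", "value", "unit", "day"])
    cond = pd.DataFrame(cond_rows, columns=["person_id", "condition_category", "day"])
    meas = meas.sort_values(["person_id", "day", "analyte", "value"], kind="mergesort").reset_index(drop=True)
    cond = cond.sort_values(["person_id", "day", "condition_category"], kind="mergesort").reset_index(drop=True)
    return meas, cond


# ---------------------------------------------------------------------------
# top-level
# ---------------------------------------------------------------------------

def simulate(config: SimulationConfig):
    """Generate the full four-table bundle plus its truth log."""
    population, truth = generate_population(config)
    generate_prescriptions(population, truth, config)
    drug = plant_change_events(population, truth, config)
    meas, cond = generate_labs_and_conditions(population, truth, config)
    bundle = TableBundle(
        persons=population,
        drug_exposures=drug,
        condition_occurrences=cond,
        measurements=meas,
        origin=config.origin,
    ).sorted()
    return bundle, truth
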