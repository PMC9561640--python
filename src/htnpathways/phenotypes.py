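"""Lab-threshold and diagnosis-based comorbidity phenotyping.

Three comorbidities are operationally defined from labs and diagnosis
categories, each as an OR over clauses evaluated on records inside a
half-open baseline window [lo, hi):

* dyslipidemia  - TC >= 240 mg/dL, HDL < 40 mg/dL, LDL >= 160 mg/dL,
  TG >= 200 mg/dL, or a dyslipidemia diagnosis;
* liver disease - AST or ALT >= 120 IU/L (3x the upper limit of normal),
  or a diagnosis of hepatic steatosis, cirrhosis, or hepatitis;
* renal disease - serum creatinine > 1.4 mg/dL, MDRD eGFR < 60
  mL/min/1.73 m^2 computed from each in-window creatinine, or a diagnosis
  of renal failure / chronic kidney disease.

Comparator strictness mirrors the operational definitions exactly
(>= 240 inclusive, > 1.4 strict, < 40 strict, < 60 strict).
"""

from __future__ import annotations

import operator
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .errors import BundleValidationError

_OPS = {">=": operator.ge, ">": operator.gt, "<": operator.lt, "<=": operator.le}

EXPECTED_UNITS = {
    "SBP": "mmHg",
    "DBP": "mmHg",
    "TC": "mg/dL",
    "HDL": "mg/dL",
    "LDL": "mg/dL",
    "TG": "mg/dL",
    "AST": "IU/L",
    "ALT": "IU/L",
    "SCR": "mg/dL",
    "HCG": "mIU/mL",
}

DYSLIPIDEMIA_DX = frozenset({"dyslipidemia"})
LIVER_DX = frozenset({"steatosis_of_liver", "cirrhosis", "hepatitis"})
RENAL_DX = frozenset({"renal_failure", "chronic_kidney_disease"})


def mdrd_egfr(scr: float, age: float, female: bool, black: bool = False,
              coefficient: float = 175.0) -> float:
    """Estimated GFR (mL/min/1.73 m^2) from the 4-variable MDRD equation.

    eGFR = coefficient * SCr^(-1.154) * age^(-0.203) * 0.742 [if female]
           * 1.212 [if black]

    The IDMS-traceable coefficient 175 is the default; pass 186 for the
    legacy calibration.
    """
    if scr <= 0:
        raise ValueError(f"serum creatinine must be positive, got {scr}")
    egfr = coefficient * scr ** -1.154 * age ** -0.203
    if female:
        egfr *= 0.742
    if black:
        egfr *= 1.212
    return egfr


@dataclass(frozen=True)
class LabClause:
    analyte: str
    comparator: str  # one of >=, >, <, <=
    threshold: float

    def holds(self, value: float) -> bool:
        return _OPS[self.comparator](value, self.threshold)


@dataclass(frozen=True)
class PhenotypeRule:
    """An OR of lab clauses and diagnosis-category lookups."""

    name: str
    lab_clauses: tuple = ()
    diagnosis_categories: frozenset = frozenset()
    egfr_below: float = None  # MDRD eGFR threshold applied to in-window SCR

    def __post_init__(self):
        if not (self.lab_clauses or self.diagnosis_categories or self.egfr_below):
            raise ValueError(f"rule {self.name!r} has no clauses")


def _in_window(df: pd.DataFrame, day_col: str, window) -> pd.DataFrame:
    lo, hi = window
    return df[(df[day_col] >= lo) & (df[day_col] < hi)]


def _check_units(meas: pd.DataFrame, analytes: Iterable[str]):
    if "unit" not in meas.columns:
        return
    for analyte in analytes:
        units = set(meas.loc[meas["analyte"] == analyte, "unit"].unique())
        bad = units - {EXPECTED_UNITS[analyte]}
        if bad:
            raise BundleValidationError(
                [f"analyte {analyte}: unexpected unit(s) {sorted(bad)}"]
            )


def evaluate_rule(
    rule: PhenotypeRule,
    measurements: pd.DataFrame,
    diagnoses: pd.DataFrame,
    window,
    demographics: dict = None,
    egfr_coefficient: float = 175.0,
) -> bool:
    """True iff any clause of the rule is satisfied by an in-window record."""
    meas = _in_window(measurements, "day", window)
    for clause in rule.lab_clauses:
        _check_units(meas, [clause.analyte])
        vals = meas.loc[meas["analyte"] == clause.analyte, "value"]
        if vals.map(clause.holds).any():
            return True
    if rule.egfr_below is not None and demographics is not None:
        scr = meas.loc[meas["analyte"] == "SCR", "value"]
        for v in scr:
            if v > 0 and mdrd_egfr(
                v,
                demographics["age"],
                demographics["female"],
                demographics.get("black", False),
                coefficient=egfr_coefficient,
            ) < rule.egfr_below:
                return True
    if rule.diagnosis_categories:
        dx = _in_window(diagnoses, "day", window)
        if dx["condition_category"].isin(rule.diagnosis_categories).any():
            return True
    return False


def default_rules() -> dict:
    """The three shipped lab-based phenotype rules, keyed by name."""
    return {
        "dyslipidemia": PhenotypeRule(
            "dyslipidemia",
            lab_clauses=(
                LabClause("TC", ">=", 240.0),
                LabClause("HDL", "<", 40.0),
                LabClause("LDL", ">=", 160.0),
                LabClause("TG", ">=", 200.0),
            ),
            diagnosis_categories=DYSLIPIDEMIA_DX,
        ),
        "liver_disease": PhenotypeRule(
            "liver_disease",
            lab_clauses=(LabClause("AST", ">=", 120.0), LabClause("ALT", ">=", 120.0)),
            diagnosis_categories=LIVER_DX,
        ),
        "renal_disease": PhenotypeRule(
            "renal_disease",
            lab_clauses=(LabClause("SCR", ">", 1.4),),
            diagnosis_categories=RENAL_DX,
            egfr_below=60.0,
        ),
    }


def load_rules(path=None) -> dict:
    """Load phenotype rules from YAML; defaults to the packaged phenotypes.yaml."""
    if path is None:
        text = resources.files("htnpathways").joinpath("data/phenotypes.yaml").read_text()
    else:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    rules = {}
    for name, spec in raw.items():
        rules[name] = PhenotypeRule(
            name,
            lab_clauses=tuple(
                LabClause(c["analyte"], c["comparator"], float(c["threshold"]))
                for c in spec.get("lab_clauses", [])
            ),
            diagnosis_categories=frozenset(spec.get("diagnosis_categories", [])),
            egfr_below=spec.get("egfr_below"),
        )
    return rules


def flag_dyslipidemia(measurements, diagnoses, window) -> bool:
    return evaluate_rule(default_rules()["dyslipidemia"], measurements, diagnoses, window)


def flag_liver_disease(measurements, diagnoses, window) -> bool:
    return evaluate_rule(default_rules()["liver_disease"], measurements, diagnoses, window)


def flag_renal_disease(measurements, diagnoses, demographics, window,
                       egfr_coefficient: float = 175.0) -> bool:
    return evaluate_rule(
        default_rules()["renal_disease"], measurements, diagnoses, window,
        demographics=demographics, egfr_coefficient=egfr_coefficient,
    )
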