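"""End-to-end orchestration: bundle -> cohort -> pathways -> matched association analysis.

Produces the report artifacts as delimited text / JSON: attrition.csv,
table1.csv (baseline comparison pre/post matching), initial_regimens.csv,
change_modes.csv, table4.csv (univariate + stepwise-selected multivariate
odds ratios), sankey.json, and run_log.json (config echo, seed, per-stage
record counts).  All randomness (matching tie-breaks) funnels through one
seed, so reruns with the same configuration yield identical artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import associations as assoc
from . import cohort as ch
from . import regimens as rg
from .errors import ConfigurationError, HtnPathwaysError, RareEventError, SeparationError
from .io import read_bundle

log = logging.getLogger(__name__)

#: Covariates entering the propensity model: index year, age, sex, prescription
#: records (count of distinct baseline medication categories) and general
#: medical history flags.
PROPENSITY_COVARIATES = (
    "index_year",
    "age",
    "male",
    "n_medications",
) + ch.DISEASE_CATEGORIES

#: Covariates screened for the association analysis.
ANALYSIS_COVARIATES = (
    "index_year",
    "age",
    "male",
    "sbp",
    "dbp",
    "hospitalization",
    "n_comorbidities",
    "n_medications",
) + ch.DISEASE_CATEGORIES + ch.MEDICATION_CATEGORIES


@dataclass
class PipelineConfig:
    input_dir: str
    output_dir: str
    baseline_window: int = 365       # days; 183 for the 6-month sensitivity run
    gap_tolerance: int = 30          # days of tolerated drug holiday
    persistence_days: int = 30       # minimum regimen persistence
    caliper_sd_logit: float = 0.2
    matched: bool = True
    max_steps: int = 5
    screen_alpha: float = 0.2        # univariate p-value screen for the stepwise model
    max_model_terms: int = 8         # cap on screened main effects
    seed: int = 0
    or_decimals: int = 2

    def validate(self):
        if self.baseline_window <= 0 or self.gap_tolerance < 0 or self.persistence_days <= 0:
            raise ConfigurationError("windows and tolerances must be positive")
        if Path(self.input_dir).resolve() == Path(self.output_dir).resolve():
            raise ConfigurationError("input and output directories must differ")


def summarize_frequency(change_counts) -> dict:
    """Min / max / median and full histogram of per-person change counts."""
    counts = pd.Series(list(change_counts), dtype=int)
    if counts.empty:
        return {"n": 0, "min": None, "max": None, "median": None, "histogram": {}}
    hist = counts.value_counts().sort_index()
    return {
        "n": int(len(counts)),
        "min": int(counts.min()),
        "max": int(counts.max()),
        "median": float(counts.median()),
        "histogram": {int(k): int(v) for k, v in hist.items()},
    }


def render_attrition(report: ch.EligibilityReport, matched_pairs: int = None) -> pd.DataFrame:
    """Ordered attrition table: screened -> each exclusion -> eligible [-> matched]."""
    rows = []
    remaining = report.screened
    rows.append({"step": "screened", "removed": 0, "remaining": remaining})
    for reason in ch.EXCLUSION_ORDER:
        removed = report.reasons.get(reason, 0)
        remaining -= removed
        rows.append({"step": f"excluded_{reason}", "removed": removed, "remaining": remaining})
    rows.append({"step": "eligible", "removed": 0, "remaining": remaining})
    if matched_pairs is not None:
        rows.append({"step": "matched", "removed": remaining - 2 * matched_pairs,
                     "remaining": 2 * matched_pairs})
    return pd.DataFrame(rows)


def _univariate_all(df: pd.DataFrame, covariates) -> list:
    """Univariate estimates, falling back to a continuity-corrected 2x2 on separation."""
    out = []
    for cov in covariates:
        if df[cov].nunique() <= 1:
            log.warning("skipping constant covariate %s", cov)
            continue
        try:
            out.append(assoc.fit_univariate(df, cov))
        except SeparationError:
            t = assoc.TwoByTwo.from_groups(df[cov] > 0, df["group"] == "changed")
            est = assoc.crude_or(t, continuity_correction=True)
            est.term = cov
            out.append(est)
            log.warning("covariate %s: separation; continuity-corrected 2x2 used", cov)
    return out


def run_association_analysis(cohort_df: pd.DataFrame, config: PipelineConfig) -> dict:
    """Matching plus univariate / stepwise multivariate logistic analysis."""
    analysis_covs = [c for c in ANALYSIS_COVARIATES if c in cohort_df.columns]
    prop_covs = [c for c in PROPENSITY_COVARIATES
                 if c in cohort_df.columns and cohort_df[c].nunique() > 1]

    table1_pre = assoc.compare_baseline(cohort_df, analysis_covs)
    if config.matched:
        while True:
            try:
                scores = assoc.fit_propensity(cohort_df, prop_covs)
                break
            except SeparationError as exc:
                if not exc.terms or not set(exc.terms) & set(prop_covs):
                    raise
                log.warning("propensity model: dropping separating term(s) %s", exc.terms)
                prop_covs = [c for c in prop_covs if c not in exc.terms]
        match = assoc.match_1to1(
            scores, (cohort_df["group"] == "changed").to_numpy(),
            caliper_sd_logit=config.caliper_sd_logit, seed=config.seed,
        )
        keep = [i for pair in match.pairs for i in pair]
        analysis_df = cohort_df.iloc[keep].reset_index(drop=True)
    else:
        match = None
        analysis_df = cohort_df
    table1_post = assoc.compare_baseline(analysis_df, analysis_covs)

    uni = _univariate_all(analysis_df, analysis_covs)
    screened = [e.term for e in sorted(uni, key=lambda e: e.p_value)
                if e.p_value < config.screen_alpha][: config.max_model_terms]
    if not screened:  # keep the model non-empty: carry the best-ranked covariates
        screened = [e.term for e in sorted(uni, key=lambda e: e.p_value)[:3]]
    selected, trace = assoc.stepwise_aic(analysis_df, screened)
    multi = assoc.fit_multivariate(analysis_df, selected) if selected else []

    return {
        "table1_pre": table1_pre,
        "table1_post": table1_post,
        "match": match,
        "analysis_df": analysis_df,
        "univariate": uni,
        "screened": screened,
        "selected": selected,
        "stepwise_trace": trace,
        "multivariate": multi,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline and write the seven report artifacts."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_counts = {}

    try:
        bundle = read_bundle(config.input_dir)
    except HtnPathwaysError as exc:
        raise type(exc)(f"[read_bundle] {exc}") from exc
    stage_counts["persons_in"] = len(bundle.persons)

    result = ch.build_cohort(
        bundle,
        window_days=config.baseline_window,
        gap_tolerance=config.gap_tolerance,
        min_persist_days=config.persistence_days,
        max_steps=config.max_steps,
    )
    cohort_df = result.cohort
    stage_counts["eligible"] = int(result.report.eligible)
    if cohort_df.empty or cohort_df["group"].nunique() < 2:
        raise HtnPathwaysError("[build_cohort] cohort too small for association analysis")

    initial = rg.tabulate_initial_regimens(cohort_df, strata=["male"])
    modes = rg.tabulate_change_modes(
        [e for evs in result.events.values() for e in evs]
    )
    sankey = rg.export_sankey(result.sequences.values())
    freq = summarize_frequency(cohort_df["n_changes"])

    stats = run_association_analysis(cohort_df, config)
    match = stats["match"]
    attrition = render_attrition(result.report, match.n_pairs if match else None)
    stage_counts["matched_pairs"] = match.n_pairs if match else None

    sensitivity = config.baseline_window != 365

    paths = {}
    paths["attrition"] = out / "attrition.csv"
    attrition.to_csv(paths["attrition"], index=False)
    paths["table1"] = out / "table1.csv"
    t1 = pd.concat(
        [stats["table1_pre"].assign(stage="pre_matching"),
         stats["table1_post"].assign(stage="post_matching")]
    )
    t1.to_csv(paths["table1"], index=False)
    paths["initial_regimens"] = out / "initial_regimens.csv"
    initial.to_csv(paths["initial_regimens"], index=False)
    paths["change_modes"] = out / "change_modes.csv"
    modes.to_csv(paths["change_modes"])
    paths["table4"] = out / "table4.csv"
    t4 = assoc.estimates_table(stats["univariate"] + stats["multivariate"],
                               decimals=config.or_decimals)
    t4["analysis"] = np.where(
        t4["adjusted"], "multivariate", "univariate"
    )
    t4["baseline_window_days"] = config.baseline_window
    t4["sensitivity"] = sensitivity
    t4.to_csv(paths["table4"], index=False)
    paths["sankey"] = out / "sankey.json"
    with open(paths["sankey"], "w", encoding="utf-8") as fh:
        json.dump(sankey, fh, indent=1)
    paths["run_log"] = out / "run_log.json"
    with open(paths["run_log"], "w", encoding="utf-8") as fh:
        json.dump(
            {
                "config": {k: str(v) for k, v in dataclasses.asdict(config).items()},
                "seed": config.seed,
                "stage_counts": stage_counts,
                "change_frequency": freq,
                "selected_terms": stats["selected"],
            },
            fh,
            indent=1,
        )
    if match is not None:
        paths["match_log"] = out / "match_log.csv"
        pd.DataFrame(match.pairs, columns=["changed_row", "unchanged_row"]).to_csv(
            paths["match_log"], index=False
        )
    return {"paths": {k: str(v) for k, v in paths.items()}, "stats": stats,
            "cohort": cohort_df, "report": result.report, "frequency": freq}
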