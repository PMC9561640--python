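"""Baseline comparison, 1:1 propensity matching, and logistic association analysis.

The outcome throughout is group membership (changed = 1, unchanged = 0).
Odds ratios from 2x2 tables use the cross-product ratio with a Wald
(Woolf) confidence interval; logistic fits go through statsmodels.  The
multivariate model is selected by stepwise minimization of AIC over main
effects and all second-order interactions, with the hierarchy principle
enforced (an interaction keeps both of its main effects in the model).

Matching is greedy nearest-neighbour without replacement on the logit of
the propensity score, with a caliper expressed in SD units of the logit
scores; the smaller group drives the matching and candidates are processed
in descending score order with seeded tie-breaking, so results are
deterministic given the seed.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import RareEventError, SeparationError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TwoByTwo:
    """Counts: a = changed & exposed, b = changed & unexposed,
    c = unchanged & exposed, d = unchanged & unexposed."""

    a: float
    b: float
    c: float
    d: float

    @classmethod
    def from_groups(cls, exposed, changed) -> "TwoByTwo":
        exposed = np.asarray(exposed, dtype=bool)
        changed = np.asarray(changed, dtype=bool)
        return cls(
            a=int((changed & exposed).sum()),
            b=int((changed & ~exposed).sum()),
            c=int((~changed & exposed).sum()),
            d=int((~changed & ~exposed).sum()),
        )


@dataclass
class EffectEstimate:
    term: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    adjusted: bool = False
    coef: float = field(default=np.nan)
    se: float = field(default=np.nan)


@dataclass
class PropensityMatch:
    pairs: list  # (changed person index, unchanged person index)
    caliper: float
    seed: int
    discarded: list

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def crude_or(t: TwoByTwo, continuity_correction: bool = False,
             alpha: float = 0.05) -> EffectEstimate:
    """Cross-product odds ratio (a*d)/(b*c) with Wald CI and p-value.

    Equivalent to the univariate logistic fit of the outcome on the binary
    exposure.  A zero cell raises :class:`RareEventError` unless the 0.5
    continuity correction is enabled.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    if min(a, b, c, d) < 0:
        raise ValueError("2x2 cells must be non-negative")
    if min(a, b, c, d) == 0:
        if not continuity_correction:
            raise RareEventError(f"zero cell in 2x2 table {t}")
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(1 - alpha / 2)
    ln = np.log(or_)
    p = 2 * stats.norm.sf(abs(ln) / se)
    return EffectEstimate(
        term="exposure",
        odds_ratio=float(or_),
        ci_low=float(np.exp(ln - z * se)),
        ci_high=float(np.exp(ln + z * se)),
        p_value=float(p),
        coef=float(ln),
        se=float(se),
    )


def standardized_mean_difference(x1, x0) -> float:
    """Pooled-SD standardized mean difference between two samples."""
    x1 = np.asarray(x1, dtype=float)
    x0 = np.asarray(x0, dtype=float)
    v = (x1.var(ddof=1) + x0.var(ddof=1)) / 2
    if v == 0:
        return 0.0
    return float((x1.mean() - x0.mean()) / np.sqrt(v))


def compare_baseline(df: pd.DataFrame, covariates: Sequence[str],
                     group_col: str = "group") -> pd.DataFrame:
    """Per-covariate two-group comparison table.

    Continuous covariates (more than two distinct values): mean +/- SD per
    group with a Student's t-test.  Categorical covariates: counts (%) with a
    Pearson chi-square test, switching to Fisher's exact test when any
    expected cell is below 5.  Constant covariates report p = 1.0.
    """
    g1 = df[df[group_col] == "changed"]
    g0 = df[df[group_col] == "unchanged"]
    if g1.empty or g0.empty:
        raise ValueError("both groups must be present")
    rows = []
    for cov in covariates:
        x1, x0 = g1[cov].astype(float), g0[cov].astype(float)
        binary = set(df[cov].astype(float).unique()) <= {0.0, 1.0}
        if df[cov].nunique() <= 1:
            log.warning("covariate %s is constant; p set to 1.0", cov)
            rows.append({"covariate": cov, "type": "constant", "p_value": 1.0,
                         "changed": x1.mean(), "unchanged": x0.mean(), "test": "none",
                         "smd": 0.0})
            continue
        if binary:
            table = np.array([
                [x1.sum(), len(x1) - x1.sum()],
                [x0.sum(), len(x0) - x0.sum()],
            ])
            expected = stats.contingency.expected_freq(table)
            if (expected < 5).any():
                _, p = stats.fisher_exact(table)
                test = "fisher"
            else:
                chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
                test = "chi2"
            rows.append({
                "covariate": cov, "type": "categorical",
                "changed": f"{int(x1.sum())} ({100 * x1.mean():.1f})",
                "unchanged": f"{int(x0.sum())} ({100 * x0.mean():.1f})",
                "p_value": float(p), "test": test,
                "smd": standardized_mean_difference(x1, x0),
            })
        else:
            tstat, p = stats.ttest_ind(x1, x0, equal_var=True)
            rows.append({
                "covariate": cov, "type": "continuous",
                "changed": f"{x1.mean():.1f} ± {x1.std(ddof=1):.1f}",
                "unchanged": f"{x0.mean():.1f} ± {x0.std(ddof=1):.1f}",
                "p_value": float(p), "test": "t",
                "smd": standardized_mean_difference(x1, x0),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# logistic machinery
# ---------------------------------------------------------------------------

def build_design(df: pd.DataFrame, terms: Sequence[str]) -> pd.DataFrame:
    """Design matrix for main effects and 'a:b' product interactions."""
    X = pd.DataFrame(index=df.index)
    for term in terms:
        if ":" in term:
            a, b = term.split(":")
            X[term] = df[a].astype(float) * df[b].astype(float)
        else:
            X[term] = df[term].astype(float)
    return X


def _outcome(df: pd.DataFrame, group_col: str) -> np.ndarray:
    g = df[group_col]
    if g.dtype == object:
        return (g == "changed").astype(float).to_numpy()
    return g.astype(float).to_numpy()


def _fit_logit(y: np.ndarray, X: pd.DataFrame, raise_on_separation: bool = True):
    """Fit a logistic model; detect separation via non-convergence/huge coefs."""
    Xc = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
        except Exception as exc:  # PerfectSeparationError and friends
            if raise_on_separation:
                bad = _suspect_separation(y, X)
                raise SeparationError(f"logistic fit failed ({exc}); suspect terms: {bad}", bad)
            return None
    slopes = res.params.drop("const", errors="ignore")  # intercept absorbs covariate scale
    if not res.mle_retvals.get("converged", True) or (len(slopes) and np.abs(slopes).max() > 15):
        if raise_on_separation:
            bad = _suspect_separation(y, X)
            raise SeparationError(f"(quasi-)separation detected; suspect terms: {bad}", bad)
        return None
    return res


def _suspect_separation(y, X) -> list:
    bad = []
    for col in X.columns:
        x = X[col]
        if x.nunique() <= 2:
            tab = pd.crosstab(x, y)
            if (tab == 0).any().any():
                bad.append(col)
    return bad


def fit_propensity(df: pd.DataFrame, covariates: Sequence[str],
                   group_col: str = "group") -> np.ndarray:
    """Per-person propensity score from a main-effects logistic model."""
    y = _outcome(df, group_col)
    X = build_design(df, covariates) if covariates else pd.DataFrame(index=df.index)
    res = _fit_logit(y, X)
    return np.asarray(res.predict(sm.add_constant(X, has_constant="add")))


def match_1to1(scores, is_changed, caliper_sd_logit: float = 0.2,
               seed: int = 0) -> PropensityMatch:
    """Greedy 1:1 nearest-neighbour matching without replacement on logit scores.

    The smaller group drives the matching; its candidates are processed in
    descending score order (ties broken by a seeded shuffle).  A pair is valid
    only when the logit distance is within caliper_sd_logit * SD(logit scores).
    """
    scores = np.asarray(scores, dtype=float)
    is_changed = np.asarray(is_changed, dtype=bool)
    if is_changed.all() or (~is_changed).all():
        raise ValueError("both groups must be non-empty")
    eps = 1e-12
    logit = np.log(np.clip(scores, eps, 1 - eps) / np.clip(1 - scores, eps, 1 - eps))
    caliper = caliper_sd_logit * logit.std(ddof=1)

    idx_changed = np.flatnonzero(is_changed)
    idx_unchanged = np.flatnonzero(~is_changed)
    driver, pool = (
        (idx_changed, idx_unchanged)
        if len(idx_changed) <= len(idx_unchanged)
        else (idx_unchanged, idx_changed)
    )
    rng = np.random.default_rng(seed)
    tiebreak = rng.permutation(len(scores))
    driver = sorted(driver, key=lambda i: (-logit[i], tiebreak[i]))
    available = set(pool)
    pairs, discarded = [], []
    for i in driver:
        if not available:
            discarded.append(i)
            continue
        cand = sorted(available, key=lambda j: (abs(logit[j] - logit[i]), tiebreak[j]))
        best = cand[0]
        if abs(logit[best] - logit[i]) <= caliper:
            available.remove(best)
            pair = (i, best) if is_changed[i] else (best, i)
            pairs.append(pair)
        else:
            discarded.append(i)
    discarded.extend(sorted(available))
    return PropensityMatch(pairs=pairs, caliper=float(caliper), seed=seed,
                           discarded=discarded)


def fit_univariate(df: pd.DataFrame, covariate: str, group_col: str = "group",
                   alpha: float = 0.05, ci_method: str = "wald") -> EffectEstimate:
    """Logistic fit of the outcome on a single covariate.

    The OR is per unit for continuous covariates, or versus the reference
    level for binary ones (identical to the 2x2 cross-product ratio).
    """
    y = _outcome(df, group_col)
    X = build_design(df, [covariate])
    res = _fit_logit(y, X)
    return _estimate_from_fit(res, covariate, y, X, alpha, ci_method, adjusted=False)


def _estimate_from_fit(res, term, y, X, alpha, ci_method, adjusted) -> EffectEstimate:
    beta = float(res.params[term])
    se = float(res.bse[term])
    if ci_method == "profile":
        lo, hi = profile_ci(y, X, term, alpha=alpha)
    else:
        z = stats.norm.ppf(1 - alpha / 2)
        lo, hi = beta - z * se, beta + z * se
    return EffectEstimate(
        term=term,
        odds_ratio=float(np.exp(beta)),
        ci_low=float(np.exp(lo)),
        ci_high=float(np.exp(hi)),
        p_value=float(res.pvalues[term]),
        adjusted=adjusted,
        coef=beta,
        se=se,
    )


def profile_ci(y, X: pd.DataFrame, term: str, alpha: float = 0.05):
    """Profile-likelihood CI for one coefficient via LR-statistic root finding."""
    from scipy.optimize import brentq

    full = _fit_logit(y, X)
    beta_hat = float(full.params[term])
    ll_full = full.llf
    crit = stats.chi2.ppf(1 - alpha, df=1)
    others = [c for c in X.columns if c != term]
    x_term = X[term].to_numpy(dtype=float)

    def deviance(beta0):
        offset = beta0 * x_term
        Xo = sm.add_constant(X[others], has_constant="add") if others else np.ones((len(y), 1))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, Xo, offset=offset).fit(disp=0, maxiter=200)
        return 2 * (ll_full - res.llf) - crit

    def find(direction):
        step = max(4 * float(full.bse[term]), 0.5)
        b = beta_hat + direction * step
        for _ in range(40):
            if deviance(b) > 0:
                return brentq(deviance, min(beta_hat, b), max(beta_hat, b), xtol=1e-6)
            b += direction * step
        return direction * np.inf

    return find(-1), find(+1)


# ---------------------------------------------------------------------------
# stepwise AIC model selection
# ---------------------------------------------------------------------------

def _hierarchy_ok(terms: set) -> bool:
    for t in terms:
        if ":" in t:
            a, b = t.split(":")
            if a not in terms or b not in terms:
                return False
    return True


def model_aic(df: pd.DataFrame, terms: Sequence[str], group_col: str = "group"):
    """AIC = 2k - 2 log L for the logistic model with the given terms."""
    y = _outcome(df, group_col)
    X = build_design(df, list(terms))
    res = _fit_logit(y, X, raise_on_separation=False)
    if res is None:
        return np.inf, None
    return float(res.aic), res


def stepwise_aic(
    df: pd.DataFrame,
    mains: Sequence[str],
    group_col: str = "group",
    include_interactions: bool = True,
    start: str = "full",
    max_steps: int = 200,
):
    """Stepwise (both directions) AIC minimization over mains + 2nd-order interactions.

    Starts from the full candidate model (or the null model with
    ``start='null'``); at each step the single add/drop move with the lowest
    AIC is taken, respecting the hierarchy principle (a main effect cannot be
    dropped while one of its interactions is in the model; an interaction can
    only be added when both mains are present).  Non-convergent candidate fits
    are skipped with a warning.  Returns (selected terms, trace).
    """
    mains = list(mains)
    interactions = (
        [f"{a}:{b}" for a, b in itertools.combinations(mains, 2)]
        if include_interactions
        else []
    )
    candidates = mains + interactions
    current = set(candidates) if start == "full" else set()
    aic, _ = model_aic(df, sorted(current), group_col)
    if not np.isfinite(aic) and start == "full":
        # full model unfittable (separation); restart from mains only
        log.warning("full candidate model unfittable; starting stepwise from main effects")
        current = set(mains)
        aic, _ = model_aic(df, sorted(current), group_col)
    trace = [(sorted(current), aic)]

    for _ in range(max_steps):
        moves = []
        for t in sorted(current):
            reduced = current - {t}
            if _hierarchy_ok(reduced):
                moves.append(reduced)
        for t in sorted(set(candidates) - current):
            augmented = current | {t}
            if _hierarchy_ok(augmented):
                moves.append(augmented)
        best_aic, best_set = aic, None
        for terms in moves:
            a, _ = model_aic(df, sorted(terms), group_col)
            if not np.isfinite(a):
                log.warning("skipping non-convergent candidate %s", sorted(terms))
                continue
            if a < best_aic - 1e-9:
                best_aic, best_set = a, terms
        if best_set is None:
            break
        current, aic = best_set, best_aic
        trace.append((sorted(current), aic))
    return sorted(current), trace


def fit_multivariate(df: pd.DataFrame, terms: Sequence[str],
                     group_col: str = "group", alpha: float = 0.05,
                     ci_method: str = "wald") -> list:
    """Adjusted ORs (exponentiated coefficients) for every selected term."""
    y = _outcome(df, group_col)
    X = build_design(df, list(terms))
    res = _fit_logit(y, X)
    return [
        _estimate_from_fit(res, t, y, X, alpha, ci_method, adjusted=True)
        for t in terms
    ]


def estimates_table(estimates: Sequence[EffectEstimate], decimals: int = 2) -> pd.DataFrame:
    """Report-style table: ORs and CI bounds rounded to ``decimals``."""
    return pd.DataFrame(
        [
            {
                "term": e.term,
                "odds_ratio": round(e.odds_ratio, decimals),
                "ci_low": round(e.ci_low, decimals),
                "ci_high": round(e.ci_high, decimals),
                "p_value": round(e.p_value, 3),
                "adjusted": e.adjusted,
            }
            for e in estimates
        ]
    )
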