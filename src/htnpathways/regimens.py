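"""Drug eras, regimens, and the six-mode medication-change taxonomy.

A *drug era* is a maximal interval of continuous exposure to one
(ingredient, daily dose), formed by merging refills separated by no more
than a gap tolerance of uncovered days.  A *regimen* is a maximal interval
over which the set of active (ingredient, class, dose) members is constant.
Transitions between persisted regimens are classified into one of six
modes: dose increased, dose reduced, medication added, medication removed,
changed within the same class, changed to a different class.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: Canonical ordering of the six anti-hypertensive medication classes.
CLASS_ORDER = ("ACEi", "ARB", "BB", "CCB", "DU", "OTHER")

DOSE_INCREASED = "DOSE_INCREASED"
DOSE_REDUCED = "DOSE_REDUCED"
MEDICATION_ADDED = "MEDICATION_ADDED"
MEDICATION_REMOVED = "MEDICATION_REMOVED"
CHANGED_WITHIN_CLASS = "CHANGED_WITHIN_CLASS"
CHANGED_TO_DIFFERENT_CLASS = "CHANGED_TO_DIFFERENT_CLASS"

#: The six change modes, in report-table order.
CHANGE_MODES = (
    DOSE_INCREASED,
    DOSE_REDUCED,
    MEDICATION_ADDED,
    MEDICATION_REMOVED,
    CHANGED_WITHIN_CLASS,
    CHANGED_TO_DIFFERENT_CLASS,
)

#: A regimen member: (ingredient, drug_class, daily_dose).
Member = tuple


@dataclass(frozen=True)
class DrugEra:
    person_id: int
    ingredient: str
    drug_class: str
    daily_dose: float
    start_day: int
    end_day: int

    def __post_init__(self):
        if self.end_day < self.start_day:
            raise ValueError(f"era end {self.end_day} before start {self.start_day}")


@dataclass(frozen=True)
class Regimen:
    """A maximal interval with a constant active (ingredient, class, dose) set."""

    person_id: int
    members: frozenset
    start_day: int
    end_day: int

    @property
    def n_days(self) -> int:
        return self.end_day - self.start_day + 1

    @property
    def ingredients(self) -> frozenset:
        return frozenset(m[0] for m in self.members)

    @property
    def classes(self) -> tuple:
        return tuple(sorted({m[1] for m in self.members}, key=CLASS_ORDER.index))

    @property
    def is_combination(self) -> bool:
        return len(self.ingredients) >= 2 or len({m[1] for m in self.members}) >= 2

    @property
    def label(self) -> str:
        return class_label(self.classes)


@dataclass(frozen=True)
class ChangeEvent:
    person_id: int
    day: int  # start day of the new regimen
    mode: str
    prev_classes: tuple
    next_classes: tuple


def class_label(classes: Iterable[str]) -> str:
    """Canonical label for a class set: sorted ACEi<ARB<BB<CCB<DU<OTHER, '+'-joined."""
    return "+".join(sorted(set(classes), key=CLASS_ORDER.index))


# ---------------------------------------------------------------------------
# interval algebra
# ---------------------------------------------------------------------------

def merge_intervals(intervals: Sequence[tuple], gap_tolerance: int = 0):
    """Merge closed integer intervals whose uncovered separation is <= gap_tolerance.

    The gap between [a, b] and [c, d] with c > b is ``c - b - 1`` days: a refill
    starting the day after the previous one is exhausted leaves a 0-day holiday.
    """
    ivs = sorted(intervals)
    merged = []
    for s, e in ivs:
        if merged and s - merged[-1][1] - 1 <= gap_tolerance:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def build_drug_eras(exposures: pd.DataFrame, gap_tolerance: int = 30) -> list:
    """Stitch refill records into drug eras, per (person, ingredient, daily dose).

    Parameters
    ----------
    exposures
        Rows for one or more persons with columns ``person_id``, ``ingredient``,
        ``drug_class``, ``daily_dose``, ``start_day``, ``end_day``.
    gap_tolerance
        Maximum run of uncovered days bridged when merging adjacent refills.
    """
    if (exposures["daily_dose"] < 0).any():
        raise ValueError("negative daily_dose in exposure records")
    eras = []
    cols = ["person_id", "ingredient", "drug_class", "daily_dose"]
    for (pid, ing, cls, dose), grp in exposures.groupby(cols, sort=True):
        ivs = merge_intervals(
            list(zip(grp["start_day"].astype(int), grp["end_day"].astype(int))),
            gap_tolerance=gap_tolerance,
        )
        for s, e in ivs:
            eras.append(DrugEra(pid, ing, cls, float(dose), s, e))
    eras.sort(key=lambda r: (r.person_id, r.start_day, r.ingredient))
    return eras


def derive_regimens(
    eras: Sequence[DrugEra],
    start_day: int,
    end_day: int,
    gap_tolerance: int = 30,
) -> list:
    """Partition [start_day, end_day] into maximal constant-member regimens.

    On covered days the member set equals the set of covering eras.  Interior
    uncovered runs no longer than ``gap_tolerance`` (a tolerated drug holiday)
    carry the preceding member set forward; longer runs remain as empty-member
    segments.  A trailing uncovered run also carries the last set forward, and
    a leading one takes the first observed set, so the window is always fully
    partitioned.
    """
    if not eras:
        return []
    person_id = eras[0].person_id
    cuts = {start_day, end_day + 1}
    for era in eras:
        s, e = max(era.start_day, start_day), min(era.end_day, end_day)
        if s > e:
            continue
        cuts.add(s)
        cuts.add(e + 1)
    bounds = sorted(cuts)
    segments = []  # (start, end, frozenset members)
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        members = frozenset(
            (era.ingredient, era.drug_class, era.daily_dose)
            for era in eras
            if era.start_day <= lo and era.end_day >= hi - 1
        )
        segments.append([lo, hi - 1, members])

    # leading empty segment adopts the first non-empty set
    first_nonempty = next((i for i, s in enumerate(segments) if s[2]), None)
    if first_nonempty is None:
        return []
    for i in range(first_nonempty):
        segments[i][2] = segments[first_nonempty][2]

    # carry-forward bridging of short interior / trailing holidays
    prev_members = segments[first_nonempty][2]
    for seg in segments:
        if not seg[2]:
            length = seg[1] - seg[0] + 1
            if length <= gap_tolerance:
                seg[2] = prev_members
        prev_members = seg[2] if seg[2] else prev_members

    regimens = []
    for lo, hi, members in segments:
        if regimens and regimens[-1].members == members:
            regimens[-1] = replace(regimens[-1], end_day=hi)
        else:
            regimens.append(Regimen(person_id, members, lo, hi))
    return regimens


def filter_transient_regimens(regimens: Sequence[Regimen], min_days: int = 30) -> list:
    """Erase regimens persisting < min_days; their interval is absorbed backwards.

    The first regimen is always kept.  Adjacent regimens left identical by an
    erased excursion are merged.  The operation is idempotent.
    """
    out: list = []
    for r in regimens:
        if not out:
            out.append(r)
        elif r.n_days < min_days:
            out[-1] = replace(out[-1], end_day=r.end_day)
        elif r.members == out[-1].members:
            out[-1] = replace(out[-1], end_day=r.end_day)
        else:
            out.append(r)
    return out


# ---------------------------------------------------------------------------
# change classification
# ---------------------------------------------------------------------------

def classify_members(prev: frozenset, next_: frozenset) -> str:
    """Classify a transition between two member sets into one of the six modes.

    Fixed precedence: dose change > medication added > medication removed >
    changed within class > changed to a different class.  A mixed dose move
    (one ingredient up, another down) falls through to the cross-class bucket
    and is logged.
    """
    if prev == next_:
        raise ValueError("classify_members requires prev != next")
    prev_ing = {m[0] for m in prev}
    next_ing = {m[0] for m in next_}
    if prev_ing == next_ing:
        prev_dose = {m[0]: m[2] for m in prev}
        next_dose = {m[0]: m[2] for m in next_}
        deltas = [next_dose[i] - prev_dose[i] for i in prev_ing if next_dose[i] != prev_dose[i]]
        if deltas and all(d > 0 for d in deltas):
            return DOSE_INCREASED
        if deltas and all(d < 0 for d in deltas):
            return DOSE_REDUCED
        log.warning("mixed dose move (some up, some down); classified as cross-class change")
        return CHANGED_TO_DIFFERENT_CLASS
    if prev_ing < next_ing:
        return MEDICATION_ADDED
    if next_ing < prev_ing:
        return MEDICATION_REMOVED
    if Counter(m[1] for m in prev) == Counter(m[1] for m in next_):
        return CHANGED_WITHIN_CLASS
    return CHANGED_TO_DIFFERENT_CLASS


def classify_change(prev: Regimen, next_: Regimen) -> ChangeEvent:
    mode = classify_members(prev.members, next_.members)
    return ChangeEvent(
        person_id=prev.person_id,
        day=next_.start_day,
        mode=mode,
        prev_classes=prev.classes,
        next_classes=next_.classes,
    )


def detect_changes(regimens: Sequence[Regimen]) -> list:
    """Classify every transition between consecutive persisted regimens."""
    return [
        classify_change(a, b)
        for a, b in zip(regimens[:-1], regimens[1:])
        if a.members != b.members
    ]


# ---------------------------------------------------------------------------
# sequences and tabulations
# ---------------------------------------------------------------------------

def extract_sequence(regimens: Sequence[Regimen], max_steps: int = 5) -> list:
    """Ordered distinct class-set labels, truncated to the first max_steps.

    Dose-only transitions leave the class label unchanged and are collapsed.
    """
    labels = []
    for r in regimens:
        lab = r.label
        if not labels or labels[-1] != lab:
            labels.append(lab)
    return labels[:max_steps]


def tabulate_initial_regimens(
    cohort: pd.DataFrame,
    strata: Sequence[str] = (),
    regimen_col: str = "initial_regimen",
) -> pd.DataFrame:
    """Counts and row percentages of the first-regimen label per stratum level.

    With ``strata=[]`` a single overall row (stratum 'all') is produced.
    Percentages are 100*count/row-total, rounded to one decimal.
    """
    for s in strata:
        if s not in cohort.columns:
            raise KeyError(f"unknown stratum {s!r}")
    frames = []
    groups = [("all", "all", cohort)]
    for s in strata:
        groups += [(s, lvl, grp) for lvl, grp in cohort.groupby(s)]
    for stratum, level, grp in groups:
        counts = grp[regimen_col].value_counts()
        total = int(counts.sum())
        for lab, n in counts.items():
            frames.append(
                {
                    "stratum": stratum,
                    "level": level,
                    "regimen": lab,
                    "count": int(n),
                    "percent": round(100.0 * n / total, 1),
                    "row_total": total,
                }
            )
    return pd.DataFrame(frames, columns=["stratum", "level", "regimen", "count", "percent", "row_total"])


def tabulate_change_modes(events, weight_col: str = None) -> pd.DataFrame:
    """Mode-by-regimen change matrix with row/column/grand totals and row percents.

    ``events`` is either a sequence of :class:`ChangeEvent` or a DataFrame with
    columns ``prev_label`` and ``mode`` (plus an optional count column named by
    ``weight_col`` for pre-aggregated cells).
    """
    if isinstance(events, pd.DataFrame):
        df = events.copy()
        if weight_col is None:
            df["_n"] = 1
        else:
            df["_n"] = df[weight_col]
    else:
        df = pd.DataFrame(
            {
                "prev_label": [class_label(e.prev_classes) for e in events],
                "mode": [e.mode for e in events],
                "_n": 1,
            }
        )
    if df.empty:
        counts = pd.DataFrame(0, index=pd.Index([], name="prev_label"), columns=list(CHANGE_MODES))
    else:
        counts = (
            df.pivot_table(index="prev_label", columns="mode", values="_n", aggfunc="sum", fill_value=0)
            .reindex(columns=list(CHANGE_MODES), fill_value=0)
        )
    counts["TOTAL"] = counts.sum(axis=1)
    counts.loc["TOTAL"] = counts.sum(axis=0)
    pct = counts.div(counts["TOTAL"].replace(0, np.nan), axis=0).mul(100).round(1)
    out = counts.astype(int).copy()
    for mode in CHANGE_MODES:
        out[mode + "_pct"] = pct[mode].fillna(0.0)
    return out


def export_sankey(sequences: Iterable[Sequence[str]]) -> dict:
    """Node/link structure for a Sankey plot of regimen sequences.

    One node per (step, label); link weight = number of persons making the
    step-k -> step-k+1 transition.
    """
    node_index: dict = {}
    nodes = []
    links: Counter = Counter()
    for seq in sequences:
        for step, lab in enumerate(seq):
            key = (step, lab)
            if key not in node_index:
                node_index[key] = len(nodes)
                nodes.append({"id": len(nodes), "step": step, "label": lab})
        for step in range(len(seq) - 1):
            links[(node_index[(step, seq[step])], node_index[(step + 1, seq[step + 1])])] += 1
    return {
        "nodes": nodes,
        "links": [
            {"source": s, "target": t, "value": v} for (s, t), v in sorted(links.items())
        ],
    }
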