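"""Shared oracles and builders for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd


def rx_frame(rows, person_id=1):
    """Exposure frame from (ingredient, drug_class, daily_dose, start_day, end_day) tuples."""
    return pd.DataFrame(
        [(person_id, *r) for r in rows],
        columns=["person_id", "ingredient", "drug_class", "daily_dose", "start_day", "end_day"],
    )


def meas_frame(rows, person_id=1):
    """Measurement frame from (analyte, value, day) tuples (units filled from defaults)."""
    from htnpathways.phenotypes import EXPECTED_UNITS

    return pd.DataFrame(
        [(person_id, a, v, EXPECTED_UNITS[a], d) for a, v, d in rows],
        columns=["person_id", "analyte", "value", "unit", "day"],
    )


def cond_frame(rows, person_id=1):
    """Condition frame from (category, day) tuples."""
    return pd.DataFrame(
        [(person_id, c, d) for c, d in rows],
        columns=["person_id", "condition_category", "day"],
    )


def day_grid(intervals, lo, hi):
    """Boolean coverage grid over [lo, hi] for closed integer intervals."""
    grid = np.zeros(hi - lo + 1, dtype=bool)
    for s, e in intervals:
        s2, e2 = max(int(s), lo), min(int(e), hi)
        if s2 <= e2:
            grid[s2 - lo : e2 - lo + 1] = True
    return grid


def grid_coverage_and_max_gap(grid):
    """(covered days, largest interior uncovered run) from a boolean grid."""
    covered = int(grid.sum())
    idx = np.flatnonzero(grid)
    if len(idx) == 0:
        return 0, 0
    interior = grid[idx[0] : idx[-1] + 1]
    max_gap = best = 0
    for v in interior:
        best = 0 if v else best + 1
        max_gap = max(max_gap, best)
    return covered, max_gap


def close_gaps_on_grid(grid, lo, tolerance):
    """Merged covered intervals after bridging uncovered runs <= tolerance (day-grid oracle)."""
    idx = np.flatnonzero(grid)
    if len(idx) == 0:
        return []
    runs = []
    start = prev = idx[0]
    for i in idx[1:]:
        if i - prev - 1 <= tolerance:
            prev = i
        else:
            runs.append((lo + start, lo + prev))
            start = prev = i
    runs.append((lo + start, lo + prev))
    return runs
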