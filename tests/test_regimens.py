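"""Drug-era stitching, regimen derivation, change classification, tabulations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import htnpathways.regimens as rg
from helpers import close_gaps_on_grid, day_grid, rx_frame


def members(*items):
    return frozenset(items)


def regimen(members_, start, end, pid=1):
    return rg.Regimen(pid, frozenset(members_), start, end)


# ---------------------------------------------------------------------------
# drug eras
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "intervals,expected",
    [
        ([(0, 29), (35, 64)], [(0, 64)]),   # 5-day holiday bridged
        ([(0, 29), (65, 94)], [(0, 29), (65, 94)]),  # 35-day holiday splits
        ([(0, 29), (60, 89)], [(0, 89)]),   # exactly 30 uncovered days bridged
        ([(0, 29), (61, 90)], [(0, 29), (61, 90)]),  # 31 days splits
    ],
)
def test_era_gap_tolerance(intervals, expected):
    df = rx_frame([("arb_1", "ARB", 50.0, s, e) for s, e in intervals])
    eras = rg.build_drug_eras(df, gap_tolerance=30)
    assert [(e.start_day, e.end_day) for e in eras] == expected


def test_negative_dose_rejected():
    df = rx_frame([("arb_1", "ARB", -1.0, 0, 29)])
    with pytest.raises(ValueError):
        rg.build_drug_eras(df)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    st.lists(
        st.tuples(st.integers(0, 1900), st.integers(1, 90)),
        min_size=1,
        max_size=25,
    ),
    st.integers(0, 40),
)
def test_era_union_matches_day_grid_oracle(refills, tol):
    """Era construction equals bridging gaps <= tolerance on a boolean day grid."""
    intervals = [(s, min(s + d - 1, 1999)) for s, d in refills]
    df = rx_frame([("arb_1", "ARB", 50.0, s, e) for s, e in intervals])
    eras = rg.build_drug_eras(df, gap_tolerance=tol)
    grid = day_grid(intervals, 0, 1999)
    assert [(e.start_day, e.end_day) for e in eras] == close_gaps_on_grid(grid, 0, tol)


# ---------------------------------------------------------------------------
# regimen derivation
# ---------------------------------------------------------------------------

def test_single_era_single_regimen():
    eras = [rg.DrugEra(1, "arb_1", "ARB", 50.0, 0, 1095)]
    regs = rg.derive_regimens(eras, 0, 1095)
    assert len(regs) == 1
    assert not regs[0].is_combination
    assert regs[0].label == "ARB"


def test_overlapping_eras_partition():
    eras = [
        rg.DrugEra(1, "arb_1", "ARB", 50.0, 0, 500),
        rg.DrugEra(1, "ccb_1", "CCB", 50.0, 300, 1095),
    ]
    regs = rg.derive_regimens(eras, 0, 1095)
    assert [(r.start_day, r.end_day, r.label) for r in regs] == [
        (0, 299, "ARB"),
        (300, 500, "ARB+CCB"),
        (501, 1095, "CCB"),
    ]
    assert regs[1].is_combination


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    st.lists(
        st.tuples(st.sampled_from(["arb_1", "ccb_1", "bb_1"]), st.integers(0, 900), st.integers(1, 400)),
        min_size=1,
        max_size=8,
    )
)
def test_regimen_pointwise_oracle(eras_spec):
    """On covered days the member set equals the covering eras; the window is
    partitioned without overlaps or holes."""
    cls = {"arb_1": "ARB", "ccb_1": "CCB", "bb_1": "BB"}
    eras = [
        rg.DrugEra(1, ing, cls[ing], 50.0, s, min(s + d - 1, 999))
        for ing, s, d in eras_spec
    ]
    lo, hi = 0, 999
    regs = rg.derive_regimens(eras, lo, hi, gap_tolerance=30)
    # partition: contiguous, ordered, covering [lo, hi]
    assert regs[0].start_day == lo and regs[-1].end_day == hi
    for a, b in zip(regs[:-1], regs[1:]):
        assert b.start_day == a.end_day + 1
    # pointwise agreement on covered days
    for day in range(lo, hi + 1, 7):
        covering = frozenset(
            (e.ingredient, e.drug_class, e.daily_dose)
            for e in eras
            if e.start_day <= day <= e.end_day
        )
        reg = next(r for r in regs if r.start_day <= day <= r.end_day)
        if covering:
            assert reg.members == covering


def test_long_holiday_not_bridged():
    eras = [
        rg.DrugEra(1, "arb_1", "ARB", 50.0, 0, 100),
        rg.DrugEra(1, "arb_1", "ARB", 50.0, 200, 300),
    ]
    regs = rg.derive_regimens(eras, 0, 300, gap_tolerance=30)
    assert [r.members == frozenset() for r in regs] == [False, True, False]


# ---------------------------------------------------------------------------
# transient filtering
# ---------------------------------------------------------------------------

def test_short_excursion_erased():
    regs = [
        regimen([("arb_1", "ARB", 50.0)], 0, 100),
        regimen([("arb_1", "ARB", 50.0), ("ccb_1", "CCB", 50.0)], 101, 120),
        regimen([("arb_1", "ARB", 50.0)], 121, 400),
    ]
    out = rg.filter_transient_regimens(regs, min_days=30)
    assert len(out) == 1
    assert (out[0].start_day, out[0].end_day) == (0, 400)


def test_persisted_regimens_kept():
    regs = [
        regimen([("arb_1", "ARB", 50.0)], 0, 100),
        regimen([("arb_1", "ARB", 50.0), ("ccb_1", "CCB", 50.0)], 101, 200),
    ]
    out = rg.filter_transient_regimens(regs, min_days=30)
    assert len(out) == 2


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.tuples(st.integers(0, 3), st.integers(1, 120)), min_size=1, max_size=10))
def test_filter_idempotent(spec):
    sets = [
        frozenset(),
        frozenset([("arb_1", "ARB", 50.0)]),
        frozenset([("arb_1", "ARB", 50.0), ("ccb_1", "CCB", 50.0)]),
        frozenset([("bb_1", "BB", 50.0)]),
    ]
    day = 0
    regs = []
    for which, dur in spec:
        regs.append(rg.Regimen(1, sets[which], day, day + dur - 1))
        day += dur
    once = rg.filter_transient_regimens(regs)
    twice = rg.filter_transient_regimens(once)
    assert once == twice


# ---------------------------------------------------------------------------
# change classification
# ---------------------------------------------------------------------------

A50 = ("arb_a", "ARB", 50.0)
A100 = ("arb_a", "ARB", 100.0)
B50 = ("arb_b", "ARB", 50.0)
C50 = ("ccb_c", "CCB", 50.0)
X50 = ("bb_x", "BB", 50.0)
Y50 = ("ccb_y", "CCB", 50.0)


@pytest.mark.parametrize(
    "prev,nxt,mode",
    [
        ({A50}, {A100}, rg.DOSE_INCREASED),
        ({A100}, {A50}, rg.DOSE_REDUCED),
        ({C50}, {C50, A50}, rg.MEDICATION_ADDED),
        ({C50, A50}, {C50}, rg.MEDICATION_REMOVED),
        ({A50}, {B50}, rg.CHANGED_WITHIN_CLASS),
        ({X50}, {Y50}, rg.CHANGED_TO_DIFFERENT_CLASS),
        # mixed dose move falls through to the cross-class bucket
        ({A50, ("ccb_c", "CCB", 100.0)}, {A100, C50}, rg.CHANGED_TO_DIFFERENT_CLASS),
    ],
)
def test_change_modes(prev, nxt, mode):
    assert rg.classify_members(frozenset(prev), frozenset(nxt)) == mode


def test_identical_regimens_rejected():
    with pytest.raises(ValueError):
        rg.classify_members(frozenset({A50}), frozenset({A50}))


# ---------------------------------------------------------------------------
# sequences, tabulations, sankey
# ---------------------------------------------------------------------------

def test_extract_sequence_collapses_and_truncates():
    seq = [
        regimen([A50], 0, 99),
        regimen([A100], 100, 199),  # dose-only: same class label
        regimen([A100, C50], 200, 1095),
    ]
    assert rg.extract_sequence(seq) == ["ARB", "ARB+CCB"]
    many = [
        regimen([A50], 0, 0), regimen([C50], 1, 1), regimen([X50], 2, 2),
        regimen([A50], 3, 3), regimen([C50], 4, 4), regimen([X50], 5, 5),
        regimen([A50], 6, 6),
    ]
    assert len(rg.extract_sequence(many, max_steps=5)) == 5


def test_label_canonical_order():
    assert rg.class_label(["DU", "ARB", "CCB"]) == "ARB+CCB+DU"


def test_initial_regimen_tabulation():
    cohort = pd.DataFrame({"initial_regimen": ["ARB"] * 3 + ["CCB"], "male": [1, 1, 0, 0]})
    tab = rg.tabulate_initial_regimens(cohort, strata=[])
    row = tab[tab.regimen == "ARB"].iloc[0]
    assert row["count"] == 3 and row["percent"] == 75.0
    single = rg.tabulate_initial_regimens(cohort.iloc[:1])
    assert single.iloc[0]["percent"] == 100.0
    with pytest.raises(KeyError):
        rg.tabulate_initial_regimens(cohort, strata=["nope"])


def test_change_mode_matrix_conservation():
    events = [
        rg.ChangeEvent(1, 100, rg.MEDICATION_ADDED, ("ARB",), ("ARB", "CCB")),
        rg.ChangeEvent(1, 300, rg.DOSE_INCREASED, ("ARB", "CCB"), ("ARB", "CCB")),
        rg.ChangeEvent(2, 150, rg.MEDICATION_ADDED, ("ARB",), ("ARB", "DU")),
    ]
    tab = rg.tabulate_change_modes(events)
    assert tab.loc["TOTAL", "TOTAL"] == len(events)
    assert tab.loc["ARB", rg.MEDICATION_ADDED] == 2
    mode_totals = tab.loc["TOTAL", list(rg.CHANGE_MODES)].sum()
    assert mode_totals == len(events)
    empty = rg.tabulate_change_modes([])
    assert empty.loc["TOTAL", "TOTAL"] == 0


def test_sankey_conservation():
    sankey = rg.export_sankey([["ARB", "ARB+CCB"]] * 10)
    assert len(sankey["links"]) == 1 and sankey["links"][0]["value"] == 10
    # inflow = outflow + terminations at the intermediate node
    seqs = [["ARB", "ARB+CCB", "CCB"], ["ARB", "ARB+CCB"], ["CCB", "ARB+CCB", "ARB"]]
    sk = rg.export_sankey(seqs)
    nodes = {n["id"]: n for n in sk["nodes"]}
    mid = next(i for i, n in nodes.items() if n["step"] == 1 and n["label"] == "ARB+CCB")
    inflow = sum(l["value"] for l in sk["links"] if l["target"] == mid)
    outflow = sum(l["value"] for l in sk["links"] if l["source"] == mid)
    terminations = sum(1 for s in seqs if len(s) == 2 and s[1] == "ARB+CCB")
    assert inflow == outflow + terminations
    assert rg.export_sankey([]) == {"nodes": [], "links": []}
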