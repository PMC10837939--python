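"""Adherence rules: worked examples, brute-force oracle, monotonicity."""

from itertools import product

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from preptraj.adherence import (
    DispensingInterval,
    correct_before,
    correct_during_after,
    dprep_score,
    edprep_score,
    is_adherent,
    reconcile,
    sex_day_covered,
)


# --- independent oracle: literal reading of the dosing rules ---------------

def oracle_before(x, pills):
    near = pills.get(x - 1, 0) + pills.get(x, 0)
    prior = any(pills.get(d, 0) >= 1 for d in range(x - 6, x - 1))
    return near >= 2 or (near >= 1 and prior)


def oracle_during_after(x, pills):
    return all(pills.get(d, 0) >= 1 for d in (x, x + 1, x + 2))


def oracle_covered(x, pills):
    return oracle_before(x, pills) and oracle_during_after(x, pills)


# --- daily-PrEP ratio -------------------------------------------------------

@pytest.mark.parametrize(
    "pills, days, score, adherent",
    [
        (30, 30, 1.0, True),
        (28, 30, 28 / 30, True),    # 0.9333 exceeds 0.9
        (27, 30, 0.9, False),       # exactly 0.9 is NOT adherent
        (0, 30, 0.0, False),
    ],
)
def test_dprep_score_and_threshold(pills, days, score, adherent):
    s = dprep_score(pills, days)
    assert s == pytest.approx(score)
    assert is_adherent(s) is adherent


def test_dprep_rejects_degenerate_interval():
    with pytest.raises(ValueError, match="at least 1 day"):
        dprep_score(5, 0)
    with pytest.raises(ValueError):
        DispensingInterval(1, 10, 10, 30)


def test_dprep_caps_overreporting(caplog):
    with caplog.at_level("WARNING"):
        assert dprep_score(35, 30) == 1.0
    assert "capped" in caplog.text


# --- coverage rules ---------------------------------------------------------

@pytest.mark.parametrize(
    "pills, expected",
    [
        ({9: 2}, True),            # two pills on X-1
        ({9: 1, 6: 1}, True),      # one near pill plus a prior pill
        ({9: 1}, False),           # a lone X-1 pill cannot qualify itself
        ({10: 2}, True),           # two pills on X itself
    ],
)
def test_correct_before_examples(pills, expected):
    assert correct_before(10, pills) is expected


@pytest.mark.parametrize(
    "pills, expected",
    [
        ({10: 1, 11: 1, 12: 1}, True),
        ({10: 1, 11: 1}, False),
        ({}, False),
    ],
)
def test_correct_during_after_examples(pills, expected):
    assert correct_during_after(10, pills) is expected


def test_gap_in_log_yields_indeterminate():
    # log only covers days >= 10: the before-window reaches unknown days
    assert correct_before(10, {10: 1}, log_start=10) is None
    # but an already satisfied rule stays True despite the gap
    assert correct_before(10, {10: 2}, log_start=10) is True
    assert correct_during_after(10, {10: 1, 11: 1}, log_start=10,
                                log_end=11) is None


def test_edprep_score_examples():
    pills = {9: 2, 10: 1, 11: 1, 12: 1}
    assert edprep_score({10, 20}, pills) == pytest.approx(0.5)
    assert edprep_score(set(), pills) is None  # no sex days -> missing
    assert edprep_score({10}, pills) == 1.0


def test_rule_engine_matches_bruteforce_over_all_small_logs():
    """Exhaustive check over every 0/1 pill log on a 10-day window."""
    x = 4  # sex day; during-window [4,6] inside the log
    mismatches = 0
    for bits in product((0, 1), repeat=10):
        pills = {d: b for d, b in enumerate(bits) if b}
        got = sex_day_covered(x, pills)
        want = oracle_covered(x, pills)
        mismatches += got is not want
        score = edprep_score({x}, pills)
        assert score == (1.0 if want else 0.0)
    assert mismatches == 0


@given(st.dictionaries(st.integers(0, 14), st.integers(1, 3), max_size=10),
       st.integers(0, 14))
def test_adding_a_pill_never_reduces_coverage(pills, extra_day):
    x = 7
    before = sex_day_covered(x, pills)
    more = dict(pills)
    more[extra_day] = more.get(extra_day, 0) + 1
    after = sex_day_covered(x, more)
    rank = {False: 0, None: 0, True: 1}
    assert rank[after] >= rank[before]


def test_consecutive_sex_days_composed_by_daily_dosing():
    pills = {d: 1 for d in range(0, 15)}
    assert sex_day_covered(7, pills) is True
    assert sex_day_covered(8, pills) is True
    assert edprep_score({7, 8}, pills) == 1.0


# --- reconciliation ---------------------------------------------------------

def _diary(sid, pills_by_day, regimen="daily"):
    days = sorted(pills_by_day)
    return pd.DataFrame({
        "subject_id": sid, "iso_date": "2019-01-01", "day": days,
        "pills_taken": [pills_by_day[d] for d in days],
        "sex_day": 0, "regimen": regimen,
    })


def test_reconcile_caps_overreport_and_flags_unmatched():
    diary = pd.concat([
        _diary(1, {d: 1 for d in range(30)}),       # 30 reported, 30 ok
        _diary(2, {d: 2 for d in range(20)}),       # 40 reported > 30
        _diary(3, {0: 1}),                          # no dispensing record
    ])
    dispensing = pd.DataFrame({
        "subject_id": [1, 2], "visit_month": [1, 1],
        "start_day": [0, 0], "end_day": [30, 30],
        "pills_dispensed": [30, 30],
    })
    fixed, audit = reconcile(diary, dispensing)
    assert fixed.loc[fixed["subject_id"] == 2, "pills_taken"].sum() == 30
    assert fixed.loc[fixed["subject_id"] == 1, "pills_taken"].sum() == 30
    actions = audit.set_index("subject_id")["action"]
    assert actions.loc[2].startswith("capped")
    assert "unmatched" in actions.loc[3]
    assert 1 not in actions.index  # within allowance: no flag
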