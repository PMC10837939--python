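"""PrEP adherence scoring from pill diaries and dispensing records.

Daily-PrEP adherence is the ratio of pills consumed to the days between
medication pickups (capped at 1). Event-driven adherence is sex-day
coverage: a sex day X counts as covered when the dose *before* (at least
two pills over days X-1/X, or one pill there if another pill fell in the
six days before X-1) and the dose *during and after* (at least one pill
on each of X, X+1, X+2) are both correct. A score strictly above 0.9
defines adherence under either regimen.

Pill logs are day-indexed mappings; days inside the declared log span
but absent from the mapping count as zero pills (a complete diary), days
outside the span are unknown. Rules are evaluated three-valued: a sex
day whose window reaches unknown days is indeterminate (None) unless
the observed pills already satisfy the rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .synthetic_cohort import DAYS_PER_MONTH

logger = logging.getLogger(__name__)

ADHERENCE_THRESHOLD = 0.9


@dataclass(frozen=True)
class DispensingInterval:
    """One pickup-to-pickup interval (day-resolution, end exclusive-start)."""

    subject_id: int
    start_day: int
    end_day: int
    pills_dispensed: int
    visit_month: int | None = None

    def __post_init__(self):
        if self.end_day <= self.start_day:
            raise ValueError(
                f"interval end ({self.end_day}) must exceed start "
                f"({self.start_day})"
            )
        if self.pills_dispensed < 0:
            raise ValueError("pills_dispensed must be >= 0")

    @property
    def days(self) -> int:
        return self.end_day - self.start_day


def _pill(pills: Mapping[int, int], day: int,
          log_start: float, log_end: float):
    """Pills on a day, or None when the day lies outside the log span."""
    if log_start <= day <= log_end:
        return int(pills.get(day, 0))
    return None


def _span(pills: Mapping[int, int], log_start, log_end):
    if log_start is None:
        log_start = min(pills) if pills else -np.inf
        log_start = min(log_start, -10**9)  # default: absent days are zero
    if log_end is None:
        log_end = 10**9
    return log_start, log_end


def correct_before(sex_day: int, pills: Mapping[int, int],
                   log_start: int | None = None,
                   log_end: int | None = None):
    """Correct dosing *before* a sex day X.

    True iff pills(X-1)+pills(X) >= 2, or pills(X-1)+pills(X) >= 1 with at
    least one pill on some day in [X-6, X-2]. Returns None when unknown
    days make the outcome indeterminate.
    """
    lo, hi = _span(pills, log_start, log_end)
    x = int(sex_day)
    near = [_pill(pills, d, lo, hi) for d in (x - 1, x)]
    prior = [_pill(pills, d, lo, hi) for d in range(x - 6, x - 1)]

    near_sum = sum(v for v in near if v is not None)
    prior_any = any(v is not None and v >= 1 for v in prior)
    # pessimistic evaluation: unknown days contribute nothing
    if near_sum >= 2 or (near_sum >= 1 and prior_any):
        return True
    if all(v is not None for v in near + prior):
        return False
    return None


def correct_during_after(sex_day: int, pills: Mapping[int, int],
                         log_start: int | None = None,
                         log_end: int | None = None):
    """Correct dosing *during and after*: >=1 pill on each of X, X+1, X+2."""
    lo, hi = _span(pills, log_start, log_end)
    x = int(sex_day)
    vals = [_pill(pills, d, lo, hi) for d in (x, x + 1, x + 2)]
    if any(v is not None and v < 1 for v in vals):
        return False
    if all(v is not None for v in vals):
        return True
    return None


def sex_day_covered(sex_day: int, pills: Mapping[int, int],
                    log_start: int | None = None,
                    log_end: int | None = None):
    """Three-valued AND of the before and during/after rules."""
    before = correct_before(sex_day, pills, log_start, log_end)
    during = correct_during_after(sex_day, pills, log_start, log_end)
    if before is False or during is False:
        return False
    if before is None or during is None:
        return None
    return True


def edprep_score(sex_days: Iterable[int], pills: Mapping[int, int],
                 log_start: int | None = None,
                 log_end: int | None = None):
    """Event-driven adherence: covered sex days / sex days.

    Returns None (missing) when the interval contains no sex days, or when
    every sex day's coverage is indeterminate. Indeterminate sex days are
    excluded from numerator and denominator.
    """
    days = sorted(set(int(d) for d in sex_days))
    if not days:
        return None
    flags = [sex_day_covered(d, pills, log_start, log_end) for d in days]
    known = [f for f in flags if f is not None]
    if not known:
        return None
    return float(sum(known)) / len(known)


def dprep_score(pills_consumed: int, interval) -> float:
    """Daily-PrEP adherence: consumed / days between pickups, capped at 1."""
    days = interval.days if isinstance(interval, DispensingInterval) else int(interval)
    if days < 1:
        raise ValueError(f"interval must span at least 1 day, got {days}")
    if pills_consumed < 0:
        raise ValueError("pills_consumed must be >= 0")
    if pills_consumed > days:
        logger.warning(
            "reported pills (%d) exceed interval days (%d); score capped at 1",
            pills_consumed, days,
        )
    return min(1.0, pills_consumed / days)


def is_adherent(score) -> bool | None:
    """Adherent means the score strictly exceeds 0.9; missing propagates."""
    if score is None or (isinstance(score, float) and np.isnan(score)):
        return None
    return bool(score > ADHERENCE_THRESHOLD)


def reconcile(diary: pd.DataFrame,
              dispensing: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-check reported intake against dispensing records.

    Flags subject-intervals whose reported pills exceed the dispensed
    total; excess pills are trimmed from the end of the interval and an
    audit entry recorded. Subjects present in only one source are
    reported as unmatched.
    """
    out = diary.copy()
    audit: list[dict] = []
    diary_ids = set(out["subject_id"].unique())
    disp_ids = set(dispensing["subject_id"].unique())
    for sid in sorted(diary_ids ^ disp_ids):
        source = "diary" if sid in diary_ids else "dispensing"
        audit.append({"subject_id": sid, "visit_month": None,
                      "reported": None, "dispensed": None,
                      "action": f"unmatched ({source} only)"})
        logger.warning("subject %s present only in %s", sid, source)

    out = out.sort_values(["subject_id", "day"]).reset_index(drop=True)
    by_subject = dict(tuple(out.groupby("subject_id", sort=False)))
    for rec in dispensing.itertuples(index=False):
        rows = by_subject.get(rec.subject_id)
        if rows is None:
            continue
        in_interval = rows[(rows["day"] >= rec.start_day)
                           & (rows["day"] < rec.end_day)]
        reported = int(in_interval["pills_taken"].sum())
        if reported > rec.pills_dispensed:
            excess = reported - rec.pills_dispensed
            audit.append({"subject_id": rec.subject_id,
                          "visit_month": rec.visit_month,
                          "reported": reported,
                          "dispensed": rec.pills_dispensed,
                          "action": f"capped (-{excess})"})
            for idx in in_interval.index[::-1]:
                if excess <= 0:
                    break
                take = int(out.at[idx, "pills_taken"])
                cut = min(take, excess)
                out.at[idx, "pills_taken"] = take - cut
                excess -= cut
    audit_df = pd.DataFrame(
        audit, columns=["subject_id", "visit_month", "reported",
                        "dispensed", "action"])
    return out, audit_df


def _segment_score(regimen: str, seg: pd.DataFrame, days: int,
                   pill_log: Mapping[int, int], log_start: int, log_end: int):
    if regimen == "daily":
        return dprep_score(int(seg["pills_taken"].sum()), days)
    sex_days = seg.loc[seg["sex_day"] == 1, "day"].tolist()
    return edprep_score(sex_days, pill_log, log_start, log_end)


def score_adherence(diary: pd.DataFrame,
                    dispensing: pd.DataFrame) -> pd.DataFrame:
    """Per-subject per-interval adherence scores and flags.

    The diary is assumed complete from each subject's first to last
    recorded day; days before enrolment count as pill-free (subjects are
    PrEP-naive at baseline). Mixed-regimen intervals are scored per
    regimen segment and combined weighted by segment days, with a log
    entry.
    """
    rows: list[dict] = []
    diary = diary.sort_values(["subject_id", "day"])
    for sid, sub in diary.groupby("subject_id", sort=True):
        pill_log = dict(zip(sub["day"].astype(int), sub["pills_taken"].astype(int)))
        log_start = -10**9  # pre-enrolment: known pill-free
        log_end = int(sub["day"].max())
        intervals = dispensing[dispensing["subject_id"] == sid]
        for rec in intervals.itertuples(index=False):
            window = sub[(sub["day"] >= rec.start_day) & (sub["day"] < rec.end_day)]
            regimens = window["regimen"].unique().tolist()
            if len(regimens) == 1:
                score = _segment_score(regimens[0], window,
                                       rec.end_day - rec.start_day,
                                       pill_log, log_start, log_end)
                regimen = regimens[0]
            else:  # regimen switch inside the interval: day-weighted blend
                logger.info("subject %s switches regimen within month-%s "
                            "interval; scoring per segment", sid, rec.visit_month)
                parts, weights = [], []
                for reg, seg in window.groupby("regimen"):
                    s = _segment_score(reg, seg, len(seg), pill_log,
                                       log_start, log_end)
                    if s is not None:
                        parts.append(s)
                        weights.append(len(seg))
                score = (float(np.average(parts, weights=weights))
                         if parts else None)
                regimen = "mixed"
            rows.append({
                "subject_id": sid,
                "visit_month": rec.visit_month,
                "regimen": regimen,
                "score": np.nan if score is None else score,
                "adherent": is_adherent(score),
            })
    return pd.DataFrame(rows)
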