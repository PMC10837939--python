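"""Hospital Anxiety and Depression Scale (HADS) scoring.

The HADS has two 7-item subscales (anxiety, depression), each item scored
0-3, so subscale totals lie in [0, 21]. A total at or above the caseness
threshold (8 by convention) screens positive for the corresponding
symptom cluster. Internal consistency is assessed with Cronbach's alpha.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .synthetic_cohort import HADS_MAX, ITEM_MAX, N_ITEMS

CASENESS_THRESHOLD = 8


class HadsScoringError(ValueError):
    """Raised when a record's items cannot be scored (missing/out of range).

    Such records should be flagged for imputation, never silently zeroed.
    """


def score_subscales(items: Sequence) -> tuple[int, int]:
    """Score 14 HADS items (7 anxiety followed by 7 depression).

    Returns ``(anxiety_total, depression_total)``. Any missing or
    out-of-range item raises :class:`HadsScoringError`.
    """
    items = list(items)
    if len(items) != 2 * N_ITEMS:
        raise HadsScoringError(
            f"expected {2 * N_ITEMS} items, got {len(items)}"
        )
    values = []
    for i, v in enumerate(items):
        if v is None or (isinstance(v, float) and np.isnan(v)):
            raise HadsScoringError(f"item {i + 1} is missing")
        iv = int(v)
        if iv != v or not 0 <= iv <= ITEM_MAX:
            raise HadsScoringError(
                f"item {i + 1} out of range: {v!r} (allowed 0..{ITEM_MAX})"
            )
        values.append(iv)
    return sum(values[:N_ITEMS]), sum(values[N_ITEMS:])


def classify_caseness(total, threshold: int = CASENESS_THRESHOLD) -> bool:
    """True iff the subscale total meets or exceeds the threshold."""
    if not 0 <= total <= HADS_MAX:
        raise ValueError(f"total must be in [0, {HADS_MAX}], got {total}")
    return bool(total >= threshold)


def cronbach_alpha(item_matrix) -> float:
    """Cronbach's alpha of an n-by-k item matrix (sample variances, ddof=1).

    alpha = k/(k-1) * (1 - sum of item variances / variance of totals).
    Returns NaN when the total-score variance is zero (undefined).
    """
    x = np.asarray(item_matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need an n>=2 by k>=2 item matrix")
    if np.isnan(x).any():
        x = x[~np.isnan(x).any(axis=1)]
        if x.shape[0] < 2:
            raise ValueError("fewer than 2 complete rows")
    k = x.shape[1]
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        return float("nan")
    item_var = x.var(axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1.0 - item_var / total_var))


def add_caseness_columns(visits: pd.DataFrame,
                         threshold: int = CASENESS_THRESHOLD) -> pd.DataFrame:
    """Append ``hads_a_case`` / ``hads_d_case`` flags to a visits table.

    If item columns (a1..a7, d1..d7) are present, totals are (re)computed
    from them first; rows whose items cannot be scored keep missing totals.
    """
    out = visits.copy()
    a_items = [f"a{i}" for i in range(1, N_ITEMS + 1)]
    d_items = [f"d{i}" for i in range(1, N_ITEMS + 1)]
    if all(c in out.columns for c in a_items + d_items):
        totals_a, totals_d = [], []
        for row in out[a_items + d_items].itertuples(index=False):
            try:
                ta, td = score_subscales(row)
            except HadsScoringError:
                ta = td = np.nan
            totals_a.append(ta)
            totals_d.append(td)
        out["hads_a"] = totals_a
        out["hads_d"] = totals_d
    for col, flag in (("hads_a", "hads_a_case"), ("hads_d", "hads_d_case")):
        out[flag] = (out[col] >= threshold).where(out[col].notna())
    return out
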