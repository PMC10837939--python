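"""Multiple imputation by chained equations and Rubin's rules.

Missing outcome cells are imputed m times by iterating per-column
conditional models over the incomplete columns: numeric columns by
predictive mean matching (PMM) on a least-squares fit, binary and
categorical columns by draws from a (multinomial) logistic model.
Downstream estimates computed on each completed dataset are combined
with Rubin's rules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ImputationConfig:
    """Settings of the chained-equations imputer."""

    m: int = 5                 # number of completed datasets
    iterations: int = 10       # chained-equation sweeps per dataset
    donors: int = 5            # PMM donor pool size
    seed: int | None = None
    impute_cols: tuple[str, ...] | None = None  # default: all with missing
    id_cols: tuple[str, ...] = ("subject_id",)  # excluded from models

    def validate(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.donors < 1:
            raise ValueError("donors must be >= 1")


def _column_kind(series: pd.Series) -> str:
    if series.dtype.kind in "ifu":
        vals = series.dropna().unique()
        if len(vals) <= 2:
            return "binary"
        return "numeric"
    return "categorical" if series.dropna().nunique() > 2 else "binary"


def _design_matrix(df: pd.DataFrame, cols: Sequence[str]) -> np.ndarray:
    parts = []
    for c in cols:
        s = df[c]
        if s.dtype.kind in "ifu":
            parts.append(s.to_numpy(dtype=float)[:, None])
        else:
            parts.append(pd.get_dummies(s, drop_first=True).to_numpy(dtype=float))
    if not parts:
        return np.ones((len(df), 1))
    X = np.column_stack(parts)
    return np.column_stack([np.ones(len(df)), X])


def _pmm_impute(y_obs, X_obs, X_mis, donors, rng):
    beta, *_ = np.linalg.lstsq(X_obs, y_obs, rcond=None)
    yhat_obs = X_obs @ beta
    yhat_mis = X_mis @ beta
    filled = np.empty(len(yhat_mis))
    for j, yh in enumerate(yhat_mis):
        d = np.abs(yhat_obs - yh)
        k = min(donors, len(d))
        pool = np.argpartition(d, k - 1)[:k]
        filled[j] = y_obs[rng.choice(pool)]
    return filled


def _classifier_impute(y_obs, X_obs, X_mis, rng):
    classes, codes = np.unique(y_obs, return_inverse=True)
    if len(classes) == 1:
        return classes[np.zeros(len(X_mis), dtype=int)]
    model = LogisticRegression(max_iter=500)
    model.fit(X_obs, codes)
    proba = model.predict_proba(X_mis)
    draws = [rng.choice(len(classes), p=p / p.sum()) for p in proba]
    return classes[np.asarray(draws, dtype=int)]


def impute(table: pd.DataFrame, config: ImputationConfig | None = None
           ) -> list[pd.DataFrame]:
    """Return m completed copies of the table (observed cells untouched)."""
    config = config or ImputationConfig()
    config.validate()

    cols = [c for c in table.columns if c not in config.id_cols]
    target_cols = list(config.impute_cols) if config.impute_cols else cols
    imputable = [c for c in target_cols if table[c].isna().any()]
    for c in imputable:
        if table[c].isna().all():
            raise ValueError(f"column '{c}' is entirely missing; cannot impute")
    if not imputable:
        return [table.copy() for _ in range(config.m)]

    missing_masks = {c: table[c].isna().to_numpy() for c in imputable}
    kinds = {c: _column_kind(table[c]) for c in imputable}
    seeds = np.random.SeedSequence(config.seed).spawn(config.m)

    completed = []
    for ss in seeds:
        rng = np.random.default_rng(ss)
        work = table.copy()
        # initial fill: random draws from the observed margin
        for c in imputable:
            obs = work[c].dropna().to_numpy()
            mask = missing_masks[c]
            work.loc[mask, c] = rng.choice(obs, size=int(mask.sum()))
        for _ in range(config.iterations):
            for c in imputable:
                mask = missing_masks[c]
                predictors = [p for p in cols if p != c]
                X = _design_matrix(work, predictors)
                y = table[c]  # original: defines obs/mis split
                if kinds[c] == "numeric":
                    filled = _pmm_impute(
                        y[~mask].to_numpy(dtype=float),
                        X[~mask], X[mask], config.donors, rng)
                else:
                    filled = _classifier_impute(
                        y[~mask].to_numpy(), X[~mask], X[mask], rng)
                work.loc[mask, c] = filled
        for c in imputable:  # keep integer-looking columns numeric
            if table[c].dtype.kind in "ifu":
                work[c] = work[c].astype(float)
        completed.append(work)
    return completed


@dataclass(frozen=True)
class RubinResult:
    """Pooled estimate with Rubin decomposition of the variance."""

    estimate: float
    within: float
    between: float
    total_variance: float
    df: float
    ci_low: float
    ci_high: float
    m: int

    @property
    def se(self) -> float:
        return float(np.sqrt(self.total_variance))


def pool_rubin(estimates: Sequence[float], variances: Sequence[float],
               alpha: float = 0.05) -> RubinResult:
    """Combine per-imputation estimates and variances by Rubin's rules.

    pooled = mean(estimates); total variance = W + (1 + 1/m) B with W the
    mean within-imputation variance and B the between-imputation variance;
    the CI uses a t reference with Rubin's degrees of freedom.
    """
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    if q.shape != u.shape or q.ndim != 1 or len(q) < 1:
        raise ValueError("estimates and variances must be equal-length 1-D")
    m = len(q)
    if m == 1:
        logger.warning("pool_rubin called with m=1; passthrough")
        se = float(np.sqrt(u[0]))
        z = stats.norm.ppf(1 - alpha / 2)
        return RubinResult(float(q[0]), float(u[0]), 0.0, float(u[0]),
                           np.inf, float(q[0] - z * se), float(q[0] + z * se), 1)
    qbar = float(q.mean())
    w = float(u.mean())
    b = float(q.var(ddof=1))
    total = w + (1.0 + 1.0 / m) * b
    if b > 0:
        df = (m - 1) * (1.0 + w / ((1.0 + 1.0 / m) * b)) ** 2
        tcrit = stats.t.ppf(1 - alpha / 2, df)
    else:
        df = np.inf
        tcrit = stats.norm.ppf(1 - alpha / 2)
    half = tcrit * np.sqrt(total)
    return RubinResult(qbar, w, b, float(total), float(df),
                       float(qbar - half), float(qbar + half), m)
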