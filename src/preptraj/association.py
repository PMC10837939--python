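"""Association analyses linking baseline covariates, trajectory groups and
adherence.

Workflow: Pearson chi-square screening of covariate-by-trajectory
contingency tables, forwarding covariates with p < 0.150 into a
proportional-odds (ordered logistic) model of the ordered trajectory
group (low < moderate < high); Kruskal-Wallis comparisons of adherence
scores across groups per follow-up visit; and Bonferroni-corrected
pairwise chi-square tests of adherent proportions between groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.miscmodels.ordinal_model import OrderedModel

from .missing_data import pool_rubin

logger = logging.getLogger(__name__)

SCREENING_THRESHOLD = 0.150


@dataclass(frozen=True)
class ChisqResult:
    statistic: float
    df: int
    pvalue: float


def chisq_test(table) -> ChisqResult:
    """Pearson chi-square (no continuity correction) on an r-by-c table."""
    if isinstance(table, pd.DataFrame):
        counts = table.to_numpy(dtype=float)
        row_labels = list(table.index)
        col_labels = list(table.columns)
    else:
        counts = np.asarray(table, dtype=float)
        row_labels = list(range(counts.shape[0]))
        col_labels = list(range(counts.shape[1])) if counts.ndim == 2 else []
    if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("need at least a 2x2 table")
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    for axis, labels, what in ((1, row_labels, "row"), (0, col_labels, "column")):
        margins = counts.sum(axis=axis)
        if (margins == 0).any():
            bad = labels[int(np.flatnonzero(margins == 0)[0])]
            raise ValueError(f"degenerate {what} with zero margin: {bad!r}")
    expected = stats.contingency.expected_freq(counts)
    if (expected < 5).any():
        logger.warning("chi-square table has %d cells with expected count < 5",
                       int((expected < 5).sum()))
    res = stats.chi2_contingency(counts, correction=False)
    return ChisqResult(float(res.statistic), int(res.dof), float(res.pvalue))


def screen_univariate(pvalues: Mapping[str, float],
                      threshold: float = SCREENING_THRESHOLD) -> list[str]:
    """Covariates with p strictly below the inclusion threshold, in order."""
    return [name for name, p in pvalues.items() if p < threshold]


@dataclass(frozen=True)
class OrderedLogitResult:
    """One covariate row of a proportional-odds fit."""

    term: str
    coef: float
    se: float
    aor: float
    ci_low: float
    ci_high: float
    pvalue: float


@dataclass
class OrderedLogitFit:
    terms: list[OrderedLogitResult]
    cutpoints: np.ndarray
    loglik: float
    n: int

    def to_frame(self) -> pd.DataFrame:
        rows = [{
            "term": t.term, "coef": t.coef, "se": t.se, "aOR": t.aor,
            "ci_low": t.ci_low, "ci_high": t.ci_high, "pvalue": t.pvalue,
        } for t in self.terms]
        return pd.DataFrame(rows)


def _check_design(X: pd.DataFrame) -> None:
    x = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {x.shape[1]} "
            f"columns: {list(X.columns)})")


def fit_ordered_logit(outcome, covariates: pd.DataFrame,
                      alpha: float = 0.05) -> OrderedLogitFit:
    """Proportional-odds model of an ordered outcome on numeric covariates.

    The outcome must be integer-coded with its natural ordering
    (0 = lowest trajectory, the reference end). Coefficients are reported
    as adjusted odds ratios with Wald CIs; a diverging coefficient
    (|coef| > 15) raises, naming the separated covariate.
    """
    y = np.asarray(outcome)
    levels = np.unique(y)
    if len(levels) < 2:
        raise ValueError("outcome needs at least two observed levels")
    X = covariates.astype(float)
    _check_design(X)
    model = OrderedModel(y, X, distr="logit")
    res = model.fit(method="lbfgs", maxiter=500, disp=False)
    k = X.shape[1]
    coefs = res.params[:k]
    ses = res.bse[:k]
    for name, c in zip(X.columns, coefs):
        if abs(c) > 15:
            raise ValueError(
                f"separation detected: coefficient for '{name}' diverged "
                f"({c:.1f})")
    z = stats.norm.ppf(1 - alpha / 2)
    terms = [
        OrderedLogitResult(
            term=name, coef=float(c), se=float(s), aor=float(np.exp(c)),
            ci_low=float(np.exp(c - z * s)), ci_high=float(np.exp(c + z * s)),
            pvalue=float(2 * stats.norm.sf(abs(c / s))),
        )
        for name, c, s in zip(X.columns, coefs, ses)
    ]
    cutpoints = model.transform_threshold_params(res.params)[1:-1]
    return OrderedLogitFit(terms=terms, cutpoints=np.asarray(cutpoints),
                           loglik=float(res.llf), n=len(y))


def pool_ordered_logit(fits: Sequence[OrderedLogitFit],
                       alpha: float = 0.05) -> pd.DataFrame:
    """Rubin-pool per-covariate coefficients across imputation fits."""
    if not fits:
        raise ValueError("no fits to pool")
    names = [t.term for t in fits[0].terms]
    rows = []
    for i, name in enumerate(names):
        est = [f.terms[i].coef for f in fits]
        var = [f.terms[i].se ** 2 for f in fits]
        pooled = pool_rubin(est, var, alpha=alpha)
        tdist = stats.t(pooled.df) if np.isfinite(pooled.df) else stats.norm
        rows.append({
            "term": name,
            "coef": pooled.estimate,
            "se": pooled.se,
            "aOR": float(np.exp(pooled.estimate)),
            "ci_low": float(np.exp(pooled.ci_low)),
            "ci_high": float(np.exp(pooled.ci_high)),
            "pvalue": float(2 * tdist.sf(abs(pooled.estimate / pooled.se))),
        })
    return pd.DataFrame(rows)


def kruskal_wallis(samples: Sequence[np.ndarray]) -> tuple[float, int, float]:
    """Tie-corrected Kruskal-Wallis H across groups -> (H, df, p)."""
    groups = [np.asarray(s, dtype=float) for s in samples]
    groups = [g[~np.isnan(g)] for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    df = len(groups) - 1
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, df, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), df, float(p)


def bonferroni(p: float, n_comparisons: int) -> float:
    """Bonferroni adjustment: p times the comparison count, capped at 1."""
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    return float(min(1.0, p * n_comparisons))


def contingency_from_labels(covariate: pd.Series,
                            group: pd.Series) -> pd.DataFrame:
    """Covariate-by-group count table from aligned label series."""
    return pd.crosstab(covariate, group)


def adherence_by_trajectory(adherence: pd.DataFrame,
                            assignments: pd.DataFrame
                            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Adherent proportions by trajectory group per visit, with a global
    chi-square and Bonferroni-adjusted pairwise chi-squares.

    ``adherence`` needs (subject_id, visit_month, adherent); missing
    adherent flags are excluded. ``assignments`` maps subject_id -> group.
    Returns (per-visit summary, pairwise comparisons).
    """
    merged = adherence.merge(assignments[["subject_id", "group"]],
                             on="subject_id", how="inner")
    merged = merged.dropna(subset=["adherent"])
    merged["adherent"] = merged["adherent"].astype(bool)
    summaries, pairwise = [], []
    for month, at_visit in merged.groupby("visit_month"):
        counts = (at_visit.groupby("group")["adherent"]
                  .agg(n="size", n_adherent="sum"))
        empty = counts[counts["n"] == 0]
        if not empty.empty:
            logger.warning("visit %s: dropping empty groups %s",
                           month, list(empty.index))
            counts = counts[counts["n"] > 0]
        groups = list(counts.index)
        table = np.column_stack([counts["n_adherent"],
                                 counts["n"] - counts["n_adherent"]])
        global_p = np.nan
        if len(groups) >= 2 and table.sum(axis=0).min() > 0:
            global_p = chisq_test(table).pvalue
        row = {"visit_month": month, "global_p": global_p}
        for g in groups:
            row[f"group{g}_n"] = int(counts.loc[g, "n"])
            row[f"group{g}_prop_adherent"] = (
                counts.loc[g, "n_adherent"] / counts.loc[g, "n"])
        summaries.append(row)

        pairs = [(a, b) for i, a in enumerate(groups) for b in groups[i + 1:]]
        for a, b in pairs:
            sub = table[[groups.index(a), groups.index(b)]]
            if sub.sum(axis=0).min() == 0:
                raw = np.nan
            else:
                raw = chisq_test(sub).pvalue
            pairwise.append({
                "visit_month": month, "group_a": a, "group_b": b,
                "p_raw": raw,
                "p_adjusted": (bonferroni(raw, len(pairs))
                               if np.isfinite(raw) else np.nan),
            })
    return pd.DataFrame(summaries), pd.DataFrame(pairwise)
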