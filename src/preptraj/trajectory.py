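"""Group-based trajectory model (GBTM).

A finite mixture of polynomial mean trajectories with Gaussian residuals,
fitted by EM. Each subject i contributes

    L_i = sum_g pi_g * prod_{t in obs(i)} Normal(y_it; poly(t; beta_g), sigma)

so subjects with missing visits enter through their observed time points
only (missing-at-random within the model). The E-step computes posterior
group memberships, the M-step solves one weighted least-squares problem
per group and updates the mixture weights and residual variance.
Residual variance is group-specific by default: symptom scales are
floor-compressed in low-scoring groups, and forcing a shared variance
makes BIC buy spurious components to mimic the heteroscedasticity. A
shared variance remains available as an option. Groups
are relabelled in ascending order of time-averaged fitted mean, so group
labels are deterministic given the data.

Model order is chosen over a grid of group counts by the Bayesian
Information Criterion among candidates whose per-group average posterior
probability (AvePP) all reach 0.7, the conventional adequacy bar.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

AVEPP_THRESHOLD = 0.7
_MIN_VAR = 1e-10


class EmptyGroupError(RuntimeError):
    """A mixture component collapsed (weight below threshold) during EM."""


@dataclass(frozen=True)
class GbtmConfig:
    """EM settings for one GBTM fit."""

    n_groups: int = 3
    degree: int = 2
    max_iter: int = 500
    tol: float = 1e-6          # relative log-likelihood change to stop
    n_restarts: int = 10
    seed: int | None = None
    variance: str = "per_group"   # "per_group" or "shared"
    min_weight: float = 1e-8
    # Residual-SD floor. Scores are discrete (integer HADS totals, pill-count
    # ratios over finite intervals), so a component SD below the measurement
    # resolution is meaningless and lets a Gaussian component collapse onto a
    # point mass (e.g. the spike of perfect adherence scores at 1.0). None
    # floors the SD at min_sigma_fraction of the observed score range.
    min_sigma: float | None = None
    min_sigma_fraction: float = 0.025

    def validate(self) -> None:
        if self.n_groups < 1:
            raise ValueError("n_groups must be >= 1")
        if self.degree < 0:
            raise ValueError("degree must be >= 0")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.variance not in ("shared", "per_group"):
            raise ValueError(f"unknown variance mode {self.variance!r}")


@dataclass
class GbtmFit:
    """Fitted mixture: weights, curves, residual scale and diagnostics."""

    config: GbtmConfig
    weights: np.ndarray            # (G,)
    coefficients: np.ndarray       # (G, degree+1), ascending powers
    sigma: np.ndarray              # (1,) shared or (G,)
    loglik: float
    n_params: int
    bic: float
    posterior: np.ndarray          # (n, G), rows sum to 1
    assignments: np.ndarray        # (n,), argmax posterior
    avepp: np.ndarray              # (G,), NaN for empty groups
    subject_ids: np.ndarray
    times: np.ndarray              # observed time grid
    converged: bool
    n_iter: int

    @property
    def n_groups(self) -> int:
        return len(self.weights)

    def mean_curves(self, times=None) -> np.ndarray:
        t = self.times if times is None else np.asarray(times, dtype=float)
        return np.polynomial.polynomial.polyval(t, self.coefficients.T)

    def assignment_shares(self) -> np.ndarray:
        return np.bincount(self.assignments,
                           minlength=self.n_groups) / len(self.assignments)


def _design(times: np.ndarray, degree: int) -> np.ndarray:
    return np.vander(times, degree + 1, increasing=True)


def _loglik_matrix(Y, M, n_obs, X, coef, sigma):
    """Per-subject per-group Gaussian log-likelihood over observed visits."""
    mu = coef @ X.T                                   # (G, T)
    resid = np.where(M, Y[None, :, :] - mu[:, None, :], 0.0)
    rss = (resid**2).sum(axis=2)                      # (G, n)
    var = np.maximum(sigma**2, _MIN_VAR)[:, None]     # (G or 1, 1)
    return -0.5 * n_obs[None, :] * np.log(2.0 * np.pi * var) - rss / (2.0 * var)


def _m_step(Y, M, n_obs, X, W, variance, sigma_floor):
    """Weighted least squares per group; returns (pi, coef, sigma).

    The variance update is maximized subject to sigma >= sigma_floor;
    since the expected complete-data log-likelihood is unimodal in the
    variance, projecting onto the feasible interval preserves the GEM
    monotonicity guarantee.
    """
    G = W.shape[0]
    d1 = X.shape[1]
    s = W @ M                       # (G, T): total weight per group/time
    sy = W @ np.where(M, Y, 0.0)    # (G, T)
    coef = np.empty((G, d1))
    for g in range(G):
        A = X.T @ (s[g][:, None] * X)
        b = X.T @ sy[g]
        coef[g] = np.linalg.solve(A + 1e-12 * np.eye(d1), b)
    mu = coef @ X.T
    resid2 = np.where(M, Y[None, :, :] - mu[:, None, :], 0.0) ** 2
    w_rss = (W[:, :, None] * resid2).sum(axis=(1, 2))   # (G,)
    w_obs = (W * n_obs[None, :]).sum(axis=1)            # (G,)
    if variance == "shared":
        sigma = np.sqrt(np.maximum(w_rss.sum() / w_obs.sum(), _MIN_VAR))
        sigma = np.array([sigma])
    else:
        sigma = np.sqrt(np.maximum(w_rss / np.maximum(w_obs, 1e-12), _MIN_VAR))
    sigma = np.maximum(sigma, sigma_floor)
    pi = W.sum(axis=1) / W.sum()
    return pi, coef, sigma


def _em(Y, M, n_obs, X, W0, config: GbtmConfig, sigma_floor: float):
    """Run EM from an initial posterior; returns parameters and history."""
    pi, coef, sigma = _m_step(Y, M, n_obs, X, W0, config.variance, sigma_floor)
    prev = -np.inf
    loglik = -np.inf
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        if pi.min() < config.min_weight:
            raise EmptyGroupError(f"group weight collapsed to {pi.min():.2e}")
        ll_ig = _loglik_matrix(Y, M, n_obs, X, coef, sigma)
        lw = np.log(pi)[:, None] + ll_ig
        ll_i = logsumexp(lw, axis=0)
        loglik = float(ll_i.sum())
        # EM guarantees monotone log-likelihood; tolerate rounding only
        assert loglik >= prev - 1e-6 * max(1.0, abs(prev)), (
            f"log-likelihood decreased: {prev} -> {loglik}"
        )
        if loglik - prev < config.tol * max(1.0, abs(loglik)):
            converged = True
            prev = loglik
            break
        prev = loglik
        W = np.exp(lw - ll_i[None, :])
        pi, coef, sigma = _m_step(Y, M, n_obs, X, W, config.variance,
                                  sigma_floor)
    return pi, coef, sigma, loglik, converged, it


def _init_posteriors(Y, M, times, config: GbtmConfig, rng):
    """Initial hard assignments: k-means on (level, slope) summaries for the
    first restart, random partitions afterwards."""
    n = Y.shape[0]
    G = config.n_groups
    inits = []
    if G == 1:
        return [np.ones((1, n))] * 1

    with np.errstate(invalid="ignore"):
        level = np.nanmean(np.where(M, Y, np.nan), axis=1)
    tbar = times.mean()
    tc = np.where(M, times[None, :] - tbar, 0.0)
    denom = (tc**2).sum(axis=1)
    yc = np.where(M, Y - level[:, None], 0.0)
    slope = np.divide((tc * yc).sum(axis=1), denom,
                      out=np.zeros(n), where=denom > 0)
    feats = np.column_stack([level, slope])
    feats = (feats - feats.mean(0)) / np.maximum(feats.std(0), 1e-12)
    km_seed = int(rng.integers(2**31 - 1))
    labels = KMeans(n_clusters=G, n_init=4, random_state=km_seed).fit_predict(feats)
    inits.append(labels)
    for _ in range(max(0, config.n_restarts - 1)):
        lab = rng.integers(G, size=n)
        # ensure every group is hit
        lab[rng.permutation(n)[:G]] = np.arange(G)
        inits.append(lab)
    posteriors = []
    for lab in inits:
        W = np.zeros((G, n))
        W[lab, np.arange(n)] = 1.0
        posteriors.append(W)
    return posteriors


def n_parameters(n_groups: int, degree: int, variance: str = "shared") -> int:
    """Free parameters: (G-1) weights + G*(degree+1) coefficients + variance."""
    return (n_groups - 1) + n_groups * (degree + 1) + (
        1 if variance == "shared" else n_groups)


def bic(loglik: float, n_params: int, n_subjects: int) -> float:
    """BIC = -2 logL + p ln(n), n = number of subjects."""
    return -2.0 * loglik + n_params * np.log(n_subjects)


def avepp(posterior: np.ndarray, assignments: np.ndarray) -> np.ndarray:
    """Mean posterior probability among subjects hard-assigned to each group;
    NaN for groups with no assigned subjects."""
    G = posterior.shape[1]
    out = np.full(G, np.nan)
    for g in range(G):
        mask = assignments == g
        if mask.any():
            out[g] = float(posterior[mask, g].mean())
    return out


def fit_gbtm(data: pd.DataFrame, config: GbtmConfig,
             subject_col: str = "subject_id",
             time_col: str = "visit_month",
             value_col: str = "value") -> GbtmFit:
    """Fit a GBTM to a long table (subject, time, value).

    Runs EM from a k-means start plus random restarts, keeps the best
    restart by log-likelihood, and relabels groups by ascending
    time-averaged fitted mean.
    """
    config.validate()
    wide = data.pivot_table(index=subject_col, columns=time_col,
                            values=value_col, aggfunc="mean")
    wide = wide.dropna(how="all")
    Y = wide.to_numpy(dtype=float)
    M = ~np.isnan(Y)
    Yz = np.where(M, Y, 0.0)
    n_obs = M.sum(axis=1).astype(float)
    times = wide.columns.to_numpy(dtype=float)
    subject_ids = wide.index.to_numpy()
    n = Y.shape[0]
    if n < config.n_groups:
        raise ValueError(
            f"need at least {config.n_groups} subjects with data, got {n}")
    X = _design(times, config.degree)

    if config.min_sigma is not None:
        sigma_floor = config.min_sigma
    else:
        spread = float(np.nanmax(Y) - np.nanmin(Y))
        sigma_floor = max(config.min_sigma_fraction * spread, 1e-8)

    rng = np.random.default_rng(config.seed)
    best = None
    for W0 in _init_posteriors(Yz, M, times, config, rng):
        try:
            result = _em(Yz, M, n_obs, X, W0, config, sigma_floor)
        except EmptyGroupError:
            logger.debug("restart abandoned: empty group")
            continue
        if best is None or result[3] > best[3]:
            best = result
    if best is None:
        raise EmptyGroupError(
            f"all {config.n_restarts} restarts collapsed a group "
            f"(G={config.n_groups})")
    pi, coef, sigma, loglik, converged, n_iter = best
    if not converged:
        logger.warning("EM did not converge in %d iterations (G=%d)",
                       config.max_iter, config.n_groups)

    # deterministic labels: ascending time-averaged fitted mean
    order = np.argsort((coef @ X.T).mean(axis=1))
    pi, coef = pi[order], coef[order]
    if config.variance == "per_group":
        sigma = sigma[order]

    ll_ig = _loglik_matrix(Yz, M, n_obs, X, coef, sigma)
    lw = np.log(pi)[:, None] + ll_ig
    posterior = np.exp(lw - logsumexp(lw, axis=0)[None, :]).T   # (n, G)
    assignments = posterior.argmax(axis=1)
    p = n_parameters(config.n_groups, config.degree, config.variance)

    return GbtmFit(
        config=config,
        weights=pi,
        coefficients=coef,
        sigma=sigma,
        loglik=loglik,
        n_params=p,
        bic=bic(loglik, p, n),
        posterior=posterior,
        assignments=assignments,
        avepp=avepp(posterior, assignments),
        subject_ids=subject_ids,
        times=times,
        converged=converged,
        n_iter=n_iter,
    )


def fit_gbtm_range(data: pd.DataFrame, groups: Iterable[int] = range(1, 6),
                   config: GbtmConfig | None = None,
                   **columns) -> list[GbtmFit]:
    """Fit GBTMs over a grid of group counts with shared settings."""
    base = config or GbtmConfig()
    return [fit_gbtm(data, replace(base, n_groups=g), **columns)
            for g in groups]


MIN_CLASS_SHARE = 0.04


def select_model(fits: Sequence[GbtmFit],
                 avepp_threshold: float = AVEPP_THRESHOLD,
                 min_class_share: float = MIN_CLASS_SHARE) -> GbtmFit:
    """Minimum-BIC fit among adequate candidates.

    A candidate is adequate when every group reaches the AvePP bar and
    every mixture weight reaches ``min_class_share``. The class-share
    condition follows applied trajectory-modelling convention: BIC on
    real-valued scores happily buys a dedicated component for a handful
    of outlying subjects, and a class too small to interpret (default
    < 4% of the sample) is not a substantive trajectory. Set
    ``min_class_share=0`` for the bare BIC+AvePP rule. Falls back to
    minimum BIC overall, with a warning, when no candidate qualifies.
    """
    if not fits:
        raise ValueError("no candidate fits")
    qualifying = [f for f in fits
                  if np.all(np.isfinite(f.avepp))
                  and np.all(f.avepp >= avepp_threshold)
                  and np.all(f.weights >= min_class_share)]
    pool = qualifying
    if not pool:
        logger.warning("no candidate reaches AvePP >= %.2f and class share "
                       ">= %.2f in every group; falling back to minimum BIC "
                       "overall", avepp_threshold, min_class_share)
        pool = list(fits)
    return min(pool, key=lambda f: f.bic)


def selection_table(fits: Sequence[GbtmFit],
                    avepp_threshold: float = AVEPP_THRESHOLD,
                    min_class_share: float = MIN_CLASS_SHARE) -> pd.DataFrame:
    """Per-candidate diagnostics mirroring a model-fitting appendix table."""
    chosen = select_model(fits, avepp_threshold, min_class_share)
    rows = []
    for f in fits:
        rows.append({
            "n_groups": f.n_groups,
            "loglik": f.loglik,
            "bic": f.bic,
            "min_avepp": float(np.nanmin(f.avepp)),
            "weights": np.round(f.weights, 4).tolist(),
            "converged": f.converged,
            "selected": f is chosen,
        })
    return pd.DataFrame(rows)


def summarize_trajectories(fit: GbtmFit, data: pd.DataFrame,
                           threshold: float = 8,
                           subject_col: str = "subject_id",
                           time_col: str = "visit_month",
                           value_col: str = "value") -> pd.DataFrame:
    """Observed per-group per-visit means and above-threshold proportions."""
    labels = pd.DataFrame({subject_col: fit.subject_ids,
                           "group": fit.assignments})
    merged = data.merge(labels, on=subject_col, how="inner")
    merged = merged.dropna(subset=[value_col])
    out = (
        merged.groupby(["group", time_col])[value_col]
        .agg(n="size", mean_score="mean",
             prop_case=lambda v: float((v >= threshold).mean()))
        .reset_index()
    )
    return out


def fit_to_dict(fit: GbtmFit) -> dict:
    """JSON-serialisable summary of a fit."""
    return {
        "n_groups": fit.n_groups,
        "degree": fit.config.degree,
        "weights": fit.weights.tolist(),
        "coefficients": fit.coefficients.tolist(),
        "sigma": fit.sigma.tolist(),
        "loglik": fit.loglik,
        "n_params": fit.n_params,
        "bic": fit.bic,
        "avepp": fit.avepp.tolist(),
        "converged": bool(fit.converged),
        "n_iter": fit.n_iter,
        "assignment_shares": fit.assignment_shares().tolist(),
        "times": fit.times.tolist(),
    }
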