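"""Screening chi-squares, proportional-odds model, Kruskal-Wallis,
Bonferroni-corrected adherence comparisons."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from preptraj.association import (
    adherence_by_trajectory,
    bonferroni,
    chisq_test,
    fit_ordered_logit,
    kruskal_wallis,
    pool_ordered_logit,
    screen_univariate,
)

# income x anxiety-trajectory counts as printed in the source cohort table
INCOME_TABLE = [[164, 148, 24], [397, 254, 36]]


def test_chisq_income_by_anxiety_trajectory():
    res = chisq_test(INCOME_TABLE)
    assert res.df == 2
    assert res.pvalue == pytest.approx(0.023, abs=0.001)


def test_chisq_independent_table_is_zero():
    res = chisq_test([[10, 20], [20, 40]])
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.pvalue == pytest.approx(1.0)


def test_chisq_hand_computed_2x2():
    res = chisq_test([[10, 20], [20, 10]])
    assert res.statistic == pytest.approx(20 / 3)
    assert res.df == 1


def test_chisq_permutation_invariance():
    a = chisq_test([[164, 148, 24], [397, 254, 36]])
    b = chisq_test([[397, 254, 36], [164, 148, 24]])
    c = chisq_test([[24, 148, 164], [36, 254, 397]])
    assert a.statistic == pytest.approx(b.statistic)
    assert a.statistic == pytest.approx(c.statistic)


def test_chisq_zero_margin_names_category():
    table = pd.DataFrame([[5, 0], [10, 0]], columns=["g1", "g2"])
    with pytest.raises(ValueError, match="g2"):
        chisq_test(table)


def test_screening_threshold_is_strict():
    assert screen_univariate({"a": 0.149}) == ["a"]
    assert screen_univariate({"a": 0.150}) == []


def test_screening_on_printed_anxiety_pvalues():
    pvals = {
        "age": 0.020, "education": 0.530, "income": 0.023,
        "gender_identity": 0.007, "marital": 0.045, "sexual_role": 0.004,
        "partners": 0.103, "cai": 0.197, "hiv_knowledge": 0.695,
        "syphilis": 0.252,
    }
    selected = screen_univariate(pvals)
    assert selected == ["age", "income", "gender_identity", "marital",
                        "sexual_role", "partners"]
    assert len(selected) == 6


def _simulate_proportional_odds(rng, n, beta, cutpoints=(-1.0, 1.5)):
    x = rng.normal(size=n)
    latent = beta * x + rng.logistic(size=n)
    y = np.digitize(latent, cutpoints)
    return pd.DataFrame({"x": x}), y


def test_null_covariate_gives_unit_odds_ratio(rng):
    X, y = _simulate_proportional_odds(rng, 4000, beta=0.0)
    fit = fit_ordered_logit(y, X)
    term = fit.terms[0]
    assert term.ci_low < 1.0 < term.ci_high
    assert abs(term.aor - 1.0) < 0.15


def test_odds_ratio_recovery_coverage():
    # Wald 95% CIs should cover the generating OR in ~95% of replicates;
    # 17/20 keeps the false-failure probability of this check near 1%.
    true_or = 2.0
    covered = 0
    for seed in range(20):
        gen = np.random.default_rng(1000 + seed)
        X, y = _simulate_proportional_odds(gen, 5000, beta=np.log(true_or))
        term = fit_ordered_logit(y, X).terms[0]
        covered += term.ci_low <= true_or <= term.ci_high
    assert covered >= 17


def test_two_level_outcome_matches_binary_logit(rng):
    X, y3 = _simulate_proportional_odds(rng, 2000, beta=0.7)
    y = (y3 >= 1).astype(int)
    ours = fit_ordered_logit(y, X)
    oracle = sm.Logit(y, sm.add_constant(X)).fit(disp=False)
    assert ours.terms[0].coef == pytest.approx(oracle.params["x"], abs=1e-4)
    assert ours.cutpoints[0] == pytest.approx(-oracle.params["const"], abs=1e-4)


def test_separation_raises_with_covariate_name(rng):
    x = np.concatenate([np.zeros(50), np.ones(50)])
    y = x.astype(int)  # perfectly separated
    with pytest.raises(Exception, match="(?i)separat|perfect"):
        fit_ordered_logit(y, pd.DataFrame({"sep_cov": x}))


def test_rank_deficient_design_rejected(rng):
    x = rng.normal(size=100)
    X = pd.DataFrame({"x1": x, "x2": 2 * x})
    y = (x > 0).astype(int)
    with pytest.raises(ValueError, match="rank"):
        fit_ordered_logit(y, X)


def test_pooled_ordered_logit_shrinks_nothing_systematic(rng):
    fits = []
    for seed in range(3):
        gen = np.random.default_rng(2000 + seed)
        X, y = _simulate_proportional_odds(gen, 3000, beta=np.log(1.8))
        fits.append(fit_ordered_logit(y, X))
    pooled = pool_ordered_logit(fits)
    assert pooled.loc[0, "ci_low"] < 1.8 < pooled.loc[0, "ci_high"]


def test_kruskal_wallis_separated_groups():
    h, df, p = kruskal_wallis([[1, 2, 3], [10, 11, 12]])
    assert df == 1
    assert h == pytest.approx(27 / 7)  # exact rank computation
    assert p == pytest.approx(stats.chi2.sf(27 / 7, 1))


def test_kruskal_wallis_identical_values():
    h, df, p = kruskal_wallis([[5, 5, 5], [5, 5, 5]])
    assert h == 0.0 and p == 1.0


def test_kruskal_wallis_tie_correction_small_instance():
    groups = [[1.0, 1.0, 2.0], [2.0, 2.0, 3.0]]
    # hand computation: ranks of (1,1,2,2,2,3) with ties -> (1.5,1.5,4,4,4,6)
    # H = 12/(n(n+1)) * sum R_j^2/n_j - 3(n+1), tie correction /(1 - sum(t^3-t)/(n^3-n))
    r1, r2 = 1.5 + 1.5 + 4, 4 + 4 + 6
    n = 6
    h_raw = 12 / (n * (n + 1)) * (r1**2 / 3 + r2**2 / 3) - 3 * (n + 1)
    tie = 1 - ((2**3 - 2) + (3**3 - 3)) / (n**3 - n)
    h, df, p = kruskal_wallis(groups)
    assert h == pytest.approx(h_raw / tie)


def test_bonferroni_adjustment():
    assert bonferroni(0.02, 3) == pytest.approx(0.06)
    assert bonferroni(0.5, 3) == 1.0
    for p in (0.001, 0.04, 0.3):
        assert bonferroni(p, 4) >= p


def _adherence_frame(props_by_group, n=200, month=12):
    rows = []
    sid = 0
    for g, prop in enumerate(props_by_group):
        for i in range(n):
            rows.append({"subject_id": sid, "visit_month": month,
                         "adherent": i < prop * n, "group": g})
            sid += 1
    frame = pd.DataFrame(rows)
    adherence = frame[["subject_id", "visit_month", "adherent"]]
    assignments = frame[["subject_id", "group"]].drop_duplicates()
    return adherence, assignments


def test_identical_adherence_gives_unit_pvalues():
    adherence, assignments = _adherence_frame([0.8, 0.8, 0.8])
    summary, pairwise = adherence_by_trajectory(adherence, assignments)
    assert summary.loc[0, "global_p"] == pytest.approx(1.0)
    assert (pairwise["p_adjusted"] == 1.0).all()
    assert len(pairwise) == 3  # three pairwise tests for three groups


def test_group_difference_detected_and_adjusted():
    adherence, assignments = _adherence_frame([0.9, 0.85, 0.5])
    summary, pairwise = adherence_by_trajectory(adherence, assignments)
    assert summary.loc[0, "global_p"] < 0.001
    assert summary.loc[0, "group2_prop_adherent"] == pytest.approx(0.5)
    assert (pairwise["p_adjusted"] >= pairwise["p_raw"]).all()
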