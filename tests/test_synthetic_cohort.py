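"""Generator behaviour: reproducibility, marginals, curves, diaries."""

from collections import namedtuple
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from preptraj.synthetic_cohort import (
    DEFAULT_ANXIETY_GROUPS,
    CohortConfig,
    TrajectoryGroupSpec,
    expand_items,
    generate_cohort,
    generate_diary,
    generate_hads_series,
    generate_visits,
    mean_curve,
    quadratic_through_extremum,
)

Subject = namedtuple(
    "Subject",
    "subject_id anxiety_group depression_group partner_band regimen dropout_visit",
)


def test_default_cohort_size_and_determinism():
    cfg = CohortConfig(seed=3)
    a = generate_cohort(cfg)
    b = generate_cohort(cfg)
    assert len(a) == 1023
    pd.testing.assert_frame_equal(a, b)
    c = generate_cohort(CohortConfig(seed=4))
    assert not a.equals(c)


def test_invalid_group_weights_rejected():
    bad = tuple(
        replace_weight(s, w) for s, w in zip(DEFAULT_ANXIETY_GROUPS, (0.5, 0.4, 0.2))
    )
    cfg = CohortConfig(group_specs_anxiety=bad)
    with pytest.raises(ValueError, match="sum to 1"):
        cfg.validate()


def replace_weight(spec: TrajectoryGroupSpec, w: float) -> TrajectoryGroupSpec:
    return replace(spec, weight=w)


def test_group_shares_converge_to_weights():
    cfg = CohortConfig(n_subjects=200_000, seed=99)
    cohort = generate_cohort(cfg)
    shares = cohort["anxiety_group"].value_counts(normalize=True).sort_index()
    np.testing.assert_allclose(shares.to_numpy(), (0.548, 0.393, 0.059),
                               atol=0.005)


def test_covariate_marginals_converge():
    cfg = CohortConfig(n_subjects=100_000, seed=5)
    cohort = generate_cohort(cfg)
    income = (cohort["income_band"] == "<619").mean()
    assert abs(income - 0.328) < 0.01
    syph = cohort["baseline_syphilis"].mean()
    assert abs(syph - 0.100) < 0.01


def test_dropout_rate_matches_configuration():
    rates = [
        generate_cohort(CohortConfig(seed=s))["dropout_visit"].notna().mean()
        for s in range(50)
    ]
    assert abs(np.mean(rates) - 0.117) < 0.01


def test_high_bell_quadratic_anchors():
    coefs = quadratic_through_extremum(10.83, 6.0, 5.30)
    assert mean_curve(coefs, 0) == pytest.approx(5.30)
    assert mean_curve(coefs, 6) == pytest.approx(10.83)
    # interior value of the symmetric bell through (0, 5.30), (6, 10.83)
    assert mean_curve(coefs, 3) == pytest.approx(9.4475)


def test_noise_free_series_equals_rounded_curve(rng):
    quiet = tuple(replace(s, residual_sd=1e-12) for s in DEFAULT_ANXIETY_GROUPS)
    cfg = CohortConfig(group_specs_anxiety=quiet)
    subject = Subject(1, 2, 0, ">=2", "daily", np.nan)  # high-bell anxiety
    rows = generate_hads_series(subject, cfg, rng)
    by_month = {r["visit_month"]: r["hads_a"] for r in rows}
    assert by_month[0] == 5      # 5.30 rounds to 5
    assert by_month[6] == 11     # 10.83 rounds to 11
    assert by_month[3] == 9      # 9.4475 rounds to 9


def test_series_respects_dropout_and_bounds(small_cohort_tables):
    config, tables = small_cohort_tables
    visits = tables["visits"]
    assert visits["hads_a"].between(0, 21).all()
    assert visits["hads_d"].between(0, 21).all()
    merged = visits.merge(tables["baseline"][["subject_id", "dropout_visit"]],
                          on="subject_id")
    dropped = merged.dropna(subset=["dropout_visit"])
    assert (dropped["visit_month"] < dropped["dropout_visit"]).all()
    # subjects without dropout attend every visit
    full = merged[merged["dropout_visit"].isna()]
    counts = full.groupby("subject_id").size()
    assert (counts == len(config.visit_months)).all()


@given(total=st.integers(min_value=0, max_value=21), seed=st.integers(0, 2**20))
def test_item_expansion_preserves_total(total, seed):
    items = expand_items(total, np.random.default_rng(seed))
    assert items.sum() == total
    assert items.min() >= 0 and items.max() <= 3
    assert len(items) == 7


def test_item_expansion_maximum_forces_all_threes(rng):
    assert (expand_items(21, rng) == 3).all()


def _fully_adherent_config() -> CohortConfig:
    certain = tuple(
        replace(s, adherent_probability_by_visit=(1.0,) * 5)
        for s in DEFAULT_ANXIETY_GROUPS
    )
    return CohortConfig(group_specs_anxiety=certain, high_mode_rate=1.0)


def test_fully_adherent_daily_subject_takes_pill_every_day(rng):
    cfg = _fully_adherent_config()
    subject = Subject(1, 0, 0, ">=2", "daily", np.nan)
    diary = generate_diary(subject, cfg, rng)
    assert (diary["pills_taken"] == 1).all()
    assert len(diary) == 360


def test_fully_adherent_event_driven_dosing_pattern(rng):
    cfg = replace(_fully_adherent_config(),
                  sex_day_rates={"<2": 0.0, ">=2": 0.0})
    # no random sex days; rebuild diary around a manually checked pattern by
    # sampling until a seed yields exactly one sex day
    cfg = replace(cfg, sex_day_rates={"<2": 0.0, ">=2": 0.004})
    subject = Subject(1, 0, 0, ">=2", "event_driven", np.nan)
    for seed in range(200):
        diary = generate_diary(subject, cfg, np.random.default_rng(seed))
        sex_days = diary.loc[diary["sex_day"] == 1, "day"].to_numpy()
        if len(sex_days) == 1 and 2 < sex_days[0] < 350:
            break
    else:
        pytest.fail("no seed produced an isolated sex day")
    x = int(sex_days[0])
    pills = dict(zip(diary["day"], diary["pills_taken"]))
    assert pills[x - 1] == 2  # two pills the day before
    assert pills[x] == 1 and pills[x + 1] == 1 and pills[x + 2] == 1
    others = diary[~diary["day"].isin([x - 1, x, x + 1, x + 2])]
    assert (others["pills_taken"] == 0).all()


def test_visits_reproducible_per_seed(small_cohort_tables):
    config, tables = small_cohort_tables
    cohort = generate_cohort(config)
    again = generate_visits(cohort, config)
    pd.testing.assert_frame_equal(tables["visits"], again)
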