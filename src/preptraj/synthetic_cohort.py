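"""Synthetic PrEP cohort generator.

Emulates a 12-month PrEP demonstration cohort of MSM with latent
mental-health trajectory structure: baseline covariates drawn from
published marginals, three latent anxiety and depression trajectory
groups with polynomial mean curves, visit-level HADS subscale scores,
daily pill/sex diaries whose adherence behaviour is linked to the
latent anxiety group, and single-event dropout.

All randomness flows from one master seed through per-stage and
per-subject `numpy.random.SeedSequence` substreams, so cohorts are
reproducible and subjects can be regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

HADS_MAX = 21
N_ITEMS = 7
ITEM_MAX = 3
DAYS_PER_MONTH = 30
STUDY_START = np.datetime64("2019-01-01")


def quadratic_through_extremum(
    y_ext: float, t_ext: float, y_end: float, t_end: float = 12.0
) -> tuple[float, float, float]:
    """Coefficients (c0, c1, c2) of the quadratic with vertex (t_ext, y_ext)
    passing through (t_end, y_end); evaluated as c0 + c1*t + c2*t**2."""
    a = (y_end - y_ext) / (t_end - t_ext) ** 2
    return (y_ext + a * t_ext**2, -2.0 * a * t_ext, a)


def mean_curve(coefficients: Sequence[float], t) -> np.ndarray:
    """Evaluate a polynomial mean curve (ascending coefficients) at months t."""
    return np.polynomial.polynomial.polyval(np.asarray(t, dtype=float),
                                            np.asarray(coefficients, dtype=float))


@dataclass(frozen=True)
class TrajectoryGroupSpec:
    """One latent trajectory group: mixture weight, polynomial mean curve of
    the HADS subscale score over months, residual SD of scores around the
    curve, and the per-follow-up-visit probability of fully adherent
    PrEP-taking behaviour."""

    label: str
    weight: float
    mean_curve_coefficients: tuple[float, ...]
    residual_sd: float
    adherent_probability_by_visit: tuple[float, ...]

    def mean_at(self, t) -> np.ndarray:
        return mean_curve(self.mean_curve_coefficients, t)


# Default groups. Mean curves are quadratics anchored to the per-visit
# score ranges each group exhibits: the "consistently low" and
# "consistently moderate" groups dip to their range minimum and rise to
# the maximum by month 12; the "high but bell-shaped" group peaks at
# month 6 and returns to baseline.
DEFAULT_ANXIETY_GROUPS: tuple[TrajectoryGroupSpec, ...] = (
    TrajectoryGroupSpec(
        "consistently_low", 0.548,
        quadratic_through_extremum(0.81, 6.0, 1.80), 1.0,
        (0.90, 0.89, 0.88, 0.87, 0.86),
    ),
    TrajectoryGroupSpec(
        "consistently_moderate", 0.393,
        quadratic_through_extremum(4.64, 3.0, 6.67), 2.0,
        (0.87, 0.86, 0.85, 0.84, 0.83),
    ),
    TrajectoryGroupSpec(
        "high_bell", 0.059,
        quadratic_through_extremum(10.83, 6.0, 5.30), 2.5,
        (0.85, 0.78, 0.71, 0.64, 0.58),
    ),
)

DEFAULT_DEPRESSION_GROUPS: tuple[TrajectoryGroupSpec, ...] = (
    TrajectoryGroupSpec(
        "consistently_low", 0.607,
        quadratic_through_extremum(0.61, 6.0, 1.31), 0.9,
        (0.90, 0.89, 0.88, 0.87, 0.86),
    ),
    TrajectoryGroupSpec(
        "consistently_moderate", 0.314,
        quadratic_through_extremum(4.16, 3.0, 6.04), 2.0,
        (0.87, 0.86, 0.85, 0.84, 0.83),
    ),
    TrajectoryGroupSpec(
        "high_bell", 0.079,
        quadratic_through_extremum(8.76, 6.0, 3.52), 2.4,
        (0.85, 0.78, 0.71, 0.64, 0.58),
    ),
)

# Baseline covariate marginals (categories and probabilities).
DEFAULT_COVARIATE_MARGINALS: dict[str, tuple[tuple, tuple]] = {
    "age_band": (("18-30", "31-50", ">50"), (0.328, 0.597, 0.074)),
    "education": (("high_school_or_less", "college_or_greater"), (0.188, 0.812)),
    "income_band": (("<619", ">=619"), (0.328, 0.672)),
    "gender_identity": (("male", "female"), (0.976, 0.024)),
    "marital_status": (
        ("single", "married_cohabiting", "separated_divorced_widowed"),
        (0.545, 0.429, 0.025),
    ),
    "sexual_role": (("top", "bottom", "versatile", "oral"),
                    (0.281, 0.275, 0.438, 0.007)),
    "partner_band": (("<2", ">=2"), (0.177, 0.823)),
    "cai": ((0, 1), (0.223, 0.777)),
    "hiv_knowledge": ((0, 1), (0.288, 0.712)),
    "baseline_syphilis": ((0, 1), (0.900, 0.100)),
}


@dataclass(frozen=True)
class CohortConfig:
    """Study-design parameters of the simulated cohort."""

    n_subjects: int = 1023
    visit_months: tuple[int, ...] = (0, 1, 3, 6, 9, 12)
    group_specs_anxiety: tuple[TrajectoryGroupSpec, ...] = DEFAULT_ANXIETY_GROUPS
    group_specs_depression: tuple[TrajectoryGroupSpec, ...] = DEFAULT_DEPRESSION_GROUPS
    dropout_fraction: float = 0.117
    regimen_split: float = 0.5  # proportion on daily PrEP
    covariate_marginals: Mapping[str, tuple[tuple, tuple]] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_MARGINALS)
    )
    seed: int = 0
    item_level: bool = False
    # sex-day rate per day by partner-count band
    sex_day_rates: Mapping[str, float] = field(
        default_factory=lambda: {"<2": 0.03, ">=2": 0.10}
    )
    # daily pill-taking probability in the fully adherent mode, and the
    # per-follow-up-visit rate of the shared low-adherence mode
    high_mode_rate: float = 0.99
    low_mode_rates: tuple[float, ...] = (0.93, 0.88, 0.82, 0.75, 0.66)

    @property
    def followup_months(self) -> tuple[int, ...]:
        return tuple(self.visit_months[1:])

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        vm = self.visit_months
        if vm[0] != 0 or any(b <= a for a, b in zip(vm, vm[1:])):
            raise ValueError(
                "visit_months must be strictly increasing and start at 0, "
                f"got {vm}"
            )
        for name, specs in (("anxiety", self.group_specs_anxiety),
                            ("depression", self.group_specs_depression)):
            total = sum(s.weight for s in specs)
            if abs(total - 1.0) > 1e-8:
                raise ValueError(
                    f"{name} group weights must sum to 1, got {total!r} "
                    f"({[s.weight for s in specs]})"
                )
            for s in specs:
                if s.residual_sd < 0:
                    raise ValueError(f"{name} group '{s.label}': residual_sd < 0")
                means = s.mean_at(vm)
                if means.min() < 0 or means.max() > HADS_MAX:
                    raise ValueError(
                        f"{name} group '{s.label}': mean curve leaves [0, {HADS_MAX}] "
                        f"on the visit grid ({means})"
                    )
                if len(s.adherent_probability_by_visit) != len(vm) - 1:
                    raise ValueError(
                        f"{name} group '{s.label}': adherent_probability_by_visit "
                        f"needs one entry per follow-up visit ({len(vm) - 1})"
                    )
        for p, what in ((self.dropout_fraction, "dropout_fraction"),
                        (self.regimen_split, "regimen_split")):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{what} must be in [0, 1], got {p}")
        for col, (cats, probs) in self.covariate_marginals.items():
            if len(cats) != len(probs) or abs(sum(probs) - 1.0) > 0.01:
                raise ValueError(f"covariate '{col}': bad category probabilities")


def _stage_seeds(config: CohortConfig):
    root = np.random.SeedSequence(config.seed)
    cohort_ss, hads_ss, diary_ss = root.spawn(3)
    return cohort_ss, hads_ss, diary_ss


def generate_cohort(config: CohortConfig | None = None) -> pd.DataFrame:
    """Draw baseline covariates, latent group labels, regimen and dropout.

    Returns one row per subject. Latent labels (``anxiety_group``,
    ``depression_group``, integer indices into the group specs) are
    carried in the frame; writers split them into a truth table.
    """
    config = config or CohortConfig()
    config.validate()
    cohort_ss, _, _ = _stage_seeds(config)
    rng = np.random.default_rng(cohort_ss)
    n = config.n_subjects

    data: dict[str, np.ndarray] = {"subject_id": np.arange(1, n + 1)}
    for col, (cats, probs) in config.covariate_marginals.items():
        p = np.asarray(probs, dtype=float)
        p = p / p.sum()
        data[col] = rng.choice(np.asarray(cats, dtype=object), size=n, p=p)

    wa = np.array([s.weight for s in config.group_specs_anxiety])
    wd = np.array([s.weight for s in config.group_specs_depression])
    data["anxiety_group"] = rng.choice(len(wa), size=n, p=wa / wa.sum())
    data["depression_group"] = rng.choice(len(wd), size=n, p=wd / wd.sum())

    data["regimen"] = np.where(
        rng.random(n) < config.regimen_split, "daily", "event_driven"
    ).astype(object)

    drops = rng.random(n) < config.dropout_fraction
    dropout_visit = np.full(n, np.nan)
    followups = np.asarray(config.followup_months, dtype=float)
    dropout_visit[drops] = rng.choice(followups, size=int(drops.sum()))
    data["dropout_visit"] = dropout_visit  # first visit NOT attended

    return pd.DataFrame(data)


def expand_items(total: int, rng: np.random.Generator) -> np.ndarray:
    """Distribute a subscale total over 7 items, each in {0..3}, uniformly
    one point at a time among items that still have headroom."""
    if not 0 <= total <= HADS_MAX:
        raise ValueError(f"total must be in [0, {HADS_MAX}], got {total}")
    items = np.zeros(N_ITEMS, dtype=int)
    for _ in range(int(total)):
        open_items = np.flatnonzero(items < ITEM_MAX)
        items[rng.choice(open_items)] += 1
    return items


def _attended_months(subject, config: CohortConfig) -> list[int]:
    dv = getattr(subject, "dropout_visit", np.nan)
    months = config.visit_months
    if dv is None or (isinstance(dv, float) and np.isnan(dv)):
        return list(months)
    return [m for m in months if m < dv]


def _truncnorm_score(mean: float, sd: float, rng: np.random.Generator) -> int:
    if sd <= 1e-12:
        x = mean
    else:
        a, b = (0.0 - mean) / sd, (HADS_MAX - mean) / sd
        x = truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng)
    return int(np.clip(round(float(x)), 0, HADS_MAX))


def generate_hads_series(subject, config: CohortConfig,
                         rng: np.random.Generator) -> list[dict]:
    """HADS-A/HADS-D observations at every attended visit for one subject.

    Subscale totals are rounded draws from a normal around the subject's
    group mean curve, truncated to [0, 21]. With ``config.item_level`` the
    totals are additionally expanded into 7 items each in {0..3}.
    """
    spec_a = config.group_specs_anxiety[int(subject.anxiety_group)]
    spec_d = config.group_specs_depression[int(subject.depression_group)]
    rows = []
    for month in _attended_months(subject, config):
        row = {
            "subject_id": subject.subject_id,
            "visit_month": month,
            "hads_a": _truncnorm_score(float(spec_a.mean_at(month)),
                                       spec_a.residual_sd, rng),
            "hads_d": _truncnorm_score(float(spec_d.mean_at(month)),
                                       spec_d.residual_sd, rng),
        }
        if config.item_level:
            for prefix, total in (("a", row["hads_a"]), ("d", row["hads_d"])):
                for i, v in enumerate(expand_items(total, rng), start=1):
                    row[f"{prefix}{i}"] = int(v)
        rows.append(row)
    return rows


def generate_visits(cohort: pd.DataFrame, config: CohortConfig) -> pd.DataFrame:
    """HADS observations for the whole cohort (per-subject substreams)."""
    _, hads_ss, _ = _stage_seeds(config)
    children = hads_ss.spawn(len(cohort))
    rows: list[dict] = []
    for subject, ss in zip(cohort.itertuples(index=False), children):
        rows.extend(generate_hads_series(subject, config, np.random.default_rng(ss)))
    return pd.DataFrame(rows)


def _interval_edges_days(config: CohortConfig) -> np.ndarray:
    return np.asarray(config.visit_months, dtype=int) * DAYS_PER_MONTH


def generate_diary(subject, config: CohortConfig,
                   rng: np.random.Generator) -> pd.DataFrame:
    """Daily pill/sex diary for one subject until dropout.

    A persistent uniform propensity decides, against the anxiety group's
    per-visit adherent probability, whether the subject behaves fully
    adherently in each between-visit interval. Fully adherent daily users
    take a pill with probability ``high_mode_rate`` per day; event-driven
    users place the protocol dosing pattern around each sex day (2 pills
    the day before — 1 if a pill was taken in the preceding six days —
    then one pill on the sex day and on each of the two following days).
    In the low mode, daily intake (or the per-episode probability of a
    complete pattern) follows the declining ``low_mode_rates``.
    """
    edges = _interval_edges_days(config)
    dv = getattr(subject, "dropout_visit", np.nan)
    if dv is None or (isinstance(dv, float) and np.isnan(dv)):
        n_days = int(edges[-1])
    else:
        n_days = int(dv) * DAYS_PER_MONTH

    day = np.arange(n_days)
    interval_idx = np.clip(np.searchsorted(edges[1:], day, side="right"),
                           0, len(edges) - 2)

    rate = config.sex_day_rates[str(subject.partner_band)]
    sex = rng.random(n_days) < rate

    # Adherence behaviour is a persistent trait: one uniform draw against
    # the group's profile decides whether the subject belongs to the fully
    # adherent mode throughout. The per-visit decline of observed adherence
    # then emerges from the low mode's falling intake rates.
    spec_a = config.group_specs_anxiety[int(subject.anxiety_group)]
    u = rng.random()  # persistent adherence propensity
    p_by_visit = np.asarray(spec_a.adherent_probability_by_visit, dtype=float)
    adherent_mode = np.repeat(u <= p_by_visit.mean(), len(p_by_visit))
    low = np.asarray(config.low_mode_rates, dtype=float)

    pills = np.zeros(n_days, dtype=int)
    if subject.regimen == "daily":
        p_day = np.where(adherent_mode[interval_idx],
                         config.high_mode_rate, low[interval_idx])
        pills = rng.binomial(1, p_day)
    else:
        for x in np.flatnonzero(sex):
            v = interval_idx[x]
            p_ok = config.high_mode_rate if adherent_mode[v] else low[v]
            doses: list[tuple[int, int]] = []
            before_day = max(x - 1, 0)
            prior = pills[max(x - 6, 0): x].sum() if x > 0 else 0
            doses.append((before_day, 1 if prior >= 1 else 2))
            for d in (x, x + 1, x + 2):
                if d < n_days:
                    doses.append((d, 1))
            if rng.random() >= p_ok:  # incomplete episode: drop one dose
                doses.pop(rng.integers(len(doses)))
            for d, k in doses:
                pills[d] += k

    return pd.DataFrame({
        "subject_id": subject.subject_id,
        "iso_date": (STUDY_START + day).astype("datetime64[D]").astype(str),
        "day": day,
        "pills_taken": pills,
        "sex_day": sex.astype(int),
        "regimen": subject.regimen,
    })


def generate_diaries(cohort: pd.DataFrame, config: CohortConfig) -> pd.DataFrame:
    _, _, diary_ss = _stage_seeds(config)
    children = diary_ss.spawn(len(cohort))
    frames = [
        generate_diary(subject, config, np.random.default_rng(ss))
        for subject, ss in zip(cohort.itertuples(index=False), children)
    ]
    return pd.concat(frames, ignore_index=True)


def generate_dispensing(cohort: pd.DataFrame, config: CohortConfig) -> pd.DataFrame:
    """Pickup intervals between attended visits; enough pills plus a small
    buffer are dispensed at the start of each interval."""
    edges = _interval_edges_days(config)
    months = config.visit_months
    rows = []
    for subject in cohort.itertuples(index=False):
        attended = _attended_months(subject, config)
        for i in range(len(attended) - 1):
            m0, m1 = attended[i], attended[i + 1]
            d0, d1 = m0 * DAYS_PER_MONTH, m1 * DAYS_PER_MONTH
            rows.append({
                "subject_id": subject.subject_id,
                "visit_month": m1,
                "start_date": str((STUDY_START + d0).astype("datetime64[D]")),
                "end_date": str((STUDY_START + d1).astype("datetime64[D]")),
                "start_day": d0,
                "end_day": d1,
                "pills_dispensed": (d1 - d0) + 2,
            })
    return pd.DataFrame(rows)


def generate_dataset(config: CohortConfig | None = None) -> dict[str, pd.DataFrame]:
    """Generate every table of a synthetic study in one call."""
    config = config or CohortConfig()
    cohort = generate_cohort(config)
    group_labels_a = {i: s.label for i, s in enumerate(config.group_specs_anxiety)}
    group_labels_d = {i: s.label for i, s in enumerate(config.group_specs_depression)}
    truth = pd.DataFrame({
        "subject_id": cohort["subject_id"],
        "anxiety_group": cohort["anxiety_group"].map(group_labels_a),
        "depression_group": cohort["depression_group"].map(group_labels_d),
        "anxiety_group_index": cohort["anxiety_group"],
        "depression_group_index": cohort["depression_group"],
    })
    baseline = cohort.drop(columns=["anxiety_group", "depression_group"])
    return {
        "baseline": baseline,
        "truth": truth,
        "visits": generate_visits(cohort, config),
        "diary": generate_diaries(cohort, config),
        "dispensing": generate_dispensing(cohort, config),
    }


def write_dataset(tables: Mapping[str, pd.DataFrame], out_dir,
                  with_truth: bool = False) -> dict[str, str]:
    """Write the generated tables as CSV; truth labels only on request."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = {}
    for name, frame in tables.items():
        if name == "truth" and not with_truth:
            continue
        path = out / f"{name}.csv"
        frame.to_csv(path, index=False)
        written[name] = str(path)
    return written
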