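# preptraj

Group-based trajectory analysis of anxiety, depression and adherence in
PrEP cohorts — as a reusable, fully tested pipeline on simulated data.

## The problem

Cohort studies of HIV pre-exposure prophylaxis (PrEP) in men who have sex
with men track mental health with the Hospital Anxiety and Depression
Scale (HADS: two 7-item subscales, each item 0–3, totals 0–21, total ≥ 8
screening positive) and measure adherence from pill diaries — a
pills-per-day ratio for daily dosing, and sex-day dosing coverage for
event-driven dosing. The analytic core is a **group-based trajectory
model (GBTM)**: a finite mixture in which each latent group g follows its
own polynomial mean trajectory,

    y_it | group g  ~  Normal( β_g0 + β_g1 t + β_g2 t², σ_g² ),
    P(group g) = π_g,

fitted by EM over subjects' repeated measures, with the number of groups
chosen by BIC among candidates whose average posterior probability
(AvePP) reaches 0.7 in every group and whose every class is large enough
to interpret. Group labels then feed a proportional-odds (ordered
logistic) regression on baseline covariates screened by χ² tests
(p < 0.150), with missing outcomes handled by multiple imputation and
Rubin pooling.

Such cohort datasets are rarely public. `preptraj` therefore ships a
synthetic-data generator that emulates the study design end to end —
1023 subjects, visits at months 0/1/3/6/9/12, three latent trajectory
groups per outcome (consistently low / consistently moderate / high but
bell-shaped), 11.7% attrition, daily pill/sex diaries with adherence
behaviour linked to the latent anxiety group — so every stage of the
analysis is testable against known ground truth.

## Worked example

```python
from preptraj import (CohortConfig, GbtmConfig, generate_cohort,
                      generate_visits, fit_gbtm_range, select_model)

cfg = CohortConfig(seed=11)                      # 1023 subjects by default
visits = generate_visits(generate_cohort(cfg), cfg)
fits = fit_gbtm_range(visits, range(1, 6),       # candidate group counts
                      GbtmConfig(seed=5), value_col="hads_a")
best = select_model(fits)
print(best.n_groups, best.weights.round(3), best.avepp.round(3))
```

prints

```
3 [0.558 0.371 0.071] [0.992 0.977 0.96 ]
```

— the three-group solution is selected; the estimated mixture weights
(55.8 / 37.1 / 7.1%) recover the generating proportions (54.8 / 39.3 /
5.9%), and every group's AvePP is far above the 0.7 adequacy bar. The
fitted mean curves (`best.mean_curves()`) reproduce the three shapes:
flat-low, dip-then-rise moderate, and a bell peaking at month 6.

The full pipeline (simulate → score HADS → score adherence → impute →
fit trajectories → associate) runs from the command line:

```bash
preptraj run-all --seed 7 --out-dir runs/demo
```

writing `visits.csv`, `adherence.csv`, `trajectories.json`,
`assignments.csv`, `table2.csv`, `table3.csv`, `fig3_data.csv` and a
hash manifest; a rerun with the same seed reproduces every artifact
byte-for-byte.

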