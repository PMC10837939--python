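# Methods

## Study design emulated by the generator

The synthetic cohort reproduces the design of a 12-month PrEP
demonstration study in MSM: `n_subjects = 1023`, clinic visits at months
0, 1, 3, 6, 9, 12, a single dropout event hitting 11.7% of subjects
(dropout visit uniform over the five follow-up visits; all visits from
the dropout visit onward are missing), a 50/50 split between daily and
event-driven regimens (the source study does not report the split), and
baseline covariates drawn independently from the published marginals
(age band, education, income band, gender identity, marital status,
sexual role, partner-count band, condomless anal intercourse, HIV
knowledge, baseline syphilis). Covariates are *not* linked to the latent
groups: joint covariate–group distributions are unreported, so
association analyses on synthetic data are null by construction and are
validated by parameter-recovery simulations instead.

### HADS trajectories

Each subject carries a latent anxiety group and an (independent) latent
depression group. Mean curves are quadratics in months anchored to the
per-visit score ranges each group exhibits:

| outcome | group | weight | curve anchors | residual SD |
|---|---|---|---|---|
| anxiety | consistently low | 0.548 | min 0.81 at month 6, 1.80 at 0/12 | 1.0 |
| anxiety | consistently moderate | 0.393 | min 4.64 at month 3, 6.67 at 12 | 2.0 |
| anxiety | high but bell-shaped | 0.059 | 5.30 at 0/12, peak 10.83 at 6 | 2.5 |
| depression | consistently low | 0.607 | min 0.61 at month 6, 1.31 at 0/12 | 0.9 |
| depression | consistently moderate | 0.314 | min 4.16 at month 3, 6.04 at 12 | 2.0 |
| depression | high but bell-shaped | 0.079 | 3.52 at 0/12, peak 8.76 at 6 | 2.4 |

Visit scores are truncated-normal draws (support [0, 21]) around the
curve, rounded to integers. A proper truncated normal is used rather
than clipping so the generator does not create a point mass at 0 that
the Gaussian mixture downstream could not represent. Residual SDs are
unreported in the source; the defaults reflect that a low-symptom group
sits against the scale floor and is therefore compressed (SD ≈ 1),
while symptomatic groups show the 2–2.5-point visit-to-visit variation
typical of HADS subscales. Item-level expansion (distributing a subscale
total over 7 items in {0..3}) exists to exercise internal-consistency
computations; the analysis itself operates on totals.

### Diaries and adherence behaviour

Sex days are Bernoulli per day (rate 0.10/day for subjects with ≥2
recent partners, 0.03/day otherwise). Adherence behaviour is a
persistent trait: one uniform draw per subject, thresholded against the
mean of the anxiety group's per-visit adherent-probability profile,
assigns the subject to a fully adherent mode (daily intake probability
0.99; event-driven episodes dosed per protocol with probability 0.99)
or to a low mode whose intake rate falls over the follow-up intervals
(0.93, 0.88, 0.82, 0.75, 0.66). Profiles by anxiety group: consistently
low (0.90…0.86), moderate (0.87…0.83), high-bell (0.85…0.58) — the
high-bell group is least adherent, and because the low mode decays, the
gap between groups in the *proportion adherent* (score > 0.9) widens
toward month 12. Adherence is tied to the anxiety (not depression)
group, mirroring the finding that anxiety, not depression, tracked
adherence. The two-mode structure mirrors the reported two adherence
trajectories (high ≈ 1.00 vs low, declining). Event-driven dosing places
2 pills on the day before a sex day (1 if a pill fell in the preceding
six days), then 1 pill on the sex day and on each of the two following
days; an incomplete episode omits one required dose at random.

## Adherence scoring rules

Daily PrEP: score = pills consumed / days between pickups, capped at 1.
Event-driven PrEP: score = covered sex days / sex days, where a sex day
X is covered when both hold:

* **before** — at least 2 pills over days {X−1, X}, or at least 1 pill
  there plus ≥1 pill in [X−6, X−2]. The two-day sum is used because a
  day-resolution diary cannot see within-day timing; the qualifying
  prior pill must fall strictly before X−1, otherwise a lone X−1 pill
  would qualify itself and the two-pill clause would be vacuous.
* **during/after** — ≥1 pill on each of X, X+1, X+2. A pill on X may
  serve both clauses (literal reading of the dosing rule).

"Adherent" means score **strictly** greater than 0.9. Intervals with no
sex days give a missing event-driven score (coverage undefined), and a
sex day whose rule window reaches days outside the diary span is
indeterminate and excluded from both numerator and denominator. Days
before enrolment count as pill-free (subjects are PrEP-naive). The
scoring ratio is implemented as covered/total so it lies in [0, 1].
Subject-intervals whose reported intake exceeds the dispensed pill count
are capped at the dispensed total with an audit entry. Intervals
containing a regimen switch are scored per segment and combined weighted
by segment days. An exhaustive test compares the rule engine against a
brute-force evaluator over all 2^10 single-pill logs around a sex day.

## Group-based trajectory model

Finite mixture of polynomial (default quadratic) mean trajectories with
Gaussian residuals, fitted by EM on the subject-level likelihood; a
subject's missing visits simply drop out of the product (MAR within the
model). M-step: weighted least squares per group on the visit grid;
mixture weights are mean posteriors; variance updates are closed-form.
Numerical choices:

* **Group-specific residual variance by default.** HADS groups genuinely
  differ in spread (floor compression); under a shared variance, BIC
  buys extra components to mimic the heteroscedasticity. A shared
  variance remains available (`variance="shared"`) and is used for
  adherence trajectories, where noise scale varies by regimen design
  (binomial denominators: interval days vs sex days) rather than by
  class — class-specific variances there would classify by regimen.
* **Residual-SD floor** at 2.5% of the observed score range (override
  with `min_sigma`): adherence scores have a point mass at exactly 1.0
  onto which an unconstrained component collapses (σ → 0, unbounded
  likelihood). The floor is a measurement-resolution argument — scores
  are integer totals or coarse ratios — and the constrained M-step
  preserves EM's monotone log-likelihood, which is asserted at every
  iteration.
* **Initialisation**: k-means on per-subject (level, slope) summaries,
  plus random-partition restarts (default 10); best restart by final
  log-likelihood; a restart that collapses a component (weight < 1e−8)
  is abandoned. Convergence when the log-likelihood gain falls below
  `tol × max(1, |loglik|)` (default 1e−6).
* **Deterministic labels**: groups sorted by time-averaged fitted mean,
  so "group 0" is always the lowest trajectory.

BIC = −2 logL + p ln(n_subjects) with p = (G−1) + G(degree+1) + (1 or G)
variance parameters. AvePP_g is the mean posterior probability among
subjects hard-assigned to g (NaN for empty groups).

**Model selection**: minimum BIC among candidates with every AvePP ≥ 0.7
*and every mixture weight ≥ 4% of the sample*. The class-share condition
follows applied trajectory-modelling convention: on real-valued scores,
BIC will happily dedicate a component to a handful of outlying subjects
(e.g. event-driven users with one or two sex days and extreme coverage
ratios), and a class too small to interpret is not a substantive
trajectory. Setting `min_class_share=0` restores the bare BIC+AvePP
rule. If no candidate qualifies, the minimum-BIC fit overall is returned
with a warning.

## Missing data

Chained-equations imputation (default m = 5 datasets, 10 sweeps):
numeric columns by predictive mean matching (5 donors) on a
least-squares fit, binary/categorical columns by draws from a
(multinomial) logistic model; observed cells are never altered; each
imputed dataset runs on an independent substream of the seed. Downstream
estimates are combined by Rubin's rules (total variance
W + (1 + 1/m)·B, t reference with Rubin degrees of freedom). In the
pipeline, trajectory models are fitted on each imputed dataset and a
subject's analysis label is the modal group across imputations (the
interaction between imputation and trajectory fitting is not specified
in the source; this choice is transparent and reproducible).

## Association analysis

Pearson χ² (no continuity correction — this reproduces the printed
income p-value exactly; low expected counts trigger a warning, not a
switch to an exact test) screens covariates at p < 0.150 (strict).
Screened covariates enter a proportional-odds model of the ordered
trajectory group (low < moderate < high, lowest as reference end) with
Wald 95% CIs; aOR > 1 means higher odds of a worse trajectory.
Per-imputation fits are Rubin-pooled on the coefficient scale.
Kruskal–Wallis (tie-corrected) compares adherence scores across groups
per visit; pairwise χ² tests of adherent proportions are
Bonferroni-multiplied and capped at 1.

## Problem sizes used in tests and the acceptance script

Model-order, share and AvePP checks use 20 default cohorts (n = 1023);
attrition uses 50 cohorts; adherence-trajectory selection uses 5 cohorts
(diary simulation and coverage scoring dominate its cost). These sizes
give Monte-Carlo error comfortably inside the stated tolerances (e.g.
SE of a mean share over 20 cohorts ≈ 0.4 pp against a ±3 pp band).

## What passing tests do and do not show

The generator matches the *reported structure* of the study — group
shapes, proportions, attrition, scale ranges, a two-mode adherence
distribution — not its unpublished microdata. Real HADS scores are
skewed and integer-valued with floor effects only partially captured by
truncated normals; real adherence behaviour includes regimen switching
(supported by the scorer, not simulated by default), post-hoc diary
correction, and informative dropout, none of which are generated.
Consequently, recovery of the printed real-data quantities that depend
on those microdata — Table-style adjusted odds ratios, adherence
medians, Cronbach's alphas (printed 0.879/0.806/0.806) — is out of
scope; those components are validated by parameter-recovery and oracle
properties instead. The gender-identity and marital-status screening
p-values printed in the source (0.007, 0.045) do not reproduce from the
printed counts alone (Pearson gives 0.003, 0.037, likely an
MI-pooled-statistic difference); they are documented rather than forced.

## Known limitations

* Gaussian outcome family; no censored-normal, ordinal or zero-inflated
  families (a hook for a censored likelihood is the natural extension).
* No covariate-dependent mixture weights and no joint multi-outcome
  trajectories.
* The "BIC value close to 0" selection wording in the source is
  non-standard; standard minimum BIC is implemented.
* Dropout is a single MCAR event; no informative-missingness sensitivity
  analysis.
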