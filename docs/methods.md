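# Methods

## Problem and reference standard

A CABG surgical-site infection is confirmed by infection-control
surveillance (manual chart review against CDC criteria); the task is to
predict that label from an aggregated claims record of the hospitalization.
Aggregation matters: Taiwan NHI-style claims carry episode totals with no
time stamps, so nothing in the feature set distinguishes prophylactic from
therapeutic antibiotic use — the models can only exploit totals, code
flags, and stay characteristics.

## The six models

**ICD-9-CM model.** Deterministic code lookup. Index-admission events match
only *secondary* diagnoses (a primary infection diagnosis on the index
admission would suggest infection present before surgery); post-discharge
events match primary or secondary diagnoses on encounters within one year.
The one-year window is assumed enforced upstream by whoever assembled the
`postdischarge_dx` field, since the aggregated record has no dates. Codes
are canonicalized to dotted form; undotted 4-digit strings are rejected as
ambiguous rather than guessed at.

**Criteria-counting models.** The six surrogate criteria use strict `>`
comparisons throughout ("more than three types", "> 21 days"): boundary
equality never satisfies a criterion. The moderate model's published
description, "more than three criteria", is implemented as *at least* k = 3
because the ≥ 4 reading nearly collapses onto the strict model and the
model is explicitly the middle of the three; `k` is a parameter so the
literal reading is one flag away. The second-line catalog holds 18 distinct
ATC codes (one source row is duplicated); cefazolin is pinned to the WHO
code J01DB04, configurable because the source never prints it.

**Logistic model.** Newton–Raphson IRLS on the six continuous variables,
convergence at max |Δβ| < 1e-8 or 100 sweeps. The model is always oriented
toward P(SSI = 1); a fit of the complementary outcome (as some commercial
packages report, with positive intercept and negative slopes) is identical
up to negating all coefficients and mapping the cutoff c ↦ 1 − c, which is
why this package standardizes one orientation instead of reproducing the
source's ambiguous one. Perfect and quasi-complete separation are detected
(non-finite working weights, diverging coefficients, or all-extreme fitted
probabilities) and reported via a flag and warning with the last finite
coefficients, never silently. Stepwise selection uses likelihood-ratio
chi-square p-values with entry and removal at 0.05 (common commercial
defaults; both configurable), forward step then backward purge until
stable, ties broken by candidate order. The ROC sweep uses the rule
"positive when score ≥ cutoff" over all distinct scores plus a flag-nobody
sentinel; AUC is the Mann–Whitney statistic with ties worth one half;
Youden ties break toward the smaller cutoff, preferring sensitivity.

**CART.** Grown from scratch: candidate thresholds are midpoints between
consecutive distinct sorted values, splits maximize the Gini-impurity
decrease, "≤ threshold goes left", ties break by variable input order then
smaller threshold. Growth defaults (min 20 cases to split, min 7 per leaf,
max depth 5) are scaled for cohorts of roughly one thousand episodes.
Misclassification costs are equal and priors are the training frequencies;
a tied leaf predicts non-SSI, the prevalent class. Pruning is weakest-link:
repeatedly collapse the internal node(s) minimizing
g(t) = [R(t) − R(T_t)] / (|leaves(T_t)| − 1) with R the training
misclassification count, recording each collapse as one strictly-increasing
alpha step of a nested subtree family. Subtree selection is stratified
V-fold (default 10) cross-validation over candidate alphas (geometric means
of consecutive recorded alphas, plus 0 and the final alpha): each fold
grows its own tree, prunes it at the candidate, and scores the held-out
fold; the minimum-cost rule picks the winner, ties toward the larger alpha
(smaller tree). A 1-SE rule is available (`rule="1se"`). If a class has
fewer members than V, V is reduced with a warning so every fold retains
both classes.

**Evaluation.** The five metrics are kept as integer count fractions;
percents are rounded half-up to two decimals only at presentation, matching
the published tables' style. Zero-denominator metrics (PPV when nothing is
flagged) are *undefined* and print as "—", never 0 or 100. Two exact
identities are enforced in tests for every computed row: accuracy =
prevalence·sensitivity + (1 − prevalence)·specificity, and PPV/NPV via
Bayes from sensitivity, specificity and prevalence.

## Synthetic cohort generator

The generator emulates the published training-hospital characteristics
table: class-conditional moments for sex, age, vessels, length of stay,
antibiotic types/doses, cefazolin use and dose, second-line use, and the
marginal probability of carrying an ICD-9-CM SSI code (materialized as
998.5 on the index admission, matching what the code model can see). Since
only moments are published, the families are modelling choices, swappable
via `CohortSpec`:

| variable | family | matched to | default (non-SSI / SSI) |
|---|---|---|---|
| SSI label | Bernoulli | prevalence | 24/1017 (center A), 17/845 (center B) |
| sex, cefazolin use, second-line, ICD flag | Bernoulli | proportion | see `ClassParams` |
| age (years) | normal truncated to [20, 100] | mean/SD | 64.98 (10.86) / 67.14 (10.95) |
| vessels ∈ {1,2,3} | 3-point discrete | mean/SD | 1.89 (0.33) / 1.67 (0.56) |
| length of stay (days) | lognormal | median (scale), mean (shape) | 16, 17.11 / 47.5, 58.29 |
| antibiotic types | 1 + negative binomial | mean/SD | 1.51 (0.90) / 3.71 (2.10) |
| total antibiotics (DDD) | gamma | mean/SD | 7.89 (8.43) / 24.07 (16.84) |
| cefazolin dose among users (DDD) | gamma | mean/SD | 4.03 (2.12) / 4.89 (3.61) |

Notes on the less obvious choices:

* **Second-line margin.** The published table's second-line row is
  internally inconsistent (overall 115 = non-SSI 115 + SSI 20); it is
  resolved as non-SSI 95/993 and SSI 20/24 so the margin reconciles
  (115 = 95 + 20).
* **Cefazolin vs total dose.** The domain invariant cefazolin ≤ total DDD
  is enforced by capping the cefazolin draw at the episode total. Capping
  (rather than raising the total) keeps the total-DDD and use-probability
  moments exact; the cefazolin *dose* mean absorbs the truncation bias
  (realized ≈ 2.8 DDD non-SSI vs the 4.0 among-user target), which no
  downstream model or check depends on. The among-user dose mean itself is
  the published overall class mean divided by the use probability, since
  only the overall figure is printed.
* **SSI length of stay.** The published SSI class is extremely dispersed
  (mean 58.3, SD 58.7 > mean, median 47.5). The lognormal is parameterized
  from median and mean, reproducing the right skew; its implied SD
  (≈ 41) undershoots the printed one — with 24 real cases the printed SD is
  itself fragile, and no published shape information exists to fit a third
  moment.
* **Independence.** Variables are independent within class (no published
  covariance information). This is the generator's main departure from real
  claims, where stay, doses and second-line use are strongly coupled
  *within* the infected class too. Consequently the simulated cohorts
  reproduce the qualitative model ordering (loose = perfect sensitivity
  with tiny PPV; tree best PPV) but not the published tables' exact cells,
  which are unrecoverable without the real data.
* **Exclusions.** Age < 20, in-hospital death and prior-operation SSI are
  modelled as already applied: age is truncated, the other two never
  generated.

Generation is vectorized and fully determined by the spec (including its
seed): identical specs give byte-identical CSVs.

## Validation design and problem sizes

* Metric arithmetic is checked exactly against every published
  two-center table cell, with confusion counts reconstructed from the
  sensitivity/specificity fractions. One published cell (verification
  decision-tree accuracy, "99.05 (838/845)") has a numerator typo — the
  row's own sensitivity and specificity cells imply 837 correct and
  837/845 = 99.05% exactly — so percents, not printed numerators, are the
  assertion target.
* The ROC/Youden implementation is checked against explicit pair-counting
  and exhaustive-cutoff oracles on 200 random datasets (n ≤ 50); the CART
  grower against an exhaustive depth-2 tree search on 100 random datasets
  (n ≤ 30), where the fully grown tree must reach at most the exhaustive
  optimum's training cost; pruning schedules must have strictly increasing
  alphas and nested subtrees. IRLS is cross-checked against an independent
  GLM implementation to 1e-6 and must recover known coefficients within 5%
  on n = 100,000 simulated episodes.
* Stepwise selection is validated on a minimal one-signal design (one
  signal plus one independent noise candidate, 20 seeded replicates,
  n = 2,000). With entry at p = 0.05 every extra noise candidate enters
  with ~5% probability, so a high exact-recovery rate is only a fair ask
  of the minimal design; wider noise designs measure the selection
  threshold, not correctness.
* Generator fidelity is measured on one seeded n = 100,000 cohort at
  *balanced* prevalence, so both classes receive ~50,000 draws. The
  class-conditional distributions do not depend on prevalence; at the
  natural 2.4% prevalence the SSI class would get ~2,400 draws and the
  tightest checks (proportions to ±0.01) would sit at one standard error —
  a coin flip, not a test of the generator.
* The qualitative model-ordering check runs ten seeded training-size
  experiments and requires the full published pattern in at least eight:
  with only ~24 SSI cases per cohort there is a small per-seed chance that
  some SSI episode meets no criterion (breaking loose's 100% sensitivity)
  or that a rare strict-model flag produces a degenerate PPV. Undefined
  PPVs (models that flag nobody) are excluded from the "tree PPV greatest"
  comparison.

## Known limitations

* Within-class independence of the generator (above) — simulated cohorts
  are a harder-than-real test for models exploiting variable interactions
  and an easier one for marginal rules.
* The logistic and tree models take the variables untransformed; the
  source's "binary variables were converted into continuous variables" is
  followed, with no further transformation because none is described.
* No confidence intervals or paired model comparisons (none are published
  to compare against).
* The ICD flag is generated marginally per class, not mechanistically from
  an infection process; the code model's simulated performance therefore
  tracks the published per-class code frequencies by construction.
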