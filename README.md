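# ssi-ident

Identification of coronary-artery-bypass-graft (CABG) surgical-site-infection
(SSI) cases from aggregated health-insurance claims data.

Infection-control surveillance (manual chart review against CDC criteria) is
the reference standard for SSI, but it is labor-intensive and unavailable at
scale. Claims databases are cheap and population-wide, yet the obvious
approach — flagging ICD-9-CM infection codes — both misses true cases and
roughly doubles the apparent infection rate. This package implements and
compares six claims-based identification models for CABG SSI, for
epidemiologists and outcomes researchers who need a validated case
definition before running patient-level studies on claims:

* **ICD-9-CM model** — positive when a postoperative-infection code
  (996.03, 996.61, 996.72, 998.5) appears among the index admission's
  secondary diagnoses, or a code from a wider list (038.0–038.4, 038.8,
  038.9, 682.6, 682.9, 780.6, 790.7, 875.0, 875.1, 891.0, 891.1, 996.03,
  996.61, 996.72, 998.3, 998.5) appears on post-discharge encounters within
  one year.
* **Models 1–3 (criteria counting)** — six binary surrogate criteria:
  antibiotic types > 3, total antibiotics > 7 DDD, cefazolin > 7 DDD, any
  second-line antibiotic, length of stay > 21 days, vessels obstructed > 2.
  Model 1 (strict) requires all six, model 2 (moderate) at least *k* = 3,
  model 3 (loose) any one.
* **Model 4 (logistic regression)** — the same six variables in continuous
  form, stepwise-selected by likelihood-ratio tests (entry/removal p =
  0.05), fitted by IRLS for P(SSI | x) = logit⁻¹(β₀ + βᵀx), with the
  operating cutoff chosen on the ROC curve by the Youden index
  J = sensitivity + specificity − 1.
* **Model 5 (CART decision tree)** — binary Gini-impurity splits, grown
  recursively and pruned by minimal cost-complexity (weakest-link) pruning
  with the subtree selected by stratified 10-fold cross-validation.

Every model is evaluated against the surveillance label with sensitivity,
specificity, PPV, NPV and accuracy, reported in the conventional
"percent (numerator/denominator)" style.

The real two-hospital claims/surveillance data (1,017 and 845 CABG
surgeries; 24 and 17 SSIs) are not public, so the package ships a seeded
synthetic cohort generator whose class-conditional distributions match the
published characteristics of the training hospital (see
`docs/methods.md`). All model machinery runs identically on real cohort
CSVs with the documented schema.

## Worked example

```python
from ssi_ident.pipeline import ExperimentConfig, run_experiment
from ssi_ident.evaluation import format_report_text

result = run_experiment(ExperimentConfig(seed=3))
print(format_report_text(result.tables))
```

```
== Training cohort ==
                  Model     Sensitivity       Specificity             PPV               NPV           Accuracy
   ICD-9-CM-based model  59.09% (13/22)  96.58% (961/995)  27.66% (13/47)  99.07% (961/970)  95.77% (974/1017)
       Model 1 (strict)    0.00% (0/22) 100.00% (995/995)               — 97.84% (995/1017)  97.84% (995/1017)
     Model 2 (moderate)  72.73% (16/22)  97.79% (973/995)  42.11% (16/38)  99.39% (973/979)  97.25% (989/1017)
        Model 3 (loose) 100.00% (22/22)  41.71% (415/995)  3.65% (22/602) 100.00% (415/415)  42.97% (437/1017)
     Model 4 (logistic)  86.36% (19/22)  91.06% (906/995) 17.59% (19/108)  99.67% (906/909)  90.95% (925/1017)
Model 5 (decision tree)  68.18% (15/22)  99.60% (991/995)  78.95% (15/19)  99.30% (991/998) 98.92% (1006/1017)
```

Reading the table: of this simulated training cohort's 22 surveillance
SSIs, the loose rule catches all 22 but flags 602 patients (PPV 3.65%),
the strict rule flags nobody (PPV undefined, printed "—"), and the decision
tree trades a little sensitivity for by far the best PPV — the qualitative
pattern that motivates the tree model. The fitted tree itself is small and
readable:

```python
print(result.tree.to_text())
```

```
node 0: n=1017 [non-SSI=995, SSI=22] p(SSI)=0.022 -> non-SSI
  los <= 45.985: node 1: n=1005 [non-SSI=994, SSI=11] p(SSI)=0.011 -> non-SSI
    antibiotic_types <= 5.5: node 2: n=998 [non-SSI=991, SSI=7] p(SSI)=0.007 -> non-SSI
    antibiotic_types > 5.5: node 9: n=7 [non-SSI=3, SSI=4] p(SSI)=0.571 -> SSI
  los > 45.985: node 10: n=12 [non-SSI=1, SSI=11] p(SSI)=0.917 -> SSI
```

A stay beyond ~46 days, or six-plus distinct antibiotics, marks an episode
as a likely SSI. The same run also reports the verification cohort (fitted
models are applied to it untouched), the logistic model's selected
variables, Youden cutoff and AUC
(`result.logistic_model`), and everything is reproducible from the seed.

The same workflow is available from the shell:

```sh
ssi-ident simulate --center A --seed 3 --out cohort_a.csv
ssi-ident classify --model moderate --in cohort_a.csv --out preds.csv
ssi-ident evaluate --pred preds.csv --truth cohort_a.csv --out report.json
ssi-ident run --seed 3 --out experiment/
```

## Cohort CSV schema

One row per CABG hospitalization: `patient_id, age, sex, los,
vessels_obstructed, antibiotic_types, antibiotic_ddd_total, cefazolin_ddd,
atc_codes_used, index_secondary_dx, postdischarge_dx, ssi_label`, with the
three list-valued columns semicolon-separated. Doses are in WHO defined
daily doses (DDD); all fields are episode totals without time stamps.
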