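# cltriage

Cervical-length surveillance triage for pregnancies after excisional
cervical treatment (cone biopsy / LLETZ / LEEP).

Women treated for cervical intra-epithelial neoplasia carry an elevated
risk of preterm birth and are followed in preterm-surveillance clinics
with serial transvaginal cervical-length (CL) measurements at three
second-trimester windows — A: 13+0–15+6, B: 16+0–18+6 and C: 20+0–22+6
weeks — with ultrasound-indicated cerclage offered when CL < 25 mm
before 24 weeks.  Most of these pregnancies deliver at term, so much of
the scanning workload is spent on women who never needed it.  This
package implements the analysis toolkit for that setting, for
clinician-researchers and biostatisticians who want to study or re-derive
sequential triage rules:

* **Cohort model** — typed pregnancy records with `W+D` gestational-age
  arithmetic, eligibility filtering, outcome strata (Group 1 = term birth
  without cerclage; Group 2 = preterm birth <37+0 and/or cerclage), the
  interval shortening statistic %ΔCL = 100·(CL_early − CL_late)/CL_early,
  and a fixed-header CSV interchange format.
* **Synthetic cohorts** — a seeded generator that emulates the subgroup
  structure of a three-site surveillance cohort (581/46/24/74 women in the
  four outcome subgroups), drawing CL at A from truncated normals and
  inducing longitudinal dependence through per-interval shortening
  fractions, with per-visit missingness and post-cerclage censoring.
* **Triage model** — the 3-step sequential rule set that labels each visit
  HIGH_RISK / DISCHARGE / CONTINUE, exposed both as plain functions and as
  a scikit-learn-style estimator (`TriageClassifier`), plus a constrained
  derivation procedure (grid search for steps A and B, a deterministic
  Gini decision tree for step C) that caps the false-low-risk rate among
  discharge calls at 5%, validated leave-one-hospital-out.
* **Screening accuracy** — Se/Sp/PPV/NPV/LR⁺ threshold sweeps over CL and
  %ΔCL, and ROC construction with trapezoid AUC.
* **Cohort statistics** — risk ratios with the Katz log-normal interval,
  a two-sided Fisher exact test, Mann-Whitney U (exact for small samples,
  tie-corrected normal otherwise) and Kruskal-Wallis.
* **Scan accounting** — scans used and avoided under a triage policy.

## Worked example

```python
import cltriage as ct

# a reproducible synthetic surveillance cohort of 725 pregnancies
records = ct.generate_cohort(ct.SyntheticCohortConfig(seed=7))
eligible, _ = ct.apply_eligibility(records)

# apply the default 3-step triage rule set and count the scans saved
model = ct.TriageModelSpec()
outcomes = [ct.run_triage(r, model) for r in eligible]
acc = ct.scan_savings(outcomes)
print(f"exit after scan 1: {acc.n_exit_after_1} ({acc.pct_exit_after_1:.1f}%)")
print(f"exit after scan 2: {acc.n_exit_after_2} ({acc.pct_exit_after_2:.1f}%)")
print(f"follow-up scans avoided: {acc.scans_avoided}/{acc.scheduled_followups}")
```

prints

```
exit after scan 1: 29 (4.0%)
exit after scan 2: 365 (50.3%)
follow-up scans avoided: 423/1450
```

— of the 725 women, 29 leave surveillance after a single reassuring scan
and another 365 after two, so 423 of the 1450 scheduled follow-up scans
are never needed.  The suture-material comparison runs on any cohort's
cerclage recipients; on printed counts it reproduces the published
contingency statistics directly:

```python
# preterm births: 9/60 monofilament vs 15/38 braided cerclages
p = ct.fisher_exact_two_sided(ct.TwoByTwo(9, 51, 15, 23))       # 0.0082
rr = ct.relative_risk(ct.TwoByTwo(23, 15, 51, 9))               # term direction
print(f"p = {p:.4f}; RR = {rr.rr:.2f} (95% CI {rr.ci_low:.2f}-{rr.ci_high:.2f})")
# p = 0.0082; RR = 0.71 (95% CI 0.54-0.94)
```

(The synthetic generator assigns suture material at random, so a suture
comparison *within a simulated cohort* is null by construction.)

A command-line interface mirrors the library:

```bash
cltriage simulate --seed 7 --out cohort.csv
cltriage triage   --cohort cohort.csv --out outcomes.csv
cltriage derive   --cohort cohort.csv --out model.yaml --report folds.json
cltriage sweep    --cohort cohort.csv --out sweep.csv --formatted
cltriage report   --simulate --seed 7 --out results/
```

Model YAML files carry the `TriageModelSpec` fields
(`a_high_lt`, `a_low_ge`, `b_high_cl_lt`, `b_high_delta_ge`,
`b_low_cl_ge`, `b_low_delta_lt`, the three step-C rules, plus the
`b_low_rule` and `c_rule1_delta_interval` variant switches); omitting
`--model` uses the published default thresholds.

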