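# pgxcohort

Pharmacogenomics-guided cohort analysis for mental-health pharmacotherapy
studies: translate a 54-gene / 104-variant test panel into CYP2D6 and
CYP2C19 metabolizer phenotypes, compute a composite **genetic mutation
score** (0–15) and a questionnaire-based **treatment effectiveness
score** (1–10, higher = worse), and link the two with the nonparametric
statistics used in pre/post cohort studies — all runnable end to end on
calibrated synthetic cohorts, so the full pipeline is testable without
patient-level data.

## Who this is for

Analysts reproducing or extending panel-based pharmacogenomic (PGx)
cohort analyses: the kind of study where workers on mental-health-related
disability are genotyped on a fixed rsID panel, prescriptions are
adjusted from the PGx profile, and medication effectiveness is compared
between baseline and a 3-month follow-up.

## The model

**Phenotyping.** Panel genotypes at CYP2D6/CYP2C19 sites are matched to
star alleles via an editable translation table (single-site definitions
restricted to the panel's rsIDs, e.g. CYP2C19\*2 = rs4244285, CYP2D6\*4 =
rs3892097). Each allele carries an activity value; the diplotype
activity score *AS* (sum of the two allele activities, scaled by
copy-number/2 for CYP2D6) maps to the metabolizer spectrum:

| phenotype    | activity score        |
|--------------|-----------------------|
| poor         | *AS* = 0              |
| intermediate | 0 < *AS* < 1.25       |
| normal       | 1.25 ≤ *AS* ≤ 2.25    |
| ultrarapid   | *AS* > 2.25           |

**Genetic mutation score.** Per gene (CYP2D6, CYP2C19): 5 points for an
extreme phenotype (poor or ultrarapid), 2 for intermediate, 0 for
normal; plus 1 point per variant pharmacodynamic site (receptor,
transporter and other PD genes), capped at 5. Range 0–15.

**Treatment effectiveness score.** Mood toward regular work tasks
(1 = "I feel good", 2–3 = "I force myself to do work", 4–5 = "I am
unable to work") plus the number of distinct reported medication side
effects capped at 5. Range 1–10; lower is better.

**Statistics.** Baseline vs follow-up by the paired Wilcoxon
signed-rank test (zero differences dropped, tie-corrected normal
approximation, no continuity correction) with effect size
r = |Z|/√N, N = total observations; genetic ↔ effectiveness association
by Spearman's ρ; discrimination of "high effectiveness score"
(≥ 8 by default) by a bootstrap-smoothed ROC curve (class-stratified
resamples, empirical curves averaged on a fixed 101-point FPR grid).

**Synthetic cohorts.** A seeded generator draws demographics,
metabolizer phenotypes and PD variant counts from calibrated marginals,
couples a latent severity to the standardized genetic score
(s = λ·z + √(1−λ²)·ε), and discretizes severity into valid mood and
side-effect components. Defaults are calibrated so an 84-patient cohort
reproduces baseline 8.39 (SD 1.22), follow-up 2.30 (SD 1.01) and
Spearman ≈ 0.28 in expectation. A genotype mode instead draws per-site
genotypes under Hardy–Weinberg equilibrium and routes them through the
real phenotyping stack.

## Worked example

```sh
pgxcohort simulate --seed 7 --out cohort/
pgxcohort analyze --in cohort/ --out report/
pgxcohort report --in report/report.json
```

prints (seed 7):

```
Patients analyzed: 84 (of 84; 0 excluded)

Full cohort (n = 84):
  age: 34.23 (9.33)
  baseline_total: 8.39 (1.17)
  followup_total: 2.33 (0.92)
  genetic_total: 7.33 (3.02)

Follow-up subset (n = 46):
  age: 35.14 (10.32)
  baseline_total: 8.39 (1.14)
  followup_total: 2.33 (0.92)
  genetic_total: 7.70 (3.07)

Wilcoxon signed-rank: W = 0.0, Z = -5.94, p = 2.77e-09, r = 0.62
Spearman (full): rho = 0.030, p = 0.79 (n = 84)
Spearman (follow-up): rho = -0.048, p = 0.751 (n = 46)
Bootstrap-smoothed ROC: AUC = 0.545 (n_boot = 1000)
```

Reading the output: all 46 followed-up patients improved (every
follow-up total below its baseline), so the signed-rank statistic is
W = 0 and the effect size r = |Z|/√92 = 0.62 — a large pre/post effect.
The single-replicate Spearman ρ is noisy at n = 84 (this seed happens
to draw a near-zero value; the across-seed mean is ≈ 0.28), which is
why calibration claims are always averaged over many seeds.

The same analyses are available as library calls
(`pgxcohort.run_pipeline`, `pgxcohort.wilcoxon_paired`, …) on plain
pandas inputs.

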