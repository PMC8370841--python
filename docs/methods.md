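# Methods

## Panel and genotype ingestion

The packaged panel (`data/panel_sites.tsv`) lists 107 gene-context
rows covering 54 distinct gene symbols and 104 unique rsID-named sites
plus the 5-HTTLPR length polymorphism. Three sources of irregularity in
the printed panel are preserved rather than silently repaired:

* rs2952768 is annotated under three gene contexts (OPRM1, UGT2B15, and
  one row with no gene label). It is stored once per gene context but
  treated as a single physical site everywhere a site is counted.
* The row with the empty gene cell is carried under the placeholder
  gene label `UNASSIGNED_ROW8` (category other-PD) so the panel is
  complete without inventing a gene assignment.
* 5-HTTLPR has no rsID; it is carried as the pseudo-site
  `SLC6A4_5HTTLPR` with alleles L/S. Only the tabular reader accepts it
  (VCF cannot represent it).

Reference/alternate alleles per site are fixed in the packaged
annotation — real dbSNP orientations where well established, otherwise
the package's own assignment. Zygosity classification depends only on
consistency with this annotation, never on external coordinates; the
whole artifact is rsID-keyed and coordinate-free.

Gene categories: the nine CYP/UGT genes are pharmacokinetic enzymes;
sixteen receptor genes and four transporter genes follow the standard
pharmacology of psychotropics; F5, VKORC1, APOE and HLA-B are carried
as non-scored safety/coagulation markers (they are not psychotropic
pharmacodynamics); every other gene is "other PD". The PD variant tally
counts receptor + transporter + other-PD sites only; variants in
non-CYP2D6/CYP2C19 PK enzymes (CYP2C9, CYP2B6, …) are deliberately
excluded from both the phenotype score and the PD tally, because the
published scoring rule bases the PK component on CYP2D6 and CYP2C19
alone and does not state how other PK genes enter; the category switch
is in one place (`PD_CATEGORIES`) if a user reads the rule otherwise.

## Star-allele translation and phenotyping

The vendor's interpretation software is proprietary, so the translation
table is packaged, explicit and replaceable (`allele_definitions.tsv`,
or a user file via `load_translation_table`). It holds single-site
definitions of the publicly documented star alleles representable on
this panel: CYP2C19 \*2–\*8 (no function) and \*17 (increased function);
CYP2D6 \*3, \*4, \*6, \*7, \*8, \*11, \*12 (no function), \*9, \*10,
\*17, \*29, \*41 (decreased function), \*2 (normal function). Panel
sites without a confident public allele assignment (e.g. CYP2D6
rs28371735, rs72549357) remain panel sites but are not allele-defining.

Diplotype calling is greedy over unphased genotypes: alleles sorted by
(more defining sites, then lower star number) each consume one variant
dose per defining site, at most two allele copies total; unexplained
slots default to \*1 (activity 1.0). Two heterozygous no-function sites
are therefore assigned in trans — the conservative clinical reading
that maximizes detected non-functionality. A test verifies the greedy
caller against exhaustive enumeration over all genotype combinations at
three defining sites.

Activity values: no function 0, decreased 0.5 (CYP2D6 \*10: 0.25),
normal 1.0, CYP2C19 \*17: 1.25. Phenotype cutoffs follow the activity-
score convention — poor at 0, intermediate below 1.25, normal up to
2.25, ultrarapid above — so \*1/\*17 (2.25) stays normal while
\*17/\*17 (2.5) is ultrarapid; \*17 homozygosity also triggers
ultrarapid explicitly. CYP2D6 activity is scaled by copy-number/2; the
copy number is an explicit input defaulting to 2 because a SNP panel
cannot see duplications, which makes CYP2D6 ultrarapid unreachable
without declared copy number — a logged limitation, not an error.
Genes entirely no-call yield an indeterminate phenotype, which scores 0
points and is treated as normal in profile typing (with a warning):
missing data must never inflate a risk score.

## Scores

Genetic mutation score: 5 per extreme (poor/ultrarapid) gene, 2 per
intermediate, 0 per normal, plus min(PD variant count, 5). The
attainable range 0–15 and the per-gene 5/2/0 map are asserted by
enumeration in the tests.

Treatment effectiveness score: mood points (1–5) plus side-effect
points (0–5). The printed anchor of the scale is "0 (Good)"; because
mood is asked on 1–5, the attainable minimum is 1 and the package
treats 0 as an anchor label, not a value. Side-effect points are the
count of distinct (case-insensitive) reported side effects capped at 5
— the simplest reproducible reading of "a maximum score of 5"; the rule
is isolated in `side_effect_points` so a severity-weighted variant can
be swapped in. The mood bands 2–3 and 4–5 require an explicit low/high
sublevel in the questionnaire, since nothing in the instrument
disambiguates a single integer otherwise.

## Statistics

* **Wilcoxon signed-rank** (pre vs post): zero differences dropped
  before ranking; W = min(rank sums); tie-corrected normal
  approximation without continuity correction; an exact-permutation
  mode for small n (tested against full 2ⁿ sign enumeration).
* **Effect size** r = |Z|/√N with N = total observations (2 × pairs) by
  default. Under the degenerate-improvement pattern (all 46 pairs
  improving, no ties) this gives r = 540.5/√8377.75/√92 ≈ 0.62, whereas
  the per-pairs convention gives ≈ 0.87; both conventions circulate in
  the applied literature, so the choice is a config switch. Effect
  sizes are labelled with the 0.1/0.3/0.5 (small/medium/large) bands.
* **Spearman** via mid-ranks (average ranks for ties) and the
  t-approximation with n−2 df; verified against a rank-then-Pearson
  oracle under ties.
* **Bootstrap-smoothed ROC**: class-stratified resamples; each
  resample's empirical ROC step function is sampled on a fixed
  101-point FPR grid and averaged; AUC is the trapezoidal area of the
  averaged, monotone-cleaned curve. n_boot defaults to 1000 with a
  fixed default seed; identical seeds give bit-identical results. The
  empirical AUC (= Mann–Whitney U/(n₁n₀), tested by brute-force pair
  counting) is reported alongside.
* **Dichotomization** of "high effectiveness" defaults to total ≥ 8 —
  an artifact decision anchored at the baseline mean, configurable,
  since no published cutoff exists.
* Descriptive summaries use SD with the n−1 denominator and percentages
  over the full column denominator (so categories with unreported
  values do not sum to 100%).

## Synthetic cohort generator

The generator emulates the published cohort facts, since patient-level
data are not deposited: n = 84 with 46 followed up; age 35.5 (SD 10.6);
sex 45 F / 38 M / 1 unreported; ethnicity 58 Caucasian / 5 Asian /
3 other / 18 unreported; per-gene metabolizer marginals (normal 0.39,
intermediate 0.35, ultrarapid 0.19, poor 0.07 for each of CYP2D6 and
CYP2C19); PD variant count ~ Poisson(4.5).

The published phenotype prevalences are *overlapping* ("of one or both
genes": 14% PM + 37% UM + 62% IM over the 71 mutated patients sums past
100%) and the profile-type counts are internally inconsistent (64 + 2 +
27 > 84; the 20.2% printed beside the count 27 is not 27/84). These
figures therefore over-determine any per-gene marginal: the defaults
match the mutated fraction (1 − 0.39² ≈ 71/84) exactly and the
overlapping figures approximately, and no test asserts the inconsistent
aggregates. Similarly, the published abstract and demographics table
disagree on the follow-up subset's sex split and mean age; the
generator calibrates to the demographics table. Follow-up selection is
uniform by default; a `followup_male_bias` knob can reproduce the sex
shift between columns.

Severity synthesis: s = λ·z + √(1−λ²)·ε with z the genetic total
standardized by its theoretical moments under the config; the latent
total 8.42 + 1.22·s is split proportionally into mood and side-effect
components, rounded and clipped — so component validity holds by
construction and the effectiveness total is always in [1, 10].
Follow-up severity is drawn from an independent latent (2.29 + 0.92·u)
and resampled per patient until strictly below the baseline total
(the improvement-guarantee flag; infeasible configs are rejected, and
the guarantee falls back to baseline − 1 in the measure-zero case where
sampling cannot achieve it). The four latent constants and λ = 0.311
were calibrated once by large-n simulation so the *realized*
(post-discretization) cohort statistics match the anchors — baseline
8.39 (1.22), follow-up 2.30 (1.01), Spearman 0.281 — and then frozen as
defaults.

What the generator does **not** emulate: medication identities and
prescription-change types, dropout mechanisms, within-patient
correlation of side-effect labels over time, and any real genotype
linkage structure (genotype mode samples sites independently under
Hardy–Weinberg at configured allele frequencies). Passing calibration
tests therefore show that the pipeline recovers the statistics of a
cohort *constructed* to have them — a self-consistency check of the
implementation, not a reproduction of the original patients.

## Numerical and reproducibility choices

All randomness flows from explicit integer seeds through
`numpy.random.SeedSequence`; sub-streams (genotype mode, questionnaire
label realization) derive deterministically from the master seed.
Report files contain a config hash and component versions but no
wall-clock timestamps, so identical config + seed reruns are
byte-identical. Numbers are rounded only at render time (two decimals
for scores and statistics, one for percentages); internal values keep
full precision. Problem sizes in the test suite (5000-patient
calibration draws, 200-replicate averages, 2000-point Hardy–Weinberg
checks, n_boot up to 1000) were chosen as the smallest sizes at which
the asserted tolerances are comfortably stable.

## Known limitations

* CYP2D6 structural variation is input, not inferred; without declared
  copy number the ultrarapid class is unreachable for CYP2D6.
* The translation table covers single-site allele definitions only; it
  cannot distinguish alleles that share a defining SNP plus additional
  sites absent from the panel (e.g. CYP2D6 \*4 vs \*10 share
  rs1065852; priority ordering resolves the call in favour of the
  more specific/lower-numbered allele).
* The ROC's published AUC depends on an unstated dichotomization
  threshold and cohort choice, so it is exposed as configuration and
  not asserted.
* Scores are ordinal; the generator's latent-Gaussian severity is a
  modelling convenience, not a claim about questionnaire psychometrics.
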