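# Methods

## The analysis model

The pipeline operates on paired diagnosis/relapse expression cohorts of
relapsing pediatric ALL patients: every patient contributes one sample at
diagnosis and one at relapse, with the time between them (disease-free
survival, months) known. Expression values are linear-scale, non-negative
summarized intensities (e.g. PLIER output for U133 Plus 2.0 arrays); the
pipeline does not perform array preprocessing and treats the matrix as
given. Probe-level matrices are collapsed to genes by the arithmetic mean
of a gene's probes on the linear scale — no log transform is applied
anywhere by default (a `log2_transform` flag exists for exploration only,
since ratio-based scores and directional calls are scale-free).

The scientific object is the 20-gene canonical NER panel. Analyses treat
the pathway as the unit of inference: the per-gene tests are descriptive,
the pathway-level chi-square on the up/down split is the aggregate test,
and the NER score reduces the panel to one number per sample.

### Directional pathway chi-square

For k of n genes up, `chi2 = (2k − n)²/n` against chi-square with 1 df,
upper tail, no Yates correction. The uncorrected statistic is used
deliberately: with n = 20 it gives p = .0253 for a 15/5 split, .0073 for
16/4 (and, by symmetry, 4/16), .371 for 12/8, .180 for 13/7-type splits,
and 1.0 for 10/10 — the reference grid for this kind of panel analysis.
The statistic is symmetric in k ↔ n−k; "significant upregulation" is read
as k > n/2 together with p < .05.

### Per-gene tests

One-tailed Student's t with the alternative "group a mean exceeds group b
mean"; callers order the groups to express the hypothesis (relapse over
diagnosis, early over late). Paired comparisons match samples by patient
id and use the mean/SD of within-pair differences (df = n−1); unpaired
comparisons use the pooled-variance form (df = n_a+n_b−2), with Welch's
correction available behind a flag but off by default. No multiple-testing
correction is applied across the 20 genes — the pathway chi-square is the
aggregate inference and per-gene p-values are reported raw.

A zero-variance configuration (all differences identical, or both groups
constant) leaves t undefined; the library signals this explicitly and
aggregate callers record p = 1 with a warning — conservative for the
upregulation alternative.

### The NER score

Within each dataset, each panel gene is divided by its mean over all
relapse-phase samples of that dataset, and the 20 relative values are
averaged per sample. Normalization is **per gene** (each gene relative to
its own relapse mean, then averaged) rather than pooled (average raw genes
first, then divide): both force the relapse-cohort mean to 1, but the
per-gene form prevents the brightest genes from dominating the composite.
Scores are invariant to global rescaling of the matrix and to sample
order, and the relapse-phase mean equals 1 to float precision (asserted at
1e-12 in the test suite).

Group summaries report mean ± SEM (sd/√n); the "±" of a cohort summary
table is interpreted as SEM, consistent with its magnitude at these group
sizes. Summary-table t-tests are two-sided by default (the table compares
means without a stated direction); the per-gene analyses stay one-tailed.

### Relapse-timing classes and cohort combination

Early relapser: time to relapse < 36 months; late: ≥ 36 months; the
boundary value is late. To combine cohorts measured on different intensity
scales, each gene is divided, within each dataset, by its mean over that
dataset's reference samples, after which the per-gene reference mean is
exactly 1 and values are unit-free. The reference group follows the
comparison: the diagnosis samples of the compared class for paired
diagnosis-vs-relapse analyses, the late relapsers of the compared phase
for early-vs-late analyses. Both are overridable.

### Score skew

Each patient pair is labelled an increase or decrease in NER score from
diagnosis to relapse and the split is tested against 50/50 with the same
1-df chi-square. Exact ties count as decreases (see numerical choices).

### Survival

Diagnosis-phase scores are pooled and patients above the mean form the
high stratum (tie → low; an `above_value` rule, e.g. threshold 1.0 = the
relapse average, is available). Disease-free survival is summarized with
the Kaplan–Meier product-limit estimator; the median is the smallest event
time t with S(t) ≤ 0.5. The log-rank test accumulates, at each distinct
event time with d events and (n, n_a) at risk, E_a += d·n_a/n and the
hypergeometric variance d·(n_a/n)(1−n_a/n)(n−d)/(n−1) (ties across strata
use this multi-event form), giving chi2 = (O_a−E_a)²/V. The hazard ratio
is the O/E estimator HR = (O_a/E_a)/(O_b/E_b) with
CI95 = exp(ln HR ± 1.96·√(1/E_a+1/E_b)) — the "log-rank HR" of consumer
survival software, chosen over Cox regression to match how such cohorts
are usually reported; Cox modelling is out of scope. In fully-relapsing
cohorts every time is an event; censoring is nevertheless supported
throughout because simulated or external cohorts may include it.

## The synthetic cohort generator

`SyntheticConfig`/`generate_cohort` realize the two-trajectory model the
analysis is designed to detect:

| parameter | default | meaning |
|---|---|---|
| `n_early`, `n_late` | (19, 27), (8, 22) | patients per class per dataset — the combined-cohort class sizes (46 early / 30 late) split as in the two-cohort study design; an int total is split near-evenly |
| `n_genes`, `n_decoy_genes` | 20, 100 | panel size (canonical NER symbols at 20) and baseline-only background genes |
| `probes_per_gene` | None → 51 probes | default allocation 11×3 + 9×2 over the panel; decoys get one probe; per-probe affinities log-uniform on [0.5, 2] so probe collapsing is a real averaging step |
| `baseline_range` | (50, 500) | per-gene baseline, log-uniform — the mid-intensity range of linear-scale summarized arrays where the multiplicative error model holds |
| `delta_early` | 1.2 | panel elevation of early relapsers, both phases (flat trajectory) |
| `delta_late_relapse` | 1.2 | panel rise of late relapsers at relapse; equal to `delta_early` makes the classes converge at relapse |
| `noise_cv` | 0.15 | CV of mean-1 multiplicative log-normal noise per cell |
| `early_window`, `late_window` | (6, 36), (36, 72) | uniform time-to-relapse windows; uniform keeps the 36-month boundary sharp |
| `dataset_scales` | (1, 3) | global intensity scale per cohort, exercising reference normalization |

The generator emulates: paired samples, two relapse classes with the
flat/rising trajectories and convergence at relapse, probe-level structure,
inter-cohort scale differences, and (optionally, at `noise_cv = 0`)
exactly closed-form outputs for every downstream stage. It does **not**
emulate: between-patient biological variability beyond cell-level noise
(real patient SEMs are larger than measurement noise alone), gene–gene
correlation, non-relapsing patients, realistic probe sequences, batch or
platform artifacts, or missing values. Passing tests therefore demonstrate
that the machinery recovers the planted structure under the stated noise
model — not that real cohorts will show effects of this size.

`generate_survival_only` draws fully-evented exponential times (default
base hazard 0.03/month, median ≈ 23 months — the scale of relapse cohorts)
for direct tests of the O/E estimator. The median O/E estimate at a true
twofold hazard and n = 40 per stratum sits near 1.86 — the known mild
shrinkage of the O/E form toward the null — which the regime check's
(1.7, 2.3) band accommodates.

## Numerical choices

- **Direction ties.** A gene whose group means differ by ≤ 1e-12
  relatively is a tie and counts as "down" (conservative against the
  upregulation alternative). The tolerance exists because groups of
  different sizes accumulate different summation roundoff; with continuous
  data ties are measure-zero, and every tie is logged.
- **Relapse-class boundary.** Exactly 36 months → late.
- **Stratification tie.** Score exactly at the threshold → low.
- **KM median on the boundary.** If S lands exactly on 0.5 the median is
  that event time (smallest t with S(t) ≤ 0.5, within 1e-12).
- **Degenerate inputs.** Hard, named errors: duplicate ids, negative or
  missing intensities, broken diagnosis/relapse pairing, zero reference or
  relapse means, all-identical stratification scores, eventless strata. A
  failed pipeline run removes its partial outputs.
- **Determinism.** All simulation flows from one integer seed
  (`numpy.random.default_rng`); report bundles are byte-identical across
  re-runs, so the run manifest carries a config hash and package version
  but deliberately no wall-clock timestamp.

## Problem sizes

The test suite and `scripts/acceptance.py` use: 100 simulated studies at
the default conditions for the pattern-rate check; 50 single-cohort
simulations (30 + 30 patients, `noise_cv` 0.1) for elevation recovery; 200
survival simulations at n = 40 per stratum for the HR regime; exhaustive
Fisher enumeration to margins of 10–12 plus random sampling to margins of
25; and exhaustive permutation checks of the KM median rule to n = 8.
Together they run in well under a minute on one CPU.

## Applying the pipeline to GEO series matrices

The two public cohorts this design targets are GSE18497 and GSE28460
(U133 Plus 2.0, matched diagnosis/relapse pediatric ALL). The pipeline
does not download data; the manual recipe is:

1. Fetch each series matrix (`GSEnnnnn_series_matrix.txt`) from GEO and
   read it with `read_expression_table(path, dialect="geo_series_matrix")`.
   Values must be linear-scale and non-negative — if the deposit is
   log-transformed, unlog it first.
2. Build the annotation TSV (`sample_id`, `patient_id`, `phase`,
   `immunophenotype`, `time_to_relapse_months`, `dataset_label`) from the
   series' characteristics fields, and a probe map (`probe_id`,
   `gene_symbol`) restricted to the panel's probe sets from the platform
   annotation.
3. Run `ner-relapse run --config analysis.yaml` on the combined files.

Exact numeric agreement with published figures from these accessions is
not guaranteed: the upstream summarization (PLIER variant, GeneSpring
settings) and the exact 51-probe list are not fully specified, so
reproduced hazard ratios should be judged against the published confidence
intervals rather than point values.

## Known limitations

- The unpaired test assumes equal variances by default; Welch is opt-in.
- The 20th panel gene is taken as ERCC4 (XPF, the core 5' incision
  nuclease) alongside the 19 symbols that are standard in figure-level
  panel listings; the panel is fully overridable in config.
- The pathway test treats genes as exchangeable Bernoulli trials; correlated
  genes (co-regulated complexes such as TFIIH or RPA) make its null
  anti-conservative. It is reported as the field reports it.
- Stratification uses the pooled diagnosis mean; per-dataset thresholds
  give near-identical splits on balanced cohorts but are not exposed.
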