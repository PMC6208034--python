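# ner-relapse

Pathway-level expression analysis of paired diagnosis/relapse cohorts in
pediatric acute lymphoblastic leukemia (ALL), centered on the nucleotide
excision repair (NER) pathway. The package asks whether the 20 canonical
NER genes move as a block between disease phases and relapse-timing
subgroups, collapses the panel to a per-sample **NER score**, and tests
whether that score at diagnosis predicts disease-free survival.

It is written for analysts working with matched diagnosis/relapse
expression cohorts (e.g. GEO series on the Affymetrix U133 Plus 2.0
platform, summarized to linear-scale intensities): it consumes a
probe-or-gene-level matrix plus a sample annotation, and ships a synthetic
cohort generator so the entire pipeline runs and is tested without any
download.

## The statistics

**Directional pathway test.** For a comparison of two sample groups, each
panel gene is called *up* if mean(group a) − mean(group b) > 0. Under a
no-change null the expected split over n = 20 genes is 10/10, and the
observed count k of upregulated genes is tested with the 1-df goodness-of-fit
statistic (no continuity correction):

    chi2 = (k − n/2)²/(n/2) + ((n−k) − n/2)²/(n/2) = (2k − n)²/n

Per-gene inference is a one-tailed Student's t-test (paired within patients
for diagnosis-vs-relapse, pooled-variance unpaired for early-vs-late
subgroups); up/down proportions of two cohorts are compared with Fisher's
exact test.

**NER score.** Within each dataset, with r_g the mean of gene g over all
relapse-phase samples,

    score(s) = (1/20) Σ_g x_gs / r_g

so the mean score of the relapse cohort is 1 by construction and a
diagnosis score reads as a fraction of relapse-level pathway expression.
Patients are classed as **early** (< 36 months to relapse) or **late**
(≥ 36 months) relapsers.

**Survival.** Patients above the pooled mean diagnosis score form the
*high* stratum, the rest *low*; disease-free survival is compared with the
Kaplan–Meier estimator and the log-rank test, and the hazard ratio uses the
O/E form HR = (O_h/E_h)/(O_l/E_l) with
CI95 = exp(ln HR ± 1.96·√(1/E_h + 1/E_l)).

## Worked example

```sh
python analysis/01_simulate_cohorts.py        # two cohorts, 76 patients
python analysis/02_pathway_directions.py
python analysis/03_ner_scores.py
python analysis/04_survival_stratification.py
```

The simulated study encodes a two-trajectory model: early relapsers carry
elevated panel expression at diagnosis and stay flat; late relapsers start
low and rise by relapse; both classes converge at relapse. The drivers
print, for seed 1:

```
combined  early_diagnosis_vs_relapse   n_up= 9/20 chi2= 0.20 p=0.655
combined  late_diagnosis_vs_relapse    n_up=20/20 chi2=20.00 p=7.74e-06
combined  early_vs_late_at_diagnosis   n_up=20/20 chi2=20.00 p=7.74e-06
combined  early_vs_late_at_relapse     n_up= 9/20 chi2= 0.20 p=0.655
...
combined  late   diagnosis 0.834+/-0.004  relapse 1.001+/-0.004  p=2.77e-24
...
combined  high n=46 median= 22.7 mo | low n=30 median= 50.1 mo | HR=4.795 (95% CI 2.837-8.104) p=1.47e-18
```

i.e. only the late relapsers gain NER expression at relapse, the early
relapsers are already elevated at diagnosis, and a high NER score at
diagnosis identifies the short-survival stratum. Tables land under
`results/`, the generated cohort under `scratch/`.

The same pipeline runs from a shell against real data:

```sh
ner-relapse run --config analysis.yaml     # expression + annotation TSVs
ner-relapse simulate --out fixture/ --seed 7
```

`docs/methods.md` documents the model, every tunable parameter, and the
recipe for applying the pipeline to downloaded GEO series matrices.

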