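# cbcprs

Polygenic-risk-score (PRS) modelling of **contralateral breast cancer (CBC)
risk in BRCA1/2 pathogenic-variant carriers** who have already had a first
breast cancer. The package is aimed at statistical geneticists and
epidemiologists who want to score a breast-cancer PRS from genotype dosages,
estimate its association with CBC under the retrospective-cohort designs
these consortia use, and translate the relative hazard into absolute,
percentile-specific risk curves that can inform decisions about
risk-reducing contralateral mastectomy.

## What it computes

* **Scoring** — `s_j = Σ_i w_i g_ij` over a variant weight panel (overall,
  ER-positive and ER-negative flavours), with effect-allele alignment,
  strand-ambiguity handling and `2p` mean imputation of missing dosages;
  scores standardized to the cohort mean and an external reference SD.
* **Cohort construction** — eligibility rules (synchronous CBC within one
  year of the first cancer excluded; unknown metastatic status retained) and
  left-truncated risk intervals: time at risk starts one year after the
  first cancer and censors at baseline, prophylactic mastectomy or death.
* **Association** — Cox models with delayed entry, country strata,
  birth-cohort-quartile adjustment and family-cluster-robust variance:
  continuous per-SD fits, percentile-band fits (40th–60th reference),
  age-at-first-cancer interaction and subgroup fits, Schoenfeld
  proportional-hazards and restricted-cubic-spline linearity diagnostics,
  stratified Harrell's C honouring left truncation, Kaplan–Meier cumulative
  risk, and chained-equation imputation with mean/Rubin pooling.
* **Absolute risk** — a constrained-incidence calculator that solves the
  baseline hazard `λ0(t)` so that incidence averaged over the standard-normal
  PRS density reproduces an external marginal schedule `λm(t)`, then emits
  cumulative-risk curves `F(t|z_p)` at chosen PRS percentiles, with an
  age-at-first-cancer interaction via `β_eff = β + γ·age`.
* **Synthetic data** — a generator with family-structured genotypes
  (Hardy–Weinberg founders, Mendelian sibships), piecewise-exponential CBC
  events with known generative `β` and `γ`, realistic censoring and
  covariate missingness, so every stage is testable against ground truth.

See `docs/methods.md` for the model details and design decisions.

## Worked example

```python
import math
from cbcprs.simulate import SimulationConfig, simulate_study
from cbcprs.eligibility import apply_eligibility, build_risk_intervals
from cbcprs.survival import fit_cox_continuous, harrell_c, km_cumulative_risk

config = SimulationConfig(n_subjects=6591, beta_true=math.log(1.12), seed=1)
study = simulate_study(config, with_genotypes=False)
eligible, exclusions = apply_eligibility(study["records_complete"])
intervals = build_risk_intervals(eligible, "all_cbc").intervals

fit = fit_cox_continuous(intervals)
c = harrell_c(intervals)
risk10, ci = km_cumulative_risk(intervals, 10.0)
```

Running this (it is `examples/03_fit_association.py`) prints:

```
eligible 6591, events 1364
HR per SD = 1.10 (95% CI 1.05-1.16), p = 0.00026   [generative truth 1.12]
Harrell's C = 0.53  (0.5 = no discrimination)
10-year cumulative risk = 24.1% (95% CI 22.7%-25.5%)
```

The fitted hazard ratio per SD recovers the generative value within
Monte-Carlo error, the concordance shows the modest discrimination expected
of a per-SD hazard ratio near 1.1, and the Kaplan–Meier estimate reflects
the high absolute CBC risk of this population. The other scripts in
`examples/` walk through scoring (`02`), percentile-band versus continuous
consistency (`04`), ER-status imputation with pooling (`05`) and absolute
risk curves by PRS percentile and age at first cancer (`06`).

## Command line

A thin CLI wraps the same functions:

```bash
cbcprs simulate --n-subjects 3000 --seed 7 --out study/
cbcprs score --weights study/weights.tsv --genotypes study/dosages.csv \
             --flavor er_negative --sd 1.0 --out prs.csv
cbcprs intervals --phenotypes study/phenotypes.csv --prs prs.csv --out intervals.csv
cbcprs associate --intervals intervals.csv --model continuous --model diagnostics --out results.json
cbcprs riskcurves --schedule incidence.csv --beta 0.113 --gamma -0.01 --out curves/
```

The external marginal incidence schedule (`age_group,t,rate` CSV) is a
user-supplied input; it is consumed, never derived, by this package.

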