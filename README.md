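# microsurv

Tumor-microbiome survival analysis for two-cohort studies, built as a
tested pipeline and exercised end to end on synthetic data with known
ground truth.

The scientific question it addresses: in resected early-stage pancreatic
ductal adenocarcinoma (PDAC), does the abundance of individual tumor
microbial species predict overall survival (OS) and relapse-free survival
(RFS), and can the associated species be summarized into a single
prognostic **Microbial Risk Score (MRS)**? The intended users are
biostatisticians and computational microbiome researchers who want the
full method — not just a per-feature scan — as reusable, tested code.

## The method

For species *t* with clr-normalized abundance
`clr_{s,t} = log(x_{s,t}+1) − mean_j log(x_{s,j}+1)`:

1. **Per-cohort Cox models.** `h_s(τ) = h_0(τ) exp(β·clr_{s,t} + γ'z_s)`
   per cohort, adjusted for age, sex, tumor stage (I/IIA vs IIB) and
   smoking; Efron tie handling.
2. **Random-effects meta-analysis.** Cohort log hazard ratios pooled by
   DerSimonian–Laird, with Cochran's Q heterogeneity (`P-het`) and a
   pooled p-value `P-meta`.
3. **Stability selection.** The scan repeats on 100 random 90%
   within-cohort subsamples; `O_j` is the fraction of iterations with
   `P-meta < 0.05`, and species with `O_j ≥ 0.60` are selected.
4. **Permutation calibration.** Outcomes are shuffled within cohort and
   the whole frequency computation re-run *n* times:
   `p_perm,j = (Σ_i 1[P_ij ≥ O_j] + 1)/(n+1)`, with BH q-values across
   species.
5. **Microbial Risk Score.** `MRS_s = Σ_k β_pooled,k · clr_{s,k}` over
   the selected species, z-scored over the combined cohorts; assessed by
   pooled Cox models (HR per SD), a median split with Kaplan–Meier curves
   and the log-rank test, and strata re-runs.
6. **Immune links.** Logistic models of median-binarized immune-cell
   fractions (22 CIBERSORT-style columns) on the MRS, Spearman
   correlations of species vs immune cells and genes, and hypergeometric
   over-representation of microbiome-correlated genes in GMT gene sets.

Alpha diversity (Chao1, Shannon, Simpson), Jensen–Shannon beta diversity
with a covariate-adjusted PERMANOVA, and rarefaction curves round out the
descriptive layer. A synthetic-data module generates two linked cohorts
(compositional counts with batch shifts, proportional-hazards OS/RFS with
calibrated censoring, linked immune fractions) with full ground truth, so
every stage can be validated against known effects. See
[docs/methods.md](docs/methods.md) for models, defaults and limitations.

## Worked example

The `analysis/` directory is a numbered, narrated walk through the whole
study on a simulated dataset (two cohorts of 140 and 63 samples, 400
species, 10 causal species at log-HR ±0.5 per clr unit):

```sh
python analysis/01_simulate.py              # data + ground truth
python analysis/02_preprocess.py            # filter + clr + batch centering
python analysis/03_diversity.py             # alpha/beta diversity, PERMANOVA
python analysis/04_survival_associations.py # Cox + meta + stability + permutation
python analysis/05_risk_score.py            # MRS, KM/log-rank, strata
python analysis/06_immune_links.py          # immune & gene links, ORA
```

Step 02 prints

```
retained 392 of 400 taxa
  removed by prevalence: 4
  removed by prevalence+mean_relab: 4
```

— the prevalence/abundance filter keeps 392 species, including all 10
causal ones. Step 04 then reports, for OS (seed 1, 100 subsample
iterations, 30 permutations):

```
[OS] selected 20 species (O_j >= 0.60 over 100 iterations)
  true causal recovered: 9 of 10 retained causal species
```

Nine of the ten planted species are recovered; the remaining selections
are species whose clr values are correlated with causal ones
(compositional hitchhiking — see the methods note). Step 05 summarizes
the risk score built from those species:

```
[MRS_Mortality] 20 species
  pooled HR per SD = 4.40 (95% CI 3.44-5.62, p = 3.45e-32)
  per-cohort HR: cohort1: 4.15, cohort2: 5.41
  log-rank chi2 = 97.1 (p = 6.74e-23); median survival low = nan,
  high = 4.1 months
```

— a per-SD hazard ratio around 4 in both cohorts, with the high-risk half
of patients dying a median ~4 months after diagnosis while the low-risk
half never reaches 50% mortality inside follow-up (median undefined under
this censoring, flagged as NaN). Step 06 recovers the planted
species–immune-cell links (e.g. `Species_0298 ~ T cells CD4 naive:
r = +0.70`) and finds only the planted gene set enriched among
microbiome-correlated genes. A true-null run (`n_causal=0`) selects
nothing and the MRS stage is skipped.

The same pipeline is scriptable on your own TSV inputs through the CLI
(`microsurv simulate|preprocess|diversity|associate|score|immune|run`),
configured by a YAML file; counts are taxa × samples TSV (GraPhlAn-style
lineage row ids are parsed), metadata one sample per row with
`cohort, age, sex, stage, smoking, os_time, os_event, rfs_time,
rfs_event`.

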