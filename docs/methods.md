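# Methods

`microsurv` implements a two-cohort tumor-microbiome survival analysis as a
tested, reusable pipeline, exercised end to end on synthetic data with
known ground truth. This note records the statistical model, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical choices that matter.

## The association model

Let `x_{s,t}` be the read count of species `t` in sample `s`. After
filtering (below), abundances are normalized per sample by the centered
log-ratio transform with a pseudocount `c` (default 1):

    clr_{s,t} = log(x_{s,t} + c) − mean_j log(x_{s,j} + c)

Each row sums to zero; the transform is invariant to scaling a sample's
counts (with the pseudocount scaled along), which is what makes
compositional abundances comparable across sequencing depths.

For each species and each outcome (overall survival, OS; relapse-free
survival, RFS), a Cox proportional-hazards model is fitted **within each
cohort** with the species' clr abundance as the exposure, adjusted for age
(continuous), sex, tumor stage (I/IIA vs IIB) and smoking status
(indicator-coded Never/Current/Former/Not reported; "Not reported" is kept
as an explicit level rather than dropped, configurable). The per-cohort
log hazard ratios `β_k` with standard errors `se_k` are pooled by
DerSimonian–Laird random-effects meta-analysis:

    w_k = 1/se_k²,  Q = Σ w_k (β_k − β_fixed)²,
    τ² = max(0, (Q − (K−1)) / (Σw − Σw²/Σw)),
    β_pooled = Σ β_k/(se_k²+τ²) / Σ 1/(se_k²+τ²)

with a heterogeneity p-value from `Q ~ χ²_{K−1}` and a two-sided normal
test on `β_pooled / se_pooled`. DerSimonian–Laird is the standard
moment-based default for pooling a small number of cohorts; with a single
cohort the pooled estimate equals that cohort's.

### Stability selection and permutation calibration

To damp the randomness of a single significance cut, the scan is repeated
`n_iter` times (default 100) on random `frac` = 90% subsamples drawn
without replacement **within each cohort** (so every meta-analysis has
both cohorts). A species' selection frequency `O_j` is the fraction of
iterations with pooled p < 0.05; species with `O_j ≥ 0.60` are selected.
Iterations in which any cohort fit fails to converge count the affected
species as not significant — conservative and reproducible. Subsample
membership is drawn from the id-sorted sample list, so results are
invariant to input row order under a fixed seed.

Significance of `O_j` itself is calibrated by permutation: each of
`n_perm` permutations shuffles the (time, event) pairs against the
exposure/covariate rows within each cohort — preserving the
covariate–microbiome structure while severing outcome links — and re-runs
the entire subsampling frequency computation, giving `P_ij`. Then

    p_perm,j = (Σ_i 1[P_ij ≥ O_j] + 1) / (n_perm + 1)

so the smallest attainable p is `1/(n_perm+1)` and `O_j = 0` yields
exactly 1. Benjamini–Hochberg q-values are computed across species. An
alternative scheme permuting clr rows instead of outcomes is available
(`permute="abundances"`); which to shuffle is a genuine design choice and
we default to outcomes because it leaves the covariate–outcome association
intact in the covariate-adjusted null.

### Microbial Risk Score

For each outcome, the MRS is the weighted sum of the selected species' clr
abundances with weights equal to their **pooled log hazard ratios** from
the full-data fit (effect sizes on the linear-predictor scale, the
polygenic-score convention; using full-data estimates rather than
averages over subsample iterations keeps the weights attached to a single
well-defined model). Scores are z-scored across the combined cohorts, so
the reported hazard ratio is per 1 SD; the per-raw-unit effect is
`exp(β/σ_raw)` and is reported alongside. The MRS is assessed by the same
per-cohort Cox + pooling machinery, and by a median split (ties to the
low-risk group, a deterministic documented rule) with Kaplan–Meier curves,
the two-group log-rank test, and a likelihood-ratio p from the deviance of
the two-group Cox fit. Median survival per group is the earliest time with
S ≤ 0.5 and is flagged undefined (NaN, with a warning) when a curve never
reaches it — common in the low-risk group under heavy censoring.

## Cox engine

Per-species scans across subsamples and permutations need on the order of
10⁵–10⁶ fits, so the Cox partial likelihood is maximized by a Newton
engine written directly in numpy and **batched across species**: all
models in one cohort share the covariate block and differ only in the
exposure column, so the score and observed information are evaluated for
all species simultaneously (risk-set sums are prefix sums over samples
sorted by descending time). Ties use the Efron approximation by default
(more accurate than Breslow and the default of standard survival
software; Breslow is available via `ties=`). Step-halving guards the
Newton updates; convergence is `max |Δβ| < 1e-9` within 40 iterations.
Monotone likelihoods (e.g. all exposed samples failing first) are flagged
`converged=False` rather than raised — detected by a diverging coefficient
(|β| > 20) or a near-singular information matrix (Wald SE > 10³, which on
a log-HR scale means the effect is unidentified). The engine agrees with
`lifelines`' `CoxPHFitter` to ~1e-6 and with brute-force
partial-likelihood maximization on small datasets to 1e-3 (both are test
oracles, never the implementation).

## Diversity

Chao1 uses the bias-corrected form `S_obs + F1(F1−1)/(2(F2+1))`; Shannon
is reported in nats and Simpson as `1 − Σp²` (common ecology defaults;
the convention is stated because base choices differ across software).
Beta diversity is the Jensen–Shannon divergence with natural logs
(bounded by log 2; the square root is a metric). Group significance on
the distance matrix uses a distance-based PERMANOVA that fits covariates
first (sequential sums of squares on the Gower-centered inner-product
matrix) and permutes the variable of interest within cohort strata,
`p = (#{F_perm ≥ F_obs}+1)/(n_perm+1)`. Because survival is a censored
time, not a group, the PERMANOVA variable defaults to event status — a
stated convention, not a claim about how such analyses must be adjusted.
Rarefaction curves are Monte-Carlo means of observed richness under
subsampling without replacement (multivariate hypergeometric draws),
which match the closed-form expectation `Σ_t (1 − C(N−n_t,d)/C(N,d))`.

## Taxa filter

A species is retained when (i) it has ≥ `min_count` (default 2) reads in
at least `min_prevalence` (default 10%) of samples, and (ii) its mean
relative abundance is ≥ `min_mean_relab` (default 1e-5, i.e. 0.001%),
both computed on the pooled cohorts (a per-cohort mode exists).
Thresholds are inclusive: the removal rule is "less than", so boundary
taxa stay. The filter is monotone — relaxing any threshold never removes
a previously retained species — and the audit report names each removed
taxon and the rule that removed it.

## Synthetic data generator

The generator emulates the structure of two resected early-stage PDAC
cohorts: sizes 140 and 63, 400 species, heavy censoring, compositional
counts with cohort-level batch shifts. Per cohort, latent log-abundances
are `μ_t + b_{c,t} + ε` with `μ_t ~ N(0, 1.5)`, batch shift
`b ~ N(0, batch_shift_sd)` and unit noise; counts are multinomial at a
depth drawn log-uniformly in [5·10³, 5·10⁴]. Survival times are drawn by
inverse transform from an exponential-baseline proportional-hazards model,
`T = −log U / (λ e^η)`, with `η` a weighted sum of the clr of the *true*
composition over the causal species (default 10 species at log-HR ±0.5)
plus covariate effects whose sizes mirror typical early-stage PDAC
registry margins (age +0.03/yr, stage IIB +0.55, small sex and smoking
effects). Relapse shares the linear predictor with a 1.5× hazard, and RFS
time is min(relapse, death), so `rfs_time ≤ os_time` holds by
construction. Censoring is uniform on [0, c] with c solved numerically
(Brent) so the expected OS censoring fraction hits the target (default
40%). Covariate margins (age ~ N(66,10), 55% male, 70% stage IIB, smoking
37/11/38/13%) are fixture realism only. Causal species are drawn from the
more abundant half of the taxon pool so configured effects act on species
that survive the prevalence filter. Immune-cell fractions are Dirichlet
draws over the 22 CIBERSORT cell types whose concentrations for designated
cell types are multiplied by `exp(link · z(clr))` of their linked causal
species; rows sum to one exactly.

What the generator does **not** emulate: read-level sequencing error,
taxonomic misassignment, zero-inflation beyond multinomial sampling,
non-proportional hazards, informative censoring, or distribution-level
(beyond mean-shift) batch effects. Passing tests therefore demonstrate
the statistical machinery under a well-specified compositional PH model,
not robustness to every pathology of real tumor RNA-seq microbiome data.
A related consequence: because effects act on the clr of the true
composition while the model sees counts-based clr, estimates carry a
small attenuation/small-sample bias that shrinks with n (measured in the
tests: mean pooled log-HR 0.515 at pooled n=500 for a true 0.5).

Two known behaviors of the method surface on synthetic data and are worth
naming. First, with two cohorts the DerSimonian–Laird p-value is slightly
conservative in mid-range (τ² truncation at zero with K=2); tail
calibration — what selection uses — is accurate (null rejection rate
0.049 at α=0.05 in the test suite). Second, clr-induced correlation
between species lets null species near strong causal ones inherit signal
("compositional hitchhiking"), so stability selection at the default
threshold admits some correlated non-causal species; this is a property
of per-species compositional scans generally, and is why the
permutation/q-value layer is reported per species rather than treated as
an exact error-rate guarantee.

## Batch centering

Full distribution-matching batch correction is out of scope; the pipeline
ships a deliberately simple stand-in that removes per-cohort per-taxon
mean shifts from the clr matrix and restores the grand mean. Row sums
stay zero because every per-taxon mean vector of a clr matrix sums to
zero across taxa. With a single cohort it is the identity.

## Problem sizes and determinism

All randomness flows through explicit integer seeds
(`numpy.random.default_rng` / `SeedSequence`); identical config + seed
reproduces outputs bitwise. Defaults follow the study design (100
subsample iterations, 500 permutations); the shipped analysis scripts and
the acceptance script run the permutation layer at 30–50 permutations and
50 subsample iterations — sizes chosen so a complete run finishes in
minutes on one CPU while leaving the permutation floor `1/(n_perm+1)`
fine enough to rank the selected species. The null-calibration experiment
uses 100 replicates of pooled n=200 with 25 species; the recovery
experiment uses 20 replicates of pooled n=400 with a log-HR 0.8 species
and 50 subsample iterations.

## Known limitations

- Wald-based per-species p-values (not likelihood-ratio) inside the scan;
  fine at these event counts, optimistic for very sparse strata.
- The PERMANOVA treatment of time-to-event data (event status as the
  grouping variable) is one convention among several.
- No phylogeny-aware beta diversity (no tree is modeled).
- The logistic immune models report Wald CIs; under perfect separation
  the fit is flagged and the CI reported as unbounded rather than
  penalized-likelihood corrected.
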