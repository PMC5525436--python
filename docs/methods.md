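# Methods

This note documents the models, algorithms and numerical choices behind
`epilipid`, what the synthetic-data generator does and does not
emulate, and the design decisions taken where more than one reasonable
implementation existed.

## 1. The interaction model and test

Each candidate SNP pair is evaluated by comparing two nested linear
models fitted by OLS on the same complete-case sample (rows missing the
trait, either dosage, or any covariate are dropped once, before either
fit):

* reduced: trait ~ intercept + SNP1 + SNP2 + age + BMI + medication +
  T2D + smoking + sex + PC1..PC10
* full: reduced + SNP1·SNP2

SNPs enter as additive minor-allele dosages (0/1/2); the interaction
term is their product. Additive coding is the convention of the
marginal-association screens the main-effect filter builds on, and the
multiplicative product is the standard single-degree-of-freedom
statistical interaction.

The test statistic is Λ = 2(ℓ_full − ℓ_reduced). With Gaussian profile
log-likelihood ℓ = −(n/2)(ln(2π·RSS/n) + 1), this reduces to
Λ = n·ln(RSS_reduced/RSS_full), which is how it is computed (one log of
an RSS ratio rather than a difference of two large log-likelihoods).
The reference distribution is χ² with 1 df — the likelihood-ratio
convention — rather than the exact partial F. The two agree to a few
percent in the tail for n in the thousands; the test suite asserts this
agreement against statsmodels' F-test as an independent oracle, and the
χ²(1) choice is the contract.

Degenerate fits never raise inside a batch: each result carries a
status (`ok`, `monomorphic`, `collinear`, `insufficient_n`). A
zero-residual full model is guarded — Λ is set to 0 when the reduced
model is also a perfect fit (nothing left to test) and to +inf
otherwise, with the reported p floored at 1e-300 so p stays in (0, 1].
ΔR² = R²_full − R²_reduced is reported alongside; by nesting it is
nonnegative up to ~1e-12 of float noise.

OLS itself is a thin numpy lstsq wrapper (`epilipid.regression`):
rank-deficiency detected from the lstsq rank, coefficient standard
errors from σ̂²(XᵀX)⁻¹ with σ̂² = RSS/(n−p). statsmodels is used in
tests as the cross-check, never in the implementation path, so the two
routes stay independent.

## 2. Candidate model generation

**Main-effect filter (MEF).** Per SNP, the marginal model
trait ~ dosage + covariates gives a two-sided t-test p-value for the
dosage coefficient; SNPs with p < 0.001 (strict) are paired
exhaustively — m passing SNPs give exactly C(m, 2) models. This arm is
run on an LD-pruned panel (below). Marginal p-values are computed
within the package on the discovery data; a per-SNP p-value table from
an external meta-analysis can be substituted, since the filter only
consumes a Series indexed by SNP ID.

**Knowledge-driven arm.** A knowledge table of (gene1, gene2, source)
rows is reduced to distinct-source counts per unordered gene pair
(duplicate rows collapse; counting is of distinct source names, not
rows). Pairs with ≥ 5 sources are expanded to all cross-gene SNP pairs
using a SNP-to-gene map with a ±50 kb window: a SNP at position p maps
to every gene with start − 50000 ≤ p < end + 50000 (0-based half-open
genes; the upstream boundary is inclusive, so a SNP exactly 50 kb away
maps). SNP pairs sharing any mapped gene are excluded — the arm is
defined on SNPs in different genes — and duplicates arising from
multi-gene SNPs are collapsed by canonical SNP-pair key. No LD pruning
is applied in this arm. Plain distinct-source counting is used for the
≥ 5 threshold; source-specific weighting schemes are deliberately out
of scope (the knowledge table is a pre-digested input).

## 3. Linkage disequilibrium

r² is the squared Pearson correlation of dosages over samples complete
at both SNPs — composite, phase-free LD, the appropriate quantity for
unphased genotypes. It is undefined (NaN, with a warning) when fewer
than two complete pairs exist or either SNP is monomorphic on them. The
all-pairs matrix is assembled from masked matrix products so each
pair's moments use its own complete-case set.

Three thresholds drive the pipeline:

* **Pruning, r² > 0.6** (MEF arm only): greedy scan in genomic-position
  order, higher-MAF SNP first on position ties; a SNP is dropped if its
  r² with any retained SNP exceeds the threshold. Global (not
  windowed) pruning — fine at candidate-panel scale. The post-condition
  (no retained pair above threshold) is asserted on every run.
* **Proxies, r² > 0.8** (strict): all other SNPs above the threshold.
  Proxies are found in the discovery genotypes themselves rather than
  an external reference panel — a documented divergence that keeps the
  pipeline self-contained; with a reference panel available the proxy
  lists can simply be supplied to `proxy_models` directly.
* **Signal sets, r² > 0.1**: single-linkage connected components of the
  thresholded r² graph, used to decide whether separate replicating
  models represent one interaction signal and to flag models whose own
  two SNPs are correlated (which would inflate the interaction term).
  The 0.1 default is configurable since "moderate correlation" has no
  single right value.

## 4. Quality control

Fixed pipeline order, recorded in the report: SNP call rate ≥ 0.95 →
Hardy-Weinberg exact test p ≥ 1e-7 → sample call rate ≥ 0.90 →
relatedness (pi-hat > 0.3) → per-analysis MAF ≥ 0.05. MAF is computed
after relatedness removal (per-analysis), from non-missing dosages as
min(f, 1−f) with f = mean(dosage)/2. The QC report stores removed and
surviving ID lists; replaying the surviving lists on the input
reproduces the output bit-exactly, which the tests assert.

**HWE exact test.** Two-sided exact test conditioning on allele counts:
the heterozygote count's conditional distribution (Levene–Haldane) is
computed by a log-scale recurrence from the minimum heterozygote count,
and the p-value sums outcomes with probability ≤ the observed outcome's
(a relative tie tolerance of 1e-12 keeps exact rational ties together
under float rounding). The implementation is validated exhaustively
against an exact-rational enumeration oracle for every genotype
configuration with n ≤ 50, agreeing to < 1e-12 (observed worst case
~8e-16).

**Relatedness.** Pairwise pi-hat by PLINK-style method of moments:
observed IBS-state counts per pair are compared with their expectations
under sample allele frequencies to solve for P(IBD=0/1/2) in sequence,
and pi-hat = P(IBD=1)/2 + P(IBD=2), clamped to [0, 1] (the raw value is
also reported; for unrelated pairs it is approximately zero-mean noise).
The computation is fully vectorised via indicator-matrix products, with
per-pair missingness handled through mask products. Removal is greedy:
iteratively drop the sample in the most over-threshold pairs (ties:
lower call rate, then lexicographically smaller ID) — deterministic and
near-minimal (it matches the brute-force minimal vertex cover on small
instances in the tests). With fewer than 50 informative SNPs the
estimator is noise, so the pipeline skips the relatedness step with a
warning instead of removing samples on meaningless estimates.

**PCA.** Missing dosages are mean-imputed for PCA only (regression
stages are complete-case per model); SNP columns are centred, scaled to
unit variance (zero-variance SNPs dropped), and decomposed by SVD. The
sign convention — the largest-magnitude loading of each component made
positive — makes scores deterministic.

## 5. Phenotype preparation

All concentrations are converted to mmol/L first (divisors 38.67 for
cholesterol and 88.57 for triglycerides — the standard clinical
factors), then LDL-C is derived by Friedewald's formula
LDL = TC − HDL − k·TG with k = 0.45 in mmol/L (0.20 in mg/dL). Derived
LDL is set missing when any input is missing or TG > 4.51 mmol/L
(400 mg/dL); the cutoff rule applies only to derived values, never to a
supplied LDL column. TG is natural-log transformed (the base only
rescales coefficients, not LRT p-values); nonpositive TG maps to
missing with a logged warning. The mg/dL and mmol/L Friedewald branches
agree after conversion to within ~0.02 mmol/L over the fasting TG
range; the residual is the rounding baked into the conventional k
factors and grows linearly in TG.

## 6. Replication

Discovery models with status `ok` and LRT p < 0.001 (strict) are
ranked ascending by p (ties broken by canonical model key). The
replication threshold for an arm is α/(m·k) with α = 0.05, m the
count of *original* (non-proxy) models and k the number of replication
cohorts; the printed form rounds to one significant figure (e.g.
0.05/1560 → 3.205e-5, shown 0.00003) while comparisons always use the
unrounded value. Each original model plus its proxy expansions —
the Cartesian product of ({a} ∪ proxies(a)) × ({b} ∪ proxies(b)) minus
the original and degenerate pairs — forms one signal. In each cohort,
models whose SNPs are absent from that cohort's panel are skipped and
logged; a cohort replicates a signal when any member attains p below
the threshold, the lowest-p member is recorded as the cohort's lead,
and direction concordance is the sign match of the lead's interaction
beta with the discovery beta. A signal counts at most once per cohort
regardless of how many members pass. Replication is per-cohort (each
cohort's own complete cases and covariates); no meta-analysis is
performed. An optional Bonferroni-adjusted discovery threshold
(α divided by the number of models tested) is available, but the flat
p < 0.001 selection is the default.

## 7. The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
not any particular population:

* **Genotypes.** Each haplotype of an individual is a chain of latent
  standard normals, AR(1) within an LD block and independent across
  blocks, thresholded at the allele-frequency quantile; the two
  haplotype indicators sum to the dosage. The latent correlation of
  each adjacent pair is calibrated by solving the tetrachoric relation
  (bivariate-normal orthant probability, Brent root-finding) so the
  *dosage* r² matches the configured target. Because binary-variable
  correlation is capped by allele-frequency mismatch, high target r²
  (0.8–0.9) is only attainable between SNPs of similar MAF — true of
  real data as well — so high-LD configurations should use a narrow
  `maf_range`. Per-SNP MAF is drawn uniformly from `maf_range`
  (constrained to [0.05, 0.5]); missing calls are injected completely
  at random at a configurable rate (default 1%).
* **Covariates.** Age uniform on [21, 80] (adult cohorts), sex/smoking/
  T2D/medication Bernoulli at plausible prevalences (0.5/0.25/0.10/
  0.15), BMI Gaussian (27, 4.5), and ten independent standard-Gaussian
  "PCs". Synthetic PCs are noise by construction: a single simulated
  population has no ancestry axes, so including them exercises the
  model's dimensionality without confounding. Real PCs from
  `epilipid.qc.compute_pcs` can be substituted when structure is
  simulated deliberately.
* **Phenotypes.** Each trait follows y = α + Σβ·dosage terms +
  Σβ₁₉·dosage products + covariate effects + Gaussian noise on its
  analysis scale. TG is built as exp(linear predictor + noise), so
  log TG is the linear-model scale and TG itself is log-normal. TC is
  constructed as LDL + HDL + 0.45·TG plus optional TC-level effects and
  noise; with the default zero TC noise the Friedewald identity holds
  exactly, enabling exact round-trip tests of the phenotype-preparation
  stage. Intercepts default to physiologic means (HDL 1.4, LDL 3.0,
  TC 5.2, TG 1.5 mmol/L) — presentation, not inference. Default
  residual SDs (HDL 0.35, LDL 0.9, log-TG 0.45) are in the range of
  population lipid SDs; they are free parameters of the generator, not
  estimates of any cohort. Effects of missing dosages are computed from
  the SNP-mean imputation so phenotypes stay complete.
* **Cohorts.** Samples are partitioned into equal disjoint cohorts; the
  first `n_discovery_cohorts` are flagged for merging into the
  discovery set, the rest are independent replication cohorts.
* **Knowledge base.** Each unordered gene pair is supported by each of
  `n_sources` sources independently with probability `density`; when
  0 < density < 1 (and ≥ 5 sources, ≥ 2 pairs exist) the table is
  deterministically adjusted so both sides of the five-source threshold
  are represented.

Identical configuration and seed reproduce every output bit-for-bit;
stages draw from independently derived streams of one seed.

**What passing tests do and do not show.** The generator has no family
structure, no ancestry stratification, no genotyping batch effects, no
phenotype measurement error beyond the Gaussian residual, no
medication-by-genotype dependence, and Hardy-Weinberg-consistent
genotypes by construction. Calibration and recovery results on it
demonstrate the statistical machinery is correct under the model's own
assumptions; they do not establish robustness to the confounding real
cohorts contain.

## 8. Validation experiments and problem sizes

`epilipid.experiments` packages the seeded Monte-Carlo checks used by
the test suite and the acceptance script:

* **Null calibration:** 1000 replicates of n = 2000 with two
  independent MAF-0.3 SNPs and pure-noise HDL; empirical type-I error
  at α = 0.05 and Kolmogorov–Smirnov uniformity of the p-values. The
  χ²(1) reference is mildly anticonservative at this n (expected size
  ≈ 0.051); observed rates across seeds fall in 0.046–0.061.
* **Recovery:** 100 replicates of n = 5000 with planted β₁₉ = 0.5;
  fraction of estimates within ±3 SE of truth (nominal ≈ 99.7%).
* **End-to-end:** 20 runs of the full MEF pipeline — 12 SNPs in six
  r² = 0.3 blocks, planted interaction across blocks, discovery
  n = 8000, three replication cohorts of n = 3000 — counting runs where
  the planted pair is selected at p < 0.001 and its signal replicates
  in ≥ 2 cohorts.
* **Null replication:** 200 null models tested in 5 cohorts of 1000 at
  the corrected threshold; false cohort-level replications per run are
  compared with the Poisson expectation m·k·threshold.

These sizes run the whole suite in a couple of minutes on one CPU while
keeping Monte-Carlo error well inside the asserted bands.

## 9. Known limitations

* Gaussian OLS only; binary traits, robust/sandwich errors and mixed
  models for residual relatedness are out of scope (relatedness is
  handled by removal, not modelling).
* The HWE exact test enumerates all heterozygote counts per SNP; exact
  but O(n) per SNP, which is irrelevant at candidate-panel scale.
* Proxy discovery from the analysis data itself cannot rescue SNPs that
  are absent from the discovery panel, unlike a reference-panel lookup.
* Pi-hat method-of-moments assumes a homogeneous population; it is not
  robust to strong stratification.
* The greedy prune and greedy relatedness removal are deterministic
  near-minimal heuristics, not exact optima (the tests check them
  against brute force only on small instances).
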