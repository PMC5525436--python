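# epilipid

SNP-SNP interaction discovery and multi-cohort replication for
quantitative lipid traits (HDL-C, LDL-C, total cholesterol,
triglycerides), with a synthetic-cohort generator so the entire
pipeline runs and is testable at desk scale.

## Who this is for

Statistical geneticists and genetic epidemiologists who want a tested,
reusable implementation of the two-arm epistasis-screening workflow
used in large lipid consortia: candidate SNP pairs are produced either
by a **main-effect filter** (pair every SNP whose marginal association
reaches p < 0.001, after LD pruning at r² > 0.6) or by a
**knowledge-driven filter** (pair SNPs across gene pairs supported by
at least five curated knowledge sources, mapping SNPs to genes with a
±50 kb window), tested for a multiplicative interaction, and carried
into independent replication cohorts together with LD-proxy models.

Real consortium genotypes are access-controlled, so the package ships a
generator for multi-cohort synthetic data with the structure the
analysis assumes: LD-block-structured biallelic dosages, lipid
phenotypes driven by main effects and planted pairwise interactions,
and the standard covariates (age, sex, BMI, smoking, type-2 diabetes,
lipid medication, 10 principal components).

## The statistic

For a trait *y* and a SNP pair (g₁, g₂) coded as minor-allele dosages,
two nested ordinary-least-squares models are fitted on the identical
complete-case sample:

    reduced:  y = α + β₁g₁ + β₂g₂ + β₃age + β₄BMI + β₅med + β₆T2D
                    + β₇smoking + β₈sex + β₉₋₁₈PC₁₋₁₀
    full:     reduced + β₁₉(g₁·g₂)

The interaction is judged by the likelihood-ratio statistic
Λ = 2(ℓ_full − ℓ_reduced) = n·ln(RSS_reduced / RSS_full), referred to
χ²(1). Models reaching p < 0.001 in the merged discovery set are tested
in each replication cohort at the Bonferroni-like threshold
α / (m·k), where m counts the arm's original (non-proxy) models and k
the replication cohorts. An original model and its r² > 0.8 proxies
form one LD *signal* that counts at most once per cohort.

Phenotype preparation follows clinical convention: concentrations in
mmol/L, LDL-C derived by Friedewald's formula LDL = TC − HDL − 0.45·TG
(missing when TG > 4.51 mmol/L), and TG analysed on the natural-log
scale.

## Worked example

Plant a β₁₉ = 0.5 interaction on HDL-C between two SNPs in different LD
blocks, run the main-effect-filter arm on a merged discovery set of
2000 samples, and test replication in three cohorts of 2000:

```python
import numpy as np
from epilipid import (
    SimulationConfig, TrueEffect, simulate_cohorts, merge_discovery,
    ld_prune, ld_matrix, find_proxies, proxy_models,
    main_effect_scan, main_effect_filter_models, batch_test,
    select_discovery_models, run_replication, summarize,
)

config = SimulationConfig(
    n_cohorts=4, n_per_cohort=2000, n_discovery_cohorts=1,
    n_snps=12, ld_block_sizes=[2] * 6, within_block_r2=0.3,
    maf_range=(0.3, 0.35),
    true_models=[TrueEffect("snp0001", "snp0003", 0.15, 0.15, 0.5, "HDL")],
    covariate_effects={"age": 0.002, "sex": -0.1},
    seed=42,
)
cohorts = simulate_cohorts(config)
discovery = merge_discovery(cohorts)
replication_cohorts = [c for c in cohorts if c.role == "replication"]

retained = ld_prune(discovery.genotypes, threshold=0.6)
pvals = main_effect_scan(
    discovery.genotypes.subset_snps(np.asarray(retained, dtype=object)),
    discovery.phenotypes["hdl"].to_numpy(),
    discovery.covariates,
)
candidates = main_effect_filter_models(pvals, 0.001, retained_snps=retained)
selected = select_discovery_models(batch_test(candidates, discovery, "hdl"), 0.001)

ldm = ld_matrix(discovery.genotypes)
proxies = {
    r.model.key(): proxy_models(
        r.model,
        find_proxies(discovery.genotypes, r.model.snp_a, 0.8, ld=ldm),
        find_proxies(discovery.genotypes, r.model.snp_b, 0.8, ld=ldm),
    )
    for r in selected
}
summaries, threshold = run_replication(selected, proxies, replication_cohorts, "hdl")
print(f"{len(candidates)} candidate models, {len(selected)} selected, "
      f"replication threshold p < {threshold:.2e}")
print(summarize(summaries, min_cohorts=2).to_string(index=False))
```

prints

```
6 candidate models, 4 selected, replication threshold p < 4.17e-03
 rank   snp_1   snp_2 locus_1 locus_2  disc_beta    disc_lrt_p  rep_beta     rep_lrt_p                rep_cohorts  n_replicating
    1 snp0001 snp0003    None    None   0.519448 5.018574e-152  0.506630 4.730463e-153 cohort02,cohort03,cohort04              3
    2 snp0002 snp0003    None    None   0.248033  1.389544e-22  0.286860  2.149063e-31 cohort02,cohort03,cohort04              3
    3 snp0001 snp0004    None    None   0.243857  4.431970e-22  0.256917  8.170142e-26 cohort02,cohort03,cohort04              3
    4 snp0002 snp0004    None    None   0.138618  2.241438e-06  0.148808  2.229097e-07 cohort02,cohort03,cohort04              3
```

Rank 1 is the planted pair, recovered at its true effect size
(β̂₁₉ ≈ 0.52 in discovery against a generative 0.5) and replicating in
all three cohorts. Ranks 2–4 are its LD shadows — block-mates of the
planted SNPs at r² ≈ 0.3 carry an attenuated copy of the signal. That
is exactly the situation the signal-set machinery
(`epilipid.ld.signal_sets`, threshold r² > 0.1) is for: all four models
collapse into one underlying interaction signal between two LD sets.

A `click` CLI wraps the same steps for file-based workflows
(`epilipid simulate / prep-pheno / qc / ld / discover / replicate /
report`); genotypes travel as VCF or rectangular dosage TSV, everything
else as TSV.

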