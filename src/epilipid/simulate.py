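"""Synthetic multi-cohort genotype/phenotype/covariate generator.

Emulates the statistical structure the interaction pipeline assumes:
unrelated diploid individuals, LD-block-structured biallelic SNPs,
four lipid traits (HDL-C, LDL-C, TC, TG in mmol/L) driven by additive
main effects, planted pairwise multiplicative interactions and
covariates, with Gaussian residuals (log-normal for TG), plus a toy
knowledge-source table for the knowledge-driven arm.

LD is generated by a latent-Gaussian haplotype mechanism: each
haplotype draws an AR(1) chain of standard normals along a block and
thresholds each at the allele-frequency quantile; the two haplotypes
sum to the dosage.  The latent correlation of each adjacent pair is
calibrated (tetrachoric relation, solved numerically) so the dosage r²
tracks the configured target.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .genotypes import GenotypeMatrix, snp_meta_frame

TRAITS = ("HDL", "LDL", "TC", "TG")

#: Phenotype-table column holding each trait's analysis scale
#: (TG is analysed as log TG).
TRAIT_COLUMN = {"HDL": "hdl", "LDL": "ldl", "TC": "tc", "TG": "log_tg"}

#: Intercepts giving physiologic trait means (mmol/L); presentation only.
DEFAULT_INTERCEPTS = {"HDL": 1.4, "LDL": 3.0, "TC": 5.2, "TG": 1.5}

#: Default residual SDs; TC defaults to 0 so the Friedewald identity
#: TC = LDL + HDL + 0.45*TG holds exactly and round-trips.
DEFAULT_NOISE_SD = {"HDL": 0.35, "LDL": 0.9, "TG": 0.45, "TC": 0.0}

FRIEDEWALD_K_MMOL = 0.45

COVARIATE_COLUMNS = ["age", "sex", "smoking", "t2d", "medication", "bmi"] + [
    f"PC{i}" for i in range(1, 11)
]


@dataclass
class TrueEffect:
    """A planted genetic effect on one trait.

    ``beta_interaction`` acts on the dosage product ``g_a * g_b``; it
    is the generative counterpart of the interaction coefficient the
    LRT estimates.  Effects on TG act on the log scale.
    """

    snp_a: str
    snp_b: str | None = None
    beta_main_a: float = 0.0
    beta_main_b: float = 0.0
    beta_interaction: float = 0.0
    trait: str = "HDL"

    def __post_init__(self) -> None:
        self.trait = self.trait.upper()
        if self.trait not in TRAITS:
            raise ValueError(f"unknown trait: {self.trait!r}")
        if self.beta_interaction != 0.0 and self.snp_b is None:
            raise ValueError("snp_b is required when beta_interaction != 0")


@dataclass
class SimulationConfig:
    """Full description of one multi-cohort simulation.

    The same config and seed always reproduce identical output.
    """

    n_cohorts: int = 4
    n_per_cohort: int = 1000
    n_snps: int = 20
    ld_block_sizes: list = field(default_factory=lambda: [5, 5, 5, 5])
    within_block_r2: float = 0.3
    maf_range: tuple = (0.05, 0.5)
    true_models: list = field(default_factory=list)
    covariate_effects: dict = field(default_factory=dict)
    noise_sd: dict | float = field(default_factory=lambda: dict(DEFAULT_NOISE_SD))
    seed: int = 0
    missing_rate: float = 0.01
    n_discovery_cohorts: int = 1
    intercepts: dict = field(default_factory=lambda: dict(DEFAULT_INTERCEPTS))

    def __post_init__(self) -> None:
        if sum(self.ld_block_sizes) != self.n_snps:
            raise ValueError("ld_block_sizes must sum to n_snps")
        if not 0 <= self.within_block_r2 < 1:
            raise ValueError("within_block_r2 must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0.05 <= lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within [0.05, 0.5]")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if not 1 <= self.n_discovery_cohorts <= self.n_cohorts:
            raise ValueError("n_discovery_cohorts must be in [1, n_cohorts]")
        for t in TRAITS:
            sd = self.trait_noise_sd(t)
            if sd < 0 or (sd == 0 and t != "TC"):
                raise ValueError(f"noise_sd for {t} must be positive")

    def trait_noise_sd(self, trait: str) -> float:
        if isinstance(self.noise_sd, dict):
            return float(self.noise_sd.get(trait, DEFAULT_NOISE_SD[trait]))
        return float(self.noise_sd)

    @property
    def n_samples(self) -> int:
        return self.n_cohorts * self.n_per_cohort

    def stage_rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), stage])


@dataclass
class CohortDataset:
    """One cohort's aligned genotype/covariate/phenotype triple."""

    name: str
    role: str  # "discovery" | "replication"
    genotypes: GenotypeMatrix
    covariates: pd.DataFrame
    phenotypes: pd.DataFrame

    @property
    def sample_ids(self) -> np.ndarray:
        return self.genotypes.sample_ids


# ---------------------------------------------------------------- genotypes
def _tetrachoric_rho(f1: float, f2: float, target_r: float) -> float:
    """Latent-normal correlation giving allele correlation ``target_r``.

    Solves phi(rho) = target_r where phi is the correlation of the two
    thresholded indicators 1{Z1 < q(f1)}, 1{Z2 < q(f2)}.  Clamped to
    0.9999 when the target exceeds the maximum attainable phi for the
    given frequencies.
    """
    if target_r <= 0:
        return 0.0
    t1, t2 = stats.norm.ppf(f1), stats.norm.ppf(f2)
    denom = np.sqrt(f1 * (1 - f1) * f2 * (1 - f2))

    def phi(rho: float) -> float:
        p11 = stats.multivariate_normal.cdf(
            [t1, t2], mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]]
        )
        return (p11 - f1 * f2) / denom

    hi = 0.9999
    if phi(hi) <= target_r:
        return hi
    return float(optimize.brentq(lambda r: phi(r) - target_r, 0.0, hi, xtol=1e-6))


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """LD-block-structured biallelic dosages for all cohorts at once.

    Within a block, adjacent SNPs attain dosage r² near
    ``config.within_block_r2``; different blocks are independent.
    Missing calls are injected completely at random at
    ``config.missing_rate``.  Blocks sit far apart on one chromosome so
    positional operations (gene windows, prune order) behave sensibly.
    """
    rng = config.stage_rng(1)
    n = config.n_samples
    maf = rng.uniform(*config.maf_range, size=config.n_snps)
    target_r = np.sqrt(config.within_block_r2)

    dosages = np.empty((n, config.n_snps))
    start = 0
    for size in config.ld_block_sizes:
        f = maf[start : start + size]
        rhos = np.array(
            [_tetrachoric_rho(f[i], f[i + 1], target_r) for i in range(size - 1)]
        )
        block = np.zeros((n, size))
        for _hap in range(2):
            z = np.empty((n, size))
            z[:, 0] = rng.standard_normal(n)
            for s in range(1, size):
                eps = rng.standard_normal(n)
                z[:, s] = rhos[s - 1] * z[:, s - 1] + np.sqrt(
                    1 - rhos[s - 1] ** 2
                ) * eps
            block += (z < stats.norm.ppf(f)).astype(float)
        dosages[:, start : start + size] = block
        start += size

    if config.missing_rate > 0:
        mask = config.stage_rng(5).random(dosages.shape) < config.missing_rate
        dosages[mask] = np.nan

    positions, block_ids = [], []
    for b, size in enumerate(config.ld_block_sizes):
        positions += [1_000_000 * (b + 1) + 5_000 * s for s in range(size)]
        block_ids += [b] * size
    snp_ids = [f"snp{j + 1:04d}" for j in range(config.n_snps)]
    snps = snp_meta_frame(snp_ids, chrom="1", pos=positions)
    snps["block"] = block_ids
    sample_ids = [f"S{i + 1:06d}" for i in range(n)]
    return GenotypeMatrix(dosages, np.array(sample_ids, dtype=object), snps)


# --------------------------------------------------------------- covariates
def simulate_covariates(
    n: int, seed: int, sample_ids: np.ndarray | None = None
) -> pd.DataFrame:
    """Covariate table: age, sex, smoking, T2D, lipid medication, BMI, 10 PCs.

    Ages are uniform on [21, 80] (the cohorts enrol adults >= 21);
    binary covariates are Bernoulli draws at plausible prevalences; the
    synthetic PCs are independent standard Gaussians standing in for
    ancestry axes.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    data = {
        "age": rng.uniform(21.0, 80.0, n),
        "sex": rng.binomial(1, 0.5, n).astype(float),
        "smoking": rng.binomial(1, 0.25, n).astype(float),
        "t2d": rng.binomial(1, 0.10, n).astype(float),
        "medication": rng.binomial(1, 0.15, n).astype(float),
        "bmi": rng.normal(27.0, 4.5, n),
    }
    for i in range(1, 11):
        data[f"PC{i}"] = rng.standard_normal(n)
    df = pd.DataFrame(data, columns=COVARIATE_COLUMNS)
    if sample_ids is not None:
        df.insert(0, "sample_id", np.asarray(sample_ids, dtype=object))
    return df


# --------------------------------------------------------------- phenotypes
def _effect_dosage(G: GenotypeMatrix, snp: str) -> np.ndarray:
    """Dosage vector for phenotype generation; missing calls take the
    SNP mean so planted effects stay defined for every sample."""
    g = G.dosage_vector(snp).copy()
    m = np.isnan(g)
    if m.any():
        g[m] = np.nanmean(g)
    return g


def simulate_phenotypes(
    G: GenotypeMatrix, X: pd.DataFrame, config: SimulationConfig
) -> pd.DataFrame:
    """Generate the lipid panel from genotypes and covariates.

    Each trait follows ``y = alpha + main effects + interaction effects
    + covariate effects + Gaussian noise`` on its analysis scale: HDL
    and LDL directly in mmol/L, TG on the log scale (so TG itself is
    log-normal), and TC as LDL + HDL + 0.45*TG plus TC-level effects
    and noise — with the default zero TC noise the Friedewald identity
    holds exactly.
    """
    if "sample_id" in X.columns:
        if not np.array_equal(X["sample_id"].to_numpy(), G.sample_ids):
            raise ValueError("sample IDs of genotypes and covariates differ")
    for eff in config.true_models:
        for snp in (eff.snp_a, eff.snp_b):
            if snp is not None and snp not in set(G.snp_ids):
                raise ValueError(f"true-model SNP {snp!r} absent from genotypes")

    rng = config.stage_rng(3)
    n = G.n_samples
    cov_term = np.zeros(n)
    for cov, beta in config.covariate_effects.items():
        cov_term += beta * X[cov].to_numpy(dtype=float)

    def genetic_term(trait: str) -> np.ndarray:
        g = np.zeros(n)
        for eff in config.true_models:
            if eff.trait != trait:
                continue
            ga = _effect_dosage(G, eff.snp_a)
            g += eff.beta_main_a * ga
            if eff.snp_b is not None:
                gb = _effect_dosage(G, eff.snp_b)
                g += eff.beta_main_b * gb + eff.beta_interaction * ga * gb
        return g

    def noise(trait: str) -> np.ndarray:
        sd = config.trait_noise_sd(trait)
        return rng.normal(0.0, sd, n) if sd > 0 else np.zeros(n)

    hdl = config.intercepts["HDL"] + genetic_term("HDL") + cov_term + noise("HDL")
    ldl = config.intercepts["LDL"] + genetic_term("LDL") + cov_term + noise("LDL")
    log_tg = (
        np.log(config.intercepts["TG"])
        + genetic_term("TG")
        + cov_term
        + noise("TG")
    )
    tg = np.exp(log_tg)
    tc = hdl + ldl + FRIEDEWALD_K_MMOL * tg + genetic_term("TC") + noise("TC")
    return pd.DataFrame(
        {
            "sample_id": G.sample_ids,
            "tc": tc,
            "hdl": hdl,
            "ldl": ldl,
            "tg": tg,
            "log_tg": log_tg,
        }
    )


# ------------------------------------------------------------ knowledge base
def simulate_knowledge_base(
    genes: pd.DataFrame, n_sources: int, density: float, seed: int
) -> pd.DataFrame:
    """Toy curated-knowledge table: (gene1, gene2, source) rows.

    Each unordered gene pair is supported by each of ``n_sources``
    named sources independently with probability ``density``.  When the
    density is strictly between 0 and 1 and at least five sources and
    two gene pairs exist, the table is adjusted deterministically so at
    least one pair has >= 5 distinct sources and one has < 5, keeping
    the source-count threshold exercisable.
    """
    if n_sources < 1:
        raise ValueError("n_sources must be >= 1")
    if not 0 <= density <= 1:
        raise ValueError("density must be in [0, 1]")
    gene_ids = sorted(genes["gene"].astype(str))
    if len(gene_ids) < 2:
        raise ValueError("need at least two genes")
    rng = np.random.default_rng(seed)
    sources = [f"source{k + 1:02d}" for k in range(n_sources)]
    pairs = [
        (gene_ids[i], gene_ids[j])
        for i in range(len(gene_ids))
        for j in range(i + 1, len(gene_ids))
    ]
    support = {p: [s for s in sources if rng.random() < density] for p in pairs}
    if 0 < density < 1 and n_sources >= 5 and len(pairs) >= 2:
        if not any(len(v) >= 5 for v in support.values()):
            support[pairs[0]] = sources[:5]
        if not any(len(v) < 5 for v in support.values()):
            support[pairs[-1]] = sources[:4]
    rows = [
        (g1, g2, s) for (g1, g2), srcs in support.items() for s in srcs
    ]
    return pd.DataFrame(rows, columns=["gene1", "gene2", "source"])


def gene_annotation_for_blocks(G: GenotypeMatrix) -> pd.DataFrame:
    """One synthetic gene per LD block, spanning the block's SNPs.

    Convenience annotation for exercising the knowledge arm on
    simulated data; coordinates are 0-based half-open.
    """
    if "block" not in G.snps.columns:
        raise ValueError("genotype metadata has no block assignment")
    rows = []
    for b, grp in G.snps.groupby("block"):
        rows.append(
            (
                str(grp["chrom"].iloc[0]),
                int(grp["pos"].min()) - 1,
                int(grp["pos"].max()) + 1,
                f"GENE{int(b) + 1}",
            )
        )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene"])


# ----------------------------------------------------------------- cohorts
def split_cohorts(
    G: GenotypeMatrix,
    X: pd.DataFrame,
    P: pd.DataFrame,
    config: SimulationConfig,
) -> list[CohortDataset]:
    """Partition samples into disjoint cohorts.

    The first ``config.n_discovery_cohorts`` cohorts are flagged for
    merging into the discovery set; the rest are independent
    replication cohorts.
    """
    if config.n_cohorts < 2:
        raise ValueError("need at least two cohorts")
    total = config.n_cohorts * config.n_per_cohort
    if total > G.n_samples:
        raise ValueError(
            f"partition of {total} samples exceeds the {G.n_samples} available"
        )
    cohorts = []
    for c in range(config.n_cohorts):
        rows = np.arange(c * config.n_per_cohort, (c + 1) * config.n_per_cohort)
        role = "discovery" if c < config.n_discovery_cohorts else "replication"
        cohorts.append(
            CohortDataset(
                name=f"cohort{c + 1:02d}",
                role=role,
                genotypes=G.subset_samples(np.isin(np.arange(G.n_samples), rows)),
                covariates=X.iloc[rows].reset_index(drop=True),
                phenotypes=P.iloc[rows].reset_index(drop=True),
            )
        )
    return cohorts


def concat_cohorts(
    cohorts: list[CohortDataset], name: str, role: str
) -> CohortDataset:
    """Stack several cohorts' samples into one dataset."""
    if not cohorts:
        raise ValueError("no cohorts to concatenate")
    G0 = cohorts[0].genotypes
    dosages = np.vstack([c.genotypes.dosages for c in cohorts])
    sample_ids = np.concatenate([c.genotypes.sample_ids for c in cohorts])
    return CohortDataset(
        name=name,
        role=role,
        genotypes=GenotypeMatrix(dosages, sample_ids, G0.snps.copy()),
        covariates=pd.concat([c.covariates for c in cohorts], ignore_index=True),
        phenotypes=pd.concat([c.phenotypes for c in cohorts], ignore_index=True),
    )


def merge_discovery(cohorts: list[CohortDataset]) -> CohortDataset:
    """Concatenate the discovery-flagged cohorts into one dataset."""
    disc = [c for c in cohorts if c.role == "discovery"]
    if not disc:
        raise ValueError("no discovery cohorts to merge")
    return concat_cohorts(disc, "discovery", "discovery")


def simulate_cohorts(config: SimulationConfig) -> list[CohortDataset]:
    """End-to-end generation: genotypes, covariates, phenotypes, split."""
    G = simulate_genotypes(config)
    X = simulate_covariates(
        config.n_samples,
        seed=int(config.stage_rng(2).integers(2**31)),
        sample_ids=G.sample_ids,
    )
    P = simulate_phenotypes(G, X, config)
    return split_cohorts(G, X, P, config)


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    """Copy of a config with a different seed."""
    return replace(config, seed=seed)
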