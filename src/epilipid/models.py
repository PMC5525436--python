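"""Candidate SNP-SNP model generation.

Two arms produce the models that go into interaction testing:

* **Main-effect filter (MEF)** — every SNP is scanned for a marginal
  association with the trait; SNPs passing p < 0.001 are paired
  exhaustively (LD-pruned input).
* **Knowledge-driven** — gene pairs supported by at least five curated
  knowledge sources are expanded to all cross-gene SNP pairs, using a
  ±50 kb SNP-to-gene mapping window (no LD pruning in this arm).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .regression import STATUS_OK, fit_linear

logger = logging.getLogger(__name__)

PROV_MEF = "main_effect_filter"
PROV_KNOWLEDGE = "knowledge"


@dataclass
class SnpPairModel:
    """An unordered SNP pair candidate, stored in canonical order."""

    snp_a: str
    snp_b: str
    provenance: str = PROV_MEF
    gene_a: str | None = None
    gene_b: str | None = None
    n_sources: int | None = None

    def __post_init__(self) -> None:
        if self.snp_a == self.snp_b:
            raise ValueError("snp_a and snp_b must differ")
        if str(self.snp_b) < str(self.snp_a):
            self.snp_a, self.snp_b = self.snp_b, self.snp_a
            self.gene_a, self.gene_b = self.gene_b, self.gene_a

    def key(self) -> str:
        return f"{self.snp_a}|{self.snp_b}"

    @property
    def is_proxy(self) -> bool:
        return self.provenance.startswith("proxy-of:")

    @property
    def original_key(self) -> str:
        """Key of the original model this one represents (itself if original)."""
        if self.is_proxy:
            return self.provenance.split(":", 1)[1]
        return self.key()


def n_interaction_models(n_snps: int, order: int = 2) -> int:
    """Number of ``order``-way interaction models among ``n_snps`` SNPs.

    E.g. 1000 SNPs give 499,500 two-way and 166,167,000 three-way models.
    """
    if n_snps < 0 or order < 1:
        raise ValueError("n_snps and order must be nonnegative/positive")
    return comb(n_snps, order)


# ------------------------------------------------------------ MEF arm
def main_effect_scan(
    G: GenotypeMatrix, y: np.ndarray, X: pd.DataFrame
) -> pd.Series:
    """Per-SNP marginal association p-values.

    For each SNP, fits ``y ~ intercept + dosage + covariates`` on the
    complete cases and returns the two-sided p-value of the dosage
    coefficient, indexed by SNP ID.  Monomorphic SNPs get NaN.
    """
    y = np.asarray(y, dtype=float)
    cov_cols = [c for c in X.columns if c != "sample_id"]
    covs = X[cov_cols].to_numpy(dtype=float)
    base_ok = ~np.isnan(y) & ~np.isnan(covs).any(axis=1)
    pvals = np.full(G.n_snps, np.nan)
    for j in range(G.n_snps):
        g = G.dosages[:, j]
        ok = base_ok & ~np.isnan(g)
        gj = g[ok]
        if gj.size == 0 or gj.std() == 0:
            logger.warning("monomorphic SNP %s: no main-effect p", G.snp_ids[j])
            continue
        design = np.column_stack([np.ones(ok.sum()), gj, covs[ok]])
        fit = fit_linear(y[ok], design)
        if fit.status == STATUS_OK:
            pvals[j] = fit.t_pvalues()[1]
    return pd.Series(pvals, index=pd.Index(G.snp_ids, name="snp_id"))


def main_effect_filter_models(
    pvals: pd.Series,
    threshold: float = 0.001,
    retained_snps: list | None = None,
) -> list[SnpPairModel]:
    """Exhaustive pairs of SNPs with main-effect p below ``threshold``.

    ``retained_snps`` restricts the scan to the LD-pruned SNP set this
    arm requires.  m passing SNPs yield exactly C(m, 2) models.
    """
    if retained_snps is not None:
        pvals = pvals.loc[[s for s in retained_snps if s in pvals.index]]
    passing = sorted(pvals.index[(pvals < threshold).fillna(False)], key=str)
    if len(passing) < 2:
        logger.warning(
            "main-effect filter left %d SNP(s): no pairable models", len(passing)
        )
        return []
    return [
        SnpPairModel(passing[i], passing[j], provenance=PROV_MEF)
        for i in range(len(passing))
        for j in range(i + 1, len(passing))
    ]


# ------------------------------------------------------ knowledge arm
def map_snps_to_genes(
    snps: pd.DataFrame, annotation: pd.DataFrame, window_bp: int = 50_000
) -> dict[str, set]:
    """Map SNPs to genes within a ±``window_bp`` window.

    Genes are 0-based half-open intervals; a SNP at position ``pos``
    maps to every gene with ``start - window <= pos < end + window``
    (the upstream boundary is inclusive, so a SNP exactly 50 kb away
    still maps).  SNPs on chromosomes absent from the annotation are
    left unmapped and logged.  Returns snp_id -> set of gene IDs.
    """
    mapping: dict[str, set] = {s: set() for s in snps["snp_id"]}
    ann_by_chrom = {str(c): grp for c, grp in annotation.groupby("chrom")}
    unmapped_chroms = set()
    for snp_id, chrom, pos in zip(snps["snp_id"], snps["chrom"], snps["pos"]):
        genes = ann_by_chrom.get(str(chrom))
        if genes is None:
            unmapped_chroms.add(str(chrom))
            continue
        hit = (genes["start"] - window_bp <= pos) & (pos < genes["end"] + window_bp)
        mapping[snp_id] = set(genes.loc[hit, "gene"])
    if unmapped_chroms:
        logger.warning(
            "SNPs on chromosome(s) %s have no gene annotation",
            ", ".join(sorted(unmapped_chroms)),
        )
    return mapping


def knowledge_source_counts(kb: pd.DataFrame) -> pd.Series:
    """Distinct-source count per unordered gene pair.

    Duplicate (pair, source) rows collapse to one; the index holds
    canonically ordered (gene1, gene2) tuples.
    """
    if len(kb) == 0:
        return pd.Series(dtype=int)
    pairs = kb.apply(
        lambda r: tuple(sorted((str(r["gene1"]), str(r["gene2"])))), axis=1
    )
    dedup = pd.DataFrame({"pair": pairs, "source": kb["source"]}).drop_duplicates()
    return dedup.groupby("pair")["source"].nunique().sort_index()


def knowledge_models(
    kb: pd.DataFrame,
    snp_gene_map: dict[str, set],
    min_sources: int = 5,
) -> list[SnpPairModel]:
    """SNP-pair models from gene pairs with >= ``min_sources`` sources.

    For each qualifying gene pair, emits all cross-gene SNP pairs; SNP
    pairs sharing any mapped gene are excluded (the arm is defined on
    SNPs in *different* genes), and duplicates across gene pairs are
    collapsed by canonical SNP-pair key.
    """
    counts = knowledge_source_counts(kb)
    gene_snps: dict[str, list] = {}
    for snp, genes in snp_gene_map.items():
        for g in genes:
            gene_snps.setdefault(g, []).append(snp)
    out: dict[str, SnpPairModel] = {}
    for (g1, g2), n_src in counts.items():
        if n_src < min_sources or g1 == g2:
            continue
        for a in sorted(gene_snps.get(g1, []), key=str):
            for b in sorted(gene_snps.get(g2, []), key=str):
                if a == b:
                    continue
                if snp_gene_map[a] & snp_gene_map[b]:
                    continue  # shared gene: not a cross-gene pair
                m = SnpPairModel(
                    a, b, provenance=PROV_KNOWLEDGE,
                    gene_a=g1, gene_b=g2, n_sources=int(n_src),
                )
                out.setdefault(m.key(), m)
    return [out[k] for k in sorted(out)]


# ----------------------------------------------------------------- I/O
def models_to_frame(models: list[SnpPairModel]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "snp_a": [m.snp_a for m in models],
            "snp_b": [m.snp_b for m in models],
            "provenance": [m.provenance for m in models],
            "gene_a": [m.gene_a for m in models],
            "gene_b": [m.gene_b for m in models],
            "n_sources": [m.n_sources for m in models],
        }
    )


def frame_to_models(df: pd.DataFrame) -> list[SnpPairModel]:
    out = []
    for row in df.itertuples(index=False):
        out.append(
            SnpPairModel(
                row.snp_a,
                row.snp_b,
                provenance=getattr(row, "provenance", PROV_MEF),
                gene_a=_opt(getattr(row, "gene_a", None)),
                gene_b=_opt(getattr(row, "gene_b", None)),
                n_sources=_opt_int(getattr(row, "n_sources", None)),
            )
        )
    return out


def _opt(v):
    return None if v is None or (isinstance(v, float) and np.isnan(v)) else v


def _opt_int(v):
    v = _opt(v)
    return None if v is None else int(v)


def read_gene_annotation(path: str) -> pd.DataFrame:
    """BED-like TSV: chrom, start, end, gene (0-based half-open)."""
    df = pd.read_csv(
        path, sep="\t", names=["chrom", "start", "end", "gene"], header=None,
        dtype={"chrom": str},
    )
    if (df["start"] >= df["end"]).any():
        raise ValueError("gene annotation requires start < end")
    if df["gene"].duplicated().any():
        raise ValueError("gene IDs must be unique")
    return df


def read_main_effect_pvalues(path: str) -> pd.Series:
    """Per-SNP p-value TSV (snp_id, p) from an external marginal scan.

    Lets the main-effect filter consume p-values from a prior
    association study instead of the internal scan.
    """
    df = pd.read_csv(path, sep="\t", names=["snp_id", "p"], header=None)
    return pd.Series(
        df["p"].to_numpy(dtype=float), index=pd.Index(df["snp_id"], name="snp_id")
    )


def read_knowledge_base(path: str) -> pd.DataFrame:
    """3-column TSV: gene1, gene2, source."""
    return pd.read_csv(
        path, sep="\t", names=["gene1", "gene2", "source"], header=None,
        dtype=str,
    )
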