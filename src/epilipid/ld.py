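"""Linkage-disequilibrium utilities: pairwise r², pruning, proxies, signal sets.

r² here is the composite (genotype-dosage) squared Pearson correlation
computed over samples complete at both SNPs — the phase-free quantity
PLINK reports for unphased data.  It drives three thresholds in the
pipeline: pruning (r² > 0.6), proxy discovery (r² > 0.8) and signal-set
grouping of replicating models (r² > 0.1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .genotypes import GenotypeMatrix
from .models import SnpPairModel

logger = logging.getLogger(__name__)


@dataclass
class LDMatrix:
    """Symmetric pairwise r² with complete-pair counts."""

    snp_ids: np.ndarray
    r2: np.ndarray
    n_pairs_used: np.ndarray

    def lookup(self, a: str, b: str) -> float:
        idx = {s: i for i, s in enumerate(self.snp_ids)}
        return float(self.r2[idx[a], idx[b]])

    def to_frame(self) -> pd.DataFrame:
        iu = np.triu_indices(len(self.snp_ids), k=1)
        return pd.DataFrame(
            {
                "snp1": self.snp_ids[iu[0]],
                "snp2": self.snp_ids[iu[1]],
                "r2": self.r2[iu],
                "n": self.n_pairs_used[iu].astype(int),
            }
        )


def pairwise_r2(g1: np.ndarray, g2: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Computed over samples non-missing in both.  Returns NaN (with a
    warning) when fewer than two complete pairs exist or either SNP is
    monomorphic on the complete pairs.
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    ok = ~np.isnan(g1) & ~np.isnan(g2)
    x, y = g1[ok], g2[ok]
    if len(x) < 2 or x.std() == 0 or y.std() == 0:
        logger.warning("r2 undefined: monomorphic or <2 complete pairs")
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def ld_matrix(G: GenotypeMatrix) -> LDMatrix:
    """All-pairs r² over pairwise-complete samples, vectorised.

    Pairwise-complete moments are assembled from masked matrix products,
    so missingness patterns may differ per pair.
    """
    D = G.dosages
    M = (~np.isnan(D)).astype(float)
    X = np.nan_to_num(D, nan=0.0)
    n = M.T @ M                    # complete pairs per SNP pair
    Sx = X.T @ M                   # sum of x over pairs complete in both
    Sxx = (X * X).T @ M
    Sxy = X.T @ X
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * Sxy - Sx * Sx.T
        varx = n * Sxx - Sx**2
        denom = varx * varx.T
        r2 = np.where(denom > 0, cov**2 / np.where(denom > 0, denom, 1.0), np.nan)
    r2 = np.clip(r2, 0.0, 1.0)
    np.fill_diagonal(r2, np.where(np.diag(varx) > 0, 1.0, np.nan))
    return LDMatrix(G.snp_ids, r2, n.astype(int))


def ld_prune(
    G: GenotypeMatrix,
    threshold: float = 0.6,
    order: np.ndarray | None = None,
    ld: LDMatrix | None = None,
) -> list:
    """Greedy LD pruning: retained SNP IDs with no pair above ``threshold``.

    SNPs are scanned in ``order`` (default genomic position, ties broken
    by keeping the higher-MAF SNP first); a SNP is dropped if its r²
    with any already-retained SNP exceeds the threshold (strict).
    """
    if ld is None:
        ld = ld_matrix(G)
    idx = {s: i for i, s in enumerate(ld.snp_ids)}
    if order is None:
        maf = G.maf()
        keys = list(
            zip(G.snps["chrom"].astype(str), G.snps["pos"], -maf, G.snp_ids)
        )
        order = G.snp_ids[np.array(sorted(range(G.n_snps), key=keys.__getitem__))]
    retained: list = []
    for snp in order:
        i = idx[snp]
        r2_row = ld.r2[i]
        if all(
            np.isnan(r2_row[idx[r]]) or r2_row[idx[r]] <= threshold
            for r in retained
        ):
            retained.append(snp)
    # post-condition: no retained pair above the threshold
    ridx = [idx[s] for s in retained]
    sub = ld.r2[np.ix_(ridx, ridx)].copy()
    np.fill_diagonal(sub, 0.0)
    assert not np.any(sub[~np.isnan(sub)] > threshold)
    return retained


def find_proxies(
    G: GenotypeMatrix,
    snp: str,
    threshold: float = 0.8,
    ld: LDMatrix | None = None,
) -> list:
    """SNPs in high LD (r² strictly above ``threshold``) with ``snp``."""
    if ld is None:
        ld = ld_matrix(G)
    if snp not in set(ld.snp_ids):
        raise KeyError(f"unknown SNP id: {snp!r}")
    idx = {s: i for i, s in enumerate(ld.snp_ids)}
    row = ld.r2[idx[snp]]
    return [
        s for s in ld.snp_ids if s != snp and not np.isnan(row[idx[s]]) and row[idx[s]] > threshold
    ]


def proxy_models(
    model: SnpPairModel, proxies_a: list, proxies_b: list
) -> list[SnpPairModel]:
    """Cartesian proxy expansion of one original SNP-pair model.

    All pairs from ({a} U proxies_a) x ({b} U proxies_b), minus the
    original pair itself and degenerate same-SNP pairs; each tagged with
    the original model's key so replication can collapse the signal.
    """
    if model.snp_a == model.snp_b:
        raise ValueError("degenerate model: identical SNPs")
    side_a = [model.snp_a] + [p for p in proxies_a if p != model.snp_a]
    side_b = [model.snp_b] + [p for p in proxies_b if p != model.snp_b]
    out, seen = [], {model.key()}
    for a in side_a:
        for b in side_b:
            if a == b:
                continue
            m = SnpPairModel(a, b, provenance=f"proxy-of:{model.key()}")
            if m.key() in seen:
                continue
            seen.add(m.key())
            out.append(m)
    return out


def signal_sets(
    snps: list, ld: LDMatrix, threshold: float = 0.1
) -> list[list]:
    """Partition SNPs into single-linkage components of the r² graph.

    Edges join SNPs with r² strictly above ``threshold``; components are
    the LD "signal sets" used to decide whether separate replicating
    models represent one underlying interaction signal.
    """
    snps = list(snps)
    idx = {s: i for i, s in enumerate(ld.snp_ids)}
    k = len(snps)
    rows, cols = [], []
    for i in range(k):
        for j in range(i + 1, k):
            r2 = ld.r2[idx[snps[i]], idx[snps[j]]]
            if not np.isnan(r2) and r2 > threshold:
                rows += [i, j]
                cols += [j, i]
    graph = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(k, k))
    n_comp, labels = connected_components(graph, directed=False)
    comps: list[list] = [[] for _ in range(n_comp)]
    for s, lab in zip(snps, labels):
        comps[lab].append(s)
    return sorted(comps, key=lambda c: (-len(c), str(c[0])))


def same_set_check(
    models: list[SnpPairModel], ld: LDMatrix, threshold: float = 0.1
) -> pd.DataFrame:
    """Within-model correlation check: do a model's SNPs share a signal set?

    Flags models whose two SNPs land in the same single-linkage
    component (i.e. are correlated at r² above ``threshold``), which
    would suggest the interaction term is inflated by LD.
    """
    snps = sorted({s for m in models for s in (m.snp_a, m.snp_b)}, key=str)
    comps = signal_sets(snps, ld, threshold)
    label = {s: i for i, comp in enumerate(comps) for s in comp}
    return pd.DataFrame(
        {
            "snp_a": [m.snp_a for m in models],
            "snp_b": [m.snp_b for m in models],
            "same_signal_set": [
                label[m.snp_a] == label[m.snp_b] for m in models
            ],
        }
    )
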