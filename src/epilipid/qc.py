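"""Discovery-phase genotype and sample quality control.

Pipeline order is fixed: SNP call rate -> Hardy-Weinberg -> sample call
rate -> relatedness (pi-hat) -> per-analysis MAF.  Every step records
enough in the :class:`QCReport` that replaying its surviving ID lists on
the input reproduces the output bit-exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

logger = logging.getLogger(__name__)

#: Relative slack when comparing outcome probabilities in the exact HWE
#: test, so that exact rational ties survive float rounding.
_HWE_TIE_RTOL = 1e-12


@dataclass
class QCReport:
    """Bookkeeping for one QC pass: what was removed, at which threshold."""

    thresholds: dict = field(default_factory=dict)
    steps: list = field(default_factory=list)
    removed_snps: dict = field(default_factory=dict)      # step -> list of IDs
    removed_samples: dict = field(default_factory=dict)   # step -> list of IDs
    kept_snps: list = field(default_factory=list)
    kept_samples: list = field(default_factory=list)

    @property
    def snps_removed_callrate(self) -> int:
        return len(self.removed_snps.get("snp_call_rate", []))

    @property
    def snps_removed_hwe(self) -> int:
        return len(self.removed_snps.get("hwe", []))

    @property
    def snps_removed_maf(self) -> int:
        return len(self.removed_snps.get("maf", []))

    @property
    def samples_removed_callrate(self) -> int:
        return len(self.removed_samples.get("sample_call_rate", []))

    @property
    def samples_removed_relatedness(self) -> int:
        return len(self.removed_samples.get("relatedness", []))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("snps_removed_callrate", self.snps_removed_callrate),
            ("snps_removed_hwe", self.snps_removed_hwe),
            ("snps_removed_maf", self.snps_removed_maf),
            ("samples_removed_callrate", self.samples_removed_callrate),
            ("samples_removed_relatedness", self.samples_removed_relatedness),
        ]
        rows += [(f"threshold_{k}", v) for k, v in self.thresholds.items()]
        return pd.DataFrame(rows, columns=["metric", "value"])


def apply_report(G: GenotypeMatrix, report: QCReport) -> GenotypeMatrix:
    """Replay a QCReport's surviving ID lists on the original input."""
    out = G.subset_snps(np.asarray(report.kept_snps, dtype=object))
    return out.subset_samples(np.asarray(report.kept_samples, dtype=object))


# ------------------------------------------------------------------ filters
def snp_call_rate_filter(
    G: GenotypeMatrix, min_call_rate: float = 0.95
) -> tuple[GenotypeMatrix, list]:
    """Retain SNPs with call rate >= ``min_call_rate`` (inclusive)."""
    if not 0 < min_call_rate <= 1:
        raise ValueError("min_call_rate must be in (0, 1]")
    if G.n_snps == 0 or G.n_samples == 0:
        raise ValueError("empty genotype matrix")
    keep = G.call_rate_per_snp() >= min_call_rate
    removed = list(G.snp_ids[~keep])
    return G.subset_snps(keep), removed


def sample_call_rate_filter(
    G: GenotypeMatrix, min_call_rate: float = 0.90
) -> tuple[GenotypeMatrix, list]:
    """Retain samples with call rate >= ``min_call_rate`` (inclusive)."""
    if not 0 < min_call_rate <= 1:
        raise ValueError("min_call_rate must be in (0, 1]")
    if G.n_snps == 0 or G.n_samples == 0:
        raise ValueError("empty genotype matrix")
    keep = G.call_rate_per_sample() >= min_call_rate
    removed = list(G.sample_ids[~keep])
    return G.subset_samples(keep), removed


def maf_filter(
    G: GenotypeMatrix, min_maf: float = 0.05
) -> tuple[GenotypeMatrix, list]:
    """Retain SNPs with folded MAF >= ``min_maf`` (inclusive).

    SNPs with no non-missing calls have undefined MAF and are removed
    with a warning.
    """
    if not 0 <= min_maf <= 0.5:
        raise ValueError("min_maf must be in [0, 0.5]")
    maf = G.maf()
    no_calls = np.isnan(maf)
    if np.any(no_calls):
        logger.warning(
            "%d SNP(s) with zero non-missing calls removed in MAF filter",
            int(no_calls.sum()),
        )
    keep = ~no_calls & (maf >= min_maf)
    removed = list(G.snp_ids[~keep])
    return G.subset_snps(keep), removed


# ------------------------------------------------------- Hardy-Weinberg test
def _hwe_het_probs(n: int, n_minor: int) -> tuple[np.ndarray, np.ndarray]:
    """Conditional distribution of the heterozygote count.

    Given ``n`` diploid individuals carrying ``n_minor`` copies of the
    minor allele, returns the possible heterozygote counts (same parity
    as ``n_minor``) and their probabilities under random allele pairing.
    Computed on the log scale for stability at large ``n``.
    """
    n_major = 2 * n - n_minor
    h_min = n_minor % 2
    h_max = min(n_minor, n_major)
    hets = np.arange(h_min, h_max + 1, 2)
    # log A(h+2) - log A(h) = log[ (n_minor-h)(n_major-h) / ((h+1)(h+2)) ]
    logw = np.zeros(len(hets))
    for i in range(1, len(hets)):
        h = hets[i - 1]
        logw[i] = logw[i - 1] + np.log(
            (n_minor - h) * (n_major - h) / ((h + 1.0) * (h + 2.0))
        )
    w = np.exp(logw - logw.max())
    return hets, w / w.sum()


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact test of Hardy-Weinberg equilibrium.

    Conditions on the observed allele counts and sums the probabilities
    of all heterozygote counts at least as improbable as the observed
    one (Levene-Haldane conditional distribution, two-sided by outcome
    probability).  Returns a p-value in (0, 1].
    """
    counts = (n_AA, n_Aa, n_aa)
    if any(c < 0 for c in counts):
        raise ValueError("genotype counts must be nonnegative")
    n = sum(counts)
    if n == 0:
        raise ValueError("at least one genotype call is required")
    n_a = n_Aa + 2 * n_aa
    n_minor = min(n_a, 2 * n - n_a)
    if n_minor == 0:
        return 1.0  # monomorphic: one possible configuration
    hets, probs = _hwe_het_probs(n, n_minor)
    p_obs = probs[np.searchsorted(hets, n_Aa)]
    p = probs[probs <= p_obs * (1.0 + _HWE_TIE_RTOL)].sum()
    return float(min(p, 1.0))


def hwe_filter(
    G: GenotypeMatrix, max_p: float = 1e-7
) -> tuple[GenotypeMatrix, list]:
    """Remove SNPs failing the exact HWE test at p < ``max_p`` (strict)."""
    keep = np.ones(G.n_snps, dtype=bool)
    for j, snp in enumerate(G.snp_ids):
        n0, n1, n2 = G.genotype_counts(snp)
        if n0 + n1 + n2 == 0:
            continue  # no calls: left to the call-rate / MAF filters
        keep[j] = hwe_exact_test(n0, n1, n2) >= max_p
    removed = list(G.snp_ids[~keep])
    return G.subset_snps(keep), removed


# ------------------------------------------------------------- relatedness
def estimate_ibd_pihat(G: GenotypeMatrix) -> pd.DataFrame:
    """Method-of-moments IBD estimation for every sample pair.

    For each pair, observed identity-by-state (IBS) counts are compared
    with their expectations under allele frequencies to estimate
    P(IBD=0/1/2); pi-hat = P(IBD=1)/2 + P(IBD=2).  Returns a frame with
    columns ``sample_1, sample_2, pihat_raw, pihat, n_snps`` where
    ``pihat`` is clamped to [0, 1].
    """
    if G.n_samples < 2:
        raise ValueError("need at least two samples")
    D = G.dosages
    p = G.allele_freq()
    informative = ~np.isnan(p) & (p > 0) & (p < 1)
    if informative.sum() < 50:
        logger.warning(
            "only %d informative SNPs: pi-hat estimates will be unstable",
            int(informative.sum()),
        )
    D = D[:, informative]
    p = p[informative]
    q = 1.0 - p

    M = (~np.isnan(D)).astype(float)
    A = [np.where(np.nan_to_num(D, nan=-1.0) == d, 1.0, 0.0) for d in (0.0, 1.0, 2.0)]
    n_complete = M @ M.T
    N2 = A[0] @ A[0].T + A[1] @ A[1].T + A[2] @ A[2].T
    N0 = A[0] @ A[2].T + A[2] @ A[0].T
    N1 = n_complete - N0 - N2

    # per-SNP IBS-state expectations conditional on IBD state
    e0_ibs0 = 2 * p**2 * q**2
    e0_ibs1 = 4 * p**3 * q + 4 * p * q**3
    e0_ibs2 = p**4 + q**4 + 4 * p**2 * q**2
    e1_ibs1 = 2 * p * q
    e1_ibs2 = p**2 + q**2

    def pair_sum(e):
        return (M * e) @ M.T

    S0_0, S0_1, S0_2 = pair_sum(e0_ibs0), pair_sum(e0_ibs1), pair_sum(e0_ibs2)
    S1_1, S1_2 = pair_sum(e1_ibs1), pair_sum(e1_ibs2)

    with np.errstate(divide="ignore", invalid="ignore"):
        k0 = N0 / S0_0
        k1 = (N1 - k0 * S0_1) / S1_1
        k2 = (N2 - k0 * S0_2 - k1 * S1_2) / n_complete
    pihat_raw = k1 / 2.0 + k2

    iu = np.triu_indices(G.n_samples, k=1)
    ids = G.sample_ids
    return pd.DataFrame(
        {
            "sample_1": ids[iu[0]],
            "sample_2": ids[iu[1]],
            "pihat_raw": pihat_raw[iu],
            "pihat": np.clip(pihat_raw[iu], 0.0, 1.0),
            "n_snps": n_complete[iu].astype(int),
        }
    )


def remove_related(
    G: GenotypeMatrix, pihat_table: pd.DataFrame, threshold: float = 0.3
) -> tuple[GenotypeMatrix, list]:
    """Greedy removal of one member of each over-threshold pair.

    Iteratively drops the sample in the most pairs with pi-hat above
    ``threshold`` (ties: lower call rate first, then lexicographic ID)
    until no related pair remains.
    """
    over = pihat_table[pihat_table["pihat"] > threshold]
    edges = {
        frozenset((a, b)) for a, b in zip(over["sample_1"], over["sample_2"])
    }
    call_rate = dict(zip(G.sample_ids, G.call_rate_per_sample()))
    removed: list = []
    while edges:
        degree: dict = {}
        for e in edges:
            for s in e:
                degree[s] = degree.get(s, 0) + 1
        worst = max(
            degree, key=lambda s: (degree[s], -call_rate[s], _neg_lex(s))
        )
        removed.append(worst)
        edges = {e for e in edges if worst not in e}
    keep = ~np.isin(G.sample_ids, removed)
    return G.subset_samples(keep), sorted(removed, key=str)


class _neg_lex(str):
    """Reverses lexicographic order inside a max() key (lower ID wins ties)."""

    def __lt__(self, other):  # max picks the lexicographically smallest
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)


# --------------------------------------------------------------------- PCA
def compute_pcs(G: GenotypeMatrix, k: int = 10) -> pd.DataFrame:
    """Top-``k`` principal component scores of the dosage matrix.

    Missing dosages are mean-imputed (PCA only); SNP columns are
    centred and scaled to unit variance, zero-variance SNPs dropped.
    Sign convention: the largest-magnitude loading of each component is
    made positive, so scores are deterministic.
    """
    if k >= min(G.n_samples, G.n_snps):
        raise ValueError("k must be smaller than both matrix dimensions")
    X = G.dosages.copy()
    means = np.nanmean(X, axis=0)
    nan_r, nan_c = np.nonzero(np.isnan(X))
    X[nan_r, nan_c] = means[nan_c]
    X -= X.mean(axis=0)
    sd = X.std(axis=0)
    keep = sd > 0
    X = X[:, keep] / sd[keep]
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    flip = np.sign(Vt[np.arange(Vt.shape[0]), np.abs(Vt).argmax(axis=1)])
    scores = (U * S) * flip
    return pd.DataFrame(
        scores[:, :k],
        index=pd.Index(G.sample_ids, name="sample_id"),
        columns=[f"PC{i + 1}" for i in range(k)],
    )


# ----------------------------------------------------------------- pipeline
def run_qc(
    G: GenotypeMatrix,
    snp_call_rate: float = 0.95,
    hwe_p: float = 1e-7,
    sample_call_rate: float = 0.90,
    pihat: float = 0.3,
    maf: float | None = None,
) -> tuple[GenotypeMatrix, QCReport]:
    """Full discovery QC pass in the fixed pipeline order.

    ``maf=None`` skips the MAF step (it is applied per-analysis, after
    relatedness removal, when a threshold is given).
    """
    report = QCReport(
        thresholds={
            "snp_call_rate": snp_call_rate,
            "hwe_p": hwe_p,
            "sample_call_rate": sample_call_rate,
            "pihat": pihat,
            "maf": maf,
        }
    )
    G, removed = snp_call_rate_filter(G, snp_call_rate)
    report.steps.append("snp_call_rate")
    report.removed_snps["snp_call_rate"] = removed

    G, removed = hwe_filter(G, hwe_p)
    report.steps.append("hwe")
    report.removed_snps["hwe"] = removed

    G, removed = sample_call_rate_filter(G, sample_call_rate)
    report.steps.append("sample_call_rate")
    report.removed_samples["sample_call_rate"] = removed

    maf_vals = G.maf()
    n_informative = int(np.sum(~np.isnan(maf_vals) & (maf_vals > 0)))
    if G.n_samples >= 2 and n_informative >= 50:
        table = estimate_ibd_pihat(G)
        G, removed = remove_related(G, table, pihat)
        report.steps.append("relatedness")
        report.removed_samples["relatedness"] = removed
    else:
        # too few polymorphic SNPs to estimate IBD: removing samples on
        # such estimates would be arbitrary, so the step is skipped
        logger.warning(
            "relatedness step skipped: %d informative SNP(s)", n_informative
        )
        report.steps.append("relatedness_skipped")

    if maf is not None:
        G, removed = maf_filter(G, maf)
        report.steps.append("maf")
        report.removed_snps["maf"] = removed

    report.kept_snps = list(G.snp_ids)
    report.kept_samples = list(G.sample_ids)
    return G, report
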