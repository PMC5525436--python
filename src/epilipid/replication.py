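"""Multi-cohort replication of discovery interaction models.

Discovery models passing p < 0.001 are carried, together with their
LD-proxy expansions, into each replication cohort.  The per-arm
replication threshold is a Bonferroni-like correction of alpha = 0.05
for the number of *original* models and the number of replication
cohorts; an original model and its proxies form one LD "signal" that
counts at most once per cohort.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .interaction import STATUS_OK, InteractionResult, batch_test
from .models import SnpPairModel

logger = logging.getLogger(__name__)


def select_discovery_models(
    results: list[InteractionResult],
    p_threshold: float = 0.001,
    bonferroni_alpha: float | None = None,
) -> list[InteractionResult]:
    """Models passing the discovery cut, ranked ascending by LRT p.

    Selection keeps ``status == ok`` results with ``p_lrt`` strictly
    below the threshold.  The default is the flat p < 0.001 cut;
    passing ``bonferroni_alpha`` instead divides it by the number of
    models tested.  Ties in p are broken by canonical model key, so
    ranks are deterministic.
    """
    threshold = p_threshold
    if bonferroni_alpha is not None:
        threshold = bonferroni_alpha / max(len(results), 1)
    passing = [
        r
        for r in results
        if r.status == STATUS_OK and not np.isnan(r.p_lrt) and r.p_lrt < threshold
    ]
    return sorted(passing, key=lambda r: (r.p_lrt, r.model.key()))


def _one_sig_fig(x: float) -> str:
    """Plain-decimal rendering of x rounded to one significant figure."""
    e = math.floor(math.log10(x))
    m = round(x / 10**e)
    if m == 10:
        m, e = 1, e + 1
    if e >= 0:
        return str(m * 10**e)
    return "0." + "0" * (-e - 1) + str(m)


def replication_threshold(
    n_original_models: int, n_cohorts: int = 10, alpha: float = 0.05
) -> tuple[float, str]:
    """Bonferroni-like replication threshold and its printed form.

    threshold = alpha / (n_original_models * n_cohorts), correcting for
    the original (non-proxy) models of the arm and the replication
    cohorts.  The display string rounds to one significant figure (the
    convention of the printed per-trait thresholds); comparisons always
    use the unrounded value.
    """
    if n_original_models < 1 or n_cohorts < 1:
        raise ValueError("model and cohort counts must be >= 1")
    threshold = alpha / (n_original_models * n_cohorts)
    return threshold, _one_sig_fig(threshold)


def test_models_in_cohort(
    models: list[SnpPairModel],
    cohort,
    trait: str,
    covariates: list[str] | None = None,
) -> tuple[list[InteractionResult], list[SnpPairModel]]:
    """Test originals + proxies in one cohort, skipping absent SNPs.

    Models whose SNPs are not on the cohort's array are skipped and
    returned separately (with a log line), mirroring proxy SNPs missing
    from a replication chip.
    """
    present = set(cohort.genotypes.snp_ids)
    testable = [m for m in models if m.snp_a in present and m.snp_b in present]
    skipped = [m for m in models if m not in testable]
    if skipped:
        logger.info(
            "cohort %s: %d model(s) skipped (SNP absent)",
            getattr(cohort, "name", "?"),
            len(skipped),
        )
    return batch_test(testable, cohort, trait, covariates), skipped


@dataclass
class ReplicationSummary:
    """One LD signal: its discovery stats and per-cohort replication."""

    signal_id: str
    rank: int
    original_model: SnpPairModel
    proxy_models: list = field(default_factory=list)
    discovery: InteractionResult | None = None
    per_cohort: dict = field(default_factory=dict)   # cohort -> lead result
    replicating_cohorts: list = field(default_factory=list)
    direction_concordant: dict = field(default_factory=dict)
    threshold_used: float = np.nan

    @property
    def n_replicating(self) -> int:
        return len(self.replicating_cohorts)

    def best_replication(self) -> InteractionResult | None:
        """Lead result among replicating cohorts (lowest p)."""
        leads = [self.per_cohort[c] for c in self.replicating_cohorts]
        if not leads:
            return None
        return min(leads, key=lambda r: r.p_lrt)


def collapse_signals(
    discovery_selection: list[InteractionResult],
    per_cohort_results: dict[str, list[InteractionResult]],
    threshold: float,
) -> list[ReplicationSummary]:
    """Group originals with their proxies and count replication per signal.

    A cohort replicates a signal when *any* member (original or proxy)
    attains p below the threshold; only one member is counted, and the
    lowest-p member is recorded as the cohort's lead together with
    whether its interaction beta matches the discovery sign.
    """
    originals = {r.model.key(): r for r in discovery_selection}
    summaries = []
    for rank, disc in enumerate(discovery_selection, start=1):
        key = disc.model.key()
        summaries.append(
            ReplicationSummary(
                signal_id=key,
                rank=rank,
                original_model=disc.model,
                discovery=disc,
                threshold_used=threshold,
            )
        )
    by_key = {s.signal_id: s for s in summaries}

    for cohort, results in sorted(per_cohort_results.items()):
        grouped: dict[str, list[InteractionResult]] = {}
        for r in results:
            orig = r.model.original_key
            if orig not in originals:
                raise ValueError(
                    f"orphan proxy model {r.model.key()!r}: no original {orig!r}"
                )
            grouped.setdefault(orig, []).append(r)
            if r.model.is_proxy and r.model.key() not in by_key[orig].proxy_models:
                by_key[orig].proxy_models.append(r.model.key())
        for orig, members in grouped.items():
            usable = [
                m for m in members
                if m.status == STATUS_OK and not np.isnan(m.p_lrt)
            ]
            if not usable:
                continue
            lead = min(usable, key=lambda r: (r.p_lrt, r.model.key()))
            summ = by_key[orig]
            summ.per_cohort[cohort] = lead
            summ.direction_concordant[cohort] = np.sign(
                lead.beta_interaction
            ) == np.sign(summ.discovery.beta_interaction)
            if lead.p_lrt < threshold:
                summ.replicating_cohorts.append(cohort)

    for s in summaries:
        assert s.n_replicating <= len(per_cohort_results)
    return summaries


SUMMARY_COLUMNS = [
    "rank", "snp_1", "snp_2", "locus_1", "locus_2", "disc_beta", "disc_lrt_p",
    "rep_beta", "rep_lrt_p", "rep_cohorts", "n_replicating",
]


def summarize(
    summaries: list[ReplicationSummary], min_cohorts: int = 1
) -> pd.DataFrame:
    """Report table of signals replicating in >= ``min_cohorts`` cohorts.

    Columns follow the discovery-rank / SNPs / loci / discovery and
    best-replication beta and LRT p / replicating-cohort-labels layout;
    rows are sorted by discovery rank.
    """
    rows = []
    for s in sorted(summaries, key=lambda x: x.rank):
        if s.n_replicating < min_cohorts:
            continue
        best = s.best_replication()
        rows.append(
            (
                s.rank,
                s.original_model.snp_a,
                s.original_model.snp_b,
                s.original_model.gene_a,
                s.original_model.gene_b,
                s.discovery.beta_interaction,
                s.discovery.p_lrt,
                best.beta_interaction if best else np.nan,
                best.p_lrt if best else np.nan,
                ",".join(s.replicating_cohorts),
                s.n_replicating,
            )
        )
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def run_replication(
    discovery_selection: list[InteractionResult],
    proxies: dict[str, list[SnpPairModel]],
    cohorts: list,
    trait: str,
    n_cohorts_for_threshold: int | None = None,
    alpha: float = 0.05,
    covariates: list[str] | None = None,
) -> tuple[list[ReplicationSummary], float]:
    """Convenience driver: threshold, per-cohort testing, collapsing.

    ``proxies`` maps each original model key to its proxy models; the
    threshold divides alpha by the count of original models and the
    number of replication cohorts (the cohort list length by default).
    """
    if n_cohorts_for_threshold is None:
        n_cohorts_for_threshold = len(cohorts)
    threshold, _ = replication_threshold(
        max(len(discovery_selection), 1), n_cohorts_for_threshold, alpha
    )
    all_models: list[SnpPairModel] = [r.model for r in discovery_selection]
    for r in discovery_selection:
        all_models.extend(proxies.get(r.model.key(), []))
    per_cohort: dict[str, list[InteractionResult]] = {}
    for cohort in cohorts:
        results, _skipped = test_models_in_cohort(
            all_models, cohort, trait, covariates
        )
        per_cohort[cohort.name] = results
    return collapse_signals(discovery_selection, per_cohort, threshold), threshold
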