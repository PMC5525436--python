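"""Likelihood-ratio test for pairwise multiplicative SNP-SNP interaction.

For each candidate pair the reduced model

    y = a + b1*SNP1 + b2*SNP2 + covariates

is compared with the full model that adds the multiplicative term
b19*(SNP1*SNP2).  Both are ordinary least squares on the identical
complete-case sample; the statistic is Lambda = 2(l_full - l_reduced)
= n*ln(RSS_reduced/RSS_full), referred to chi-square with 1 df.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix
from .models import SnpPairModel
from .regression import (
    STATUS_COLLINEAR,
    STATUS_INSUFFICIENT_N,
    STATUS_OK,
    LinearFit,
    fit_linear,
)

STATUS_MONOMORPHIC = "monomorphic"

#: Covariate columns of the standard adjustment set: age, BMI, lipid
#: medication, type-2 diabetes, smoking, sex and 10 principal components.
DEFAULT_COVARIATES = ["age", "bmi", "medication", "t2d", "smoking", "sex"] + [
    f"PC{i}" for i in range(1, 11)
]

#: Floor keeping reported LRT p-values in (0, 1] even for perfect fits.
_P_FLOOR = 1e-300


@dataclass
class InteractionResult:
    """One fitted SNP-SNP model: interaction estimate and LRT."""

    model: SnpPairModel
    beta_interaction: float = np.nan
    se_interaction: float = np.nan
    beta_main_a: float = np.nan
    beta_main_b: float = np.nan
    lrt_stat: float = np.nan
    p_lrt: float = np.nan
    r2_full: float = np.nan
    r2_reduced: float = np.nan
    diff_r2: float = np.nan
    n_used: int = 0
    status: str = STATUS_OK


def _covariate_matrix(X: pd.DataFrame, covariates: list[str] | None) -> np.ndarray:
    cols = covariates if covariates is not None else [
        c for c in DEFAULT_COVARIATES if c in X.columns
    ]
    return X[cols].to_numpy(dtype=float)


def lrt_interaction(
    model: SnpPairModel,
    G: GenotypeMatrix,
    y: np.ndarray,
    X: pd.DataFrame,
    covariates: list[str] | None = None,
) -> InteractionResult:
    """Fit reduced and full models for one SNP pair and test b19 = 0.

    Rows missing the trait, either dosage, or any covariate are dropped
    once, so both fits see the identical sample.  Degenerate inputs are
    reported through ``status`` (monomorphic / collinear /
    insufficient_n) rather than raised.
    """
    res = InteractionResult(model=model)
    g_a = G.dosage_vector(model.snp_a)
    g_b = G.dosage_vector(model.snp_b)
    y = np.asarray(y, dtype=float)
    covs = _covariate_matrix(X, covariates)
    ok = (
        ~np.isnan(y)
        & ~np.isnan(g_a)
        & ~np.isnan(g_b)
        & ~np.isnan(covs).any(axis=1)
    )
    n = int(ok.sum())
    res.n_used = n
    ga, gb, yy, cc = g_a[ok], g_b[ok], y[ok], covs[ok]
    n_params_full = 4 + cc.shape[1]
    if n <= n_params_full:
        res.status = STATUS_INSUFFICIENT_N
        return res
    if ga.std() == 0 or gb.std() == 0:
        res.status = STATUS_MONOMORPHIC
        return res

    ones = np.ones(n)
    reduced = fit_linear(yy, np.column_stack([ones, ga, gb, cc]))
    full = fit_linear(yy, np.column_stack([ones, ga, gb, cc, ga * gb]))
    if STATUS_COLLINEAR in (reduced.status, full.status):
        res.status = STATUS_COLLINEAR
        return res
    if STATUS_INSUFFICIENT_N in (reduced.status, full.status):
        res.status = STATUS_INSUFFICIENT_N
        return res
    _fill_lrt(res, reduced, full)
    return res


def _fill_lrt(res: InteractionResult, reduced: LinearFit, full: LinearFit) -> None:
    n = full.n
    res.beta_main_a = full.coef[1]
    res.beta_main_b = full.coef[2]
    res.beta_interaction = full.coef[-1]
    res.se_interaction = full.se[-1]
    res.r2_full = full.r2
    res.r2_reduced = reduced.r2
    res.diff_r2 = full.r2 - reduced.r2
    if full.perfect_fit:
        # zero residual in the full model: Lambda unbounded unless the
        # reduced model is also a perfect fit (then nothing to test)
        res.lrt_stat = 0.0 if reduced.perfect_fit else np.inf
    else:
        res.lrt_stat = max(n * np.log(reduced.rss / full.rss), 0.0)
    res.p_lrt = max(float(stats.chi2.sf(res.lrt_stat, df=1)), _P_FLOOR)


RESULT_COLUMNS = [
    "trait", "snp_a", "snp_b", "provenance", "n_used", "beta_int", "se_int",
    "beta_main_a", "beta_main_b", "lrt_stat", "p_lrt", "r2_full",
    "r2_reduced", "diff_r2", "status",
]


def results_to_frame(
    results: list[InteractionResult], trait: str
) -> pd.DataFrame:
    rows = [
        (
            trait, r.model.snp_a, r.model.snp_b, r.model.provenance, r.n_used,
            r.beta_interaction, r.se_interaction, r.beta_main_a, r.beta_main_b,
            r.lrt_stat, r.p_lrt, r.r2_full, r.r2_reduced, r.diff_r2, r.status,
        )
        for r in results
    ]
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def batch_test(
    models: list[SnpPairModel],
    cohort,
    trait: str,
    covariates: list[str] | None = None,
) -> list[InteractionResult]:
    """Test every model against one cohort's trait, never aborting.

    ``cohort`` is any object exposing ``genotypes`` (GenotypeMatrix),
    ``phenotypes`` (frame with the trait column) and ``covariates``
    (frame); rows are sample-aligned.  Models whose SNPs are absent
    from the cohort are *not* silently skipped here — callers that want
    skipping (replication) filter first.  Output order follows input
    order, so identical inputs give identical tables.
    """
    y = cohort.phenotypes[trait].to_numpy(dtype=float)
    return [
        lrt_interaction(m, cohort.genotypes, y, cohort.covariates, covariates)
        for m in models
    ]
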