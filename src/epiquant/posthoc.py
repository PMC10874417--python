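"""Post-hoc analysis of significant pairs: hierarchical R^2 and LD checks.

The variance partition fits three nested models on one identical
complete-case subset — covariates only, + both additive SNP terms,
+ the multiplicative term — and reports R^2 = 1 - RSS/TSS increments.
Using a single subset guarantees every increment is non-negative.

Linkage disequilibrium is measured as the squared Pearson correlation of
minor-allele counts (composite genotype r^2); no phase information exists
in this pipeline, and at a 0.8 screening threshold the distinction from
haplotype r^2 is immaterial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import (
    MISSING,
    CovariateMatrix,
    GenotypeDataset,
    PhenotypeVector,
    UndefinedStatisticError,
)
from .scan import _base_mask, _genotype_columns


@dataclass(frozen=True)
class VariancePartition:
    """Hierarchical R^2 decomposition for one SNP pair.

    ``r2_cov`` is trait variance explained by covariates alone, ``dr2_add``
    the increment from the two additive genotype terms, ``dr2_int`` the
    increment from their product; ``r2_full`` is their sum.
    """

    r2_cov: float
    dr2_add: float
    dr2_int: float
    r2_full: float
    n_used: int
    df2: int
    invalid: bool = False
    reason: str | None = None

    @property
    def f_from_dr2(self) -> float:
        """Partial F recomputed from the increment: (dr2_int / (1 - r2_full)) * df2."""
        return self.dr2_int / (1.0 - self.r2_full) * self.df2


@dataclass(frozen=True)
class LDResult:
    snp1_index: int
    snp2_index: int
    r2: float


def _r2(y: np.ndarray, X: np.ndarray, tss: float) -> float:
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ beta) ** 2))
    return 1.0 - rss / tss


def variance_partition(
    Y: PhenotypeVector,
    C: CovariateMatrix,
    s1: np.ndarray,
    s2: np.ndarray,
    missing_policy: str = "complete_case",
) -> VariancePartition:
    """Three nested OLS fits on the identical sample subset."""
    base = _base_mask(Y, C)
    g1, keep1 = _genotype_columns(s1, base, missing_policy)
    g2, keep2 = _genotype_columns(s2, base, missing_policy)
    keep = keep1 & keep2
    y = Y.values[base][keep]
    Cm = C.values[base][keep]
    g1, g2 = g1[keep], g2[keep]
    n_used = y.shape[0]
    p_full = 1 + C.k + 3
    df2 = n_used - p_full
    if n_used <= p_full:
        raise ValueError(f"only {n_used} usable samples for {p_full} parameters")

    tss = float(np.sum((y - y.mean()) ** 2))
    if tss <= 1e-16 * n_used * float(np.mean(y * y)):
        raise UndefinedStatisticError("zero trait variance on the fitted subset")

    ones = np.ones(n_used)
    X2 = np.column_stack([ones, Cm, g1, g2, g1 * g2])
    if np.linalg.matrix_rank(X2) < X2.shape[1]:
        return VariancePartition(
            np.nan, np.nan, np.nan, np.nan, n_used, df2,
            invalid=True, reason="rank_deficient_design",
        )

    # One unpivoted QR over the block-ordered design: the squared projections
    # of y on successive Q columns are the per-block explained sums of
    # squares, so each increment is a sum of squares rather than a
    # difference of fitted R^2 values (no cancellation, increments >= 0 by
    # construction, and the interaction increment reproduces the scan F's
    # numerator exactly).
    Q, _ = np.linalg.qr(X2)
    z = Q.T @ y
    k = Cm.shape[1]
    # z[0] is the intercept projection; later Q columns are orthogonal to it,
    # so block sums of z^2 are explained sums of squares about the mean
    ss_cov = float(np.sum(z[1: 1 + k] ** 2))
    ss_add = float(np.sum(z[1 + k: 3 + k] ** 2))
    ss_int = float(z[3 + k] ** 2)
    r2_cov = ss_cov / tss
    dr2_add = ss_add / tss
    dr2_int = ss_int / tss
    return VariancePartition(
        r2_cov, dr2_add, dr2_int, r2_cov + dr2_add + dr2_int, n_used, df2
    )


def whole_sample_r2_cov(Y: PhenotypeVector, C: CovariateMatrix) -> float:
    """Covariate-only R^2 on all phenotype/covariate-complete samples.

    Companion to the per-pair ``r2_cov``: large studies conventionally quote
    a single covariate R^2 computed once on the full sample.
    """
    mask = _base_mask(Y, C)
    y = Y.values[mask]
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss <= 1e-16 * y.size * float(np.mean(y * y)):
        raise UndefinedStatisticError("zero trait variance")
    X0 = np.column_stack([np.ones(mask.sum()), C.values[mask]])
    return _r2(y, X0, tss)


def ld_r2(g1: np.ndarray, g2: np.ndarray) -> float:
    """Squared Pearson correlation of two genotype columns over complete cases."""
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    mask = (g1 != MISSING) & (g2 != MISSING)
    if mask.sum() < 2:
        raise UndefinedStatisticError("LD r^2 needs >= 2 complete-case samples")
    a = g1[mask].astype(np.float64)
    b = g2[mask].astype(np.float64)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise UndefinedStatisticError("LD r^2 undefined for a constant genotype column")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def independence_report(
    snp_set,
    dataset: GenotypeDataset,
    r2_threshold: float = 0.8,
) -> list[LDResult]:
    """Evaluate all within-set genotype correlations; report pairs above threshold.

    An empty return means the set is declared independent at the threshold.
    """
    idx = sorted(int(i) for i in snp_set)
    out: list[LDResult] = []
    for a in range(len(idx)):
        for b in range(a + 1, len(idx)):
            i, j = idx[a], idx[b]
            r2 = ld_r2(dataset.genotypes[:, i], dataset.genotypes[:, j])
            if r2 > r2_threshold:
                out.append(LDResult(i, j, r2))
    return out


def write_ld_report(results: list[LDResult], path, dataset: GenotypeDataset | None = None) -> None:
    rows = [
        {
            "snp1": dataset.snps[r.snp1_index].snp_id if dataset else str(r.snp1_index),
            "snp2": dataset.snps[r.snp2_index].snp_id if dataset else str(r.snp2_index),
            "r2": r.r2,
        }
        for r in results
    ]
    pd.DataFrame(rows, columns=["snp1", "snp2", "r2"]).to_csv(
        path, sep="\t", index=False, float_format="%.12g"
    )
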