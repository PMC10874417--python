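"""Exhaustive pairwise SNP x SNP interaction testing by nested linear models.

For every unordered SNP pair {j, k} the reduced model

    Y ~ 1 + covariates + s_j + s_k

is compared against the full model that adds the multiplicative term
``s_j * s_k`` of the coded minor-allele counts.  The interaction p-value
comes from the partial F statistic with (1, df2) degrees of freedom,
df2 = n_used - (1 + n_cov + 3).

Two code paths produce identical statistics (the package's internal
contract, checked by tests): an exact per-pair least-squares fit
(:func:`interaction_test`) and a blocked engine (:func:`pairwise_scan`)
that residualises covariates once and evaluates all pairs in a tile from
cross-products.  Numerically delicate pairs detected in the blocked path
(near-collinear designs, perfect fits) are re-evaluated through the exact
path so degenerate/invalid flags are authoritative.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .datatypes import (
    MISSING,
    ConfigError,
    CovariateMatrix,
    GenotypeDataset,
    PhenotypeVector,
)

_REL_TOL = 1e-8  # relative tolerance flagging near-singular pair designs


@dataclass(frozen=True)
class InteractionResult:
    """Statistics for one tested SNP pair.

    ``invalid`` marks rank-deficient designs (statistics are NaN);
    ``degenerate`` marks perfect fits (RSS_full = 0, reported F = +inf,
    p = 0).  Invalid pairs are reported, never silently dropped, so the
    pair accounting of a scan is exact.
    """

    snp1_index: int
    snp2_index: int
    beta_int: float
    se_int: float
    F: float
    df2: int
    p: float
    n_used: int
    degenerate: bool = False
    invalid: bool = False
    reason: str | None = None


@dataclass(frozen=True)
class ScanConfig:
    p_threshold: float = 1.0
    block_size: int = 256
    missing_policy: str = "complete_case"  # or "mean_impute"
    same_chrom_min_distance_bp: int | None = None
    cross_chromosome: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.p_threshold <= 1.0:
            raise ConfigError(f"p_threshold {self.p_threshold} outside (0, 1]")
        if self.block_size < 1:
            raise ConfigError("block_size must be >= 1")
        if self.missing_policy not in ("complete_case", "mean_impute"):
            raise ConfigError(f"unknown missing_policy {self.missing_policy!r}")


@dataclass
class ScanResult:
    """Pairs passing the p-value threshold plus all invalid-flagged pairs."""

    significant: list[InteractionResult]
    invalid: list[InteractionResult]
    n_pairs_tested: int
    config: ScanConfig

    def __iter__(self):
        return iter(self.significant)


def bonferroni_threshold(n_snps: int, alpha: float = 0.05) -> float:
    """Family-wise threshold alpha / C(n_snps, 2), with exact integer pair count."""
    if n_snps < 2:
        raise ConfigError("Bonferroni threshold needs at least 2 SNPs")
    if not 0.0 < alpha < 1.0:
        raise ConfigError("alpha must lie in (0, 1)")
    n_pairs = n_snps * (n_snps - 1) // 2
    return alpha / n_pairs


# ---------------------------------------------------------------------------
# Exact per-pair path
# ---------------------------------------------------------------------------

def _base_mask(Y: PhenotypeVector, C: CovariateMatrix) -> np.ndarray:
    if Y.n != C.n:
        raise ValueError("phenotype and covariates not aligned")
    return Y.observed_mask() & C.complete_mask()


def _genotype_columns(s, mask, policy):
    """Return (float column on masked rows, per-pair keep mask within rows)."""
    s = np.asarray(s)
    sm = s[mask].astype(np.float64)
    miss = np.asarray(s)[mask] == MISSING
    if policy == "mean_impute":
        if miss.all():
            raise ValueError("cannot mean-impute an all-missing genotype column")
        sm[miss] = sm[~miss].mean()
        return sm, np.ones(sm.shape[0], dtype=bool)
    return sm, ~miss


def interaction_test(
    Y: PhenotypeVector,
    C: CovariateMatrix,
    s1: np.ndarray,
    s2: np.ndarray,
    missing_policy: str = "complete_case",
    snp1_index: int = 0,
    snp2_index: int = 1,
) -> InteractionResult:
    """Exact nested-OLS interaction F-test for one SNP pair.

    Missing handling: samples with missing phenotype or covariates are
    always dropped; under ``complete_case`` samples missing either genotype
    are dropped too, under ``mean_impute`` genotypes are imputed with the
    column mean over the phenotype/covariate-complete rows.
    """
    base = _base_mask(Y, C)
    g1, keep1 = _genotype_columns(s1, base, missing_policy)
    g2, keep2 = _genotype_columns(s2, base, missing_policy)
    keep = keep1 & keep2
    y = Y.values[base][keep]
    Cm = C.values[base][keep]
    g1, g2 = g1[keep], g2[keep]

    n_used = y.shape[0]
    p_full = 1 + C.k + 3
    if n_used <= p_full:
        raise ValueError(
            f"only {n_used} usable samples for {p_full} parameters"
        )
    ones = np.ones(n_used)
    X_red = np.column_stack([ones, Cm, g1, g2])
    X_full = np.column_stack([X_red, g1 * g2])
    df2 = n_used - p_full

    def _invalid(reason: str) -> InteractionResult:
        return InteractionResult(
            snp1_index, snp2_index, np.nan, np.nan, np.nan, df2, np.nan,
            n_used, invalid=True, reason=reason,
        )

    if np.linalg.matrix_rank(X_full) < p_full:
        return _invalid("rank_deficient_design")

    beta_f, _, _, _ = np.linalg.lstsq(X_full, y, rcond=None)
    rss_full = float(np.sum((y - X_full @ beta_f) ** 2))
    beta_r, _, _, _ = np.linalg.lstsq(X_red, y, rcond=None)
    rss_red = float(np.sum((y - X_red @ beta_r) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss <= 1e-16 * n_used * float(np.mean(y * y)):
        return _invalid("zero_trait_variance")

    beta_int = float(beta_f[-1])
    if rss_full <= 1e-12 * tss:
        return InteractionResult(
            snp1_index, snp2_index, beta_int, 0.0, np.inf, df2, 0.0,
            n_used, degenerate=True, reason="perfect_fit",
        )

    xtx_inv = np.linalg.inv(X_full.T @ X_full)
    sigma2 = rss_full / df2
    se_int = float(np.sqrt(sigma2 * xtx_inv[-1, -1]))
    f_stat = max((rss_red - rss_full) / sigma2, 0.0)
    p_value = float(stats.f.sf(f_stat, 1, df2))
    return InteractionResult(
        snp1_index, snp2_index, beta_int, se_int, float(f_stat), df2,
        p_value, n_used,
    )


# ---------------------------------------------------------------------------
# Blocked engine
# ---------------------------------------------------------------------------

def _pair_allowed_matrix(chrom_i, chrom_j, pos_i, pos_j, config: ScanConfig):
    same = chrom_i[:, None] == chrom_j[None, :]
    allowed = np.ones(same.shape, dtype=bool)
    if not config.cross_chromosome:
        allowed &= same
    if config.same_chrom_min_distance_bp is not None:
        dist = np.abs(pos_i[:, None] - pos_j[None, :])
        allowed &= ~same | (dist >= config.same_chrom_min_distance_bp)
    return allowed


def pairwise_scan(
    dataset: GenotypeDataset,
    Y: PhenotypeVector,
    C: CovariateMatrix,
    config: ScanConfig = ScanConfig(),
) -> ScanResult:
    """Test every admissible unordered SNP pair exactly once.

    Pairs whose two columns carry no missing genotype (always true under
    ``mean_impute``) go through the vectorised tile engine; pairs touching
    a column with missingness fall back to the exact per-pair fit, so
    complete-case subsets are honoured exactly.  The emitted set is
    independent of ``block_size`` and of SNP storage order.
    """
    m = dataset.n_snps
    if Y.n != dataset.n_samples:
        raise ValueError("phenotype not aligned to dataset")
    base = _base_mask(Y, C)
    chroms = dataset.chromosomes
    positions = dataset.positions

    G = dataset.genotypes[base, :]
    y = Y.values[base]
    Cm = C.values[base]
    n = y.shape[0]
    k = C.k
    p_full = 1 + k + 3
    if n <= p_full:
        raise ValueError(f"only {n} usable samples for {p_full} parameters")
    df2 = n - p_full

    if config.missing_policy == "mean_impute":
        Gf = G.astype(np.float64)
        miss = G == MISSING
        if miss.any():
            counts = (~miss).sum(axis=0)
            if np.any(counts == 0):
                raise ValueError("cannot mean-impute an all-missing genotype column")
            means = np.where(miss, 0.0, Gf).sum(axis=0) / counts
            Gf = np.where(miss, means[None, :], Gf)
        clean_cols = np.arange(m)
    else:
        col_has_missing = (G == MISSING).any(axis=0)
        clean_cols = np.flatnonzero(~col_has_missing)
        Gf = G[:, clean_cols].astype(np.float64)

    significant: list[InteractionResult] = []
    invalid: list[InteractionResult] = []
    n_pairs_tested = 0

    def _emit(res: InteractionResult) -> None:
        if res.invalid:
            invalid.append(res)
        elif res.p <= config.p_threshold:
            significant.append(res)

    def _exact(i: int, j: int) -> InteractionResult:
        return interaction_test(
            Y, C, dataset.genotypes[:, i], dataset.genotypes[:, j],
            config.missing_policy, snp1_index=i, snp2_index=j,
        )

    # ---- vectorised path over clean columns ----
    if clean_cols.size >= 2:
        X0 = np.column_stack([np.ones(n), Cm])
        Q, _ = np.linalg.qr(X0)
        yt = y - Q @ (Q.T @ y)
        Gt = Gf - Q @ (Q.T @ Gf)
        yy = float(yt @ yt)
        gy = Gt.T @ yt
        aa = np.einsum("ni,ni->i", Gt, Gt)

        bs = config.block_size
        n_clean = clean_cols.size
        starts = range(0, n_clean, bs)
        blocks = [np.arange(s, min(s + bs, n_clean)) for s in starts]
        for bi, I in enumerate(blocks):
            GfI, GtI = Gf[:, I], Gt[:, I]
            for J in blocks[bi:]:
                GfJ, GtJ = Gf[:, J], Gt[:, J]
                diagonal = J[0] == I[0]

                allowed = _pair_allowed_matrix(
                    chroms[clean_cols[I]], chroms[clean_cols[J]],
                    positions[clean_cols[I]], positions[clean_cols[J]], config,
                )
                if diagonal:
                    allowed &= np.triu(np.ones(allowed.shape, dtype=bool), k=1)
                if not allowed.any():
                    continue
                n_pairs_tested += int(allowed.sum())

                AB = GtI.T @ GtJ
                P = GfI[:, :, None] * GfJ[:, None, :]
                Pt = P - np.einsum("nk,kij->nij", Q, np.einsum("nk,nij->kij", Q, P))
                pp = np.einsum("nij,nij->ij", Pt, Pt)
                py = np.einsum("n,nij->ij", yt, Pt)
                pa = np.einsum("ni,nij->ij", GtI, Pt)
                pb = np.einsum("nj,nij->ij", GtJ, Pt)

                aaI = aa[I][:, None]
                bbJ = aa[J][None, :]
                ayI = gy[I][:, None]
                byJ = gy[J][None, :]
                det = aaI * bbJ - AB**2
                suspicious = det <= _REL_TOL * aaI * bbJ
                with np.errstate(divide="ignore", invalid="ignore"):
                    qf_yy = (ayI**2 * bbJ + byJ**2 * aaI - 2 * ayI * byJ * AB) / det
                    qf_yp = (ayI * pa * bbJ + byJ * pb * aaI - (ayI * pb + byJ * pa) * AB) / det
                    qf_pp = (pa**2 * bbJ + pb**2 * aaI - 2 * pa * pb * AB) / det
                    rss_red = yy - qf_yy
                    upu = pp - qf_pp
                    upe = py - qf_yp
                    suspicious |= upu <= _REL_TOL * pp
                    expl = upe**2 / upu
                    rss_full = rss_red - expl
                    suspicious |= rss_full <= _REL_TOL * yy
                    f_stat = expl * df2 / rss_full
                with np.errstate(invalid="ignore"):
                    p_val = stats.f.sf(np.maximum(f_stat, 0.0), 1, df2)

                hits = allowed & ~suspicious & (p_val <= config.p_threshold)
                for a, b in zip(*np.nonzero(hits)):
                    i = int(clean_cols[I[a]])
                    j = int(clean_cols[J[b]])
                    beta = float(upe[a, b] / upu[a, b])
                    sigma2 = rss_full[a, b] / df2
                    se = float(np.sqrt(sigma2 / upu[a, b]))
                    significant.append(
                        InteractionResult(
                            i, j, beta, se, float(max(f_stat[a, b], 0.0)),
                            df2, float(p_val[a, b]), n,
                        )
                    )
                # delicate pairs go through the exact path for authoritative flags
                for a, b in zip(*np.nonzero(allowed & suspicious)):
                    _emit(_exact(int(clean_cols[I[a]]), int(clean_cols[J[b]])))

    # ---- per-pair path for columns with missing genotypes ----
    if config.missing_policy == "complete_case":
        dirty = np.flatnonzero((G == MISSING).any(axis=0))
        if dirty.size:
            allowed_fn = lambda i, j: bool(
                _pair_allowed_matrix(
                    chroms[[i]], chroms[[j]], positions[[i]], positions[[j]], config
                )[0, 0]
            )
            dirty_set = set(dirty.tolist())
            for i in dirty:
                # pairs (i, j) with j > i; both-dirty pairs are owned by the
                # smaller dirty index
                for j in range(i + 1, m):
                    if not allowed_fn(i, j):
                        continue
                    n_pairs_tested += 1
                    _emit(_exact(int(i), int(j)))
                # pairs (j, i) with a clean j < i
                for j in range(0, i):
                    if j in dirty_set or not allowed_fn(j, i):
                        continue
                    n_pairs_tested += 1
                    _emit(_exact(int(j), int(i)))

    significant.sort(key=lambda r: (r.snp1_index, r.snp2_index))
    invalid.sort(key=lambda r: (r.snp1_index, r.snp2_index))
    return ScanResult(significant, invalid, n_pairs_tested, config)
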