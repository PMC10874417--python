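"""Genotype quality control: call rates, MAF, Hardy-Weinberg, sex check.

The composite :func:`apply_qc` applies the filters in the study's listed
order (SNP call rate -> sample call rate -> MAF -> sex check -> listed
exclusions -> HWE -> autosomes only -> missing phenotype), each computed on
the data surviving earlier steps, and reports per-step attrition.
Relatedness and ancestry-based removals are not computed here; they enter
as a user-supplied sample exclusion list.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    AUTOSOME_MAX,
    MISSING,
    GenotypeDataset,
    PhenotypeVector,
    UndefinedStatisticError,
)


class EmptyFilterResultError(RuntimeError):
    """All items were removed at a named QC step."""

    def __init__(self, step: str, axis: str):
        super().__init__(f"QC step {step!r} removed every remaining {axis}")
        self.step = step


@dataclass(frozen=True)
class QCThresholds:
    """Filter thresholds; defaults follow the study protocol."""

    snp_call_rate_min: float = 0.95
    sample_call_rate_min: float = 0.95
    maf_min: float = 0.05
    hwe_p_min: float = 1e-6
    sex_f_female_max: float = 0.2
    sex_f_male_min: float = 0.8
    autosomes_only: bool = True

    def __post_init__(self) -> None:
        for name in ("snp_call_rate_min", "sample_call_rate_min", "maf_min", "hwe_p_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not self.sex_f_female_max < self.sex_f_male_min:
            raise ValueError("sex F bounds must satisfy female_max < male_min")


@dataclass
class QCReport:
    """Ordered per-step attrition: (step, removed, remaining)."""

    steps: list[tuple[str, int, int]] = field(default_factory=list)
    final_n_samples: int = 0
    final_n_snps: int = 0

    def add(self, step: str, removed: int, remaining: int) -> None:
        self.steps.append((step, removed, remaining))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["step", "removed", "remaining"])

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Per-filter statistics
# ---------------------------------------------------------------------------

def snp_call_rate(dataset: GenotypeDataset) -> np.ndarray:
    """Fraction of non-missing genotypes per SNP."""
    if dataset.n_samples == 0:
        raise UndefinedStatisticError("call rate undefined with zero samples")
    return (dataset.genotypes != MISSING).mean(axis=0)


def sample_call_rate(dataset: GenotypeDataset) -> np.ndarray:
    """Fraction of non-missing genotypes per sample."""
    if dataset.n_snps == 0:
        raise UndefinedStatisticError("call rate undefined with zero SNPs")
    return (dataset.genotypes != MISSING).mean(axis=1)


def minor_allele_frequency(genotype_column: np.ndarray) -> float:
    """Folded allele frequency min(f, 1-f) of one genotype column."""
    g = np.asarray(genotype_column)
    obs = g[g != MISSING]
    if obs.size == 0:
        raise UndefinedStatisticError("MAF undefined: all genotypes missing")
    f = obs.sum() / (2.0 * obs.size)
    return float(min(f, 1.0 - f))


def maf_per_snp(dataset: GenotypeDataset) -> np.ndarray:
    g = dataset.genotypes
    obs = g != MISSING
    n_obs = obs.sum(axis=0)
    if np.any(n_obs == 0):
        raise UndefinedStatisticError("MAF undefined for an all-missing SNP")
    f = np.where(obs, g, 0).sum(axis=0) / (2.0 * n_obs)
    return np.minimum(f, 1.0 - f)


def hwe_chi2(n_AA: int, n_Aa: int, n_aa: int) -> tuple[float, float]:
    """One-degree-of-freedom chi-square goodness-of-fit test for HWE.

    ``n_AA`` counts homozygotes for the counted allele.  Monomorphic input
    returns (0, 1) by convention.
    """
    counts = np.array([n_AA, n_Aa, n_aa], dtype=np.float64)
    if np.any(counts < 0):
        raise ValueError("genotype counts must be non-negative")
    n = counts.sum()
    if n == 0:
        raise UndefinedStatisticError("HWE test undefined with zero total count")
    p_hat = (2 * counts[0] + counts[1]) / (2 * n)
    if p_hat in (0.0, 1.0):
        return 0.0, 1.0
    expected = np.array([p_hat**2, 2 * p_hat * (1 - p_hat), (1 - p_hat) ** 2]) * n
    mask = expected > 0
    chi2 = float(np.sum((counts[mask] - expected[mask]) ** 2 / expected[mask]))
    return chi2, float(stats.chi2.sf(chi2, df=1))


def hwe_per_snp(dataset: GenotypeDataset) -> np.ndarray:
    """Vector of HWE p-values, one per SNP (missing genotypes excluded)."""
    g = dataset.genotypes
    p_values = np.ones(dataset.n_snps)
    for j in range(dataset.n_snps):
        col = g[:, j]
        col = col[col != MISSING]
        if col.size == 0:
            raise UndefinedStatisticError(f"HWE undefined: SNP {j} all missing")
        n2 = int((col == 2).sum())
        n1 = int((col == 1).sum())
        n0 = int((col == 0).sum())
        _, p_values[j] = hwe_chi2(n2, n1, n0)
    return p_values


def sex_check_f(
    x_genotypes: np.ndarray, het_expected: np.ndarray,
    f_female_max: float = 0.2, f_male_min: float = 0.8,
) -> tuple[float, str]:
    """Inbreeding-style F from one sample's X-chromosome genotypes.

    F = (O_hom - E_hom) / (L - E_hom), with O_hom the observed homozygous
    loci and E_hom = sum(1 - 2 p_l (1 - p_l)) over the L non-missing loci,
    ``het_expected`` supplying the per-locus population heterozygosity
    2 p_l (1 - p_l).  Returns (F, label) with label female if F < 0.2,
    male if F > 0.8, else unknown.
    """
    g = np.asarray(x_genotypes)
    het = np.asarray(het_expected, dtype=np.float64)
    if g.shape != het.shape:
        raise ValueError("genotype and heterozygosity vectors must align")
    obs = g != MISSING
    L = int(obs.sum())
    if L == 0:
        raise UndefinedStatisticError("sex check: no non-missing X genotypes")
    o_hom = int(np.sum((g[obs] == 0) | (g[obs] == 2)))
    e_hom = float(np.sum(1.0 - het[obs]))
    denom = L - e_hom
    if denom == 0:
        raise UndefinedStatisticError("sex check: L - E_hom = 0, F undefined")
    f = (o_hom - e_hom) / denom
    if f < f_female_max:
        label = "female"
    elif f > f_male_min:
        label = "male"
    else:
        label = "unknown"
    return float(f), label


def infer_sex(dataset: GenotypeDataset, thresholds: QCThresholds) -> list[tuple[float, str]]:
    """Per-sample sex inference from the dataset's X-chromosome SNPs (chrom 23)."""
    x_cols = np.flatnonzero(dataset.chromosomes == 23)
    if x_cols.size == 0:
        raise UndefinedStatisticError("no X-chromosome SNPs in dataset")
    gx = dataset.genotypes[:, x_cols]
    obs = gx != MISSING
    n_obs = obs.sum(axis=0)
    freq = np.where(n_obs > 0, np.where(obs, gx, 0).sum(axis=0) / (2.0 * np.maximum(n_obs, 1)), 0.0)
    het = 2.0 * freq * (1.0 - freq)
    out = []
    for i in range(dataset.n_samples):
        out.append(
            sex_check_f(gx[i], het, thresholds.sex_f_female_max, thresholds.sex_f_male_min)
        )
    return out


# ---------------------------------------------------------------------------
# Composite filter
# ---------------------------------------------------------------------------

def apply_qc(
    dataset: GenotypeDataset,
    phenotype: PhenotypeVector,
    thresholds: QCThresholds = QCThresholds(),
    exclude_samples: set[str] | None = None,
) -> tuple[GenotypeDataset, PhenotypeVector, QCReport]:
    """Run the ordered QC filters and return filtered data plus a report.

    Each filter is computed on the samples/SNPs surviving earlier steps.
    Samples listed in ``exclude_samples`` (relatedness / ancestry removals
    decided outside this pipeline) are dropped after the sex check.  Samples
    with a missing phenotype are removed last.
    """
    if phenotype.n != dataset.n_samples:
        raise ValueError("phenotype not aligned to dataset")
    report = QCReport()
    pheno_values = phenotype.values.copy()
    pheno_missing = phenotype.missing.copy()

    def _keep_samples(mask: np.ndarray, step: str) -> None:
        nonlocal dataset, pheno_values, pheno_missing
        removed = int((~mask).sum())
        if removed and not mask.any():
            raise EmptyFilterResultError(step, "sample")
        if removed:
            dataset = dataset.subset(sample_index=mask)
            pheno_values = pheno_values[mask]
            pheno_missing = pheno_missing[mask]
        report.add(step, removed, dataset.n_samples)

    def _keep_snps(mask: np.ndarray, step: str) -> None:
        nonlocal dataset
        removed = int((~mask).sum())
        if removed and not mask.any():
            raise EmptyFilterResultError(step, "SNP")
        if removed:
            dataset = dataset.subset(snp_index=mask)
        report.add(step, removed, dataset.n_snps)

    # 1. SNP call rate
    _keep_snps(snp_call_rate(dataset) >= thresholds.snp_call_rate_min, "snp_call_rate")
    # 2. sample call rate
    _keep_samples(sample_call_rate(dataset) >= thresholds.sample_call_rate_min, "sample_call_rate")
    # 3. minor allele frequency
    _keep_snps(maf_per_snp(dataset) >= thresholds.maf_min, "maf")
    # 4. sex check (only if X data present): drop samples whose inferred sex
    #    contradicts (or cannot confirm) a reported sex.
    if np.any(dataset.chromosomes == 23):
        inferred = infer_sex(dataset, thresholds)
        keep = np.ones(dataset.n_samples, dtype=bool)
        for i, sample in enumerate(dataset.samples):
            if sample.sex != "unknown" and inferred[i][1] != sample.sex:
                keep[i] = False
        _keep_samples(keep, "sex_check")
    else:
        report.add("sex_check", 0, dataset.n_samples)
    # 5./7. externally decided exclusions (relatedness, ancestry)
    if exclude_samples:
        keep = np.array([s.sample_id not in exclude_samples for s in dataset.samples])
        _keep_samples(keep, "listed_exclusions")
    else:
        report.add("listed_exclusions", 0, dataset.n_samples)
    # 6. Hardy-Weinberg equilibrium (autosomes only: hemizygous X calls
    #    violate the diploid expectation by construction)
    hwe_ok = hwe_per_snp(dataset) >= thresholds.hwe_p_min
    _keep_snps(hwe_ok | (dataset.chromosomes > AUTOSOME_MAX), "hwe")
    # 8. autosomes only
    if thresholds.autosomes_only:
        _keep_snps(dataset.chromosomes <= AUTOSOME_MAX, "autosomes_only")
    else:
        report.add("autosomes_only", 0, dataset.n_snps)
    # finally: phenotype completeness
    _keep_samples(~pheno_missing, "missing_phenotype")

    report.final_n_samples = dataset.n_samples
    report.final_n_snps = dataset.n_snps
    filtered_pheno = PhenotypeVector(values=pheno_values, missing=pheno_missing)
    return dataset, filtered_pheno, report
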