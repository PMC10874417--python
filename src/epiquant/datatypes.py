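"""Core containers for genotype, phenotype and covariate data.

The genotype matrix is stored sample-major (rows = samples, columns = SNPs)
as ``int8`` minor-allele counts in {0, 1, 2}, with :data:`MISSING` (-1) as
the single in-memory missing sentinel.  File-format specific missing codes
(the PLINK 2-bit ``01`` code, ``-9``, ``NaN``) are translated at the I/O
boundary and never appear inside the matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: In-memory missing-genotype sentinel (never -9 or NaN inside the matrix).
MISSING: int = -1

SEX_LEVELS = ("male", "female", "unknown")
DIAGNOSIS_LEVELS = ("NC", "MCI", "AD", "missing")

#: PLINK numeric chromosome codes accepted at I/O time: 1-22 autosomes,
#: 23=X, 24=Y, 25=XY pseudo-autosomal, 26=MT.
CHROM_MIN, CHROM_MAX = 1, 26
AUTOSOME_MAX = 22


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class TruncatedFileError(FormatError):
    """A binary file is shorter than its metadata implies."""


class UnsupportedOrientationError(FormatError):
    """A PLINK .bed file is individual-major (mode byte 0x00)."""


class AlignmentError(ValueError):
    """Sample identifiers cannot be reconciled across inputs."""


class UndefinedStatisticError(ValueError):
    """A statistic is undefined on the given input (e.g. all-missing column)."""


class InfeasibleTargetError(ValueError):
    """A requested variance share cannot be realised."""


class ConfigError(ValueError):
    """An invalid configuration value."""


@dataclass(frozen=True)
class SNPInfo:
    """Identity of one biallelic locus.

    ``allele1`` is the counted allele (PLINK A1, conventionally the minor
    allele); genotype values count copies of ``allele1``.
    """

    snp_id: str
    chrom: int
    pos_bp: int
    allele1: str
    allele2: str

    def __post_init__(self) -> None:
        if not (CHROM_MIN <= self.chrom <= CHROM_MAX):
            raise ValueError(f"chromosome code {self.chrom} outside [{CHROM_MIN}, {CHROM_MAX}]")
        if self.pos_bp < 1:
            raise ValueError(f"position {self.pos_bp} must be >= 1 (1-based)")
        if self.allele1 == self.allele2:
            raise ValueError(f"{self.snp_id}: alleles must differ")

    @property
    def is_autosomal(self) -> bool:
        return self.chrom <= AUTOSOME_MAX


@dataclass(frozen=True)
class SampleInfo:
    sample_id: str
    sex: str = "unknown"
    diagnosis: str = "missing"

    def __post_init__(self) -> None:
        if self.sex not in SEX_LEVELS:
            raise ValueError(f"sex {self.sex!r} not in {SEX_LEVELS}")
        if self.diagnosis not in DIAGNOSIS_LEVELS:
            raise ValueError(f"diagnosis {self.diagnosis!r} not in {DIAGNOSIS_LEVELS}")


@dataclass
class GenotypeDataset:
    """Samples x SNPs minor-allele-count matrix plus aligned metadata."""

    genotypes: np.ndarray  # (n_samples, n_snps) int8, entries in {0,1,2,MISSING}
    snps: list[SNPInfo]
    samples: list[SampleInfo]

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ValueError("genotype matrix must be 2-D (samples x SNPs)")
        m, n = self.genotypes.shape
        if m != len(self.samples):
            raise ValueError(f"{m} genotype rows but {len(self.samples)} sample records")
        if n != len(self.snps):
            raise ValueError(f"{n} genotype columns but {len(self.snps)} SNP records")
        valid = np.isin(self.genotypes, (0, 1, 2, MISSING))
        if not valid.all():
            bad = np.unique(self.genotypes[~valid])
            raise ValueError(f"genotype entries outside {{0,1,2,{MISSING}}}: {bad.tolist()}")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("sample_id values are not unique")

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    @property
    def chromosomes(self) -> np.ndarray:
        return np.array([s.chrom for s in self.snps], dtype=np.int64)

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.pos_bp for s in self.snps], dtype=np.int64)

    def autosomal_mask(self) -> np.ndarray:
        return self.chromosomes <= AUTOSOME_MAX

    # -- subsetting ------------------------------------------------------
    def subset(self, sample_index=None, snp_index=None) -> "GenotypeDataset":
        """Return a new dataset restricted to the given index arrays.

        Index arrays may be integer or boolean; order is preserved for
        integer indices.
        """
        g = self.genotypes
        samples = self.samples
        snps = self.snps
        if sample_index is not None:
            sample_index = np.asarray(sample_index)
            if sample_index.dtype == bool:
                sample_index = np.flatnonzero(sample_index)
            g = g[sample_index, :]
            samples = [samples[i] for i in sample_index]
        if snp_index is not None:
            snp_index = np.asarray(snp_index)
            if snp_index.dtype == bool:
                snp_index = np.flatnonzero(snp_index)
            g = g[:, snp_index]
            snps = [snps[i] for i in snp_index]
        return GenotypeDataset(g.copy(), list(snps), list(samples))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeDataset):
            return NotImplemented
        return (
            self.snps == other.snps
            and self.samples == other.samples
            and np.array_equal(self.genotypes, other.genotypes)
        )


@dataclass
class PhenotypeVector:
    """A quantitative trait aligned to a dataset's sample order."""

    values: np.ndarray  # float64, arbitrary where missing
    missing: np.ndarray  # bool mask, True = missing

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.values.shape != self.missing.shape or self.values.ndim != 1:
            raise ValueError("values and missing mask must be equal-length 1-D arrays")
        observed = self.values[~self.missing]
        if observed.size and not np.all(np.isfinite(observed)):
            raise ValueError("non-missing phenotype values must be finite")

    @classmethod
    def from_values(cls, values) -> "PhenotypeVector":
        """Build from a float vector, treating NaN as missing."""
        values = np.asarray(values, dtype=np.float64)
        return cls(values=values, missing=~np.isfinite(values))

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def observed_mask(self) -> np.ndarray:
        return ~self.missing


@dataclass
class CovariateMatrix:
    """Design columns for the non-genetic covariates (no intercept column).

    Default layout matches the study model: age in years, a 0/1 sex
    indicator (1 = male), and diagnosis dummies against a reference level.
    Rows with NaN anywhere are treated as covariate-missing samples.
    """

    values: np.ndarray  # (n_samples, k) float64, NaN allowed
    names: list[str]
    rank_warning: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("covariate matrix must be 2-D")
        if self.values.shape[1] != len(self.names):
            raise ValueError("column count does not match names")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]

    def complete_mask(self) -> np.ndarray:
        return np.all(np.isfinite(self.values), axis=1)
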