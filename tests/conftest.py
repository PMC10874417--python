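"""Shared fixtures: small deterministic datasets for unit tests."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from epiquant import (
    CovariateMatrix,
    GenotypeDataset,
    PhenotypeVector,
    SampleInfo,
    SNPInfo,
)

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=30)
settings.load_profile("suite")


def make_dataset(genotypes, chroms=None, positions=None, sample_sex=None) -> GenotypeDataset:
    """Build a dataset from a raw matrix with synthetic metadata."""
    genotypes = np.asarray(genotypes, dtype=np.int8)
    m, n = genotypes.shape
    chroms = chroms if chroms is not None else [(j % 22) + 1 for j in range(n)]
    positions = positions if positions is not None else [1000 * (j + 1) for j in range(n)]
    snps = [
        SNPInfo(f"rs{j + 1:04d}", int(chroms[j]), int(positions[j]), "A", "G")
        for j in range(n)
    ]
    samples = [
        SampleInfo(
            f"S{i + 1:03d}",
            sex=(sample_sex[i] if sample_sex else "unknown"),
        )
        for i in range(m)
    ]
    return GenotypeDataset(genotypes, snps, samples)


@pytest.fixture
def rng():
    return np.random.default_rng(20240217)


@pytest.fixture
def small_dataset(rng):
    """60 samples x 12 SNPs, HWE genotypes, no missing."""
    freqs = rng.uniform(0.2, 0.5, size=12)
    g = rng.binomial(2, freqs[None, :], size=(60, 12)).astype(np.int8)
    return make_dataset(g)


@pytest.fixture
def regression_inputs(rng):
    """Aligned (Y, C, s1, s2) with genuine covariate and interaction signal."""
    n = 120
    age = rng.uniform(60, 90, n)
    sex = rng.integers(0, 2, n).astype(float)
    dx1 = rng.integers(0, 2, n).astype(float)
    s1 = rng.binomial(2, 0.3, n)
    s2 = rng.binomial(2, 0.35, n)
    y = 0.02 * age + 0.3 * sex + 0.25 * s1 * s2 + rng.normal(size=n)
    Y = PhenotypeVector.from_values(y)
    C = CovariateMatrix(
        values=np.column_stack([age, sex, dx1]), names=["age", "sex", "dx"]
    )
    return Y, C, s1, s2
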