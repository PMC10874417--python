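"""Interaction F-test and blocked scan: oracle equivalence and invariances."""

from __future__ import annotations

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

from epiquant import (
    CovariateMatrix,
    PhenotypeVector,
    ScanConfig,
    bonferroni_threshold,
    interaction_test,
    pairwise_scan,
)
from epiquant.datatypes import ConfigError
from epiquant.simulate import SimSpec, simulate_null, simulate_study

from conftest import make_dataset


def _no_covariates(n):
    return CovariateMatrix(values=np.empty((n, 0)), names=[])


# ---------------------------------------------------------------------------
# single-pair test
# ---------------------------------------------------------------------------

def test_perfect_fit_is_degenerate_with_p_zero():
    s1 = np.array([0, 0, 1, 1, 2, 2, 1, 0])
    s2 = np.array([0, 1, 0, 1, 0, 1, 2, 2])
    y = (s1 * s2).astype(float)
    res = interaction_test(
        PhenotypeVector.from_values(y), _no_covariates(8), s1, s2
    )
    assert res.degenerate
    assert res.p == 0.0
    assert np.isinf(res.F)


def test_constant_snp_gives_invalid_flag(rng):
    n = 50
    s1 = np.ones(n, dtype=np.int8)  # constant: product collinear with s2
    s2 = rng.binomial(2, 0.4, n)
    y = rng.normal(size=n)
    res = interaction_test(
        PhenotypeVector.from_values(y), _no_covariates(n), s1, s2
    )
    assert res.invalid
    assert np.isnan(res.F) and np.isnan(res.p)


def test_statsmodels_nested_f_oracle_seeded_instance():
    """n=100, MAF 0.3 both SNPs, null trait, age/sex/Dx covariates: F, p and
    beta match a textbook nested OLS fit to 1e-8 relative."""
    rng = np.random.default_rng(42)
    n = 100
    s1 = rng.binomial(2, 0.3, n)
    s2 = rng.binomial(2, 0.3, n)
    y = rng.normal(size=n)
    age = rng.uniform(60, 90, n)
    sex = rng.binomial(1, 0.5, n).astype(float)
    dx = rng.integers(0, 3, n)
    C = CovariateMatrix(
        values=np.column_stack([age, sex, dx == 1, dx == 2]).astype(float),
        names=["age", "sex", "dx_MCI", "dx_AD"],
    )
    res = interaction_test(PhenotypeVector.from_values(y), C, s1, s2)

    X_red = sm.add_constant(np.column_stack([C.values, s1, s2]))
    X_full = np.column_stack([X_red, s1 * s2])
    fit_red = sm.OLS(y, X_red).fit()
    fit_full = sm.OLS(y, X_full).fit()
    F, p, _ = fit_full.compare_f_test(fit_red)
    assert res.F == pytest.approx(F, rel=1e-8)
    assert res.p == pytest.approx(p, rel=1e-8)
    assert res.beta_int == pytest.approx(fit_full.params[-1], rel=1e-8)
    assert res.se_int == pytest.approx(fit_full.bse[-1], rel=1e-8)
    assert res.df2 == n - 8
    assert res.F == pytest.approx((res.beta_int / res.se_int) ** 2, rel=1e-8)


def test_symmetry_in_snp_order(regression_inputs):
    Y, C, s1, s2 = regression_inputs
    a = interaction_test(Y, C, s1, s2)
    b = interaction_test(Y, C, s2, s1)
    assert a.F == pytest.approx(b.F, rel=1e-12)
    assert a.p == pytest.approx(b.p, rel=1e-12)


def test_sample_permutation_leaves_statistics_unchanged(regression_inputs, rng):
    Y, C, s1, s2 = regression_inputs
    perm = rng.permutation(Y.n)
    a = interaction_test(Y, C, s1, s2)
    b = interaction_test(
        PhenotypeVector.from_values(Y.values[perm]),
        CovariateMatrix(values=C.values[perm], names=C.names),
        s1[perm],
        s2[perm],
    )
    assert a.F == pytest.approx(b.F, rel=1e-10)
    assert a.beta_int == pytest.approx(b.beta_int, rel=1e-10)


def test_missing_policies_differ_only_in_subset(regression_inputs):
    Y, C, s1, s2 = regression_inputs
    s1 = np.asarray(s1).copy()
    s1[:5] = -1  # MISSING
    cc = interaction_test(Y, C, s1, s2, "complete_case")
    mi = interaction_test(Y, C, s1, s2, "mean_impute")
    assert cc.n_used == Y.n - 5
    assert mi.n_used == Y.n
    assert cc.p != mi.p


# ---------------------------------------------------------------------------
# blocked scan
# ---------------------------------------------------------------------------

def test_null_scan_emits_all_pairs_at_threshold_one():
    bundle = simulate_null(n=80, m=50, seed=9)
    result = pairwise_scan(
        bundle.dataset, bundle.phenotype, bundle.covariates,
        ScanConfig(p_threshold=1.0),
    )
    assert result.n_pairs_tested == 1225
    assert len(result.significant) + len(result.invalid) == 1225


@pytest.mark.parametrize("block_size", [7, 50])
def test_block_size_does_not_change_results(block_size):
    bundle = simulate_null(n=80, m=50, seed=10)
    ref = pairwise_scan(
        bundle.dataset, bundle.phenotype, bundle.covariates,
        ScanConfig(p_threshold=1.0, block_size=17),
    )
    alt = pairwise_scan(
        bundle.dataset, bundle.phenotype, bundle.covariates,
        ScanConfig(p_threshold=1.0, block_size=block_size),
    )
    assert [(r.snp1_index, r.snp2_index) for r in ref.significant] == [
        (r.snp1_index, r.snp2_index) for r in alt.significant
    ]
    np.testing.assert_allclose(
        [r.p for r in ref.significant], [r.p for r in alt.significant],
        rtol=1e-10,
    )


def test_scan_matches_exhaustive_single_pair_oracle():
    """Planted dataset at Bonferroni: the emitted set equals testing every
    pair one at a time and filtering."""
    spec = SimSpec(n_samples=800, n_snps=60, n_planted_pairs=3, seed=21)
    bundle = simulate_study(spec)
    threshold = bonferroni_threshold(60, 0.05)
    result = pairwise_scan(
        bundle.dataset, bundle.phenotype, bundle.covariates,
        ScanConfig(p_threshold=threshold),
    )
    oracle = set()
    for i in range(60):
        for j in range(i + 1, 60):
            res = interaction_test(
                bundle.phenotype, bundle.covariates,
                bundle.dataset.genotypes[:, i], bundle.dataset.genotypes[:, j],
                snp1_index=i, snp2_index=j,
            )
            if not res.invalid and res.p <= threshold:
                oracle.add((i, j))
    assert {(r.snp1_index, r.snp2_index) for r in result.significant} == oracle
    # most planted pairs clear the family-wise threshold at this sample size
    assert len(oracle & set(bundle.truth.planted_index_pairs())) >= 2


def test_scan_with_missing_genotypes_matches_exact_path(rng):
    bundle = simulate_null(n=120, m=20, seed=31, missing_rate=0.05)
    result = pairwise_scan(
        bundle.dataset, bundle.phenotype, bundle.covariates,
        ScanConfig(p_threshold=1.0),
    )
    assert result.n_pairs_tested == 190
    by_pair = {(r.snp1_index, r.snp2_index): r for r in result.significant}
    for (i, j) in [(0, 1), (3, 17), (10, 19)]:
        exact = interaction_test(
            bundle.phenotype, bundle.covariates,
            bundle.dataset.genotypes[:, i], bundle.dataset.genotypes[:, j],
            snp1_index=i, snp2_index=j,
        )
        assert by_pair[(i, j)].p == pytest.approx(exact.p, rel=1e-9)
        assert by_pair[(i, j)].n_used == exact.n_used


def test_proximity_and_chromosome_exclusion_rules():
    bundle = simulate_null(n=80, m=44, seed=12)
    # same chromosome = indices 22 apart under round-robin assignment
    cfg = ScanConfig(p_threshold=1.0, cross_chromosome=False)
    result = pairwise_scan(bundle.dataset, bundle.phenotype, bundle.covariates, cfg)
    chroms = bundle.dataset.chromosomes
    assert all(
        chroms[r.snp1_index] == chroms[r.snp2_index] for r in result.significant
    )
    assert result.n_pairs_tested == 22  # 22 chromosomes x C(2,2) pairs

    far = ScanConfig(p_threshold=1.0, same_chrom_min_distance_bp=10**9)
    result2 = pairwise_scan(bundle.dataset, bundle.phenotype, bundle.covariates, far)
    assert all(
        chroms[r.snp1_index] != chroms[r.snp2_index] for r in result2.significant
    )
    assert result2.n_pairs_tested == 44 * 43 // 2 - 22


def test_invalid_pairs_are_reported_not_dropped():
    rng = np.random.default_rng(3)
    n = 60
    g = rng.binomial(2, 0.4, size=(n, 5)).astype(np.int8)
    g[:, 2] = g[:, 1]  # duplicated column: pair (1, 2) rank-deficient
    ds = make_dataset(g)
    y = PhenotypeVector.from_values(rng.normal(size=n))
    C = CovariateMatrix(values=rng.uniform(60, 90, (n, 1)), names=["age"])
    result = pairwise_scan(ds, y, C, ScanConfig(p_threshold=1.0))
    assert (1, 2) in {(r.snp1_index, r.snp2_index) for r in result.invalid}
    assert len(result.significant) + len(result.invalid) == 10


# ---------------------------------------------------------------------------
# Bonferroni
# ---------------------------------------------------------------------------

def test_bonferroni_threshold_values():
    assert bonferroni_threshold(2, 0.05) == 0.05
    assert bonferroni_threshold(50, 0.05) == 0.05 / 1225
    # big-integer oracle at the study's post-QC SNP count
    n = 563_980
    pairs = n * (n - 1) // 2
    assert pairs == 159_036_438_210
    assert bonferroni_threshold(n, 0.05) == 0.05 / pairs
    with pytest.raises(ConfigError):
        bonferroni_threshold(1, 0.05)


# ---------------------------------------------------------------------------
# statistical behaviour
# ---------------------------------------------------------------------------

def test_monotone_power_in_interaction_effect():
    """Empirical power is non-decreasing along an increasing beta_int grid."""
    rng = np.random.default_rng(77)
    n, reps = 200, 500
    betas = [0.0, 0.25, 0.6]
    power = []
    for beta in betas:
        hits = 0
        for _ in range(reps):
            s1 = rng.binomial(2, 0.3, n)
            s2 = rng.binomial(2, 0.3, n)
            y = beta * s1 * s2 + rng.normal(size=n)
            res = interaction_test(
                PhenotypeVector.from_values(y), _no_covariates(n), s1, s2
            )
            hits += res.p < 0.05
        power.append(hits / reps)
    assert power[0] < 0.10  # near the nominal level under the null
    # tolerate Monte-Carlo noise of a few percent
    assert power[1] >= power[0] - 0.03
    assert power[2] >= power[1] - 0.03
    assert power[2] > 0.9
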