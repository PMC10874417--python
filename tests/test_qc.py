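"""QC statistics: call rates, MAF folding, Hardy-Weinberg, sex check, ordering."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from epiquant import (
    MISSING,
    PhenotypeVector,
    QCThresholds,
    apply_qc,
    hwe_chi2,
    minor_allele_frequency,
    sample_call_rate,
    sex_check_f,
    snp_call_rate,
)
from epiquant.datatypes import UndefinedStatisticError
from epiquant.qc import hwe_per_snp, maf_per_snp

from conftest import make_dataset


# ---------------------------------------------------------------------------
# call rates
# ---------------------------------------------------------------------------

def test_call_rates_count_missing_exactly():
    g = np.zeros((8, 3), dtype=np.int8)
    g[0, 1] = MISSING            # SNP 1: 1 of 8 missing
    g[:, 2] = MISSING            # SNP 2: fully missing
    ds = make_dataset(g)
    np.testing.assert_allclose(snp_call_rate(ds), [1.0, 0.875, 0.0])

    g2 = np.zeros((3, 10), dtype=np.int8)
    g2[1, :2] = MISSING          # sample 1: 2 of 10 missing
    g2[2, :] = MISSING           # sample 2: all missing
    ds2 = make_dataset(g2)
    np.testing.assert_allclose(sample_call_rate(ds2), [1.0, 0.8, 0.0])


# ---------------------------------------------------------------------------
# MAF
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "column, expected",
    [
        ([0, 0, 0, 0], 0.0),
        ([0, 1, 2, 1, 0], 0.4),       # 4 of 10 alleles
        ([2, 2, 2, 1], 0.125),        # f = 7/8, folded
        ([1, MISSING, 2], 0.25),      # f = 3/4 folded, missing excluded
    ],
)
def test_maf_examples(column, expected):
    assert minor_allele_frequency(np.array(column)) == pytest.approx(expected)


def test_maf_all_missing_is_undefined():
    with pytest.raises(UndefinedStatisticError):
        minor_allele_frequency(np.full(5, MISSING))


@given(st.lists(st.sampled_from([0, 1, 2]), min_size=1, max_size=40))
def test_maf_invariant_under_allele_relabel(column):
    g = np.array(column)
    assert minor_allele_frequency(g) == pytest.approx(minor_allele_frequency(2 - g))


# ---------------------------------------------------------------------------
# Hardy-Weinberg
# ---------------------------------------------------------------------------

def test_hwe_exact_proportions_give_chi2_zero():
    chi2, p = hwe_chi2(25, 50, 25)
    assert chi2 == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_hwe_monomorphic_convention():
    assert hwe_chi2(100, 0, 0) == (0.0, 1.0)
    assert hwe_chi2(0, 0, 50) == (0.0, 1.0)


def test_hwe_hand_evaluated_example():
    """(60, 20, 20): p_hat = 0.7, expected (49, 42, 9), chi2 = sum (O-E)^2/E."""
    chi2, p = hwe_chi2(60, 20, 20)
    expected_chi2 = (60 - 49) ** 2 / 49 + (20 - 42) ** 2 / 42 + (20 - 9) ** 2 / 9
    assert chi2 == pytest.approx(expected_chi2, rel=1e-12)
    assert chi2 == pytest.approx(27.44, abs=0.01)
    assert p == pytest.approx(stats.chi2.sf(expected_chi2, 1), rel=1e-12)
    assert p == pytest.approx(1.6e-7, rel=0.05)


def test_hwe_errors():
    with pytest.raises(UndefinedStatisticError):
        hwe_chi2(0, 0, 0)
    with pytest.raises(ValueError):
        hwe_chi2(-1, 2, 3)


def test_hwe_pvalues_uniform_under_null():
    """On 10,000 HWE-simulated SNPs the p-values pass a KS uniformity check."""
    rng = np.random.default_rng(11)
    n, m = 500, 10_000
    freqs = rng.uniform(0.1, 0.5, m)
    g = rng.binomial(2, freqs[None, :], size=(n, m)).astype(np.int8)
    ds = make_dataset(g, chroms=[(j % 22) + 1 for j in range(m)])
    p = hwe_per_snp(ds)
    assert stats.kstest(p, "uniform").pvalue > 0.01
    # rejection rate at alpha = 0.05 within the exact binomial 99% interval
    rate = float((p < 0.05).mean())
    lo, hi = stats.binom.interval(0.99, m, 0.05)
    assert lo / m <= rate <= hi / m


# ---------------------------------------------------------------------------
# sex check
# ---------------------------------------------------------------------------

def test_sex_check_boundary_cases():
    het = np.full(100, 0.4)  # E_hom = 60
    all_hom = np.zeros(100, dtype=np.int8)
    f, label = sex_check_f(all_hom, het)
    assert f == pytest.approx(1.0)
    assert label == "male"

    # O_hom = E_hom = 60 -> F = 0 -> female
    g = np.concatenate([np.zeros(60, dtype=np.int8), np.ones(40, dtype=np.int8)])
    f, label = sex_check_f(g, het)
    assert f == pytest.approx(0.0)
    assert label == "female"

    # O_hom = 80, E_hom = 60, L = 100 -> F = 0.5 -> unknown
    g = np.concatenate([np.zeros(80, dtype=np.int8), np.ones(20, dtype=np.int8)])
    f, label = sex_check_f(g, het)
    assert f == pytest.approx(0.5)
    assert label == "unknown"


def test_sex_check_undefined_denominator():
    with pytest.raises(UndefinedStatisticError):
        sex_check_f(np.zeros(4, dtype=np.int8), np.zeros(4))


# ---------------------------------------------------------------------------
# apply_qc
# ---------------------------------------------------------------------------

def _clean_bundle(rng, n=80, m=10):
    freqs = rng.uniform(0.2, 0.5, m)
    g = rng.binomial(2, freqs[None, :], size=(n, m)).astype(np.int8)
    ds = make_dataset(g)
    ph = PhenotypeVector.from_values(rng.normal(size=n))
    return ds, ph


def test_apply_qc_passthrough_reports_zero_removed(rng):
    ds, ph = _clean_bundle(rng)
    out, out_ph, report = apply_qc(ds, ph)
    assert out == ds
    np.testing.assert_array_equal(out_ph.values, ph.values)
    assert all(removed == 0 for _, removed, _ in report.steps)


def test_apply_qc_single_low_call_rate_snp_removed(rng):
    ds, ph = _clean_bundle(rng, n=100)
    g = ds.genotypes.copy()
    g[:10, 4] = MISSING  # call rate 0.90 < 0.95
    ds2 = make_dataset(g)
    out, _, report = apply_qc(ds2, ph)
    assert out.n_snps == ds.n_snps - 1
    assert "rs0005" not in out.snp_ids
    step = dict((s, (r, k)) for s, r, k in report.steps)
    assert step["snp_call_rate"][0] == 1


def test_apply_qc_planted_violations_match_per_filter_oracle(rng):
    """Each filter's removal set equals independently applying its formula
    to the data surviving the earlier steps."""
    n = 200
    ds, ph = _clean_bundle(rng, n=n, m=12)
    g = ds.genotypes.copy()
    g[: int(n * 0.1), 0] = MISSING            # SNP 0: call rate 0.90
    g[:, 1] = np.int8(0); g[0, 1] = np.int8(1)  # SNP 1: MAF 1/400 < 0.05
    half = n // 2                              # SNP 2: gross HWE violation
    g[:, 2] = np.int8(0); g[:half, 2] = np.int8(2)
    g[5, :] = MISSING                          # sample 5: call rate 0
    ds2 = make_dataset(g)
    ph2 = PhenotypeVector.from_values(ph.values.copy())
    ph2.values[7] = np.nan
    ph2.missing[7] = True

    out, out_ph, report = apply_qc(ds2, ph2)
    step = {s: removed for s, removed, _ in report.steps}
    assert step["snp_call_rate"] == 1
    assert step["sample_call_rate"] == 1
    assert step["maf"] == 1
    assert step["hwe"] == 1
    assert step["missing_phenotype"] == 1
    assert out.n_snps == 9
    assert out.n_samples == n - 2

    # oracle: recompute the surviving sets by sequentially applying formulas
    keep_snps = snp_call_rate(ds2) >= 0.95
    ds_o = ds2.subset(snp_index=keep_snps)
    keep_samples = sample_call_rate(ds_o) >= 0.95
    ds_o = ds_o.subset(sample_index=keep_samples)
    ds_o = ds_o.subset(snp_index=maf_per_snp(ds_o) >= 0.05)
    ds_o = ds_o.subset(snp_index=hwe_per_snp(ds_o) >= 1e-6)
    pheno_keep = ~ph2.missing[keep_samples]
    ds_o = ds_o.subset(sample_index=pheno_keep)
    assert out == ds_o


def test_apply_qc_is_idempotent(rng):
    ds, ph = _clean_bundle(rng, n=150)
    g = ds.genotypes.copy()
    g[:30, 3] = MISSING
    once, ph1, _ = apply_qc(make_dataset(g), ph)
    twice, ph2, report2 = apply_qc(once, ph1)
    assert twice == once
    np.testing.assert_array_equal(ph2.values, ph1.values)
    assert all(removed == 0 for _, removed, _ in report2.steps)


def test_apply_qc_autosome_and_sex_steps(rng):
    """X SNPs drive the sex check, then leave at the autosome step."""
    n = 120
    rngl = np.random.default_rng(5)
    freqs = rngl.uniform(0.2, 0.5, 8)
    auto = rngl.binomial(2, freqs[None, :], size=(n, 8)).astype(np.int8)
    # X block: females HWE hets, males hemizygous (always homozygous calls);
    # 400 loci keep the female F sampling noise well below the 0.2 bound
    L = 400
    males = np.arange(n) < n // 2
    x = rngl.binomial(2, 0.5, size=(n, L)).astype(np.int8)
    x[males] = 2 * rngl.binomial(1, 0.5, size=(int(males.sum()), L)).astype(np.int8)
    g = np.column_stack([auto, x]).astype(np.int8)
    chroms = [1] * 8 + [23] * L
    sex = ["male" if m else "female" for m in males]
    ds = make_dataset(g, chroms=chroms, sample_sex=sex)
    ph = PhenotypeVector.from_values(rngl.normal(size=n))
    out, _, report = apply_qc(ds, ph)
    step = {s: removed for s, removed, _ in report.steps}
    assert step["sex_check"] == 0        # reported sex matches inferred
    assert step["autosomes_only"] >= 1   # the X block leaves here
    assert set(out.chromosomes) <= set(range(1, 23))

    # a male mislabelled as female is removed at the sex check
    bad_sex = list(sex)
    bad_sex[0] = "female"
    ds_bad = make_dataset(g, chroms=chroms, sample_sex=bad_sex)
    _, _, report_bad = apply_qc(ds_bad, ph)
    assert {s: r for s, r, _ in report_bad.steps}["sex_check"] == 1


def test_apply_qc_exclusion_list(rng):
    ds, ph = _clean_bundle(rng)
    out, _, report = apply_qc(ds, ph, exclude_samples={"S001", "S007"})
    assert {s: r for s, r, _ in report.steps}["listed_exclusions"] == 2
    assert "S001" not in out.sample_ids
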