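"""Synthetic genotype/phenotype generator emulating the study's structure.

Defaults emulate the cohort the analysis was designed for: n = 858
samples; biallelic autosomal SNPs in Hardy-Weinberg proportions with
allele frequencies uniform on (0.05, 0.5); age ~ Uniform(55, 91) years,
sex ~ Bernoulli(0.5) (1 = male), a 3-level diagnosis with probabilities
(0.331, 0.534, 0.134) for NC/MCI/AD; covariate effect sizes solved so
the covariates explain 13.3% of the covariate-plus-noise trait variance;
and (optionally) sparse planted SNP-pair interactions whose population
hierarchical-R^2 increment is hit exactly by a closed-form variance
identity.  Genotypes are independent across SNPs unless an LD copy is
requested.  Everything is reproducible byte-for-byte from (spec, seed).

The generative trait model mirrors the fitted one::

    Y = b0 + C @ b_cov + sum_pairs (b1 s_j + b2 s_k + b_int s_j s_k) + eps,
    eps ~ N(0, noise_sd^2)
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datatypes import (
    MISSING,
    CovariateMatrix,
    GenotypeDataset,
    InfeasibleTargetError,
    PhenotypeVector,
    SampleInfo,
    SNPInfo,
)

#: Covariate share of the covariate+noise trait variance, and its split
#: across age / sex / diagnosis.  The share reproduces the ~13.3% covariate
#: R^2 scale of the study cohort; the split gives age the largest role and
#: an AD-vs-MCI effect ratio matching the cohort's trait means.
COV_SHARE = 0.133
_COV_SPLIT = (0.5, 0.1, 0.4)  # age, sex, diagnosis
_AD_OVER_MCI = 2.75  # ratio of AD to MCI diagnosis effects

DEFAULT_DX_PROBS = (0.331, 0.534, 0.134)  # NC, MCI, AD
DEFAULT_AGE_RANGE = (55.0, 91.0)


@dataclass(frozen=True)
class PlantedPair:
    """One planted epistatic pair with its generative coefficients."""

    snp1: int
    snp2: int
    beta1: float
    beta2: float
    beta_int: float


@dataclass
class SimSpec:
    """Generator parameters; defaults are the emulated study conditions."""

    n_samples: int = 858
    n_snps: int = 1000
    maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.0
    age_range: tuple[float, float] = DEFAULT_AGE_RANGE
    dx_probs: tuple[float, float, float] = DEFAULT_DX_PROBS
    noise_sd: float = 1.0
    intercept: float = 0.0
    planted: list[PlantedPair] = field(default_factory=list)
    # targets used when `planted` is empty but n_planted_pairs > 0
    n_planted_pairs: int = 0
    target_dr2_int: float = 0.05
    main_share: float = 0.003  # per-SNP main-effect variance share
    planted_maf: float = 0.25  # planted loci get a fixed, feasible frequency
    seed: int = 0


@dataclass
class SimTruth:
    """Planted-effect registry for recovery testing."""

    spec: SimSpec
    allele_freqs: np.ndarray
    planted: list[PlantedPair]
    achieved_dr2_int: list[float]
    trait_variance: float
    covariate_variance: float

    def planted_index_pairs(self) -> list[tuple[int, int]]:
        return [(p.snp1, p.snp2) for p in self.planted]

    def write(self, path) -> None:
        frame = pd.DataFrame(
            [
                {
                    "snp1": p.snp1,
                    "snp2": p.snp2,
                    "beta1": p.beta1,
                    "beta2": p.beta2,
                    "beta_int": p.beta_int,
                    "dr2_int": d,
                }
                for p, d in zip(self.planted, self.achieved_dr2_int)
            ],
            columns=["snp1", "snp2", "beta1", "beta2", "beta_int", "dr2_int"],
        )
        frame.to_csv(path, sep="\t", index=False, float_format="%.12g")


@dataclass
class SimBundle:
    dataset: GenotypeDataset
    phenotype: PhenotypeVector
    covariates: CovariateMatrix
    covariate_table: pd.DataFrame
    truth: SimTruth


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(
    n: int,
    m: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    missing_rate: float = 0.0,
    seed: int = 0,
    freqs: np.ndarray | None = None,
) -> tuple[GenotypeDataset, np.ndarray]:
    """Simulate a samples x SNPs dataset in HWE; returns (dataset, freqs).

    Per SNP an allele frequency is drawn uniform in ``maf_range`` (or taken
    from ``freqs``), genotypes are Binomial(2, p) i.i.d. across samples, and
    missingness is planted i.i.d. at ``missing_rate``.  SNPs get synthetic
    rsIDs, round-robin chromosomes 1-22 and strictly increasing positions
    per chromosome.
    """
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError(f"maf_range {maf_range} must lie within (0, 0.5]")
    rng = np.random.default_rng(seed)
    if freqs is None:
        freqs = rng.uniform(lo, hi, size=m)
    else:
        freqs = np.asarray(freqs, dtype=np.float64)
        if freqs.shape != (m,):
            raise ValueError("freqs must have one entry per SNP")
    genotypes = rng.binomial(2, freqs[None, :], size=(n, m)).astype(np.int8)
    if missing_rate > 0:
        mask = rng.random(size=(n, m)) < missing_rate
        genotypes[mask] = MISSING

    snps = []
    chrom_counter = np.zeros(22, dtype=np.int64)
    for j in range(m):
        chrom = (j % 22) + 1
        chrom_counter[chrom - 1] += 1
        pos = int(chrom_counter[chrom - 1]) * 50_000 + 10_000
        snps.append(SNPInfo(f"rsS{j + 1:06d}", chrom, pos, "A", "G"))
    samples = [SampleInfo(f"S{i + 1:05d}") for i in range(n)]
    return GenotypeDataset(genotypes, snps, samples), freqs


def add_ld_copy(
    dataset: GenotypeDataset, source: int, theta: float, seed: int
) -> GenotypeDataset:
    """Append a haplotype-copy of one SNP, flipping each genotype step with
    probability ``theta`` — a minimal mechanism for planting LD."""
    rng = np.random.default_rng(seed)
    col = dataset.genotypes[:, source].copy()
    flip = rng.random(col.shape[0]) < theta
    nonmiss = col != MISSING
    jitter = rng.integers(0, 3, size=col.shape[0]).astype(np.int8)
    col = np.where(flip & nonmiss, jitter, col)
    src = dataset.snps[source]
    new_snp = SNPInfo(f"{src.snp_id}_copy", src.chrom, src.pos_bp + 1, src.allele1, src.allele2)
    g = np.column_stack([dataset.genotypes, col]).astype(np.int8)
    return GenotypeDataset(g, dataset.snps + [new_snp], list(dataset.samples))


# ---------------------------------------------------------------------------
# Effect-size calibration
# ---------------------------------------------------------------------------

def _moments(p: float) -> tuple[float, float]:
    """(mean, variance) of a Binomial(2, p) minor-allele count."""
    return 2.0 * p, 2.0 * p * (1.0 - p)


def calibrate_beta_int(
    maf1: float,
    maf2: float,
    covariate_var: float,
    noise_sd: float,
    target_dr2: float,
) -> float:
    """Interaction coefficient whose population R^2 increment equals ``target_dr2``.

    For independent HWE genotypes the residual of s1*s2 on {1, s1, s2} has
    variance Var(s1) Var(s2), so the hierarchical increment of the product
    term is beta^2 Var(s1) Var(s2) / Var(Y).  Solving the variance identity
    with Var(Y) = covariate_var + noise_sd^2 + (marginal product variance)
    gives the closed form used here; a target whose induced total genetic
    share would reach 1 is infeasible.
    """
    if not 0.0 <= target_dr2 < 1.0:
        raise InfeasibleTargetError(f"target_dr2 {target_dr2} outside [0, 1)")
    if target_dr2 == 0.0:
        return 0.0
    m1, v1 = _moments(maf1)
    m2, v2 = _moments(maf2)
    base = covariate_var + noise_sd**2
    # marginal variance of the product term relative to its residual variance
    g = target_dr2 * (1.0 + m2**2 / v2 + m1**2 / v1)
    if g >= 1.0:
        raise InfeasibleTargetError(
            f"target_dr2 {target_dr2} infeasible at MAFs ({maf1}, {maf2})"
        )
    var_y = base / (1.0 - g)
    return float(np.sqrt(target_dr2 * var_y / (v1 * v2)))


def _solve_planted_betas(
    freq_pairs: list[tuple[float, float]],
    covariate_var: float,
    noise_sd: float,
    target_dr2_int: float,
    main_share: float,
) -> tuple[list[tuple[float, float, float]], float]:
    """Jointly solve all planted pairs' coefficients against one total variance.

    Every beta scales with sqrt(Var(Y)), so the total genetic variance share
    g is a pure function of the targets and allele frequencies:
    Var(Y) = (covariate_var + noise_sd^2) / (1 - g).  Returns the per-pair
    (beta1, beta2, beta_int) and the analytic Var(Y).
    """
    base = covariate_var + noise_sd**2
    t_int, t_main = target_dr2_int, main_share
    g = 0.0
    for p1, p2 in freq_pairs:
        m1, v1 = _moments(p1)
        m2, v2 = _moments(p2)
        g += (
            (np.sqrt(t_main) + m2 * np.sqrt(t_int / v2)) ** 2
            + (np.sqrt(t_main) + m1 * np.sqrt(t_int / v1)) ** 2
            + t_int
        )
    if g >= 1.0:
        raise InfeasibleTargetError(
            f"total planted genetic variance share {g:.3f} >= 1"
        )
    var_y = base / (1.0 - g)
    betas = []
    for p1, p2 in freq_pairs:
        m1, v1 = _moments(p1)
        m2, v2 = _moments(p2)
        beta_int = float(np.sqrt(t_int * var_y / (v1 * v2)))
        beta1 = float(np.sqrt(t_main * var_y / v1))
        beta2 = float(np.sqrt(t_main * var_y / v2))
        betas.append((beta1, beta2, beta_int))
    return betas, float(var_y)


def _covariate_betas(
    age_range, dx_probs, noise_sd
) -> tuple[np.ndarray, float]:
    """Effect sizes making covariates explain COV_SHARE of covariate+noise variance."""
    cov_var_target = COV_SHARE / (1.0 - COV_SHARE) * noise_sd**2
    share_age, share_sex, share_dx = _COV_SPLIT
    var_age = (age_range[1] - age_range[0]) ** 2 / 12.0
    b_age = np.sqrt(share_age * cov_var_target / var_age)
    b_sex = np.sqrt(share_sex * cov_var_target / 0.25)
    _, p_m, p_a = dx_probs
    r = _AD_OVER_MCI
    # Var(b (X_mci + r X_ad)) with multinomial covariance -p_m p_a
    unit = p_m * (1 - p_m) + r**2 * p_a * (1 - p_a) - 2 * r * p_m * p_a
    b_mci = np.sqrt(share_dx * cov_var_target / unit)
    betas = np.array([b_age, b_sex, b_mci, r * b_mci])
    return betas, float(cov_var_target)


# ---------------------------------------------------------------------------
# Phenotype and full bundles
# ---------------------------------------------------------------------------

def _simulate_covariates(n, spec: SimSpec, rng) -> tuple[pd.DataFrame, CovariateMatrix]:
    age = rng.uniform(spec.age_range[0], spec.age_range[1], size=n)
    sex = rng.integers(0, 2, size=n)  # 1 = male
    dx_levels = np.array(["NC", "MCI", "AD"])
    probs = np.asarray(spec.dx_probs, dtype=np.float64)
    dx = dx_levels[rng.choice(3, size=n, p=probs / probs.sum())]
    table = pd.DataFrame(
        {
            "sample_id": [f"S{i + 1:05d}" for i in range(n)],
            "age": age,
            "sex": np.where(sex == 1, "male", "female"),
            "diagnosis": dx,
        }
    )
    values = np.column_stack(
        [age, sex.astype(float), (dx == "MCI").astype(float), (dx == "AD").astype(float)]
    )
    cov = CovariateMatrix(values=values, names=["age", "sex", "dx_MCI", "dx_AD"])
    return table, cov


def simulate_phenotype(
    dataset: GenotypeDataset,
    spec: SimSpec,
    covariates: CovariateMatrix,
    planted: list[PlantedPair],
    rng: np.random.Generator,
    freqs: np.ndarray,
    var_y: float,
    cov_var: float,
) -> tuple[PhenotypeVector, SimTruth]:
    """Draw the trait from the generative linear model (internal worker)."""
    n = dataset.n_samples
    cov_betas, _ = _covariate_betas(spec.age_range, spec.dx_probs, spec.noise_sd)
    # centre age so the intercept keeps its meaning
    age_mid = 0.5 * (spec.age_range[0] + spec.age_range[1])
    C = covariates.values.copy()
    C[:, 0] -= age_mid
    y = spec.intercept + C @ cov_betas
    for pair in planted:
        s1 = dataset.genotypes[:, pair.snp1].astype(np.float64)
        s2 = dataset.genotypes[:, pair.snp2].astype(np.float64)
        if np.any(s1 == MISSING) or np.any(s2 == MISSING):
            raise ValueError("planted loci must be missing-free")
        y = y + pair.beta1 * s1 + pair.beta2 * s2 + pair.beta_int * s1 * s2
    y = y + rng.normal(0.0, spec.noise_sd, size=n)

    achieved = []
    for pair in planted:
        _, v1 = _moments(freqs[pair.snp1])
        _, v2 = _moments(freqs[pair.snp2])
        achieved.append(pair.beta_int**2 * v1 * v2 / var_y)
    truth = SimTruth(
        spec=spec,
        allele_freqs=freqs,
        planted=planted,
        achieved_dr2_int=achieved,
        trait_variance=var_y,
        covariate_variance=cov_var,
    )
    return PhenotypeVector.from_values(y), truth


def simulate_study(spec: SimSpec) -> SimBundle:
    """Generate a full genotype/covariate/trait bundle from one spec + seed."""
    root = np.random.SeedSequence(spec.seed)
    geno_rng_seed, cov_seed, noise_seed, refill_seed = root.spawn(4)

    planted = list(spec.planted)
    n_pairs = len(planted) or spec.n_planted_pairs
    pair_indices = (
        [(p.snp1, p.snp2) for p in planted]
        if planted
        else [(2 * k, 2 * k + 1) for k in range(n_pairs)]
    )
    for i, j in pair_indices:
        if not (0 <= i < spec.n_snps and 0 <= j < spec.n_snps and i != j):
            raise ValueError(f"planted pair ({i}, {j}) out of range or degenerate")
    flat = [i for ij in pair_indices for i in ij]
    if len(set(flat)) != len(flat):
        raise ValueError("planted pairs must use distinct SNPs")

    # allele frequencies: planted loci pinned to a feasible frequency
    rng_geno = np.random.default_rng(geno_rng_seed)
    freqs = rng_geno.uniform(spec.maf_range[0], spec.maf_range[1], size=spec.n_snps)
    if not planted and n_pairs:
        for i, j in pair_indices:
            freqs[i] = freqs[j] = spec.planted_maf

    dataset, freqs = simulate_genotypes(
        spec.n_samples, spec.n_snps, spec.maf_range,
        spec.missing_rate, seed=rng_geno, freqs=freqs,
    )
    # planted loci must stay missing-free for the generative model
    if spec.missing_rate > 0 and flat:
        g = dataset.genotypes
        refill_rng = np.random.default_rng(refill_seed)
        for col in flat:
            miss = g[:, col] == MISSING
            if miss.any():
                refill = refill_rng.binomial(2, freqs[col], miss.sum())
                g[miss, col] = refill.astype(np.int8)

    cov_table, covariates = _simulate_covariates(
        spec.n_samples, spec, np.random.default_rng(cov_seed)
    )
    _, cov_var = _covariate_betas(spec.age_range, spec.dx_probs, spec.noise_sd)

    if not planted and n_pairs:
        freq_pairs = [(freqs[i], freqs[j]) for i, j in pair_indices]
        betas, var_y = _solve_planted_betas(
            freq_pairs, cov_var, spec.noise_sd, spec.target_dr2_int, spec.main_share
        )
        planted = [
            PlantedPair(i, j, b1, b2, bi)
            for (i, j), (b1, b2, bi) in zip(pair_indices, betas)
        ]
    else:
        var_y = cov_var + spec.noise_sd**2
        for pair in planted:
            m1, v1 = _moments(freqs[pair.snp1])
            m2, v2 = _moments(freqs[pair.snp2])
            var_y += (
                v1 * (pair.beta1 + pair.beta_int * m2) ** 2
                + v2 * (pair.beta2 + pair.beta_int * m1) ** 2
                + pair.beta_int**2 * v1 * v2
            )

    phenotype, truth = simulate_phenotype(
        dataset, spec, covariates, planted,
        np.random.default_rng(noise_seed), freqs, var_y, cov_var,
    )
    # mirror drawn sex/diagnosis into the sample metadata so written .fam
    # files carry them
    samples = [
        SampleInfo(sid, sex=sx, diagnosis=dx)
        for sid, sx, dx in zip(
            cov_table["sample_id"], cov_table["sex"].map({"male": "male", "female": "female"}),
            cov_table["diagnosis"],
        )
    ]
    dataset = GenotypeDataset(dataset.genotypes, dataset.snps, samples)
    return SimBundle(dataset, phenotype, covariates, cov_table, truth)


def simulate_null(n: int, m: int, seed: int, missing_rate: float = 0.0) -> SimBundle:
    """A bundle with covariate and noise structure but zero genetic effects."""
    spec = SimSpec(
        n_samples=n, n_snps=m, missing_rate=missing_rate,
        n_planted_pairs=0, seed=seed,
    )
    return simulate_study(spec)
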