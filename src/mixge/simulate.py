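"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates a birth-cohort neuroimaging-genetics study:
biallelic SNP dosages in Hardy-Weinberg proportions with optional AR(1)
linkage disequilibrium, an EPDS-like exposure score (integers 0-30,
mean 8.56, SD 4.50), demographic covariates with realistic category
mixes, and a quantitative outcome generated from

    Y = X bX + E bE + G gamma + diag(E) G (pi * 1 + delta) + eps,

with per-SNP main effects gamma, an accumulative interaction pi, random
heterogeneous interactions delta ~ N(0, tau) and Gaussian residual
noise.  The realized truth (gamma, delta, pi, tau, sigma) is recorded
per replicate so recovery and calibration tests can refer to it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotype import GenotypeMatrix, SnpRecord

__all__ = [
    "SimulationConfig",
    "SimTruth",
    "scenario",
    "simulate_genotypes",
    "simulate_exposure",
    "simulate_covariates",
    "simulate_cohort",
    "simulate_scan_dataset",
    "simulate_maternal_genotypes",
    "write_vcf",
    "write_dosage_table",
]

# Demographic mixes follow the neonatal sample of the emulated cohort:
# 87/161 male; ethnicity 45.3/41.6/13.0% Chinese/Malay/Indian; education
# in five ordered bands.
_ETHNICITY = {"chinese": 0.4534, "malay": 0.4162, "indian": 0.1304}
_EDUCATION = {
    "primary": 0.0373,
    "secondary": 0.3354,
    "pre_university": 0.4471,
    "university": 0.1429,
    "postgraduate": 0.0373,
}


@dataclass
class SimulationConfig:
    """Generating parameters of a synthetic cohort.

    Effects are on the outcome scale (mm^3 for a volume-like outcome):
    ``pi_burden`` is the accumulative interaction per (exposure-unit x
    summed dosage), ``tau`` the variance of the per-SNP heterogeneous
    interaction effects, ``sigma`` the residual SD.  ``gamma_main_sd``
    is the SD of per-SNP main effects.  ``ld_rho`` is the AR(1)
    correlation of the latent Gaussian used to generate genotypes.
    """

    n_subjects: int = 161
    n_snps: int = 50
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_rho: float = 0.0
    dosage_jitter_sd: float = 0.0
    exposure_mean: float = 8.56
    exposure_sd: float = 4.50
    exposure_min: int = 0
    exposure_max: int = 30
    male_fraction: float = 87 / 161
    ethnicity_props: dict = field(default_factory=lambda: dict(_ETHNICITY))
    education_props: dict = field(default_factory=lambda: dict(_EDUCATION))
    age_mean: float = 0.027
    age_sd: float = 0.01
    timepoint: str = "birth"
    include_postnatal: bool = False
    postnatal_mean: float = 6.23
    postnatal_sd: float = 4.80
    beta_intercept: float = 1700.0
    beta_sex: float = 80.0
    beta_age: float = 200.0
    beta_E: float = 5.0
    beta_postnatal: float = 2.0
    gamma_main_sd: float = 10.0
    pi_burden: float = 0.0
    tau: float = 0.0
    delta_fixed: np.ndarray | None = None
    sigma: float = 250.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if not (0 <= self.ld_rho < 1):
            raise ValueError("ld_rho must lie in [0, 1)")
        if self.tau < 0 or self.sigma <= 0:
            raise ValueError("need tau >= 0 and sigma > 0")
        for props in (self.ethnicity_props, self.education_props):
            if abs(sum(props.values()) - 1.0) > 1e-6:
                raise ValueError("category proportions must sum to 1")


@dataclass
class SimTruth:
    """Realized generating parameters of one synthetic cohort."""

    pi_burden: float
    tau: float
    sigma: float
    beta_E: float
    gamma: np.ndarray
    delta: np.ndarray
    seed: int


# Scenario presets.  Interaction magnitudes were fixed once by a power
# calculation targeting mid-range power at the default n=161, m=50:
# pi=1.2 gives the burden test moderate power; tau=25 (delta SD 5,
# signs mixed by symmetry) does the same for the variance-component
# test.  "mixed" halves both so neither component saturates.
_SCENARIOS = {
    "null": dict(pi_burden=0.0, tau=0.0),
    "burden": dict(pi_burden=1.2, tau=0.0),
    "heterogeneous": dict(pi_burden=0.0, tau=25.0),
    "mixed": dict(pi_burden=0.8, tau=12.0),
}


def scenario(name: str, **overrides) -> SimulationConfig:
    """Named canonical configurations: null, burden, heterogeneous, mixed."""
    if name not in _SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; choose from {sorted(_SCENARIOS)}")
    params = dict(_SCENARIOS[name])
    params.update(overrides)
    return SimulationConfig(**params)


def _rng(config: SimulationConfig, rng: np.random.Generator | None) -> np.random.Generator:
    return rng if rng is not None else np.random.default_rng(config.seed)


def simulate_genotypes(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    chrom: str = "1",
    pos_start: int = 10_000,
    pos_step: int = 500,
) -> GenotypeMatrix:
    """SNP dosages marginally in Hardy-Weinberg proportions.

    A latent AR(1) Gaussian vector per subject is thresholded at the
    normal quantiles of (1-p)^2 and (1-p)^2 + 2p(1-p) per SNP, giving
    hard calls {0, 1, 2} with HWE margins and LD controlled by
    ``ld_rho``.  With ``dosage_jitter_sd > 0`` the calls are perturbed
    and clipped to [0, 2] to mimic imputed fractional dosages.
    """
    rng = _rng(config, rng)
    n, m = config.n_subjects, config.n_snps
    maf = rng.uniform(*config.maf_range, size=m)
    z = rng.standard_normal((n, m))
    if config.ld_rho > 0:
        for j in range(1, m):
            z[:, j] = config.ld_rho * z[:, j - 1] + np.sqrt(1 - config.ld_rho**2) * z[:, j]
    q0 = (1 - maf) ** 2
    t1 = stats.norm.ppf(q0)
    t2 = stats.norm.ppf(q0 + 2 * maf * (1 - maf))
    dos = (z > t1[None, :]).astype(float) + (z > t2[None, :])
    source = "hard_call"
    if config.dosage_jitter_sd > 0:
        dos = np.clip(dos + rng.normal(0, config.dosage_jitter_sd, size=dos.shape), 0, 2)
        source = "dosage"
    snps = [
        SnpRecord(
            snp_id=f"snp{j:05d}",
            chrom=chrom,
            pos=pos_start + j * pos_step,
            ref_allele="A",
            alt_allele="C",
            maf=float(maf[j]),
            call_source=source,
        )
        for j in range(m)
    ]
    subjects = [f"S{i:04d}" for i in range(n)]
    return GenotypeMatrix(subjects, snps, dos)


def simulate_maternal_genotypes(
    child: GenotypeMatrix,
    rng: np.random.Generator,
) -> GenotypeMatrix:
    """Maternal dosages for the same SNPs and subjects.

    Mothers share one transmitted allele with the child (picked at
    random from the child's two) and draw the other from the population
    frequency, giving realistic mother-child correlation ~0.5.
    """
    maf = np.array([s.maf for s in child.snps])
    d = np.round(child.dosages)
    transmitted = np.where(
        d == 1, rng.integers(0, 2, size=d.shape), (d / 2).astype(int)
    )
    other = rng.binomial(1, maf[None, :], size=d.shape)
    return GenotypeMatrix(
        list(child.subject_ids), list(child.snps), (transmitted + other).astype(float)
    )


def simulate_exposure(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """EPDS-like integer scores: clamped, rounded Gaussian on [0, 30]."""
    rng = _rng(config, rng)
    e = rng.normal(config.exposure_mean, config.exposure_sd, size=config.n_subjects)
    return np.clip(np.round(e), config.exposure_min, config.exposure_max).astype(float)


def simulate_covariates(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Sex, age and categorical covariates with the configured mixes."""
    rng = _rng(config, rng)
    n = config.n_subjects
    sex = np.where(rng.random(n) < config.male_fraction, "male", "female")
    age = rng.normal(config.age_mean, config.age_sd, size=n)
    eth = rng.choice(
        list(config.ethnicity_props), p=list(config.ethnicity_props.values()), size=n
    )
    edu = rng.choice(
        list(config.education_props), p=list(config.education_props.values()), size=n
    )
    return pd.DataFrame(
        {"sex": sex, "age_at_scan": age, "ethnicity": eth, "education": edu}
    )


def simulate_cohort(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, GenotypeMatrix, SimTruth]:
    """Full synthetic cohort: phenotype table, genotypes and truth.

    The outcome column is named "volume".  The exposure enters the
    interaction terms on its raw scale, as in the analysis model.
    """
    rng = _rng(config, rng)
    gm = simulate_genotypes(config, rng)
    e = simulate_exposure(config, rng)
    cov = simulate_covariates(config, rng)
    n, m = config.n_subjects, config.n_snps
    gamma = rng.normal(0.0, config.gamma_main_sd, size=m)
    if config.delta_fixed is not None:
        delta = np.asarray(config.delta_fixed, dtype=float)
        if delta.shape != (m,):
            raise ValueError("delta_fixed must have one entry per SNP")
    else:
        delta = rng.normal(0.0, np.sqrt(config.tau), size=m) if config.tau > 0 else np.zeros(m)
    g = gm.dosages
    y = (
        config.beta_intercept
        + config.beta_sex * (cov["sex"] == "male").to_numpy(float)
        + config.beta_age * cov["age_at_scan"].to_numpy()
        + config.beta_E * e
        + g @ gamma
        + (e[:, None] * g) @ (config.pi_burden * np.ones(m) + delta)
        + rng.normal(0.0, config.sigma, size=n)
    )
    cohort = pd.DataFrame(
        {
            "subject_id": gm.subject_ids,
            "volume": y,
            "E_prenatal": e,
            **{c: cov[c] for c in cov.columns},
            "timepoint": config.timepoint,
        }
    )
    if config.include_postnatal:
        ep = rng.normal(config.postnatal_mean, config.postnatal_sd, size=n)
        cohort["E_postnatal"] = np.clip(np.round(ep), 0, 30)
        cohort["volume"] = cohort["volume"] + config.beta_postnatal * cohort["E_postnatal"]
    truth = SimTruth(
        pi_burden=config.pi_burden,
        tau=config.tau,
        sigma=config.sigma,
        beta_E=config.beta_E,
        gamma=gamma,
        delta=delta,
        seed=config.seed,
    )
    return cohort, gm, truth


def simulate_scan_dataset(
    config: SimulationConfig,
    n_genes: int = 10,
    causal_gene: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, GenotypeMatrix, list, SimTruth]:
    """A multi-gene dataset for end-to-end scan tests.

    ``n_genes`` independent SNP blocks of ``config.n_snps`` each are
    placed 100 kb apart on one chromosome, every gene contributing main
    effects; the configured interaction effects (pi, tau) act only on
    ``causal_gene`` (no gene if None).  Returns (cohort, genotypes,
    loci, truth) where loci is a list of GeneLocus covering each block.
    """
    from dataclasses import replace as _replace

    from .genotype import GeneLocus

    rng = _rng(config, rng)
    n, m = config.n_subjects, config.n_snps
    blocks, loci, snps = [], [], []
    for g in range(n_genes):
        start = 10_000 + g * 100_000
        gm = simulate_genotypes(config, rng, pos_start=start)
        blocks.append(gm.dosages)
        snps.extend(
            _replace(s, snp_id=f"gene{g:02d}_{s.snp_id}") for s in gm.snps
        )
        loci.append(
            GeneLocus(f"gene{g:02d}", "1", start, start + (m - 1) * 500, flank_bp=1000)
        )
    dosages = np.column_stack(blocks)
    subjects = [f"S{i:04d}" for i in range(n)]
    genotypes = GenotypeMatrix(subjects, snps, dosages)
    e = simulate_exposure(config, rng)
    cov = simulate_covariates(config, rng)
    gamma = rng.normal(0.0, config.gamma_main_sd, size=n_genes * m)
    delta = np.zeros(n_genes * m)
    pi_vec = np.zeros(n_genes * m)
    if causal_gene is not None:
        sl = slice(causal_gene * m, (causal_gene + 1) * m)
        pi_vec[sl] = config.pi_burden
        if config.tau > 0:
            delta[sl] = rng.normal(0.0, np.sqrt(config.tau), size=m)
    y = (
        config.beta_intercept
        + config.beta_sex * (cov["sex"] == "male").to_numpy(float)
        + config.beta_age * cov["age_at_scan"].to_numpy()
        + config.beta_E * e
        + dosages @ gamma
        + (e[:, None] * dosages) @ (pi_vec + delta)
        + rng.normal(0.0, config.sigma, size=n)
    )
    cohort = pd.DataFrame(
        {
            "subject_id": subjects,
            "volume": y,
            "E_prenatal": e,
            **{c: cov[c] for c in cov.columns},
            "timepoint": config.timepoint,
        }
    )
    truth = SimTruth(config.pi_burden, config.tau, config.sigma, config.beta_E, gamma, delta, config.seed)
    return cohort, genotypes, loci, truth


# ---------------------------------------------------------------------------
# writers matching the readers' dialects


def write_vcf(gm: GenotypeMatrix, path: str, with_dosage: bool = True) -> None:
    """Write a minimal VCF v4.2 with GT and (optionally) DS fields."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in dict.fromkeys(s.chrom for s in gm.snps):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if with_dosage:
            fh.write(
                '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Alt dosage">\n'
            )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.subject_ids)
            + "\n"
        )
        fmt = "GT:DS" if with_dosage else "GT"
        for j, snp in enumerate(gm.snps):
            cells = []
            for x in gm.dosages[:, j]:
                if np.isnan(x):
                    gt = "./."
                else:
                    h = int(round(x))
                    gt = ["0/0", "0/1", "1/1"][h]
                if with_dosage:
                    cells.append(f"{gt}:." if np.isnan(x) else f"{gt}:{x:g}")
                else:
                    cells.append(gt)
            fh.write(
                f"{snp.chrom}\t{snp.pos}\t{snp.snp_id}\t{snp.ref_allele}\t"
                f"{snp.alt_allele}\t.\tPASS\t.\t{fmt}\t" + "\t".join(cells) + "\n"
            )


def write_dosage_table(gm: GenotypeMatrix, path: str) -> None:
    """Write the plain CSV dosage dialect the reader accepts."""
    df = pd.DataFrame(gm.dosages, columns=gm.snp_ids)
    df.insert(0, "subject_id", gm.subject_ids)
    df.to_csv(path, index=False)
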