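"""Synthetic cohort with a planted mediated genetic architecture.

Generates everything the downstream pipeline consumes — a genotype
panel, a case-control GWAS summary-statistics table, and a per-individual
biomarker/covariate table — with a known causal configuration so that
recovery can be verified:

* a *dependent* variant set acts only on the liability of a binary
  amyloid (mediator) status;
* a disjoint *independent* variant set acts only directly on the
  continuous P-tau outcome;
* the mediator itself shifts the outcome by ``b_med``;
* remaining variants are null.

Genotypes are biallelic, in Hardy-Weinberg equilibrium at a drawn MAF,
with block LD from a haplotype-level first-order autoregressive Gaussian
copula.  Variant effects inside the phenotype models apply to
standardized genotypes z(G) = (G - 2p) / sqrt(2p(1-p)), so effect sizes
are per-SD and comparable across MAFs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .genotypes import GenotypePanel
from .io import SUMSTATS_COLUMNS

DIAGNOSIS_LEVELS = ("CU", "MCI", "AD")


@dataclass(frozen=True)
class CausalConfig:
    """Planted causal architecture for a synthetic cohort.

    Effects are standardized (per SD of genotype / liability / outcome
    noise scale).  ``dependent_set`` variants act on the mediator
    liability only; ``independent_set`` variants act directly on the
    outcome only; the two sets must be disjoint.
    """

    dependent_set: tuple = ()
    independent_set: tuple = ()
    w_dep: float = 0.25
    w_ind: float = 0.15
    mediator_prevalence: float = 0.4
    b_med: float = 0.8
    age_effect_mediator: float = 0.2
    sex_effect_mediator: float = 0.1
    age_effect_outcome: float = 0.2
    sex_effect_outcome: float = 0.1
    sigma_mediator: float = 1.0
    sigma_outcome: float = 1.0
    ab_cutoff: float = 0.091

    def __post_init__(self):
        object.__setattr__(self, "dependent_set", tuple(self.dependent_set))
        object.__setattr__(self, "independent_set", tuple(self.independent_set))
        overlap = set(self.dependent_set) & set(self.independent_set)
        if overlap:
            raise ValueError(f"dependent/independent sets overlap: {sorted(overlap)}")
        if not (0.0 < self.mediator_prevalence < 1.0):
            raise ValueError("mediator_prevalence must be strictly in (0, 1)")
        for name in (
            "w_dep", "w_ind", "b_med",
            "age_effect_mediator", "sex_effect_mediator",
            "age_effect_outcome", "sex_effect_outcome",
            "sigma_mediator", "sigma_outcome",
        ):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"effect size {name} must be finite")

    def null_sets(self, all_ids) -> tuple:
        planted = set(self.dependent_set) | set(self.independent_set)
        return tuple(v for v in all_ids if v not in planted)

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)


@dataclass
class SyntheticCohort:
    """Bundle of simulated data plus the ground-truth configuration."""

    panel: GenotypePanel
    sumstats: pd.DataFrame
    cohort: pd.DataFrame
    config: CausalConfig

    def __post_init__(self):
        panel_ids = set(self.panel.variant_ids)
        if not set(self.sumstats["SNP"]).issubset(panel_ids):
            raise ValueError("summary stats contain variants absent from panel")
        med = self.cohort["abeta_status"]
        if not set(med.dropna().unique()).issubset({0, 1}):
            raise ValueError("mediator column must be binary")


# ------------------------------------------------------------------ genotypes


def simulate_genotypes(
    n_individuals: int,
    n_variants: int,
    maf_range=(0.05, 0.5),
    ld_block_size: int = 1,
    ld_rho: float = 0.0,
    seed: int = 0,
    missing_rate: float = 0.0,
) -> GenotypePanel:
    """Simulate HWE genotypes with block LD.

    Each of the two haplotypes per individual carries a latent Gaussian
    AR(1) process within a block (lag-one correlation ``ld_rho``,
    independent across blocks); the allele indicator thresholds the
    latent variable at the drawn MAF, which preserves HWE marginally
    and yields tunable pairwise r^2 decay within blocks.
    """
    lo, hi = maf_range
    if not (0.05 <= lo <= hi <= 0.5):
        raise ValueError(
            f"maf_range must satisfy 0.05 <= lo <= hi <= 0.5, got {maf_range}"
        )
    if n_individuals < 2:
        raise ValueError("n_individuals must be >= 2")
    if n_variants < 1:
        raise ValueError("n_variants must be >= 1")
    if ld_block_size < 1:
        raise ValueError("ld_block_size must be >= 1")
    if not (0.0 <= ld_rho < 1.0):
        raise ValueError("ld_rho must be in [0, 1)")
    if not (0.0 <= missing_rate < 1.0):
        raise ValueError("missing_rate must be in [0, 1)")

    rng = np.random.default_rng(seed)
    mafs = rng.uniform(lo, hi, size=n_variants)
    thresholds = ndtri(mafs)

    def haplotypes():
        z = np.empty((n_individuals, n_variants))
        for start in range(0, n_variants, ld_block_size):
            stop = min(start + ld_block_size, n_variants)
            width = stop - start
            e = rng.standard_normal((n_individuals, width))
            z[:, start] = e[:, 0]
            for j in range(1, width):
                z[:, start + j] = (
                    ld_rho * z[:, start + j - 1]
                    + np.sqrt(1.0 - ld_rho**2) * e[:, j]
                )
        return (z < thresholds).astype(float)

    dosages = haplotypes() + haplotypes()

    if missing_rate > 0:
        mask = rng.random(dosages.shape) < missing_rate
        dosages[mask] = np.nan

    # metadata: one chromosome per block (cycling 1..22); 10 kb spacing
    # within a block, 2 Mb gaps between same-chromosome blocks so that
    # clumping windows never straddle independent blocks
    n_blocks = (n_variants + ld_block_size - 1) // ld_block_size
    chroms, positions = [], []
    chrom_cursor = {}
    for b in range(n_blocks):
        chrom = str(b % 22 + 1)
        pos = chrom_cursor.get(chrom, 0) + 2_000_000
        width = min(ld_block_size, n_variants - b * ld_block_size)
        for j in range(width):
            chroms.append(chrom)
            positions.append(pos + j * 10_000)
        chrom_cursor[chrom] = positions[-1]
    bases = np.array(list("ACGT"))
    a1 = rng.choice(bases, size=n_variants)
    shift = rng.integers(1, 4, size=n_variants)
    a2 = bases[(np.searchsorted(bases, a1) + shift) % 4]
    variants = pd.DataFrame(
        {
            "id": [f"snp{i:05d}" for i in range(n_variants)],
            "chrom": chroms,
            "pos": positions,
            "a1": a1,
            "a2": a2,
        }
    )
    return GenotypePanel(dosages=dosages, variants=variants)


# -------------------------------------------------------------- summary stats


def simulate_summary_stats(
    panel: GenotypePanel,
    config: CausalConfig,
    gwas_n: float = 50_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Emulate a case-control discovery GWAS over the panel's variants.

    Causal variants carry their configured standardized effect
    (converted to the per-allele scale); estimates are the truth plus
    Gaussian sampling noise with SE = 1 / sqrt(2 * gwas_n * p(1-p)),
    and p-values come from the two-sided normal z of estimate / SE.
    ``gwas_n = inf`` is the noise-free limit (SE treated as 0).
    """
    ids = panel.variant_ids
    known = set(ids)
    for v in tuple(config.dependent_set) + tuple(config.independent_set):
        if v not in known:
            raise ValueError(f"config variant {v!r} not in panel")
    rng = np.random.default_rng(seed)
    freq = panel.allele_frequency()
    het_var = np.clip(2.0 * freq * (1.0 - freq), 1e-12, None)

    w_std = np.zeros(len(ids))
    idx = {v: i for i, v in enumerate(ids)}
    for v in config.dependent_set:
        w_std[idx[v]] = config.w_dep
    for v in config.independent_set:
        w_std[idx[v]] = config.w_ind
    beta_true = w_std / np.sqrt(het_var)

    if np.isinf(gwas_n):
        se = np.zeros(len(ids))
        beta_hat = beta_true.copy()
    else:
        se = 1.0 / np.sqrt(2.0 * gwas_n * freq * (1.0 - freq))
        beta_hat = beta_true + rng.standard_normal(len(ids)) * se
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta_hat / se,
                     np.where(beta_hat == 0, 0.0, np.inf))
    pvals = np.clip(2.0 * (1.0 - ndtr(np.abs(z))), np.finfo(float).tiny, 1.0)
    pvals[np.isinf(z)] = np.finfo(float).tiny

    stats = pd.DataFrame(
        {
            "SNP": ids,
            "CHR": panel.variants["chrom"].to_numpy(),
            "BP": panel.variants["pos"].to_numpy(),
            "A1": panel.variants["a1"].to_numpy(),
            "A2": panel.variants["a2"].to_numpy(),
            "BETA": beta_hat,
            "SE": se,
            "P": pvals,
        }
    )
    return stats[SUMSTATS_COLUMNS]


# ----------------------------------------------------------------- phenotypes


def simulate_phenotypes(
    panel: GenotypePanel, config: CausalConfig, seed: int = 0
) -> pd.DataFrame:
    """Simulate biomarkers, covariates, and the binary amyloid mediator.

    The mediator thresholds a Gaussian liability (dependent-set genetic
    effects + covariates + noise) at its empirical ``1 - prevalence``
    quantile.  The P-tau outcome is ``b_med * mediator`` plus the
    independent-set genetic effects, covariates, and noise; T-tau adds
    further independent noise on top of the same signal.  NfL and
    Abeta1-38/1-40 are null biomarkers (no variant effects), and the
    Abeta1-42 / Abeta42/40 ratio pair is constructed so that
    dichotomizing the ratio at ``ab_cutoff`` (low = pathologic)
    reproduces the mediator exactly.
    """
    ids = panel.variant_ids
    known = set(ids)
    for v in tuple(config.dependent_set) + tuple(config.independent_set):
        if v not in known:
            raise ValueError(f"config variant {v!r} not in panel")

    rng = np.random.default_rng(seed)
    n = panel.n_individuals
    d = panel.imputed()
    freq = np.clip(d.mean(axis=0) / 2.0, 1e-9, 1 - 1e-9)
    zg = (d - 2.0 * freq) / np.sqrt(2.0 * freq * (1.0 - freq))
    idx = {v: i for i, v in enumerate(ids)}

    # covariates (placeholder distributions, not cohort estimates)
    age = rng.uniform(60.0, 85.0, n)
    sex = rng.integers(0, 2, n).astype(float)
    education = rng.uniform(6.0, 20.0, n)
    mmse = rng.choice(
        np.arange(24, 31), size=n, p=[0.04, 0.06, 0.1, 0.15, 0.2, 0.25, 0.2]
    ).astype(float)
    apoe_e4 = rng.choice([0, 1, 2], size=n, p=[0.64, 0.32, 0.04]).astype(float)
    apoe_e2 = rng.choice([0, 1, 2], size=n, p=[0.85, 0.14, 0.01]).astype(float)
    age_z = (age - 72.5) / 7.217  # SD of Uniform(60, 85)

    def genetic(ids_subset, w):
        if not ids_subset:
            return np.zeros(n)
        cols = [idx[v] for v in ids_subset]
        return zg[:, cols].sum(axis=1) * w

    liability = (
        genetic(list(config.dependent_set), config.w_dep)
        + config.age_effect_mediator * age_z
        + config.sex_effect_mediator * sex
        + rng.standard_normal(n) * config.sigma_mediator
    )
    cut = np.quantile(liability, 1.0 - config.mediator_prevalence)
    mediator = (liability > cut).astype(float)

    outcome = (
        config.b_med * mediator
        + genetic(list(config.independent_set), config.w_ind)
        + config.age_effect_outcome * age_z
        + config.sex_effect_outcome * sex
        + rng.standard_normal(n) * config.sigma_outcome
    )

    # concentrations: strictly monotone transforms of the linear signals,
    # so rank-based analyses are unaffected by the scale chosen
    p_tau = 60.0 * np.exp(0.30 * outcome)
    t_tau = 300.0 * np.exp(0.25 * (outcome + rng.standard_normal(n) * 0.5))
    nfl = np.exp(rng.normal(6.7, 0.45, n))
    ab38 = rng.normal(2200.0, 350.0, n).clip(300.0)
    ab40 = rng.normal(10_000.0, 1500.0, n).clip(2000.0)
    # ratio bimodal around the cutoff; pathologic (mediator=1) strictly below
    ratio = np.where(
        mediator == 1.0,
        config.ab_cutoff * rng.uniform(0.45, 0.95, n),
        config.ab_cutoff * rng.uniform(1.05, 1.75, n),
    )
    ab42 = ratio * ab40

    diag_p = {0.0: (0.78, 0.16, 0.06), 1.0: (0.45, 0.30, 0.25)}
    diagnosis = np.array(
        [rng.choice(DIAGNOSIS_LEVELS, p=diag_p[m]) for m in mediator]
    )

    return pd.DataFrame(
        {
            "iid": list(panel.samples),
            "t_tau": t_tau,
            "p_tau181": p_tau,
            "abeta38": ab38,
            "abeta40": ab40,
            "abeta42": ab42,
            "abeta_ratio": ratio,
            "nfl": nfl,
            "abeta_status": mediator,
            "age": age,
            "sex": sex,
            "education": education,
            "mmse": mmse,
            "apoe_e4": apoe_e4,
            "apoe_e2": apoe_e2,
            "diagnosis": diagnosis,
        }
    )


def simulate_cohort(
    n_individuals: int,
    n_variants: int,
    config: CausalConfig | None = None,
    n_dependent: int = 10,
    n_independent: int = 20,
    maf_range=(0.05, 0.5),
    ld_block_size: int = 1,
    ld_rho: float = 0.0,
    gwas_n: float = 50_000,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> SyntheticCohort:
    """One-call generator: genotypes + summary stats + phenotypes.

    When ``config`` is omitted, dependent/independent sets are drawn at
    random (without replacement, disjoint) with the default effect
    sizes.  The root seed is split deterministically per stage.
    """
    ss = np.random.SeedSequence(seed)
    s_geno, s_pick, s_stats, s_pheno = (
        int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(4)
    )
    panel = simulate_genotypes(
        n_individuals,
        n_variants,
        maf_range=maf_range,
        ld_block_size=ld_block_size,
        ld_rho=ld_rho,
        seed=s_geno,
        missing_rate=missing_rate,
    )
    if config is None:
        if n_dependent + n_independent > n_variants:
            raise ValueError("more planted variants requested than simulated")
        rng = np.random.default_rng(s_pick)
        picked = rng.choice(
            panel.variant_ids, size=n_dependent + n_independent, replace=False
        )
        config = CausalConfig(
            dependent_set=tuple(picked[:n_dependent]),
            independent_set=tuple(picked[n_dependent:]),
        )
    sumstats = simulate_summary_stats(panel, config, gwas_n=gwas_n, seed=s_stats)
    cohort = simulate_phenotypes(panel, config, seed=s_pheno)
    return SyntheticCohort(panel=panel, sumstats=sumstats, cohort=cohort, config=config)
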