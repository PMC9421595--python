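"""Genotype container, variant-level QC, pairwise LD, and genotype PCs.

The central object is :class:`GenotypePanel`: an individuals x variants
dosage matrix (minor/effect-allele counts in {0, 1, 2}, ``NaN`` for
missing calls) plus per-variant metadata (id, chromosome, 1-based
position, effect allele A1, other allele A2) and individual ids.

Variant-level QC follows the standard chip-QC regime for autosomal
biallelic variants: call rate, minor allele frequency, and an exact
Hardy-Weinberg equilibrium test.  Person-level QC (sex concordance,
heterozygosity) and imputation are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

VARIANT_COLUMNS = ["id", "chrom", "pos", "a1", "a2"]


@dataclass
class GenotypePanel:
    """Dosage matrix plus variant metadata.

    Attributes
    ----------
    dosages : (n_individuals, n_variants) float array
        Counts of the A1 allele; entries in {0, 1, 2} or NaN (missing).
    variants : DataFrame with columns id, chrom, pos, a1, a2
        1-based inclusive coordinates (VCF/PLINK convention).
    samples : list of individual ids.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    samples: list = field(default_factory=list)

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (individuals x variants)")
        self.variants = self.variants.reset_index(drop=True)
        missing_cols = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing_cols:
            raise ValueError(f"variant table missing columns: {missing_cols}")
        if self.dosages.shape[1] != len(self.variants):
            raise ValueError("column count must equal variant-record count")
        if not self.samples:
            self.samples = [f"id{i:06d}" for i in range(self.dosages.shape[0])]
        if len(self.samples) != self.dosages.shape[0]:
            raise ValueError("sample count must equal dosage row count")
        if self.variants["id"].duplicated().any():
            dup = self.variants["id"][self.variants["id"].duplicated()].tolist()
            raise ValueError(f"duplicate variant ids: {dup[:5]}")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate individual ids")
        if (self.variants["pos"] < 0).any():
            raise ValueError("positions must be non-negative")
        with np.errstate(invalid="ignore"):
            bad = ~np.isnan(self.dosages) & ~np.isin(self.dosages, (0.0, 1.0, 2.0))
        if bad.any():
            raise ValueError("dosages must be in {0, 1, 2} or NaN")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def variant_ids(self) -> list:
        return self.variants["id"].tolist()

    def column_index(self, variant_id) -> int:
        idx = self.variants.index[self.variants["id"] == variant_id]
        if len(idx) == 0:
            raise KeyError(f"variant {variant_id!r} not in panel")
        return int(idx[0])

    def dosage_of(self, variant_id) -> np.ndarray:
        return self.dosages[:, self.column_index(variant_id)]

    def allele_frequency(self) -> np.ndarray:
        """Per-variant A1 allele frequency over non-missing calls."""
        return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        f = self.allele_frequency()
        return np.minimum(f, 1.0 - f)

    def call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosages).mean(axis=0)

    def imputed(self) -> np.ndarray:
        """Dosages with missing entries replaced by the variant mean.

        The per-variant mean equals twice the A1 allele frequency, the
        PLINK-style mean-dosage policy used for both scoring and PCA.
        """
        d = self.dosages.copy()
        means = np.nanmean(d, axis=0)
        means = np.where(np.isnan(means), 0.0, means)
        nan_r, nan_c = np.where(np.isnan(d))
        d[nan_r, nan_c] = means[nan_c]
        return d

    def subset_variants(self, ids) -> "GenotypePanel":
        cols = [self.column_index(v) for v in ids]
        return GenotypePanel(
            dosages=self.dosages[:, cols],
            variants=self.variants.iloc[cols].reset_index(drop=True),
            samples=list(self.samples),
        )


@dataclass(frozen=True)
class QCThresholds:
    """Variant-retention thresholds: MAF >= maf_min, call rate >
    call_rate_min, HWE exact p > hwe_p_min."""

    maf_min: float = 0.05
    call_rate_min: float = 0.99
    hwe_p_min: float = 5e-08

    def __post_init__(self):
        for name in ("maf_min", "call_rate_min", "hwe_p_min"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact two-sided Hardy-Weinberg equilibrium test.

    Conditional on the allele counts, the heterozygote count under HWE
    follows a (hypergeometric-type) exact distribution; the p-value is
    the summed probability of all heterozygote counts no more probable
    than the observed one (ties included).  Returns p in (0, 1].
    """
    counts = (n_AA, n_Aa, n_aa)
    if any(c < 0 or c != int(c) for c in counts):
        raise ValueError("genotype counts must be non-negative integers")
    n_AA, n_Aa, n_aa = (int(c) for c in counts)
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("at least one genotyped individual required")
    n_a = 2 * n_aa + n_Aa
    rare = min(n_a, 2 * n - n_a)
    # feasible heterozygote counts share the parity of the rare-allele count
    hets = np.arange(rare % 2, rare + 1, 2)
    hom_rare = (rare - hets) // 2
    hom_common = n - hets - hom_rare
    logp = hets * np.log(2.0) - (
        gammaln(hom_rare + 1) + gammaln(hets + 1) + gammaln(hom_common + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs = min(n_Aa, rare)  # n_Aa <= rare always holds for consistent counts
    p_obs = probs[hets == n_Aa]
    if len(p_obs) == 0:
        raise ValueError(
            f"heterozygote count {n_Aa} infeasible for rare-allele count {rare}"
        )
    p_obs = float(p_obs[0])
    # ties included: configurations with probability <= observed (tolerance
    # absorbs floating-point noise in the <= comparison)
    p = float(probs[probs <= p_obs * (1.0 + 1e-12)].sum())
    return min(p, 1.0)


def qc_filter(panel: GenotypePanel, thresholds: QCThresholds | None = None):
    """Apply variant-level QC; returns (filtered panel, per-variant report).

    Criteria are evaluated in a fixed order — call rate, MAF, HWE — and
    the report records the first failing criterion per removed variant.
    """
    if thresholds is None:
        thresholds = QCThresholds()
    if panel.n_variants == 0:
        raise ValueError("empty panel")
    call = panel.call_rate()
    maf = panel.maf()
    d = panel.dosages
    n_ref = np.nansum(d == 0.0, axis=0).astype(int)
    n_het = np.nansum(d == 1.0, axis=0).astype(int)
    n_alt = np.nansum(d == 2.0, axis=0).astype(int)

    rows = []
    keep = []
    for j, vid in enumerate(panel.variant_ids):
        reason = ""
        total = n_ref[j] + n_het[j] + n_alt[j]
        hwe_p = np.nan
        if not call[j] > thresholds.call_rate_min:
            reason = "call_rate"
        elif np.isnan(maf[j]) or maf[j] < thresholds.maf_min:
            reason = "maf"
        else:
            hwe_p = hwe_exact_test(n_ref[j], n_het[j], n_alt[j]) if total else np.nan
            if not hwe_p > thresholds.hwe_p_min:
                reason = "hwe"
        kept = reason == ""
        keep.append(kept)
        rows.append(
            {
                "id": vid,
                "kept": kept,
                "reason": reason if not kept else "",
                "call_rate": call[j],
                "maf": maf[j],
                "hwe_p": hwe_p,
            }
        )
    report = pd.DataFrame(rows)
    keep = np.asarray(keep)
    filtered = GenotypePanel(
        dosages=panel.dosages[:, keep],
        variants=panel.variants.loc[keep].reset_index(drop=True),
        samples=list(panel.samples),
    )
    return filtered, report


def ld_r2(panel: GenotypePanel, variant_i, variant_j) -> float:
    """Squared Pearson correlation between two dosage columns.

    Computed on unphased dosages (composite LD), with missing entries
    excluded pairwise.  Symmetric in its arguments.
    """
    x = panel.dosage_of(variant_i)
    y = panel.dosage_of(variant_j)
    mask = ~np.isnan(x) & ~np.isnan(y)
    if mask.sum() < 2:
        raise ValueError("need >=2 individuals with non-missing dosages for both")
    x = x[mask]
    y = y[mask]
    sx = x.std()
    sy = y.std()
    if sx == 0.0 or sy == 0.0:
        raise ValueError("monomorphic dosage column: LD undefined")
    r = float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))
    return min(r * r, 1.0)


def compute_pcs(panel: GenotypePanel, k: int = 10) -> pd.DataFrame:
    """Genotype principal components (population-structure covariates).

    Dosages are mean-imputed per variant, column-standardized, and
    decomposed by SVD; the returned scores are the left singular
    vectors scaled by the singular values.  Sign is fixed per component
    so the largest-magnitude variant loading is positive.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > min(panel.n_individuals, panel.n_variants):
        raise ValueError("k exceeds min(individuals, variants)")
    d = panel.imputed()
    d = d - d.mean(axis=0)
    sd = d.std(axis=0)
    nz = sd > 0
    d[:, nz] = d[:, nz] / sd[nz]
    u, s, vt = np.linalg.svd(d, full_matrices=False)
    rank = int((s > s[0] * 1e-9).sum()) if s.size and s[0] > 0 else 0
    if k > rank:
        raise ValueError(f"k={k} exceeds matrix rank {rank}")
    u = u[:, :k]
    s = s[:k]
    v = vt[:k].T
    for j in range(k):
        i_star = int(np.argmax(np.abs(v[:, j])))
        if v[i_star, j] < 0:
            u[:, j] = -u[:, j]
            v[:, j] = -v[:, j]
    scores = u * s
    return pd.DataFrame(
        scores, index=list(panel.samples), columns=[f"PC{i+1}" for i in range(k)]
    )
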