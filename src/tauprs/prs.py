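"""Polygenic risk scores: LD clumping, region exclusion, weighted scoring,
and the p-value-threshold model series (PRS1-PRS7).

A PRS is the weighted sum of effect-allele dosages, with weights taken
from external GWAS summary statistics.  Variants are first greedily
clumped (most significant variant retained per correlated neighborhood,
r^2 < 0.1 over 1,000 kb by default) after excluding the APOE region
(chr19:44,400,000-46,500,000, GRCh37), then subset at successively
stricter GWAS p-value thresholds to yield a nested family of models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypePanel, ld_r2

DEFAULT_THRESHOLDS = (0.05, 5e-3, 5e-4, 5e-5, 5e-6, 5e-7, 5e-8)


@dataclass(frozen=True)
class GenomicRegion:
    """1-based inclusive genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("region start must be <= end")
        object.__setattr__(self, "chrom", str(self.chrom).removeprefix("chr"))


#: APOE locus on GRCh37/hg19, excluded from the main PRS models.
APOE_REGION = GenomicRegion(chrom="19", start=44_400_000, end=46_500_000)


@dataclass
class PRSModel:
    """A single thresholded PRS: retained variants, weights, and scores.

    ``scores`` is z-scored over the cohort (association effect sizes are
    then per SD of PRS); ``raw_scores`` keeps the unnormalized dot
    product.
    """

    label: str
    threshold: float
    variant_ids: list
    weights: dict
    raw_scores: np.ndarray
    scores: np.ndarray
    includes_apoe: bool = False
    warning: str | None = None

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)


def exclude_region(stats: pd.DataFrame, region: GenomicRegion) -> pd.DataFrame:
    """Drop variants inside a region (inclusive bounds); order preserved."""
    chrom = stats["CHR"].astype(str).str.removeprefix("chr")
    inside = (
        (chrom == region.chrom)
        & (stats["BP"] >= region.start)
        & (stats["BP"] <= region.end)
    )
    return stats.loc[~inside].reset_index(drop=True)


def clump(
    stats: pd.DataFrame,
    panel: GenotypePanel,
    r2_max: float = 0.1,
    window_kb: float = 1000.0,
) -> list:
    """Greedy LD clumping; returns retained variant ids.

    Variants are visited by ascending p-value (ties: smaller position,
    then id); each visited variant that is still active is retained as
    an index, and every remaining variant on the same chromosome within
    ``window_kb`` with r^2 >= ``r2_max`` against it is removed.
    """
    if len(stats) == 0:
        return []
    missing = set(stats["SNP"]) - set(panel.variant_ids)
    if missing:
        raise ValueError(f"summary-stats variants absent from panel: {sorted(missing)[:5]}")
    window = window_kb * 1000.0
    df = stats[["SNP", "CHR", "BP", "P"]].copy()
    df["CHR"] = df["CHR"].astype(str)
    df = df.sort_values(["P", "BP", "SNP"], kind="mergesort").reset_index(drop=True)
    active = dict.fromkeys(df["SNP"], True)
    by_chrom = {c: g for c, g in df.groupby("CHR")}
    retained = []
    for row in df.itertuples(index=False):
        if not active[row.SNP]:
            continue
        active[row.SNP] = False
        retained.append(row.SNP)
        near = by_chrom[row.CHR]
        near = near[(near["BP"] - row.BP).abs() <= window]
        for other in near.itertuples(index=False):
            if not active.get(other.SNP, False):
                continue
            try:
                r2 = ld_r2(panel, row.SNP, other.SNP)
            except ValueError:
                continue  # monomorphic partner cannot be in LD
            if r2 >= r2_max:
                active[other.SNP] = False
    return retained


def score(
    panel: GenotypePanel,
    weights: dict,
    stats_alleles: dict | None = None,
) -> np.ndarray:
    """Weighted allele score per individual (raw dot product).

    ``weights`` maps variant id -> effect size on the summary-stats
    effect allele.  When ``stats_alleles`` (id -> (A1, A2)) is given,
    alleles are harmonized against the panel: a swapped A1/A2 reflects
    the dosage (2 - G); any other mismatch — including a pair that only
    matches by strand complement (A/T, C/G ambiguity) — is an error.
    Missing dosages are mean-imputed (2 x effect-allele frequency).
    """
    absent = [v for v in weights if v not in set(panel.variant_ids)]
    if absent:
        raise ValueError(f"weights reference variants absent from panel: {absent[:5]}")
    total = np.zeros(panel.n_individuals)
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    for vid, beta in weights.items():
        j = panel.column_index(vid)
        d = panel.dosages[:, j]
        mean = np.nanmean(d)
        d = np.where(np.isnan(d), 0.0 if np.isnan(mean) else mean, d)
        if stats_alleles is not None:
            sa1, sa2 = stats_alleles[vid]
            pa1 = panel.variants.at[j, "a1"]
            pa2 = panel.variants.at[j, "a2"]
            if (sa1, sa2) == (pa1, pa2):
                pass
            elif (sa1, sa2) == (pa2, pa1):
                d = 2.0 - d
            elif {sa1, sa2} == {comp[pa1], comp[pa2]}:
                raise ValueError(
                    f"strand-ambiguous allele mismatch for {vid}: "
                    f"stats {sa1}/{sa2} vs panel {pa1}/{pa2}"
                )
            else:
                raise ValueError(
                    f"allele mismatch for {vid}: stats {sa1}/{sa2} "
                    f"vs panel {pa1}/{pa2}"
                )
        total += beta * d
    return total


def standardize(raw: np.ndarray) -> np.ndarray:
    """Z-score a raw PRS vector; all-constant input maps to zeros."""
    sd = raw.std()
    if sd == 0:
        return np.zeros_like(raw)
    out = (raw - raw.mean()) / sd
    return out - out.mean()  # second pass keeps |mean| at rounding level


def threshold_series(
    stats: pd.DataFrame,
    panel: GenotypePanel,
    thresholds=DEFAULT_THRESHOLDS,
    r2_max: float = 0.1,
    window_kb: float = 1000.0,
    apoe_region: GenomicRegion | None = APOE_REGION,
    labels=None,
) -> list:
    """Build the nested PRS model family over a threshold ladder.

    Region exclusion and clumping run once on the full summary stats;
    each threshold then subsets the clumped variant list (p <=
    threshold), so stricter models' variant sets are nested inside
    looser ones.  Set ``apoe_region=None`` for the APOE-inclusive
    models.
    """
    thresholds = list(thresholds)
    if any(b >= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be strictly decreasing")
    if labels is None:
        labels = [f"PRS{i+1}" for i in range(len(thresholds))]
    includes_apoe = apoe_region is None
    working = stats if includes_apoe else exclude_region(stats, apoe_region)
    clumped = clump(working, panel, r2_max=r2_max, window_kb=window_kb)
    sub = working.set_index("SNP").loc[clumped]
    models = []
    for label, thr in zip(labels, thresholds):
        keep = sub[sub["P"] <= thr]
        ids = keep.index.tolist()
        weights = dict(zip(ids, keep["BETA"]))
        alleles = {v: (keep.at[v, "A1"], keep.at[v, "A2"]) for v in ids}
        warning = None
        if ids:
            raw = score(panel, weights, stats_alleles=alleles)
        else:
            raw = np.zeros(panel.n_individuals)
            warning = f"{label}: no variants at p <= {thr:g}"
            warnings.warn(warning, stacklevel=2)
        models.append(
            PRSModel(
                label=label,
                threshold=thr,
                variant_ids=ids,
                weights=weights,
                raw_scores=raw,
                scores=standardize(raw),
                includes_apoe=includes_apoe,
                warning=warning,
            )
        )
    return models


def models_to_frame(models, samples) -> pd.DataFrame:
    """Standardized scores as a tidy table: iid + one column per model."""
    out = pd.DataFrame({"iid": list(samples)})
    for m in models:
        out[m.label] = m.scores
    return out
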