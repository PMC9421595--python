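"""Readers and writers for the on-disk interchange formats.

Everything is plain text: tab-separated tables with headers, plus an
optional VCF path for genotypes.  Dialects:

* dosage TSV — first column ``iid``, one column per variant id; missing
  dosages as ``NA``.
* variant TSV — columns ``id, chrom, pos, a1, a2`` (1-based positions).
* summary-stats TSV — columns ``SNP, CHR, BP, A1, A2, BETA, SE, P``
  (header required).
* cohort TSV — one row per individual, ``iid`` column first.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genotypes import VARIANT_COLUMNS, GenotypePanel

SUMSTATS_COLUMNS = ["SNP", "CHR", "BP", "A1", "A2", "BETA", "SE", "P"]


# ---------------------------------------------------------------- genotypes


def write_dosages_tsv(panel: GenotypePanel, path) -> None:
    df = pd.DataFrame(panel.dosages, columns=panel.variant_ids)
    df.insert(0, "iid", panel.samples)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def write_variants_tsv(panel: GenotypePanel, path) -> None:
    panel.variants[VARIANT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_panel_tsv(dosage_path, variant_path) -> GenotypePanel:
    dos = pd.read_csv(dosage_path, sep="\t", na_values=["NA"])
    variants = pd.read_csv(variant_path, sep="\t", dtype={"chrom": str})
    samples = dos["iid"].astype(str).tolist()
    matrix = dos.drop(columns=["iid"])
    if list(matrix.columns) != variants["id"].astype(str).tolist():
        raise ValueError("dosage columns do not match variant table ids")
    return GenotypePanel(
        dosages=matrix.to_numpy(dtype=float), variants=variants, samples=samples
    )


def read_vcf(path) -> GenotypePanel:
    """Read GT fields from a VCF into a panel (dosage of ALT, taken as A1)."""
    from cyvcf2 import VCF  # optional dependency, text VCFs supported

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, chroms, poss, a1s, a2s, cols = [], [], [], [], [], []
    for rec in vcf:
        if len(rec.ALT) != 1:
            continue  # biallelic only
        ids.append(rec.ID or f"{rec.CHROM}:{rec.POS}")
        chroms.append(str(rec.CHROM).removeprefix("chr"))
        poss.append(rec.POS)
        a1s.append(rec.ALT[0])
        a2s.append(rec.REF)
        gts = rec.genotype.array()[:, :2]
        dose = np.where((gts < 0).any(axis=1), np.nan, (gts > 0).sum(axis=1))
        cols.append(dose.astype(float))
    variants = pd.DataFrame(
        {"id": ids, "chrom": chroms, "pos": poss, "a1": a1s, "a2": a2s}
    )
    return GenotypePanel(
        dosages=np.column_stack(cols) if cols else np.empty((len(samples), 0)),
        variants=variants,
        samples=samples,
    )


def write_vcf(panel: GenotypePanel, path) -> None:
    """Minimal unphased GT-only VCF (A2 as REF, A1 as ALT)."""
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(s) for s in panel.samples)
            + "\n"
        )
        order = np.lexsort((panel.variants["pos"], panel.variants["chrom"]))
        for j in order:
            v = panel.variants.iloc[j]
            gts = [
                gt_map.get(d, "./.") if not np.isnan(d) else "./."
                for d in panel.dosages[:, j]
            ]
            fh.write(
                f"{v['chrom']}\t{v['pos']}\t{v['id']}\t{v['a2']}\t{v['a1']}"
                f"\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


# ------------------------------------------------------------ summary stats


def write_sumstats_tsv(stats: pd.DataFrame, path) -> None:
    stats[SUMSTATS_COLUMNS].to_csv(path, sep="\t", index=False)


def read_sumstats_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"CHR": str})
    missing = [c for c in SUMSTATS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"summary-stats file missing required columns: {missing}")
    return df


# ------------------------------------------------------------------ cohort


def write_cohort_tsv(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_cohort_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])


def write_table_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    """Generic tidy-table writer (QC reports, PC scores, scan results)."""
    df.to_csv(path, sep="\t", index=index, na_rep="NA")
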