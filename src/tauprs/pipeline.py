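"""Pipeline orchestration: simulate -> QC -> PCs -> PRS series -> scans ->
mediation -> decomposition, driven by a single YAML config.

Every stage writes TSV/JSON outputs into the configured directory and a
manifest records the config hash, seed, and a checksum per output file;
rerunning the same config reproduces byte-identical outputs (one root
seed, split deterministically per stage).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association, decomposition, io, mediation, prs, synthetic
from .genotypes import QCThresholds, compute_pcs, qc_filter

STAGES = [
    "inputs", "qc", "pca", "prs", "scan", "scan_adjusted", "mediation",
    "decomposition",
]


@dataclass
class RunConfig:
    """Validated pipeline configuration (see ``load_config``)."""

    seed: int
    output_dir: str
    simulate: dict | None = None
    inputs: dict | None = None
    qc: dict = field(default_factory=dict)
    clump: dict = field(default_factory=dict)
    thresholds: list = field(default_factory=lambda: list(prs.DEFAULT_THRESHOLDS))
    exclude_apoe: bool = True
    apoe_region: dict = field(default_factory=dict)
    n_pcs: int = 10
    ab_cutoff: float = 0.091
    pathologic_low: bool = True
    alpha: float = 0.05
    mediation: dict = field(default_factory=dict)
    decomposition: dict = field(default_factory=dict)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return validate_config(raw)


def validate_config(raw: dict) -> RunConfig:
    """Schema check with an aggregated error report (no partial runs)."""
    errors = []
    if "seed" not in raw:
        errors.append("seed is mandatory")
    elif not isinstance(raw["seed"], int):
        errors.append("seed must be an integer")
    if "output_dir" not in raw:
        errors.append("output_dir is mandatory")
    has_sim = raw.get("simulate") is not None
    has_inp = raw.get("inputs") is not None
    if has_sim == has_inp:
        errors.append("exactly one of 'simulate' or 'inputs' must be given")
    if has_inp:
        need = {"dosages", "variants", "sumstats", "cohort"}
        missing = need - set(raw["inputs"] or {})
        if missing:
            errors.append(f"inputs block missing paths: {sorted(missing)}")
    thr = raw.get("thresholds", list(prs.DEFAULT_THRESHOLDS))
    if any(b >= a for a, b in zip(thr, thr[1:])):
        errors.append("thresholds must be strictly decreasing")
    known = {f.name for f in RunConfig.__dataclass_fields__.values()}
    unknown = set(raw) - known
    if unknown:
        errors.append(f"unknown config keys: {sorted(unknown)}")
    if errors:
        raise ValueError("invalid config:\n  - " + "\n  - ".join(errors))
    return RunConfig(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _config_hash(config: RunConfig) -> str:
    from dataclasses import asdict

    canonical = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()


def _stage_seed(root_seed: int, stage: str) -> int:
    ss = np.random.SeedSequence([root_seed, STAGES.index(stage)])
    return int(ss.generate_state(1)[0] % (2**31))


def run(config: RunConfig) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config_hash": _config_hash(config), "seed": config.seed, "stages": {}}

    def record(stage: str, files: dict, extra: dict | None = None):
        entry = {"status": "ok", "outputs": {n: _sha256(p) for n, p in files.items()}}
        if extra:
            entry.update(extra)
        manifest["stages"][stage] = entry

    # ---- inputs: simulate or load -------------------------------------
    if config.simulate is not None:
        sim = dict(config.simulate)
        causal = sim.pop("causal", {})
        syn = synthetic.simulate_cohort(
            n_individuals=sim.get("n_individuals", 2000),
            n_variants=sim.get("n_variants", 500),
            n_dependent=causal.get("n_dependent", 10),
            n_independent=causal.get("n_independent", 20),
            maf_range=tuple(sim.get("maf_range", (0.05, 0.5))),
            ld_block_size=sim.get("ld_block_size", 1),
            ld_rho=sim.get("ld_rho", 0.0),
            gwas_n=sim.get("gwas_n", 50_000),
            missing_rate=sim.get("missing_rate", 0.0),
            seed=_stage_seed(config.seed, "inputs"),
        )
        panel, sumstats, cohort = syn.panel, syn.sumstats, syn.cohort
        files = {
            "dosages.tsv": out / "dosages.tsv",
            "variants.tsv": out / "variants.tsv",
            "sumstats.tsv": out / "sumstats.tsv",
            "cohort.tsv": out / "cohort.tsv",
            "ground_truth.json": out / "ground_truth.json",
        }
        io.write_dosages_tsv(panel, files["dosages.tsv"])
        io.write_variants_tsv(panel, files["variants.tsv"])
        io.write_sumstats_tsv(sumstats, files["sumstats.tsv"])
        io.write_cohort_tsv(cohort, files["cohort.tsv"])
        files["ground_truth.json"].write_text(syn.config.to_json())
        record("inputs", files, {"n_individuals": panel.n_individuals,
                                 "n_variants": panel.n_variants})
    else:
        panel = io.read_panel_tsv(config.inputs["dosages"], config.inputs["variants"])
        sumstats = io.read_sumstats_tsv(config.inputs["sumstats"])
        cohort = io.read_cohort_tsv(config.inputs["cohort"])
        record("inputs", {}, {"n_individuals": panel.n_individuals,
                              "n_variants": panel.n_variants})

    # ---- variant QC ----------------------------------------------------
    thresholds = QCThresholds(**config.qc)
    panel, qc_report = qc_filter(panel, thresholds)
    sumstats = sumstats[sumstats["SNP"].isin(panel.variant_ids)].reset_index(drop=True)
    p = out / "qc_report.tsv"
    io.write_table_tsv(qc_report, p)
    record("qc", {"qc_report.tsv": p},
           {"n_in": len(qc_report), "n_out": panel.n_variants,
            "dropped": {r: int(c) for r, c in
                        qc_report.loc[~qc_report["kept"], "reason"]
                        .value_counts().items()}})

    # ---- genotype PCs --------------------------------------------------
    n_pcs = min(config.n_pcs, panel.n_individuals, panel.n_variants)
    pcs = compute_pcs(panel, k=n_pcs)
    cohort = cohort.reset_index(drop=True)
    for col in pcs.columns:
        cohort[col] = pcs[col].to_numpy()
    p = out / "pc_scores.tsv"
    io.write_table_tsv(pcs.reset_index(names="iid"), p)
    record("pca", {"pc_scores.tsv": p}, {"k": n_pcs})

    # ---- PRS series ----------------------------------------------------
    region = (
        prs.GenomicRegion(**config.apoe_region)
        if config.apoe_region
        else prs.APOE_REGION
    )
    models = prs.threshold_series(
        sumstats,
        panel,
        thresholds=config.thresholds,
        r2_max=config.clump.get("r2_max", 0.1),
        window_kb=config.clump.get("window_kb", 1000),
        apoe_region=region if config.exclude_apoe else None,
    )
    p = out / "prs_scores.tsv"
    io.write_table_tsv(prs.models_to_frame(models, panel.samples), p)
    record("prs", {"prs_scores.tsv": p},
           {"variant_counts": {m.label: m.n_variants for m in models}})

    # ---- association scans --------------------------------------------
    scan_kwargs = dict(
        n_pcs=n_pcs, ab_cutoff=config.ab_cutoff,
        pathologic_low=config.pathologic_low, alpha=config.alpha,
    )
    usable = [m for m in models if m.n_variants > 0]
    results = association.scan(usable, cohort, adjust_for_mediator=False, **scan_kwargs)
    p = out / "associations.tsv"
    io.write_table_tsv(results, p)
    record("scan", {"associations.tsv": p})

    results_adj = association.scan(
        usable, cohort, adjust_for_mediator=True, **scan_kwargs
    )
    p = out / "associations_mediator_adjusted.tsv"
    io.write_table_tsv(results_adj, p)
    record("scan_adjusted", {"associations_mediator_adjusted.tsv": p})

    # ---- mediation of the configured model on P-tau181 -----------------
    med_label = config.mediation.get("model", "PRS1")
    model = next((m for m in usable if m.label == med_label), None)
    covariates = association.covariate_matrix(
        cohort, include_apoe=not (model.includes_apoe if model else False),
        n_pcs=n_pcs,
    )
    outcome = association.inverse_normal_transform(cohort["p_tau181"])
    mediator_v = cohort[association.MEDIATOR_COLUMN].to_numpy(dtype=float)
    if model is None:
        manifest["stages"]["mediation"] = {
            "status": f"skipped: model {med_label} empty or absent", "outputs": {}}
        manifest["stages"]["decomposition"] = {
            "status": "skipped: upstream mediation skipped", "outputs": {}}
    else:
        med = mediation.mediate(
            model.scores, mediator_v, outcome, covariates=covariates,
            n_boot=config.mediation.get("n_boot", 1000),
            seed=_stage_seed(config.seed, "mediation"),
        )
        p = out / "mediation.json"
        p.write_text(json.dumps(med.to_dict(), indent=2, sort_keys=True))
        record("mediation", {"mediation.json": p}, {"model": med_label})

        # ---- decomposition of the configured model ---------------------
        dec_cfg = config.decomposition
        dec_label = dec_cfg.get("model", med_label)
        dmodel = next((m for m in usable if m.label == dec_label), None)
        if dmodel is None or dmodel.n_variants < 2:
            manifest["stages"]["decomposition"] = {
                "status": f"skipped: model {dec_label} too small", "outputs": {}}
        else:
            result = decomposition.decompose(
                panel,
                dmodel.weights,
                outcome,
                mediator_v,
                covariates=association.covariate_matrix(
                    cohort, include_apoe=not dmodel.includes_apoe, n_pcs=n_pcs
                ),
                alpha=dec_cfg.get("alpha", config.alpha),
                n_boot_screen=dec_cfg.get("n_boot_screen", 200),
                n_boot_final=dec_cfg.get("n_boot_final", 1000),
                order=dec_cfg.get("order", "ascending"),
                seed=_stage_seed(config.seed, "decomposition"),
            )
            files = {
                "loo_scan.tsv": out / "loo_scan.tsv",
                "nested_profile.tsv": out / "nested_profile.tsv",
                "independent_subset.txt": out / "independent_subset.txt",
                "dependent_subset.txt": out / "dependent_subset.txt",
                "decomposition.json": out / "decomposition.json",
            }
            io.write_table_tsv(
                pd.DataFrame([r.__dict__ for r in result.loo_records]),
                files["loo_scan.tsv"],
            )
            io.write_table_tsv(result.profile.frame, files["nested_profile.tsv"])
            files["independent_subset.txt"].write_text(
                "\n".join(result.optimal_independent_subset) + "\n"
                if result.optimal_independent_subset else "")
            files["dependent_subset.txt"].write_text(
                "\n".join(result.exclusive_dependent_subset) + "\n"
                if result.exclusive_dependent_subset else "")
            files["decomposition.json"].write_text(json.dumps(
                {
                    "model": dec_label,
                    "n_strengthened": result.n_strengthened,
                    "n_weakened": result.n_weakened,
                    "candidate_ks": result.selection.candidate_ks,
                    "optimal_k": result.selection.optimal_k,
                    "independent_validation": result.independent_validation,
                    "dependent_validation": result.dependent_validation,
                    "joint": result.joint,
                },
                indent=2, sort_keys=True,
            ))
            record("decomposition", files, {"model": dec_label})

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
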