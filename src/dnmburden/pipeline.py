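"""End-to-end orchestration: simulate -> discover -> annotate -> hard-call
-> burden/association, with a reproducible run report.

The report mirrors the study flow: DNM discovery in trios yields candidate
genes, which define the gene set for imputation-style hard-calling and
rare-variant burden testing in a case-control cohort. A run is a pure
function of (config, seed): identical configs produce byte-identical
reports.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotate, association, hardcall, io as dio, trio
from .models import GeneModel
from .synthetic import (CohortSimConfig, TrioSimConfig, default_gene_panel,
                        simulate_cohort, simulate_trios)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Thresholds and stage toggles for a full pipeline run.

    Defaults follow the study's analysis settings: info-score floor 0.3,
    hard-call probability 0.5, variant/individual missingness 0.10 / 0.08,
    MAF 0.01 as the rare/common boundary, 5% FDR over the tested genes,
    alpha 0.05. Cohort sizes for the default run are desk-scale; the
    simulator's own defaults carry the full study sizes.
    """

    seed: int = 0
    outdir: str = "dnmburden_run"
    # stage toggles
    run_discovery: bool = True
    run_association: bool = True
    run_common_scan: bool = True
    # discovery
    trio_overrides: dict = field(default_factory=dict)
    posterior_threshold: float = 0.9
    # association
    explicit_genes: list = field(default_factory=list)  # used when discovery is off
    cohort_n_cases: int = 800
    cohort_n_controls: int = 1400
    cohort_overrides: dict = field(default_factory=dict)
    info_min: float = 0.3
    variant_missing_max: float = 0.10
    individual_missing_max: float = 0.08
    rare_maf_threshold: float = 0.01
    common_maf_min: float = 0.01
    fdr_q: float = 0.05
    alpha: float = 0.05
    bonferroni_n_tests: int = 3000
    write_intermediates: bool = True

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)


def config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def validate_fixtures() -> dict:
    """Schema checks on the packaged variant and gene fixture tables."""
    problems = []
    t1 = annotate.load_variant_table()
    if len(t1) != 14:
        problems.append(f"variant table has {len(t1)} rows, expected 14")
    keys = list(zip(t1["chrom"], t1["pos"], t1["ref"], t1["alt"]))
    if len(set(keys)) != len(keys):
        problems.append("variant table has a duplicated variant key")
    bad_class = set(t1["mutation_class"]) - {"Ti", "Tv", "TiCpG"}
    if bad_class:
        problems.append(f"unknown mutation classes: {sorted(bad_class)}")
    if (t1["cadd_phred"] < 0).any():
        problems.append("negative CADD score in variant table")
    maf = t1["exac_maf"].dropna()
    if ((maf <= 0) | (maf > 1)).any():
        problems.append("exac_maf outside (0, 1]")

    t2 = annotate.load_gene_table()
    if len(t2) != 14:
        problems.append(f"gene table has {len(t2)} rows, expected 14")
    if t2["gene"].duplicated().any():
        dup = t2.loc[t2["gene"].duplicated(), "gene"].tolist()
        problems.append(f"duplicated gene rows: {dup}")
    n_unscored = int(t2["constraint_z"].isna().sum())
    if n_unscored != 1:
        problems.append(f"{n_unscored} genes lack a constraint score, expected 1")
    if not set(t1["gene"]) <= set(t2["gene"]):
        problems.append("variant-table genes missing from gene table")
    return {"passed": not problems, "problems": problems}


class _StageLogger:
    """JSON-lines stage log with timings (timings never enter the report)."""

    def __init__(self, path):
        self.path = Path(path)
        self.path.write_text("")

    def stage(self, name, **payload):
        entry = {"stage": name, "elapsed_s": payload.pop("elapsed_s", None), **payload}
        with open(self.path, "a") as fh:
            fh.write(json.dumps(entry, sort_keys=True, default=str) + "\n")


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the enabled stages in order and return the run report."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage_log = _StageLogger(outdir / "run_log.jsonl")
    report = {
        "provenance": {"seed": cfg.seed, "config_hash": config_hash(cfg),
                       "config": cfg.to_dict()},
        "fixtures": validate_fixtures(),
    }

    candidate_genes: list = []
    gene_models: dict = {}

    if cfg.run_discovery:
        t0 = time.perf_counter()
        trio_cfg = TrioSimConfig(seed=cfg.seed, **cfg.trio_overrides)
        sim = simulate_trios(trio_cfg)
        paths = sim.write(outdir / "trios") if cfg.write_intermediates else {}
        gene_models = {g.gene_id: g for g in sim.genes}

        if cfg.write_intermediates:
            ped = dio.read_ped(paths["ped"])
            observations = dio.read_trio_vcf(paths["vcf"], ped)
        else:
            sim.write(outdir / "trios")
            ped = dio.read_ped(outdir / "trios" / "trios.ped")
            observations = dio.read_trio_vcf(outdir / "trios" / "trios.vcf", ped)
        candidates, cascade = trio.run_filter_cascade(
            observations, sim.annotation, sim.nepg_genes,
            eps=trio_cfg.seq_error, threshold=cfg.posterior_threshold)
        obs_by_key = {(o.site.key, o.family_id): o for o in observations}
        survivors = [c for c in candidates if c.final_status == "candidate"]
        for c in survivors:
            trio.flag_false_positive_modes(c, obs_by_key[(c.site.key, c.family_id)])
        scan = trio.case_only_scan(observations, sim.annotation,
                                   maf_threshold=cfg.rare_maf_threshold,
                                   eps=trio_cfg.seq_error,
                                   threshold=cfg.posterior_threshold)
        cand_frame = trio.candidates_to_frame(candidates)
        if cfg.write_intermediates:
            dio.write_tsv(outdir / "dnm_candidates.tsv", cand_frame)
            (outdir / "cascade_report.json").write_text(
                json.dumps(cascade.to_dict(), indent=2, sort_keys=True))
        candidate_genes = sorted({c.gene for c in survivors if c.gene})
        report["discovery"] = {
            "cascade": cascade.to_dict(),
            "n_survivors": len(survivors),
            "n_mosaic_flagged": int(sum(c.mosaic for c in survivors)),
            "n_psv_flagged": int(sum(c.psv_suspect for c in survivors)),
            "candidate_genes": candidate_genes,
            "case_only_scan": scan,
        }
        stage_log.stage("discovery", elapsed_s=round(time.perf_counter() - t0, 3),
                        n_survivors=len(survivors))

    # variant/gene fixture summaries (the Table-1/2-style metrics section)
    report["annotation_summary"] = {
        "variant_metrics": annotate.summarize_variant_metrics(annotate.load_variant_table()),
        "gene_metrics": annotate.summarize_gene_metrics(annotate.load_gene_table()),
    }

    if cfg.run_association:
        t0 = time.perf_counter()
        if not cfg.run_discovery or not candidate_genes:
            genes = (list(cfg.explicit_genes) or
                     [g.gene_id for g in default_gene_panel(14)])
            gene_models = gene_models or {g.gene_id: g for g in default_gene_panel(60)}
            candidate_genes = [g for g in genes if g in gene_models] or list(gene_models)[:14]
        assoc_genes = [gene_models[g] for g in candidate_genes]
        cohort_kwargs = dict(
            n_cases=cfg.cohort_n_cases, n_controls=cfg.cohort_n_controls,
            genes=assoc_genes, seed=cfg.seed + 1)
        cohort_kwargs.update(cfg.cohort_overrides)
        cohort_cfg = CohortSimConfig(**cohort_kwargs)
        cohort = simulate_cohort(cohort_cfg)
        if cfg.write_intermediates:
            cohort.write(outdir / "cohort")

        gpm = hardcall.restrict_to_regions(cohort.gpm, assoc_genes)
        hcm, call_report = hardcall.apply_call_filters(
            gpm, info_min=cfg.info_min,
            variant_missing_max=cfg.variant_missing_max,
            individual_missing_max=cfg.individual_missing_max)
        if cfg.write_intermediates:
            (outdir / "hardcall_report.json").write_text(
                json.dumps(call_report, indent=2, sort_keys=True))
            dosage = pd.DataFrame(hcm.genotypes, columns=hcm.samples)
            dosage.insert(0, "pos", hcm.variants["pos"].to_numpy())
            dosage.insert(0, "chrom", hcm.variants["chrom"].to_numpy())
            dio.write_tsv(outdir / "hard_calls.tsv", dosage)
        report["hardcall"] = call_report

        results = [association.gene_burden_test(hcm, g, cohort.phenotypes,
                                                maf_threshold=cfg.rare_maf_threshold)
                   for g in assoc_genes]
        flags = association.fdr_correct([r.p_value for r in results], q=cfg.fdr_q)
        for r, f in zip(results, flags):
            r.fdr_significant = bool(f)
        pooled = (association.pooled_burden_test(hcm, assoc_genes, cohort.phenotypes,
                                                 maf_threshold=cfg.rare_maf_threshold)
                  if len(assoc_genes) >= 2 else None)
        sub_results = {}
        for label in cohort_cfg.subpheno_rates:
            sub = [association.subphenotype_burden(hcm, g, cohort.phenotypes, label,
                                                   maf_threshold=cfg.rare_maf_threshold)
                   for g in assoc_genes]
            sub_flags = association.fdr_correct([r.p_value for r in sub], q=cfg.fdr_q)
            for r, f in zip(sub, sub_flags):
                r.fdr_significant = bool(f)
            sub_results[label] = sub

        burden_frame = association.burden_results_frame(results)
        if cfg.write_intermediates:
            dio.write_tsv(outdir / "burden_results.tsv", burden_frame)
        report["association"] = {
            "genes_tested": [g.gene_id for g in assoc_genes],
            "burden": [r.to_dict() for r in results],
            "pooled": pooled.to_dict() if pooled else None,
            "subphenotypes": {k: [r.to_dict() for r in v] for k, v in sub_results.items()},
            "fdr_q": cfg.fdr_q,
        }
        stage_log.stage("association", elapsed_s=round(time.perf_counter() - t0, 3),
                        n_genes=len(assoc_genes))

        if cfg.run_common_scan:
            t0 = time.perf_counter()
            scan = association.common_variant_scan(
                hcm, cohort.phenotypes, maf_min=cfg.common_maf_min,
                bonferroni_n=cfg.bonferroni_n_tests, alpha=cfg.alpha)
            scan_frame = association.assoc_results_frame(scan)
            if cfg.write_intermediates and not scan_frame.empty:
                dio.write_tsv(outdir / "common_variant_results.tsv", scan_frame)
            report["common_scan"] = {
                "n_tested": len(scan),
                "bonferroni_threshold": association.bonferroni_threshold(
                    cfg.alpha, cfg.bonferroni_n_tests),
                "n_significant": int(sum(bool(r.bonferroni_significant) for r in scan)),
                "min_p": float(min((r.p_value for r in scan), default=1.0)),
            }
            stage_log.stage("common_scan", elapsed_s=round(time.perf_counter() - t0, 3),
                            n_tested=len(scan))

    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True, default=str))
    return report
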