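"""Synthetic trio-WES and case-control cohort generators.

These generators produce data with the statistical structure the discovery
and association stages assume: roughly one exonic de novo mutation (DNM)
per proband, sequencing-error-driven alt-allele traces in parents,
paralog-induced artifact sites confined to NGS-error-prone genes (NEPG),
occasional germline-mosaic DNMs shared with an unaffected sibling, a rare
site-frequency spectrum with carrier odds-ratio disease effects, and
imputation-style genotype-probability triples of varying certainty.

Everything is a deterministic function of (config, seed): identical
configs yield byte-identical output files.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as dio
from .models import GeneModel, GenotypeProbabilityMatrix, Site, TruthRecord

BASES = ("A", "C", "G", "T")
NONSILENT = ("missense", "stop_gain", "stop_loss", "splice", "frameshift", "inframe_indel")
SILENT = ("synonymous", "utr", "intronic")

# consequence mix for background polymorphic sites (exome-like: mostly
# missense/synonymous with a tail of truncating and non-coding classes)
_CONSEQUENCES = ("missense", "synonymous", "intronic", "utr", "stop_gain", "splice",
                 "frameshift", "inframe_indel")
_CONSEQUENCE_W = (0.38, 0.30, 0.12, 0.06, 0.04, 0.04, 0.03, 0.03)


def default_gene_panel(n_genes: int = 60, chrom: str = "1", n_exons: int = 3,
                       exon_len: int = 300, intron_len: int = 200,
                       spacing: int = 10_000) -> list:
    """A deterministic synthetic gene panel tiled along one chromosome.

    Exons are 0-based half-open, matching BED convention.
    """
    genes = []
    cursor = 1_000
    for g in range(n_genes):
        exons = []
        start = cursor
        for _ in range(n_exons):
            exons.append((start, start + exon_len))
            start += exon_len + intron_len
        genes.append(GeneModel(f"GENE{g + 1:03d}", chrom, tuple(exons)))
        cursor = start + spacing
    return genes


@dataclass
class TrioSimConfig:
    """Conditions for the trio-WES simulation.

    Defaults mirror the discovery design: 30 parent-affected-offspring
    trios, an expectation of one exonic DNM per proband, and deep
    exome-like coverage.
    """

    n_trios: int = 30
    dnm_rate: float = 1.0
    mean_depth: float = 60.0
    seq_error: float = 0.005
    n_background_sites: int = 1500
    nepg_fraction: float = 0.10
    mosaic_prob: float = 0.05
    sibling_prob: float = 0.5
    artifact_rate: float = 0.1
    n_genes: int = 60
    seed: int = 0

    def validate(self) -> None:
        for name in ("seq_error", "nepg_fraction", "mosaic_prob", "sibling_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.dnm_rate < 0:
            raise ValueError("dnm_rate must be >= 0")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")
        if self.n_trios <= 0:
            raise ValueError("n_trios must be > 0")
        if self.artifact_rate < 0:
            raise ValueError("artifact_rate must be >= 0")


@dataclass
class TrioSimResult:
    site_records: list
    samples: list
    ped: pd.DataFrame
    truth: list
    annotation: pd.DataFrame  # site_id, chrom, pos, ref, alt, gene, consequence, maf, context
    genes: list
    nepg_genes: list
    config: TrioSimConfig

    def write(self, outdir) -> dict:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "vcf": outdir / "trios.vcf",
            "ped": outdir / "trios.ped",
            "truth": outdir / "trio_truth.tsv",
            "annotation": outdir / "trio_annotation.tsv",
            "genes": outdir / "genes.bed",
            "nepg": outdir / "nepg_genes.tsv",
        }
        dio.write_vcf(paths["vcf"], self.site_records, self.samples)
        dio.write_ped(paths["ped"], self.ped)
        dio.write_truth(paths["truth"], self.truth)
        dio.write_tsv(paths["annotation"], self.annotation)
        dio.write_gene_bed(paths["genes"], self.genes)
        pd.DataFrame({"gene": self.nepg_genes}).to_csv(paths["nepg"], sep="\t", index=False)
        return {k: str(v) for k, v in paths.items()}


def _theta(genotype: int, eps: float) -> float:
    """Expected alt-read fraction for a diploid genotype."""
    return (eps, 0.5, 1.0 - eps)[genotype]


def _draw_reads(rng, genotype: int, mean_depth: float, eps: float) -> tuple:
    depth = rng.poisson(mean_depth)
    alt = rng.binomial(depth, _theta(genotype, eps)) if depth > 0 else 0
    return depth - alt, alt


def _random_snv(rng, used: set, gene: GeneModel) -> tuple:
    """A random exonic SNV position in ``gene`` not colliding with ``used``."""
    for _ in range(200):
        s, e = gene.exons[int(rng.integers(len(gene.exons)))]
        pos = int(rng.integers(s, e)) + 1  # 1-based
        if pos not in used:
            used.add(pos)
            ref = BASES[int(rng.integers(4))]
            alt = rng.choice([b for b in BASES if b != ref])
            left = BASES[int(rng.integers(4))]
            right = BASES[int(rng.integers(4))]
            return pos, ref, str(alt), left + ref + right
    raise RuntimeError(f"could not place a new site in {gene.gene_id}")


def simulate_trios(cfg: TrioSimConfig) -> TrioSimResult:
    """Simulate a multi-sample trio VCF with injected DNMs and artifacts.

    Per proband the number of true DNMs is Poisson(``dnm_rate``); each DNM
    is a missense change in a non-NEPG gene, heterozygous in the proband
    with both parents hom-ref (alt reads in parents arise only through
    ``seq_error``). A ``mosaic_prob`` fraction of DNM events is germline
    mosaic: the same allele is carried heterozygously by an unaffected
    sibling. Paralog artifact sites lie in NEPG genes and show alt-read
    traces in several family members.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    genes = default_gene_panel(cfg.n_genes)
    n_nepg = int(math.floor(cfg.nepg_fraction * len(genes)))
    nepg_idx = rng.choice(len(genes), size=n_nepg, replace=False) if n_nepg else np.array([], dtype=int)
    nepg_genes = sorted(genes[i].gene_id for i in nepg_idx)
    nepg_set = set(nepg_genes)
    clean_genes = [g for g in genes if g.gene_id not in nepg_set]
    if not clean_genes:
        raise ValueError("nepg_fraction leaves no gene for DNM placement")

    # family structure
    families, ped_rows, samples = [], [], []
    has_sibling = rng.random(cfg.n_trios) < cfg.sibling_prob
    for t in range(cfg.n_trios):
        fam = f"FAM{t + 1:03d}"
        members = {"father": f"{fam}_F", "mother": f"{fam}_M", "child": f"{fam}_C"}
        members["siblings"] = [f"{fam}_S1"] if has_sibling[t] else []
        families.append({"id": fam, **members})

    # DNM / mosaic events (may force a sibling into a family)
    dnm_events = []  # (family index, is_mosaic)
    n_dnm = rng.poisson(cfg.dnm_rate, size=cfg.n_trios)
    for t in range(cfg.n_trios):
        for _ in range(int(n_dnm[t])):
            is_mosaic = bool(rng.random() < cfg.mosaic_prob)
            if is_mosaic and not families[t]["siblings"]:
                families[t]["siblings"] = [f"{families[t]['id']}_S1"]
            dnm_events.append((t, is_mosaic))

    for fam in families:
        fid = fam["id"]
        ped_rows += [
            (fid, fam["father"], "0", "0", 1, 1),
            (fid, fam["mother"], "0", "0", 2, 1),
            (fid, fam["child"], fam["father"], fam["mother"], int(rng.integers(1, 3)), 2),
        ]
        ped_rows += [(fid, s, fam["father"], fam["mother"], int(rng.integers(1, 3)), 1)
                     for s in fam["siblings"]]
        samples += [fam["father"], fam["mother"], fam["child"], *fam["siblings"]]
    ped = pd.DataFrame(ped_rows, columns=dio.PED_COLUMNS)

    used_pos: set = set()
    site_records, truth, annot_rows = [], [], []

    def emit(site, gene_id, consequence, maf, context, genotypes, truth_class, carriers,
             artifact_members=()):
        calls = {}
        for s in samples:
            g = genotypes.get(s, 0)
            if s in artifact_members:
                depth = rng.poisson(cfg.mean_depth)
                alt = rng.binomial(depth, 0.3) if depth > 0 else 0
                ref_c, alt_c = depth - alt, alt
                gt = 1 if alt_c > 0 else 0  # what an upstream naive caller would emit
            else:
                ref_c, alt_c = _draw_reads(rng, g, cfg.mean_depth, cfg.seq_error)
                gt = g
            calls[s] = (gt, ref_c, alt_c)
        site_records.append({"chrom": site.chrom, "pos": site.pos, "ref": site.ref,
                             "alt": site.alt, "calls": calls})
        truth.append(TruthRecord(str(site), truth_class, tuple(carriers)))
        annot_rows.append({"site_id": str(site), "chrom": site.chrom, "pos": site.pos,
                           "ref": site.ref, "alt": site.alt, "gene": gene_id,
                           "consequence": consequence, "maf": maf, "context": context})

    # background inherited polymorphism
    for _ in range(cfg.n_background_sites):
        gene = genes[int(rng.integers(len(genes)))]
        pos, ref, alt, ctx = _random_snv(rng, used_pos, gene)
        site = Site(gene.chrom, pos, ref, alt)
        consequence = str(rng.choice(_CONSEQUENCES, p=_CONSEQUENCE_W))
        maf = float(np.exp(rng.uniform(np.log(5e-4), np.log(0.5))))
        genotypes, carriers = {}, []
        for fam in families:
            gp = int(rng.binomial(2, maf))
            gm = int(rng.binomial(2, maf))
            genotypes[fam["father"]], genotypes[fam["mother"]] = gp, gm
            for kid in [fam["child"], *fam["siblings"]]:
                a1 = rng.random() < gp / 2.0
                a2 = rng.random() < gm / 2.0
                genotypes[kid] = int(a1) + int(a2)
            carriers += [s for s in (fam["father"], fam["mother"], fam["child"], *fam["siblings"])
                         if genotypes[s] > 0]
        emit(site, gene.gene_id, consequence, maf, ctx, genotypes, "inherited", carriers)

    # true DNMs and germline mosaics
    for t, is_mosaic in dnm_events:
        fam = families[t]
        gene = clean_genes[int(rng.integers(len(clean_genes)))]
        pos, ref, alt, ctx = _random_snv(rng, used_pos, gene)
        site = Site(gene.chrom, pos, ref, alt)
        genotypes = {fam["child"]: 1}
        carriers = [fam["child"]]
        if is_mosaic:
            sib = fam["siblings"][0]
            genotypes[sib] = 1
            carriers.append(sib)
        emit(site, gene.gene_id, "missense", np.nan, ctx, genotypes,
             "mosaic" if is_mosaic else "true_dnm", carriers)

    # paralog-induced artifact sites (mapping noise in NEPG genes)
    if nepg_genes:
        n_art = rng.poisson(cfg.artifact_rate, size=cfg.n_trios)
        for t in range(cfg.n_trios):
            fam = families[t]
            for _ in range(int(n_art[t])):
                gene = genes[int(nepg_idx[int(rng.integers(len(nepg_idx)))])]
                pos, ref, alt, ctx = _random_snv(rng, used_pos, gene)
                site = Site(gene.chrom, pos, ref, alt)
                parent = fam["father"] if rng.random() < 0.5 else fam["mother"]
                emit(site, gene.gene_id, "missense", np.nan, ctx, {},
                     "paralog_artifact", [], artifact_members={fam["child"], parent})

    annotation = pd.DataFrame(
        annot_rows,
        columns=["site_id", "chrom", "pos", "ref", "alt", "gene", "consequence", "maf", "context"],
    ).sort_values(["chrom", "pos"]).reset_index(drop=True)
    return TrioSimResult(site_records, samples, ped, truth, annotation, genes, nepg_genes, cfg)


# ---------------------------------------------------------------------------
# Case-control cohort with genotype-probability triples
# ---------------------------------------------------------------------------

@dataclass
class CohortSimConfig:
    """Conditions for the imputed case-control cohort simulation.

    Default cohort sizes mirror the follow-up association cohort
    (4036 cases, 6995 controls); sub-phenotype prevalences mirror the
    anti-dsDNA (1261/4036) and renal-involvement-with-hypocomplementemia
    (186/4036) case subsets.
    """

    n_cases: int = 4036
    n_controls: int = 6995
    genes: list = field(default_factory=lambda: default_gene_panel(14))
    causal_genes: Optional[tuple] = None  # default: first gene
    rare_maf_range: tuple = (5e-4, 0.01)
    common_maf_range: tuple = (0.05, 0.5)
    n_rare_per_gene: int = 20
    n_common_per_gene: int = 8
    carrier_or: float = 2.0
    subpheno_rates: dict = field(default_factory=lambda: {"anti_dsdna": 0.3124, "renal_hypocomp": 0.0461})
    subpheno_effects: dict = field(default_factory=dict)  # label -> (gene_id, odds_ratio)
    prob_certainty: float = 2000.0
    missing_rate: float = 0.02
    n_covariates: int = 4
    covariate_effects: Optional[tuple] = None  # default 0.1 per covariate
    base_prevalence: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("case/control counts must be positive")
        if not self.genes:
            raise ValueError("gene list must be non-empty")
        if self.carrier_or <= 0:
            raise ValueError("carrier_or must be > 0")
        lo, hi = self.rare_maf_range
        if not (0 < lo <= hi <= 0.01):
            raise ValueError("rare_maf_range must lie within (0, 0.01]")
        if not 0 <= self.missing_rate <= 1:
            raise ValueError("missing_rate must be in [0, 1]")

    def resolved_causal(self) -> tuple:
        if self.causal_genes is None:
            return (self.genes[0].gene_id,)
        return tuple(self.causal_genes)


@dataclass
class CohortSimResult:
    gpm: GenotypeProbabilityMatrix
    true_genotypes: np.ndarray  # variants x individuals, 0/1/2
    phenotypes: pd.DataFrame
    truth: list
    genes: list
    config: CohortSimConfig

    def write(self, outdir) -> dict:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "gen": outdir / "cohort.gen",
            "sample": outdir / "cohort.sample",
            "phenotypes": outdir / "phenotypes.tsv",
            "truth": outdir / "cohort_truth.tsv",
            "genes": outdir / "cohort_genes.bed",
        }
        dio.write_gen(paths["gen"], self.gpm.variants, self.gpm.probs)
        dio.write_sample(paths["sample"], self.gpm.samples)
        dio.write_tsv(paths["phenotypes"], self.phenotypes)
        dio.write_truth(paths["truth"], self.truth)
        dio.write_gene_bed(paths["genes"], self.genes)
        return {k: str(v) for k, v in paths.items()}


def _simulate_triples(rng, genotypes: np.ndarray, certainty: float, missing_rate: float) -> np.ndarray:
    """Dirichlet probability triples centred on the true genotypes.

    ``certainty`` is the Dirichlet concentration added to the true-genotype
    component; ``certainty = inf`` gives degenerate (exact) triples. A
    ``missing_rate`` fraction of triples is drawn near-uniform
    (Dirichlet(30,30,30)), emulating sites the imputation cannot resolve.
    """
    n_var, n_ind = genotypes.shape
    onehot = np.eye(3)[genotypes]  # (n_var, n_ind, 3)
    if np.isinf(certainty):
        probs = onehot.astype(float)
    else:
        alpha = 1.0 + certainty * onehot
        gam = rng.gamma(alpha)
        probs = gam / gam.sum(axis=2, keepdims=True)
    if missing_rate > 0:
        mask = rng.random((n_var, n_ind)) < missing_rate
        if mask.any():
            gam = rng.gamma(np.full((int(mask.sum()), 3), 30.0))
            probs[mask] = gam / gam.sum(axis=1, keepdims=True)
    return probs


def simulate_cohort(cfg: CohortSimConfig) -> CohortSimResult:
    """Simulate a case-control cohort of genotype-probability triples.

    Genotypes are Hardy-Weinberg draws at each site's simulated MAF; rare
    sites draw their MAF log-uniformly on ``rare_maf_range``. Disease
    status follows a logistic model with log(``carrier_or``) on the
    indicator of carrying >=1 rare alt allele in a causal gene, plus
    independent standard-normal covariates. Cases and controls are
    accumulated by rejection sampling until both groups are full.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    causal = set(cfg.resolved_causal())
    unknown = causal - {g.gene_id for g in cfg.genes}
    if unknown:
        raise ValueError(f"causal genes not in gene list: {sorted(unknown)}")

    # site panel
    rows, mafs, rare_mask, causal_mask = [], [], [], []
    used: set = set()
    lo, hi = cfg.rare_maf_range
    for gene in cfg.genes:
        for i in range(cfg.n_rare_per_gene + cfg.n_common_per_gene):
            is_rare = i < cfg.n_rare_per_gene
            pos, ref, alt, _ctx = _random_snv(rng, used, gene)
            if is_rare:
                maf = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            else:
                maf = float(rng.uniform(*cfg.common_maf_range))
            rows.append({"chrom": gene.chrom, "pos": pos, "ref": ref, "alt": alt,
                         "snp_id": f"{gene.chrom}:{pos}", "gene": gene.gene_id})
            mafs.append(maf)
            rare_mask.append(is_rare)
            causal_mask.append(is_rare and gene.gene_id in causal)
    sort_idx = np.argsort(pd.DataFrame(rows)["pos"].to_numpy(), kind="stable")
    mafs = np.asarray(mafs)[sort_idx]
    rare_mask = np.asarray(rare_mask)[sort_idx]
    causal_mask = np.asarray(causal_mask)[sort_idx]
    variants = pd.DataFrame(rows).iloc[sort_idx].reset_index(drop=True)
    n_var = len(variants)

    beta_cov = (np.full(cfg.n_covariates, 0.1) if cfg.covariate_effects is None
                else np.asarray(cfg.covariate_effects, dtype=float))
    if len(beta_cov) != cfg.n_covariates:
        raise ValueError("covariate_effects length must equal n_covariates")
    beta0 = math.log(cfg.base_prevalence / (1 - cfg.base_prevalence))
    log_or = math.log(cfg.carrier_or)

    need_cases, need_controls = cfg.n_cases, cfg.n_controls
    case_g, case_cov, ctrl_g, ctrl_cov = [], [], [], []
    batch = max(1000, (need_cases + need_controls) // 2)
    guard = 0
    while need_cases > 0 or need_controls > 0:
        guard += 1
        if guard > 2000:
            raise RuntimeError("rejection sampling failed to fill the cohort")
        g = rng.binomial(2, mafs[:, None], size=(n_var, batch)).astype(np.int8)
        cov = rng.standard_normal((batch, cfg.n_covariates))
        carrier = (g[causal_mask] > 0).any(axis=0) if causal_mask.any() else np.zeros(batch, bool)
        eta = beta0 + log_or * carrier + cov @ beta_cov
        y = rng.random(batch) < 1.0 / (1.0 + np.exp(-eta))
        for label, g_pool, c_pool, need in ((True, case_g, case_cov, need_cases),
                                            (False, ctrl_g, ctrl_cov, need_controls)):
            idx = np.flatnonzero(y == label)[:need]
            if idx.size:
                g_pool.append(g[:, idx])
                c_pool.append(cov[idx])
        need_cases = cfg.n_cases - sum(x.shape[1] for x in case_g)
        need_controls = cfg.n_controls - sum(x.shape[1] for x in ctrl_g)

    geno = np.concatenate(
        [np.concatenate(case_g, axis=1)[:, :cfg.n_cases],
         np.concatenate(ctrl_g, axis=1)[:, :cfg.n_controls]], axis=1)
    covs = np.concatenate(
        [np.concatenate(case_cov, axis=0)[:cfg.n_cases],
         np.concatenate(ctrl_cov, axis=0)[:cfg.n_controls]], axis=0)
    status = np.r_[np.ones(cfg.n_cases, int), np.zeros(cfg.n_controls, int)]
    sample_ids = [f"CASE{i + 1:05d}" for i in range(cfg.n_cases)] + \
                 [f"CTRL{i + 1:05d}" for i in range(cfg.n_controls)]

    # sub-phenotype labels among cases (optionally genotype-dependent)
    pheno = pd.DataFrame({"individual_id": sample_ids, "status": status})
    gene_of = variants["gene"].to_numpy()
    for label, rate in cfg.subpheno_rates.items():
        p = np.zeros(len(sample_ids))
        base_logit = math.log(rate / (1 - rate))
        eta = np.full(cfg.n_cases, base_logit)
        if label in cfg.subpheno_effects:
            eff_gene, eff_or = cfg.subpheno_effects[label]
            sites = np.flatnonzero((gene_of == eff_gene) & rare_mask)
            carrier = (geno[sites][:, :cfg.n_cases] > 0).any(axis=0)
            eta = eta + math.log(eff_or) * carrier
        p[:cfg.n_cases] = 1.0 / (1.0 + np.exp(-eta))
        pheno[f"subpheno_{label}"] = (rng.random(len(sample_ids)) < p).astype(int)
    for c in range(cfg.n_covariates):
        pheno[f"cov{c + 1}"] = covs[:, c]

    probs = _simulate_triples(rng, geno, cfg.prob_certainty, cfg.missing_rate)
    gpm = GenotypeProbabilityMatrix(variants.drop(columns=["gene"]), sample_ids, probs)

    ids = np.asarray(sample_ids)
    truth = []
    for v in range(n_var):
        cls = "causal_rare" if causal_mask[v] else "neutral"
        carriers = tuple(ids[geno[v] > 0]) if rare_mask[v] else ()
        truth.append(TruthRecord(f"{variants.iloc[v]['chrom']}:{variants.iloc[v]['pos']}"
                                 f":{variants.iloc[v]['ref']}:{variants.iloc[v]['alt']}",
                                 cls, carriers))
    return CohortSimResult(gpm, geno, pheno, truth, list(cfg.genes), cfg)
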