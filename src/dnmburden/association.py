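"""Gene-level collapsing burden tests and per-variant common-variant scans.

The rare-variant engine is a CAST-style collapsing test: within a gene's
coding exons, individuals carrying >=1 minor allele at >=1 rare
(MAF < 1%) site are compared between cases and controls with a one-sided
exact test on the 2x2 carrier table (the alternative is a carrier excess
in cases, i.e. rare variants are assumed causal, not protective). A label
shuffling permutation engine is available as a cross-check. Common
variants (MAF > 1%) are tested per site with an additive logistic model
adjusted for covariates; Benjamini-Hochberg FDR and Bonferroni handle
multiplicity.
"""
from __future__ import annotations

import math
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .models import MISSING, AssocResult, BurdenResult, GeneModel, HardCallMatrix, Site


# ---------------------------------------------------------------------------
# Carrier collapsing
# ---------------------------------------------------------------------------

def variant_maf(genotypes: np.ndarray) -> np.ndarray:
    """Minor-allele frequency per variant from an additive genotype matrix,
    computed over non-missing calls in the combined analyzed sample."""
    g = np.ma.masked_equal(genotypes, MISSING)
    n = g.count(axis=1)
    with np.errstate(invalid="ignore"):
        af = np.where(n > 0, g.sum(axis=1).filled(0) / (2.0 * np.maximum(n, 1)), 0.0)
    return np.minimum(af, 1.0 - af)


def collapse_carriers(hcm: HardCallMatrix, gene: GeneModel,
                      maf_threshold: float = 0.01) -> dict:
    """Per-individual indicator of carrying >=1 rare minor allele in a gene.

    Qualifying sites are polymorphic variants in the gene's coding exons
    with MAF (combined sample) strictly below ``maf_threshold``. Missing
    genotypes contribute nothing. A gene with zero qualifying sites yields
    an all-zero indicator flagged degenerate.
    """
    pos = hcm.variants["pos"].astype(int).to_numpy()
    chrom = hcm.variants["chrom"].astype(str).to_numpy()
    in_gene = np.array([c == gene.chrom and gene.contains(p) for c, p in zip(chrom, pos)])
    maf = variant_maf(hcm.genotypes)
    af = np.ma.masked_equal(hcm.genotypes, MISSING).mean(axis=1).filled(0) / 2.0
    qualifying = in_gene & (maf > 0) & (maf < maf_threshold)

    carrier = np.zeros(len(hcm.samples), dtype=bool)
    for v in np.flatnonzero(qualifying):
        g = hcm.genotypes[v]
        if af[v] <= 0.5:  # alt is the minor allele
            carrier |= g >= 1
        else:  # ref is the minor allele
            carrier |= (g == 0) | (g == 1)
    return {
        "carrier": carrier,
        "n_rare_sites": int(qualifying.sum()),
        "degenerate": not bool(qualifying.any()),
        "gene": gene.gene_id,
    }


# ---------------------------------------------------------------------------
# One-tailed collapsing burden test
# ---------------------------------------------------------------------------

def hypergeom_tail_p(k, N, K, n):
    """P(X >= k) for X ~ Hypergeometric(N, K, n); vectorised."""
    return stats.hypergeom.sf(np.asarray(k) - 1, N, K, n)


def burden_test(carrier: np.ndarray, status: np.ndarray, *,
                gene: str = "", maf_threshold: float = 0.01, n_rare_sites: int = 0,
                degenerate: bool = False, engine: str = "exact",
                n_permutations: int = 100_000, seed: Optional[int] = None) -> BurdenResult:
    """One-tailed collapsing test for a carrier excess in cases.

    ``engine='exact'`` computes the hypergeometric upper tail of the 2x2
    carrier table (equivalently a one-sided Fisher test);
    ``engine='permutation'`` shuffles case/control labels and uses the
    add-one estimator p = (b + 1) / (B + 1).
    """
    carrier = np.asarray(carrier, dtype=bool)
    status = np.asarray(status, dtype=int)
    if carrier.shape != status.shape:
        raise ValueError("carrier and status must align")
    n_cases = int((status == 1).sum())
    n_controls = int((status == 0).sum())
    if n_cases == 0 or n_controls == 0:
        raise ValueError("need at least one case and one control")
    k = int((carrier & (status == 1)).sum())
    K = int(carrier.sum())
    N = n_cases + n_controls

    if degenerate or K == 0:
        p = 1.0
        degenerate = True
    elif engine == "exact":
        p = float(hypergeom_tail_p(k, N, K, n_cases))
    elif engine == "permutation":
        rng = np.random.default_rng(seed)
        # shuffling binary labels over a fixed carrier vector is exactly a
        # hypergeometric draw of case-carriers
        perm = rng.hypergeometric(K, N - K, n_cases, size=n_permutations)
        p = (np.count_nonzero(perm >= k) + 1.0) / (n_permutations + 1.0)
    else:
        raise ValueError(f"unknown engine {engine!r}")

    return BurdenResult(
        gene=gene, maf_threshold=maf_threshold, n_rare_sites=n_rare_sites,
        case_carriers=k, n_cases=n_cases,
        control_carriers=K - k, n_controls=n_controls,
        p_value=min(1.0, p), engine=engine, degenerate=degenerate,
    )


def gene_burden_test(hcm: HardCallMatrix, gene: GeneModel, phenotypes: pd.DataFrame,
                     maf_threshold: float = 0.01, **kwargs) -> BurdenResult:
    """Collapse one gene's rare sites and run the one-tailed burden test."""
    collapsed = collapse_carriers(hcm, gene, maf_threshold)
    status = _aligned_status(hcm, phenotypes)
    return burden_test(collapsed["carrier"], status, gene=gene.gene_id,
                       maf_threshold=maf_threshold,
                       n_rare_sites=collapsed["n_rare_sites"],
                       degenerate=collapsed["degenerate"], **kwargs)


def pooled_burden_test(hcm: HardCallMatrix, genes: Iterable[GeneModel],
                       phenotypes: pd.DataFrame, maf_threshold: float = 0.01,
                       **kwargs) -> BurdenResult:
    """Collapse the union of all genes' qualifying sites as one super-gene."""
    genes = list(genes)
    if len(genes) < 2:
        raise ValueError("pooled test needs at least two genes")
    carrier = np.zeros(len(hcm.samples), dtype=bool)
    n_sites = 0
    for gene in genes:
        c = collapse_carriers(hcm, gene, maf_threshold)
        carrier |= c["carrier"]
        n_sites += c["n_rare_sites"]
    status = _aligned_status(hcm, phenotypes)
    return burden_test(carrier, status, gene="+".join(g.gene_id for g in genes),
                       maf_threshold=maf_threshold, n_rare_sites=n_sites,
                       degenerate=n_sites == 0, **kwargs)


def subphenotype_burden(hcm: HardCallMatrix, gene: GeneModel, phenotypes: pd.DataFrame,
                        label: str, maf_threshold: float = 0.01, **kwargs) -> BurdenResult:
    """Burden test with cases restricted to a sub-phenotype label;
    the full control set is reused."""
    col = f"subpheno_{label}" if f"subpheno_{label}" in phenotypes.columns else label
    if col not in phenotypes.columns:
        raise ValueError(f"sub-phenotype label {label!r} not in phenotype table")
    status = _aligned_status(hcm, phenotypes)
    labels = phenotypes.set_index("individual_id").loc[list(hcm.samples), col].to_numpy()
    if int(((status == 1) & (labels == 1)).sum()) == 0:
        raise ValueError(f"no label-positive cases for {label!r}")
    keep = (status == 0) | ((status == 1) & (labels == 1))
    collapsed = collapse_carriers(hcm, gene, maf_threshold)
    res = burden_test(collapsed["carrier"][keep], status[keep],
                      gene=gene.gene_id, maf_threshold=maf_threshold,
                      n_rare_sites=collapsed["n_rare_sites"],
                      degenerate=collapsed["degenerate"], **kwargs)
    return res


def _aligned_status(hcm: HardCallMatrix, phenotypes: pd.DataFrame) -> np.ndarray:
    pheno = phenotypes.set_index("individual_id")
    try:
        return pheno.loc[list(hcm.samples), "status"].to_numpy(dtype=int)
    except KeyError as exc:
        raise ValueError("phenotype table missing individuals from the call matrix") from exc


# ---------------------------------------------------------------------------
# Multiplicity
# ---------------------------------------------------------------------------

def fdr_correct(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up significance flags at level ``q``."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if ((p < 0) | (p > 1) | ~np.isfinite(p)).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def bonferroni_threshold(alpha: float = 0.05, n_tests: int = 1) -> float:
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def truncate_sig(x: float, digits: int = 3) -> float:
    """Truncate (toward zero) to ``digits`` significant figures, matching
    the convention of reporting 0.05/3000 as 1.66E-5."""
    if x == 0:
        return 0.0
    mag = math.floor(math.log10(abs(x)))
    factor = 10.0 ** (digits - 1 - mag)
    return math.trunc(x * factor) / factor


# ---------------------------------------------------------------------------
# Common-variant scan
# ---------------------------------------------------------------------------

def _logistic_score_test(y: np.ndarray, x: np.ndarray, Z: np.ndarray) -> tuple:
    """Rao score test for adding ``x`` to a fitted-null logistic model with
    design ``Z`` (intercept + covariates). Defined even under separation."""
    import statsmodels.api as sm

    null = sm.Logit(y, Z).fit(disp=0, maxiter=200)
    p0 = null.predict(Z)
    w = p0 * (1.0 - p0)
    u = float(x @ (y - p0))
    zwz = Z.T @ (Z * w[:, None])
    zwx = Z.T @ (x * w)
    v = float(x @ (x * w) - zwx @ np.linalg.solve(zwz, zwx))
    if v <= 0:
        return 0.0, 1.0
    chi2 = u * u / v
    return u / v, float(stats.chi2.sf(chi2, df=1))


def common_variant_scan(hcm: HardCallMatrix, phenotypes: pd.DataFrame,
                        covariate_cols: Optional[list] = None,
                        maf_min: float = 0.01,
                        bonferroni_n: Optional[int] = None,
                        alpha: float = 0.05) -> list:
    """Per-variant additive logistic association with covariates.

    Variants with combined-sample MAF <= ``maf_min`` (including
    monomorphic sites) are skipped. Missing genotypes are mean-imputed on
    the dosage scale. Wald p-values from the full fit are reported; when
    the fit fails (e.g. separation) the score test against the
    covariate-only null is used instead.
    """
    import statsmodels.api as sm

    if covariate_cols is None:
        covariate_cols = [c for c in phenotypes.columns if c.startswith("cov")]
    pheno = phenotypes.set_index("individual_id").loc[list(hcm.samples)]
    y = pheno["status"].to_numpy(dtype=float)
    covs = pheno[covariate_cols].to_numpy(dtype=float)
    if np.isnan(covs).any():
        raise ValueError("covariates must be complete for analyzed individuals")
    Z = np.column_stack([np.ones(len(y)), covs])
    mafs = variant_maf(hcm.genotypes)

    threshold = bonferroni_threshold(alpha, bonferroni_n) if bonferroni_n else None
    results = []
    for v in range(len(hcm.variants)):
        if mafs[v] <= maf_min:
            continue
        g = hcm.genotypes[v].astype(float)
        miss = g == MISSING
        if miss.all():
            continue
        g[miss] = g[~miss].mean()
        row = hcm.variants.iloc[v]
        site = Site(str(row["chrom"]), int(row["pos"]), row["ref"], row["alt"])
        X = np.column_stack([Z, g])
        beta = p = None
        test = "wald"
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
            if np.isfinite(fit.bse[-1]) and fit.mle_retvals.get("converged", True):
                beta, p = float(fit.params[-1]), float(fit.pvalues[-1])
        except Exception:
            pass
        if p is None or not np.isfinite(p):
            beta, p = _logistic_score_test(y, g, Z)
            test = "score"
        res = AssocResult(site=site, maf=float(mafs[v]), beta=beta, p_value=p, test=test)
        if threshold is not None:
            res.bonferroni_significant = p < threshold
        results.append(res)
    return results


def burden_results_frame(results: list) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in results])


def assoc_results_frame(results: list) -> pd.DataFrame:
    return pd.DataFrame([
        {"chrom": r.site.chrom, "pos": r.site.pos, "ref": r.site.ref, "alt": r.site.alt,
         "maf": r.maf, "beta": r.beta, "p_value": r.p_value, "test": r.test,
         "bonferroni_significant": r.bonferroni_significant}
        for r in results
    ])
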