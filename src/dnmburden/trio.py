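"""Trio de novo mutation (DNM) discovery.

A bespoke likelihood genotype caller over per-sample allelic depths feeds a
sequential filter cascade:

    (A) removal of sites in NGS-error-prone genes (NEPG);
    (B) the de novo inheritance pattern -- child heterozygous with both
        parents hom-ref -- combined with a strict parental-trace rule
        (zero alternate reads in either parent);
    (C) non-silent consequence annotation.

Surviving candidates are screened for two known false-positive modes:
germline mosaicism (the allele is also carried by an unaffected sibling)
and paralogous sequence variants (PSV).
"""
from __future__ import annotations

import logging
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .models import DNMCandidate, FilterCascadeReport, Site, TrioObservation
from .synthetic import NONSILENT

log = logging.getLogger(__name__)

# prior at sites with no frequency annotation: overwhelmingly hom-ref with
# a small heterozygote prior (de novo / unobserved variation)
DEFAULT_HET_PRIOR = 1e-4
POSTERIOR_CALL_THRESHOLD = 0.9


def hwe_priors(maf: float) -> np.ndarray:
    """Hardy-Weinberg genotype priors from a population MAF."""
    if not 0.0 <= maf <= 1.0:
        raise ValueError("maf must be in [0, 1]")
    return np.array([(1 - maf) ** 2, 2 * maf * (1 - maf), maf ** 2])


def default_priors() -> np.ndarray:
    het = DEFAULT_HET_PRIOR
    hom_alt = het ** 2
    return np.array([1.0 - het - hom_alt, het, hom_alt])


def _binom_logpmf(k: int, n: int, p: float) -> float:
    if p <= 0.0:
        return 0.0 if k == 0 else -np.inf
    if p >= 1.0:
        return 0.0 if k == n else -np.inf
    return (gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
            + k * np.log(p) + (n - k) * np.log1p(-p))


def genotype_posterior(ref_count: int, alt_count: int, eps: float,
                       priors: Optional[np.ndarray] = None) -> Optional[np.ndarray]:
    """Posterior over (hom-ref, het, hom-alt) from binomial read likelihoods.

    The alt-read fraction is eps, 0.5 and 1-eps for the three genotypes.
    Returns None (no-call) when total depth is zero.
    """
    depth = ref_count + alt_count
    if depth == 0:
        return None
    priors = default_priors() if priors is None else np.asarray(priors, float)
    loglik = np.array([_binom_logpmf(alt_count, depth, th) for th in (eps, 0.5, 1.0 - eps)])
    with np.errstate(divide="ignore"):
        logpost = loglik + np.log(priors)
    logpost -= logpost.max()
    post = np.exp(logpost)
    return post / post.sum()


def _hard_genotype(post: Optional[np.ndarray], threshold: float = POSTERIOR_CALL_THRESHOLD):
    if post is None:
        return None, float("nan")
    g = int(np.argmax(post))
    return (g, float(post[g])) if post[g] >= threshold else (None, float(post[g]))


def call_trio_genotypes(obs: TrioObservation, eps: float,
                        priors: Optional[np.ndarray] = None,
                        threshold: float = POSTERIOR_CALL_THRESHOLD) -> dict:
    """Call genotypes for every family member from allelic depths.

    Returns {member: (genotype or None, posterior of the called genotype)}
    for child / father / mother / sibling_<i>, and stores hard calls on the
    observation in place.
    """
    members = {"child": obs.child, "father": obs.father, "mother": obs.mother}
    members.update({f"sibling_{i}": s for i, s in enumerate(obs.siblings)})
    calls = {}
    for name, m in members.items():
        post = genotype_posterior(m.ref_count, m.alt_count, eps, priors)
        g, p = _hard_genotype(post, threshold)
        m.genotype = g
        calls[name] = (g, p)
    return calls


# ---------------------------------------------------------------------------
# Individual filters
# ---------------------------------------------------------------------------

def denovo_pattern_filter(child_gt: Optional[int], father_gt: Optional[int],
                          mother_gt: Optional[int]) -> tuple:
    """Pass iff the trio shows the Het:Ref:Ref child:father:mother pattern."""
    if child_gt is None or father_gt is None or mother_gt is None:
        return False, "uncallable"
    if child_gt == 1 and father_gt == 0 and mother_gt == 0:
        return True, ""
    return False, "not de novo pattern"


def parental_trace_filter(obs: TrioObservation) -> tuple:
    """Pass iff neither parent shows any trace of the alternate allele.

    A single alternate read in either parent fails; so does absence of
    read data (no evidence is not evidence of absence).
    """
    if obs.father.depth == 0 or obs.mother.depth == 0:
        return False, "no depth data"
    if obs.father.alt_count == 0 and obs.mother.alt_count == 0:
        return True, ""
    return False, "parental alt trace"


def nepg_filter(gene: Optional[str], nepg_genes: Iterable[str]) -> tuple:
    """Fail iff the site's gene is on the NGS-error-prone gene list."""
    if gene is not None and gene in set(nepg_genes):
        return False, "NEPG gene"
    return True, ""


def nonsilent_filter(consequence: Optional[str]) -> tuple:
    """Pass iff the consequence is protein-altering."""
    if consequence is None or (isinstance(consequence, float) and np.isnan(consequence)):
        return False, "unannotated"
    if consequence in NONSILENT:
        return True, ""
    return False, "silent"


# ---------------------------------------------------------------------------
# Cascade
# ---------------------------------------------------------------------------

def _site_lookup(annotation: pd.DataFrame) -> dict:
    return {
        (str(r["chrom"]), int(r["pos"]), r["ref"], r["alt"]):
            {"gene": r.get("gene"), "consequence": r.get("consequence"),
             "maf": r.get("maf"), "context": r.get("context")}
        for _, r in annotation.iterrows()
    }


def run_filter_cascade(observations: list, annotation: pd.DataFrame,
                       nepg_genes: Iterable[str], eps: float,
                       threshold: float = POSTERIOR_CALL_THRESHOLD) -> tuple:
    """Call genotypes and apply the sequential A/B/C filter cascade.

    ``observations`` is a flat list of per-family per-site TrioObservation.
    A site/family pair enters the cascade when the child carries a called
    alternate allele. Rejected candidates never re-enter later stages.
    Returns (candidates, FilterCascadeReport); the report counts every
    stage and lists rejected sites per stage.
    """
    lookup = _site_lookup(annotation)
    nepg = set(nepg_genes)

    entering = []
    for obs in observations:
        if obs.child.alt_count == 0:
            continue  # a child with zero alt reads can never be called alt
        ann = lookup.get(obs.site.key, {})
        maf = ann.get("maf")
        priors = hwe_priors(float(maf)) if maf is not None and np.isfinite(maf) else None
        calls = call_trio_genotypes(obs, eps, priors, threshold)
        child_gt, child_p = calls["child"]
        if child_gt in (1, 2):
            entering.append((obs, calls, ann))

    report = FilterCascadeReport(n_input=len(entering))
    candidates = []
    for obs, calls, ann in entering:
        candidates.append((DNMCandidate(
            site=obs.site, family_id=obs.family_id, gene=ann.get("gene"),
            child_genotype=calls["child"][0], child_posterior=calls["child"][1],
        ), obs, calls, ann))

    # stage A: NEPG removal
    survivors, rejected = [], []
    for cand, obs, calls, ann in candidates:
        ok, reason = nepg_filter(cand.gene, nepg)
        cand.nepg_pass = ok
        if ok:
            survivors.append((cand, obs, calls, ann))
        else:
            cand.rejection_reason = reason
            rejected.append(cand.site)
    report.add_stage("A_nepg", len(candidates), len(survivors), rejected)
    stage_in = survivors

    # stage B: de novo pattern + parental trace
    survivors, rejected = [], []
    for cand, obs, calls, ann in stage_in:
        ok_p, reason_p = denovo_pattern_filter(calls["child"][0], calls["father"][0],
                                               calls["mother"][0])
        cand.denovo_pattern_pass = ok_p
        ok_t, reason_t = parental_trace_filter(obs)
        cand.parental_trace_pass = ok_t
        if ok_p and ok_t:
            survivors.append((cand, obs, calls, ann))
        else:
            cand.rejection_reason = reason_p or reason_t
            rejected.append(cand.site)
    report.add_stage("B_denovo_pattern_trace", len(stage_in), len(survivors), rejected)
    stage_in = survivors

    # stage C: non-silent annotation
    survivors, rejected = [], []
    for cand, obs, calls, ann in stage_in:
        ok, reason = nonsilent_filter(ann.get("consequence"))
        cand.nonsilent_pass = ok
        if ok:
            survivors.append((cand, obs, calls, ann))
        else:
            cand.rejection_reason = reason
            rejected.append(cand.site)
    report.add_stage("C_nonsilent", len(stage_in), len(survivors), rejected)

    all_cands = [c for c, *_ in candidates]
    return all_cands, report


def flag_false_positive_modes(cand: DNMCandidate, obs: TrioObservation,
                              paralog_map: Optional[dict] = None) -> DNMCandidate:
    """Flag germline mosaicism and paralogous-sequence-variant suspects.

    Mosaic: >=1 unaffected sibling carries the same alternate allele.
    PSV suspect: the gene has a configured high-identity paralog whose
    variant positions include this site (an empty position set means any
    position in the gene is suspect). Trios without siblings are left
    unflagged (unknown is not evidence).
    """
    if cand.final_status != "candidate":
        raise ValueError("false-positive flagging applies to surviving candidates only")
    cand.mosaic = any(s.genotype in (1, 2) for s in obs.siblings)
    cand.psv_suspect = False
    if paralog_map and cand.gene in paralog_map:
        positions = paralog_map[cand.gene].get("positions") or ()
        cand.psv_suspect = (not positions) or (cand.site.pos in set(positions))
    return cand


def case_only_scan(observations: list, annotation: pd.DataFrame,
                   maf_threshold: float = 0.01, eps: float = 0.005,
                   threshold: float = POSTERIOR_CALL_THRESHOLD) -> dict:
    """Proband-only scan: heterozygous, rare, non-silent variants.

    Ignores the parents entirely, mirroring a cases-only exome analysis;
    used to contrast candidate-set sizes against the trio cascade.
    Returns distinct variant and gene counts.
    """
    lookup = _site_lookup(annotation)
    hit_sites, hit_genes = set(), set()
    if maf_threshold <= 0:
        return {"n_variants": 0, "n_genes": 0}
    for obs in observations:
        if obs.child.alt_count == 0:
            continue
        ann = lookup.get(obs.site.key, {})
        maf = ann.get("maf")
        has_maf = maf is not None and np.isfinite(maf)
        # sites absent from frequency tables are population-unseen, hence rare
        if has_maf and maf >= maf_threshold:
            continue
        ok, _ = nonsilent_filter(ann.get("consequence"))
        if not ok:
            continue
        priors = hwe_priors(float(maf)) if maf is not None and np.isfinite(maf) else None
        post = genotype_posterior(obs.child.ref_count, obs.child.alt_count, eps, priors)
        g, _p = _hard_genotype(post, threshold)
        if g == 1:
            hit_sites.add(obs.site.key)
            if ann.get("gene"):
                hit_genes.add(ann["gene"])
    return {"n_variants": len(hit_sites), "n_genes": len(hit_genes)}


def candidates_to_frame(candidates: list) -> pd.DataFrame:
    rows = []
    for c in candidates:
        rows.append({
            "chrom": c.site.chrom, "pos": c.site.pos, "ref": c.site.ref, "alt": c.site.alt,
            "family_id": c.family_id, "gene": c.gene, "child_genotype": c.child_genotype,
            "child_posterior": c.child_posterior, "nepg_pass": c.nepg_pass,
            "denovo_pattern_pass": c.denovo_pattern_pass,
            "parental_trace_pass": c.parental_trace_pass, "nonsilent_pass": c.nonsilent_pass,
            "mosaic": c.mosaic, "psv_suspect": c.psv_suspect,
            "final_status": c.final_status, "rejection_reason": c.rejection_reason,
        })
    return pd.DataFrame(rows)
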