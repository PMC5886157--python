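"""Genotype-probability hard-calling and quality filtering.

Converts imputation-style probability triples into discrete genotypes with
the study's confidence rules: an info-score floor of 0.3, a strict
most-likely-genotype probability threshold of 0.5, removal of variants
with more than 10% missing hard calls, and a QC flag (not an exclusion)
for individuals at or above 8% missingness.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .models import MISSING, GeneModel, GenotypeProbabilityMatrix, HardCallMatrix

INFO_MIN = 0.3
HARDCALL_PROB = 0.5
VARIANT_MISSING_MAX = 0.10
INDIVIDUAL_MISSING_MAX = 0.08


def info_score(triples: np.ndarray) -> float:
    """IMPUTE2-style info score for one variant.

    The ratio-of-variances measure: 1 minus the mean per-individual
    posterior dosage variance over the binomial variance 2*p*(1-p) at the
    estimated allele frequency p. Clamped to [0, 1]; a monomorphic
    estimate (p in {0, 1}) is defined as fully informative (score 1).
    """
    triples = np.asarray(triples, dtype=float)
    if triples.ndim != 2 or triples.shape[1] != 3:
        raise ValueError("expected an (n_individuals, 3) array")
    if triples.shape[0] < 2:
        raise ValueError("info score needs at least 2 individuals")
    e = triples[:, 1] + 2.0 * triples[:, 2]
    e2 = triples[:, 1] + 4.0 * triples[:, 2]
    var = e2 - e ** 2
    p = e.mean() / 2.0
    if p <= 0.0 or p >= 1.0:
        return 1.0
    raw = 1.0 - var.mean() / (2.0 * p * (1.0 - p))
    return float(min(1.0, max(0.0, raw)))


def info_scores(gpm: GenotypeProbabilityMatrix) -> np.ndarray:
    return np.array([info_score(gpm.probs[v]) for v in range(gpm.n_variants)])


def hard_call(triple) -> int:
    """Most likely genotype if its probability strictly exceeds 0.5, else missing.

    Ties at exactly 0.5 cannot exceed the threshold and are missing.
    """
    triple = np.asarray(triple, dtype=float)
    if triple.shape != (3,) or not np.isclose(triple.sum(), 1.0, atol=1e-6):
        raise ValueError("malformed probability triple")
    g = int(np.argmax(triple))
    return g if triple[g] > HARDCALL_PROB else MISSING


def hard_call_matrix(gpm: GenotypeProbabilityMatrix) -> HardCallMatrix:
    """Vectorised hard-calling of a whole probability matrix."""
    best = gpm.probs.argmax(axis=2)
    pmax = gpm.probs.max(axis=2)
    geno = np.where(pmax > HARDCALL_PROB, best, MISSING).astype(np.int8)
    return HardCallMatrix(gpm.variants.copy(), list(gpm.samples), geno)


def restrict_to_regions(gpm: GenotypeProbabilityMatrix, genes) -> GenotypeProbabilityMatrix:
    """Keep only variants falling in the coding exons of ``genes``.

    BED-style intervals (0-based half-open) against 1-based positions.
    """
    keep = np.zeros(gpm.n_variants, dtype=bool)
    for i, (_, row) in enumerate(gpm.variants.iterrows()):
        keep[i] = any(g.chrom == str(row["chrom"]) and g.contains(int(row["pos"]))
                      for g in genes)
    return GenotypeProbabilityMatrix(
        gpm.variants.loc[keep].reset_index(drop=True),
        list(gpm.samples),
        gpm.probs[keep],
    )


def apply_call_filters(gpm: GenotypeProbabilityMatrix,
                       info_min: float = INFO_MIN,
                       variant_missing_max: float = VARIANT_MISSING_MAX,
                       individual_missing_max: float = INDIVIDUAL_MISSING_MAX) -> tuple:
    """Info filter, hard-calling, then missingness filtering.

    Order: (1) drop variants with info score below ``info_min``; (2) hard
    call; (3) drop variants whose missing fraction strictly exceeds
    ``variant_missing_max``; (4) flag -- do not drop -- individuals with
    missing fraction >= ``individual_missing_max``. Returns
    (HardCallMatrix, exclusion report dict).
    """
    scores = info_scores(gpm)
    info_keep = scores >= info_min
    kept = GenotypeProbabilityMatrix(
        gpm.variants.loc[info_keep].reset_index(drop=True),
        list(gpm.samples),
        gpm.probs[info_keep],
    )
    hcm = hard_call_matrix(kept)
    vm = hcm.variant_missing_fraction
    miss_keep = vm <= variant_missing_max
    filtered = HardCallMatrix(
        hcm.variants.loc[miss_keep].reset_index(drop=True),
        list(hcm.samples),
        hcm.genotypes[miss_keep],
    )
    im = filtered.individual_missing_fraction
    flagged = [s for s, f in zip(filtered.samples, im) if f >= individual_missing_max]
    report = {
        "n_variants_in": int(gpm.n_variants),
        "n_removed_low_info": int((~info_keep).sum()),
        "n_removed_high_missing": int((~miss_keep).sum()),
        "n_variants_out": int(len(filtered.variants)),
        "info_min": info_min,
        "variant_missing_max": variant_missing_max,
        "individual_missing_max": individual_missing_max,
        "flagged_individuals": flagged,
        "max_individual_missing": float(im.max()) if len(filtered.variants) else 0.0,
    }
    return filtered, report
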