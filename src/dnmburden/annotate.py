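"""Variant- and gene-level annotation and candidate-set summaries.

Ships two fixture tables transcribed from the confirmed DNM set of the
extreme-phenotype SLE trio study: per-variant metrics (ExAC frequency,
CADD Phred, mutation class) and per-gene missense-constraint Z-scores.
"""
from __future__ import annotations

import logging
from importlib import resources
from typing import Optional

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}
CONSTRAINT_Z_CUTOFF = 3.09  # one-sided 0.1% normal quantile
CADD_CUTOFF = 30.0


def _data_path(name: str):
    return resources.files("dnmburden.data") / name


def load_variant_table() -> pd.DataFrame:
    """Packaged per-variant DNM metrics (14 confirmed variants)."""
    df = pd.read_csv(_data_path("table1_dnm_variants.tsv"), sep="\t")
    df["exac_maf"] = pd.to_numeric(df["exac_maf"], errors="coerce")
    return df


def load_gene_table() -> pd.DataFrame:
    """Packaged per-gene metrics (14 DNM genes; one without a Z-score)."""
    df = pd.read_csv(_data_path("table2_dnm_genes.tsv"), sep="\t")
    df["constraint_z"] = pd.to_numeric(df["constraint_z"], errors="coerce")
    return df


def classify_mutation_type(ref: str, alt: str, context: Optional[str] = None) -> str:
    """Classify an SNV as Tv, Ti, or TiCpG.

    Transitions (purine<->purine or pyrimidine<->pyrimidine) are upgraded
    to TiCpG when the reference base participates in a CpG dinucleotide in
    the reference trinucleotide ``context`` (centre base = ref): a C
    followed by G, or a G preceded by C. The classification is
    strand-symmetric. Without context no CpG upgrade is possible.
    """
    ref, alt = ref.upper(), alt.upper()
    if len(ref) != 1 or len(alt) != 1 or ref not in "ACGT" or alt not in "ACGT":
        raise ValueError("SNV required")
    if ref == alt:
        raise ValueError("ref and alt must differ")
    is_ti = (ref in PURINES) == (alt in PURINES)
    if not is_ti:
        return "Tv"
    if context is None:
        log.warning("no reference context for %s>%s; CpG upgrade skipped", ref, alt)
        return "Ti"
    context = context.upper()
    if len(context) != 3 or context[1] != ref:
        raise ValueError("context must be a trinucleotide centred on ref")
    if (ref == "C" and context[2] == "G") or (ref == "G" and context[0] == "C"):
        return "TiCpG"
    return "Ti"


def summarize_variant_metrics(table: pd.DataFrame, cadd_cutoff: float = CADD_CUTOFF,
                              n_trios: int = 30) -> dict:
    """Headline statistics over a confirmed-DNM variant table."""
    if table.empty:
        raise ValueError("empty variant table")
    n = len(table)
    n_cadd = int((table["cadd_phred"] > cadd_cutoff).sum())
    n_exac = int(table["exac_maf"].notna().sum())
    n_probands = int(table["family"].nunique())
    tally = table["mutation_class"].value_counts().to_dict()
    return {
        "n_variants": n,
        "n_cadd_above_cutoff": n_cadd,
        "pct_cadd_above_cutoff": round(100.0 * n_cadd / n, 1),
        "n_exac_present": n_exac,
        "n_distinct_probands": n_probands,
        "pct_probands": round(100.0 * n_probands / n_trios, 1),
        "mutation_class_tally": {k: int(v) for k, v in tally.items()},
    }


def summarize_gene_metrics(table: pd.DataFrame, z_cutoff: float = CONSTRAINT_Z_CUTOFF) -> dict:
    """Constraint summary: count of significantly constrained genes and the
    median Z over genes with an available score."""
    if table.empty:
        raise ValueError("empty gene table")
    scored = table["constraint_z"].dropna()
    if scored.empty:
        raise ValueError("no gene has an available constraint score")
    return {
        "n_genes": len(table),
        "n_scored": int(len(scored)),
        "n_constrained": int((scored > z_cutoff).sum()),
        "median_z": float(scored.median()),
        "constrained_genes": sorted(table.loc[table["constraint_z"] > z_cutoff, "gene"]),
    }


def _keyed(table: pd.DataFrame, value_col: str) -> dict:
    keys = list(zip(table["chrom"].astype(str), table["pos"].astype(int),
                    table["ref"], table["alt"]))
    if len(set(keys)) != len(keys):
        raise ValueError("ambiguous annotation: duplicate variant key in table")
    return dict(zip(keys, table[value_col]))


def annotate_candidates(candidates: pd.DataFrame,
                        maf_table: Optional[pd.DataFrame] = None,
                        cadd_table: Optional[pd.DataFrame] = None,
                        consequence_table: Optional[pd.DataFrame] = None,
                        context_table: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Join variant-level metrics onto a candidate table.

    Lookup tables are keyed by (chrom, pos, ref, alt); a duplicated key is
    an integrity error. Absence from the frequency table is recorded as
    null (not observed), never as zero.
    """
    out = candidates.copy()
    out["chrom"] = out["chrom"].astype(str)
    keys = list(zip(out["chrom"], out["pos"].astype(int), out["ref"], out["alt"]))

    def pull(table, col):
        if table is None:
            return [np.nan] * len(out)
        mapping = _keyed(table, col)
        return [mapping.get(k, np.nan) for k in keys]

    out["exac_maf"] = pd.to_numeric(pull(maf_table, "exac_maf"), errors="coerce")
    out["cadd_phred"] = pd.to_numeric(pull(cadd_table, "cadd_phred"), errors="coerce")
    if consequence_table is not None:
        out["consequence"] = pull(consequence_table, "consequence")
    contexts = pull(context_table, "context")
    classes = []
    for (chrom, pos, ref, alt), ctx in zip(keys, contexts):
        if len(ref) != 1 or len(alt) != 1:
            classes.append(np.nan)  # indels carry no Ti/Tv class
            continue
        ctx = ctx if isinstance(ctx, str) else None
        classes.append(classify_mutation_type(ref, alt, ctx))
    out["mutation_class"] = classes
    bad = out["exac_maf"].dropna()
    if ((bad <= 0) | (bad > 1)).any():
        raise ValueError("exac_maf entries must lie in (0, 1]")
    return out
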