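"""Core domain types shared across the pipeline.

Conventions used repo-wide: VCF and GEN positions are 1-based; BED-style
exon intervals are 0-based half-open. Genotypes are coded additively
(0 = hom-ref, 1 = het, 2 = hom-alt) with -1 for missing.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

MISSING = -1

GENOTYPE_LABELS = ("hom_ref", "het", "hom_alt")


@dataclass(frozen=True)
class Site:
    """A biallelic variant site (1-based position)."""

    chrom: str
    pos: int
    ref: str
    alt: str

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


@dataclass(frozen=True)
class GeneModel:
    """A gene with merged coding-exon intervals (0-based half-open)."""

    gene_id: str
    chrom: str
    exons: tuple  # tuple of (start, end) 0-based half-open
    source: str = "synthetic"

    def __post_init__(self):
        exons = sorted(tuple(e) for e in self.exons)
        merged = []
        for s, e in exons:
            if e <= s:
                raise ValueError(f"empty exon interval ({s}, {e}) in {self.gene_id}")
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        object.__setattr__(self, "exons", tuple(merged))

    def contains(self, pos_1based: int) -> bool:
        p = pos_1based - 1
        return any(s <= p < e for s, e in self.exons)

    @property
    def span(self) -> tuple:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def coding_length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass
class MemberObservation:
    """Read evidence and called genotype for one family member at one site."""

    ref_count: int
    alt_count: int
    genotype: Optional[int] = None  # 0/1/2, None when uncalled

    @property
    def depth(self) -> int:
        return self.ref_count + self.alt_count


@dataclass
class TrioObservation:
    """Per-site evidence for child, father, mother and optional siblings."""

    site: Site
    child: MemberObservation
    father: MemberObservation
    mother: MemberObservation
    siblings: list = field(default_factory=list)
    family_id: str = ""

    def __post_init__(self):
        for m in (self.child, self.father, self.mother, *self.siblings):
            if m.ref_count < 0 or m.alt_count < 0:
                raise ValueError("read counts must be non-negative")


@dataclass
class DNMCandidate:
    """A candidate de novo mutation with per-stage filter decisions."""

    site: Site
    family_id: str
    gene: Optional[str] = None
    child_genotype: Optional[int] = None
    child_posterior: float = float("nan")
    nepg_pass: Optional[bool] = None
    denovo_pattern_pass: Optional[bool] = None
    parental_trace_pass: Optional[bool] = None
    nonsilent_pass: Optional[bool] = None
    mosaic: bool = False
    psv_suspect: bool = False
    rejection_reason: Optional[str] = None

    @property
    def final_status(self) -> str:
        if all(
            f is True
            for f in (
                self.nepg_pass,
                self.denovo_pattern_pass,
                self.parental_trace_pass,
                self.nonsilent_pass,
            )
        ):
            return "candidate"
        return "rejected"


@dataclass
class FilterCascadeReport:
    """Stage-by-stage accounting of the sequential DNM filter cascade."""

    n_input: int = 0
    stages: list = field(default_factory=list)  # [(name, n_in, n_out, rejected sites)]

    def add_stage(self, name: str, n_in: int, n_out: int, rejected: list) -> None:
        if n_out > n_in:
            raise ValueError("cascade counts must be non-increasing")
        self.stages.append(
            {"stage": name, "n_in": n_in, "n_out": n_out, "rejected": [str(s) for s in rejected]}
        )

    @property
    def n_survivors(self) -> int:
        return self.stages[-1]["n_out"] if self.stages else self.n_input

    def to_dict(self) -> dict:
        return {"n_input": self.n_input, "stages": self.stages, "n_survivors": self.n_survivors}


@dataclass
class GenotypeProbabilityMatrix:
    """Imputation-style genotype probabilities, variants x individuals x 3.

    ``probs[v, i]`` is (P(hom-ref), P(het), P(hom-alt)) for individual ``i``
    at variant ``v``. ``variants`` is a DataFrame with columns
    chrom, pos, ref, alt (plus optional snp_id).
    """

    variants: pd.DataFrame
    samples: list
    probs: np.ndarray

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (len(self.variants), len(self.samples), 3):
            raise ValueError("probs shape must be (n_variants, n_samples, 3)")
        sums = self.probs.sum(axis=2)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("probability triples must each sum to 1")

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def dosage(self) -> np.ndarray:
        """Posterior mean alt-allele dosage, variants x individuals."""
        return self.probs[:, :, 1] + 2.0 * self.probs[:, :, 2]


@dataclass
class HardCallMatrix:
    """Discrete genotypes derived from a probability matrix.

    ``genotypes`` is int8, variants x individuals, with -1 for missing.
    """

    variants: pd.DataFrame
    samples: list
    genotypes: np.ndarray

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.variants), len(self.samples)):
            raise ValueError("genotype matrix shape mismatch")

    @property
    def variant_missing_fraction(self) -> np.ndarray:
        return (self.genotypes == MISSING).mean(axis=1)

    @property
    def individual_missing_fraction(self) -> np.ndarray:
        if len(self.variants) == 0:
            return np.zeros(len(self.samples))
        return (self.genotypes == MISSING).mean(axis=0)


@dataclass
class BurdenResult:
    """One-tailed collapsing burden test result for one gene (or pooled set)."""

    gene: str
    maf_threshold: float
    n_rare_sites: int
    case_carriers: int
    n_cases: int
    control_carriers: int
    n_controls: int
    p_value: float
    engine: str = "exact"
    degenerate: bool = False
    fdr_significant: Optional[bool] = None

    def to_dict(self) -> dict:
        return {
            "gene": self.gene,
            "maf_threshold": self.maf_threshold,
            "n_rare_sites": self.n_rare_sites,
            "case_carriers": self.case_carriers,
            "n_cases": self.n_cases,
            "control_carriers": self.control_carriers,
            "n_controls": self.n_controls,
            "p_value": self.p_value,
            "engine": self.engine,
            "degenerate": self.degenerate,
            "fdr_significant": self.fdr_significant,
        }


@dataclass
class AssocResult:
    """Per-variant additive association result for a common variant."""

    site: Site
    maf: float
    beta: float
    p_value: float
    test: str  # "wald" or "score"
    bonferroni_significant: Optional[bool] = None


@dataclass(frozen=True)
class TruthRecord:
    """Ground-truth label for one simulated site."""

    site_id: str
    truth_class: str  # true_dnm | mosaic | paralog_artifact | inherited | causal_rare | neutral
    carriers: tuple = ()

    VALID = ("true_dnm", "mosaic", "paralog_artifact", "inherited", "causal_rare", "neutral")

    def __post_init__(self):
        if self.truth_class not in self.VALID:
            raise ValueError(f"unknown truth class {self.truth_class!r}")


def check_phenotype_table(pheno: pd.DataFrame) -> pd.DataFrame:
    """Validate a phenotype/covariate table.

    Requires columns ``individual_id`` and binary ``status`` (1=case,
    0=control); sub-phenotype columns must be 0 for controls.
    """
    required = {"individual_id", "status"}
    missing = required - set(pheno.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
    if not set(pheno["status"].unique()) <= {0, 1}:
        raise ValueError("status must be binary 0/1")
    for col in pheno.columns:
        if col.startswith("subpheno_"):
            bad = pheno.loc[pheno["status"] == 0, col]
            if (bad != 0).any():
                raise ValueError(f"sub-phenotype {col} set for a control individual")
    return pheno
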