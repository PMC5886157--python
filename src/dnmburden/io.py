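"""File-format layer: VCF, PED, Oxford GEN/SAMPLE, BED and TSV tables.

All coordinate conversions live here. VCF and GEN are 1-based; BED is
0-based half-open. VCF output is plain text v4.2 with GT:AD per sample so
that identical inputs produce byte-identical files.
"""
from __future__ import annotations

import os
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .models import GeneModel, MemberObservation, Site, TrioObservation, TruthRecord

GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", None: "./."}
GT_FROM_STRING = {"0/0": 0, "0|0": 0, "0/1": 1, "1/0": 1, "0|1": 1, "1|0": 1, "1/1": 2, "1|1": 2}


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def write_vcf(path, site_records: list, samples: list) -> None:
    """Write a multi-sample VCF v4.2 with GT:AD.

    ``site_records`` is a list of dicts with keys chrom, pos, ref, alt and
    ``calls``: {sample: (genotype or None, ref_count, alt_count)}.
    """
    lines = [
        "##fileformat=VCFv4.2",
        "##source=dnmburden",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    for rec in sorted(site_records, key=lambda r: (str(r["chrom"]), int(r["pos"]), r["ref"], r["alt"])):
        fields = [
            str(rec["chrom"]),
            str(rec["pos"]),
            rec.get("id", "."),
            rec["ref"],
            rec["alt"],
            ".",
            "PASS",
            ".",
            "GT:AD",
        ]
        for s in samples:
            gt, ref_c, alt_c = rec["calls"][s]
            fields.append(f"{GT_STRINGS[gt]}:{ref_c},{alt_c}")
        lines.append("\t".join(fields))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_trio_vcf(path, pedigree: pd.DataFrame) -> list:
    """Read a GT:AD VCF into TrioObservation lists, one per family per site.

    ``pedigree`` is a 6-column PED DataFrame (see :func:`read_ped`).
    Returns a flat list of TrioObservation.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    sample_idx = {s: i for i, s in enumerate(samples)}
    families = _family_structure(pedigree)

    observations = []
    for variant in vcf:
        if len(variant.ALT) != 1:
            raise ValueError(f"multiallelic record at {variant.CHROM}:{variant.POS}; decompose first")
        site = Site(str(variant.CHROM), int(variant.POS), variant.REF, variant.ALT[0])
        ad = variant.format("AD")
        gts = variant.gt_types  # 0=hom-ref,1=het,2=unknown,3=hom-alt
        gt_map = {0: 0, 1: 1, 3: 2, 2: None}

        def member(sample_id):
            i = sample_idx[sample_id]
            ref_c, alt_c = int(ad[i][0]), int(ad[i][1])
            return MemberObservation(max(ref_c, 0), max(alt_c, 0), gt_map[int(gts[i])])

        for fam_id, fam in families.items():
            observations.append(
                TrioObservation(
                    site=site,
                    child=member(fam["child"]),
                    father=member(fam["father"]),
                    mother=member(fam["mother"]),
                    siblings=[member(s) for s in fam["siblings"]],
                    family_id=fam_id,
                )
            )
    return observations


def _family_structure(ped: pd.DataFrame) -> dict:
    """Resolve child / parents / unaffected siblings per family.

    The affected offspring (phenotype 2) is the proband; other offspring
    rows are unaffected siblings.
    """
    families = {}
    for fam_id, grp in ped.groupby("family_id", sort=True):
        offspring = grp[(grp["father_id"] != "0") & (grp["mother_id"] != "0")]
        probands = offspring[offspring["phenotype"] == 2]
        if len(probands) != 1:
            raise ValueError(f"family {fam_id}: expected exactly one affected offspring")
        proband = probands.iloc[0]
        sibs = offspring[offspring["individual_id"] != proband["individual_id"]]
        families[fam_id] = {
            "child": proband["individual_id"],
            "father": proband["father_id"],
            "mother": proband["mother_id"],
            "siblings": list(sibs["individual_id"]),
        }
    return families


# ---------------------------------------------------------------------------
# PED
# ---------------------------------------------------------------------------

PED_COLUMNS = ["family_id", "individual_id", "father_id", "mother_id", "sex", "phenotype"]


def write_ped(path, ped: pd.DataFrame) -> None:
    ped[PED_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_ped(path) -> pd.DataFrame:
    ped = pd.read_csv(path, sep=r"\s+", header=None, names=PED_COLUMNS, dtype=str)
    ped["sex"] = ped["sex"].astype(int)
    ped["phenotype"] = ped["phenotype"].astype(int)
    return ped


# ---------------------------------------------------------------------------
# Oxford GEN / SAMPLE
# ---------------------------------------------------------------------------

def write_gen(path, variants: pd.DataFrame, probs: np.ndarray) -> None:
    """Write an Oxford GEN file: 5 leading columns then 3 probabilities per
    individual (snp_id, rs_id, pos, allele_A, allele_B)."""
    n_var, n_ind, _ = probs.shape
    with open(path, "w") as fh:
        for v in range(n_var):
            row = variants.iloc[v]
            snp_id = row.get("snp_id", f"{row['chrom']}:{row['pos']}")
            lead = [str(snp_id), f"rs_{v}", str(int(row["pos"])), row["ref"], row["alt"]]
            p = probs[v].reshape(-1)
            fh.write(" ".join(lead + [format(x, ".6f") for x in p]) + "\n")


def read_gen(path, chrom: str = "1") -> tuple:
    """Read an Oxford GEN file -> (variants DataFrame, probs array)."""
    rows, trips = [], []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            snp_id, _rs, pos, ref, alt = parts[:5]
            p = np.asarray(parts[5:], dtype=float).reshape(-1, 3)
            chrom_v = snp_id.split(":")[0] if ":" in snp_id else chrom
            rows.append({"chrom": chrom_v, "pos": int(pos), "ref": ref, "alt": alt, "snp_id": snp_id})
            trips.append(p)
    return pd.DataFrame(rows), np.asarray(trips)


def write_sample(path, sample_ids: Iterable[str]) -> None:
    with open(path, "w") as fh:
        fh.write("ID_1 ID_2 missing\n0 0 0\n")
        for s in sample_ids:
            fh.write(f"{s} {s} 0\n")


def read_sample(path) -> list:
    df = pd.read_csv(path, sep=r"\s+")
    return list(df["ID_1"].iloc[1:])  # skip the type row


# ---------------------------------------------------------------------------
# BED gene models
# ---------------------------------------------------------------------------

def write_gene_bed(path, genes: Iterable[GeneModel]) -> None:
    """One BED row per coding exon (0-based half-open), name = gene id."""
    with open(path, "w") as fh:
        for g in genes:
            for s, e in g.exons:
                fh.write(f"{g.chrom}\t{s}\t{e}\t{g.gene_id}\n")


def read_gene_bed(path) -> list:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "gene"],
                     dtype={"chrom": str})
    genes = []
    for (gene, chrom), grp in df.groupby(["gene", "chrom"], sort=True):
        genes.append(GeneModel(gene, chrom, tuple(zip(grp["start"], grp["end"])), source="bed"))
    return genes


# ---------------------------------------------------------------------------
# Truth / annotation / phenotype tables
# ---------------------------------------------------------------------------

def write_truth(path, records: Iterable[TruthRecord]) -> None:
    rows = [
        {"site_id": r.site_id, "truth_class": r.truth_class, "carriers": ",".join(r.carriers)}
        for r in records
    ]
    pd.DataFrame(rows, columns=["site_id", "truth_class", "carriers"]).to_csv(path, sep="\t", index=False)


def read_truth(path) -> list:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    return [
        TruthRecord(r["site_id"], r["truth_class"], tuple(c for c in str(r["carriers"]).split(",") if c))
        for _, r in df.iterrows()
    ]


def write_tsv(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)
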