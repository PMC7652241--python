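"""Readers and writers for the pipeline's on-disk formats.

Coordinate conventions: VCF and all internal genotype handling are 1-based
inclusive; BED regions are 0-based half-open and converted on read/write.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import MISSING, FamilyDataset

SEX_CODES = {"female", "male"}
ROLE_CODES = {"mother", "father", "offspring"}


def read_vcf(path, pedigree: pd.DataFrame | None = None) -> FamilyDataset:
    """Load biallelic SNPs from a VCF into a FamilyDataset.

    Multiallelic records are skipped (counted in ``truth['multiallelic_skipped']``
    for the report).  GT is required; DP/GQ default to 0 when absent.  The
    RADtag id is taken from the INFO field RT when present, else each site
    is its own tag.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, gts, dps, gqs = [], [], [], []
    skipped = 0
    for v in vcf:
        if len(v.ALT) != 1:
            skipped += 1
            continue
        g = np.array(v.gt_types, dtype=np.int8)  # 0=hom ref,1=het,2=unknown,3=hom alt
        gt = np.where(g == 0, 0, np.where(g == 1, 1, np.where(g == 3, 2, MISSING))).astype(np.int8)
        try:
            dp = np.asarray(v.format("DP")).reshape(-1).astype(np.int32)
        except Exception:
            dp = np.zeros(len(samples), dtype=np.int32)
        try:
            gq = np.asarray(v.format("GQ")).reshape(-1).astype(np.int16)
        except Exception:
            gq = np.zeros(len(samples), dtype=np.int16)
        tag = v.INFO.get("RT") or f"{v.CHROM}_{v.POS}"
        rows.append((v.CHROM, v.POS, tag))
        gts.append(gt)
        dps.append(dp)
        gqs.append(gq)
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "radtag"])
    if pedigree is None:
        pedigree = pd.DataFrame(
            {"id": samples, "family": "na", "role": "offspring", "sex": "female"}
        )
    ds = FamilyDataset(
        pedigree=pedigree,
        samples=samples,
        sites=sites,
        gt=np.array(gts, dtype=np.int8).reshape(len(sites), len(samples)),
        dp=np.array(dps, dtype=np.int32).reshape(len(sites), len(samples)),
        gq=np.array(gqs, dtype=np.int16).reshape(len(sites), len(samples)),
        truth={"multiallelic_skipped": skipped},
    )
    return ds


def read_sample_sheet(path) -> pd.DataFrame:
    """Validated pedigree TSV with columns id, family, role, sex."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"id", "family", "role", "sex"}
    if not required <= set(df.columns):
        raise ValueError(f"sample sheet must have columns {sorted(required)}")
    if df["id"].duplicated().any():
        dups = list(df.loc[df["id"].duplicated(), "id"])
        raise ValueError(f"duplicate sample ids: {dups}")
    bad_sex = set(df["sex"]) - SEX_CODES
    if bad_sex:
        raise ValueError(f"unknown sex codes {sorted(bad_sex)}; allowed: {sorted(SEX_CODES)}")
    bad_role = set(df["role"]) - ROLE_CODES
    if bad_role:
        raise ValueError(f"unknown roles {sorted(bad_role)}; allowed: {sorted(ROLE_CODES)}")
    for fam, sub in df.groupby("family"):
        for role, sex in (("mother", "female"), ("father", "male")):
            r = sub[sub["role"] == role]
            if len(r) > 1:
                raise ValueError(f"family {fam} has {len(r)} {role}s")
            if len(r) == 1 and r["sex"].iat[0] != sex:
                raise ValueError(f"family {fam}: {role} must be {sex}")
    return df


def read_counts_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_transcript_bed(path) -> pd.DataFrame:
    """BED (0-based half-open) -> transcript table with 1-based start."""
    bed = pd.read_csv(path, sep="\t", header=None,
                      names=["chrom", "start", "end", "transcript_id"])
    bed["start"] = bed["start"] + 1
    bed["length"] = bed["end"] - bed["start"] + 1
    return bed


def read_de_table(path) -> pd.DataFrame:
    """External differential-expression table: transcript_id, logFC, FDR."""
    df = pd.read_csv(path, sep="\t")
    required = {"transcript_id", "logFC", "FDR"}
    if not required <= set(df.columns):
        raise ValueError(f"DE table must have columns {sorted(required)}")
    return df.set_index("transcript_id")


def parse_region(text: str) -> tuple:
    """'Chr7:0-10300000' -> ('Chr7', max(start,1), end), 1-based inclusive."""
    chrom, span = text.split(":")
    start, end = span.replace(",", "").split("-")
    return chrom, max(int(start), 1), int(end)


def write_tsv(df: pd.DataFrame, path, header_comment: str | None = None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=False)
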