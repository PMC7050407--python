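"""Readers and testability filters for allelic count and genotype tables.

The differential-ASE pipeline consumes per-sample allelic read counts at
heterozygous SNPs in the tab-separated schema emitted by standard allele
counters (columns ``contig, position, variantID, refAllele, altAllele,
refCount, altCount, totalCount``; extra columns are preserved untouched),
an array-style genotype table (VCF with GT, or a wide TSV), and a sample
metadata table mapping samples to subjects, groups and brain regions.

A SNP enters the model only if, in a given region, enough genotyped
heterozygotes with adequate read depth exist in *both* groups:

* a subject qualifies at a SNP when genotyped heterozygous and its total
  read count there is strictly greater than ``min_reads`` (default 10);
* the SNP is testable when at least ``min_het_per_group`` (default 5)
  qualifying subjects exist in each group.

Every dropped subject or SNP is recorded in a filter-audit table with the
reason, so the filter is fully accountable.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "SnpSite",
    "SnpDataset",
    "read_ase_counts",
    "read_samples",
    "read_genotypes",
    "filter_testable_snps",
]

REQUIRED_COUNT_COLS = [
    "contig",
    "position",
    "refAllele",
    "altAllele",
    "refCount",
    "altCount",
]

_VALID_BASES = set("ACGT")


@dataclasses.dataclass(frozen=True)
class SnpSite:
    """One biallelic SNP (1-based, closed, VCF-convention coordinates)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    snp_id: str
    gene: str | None = None
    feature: str | None = None

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError("position must be >= 1")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")
        if not (set(self.ref) <= _VALID_BASES and set(self.alt) <= _VALID_BASES):
            raise ValueError("alleles must be over A/C/G/T")


@dataclasses.dataclass
class SnpDataset:
    """Model-ready data for one SNP in one region.

    ``table`` has one row per qualifying heterozygous subject with columns
    subject_id, group, ref_count, alt_count.
    """

    site: SnpSite
    region: str
    table: pd.DataFrame

    @property
    def n_het_aud(self) -> int:
        return int((self.table["group"] == "AUD").sum())

    @property
    def n_het_ctl(self) -> int:
        return int((self.table["group"] == "control").sum())


# ---------------------------------------------------------------------------
# readers


def read_ase_counts(path) -> pd.DataFrame:
    """Read and validate an allele-counter TSV.

    Unknown extra columns (e.g. ``sample``, mapping-QC columns) are
    preserved.  Malformed or negative-count rows raise with the offending
    1-based file line number.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_COUNT_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    if df.empty:
        return df
    for col in ("position", "refCount", "altCount"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna()
        if bad.any():
            line = int(df.index[bad][0]) + 2   # header is line 1
            raise ValueError(f"{path}: malformed {col} at line {line}")
        df[col] = vals.astype(int)
    neg = (df["refCount"] < 0) | (df["altCount"] < 0)
    if neg.any():
        line = int(df.index[neg][0]) + 2
        raise ValueError(f"{path}: negative count at line {line}")
    if "totalCount" not in df.columns:
        df["totalCount"] = df["refCount"] + df["altCount"]
    same = df["refAllele"].astype(str) == df["altAllele"].astype(str)
    if same.any():
        line = int(df.index[same][0]) + 2
        raise ValueError(f"{path}: ref and alt alleles identical at line {line}")
    # multi-allelic (same site, different allele pair) is not supported
    alleles_per_site = df.groupby(["contig", "position"])[
        ["refAllele", "altAllele"]
    ].nunique()
    multi = alleles_per_site[(alleles_per_site > 1).any(axis=1)]
    if len(multi):
        site = multi.index[0]
        raise ValueError(f"{path}: multi-allelic site at {site[0]}:{site[1]}")
    return df


def read_samples(path) -> pd.DataFrame:
    """Read sample metadata (sample_id, subject_id, group, region)."""
    df = pd.read_csv(path, sep="\t")
    required = ["sample_id", "subject_id", "group", "region"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"{path}: duplicate sample_id {dup!r}")
    bad = ~df["group"].isin(["AUD", "control"])
    if bad.any():
        raise ValueError(
            f"{path}: group must be 'AUD' or 'control', got "
            f"{df.loc[bad, 'group'].iloc[0]!r}"
        )
    multi = df.groupby(["subject_id", "region"]).size()
    if (multi > 1).any():
        key = multi[multi > 1].index[0]
        raise ValueError(
            f"{path}: subject {key[0]!r} has multiple samples in region {key[1]!r}"
        )
    return df


_GT_CODE = {
    (0, 0): "hom_ref",
    (0, 1): "het",
    (1, 0): "het",
    (1, 1): "hom_alt",
}


def _code_gt_string(gt: str) -> str:
    gt = gt.replace("|", "/")
    if gt in ("./.", ".", ""):
        return "missing"
    try:
        a, b = (int(x) for x in gt.split("/"))
    except ValueError:
        return "missing"
    return _GT_CODE.get((a, b), "missing")


def read_genotypes(path, format: str = "vcf") -> pd.DataFrame:
    """Read genotypes as a SNP-by-subject table of call strings.

    Calls are ``hom_ref``, ``het``, ``hom_alt`` or ``missing``; phase is
    ignored.  ``format='vcf'`` parses a VCF v4.x with GT; ``format='tsv'``
    expects a wide table with site columns followed by one GT-string
    column per subject.  Multi-allelic VCF records are rejected.
    The index is the variant ID (falling back to chrom:pos).
    """
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", dtype=str)
        site_cols = [
            c
            for c in ("contig", "position", "refAllele", "altAllele", "variantID")
            if c in df.columns
        ]
        if "variantID" not in df.columns:
            raise ValueError(f"{path}: genotype TSV needs a variantID column")
        subj_cols = [c for c in df.columns if c not in site_cols]
        out = df[subj_cols].map(_code_gt_string)
        out.index = df["variantID"]
        return out
    if format != "vcf":
        raise ValueError("format must be 'vcf' or 'tsv'")
    rows, ids = [], []
    with pysam.VariantFile(str(path)) as vf:
        subjects = list(vf.header.samples)
        for rec in vf.fetch() if vf.index is not None else vf:
            if rec.alts is None or len(rec.alts) != 1:
                raise ValueError(
                    f"{path}: multi-allelic record at {rec.chrom}:{rec.pos}"
                )
            ids.append(rec.id or f"{rec.chrom}:{rec.pos}")
            calls = []
            for s in subjects:
                alleles = rec.samples[s]["GT"]
                if alleles is None or any(a is None for a in alleles):
                    calls.append("missing")
                else:
                    calls.append(_GT_CODE.get(tuple(sorted(alleles)), "missing"))
            rows.append(calls)
    return pd.DataFrame(rows, index=ids, columns=subjects)


# ---------------------------------------------------------------------------
# filtering


def _infer_het_from_counts(row) -> bool:
    # optional heuristic, off by default: both alleles need >= 1 read
    return row["refCount"] >= 1 and row["altCount"] >= 1


def filter_testable_snps(
    counts: pd.DataFrame,
    genotypes: pd.DataFrame,
    samples: pd.DataFrame,
    min_het_per_group: int = 5,
    min_reads: int = 10,
    het_from_counts: bool = False,
) -> tuple[list[SnpDataset], pd.DataFrame]:
    """Apply the testability filters and build per-SNP model datasets.

    A subject contributes to a SNP only when genotyped heterozygous there
    (or, with ``het_from_counts=True``, when both alleles have reads — a
    heuristic flagged in the audit) and its total read count is strictly
    greater than ``min_reads``.  A SNP is retained when at least
    ``min_het_per_group`` qualifying subjects exist in both groups.  The
    counts table must carry a ``sample`` column joining it to the sample
    metadata; all samples must belong to one region.

    Returns the retained datasets sorted by (chrom, pos) and the audit
    table accounting for every dropped subject row and SNP.
    """
    audit: list[dict] = []
    if counts.empty:
        return [], pd.DataFrame(
            audit, columns=["level", "variantID", "sample", "reason"]
        )
    if "sample" not in counts.columns:
        raise ValueError("counts table needs a 'sample' column for filtering")
    meta = samples.set_index("sample_id")
    regions = set()
    datasets: list[SnpDataset] = []

    merged = counts.copy()
    known = merged["sample"].isin(meta.index)
    for s in merged.loc[~known, "sample"].unique():
        audit.append(
            {
                "level": "sample",
                "variantID": "*",
                "sample": s,
                "reason": "sample_missing_from_metadata",
            }
        )
    merged = merged[known]
    merged = merged.assign(
        subject_id=meta.loc[merged["sample"], "subject_id"].to_numpy(),
        group=meta.loc[merged["sample"], "group"].to_numpy(),
        region=meta.loc[merged["sample"], "region"].to_numpy(),
    )
    regions = set(merged["region"].unique())
    if len(regions) > 1:
        raise ValueError(
            "filter_testable_snps expects counts from a single region; "
            f"got {sorted(regions)}"
        )
    region = regions.pop() if regions else ""

    for (contig, position), site_rows in merged.groupby(
        ["contig", "position"], sort=False
    ):
        vid = str(site_rows["variantID"].iloc[0])
        gt_id = vid if vid in genotypes.index else f"{contig}:{position}"
        keep_rows = []
        for _, row in site_rows.iterrows():
            subj = row["subject_id"]
            if het_from_counts:
                is_het = _infer_het_from_counts(row)
                het_reason = "not_het_by_counts"
            else:
                if gt_id not in genotypes.index or subj not in genotypes.columns:
                    audit.append(
                        {
                            "level": "subject",
                            "variantID": vid,
                            "sample": row["sample"],
                            "reason": "genotype_missing",
                        }
                    )
                    continue
                call = genotypes.at[gt_id, subj]
                if call == "missing":
                    audit.append(
                        {
                            "level": "subject",
                            "variantID": vid,
                            "sample": row["sample"],
                            "reason": "genotype_missing",
                        }
                    )
                    continue
                is_het = call == "het"
                het_reason = "not_heterozygous"
            if not is_het:
                audit.append(
                    {
                        "level": "subject",
                        "variantID": vid,
                        "sample": row["sample"],
                        "reason": het_reason,
                    }
                )
                continue
            total = int(row["refCount"]) + int(row["altCount"])
            if total <= min_reads:
                audit.append(
                    {
                        "level": "subject",
                        "variantID": vid,
                        "sample": row["sample"],
                        "reason": f"total_reads_le_{min_reads}",
                    }
                )
                continue
            keep_rows.append(
                {
                    "subject_id": subj,
                    "group": row["group"],
                    "ref_count": int(row["refCount"]),
                    "alt_count": int(row["altCount"]),
                }
            )
        tab = pd.DataFrame(
            keep_rows, columns=["subject_id", "group", "ref_count", "alt_count"]
        )
        n_aud = int((tab["group"] == "AUD").sum())
        n_ctl = int((tab["group"] == "control").sum())
        if n_aud < min_het_per_group or n_ctl < min_het_per_group:
            audit.append(
                {
                    "level": "snp",
                    "variantID": vid,
                    "sample": "*",
                    "reason": (
                        f"het_subjects_aud_{n_aud}_ctl_{n_ctl}_"
                        f"lt_{min_het_per_group}"
                    ),
                }
            )
            continue
        site = SnpSite(
            chrom=str(contig),
            pos=int(position),
            ref=str(site_rows["refAllele"].iloc[0]),
            alt=str(site_rows["altAllele"].iloc[0]),
            snp_id=vid,
        )
        datasets.append(SnpDataset(site=site, region=region, table=tab))

    def sort_key(ds: SnpDataset):
        chrom = ds.site.chrom.removeprefix("chr")
        return (chrom.zfill(2) if chrom.isdigit() else chrom, ds.site.pos)

    datasets.sort(key=sort_key)
    audit_df = pd.DataFrame(
        audit, columns=["level", "variantID", "sample", "reason"]
    )
    return datasets, audit_df
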