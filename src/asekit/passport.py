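"""Reporter-assay (PASSPORT-seq style) computational pipeline.

A pooled massively-parallel reporter assay clones both alleles of candidate
3'UTR SNPs downstream of a reporter gene, transfects the pool into cell
lines, and sequences both the plasmid DNA and the expressed RNA from the
same cells.  Each read is condition barcode + UMI + designed insert.  A
variant is functional when the alt:ref ratio differs between RNA and DNA —
an allele-by-source interaction in a negative-binomial GLM on UMI counts.

This module covers the computational arm end to end: oligo-library design,
barcode demultiplexing, UMI extraction, allele assignment by exact sequence
identity against the designed inserts, UMI deduplication (``unique`` and
``directional`` network collapse), the per-SNP per-cell-line NB-GLM
activity test, cross-cell-line consistency calling, and detection QC.
"""

from __future__ import annotations

import dataclasses
from collections import Counter, defaultdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from . import nbglmm
from .nbglmm import NbGlmmData, bh_fdr, fit_nb_glm, wald_test

__all__ = [
    "OligoConstruct",
    "PassportTestResult",
    "design_library",
    "read_fastq",
    "demultiplex",
    "extract_umi",
    "AlleleIndex",
    "assign_allele",
    "dedup_count",
    "count_pipeline",
    "test_snp_activity",
    "run_cell_line",
    "call_consistent_hits",
    "detection_summary",
]

LN2 = float(np.log(2.0))


@dataclasses.dataclass(frozen=True)
class OligoConstruct:
    """One designed reporter insert: one allele of one SNP with flanks."""

    snp_id: str
    allele: str          # "ref" | "alt"
    sequence: str
    flank_len: int

    def __post_init__(self):
        if self.allele not in ("ref", "alt"):
            raise ValueError("allele must be 'ref' or 'alt'")


@dataclasses.dataclass
class PassportTestResult:
    snp_id: str
    cell_line: str
    beta12: float
    adj_log2_fc: float
    p_value: float
    q_value: float
    detected: bool
    fit_status: str = "converged"


# ---------------------------------------------------------------------------
# library design


def design_library(
    manifest: pd.DataFrame, flank_len: int = 30
) -> tuple[list[OligoConstruct], pd.DataFrame]:
    """Design two reporter constructs (one per allele) for every SNP.

    ``manifest`` needs columns snp_id, refAllele, altAllele, left_flank,
    right_flank.  The insert is ``left[-flank_len:] + allele +
    right[:flank_len]`` so the two constructs of a SNP differ at exactly
    the centered variant base.  Duplicate insert sequences across the
    library make read assignment ambiguous and are rejected.

    Returns the construct list and a manifest table (snp_id, allele, name,
    sequence) suitable for writing a FASTA reference.
    """
    constructs: list[OligoConstruct] = []
    for _, row in manifest.iterrows():
        snp = str(row["snp_id"])
        left, right = str(row["left_flank"]), str(row["right_flank"])
        if len(left) < flank_len or len(right) < flank_len:
            raise ValueError(f"insufficient flanking sequence for SNP {snp}")
        for allele, base in (("ref", row["refAllele"]), ("alt", row["altAllele"])):
            seq = left[-flank_len:] + str(base) + right[:flank_len]
            constructs.append(
                OligoConstruct(snp_id=snp, allele=allele, sequence=seq, flank_len=flank_len)
            )
    seqs = Counter(c.sequence for c in constructs)
    dups = [s for s, n in seqs.items() if n > 1]
    if dups:
        raise ValueError(
            f"{len(dups)} duplicate insert sequence(s) across the library; "
            "assignment would be ambiguous"
        )
    table = pd.DataFrame(
        {
            "snp_id": [c.snp_id for c in constructs],
            "allele": [c.allele for c in constructs],
            "name": [f"{c.snp_id}_{c.allele}" for c in constructs],
            "sequence": [c.sequence for c in constructs],
        }
    )
    return constructs, table


def write_library_fasta(table: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for _, row in table.iterrows():
            fh.write(f">{row['name']}\n{row['sequence']}\n")


# ---------------------------------------------------------------------------
# read handling


def read_fastq(path) -> list[tuple[str, str]]:
    """Load a FASTQ as (name, sequence) pairs (qualities are not used)."""
    with pysam.FastxFile(str(path)) as fh:
        return [(entry.name, entry.sequence) for entry in fh]


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def demultiplex(
    reads: Iterable[tuple[str, str]],
    barcode_map: Mapping[str, tuple],
    max_mismatch: int = 0,
) -> tuple[dict[tuple, list[tuple[str, str]]], int]:
    """Partition reads by their leading condition barcode.

    A read is assigned to the unique barcode within ``max_mismatch`` of its
    prefix; ties between equidistant barcodes and reads shorter than the
    barcode are left unassigned.  Returns (condition -> trimmed reads,
    n_unassigned); trimmed reads retain name and the sequence after the
    barcode.  Assigned plus unassigned always equals the input count.
    """
    lens = {len(b) for b in barcode_map}
    if len(lens) != 1:
        raise ValueError("all barcodes must share one length")
    blen = lens.pop()
    exact = dict(barcode_map)
    out: dict[tuple, list[tuple[str, str]]] = {v: [] for v in barcode_map.values()}
    unassigned = 0
    for name, seq in reads:
        if len(seq) < blen:
            unassigned += 1
            continue
        prefix = seq[:blen]
        cond = exact.get(prefix)
        if cond is None and max_mismatch > 0:
            best, best_d, ties = None, max_mismatch + 1, 0
            for bc, c in exact.items():
                d = _hamming(prefix, bc)
                if d < best_d:
                    best, best_d, ties = c, d, 1
                elif d == best_d:
                    ties += 1
            cond = best if (best is not None and ties == 1) else None
        if cond is None:
            unassigned += 1
        else:
            out[cond].append((name, seq[blen:]))
    return out, unassigned


def extract_umi(
    reads: Iterable[tuple[str, str]], umi_len: int
) -> tuple[list[tuple[str, str, str]], int]:
    """Split the leading UMI off each barcode-trimmed read.

    Returns ([(name, umi, insert)], n_discarded) where reads not strictly
    longer than the UMI are discarded and tallied.  UMIs containing N are
    retained (flagged downstream by their sequence).
    """
    out: list[tuple[str, str, str]] = []
    discarded = 0
    for name, seq in reads:
        if len(seq) <= umi_len:
            discarded += 1
            continue
        out.append((name, seq[:umi_len], seq[umi_len:]))
    return out, discarded


class AlleleIndex:
    """Exact-sequence lookup of reads against the designed insert library.

    The inserts are short designed sequences whose variant base is known,
    so assignment is by sequence identity (with substring containment for
    truncated reads) rather than alignment: a read is assigned when exactly
    one construct matches, ambiguous when several do (e.g. it covers only
    the shared flank), and unmapped otherwise.  ``max_mismatch=1`` adds a
    sequencing-error-tolerant fallback for full-length reads: one
    substitution is allowed anywhere *except* the variant base, which
    alone distinguishes the two alleles.  Results are memoised per
    distinct read sequence.
    """

    def __init__(self, library: Sequence[OligoConstruct], max_mismatch: int = 0):
        if max_mismatch not in (0, 1):
            raise ValueError("max_mismatch must be 0 or 1")
        self.library = list(library)
        self.max_mismatch = max_mismatch
        self._full = {c.sequence: (c.snp_id, c.allele) for c in self.library}
        self._cache: dict[str, tuple[str, str] | str] = {}

    def _mismatch_hits(self, seq: str):
        hits = []
        for c in self.library:
            if len(seq) != len(c.sequence):
                continue
            mism = [i for i, (x, y) in enumerate(zip(seq, c.sequence)) if x != y]
            if len(mism) <= 1 and c.flank_len not in mism:
                hits.append((c.snp_id, c.allele))
        return hits

    def assign(self, seq: str):
        """Return (snp_id, allele), 'ambiguous' or 'unmapped'."""
        hit = self._full.get(seq)
        if hit is not None:
            return hit
        cached = self._cache.get(seq)
        if cached is not None:
            return cached
        matches = [
            (c.snp_id, c.allele)
            for c in self.library
            if (seq in c.sequence) or (c.sequence in seq)
        ]
        if not matches and self.max_mismatch == 1:
            matches = self._mismatch_hits(seq)
        if len(matches) == 1:
            res = matches[0]
        elif matches:
            res = "ambiguous"
        else:
            res = "unmapped"
        self._cache[seq] = res
        return res


def assign_allele(
    reads: Iterable[tuple[str, str, str]], index: AlleleIndex
) -> tuple[list[tuple[str, str, str]], int, int]:
    """Assign (name, umi, insert) reads to constructs.

    Returns ([(snp_id, allele, umi)], n_ambiguous, n_unmapped); assigned +
    ambiguous + unmapped equals the input count.
    """
    assigned: list[tuple[str, str, str]] = []
    ambiguous = unmapped = 0
    for _, umi, insert in reads:
        res = index.assign(insert)
        if res == "ambiguous":
            ambiguous += 1
        elif res == "unmapped":
            unmapped += 1
        else:
            assigned.append((res[0], res[1], umi))
    return assigned, ambiguous, unmapped


# ---------------------------------------------------------------------------
# UMI deduplication


def _directional_clusters(counts: Counter) -> int:
    """Count clusters under the directional UMI-network collapse rule.

    UMI B is absorbed into A when Hamming(A, B) == 1 and
    count(A) >= 2 * count(B) - 1; cluster roots are found by breadth-first
    search from high-count UMIs downward.
    """
    umis = sorted(counts, key=lambda u: (-counts[u], u))
    adj: dict[str, list[str]] = defaultdict(list)
    for i, a in enumerate(umis):
        for b in umis[i + 1 :]:
            if _hamming(a, b) == 1:
                if counts[a] >= 2 * counts[b] - 1:
                    adj[a].append(b)
                if counts[b] >= 2 * counts[a] - 1:
                    adj[b].append(a)
    visited: set[str] = set()
    n_clusters = 0
    for u in umis:
        if u in visited:
            continue
        n_clusters += 1
        stack = [u]
        visited.add(u)
        while stack:
            cur = stack.pop()
            for nxt in adj[cur]:
                if nxt not in visited and counts[cur] >= 2 * counts[nxt] - 1:
                    visited.add(nxt)
                    stack.append(nxt)
    return n_clusters


def dedup_count(
    assigned_by_condition: Mapping[tuple, list[tuple[str, str, str]]],
    method: str = "unique",
) -> pd.DataFrame:
    """UMI-deduplicated molecule counts per (SNP, allele, condition).

    ``unique`` counts distinct UMI strings; ``directional`` additionally
    collapses likely PCR/sequencing-error neighbours with the standard
    count-adjacency rule.  Conditions are (cell_line, replicate, source)
    tuples.  Returns a table with columns snp_id, allele, cell_line,
    replicate, source, umi_count, read_count.
    """
    if method not in ("unique", "directional"):
        raise ValueError("method must be 'unique' or 'directional'")
    rows: list[dict] = []
    for cond, recs in assigned_by_condition.items():
        cell_line, replicate, source = cond
        groups: dict[tuple[str, str], Counter] = defaultdict(Counter)
        for snp_id, allele, umi in recs:
            groups[(snp_id, allele)][umi] += 1
        for (snp_id, allele), umi_counts in sorted(groups.items()):
            n_reads = sum(umi_counts.values())
            if method == "unique":
                n_umi = len(umi_counts)
            else:
                n_umi = _directional_clusters(umi_counts)
            rows.append(
                {
                    "snp_id": snp_id,
                    "allele": allele,
                    "cell_line": cell_line,
                    "replicate": replicate,
                    "source": source,
                    "umi_count": n_umi,
                    "read_count": n_reads,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "snp_id",
            "allele",
            "cell_line",
            "replicate",
            "source",
            "umi_count",
            "read_count",
        ],
    )


def count_pipeline(
    fastq_path,
    barcode_table: pd.DataFrame,
    library: Sequence[OligoConstruct],
    umi_len: int = 10,
    max_mismatch: int = 0,
    assign_mismatch: int = 0,
    dedup_method: str = "unique",
) -> tuple[pd.DataFrame, dict]:
    """FASTQ to UMI-count table: demultiplex, trim UMIs, assign, dedup.

    ``barcode_table`` has columns barcode, cell_line, replicate, source.
    Returns the count table and a QC dict with per-stage read tallies
    (which always conserve the input read count).
    """
    reads = read_fastq(fastq_path)
    bc_map = {
        row["barcode"]: (row["cell_line"], int(row["replicate"]), row["source"])
        for _, row in barcode_table.iterrows()
    }
    if len(bc_map) != len(barcode_table):
        raise ValueError("duplicate barcodes in barcode table")
    by_cond, n_unassigned = demultiplex(reads, bc_map, max_mismatch=max_mismatch)
    assigned_by_cond: dict[tuple, list[tuple[str, str, str]]] = {}
    n_short = n_ambiguous = n_unmapped = n_assigned = 0
    index = AlleleIndex(library, max_mismatch=assign_mismatch)
    for cond, cond_reads in by_cond.items():
        with_umi, discarded = extract_umi(cond_reads, umi_len)
        n_short += discarded
        assigned, amb, unm = assign_allele(with_umi, index)
        n_ambiguous += amb
        n_unmapped += unm
        n_assigned += len(assigned)
        assigned_by_cond[cond] = assigned
    counts = dedup_count(assigned_by_cond, method=dedup_method)
    qc = {
        "n_reads": len(reads),
        "n_unassigned_barcode": n_unassigned,
        "n_too_short": n_short,
        "n_ambiguous": n_ambiguous,
        "n_unmapped": n_unmapped,
        "n_assigned": n_assigned,
    }
    return counts, qc


# ---------------------------------------------------------------------------
# statistics


def test_snp_activity(
    counts: pd.DataFrame,
    snp_id: str,
    cell_line: str,
    lib_sizes: Mapping[tuple, float] | None = None,
) -> PassportTestResult:
    """NB-GLM test of differential allelic activity (RNA vs DNA).

    Observations are the UMI counts of one SNP in one cell line over
    (allele, source, replicate); the model has fixed effects allele,
    source and allele-by-source with an offset equal to the log total UMI
    count of each (replicate, source) library, so library depth is
    normalised rather than estimated.  The interaction is the log change
    of the alt:ref ratio from DNA to RNA; a Wald test against zero scores
    functionality.  SNPs without both alleles observed in both sources are
    reported undetected and untested.
    """
    sub = counts[(counts["snp_id"] == snp_id) & (counts["cell_line"] == cell_line)]
    detected = True
    for src in ("DNA", "RNA"):
        for allele in ("ref", "alt"):
            tot = sub[(sub["source"] == src) & (sub["allele"] == allele)][
                "umi_count"
            ].sum()
            if tot == 0:
                detected = False
    if not detected or sub.empty:
        return PassportTestResult(
            snp_id=snp_id,
            cell_line=cell_line,
            beta12=np.nan,
            adj_log2_fc=np.nan,
            p_value=np.nan,
            q_value=np.nan,
            detected=False,
            fit_status="undetected",
        )
    y = sub["umi_count"].to_numpy(dtype=float)
    x_allele = (sub["allele"] == "alt").to_numpy(dtype=float)
    x_source = (sub["source"] == "RNA").to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(y), x_allele, x_source, x_allele * x_source])
    if lib_sizes is None:
        totals = (
            counts[counts["cell_line"] == cell_line]
            .groupby(["replicate", "source"])["umi_count"]
            .sum()
        )
        lib_sizes = {k: float(v) for k, v in totals.items()}
    offset = np.log(
        np.array(
            [
                max(lib_sizes[(int(r), s)], 1.0)
                for r, s in zip(sub["replicate"], sub["source"])
            ]
        )
    )
    data = NbGlmmData(
        y=y,
        X=X,
        names=("intercept", "allele", "source", "allele:source"),
        offset=offset,
    )
    fit = fit_nb_glm(data)
    if not fit.ok:
        return PassportTestResult(
            snp_id=snp_id,
            cell_line=cell_line,
            beta12=float(fit.coef("allele:source")),
            adj_log2_fc=float(fit.coef("allele:source")) / LN2,
            p_value=np.nan,
            q_value=np.nan,
            detected=True,
            fit_status=fit.status,
        )
    w = wald_test(fit, "allele:source")
    return PassportTestResult(
        snp_id=snp_id,
        cell_line=cell_line,
        beta12=w.estimate,
        adj_log2_fc=w.estimate / LN2,
        p_value=w.p_value,
        q_value=np.nan,
        detected=True,
        fit_status=fit.status,
    )


def run_cell_line(counts: pd.DataFrame, cell_line: str) -> pd.DataFrame:
    """Test every SNP in one cell line and BH-adjust within the cell line."""
    snps = sorted(counts[counts["cell_line"] == cell_line]["snp_id"].unique())
    totals = (
        counts[counts["cell_line"] == cell_line]
        .groupby(["replicate", "source"])["umi_count"]
        .sum()
    )
    lib_sizes = {k: float(v) for k, v in totals.items()}
    results = [
        test_snp_activity(counts, snp, cell_line, lib_sizes=lib_sizes)
        for snp in snps
    ]
    df = pd.DataFrame([dataclasses.asdict(r) for r in results])
    tested = df["p_value"].notna()
    if tested.any():
        df.loc[tested, "q_value"] = bh_fdr(df.loc[tested, "p_value"].to_numpy())
    return df


def call_consistent_hits(
    results_by_cell_line: Mapping[str, pd.DataFrame], fdr: float = 0.05
) -> pd.DataFrame:
    """SNPs significant in every cell line, with direction concordance.

    Returns one row per SNP significant (q < fdr) in all cell lines with a
    ``consistent`` flag that is true when the interaction sign agrees
    everywhere.
    """
    lines = list(results_by_cell_line)
    if len(lines) < 2:
        raise ValueError("need results from at least two cell lines")
    sig_sets = []
    for cl in lines:
        df = results_by_cell_line[cl]
        sig = df[(df["q_value"].notna()) & (df["q_value"] < fdr)]
        sig_sets.append(set(sig["snp_id"]))
    common = sorted(set.intersection(*sig_sets))
    rows = []
    for snp in common:
        signs = [
            float(
                np.sign(
                    results_by_cell_line[cl]
                    .set_index("snp_id")
                    .loc[snp, "beta12"]
                )
            )
            for cl in lines
        ]
        rows.append(
            {
                "snp_id": snp,
                **{f"sign_{cl}": s for cl, s in zip(lines, signs)},
                "consistent": len(set(signs)) == 1,
            }
        )
    return pd.DataFrame(rows)


def detection_summary(counts: pd.DataFrame, screened_snps: Sequence[str]) -> dict:
    """Detection QC: a SNP is detected when both alleles have nonzero RNA
    UMI counts in every cell line screened.

    Returns per-SNP flags and the detection rate as a percentage rounded
    to one decimal.
    """
    cell_lines = sorted(counts["cell_line"].unique())
    rna = counts[counts["source"] == "RNA"]
    totals = rna.groupby(["snp_id", "cell_line", "allele"])["umi_count"].sum()
    flags = {}
    for snp in screened_snps:
        ok = True
        for cl in cell_lines:
            for allele in ("ref", "alt"):
                if totals.get((snp, cl, allele), 0) <= 0:
                    ok = False
        flags[snp] = ok
    n_detected = sum(flags.values())
    n_screened = len(screened_snps)
    rate = round(100.0 * n_detected / n_screened, 1) if n_screened else 0.0
    return {
        "detected": flags,
        "n_detected": n_detected,
        "n_screened": n_screened,
        "detection_rate_pct": rate,
    }
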