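"""Synthetic-data generators for every input of the ASE pipelines.

The generators emulate the statistical structure the downstream models
assume, and emit ground-truth tables so that recovery, calibration and
round-trip tests can score the pipeline against known answers:

* a two-group brain cohort (AUD vs control, several regions) with
  array-style genotypes and NB-over-dispersed allelic RNA-seq counts at
  heterozygous SNPs, including per-subject random intercepts and planted
  allele-by-group interaction effects;
* pooled reporter-assay sequencing reads (barcode + UMI + designed insert)
  for both alleles of each screened SNP across cell lines, replicates and
  DNA/RNA sources, with PCR-duplicate injection;
* per-dose allelic counts for an ethanol (or any dosed-exposure)
  experiment with a planted log-ratio dose slope.

All randomness flows through one ``numpy.random.Generator`` derived from
the config seed; identical configs produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .passport import OligoConstruct

__all__ = [
    "SimConfig",
    "PassportDesign",
    "generate_cohort",
    "generate_ase_counts",
    "generate_passport_reads",
    "generate_ethanol_counts",
    "write_vcf",
    "ASE_COUNT_COLUMNS",
]

ASE_COUNT_COLUMNS = [
    "contig",
    "position",
    "variantID",
    "refAllele",
    "altAllele",
    "refCount",
    "altCount",
    "totalCount",
]

_BASES = np.array(list("ACGT"))


@dataclasses.dataclass
class SimConfig:
    """Study-design and noise parameters for the brain-cohort simulation.

    Defaults mirror the emulated study: 30 AUD and 30 control subjects
    sampled in four brain regions.  ``theta`` is the NB2 dispersion
    (variance ``mu + mu^2/theta``) and ``sigma_b`` the SD of the
    per-subject random intercept on the log-mean scale; neither is
    reported for the real data, so the defaults are plausible mid-range
    values for deep bulk RNA-seq, not estimates.
    """

    n_aud: int = 30
    n_ctl: int = 30
    regions: tuple[str, ...] = ("BLA", "CE", "NAC", "SFC")
    n_snps: int = 100
    frac_differential: float = 0.1
    beta12_true: float = float(np.log(2.0))   # natural-log scale
    beta1_base: float = 0.0
    theta: float = 10.0
    sigma_b: float = 0.3
    depth_mean: float = 50.0
    het_prob: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_aud <= 0 or self.n_ctl <= 0:
            raise ValueError("both groups need at least one subject")
        if self.n_snps < 0:
            raise ValueError("n_snps must be non-negative")
        if not 0.0 <= self.frac_differential <= 1.0:
            raise ValueError("frac_differential must lie in [0, 1]")
        if not 0.0 <= self.het_prob <= 1.0:
            raise ValueError("het_prob must lie in [0, 1]")
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        if self.sigma_b < 0:
            raise ValueError("sigma_b must be non-negative")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        if not self.regions:
            raise ValueError("at least one region required")


def _nb_draw(rng: np.random.Generator, mean, theta: float):
    """NB2 draw via the gamma-Poisson mixture; handles large theta stably."""
    mean = np.asarray(mean, dtype=float)
    if theta > 1e7:        # effectively Poisson
        return rng.poisson(mean)
    lam = rng.gamma(shape=theta, scale=mean / theta)
    return rng.poisson(lam)


# ---------------------------------------------------------------------------
# brain cohort


def _snp_sites(rng: np.random.Generator, n_snps: int) -> pd.DataFrame:
    chroms = [f"chr{(i % 22) + 1}" for i in range(n_snps)]
    pos = 10_000 + 1_000 * np.arange(n_snps)
    ref_idx = rng.integers(0, 4, n_snps)
    alt_idx = (ref_idx + rng.integers(1, 4, n_snps)) % 4
    return pd.DataFrame(
        {
            "contig": chroms,
            "position": pos,
            "variantID": [f"rs{100000 + i}" for i in range(n_snps)],
            "refAllele": _BASES[ref_idx],
            "altAllele": _BASES[alt_idx],
        }
    )


def generate_cohort(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate sample metadata and genotypes for a two-group cohort.

    Returns ``(samples, genotypes)``.  ``samples`` has one row per subject
    per region (columns sample_id, subject_id, group, region); ``genotypes``
    is SNP-by-subject with GT-style strings, het calls drawn independently
    with ``het_prob`` and the non-het mass split evenly between the two
    homozygotes.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    subjects = [f"AUD{i + 1:03d}" for i in range(config.n_aud)] + [
        f"CTL{i + 1:03d}" for i in range(config.n_ctl)
    ]
    groups = ["AUD"] * config.n_aud + ["control"] * config.n_ctl
    rows = [
        {
            "sample_id": f"{subj}_{region}",
            "subject_id": subj,
            "group": grp,
            "region": region,
        }
        for region in config.regions
        for subj, grp in zip(subjects, groups)
    ]
    samples = pd.DataFrame(rows)

    sites = _snp_sites(rng, config.n_snps)
    u = rng.random((config.n_snps, len(subjects)))
    gt = np.where(
        u < config.het_prob,
        "0/1",
        np.where(u < config.het_prob + (1 - config.het_prob) / 2, "0/0", "1/1"),
    )
    genotypes = pd.DataFrame(gt, columns=subjects)
    genotypes.insert(0, "variantID", sites["variantID"])
    for col in ("contig", "position", "refAllele", "altAllele"):
        genotypes.insert(genotypes.columns.get_loc("variantID"), col, sites[col])
    return samples, genotypes


def generate_ase_counts(
    config: SimConfig,
    genotypes: pd.DataFrame,
    samples: pd.DataFrame,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Draw allelic counts per region under the NB random-intercept model.

    For each heterozygous (subject, SNP) pair in each region a subject
    intercept ``b ~ Normal(0, sigma_b^2)`` is drawn (independently per SNP
    and region, matching the per-SNP model fitted downstream) and

        ref ~ NB(exp(beta0 + b), theta)
        alt ~ NB(exp(beta0 + beta1 + beta12 * [group == AUD] + b), theta)

    with ``beta0`` calibrated so that the expected total (including the
    log-normal mean factor ``exp(sigma_b^2 / 2)`` of the random intercept)
    equals ``depth_mean`` in both groups.  Homozygous subjects receive all
    reads on the carried allele; missing genotypes yield no record.

    Returns a mapping region -> count table in the allele-counter TSV
    schema (plus a ``sample`` column), and the per-SNP truth table.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    n_snps = len(genotypes)
    subject_cols = [c for c in genotypes.columns if c not in ASE_COUNT_COLUMNS[:5]]
    grp_of = dict(zip(samples["subject_id"], samples["group"]))

    is_diff = rng.random(n_snps) < config.frac_differential
    beta12 = np.where(is_diff, config.beta12_true, 0.0)
    truth = pd.DataFrame(
        {
            "snp_id": genotypes["variantID"],
            "is_differential": is_diff,
            "beta12_true": beta12,
            "beta1_true": config.beta1_base,
        }
    )

    lognorm_mean = np.exp(config.sigma_b**2 / 2.0)
    gt_mat = genotypes[subject_cols].to_numpy()
    region_tables: dict[str, pd.DataFrame] = {}
    for region in config.regions:
        recs: list[dict] = []
        for j, subj in enumerate(subject_cols):
            grp = grp_of.get(subj)
            if grp is None:
                continue
            g_ind = 1.0 if grp == "AUD" else 0.0
            b = rng.normal(0.0, config.sigma_b, n_snps)
            ratio = np.exp(config.beta1_base + beta12 * g_ind)
            mu0 = config.depth_mean / ((1.0 + ratio) * lognorm_mean)
            gt_col = gt_mat[:, j]
            het = gt_col == "0/1"
            mu_ref = np.where(het, mu0, config.depth_mean / lognorm_mean)
            mu_alt = np.where(het, mu0 * ratio, config.depth_mean / lognorm_mean)
            ref = _nb_draw(rng, mu_ref * np.exp(b), config.theta)
            alt = _nb_draw(rng, mu_alt * np.exp(b), config.theta)
            ref = np.where(gt_col == "1/1", 0, ref)
            alt = np.where(gt_col == "0/0", 0, alt)
            keep = gt_col != "./."
            idx = np.nonzero(keep)[0]
            for i in idx:
                recs.append(
                    {
                        "contig": genotypes["contig"].iat[i],
                        "position": int(genotypes["position"].iat[i]),
                        "variantID": genotypes["variantID"].iat[i],
                        "refAllele": genotypes["refAllele"].iat[i],
                        "altAllele": genotypes["altAllele"].iat[i],
                        "refCount": int(ref[i]),
                        "altCount": int(alt[i]),
                        "totalCount": int(ref[i]) + int(alt[i]),
                        "sample": f"{subj}_{region}",
                    }
                )
        region_tables[region] = pd.DataFrame(
            recs, columns=ASE_COUNT_COLUMNS + ["sample"]
        )
    return region_tables, truth


def write_vcf(genotypes: pd.DataFrame, path) -> None:
    """Write the cohort genotype table as a minimal VCF v4.2 (GT only)."""
    subject_cols = [c for c in genotypes.columns if c not in ASE_COUNT_COLUMNS[:5]]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        contigs = pd.unique(genotypes["contig"])
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(subject_cols)
            + "\n"
        )
        for _, row in genotypes.iterrows():
            gts = "\t".join(str(row[s]) for s in subject_cols)
            fh.write(
                f"{row['contig']}\t{row['position']}\t{row['variantID']}\t"
                f"{row['refAllele']}\t{row['altAllele']}\t.\t.\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# reporter-assay reads


@dataclasses.dataclass
class PassportDesign:
    """Layout of the pooled reporter-assay sequencing experiment.

    The read layout (8 nt condition barcode, then a 10 nt UMI, then the
    designed insert) is a documented convention of this simulator; real
    assays vary and the pipeline takes both lengths as parameters.
    """

    cell_lines: tuple[str, ...] = ("SH-SY5Y", "SK-N-BE2")
    n_replicates: int = 6
    sources: tuple[str, ...] = ("DNA", "RNA")
    barcode_len: int = 8
    umi_len: int = 10
    mean_molecules: float = 300.0
    theta: float = 20.0
    duplication_rate: float = 0.0

    def conditions(self) -> list[tuple[str, int, str]]:
        return [
            (cl, rep, src)
            for cl in self.cell_lines
            for rep in range(1, self.n_replicates + 1)
            for src in self.sources
        ]


def _random_kmers(rng: np.random.Generator, n: int, k: int) -> list[str]:
    """Distinct random DNA k-mers (rejection sampling)."""
    out: list[str] = []
    seen: set[str] = set()
    while len(out) < n:
        s = "".join(_BASES[rng.integers(0, 4, k)])
        if s not in seen:
            seen.add(s)
            out.append(s)
    return out


def generate_passport_reads(
    library: Sequence[OligoConstruct],
    design: PassportDesign,
    planted_effects: Mapping[str, float],
    seed: int,
    fastq_path,
    error_rate: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate pooled reporter-assay reads with UMIs and PCR duplicates.

    Molecule counts per (construct, condition) are NB draws around
    ``design.mean_molecules``; for RNA libraries the alternative-allele
    construct's mean is scaled by ``exp(effect)`` where ``effect`` is the
    planted allelic-activity shift for that SNP (natural-log scale, 0 if
    absent).  Each molecule carries a random UMI and is emitted
    ``Geometric(1 - duplication_rate)`` times.  Reads are barcode + UMI +
    full insert at constant Q30 and are written in a seed-deterministic
    shuffled order.

    ``error_rate`` applies i.i.d. uniform base substitutions across each
    emitted read (default 0: error-free, making the unique-UMI round trip
    exact).  Returns ``(barcode_map, truth)`` where truth holds, per
    construct and condition, the distinct-UMI molecule count and the
    emitted read count.
    """
    if not library:
        raise ValueError("construct library is empty")
    if not 0.0 <= design.duplication_rate < 1.0:
        raise ValueError("duplication_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    conditions = design.conditions()
    barcodes = _random_kmers(rng, len(conditions), design.barcode_len)
    barcode_map = pd.DataFrame(
        [
            {"barcode": bc, "cell_line": cl, "replicate": rep, "source": src}
            for bc, (cl, rep, src) in zip(barcodes, conditions)
        ]
    )
    if barcode_map["barcode"].duplicated().any():
        raise ValueError("duplicate barcodes across conditions")

    reads: list[tuple[str, str]] = []   # (name, sequence)
    truth_rows: list[dict] = []
    for bc, (cl, rep, src) in zip(barcodes, conditions):
        for cons in library:
            eff = planted_effects.get(cons.snp_id, 0.0)
            mean = design.mean_molecules
            if src == "RNA" and cons.allele == "alt":
                mean *= float(np.exp(eff))
            n_mol = int(_nb_draw(rng, mean, design.theta))
            umis = [
                "".join(_BASES[rng.integers(0, 4, design.umi_len)])
                for _ in range(n_mol)
            ]
            n_reads = 0
            for umi in umis:
                copies = (
                    1
                    if design.duplication_rate == 0.0
                    else int(rng.geometric(1.0 - design.duplication_rate))
                )
                for _ in range(copies):
                    reads.append(
                        (
                            f"{cons.snp_id}:{cons.allele}:{cl}:{rep}:{src}:{len(reads)}",
                            bc + umi + cons.sequence,
                        )
                    )
                n_reads += copies
            truth_rows.append(
                {
                    "snp_id": cons.snp_id,
                    "allele": cons.allele,
                    "cell_line": cl,
                    "replicate": rep,
                    "source": src,
                    "n_molecules": len(set(umis)),
                    "n_reads": n_reads,
                }
            )
    order = rng.permutation(len(reads))
    with open(fastq_path, "w") as fh:
        for i in order:
            name, seq = reads[i]
            if error_rate > 0.0:
                arr = np.array(list(seq))
                hit = rng.random(arr.size) < error_rate
                if hit.any():
                    arr[hit] = _BASES[rng.integers(0, 4, int(hit.sum()))]
                    seq = "".join(arr)
            fh.write(f"@{name}\n{seq}\n+\n{'?' * len(seq)}\n")
    truth = pd.DataFrame(truth_rows)
    return barcode_map, truth


# ---------------------------------------------------------------------------
# ethanol dose response


def generate_ethanol_counts(
    doses: Sequence[float],
    n_reps: int,
    planted_dose_slope: float = 0.0,
    n_snps: int = 1,
    frac_responsive: float = 1.0,
    base_log_ratio: float = 0.0,
    sigma_rep: float = 0.1,
    theta: float = 10.0,
    depth_mean: float = 200.0,
    timepoints: Sequence[str] = ("42h",),
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate per-dose allelic counts with a planted log-ratio slope.

    For each (SNP, dose, replicate, timepoint) the two allele counts are NB
    draws with

        log mu_allele = log(depth/2) + b_rep + [alt] * (base + slope * dose)

    where ``b_rep ~ Normal(0, sigma_rep^2)`` is a per-replicate library
    intercept shared by both alleles.  A fraction ``frac_responsive`` of
    SNPs carries ``planted_dose_slope`` (per mM, natural-log scale); the
    rest have slope 0.  Returns ``(counts, truth)``.
    """
    doses = list(doses)
    if not doses:
        raise ValueError("at least one dose required")
    if n_reps < 2:
        raise ValueError("at least two replicates required")
    rng = np.random.default_rng(seed)
    responsive = rng.random(n_snps) < frac_responsive
    slopes = np.where(responsive, planted_dose_slope, 0.0)
    rows: list[dict] = []
    for i in range(n_snps):
        snp = f"rs{900000 + i}"
        for tp in timepoints:
            for rep in range(1, n_reps + 1):
                b_rep = rng.normal(0.0, sigma_rep)
                for dose in doses:
                    log_ratio = base_log_ratio + slopes[i] * dose
                    mu_ref = depth_mean / (1.0 + np.exp(log_ratio)) * np.exp(b_rep)
                    mu_alt = mu_ref * np.exp(log_ratio)
                    rows.append(
                        {
                            "snp_id": snp,
                            "dose_mM": dose,
                            "replicate": rep,
                            "timepoint": tp,
                            "refCount": int(_nb_draw(rng, mu_ref, theta)),
                            "altCount": int(_nb_draw(rng, mu_alt, theta)),
                        }
                    )
    truth = pd.DataFrame(
        {
            "snp_id": [f"rs{900000 + i}" for i in range(n_snps)],
            "is_responsive": responsive,
            "slope_true": slopes,
            "base_log_ratio": base_log_ratio,
        }
    )
    return pd.DataFrame(rows), truth
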