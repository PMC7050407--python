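"""Differential allele-specific expression between subject groups.

For each testable SNP in each brain region the two allele counts of every
heterozygous subject enter a negative-binomial GLMM,

    log(mu) = b0 + b1 * allele + b2 * group + b12 * allele*group + b_subject,

with allele coded 0 = reference / 1 = alternative, group coded 0 = control
/ 1 = AUD, and a per-subject Gaussian random intercept absorbing the
pairing of the two counts from one individual.  The interaction ``b12``
measures the change in allelic imbalance between groups; its null is no
group difference.  Because the contrast is between groups at the same
site, shared reference-mapping bias cancels and no per-allele bias
correction is applied.

The model's link is the natural log; results are additionally reported as
an "adjusted log2 fold change" ``adj_log2_fc = b12 / ln 2``, the log2 ratio
of alt:ref odds between groups, and the significance call combines an FDR
cut with an effect-size cut on that scale (a flag switches the threshold to
the raw natural-log coefficient instead).
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .counts_io import SnpDataset
from .nbglmm import NbGlmmData, bh_fdr, fit_nb_glmm, lr_test, wald_test

__all__ = [
    "AseTestResult",
    "ConsistencyReport",
    "PowerEstimate",
    "test_snp",
    "run_region",
    "classify_significant",
    "cross_region_consistency",
    "estimate_power",
    "power_grid",
]

LN2 = float(np.log(2.0))

RESULT_COLUMNS = [
    "variantID",
    "contig",
    "position",
    "region",
    "beta12",
    "adj_log2_fc",
    "p_value",
    "q_value",
    "direction",
    "n_het_aud",
    "n_het_ctl",
    "fit_status",
    "theta",
    "sigma_b",
]


@dataclasses.dataclass
class AseTestResult:
    site_id: str
    contig: str
    position: int
    region: str
    beta12: float
    adj_log2_fc: float
    p_value: float
    q_value: float
    direction: str          # "up" = higher alt fraction in AUD
    n_het_aud: int
    n_het_ctl: int
    fit_status: str
    theta: float = np.nan
    sigma_b: float = np.nan


@dataclasses.dataclass
class ConsistencyReport:
    primary_region: str
    rows: pd.DataFrame      # site, q_primary, other_region, p_other, signs, concordant
    n_overlap: int
    n_concordant: int


@dataclasses.dataclass
class PowerEstimate:
    depth: float
    n_het_per_group: int
    beta12_true: float
    alpha: float
    n_sims: int
    power: float
    mc_se: float


def build_design(dataset: SnpDataset) -> NbGlmmData:
    """Two observations per subject: (ref, X1=0) and (alt, X1=1)."""
    tab = dataset.table
    n = len(tab)
    y = np.concatenate([tab["ref_count"].to_numpy(), tab["alt_count"].to_numpy()])
    allele = np.concatenate([np.zeros(n), np.ones(n)])
    grp = (tab["group"] == "AUD").to_numpy(dtype=float)
    group = np.concatenate([grp, grp])
    subject = np.concatenate([tab["subject_id"].to_numpy()] * 2)
    X = np.column_stack([np.ones(2 * n), allele, group, allele * group])
    return NbGlmmData(
        y=y,
        X=X,
        names=("intercept", "allele", "group", "allele:group"),
        subject=subject,
    )


def test_snp(dataset: SnpDataset, test: str = "wald") -> AseTestResult:
    """Fit the per-SNP GLMM and test the allele-by-group interaction."""
    data = build_design(dataset)
    fit = fit_nb_glmm(data)
    beta12 = float(fit.coef("allele:group")) if fit.beta is not None else np.nan
    if fit.ok:
        if test == "lrt":
            w = lr_test(data, "allele:group")
        else:
            w = wald_test(fit, "allele:group")
        p = w.p_value
        beta12 = w.estimate
    else:
        p = np.nan
    return AseTestResult(
        site_id=dataset.site.snp_id,
        contig=dataset.site.chrom,
        position=dataset.site.pos,
        region=dataset.region,
        beta12=beta12,
        adj_log2_fc=beta12 / LN2,
        p_value=p,
        q_value=np.nan,
        direction="up" if beta12 > 0 else "down",
        n_het_aud=dataset.n_het_aud,
        n_het_ctl=dataset.n_het_ctl,
        fit_status=fit.status,
        theta=fit.theta,
        sigma_b=fit.sigma_b,
    )


def run_region(
    datasets: Sequence[SnpDataset], test: str = "wald"
) -> pd.DataFrame:
    """Test all SNPs of one region and BH-adjust within the region.

    Only SNPs with a usable fit enter the FDR adjustment; degenerate or
    non-converged fits keep a missing q-value.  Rows are sorted by
    (chrom, pos).
    """
    regions = {d.region for d in datasets}
    if len(regions) > 1:
        raise ValueError(f"datasets span multiple regions: {sorted(regions)}")
    results = [test_snp(d, test=test) for d in datasets]
    df = pd.DataFrame(
        [
            {
                "variantID": r.site_id,
                "contig": r.contig,
                "position": r.position,
                "region": r.region,
                "beta12": r.beta12,
                "adj_log2_fc": r.adj_log2_fc,
                "p_value": r.p_value,
                "q_value": r.q_value,
                "direction": r.direction,
                "n_het_aud": r.n_het_aud,
                "n_het_ctl": r.n_het_ctl,
                "fit_status": r.fit_status,
                "theta": r.theta,
                "sigma_b": r.sigma_b,
            }
            for r in results
        ],
        columns=RESULT_COLUMNS,
    )
    ok = df["p_value"].notna()
    if ok.any():
        df.loc[ok, "q_value"] = bh_fdr(df.loc[ok, "p_value"].to_numpy())
    key = df["contig"].str.removeprefix("chr")
    df = df.assign(
        _ck=[k.zfill(2) if k.isdigit() else k for k in key]
    ).sort_values(["_ck", "position"], kind="stable")
    return df.drop(columns="_ck").reset_index(drop=True)


def pool_fdr_across_regions(
    results_by_region: Mapping[str, pd.DataFrame],
) -> dict[str, pd.DataFrame]:
    """Recompute q-values with BH across ALL regions pooled.

    Alternative multiplicity scope to the default per-region adjustment;
    returns new result tables with the pooled q-values substituted.
    """
    frames = {r: df.copy() for r, df in results_by_region.items()}
    stacked = pd.concat(
        [df.assign(_region_key=r) for r, df in frames.items()], ignore_index=True
    )
    ok = stacked["p_value"].notna()
    stacked.loc[ok, "q_value"] = bh_fdr(stacked.loc[ok, "p_value"].to_numpy())
    out = {}
    for r in frames:
        sub = stacked[stacked["_region_key"] == r].drop(columns="_region_key")
        out[r] = sub.reset_index(drop=True)
    return out


def classify_significant(
    results: pd.DataFrame,
    fdr_cut: float = 0.05,
    min_abs_adj_l2fc: float = 1.0,
    effect_scale: str = "log2",
) -> tuple[pd.DataFrame, dict]:
    """Significant SNPs: q < fdr_cut AND |effect| > min_abs_adj_l2fc.

    The effect-size threshold applies to ``adj_log2_fc`` by default;
    ``effect_scale='natural'`` applies it to the raw coefficient instead.
    Returns the retained subset and per-direction counts.
    """
    if effect_scale not in ("log2", "natural"):
        raise ValueError("effect_scale must be 'log2' or 'natural'")
    eff = results["adj_log2_fc"] if effect_scale == "log2" else results["beta12"]
    keep = (
        results["q_value"].notna()
        & (results["q_value"] < fdr_cut)
        & (eff.abs() > min_abs_adj_l2fc)
    )
    sub = results[keep].copy()
    counts = {
        "n_significant": int(len(sub)),
        "n_up": int((sub["beta12"] > 0).sum()),
        "n_down": int((sub["beta12"] < 0).sum()),
    }
    return sub, counts


def cross_region_consistency(
    results_by_region: Mapping[str, pd.DataFrame],
    primary_region: str,
    fdr_primary: float = 0.05,
    p_secondary: float = 0.05,
) -> ConsistencyReport:
    """Replication of primary-region discoveries in the other regions.

    SNPs with q < ``fdr_primary`` in the primary region (FDR only — no
    effect-size cut) are looked up in every other region; each region
    where the SNP has p < ``p_secondary`` contributes a row, concordant
    when the interaction sign matches the primary region.  SNPs absent
    from a secondary region are skipped, not counted discordant.
    """
    if len(results_by_region) < 2:
        raise ValueError("need at least two regions")
    if primary_region not in results_by_region:
        raise ValueError(f"unknown primary region {primary_region!r}")
    prim = results_by_region[primary_region]
    hits = prim[(prim["q_value"].notna()) & (prim["q_value"] < fdr_primary)]
    rows = []
    for _, hit in hits.iterrows():
        for region, other in results_by_region.items():
            if region == primary_region:
                continue
            match = other[other["variantID"] == hit["variantID"]]
            if match.empty:
                continue
            m = match.iloc[0]
            if not (pd.notna(m["p_value"]) and m["p_value"] < p_secondary):
                continue
            rows.append(
                {
                    "variantID": hit["variantID"],
                    "q_primary": hit["q_value"],
                    "beta12_primary": hit["beta12"],
                    "other_region": region,
                    "p_other": m["p_value"],
                    "beta12_other": m["beta12"],
                    "concordant": bool(
                        np.sign(hit["beta12"]) == np.sign(m["beta12"])
                    ),
                }
            )
    rows_df = pd.DataFrame(
        rows,
        columns=[
            "variantID",
            "q_primary",
            "beta12_primary",
            "other_region",
            "p_other",
            "beta12_other",
            "concordant",
        ],
    )
    return ConsistencyReport(
        primary_region=primary_region,
        rows=rows_df,
        n_overlap=int(len(rows_df)),
        n_concordant=int(rows_df["concordant"].sum()) if len(rows_df) else 0,
    )


# ---------------------------------------------------------------------------
# power simulation


def simulate_snp_dataset(
    rng: np.random.Generator,
    n_het_per_group: int,
    depth: float,
    beta12: float,
    beta1: float = 0.0,
    theta: float = 10.0,
    sigma_b: float = 0.3,
) -> SnpDataset:
    """One synthetic testable SNP under the generative GLMM (helper shared
    by the power simulation and the calibration studies)."""
    from .counts_io import SnpSite
    from .simulate import _nb_draw

    rows = []
    lognorm = np.exp(sigma_b**2 / 2.0)
    for grp, g in (("control", 0.0), ("AUD", 1.0)):
        ratio = np.exp(beta1 + beta12 * g)
        mu0 = depth / ((1.0 + ratio) * lognorm)
        b = rng.normal(0.0, sigma_b, n_het_per_group)
        ref = _nb_draw(rng, mu0 * np.exp(b), theta)
        alt = _nb_draw(rng, mu0 * ratio * np.exp(b), theta)
        for i in range(n_het_per_group):
            rows.append(
                {
                    "subject_id": f"{grp}{i}",
                    "group": grp,
                    "ref_count": int(ref[i]),
                    "alt_count": int(alt[i]),
                }
            )
    site = SnpSite(chrom="chr1", pos=1000, ref="A", alt="G", snp_id="sim")
    return SnpDataset(site=site, region="SIM", table=pd.DataFrame(rows))


def estimate_power(
    depth: float,
    n_het_per_group: int,
    beta12_true: float,
    theta: float = 10.0,
    sigma_b: float = 0.3,
    alpha: float = 0.05,
    n_sims: int = 200,
    seed: int = 0,
) -> PowerEstimate:
    """Monte-Carlo power of the interaction test at one design point.

    Simulates ``n_sims`` SNPs under the generative model, runs the full
    per-SNP test and reports the rejection fraction at ``alpha`` with its
    binomial Monte-Carlo standard error.  Fits that fail are counted as
    non-rejections (they would not be called in practice).
    """
    if n_sims < 100:
        raise ValueError("use at least 100 simulations")
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_sims):
        ds = simulate_snp_dataset(
            rng, n_het_per_group, depth, beta12_true, theta=theta, sigma_b=sigma_b
        )
        res = test_snp(ds)
        if np.isfinite(res.p_value) and res.p_value < alpha:
            rejections += 1
    power = rejections / n_sims
    return PowerEstimate(
        depth=depth,
        n_het_per_group=n_het_per_group,
        beta12_true=beta12_true,
        alpha=alpha,
        n_sims=n_sims,
        power=power,
        mc_se=float(np.sqrt(power * (1 - power) / n_sims)),
    )


def power_grid(
    depths: Sequence[float],
    n_hets: Sequence[int],
    beta12_true: float,
    theta: float = 10.0,
    sigma_b: float = 0.3,
    alpha: float = 0.05,
    n_sims: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Power over a read-depth by sample-size grid."""
    rows = []
    for i, depth in enumerate(depths):
        for j, n in enumerate(n_hets):
            est = estimate_power(
                depth,
                n,
                beta12_true,
                theta=theta,
                sigma_b=sigma_b,
                alpha=alpha,
                n_sims=n_sims,
                seed=seed + 1000 * i + j,
            )
            rows.append(dataclasses.asdict(est))
    return pd.DataFrame(rows)
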