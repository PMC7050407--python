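"""Dose-responsive allelic imbalance under ethanol exposure.

Cells carrying heterozygous SNPs are exposed to increasing ethanol doses
(physiological range, 0/10/20 mM by default) and RNA-sequenced; a SNP is
dose-responsive when its allelic ratio changes systematically with dose.
The model is a negative-binomial GLMM on the two allele counts per
(replicate, dose) library,

    log(mu) = b0 + b1 * [alt] + g * dose + d * [alt] * dose + b_replicate,

with dose continuous in mM and a per-replicate random intercept for
library depth.  The allele-by-dose coefficient ``d`` is the per-mM change
in log(alt/ref); a Wald test on ``d`` scores dose response (a
categorical-dose likelihood-ratio mode is available).  The exact model
behind the original screen is not published; this parameterisation is this
package's stated reconstruction.

Entry filters: mean total reads per library strictly above ``min_avg_depth``
(default 15) and a pooled minor-allele fraction of at least
``min_minor_frac`` (default 10%) in the treated or the untreated pool.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd

from .nbglmm import NbGlmmData, fit_nb_glmm, lr_test, wald_test

__all__ = [
    "DoseTestResult",
    "filter_dose_snps",
    "test_dose_response",
    "run_dose_screen",
    "compare_directions",
]


@dataclasses.dataclass
class DoseTestResult:
    snp_id: str
    dose_slope: float       # per-mM change of log(alt/ref)
    p_value: float
    passed_filters: bool
    fit_status: str = "converged"


def filter_dose_snps(
    records: pd.DataFrame,
    min_avg_depth: float = 15.0,
    min_minor_frac: float = 0.10,
) -> tuple[set[str], pd.DataFrame]:
    """Select testable SNPs and account for every exclusion.

    A SNP passes when (a) its mean total count per library is strictly
    greater than ``min_avg_depth`` and (b) pooling reads within the
    treated (dose > 0) or the untreated (dose == 0) libraries, the minor
    allele carries at least ``min_minor_frac`` of the reads in at least
    one pool.  Returns (passing snp_ids, audit table).
    """
    audit = []
    passing: set[str] = set()
    for snp, sub in records.groupby("snp_id"):
        totals = sub["refCount"] + sub["altCount"]
        avg_depth = float(totals.mean())
        if not avg_depth > min_avg_depth:
            audit.append(
                {"snp_id": snp, "reason": f"avg_depth_{avg_depth:g}_le_{min_avg_depth:g}"}
            )
            continue
        ok = False
        for treated in (False, True):
            pool = sub[(sub["dose_mM"] > 0) == treated]
            if pool.empty:
                continue
            ref, alt = pool["refCount"].sum(), pool["altCount"].sum()
            tot = ref + alt
            if tot == 0:
                continue
            minor = min(ref, alt) / tot
            if minor >= min_minor_frac:
                ok = True
        if not ok:
            audit.append({"snp_id": snp, "reason": "minor_fraction_below_threshold"})
            continue
        passing.add(str(snp))
    return passing, pd.DataFrame(audit, columns=["snp_id", "reason"])


def _dose_design(sub: pd.DataFrame, timepoint_covariate: bool) -> NbGlmmData:
    n = len(sub)
    y = np.concatenate([sub["refCount"].to_numpy(), sub["altCount"].to_numpy()]).astype(
        float
    )
    allele = np.concatenate([np.zeros(n), np.ones(n)])
    dose = np.tile(sub["dose_mM"].to_numpy(dtype=float), 2)
    # replicate libraries are distinct per (replicate, dose, timepoint)
    lib = np.tile(
        (
            sub["replicate"].astype(str)
            + ":"
            + sub["dose_mM"].astype(str)
            + ":"
            + sub.get("timepoint", pd.Series(["-"] * n, index=sub.index)).astype(str)
        ).to_numpy(),
        2,
    )
    cols = [np.ones(2 * n), allele, dose, allele * dose]
    names = ["intercept", "allele", "dose", "allele:dose"]
    if timepoint_covariate and "timepoint" in sub.columns:
        tps = sorted(sub["timepoint"].unique())
        for tp in tps[1:]:
            cols.append(np.tile((sub["timepoint"] == tp).to_numpy(float), 2))
            names.append(f"timepoint[{tp}]")
    X = np.column_stack(cols)
    return NbGlmmData(y=y, X=X, names=tuple(names), subject=lib)


def test_dose_response(
    records: pd.DataFrame,
    snp_id: str,
    test: str = "wald",
    timepoint_covariate: bool = False,
) -> DoseTestResult:
    """NB-GLMM test of the allele-by-dose interaction for one SNP.

    ``test='lrt'`` switches to a likelihood-ratio test of the interaction;
    timepoints are pooled unless ``timepoint_covariate`` adds them as
    fixed effects.
    """
    sub = records[records["snp_id"] == snp_id]
    if sub["dose_mM"].nunique() < 2:
        raise ValueError(f"{snp_id}: at least two doses required")
    data = _dose_design(sub, timepoint_covariate)
    fit = fit_nb_glmm(data)
    if not fit.ok:
        return DoseTestResult(
            snp_id=snp_id,
            dose_slope=np.nan,
            p_value=np.nan,
            passed_filters=True,
            fit_status=fit.status,
        )
    if test == "lrt":
        w = lr_test(data, "allele:dose")
    else:
        w = wald_test(fit, "allele:dose")
    return DoseTestResult(
        snp_id=snp_id,
        dose_slope=w.estimate,
        p_value=w.p_value,
        passed_filters=True,
        fit_status=fit.status,
    )


def run_dose_screen(
    records: pd.DataFrame,
    min_avg_depth: float = 15.0,
    min_minor_frac: float = 0.10,
    test: str = "wald",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Filter then test every SNP; returns (results, filter audit).

    SNPs failing the filters appear with ``passed_filters=False`` and no
    p-value.
    """
    passing, audit = filter_dose_snps(records, min_avg_depth, min_minor_frac)
    rows = []
    for snp in sorted(records["snp_id"].unique()):
        if snp in passing:
            res = test_dose_response(records, snp, test=test)
        else:
            res = DoseTestResult(
                snp_id=snp,
                dose_slope=np.nan,
                p_value=np.nan,
                passed_filters=False,
                fit_status="filtered",
            )
        rows.append(dataclasses.asdict(res))
    return pd.DataFrame(rows), audit


def compare_directions(
    brain: Mapping[str, float],
    passport: Mapping[str, float],
    dose: Mapping[str, float],
) -> pd.DataFrame:
    """Per-SNP sign comparison across the three analyses.

    Inputs map snp_id to the signed effect in each analysis (brain
    interaction, reporter-assay interaction, dose slope); missing entries
    yield 'n/a'.  ``opposite_flag`` is defined only when both the brain
    and dose signs exist and marks ethanol effects running against the
    brain direction.
    """
    def sgn(v):
        if v is None or (isinstance(v, float) and not np.isfinite(v)):
            return "n/a"
        return "+" if v > 0 else ("-" if v < 0 else "n/a")

    snps = sorted(set(brain) | set(passport) | set(dose))
    rows = []
    for snp in snps:
        sb = sgn(brain.get(snp))
        sp = sgn(passport.get(snp))
        sd = sgn(dose.get(snp))
        opposite = (sb != sd) if (sb != "n/a" and sd != "n/a") else None
        rows.append(
            {
                "snp_id": snp,
                "sign_brain": sb,
                "sign_passport": sp,
                "sign_ethanol": sd,
                "opposite_flag": opposite,
            }
        )
    return pd.DataFrame(rows)
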