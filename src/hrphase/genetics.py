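"""Genotype screening and genotype-phase association.

Variants are screened on allele frequency computed over the full
genotyped table: the reference (non-effect) allele is the most frequent
allele, the alternate (effect) allele the second most frequent, and
variants with alternate allele frequency below 1% are excluded.
Genotypes are coded additively as the number of alternate-allele
copies; participants carrying any allele other than the top two are
excluded from that variant's analysis.  Phase is regressed on dosage
plus age, Y-chromosome presence and five ancestry principal components
by OLS with heteroskedasticity-consistent (sandwich) standard errors,
and p-values are Bonferroni-adjusted over the number of variants
tested.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .results import AssociationResult

__all__ = [
    "compute_allele_frequencies",
    "code_additive",
    "associate_snv_phase",
    "run_snv_scan",
]

COVARIATES = ["age", "y_chromosome", "pc1", "pc2", "pc3", "pc4", "pc5"]


def compute_allele_frequencies(genotypes: pd.DataFrame,
                               min_alt_af: float = 0.01) -> pd.DataFrame:
    """Per-SNV allele counts, top-two alleles and the AF exclusion flag.

    Parameters
    ----------
    genotypes : long-format table with columns participant_id, snv_id,
        allele1, allele2 (each diploid call contributes two alleles).
    min_alt_af : variants with alternate AF strictly below this are
        flagged ``excluded``.

    Returns
    -------
    One row per snv_id: ref_allele, alt_allele (None if monomorphic),
    ref_af, alt_af, n_participants, allele_counts (dict), excluded.
    """
    rows = []
    for snv_id, grp in genotypes.groupby("snv_id", sort=True):
        alleles = pd.concat([grp["allele1"], grp["allele2"]], ignore_index=True)
        counts = alleles.value_counts()
        total = int(counts.sum())
        ref = counts.index[0]
        if len(counts) > 1:
            alt = counts.index[1]
            alt_af = counts.iloc[1] / total
        else:
            alt, alt_af = None, 0.0
        rows.append({
            "snv_id": snv_id,
            "ref_allele": ref,
            "alt_allele": alt,
            "ref_af": counts.iloc[0] / total,
            "alt_af": float(alt_af),
            "n_participants": int(len(grp)),
            "allele_counts": counts.to_dict(),
            "excluded": bool(alt_af < min_alt_af),
        })
    return pd.DataFrame(rows)


def code_additive(genotypes: pd.DataFrame, snv_row: pd.Series) -> pd.Series:
    """Additive dosage (# alternate alleles) for one SNV.

    Participants whose call includes any allele other than the SNV's
    ref/alt pair get NaN (excluded from that SNV's analysis).

    Parameters
    ----------
    genotypes : long-format table restricted or not to the SNV; rows
        for other SNVs are ignored.
    snv_row : a row of :func:`compute_allele_frequencies` output.
    """
    if snv_row.get("excluded", False):
        raise ValueError(f"SNV {snv_row['snv_id']} is AF-excluded")
    grp = genotypes[genotypes["snv_id"] == snv_row["snv_id"]]
    ref, alt = snv_row["ref_allele"], snv_row["alt_allele"]
    a1, a2 = grp["allele1"], grp["allele2"]
    valid = a1.isin([ref, alt]) & a2.isin([ref, alt])
    dosage = (a1 == alt).astype(float) + (a2 == alt).astype(float)
    dosage[~valid] = np.nan
    dosage.index = grp["participant_id"].to_numpy()
    return dosage


def associate_snv_phase(cohort: pd.DataFrame, dosage: pd.Series, snv_id: str,
                        m_tests: int = 1, cov_type: str = "HC1") -> AssociationResult:
    """OLS of phase (hours) on dosage + age + Y + PC1-5, robust SEs.

    The effect is reported in minutes of phase per alternate allele
    (coefficient x 60); the p-value is two-sided from the robust z
    statistic and Bonferroni-adjusted by ``m_tests``.
    """
    df = cohort.set_index("participant_id") if "participant_id" in cohort.columns else cohort
    df = df.join(dosage.rename("dosage"), how="inner").dropna(subset=["dosage", "phi"])
    n = len(df)
    if df["dosage"].nunique() < 2:
        return AssociationResult(snv_id, np.nan, np.nan, np.nan, np.nan, n,
                                 converged=False, flag="constant_dosage")
    X = sm.add_constant(df[["dosage"] + COVARIATES].astype(float))
    try:
        fit = sm.OLS(df["phi"].astype(float), X).fit(cov_type=cov_type)
    except np.linalg.LinAlgError:
        return AssociationResult(snv_id, np.nan, np.nan, np.nan, np.nan, n,
                                 converged=False, flag="singular")
    beta_h = fit.params["dosage"]
    se_h = fit.bse["dosage"]
    p = float(fit.pvalues["dosage"])
    ci = fit.conf_int().loc["dosage"]
    return AssociationResult(
        target=snv_id, beta=float(beta_h * 60.0), se=float(se_h * 60.0), p=p,
        p_adjusted=min(1.0, p * m_tests), n=n,
        ci_low=float(ci[0] * 60.0), ci_high=float(ci[1] * 60.0))


def run_snv_scan(cohort: pd.DataFrame, genotypes: pd.DataFrame,
                 min_alt_af: float = 0.01, cov_type: str = "HC1") -> pd.DataFrame:
    """Screen all SNVs and associate each passing variant with phase.

    Bonferroni m = number of variants surviving the AF filter, taken
    from the actual run.
    """
    snv_table = compute_allele_frequencies(genotypes, min_alt_af=min_alt_af)
    tested = snv_table[~snv_table["excluded"]]
    m = len(tested)
    rows = []
    for _, snv_row in tested.iterrows():
        dosage = code_additive(genotypes, snv_row)
        res = associate_snv_phase(cohort, dosage, snv_row["snv_id"],
                                  m_tests=m, cov_type=cov_type)
        rows.append({
            "snv_id": res.target, "beta_min": res.beta, "se_min": res.se,
            "p": res.p, "p_adj": res.p_adjusted, "n": res.n,
            "alt_af": snv_row["alt_af"], "converged": res.converged,
            "flag": res.flag,
        })
    return pd.DataFrame(rows)
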