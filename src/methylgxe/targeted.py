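"""Focused single-locus analyses.

* ANOVA of promoter-cluster methylation across the three genotypes of a
  cis-SNP (additive trend expected: TT > CT > CC or the reverse).
* Enzyme-activity model: activity ~ promoter M-value + coding genotype + sex.
* Array-vs-pyrosequencing validation: per-probe Pearson correlation.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import MethylationDataset, beta_to_m

GENOTYPE_ORDER = ("CC", "CT", "TT")


def snp_cluster_anova(
    ds: MethylationDataset,
    cluster_probes: Sequence[str],
    genotype_column: str = "pon1_108_genotype",
) -> pd.DataFrame:
    """Per-probe one-way ANOVA of beta values across SNP genotype groups.

    The genotype is treated categorically (three groups); the trend column
    is the sign of mean(TT) - mean(CC).  Genotype groups with no samples
    are excluded and flagged; fewer than two populated groups is an error.
    """
    geno = ds.samples[genotype_column].astype(str)
    present = [g for g in GENOTYPE_ORDER if (geno == g).sum() > 0]
    if len(present) < 2:
        raise ValueError("need at least 2 genotype groups with samples")
    usable = [g for g in present if (geno == g).sum() >= 2]
    rows = []
    for probe in cluster_probes:
        beta = ds.beta.loc[probe]
        groups = {g: beta[geno[geno == g].index].to_numpy() for g in usable}
        f, p = stats.f_oneway(*groups.values())
        if np.isnan(f):  # identical values in every group
            f, p = 0.0, 1.0
        means = {f"mean_{g}": (float(np.mean(groups[g])) if g in groups else np.nan)
                 for g in GENOTYPE_ORDER}
        if "CC" in groups and "TT" in groups:
            trend = float(np.sign(np.mean(groups["TT"]) - np.mean(groups["CC"])))
        else:
            trend = np.nan
        rows.append(
            {"probe": probe, **means, "F": float(f), "p": float(p),
             "trend": trend,
             "excluded_groups": ";".join(g for g in GENOTYPE_ORDER if g not in usable)}
        )
    return pd.DataFrame(rows).set_index("probe")


def activity_model(
    activity: pd.Series,
    m_values: pd.Series,
    genotype: pd.Series,
    sex: pd.Series,
) -> dict:
    """OLS: activity ~ M + genotype + sex, on complete cases.

    Returns the methylation slope and p (the quantity of interest), the
    genotype coefficient and p, the sex coefficient, and a collinearity
    flag when |corr(M, genotype)| > 0.99.
    """
    data = pd.DataFrame(
        {
            "activity": pd.to_numeric(activity),
            "m": pd.to_numeric(m_values),
            "genotype": pd.to_numeric(genotype),
            "sex": pd.to_numeric(sex),
        }
    ).dropna()
    if len(data) < 10:
        raise ValueError(f"fewer than 10 complete cases ({len(data)})")
    flag = ""
    if data["genotype"].var() > 0 and abs(data["m"].corr(data["genotype"])) > 0.99:
        flag = "collinear_m_genotype"
    X = np.column_stack(
        [np.ones(len(data)), data["m"], data["genotype"], data["sex"]]
    )
    y = data["activity"].to_numpy()
    XtX_inv = np.linalg.pinv(X.T @ X)
    beta = XtX_inv @ X.T @ y
    resid = y - X @ beta
    df = len(data) - X.shape[1]
    s2 = float(resid @ resid) / df
    se = np.sqrt(s2 * np.diag(XtX_inv))
    t = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    p = 2 * stats.t.sf(np.abs(t), df)
    return {
        "m_slope": float(beta[1]), "m_p": float(p[1]),
        "genotype_coef": float(beta[2]), "genotype_p": float(p[2]),
        "sex_coef": float(beta[3]),
        "n": int(len(data)), "flag": flag,
    }


def pyro_validation(
    array_beta: pd.DataFrame,
    pyro_percent: pd.DataFrame,
) -> pd.DataFrame:
    """Per-probe Pearson correlation of array betas against pyrosequencing
    percentages (converted to fractions).  Rows: probes; columns must be
    paired samples.  Zero-variance probes are flagged, not tested."""
    common_p = array_beta.index.intersection(pyro_percent.index)
    common_s = array_beta.columns.intersection(pyro_percent.columns)
    if len(common_s) < 3:
        raise ValueError("need at least 3 paired samples")
    pv = pyro_percent.loc[common_p, common_s].astype(float)
    if (pv.values < 0).any() or (pv.values > 100).any():
        raise ValueError("pyro percentages must lie in [0, 100]")
    av = array_beta.loc[common_p, common_s].astype(float)
    rows = []
    for probe in common_p:
        x = av.loc[probe].to_numpy()
        y = (pv.loc[probe] / 100.0).to_numpy()
        if np.var(x) == 0 or np.var(y) == 0:
            rows.append({"probe": probe, "r": np.nan, "p": np.nan,
                         "n": len(x), "flag": "zero_variance"})
            continue
        r, p = stats.pearsonr(x, y)
        rows.append({"probe": probe, "r": float(r), "p": float(p),
                     "n": len(x), "flag": ""})
    return pd.DataFrame(rows).set_index("probe")
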