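"""Per-probe dual-model differential methylation analysis on M-values.

Two ordinary least-squares models are fit per probe, sex-adjusted:

* Model A (interaction): ``M ~ exposure + carrier + exposure:carrier + sex``.
  A probe is significant when the interaction p-value is <= 0.1 and the
  exposure effect *within carriers* (the linear contrast of the exposure and
  interaction coefficients, tested with the full-model residual variance)
  has p <= 0.001.
* Model B (no interaction): ``M ~ exposure + carrier + sex`` with exposure
  p <= 0.001 and genotype p <= 0.1.

Both models additionally require the extreme-group filter: the
exposed-carrier cell must have strictly the highest (hyper) or lowest
(hypo) mean methylation of the four design cells, on the beta scale.
Raw-p thresholds are used; no multiplicity correction is applied at this
stage (optional BH/Bonferroni columns are available downstream).
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GROUPS, MethylationDataset

DEFAULT_THRESHOLDS = {
    "p_interaction": 0.1,
    "p_exposure_in_carriers": 0.001,
    "p_exposure_main": 0.001,
    "p_genotype_main": 0.1,
}


def _design_matrices(samples: pd.DataFrame):
    exp = samples["exposure"].to_numpy(dtype=float)
    car = samples["carrier"].to_numpy(dtype=float)
    sex = samples["sex"].to_numpy(dtype=float)
    ones = np.ones_like(exp)
    Xa = np.column_stack([ones, exp, car, exp * car, sex])
    Xb = np.column_stack([ones, exp, car, sex])
    return Xa, Xb


def _ols_all_probes(M: np.ndarray, X: np.ndarray):
    """Vectorised OLS of every probe (rows of M) on a shared design X.

    Returns (coefs p x k, se p x k, sigma2 p, XtX_inv k x k, df).
    """
    n, k = X.shape
    XtX_inv = np.linalg.inv(X.T @ X)
    proj = XtX_inv @ X.T  # k x n
    B = M @ proj.T  # probes x k
    resid = M - B @ X.T
    df = n - k
    sigma2 = (resid**2).sum(axis=1) / df
    se = np.sqrt(np.outer(sigma2, np.diag(XtX_inv)))
    return B, se, sigma2, XtX_inv, df


def _t_p(t: np.ndarray, df: int) -> np.ndarray:
    return 2.0 * stats.t.sf(np.abs(t), df)


def run_dmp_scan(
    ds: MethylationDataset,
    thresholds: Optional[dict] = None,
    stratified_carrier_test: bool = False,
) -> tuple:
    """Scan every retained probe with both models.

    Parameters
    ----------
    stratified_carrier_test
        If True, the exposure-in-carriers p-value is taken from a separate
        regression ``M ~ exposure + sex`` on carrier samples only, instead
        of the full-model linear contrast (the default).

    Returns
    -------
    (results DataFrame indexed by probe, summary dict)
    """
    thr = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        thr.update(thresholds)

    samples = ds.samples
    labels = ds.group_labels()
    cell_counts = labels.value_counts()
    for g in GROUPS:
        if cell_counts.get(g, 0) < 2:
            raise ValueError(f"design cell {g} has fewer than 2 samples")

    M = ds.m.to_numpy()
    Xa, Xb = _design_matrices(samples)
    if np.linalg.matrix_rank(Xa) < Xa.shape[1]:
        raise ValueError("singular interaction design (check sex/exposure coding)")

    variant = M.var(axis=1) > 0
    flagged = pd.Series("", index=ds.beta.index, dtype=object)
    flagged[~variant] = "invariant_probe"

    Mv = M[variant]
    Ba, se_a, s2a, XtXa, dfa = _ols_all_probes(Mv, Xa)
    Bb, se_b, s2b, XtXb, dfb = _ols_all_probes(Mv, Xb)

    p_int = _t_p(Ba[:, 3] / se_a[:, 3], dfa)
    # exposure effect within carriers: contrast c = e_exposure + e_interaction
    c = np.zeros(Xa.shape[1])
    c[1] = 1.0
    c[3] = 1.0
    c_var = float(c @ XtXa @ c)
    contrast = Ba[:, 1] + Ba[:, 3]
    se_contrast = np.sqrt(s2a * c_var)
    p_exp_car = _t_p(contrast / se_contrast, dfa)

    if stratified_carrier_test:
        carrier_mask = samples["carrier"].to_numpy(dtype=bool)
        Ms = Mv[:, carrier_mask]
        Xs = np.column_stack(
            [
                np.ones(carrier_mask.sum()),
                samples.loc[carrier_mask, "exposure"].to_numpy(dtype=float),
                samples.loc[carrier_mask, "sex"].to_numpy(dtype=float),
            ]
        )
        Bs, se_s, _, _, dfs = _ols_all_probes(Ms, Xs)
        p_exp_car = _t_p(Bs[:, 1] / se_s[:, 1], dfs)

    p_exp_main = _t_p(Bb[:, 1] / se_b[:, 1], dfb)
    p_geno_main = _t_p(Bb[:, 2] / se_b[:, 2], dfb)

    means = ds.group_mean_beta()
    mean_ec = means["exposed_carrier"].to_numpy()
    others = means[[g for g in GROUPS if g != "exposed_carrier"]].to_numpy()
    is_max = mean_ec > others.max(axis=1)  # strict: ties fail the filter
    is_min = mean_ec < others.min(axis=1)
    extreme = is_max | is_min
    direction = np.where(is_max, "hyper", np.where(is_min, "hypo", "none"))

    res = pd.DataFrame(index=ds.beta.index)
    for col in (
        "p_interaction",
        "p_exposure_in_carriers",
        "p_exposure_main",
        "p_genotype_main",
    ):
        res[col] = np.nan
    res.loc[variant, "p_interaction"] = p_int
    res.loc[variant, "p_exposure_in_carriers"] = p_exp_car
    res.loc[variant, "p_exposure_main"] = p_exp_main
    res.loc[variant, "p_genotype_main"] = p_geno_main
    for g in GROUPS:
        res[f"mean_{g}"] = means[g]
    res["extreme_flag"] = extreme
    res["direction"] = direction
    res["sig_model_A"] = (
        variant
        & (res["p_interaction"] <= thr["p_interaction"])
        & (res["p_exposure_in_carriers"] <= thr["p_exposure_in_carriers"])
        & extreme
    )
    res["sig_model_B"] = (
        variant
        & (res["p_exposure_main"] <= thr["p_exposure_main"])
        & (res["p_genotype_main"] <= thr["p_genotype_main"])
        & extreme
    )
    res["flag"] = flagged
    res.loc[~variant, "direction"] = "none"

    summary = summarize_dmp(res)
    return res, summary


def summarize_dmp(res: pd.DataFrame) -> dict:
    """Book-keeping counts for a DMP result table."""
    a = res[res["sig_model_A"]]
    b = res[res["sig_model_B"]]
    return {
        "n_probes": int(len(res)),
        "n_sig_model_A": int(len(a)),
        "n_sig_model_B": int(len(b)),
        "n_hyper_model_A": int((a["direction"] == "hyper").sum()),
        "n_hypo_model_A": int((a["direction"] == "hypo").sum()),
        "n_hyper_model_B": int((b["direction"] == "hyper").sum()),
        "n_hypo_model_B": int((b["direction"] == "hypo").sum()),
        "n_flagged": int((res["flag"] != "").sum()),
    }


def total_from_direction_counts(n_hyper: int, n_hypo: int) -> int:
    """Total significant count from its hyper/hypo split."""
    return int(n_hyper) + int(n_hypo)
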