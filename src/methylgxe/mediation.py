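"""Baron-Kenny four-model mediation with nonparametric bootstrap ACME.

The causal chain tested is exposure -> methylation mark (M-value) ->
outcome.  Four OLS fits establish the classical criteria:

1. outcome ~ exposure            (total effect)
2. mark    ~ exposure            (path a)
3. outcome ~ mark                (marginal b)
4. outcome ~ exposure + mark     (direct effect c' and conditional b)

All models optionally adjust for sex (on for leptin and body-fat outcomes,
off for BMI-Z-based outcomes, which are already sex-standardized).
Partial mediation requires models 1-3 significant, the mark significant in
model 4, and |c'| < |total effect|; full mediation additionally requires
the model-4 exposure coefficient to be non-significant.  The average causal
mediation effect (ACME) is the a*b product, with a case-resampling
bootstrap percentile interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import MethylationDataset, beta_to_m

OUTCOME_SEX_ADJUST = {
    "leptin_ln": True,
    "bodyfat": True,
    "bmi_z": False,
    "delta_bmi_z": False,
}


@dataclass
class MediationResult:
    mark: str
    outcome: str
    model1: tuple  # (exposure coef, p)
    model2: tuple
    model3: tuple
    model4_exposure: tuple
    model4_mark: tuple
    classification: str  # none | partial | full
    acme: float = np.nan
    acme_ci: tuple = (np.nan, np.nan)
    acme_p: float = np.nan
    n_boot: int = 0
    seed: Optional[int] = None
    n: int = 0
    flag: str = ""

    def to_dict(self) -> dict:
        return {
            "mark": self.mark,
            "outcome": self.outcome,
            "m1_coef": self.model1[0], "m1_p": self.model1[1],
            "m2_coef": self.model2[0], "m2_p": self.model2[1],
            "m3_coef": self.model3[0], "m3_p": self.model3[1],
            "m4_exposure_coef": self.model4_exposure[0],
            "m4_exposure_p": self.model4_exposure[1],
            "m4_mark_coef": self.model4_mark[0], "m4_mark_p": self.model4_mark[1],
            "classification": self.classification,
            "acme": self.acme,
            "acme_ci_lo": self.acme_ci[0], "acme_ci_hi": self.acme_ci[1],
            "acme_p": self.acme_p, "n_boot": self.n_boot, "n": self.n,
            "flag": self.flag,
        }


def ln_transform(values: pd.Series) -> pd.Series:
    """Natural log with a guard against non-positive concentrations."""
    v = pd.to_numeric(values)
    if (v <= 0).any():
        raise ValueError("cannot ln-transform non-positive values")
    return np.log(v)


def _ols_coef_p(y: np.ndarray, cols: list) -> list:
    """OLS of y on [1, cols...]; returns [(coef, p), ...] for each column."""
    X = np.column_stack([np.ones(len(y))] + cols)
    XtX_inv = np.linalg.pinv(X.T @ X)
    beta = XtX_inv @ X.T @ y
    resid = y - X @ beta
    df = len(y) - X.shape[1]
    if df <= 0:
        raise ValueError("too few cases for the model")
    s2 = float(resid @ resid) / df
    se = np.sqrt(s2 * np.diag(XtX_inv))
    out = []
    for j in range(1, X.shape[1]):
        if se[j] == 0:
            out.append((float(beta[j]), 1.0))
        else:
            t = beta[j] / se[j]
            out.append((float(beta[j]), float(2 * stats.t.sf(abs(t), df))))
    return out


def baron_kenny(
    mark_m: pd.Series,
    outcome: pd.Series,
    exposure: pd.Series,
    sex: Optional[pd.Series] = None,
    adjust_sex: bool = True,
    alpha: float = 0.05,
    mark_id: str = "",
    outcome_name: str = "",
) -> MediationResult:
    """Run the four-model procedure on complete cases."""
    data = pd.DataFrame(
        {"mark": mark_m, "outcome": outcome, "exposure": exposure}
    )
    if adjust_sex:
        if sex is None:
            raise ValueError("adjust_sex=True requires a sex covariate")
        data["sex"] = sex
    data = data.dropna()
    if len(data) < 10:
        raise ValueError(f"fewer than 10 complete cases ({len(data)})")
    res = MediationResult(
        mark=mark_id, outcome=outcome_name,
        model1=(np.nan, np.nan), model2=(np.nan, np.nan),
        model3=(np.nan, np.nan), model4_exposure=(np.nan, np.nan),
        model4_mark=(np.nan, np.nan), classification="none", n=len(data),
    )
    if data["mark"].var() == 0 or data["outcome"].var() == 0:
        res.flag = "zero_variance"
        return res
    y = data["outcome"].to_numpy(dtype=float)
    mk = data["mark"].to_numpy(dtype=float)
    ex = data["exposure"].to_numpy(dtype=float)
    extra = [data["sex"].to_numpy(dtype=float)] if adjust_sex else []

    res.model1 = _ols_coef_p(y, [ex] + extra)[0]
    res.model2 = _ols_coef_p(mk, [ex] + extra)[0]
    res.model3 = _ols_coef_p(y, [mk] + extra)[0]
    m4 = _ols_coef_p(y, [ex, mk] + extra)
    res.model4_exposure, res.model4_mark = m4[0], m4[1]

    steps = (
        res.model1[1] <= alpha
        and res.model2[1] <= alpha
        and res.model3[1] <= alpha
        and res.model4_mark[1] <= alpha
        and abs(res.model4_exposure[0]) < abs(res.model1[0])
    )
    if steps:
        res.classification = (
            "full" if res.model4_exposure[1] > alpha else "partial"
        )
    return res


def bootstrap_acme(
    mark_m: pd.Series,
    outcome: pd.Series,
    exposure: pd.Series,
    sex: Optional[pd.Series] = None,
    adjust_sex: bool = True,
    n_boot: int = 1000,
    seed: int = 0,
    max_retries: int = 100,
) -> tuple:
    """Case-resampling bootstrap of the indirect effect a*b.

    Returns (acme_point, (ci_lo, ci_hi), p, n_boot).  The point estimate is
    the a*b product from the original data (model 2 a, model 4 conditional
    b); the two-sided p is 2*min(frac<=0, frac>=0), floored at 2/n_boot.
    """
    if n_boot < 200:
        raise ValueError("n_boot must be at least 200")
    data = pd.DataFrame({"mark": mark_m, "outcome": outcome, "exposure": exposure})
    if adjust_sex:
        if sex is None:
            raise ValueError("adjust_sex=True requires a sex covariate")
        data["sex"] = sex
    data = data.dropna()
    n = len(data)
    y = data["outcome"].to_numpy(dtype=float)
    mk = data["mark"].to_numpy(dtype=float)
    ex = data["exposure"].to_numpy(dtype=float)
    sx = data["sex"].to_numpy(dtype=float) if adjust_sex else None

    def ab(idx) -> float:
        e, m_, y_ = ex[idx], mk[idx], y[idx]
        cols2 = [e] + ([sx[idx]] if adjust_sex else [])
        a = _ols_coef_p(m_, cols2)[0][0]
        cols4 = [e, m_] + ([sx[idx]] if adjust_sex else [])
        b = _ols_coef_p(y_, cols4)[1][0]
        return a * b

    point = ab(np.arange(n))
    rng = np.random.default_rng(seed)
    draws = np.empty(n_boot)
    for i in range(n_boot):
        for _ in range(max_retries):
            idx = rng.integers(0, n, size=n)
            if len(np.unique(ex[idx])) > 1 and np.var(mk[idx]) > 0:
                break
        else:
            raise RuntimeError("could not draw a non-degenerate bootstrap resample")
        draws[i] = ab(idx)
    ci = (float(np.percentile(draws, 2.5)), float(np.percentile(draws, 97.5)))
    frac_le = float(np.mean(draws <= 0))
    frac_ge = float(np.mean(draws >= 0))
    p = max(2.0 * min(frac_le, frac_ge), 2.0 / n_boot)
    return float(point), ci, float(min(p, 1.0)), n_boot


def mediation_screen(
    ds: MethylationDataset,
    candidate_marks: Sequence[str],
    outcomes: Sequence[str] = ("leptin_ln", "delta_bmi_z", "bodyfat", "bmi_z"),
    scope: str = "carriers",
    alpha: float = 0.05,
    n_boot: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Four-model screen of every (mark, outcome) pair.

    ``candidate_marks`` must already be restricted to the DMP-and-DMR
    overlap; marks absent from the dataset raise.  By default the screen
    runs on R-allele carrier samples only (the gene-environment framing:
    exposure effects within carriers); ``scope="all"`` uses every sample.
    Set ``n_boot`` > 0 to attach bootstrap ACME intervals.
    """
    candidate_marks = list(candidate_marks)
    if not candidate_marks:
        raise ValueError("no candidate marks supplied")
    missing = set(candidate_marks) - set(ds.beta.index)
    if missing:
        raise KeyError(f"marks not in dataset: {sorted(missing)[:3]}")
    if scope == "carriers":
        use = ds.samples.index[ds.samples["carrier"] == 1]
    elif scope == "all":
        use = ds.samples.index
    else:
        raise ValueError("scope must be 'carriers' or 'all'")
    sub = ds.samples.loc[use]
    m_all = beta_to_m(ds.beta.loc[candidate_marks, use])

    rows = []
    for k, mark in enumerate(candidate_marks):
        for outcome in outcomes:
            adjust_sex = OUTCOME_SEX_ADJUST.get(outcome, True)
            res = baron_kenny(
                m_all.loc[mark],
                pd.to_numeric(sub[outcome]),
                sub["exposure"],
                sex=sub["sex"],
                adjust_sex=adjust_sex,
                alpha=alpha,
                mark_id=mark,
                outcome_name=outcome,
            )
            if n_boot and res.classification != "none":
                acme, ci, p, nb = bootstrap_acme(
                    m_all.loc[mark], pd.to_numeric(sub[outcome]), sub["exposure"],
                    sex=sub["sex"], adjust_sex=adjust_sex,
                    n_boot=n_boot, seed=seed + k,
                )
                res.acme, res.acme_ci, res.acme_p, res.n_boot = acme, ci, p, nb
                res.seed = seed + k
            rows.append(res.to_dict())
    return pd.DataFrame(rows)


def summarize_mediation(screen: pd.DataFrame) -> dict:
    """Per-outcome counts of marks classified partial-or-full."""
    out = {}
    for outcome, sub in screen.groupby("outcome"):
        out[outcome] = int(sub["classification"].isin(["partial", "full"]).sum())
    return out
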