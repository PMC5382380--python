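"""Reference-based leukocyte deconvolution (Houseman-style constrained
projection) and association checks of the estimated proportions.

Signature probes are chosen in two passes: the ``n_variable`` most variable
probes in the mixture data, then the ``n_top`` probes whose reference
methylomes differ most between the six cell types.  Per-sample proportions
solve min ||beta_sample - R w||^2 subject to w >= 0, sum w = 1, via NNLS
with a heavily weighted sum-to-one row.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import nnls

from .datatypes import CELL_TYPES, CellProportions, MethylationDataset

#: weight of the sum-to-one constraint row in the augmented NNLS system
SUM_WEIGHT = 1e3


def select_signature_probes(
    ds: MethylationDataset,
    reference: pd.DataFrame,
    n_variable: int = 100_000,
    n_top: int = 500,
) -> list:
    """Pick the deconvolution signature.

    Candidates are the ``n_variable`` most variable probes (variance of beta
    across the mixture samples); among those, the ``n_top`` probes with the
    largest between-cell-type dispersion of reference betas are returned.
    Both counts are capped at the available probe number.
    """
    common = ds.beta.index.intersection(reference.index)
    frac_missing = 1.0 - len(common) / ds.n_probes
    if frac_missing > 0.05:
        raise ValueError(
            f"reference is missing {frac_missing:.1%} of dataset probes (> 5%)"
        )
    n_variable = min(n_variable, len(common))
    n_top = min(n_top, n_variable)
    if n_top <= 0:
        raise ValueError("n_top must be positive")
    variance = ds.beta.loc[common].var(axis=1)
    candidates = variance.sort_values(ascending=False).index[:n_variable]
    # between-type dispersion of the reference profiles (the F-statistic
    # numerator; the reference carries one methylome per type)
    disp = reference.loc[candidates].var(axis=1)
    return list(disp.sort_values(ascending=False).index[:n_top])


def estimate_proportions(
    ds: MethylationDataset,
    reference: pd.DataFrame,
    signature: Sequence[str],
) -> CellProportions:
    """Constrained projection of each sample onto the reference methylomes."""
    signature = list(signature)
    if not signature:
        raise ValueError("signature probe list is empty")
    R = reference.loc[signature].to_numpy(dtype=float)
    types = list(reference.columns)
    rank = np.linalg.matrix_rank(R)
    if rank < R.shape[1]:
        corr = np.corrcoef(R.T)
        pairs = [
            (types[i], types[j])
            for i in range(len(types))
            for j in range(i + 1, len(types))
            if abs(corr[i, j]) > 0.999999
        ]
        raise ValueError(
            f"reference is rank-deficient on the signature probes; "
            f"collinear cell types: {pairs or 'unidentified'}"
        )
    A = np.vstack([R, SUM_WEIGHT * np.ones((1, R.shape[1]))])
    weights = np.zeros((ds.n_samples, R.shape[1]))
    resid = np.zeros(ds.n_samples)
    Y = ds.beta.loc[signature].to_numpy(dtype=float)
    for i in range(ds.n_samples):
        b = np.concatenate([Y[:, i], [SUM_WEIGHT]])
        w, _ = nnls(A, b)
        total = w.sum()
        if total <= 0:
            raise RuntimeError("degenerate NNLS solution (all-zero weights)")
        w = w / total
        weights[i] = w
        resid[i] = float(np.linalg.norm(Y[:, i] - R @ w))
    wdf = pd.DataFrame(weights, index=ds.beta.columns, columns=types)
    return CellProportions(
        weights=wdf, residual_norm=pd.Series(resid, index=ds.beta.columns)
    )


def proportion_associations(
    props: CellProportions,
    samples: pd.DataFrame,
    outcomes: Sequence[str] = ("bodyfat", "delta_bmi_z", "bmi_z", "leptin", "age"),
) -> pd.DataFrame:
    """ANOVA of proportions vs exposure/genotype plus simple regressions
    against numeric outcomes.  Constant proportion vectors are flagged and
    skipped."""
    rows = []
    for ct in props.weights.columns:
        w = props.weights[ct]
        if np.isclose(w.var(), 0.0):
            rows.append(
                {"cell_type": ct, "test": "skipped_constant", "term": "",
                 "estimate": np.nan, "p": np.nan}
            )
            continue
        for factor in ("exposure", "carrier"):
            levels = pd.unique(samples[factor])
            groups = [w[samples[factor] == lv].to_numpy() for lv in levels]
            if any(len(g) == 0 for g in groups):
                raise ValueError(f"empty {factor} group in ANOVA")
            f, p = stats.f_oneway(*groups)
            rows.append(
                {"cell_type": ct, "test": "anova", "term": factor,
                 "estimate": float(f), "p": float(p)}
            )
        for out in outcomes:
            y = pd.to_numeric(samples[out])
            res = stats.linregress(w.to_numpy(), y.to_numpy())
            rows.append(
                {"cell_type": ct, "test": "linregress", "term": out,
                 "estimate": float(res.slope), "p": float(res.pvalue)}
            )
    return pd.DataFrame(rows)
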