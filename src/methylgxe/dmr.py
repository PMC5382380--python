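"""Kernel-smoothing DMR caller for exposed-carrier contrasts.

The statistical skeleton: per-CpG pooled-variance two-sample t statistics on
M-values (exposed carriers against one of the other three design cells) are
squared and Gaussian-kernel smoothed along each chromosome (bandwidth
sigma = lambda_bp / C, truncated at lambda_bp).  The smoothed score is
referred to a scaled chi-square whose scale and degrees of freedom are
moment-matched (Satterthwaite), p-values are BH-adjusted genome-wide, and
runs of adjacent significant CpGs (gap <= lambda_bp, >= min_cpgs members)
become candidate regions.  A region is reported only when the
exposed-carrier group shows strictly the highest or lowest region-mean
methylation of the four design cells.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import GROUPS, MethylationDataset

CONTRAST_GROUPS = ("exposed_QQ", "unexposed_carrier", "unexposed_QQ")


def per_cpg_contrast_stats(ds: MethylationDataset, contrast: str) -> pd.DataFrame:
    """Pooled-variance two-sample t per probe: exposed_carrier vs `contrast`.

    Probes with zero pooled variance get t = 0 and are flagged.
    """
    if contrast not in CONTRAST_GROUPS:
        raise ValueError(f"contrast must be one of {CONTRAST_GROUPS}")
    labels = ds.group_labels()
    g1 = labels.index[labels == "exposed_carrier"]
    g2 = labels.index[labels == contrast]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("both contrast groups need at least 2 samples")
    M = ds.m
    X1, X2 = M[g1].to_numpy(), M[g2].to_numpy()
    n1, n2 = X1.shape[1], X2.shape[1]
    m1, m2 = X1.mean(axis=1), X2.mean(axis=1)
    v1 = X1.var(axis=1, ddof=1)
    v2 = X2.var(axis=1, ddof=1)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    denom = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    zero = denom == 0
    t = np.zeros_like(m1)
    t[~zero] = (m1 - m2)[~zero] / denom[~zero]
    out = pd.DataFrame(
        {
            "chromosome": ds.manifest["chromosome"],
            "position": ds.manifest["position"],
            "t": t,
            "df": df,
            "zero_variance": zero,
        },
        index=ds.beta.index,
    )
    return out


def smooth_and_score(
    stats_df: pd.DataFrame, lambda_bp: float = 1000.0, C: float = 2.0
) -> pd.DataFrame:
    """Gaussian-smoothed t^2 with moment-matched scaled-chi-square p-values.

    Per probe, the kernel-weighted mean of squared t among probes within
    lambda_bp on the same chromosome; an isolated probe's score is its own
    t^2.  Under the null each t^2 is F(1, df)-distributed; the weighted
    mean's first two moments are matched to g * chi2_k, giving
    p = chi2.sf(score / g, k).  BH adjustment is applied over all probes.
    """
    sigma = lambda_bp / C
    df = int(stats_df["df"].iloc[0])
    if df <= 4:
        raise ValueError("contrast degrees of freedom must exceed 4")
    e = df / (df - 2.0)
    v = 2.0 * df**2 * (df - 1.0) / ((df - 2.0) ** 2 * (df - 4.0))

    scores = np.empty(len(stats_df))
    sum_a2 = np.empty(len(stats_df))
    order_index = []
    for chrom, sub in stats_df.groupby("chromosome", sort=False):
        pos = sub["position"].to_numpy(dtype=float)
        if np.any(np.diff(pos) < 0):
            raise ValueError(f"positions not sorted within {chrom}")
        t2 = sub["t"].to_numpy() ** 2
        lo = np.searchsorted(pos, pos - lambda_bp, side="left")
        hi = np.searchsorted(pos, pos + lambda_bp, side="right")
        width = hi - lo
        K = int(width.max())
        n = len(pos)
        idx = lo[:, None] + np.arange(K)[None, :]
        valid = idx < hi[:, None]
        idx = np.clip(idx, 0, n - 1)
        d = pos[idx] - pos[:, None]
        w = np.exp(-0.5 * (d / sigma) ** 2)
        w[~valid] = 0.0
        wsum = w.sum(axis=1)
        a = w / wsum[:, None]
        s = (a * t2[idx]).sum(axis=1)
        scores[len(order_index) : len(order_index) + n] = s
        sum_a2[len(order_index) : len(order_index) + n] = (a**2).sum(axis=1)
        order_index.extend(sub.index)

    var_s = v * sum_a2
    g = var_s / (2.0 * e)
    k = 2.0 * e**2 / var_s
    p = stats.chi2.sf(scores / g, k)
    out = stats_df.loc[order_index].copy()
    out["score"] = scores
    out["p"] = p
    out["p_adj"] = multipletests(p, method="fdr_bh")[1]
    return out.loc[stats_df.index]


def call_regions(
    scored: pd.DataFrame,
    ds: MethylationDataset,
    contrast: str,
    lambda_bp: float = 1000.0,
    min_cpgs: int = 2,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Group adjacent significant CpGs into directional regions."""
    sig = scored[scored["p_adj"] < alpha]
    means = ds.group_mean_beta()
    rows = []
    for chrom, sub in sig.groupby("chromosome", sort=False):
        sub = sub.sort_values("position")
        pos = sub["position"].to_numpy()
        breaks = np.where(np.diff(pos) > lambda_bp)[0]
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [len(pos) - 1]])
        for s, eidx in zip(starts, ends):
            members = sub.index[s : eidx + 1]
            if len(members) < min_cpgs:
                continue
            gm = means.loc[members].mean(axis=0)
            ec = gm["exposed_carrier"]
            others = gm[[g for g in GROUPS if g != "exposed_carrier"]]
            if ec > others.max():
                direction = "hyper"
            elif ec < others.min():
                direction = "hypo"
            else:
                continue  # exposed carriers not extreme: not a sig-DMR
            genes = sorted(
                {
                    g
                    for raw in ds.manifest.loc[members, "gene"]
                    for g in str(raw).split(";")
                    if g
                }
            )
            rows.append(
                {
                    "chromosome": chrom,
                    "start": int(pos[s]),
                    "end": int(pos[eidx]),
                    "n_cpgs": int(len(members)),
                    "contrast": contrast,
                    "p_adj": float(sub.loc[members, "p_adj"].min()),
                    **{f"mean_{g}": float(gm[g]) for g in GROUPS},
                    "direction": direction,
                    "genes": ";".join(genes),
                    "probes": ";".join(members),
                }
            )
    cols = (
        ["chromosome", "start", "end", "n_cpgs", "contrast", "p_adj"]
        + [f"mean_{g}" for g in GROUPS]
        + ["direction", "genes", "probes"]
    )
    return pd.DataFrame(rows, columns=cols)


def run_dmr_scan(
    ds: MethylationDataset,
    lambda_bp: float = 1000.0,
    C: float = 2.0,
    min_cpgs: int = 2,
    alpha: float = 0.05,
    contrasts: Sequence[str] = CONTRAST_GROUPS,
) -> pd.DataFrame:
    """Scan all three contrasts; the union of regions is reported with
    per-contrast provenance (a region qualifies via any one contrast)."""
    frames = []
    for contrast in contrasts:
        st = per_cpg_contrast_stats(ds, contrast)
        scored = smooth_and_score(st, lambda_bp=lambda_bp, C=C)
        frames.append(
            call_regions(
                scored, ds, contrast, lambda_bp=lambda_bp,
                min_cpgs=min_cpgs, alpha=alpha,
            )
        )
    non_empty = [f for f in frames if len(f)]
    if not non_empty:
        return frames[0]
    out = pd.concat(non_empty, ignore_index=True)
    return out.sort_values(["chromosome", "start", "contrast"]).reset_index(drop=True)


def summarize_dmr(regions: pd.DataFrame) -> dict:
    return {
        "n_regions": int(len(regions)),
        "n_hyper": int((regions["direction"] == "hyper").sum()),
        "n_hypo": int((regions["direction"] == "hypo").sum()),
    }


def dmr_to_bed(regions: pd.DataFrame) -> pd.DataFrame:
    """BED (0-based, half-open) view: name=gene|direction,
    score = -10*log10(p_adj) capped at 1000."""
    score = np.minimum(
        1000.0, -10.0 * np.log10(np.maximum(regions["p_adj"].to_numpy(), 1e-300))
    )
    return pd.DataFrame(
        {
            "chrom": regions["chromosome"],
            "chromStart": regions["start"] - 1,
            "chromEnd": regions["end"],
            "name": regions["genes"].str.replace(";", ",") + "|" + regions["direction"],
            "score": np.round(score, 1),
        }
    )
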