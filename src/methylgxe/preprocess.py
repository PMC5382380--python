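"""Probe filtering, beta/M transforms, batch diagnostics and adjustment.

The filtering order follows standard 450K practice: before normalization,
probes with a SNP within 3 bp of the interrogated CpG, probes failing an
iterative greedy detection-p prune, and probes with missing values are
removed; after normalization, non-CpG (ch/rs) probes and sex-chromosome
probes are removed.  Within-array normalization itself is a documented
pass-through (or rank-based quantile option): the bespoke content of this
pipeline lies downstream of it.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .datatypes import (
    BatchDiagnostics,
    FilterReport,
    MethylationDataset,
    beta_to_m,
    m_to_beta,
)

# chromosome aliases treated as sex chromosomes (case-insensitive)
SEX_CHROM_ALIASES = {"x", "chrx", "23", "y", "chry", "24"}


def _is_sex_chromosome(chrom: pd.Series) -> pd.Series:
    return chrom.astype(str).str.lower().isin(SEX_CHROM_ALIASES)


def greedycut(detection_p: pd.DataFrame, threshold: float = 0.01):
    """Iterative greedy pruning of unreliable probes/samples.

    At each step the probe *or* sample with the highest fraction of
    detection-p failures (> threshold) is removed, until no entry fails.
    Ties are broken probe-before-sample, then by lexical id.

    Returns (removed_probe_ids, removed_sample_ids).
    """
    fail = (detection_p > threshold).astype(float)
    removed_probes: list = []
    removed_samples: list = []
    while fail.size and fail.values.any():
        probe_frac = fail.mean(axis=1)
        sample_frac = fail.mean(axis=0)
        best_probe = probe_frac.sort_index().idxmax()  # lexical tie-break
        best_sample = sample_frac.sort_index().idxmax()
        if probe_frac[best_probe] >= sample_frac[best_sample]:
            removed_probes.append(best_probe)
            fail = fail.drop(index=best_probe)
        else:
            removed_samples.append(best_sample)
            fail = fail.drop(columns=best_sample)
    return removed_probes, removed_samples


def filter_probes_pre_norm(
    ds: MethylationDataset, detection_threshold: float = 0.01
) -> tuple:
    """Pre-normalization filters: SNP-adjacent probes, greedycut, missing values.

    Each removed probe is reported with a single reason, priority
    snp_within_3bp > greedycut > missing_value.
    """
    report = FilterReport()
    snp_ids = ds.manifest.index[ds.manifest["snp_within_3bp"].astype(bool)]
    for p in snp_ids:
        report.removed[p] = "snp_within_3bp"

    if ds.detection_p is not None:
        gc_probes, gc_samples = greedycut(ds.detection_p, detection_threshold)
        for p in gc_probes:
            report.removed.setdefault(p, "greedycut")
        report.removed_samples = list(gc_samples)

    missing = ds.beta.index[ds.beta.isna().any(axis=1)]
    for p in missing:
        report.removed.setdefault(p, "missing_value")

    out = ds.drop_probes(list(report.removed))
    if report.removed_samples:
        keep = out.beta.columns.difference(report.removed_samples)
        out = out.subset_samples(out.beta.columns[out.beta.columns.isin(keep)])
    if out.n_probes == 0:
        raise ValueError("all probes removed by pre-normalization filtering")
    report.n_retained = out.n_probes
    return out, report


def filter_probes_post_norm(ds: MethylationDataset) -> tuple:
    """Post-normalization filters: non-CpG probes and sex-chromosome probes."""
    report = FilterReport()
    non_cpg = ds.manifest.index[ds.manifest["probe_class"].astype(str) != "cg"]
    for p in non_cpg:
        report.removed[p] = "non_cpg"
    sex = ds.manifest.index[_is_sex_chromosome(ds.manifest["chromosome"])]
    for p in sex:
        report.removed.setdefault(p, "sex_chromosome")
    out = ds.drop_probes(list(report.removed))
    report.n_retained = out.n_probes
    return out, report


def normalize_beta(ds: MethylationDataset, method: str = "none") -> MethylationDataset:
    """Within-array normalization.

    ``none``
        Pass-through (default).
    ``quantile``
        Rank-based quantile normalization across samples: every sample's
        betas are mapped onto the mean sorted profile.
    """
    if method == "none":
        return ds
    if method != "quantile":
        raise ValueError(f"unknown normalization method {method!r}")
    vals = ds.beta.to_numpy()
    order = np.argsort(vals, axis=0)
    ranks = np.empty_like(order)
    rows = np.arange(vals.shape[0])
    for j in range(vals.shape[1]):
        ranks[order[:, j], j] = rows
    target = np.sort(vals, axis=0).mean(axis=1)
    out = target[ranks]
    beta = pd.DataFrame(out, index=ds.beta.index, columns=ds.beta.columns)
    return MethylationDataset(
        beta=beta,
        manifest=ds.manifest.copy(),
        samples=ds.samples.copy(),
        detection_p=None if ds.detection_p is None else ds.detection_p.copy(),
    )


def run_preprocess(
    ds: MethylationDataset,
    detection_threshold: float = 0.01,
    normalization: str = "none",
) -> tuple:
    """Convenience wrapper: pre-filter -> normalize -> post-filter.

    Returns (dataset, pre_report, post_report).
    """
    out, pre = filter_probes_pre_norm(ds, detection_threshold)
    out = normalize_beta(out, normalization)
    out, post = filter_probes_post_norm(out)
    return out, pre, post


# ---------------------------------------------------------------------------
# batch diagnostics and adjustment
# ---------------------------------------------------------------------------

def batch_diagnostics(
    ds: MethylationDataset, covariates: Sequence[str], n_pcs: int = 8
) -> BatchDiagnostics:
    """PCA of M-values plus per-PC covariate association tests.

    For each of the first eight PCs and each covariate, a Kruskal-Wallis
    p-value (> 2 covariate levels) or two-sided Wilcoxon rank-sum p-value
    (2 levels) is reported.  Single-level covariates are flagged and not
    tested.
    """
    if ds.n_samples < 3:
        raise ValueError("batch diagnostics need at least 3 samples")
    for c in covariates:
        if c not in ds.samples.columns:
            raise KeyError(f"covariate {c!r} not in sample sheet")
    M = ds.m.to_numpy().T  # samples x probes
    k = min(n_pcs, ds.n_samples - 1, M.shape[1])
    pca = PCA(n_components=k, svd_solver="randomized", random_state=0)
    scores = pca.fit_transform(M - M.mean(axis=0))
    pc_scores = pd.DataFrame(
        scores, index=ds.samples.index, columns=[f"PC{i + 1}" for i in range(k)]
    )
    rows = []
    skipped = []
    for cov in covariates:
        vals = ds.samples[cov]
        levels = pd.unique(vals.dropna())
        if len(levels) < 2:
            skipped.append(cov)
            warnings.warn(f"covariate {cov!r} has a single level; no test run")
            continue
        for pc in pc_scores.columns:
            groups = [
                pc_scores.loc[vals == lv, pc].to_numpy() for lv in levels
            ]
            if len(levels) == 2:
                stat, p = stats.ranksums(groups[0], groups[1])
                test = "wilcoxon_ranksum"
            else:
                stat, p = stats.kruskal(*groups)
                test = "kruskal_wallis"
            rows.append({"pc": pc, "covariate": cov, "test": test, "p": float(p)})
    return BatchDiagnostics(
        pc_scores=pc_scores,
        association_p=pd.DataFrame(rows, columns=["pc", "covariate", "test", "p"]),
        rank_limited=k < n_pcs,
        skipped=skipped,
    )


def adjust_batch(
    ds: MethylationDataset,
    batch: str = "batch",
    protect: Sequence[str] = ("exposure", "carrier", "sex"),
) -> MethylationDataset:
    """Location-only batch adjustment on the M scale.

    Per probe, the batch-level mean of the residuals (after projecting out
    the protected covariates) is estimated and subtracted.  Whether to
    correct is decided from the data, mirroring the diagnose-then-correct
    workflow: when the across-probe mean squared batch deviation clearly
    exceeds its sampling variance (ratio > 2), batch means of the residuals
    are equalized exactly; otherwise the deviations are attributed to
    sampling noise and shrunk toward zero with the moment-based factor
    ``tau2 / (tau2 + s2/n_b)``, making the adjustment a near no-op on
    batch-effect-free data.  Protected-covariate effects are untouched in
    expectation.
    """
    b = ds.samples[batch].astype(str)
    levels = pd.unique(b)
    if len(levels) < 2:
        raise ValueError("adjust_batch needs at least 2 batch levels")
    counts = b.value_counts()
    if (counts < 2).any():
        small = list(counts.index[counts < 2])
        raise ValueError(f"batch level(s) {small} have fewer than 2 samples")
    for cov in protect:
        tab = pd.crosstab(b, ds.samples[cov])
        if ((tab > 0).sum(axis=1) == 1).all() and ((tab > 0).sum(axis=0) == 1).all():
            raise ValueError(
                f"batch {batch!r} is confounded 1:1 with protected covariate {cov!r}"
            )

    M = ds.m.to_numpy()  # probes x samples
    X = np.column_stack(
        [np.ones(ds.n_samples)]
        + [pd.to_numeric(ds.samples[c]).to_numpy(dtype=float) for c in protect]
    )
    # hat matrix of the protected design, shared across probes
    pinv = np.linalg.pinv(X)
    fitted = (M @ pinv.T) @ X.T
    resid = M - fitted
    adj = M.copy()
    for lv in levels:
        cols = np.where(b.to_numpy() == lv)[0]
        n_b = len(cols)
        delta = resid[:, cols].mean(axis=1)  # estimated batch deviation
        samp_var = resid[:, cols].var(axis=1, ddof=1) / n_b
        evidence = float(np.mean(delta**2)) / max(float(np.mean(samp_var)), 1e-12)
        if evidence > 2.0:  # clear batch effect: equalize exactly
            shrink = np.ones_like(delta)
        else:
            tau2 = max(0.0, float(np.mean(delta**2 - samp_var)))
            shrink = tau2 / (tau2 + np.maximum(samp_var, 1e-12))
        adj[:, cols] -= (shrink * delta)[:, None]
    beta = m_to_beta(pd.DataFrame(adj, index=ds.beta.index, columns=ds.beta.columns))
    return MethylationDataset(
        beta=beta,
        manifest=ds.manifest.copy(),
        samples=ds.samples.copy(),
        detection_p=None if ds.detection_p is None else ds.detection_p.copy(),
    )
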