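"""Core containers shared by every stage of the pipeline.

The central object is :class:`MethylationDataset`, which bundles the beta
matrix (probes x samples), the probe manifest, the sample sheet and an
optional detection-p matrix.  Betas are the primary stored scale; M-values
(log2 odds) are derived on demand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

#: Clamp applied before the logit transform so M-values stay finite.
EPS = 1e-6

#: Canonical order of the four exposure x PON1-192 genotype design cells.
GROUPS = ("unexposed_QQ", "exposed_QQ", "unexposed_carrier", "exposed_carrier")

#: The six leukocyte types of the reference-based deconvolution.
CELL_TYPES = ("granulocyte", "CD4T", "CD8T", "B", "monocyte", "NK")


def beta_to_m(beta):
    """M = log2(beta / (1 - beta)), with betas clamped to [EPS, 1-EPS].

    Accepts scalars, arrays or DataFrames.  Values outside [0, 1] are an
    error: they cannot be methylation fractions.
    """
    arr = np.asarray(beta, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("beta values must lie in [0, 1]")
    clamped = np.clip(arr, EPS, 1.0 - EPS)
    m = np.log2(clamped / (1.0 - clamped))
    if isinstance(beta, pd.DataFrame):
        return pd.DataFrame(m, index=beta.index, columns=beta.columns)
    if isinstance(beta, pd.Series):
        return pd.Series(m, index=beta.index, name=beta.name)
    if np.isscalar(beta):
        return float(m)
    return m


def m_to_beta(m):
    """Inverse of :func:`beta_to_m`: beta = 2^M / (1 + 2^M)."""
    arr = np.asarray(m, dtype=float)
    beta = 1.0 / (1.0 + np.exp2(-arr))
    if isinstance(m, pd.DataFrame):
        return pd.DataFrame(beta, index=m.index, columns=m.columns)
    if isinstance(m, pd.Series):
        return pd.Series(beta, index=m.index, name=m.name)
    if np.isscalar(m):
        return float(beta)
    return beta


@dataclass
class MethylationDataset:
    """Beta matrix + manifest + sample sheet (+ optional detection p).

    Parameters
    ----------
    beta : DataFrame, probes x samples, values in (0, 1)
    manifest : DataFrame indexed by probe id with columns
        ``chromosome, position, probe_class, snp_within_3bp, gene,
        gene_element, cpg_context, chromatin_state, tfbs``
    samples : DataFrame indexed by sample id; must carry the design
        covariates (``exposure``, ``carrier``, ``sex``) plus whatever
        outcomes downstream stages need.
    detection_p : optional DataFrame aligned with ``beta``.
    """

    beta: pd.DataFrame
    manifest: pd.DataFrame
    samples: pd.DataFrame
    detection_p: Optional[pd.DataFrame] = None

    def __post_init__(self):
        if self.beta.index.has_duplicates:
            raise ValueError("duplicate probe ids in beta matrix")
        if self.beta.columns.has_duplicates:
            raise ValueError("duplicate sample ids in beta matrix")
        missing = self.beta.index.difference(self.manifest.index)
        if len(missing):
            raise ValueError(
                f"manifest does not cover {len(missing)} probes "
                f"(e.g. {list(missing[:3])})"
            )
        missing_s = self.beta.columns.difference(self.samples.index)
        if len(missing_s):
            raise ValueError(f"sample sheet does not cover {list(missing_s[:3])}")
        # keep manifest/samples aligned with the matrix
        self.manifest = self.manifest.loc[self.beta.index]
        self.samples = self.samples.loc[self.beta.columns]
        if self.detection_p is not None:
            self.detection_p = self.detection_p.loc[self.beta.index, self.beta.columns]

    @property
    def m(self) -> pd.DataFrame:
        """M-value matrix derived from beta (not cached)."""
        return beta_to_m(self.beta)

    @property
    def n_probes(self) -> int:
        return self.beta.shape[0]

    @property
    def n_samples(self) -> int:
        return self.beta.shape[1]

    def group_labels(self) -> pd.Series:
        """Map each sample to one of the four design-cell labels."""
        exp = self.samples["exposure"].astype(int)
        car = self.samples["carrier"].astype(int)
        idx = exp + 2 * car  # 0=unexp QQ, 1=exp QQ, 2=unexp carrier, 3=exp carrier
        return pd.Series([GROUPS[i] for i in idx], index=self.samples.index, name="group")

    def group_mean_beta(self) -> pd.DataFrame:
        """Per-probe mean beta within each of the four design cells."""
        labels = self.group_labels()
        out = {}
        for g in GROUPS:
            cols = labels.index[labels == g]
            out[g] = self.beta[cols].mean(axis=1)
        return pd.DataFrame(out)

    def subset_probes(self, probe_ids) -> "MethylationDataset":
        keep = self.beta.index.intersection(pd.Index(probe_ids))
        det = self.detection_p.loc[keep] if self.detection_p is not None else None
        return MethylationDataset(
            beta=self.beta.loc[keep],
            manifest=self.manifest.loc[keep],
            samples=self.samples.copy(),
            detection_p=det,
        )

    def drop_probes(self, probe_ids) -> "MethylationDataset":
        keep = self.beta.index.difference(pd.Index(probe_ids))
        # preserve original ordering
        keep = self.beta.index[self.beta.index.isin(keep)]
        return self.subset_probes(keep)

    def subset_samples(self, sample_ids) -> "MethylationDataset":
        keep = self.beta.columns.intersection(pd.Index(sample_ids))
        det = self.detection_p[keep] if self.detection_p is not None else None
        return MethylationDataset(
            beta=self.beta[keep],
            manifest=self.manifest.copy(),
            samples=self.samples.loc[keep],
            detection_p=det,
        )


@dataclass
class FilterReport:
    """Book-keeping for a probe-filtering pass."""

    removed: dict = field(default_factory=dict)  # probe id -> reason
    removed_samples: list = field(default_factory=list)
    n_retained: int = 0

    def counts(self) -> dict:
        out: dict = {}
        for reason in self.removed.values():
            out[reason] = out.get(reason, 0) + 1
        return out

    @property
    def n_removed(self) -> int:
        return len(self.removed)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"probe": list(self.removed), "reason": list(self.removed.values())}
        ).set_index("probe")


@dataclass
class BatchDiagnostics:
    """First-eight-PC scores and their covariate association tests."""

    pc_scores: pd.DataFrame  # samples x <=8
    association_p: pd.DataFrame  # columns: pc, covariate, test, p
    rank_limited: bool = False
    skipped: list = field(default_factory=list)  # single-level covariates


@dataclass
class CellProportions:
    """Per-sample simplex weights over the six leukocyte types."""

    weights: pd.DataFrame  # samples x CELL_TYPES
    residual_norm: pd.Series

    def __post_init__(self):
        sums = self.weights.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("cell proportions must sum to 1 per sample")
        if (self.weights.values < -1e-9).any():
            raise ValueError("cell proportions must be non-negative")
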