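"""DMP/DMR integration and Fisher-exact enrichment analyses.

``overlap_dmps_dmrs`` intersects significant single-CpG hits with the
significant regions into a high-confidence gene list.  The enrichment
routines share one 2x2-table engine: counts of hits in/out of a category
against the analyzed background, a two-sided Fisher exact p (the
sum-of-tables-with-probability-<=-observed convention), and the requested
multiplicity adjustment.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import MethylationDataset


def overlap_percentage(n_overlap: int, n_total: int) -> float:
    """100 * count / total, rounded to one decimal (the reporting convention)."""
    if n_total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * n_overlap / n_total, 1)


def overlap_dmps_dmrs(
    dmp_ids: Sequence[str],
    regions: pd.DataFrame,
    manifest: pd.DataFrame,
) -> dict:
    """Which significant DMPs fall inside any significant region.

    A DMP overlaps when its position lies within the region's closed
    interval [start, end] on the same chromosome.  Returns a dict with the
    overlapping ids, the rounded percentage, and the high-confidence gene
    list (unique non-empty gene symbols of the overlapping DMPs,
    multi-gene annotations split on ';').
    """
    dmp_ids = list(dmp_ids)
    overlapping = []
    by_chrom = {c: sub for c, sub in regions.groupby("chromosome")} if len(regions) else {}
    for pid in dmp_ids:
        chrom = manifest.at[pid, "chromosome"]
        pos = manifest.at[pid, "position"]
        sub = by_chrom.get(chrom)
        if sub is None:
            continue
        if ((sub["start"] <= pos) & (pos <= sub["end"])).any():
            overlapping.append(pid)
    genes = sorted(
        {
            g
            for pid in overlapping
            for g in str(manifest.at[pid, "gene"]).split(";")
            if g
        }
    )
    pct = overlap_percentage(len(overlapping), len(dmp_ids)) if dmp_ids else 0.0
    return {
        "overlapping_dmps": overlapping,
        "n_overlap": len(overlapping),
        "n_dmps": len(dmp_ids),
        "percentage": pct,
        "genes": genes,
    }


def _fisher_row(a: int, b: int, c: int, d: int) -> dict:
    """Fisher test of hits (a in / b out of category) vs the rest of the
    background (c - a in / d - b out).  The reported c, d stay the full
    background counts (hits included), the comparison convention of the
    enrichment plots; the test itself needs the disjoint table."""
    rest_in, rest_out = c - a, d - b
    num, den = a * rest_out, b * rest_in
    odds = np.inf if (den == 0 and num > 0) else (0.0 if num == 0 else num / den)
    # scipy's two-sided Fisher exact: sum of tables with probability <= observed
    _, p = sps.fisher_exact([[a, b], [rest_in, rest_out]], alternative="two-sided")
    return {"a": a, "b": b, "c": c, "d": d, "odds_ratio": float(odds), "p": float(p)}


def _enrichment_table(
    hit_mask: pd.Series,
    category_masks: dict,
    adjust: str = "none",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One Fisher test per category.

    a = hits in category, b = hits outside; the reported c/d are the
    background totals in/out of the category (hits included)."""
    n_hits = int(hit_mask.sum())
    n_bg = int(len(hit_mask))
    rows = []
    for label, mask in category_masks.items():
        a = int((hit_mask & mask).sum())
        b = n_hits - a
        c = int(mask.sum())
        d = n_bg - c
        row = _fisher_row(a, b, c, d)
        row["category"] = label
        row["zero_cell"] = a == 0 or b == 0 or c == 0 or d == 0
        rows.append(row)
    out = pd.DataFrame(rows)
    m = len(out)
    if adjust == "bonferroni":
        out["p_adj"] = np.minimum(1.0, out["p"] * m)
    elif adjust == "bh":
        from statsmodels.stats.multitest import multipletests

        out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    elif adjust == "none":
        out["p_adj"] = out["p"]
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    out["adjust"] = adjust
    expected = out["a"] / np.maximum(out["b"] + out["a"], 1)  # hit fraction in cat
    bg_frac = out["c"] / n_bg
    sig = out["p_adj"] < alpha
    out["call"] = np.where(
        ~sig, "ns", np.where(out["a"] / max(n_hits, 1) > bg_frac, "enriched", "depleted")
    )
    cols = ["category", "a", "b", "c", "d", "odds_ratio", "p", "p_adj",
            "adjust", "call", "zero_cell"]
    return out[cols]


def annotation_enrichment(
    dmp_ids: Sequence[str],
    background_ids: Sequence[str],
    manifest: pd.DataFrame,
    category_column: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fisher enrichment of DMPs over the levels of one manifest column
    (gene element, CpG context or chromatin state); no multiplicity
    adjustment by default, matching the p<0.05 convention for these plots."""
    bg = pd.Index(background_ids)
    if not pd.Index(dmp_ids).isin(bg).all():
        raise ValueError("background must contain every DMP")
    col = manifest.loc[bg, category_column].astype(str)
    hit = pd.Series(bg.isin(pd.Index(dmp_ids)), index=bg)
    masks = {}
    for level in sorted(col.unique()):
        mask = col == level
        masks[level] = mask
    return _enrichment_table(hit, masks, adjust="none", alpha=alpha)


def tfbs_enrichment(
    dmp_ids: Sequence[str],
    background_ids: Sequence[str],
    manifest: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-TFBS Fisher tests with Bonferroni adjustment across the TFBS
    tested.  The universe is the analyzed (post-filter) probe set."""
    bg = pd.Index(background_ids)
    hit = pd.Series(bg.isin(pd.Index(dmp_ids)), index=bg)
    memberships = manifest.loc[bg, "tfbs"].astype(str)
    split = memberships.str.split(";")
    labels = sorted({t for row in split for t in row if t})
    masks = {}
    for tf in labels:
        masks[tf] = split.apply(lambda row, tf=tf: tf in row)
    return _enrichment_table(hit, masks, adjust="bonferroni", alpha=alpha)


def bonferroni(p: float, m: int) -> float:
    """min(1, m * p)."""
    return min(1.0, m * p)


def gene_set_enrichment(
    gene_list: Sequence[str],
    gene_sets: dict,
    universe: Sequence[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fisher test of a gene list against each gene set, ranked by -log10 p."""
    uni = pd.Index(pd.unique(pd.Series(list(universe))))
    if len(uni) == 0:
        raise ValueError("empty gene universe")
    genes = pd.Index(pd.unique(pd.Series(list(gene_list)))).intersection(uni)
    hit = pd.Series(uni.isin(genes), index=uni)
    masks = {name: pd.Series(uni.isin(pd.Index(members)), index=uni)
             for name, members in gene_sets.items()}
    out = _enrichment_table(hit, masks, adjust="none", alpha=alpha)
    out["neg_log10_p"] = -np.log10(np.maximum(out["p"], 1e-300))
    return out.sort_values("neg_log10_p", ascending=False).reset_index(drop=True)


def disease_mapping(
    gene_list: Sequence[str],
    association_table: pd.DataFrame,
    min_score: float = 0.1,
) -> pd.DataFrame:
    """Join a (gene, disease, score) table onto the gene list, keeping
    associations with score strictly above ``min_score``."""
    genes = set(gene_list)
    keep = association_table[
        (association_table["score"] > min_score)
        & association_table["gene"].isin(genes)
    ]
    return keep.sort_values(["gene", "score"], ascending=[True, False]).reset_index(
        drop=True
    )


def read_gmt(path) -> dict:
    """Parse a GMT-style gene-set file: name <tab> description <tab> genes..."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = [g for g in parts[2:] if g]
    return sets
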